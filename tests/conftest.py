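import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allotrait as at

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset() -> at.SyntheticDataset:
    """The default synthetic study: 14 species x 15 trees, trait-coupled intercepts."""
    return at.generate_dataset()


@pytest.fixture(scope="session")
def reduced_mcmc() -> at.McmcSettings:
    return at.McmcSettings.reduced(seed=101)


@pytest.fixture(scope="session")
def height_fit(default_dataset, reduced_mcmc) -> at.PosteriorDraws:
    return at.fit_hierarchical(
        default_dataset.observations, at.ModelSpec(response="height"), reduced_mcmc
    )


@pytest.fixture(scope="session")
def crown_fit(default_dataset, reduced_mcmc) -> at.PosteriorDraws:
    return at.fit_hierarchical(
        default_dataset.observations,
        at.ModelSpec(response="crown_radius"),
        reduced_mcmc,
    )


@pytest.fixture()
def three_taxon_tree() -> at.Phylogeny:
    return at.Phylogeny.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")


def random_binary_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random binary topology with lognormal branch lengths (test-side helper)."""
    if len(labels) == 1:
        return f"{labels[0]}:{rng.lognormal(0.0, 0.5):.10g}"
    k = int(rng.integers(1, len(labels)))
    order = rng.permutation(len(labels))
    left = [labels[i] for i in order[:k]]
    right = [labels[i] for i in order[k:]]
    return (
        f"({random_binary_newick(rng, left)},{random_binary_newick(rng, right)})"
        f":{rng.lognormal(0.0, 0.5):.10g}"
    )


def random_tree(rng: np.random.Generator, n_tips: int) -> at.Phylogeny:
    labels = [f"T{i:02d}" for i in range(n_tips)]
    k = int(rng.integers(1, n_tips))
    order = rng.permutation(n_tips)
    left = [labels[i] for i in order[:k]]
    right = [labels[i] for i in order[k:]]
    s = f"({random_binary_newick(rng, left)},{random_binary_newick(rng, right)});"
    return at.Phylogeny.from_newick(s)
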