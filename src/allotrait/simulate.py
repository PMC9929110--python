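"""Synthetic forests with known allometric and phylogenetic structure.

The field data this pipeline was designed for (14 dominant dicot species in
a subtropical wet forest, ≥10 stems per species) are not publicly deposited,
so every downstream stage is exercised against data generated here with the
exact statistical structure the analysis assumes:

* a pure-birth (Yule) ultrametric phylogeny standing in for the published
  barcode tree;
* species-mean functional traits evolved by Brownian motion along that tree,
  so the independent-contrasts assumption holds exactly;
* species-level allometric intercepts and slopes drawn from a bivariate
  normal hyperdistribution, with an optional linear coupling from
  standardized trait values into the intercepts (the effect the correlation
  pipeline is meant to detect);
* individual trees with log10-normal DBH and log-normal residuals about the
  species line ``log10(y) = α_j + β_j · log10(DBH)``.

Defaults emulate the study design: 14 species × 15 trees, slopes near 0.75
(height) and 0.70 (crown radius) with little interspecific spread, clear
intercept variation, and intercept–trait couplings whose signs mirror the
reported wood-density / seed-mass / leaf-P relationships.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as aio
from .io import AllometryObservation, TRAIT_COLUMNS
from .phylogeny import Phylogeny

DEFAULT_BM_ROOTS: dict[str, float] = {
    "leaf_pct_n": 2.0,      # %
    "leaf_pct_p": 0.15,     # %
    "wood_density": 0.60,   # g/cm^3
    "leaf_area": 50.0,      # cm^2
    "sla": 120.0,           # cm^2/g
    "seed_mass": 0.5,       # g
}

# BM rates (variance per unit branch length) sized so that tip spread is
# roughly 10-15% of the root value on a unit-rate Yule tree of ~2 depth,
# keeping every simulated trait safely positive.
DEFAULT_BM_RATES: dict[str, float] = {
    "leaf_pct_n": 0.02,
    "leaf_pct_p": 2.0e-4,
    "wood_density": 2.0e-3,
    "leaf_area": 30.0,
    "sla": 150.0,
    "seed_mass": 5.0e-3,
}


@dataclass(frozen=True)
class AllometryRegime:
    """Generating regime for one response (height or crown radius).

    ``hyper_mean_alpha`` is the mean log10 response at DBH = 1 cm;
    ``coupling`` maps trait names to the shift (log10 units) added to a
    species' intercept mean per standard deviation of that trait.
    """

    hyper_mean_alpha: float
    hyper_mean_beta: float
    sd_alpha: float = 0.10
    sd_beta: float = 0.025
    rho_alpha_beta: float = -0.3
    residual_sd: float = 0.05
    coupling: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.sd_alpha < 0 or self.sd_beta < 0:
            raise ValueError("hyper SDs must be >= 0")
        if not -1.0 <= self.rho_alpha_beta <= 1.0:
            raise ValueError("|rho_alpha_beta| must be <= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        unknown = set(self.coupling) - set(TRAIT_COLUMNS)
        if unknown:
            raise ValueError(f"coupling names unknown traits {sorted(unknown)}")


def _default_height() -> AllometryRegime:
    # 10^0.45 ≈ 2.8 m saplings at 1 cm DBH, ~26 m at 19 cm
    return AllometryRegime(
        hyper_mean_alpha=0.45, hyper_mean_beta=0.75,
        coupling={"wood_density": -0.06},
    )


def _default_crown() -> AllometryRegime:
    # 10^-0.35 ≈ 0.45 m crown radius at 1 cm DBH
    return AllometryRegime(
        hyper_mean_alpha=-0.35, hyper_mean_beta=0.70,
        coupling={"wood_density": 0.05, "seed_mass": 0.05, "leaf_pct_p": -0.04},
    )


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 14
    n_per_species: int = 15
    height: AllometryRegime = field(default_factory=_default_height)
    crown: AllometryRegime = field(default_factory=_default_crown)
    bm_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BM_RATES))
    bm_roots: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BM_ROOTS))
    dbh_log10_mean: float = 0.9   # cm; 10^0.9 ≈ 8 cm median
    dbh_log10_sd: float = 0.35    # ≈ 1-30 cm range
    seed: int = 20230214

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_per_species < 2:
            raise ValueError("n_per_species must be >= 2")
        if self.dbh_log10_sd <= 0:
            raise ValueError("dbh_log10_sd must be > 0")

    @property
    def responses(self) -> dict[str, AllometryRegime]:
        return {"height": self.height, "crown_radius": self.crown}

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticDataset:
    """An internally consistent bundle of tree, traits, parameters, trees."""

    phylogeny: Phylogeny
    traits: pd.DataFrame
    true_params: dict[str, pd.DataFrame]  # response -> (species × [alpha, beta])
    observations: list[AllometryObservation]
    config: SyntheticConfig

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "allometry": out / "allometry.csv",
            "traits": out / "traits.csv",
            "tree": out / "tree.nwk",
            "true_params": out / "true_params.csv",
        }
        aio.write_allometry_csv(self.observations, paths["allometry"])
        aio.write_trait_csv(self.traits, paths["traits"])
        aio.write_newick(self.phylogeny, paths["tree"])
        rows = []
        for response, params in self.true_params.items():
            for species, row in params.iterrows():
                rows.append((species, response, row["alpha"], row["beta"]))
        pd.DataFrame(rows, columns=["species", "response", "alpha", "beta"]).to_csv(
            paths["true_params"], index=False, float_format="%.12g"
        )
        return paths


def species_labels(n: int) -> list[str]:
    return [f"SP{i + 1:02d}" for i in range(n)]


def simulate_phylogeny(n_species: int, seed) -> Phylogeny:
    """Ultrametric pure-birth (Yule, unit rate) tree with ``n_species`` tips.

    Lineages split at exponential waiting times with rate equal to the
    current lineage count; after the n-th lineage appears one further
    exponential wait sets the present, so all tips are contemporaneous and
    every branch length is strictly positive.  Tips are labelled SP01..SPnn.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    # node = [birth_time, end_time, left, right]; leaves have left=right=None
    root_children = [[0.0, None, None, None], [0.0, None, None, None]]
    active = list(root_children)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = rng.integers(k)
        node = active.pop(i)
        node[1] = t
        children = [[t, None, None, None], [t, None, None, None]]
        node[2], node[3] = children
        active.extend(children)
    t_end = t + rng.exponential(1.0 / n_species)
    for node in active:
        node[1] = t_end

    labels = iter(species_labels(n_species))

    def newick(node) -> str:
        length = node[1] - node[0]
        if node[2] is None:
            return f"{next(labels)}:{length:.12g}"
        return f"({newick(node[2])},{newick(node[3])}):{length:.12g}"

    s = f"({newick(root_children[0])},{newick(root_children[1])});"
    return Phylogeny.from_newick(s)


def simulate_traits_bm(
    tree: Phylogeny,
    rates: Mapping[str, float],
    root_values: Mapping[str, float],
    seed,
) -> pd.DataFrame:
    """Evolve each trait independently by Brownian motion along the tree.

    Tip value = root value + sum over the root-to-tip path of
    Normal(0, rate × branch length) increments.  A rate of exactly zero is
    the degenerate diffusion (all tips equal the root); negative rates are
    rejected.  Returns a species × trait DataFrame in tip-label order.
    """
    for trait, rate in rates.items():
        if rate < 0:
            raise ValueError(f"negative BM rate for {trait}")
    missing = set(rates) - set(root_values)
    if missing:
        raise ValueError(f"missing root values for {sorted(missing)}")
    rng = np.random.default_rng(seed)
    traits = list(rates)
    values: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    rate_vec = np.array([rates[t] for t in traits])
    for key, parent, bl, label in tree.walk_preorder():
        if parent is None:
            values[key] = np.array([root_values[t] for t in traits], dtype=float)
        else:
            step = rng.normal(0.0, np.sqrt(rate_vec * bl))
            values[key] = values[parent] + step
        if label is not None:
            tips[label] = values[key]
    out = pd.DataFrame.from_dict(tips, orient="index", columns=traits)
    out.index.name = "species"
    return out.sort_index()


def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait across species (sample SD); constant traits map to 0."""
    z = traits.copy().astype(float)
    for col in z.columns:
        sd = z[col].std(ddof=1)
        z[col] = 0.0 if (not np.isfinite(sd) or sd == 0) else (z[col] - z[col].mean()) / sd
    return z


def simulate_allometric_params(
    traits: pd.DataFrame, config: SyntheticConfig, seed
) -> dict[str, pd.DataFrame]:
    """Draw species (α_j, β_j) for each response.

    For response r, (α_j, β_j) ~ bivariate normal with mean
    (hyper_mean_alpha + Σ_t coupling_t · z_tj, hyper_mean_beta), SDs
    (sd_alpha, sd_beta) and correlation rho_alpha_beta, where z_tj is the
    standardized trait value.  All couplings zero gives trait-independent
    parameters.
    """
    species = list(traits.index)
    z = standardize_traits(traits)
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for response, reg in config.responses.items():
        shift = np.zeros(len(species))
        for trait, coef in reg.coupling.items():
            if trait not in traits.columns:
                raise ValueError(f"coupling trait {trait!r} absent from trait table")
            shift = shift + coef * z[trait].to_numpy()
        mean_a = reg.hyper_mean_alpha + shift
        mean_b = np.full(len(species), reg.hyper_mean_beta)
        zdraw = rng.standard_normal((len(species), 2))
        rho = reg.rho_alpha_beta
        alpha = mean_a + reg.sd_alpha * zdraw[:, 0]
        beta = mean_b + reg.sd_beta * (
            rho * zdraw[:, 0] + np.sqrt(1.0 - rho**2) * zdraw[:, 1]
        )
        out[response] = pd.DataFrame(
            {"alpha": alpha, "beta": beta}, index=pd.Index(species, name="species")
        )
    return out


def simulate_observations(
    params: dict[str, pd.DataFrame], config: SyntheticConfig, seed
) -> list[AllometryObservation]:
    """Simulate individual trees under the generating allometries.

    Each tree gets one DBH (log10-normal) shared by both responses; each
    response then adds independent Normal(0, residual_sd) noise on the log10
    scale and is exponentiated to natural units.
    """
    species = list(params["height"].index)
    if list(params["crown_radius"].index) != species:
        raise ValueError("height and crown parameter tables disagree on species")
    rng = np.random.default_rng(seed)
    obs: list[AllometryObservation] = []
    n = config.n_per_species
    for sp in species:
        log_d = rng.normal(config.dbh_log10_mean, config.dbh_log10_sd, size=n)
        responses = {}
        for response, reg in config.responses.items():
            row = params[response].loc[sp]
            mu = row["alpha"] + row["beta"] * log_d
            noise = rng.normal(0.0, reg.residual_sd, size=n) if reg.residual_sd > 0 else 0.0
            responses[response] = 10.0 ** (mu + noise)
        for i in range(n):
            obs.append(
                AllometryObservation(
                    species_code=sp,
                    dbh_cm=float(10.0 ** log_d[i]),
                    height_m=float(responses["height"][i]),
                    crown_radius_m=float(responses["crown_radius"][i]),
                )
            )
    return obs


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete, reproducible synthetic dataset from one seed."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_params, s_obs = ss.spawn(4)
    tree = simulate_phylogeny(config.n_species, s_tree)
    traits = simulate_traits_bm(tree, config.bm_rates, config.bm_roots, s_traits)
    aio.validate_trait_table(traits, name="synthetic traits")
    params = simulate_allometric_params(traits, config, s_params)
    obs = simulate_observations(params, config, s_obs)
    return SyntheticDataset(
        phylogeny=tree, traits=traits, true_params=params,
        observations=obs, config=config,
    )


__all__ = [
    "AllometryRegime",
    "SyntheticConfig",
    "SyntheticDataset",
    "DEFAULT_BM_RATES",
    "DEFAULT_BM_ROOTS",
    "simulate_phylogeny",
    "simulate_traits_bm",
    "simulate_allometric_params",
    "simulate_observations",
    "standardize_traits",
    "generate_dataset",
    "species_labels",
]
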