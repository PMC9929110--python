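"""Posterior-propagated, phylogenetically controlled trait correlations.

Each analysis resamples the retained MCMC draws (uniformly with
replacement, seeded; optionally each draw exactly once) and, per sampled
draw, converts the J-vector of species-level quantities — intercepts,
slopes, or expected dimensions at a reference DBH — into independent
contrasts on the study phylogeny and correlates them with the (fixed) trait
contrasts by Kendall's tau-b.  The resulting distribution of tau values is
summarized as its median and equal-tailed 95% interval; an interval that
excludes zero marks a trait–architecture relationship supported despite
posterior uncertainty in the allometric parameters.

Traits enter as species means with no uncertainty; the default reference
grid is 1, 3, …, 19 cm DBH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PosteriorDraws, predict_at_diameter
from .phylogeny import Phylogeny
from .pic import _tau_b

DEFAULT_REFERENCE_DBHS: tuple[float, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)
DEFAULT_N_SAMPLES = 10_000


@dataclass(frozen=True)
class TauSummary:
    """Median and equal-tailed 95% interval of a tau distribution."""

    median_tau: float
    lo95: float
    hi95: float
    excludes_zero: bool

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.lo95 <= self.median_tau <= self.hi95 <= 1.0 + 1e-12):
            raise ValueError("invalid tau summary ordering or range")


def summarize_tau(samples: Sequence[float]) -> TauSummary:
    """Median and 2.5/97.5 percentiles (linear interpolation) of tau values."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("empty tau sample")
    lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5])
    return TauSummary(
        median_tau=float(med), lo95=float(lo), hi95=float(hi),
        excludes_zero=not (lo <= 0.0 <= hi),
    )


def _check_alignment(draws: PosteriorDraws, traits: pd.DataFrame, tree: Phylogeny):
    tips = tree.tip_labels
    if draws.species_order != tips:
        raise ValueError(
            "species order of posterior draws does not match tree tips: "
            f"{draws.species_order} vs {tips}"
        )
    if sorted(traits.index) != tips:
        raise ValueError(
            f"trait table species do not match tree tips: "
            f"{sorted(traits.index)} vs {tips}"
        )


def _sample_indices(rng, S: int, n_samples: int, use_all_draws: bool) -> np.ndarray:
    if use_all_draws:
        if S < n_samples:
            raise ValueError(
                f"use_all_draws requires at least n_samples={n_samples} retained "
                f"draws, have {S}"
            )
        return np.arange(n_samples)
    return rng.integers(0, S, size=n_samples)


def _trait_contrasts(traits: pd.DataFrame, tree: Phylogeny) -> dict[str, np.ndarray]:
    C, _ = tree.contrast_matrix()
    tips = tree.tip_labels
    return {
        trait: C @ traits.loc[tips, trait].to_numpy(dtype=float)
        for trait in traits.columns
    }


def _summary_row(taus: np.ndarray) -> tuple[float, float, float, bool]:
    s = summarize_tau(taus)
    return s.median_tau, s.lo95, s.hi95, s.excludes_zero


def sample_parameter_correlations(
    draws: PosteriorDraws,
    traits: pd.DataFrame,
    tree: Phylogeny,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed=None,
    use_all_draws: bool = False,
    targets: Sequence[str] = ("intercept", "slope"),
) -> pd.DataFrame:
    """Tau between each trait and each allometric parameter, under posterior
    uncertainty.

    For each resampled posterior draw the J-vector of intercepts (α_j) or
    slopes (β_j) is contrasted on the tree and correlated with each trait's
    contrasts; rows report the median and 95% interval over ``n_samples``
    taus per (trait, parameter) pair.
    """
    _check_alignment(draws, traits, tree)
    rng = np.random.default_rng(seed)
    idx = _sample_indices(rng, draws.S, n_samples, use_all_draws)
    C, _ = tree.contrast_matrix()
    tc = _trait_contrasts(traits, tree)
    rows = []
    for target in targets:
        mat = draws.alpha if target == "intercept" else draws.beta
        contr = mat[idx] @ C.T
        for trait, tvec in tc.items():
            med, lo, hi, excl = _summary_row(_tau_b(contr, tvec))
            rows.append(
                (draws.spec.response, target, trait, med, lo, hi, excl)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "response", "target", "trait",
            "median_tau", "lo95", "hi95", "excludes_zero",
        ],
    )


def sample_sizeclass_correlations(
    draws: PosteriorDraws,
    traits: pd.DataFrame,
    tree: Phylogeny,
    reference_dbhs: Sequence[float] = DEFAULT_REFERENCE_DBHS,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed=None,
    use_all_draws: bool = False,
) -> pd.DataFrame:
    """Tau between each trait and the expected dimension at each reference DBH.

    Per sampled draw and reference diameter, the expected response
    (natural units, no residual noise) for every species is contrasted on
    the tree and correlated with each trait's contrasts.
    """
    _check_alignment(draws, traits, tree)
    for d in reference_dbhs:
        if not d > 0:
            raise ValueError("reference DBHs must be positive")
    rng = np.random.default_rng(seed)
    idx = _sample_indices(rng, draws.S, n_samples, use_all_draws)
    C, _ = tree.contrast_matrix()
    tc = _trait_contrasts(traits, tree)
    rows = []
    for d in reference_dbhs:
        pred = predict_at_diameter(draws, float(d))[idx]
        contr = pred @ C.T
        for trait, tvec in tc.items():
            med, lo, hi, excl = _summary_row(_tau_b(contr, tvec))
            rows.append(
                (draws.spec.response, float(d), trait, med, lo, hi, excl)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "response", "reference_dbh_cm", "trait",
            "median_tau", "lo95", "hi95", "excludes_zero",
        ],
    )


def height_crown_coupling(
    draws_height: PosteriorDraws,
    draws_crown: PosteriorDraws,
    tree: Phylogeny,
    reference_dbhs: Sequence[float] = DEFAULT_REFERENCE_DBHS,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed=None,
    paired: bool = True,
) -> pd.DataFrame:
    """Tau between expected height and expected crown radius per reference DBH.

    The two models are fit independently, so pairing their draws is a
    convention: by default draw s of the height posterior is matched with
    draw s of the crown posterior (requires equal retained draw counts);
    with ``paired=False`` the two posteriors are resampled independently.
    """
    if draws_height.species_order != draws_crown.species_order:
        raise ValueError("height and crown posteriors cover different species")
    if draws_height.species_order != tree.tip_labels:
        raise ValueError("posterior species do not match tree tips")
    rng = np.random.default_rng(seed)
    if paired:
        if draws_height.S != draws_crown.S:
            raise ValueError("paired sampling requires equal retained draw counts")
        idx_h = rng.integers(0, draws_height.S, size=n_samples)
        idx_c = idx_h
    else:
        idx_h = rng.integers(0, draws_height.S, size=n_samples)
        idx_c = rng.integers(0, draws_crown.S, size=n_samples)
    C, _ = tree.contrast_matrix()
    rows = []
    for d in reference_dbhs:
        if not d > 0:
            raise ValueError("reference DBHs must be positive")
        ph = predict_at_diameter(draws_height, float(d))[idx_h] @ C.T
        pc = predict_at_diameter(draws_crown, float(d))[idx_c] @ C.T
        med, lo, hi, excl = _summary_row(_tau_b(ph, pc))
        rows.append((float(d), med, lo, hi, excl))
    return pd.DataFrame(
        rows,
        columns=["reference_dbh_cm", "median_tau", "lo95", "hi95", "excludes_zero"],
    )


__all__ = [
    "DEFAULT_REFERENCE_DBHS",
    "DEFAULT_N_SAMPLES",
    "TauSummary",
    "summarize_tau",
    "sample_parameter_correlations",
    "sample_sizeclass_correlations",
    "height_crown_coupling",
]
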