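"""Hierarchical Bayesian height–DBH and crown–DBH allometry models.

Two functional forms are fit on the log10 scale with a shared residual SD
and partial pooling of species-level parameters:

* linearized power law:  log10(y_ij) ~ Normal(α_j + β_j · log10(DBH_ij), σ)
* asymptotic:            log10(y_ij) ~ Normal(a_j · (1 − exp(−b_j · DBH_ij)), σ)

In both, the species pair (α_j, β_j) — respectively (a_j, log b_j) — follows
a bivariate normal hyperdistribution with means (μ_α, μ_β), standard
deviations (sd_α, sd_β) and correlation ρ.  Priors: normal on the
hyper-means (the slope prior centred on global angiosperm scaling
exponents, 0.75 for height and 0.70 for crown radius, with a deliberately
wide SD), half-normal(1) on sd_α and sd_β, uniform(−1, 1) on ρ and
half-normal on σ.

Sampling is Markov chain Monte Carlo with conjugate Gibbs updates where the
full conditionals are available in closed form (the per-species (α_j, β_j)
pair and the hyper-means under the power-law likelihood; the hyper-means
under both forms) and adaptive random-walk Metropolis for the remaining
parameters (sd_α, sd_β, ρ, σ, and the per-species (a_j, log b_j) pairs of
the asymptotic form).  Step sizes adapt during warmup only, so the
post-warmup chain is a valid time-homogeneous MCMC.  Convergence is
reported as split R-hat and bulk effective sample size per parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import AllometryObservation

logger = logging.getLogger(__name__)

RESPONSES = ("height", "crown_radius")
FORMS = ("power_linearized", "asymptotic")

#: split R-hat above which a fit is flagged (never silently)
RHAT_GATE = 1.05


# --------------------------------------------------------------------- specs
@dataclass(frozen=True)
class ModelSpec:
    """Functional form, response and priors for one allometry model.

    For the power-law form ``prior_intercept_*`` and ``prior_slope_*`` are
    the normal priors on the hyper-means μ_α and μ_β.  For the asymptotic
    form they apply to the hyper-means of a (log10 asymptotic size) and
    log b (log approach rate).  ``scale_prior_sd`` is the half-normal scale
    for the residual σ; the hyper-SD priors are half-normal(1) and ρ is
    uniform on (−1, 1).
    """

    response: str
    form: str = "power_linearized"
    prior_slope_mean: float | None = None
    prior_slope_sd: float = 0.5
    prior_intercept_mean: float | None = None
    prior_intercept_sd: float = 1.0
    scale_prior_sd: float = 1.0

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        for name in ("prior_slope_sd", "prior_intercept_sd", "scale_prior_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.prior_slope_mean is None:
            if self.form == "power_linearized":
                v = 0.75 if self.response == "height" else 0.70
            else:
                v = math.log(0.15)  # prior centre for log b: b ≈ 0.15 per cm
            object.__setattr__(self, "prior_slope_mean", v)
        if self.prior_intercept_mean is None:
            if self.form == "power_linearized":
                v = 0.0
            else:
                # log10 asymptote: ~20 m canopy height, ~4 m crown radius
                v = 1.3 if self.response == "height" else 0.6
            object.__setattr__(self, "prior_intercept_mean", v)


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 4
    n_iter: int = 20_000
    n_warmup: int = 10_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not 0 < self.n_warmup < self.n_iter:
            raise ValueError("need 0 < n_warmup < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.n_warmup) % self.thin:
            raise ValueError("(n_iter - n_warmup) must be divisible by thin")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_warmup) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "McmcSettings":
        """Desk-scale profile: 4 chains × 2,000 iterations, warmup 1,000."""
        return cls(n_chains=4, n_iter=2_000, n_warmup=1_000, seed=seed, **kw)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one response and functional form.

    ``alpha``/``beta`` hold the species-level parameters, shape (S, J) with
    S = n_chains × (n_iter − n_warmup)/thin, chain-major.  For the
    power-law form they are the log10 intercept at DBH = 1 cm and the
    log-log slope; for the asymptotic form, the log10 asymptote a_j and the
    approach rate b_j (natural scale, > 0; the hierarchy and ``mu_beta``/
    ``sd_beta`` live on log b).
    """

    alpha: np.ndarray
    beta: np.ndarray
    mu_alpha: np.ndarray
    mu_beta: np.ndarray
    sd_alpha: np.ndarray
    sd_beta: np.ndarray
    rho: np.ndarray
    sigma: np.ndarray
    species_order: list[str]
    spec: ModelSpec
    n_chains: int
    convergence: dict = field(default_factory=dict)

    @property
    def S(self) -> int:
        return self.alpha.shape[0]

    @property
    def J(self) -> int:
        return self.alpha.shape[1]

    def validate(self) -> None:
        for name in ("sigma", "sd_alpha", "sd_beta"):
            if not np.all(getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not np.all(np.abs(self.rho) <= 1):
            raise ValueError("|rho| must be <= 1")
        for name in ("alpha", "beta", "mu_alpha", "mu_beta",
                     "sd_alpha", "sd_beta", "rho", "sigma"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")


@dataclass(frozen=True)
class WaicResult:
    """Watanabe–Akaike information criterion, −2(lppd − p_waic)."""

    lppd: float
    p_waic: float
    waic: float
    pointwise: np.ndarray


# ------------------------------------------------------------ data plumbing
def _prepare(data, response: str, species_order: list[str] | None = None):
    """Extract (log10 DBH, DBH, log10 response, species index, species order).

    Accepts a sequence of :class:`AllometryObservation` or a DataFrame with
    species/dbh_cm/height_m/crown_radius_m columns.  Records missing the
    modeled response are dropped (logged); species order is sorted species
    codes unless supplied.
    """
    if isinstance(data, pd.DataFrame):
        rows = [
            AllometryObservation(
                species_code=str(r["species"]),
                dbh_cm=float(r["dbh_cm"]),
                height_m=None if pd.isna(r.get("height_m")) else float(r["height_m"]),
                crown_radius_m=None
                if pd.isna(r.get("crown_radius_m"))
                else float(r["crown_radius_m"]),
            )
            for r in data.to_dict("records")
        ]
    else:
        rows = list(data)
    attr = "height_m" if response == "height" else "crown_radius_m"
    usable = [o for o in rows if getattr(o, attr) is not None]
    dropped = len(rows) - len(usable)
    if dropped:
        logger.info("dropped %d records missing %s", dropped, response)
    fitting = species_order is None
    if fitting:
        species_order = sorted({o.species_code for o in usable})
        if len(species_order) < 2:
            raise ValueError("hierarchical model needs at least 2 species")
    else:
        extra = {o.species_code for o in usable} - set(species_order)
        if extra:
            raise ValueError(f"species in data absent from draws: {sorted(extra)}")
    idx = {s: k for k, s in enumerate(species_order)}
    d = np.array([o.dbh_cm for o in usable])
    y = np.log10([getattr(o, attr) for o in usable])
    j = np.array([idx[o.species_code] for o in usable])
    if fitting:
        counts = np.bincount(j, minlength=len(species_order))
        thin_species = [s for s, c in zip(species_order, counts) if c < 2]
        if thin_species:
            raise ValueError(
                f"species with fewer than 2 usable records: {thin_species}"
            )
    return np.log10(d), d, y, j, list(species_order)


@dataclass
class _Stats:
    n: np.ndarray
    Sx: np.ndarray
    Sxx: np.ndarray
    Sy: np.ndarray
    Sxy: np.ndarray
    Syy: np.ndarray


def _suffstats(x, y, j, J) -> _Stats:
    return _Stats(
        n=np.bincount(j, minlength=J).astype(float),
        Sx=np.bincount(j, weights=x, minlength=J),
        Sxx=np.bincount(j, weights=x * x, minlength=J),
        Sy=np.bincount(j, weights=y, minlength=J),
        Sxy=np.bincount(j, weights=x * y, minlength=J),
        Syy=np.bincount(j, weights=y * y, minlength=J),
    )


def _marginal_loglik(st: _Stats, mu, sa, sb, rho, sigma) -> float:
    """Log p(y | μ, Σ, σ) with the species pairs (α_j, β_j) integrated out.

    Per species, y_j ~ Normal(X_j μ, σ²I + X_j Σ X_jᵀ); evaluated through
    the Woodbury identity and the 2×2 matrix P_j = Σ⁻¹ + X_jᵀX_j/σ², so the
    cost is O(J) on sufficient statistics regardless of sample size.  Used
    by the collapsed Metropolis updates of (sd_α, sd_β, ρ, σ), which would
    otherwise mix slowly through the scale–parameter funnel.
    """
    om = 1.0 - rho * rho
    if om <= 0 or sa <= 0 or sb <= 0 or sigma <= 0:
        return -math.inf
    Si = _precision(sa, sb, rho)
    s2 = sigma * sigma
    a = Si[0, 0] + st.n / s2
    b = Si[0, 1] + st.Sx / s2
    d = Si[1, 1] + st.Sxx / s2
    detP = a * d - b * b
    u1 = st.Sy - (st.n * mu[0] + st.Sx * mu[1])
    u2 = st.Sxy - (st.Sx * mu[0] + st.Sxx * mu[1])
    quad_u = (d * u1 * u1 - 2.0 * b * u1 * u2 + a * u2 * u2) / detP
    rr = (
        st.Syy
        - 2.0 * (mu[0] * st.Sy + mu[1] * st.Sxy)
        + mu[0] * mu[0] * st.n
        + 2.0 * mu[0] * mu[1] * st.Sx
        + mu[1] * mu[1] * st.Sxx
    )
    q = rr / s2 - quad_u / (s2 * s2)
    N = float(st.n.sum())
    J = st.n.size
    log_det_sigma = 2.0 * (math.log(sa) + math.log(sb)) + math.log(om)
    return -0.5 * (
        N * math.log(2.0 * math.pi * s2)
        + J * log_det_sigma
        + float(np.log(detP).sum())
        + float(q.sum())
    )


# ---------------------------------------------------------- sampler pieces
def _precision(sa, sb, rho):
    """Inverse of the 2×2 hyper-covariance built from SDs and correlation."""
    om = 1.0 - rho * rho
    return np.array(
        [
            [1.0 / (sa * sa * om), -rho / (sa * sb * om)],
            [-rho / (sa * sb * om), 1.0 / (sb * sb * om)],
        ]
    )


def _sample_theta_conjugate(rng, st: _Stats, sigma2, mu, Lam):
    """Closed-form Gibbs draw of (α_j, β_j) under the linear likelihood.

    Posterior precision A_j = X_jᵀX_j/σ² + Λ, mean A_j⁻¹(X_jᵀy_j/σ² + Λμ);
    sampled batched over species via the analytic 2×2 Cholesky.
    """
    a = st.n / sigma2 + Lam[0, 0]
    b = st.Sx / sigma2 + Lam[0, 1]
    d = st.Sxx / sigma2 + Lam[1, 1]
    r1 = st.Sy / sigma2 + Lam[0, 0] * mu[0] + Lam[0, 1] * mu[1]
    r2 = st.Sxy / sigma2 + Lam[0, 1] * mu[0] + Lam[1, 1] * mu[1]
    det = a * d - b * b
    m1 = (d * r1 - b * r2) / det
    m2 = (a * r2 - b * r1) / det
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(d - l21 * l21)
    z = rng.standard_normal((2, a.size))
    u2 = z[1] / l22
    u1 = (z[0] - l21 * u2) / l11
    return m1 + u1, m2 + u2


def _sample_mu(rng, ta, tb, Lam, m0, s0_var):
    """Gibbs draw of the hyper-means given θ and Σ (normal prior, diag S0)."""
    J = ta.size
    P = J * Lam + np.diag(1.0 / s0_var)
    rhs = Lam @ np.array([ta.sum(), tb.sum()]) + m0 / s0_var
    a, b, d = P[0, 0], P[0, 1], P[1, 1]
    det = a * d - b * b
    m = np.array([(d * rhs[0] - b * rhs[1]) / det, (a * rhs[1] - b * rhs[0]) / det])
    l11 = math.sqrt(a)
    l21 = b / l11
    l22 = math.sqrt(d - l21 * l21)
    z = rng.standard_normal(2)
    u2 = z[1] / l22
    u1 = (z[0] - l21 * u2) / l11
    return m + np.array([u1, u2])


def _bvn_loglik(ta, tb, mu, sa, sb, rho, per_species=False):
    da = (ta - mu[0]) / sa
    db = (tb - mu[1]) / sb
    om = 1.0 - rho * rho
    q = (da * da - 2.0 * rho * da * db + db * db) / om
    const = -(math.log(sa) + math.log(sb) + 0.5 * math.log(om))
    if per_species:
        return const - 0.5 * q
    return ta.size * const - 0.5 * q.sum()


class _AdaptiveStep:
    """Random-walk step with warmup-only multiplicative adaptation."""

    def __init__(self, step: float, target: float = 0.44, window: int = 50):
        self.step = step
        self.target = target
        self.window = window
        self._acc = 0.0
        self._n = 0

    def record(self, accepted: float, adapting: bool):
        if not adapting:
            return
        self._acc += accepted
        self._n += 1
        if self._n >= self.window:
            rate = self._acc / self._n
            self.step = float(np.clip(self.step * math.exp(rate - self.target), 1e-4, 10.0))
            self._acc = 0.0
            self._n = 0


def _halfnormal_logpdf(s, scale):
    return -0.5 * (s / scale) ** 2


def _mh_scalar(rng, cur_log, logpost, step):
    """One random-walk Metropolis move on an unconstrained scalar."""
    prop = cur_log + step * rng.standard_normal()
    lp_cur = logpost(cur_log)
    lp_prop = logpost(prop)
    if math.log(rng.uniform()) < lp_prop - lp_cur:
        return prop, 1.0
    return cur_log, 0.0


# ------------------------------------------------------------------ fitting
def _diagnostics(store: dict[str, np.ndarray], n_chains: int) -> dict:
    """Split R-hat and bulk ESS per parameter via arviz."""
    import arviz as az  # deferred: heavy import

    posterior = {}
    for name, arr in store.items():
        posterior[name] = arr.reshape(n_chains, -1, *arr.shape[1:])
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(max(np.nanmax(rhat[v].values) for v in rhat.data_vars))
    ess_min = float(min(np.nanmin(ess[v].values) for v in ess.data_vars))
    flagged = bool(rhat_max > RHAT_GATE)
    if flagged:
        warnings.warn(
            f"split R-hat {rhat_max:.3f} exceeds {RHAT_GATE}; "
            "inspect convergence before using these draws",
            RuntimeWarning,
            stacklevel=3,
        )
    return {
        "max_rhat": rhat_max,
        "min_ess_bulk": ess_min,
        "rhat_warning": flagged,
        "rhat": {v: np.asarray(rhat[v].values).tolist() for v in rhat.data_vars},
    }


def _chain_seeds(seed, n_chains):
    return np.random.SeedSequence(seed).spawn(n_chains)


def fit_hierarchical(
    data, spec: ModelSpec, mcmc: McmcSettings
) -> PosteriorDraws:
    """Fit the partial-pooling linearized power-law allometry by MCMC.

    Gibbs updates for (α_j, β_j) and the hyper-means (both conjugate under
    the normal likelihood), adaptive Metropolis for sd_α, sd_β, ρ and σ.
    Returns chain-major stacked draws with a convergence report attached.
    """
    if spec.form != "power_linearized":
        raise ValueError("fit_hierarchical fits the power_linearized form")
    x, _, y, j, species = _prepare(data, spec.response)
    J = len(species)
    N = y.size
    st = _suffstats(x, y, j, J)
    m0 = np.array([spec.prior_intercept_mean, spec.prior_slope_mean])
    s0_var = np.array([spec.prior_intercept_sd**2, spec.prior_slope_sd**2])

    # pooled-OLS starting point, shared across chains then jittered per chain
    X = np.column_stack([np.ones(N), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha0 = np.empty(J)
    beta0 = np.empty(J)
    for k in range(J):
        sel = j == k
        xs, ys = x[sel], y[sel]
        if xs.size >= 2 and np.ptp(xs) > 1e-9:
            b = np.polyfit(xs, ys, 1)
            alpha0[k], beta0[k] = b[1], b[0]
        else:
            beta0[k] = coef[1]
            alpha0[k] = ys.mean() - coef[1] * xs.mean()
    resid0 = y - alpha0[j] - beta0[j] * x
    sigma0 = max(float(resid0.std()), 1e-4)

    n_kept = mcmc.n_kept
    S_total = mcmc.n_chains * n_kept
    store = {
        "alpha": np.empty((S_total, J)),
        "beta": np.empty((S_total, J)),
        "mu_alpha": np.empty(S_total),
        "mu_beta": np.empty(S_total),
        "sd_alpha": np.empty(S_total),
        "sd_beta": np.empty(S_total),
        "rho": np.empty(S_total),
        "sigma": np.empty(S_total),
    }

    for c, ss in enumerate(_chain_seeds(mcmc.seed, mcmc.n_chains)):
        rng = np.random.default_rng(ss)
        ta = alpha0 + 0.05 * rng.standard_normal(J)
        tb = beta0 + 0.02 * rng.standard_normal(J)
        mu = np.array([ta.mean(), tb.mean()])
        sa = max(float(ta.std()), 0.02)
        sb = max(float(tb.std()), 0.01)
        rho = 0.0
        sigma = sigma0 * math.exp(0.2 * rng.standard_normal())
        steps = {k: _AdaptiveStep(0.3) for k in ("sa", "sb", "sigma")}
        steps["rho"] = _AdaptiveStep(0.2)
        base = c * n_kept
        kept = 0

        def posterior(sa_, sb_, rho_, sig_):
            """Collapsed target for the scale block: θ integrated out."""
            if abs(rho_) >= 1.0:
                return -math.inf
            return (
                _marginal_loglik(st, mu, sa_, sb_, rho_, sig_)
                + _halfnormal_logpdf(sa_, 1.0)
                + _halfnormal_logpdf(sb_, 1.0)
                + _halfnormal_logpdf(sig_, spec.scale_prior_sd)
                # log-scale Jacobians for the three positive parameters
                + math.log(sa_) + math.log(sb_) + math.log(sig_)
            )

        cur_lp = posterior(sa, sb, rho, sigma)
        for it in range(mcmc.n_iter):
            adapting = it < mcmc.n_warmup

            # --- collapsed Metropolis block on (sd_alpha, sd_beta, rho, sigma)
            for name in ("sa", "sb", "rho", "sigma"):
                stp = steps[name].step
                eps = stp * rng.standard_normal()
                if name == "sa":
                    prop = (sa * math.exp(eps), sb, rho, sigma)
                elif name == "sb":
                    prop = (sa, sb * math.exp(eps), rho, sigma)
                elif name == "rho":
                    prop = (sa, sb, rho + eps, sigma)
                else:
                    prop = (sa, sb, rho, sigma * math.exp(eps))
                lp = posterior(*prop)
                if math.log(rng.uniform()) < lp - cur_lp:
                    sa, sb, rho, sigma = prop
                    cur_lp = lp
                    steps[name].record(1.0, adapting)
                else:
                    steps[name].record(0.0, adapting)

            # --- exact conditional draws: species pairs, then hyper-means
            Lam = _precision(sa, sb, rho)
            ta, tb = _sample_theta_conjugate(rng, st, sigma * sigma, mu, Lam)
            mu = _sample_mu(rng, ta, tb, Lam, m0, s0_var)
            cur_lp = posterior(sa, sb, rho, sigma)  # μ moved under the block

            if it >= mcmc.n_warmup and (it - mcmc.n_warmup) % mcmc.thin == 0:
                s = base + kept
                store["alpha"][s] = ta
                store["beta"][s] = tb
                store["mu_alpha"][s] = mu[0]
                store["mu_beta"][s] = mu[1]
                store["sd_alpha"][s] = sa
                store["sd_beta"][s] = sb
                store["rho"][s] = rho
                store["sigma"][s] = sigma
                kept += 1

    conv = _diagnostics(store, mcmc.n_chains)
    draws = PosteriorDraws(
        species_order=species, spec=spec, n_chains=mcmc.n_chains,
        convergence=conv, **store,
    )
    draws.validate()
    return draws


def fit_asymptotic(data, spec: ModelSpec, mcmc: McmcSettings) -> PosteriorDraws:
    """Fit the saturating form log10(y) = a_j·(1 − exp(−b_j·DBH)) by MCMC.

    The hierarchy is a bivariate normal on (a_j, log b_j); species pairs
    move by joint adaptive random-walk Metropolis (accepted per species),
    the hyper-means remain conjugate, and scales/ρ/σ update as in the
    power-law sampler.  Returned ``beta`` is b_j on the natural scale.
    """
    if spec.form != "asymptotic":
        raise ValueError("fit_asymptotic fits the asymptotic form")
    _, d, y, j, species = _prepare(data, spec.response)
    J = len(species)
    N = y.size
    m0 = np.array([spec.prior_intercept_mean, spec.prior_slope_mean])
    s0_var = np.array([spec.prior_intercept_sd**2, spec.prior_slope_sd**2])

    ymax = np.array([y[j == k].max() for k in range(J)])

    n_kept = mcmc.n_kept
    S_total = mcmc.n_chains * n_kept
    store = {
        "a": np.empty((S_total, J)),
        "log_b": np.empty((S_total, J)),
        "mu_alpha": np.empty(S_total),
        "mu_beta": np.empty(S_total),
        "sd_alpha": np.empty(S_total),
        "sd_beta": np.empty(S_total),
        "rho": np.empty(S_total),
        "sigma": np.empty(S_total),
    }

    def mean_fn(a, lb):
        return a[j] * (1.0 - np.exp(-np.exp(lb)[j] * d))

    for c, ss in enumerate(_chain_seeds(mcmc.seed, mcmc.n_chains)):
        rng = np.random.default_rng(ss)
        ta = ymax + 0.1 + 0.05 * rng.standard_normal(J)  # log10 asymptote ≥ max obs
        tlb = math.log(0.12) + 0.1 * rng.standard_normal(J)
        mu = np.array([ta.mean(), tlb.mean()])
        sa, sb, rho = 0.2, 0.3, 0.0
        resid = y - mean_fn(ta, tlb)
        sigma = max(float(resid.std()), 1e-3)
        steps = {k: _AdaptiveStep(0.3) for k in ("sa", "sb", "sigma")}
        steps["rho"] = _AdaptiveStep(0.2)
        steps["theta"] = _AdaptiveStep(0.1, target=0.30)
        base = c * n_kept
        kept = 0
        for it in range(mcmc.n_iter):
            adapting = it < mcmc.n_warmup
            sigma2 = sigma * sigma

            # joint per-species RW-MH on (a_j, log b_j); several sweeps per
            # iteration because this is the sampler's slowest-mixing block
            for _ in range(3):
                stp = steps["theta"].step
                pa = ta + stp * rng.standard_normal(J)
                plb = tlb + 2.0 * stp * rng.standard_normal(J)
                r_cur = y - mean_fn(ta, tlb)
                r_prop = y - mean_fn(pa, plb)
                sse_cur = np.bincount(j, weights=r_cur * r_cur, minlength=J)
                sse_prop = np.bincount(j, weights=r_prop * r_prop, minlength=J)
                lp_cur = _bvn_loglik(ta, tlb, mu, sa, sb, rho, per_species=True)
                lp_prop = _bvn_loglik(pa, plb, mu, sa, sb, rho, per_species=True)
                logr = (sse_cur - sse_prop) / (2.0 * sigma2) + lp_prop - lp_cur
                accept = np.log(rng.uniform(size=J)) < logr
                ta = np.where(accept, pa, ta)
                tlb = np.where(accept, plb, tlb)
                steps["theta"].record(float(accept.mean()), adapting)

            Lam = _precision(sa, sb, rho)
            mu = _sample_mu(rng, ta, tlb, Lam, m0, s0_var)

            def bvn(sa_, sb_, rho_):
                return _bvn_loglik(ta, tlb, mu, sa_, sb_, rho_)

            new, acc = _mh_scalar(
                rng, math.log(sa),
                lambda ls: bvn(math.exp(ls), sb, rho)
                + _halfnormal_logpdf(math.exp(ls), 1.0) + ls,
                steps["sa"].step,
            )
            sa = math.exp(new)
            steps["sa"].record(acc, adapting)

            new, acc = _mh_scalar(
                rng, math.log(sb),
                lambda ls: bvn(sa, math.exp(ls), rho)
                + _halfnormal_logpdf(math.exp(ls), 1.0) + ls,
                steps["sb"].step,
            )
            sb = math.exp(new)
            steps["sb"].record(acc, adapting)

            new, acc = _mh_scalar(
                rng, rho,
                lambda r: bvn(sa, sb, r) if abs(r) < 1.0 else -math.inf,
                steps["rho"].step,
            )
            rho = new
            steps["rho"].record(acc, adapting)

            resid = y - mean_fn(ta, tlb)
            sse = float(resid @ resid)
            new, acc = _mh_scalar(
                rng, math.log(sigma),
                lambda ls: -N * ls - sse / (2.0 * math.exp(2.0 * ls))
                + _halfnormal_logpdf(math.exp(ls), spec.scale_prior_sd) + ls,
                steps["sigma"].step,
            )
            sigma = math.exp(new)
            steps["sigma"].record(acc, adapting)

            if it >= mcmc.n_warmup and (it - mcmc.n_warmup) % mcmc.thin == 0:
                s = base + kept
                store["a"][s] = ta
                store["log_b"][s] = tlb
                store["mu_alpha"][s] = mu[0]
                store["mu_beta"][s] = mu[1]
                store["sd_alpha"][s] = sa
                store["sd_beta"][s] = sb
                store["rho"][s] = rho
                store["sigma"][s] = sigma
                kept += 1

    conv = _diagnostics(store, mcmc.n_chains)
    draws = PosteriorDraws(
        alpha=store["a"], beta=np.exp(store["log_b"]),
        mu_alpha=store["mu_alpha"], mu_beta=store["mu_beta"],
        sd_alpha=store["sd_alpha"], sd_beta=store["sd_beta"],
        rho=store["rho"], sigma=store["sigma"],
        species_order=species, spec=spec, n_chains=mcmc.n_chains,
        convergence=conv,
    )
    draws.validate()
    return draws


def fit(data, spec: ModelSpec, mcmc: McmcSettings) -> PosteriorDraws:
    """Dispatch to the sampler for ``spec.form``."""
    if spec.form == "power_linearized":
        return fit_hierarchical(data, spec, mcmc)
    return fit_asymptotic(data, spec, mcmc)


# ----------------------------------------------------------------- WAIC etc
def _mean_matrix(draws: PosteriorDraws, log_d: np.ndarray, d: np.ndarray, j: np.ndarray):
    if draws.spec.form == "power_linearized":
        return draws.alpha[:, j] + draws.beta[:, j] * log_d[None, :]
    return draws.alpha[:, j] * (1.0 - np.exp(-draws.beta[:, j] * d[None, :]))


def log_likelihood_pointwise(draws: PosteriorDraws, data) -> np.ndarray:
    """(S × N) matrix of Normal log densities of each observed log10 response."""
    log_d, d, y, j, _ = _prepare(data, draws.spec.response, draws.species_order)
    mu = _mean_matrix(draws, log_d, d, j)
    sig = draws.sigma[:, None]
    z = (y[None, :] - mu) / sig
    return -0.5 * math.log(2.0 * math.pi) - np.log(sig) - 0.5 * z * z


def compute_waic(loglik: np.ndarray) -> WaicResult:
    """WAIC from a pointwise log-likelihood matrix.

    lppd_i = log mean_s exp(loglik[s,i]) (log-sum-exp stabilized),
    p_waic_i = var_s loglik[s,i] (denominator S−1),
    waic = −2 Σ_i (lppd_i − p_waic_i) = Σ_i pointwise_i.
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 2:
        raise ValueError("need an (S >= 2) x N log-likelihood matrix")
    S = loglik.shape[0]
    lppd_i = logsumexp(loglik, axis=0) - math.log(S)
    p_i = loglik.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    return WaicResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(pointwise.sum()),
        pointwise=pointwise,
    )


def predict_at_diameter(draws: PosteriorDraws, dbh_cm: float) -> np.ndarray:
    """Expected response (natural units, no residual noise) at one DBH.

    Returns an (S × J) matrix: 10^(α_j + β_j·log10 DBH) for the power form,
    10^(a_j·(1 − exp(−b_j·DBH))) for the asymptotic form.
    """
    if not dbh_cm > 0:
        raise ValueError("dbh_cm must be > 0")
    if draws.spec.form == "power_linearized":
        mu = draws.alpha + draws.beta * math.log10(dbh_cm)
    else:
        mu = draws.alpha * (1.0 - np.exp(-draws.beta * dbh_cm))
    return 10.0**mu


def summarize_parameters(
    draws: PosteriorDraws, include_hyper: bool = False
) -> pd.DataFrame:
    """Median and equal-tailed 95% interval per species per parameter."""
    if draws.S < 2:
        raise ValueError("need at least 2 draws to summarize")
    rows = []
    names = ("alpha", "beta")
    for pname in names:
        arr = getattr(draws, pname)
        lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
        for k, sp in enumerate(draws.species_order):
            rows.append((draws.spec.response, sp, pname, med[k], lo[k], hi[k]))
    if include_hyper:
        for pname in ("mu_alpha", "mu_beta", "sd_alpha", "sd_beta", "rho", "sigma"):
            lo, med, hi = np.percentile(getattr(draws, pname), [2.5, 50.0, 97.5])
            rows.append((draws.spec.response, "", pname, med, lo, hi))
    return pd.DataFrame(
        rows, columns=["response", "species", "parameter", "median", "lo95", "hi95"]
    )


# -------------------------------------------------------------- persistence
_HYPER_NAMES = ("mu_alpha", "mu_beta", "sd_alpha", "sd_beta", "rho", "sigma")


def draws_to_csv(draws: PosteriorDraws, path) -> None:
    """Persist draws in long format (draw, chain, species, parameter, value).

    Hyperparameter rows carry an empty species field; a ``<path>.meta.json``
    sidecar records the response, form, species order and chain count so the
    draws can be reloaded without the fitting data.
    """
    path = Path(path)
    S, J = draws.S, draws.J
    per_chain = S // draws.n_chains
    chain = np.repeat(np.arange(draws.n_chains), per_chain)
    frames = []
    for pname in ("alpha", "beta"):
        arr = getattr(draws, pname)
        frames.append(
            pd.DataFrame(
                {
                    "draw": np.repeat(np.arange(S), J),
                    "chain": np.repeat(chain, J),
                    "species": np.tile(draws.species_order, S),
                    "parameter": pname,
                    "value": arr.ravel(),
                }
            )
        )
    for pname in _HYPER_NAMES:
        frames.append(
            pd.DataFrame(
                {
                    "draw": np.arange(S),
                    "chain": chain,
                    "species": "",
                    "parameter": pname,
                    "value": getattr(draws, pname),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.12g"
    )
    meta = {
        "response": draws.spec.response,
        "form": draws.spec.form,
        "species_order": draws.species_order,
        "n_chains": draws.n_chains,
        "spec": dataclasses.asdict(draws.spec),
        "convergence": {
            k: draws.convergence.get(k)
            for k in ("max_rhat", "min_ess_bulk", "rhat_warning")
        },
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def draws_from_csv(path) -> PosteriorDraws:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    species = list(meta["species_order"])
    spec = ModelSpec(**meta["spec"])
    S = int(df["draw"].max()) + 1
    J = len(species)
    arrays: dict[str, np.ndarray] = {}
    for pname in ("alpha", "beta"):
        sub = df[df["parameter"] == pname]
        piv = sub.pivot(index="draw", columns="species", values="value")
        arrays[pname] = piv.loc[np.arange(S), species].to_numpy()
    hyper = {}
    for pname in _HYPER_NAMES:
        sub = df[df["parameter"] == pname].sort_values("draw")
        hyper[pname] = sub["value"].to_numpy()
    draws = PosteriorDraws(
        alpha=arrays["alpha"], beta=arrays["beta"],
        species_order=species, spec=spec,
        n_chains=int(meta["n_chains"]),
        convergence=meta.get("convergence", {}),
        **hyper,
    )
    draws.validate()
    return draws


__all__ = [
    "ModelSpec",
    "McmcSettings",
    "PosteriorDraws",
    "WaicResult",
    "RESPONSES",
    "FORMS",
    "RHAT_GATE",
    "fit",
    "fit_hierarchical",
    "fit_asymptotic",
    "log_likelihood_pointwise",
    "compute_waic",
    "predict_at_diameter",
    "summarize_parameters",
    "draws_to_csv",
    "draws_from_csv",
]
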