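import math

import numpy as np
import pytest

import allotrait as at
from allotrait.io import AllometryObservation
from allotrait.model import (
    _precision,
    _sample_theta_conjugate,
    _suffstats,
    compute_waic,
    draws_from_csv,
    draws_to_csv,
    log_likelihood_pointwise,
    predict_at_diameter,
    summarize_parameters,
)


def _toy_draws(alpha, beta, species=None, response="height", form="power_linearized", **hyper):
    """Hand-assembled PosteriorDraws for unit tests."""
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    S, J = alpha.shape
    species = species or [f"SP{k + 1:02d}" for k in range(J)]
    defaults = dict(
        mu_alpha=np.zeros(S), mu_beta=np.full(S, 0.7),
        sd_alpha=np.full(S, 0.1), sd_beta=np.full(S, 0.02),
        rho=np.zeros(S), sigma=np.full(S, 0.05),
    )
    defaults.update(hyper)
    return at.PosteriorDraws(
        alpha=alpha, beta=beta, species_order=list(species),
        spec=at.ModelSpec(response=response, form=form),
        n_chains=1, **defaults,
    )


class TestWaic:
    def test_toy_matrix_against_hand_computation(self):
        # independent arithmetic on the same 3-draw x 2-observation matrix
        ll = np.array([[-1.0, -2.0], [-1.5, -2.5], [-0.5, -1.5]])
        lppd = sum(
            math.log(sum(math.exp(v) for v in ll[:, i]) / 3) for i in range(2)
        )
        pw = sum(
            float(np.var(ll[:, i], ddof=1)) for i in range(2)
        )
        expected = -2.0 * (lppd - pw)
        res = compute_waic(ll)
        assert res.waic == pytest.approx(expected, abs=1e-12)
        assert res.lppd == pytest.approx(lppd, abs=1e-12)
        assert res.p_waic == pytest.approx(pw, abs=1e-12)

    def test_identical_draws_have_zero_penalty(self):
        ll = np.tile([[-1.2, -0.3, -2.0]], (5, 1))
        res = compute_waic(ll)
        assert res.p_waic == pytest.approx(0.0, abs=1e-12)
        assert res.waic == pytest.approx(-2.0 * ll[0].sum(), abs=1e-12)

    def test_waic_is_sum_of_pointwise(self):
        rng = np.random.default_rng(0)
        res = compute_waic(rng.normal(-1, 0.3, size=(40, 17)))
        assert res.waic == pytest.approx(res.pointwise.sum(), abs=1e-8)
        assert res.p_waic >= 0

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            compute_waic(np.array([[-1.0, -2.0]]))


class TestPointwiseLoglik:
    def _data(self):
        return [
            AllometryObservation("SP01", 10.0, height_m=7.0),
            AllometryObservation("SP01", 5.0, height_m=4.0),
            AllometryObservation("SP02", 8.0, height_m=6.0),
        ]

    def test_density_at_mode_with_unit_sigma(self):
        data = [AllometryObservation("SP01", 10.0, height_m=10.0),
                AllometryObservation("SP01", 5.0, height_m=5.0)]
        # alpha=0, beta=1 puts the mean exactly at each observed log10 height
        draws = _toy_draws([[0.0, 0.0]], [[1.0, 1.0]],
                           species=["SP01", "SP02"], sigma=np.array([1.0]))
        ll = log_likelihood_pointwise(draws, data)
        np.testing.assert_allclose(ll, -0.5 * math.log(2 * math.pi), atol=1e-12)
        assert ll[0, 0] == pytest.approx(-0.9189, abs=5e-5)

    def test_doubling_sigma_costs_log_two_at_the_mode(self):
        data = [AllometryObservation("SP01", 10.0, height_m=10.0)]
        d1 = _toy_draws([[0.0]], [[1.0]], species=["SP01"], sigma=np.array([1.0]))
        d2 = _toy_draws([[0.0]], [[1.0]], species=["SP01"], sigma=np.array([2.0]))
        l1 = log_likelihood_pointwise(d1, data)[0, 0]
        l2 = log_likelihood_pointwise(d2, data)[0, 0]
        assert l1 - l2 == pytest.approx(math.log(2), abs=1e-12)

    def test_shape_and_unknown_species(self):
        draws = _toy_draws(
            np.zeros((4, 2)), np.full((4, 2), 0.7), species=["SP01", "SP02"]
        )
        assert log_likelihood_pointwise(draws, self._data()).shape == (4, 3)
        bad = self._data() + [AllometryObservation("SPXX", 5.0, height_m=3.0)]
        with pytest.raises(ValueError, match="SPXX"):
            log_likelihood_pointwise(draws, bad)


class TestPredict:
    def test_identity_line(self):
        draws = _toy_draws([[0.0]], [[1.0]], species=["SP01"])
        assert predict_at_diameter(draws, 10.0)[0, 0] == pytest.approx(10.0)

    def test_intercept_interpretation_at_one_cm(self):
        draws = _toy_draws([[0.3]], [[0.75]], species=["SP01"])
        assert predict_at_diameter(draws, 1.0)[0, 0] == pytest.approx(10**0.3)

    def test_monotone_in_dbh(self):
        draws = _toy_draws([[0.3, 0.1]], [[0.75, 0.6]])
        grid = [1.0, 3.0, 7.0, 19.0]
        preds = np.array([predict_at_diameter(draws, d)[0] for d in grid])
        assert np.all(np.diff(preds, axis=0) > 0)

    def test_nonpositive_dbh_rejected(self):
        draws = _toy_draws([[0.3]], [[0.75]], species=["SP01"])
        with pytest.raises(ValueError):
            predict_at_diameter(draws, 0.0)

    def test_asymptotic_saturation_limit(self):
        draws = _toy_draws([[1.3]], [[50.0]], species=["SP01"], form="asymptotic")
        for d in (5.0, 10.0, 19.0):
            assert predict_at_diameter(draws, d)[0, 0] == pytest.approx(10**1.3, rel=1e-9)


class TestSummaries:
    def test_constant_draws_collapse_interval(self):
        draws = _toy_draws(np.full((10, 1), 0.4), np.full((10, 1), 0.7), species=["SP01"])
        df = summarize_parameters(draws)
        row = df[(df.species == "SP01") & (df.parameter == "alpha")].iloc[0]
        assert (row["median"], row["lo95"], row["hi95"]) == (0.4, 0.4, 0.4)

    def test_percentiles_use_linear_interpolation(self):
        vals = np.arange(1.0, 10_001.0)
        draws = _toy_draws(
            vals[:, None], np.full((10_000, 1), 0.7), species=["SP01"],
            mu_alpha=np.zeros(10_000), mu_beta=np.zeros(10_000),
            sd_alpha=np.ones(10_000), sd_beta=np.ones(10_000),
            rho=np.zeros(10_000), sigma=np.ones(10_000),
        )
        df = summarize_parameters(draws)
        row = df[df.parameter == "alpha"].iloc[0]
        assert row["median"] == pytest.approx(5000.5)
        assert row["lo95"] == pytest.approx(250.975)
        assert row["hi95"] == pytest.approx(9750.025)

    def test_row_count(self, height_fit):
        df = summarize_parameters(height_fit)
        assert len(df) == height_fit.J * 2


class TestConjugateUpdate:
    def test_matches_closed_form_normal_posterior(self):
        """The Gibbs block for (α_j, β_j) is a draw from the exact conjugate
        posterior; check its Monte-Carlo mean/covariance against the closed
        form on a fixed two-species problem."""
        rng = np.random.default_rng(5)
        x = rng.normal(0.9, 0.3, 30)
        y = 0.4 + 0.75 * x + rng.normal(0, 0.05, 30)
        j = np.repeat([0, 1], 15)
        st = _suffstats(x, y, j, 2)
        sigma, mu = 0.05, np.array([0.3, 0.7])
        Lam = _precision(0.1, 0.05, 0.2)
        draws = np.array([
            np.column_stack(_sample_theta_conjugate(
                np.random.default_rng(1000 + r), st, sigma**2, mu, Lam))
            for r in range(20_000)
        ])  # (R, J, 2)
        for k in range(2):
            sel = j == k
            X = np.column_stack([np.ones(sel.sum()), x[sel]])
            A = X.T @ X / sigma**2 + Lam
            mean = np.linalg.solve(A, X.T @ y[sel] / sigma**2 + Lam @ mu)
            cov = np.linalg.inv(A)
            got_mean = draws[:, k, :].mean(axis=0)
            got_cov = np.cov(draws[:, k, :].T)
            np.testing.assert_allclose(
                got_mean, mean,
                atol=float(4 * np.sqrt(np.diag(cov).max() / 20_000)),
            )
            np.testing.assert_allclose(got_cov, cov, atol=0.1 * np.abs(cov).max() + 1e-8)


class TestFitContracts:
    def test_single_species_rejected(self, reduced_mcmc):
        data = [AllometryObservation("SP01", d, height_m=d)
                for d in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError, match="2 species"):
            at.fit_hierarchical(data, at.ModelSpec(response="height"), reduced_mcmc)

    def test_species_with_single_record_rejected(self, reduced_mcmc):
        data = [
            AllometryObservation("SP01", 1.0, height_m=2.0),
            AllometryObservation("SP01", 2.0, height_m=3.0),
            AllometryObservation("SP02", 2.0, height_m=3.0),
        ]
        with pytest.raises(ValueError, match="SP02"):
            at.fit_hierarchical(data, at.ModelSpec(response="height"), reduced_mcmc)

    def test_draw_count_invariant(self, height_fit, reduced_mcmc):
        assert height_fit.S == reduced_mcmc.n_chains * reduced_mcmc.n_kept
        height_fit.validate()
        assert "max_rhat" in height_fit.convergence

    def test_shrinkage_pulls_toward_hyper_mean(self):
        """Partial pooling on unbalanced data: at each species' own mean
        predictor, the posterior fit lies between the species' least-squares
        fit and the hyper-line.  (Betweenness is evaluated at the species'
        data centroid; at extrapolated diameters such as DBH = 1 cm the
        jointly shrunken slope can carry the intercept outside the naive
        interval even though the fit itself is pooled.)"""
        rng = np.random.default_rng(0)
        ds = at.generate_dataset(at.SyntheticConfig(seed=2024))
        keep = {sp: int(rng.integers(3, 16)) for sp in ds.traits.index}
        count = dict.fromkeys(keep, 0)
        obs = []
        for o in ds.observations:
            if count[o.species_code] < keep[o.species_code]:
                obs.append(o)
                count[o.species_code] += 1
        draws = at.fit_hierarchical(
            obs, at.ModelSpec(response="height"), at.McmcSettings.reduced(seed=55)
        )
        med_a = np.median(draws.alpha, axis=0)
        med_b = np.median(draws.beta, axis=0)
        mu_a = np.median(draws.mu_alpha)
        mu_b = np.median(draws.mu_beta)
        inside = total = 0
        for k, sp in enumerate(draws.species_order):
            sel = [o for o in obs if o.species_code == sp]
            x = np.log10([o.dbh_cm for o in sel])
            y = np.log10([o.height_m for o in sel])
            xb = x.mean()
            fit_at = med_a[k] + med_b[k] * xb
            ols_at = np.polyval(np.polyfit(x, y, 1), xb)
            hyper_at = mu_a + mu_b * xb
            if abs(ols_at - hyper_at) < 1e-3:
                continue
            total += 1
            lo, hi = sorted((ols_at, hyper_at))
            inside += lo - 5e-3 <= fit_at <= hi + 5e-3
        assert total >= 10
        assert inside == total

    def test_posterior_csv_round_trip(self, height_fit, tmp_path):
        p = tmp_path / "posterior_height.csv"
        draws_to_csv(height_fit, p)
        back = draws_from_csv(p)
        np.testing.assert_allclose(back.alpha, height_fit.alpha, rtol=1e-11)
        np.testing.assert_allclose(back.sigma, height_fit.sigma, rtol=1e-11)
        assert back.species_order == height_fit.species_order
        assert back.spec == height_fit.spec
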