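import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist, norm

from avivuln.demographic_model import (
    ConstraintLevel,
    DemographicPriors,
    MCMCConfig,
    MatrixModelSpec,
    build_projection_matrix,
    dic,
    dominant_lambda,
    fit_demographic_model,
    gelman_rubin,
    log_posterior,
    select_model,
    stable_stage_distribution,
)
from avivuln.synthetic_world import simulate_index_series
from conftest import make_point_posterior


def oracle_loglik(params, y, spec, ssd):
    """Independent scalar-PDF evaluation of the state-space likelihood."""
    a = build_projection_matrix(params, spec)
    n = np.asarray(ssd) * params["n0"]
    totals = []
    for _ in range(len(y)):
        totals.append(n.sum())
        n = a @ n
    mu = np.log(params["q"] * np.array(totals))
    return float(
        norm.logpdf(np.log(y), mu, params["sigma"]).sum() - np.sum(np.log(y))
    )


class TestProjectionMatrix:
    def test_two_age_direct_placement(self):
        spec = MatrixModelSpec(n_ages=2)
        a = build_projection_matrix({"phi_1": 0.5, "phi_a": 0.5, "f": 1.0}, spec)
        np.testing.assert_array_equal(a, [[0.0, 1.0], [0.5, 0.5]])

    def test_five_age_structure_count(self):
        spec = MatrixModelSpec(n_ages=5)
        a = build_projection_matrix(
            {"phi_1": 0.4, "phi_2": 0.6, "phi_a": 0.85, "f": 0.7}, spec
        )
        assert np.count_nonzero(a) == 6  # 1 fecundity + 4 subdiagonal + 1 corner
        assert a[0, 4] == 0.7 and a[4, 4] == 0.85
        assert a[1, 0] == 0.4 and a[2, 1] == a[3, 2] == a[4, 3] == 0.6

    def test_missing_parameter_raises(self):
        with pytest.raises(KeyError):
            build_projection_matrix({"phi_1": 0.5, "f": 1.0}, MatrixModelSpec(n_ages=2))

    def test_early_breeding_flag_adds_fecundity_entries(self):
        spec = MatrixModelSpec(n_ages=3, age_first_breeding=1, terminal_breeding_only=False)
        a = build_projection_matrix(
            {"phi_1": 0.4, "phi_2": 0.6, "phi_a": 0.8, "f": 0.5}, spec
        )
        assert a[0, 1] == a[0, 2] == 0.5


class TestDominantLambda:
    def test_identity(self):
        assert dominant_lambda(np.eye(3)) == pytest.approx(1.0)

    def test_characteristic_root(self):
        # lambda^2 - 0.5 lambda - 0.5 = 0 has root 1
        assert dominant_lambda([[0, 1], [0.5, 0.5]]) == pytest.approx(1.0)

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(0)
        a = rng.random((3, 3))
        v = np.ones(3)
        for _ in range(500):
            v = a @ v
            v /= v.sum()
        lam_power = (a @ v).sum() / v.sum()
        assert dominant_lambda(a) == pytest.approx(lam_power, abs=1e-6)

    def test_stable_stage_distribution_is_eigenvector(self):
        a = np.array([[0.0, 0.4], [0.5, 0.8]])
        v = stable_stage_distribution(a)
        lam = dominant_lambda(a)
        np.testing.assert_allclose(a @ v, lam * v, rtol=1e-10)
        assert v.sum() == pytest.approx(1.0)


class TestLogPosterior:
    def grid_points(self):
        return [
            {"phi_1": 0.5, "phi_a": 0.8, "f": 0.4, "q": 1.0, "sigma": 0.1, "n0": 120.0},
            {"phi_1": 0.45, "phi_a": 0.82, "f": 0.5, "q": 1.3, "sigma": 0.05, "n0": 90.0},
            {"phi_1": 0.6, "phi_a": 0.75, "f": 0.3, "q": 0.8, "sigma": 0.2, "n0": 150.0},
        ]

    def test_flat_priors_reduce_to_likelihood_oracle(self, demog, series):
        spec = demog.model_spec()
        ssd = stable_stage_distribution(demog.projection_matrix())
        y = series["index"].to_numpy()
        for params in self.grid_points():
            lp = log_posterior(params, series, None, ConstraintLevel(1), spec, ssd=ssd)
            assert lp == pytest.approx(oracle_loglik(params, y, spec, ssd), rel=1e-9)

    def test_informed_prior_adds_independent_density(self, demog, series, priors):
        spec = demog.model_spec()
        ssd = stable_stage_distribution(demog.projection_matrix())
        params = self.grid_points()[0]
        level = ConstraintLevel(2)
        with_prior = log_posterior(params, series, priors, level, spec, ssd=ssd)
        flat = log_posterior(params, series, None, level, spec, ssd=ssd)
        # independently coded truncated Beta / Normal prior densities
        expected = 0.0
        for name in ("phi_1", "phi_a"):
            m, se = priors.survival[name]
            kappa = m * (1 - m) / se**2 - 1
            a, b = m * kappa, (1 - m) * kappa
            lo, hi = max(1e-6, m - 0.2), min(1 - 1e-6, m + 0.2)
            mass = beta_dist.cdf(hi, a, b) - beta_dist.cdf(lo, a, b)
            expected += beta_dist.logpdf(params[name], a, b) - math.log(mass)
        mf, sef = priors.fecundity
        mass = norm.cdf(mf + 0.5 * mf, mf, sef) - norm.cdf(mf - 0.5 * mf, mf, sef)
        expected += norm.logpdf(params["f"], mf, sef) - math.log(mass)
        u = math.log(params["q"] * params["n0"])
        v = math.log(params["q"] / params["n0"])
        y0 = float(series["index"].iloc[0])
        expected += norm.logpdf(u, math.log(y0), 2.0) + norm.logpdf(v, 0.0, 1.0)
        sigma = params["sigma"]
        expected += (
            math.log(2.0) - 0.5 * math.log(2 * math.pi) - 0.5 * sigma**2 + math.log(sigma)
        )
        assert with_prior - flat == pytest.approx(expected, rel=1e-9)

    def test_out_of_support_is_minus_inf(self, demog, series, priors):
        spec = demog.model_spec()
        params = self.grid_points()[0] | {"phi_a": 0.95}  # outside mean +/- 0.1
        assert log_posterior(params, series, priors, ConstraintLevel(3), spec) == -math.inf


class TestGelmanRubin:
    def test_identical_chains_hit_closed_form(self):
        chain = np.random.default_rng(0).normal(size=100)
        n = 100
        assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(
            math.sqrt((n - 1) / n)
        )

    def test_split_stream_is_near_one(self):
        x = np.random.default_rng(1).normal(size=2000)
        assert gelman_rubin(x.reshape(2, 1000)) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        assert gelman_rubin(chains) > 1.1

    def test_agrees_with_arviz_on_mixed_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 500))
        ours = gelman_rubin(chains)
        theirs = float(
            arviz.rhat(arviz.convert_to_dataset(chains[:, :, None]))["x"].values.item()
        )
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_stuck_parameter_warns(self):
        with pytest.warns(UserWarning):
            assert gelman_rubin(np.zeros((2, 50))) == 1.0


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self, demog, series):
        spec = demog.model_spec()
        params = {"phi_1": 0.5, "phi_a": 0.8, "f": 0.4, "q": 1.0, "sigma": 0.1, "n0": 100.0}
        point = make_point_posterior(params, spec)
        val = dic(point, series, spec)
        d_at = -2 * oracle_loglik(params, series["index"].to_numpy(), spec, point.ssd)
        assert val == pytest.approx(d_at, rel=1e-9)  # p_D = 0

    def test_ignored_parameter_leaves_dic_unchanged(self, demog, series):
        spec = demog.model_spec()
        params = {"phi_1": 0.5, "phi_a": 0.8, "f": 0.4, "q": 1.0, "sigma": 0.1, "n0": 100.0}
        point = make_point_posterior(params, spec)
        base = dic(point, series, spec)
        point.draws["unused"] = np.linspace(0, 1, len(point.draws))
        assert dic(point, series, spec) == pytest.approx(base, rel=1e-12)

    def test_small_grid_posterior_matches_direct_summation(self, demog, series):
        spec = demog.model_spec()
        rows = [
            {"phi_1": 0.5, "phi_a": 0.80, "f": 0.40, "q": 1.0, "sigma": 0.10, "n0": 100.0},
            {"phi_1": 0.48, "phi_a": 0.82, "f": 0.42, "q": 1.1, "sigma": 0.08, "n0": 110.0},
            {"phi_1": 0.52, "phi_a": 0.78, "f": 0.38, "q": 0.9, "sigma": 0.12, "n0": 90.0},
        ]
        point = make_point_posterior(rows[0], spec, n=3)
        for i, r in enumerate(rows):
            for key, val in r.items():
                point.draws.loc[i, key] = val
        y = series["index"].to_numpy()
        d_bar = np.mean([-2 * oracle_loglik(r, y, spec, point.ssd) for r in rows])
        mean_params = {k: np.mean([r[k] for r in rows]) for k in rows[0]}
        d_mean = -2 * oracle_loglik(mean_params, y, spec, point.ssd)
        assert dic(point, series, spec) == pytest.approx(2 * d_bar - d_mean, rel=1e-9)


class TestFit:
    def test_recovers_rates_simulated_at_prior_means(self, fits_by_level, demog):
        fit = fits_by_level[3]
        truth = demog.params()
        for name in ("phi_1", "phi_a"):
            assert float(fit.draws[name].mean()) == pytest.approx(truth[name], abs=0.05)
        lo, hi = fit.lambda_interval()
        assert lo <= 1.0 <= hi

    def test_truncation_respected_at_constrained_levels(self, fits_by_level, priors):
        for lv in (2, 3):
            hw = ConstraintLevel(lv).survival_halfwidth
            fit = fits_by_level[lv]
            for name, (m, _) in priors.survival.items():
                vals = fit.draws[name]
                assert vals.between(m - hw - 1e-12, m + hw + 1e-12).all()
            mf, _ = priors.fecundity
            rw = ConstraintLevel(lv).fecundity_relwidth
            assert fit.draws["f"].between(mf * (1 - rw) - 1e-12, mf * (1 + rw) + 1e-12).all()

    def test_all_levels_converge(self, fits_by_level):
        for fit in fits_by_level.values():
            assert fit.converged
            assert max(fit.rhat.values()) < 1.1

    def test_same_seed_reproduces_draws_exactly(self, series, priors, demog):
        cfg = MCMCConfig(n_chains=2, n_burn=1000, n_iter=2000, thin=20, seed=33)
        a = fit_demographic_model(series, priors, ConstraintLevel(3), demog.model_spec(), cfg)
        b = fit_demographic_model(series, priors, ConstraintLevel(3), demog.model_spec(), cfg)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_noisier_observations_widen_lambda_posterior(self, demog, priors):
        spec = demog.model_spec()
        for seed in (1, 2, 3):
            sds = []
            for sigma in (0.05, 0.10):
                s = simulate_index_series(demog, 48, 0.05, sigma, 2000, seed=seed)
                f = fit_demographic_model(
                    s, priors, ConstraintLevel(3), spec, MCMCConfig(seed=seed)
                )
                sds.append(float(f.draws["lambda"].std()))
            assert sds[1] > sds[0]

    def test_short_series_rejected(self, priors, demog):
        with pytest.raises(ValueError):
            fit_demographic_model(
                pd.DataFrame({"index": np.ones(5)}), priors,
                ConstraintLevel(1), demog.model_spec(),
            )


class TestSelectModel:
    def test_lowest_dic_converged_wins(self, fits_by_level):
        sel = select_model(list(fits_by_level.values()))
        assert sel.status == "ok"
        best = min(fits_by_level.values(), key=lambda f: f.dic)
        assert sel.chosen.level == best.level
        assert len(sel.table) == 3

    def test_nonconverged_candidates_are_skipped(self, fits_by_level):
        import copy

        fits = [copy.copy(f) for f in fits_by_level.values()]
        best = min(range(3), key=lambda i: fits[i].dic)
        fits[best].converged = False
        sel = select_model(fits)
        remaining = [f for i, f in enumerate(fits) if i != best]
        assert sel.chosen.level == min(remaining, key=lambda f: f.dic).level

    def test_no_converged_candidate_excludes_species(self, fits_by_level):
        import copy

        fits = [copy.copy(f) for f in fits_by_level.values()]
        for f in fits:
            f.converged = False
        sel = select_model(fits)
        assert sel.status == "excluded" and sel.chosen is None

    def test_implausible_lambda_raises_feasibility_warning(self, demog):
        spec = demog.model_spec()
        point = make_point_posterior(
            {"phi_1": 0.9, "phi_a": 0.95, "f": 3.0}, spec
        )  # lambda far above 2
        point.dic = 0.0
        sel = select_model([point])
        assert sel.status == "ok" and sel.warnings
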