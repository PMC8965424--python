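import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from avivuln.demographic_model import MatrixModelSpec, build_projection_matrix, dominant_lambda
from avivuln.vulnerability_analysis import (
    FatalityScenario,
    absolute_grid,
    classify_vulnerability,
    compute_ciu,
    current_fatalities,
    perturbed_adult_survival,
    proportional_grid,
    relative_risk,
    scenario_lambdas,
    summarize_correlates,
    vulnerability_curve,
)
from conftest import make_point_posterior


class TestClosedForms:
    @pytest.mark.parametrize(
        "np_size,phi_a,expected",
        [(5000, 0.8, 1000.0), (5000, 1.0, 0.0), (10000, 0.65, 3500.0)],
    )
    def test_current_fatalities(self, np_size, phi_a, expected):
        assert current_fatalities(np_size, phi_a) == pytest.approx(expected)

    def test_perturbed_survival_identity_and_inversion(self):
        assert perturbed_adult_survival(0.8, 0.0, 5000) == 0.8
        assert perturbed_adult_survival(0.8, 1000.0, 5000) == pytest.approx(0.6)

    def test_floor_warns_on_extirpation(self):
        with pytest.warns(UserWarning):
            assert perturbed_adult_survival(0.8, 4000.0 + 1, 5000) == 0.0
        assert perturbed_adult_survival(0.8, 0.8 * 5000, 5000) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        phi_a=st.floats(0.05, 0.99),
        np_size=st.floats(100.0, 1e7),
        frac=st.floats(0.0, 1.0),
    )
    def test_conservation_identity(self, phi_a, np_size, frac):
        """D(phi_a') = D(phi_a) + delta for any delta below the floor."""
        delta = frac * phi_a * np_size * 0.999
        new_phi = perturbed_adult_survival(phi_a, delta, np_size)
        lhs = current_fatalities(np_size, new_phi)
        rhs = current_fatalities(np_size, phi_a) + delta
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)


@pytest.fixture(scope="module")
def point_draws():
    spec = MatrixModelSpec(n_ages=2)
    params = {"phi_1": 0.5, "phi_a": 0.8, "f": 0.4}
    return make_point_posterior(params, spec), spec, params


class TestScenarioLambdas:
    def test_zero_delta_reproduces_baseline(self, chosen_fit):
        a = scenario_lambdas(
            chosen_fit, None, FatalityScenario("absolute", 0.0), 5000, iters=50, seed=4
        )
        b = scenario_lambdas(
            chosen_fit, None, FatalityScenario("absolute", 0.0), 5000, iters=50, seed=4
        )
        np.testing.assert_array_equal(a, b)

    def test_point_posterior_matches_eigen_oracle(self, point_draws):
        draws, spec, params = point_draws
        np_size, delta = 5000.0, 1000.0
        lam = scenario_lambdas(
            draws, spec, FatalityScenario("absolute", delta), np_size, iters=10, seed=0
        )
        perturbed = dict(params, phi_a=params["phi_a"] - delta / np_size)
        expected = dominant_lambda(build_projection_matrix(perturbed, spec))
        np.testing.assert_allclose(lam, expected, atol=1e-6)

    def test_mean_lambda_nonincreasing_in_delta(self, point_draws):
        draws, spec, _ = point_draws
        idx = np.zeros(10, dtype=int)
        means = [
            scenario_lambdas(
                draws, spec, FatalityScenario("absolute", d), 5000.0, draw_indices=idx
            ).mean()
            for d in (0.0, 500.0, 1000.0, 2000.0, 4000.0)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))


class TestCIU:
    def test_identity(self):
        lam = np.full(10, 1.01)
        ciu, vuln = compute_ciu(lam, lam)
        assert ciu == 1.0 and vuln == 0.0

    def test_five_percent_reduction(self):
        ciu, vuln = compute_ciu(np.full(5, 0.95), np.full(5, 1.0))
        assert vuln == pytest.approx(0.05)

    def test_exact_threshold_counts_as_vulnerable(self):
        ciu, vuln = compute_ciu(np.full(5, 0.8), np.full(5, 1.0))
        curve = pd.DataFrame({"delta_d": [5000.0], "vulnerability": [vuln]})
        assert vuln == pytest.approx(0.2)
        assert classify_vulnerability(curve) == "moderately vulnerable"


class TestClassification:
    @pytest.mark.parametrize(
        "cross_at,expected",
        [
            (800, "highly vulnerable"),
            (1000, "highly vulnerable"),
            (1001, "moderately vulnerable"),
            (3000, "moderately vulnerable"),
            (None, "not vulnerable"),
        ],
    )
    def test_threshold_rules(self, cross_at, expected):
        dd = np.arange(100, 5001, 100, dtype=float)
        if cross_at is None:
            vuln = np.full(dd.size, 0.1)
        else:
            vuln = np.where(dd >= cross_at, 0.25, 0.05)
            if cross_at not in dd:
                dd = np.sort(np.append(dd, cross_at))
                vuln = np.where(dd >= cross_at, 0.25, 0.05)
        assert classify_vulnerability(pd.DataFrame({"delta_d": dd, "vulnerability": vuln})) == expected

    def test_grids(self):
        assert absolute_grid(1e6)[0] == 100 and absolute_grid(1e6)[-1] == 5000
        assert absolute_grid(2500)[-1] == 2500  # capped at Np below 5000
        g = proportional_grid(1000.0)
        assert g[0] == pytest.approx(10.0) and g[-1] == pytest.approx(500.0)


class TestVulnerabilityCurve:
    def test_monotone_and_zero_at_origin(self, point_draws):
        draws, spec, _ = point_draws
        for mode, grid in (
            ("absolute", absolute_grid(4000.0)),
            ("proportional", np.arange(1, 51) / 100.0),
        ):
            curve = vulnerability_curve(
                draws, 4000.0, grid, mode=mode, iters=20, seed=1
            )
            vuln = curve["vulnerability"].to_numpy()
            assert np.all(np.diff(vuln) >= -1e-12)
            zero = vulnerability_curve(draws, 4000.0, [0.0], mode=mode, iters=20, seed=1)
            assert zero["vulnerability"].iloc[0] == 0.0


class TestRelativeRisk:
    def test_rate_ratio_arithmetic(self):
        assert relative_risk(10, 1000, 5, 2000).rr == pytest.approx(4.0)
        assert relative_risk(5, 1000, 10, 2000).rr == pytest.approx(1.0)

    def test_ci_matches_independent_log_wald(self):
        r = relative_risk(10, 1000, 5, 2000)
        se = math.sqrt(1 / 10 - 1 / 1000 + 1 / 5 - 1 / 2000)
        assert r.ci_low == pytest.approx(4.0 * math.exp(-1.96 * se))
        assert r.ci_high == pytest.approx(4.0 * math.exp(1.96 * se))
        assert r.ci_low <= r.rr <= r.ci_high

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        xl=st.integers(1, 500), xn=st.integers(1, 500),
        nl=st.floats(1000.0, 1e6), nn=st.floats(1000.0, 1e6),
    )
    def test_reciprocity(self, xl, xn, nl, nn):
        fwd = relative_risk(xl, nl, xn, nn).rr
        rev = relative_risk(xn, nn, xl, nl).rr
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_zero_counts_undefined(self):
        assert relative_risk(0, 1000, 5, 2000).status == "undefined"
        assert relative_risk(5, 1000, 0, 2000).status == "undefined"


class TestCorrelates:
    def results(self):
        return pd.DataFrame(
            {
                "species": ["a", "b", "c", "d"],
                "origin_class": ["local"] * 4,
                "classification": [
                    "highly vulnerable", "not vulnerable",
                    "moderately vulnerable", "not vulnerable",
                ],
                "vulnerability": [0.5, 0.01, 0.3, 0.02],
                "np_mean": [2e3, 2e6, 5e4, 8e6],
            }
        )

    def test_single_group_matches_overall(self):
        traits = pd.DataFrame({"species": list("abcd"), "guild": ["raptor"] * 4})
        out = summarize_correlates(self.results(), traits)
        row = out[(out.correlate == "guild") & (out.group == "raptor")].iloc[0]
        assert row["n"] == 4 and row["proportion_vulnerable"] == 0.5

    def test_engineered_association_recounted(self):
        traits = pd.DataFrame(
            {"species": list("abcd"), "habitat": ["grass", "scrub", "grass", "scrub"]}
        )
        out = summarize_correlates(self.results(), traits)
        grass = out[(out.correlate == "habitat") & (out.group == "grass")].iloc[0]
        scrub = out[(out.correlate == "habitat") & (out.group == "scrub")].iloc[0]
        assert grass["proportion_vulnerable"] == 1.0
        assert scrub["proportion_vulnerable"] == 0.0
        assert grass["median_vulnerability"] == pytest.approx(0.4)

    def test_unknown_species_rejected(self):
        traits = pd.DataFrame({"species": ["a"], "guild": ["raptor"]})
        with pytest.raises(KeyError):
            summarize_correlates(self.results(), traits)
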