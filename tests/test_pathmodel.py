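"""Path-model estimation, effect decomposition, and fit statistics.

The module's core oracle is reduced-form equivalence: in a saturated
layered model the standardized total effect of an exogenous variable on
the outcome equals the standardized coefficient of the single regression
of the outcome on the exogenous block alone, computed from the same
covariance matrix.  A second oracle enumerates directed paths explicitly
and compares against the (I - B)^{-1} - I closed form.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from adherepath.pathmodel import (EstimationError, SpecError, cd,
                                  decompose_effects, effects_report,
                                  fit_path_model, implied_covariance,
                                  prune_and_refit, saturated_mediation_spec,
                                  srmr)
from adherepath.ssd import SummaryDataset


def ssd_from_cov(cov, names, n=1000):
    cov = np.asarray(cov, dtype=float)
    return SummaryDataset(names=names, n=n, means=np.zeros(len(names)),
                          sds=np.sqrt(np.diag(cov)), cov=cov)


def random_psd_ssd(rng, k, n=5000):
    a = rng.normal(size=(k, k))
    cov = a @ a.T + np.eye(k) * 0.5
    return ssd_from_cov(cov, [f"v{i}" for i in range(k)], n=n)


def reduced_form_std_coefs(ssd, exog, outcome):
    """Independent oracle: standardized coefficients of outcome ~ exog."""
    idx = [ssd.index(e) for e in exog]
    y = ssd.index(outcome)
    beta = np.linalg.solve(ssd.cov[np.ix_(idx, idx)], ssd.cov[idx, y])
    return beta * ssd.sds[idx] / ssd.sds[y]


class TestSpec:
    @pytest.mark.parametrize("n_exog,n_med,expected", [(2, 6, 20), (4, 6, 34)])
    def test_saturated_edge_count(self, n_exog, n_med, expected):
        spec = saturated_mediation_spec(
            [f"x{i}" for i in range(n_exog)],
            [f"m{i}" for i in range(n_med)], "y")
        assert len(spec.edges) == expected

    def test_zero_mediators_is_a_single_regression(self):
        spec = saturated_mediation_spec(["x1", "x2"], [], "y")
        assert spec.edges == {("x1", "y"), ("x2", "y")}

    def test_overlapping_names_rejected(self):
        with pytest.raises(SpecError):
            saturated_mediation_spec(["x"], ["x"], "y")

    def test_layer_violations_rejected(self):
        from adherepath.pathmodel import PathModelSpec
        with pytest.raises(SpecError):
            PathModelSpec(("x",), ("m",), "y", frozenset({("y", "m")}))


class TestFit:
    def test_zero_cross_covariance_gives_zero_coefficients(self):
        ssd = ssd_from_cov(np.diag([1.0, 2.0, 3.0]), ["x", "m", "y"])
        fit = fit_path_model(ssd, saturated_mediation_spec(["x"], ["m"], "y"))
        assert np.all(fit.B_raw.to_numpy() == 0)
        assert fit.residual_variances["y"] == pytest.approx(3.0)

    def test_chain_coefficients_recovered(self):
        # true model x -> m (0.6) -> y (0.5); covariance built from the model
        cov = np.array([[1.0, 0.6, 0.30],
                        [0.6, 1.0, 0.50],
                        [0.30, 0.50, 1.0]])
        ssd = ssd_from_cov(cov, ["x", "m", "y"])
        spec = saturated_mediation_spec(["x"], ["m"], "y")
        fit = fit_path_model(ssd, spec)
        assert fit.B_raw.loc["m", "x"] == pytest.approx(0.6)
        assert fit.B_raw.loc["y", "m"] == pytest.approx(0.5)
        assert fit.B_raw.loc["y", "x"] == pytest.approx(0.0, abs=1e-12)

    def test_singular_predictors_raise_with_culprits(self):
        cov = np.ones((3, 3))  # x1 == x2 -> singular normal equations
        np.fill_diagonal(cov, 1.0)
        ssd = ssd_from_cov(cov + 1e-15, ["x1", "x2", "y"])
        with pytest.raises(EstimationError, match="x1"):
            fit_path_model(ssd, saturated_mediation_spec(["x1", "x2"], [], "y"))

    def test_matches_statsmodels_on_raw_data(self, rng):
        """Normal-equation fit from moments == OLS on the patient-level data."""
        import statsmodels.api as sm
        from adherepath.ssd import build_ssd
        n = 3000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.3 * x + 0.4 * m + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_path_model(build_ssd(df), saturated_mediation_spec(["x"], ["m"], "y"))
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()
        assert fit.B_raw.loc["y", "x"] == pytest.approx(ols.params[1], rel=1e-9)
        assert fit.B_raw.loc["y", "m"] == pytest.approx(ols.params[2], rel=1e-9)
        assert fit.se.loc["y", "x"] == pytest.approx(ols.bse[1], rel=1e-6)


class TestEffects:
    def test_chain_product_rule(self):
        cov = np.array([[1.0, 0.5, 0.20],
                        [0.5, 1.0, 0.50],
                        [0.20, 0.50, 1.0]])
        ssd = ssd_from_cov(cov, ["a", "b", "c"])
        spec = saturated_mediation_spec(["a"], ["b"], "c")
        eff = decompose_effects(fit_path_model(ssd, spec))
        # a -> b is 0.5; b -> c given a is 0.5; direct a -> c is 0 + products
        assert eff.total.loc["a", "c"] == pytest.approx(
            eff.direct.loc["a", "c"] + eff.indirect.loc["a", "c"])
        assert eff.indirect.loc["a", "c"] == pytest.approx(
            eff.direct.loc["a", "b"] * eff.direct.loc["b", "c"])

    def test_total_equals_direct_plus_indirect_to_machine_precision(self, hird):
        spec = saturated_mediation_spec(
            ["age", "qci_score"],
            [n for n in hird.names if n not in ("age", "qci_score", "mpr", "pdc")],
            "mpr")
        eff = decompose_effects(fit_path_model(hird, spec))
        np.testing.assert_allclose(
            eff.total.to_numpy(),
            (eff.direct + eff.indirect).to_numpy(), atol=1e-14)
        # nothing flows out of the outcome
        assert np.all(eff.total.loc["mpr"].to_numpy() == 0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3), st.integers(1, 4))
    def test_reduced_form_equivalence(self, seed, n_exog, n_med):
        """Saturated total effects == single-regression standardized betas."""
        rng = np.random.default_rng(seed)
        k = n_exog + n_med + 1
        ssd = random_psd_ssd(rng, k)
        exog = ssd.names[:n_exog]
        meds = ssd.names[n_exog:n_exog + n_med]
        outcome = ssd.names[-1]
        spec = saturated_mediation_spec(exog, meds, outcome)
        eff = decompose_effects(fit_path_model(ssd, spec))
        oracle = reduced_form_std_coefs(ssd, exog, outcome)
        got = np.array([eff.total.loc[e, outcome] for e in exog])
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 6))
    def test_path_enumeration_oracle(self, seed, k):
        """(I - B)^{-1} - I equals the brute-force sum over directed paths."""
        from adherepath.pathmodel import _total_from_B
        rng = np.random.default_rng(seed)
        B = np.zeros((k, k))  # (dependent, predictor): strictly lower layered
        for dep in range(1, k):
            for pred in range(dep):
                if rng.random() < 0.7:
                    B[dep, pred] = rng.normal() * 0.4
        total = _total_from_B(B)

        def paths_sum(src, dst):
            # enumerate all directed paths src -> ... -> dst
            acc = 0.0
            stack = [(src, 1.0)]
            while stack:
                node, prod = stack.pop()
                for nxt in range(node + 1, k):
                    w = B[nxt, node]
                    if w != 0:
                        if nxt == dst:
                            acc += prod * w
                        else:
                            stack.append((nxt, prod * w))
            return acc

        for i, j in itertools.permutations(range(k), 2):
            assert total[i, j] == pytest.approx(paths_sum(i, j), abs=1e-10)

    def test_scale_invariance_of_standardized_effects(self, hird):
        spec = saturated_mediation_spec(
            ["age", "qci_score"],
            [n for n in hird.names if n not in ("age", "qci_score", "mpr", "pdc")],
            "mpr")
        base = decompose_effects(fit_path_model(hird, spec))
        scaled = hird.copy()
        c = 7.3
        i = scaled.index("age")
        scaled.cov[i, :] *= c
        scaled.cov[:, i] *= c
        scaled.sds[i] *= c
        scaled.means[i] *= c
        rescaled = decompose_effects(fit_path_model(scaled, spec))
        np.testing.assert_allclose(base.total.to_numpy(),
                                   rescaled.total.to_numpy(), atol=1e-10)

    def test_large_sample_stars(self, hird):
        """At n = 37 359, effects beyond 0.03 in magnitude are starred at 99%."""
        spec = saturated_mediation_spec(
            ["age", "qci_score"],
            [n for n in hird.names if n not in ("age", "qci_score", "mpr", "pdc")],
            "mpr")
        eff = decompose_effects(fit_path_model(hird, spec))
        for src in spec.variables[:-1]:
            if abs(eff.total.loc[src, "mpr"]) > 0.03:
                assert eff.stars(src, "mpr") == "***"


class TestFitStatistics:
    def test_srmr_zero_for_saturated_structure(self):
        cov = np.array([[1.0, 0.6, 0.30],
                        [0.6, 1.0, 0.50],
                        [0.30, 0.50, 1.0]])
        ssd = ssd_from_cov(cov, ["x", "m", "y"])
        fit = fit_path_model(ssd, saturated_mediation_spec(["x"], ["m"], "y"))
        assert srmr(ssd, fit) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(implied_covariance(fit).to_numpy(), cov,
                                   atol=1e-12)

    def test_srmr_closed_form_for_constrained_chain(self):
        # remove x -> y; sample cov(x, y) = 0.35 while the chain implies 0.30
        cov = np.array([[1.0, 0.6, 0.35],
                        [0.6, 1.0, 0.50],
                        [0.35, 0.50, 1.0]])
        ssd = ssd_from_cov(cov, ["x", "m", "y"])
        spec = saturated_mediation_spec(["x"], ["m"], "y").drop_edges([("x", "y")])
        fit = fit_path_model(ssd, spec)
        # single residual cell 0.35 - 0.6*0.5 = 0.05 over 6 unique elements
        assert srmr(ssd, fit) == pytest.approx(0.05 / np.sqrt(6), abs=1e-9)

    def test_srmr_positive_when_signal_constrained_to_zero(self, hird):
        spec = saturated_mediation_spec(["age"], [], "mpr").drop_edges([("age", "mpr")])
        fit = fit_path_model(hird.subset(["age", "mpr"]), spec)
        assert srmr(hird.subset(["age", "mpr"]), fit) > 0.01

    def test_cd_equals_single_equation_r2(self):
        cov = np.array([[1.0, 0.5], [0.5, 2.0]])
        ssd = ssd_from_cov(cov, ["x", "y"])
        fit = fit_path_model(ssd, saturated_mediation_spec(["x"], [], "y"))
        r2 = 1 - fit.residual_variances["y"] / 2.0
        assert cd(ssd, fit) == pytest.approx(r2)
        assert r2 == pytest.approx(0.5 ** 2 / 2.0 / 1.0)  # beta^2 var(x)/var(y)

    def test_cd_zero_when_no_signal(self):
        ssd = ssd_from_cov(np.diag([1.0, 1.0]), ["x", "y"])
        fit = fit_path_model(ssd, saturated_mediation_spec(["x"], [], "y"))
        assert cd(ssd, fit) == pytest.approx(0.0, abs=1e-12)

    def test_cd_one_for_deterministic_system(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12]])
        ssd = ssd_from_cov(cov, ["x", "y"])
        fit = fit_path_model(ssd, saturated_mediation_spec(["x"], [], "y"))
        assert cd(ssd, fit) == pytest.approx(1.0, abs=1e-6)


class TestReporting:
    def test_absent_predictors_print_na(self, hird):
        spec = saturated_mediation_spec(
            ["age", "qci_score"],
            [n for n in hird.names if n not in ("age", "qci_score", "mpr", "pdc")],
            "mpr")
        eff = decompose_effects(fit_path_model(hird, spec))
        table = effects_report(eff, spec, predictors=["age", "rewards"])
        assert table.loc["rewards", "total_effect"] == "N/A"
        assert table.loc["age", "total_effect"] == f"{eff.total.loc['age', 'mpr']:.4f}"

    def test_zero_effects_unstarred(self):
        ssd = ssd_from_cov(np.diag([1.0, 1.0, 1.0]), ["x", "m", "y"])
        spec = saturated_mediation_spec(["x"], ["m"], "y")
        eff = decompose_effects(fit_path_model(ssd, spec))
        table = effects_report(eff, spec)
        assert table.loc["x", "total_effect"] == "0.0000"
        assert table.loc["x", "stars"] == ""

    def test_prune_and_refit_drops_weak_paths(self, hird):
        spec = saturated_mediation_spec(
            ["age", "qci_score"],
            [n for n in hird.names if n not in ("age", "qci_score", "mpr", "pdc")],
            "mpr")
        pruned_fit, pruned_spec = prune_and_refit(hird, spec, alpha=0.10)
        assert len(pruned_spec.edges) < len(spec.edges)
        # surviving paths keep their sign and approximate size
        for (pred, dep) in pruned_spec.edges:
            full = fit_path_model(hird, spec).B_std.loc[dep, pred]
            assert np.sign(pruned_fit.B_std.loc[dep, pred]) == np.sign(full)
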