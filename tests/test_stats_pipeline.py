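"""FDR, partial Spearman, GLM fitting, screening, and replication."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from semspace.stats_pipeline import (
    FitError,
    RegressionResult,
    TermResult,
    assess_replication,
    fdr_adjust,
    fit_glm,
    partial_spearman,
    run_group_analysis,
    run_mmse_analysis,
    screen_covariates,
)


def _bh_oracle(pvals):
    """Literal step-up: sort ascending, q(i) = min_{j>=i} p(j)*m/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestFDR:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_ties_all_equal(self):
        np.testing.assert_allclose(fdr_adjust([0.5] * 10), [0.5] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.5])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 51))
        p = rng.uniform(size=m)
        np.testing.assert_allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)


def _oracle_partial(x, y, cov):
    """Independent residual-correlation oracle via explicit projection."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    z = np.column_stack([np.ones(len(x))] + [sps.rankdata(c) for c in cov.T])
    proj = z @ np.linalg.pinv(z)
    ex, ey = rx - proj @ rx, ry - proj @ ry
    return float(ex @ ey / (np.linalg.norm(ex) * np.linalg.norm(ey)))


class TestPartialSpearman:
    def test_perfect_monotone_without_covariates(self):
        x = np.array([1.0, 3.0, 7.0, 9.0, 20.0])
        rho, p = partial_spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_near_duplicate_covariate_absorbs_association(self, rng):
        # y carries no association with x; controlling for a noisy copy
        # of x keeps the Monte-Carlo mean partial rho at 0
        rhos = []
        for _ in range(1000):
            x = rng.standard_normal(40)
            y = rng.standard_normal(40)
            twin = x + 0.05 * rng.standard_normal(40)
            rho, _ = partial_spearman(x, y, covariates=twin[:, None])
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_matches_projection_oracle(self, rng):
        for _ in range(25):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            cov = rng.standard_normal((12, 2))
            rho, _ = partial_spearman(x, y, cov)
            assert rho == pytest.approx(_oracle_partial(x, y, cov), abs=1e-10)

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(40),
                "y": rng.standard_normal(40),
                "c1": rng.standard_normal(40),
                "c2": rng.standard_normal(40),
            }
        )
        expected = pingouin.partial_corr(
            df, x="x", y="y", covar=["c1", "c2"], method="spearman"
        )
        rho, p = partial_spearman(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        assert rho == pytest.approx(float(expected["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-10)

    def test_constant_input_is_missing(self):
        rho, p = partial_spearman([1.0] * 10, np.arange(10.0))
        assert math.isnan(rho) and math.isnan(p)


class TestFitGLM:
    def test_exact_linear_recovery(self):
        group = np.repeat([0.0, 1.0], 10)
        y = 2.0 + 3.0 * group
        res = fit_glm(y, pd.DataFrame({"group_pad": group}), family="gaussian_identity")
        assert res.terms["group_pad"].coef == pytest.approx(3.0, abs=1e-8)
        assert res.terms["const"].coef == pytest.approx(2.0, abs=1e-8)

    def test_gamma_log_noiseless_inversion(self, rng):
        x = rng.uniform(-1, 1, size=50)
        y = np.exp(1.0 + 0.5 * x)
        res = fit_glm(y, pd.DataFrame({"x": x}), family="gamma_log")
        assert res.terms["const"].coef == pytest.approx(1.0, abs=1e-6)
        assert res.terms["x"].coef == pytest.approx(0.5, abs=1e-6)

    def test_gaussian_matches_normal_equations(self, rng):
        x = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        res = fit_glm(y, pd.DataFrame(x, columns=["a", "b"]), family="gaussian_identity")
        design = np.column_stack([np.ones(8), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert res.terms["const"].coef == pytest.approx(beta[0], abs=1e-10)
        assert res.terms["a"].coef == pytest.approx(beta[1], abs=1e-10)
        assert res.terms["b"].coef == pytest.approx(beta[2], abs=1e-10)

    def test_auto_family_keeps_gaussian_for_well_scaled_response(self, rng):
        x = rng.standard_normal(100)
        y = 0.2 * x + rng.standard_normal(100) * 0.1
        res = fit_glm(y, pd.DataFrame({"x": x}), family="auto")
        assert res.family == "gaussian_identity"
        assert res.gof_p >= 0.05

    def test_auto_family_switches_to_gamma_for_skewed_response(self, rng):
        x = rng.standard_normal(150)
        y = np.exp(3.0 + 0.5 * x + rng.standard_normal(150))  # heavy right skew
        res = fit_glm(y, pd.DataFrame({"x": x}), family="auto")
        assert res.family == "gamma_log"

    def test_singular_design_names_collinear_terms(self, rng):
        x = rng.standard_normal(20)
        preds = pd.DataFrame({"x": x, "x2": 2.0 * x})
        with pytest.raises(FitError, match="x2"):
            fit_glm(rng.standard_normal(20), preds, family="gaussian_identity")

    def test_gamma_rejects_nonpositive_response(self, rng):
        y = np.array([1.0, -2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(FitError, match="positive"):
            fit_glm(y, pd.DataFrame({"x": np.arange(6.0)}), family="gamma_log")

    def test_ci_contains_coefficient_and_q_defaults_missing(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        res = fit_glm(y, pd.DataFrame({"x": x}))
        t = res.terms["x"]
        assert t.ci_low <= t.coef <= t.ci_high
        assert math.isnan(t.q)


def _noise_features(rng, n=60, measures=("m1", "m2", "m3", "m4", "m5")):
    data = {
        "group_pad": rng.integers(0, 2, size=n).astype(float),
        "language_el": np.zeros(n),
        "age": rng.normal(70, 5, size=n),
        "sex_female": rng.integers(0, 2, size=n).astype(float),
        "education": rng.normal(12, 3, size=n),
        "word_ttr": rng.uniform(0.5, 1.0, size=n),
        "word_count": rng.normal(50, 10, size=n),
        "subword_ttr": rng.uniform(0.3, 0.8, size=n),
        "mmse": rng.normal(24, 4, size=n),
    }
    for m in measures:
        data[m] = rng.standard_normal(n)
    return pd.DataFrame(data)


class TestScreening:
    def test_strong_candidate_selected(self, rng):
        n = 200
        df = _noise_features(rng, n=n)
        df["m1"] = df["age"] * 0.1 + rng.standard_normal(n) * 0.05  # rho ~ 0.9
        selected, table = screen_covariates(df, measures=("m1", "m2"))
        assert "age" in selected["m1"]
        assert set(table.columns) == {"measure", "candidate", "rho", "p", "q"}

    def test_null_false_selection_rate_controlled(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            df = _noise_features(rng, n=50)
            selected, _ = screen_covariates(df, measures=("m1", "m2", "m3", "m4", "m5"))
            if any(selected[m] for m in selected):
                hits += 1
        # BH at q<0.05 under a global null keeps the chance of any
        # selection near 5%; allow binomial slack
        assert hits / reps <= 0.11

    def test_no_candidates_selected_gives_empty_sets(self, rng):
        selected, _ = screen_covariates(_noise_features(rng), measures=("m1",))
        assert selected["m1"] == ()


class TestGroupAnalysis:
    def test_injected_effect_recovered_with_sign(self, rng):
        n = 300
        df = _noise_features(rng, n=n, measures=("ft_gsim",))
        df["ft_gsim"] = 0.5 + 0.05 * df["group_pad"] + rng.standard_normal(n) * 0.05
        results, failures = run_group_analysis(df, measures=("ft_gsim",))
        assert not failures
        focal = results[0].focal
        assert focal.coef > 0
        assert focal.q < 0.05

    def test_all_missing_measure_skipped_others_reported(self, rng):
        df = _noise_features(rng, measures=("ok", "broken"))
        df["broken"] = np.nan
        results, failures = run_group_analysis(df, measures=("ok", "broken"))
        assert [r.measure for r in results] == ["ok"]
        assert "broken" in failures

    def test_ppl_model_always_adjusts_for_subword_ttr(self, rng):
        df = _noise_features(rng, measures=("ppl",))
        df["ppl"] = np.exp(rng.normal(4, 0.3, size=len(df)))
        results, _ = run_group_analysis(df, measures=("ppl",))
        assert "subword_ttr" in results[0].terms

    def test_null_cohort_false_positives_at_bh_level(self, rng):
        reps, hits = 60, 0
        measures = tuple(f"m{i}" for i in range(1, 8))
        for _ in range(reps):
            df = _noise_features(rng, n=80, measures=measures)
            results, _ = run_group_analysis(df, measures=measures)
            if any(r.focal.q < 0.05 for r in results):
                hits += 1
        assert hits / reps <= 0.15  # ~5% nominal plus binomial slack


class TestMMSEAnalysis:
    def test_negative_mmse_slope_recovered(self, rng):
        df = _noise_features(rng, n=200, measures=("ft_gsim",))
        df["group_pad"] = 1.0
        df["ft_gsim"] = 0.8 - 0.01 * df["mmse"] + rng.standard_normal(200) * 0.02
        results, failures = run_mmse_analysis(df, measures=("ft_gsim",))
        assert not failures
        assert results[0].focal.coef < 0
        assert results[0].focal_term == "mmse"

    def test_constant_mmse_flagged_as_failure(self, rng):
        df = _noise_features(rng, measures=("m1",))
        df["group_pad"] = 1.0
        df["mmse"] = 25.0
        results, failures = run_mmse_analysis(df, measures=("m1",))
        assert not results and "m1" in failures

    def test_ci_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (10, 300):
            df = _noise_features(rng, n=n, measures=("m1",))
            df["group_pad"] = 1.0
            df["m1"] = 0.5 - 0.01 * df["mmse"] + rng.standard_normal(n) * 0.05
            results, _ = run_mmse_analysis(df, measures=("m1",))
            t = results[0].focal
            widths.append(t.ci_high - t.ci_low)
        assert widths[1] < widths[0]


def _result(coef, ci, measure="gsim", term="group_pad"):
    return RegressionResult(
        measure=measure,
        family="gaussian_identity",
        terms={term: TermResult(coef=coef, se=0.1, z=coef / 0.1, p=0.05, ci_low=ci[0], ci_high=ci[1])},
        gof_p=0.5,
        n=100,
        focal_term=term,
    )


class TestReplication:
    @pytest.mark.parametrize(
        "b_en, b_el, ci_el, sign_ok, contain_ok",
        [
            (0.5, 0.3, (0.1, 0.9), True, True),
            (0.5, -0.2, (-0.6, 0.7), False, True),
            (0.5, 0.1, (0.05, 0.15), True, False),
            (0.5, -0.1, (-0.3, -0.05), False, False),
        ],
    )
    def test_truth_table(self, b_en, b_el, ci_el, sign_ok, contain_ok):
        verdict = assess_replication(
            _result(b_en, (0.2, 0.8)), _result(b_el, ci_el), "group_pad"
        )
        assert verdict.sign_match is sign_ok
        assert verdict.ci_containment is contain_ok
        assert verdict.replicated is (sign_ok and contain_ok)

    def test_replicated_implies_sign_match(self):
        verdict = assess_replication(
            _result(0.5, (0.2, 0.8)), _result(0.3, (0.1, 0.9)), "group_pad"
        )
        assert not verdict.replicated or verdict.sign_match

    def test_missing_term_rejected(self):
        with pytest.raises(KeyError, match="mmse"):
            assess_replication(_result(0.5, (0, 1)), _result(0.3, (0, 1)), "mmse")
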