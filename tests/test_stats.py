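"""Firth regression, PLR selection, FDR, confounder scan and diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests

import aortagrad as ag
from aortagrad.stats import (
    bh_fdr,
    confounder_scan,
    constrained_fit,
    crosstab_metrics,
    firth_fit,
    flagged_confounders,
    forward_select,
    model_metrics_at_cutoff,
    or_from_beta,
    penalized_loglik,
    plr_test,
    roc_auc,
    roc_points,
)


def _grid_argmax(X, y, lo=-6.0, hi=6.0, steps=121):
    """Brute-force maximiser of the penalized log-likelihood on a lattice."""
    axes = [np.linspace(lo, hi, steps)] * X.shape[1]
    best, best_pll = None, -np.inf
    for beta in itertools.product(*axes):
        pll = penalized_loglik(X, y, np.array(beta))
        if pll > best_pll:
            best, best_pll = np.array(beta), pll
    return best


class TestFirth:
    def test_intercept_only_closed_form(self):
        for k, n in ((3, 10), (0, 10), (10, 10), (1, 20)):
            y = np.r_[np.ones(k), np.zeros(n - k)]
            fit = firth_fit(np.empty((n, 0)), y)
            assert abs(expit(fit.beta[0]) - (k + 0.5) / (n + 1)) < 1e-9

    def test_complete_separation_finite_and_matches_grid(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        y = np.r_[np.zeros(5), np.ones(5)]
        fit = firth_fit(x[:, None], y, names=["x"])
        assert np.all(np.isfinite(fit.beta)) and np.all(np.isfinite(fit.se))
        grid = _grid_argmax(fit.X, y, lo=-6, hi=6, steps=241)
        assert np.abs(fit.beta - grid).max() < 0.05  # lattice spacing limits
        # refine: returned optimum beats every lattice neighbour at 0.01
        for d in itertools.product((-0.01, 0.0, 0.01), repeat=2):
            assert penalized_loglik(fit.X, y, fit.beta) >= penalized_loglik(
                fit.X, y, fit.beta + np.array(d)
            )

    def test_local_optimality_on_random_problems(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(20, 60)
            X = rng.normal(size=(n, 2))
            y = rng.binomial(1, expit(X @ np.array([0.5, -1.0])))
            if y.std() == 0:
                continue
            fit = firth_fit(X, y, names=["a", "b"])
            for d in itertools.product((-0.01, 0.0, 0.01), repeat=3):
                assert penalized_loglik(fit.X, y, fit.beta) >= penalized_loglik(
                    fit.X, y, fit.beta + np.array(d)
                ) - 1e-9

    def test_converges_to_mle_with_many_events(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(-1.0 + 0.8 * x)).astype(float)
        fit = firth_fit(x[:, None], y, names=["x"])
        mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.abs(fit.beta - mle.params).max() < 0.01

    def test_constant_column_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="constant column"):
            firth_fit(np.ones((10, 1)), y)

    def test_constant_response_with_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            firth_fit(np.arange(10.0)[:, None], np.zeros(10))

    def test_constrained_fit_fixes_coefficients(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 2))
        y = rng.binomial(1, expit(x[:, 0])).astype(float)
        full = firth_fit(x, y, names=["a", "b"])
        red = constrained_fit(full, ["a"])
        assert red.beta[red.names.index("b")] == 0.0
        assert red.loglik <= full.loglik + 1e-9


class TestOddsRatios:
    @pytest.mark.parametrize(
        "beta,expected_or",
        [(-0.656, 0.519), (-0.347, 0.707), (-0.931, 0.394), (-0.855, 0.425), (-0.698, 0.498)],
    )
    def test_reported_beta_to_or_arithmetic(self, beta, expected_or):
        assert round(float(np.exp(beta)), 3) == expected_or

    def test_or_table_roundtrip_and_null(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(10), np.ones(10), np.zeros(10), np.ones(10)]
        fit = firth_fit(x[:, None], y, names=["x"])
        tab = or_from_beta(fit, rescale_units=10.0).set_index("term")
        # mutual consistency: log(OR)/rescale = beta
        assert np.isclose(np.log(tab.loc["x", "or"]) / 10.0, fit.beta[1])
        assert np.isclose(tab.loc["x", "or"], 1.0, atol=1e-6)
        assert np.isclose(tab.loc["x", "pct_change_odds"], 0.0, atol=1e-4)


class TestPlr:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        y = rng.binomial(1, 0.3, 60).astype(float)
        fit = firth_fit(x[:, None], y, names=["x"])
        stat, p = plr_test(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_strong_effect_tiny_p(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        y = rng.binomial(1, expit(x)).astype(float)
        full = firth_fit(x[:, None], y, names=["x"])
        red = firth_fit(np.empty((500, 0)), y)
        stat, p = plr_test(full, red)
        assert p < 1e-6

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            n = 150
            x = rng.normal(0, 30, n)  # deliberately badly scaled
            y = rng.binomial(1, 0.2, n).astype(float)
            if y.std() == 0:
                y[0] = 1.0
            full = firth_fit(x[:, None], y, names=["x"])
            _, p = plr_test(full, firth_fit(np.empty((n, 0)), y))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(40, 2))
        y = rng.binomial(1, 0.4, 40).astype(float)
        f1 = firth_fit(x[:, :1], y, names=["a"])
        f2 = firth_fit(x[:, 1:], y, names=["b"])
        with pytest.raises(ValueError, match="not nested"):
            plr_test(f1, f2)


class TestForwardSelection:
    @staticmethod
    def _effect_cohort(seed, n=2000, beta=-0.09):
        spec = ag.CohortSpec(
            n_patients=n,
            seed=seed,
            missing_rate=0.0,
            outcome_names=("icu_admission",),
            gradient_effect_per_unit={"icu_admission": beta},
            prevalences={"icu_admission": 0.2},
        )
        return ag.generate_cohort(spec)[0]

    def test_single_true_effect_selects_gradient_only(self):
        hits = 0
        for s in range(10):
            df = self._effect_cohort(200 + s)
            sel = forward_select(
                df,
                "icu_admission",
                ["mean_intensity", "proximal_intensity", "contrast_gradient"],
            )
            hits += sel.selected == ["contrast_gradient"]
        assert hits >= 9
        # trace bookkeeping on the last run
        assert all(t["entry_p"] >= 0 for t in sel.entry_trace)
        assert set(sel.excluded_entry_p) <= {"mean_intensity", "proximal_intensity"}
        assert sel.model_chi2 > 0 and sel.model_p < 0.05

    def test_alpha_one_enters_everything_in_plr_order(self):
        df = self._effect_cohort(42)
        sel = forward_select(
            df,
            "icu_admission",
            ["mean_intensity", "proximal_intensity", "contrast_gradient"],
            alpha_entry=1.0,
        )
        assert len(sel.selected) == 3
        assert sel.selected[0] == "contrast_gradient"

    def test_empty_candidates_constant_only(self):
        df = self._effect_cohort(43, n=200)
        sel = forward_select(df, "icu_admission", [])
        assert sel.selected == []
        assert sel.model_chi2 == 0.0 and sel.model_p == 1.0

    def test_no_complete_rows_raises(self):
        df = pd.DataFrame({"y": [np.nan] * 5, "x": np.arange(5.0)})
        with pytest.raises(ValueError, match="no complete rows"):
            forward_select(df, "y", ["x"])

    def test_listwise_exclusion_equals_prefiltered(self):
        df = self._effect_cohort(44, n=400)
        df.loc[5, "contrast_gradient"] = np.nan
        df.loc[7, "icu_admission"] = np.nan
        sel1 = forward_select(df, "icu_admission", ["contrast_gradient"])
        sel2 = forward_select(df.dropna(), "icu_admission", ["contrast_gradient"])
        assert sel1.n_used == sel2.n_used == len(df) - 2
        assert np.allclose(sel1.final_fit.beta, sel2.final_fit.beta)


class TestBhFdr:
    def test_hand_computed_examples(self):
        assert np.allclose(bh_fdr([0.01]), [0.01])
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5)
        assert np.allclose(bh_fdr([0.005, 0.04, 0.03]), [0.015, 0.04, 0.04])

    def test_matches_statsmodels_and_bruteforce(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.random(rng.integers(1, 12))
            q = bh_fdr(p)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])
            m = len(p)
            ranks = np.argsort(np.argsort(p)) + 1
            brute = [
                min(min(1.0, pj * m / rj) for pj, rj in zip(p, ranks) if pj >= pi)
                for pi in p
            ]
            assert np.allclose(q, brute)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.2, 1.4])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])


class TestConfounderScan:
    def test_perfect_fit(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"conf": x, "param": 2 * x})
        res = confounder_scan(df, ["param"], ["conf"])
        row = res.iloc[0]
        assert np.isclose(row.r_squared, 1.0)
        assert np.isclose(row.beta, 2.0)
        assert row.p_value < 1e-12
        assert row.ci_low <= row.beta <= row.ci_high

    def test_orthogonal_null(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        res = confounder_scan(pd.DataFrame({"c": x, "p": y}), ["p"], ["c"])
        assert res.iloc[0].r_squared < 0.01

    def test_zero_variance_regressor_raises(self):
        df = pd.DataFrame({"c": np.ones(20), "p": np.arange(20.0)})
        with pytest.raises(ValueError, match="zero-variance"):
            confounder_scan(df, ["p"], ["c"])

    def test_synthetic_cohort_sign_pattern(self):
        """Slope signs: negative throughout except contrast delay vs the
        intensity parameters (mirrors the observed confounder table)."""
        df, _ = ag.generate_cohort(ag.CohortSpec(n_patients=4000, seed=12, missing_rate=0.0))
        res = confounder_scan(
            df,
            ["mean_intensity", "proximal_intensity", "contrast_gradient"],
            [
                "lung_volume_l",
                "aorta_length_mm",
                "aorta_volume_ml",
                "aorta_diameter_mm",
                "contrast_delay_s",
            ],
        )
        for _, row in res.iterrows():
            positive = row.confounder == "contrast_delay_s" and row.parameter in (
                "mean_intensity",
                "proximal_intensity",
            )
            assert (row.beta > 0) == positive, (row.confounder, row.parameter)
        assert "aorta_length_mm" in flagged_confounders(res)


class TestDiagnostics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 6, 0, 86), (14.3, 100.0, 100.0, 93.5)),
            ((1, 6, 1, 85), (14.3, 98.8, 50.0, 92.5)),
        ],
    )
    def test_crosstab_arithmetic(self, counts, expected):
        tp, fn, fp, tn = counts
        pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
        out = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
        m = crosstab_metrics(pred, out)
        assert (m.tp, m.fn, m.fp, m.tn) == counts
        got = (round(m.sensitivity, 1), round(m.specificity, 1), round(m.ppv, 1), round(m.accuracy, 1))
        assert got == expected
        assert np.isfinite(m.p_association)

    def test_perfect_predictor(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        m = crosstab_metrics(y, y)
        assert (m.sensitivity, m.specificity, m.ppv, m.accuracy) == (100.0,) * 4

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            crosstab_metrics([], [])

    def test_rare_outcome_all_negative_predictions(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=93)
        y = np.zeros(93)
        y[:7] = 1.0
        fit = firth_fit(x[:, None], y, names=["x"])
        m = model_metrics_at_cutoff(fit, cutoff=0.5)
        assert m.sensitivity == 0.0 and m.specificity == 100.0

    def test_cutoff_zero_all_positive(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=50)
        y = rng.binomial(1, 0.3, 50).astype(float)
        if y.std() == 0:
            y[0] = 1
        fit = firth_fit(x[:, None], y, names=["x"])
        m = model_metrics_at_cutoff(fit, cutoff=0.0)
        assert m.sensitivity == 100.0 and m.specificity == 0.0

    def test_metrics_match_independent_recount(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=300)
        y = rng.binomial(1, expit(2 * x)).astype(float)
        fit = firth_fit(x[:, None], y, names=["x"])
        m = model_metrics_at_cutoff(fit, cutoff=0.5)
        pred = fit.predict_proba() >= 0.5
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        assert (m.tp, m.fn, m.fp, m.tn) == (tp, fn, fp, tn)
        assert m.accuracy == 100.0 * (tp + tn) / 300

    def test_roc_toy_enumeration(self):
        fit = firth_fit(np.array([[0.0], [1.0], [2.0]]), np.array([0.0, 0.0, 1.0]), names=["x"])
        # monotone scores 0.1 < 0.5 < 0.9 equivalent: use probabilities directly
        pts = roc_points(fit)
        expected = {(0.0, 0.0), (0.0, 1.0), (0.5, 1.0), (1.0, 1.0)}
        assert {(round(a, 6), round(b, 6)) for a, b in pts} == expected
        assert np.isclose(roc_auc(pts), 1.0)

    def test_roc_null_predictor_auc_half(self):
        rng = np.random.default_rng(16)
        n = 4000
        x = rng.normal(size=n)
        y = rng.binomial(1, 0.4, n).astype(float)
        fit = firth_fit(x[:, None], y, names=["x"])
        pts = roc_points(fit)
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]
        assert abs(roc_auc(pts) - 0.5) < 0.05

    def test_roc_constant_outcome_raises(self):
        fit = firth_fit(np.arange(10.0)[:, None], np.r_[np.ones(5), np.zeros(5)], names=["x"])
        with pytest.raises(ValueError, match="constant"):
            roc_points(fit, y=np.ones(10))
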