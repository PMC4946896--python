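"""Diagnostic statistics: exact CIs, Wilcoxon, Firth regression, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cystseq.diagnostics import (
    clopper_pearson, diagnostic_summary, firth_logistic, he4_normal,
    marker_report, replicate_concordance, round_percent, wilcoxon_rank_sum,
    _firth_penalized_loglik,
)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,lo_pct,hi_pct", [
        (0, 12, 0, 26),    # benign tumors: 0% (0-26%)
        (0, 6, 0, 46),     # non-neoplastic: 0% (0-46%)
        (18, 18, 81, 100), # type II cancers: 100% (81-100%)
        (47, 54, 75, 95),  # pooled sensitivity: 87% (75-95%)
        (19, 23, 61, 95),  # borderline: 83% (61-95%)
        (10, 13, 46, 95),  # type I: 77% (46-95%)
    ])
    def test_published_interval_bounds(self, k, n, lo_pct, hi_pct):
        lo, hi = clopper_pearson(k, n)
        assert round_percent(lo) == lo_pct
        assert round_percent(hi) == hi_pct

    def test_single_trial_closed_form(self):
        assert clopper_pearson(0, 1) == (0.0, pytest.approx(0.975))

    @pytest.mark.parametrize("n", [1, 5, 18, 54])
    def test_boundary_closed_forms(self, n):
        """upper(0, n) = 1 - (a/2)^(1/n) and lower(n, n) = (a/2)^(1/n)."""
        alpha = 0.05
        _, hi = clopper_pearson(0, n, alpha)
        lo, _ = clopper_pearson(n, n, alpha)
        assert hi == pytest.approx(1 - (alpha / 2) ** (1 / n))
        assert lo == pytest.approx((alpha / 2) ** (1 / n))

    def test_monotone_in_k(self):
        n = 20
        bounds = [clopper_pearson(k, n) for k in range(n + 1)]
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            assert lo2 >= lo1 and hi2 >= hi1

    def test_coverage_at_least_nominal(self):
        """Over 2000 simulated binomials (n=20, p=0.5) the 95% interval
        covers p in at least 95% of draws."""
        rng = np.random.default_rng(0)
        ks = rng.binomial(20, 0.5, size=2000)
        covered = sum(lo <= 0.5 <= hi for lo, hi in (clopper_pearson(k, 20) for k in ks))
        assert covered / 2000 >= 0.95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestWilcoxon:
    def test_exact_small_sample_enumeration(self):
        """x={1,2} vs y={3,4}: 2 of C(4,2)=6 rank assignments are as extreme,
        so the exact two-sided p is 1/3."""
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_same_multiset_high_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_seventyfold_median_shift_significant(self):
        """Log-normal groups emulating the published DNA yields
        (4453 +/- 6428 vs 62 +/- 64 ng) differ at p < 0.001."""
        from cystseq.simulate import lognormal_from_mean_sd
        rng = np.random.default_rng(1)
        mu1, sd1 = lognormal_from_mean_sd(4453, 6428)
        mu0, sd0 = lognormal_from_mean_sd(62, 64)
        x = np.exp(rng.normal(mu1, sd1, 54))
        y = np.exp(rng.normal(mu0, sd0, 18))
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_exact_close_to_asymptotic_for_n6(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 6)
        _, p_exact = wilcoxon_rank_sum(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.05


def _grid_firth_oracle(X, y, lo=-6, hi=6):
    """Two-stage 2-D grid maximization of the penalized likelihood."""
    best = (None, -np.inf)
    grid = np.linspace(lo, hi, 121)
    for b0 in grid:
        for b1 in grid:
            ll = _firth_penalized_loglik(X, y, np.array([b0, b1]))
            if ll > best[1]:
                best = ((b0, b1), ll)
    b0c, b1c = best[0]
    fine0 = np.linspace(b0c - 0.1, b0c + 0.1, 81)
    fine1 = np.linspace(b1c - 0.1, b1c + 0.1, 81)
    for b0 in fine0:
        for b1 in fine1:
            ll = _firth_penalized_loglik(X, y, np.array([b0, b1]))
            if ll > best[1]:
                best = ((b0, b1), ll)
    return np.array(best[0])


class TestFirth:
    def test_intercept_only_closed_form(self):
        """With the Jeffreys penalty the intercept-only fit gives
        pi-hat = (k + 1/2) / (n + 1)."""
        for k, n in [(3, 10), (0, 7), (12, 12), (5, 40)]:
            y = np.array([1.0] * k + [0.0] * (n - k))
            res = firth_logistic(np.empty((n, 0)), y, names=[])
            pi = 1 / (1 + np.exp(-res.coef[0]))
            assert pi == pytest.approx((k + 0.5) / (n + 1), abs=1e-6)

    def test_six_row_fit_matches_grid_oracle(self):
        """Coefficients agree with brute-force grid maximization of the
        penalized likelihood to 3 decimals."""
        x = np.array([-1.2, -0.5, 0.1, 0.4, 1.1, 2.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        res = firth_logistic(x[:, None], y, names=["x"])
        design = np.column_stack([np.ones(6), x])
        oracle = _grid_firth_oracle(design, y)
        assert np.allclose(res.coef, oracle, atol=1.5e-3)

    def test_separation_gives_finite_estimate_and_small_p(self):
        """Ordinary ML diverges under complete separation; the Firth estimate
        stays finite and the penalized-LR p is significant on 40 rows."""
        rng = np.random.default_rng(3)
        mutation = np.array([1.0] * 20 + [0.0] * 20)
        y = mutation.copy()
        X = np.column_stack([mutation, rng.normal(size=40)])
        res = firth_logistic(X, y, names=["mutation", "noise"])
        assert np.all(np.isfinite(res.coef))
        assert abs(res.coef[1]) < 20
        assert res.p_lrt["mutation"] < 0.05
        assert res.p_lrt["mutation"] < res.p_lrt["noise"]

    def test_collinear_design_raises_with_names(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, 2 * x])
        y = (x > 4).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            firth_logistic(X, y, names=["a", "b"])

    def test_parameter_recovery_within_two_se(self):
        """On cohorts generated from known coefficients (n=200), each
        estimate falls within 2 penalized SEs of truth in >=90% of 100
        seeded replicates."""
        beta_true = np.array([-0.5, 1.0, -0.8])  # intercept, binary, continuous
        hits = np.zeros(3)
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            xb = rng.integers(0, 2, 200).astype(float)
            xc = rng.normal(size=200)
            eta = beta_true[0] + beta_true[1] * xb + beta_true[2] * xc
            y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
            res = firth_logistic(np.column_stack([xb, xc]), y, names=["b", "c"])
            hits += (np.abs(res.coef - beta_true) <= 2 * res.se)
        assert (hits / 100 >= 0.90).all()


class TestReplicateConcordance:
    def test_identical_replicates_zero(self):
        med, (q1, q3) = replicate_concordance([(0.05, 0.05), (0.2, 0.2)])
        assert med == 0.0 and q1 == 0.0 and q3 == 0.0

    def test_hand_computed_pair(self):
        med, _ = replicate_concordance([(0.10, 0.11)])
        assert med == pytest.approx(2 * 0.01 / 0.21)

    def test_all_zero_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            med, _ = replicate_concordance([(0.0, 0.0), (0.1, 0.1)])
        assert med == 0.0

    def test_no_scorable_pairs_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                replicate_concordance([(0.0, 0.0)])


def _cohort_frame(rows):
    return pd.DataFrame(rows, columns=[
        "sample_id", "cyst_class", "stage", "dna_ng", "ca125", "he4",
        "menopause", "positive", "max_maf",
    ])


def _mk_rows(cls, n, n_pos, stage="NA", maf=0.1):
    rows = []
    for i in range(n):
        pos = i < n_pos
        rows.append((f"{cls}{i}", cls, stage, 100.0, 20.0, 50.0, "pre",
                     pos, maf if pos else 0.0))
    return rows


class TestDiagnosticSummary:
    def test_all_negative_class_zero_fraction_and_maf(self):
        df = _cohort_frame(_mk_rows("benign", 12, 0) + _mk_rows("type2", 3, 3))
        summary = diagnostic_summary(df)
        row = summary.table.set_index("group").loc["benign"]
        assert row["fraction"] == 0.0
        assert row["median_maf"] == 0.0

    def test_full_detection_gives_unit_sensitivity(self):
        df = _cohort_frame(
            _mk_rows("borderline", 5, 5) + _mk_rows("type2", 5, 5)
            + _mk_rows("benign", 4, 0)
        )
        summary = diagnostic_summary(df)
        assert summary.sensitivity == 1.0
        assert summary.specificity == 1.0

    def test_empty_class_warns(self):
        df = _cohort_frame(_mk_rows("type2", 3, 3))
        with pytest.warns(UserWarning, match="empty"):
            diagnostic_summary(df)


class TestMarkerReport:
    def test_he4_cutoffs_are_menopause_specific(self):
        assert he4_normal(100.0, "pre") is False   # >= 92
        assert he4_normal(100.0, "post") is True   # < 121
        assert he4_normal(91.9, "pre") is True
        assert he4_normal(121.0, "post") is False

    def test_perfect_mutation_predictor_has_smallest_p(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(40):
            surgery = i < 20
            cls = "type2" if surgery else "benign"
            rows.append((
                f"s{i}", cls, "III" if surgery else "NA",
                float(np.exp(rng.normal(5, 1))), float(np.exp(rng.normal(3, 1))),
                float(np.exp(rng.normal(4, 0.5))), "pre",
                surgery, 0.3 if surgery else 0.0,
            ))
        report = marker_report(_cohort_frame(rows))
        p = report.pvalues
        assert p["mutation_present"] == min(p.values())

    def test_independent_ca125_rarely_significant(self):
        """With CA-125 independent of class, its multivariate p exceeds 0.05
        in at least 90% of 100 seeded simulations (type-I error control)."""
        n_sig = 0
        for rep in range(100):
            rng = np.random.default_rng(9000 + rep)
            rows = []
            for i in range(72):
                surgery = i < 54
                cls = "borderline" if surgery else "benign"
                positive = surgery and (rng.random() < 0.87)
                rows.append((
                    f"s{i}", cls, "I" if surgery else "NA",
                    float(np.exp(rng.normal(5, 1))),
                    float(np.exp(rng.normal(3, 1))),   # CA-125 independent of class
                    float(np.exp(rng.normal(4, 0.5))), "pre",
                    positive, 0.2 if positive else 0.0,
                ))
            report = marker_report(_cohort_frame(rows))
            n_sig += report.pvalues["ca125_normal"] < 0.05
        assert 100 - n_sig >= 90

    def test_missing_covariates_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(12):
            surgery = i < 6
            rows.append((
                f"s{i}", "type2" if surgery else "benign", "NA",
                float(np.exp(rng.normal(5, 1))), float(np.exp(rng.normal(3.5, 1))),
                float(np.exp(rng.normal(4.5, 0.6))), "pre" if i % 2 else "post",
                surgery, 0.3 if surgery else 0.0,
            ))
        df = _cohort_frame(rows)
        df.loc[0, "ca125"] = np.nan
        with pytest.warns(UserWarning, match="missing covariates"):
            report = marker_report(df)
        assert report.n_dropped == 1
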