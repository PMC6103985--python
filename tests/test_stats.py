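import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from conftest import brute_force_auc
from ectopulse.simulate import CohortSimConfig, simulate_cohort_summaries
from ectopulse.stats import (
    confusion_stats,
    paired_t,
    roc_auc,
    run_classification,
    spearman_rho,
    two_sample_t_pooled,
    youden_threshold,
)

# Independent oracle values computed with R pROC (DeLong) on this fixture.
PROC_SCORES = np.array([2.1, -0.5, 1.3, 0.2, -1.1, 3.4, 0.9, -0.3, 2.8, 1.0,
                        -2.0, 0.4, 5.1, 4.2, 6.0, 3.3, 2.2, 7.1])
PROC_LABELS = np.array([0] * 12 + [1] * 6, dtype=bool)
PROC_AUC = 0.9583333333
PROC_DELONG_VAR = 0.0017045455
PROC_CI = (0.8774139835, 1.0)


class TestRocAuc:
    def test_small_example_matches_pairwise_count(self):
        r = roc_auc([1, 2, 3, 2.5, 4], [0, 0, 0, 1, 1])
        assert r.auc == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        r = roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        assert r.auc == 1.0 and r.ci_high == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(123)
        scores = rng.normal(size=1000)
        labels = np.repeat([0, 1], 500)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_delong_oracle(self):
        r = roc_auc(PROC_SCORES, PROC_LABELS)
        assert r.auc == pytest.approx(PROC_AUC, abs=1e-9)
        assert r.se**2 == pytest.approx(PROC_DELONG_VAR, abs=1e-9)
        assert r.ci_low == pytest.approx(PROC_CI[0], abs=1e-6)
        assert r.ci_high == pytest.approx(PROC_CI[1], abs=1e-9)  # clipped to 1

    def test_matches_sklearn_and_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n1, n2 = rng.integers(2, 15, 2)
            scores = np.round(rng.normal(size=n1 + n2), 1)  # provoke ties
            labels = np.r_[np.zeros(n1, bool), np.ones(n2, bool)]
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)), min_size=6, max_size=20))
    def test_invariant_under_increasing_transform(self, vals):
        scores = np.asarray(vals)
        labels = np.arange(len(scores)) % 2 == 0
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores / 25.0), labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestYouden:
    def test_perfectly_separable(self):
        y = youden_threshold([1, 2, 3, 4], [0, 0, 1, 1])
        assert y.threshold == pytest.approx(2.5)
        assert y.sens_pct == 100.0 and y.spec_pct == 100.0

    def test_tie_break_toward_higher_specificity(self):
        # non-resp {1,3}, resp {2,4}: J=0.5 at thresholds 1.5 and 3.5
        y = youden_threshold([1, 3, 2, 4], [0, 0, 1, 1])
        assert y.youden_j == pytest.approx(0.5)
        assert y.threshold == pytest.approx(3.5)
        assert y.spec_pct == 100.0 and y.sens_pct == 50.0

    def test_degenerate_identical_scores(self):
        with pytest.warns(UserWarning, match="degenerate"):
            y = youden_threshold([2.0, 2.0, 2.0], [0, 1, 1])
        assert y.degenerate and y.youden_j == 0.0

    def test_no_cutpoint_beats_reported_j(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            scores = np.round(rng.normal(size=14), 1)
            labels = rng.random(14) < 0.4
            if labels.all() or not labels.any():
                continue
            y = youden_threshold(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            for thr in np.concatenate([scores - 1e-6, scores + 1e-6]):
                j = np.mean(pos > thr) + np.mean(neg <= thr) - 1
                assert j <= y.youden_j + 1e-9


class TestConfusion:
    def test_published_sbp_rel_counts(self):
        c = confusion_stats(tp=4, fn=2, fp=0, tn=20).rounded()
        assert c == {"sens_pct": 67, "spec_pct": 100, "ppv_pct": 100, "npv_pct": 91}

    def test_reconstructed_pep_abs_counts(self):
        c = confusion_stats(tp=4, fn=2, fp=4, tn=14).rounded()
        assert c == {"sens_pct": 67, "spec_pct": 78, "ppv_pct": 50, "npv_pct": 88}

    def test_zero_denominator_reported_missing(self):
        c = confusion_stats(tp=0, fn=0, fp=0, tn=20)
        assert c.sens_pct is None and c.spec_pct == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_stats(-1, 0, 0, 1)


class TestTTests:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,t_expect,p_print",
        [
            (-0.1, 5.6, 20, 5.9, 6.6, 6, 2.21, 0.04),   # SBP change
            (4.0, 6.7, 18, 10.6, 7.0, 6, 2.07, 0.05),   # PP change
            (4.0, 5.3, 18, 7.5, 2.9, 6, 1.53, 0.14),    # PEP change
        ],
    )
    def test_group_comparisons_from_summary_stats(self, m1, s1, n1, m2, s2, n2, t_expect, p_print):
        t, df, p = two_sample_t_pooled(m1, s1, n1, m2, s2, n2)
        assert df == n1 + n2 - 2
        assert t == pytest.approx(t_expect, abs=0.01)
        assert round(p, 2) == p_print

    def test_identical_groups(self):
        t, _, p = two_sample_t_pooled(5.0, 2.0, 10, 5.0, 2.0, 10)
        assert t == 0.0 and p == 1.0

    def test_raw_vectors_match_summary_path(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 2, 9)
        t1, df1, p1 = two_sample_t_pooled(x1=x, x2=y)
        t2, df2, p2 = two_sample_t_pooled(
            float(x.mean()), float(x.std(ddof=1)), len(x),
            float(y.mean()), float(y.std(ddof=1)), len(y),
        )
        assert t1 == pytest.approx(t2, abs=1e-12) and p1 == pytest.approx(p2, abs=1e-12)
        assert (t1, p1) == pytest.approx(sps.ttest_ind(y, x, equal_var=True), abs=1e-12)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_pooled(0, 1, 1, 0, 1, 5)

    def test_paired_identical(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_paired_constant_shift_warns(self):
        before = np.array([70.0, 75.0, 80.0, 85.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_t(before, before + 9.0)
        assert p == 0.0

    def test_paired_map_shift_significant(self):
        # MAP rising ~9 mmHg with difference SD 5 over 26 patients
        rng = np.random.default_rng(31)
        before = rng.normal(73, 15, 26)
        after = before + rng.normal(9, 5, 26)
        _, p = paired_t(before, after)
        assert p < 1e-5


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_ranks(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho, p = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


class TestRunClassification:
    def test_full_grid_on_simulated_cohort(self):
        df = simulate_cohort_summaries(CohortSimConfig(), seed=0)
        results, comparisons = run_classification(df)
        assert len(results) == 16  # 4 variables x 2 scales x 2 SV thresholds
        done = [r for r in results if r.missing_reason is None]
        assert len(done) == 16
        for r in done:
            assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1
            assert r.n_resp + r.n_nonresp == len(df)
        assert {(c.variable, c.scale) for c in comparisons} >= {("sbp", "abs"), ("pp", "rel")}

    def test_single_class_rows_reported_missing(self):
        df = simulate_cohort_summaries(CohortSimConfig(n_resp=0, n_nonresp=10), seed=1)
        results, _ = run_classification(df)
        assert all(r.missing_reason for r in results)

    def test_binormal_mean_auc_matches_closed_form(self):
        # empirical AUC converges to Phi(dmu / sqrt(s1^2 + s2^2))
        rng = np.random.default_rng(8)
        aucs = []
        for _ in range(400):
            a = rng.normal(0, 1, 25)
            b = rng.normal(1.2, 1.5, 25)
            aucs.append(roc_auc(np.r_[a, b], np.r_[np.zeros(25), np.ones(25)].astype(bool)).auc)
        expect = sps.norm.cdf(1.2 / np.hypot(1, 1.5))
        assert np.mean(aucs) == pytest.approx(expect, abs=0.02)
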