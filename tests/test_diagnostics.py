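"""Diagnostics: exhaustive small-sample oracles for AUC and Youden,
permutation oracle for Mann-Whitney, DeLong against bootstrap, ICC
against the hand ANOVA decomposition and pingouin."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ufdce.diagnostics import (
    _paired_auc_variance,
    compare_groups,
    confusion_metrics,
    delong_paired_test,
    icc_agreement,
    normality_gate,
    paired_duration_tests,
    roc_auc,
    youden_cutoff,
)
from ufdce.exceptions import InsufficientDataError


def pair_count_auc(scores, y):
    """Brute-force AUC: P(malignant score > benign score) + 1/2 P(tie)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestNormalityGate:
    def test_level_on_normal_draws(self):
        hits = sum(
            normality_gate(np.random.default_rng(seed).normal(size=500)) == "normal"
            for seed in range(100)
        )
        assert hits >= 90

    def test_power_on_lognormal_draws(self):
        hits = sum(
            normality_gate(np.exp(np.random.default_rng(seed).normal(size=500)))
            == "non-normal"
            for seed in range(100)
        )
        assert hits >= 99

    def test_constant_vector_degenerate(self):
        assert normality_gate(np.full(20, 3.0)) == "non-normal"

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_groups(g, g, test="t")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_mann_whitney_matches_permutation_oracle(self):
        benign = np.array([1.0, 2.0, 3.0])
        malignant = np.array([4.0, 5.0, 6.0])
        res = compare_groups(benign, malignant, test="mann-whitney")
        # exhaustive enumeration over all C(6,3)=20 label assignments of
        # the Mann-Whitney U statistic
        pooled = np.concatenate([benign, malignant])
        u_obs = stats.mannwhitneyu(malignant, benign).statistic
        n1 = len(malignant)
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), n1):
            mal = pooled[list(idx)]
            ben = np.delete(pooled, list(idx))
            u = stats.mannwhitneyu(mal, ben).statistic
            # two-sided: as or more extreme in either direction
            total += 1
            if abs(u - n1 * n1 / 2) >= abs(u_obs - n1 * n1 / 2):
                count += 1
        assert res.p == pytest.approx(count / total)
        assert res.test == "mann-whitney"

    def test_type_one_error_calibrated(self):
        rejections = 0
        reps = 500
        rng = np.random.default_rng(2024)
        for _ in range(reps):
            b = rng.normal(size=25)
            m = rng.normal(size=35)
            rejections += compare_groups(b, m).p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [2.0, 3.0])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], ["benign"] * 3 + ["malignant"] * 3)
        assert res.auc == 1.0

    def test_pair_count_oracle_small_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(4, 13)
            y = np.zeros(n, dtype=int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, n).astype(float)  # ties likely
            assert roc_auc(scores, y).auc == pytest.approx(
                pair_count_auc(scores, y), abs=1e-12
            )

    def test_null_distribution_centred(self):
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(1000):
            scores = rng.normal(size=40)
            y = np.array([0] * 20 + [1] * 20)
            aucs.append(roc_auc(scores, y).auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["benign"] * 3)

    def test_ci_clipped_and_ordered(self):
        rng = np.random.default_rng(11)
        res = roc_auc(rng.normal(size=30), rng.integers(0, 2, 30))
        assert 0.0 <= res.ci[0] <= res.auc <= res.ci[1] <= 1.0

    def test_binormal_recovery(self):
        # empirical AUC converges to Phi(dmu / sqrt(s0^2 + s1^2))
        mu, s0, s1 = 1.0, 1.0, 1.5
        theory = stats.norm.cdf(mu / np.hypot(s0, s1))
        rng = np.random.default_rng(13)
        reps = 300
        aucs = np.empty(reps)
        for r in range(reps):
            scores = np.concatenate(
                [rng.normal(0, s0, 55), rng.normal(mu, s1, 96)]
            )
            y = np.array([0] * 55 + [1] * 96)
            aucs[r] = roc_auc(scores, y).auc
        se = aucs.std(ddof=1) / np.sqrt(reps)
        assert abs(aucs.mean() - theory) <= 3 * se


class TestDelongPaired:
    def test_identical_scores_degenerate(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            assert delong_paired_test(s, s, y) == 1.0

    def test_level_under_null(self):
        rng = np.random.default_rng(21)
        reps = 500
        rej = 0
        y = np.array([0] * 25 + [1] * 35)
        for _ in range(reps):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            rej += delong_paired_test(a, b, y) < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_variance_against_bootstrap(self):
        # paired bootstrap oracle for Var(AUC_a - AUC_b) on one seeded set
        rng = np.random.default_rng(31)
        n = 60
        y = np.array([0] * 25 + [1] * 35)
        latent = rng.normal(size=n) + y * 1.0
        a = latent + rng.normal(scale=0.8, size=n)
        b = latent + rng.normal(scale=0.8, size=n)
        _, _, var_delong = _paired_auc_variance(a, b, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            auc_a, auc_b, _ = _paired_auc_variance(a[idx], b[idx], y[idx])
            boots.append(auc_a - auc_b)
        var_boot = np.var(boots, ddof=1)
        assert abs(var_delong - var_boot) / var_boot < 0.15


class TestYoudenCutoff:
    def test_perfect_split(self):
        res = youden_cutoff([1, 2, 3, 4], ["benign", "benign", "malignant", "malignant"])
        assert res.cutoff == 2.5
        assert res.youden_j == 1.0
        assert (res.tp, res.fp, res.tn, res.fn) == (2, 0, 2, 0)

    def test_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(4, 13)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = rng.integers(0, 4, n).astype(float)
            if np.unique(scores).size < 2:
                continue
            res = youden_cutoff(scores, y)
            # brute force over every possible threshold (all midpoints)
            uniq = np.unique(scores)
            best_j = max(
                ((scores >= c) & (y == 1)).sum() / y.sum()
                + ((scores < c) & (y == 0)).sum() / (1 - y).sum()
                - 1.0
                for c in (uniq[:-1] + uniq[1:]) / 2
            )
            assert res.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_tie_resolves_to_lowest_cutoff(self):
        # two thresholds reach J = 0.5; the lower one is reported
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = ["benign", "malignant", "benign", "malignant"]
        res = youden_cutoff(scores, labels)
        assert res.cutoff == 1.5

    def test_all_scores_equal_flagged(self):
        res = youden_cutoff([2.0, 2.0, 2.0], ["benign", "malignant", "malignant"])
        assert not res.informative
        assert res.youden_j == 0.0

    def test_panel_self_consistent(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=40) + np.repeat([0, 1], 20)
        labels = np.repeat(["benign", "malignant"], 20)
        res = youden_cutoff(scores, labels)
        m = res.metrics
        assert m["sensitivity"].numer == res.tp and m["sensitivity"].denom == res.tp + res.fn
        assert m["specificity"].numer == res.tn and m["specificity"].denom == res.tn + res.fp
        assert m["accuracy"].pct == round(
            100 * (res.tp + res.tn) / (res.tp + res.tn + res.fp + res.fn), 2
        )
        assert res.tp + res.fp + res.tn + res.fn == 40


class TestConfusionMetrics:
    def test_all_correct(self):
        m = confusion_metrics(tp=1, fp=0, tn=1, fn=0)
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert m[name].pct == 100.0

    def test_undefined_ppv_reported_missing(self):
        m = confusion_metrics(tp=0, fp=0, tn=1, fn=1)
        assert m["ppv"] is None
        assert m["sensitivity"].pct == 0.0

    def test_clopper_pearson_bounds(self):
        m = confusion_metrics(tp=47, fp=14, tn=41, fn=49)
        s = m["sensitivity"]
        assert s.ci[0] < s.pct < s.ci[1]
        # exact interval from the beta quantiles, computed independently
        lo = stats.beta.ppf(0.025, 47, 96 - 47 + 1) * 100
        hi = stats.beta.ppf(0.975, 47 + 1, 96 - 47) * 100
        assert s.ci == (round(lo, 2), round(hi, 2))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 1)


class TestPairedDurationTests:
    @staticmethod
    def records_from_matrix(x, labels=None, group="malignant"):
        n, d = x.shape
        rows = []
        for i in range(n):
            for j in range(d):
                rows.append(
                    {
                        "lesion_id": f"L{i}",
                        "label": group,
                        "duration_label": f"SD{j}",
                        "duration_s": 40.5 + 13.5 * j,
                        "ms": x[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_durations_give_p_one(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=10)
        x = np.column_stack([col, col, col + rng.normal(size=10)])
        rec = self.records_from_matrix(x)
        res = paired_duration_tests(rec, "ms", "malignant")
        assert res.p_adj.loc["SD0", "SD1"] == 1.0

    def test_paired_t_matches_hand_formula(self):
        # five lesions, two durations: classic paired t by hand
        a = np.array([0.40, 0.55, 0.48, 0.60, 0.52])
        b = np.array([0.50, 0.61, 0.55, 0.72, 0.57])
        x = np.column_stack([a, b])
        res = paired_duration_tests(self.records_from_matrix(x), "ms", "malignant")
        d = b - a
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(d) - 1)
        assert res.tests.loc["SD0", "SD1"] == "paired-t"
        assert res.p_raw.loc["SD0", "SD1"] == pytest.approx(p_hand, rel=1e-9)
        assert res.p_adj.loc["SD0", "SD1"] == pytest.approx(min(1.0, p_hand), rel=1e-9)

    def test_bonferroni_properties(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 8))
        res = paired_duration_tests(self.records_from_matrix(x), "ms", "malignant")
        off = ~np.eye(8, dtype=bool)
        raw = res.p_raw.to_numpy()[off]
        adj = res.p_adj.to_numpy()[off]
        assert np.all(adj >= raw - 1e-15)
        assert np.all(adj <= 1.0)
        np.testing.assert_array_equal(res.p_adj.to_numpy(), res.p_adj.to_numpy().T)

    def test_family_wise_error_controlled(self):
        # exchangeable null across 8 durations; FWER of the Bonferroni
        # family stays at or below the nominal level
        rng = np.random.default_rng(77)
        reps = 300
        fw = 0
        for _ in range(reps):
            x = rng.normal(size=(20, 8))
            res = paired_duration_tests(self.records_from_matrix(x), "ms", "malignant")
            off = ~np.eye(8, dtype=bool)
            fw += np.nanmin(res.p_adj.to_numpy()[off]) < 0.05
        rate = fw / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 2 * se

    def test_listwise_exclusion(self):
        x = np.random.default_rng(1).normal(size=(8, 3))
        rec = self.records_from_matrix(x)
        rec.loc[(rec["lesion_id"] == "L0") & (rec["duration_label"] == "SD1"), "ms"] = np.nan
        res = paired_duration_tests(rec, "ms", "malignant")
        assert res.n_excluded == 1 and res.n_lesions == 7


class TestIccAgreement:
    def test_identity(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = icc_agreement(a, a)
        assert res.icc == pytest.approx(1.0)

    def test_shift_penalised_vs_consistency(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        b = a + 1.0  # systematic shift: perfect consistency, poor agreement
        res = icc_agreement(a, b)
        # consistency ICC from the same ANOVA terms
        x = np.column_stack([a, b])
        n, k = x.shape
        grand = x.mean()
        msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
        mse_c = (
            np.sum((x - x.mean(axis=1)[:, None] - x.mean(axis=0)[None, :] + grand) ** 2)
            / ((n - 1) * (k - 1))
        )
        icc_consistency = (msr - mse_c) / (msr + (k - 1) * mse_c)
        assert res.icc < icc_consistency

    def test_worked_table_matches_hand_anova(self):
        # 6 lesions x 2 raters, ANOVA decomposition computed by hand
        a = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        b = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        res = icc_agreement(a, b)
        x = np.column_stack([a, b])
        n, k = 6, 2
        grand = x.mean()
        ssr = k * np.sum((x.mean(axis=1) - grand) ** 2)
        ssc = n * np.sum((x.mean(axis=0) - grand) ** 2)
        sse = np.sum(
            (x - x.mean(axis=1)[:, None] - x.mean(axis=0)[None, :] + grand) ** 2
        )
        msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
        icc_hand = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.icc == pytest.approx(icc_hand, rel=1e-12)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(15)
        a = rng.normal(10, 2, 30)
        b = a + rng.normal(0.3, 0.8, 30)
        res = icc_agreement(a, b)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(30), 2),
                "raters": np.repeat(["A", "B"], 30),
                "ratings": np.concatenate([a, b]),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]  # two-way random, agreement
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci[0] == pytest.approx(row["CI95"][0], abs=0.02)
        assert res.ci[1] == pytest.approx(row["CI95"][1], abs=0.02)

    def test_zero_variance_undefined(self):
        res = icc_agreement(np.full(6, 2.0), np.full(6, 2.0))
        assert np.isnan(res.icc)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            icc_agreement([1, 2], [1, 2])
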