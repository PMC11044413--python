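"""Nonparametric tests, ROC machinery, CV logistic models, DeLong."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from compartdwi import (
    InvalidInputError,
    StratificationError,
    delong_compare,
    fit_diagnostic_model,
    kruskal_wallis,
    mann_whitney,
    roc_single_parameter,
)
from compartdwi.stats import (
    DiagnosticModel,
    MODEL_FEATURES,
    group_comparison_table,
    model_comparison_report,
    roc_table,
)


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
    mu = n1 * len(b) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        u = sum(x > y for x in ga for y in gb) + 0.5 * sum(x == y for x in ga for y in gb)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestKruskalWallis:
    def test_permuted_groups_give_null_result(self, rng):
        vals = rng.normal(size=30)
        groups = [rng.permutation(vals), rng.permutation(vals), rng.permutation(vals)]
        h, p = kruskal_wallis(groups)
        # identical multisets: every group has the same rank sum
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_separated_groups_vs_permutation_oracle(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(5, 1, 10), rng.normal(10, 1, 10)]
        h, p = kruskal_wallis(groups)
        assert p < 0.001
        # permutation null: observed H must exceed every permuted H seen
        pooled = np.concatenate(groups)
        exceed = 0
        for _ in range(2000):
            perm = rng.permutation(pooled)
            h_perm, _ = kruskal_wallis([perm[:10], perm[10:20], perm[20:]])
            if h_perm >= h:
                exceed += 1
        assert exceed / 2000 < 0.001

    def test_two_identical_one_shifted(self, rng):
        g = rng.normal(size=12)
        _, p = kruskal_wallis([g, g.copy(), g + 50])
        assert p < 0.001

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            kruskal_wallis([[1, 2], [3, 4]])
        with pytest.raises(InvalidInputError):
            kruskal_wallis([[1, 2], [3, 4], [5]])


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        a = [1.0, 2.0, 5.0, 7.0]
        res = mann_whitney(a, list(a))
        assert abs(res.z) < 1e-9
        assert not res.significant

    def test_exact_small_sample_vs_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mann_whitney(a, b)
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_exact_matches_enumeration_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(size=5)
        res = mann_whitney(a, b)
        assert res.p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_exact_and_normal_p_agree_for_moderate_n(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=15), rng.normal(size=15)
            res = mann_whitney(a, b)  # exact path (225 pairs, tie-free)
            p_normal = 2 * norm.sf(abs(res.z))
            assert abs(res.p - p_normal) < 0.01

    def test_type_one_error_at_nominal_rate(self):
        """Null rejection rate at alpha=0.0167 within 2 binomial SEs."""
        rng = np.random.default_rng(2024)
        n_sim, rejections = 2000, 0
        for _ in range(n_sim):
            if mann_whitney(rng.normal(size=41), rng.normal(size=116)).significant:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.0167 * (1 - 0.0167) / n_sim)
        assert abs(rate - 0.0167) <= 2 * se

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([1.0], [2.0, 3.0])


class TestROCSingleParameter:
    def test_perfect_separation(self):
        roc = roc_single_parameter([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0
        assert roc.sensitivity == 100.0 and roc.specificity == 100.0

    def test_chance_level_for_independent_labels(self, rng):
        v = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        roc = roc_single_parameter(v, y)
        assert 0.5 <= roc.auc < 0.55  # direction auto-choice keeps auc >= 0.5

    def test_threshold_between_observed_values(self):
        roc = roc_single_parameter([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.direction == "greater"
        assert 2.0 < roc.threshold < 3.0
        assert roc.criterion.startswith(">")

    def test_sign_flip_invariance_of_auc(self, rng):
        v = rng.normal(size=100) + np.repeat([0.0, 1.0], 50)
        y = np.repeat([0, 1], 50)
        fwd = roc_single_parameter(v, y)
        rev = roc_single_parameter(-v, y)
        assert fwd.auc == pytest.approx(rev.auc, abs=1e-12)
        assert fwd.direction == "greater" and rev.direction == "less"
        assert rev.criterion.startswith("<=")
        assert rev.threshold == pytest.approx(-fwd.threshold)

    def test_rank_identity_auc_equals_scaled_u(self, rng):
        """AUC equals U/(n1*n2) from the Mann-Whitney statistic, to 1e-12."""
        for _ in range(50):
            n1, n2 = rng.integers(5, 40, 2)
            pos = rng.normal(1, 1, n1)
            neg = rng.normal(0, 1, n2)
            v = np.concatenate([pos, neg])
            y = np.concatenate([np.ones(n1, int), np.zeros(n2, int)])
            auc = roc_single_parameter(v, y).auc
            u = mann_whitney(pos, neg).u
            expected = max(u, n1 * n2 - u) / (n1 * n2)  # direction auto-choice
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_single_parameter([1.0, 2.0], [1, 1])


class TestDiagnosticModel:
    def _table(self, rng, n=100, signal=0.0):
        half = n // 2
        cls = np.array(["malignant"] * half + ["benign"] * (n - half))
        x = rng.normal(size=n) + signal * (cls == "malignant")
        return pd.DataFrame({"tissue_class": cls, "X": x,
                             "Y": rng.normal(size=n)})

    def test_no_signal_gives_chance_auc(self, rng):
        table = self._table(rng, n=200, signal=0.0)
        res = fit_diagnostic_model(table, ["X", "Y"], ("malignant", "benign"), seed=0)
        assert abs(res.mean_auc - 0.5) < 0.12  # CV noise at n=200

    def test_perfect_separator_gives_auc_one(self, rng):
        table = self._table(rng, n=60, signal=100.0)
        res = fit_diagnostic_model(table, ["X"], ("malignant", "benign"), seed=0)
        assert res.mean_auc == pytest.approx(1.0)

    def test_mean_auc_is_mean_of_fold_aucs(self, small_cohort):
        res = DiagnosticModel.from_dataframe(
            small_cohort, "IVIM", ("malignant", "benign")).fit(5, seed=3)
        assert len(res.fold_aucs) == 5
        assert res.mean_auc == pytest.approx(np.mean(res.fold_aucs))
        assert np.isnan(res.oof_scores).sum() == 0

    def test_hybrid_dominates_adc_on_average(self, small_cohort):
        """The nested IVIM+RSI feature set should not lose to ADC alone on
        average over seeds (same folds per seed)."""
        diffs = []
        for seed in range(8):
            hybrid = DiagnosticModel.from_dataframe(
                small_cohort, "IVIM+RSI", ("malignant", "benign")).fit(5, seed)
            adc = DiagnosticModel.from_dataframe(
                small_cohort, "ADC", ("malignant", "benign")).fit(5, seed)
            diffs.append(hybrid.mean_auc - adc.mean_auc)
        assert np.mean(diffs) >= 0

    def test_stratification_error_when_class_too_small(self, rng):
        table = self._table(rng, n=12)
        with pytest.raises(StratificationError):
            fit_diagnostic_model(table, ["X"], ("malignant", "benign"), folds=5)

    def test_summary_text(self, small_cohort):
        res = DiagnosticModel.from_dataframe(
            small_cohort, "ADC", ("malignant", "benign")).fit(5, seed=0)
        text = res.summary()
        assert "mean AUC" in text and "ADC" in text


class TestDeLong:
    def test_identical_scores(self, rng):
        y = np.repeat([0, 1], 30)
        s = rng.normal(size=60) + y
        auc_a, auc_b, p = delong_compare(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_monotone_transform_invariance(self, rng):
        y = np.repeat([0, 1], 40)
        s = rng.normal(size=80) + 0.8 * y
        auc_a, auc_b, p = delong_compare(s, np.exp(3 * s) + 7, y)
        assert auc_a == pytest.approx(auc_b, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_type_one_error_at_nominal_rate(self):
        rng = np.random.default_rng(99)
        n_sim, rejections = 500, 0
        y = np.repeat([1, 0], [60, 60])
        for _ in range(n_sim):
            _, _, p = delong_compare(rng.normal(size=120), rng.normal(size=120), y)
            if p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 2 * se

    def test_detects_a_clearly_better_score(self, rng):
        y = np.repeat([1, 0], [100, 100])
        good = rng.normal(size=200) + 2.0 * y
        bad = rng.normal(size=200)
        auc_a, auc_b, p = delong_compare(good, bad, y)
        assert auc_a > auc_b
        assert p < 0.001

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            delong_compare([1, 2, 3], [1, 2], [0, 1, 1])


class TestReportBuilders:
    def test_group_comparison_table_columns(self, small_cohort):
        rep = group_comparison_table(small_cohort, ["ADC", "Dt", "F1"])
        assert {"parameter", "H", "p_omnibus", "z_malignant_vs_benign",
                "p_malignant_vs_benign"} <= set(rep.columns)
        # display convention: diffusivities rescaled x1e3
        adc_row = rep.set_index("parameter").loc["ADC"]
        raw = small_cohort.loc[small_cohort.tissue_class == "malignant", "ADC"].mean()
        assert adc_row["malignant_mean"] == pytest.approx(raw * 1e3)

    def test_two_class_table_skips_omnibus(self, small_cohort):
        two = small_cohort[small_cohort.tissue_class != "normal"]
        rep = group_comparison_table(two, ["ADC"])
        assert "H" not in rep.columns
        assert "p_malignant_vs_benign" in rep.columns

    def test_roc_table_rows(self, small_cohort):
        rep = roc_table(small_cohort, ["ADC", "C1"], ("malignant", "benign"))
        assert list(rep["parameter"]) == ["ADC", "C1"]
        assert ((rep["AUC"] >= 0.5) & (rep["AUC"] <= 1.0)).all()
        assert set(rep["direction"]) <= {">", "<="}

    def test_model_comparison_report_schema(self, small_cohort):
        rep = model_comparison_report(small_cohort, ("malignant", "benign"),
                                      folds=5, seed=0,
                                      model_names=["ADC", "IVIM+RSI"])
        assert set(rep["models"]) == {"ADC", "IVIM+RSI"}
        for m in rep["models"].values():
            assert len(m["fold_aucs"]) == 5
            assert m["mean_auc"] == pytest.approx(np.mean(m["fold_aucs"]))
        assert "ADC vs IVIM+RSI" in rep["delong"]
        assert set(MODEL_FEATURES["IVIM+RSI"]) == set(
            MODEL_FEATURES["IVIM"] + MODEL_FEATURES["RSI"])
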