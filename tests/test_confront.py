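"""Cluster-vs-clinical confrontation: matching, metrics, CIs, Fisher, covariates."""

import math
from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

import proteostrat as ps


def fisher_bruteforce(a, b, c, d):
    """Two-sided Fisher p by enumeration of all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestBinaryMetrics:
    def test_published_exacerbation_counts(self):
        m = ps.binary_metrics(8, 5, 2, 19)
        assert m["SE"] == pytest.approx(0.800, abs=5e-4)
        assert m["SP"] == pytest.approx(0.792, abs=5e-4)
        assert m["PPV"] == pytest.approx(0.615, abs=5e-4)
        assert m["NPV"] == pytest.approx(0.905, abs=5e-4)
        assert m["ACC"] == pytest.approx(0.794, abs=5e-4)
        assert m["MCC"] == pytest.approx(0.5547, abs=5e-4)
        assert round(m["MCC"], 2) == 0.55

    def test_published_diagnosis_counts(self):
        m = ps.binary_metrics(16, 8, 8, 2)
        assert m["MCC"] == pytest.approx(-32 / 240)
        assert round(m["MCC"], 2) == -0.13

    def test_zero_denominators_yield_nan_not_exception(self):
        m = ps.binary_metrics(0, 0, 3, 4)
        assert math.isnan(m["PPV"])
        assert not math.isnan(m["ACC"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ps.binary_metrics(-1, 0, 0, 1)

    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           fn=st.integers(0, 30), tn=st.integers(0, 30))
    def test_metric_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = ps.binary_metrics(tp, fp, fn, tn)
        if not math.isnan(m["SE"]):
            assert m["SE"] * (tp + fn) == pytest.approx(tp)
        if not math.isnan(m["SP"]):
            assert m["SP"] * (tn + fp) == pytest.approx(tn)
        assert m["ACC"] * (tp + fp + fn + tn) == pytest.approx(tp + tn)
        if not math.isnan(m["MCC"]):
            assert -1.0 - 1e-12 <= m["MCC"] <= 1.0 + 1e-12

    @given(st.integers(1, 500))
    def test_mcc_equals_pearson_of_binary_vectors(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, size=30)
        pred = rng.integers(0, 2, size=30)
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        mcc = ps.binary_metrics(tp, fp, fn, tn)["MCC"]
        if truth.std() == 0 or pred.std() == 0:
            assert math.isnan(mcc)
        else:
            assert mcc == pytest.approx(np.corrcoef(truth, pred)[0, 1])


class TestWaldCi:
    @pytest.mark.parametrize("p,n,expected", [
        (0.80, 10, 25), (0.67, 24, 19), (0.0, 10, 0), (1.0, 24, 0),
    ])
    def test_examples(self, p, n, expected):
        assert ps.wald_ci_halfwidth(p, n) == expected

    def test_unrounded_value(self):
        assert ps.wald_ci_halfwidth(0.80, 10, rounded=False) == pytest.approx(24.79, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ps.wald_ci_halfwidth(1.2, 10)
        with pytest.raises(ValueError):
            ps.wald_ci_halfwidth(0.5, 0)


class TestFisherExact:
    def test_published_diagnosis_table(self):
        assert ps.fisher_exact_2x2(8, 2, 16, 8) == pytest.approx(0.68, abs=0.005)

    def test_diagonal_table(self):
        assert ps.fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_balanced_table_p_one(self):
        assert ps.fisher_exact_2x2(3, 3, 3, 3) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ps.fisher_exact_2x2(0, 0, 0, 0)

    @given(st.integers(0, 1000))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 11, size=4)
        if a + b + c + d == 0:
            return
        assert ps.fisher_exact_2x2(int(a), int(b), int(c), int(d)) == pytest.approx(
            fisher_bruteforce(int(a), int(b), int(c), int(d)), abs=1e-9
        )


class TestBonferroni:
    def test_caps_at_one(self):
        assert ps.bonferroni_adjust([0.68], 2) == [1.0]

    def test_multiplies(self):
        assert ps.bonferroni_adjust([0.004], 2) == [0.008]

    def test_identity_at_m_one(self):
        assert ps.bonferroni_adjust([0.3], 1) == [0.3]

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            ps.bonferroni_adjust([0.1, 0.2], 1)


class TestMatching:
    def test_accuracy_maximising_beats_majority_on_diagnosis_layout(self, diagnosis_table2):
        labels, ann = diagnosis_table2
        r = ps.match_clusters_to_classes(labels, ann, "SCOPD")
        # both clusters are SCOPD-majority; accuracy maximisation puts A positive
        assert r.predicted_positive_clusters == ("A",)
        assert (r.tp, r.fp, r.fn, r.tn) == (16, 8, 8, 2)

    def test_exacerbation_layout_counts(self, exacerbation_table4):
        labels, ann = exacerbation_table4
        r = ps.match_clusters_to_classes(labels, ann, "AECOPD")
        assert r.predicted_positive_clusters == ("A",)
        assert (r.tp, r.fp, r.fn, r.tn) == (8, 5, 2, 19)

    def test_single_cluster_degenerates_to_majority(self):
        labels = pd.Series(["A"] * 10, index=[f"s{i}" for i in range(10)])
        ann = ps.SampleAnnotation(pd.DataFrame(
            {"group": ["X"] * 7 + ["Y"] * 3}, index=labels.index))
        r = ps.match_clusters_to_classes(labels, ann, "Y")
        assert r.metrics["ACC"] == pytest.approx(0.7)

    @given(st.integers(0, 200))
    def test_matching_is_optimal_over_all_assignments(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        n_clusters = rng.integers(2, 5)
        labels = pd.Series(rng.integers(0, n_clusters, size=n),
                           index=[f"s{i}" for i in range(n)])
        groups = np.where(rng.random(n) < 0.5, "X", "Y")
        if len(set(groups)) < 2 or labels.nunique() < 2:
            return
        ann = ps.SampleAnnotation(pd.DataFrame({"group": groups}, index=labels.index))
        r = ps.match_clusters_to_classes(labels, ann, "X")
        ids = sorted(labels.unique())
        best_acc = 0.0
        for rsize in range(1, len(ids)):
            for pos in combinations(ids, rsize):
                pred = labels.isin(pos).to_numpy()
                acc = np.mean(pred == (groups == "X"))
                best_acc = max(best_acc, acc)
        assert r.metrics["ACC"] == pytest.approx(best_acc)

    def test_report_invariant_to_cluster_relabeling(self, exacerbation_table4):
        labels, ann = exacerbation_table4
        r1 = ps.match_clusters_to_classes(labels, ann, "AECOPD")
        swapped = labels.map({"A": "Z", "B": "Q"})
        r2 = ps.match_clusters_to_classes(swapped, ann, "AECOPD")
        assert (r1.tp, r1.fp, r1.fn, r1.tn) == (r2.tp, r2.fp, r2.fn, r2.tn)
        assert r1.metrics == r2.metrics

    def test_one_empty_group_rejected(self):
        labels = pd.Series([0, 1], index=["a", "b"])
        ann = ps.SampleAnnotation(pd.DataFrame({"group": ["X", "X"]},
                                               index=["a", "b"]))
        with pytest.raises(ValueError):
            ps.match_clusters_to_classes(labels, ann, "X")

    def test_per_metric_ci_mode_uses_own_denominators(self, exacerbation_table4):
        labels, ann = exacerbation_table4
        r = ps.match_clusters_to_classes(labels, ann, "AECOPD", ci_mode="per_metric")
        # SP denominator is TN+FP = 24, not the positive-class size 10
        assert r.ci_halfwidths["SP"] == ps.wald_ci_halfwidth(19 / 24, 24)


class TestCompareCovariates:
    def _ann(self, values: dict, index) -> ps.SampleAnnotation:
        df = pd.DataFrame(values, index=index)
        df["group"] = "X"
        return ps.SampleAnnotation(df)

    def test_identical_distributions_give_p_one(self):
        idx = [f"s{i}" for i in range(12)]
        labels = pd.Series([0] * 6 + [1] * 6, index=idx)
        ann = self._ann({"age": [50, 60, 70, 55, 65, 75] * 2}, idx)
        out = ps.compare_covariates(labels, ann, ["age"])
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_shifted_bmi_detected(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(34)]
        labels = pd.Series([0] * 13 + [1] * 21, index=idx)
        bmi = np.concatenate([rng.normal(30, 1, 13), rng.normal(25, 1, 21)])
        ann = self._ann({"bmi": bmi}, idx)
        out = ps.compare_covariates(labels, ann, ["bmi"])
        assert out.loc[0, "p_adjusted"] < 0.05
        assert out.loc[0, "test_used"] in ("student", "welch")

    def test_categorical_uses_fisher(self):
        idx = [f"s{i}" for i in range(34)]
        labels = pd.Series([0] * 13 + [1] * 21, index=idx)
        sex = ["M"] * 6 + ["F"] * 7 + ["M"] * 13 + ["F"] * 8
        ann = self._ann({"sex": sex}, idx)
        out = ps.compare_covariates(labels, ann, ["sex"])
        expected = ps.fisher_exact_2x2(7, 6, 8, 13)  # F counted first alphabetically
        assert out.loc[0, "p_raw"] == pytest.approx(expected)
        assert out.loc[0, "test_used"] == "fisher-exact"

    def test_constant_covariate_notes_p_one(self):
        idx = [f"s{i}" for i in range(8)]
        labels = pd.Series([0] * 4 + [1] * 4, index=idx)
        ann = self._ann({"age": [65.0] * 8}, idx)
        out = ps.compare_covariates(labels, ann, ["age"])
        assert out.loc[0, "p_raw"] == 1.0
        assert "constant" in out.loc[0, "note"]

    def test_adjusted_p_bounds(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(20)]
        labels = pd.Series([0] * 10 + [1] * 10, index=idx)
        ann = self._ann({"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}, idx)
        out = ps.compare_covariates(labels, ann, ["a", "b"])
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_adjusted"] <= 1.0).all()
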