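"""Confrontation of blind clusters with clinical groups.

Clusters are produced without any clinical information; only afterwards
are they matched against the clinical grouping.  Clusters are assigned to
predicted classes by accuracy maximisation (the assignment that best
explains the clinical split), a 2x2 confusion matrix is formed with a
stated positive class, and the standard metric suite is computed:

    SE = TP/(TP+FN)    SP = TN/(TN+FP)    PPV = TP/(TP+FP)
    NPV = TN/(TN+FN)   ACC = (TP+TN)/n
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

CI half-widths are Wald, 100 * 1.96 * sqrt(p(1-p)/n).  Two conventions
for n are supported: ``ci_mode="paper"`` uses the positive-class size for
every metric (the convention that reproduces the published tables);
``ci_mode="per_metric"`` uses each metric's own denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SampleAnnotation

METRIC_NAMES = ("SE", "SP", "PPV", "NPV", "ACC")


def percent_display(value: float, decimals: int = 0) -> float:
    """Proportion -> printed percentage, half-up and double-rounded.

    Rounds the proportion to 3 decimals first and then the percentage to
    ``decimals`` places, both half-up; e.g. 19/21 -> 0.905 -> 90.5 -> 91.
    This is the display convention of the published tables (visible in
    the same tables' NPV and PPV cells).
    """
    if math.isnan(value):
        return float("nan")
    v = math.floor(value * 1000 + 0.5) / 1000
    scale = 10 ** decimals
    return math.floor(v * 100 * scale + 0.5) / scale


@dataclass
class ConfrontationReport:
    """2x2 confrontation of a blind partition with a binary clinical split."""

    positive_class: str
    predicted_positive_clusters: tuple
    tp: int
    fp: int
    fn: int
    tn: int
    metrics: dict[str, float]
    mcc: float
    ci_halfwidths: dict[str, float]
    fisher_p_raw: float
    p_bonferroni: float
    n_comparisons: int
    ci_mode: str = "paper"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            v = self.metrics[name]
            rows.append({
                "metric": name,
                "value_pct": percent_display(v, decimals=1),
                "ci_halfwidth": self.ci_halfwidths.get(name, float("nan")),
            })
        rows.append({"metric": "MCC", "value_pct": round(self.mcc, 2),
                     "ci_halfwidth": float("nan")})
        df = pd.DataFrame(rows)
        df["raw_p"] = self.fisher_p_raw
        df["bonferroni"] = self.p_bonferroni
        return df


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Confusion-matrix metric suite incl. MCC; zero denominators give NaN."""
    for name, v in (("TP", tp), ("FP", fp), ("FN", fn), ("TN", tn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    out = {
        "SE": ratio(tp, tp + fn),
        "SP": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "ACC": (tp + tn) / n,
    }
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["MCC"] = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else float("nan")
    return out


def wald_ci_halfwidth(p_hat: float, n_ref: int, rounded: bool = True) -> float:
    """95% Wald half-width in percentage points: 100 * 1.96 * sqrt(p(1-p)/n)."""
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must be in [0, 1]")
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    hw = 100.0 * 1.96 * math.sqrt(p_hat * (1.0 - p_hat) / n_ref)
    return float(round(hw)) if rounded else hw


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def bonferroni_adjust(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: p -> min(1, p * m); m defaults to len(p)."""
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("family size m smaller than number of p-values")
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in p_values]


def _assignments(cluster_ids: list) -> list[tuple]:
    """Nonempty proper subsets of clusters that may be called predicted-positive."""
    if len(cluster_ids) == 1:
        return [(cluster_ids[0],), ()]
    subsets = chain.from_iterable(
        combinations(cluster_ids, r) for r in range(1, len(cluster_ids))
    )
    return [tuple(s) for s in subsets]


def match_clusters_to_classes(
    labels: pd.Series,
    ann: SampleAnnotation,
    positive_class: str,
    ci_mode: str = "paper",
    n_comparisons: int = 2,
) -> ConfrontationReport:
    """Assign clusters to classes by accuracy maximisation and report metrics.

    Exactly two clinical groups must be present among the labelled samples;
    with more than two clusters, subsets of clusters are assigned to the
    positive class by the same maximisation.  The Fisher p tests the
    cluster x group contingency table; Bonferroni uses ``n_comparisons``
    (default 2: the two confrontation analyses of a full run).
    """
    groups = ann.groups.reindex(labels.index)
    if groups.isna().any():
        raise ValueError("samples without annotation in labels")
    present_groups = sorted(groups.unique())
    if len(present_groups) != 2:
        raise ValueError(f"exactly two clinical groups required, got {present_groups}")
    if positive_class not in present_groups:
        raise ValueError(f"positive class {positive_class!r} not among {present_groups}")
    truth_pos = (groups == positive_class).to_numpy()
    if truth_pos.all() or not truth_pos.any():
        raise ValueError("one clinical group is empty")

    cluster_ids = sorted(labels.unique())
    best = None
    for pos_set in _assignments(cluster_ids):
        pred_pos = labels.isin(pos_set).to_numpy()
        tp = int(np.sum(pred_pos & truth_pos))
        fp = int(np.sum(pred_pos & ~truth_pos))
        fn = int(np.sum(~pred_pos & truth_pos))
        tn = int(np.sum(~pred_pos & ~truth_pos))
        acc = (tp + tn) / len(labels)
        key = (acc, -len(pos_set))
        if best is None or key > best[0]:
            best = (key, pos_set, (tp, fp, fn, tn))
    _, pos_set, (tp, fp, fn, tn) = best

    metrics = binary_metrics(tp, fp, fn, tn)
    mcc = metrics.pop("MCC")

    n_pos = tp + fn
    denominators = {
        "SE": tp + fn, "SP": tn + fp, "PPV": tp + fp, "NPV": tn + fn,
        "ACC": tp + fp + fn + tn,
    }
    ci = {}
    for name in METRIC_NAMES:
        p_hat = metrics[name]
        if math.isnan(p_hat):
            ci[name] = float("nan")
            continue
        n_ref = n_pos if ci_mode == "paper" else denominators[name]
        ci[name] = wald_ci_halfwidth(p_hat, max(n_ref, 1))

    # prediction x clinical-group contingency (= the cluster x group table
    # for two clusters, up to row order, which Fisher's p ignores)
    fisher_p = fisher_exact_2x2(tp, fp, fn, tn)

    return ConfrontationReport(
        positive_class=positive_class,
        predicted_positive_clusters=tuple(pos_set),
        tp=tp, fp=fp, fn=fn, tn=tn,
        metrics=metrics,
        mcc=mcc,
        ci_halfwidths=ci,
        fisher_p_raw=fisher_p,
        p_bonferroni=bonferroni_adjust([fisher_p], n_comparisons)[0],
        n_comparisons=n_comparisons,
        ci_mode=ci_mode,
    )


def compare_covariates(
    labels: pd.Series,
    ann: SampleAnnotation,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Compare clinical covariates between two clusters.

    Continuous covariates: Kolmogorov-Smirnov normality check recorded,
    Levene (center=mean) gates Student vs Welch t-test.  Categorical
    covariates: two-sided Fisher exact on the 2x2 table.  Bonferroni over
    the covariate family.  Returns one row per covariate.
    """
    if covariates is None:
        covariates = ann.covariates
    cluster_ids = sorted(labels.unique())
    if len(cluster_ids) != 2:
        raise ValueError("covariate comparison needs exactly two clusters")
    tab = ann.table.reindex(labels.index)
    in_a = (labels == cluster_ids[0]).to_numpy()

    rows = []
    for cov in covariates:
        col = tab[cov]
        a, b = col[in_a].dropna(), col[~in_a].dropna()
        n_excluded = int(col.isna().sum())
        if pd.api.types.is_numeric_dtype(col):
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and (
                len(a) and len(b) and a.iloc[0] == b.iloc[0]
            ):
                rows.append({
                    "covariate": cov, "type": "continuous", "test_used": "none",
                    "summary_A": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                    "summary_B": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                    "ks_p": float("nan"), "levene_p": float("nan"),
                    "p_raw": 1.0, "n_excluded": n_excluded,
                    "note": "constant in both clusters",
                })
                continue
            pooled = np.concatenate([a, b])
            ks_p = stats.kstest(
                (pooled - pooled.mean()) / (pooled.std(ddof=1) or 1.0), "norm"
            ).pvalue
            lev_p = stats.levene(a, b, center="mean").pvalue
            equal_var = lev_p >= 0.05
            t_res = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append({
                "covariate": cov, "type": "continuous",
                "test_used": "student" if equal_var else "welch",
                "summary_A": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                "summary_B": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                "ks_p": float(ks_p), "levene_p": float(lev_p),
                "p_raw": float(t_res.pvalue), "n_excluded": n_excluded,
                "note": "",
            })
        else:
            levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                rows.append({
                    "covariate": cov, "type": "categorical", "test_used": "none",
                    "summary_A": "", "summary_B": "",
                    "ks_p": float("nan"), "levene_p": float("nan"),
                    "p_raw": 1.0, "n_excluded": n_excluded,
                    "note": "constant in both clusters",
                })
                continue
            if len(levels) > 2:
                raise ValueError(
                    f"categorical covariate {cov!r} has >2 levels; "
                    "Fisher exact supports 2x2 only"
                )
            ref = levels[0]
            t = [
                [int((a == ref).sum()), int((a != ref).sum())],
                [int((b == ref).sum()), int((b != ref).sum())],
            ]
            p = fisher_exact_2x2(t[0][0], t[0][1], t[1][0], t[1][1])
            rows.append({
                "covariate": cov, "type": "categorical", "test_used": "fisher-exact",
                "summary_A": f"{t[0][0]}/{len(a)} {ref}",
                "summary_B": f"{t[1][0]}/{len(b)} {ref}",
                "ks_p": float("nan"), "levene_p": float("nan"),
                "p_raw": float(p), "n_excluded": n_excluded,
                "note": "",
            })
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bonferroni_adjust(df["p_raw"].tolist(), len(covariates))
    return df
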