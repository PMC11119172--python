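"""Differential abundance between two blind clusters.

Runs on the normalised (log2, Ig-unified) but NOT imputed matrix: tests
use detected values only.  Proteins detected in at least 50% of the
samples of each cluster are eligible; Levene's test (center = mean) at
alpha = 0.05 gates Student vs Welch two-sample t-tests; log2 fold change
is the difference of cluster mean log2 intensities (cluster A minus
cluster B); Benjamini-Hochberg converts raw p-values to q-values, and
proteins with q below the threshold are called over-/under-represented in
cluster A by the sign of the fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOG2, QuantMatrix

DAP_COLUMNS = [
    "protein_id", "detect_frac_A", "detect_frac_B", "levene_p",
    "test_used", "log2fc", "p_raw", "q_bh", "call",
]


def detection_filter(
    m: QuantMatrix, labels: pd.Series, min_detect_frac: float = 0.5
) -> tuple[list, list]:
    """Partition proteins into (tested, skipped) by per-cluster detection rate.

    A protein is tested when its present-value fraction is >= 50% in each
    cluster separately (inclusive at the boundary).  Refuses imputed input:
    detection rates are meaningless after imputation.
    """
    m.require(scale=LOG2, imputed=False, stage="detection_filter")
    cluster_ids = sorted(labels.unique())
    if len(cluster_ids) != 2:
        raise ValueError("detection filter needs exactly two clusters")
    cols_a = labels.index[labels == cluster_ids[0]]
    cols_b = labels.index[labels == cluster_ids[1]]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("empty cluster")
    present = m.data.notna()
    frac_a = present[cols_a].mean(axis=1)
    frac_b = present[cols_b].mean(axis=1)
    ok = (frac_a >= min_detect_frac) & (frac_b >= min_detect_frac)
    return list(m.data.index[ok]), list(m.data.index[~ok])


def variance_gate(values_a: np.ndarray, values_b: np.ndarray,
                  alpha: float = 0.05, center: str = "mean") -> tuple[str, float]:
    """Levene gate: p >= alpha -> 'student', p < alpha -> 'welch'.

    Returns (test name, Levene p).  Identical spread (zero Levene
    statistic) selects Student.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 present values per cluster")
    za, zb = np.abs(a - a.mean()), np.abs(b - b.mean())
    if za.std() == 0 and zb.std() == 0:
        # degenerate denominator: statistic is 0 (equal spread) or infinite
        if np.isclose(za.mean(), zb.mean()):
            return "student", 1.0
        return "welch", 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.levene(a, b, center=center).pvalue
    if np.isnan(p):
        return "student", 1.0
    return ("student" if p >= alpha else "welch"), float(p)


def test_protein(values_a: np.ndarray, values_b: np.ndarray,
                 gate: str) -> tuple[float, float]:
    """Gated two-sided t-test and log2 fold change (mean A - mean B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    log2fc = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (1.0 if a.mean() == b.mean() else 0.0), log2fc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=(gate == "student"))
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return p, log2fc


def bh_fdr(p_raw: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_dap(
    m: QuantMatrix,
    labels: pd.Series,
    q_threshold: float = 0.05,
    min_detect_frac: float = 0.5,
    levene_alpha: float = 0.05,
    levene_center: str = "mean",
) -> pd.DataFrame:
    """Full differential-abundance table between two clusters.

    Cluster "A" is the cluster with the smaller sorted label (reported
    first); log2fc and over/under calls are relative to it.  Rows failing
    the detection or minimum-sample gate carry NaN statistics and
    ``test_used`` = 'skipped'.
    """
    tested, skipped = detection_filter(m, labels, min_detect_frac)
    cluster_ids = sorted(labels.unique())
    cols_a = labels.index[labels == cluster_ids[0]]
    cols_b = labels.index[labels == cluster_ids[1]]

    records = []
    skipped_set = set(skipped)
    present = m.data.notna()
    frac_a = present[cols_a].mean(axis=1)
    frac_b = present[cols_b].mean(axis=1)
    for pid in m.data.index:
        rec = {
            "protein_id": pid,
            "detect_frac_A": float(frac_a[pid]),
            "detect_frac_B": float(frac_b[pid]),
            "levene_p": np.nan, "test_used": "skipped",
            "log2fc": np.nan, "p_raw": np.nan, "q_bh": np.nan, "call": "ns",
        }
        if pid in skipped_set:
            records.append(rec)
            continue
        a = m.data.loc[pid, cols_a].dropna().to_numpy()
        b = m.data.loc[pid, cols_b].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rec["test_used"] = "skipped"
            records.append(rec)
            continue
        gate, lev_p = variance_gate(a, b, alpha=levene_alpha, center=levene_center)
        p, log2fc = test_protein(a, b, gate)
        rec.update(levene_p=lev_p, test_used=gate, log2fc=log2fc, p_raw=p)
        records.append(rec)

    df = pd.DataFrame(records, columns=DAP_COLUMNS).set_index("protein_id")
    tested_mask = df["p_raw"].notna()
    if tested_mask.any():
        df.loc[tested_mask, "q_bh"] = bh_fdr(df.loc[tested_mask, "p_raw"].to_numpy())
    sig = tested_mask & (df["q_bh"] < q_threshold)
    df.loc[sig & (df["log2fc"] > 0), "call"] = "over"
    df.loc[sig & (df["log2fc"] < 0), "call"] = "under"
    return df.reset_index()


def call_daps(dap_table: pd.DataFrame, q_threshold: float = 0.05) -> tuple[int, int]:
    """Count (over, under) DAPs at the q threshold, relative to cluster A."""
    tested = dap_table["q_bh"].notna()
    sig = tested & (dap_table["q_bh"] < q_threshold)
    n_over = int((sig & (dap_table["log2fc"] > 0)).sum())
    n_under = int((sig & (dap_table["log2fc"] < 0)).sum())
    return n_over, n_under


def export_dap_annotations(dap_table: pd.DataFrame, mapping_path) -> pd.DataFrame:
    """Join a user-supplied two-column id-mapping table (protein_id\\tname).

    Offline replacement for remote id-mapping services: the caller brings
    the mapping file.  Duplicate keys: first wins with a warning; unmapped
    ids get ``mapped`` = False.  The join is loss-less (row count kept).
    """
    mapping: dict[str, str] = {}
    dupes = 0
    with open(mapping_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{mapping_path}: line {lineno}: expected 2 tab-separated "
                    f"fields, got {len(parts)}"
                )
            key, name = parts
            if key in mapping:
                dupes += 1
                continue
            mapping[key] = name
    if dupes:
        warnings.warn(f"{dupes} duplicate mapping keys ignored (first wins)",
                      stacklevel=2)
    out = dap_table.copy()
    out["mapped_name"] = out["protein_id"].map(mapping)
    out["mapped"] = out["mapped_name"].notna()
    return out
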