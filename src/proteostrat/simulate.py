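"""Synthetic plasma-proteomic cohorts with planted structure.

Generates wide LFQ-style matrices with the statistical features the
downstream analysis assumes: log-normal intensities, a mean-shift group
effect on a subset of proteins (log2 scale), left-censored (MNAR)
missingness at a global intensity quantile, and immunoglobulin rows split
into constant-chain / complete-protein accession codes.  Ground truth
(affected proteins, censored cells, split fractions) is recorded so that
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RAW, IgMapping, QuantMatrix, SampleAnnotation

# suffixes used for split immunoglobulin accession codes
IG_CHAIN_SUFFIX = "_IGC"  # constant-chain code
IG_FULL_SUFFIX = "_IGF"  # complete-protein code


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    The defaults mirror the study design this generator emulates:
    10 healthy controls, 24 stable COPD and 10 exacerbated COPD samples
    over ~350 protein groups, with a log2 mean shift planted in the
    group named by ``effect_group`` (default: last group listed).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CONTROL": 10, "SCOPD": 24, "AECOPD": 10}
    )
    n_proteins: int = 349
    n_affected: int = 0
    effect_log2fc: float = 0.0
    effect_group: str | None = None
    base_mean_log2: float = 20.0
    base_sd_log2: float = 1.0
    group_sd_multiplier: dict[str, float] = field(default_factory=dict)
    censor_quantile: float = 0.0
    censor_prob: float = 0.0
    n_ig_fragments: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group or sum(self.n_per_group.values()) <= 0:
            raise ValueError("cohort needs at least one sample")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("negative group size")
        if self.n_proteins <= 0:
            raise ValueError("cohort needs at least one protein")
        if not (0 <= self.n_affected <= self.n_proteins):
            raise ValueError("n_affected must be in [0, n_proteins]")
        if not (0.0 <= self.censor_quantile <= 1.0):
            raise ValueError("censor_quantile must be in [0, 1]")
        if not (0.0 <= self.censor_prob <= 1.0):
            raise ValueError("censor_prob must be in [0, 1]")
        if not (0 <= self.n_ig_fragments <= self.n_proteins):
            raise ValueError("n_ig_fragments must be in [0, n_proteins]")
        if self.effect_group is None:
            self.effect_group = list(self.n_per_group)[-1]
        if self.effect_group not in self.n_per_group:
            raise ValueError(f"effect_group {self.effect_group!r} not a cohort group")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for exact recovery scoring."""

    affected_protein_ids: set[str] = field(default_factory=set)
    true_group_of_sample: dict[str, str] = field(default_factory=dict)
    censored_cells: set[tuple[str, str]] = field(default_factory=set)


def generate_cohort(spec: CohortSpec) -> tuple[QuantMatrix, SampleAnnotation, TruthRecord]:
    """Draw a complete (no-missingness) raw intensity matrix plus annotation.

    log2-intensity of protein p in sample s is Normal(mu + effect, sd) with
    effect = ``effect_log2fc`` iff p is affected and s belongs to
    ``effect_group``; raw intensity is 2**log2-intensity.
    """
    rng = np.random.default_rng(spec.seed)
    protein_ids = [f"P{i:04d}" for i in range(spec.n_proteins)]
    sample_ids: list[str] = []
    groups: list[str] = []
    for g, n in spec.n_per_group.items():
        for j in range(n):
            sample_ids.append(f"{g}_{j:02d}")
            groups.append(g)

    affected = set(rng.choice(protein_ids, size=spec.n_affected, replace=False).tolist())
    affected_mask = np.array([pid in affected for pid in protein_ids])

    log2 = np.empty((spec.n_proteins, len(sample_ids)))
    for j, g in enumerate(groups):
        sd = spec.base_sd_log2 * spec.group_sd_multiplier.get(g, 1.0)
        col = rng.normal(spec.base_mean_log2, sd, size=spec.n_proteins)
        if g == spec.effect_group:
            col = col + np.where(affected_mask, spec.effect_log2fc, 0.0)
        log2[:, j] = col

    data = pd.DataFrame(np.exp2(log2), index=protein_ids, columns=sample_ids)
    matrix = QuantMatrix(data, scale=RAW)

    ann = pd.DataFrame(
        {
            "group": groups,
            "age": rng.normal(65, 9, size=len(sample_ids)).round(0),
            "sex": rng.choice(["M", "F"], size=len(sample_ids)),
            "bmi": rng.normal(25, 5, size=len(sample_ids)).round(1).clip(15, None),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = TruthRecord(
        affected_protein_ids=affected,
        true_group_of_sample=dict(zip(sample_ids, groups)),
    )
    return matrix, SampleAnnotation(ann), truth


def apply_mnar_missingness(
    m: QuantMatrix, censor_quantile: float, censor_prob: float, seed: int
) -> tuple[QuantMatrix, set[tuple[str, str]]]:
    """Left-censor low intensities: cells below the global ``censor_quantile``
    of all intensities are set missing with probability ``censor_prob``.

    Cells at or above the threshold are never censored, emulating the
    abundance-dependent dropout of label-free MS.  Returns the censored
    cell set exactly.
    """
    if m.missing_mask().to_numpy().any():
        raise ValueError("input matrix already has missing cells")
    if not (0.0 <= censor_quantile <= 1.0 and 0.0 <= censor_prob <= 1.0):
        raise ValueError("censor_quantile and censor_prob must be in [0, 1]")
    vals = m.data.to_numpy()
    if censor_quantile == 0.0 or censor_prob == 0.0:
        return m.with_data(m.data.copy()), set()
    threshold = np.quantile(vals, censor_quantile)
    rng = np.random.default_rng(seed)
    below = vals < threshold
    hit = below & (rng.random(vals.shape) < censor_prob)
    out = vals.copy()
    out[hit] = np.nan
    censored = {
        (m.data.index[i], m.data.columns[j]) for i, j in zip(*np.nonzero(hit))
    }
    return m.with_data(pd.DataFrame(out, index=m.data.index, columns=m.data.columns)), censored


def split_ig_codes(
    m: QuantMatrix, n_ig_fragments: int, seed: int, whole_prob: float = 0.2
) -> tuple[QuantMatrix, IgMapping]:
    """Split selected protein rows into constant-chain / complete-protein codes.

    Each selected row becomes two rows whose raw intensities sum cell-wise
    to the original (split fraction ~ Uniform(0.2, 0.8) per cell; with
    probability ``whole_prob`` the whole value goes to one code and the
    other is missing).  The returned mapping sends both codes back to the
    original id, so unification is an exact inverse.
    """
    m.require(scale=RAW, stage="split_ig_codes")
    if n_ig_fragments > m.n_proteins:
        raise ValueError("n_ig_fragments exceeds protein count")
    if n_ig_fragments == 0:
        return m.with_data(m.data.copy()), IgMapping()

    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(m.protein_ids, size=n_ig_fragments, replace=False).tolist())
    rows = []
    index = []
    mapping: dict[str, str] = {}
    for pid in m.protein_ids:
        row = m.data.loc[pid]
        if pid not in chosen:
            rows.append(row.to_numpy())
            index.append(pid)
            continue
        frac = rng.uniform(0.2, 0.8, size=m.n_samples)
        whole = rng.random(m.n_samples) < whole_prob
        whole_to_chain = rng.random(m.n_samples) < 0.5
        v = row.to_numpy()
        # compute the larger fragment first; the complement v - a is then
        # exact (Sterbenz lemma, a >= v/2), so the two codes sum bit-exactly
        # to v and unification is an exact inverse
        big = np.maximum(frac, 1.0 - frac)
        a = big * v
        rest = v - a
        chain = np.where(whole, np.where(whole_to_chain, v, np.nan),
                         np.where(frac >= 0.5, a, rest))
        full = np.where(whole, np.where(whole_to_chain, np.nan, v),
                        np.where(frac >= 0.5, rest, a))
        # original missing cells stay missing in both codes
        chain = np.where(np.isnan(v), np.nan, chain)
        full = np.where(np.isnan(v), np.nan, full)
        c_id, f_id = pid + IG_CHAIN_SUFFIX, pid + IG_FULL_SUFFIX
        rows.extend([chain, full])
        index.extend([c_id, f_id])
        mapping[c_id] = pid
        mapping[f_id] = pid
    data = pd.DataFrame(np.vstack(rows), index=index, columns=m.sample_ids)
    return m.with_data(data, ig_unified=False), IgMapping(mapping)
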