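"""Blind sample stratification by resampling-consensus K-means.

Samples (not proteins) are the clustered objects; each sample's feature
vector is its full log2 proteomic profile.  The cluster number is chosen
by the Monti consensus procedure: for each candidate k, the data are
repeatedly subsampled and clustered, the consensus matrix records how
often each sample pair co-clusters among the resamples drawing both, and
the area under the CDF of consensus values A(k) yields the relative
area increase Delta(k) used to find where adding clusters stops paying.
The final partition comes from average-linkage hierarchical clustering of
the consensus dissimilarity (1 - consensus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation, AgglomerativeClustering, KMeans, MeanShift

from .containers import LOG2, QuantMatrix

ALGORITHMS = ("kmeans", "affinity_propagation", "mean_shift", "ward")


@dataclass
class ClusteringConfig:
    """Knobs of the consensus-clustering stage.

    ``n_restarts`` is the number of random K-means initialisations kept
    best-of for the reference clustering; ``n_restarts_per_resample``
    bounds the restarts inside each consensus resample (the resampling
    already averages over initialisation noise, so a large best-of there
    buys little and costs H-fold).
    """

    k_candidates: tuple[int, ...] = (2, 3, 4)
    n_restarts: int = 5000
    n_resamples: int = 500
    subsample_fraction: float = 0.8
    seed: int = 0
    algorithm: str = "kmeans"
    n_restarts_per_resample: int = 10
    select_method: str = "pac"  # "pac" or "delta"
    delta_threshold: float = 0.1
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    max_lloyd_iter: int = 300
    zscore: bool = False

    def __post_init__(self) -> None:
        if any(k < 2 for k in self.k_candidates):
            raise ValueError("every candidate k must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class ConsensusResult:
    """Everything the consensus run produced, per candidate k."""

    consensus_matrices: dict[int, pd.DataFrame]
    area_table: pd.DataFrame  # columns: k, area_under_cdf, delta_area
    selected_k: int
    final_labels: pd.Series  # sample id -> cluster id (0-based)
    warnings: list[str] = field(default_factory=list)


def _feature_matrix(m: QuantMatrix, zscore: bool = False) -> np.ndarray:
    """Samples-as-rows feature matrix; rejects missing and degenerate input."""
    m.require(scale=LOG2, stage="clustering")
    if m.missing_mask().to_numpy().any():
        raise ValueError("clustering input must be fully imputed (no missing cells)")
    X = m.data.to_numpy().T  # samples x proteins
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant matrix: all samples identical, clustering undefined")
    if zscore:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


def run_kmeans(
    m: QuantMatrix, k: int, n_restarts: int = 5000, seed: int = 0,
    zscore: bool = False, max_iter: int = 300,
) -> pd.Series:
    """Best-of-``n_restarts`` K-means labeling of the samples."""
    X = _feature_matrix(m, zscore=zscore)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds n_samples={X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter,
                random_state=seed % (2**32))
    labels = km.fit_predict(X)
    return pd.Series(labels, index=m.sample_ids, name="cluster")


def consensus_matrix(m: QuantMatrix, k: int, cfg: ClusteringConfig) -> pd.DataFrame:
    """Monti consensus matrix for one candidate k.

    Entry (i, j) = co-clustering count / co-drawing count over
    ``cfg.n_resamples`` subsamples of ``cfg.subsample_fraction`` of the
    samples, drawn without replacement.  Pairs never drawn together get 0
    with a warning; the diagonal is 1 by convention.
    """
    X = _feature_matrix(m, zscore=cfg.zscore)
    n = X.shape[0]
    sub_n = max(1, int(round(cfg.subsample_fraction * n)))
    if sub_n < k:
        raise ValueError(f"subsample of {sub_n} samples is smaller than k={k}")
    rng = np.random.default_rng(cfg.seed)
    co_cluster = np.zeros((n, n))
    co_drawn = np.zeros((n, n))
    for _ in range(cfg.n_resamples):
        idx = rng.choice(n, size=sub_n, replace=False)
        seed_h = int(rng.integers(0, 2**31))
        km = KMeans(n_clusters=k, n_init=cfg.n_restarts_per_resample,
                    max_iter=cfg.max_lloyd_iter, random_state=seed_h)
        labels = km.fit_predict(X[idx])
        ind = np.zeros(n, dtype=bool)
        ind[idx] = True
        co_drawn += np.outer(ind, ind)
        for c in np.unique(labels):
            members = idx[labels == c]
            sel = np.zeros(n, dtype=bool)
            sel[members] = True
            co_cluster += np.outer(sel, sel)
    never = (co_drawn == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pairs never co-drawn; their "
            "consensus is set to 0", stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(co_drawn > 0, co_cluster / np.maximum(co_drawn, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    return pd.DataFrame(M, index=m.sample_ids, columns=m.sample_ids)


def _area_under_cdf(consensus: pd.DataFrame) -> float:
    """Exact area under the empirical CDF of off-diagonal consensus values.

    For a step CDF of values in [0, 1] the area equals 1 - mean(values).
    """
    M = consensus.to_numpy()
    iu = np.triu_indices_from(M, k=1)
    vals = M[iu]
    return float(1.0 - vals.mean())


def _pac(consensus: pd.DataFrame, bounds: tuple[float, float] = (0.1, 0.9)) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus values
    strictly inside ``bounds`` (neither clearly together nor clearly apart)."""
    M = consensus.to_numpy()
    iu = np.triu_indices_from(M, k=1)
    vals = M[iu]
    lo, hi = bounds
    return float(np.mean((vals > lo) & (vals < hi)))


def select_k(
    consensus_per_k: dict[int, pd.DataFrame],
    delta_threshold: float = 0.1,
    method: str = "pac",
    pac_bounds: tuple[float, float] = (0.1, 0.9),
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster number from the per-k consensus matrices.

    Two criteria over the empirical CDF of off-diagonal consensus values
    are computed and reported for every candidate:

    * area under the CDF A(k) and its relative increase
      Delta(k_min) = A(k_min), Delta(k) = (A(k) - A(k-1)) / A(k-1);
    * PAC(k), the proportion of ambiguous (mid-range) consensus values.

    ``method="pac"`` (default) selects the k with minimal PAC — the
    cleanest consensus, 0 when every resample agrees.  ``method="delta"``
    selects the largest k with Delta(k) >= ``delta_threshold``, else the
    argmax of Delta.  Ties favour the smallest k (parsimony).
    """
    if not consensus_per_k:
        raise ValueError("no candidate consensus matrices")
    if method not in ("pac", "delta"):
        raise ValueError(f"unknown selection method {method!r}")
    ks = sorted(consensus_per_k)
    areas = [_area_under_cdf(consensus_per_k[k]) for k in ks]
    pacs = [_pac(consensus_per_k[k], pac_bounds) for k in ks]
    deltas = [areas[0]]
    for i in range(1, len(ks)):
        prev = areas[i - 1]
        deltas.append((areas[i] - prev) / prev if prev > 0 else 0.0)
    deltas = [max(d, 0.0) for d in deltas]  # standard correction: Delta >= 0
    table = pd.DataFrame(
        {"k": ks, "area_under_cdf": areas, "delta_area": deltas, "pac": pacs}
    )
    if method == "pac":
        best = min(pacs)
        selected = min(k for k, p in zip(ks, pacs) if p == best)
    else:
        above = [k for k, d in zip(ks, deltas) if d >= delta_threshold]
        if above:
            selected = max(above)
        else:
            best = max(deltas)
            selected = min(k for k, d in zip(ks, deltas) if d == best)
    return selected, table


def ensemble_partition(consensus: pd.DataFrame, k: int) -> pd.Series:
    """Final ensemble labels: average-linkage tree of (1 - consensus), cut at k."""
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    D = 1.0 - consensus.to_numpy()
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 0..k-1 in order of first appearance for determinism
    order: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in order:
            order[r] = len(order)
        labels.append(order[r])
    return pd.Series(labels, index=consensus.index, name="cluster")


def run_consensus(m: QuantMatrix, cfg: ClusteringConfig) -> ConsensusResult:
    """Full consensus run: matrices per candidate k, k-selection, final labels."""
    caught: list[str] = []
    matrices: dict[int, pd.DataFrame] = {}
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        for k in cfg.k_candidates:
            sub_cfg = ClusteringConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
            matrices[k] = consensus_matrix(m, k, sub_cfg)
        caught.extend(str(w.message) for w in wrec)
    selected, table = select_k(matrices, cfg.delta_threshold,
                               method=cfg.select_method, pac_bounds=cfg.pac_bounds)
    labels = ensemble_partition(matrices[selected], selected)
    return ConsensusResult(
        consensus_matrices=matrices,
        area_table=table,
        selected_k=selected,
        final_labels=labels,
        warnings=caught,
    )


def run_alternative(m: QuantMatrix, algorithm: str, cfg: ClusteringConfig,
                    k: int | None = None) -> pd.Series:
    """Comparison clusterings: affinity propagation, mean shift, Ward.

    Affinity propagation and mean shift choose their own cluster count;
    Ward requires ``k``.  Same label contract as K-means.
    """
    X = _feature_matrix(m, zscore=cfg.zscore)
    try:
        if algorithm == "affinity_propagation":
            model = AffinityPropagation(random_state=cfg.seed % (2**32))
        elif algorithm == "mean_shift":
            from sklearn.cluster import estimate_bandwidth
            bw = estimate_bandwidth(X, quantile=0.5,
                                    random_state=cfg.seed % (2**32))
            model = MeanShift(bandwidth=bw if bw > 0 else None)
        elif algorithm == "ward":
            if k is None:
                raise ValueError("ward requires k")
            model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        elif algorithm == "kmeans":
            return run_kmeans(m, k or 2, cfg.n_restarts, cfg.seed, zscore=cfg.zscore)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        labels = model.fit_predict(X)
    except ValueError:
        raise
    except Exception as exc:  # surface backend failures with the algorithm name
        raise RuntimeError(f"{algorithm} failed: {exc}") from exc
    return pd.Series(labels, index=m.sample_ids, name="cluster")
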