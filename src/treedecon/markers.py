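"""Per-cluster marker-gene selection.

A gene is a marker for a cluster if it is consistently over-expressed in
that cluster against randomly drawn background clusters.  For each target
cluster we repeat ``n_bs`` bootstrap rounds: draw ``n_b`` background
clusters, subsample cells, and run a one-sided Wilcoxon rank-sum test per
gene (target > background).  The aggregated score is the median of
-log10(p) across rounds, zeroed for genes whose median mean-difference is
not positive.  A dynamic per-cluster threshold then comes from DBSCAN
outlier analysis on the 1-D score distribution: the bulk of uninformative
genes forms a dense cluster, and high-score noise points are the marker
candidates, clipped to the configured [N_min, N_max] band.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import DBSCAN

from .reference import SingleCellReference

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
EPS_FLOOR = 1e-6


@dataclass(frozen=True)
class MarkerConfig:
    """Tuning knobs for bootstrap marker selection.

    n_b
        Background clusters drawn per bootstrap round.
    n_bs
        Number of bootstrap rounds.
    n_min, n_max
        Per-cluster marker count bounds (pre-deduplication).
    cells_per_cluster_cap
        Cells subsampled per cluster per round, balancing test sizes.
    dbscan_eps_mads
        DBSCAN eps expressed in units of the median absolute deviation
        of the score distribution.
    dbscan_min_samples
        DBSCAN core-point threshold.
    """

    n_b: int = 4
    n_bs: int = 100
    n_min: int = 28
    n_max: int = 35
    cells_per_cluster_cap: int = 100
    dbscan_eps_mads: float = 3.0
    dbscan_min_samples: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_min > self.n_max:
            raise ValueError("n_min must be <= n_max")
        for name in ("n_b", "n_bs", "n_min", "n_max", "cells_per_cluster_cap",
                     "dbscan_min_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dbscan_eps_mads <= 0:
            raise ValueError("dbscan_eps_mads must be positive")


@dataclass
class MarkerSet:
    """Selected markers per cluster plus the deduplicated assignment.

    ``per_cluster`` holds the raw per-cluster selections (each within the
    [n_min, n_max] band whenever enough positive-score genes existed);
    ``assigned`` resolves genes picked by several clusters to the cluster
    where they scored highest (ties to the lexicographically first
    cluster), which is why the union can fall below K × n_min.
    """

    per_cluster: dict[str, list[tuple[str, float]]]
    config: MarkerConfig
    assigned: dict[str, list[tuple[str, float]]] = field(init=False)

    def __post_init__(self) -> None:
        best: dict[str, tuple[float, str]] = {}
        for cluster in sorted(self.per_cluster):
            for gene, score in self.per_cluster[cluster]:
                key = (-score, cluster)
                if gene not in best or key < best[gene]:
                    best[gene] = key
        assigned: dict[str, list[tuple[str, float]]] = {c: [] for c in sorted(self.per_cluster)}
        for cluster in sorted(self.per_cluster):
            for gene, score in self.per_cluster[cluster]:
                if best[gene][1] == cluster:
                    assigned[cluster].append((gene, score))
        self.assigned = assigned

    @property
    def union(self) -> list[str]:
        seen: list[str] = []
        for cluster in sorted(self.assigned):
            seen.extend(g for g, _ in self.assigned[cluster])
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cluster in sorted(self.per_cluster):
            for rank, (gene, score) in enumerate(self.per_cluster[cluster], start=1):
                rows.append((cluster, rank, gene, score))
        return pd.DataFrame(rows, columns=["cluster", "rank", "gene_id", "score"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: MarkerConfig | None = None) -> "MarkerSet":
        per_cluster: dict[str, list[tuple[str, float]]] = {}
        for cluster, sub in frame.sort_values(["cluster", "rank"]).groupby("cluster"):
            per_cluster[str(cluster)] = [
                (str(g), float(s)) for g, s in zip(sub["gene_id"], sub["score"])
            ]
        return cls(per_cluster=per_cluster, config=config or MarkerConfig())


def _cluster_rng(cfg: MarkerConfig, cluster: str) -> np.random.Generator:
    # label-keyed child stream: deterministic regardless of iteration order
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, zlib.crc32(str(cluster).encode())])
    )


def bootstrap_scores(
    ref: SingleCellReference,
    cluster: str,
    cfg: MarkerConfig,
    cpm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregated over-expression scores of every gene for one cluster.

    Returns a DataFrame indexed by gene with columns ``score`` (median of
    -log10 p over bootstraps, 0 for genes without positive median effect)
    and ``median_diff`` (median target-minus-background mean CPM).
    """
    labels = ref.cluster_labels
    if cluster not in labels:
        raise KeyError(f"unknown cluster {cluster!r}")
    others = [c for c in labels if c != cluster]
    if len(others) < cfg.n_b:
        raise ValueError(
            f"need at least n_b={cfg.n_b} background clusters, have {len(others)}"
        )
    if cpm is None:
        cpm = ref.cpm()

    rng = _cluster_rng(cfg, cluster)
    target_idx = np.flatnonzero(ref.clusters == cluster)
    by_cluster = {c: np.flatnonzero(ref.clusters == c) for c in others}
    cap = cfg.cells_per_cluster_cap

    n_genes = ref.n_genes
    logp = np.empty((cfg.n_bs, n_genes))
    diffs = np.empty((cfg.n_bs, n_genes))
    for b in range(cfg.n_bs):
        bg_labels = rng.choice(len(others), size=cfg.n_b, replace=False)
        t_idx = target_idx
        if len(t_idx) > cap:
            t_idx = rng.choice(t_idx, size=cap, replace=False)
        bg_parts = []
        for j in bg_labels:
            idx = by_cluster[others[j]]
            if len(idx) > cap:
                idx = rng.choice(idx, size=cap, replace=False)
            bg_parts.append(idx)
        bg_idx = np.concatenate(bg_parts)

        x = cpm[t_idx]
        y = cpm[bg_idx]
        res = mannwhitneyu(x, y, alternative="greater", axis=0, method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance (all-tied) genes
        logp[b] = -np.log10(np.maximum(p, P_FLOOR))
        diffs[b] = x.mean(axis=0) - y.mean(axis=0)

    score = np.median(logp, axis=0)
    median_diff = np.median(diffs, axis=0)
    score[median_diff <= 0] = 0.0
    return pd.DataFrame(
        {"score": score, "median_diff": median_diff}, index=ref.gene_ids
    )


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def dbscan_outlier_select(
    scores: pd.DataFrame | pd.Series, cfg: MarkerConfig
) -> list[tuple[str, float]]:
    """Dynamic-threshold marker pick from a per-gene score table.

    DBSCAN runs on the 1-D score values with eps proportional to the MAD
    of the positive scores (most genes score exactly 0, so the all-gene
    MAD would collapse).  The largest density cluster is the background
    score mass; every point above its maximum — isolated noise points as
    well as small high-score clusters — is a marker candidate, then
    clipped into [n_min, n_max].  With fewer than n_min positive-score
    genes, all of them are returned with a warning.
    """
    if isinstance(scores, pd.DataFrame):
        series = scores["score"]
    else:
        series = scores
    if len(series) == 0:
        raise ValueError("empty score table")
    series = series.astype(float)
    # deterministic ordering: descending score, then gene id
    ordered = series.sort_index().sort_values(ascending=False, kind="stable")

    positive = ordered[ordered > 0]
    if len(positive) < cfg.n_min:
        logger.warning(
            "only %d positive-score genes (< n_min=%d); returning all of them",
            len(positive), cfg.n_min,
        )
        return list(positive.items())

    values = series.values
    eps = max(cfg.dbscan_eps_mads * _mad(positive.values), EPS_FLOOR)
    labels = DBSCAN(eps=eps, min_samples=cfg.dbscan_min_samples).fit_predict(
        values.reshape(-1, 1)
    )

    candidates: list[tuple[str, float]] = []
    core_labels = labels[labels >= 0]
    if core_labels.size:
        largest = np.bincount(core_labels).argmax()
        cutoff = values[labels == largest].max()
        outlier_genes = set(series.index[values > cutoff])
        candidates = [(g, s) for g, s in ordered.items() if g in outlier_genes]

    if len(candidates) > cfg.n_max:
        candidates = candidates[: cfg.n_max]
    elif len(candidates) < cfg.n_min:
        have = {g for g, _ in candidates}
        for gene, score in positive.items():
            if len(candidates) >= cfg.n_min:
                break
            if gene not in have:
                candidates.append((gene, score))
                have.add(gene)
        candidates.sort(key=lambda gs: (-gs[1], gs[0]))
    return candidates


def select_all_markers(
    ref: SingleCellReference,
    cfg: MarkerConfig,
    score_tables: dict[str, pd.DataFrame] | None = None,
) -> MarkerSet:
    """Run bootstrap scoring + DBSCAN selection for every cluster.

    ``score_tables`` lets callers reuse previously computed scores (the
    tuning grid varies only [n_min, n_max] for some points).
    """
    labels = ref.cluster_labels
    if cfg.n_b > len(labels) - 1:
        raise ValueError(f"n_b={cfg.n_b} exceeds available background clusters ({len(labels) - 1})")
    cpm = ref.cpm()
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for cluster in labels:
        if score_tables is not None and cluster in score_tables:
            table = score_tables[cluster]
        else:
            table = bootstrap_scores(ref, cluster, cfg, cpm=cpm)
            if score_tables is not None:
                score_tables[cluster] = table
        per_cluster[cluster] = dbscan_outlier_select(table, cfg)
    return MarkerSet(per_cluster=per_cluster, config=cfg)
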