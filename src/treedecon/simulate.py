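"""Synthetic single-cell references and pseudo-bulk mixtures.

The generator emulates the statistical structure the deconvolution method
consumes: a multi-subject, multi-cluster negative-binomial count matrix
with planted cluster-specific markers (fold-elevated in exactly one
cluster), log-normal per-subject effects (cross-subject variation) and
log-normal per-cell noise (cross-cell variation beyond the NB sampling
noise).  Pseudo-bulk mixtures with Dirichlet-distributed known
proportions then serve as ground truth for tuning and validation —
either exact linear combinations of cluster profiles (the noiseless
identity Y = B_full P) or sums of sampled cells, optionally from a
held-out subject to stress cross-subject generalisation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconvolve import (
    BulkExpressionMatrix,
    evaluate_recovery,
    tree_deconvolve,
)
from .markers import MarkerConfig, select_all_markers
from .reference import (
    CPM_SCALE,
    ClusterTree,
    SingleCellReference,
    build_signature,
    cluster_profiles,
    default_synthetic_tree,
    gene_weights,
    group_signature,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for the synthetic single-cell reference.

    Counts are negative binomial with mean
    mu = base_mean * subject_effect * cell_effect * (marker_fold if the
    gene is a planted marker of the cell's cluster else 1) and dispersion
    ``nb_dispersion`` (variance mu + mu^2/dispersion).  Base means are
    log10-uniform over ``base_mean_log_range``; subject and cell effects
    are log-normal with the given standard deviations on the log scale.
    """

    n_genes: int = 2000
    n_clusters: int = 9
    n_subjects: int = 4
    cells_per_cluster_per_subject: int = 40
    markers_per_cluster: int = 30
    marker_fold: float = 8.0
    nb_dispersion: float = 2.0
    base_mean_log_range: tuple[float, float] = (-1.0, 1.5)
    subject_effect_sd: float = 0.25
    cell_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("markers_per_cluster x n_clusters exceeds n_genes")
        for name in ("n_genes", "n_clusters", "n_subjects",
                     "cells_per_cluster_per_subject", "markers_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.subject_effect_sd < 0 or self.cell_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class PseudoBulkDataset:
    """Simulated bulk mixtures with known cell-type composition."""

    bulk: BulkExpressionMatrix
    true_proportions: pd.DataFrame
    mode: str
    seed: int
    params: dict = field(default_factory=dict)


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[SingleCellReference, dict[str, list[str]]]:
    """Draw a synthetic annotated reference plus the planted-marker ledger."""
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    clusters = [f"c{i}" for i in range(cfg.n_clusters)]
    subjects = [f"s{i}" for i in range(cfg.n_subjects)]

    base_mean = 10.0 ** rng.uniform(*cfg.base_mean_log_range, size=cfg.n_genes)
    subject_effect = rng.lognormal(
        mean=0.0, sigma=cfg.subject_effect_sd, size=(cfg.n_subjects, cfg.n_genes)
    )

    marker_idx = rng.choice(
        cfg.n_genes, size=cfg.markers_per_cluster * cfg.n_clusters, replace=False
    )
    planted: dict[str, list[str]] = {}
    fold = np.ones((cfg.n_clusters, cfg.n_genes))
    for ci, cluster in enumerate(clusters):
        idx = marker_idx[ci * cfg.markers_per_cluster : (ci + 1) * cfg.markers_per_cluster]
        fold[ci, idx] = cfg.marker_fold
        planted[cluster] = sorted(genes[idx])

    n_cells = cfg.n_clusters * cfg.n_subjects * cfg.cells_per_cluster_per_subject
    counts = np.empty((n_cells, cfg.n_genes), dtype=np.int64)
    cell_clusters = np.empty(n_cells, dtype=object)
    cell_subjects = np.empty(n_cells, dtype=object)
    row = 0
    for ci, si in itertools.product(range(cfg.n_clusters), range(cfg.n_subjects)):
        n = cfg.cells_per_cluster_per_subject
        mu = base_mean * subject_effect[si] * fold[ci]
        if cfg.cell_noise_sd > 0:
            cell_eff = rng.lognormal(0.0, cfg.cell_noise_sd, size=(n, cfg.n_genes))
        else:
            cell_eff = np.ones((n, cfg.n_genes))
        mu_cells = np.maximum(mu * cell_eff, 1e-12)
        r = cfg.nb_dispersion
        counts[row : row + n] = rng.negative_binomial(r, r / (r + mu_cells))
        cell_clusters[row : row + n] = clusters[ci]
        cell_subjects[row : row + n] = subjects[si]
        row += n

    cell_ids = np.array([f"cell{i:06d}" for i in range(n_cells)], dtype=object)
    ref = SingleCellReference(
        counts=counts,
        gene_ids=genes,
        cell_ids=cell_ids,
        clusters=cell_clusters,
        subjects=cell_subjects,
    )
    return ref, planted


def simulate_pseudobulk(
    ref: SingleCellReference,
    n_samples: int,
    mode: str = "exact-mixture",
    dirichlet_alpha: float | np.ndarray = 1.0,
    cells_per_sample: int = 500,
    seed: int = 0,
    holdout_subject: str | None = None,
) -> PseudoBulkDataset:
    """Build pseudo-bulk samples with Dirichlet(alpha) true proportions.

    exact-mixture: bulk column = sum_k p_k * (cluster k mean CPM profile),
    a noiseless linear identity.  cell-sampling: draw ``cells_per_sample``
    cells (with replacement) at the true cluster frequencies — restricted
    to ``holdout_subject`` when given — sum their counts and CPM-normalise.
    """
    if mode not in ("exact-mixture", "cell-sampling"):
        raise ValueError(f"unknown pseudo-bulk mode {mode!r}")
    clusters = ref.cluster_labels
    k = len(clusters)
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (k,))
    if (alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n_samples).T  # clusters x samples
    sample_ids = [f"pb{j:03d}" for j in range(n_samples)]
    truth = pd.DataFrame(props, index=clusters, columns=sample_ids)

    if mode == "exact-mixture":
        profiles, _, _ = cluster_profiles(ref)
        B_full = profiles.loc[clusters].T  # genes x clusters
        bulk_values = B_full.values @ props
        bulk = pd.DataFrame(bulk_values, index=profiles.columns, columns=sample_ids)
    else:
        if holdout_subject is not None:
            pool_mask = ref.subjects == holdout_subject
            if not pool_mask.any():
                raise ValueError(f"unknown subject {holdout_subject!r}")
        else:
            pool_mask = np.ones(ref.n_cells, dtype=bool)
        counts = ref.counts_dense()
        by_cluster = {
            c: np.flatnonzero(pool_mask & (ref.clusters == c)) for c in clusters
        }
        cols = np.zeros((ref.n_genes, n_samples))
        for j in range(n_samples):
            n_per = rng.multinomial(cells_per_sample, props[:, j])
            for ci, c in enumerate(clusters):
                if n_per[ci] == 0:
                    continue
                pool = by_cluster[c]
                if pool.size == 0:
                    raise ValueError(
                        f"no cells available for cluster {c!r} in the sampling pool"
                    )
                chosen = rng.choice(pool, size=n_per[ci], replace=True)
                cols[:, j] += counts[chosen].sum(axis=0)
        totals = cols.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("pseudo-bulk sample with zero total counts")
        bulk = pd.DataFrame(
            cols * (CPM_SCALE / totals), index=ref.gene_ids, columns=sample_ids
        )

    return PseudoBulkDataset(
        bulk=BulkExpressionMatrix(values=bulk),
        true_proportions=truth,
        mode=mode,
        seed=seed,
        params={
            "dirichlet_alpha": alpha.tolist(),
            "cells_per_sample": cells_per_sample if mode == "cell-sampling" else None,
            "holdout_subject": holdout_subject,
        },
    )


def _run_one(
    ref: SingleCellReference,
    marker_cfg: MarkerConfig,
    dataset: PseudoBulkDataset,
    tree: ClusterTree,
    score_tables: dict | None = None,
):
    markers = select_all_markers(ref, marker_cfg, score_tables=score_tables)
    profiles, subject_profiles, _ = cluster_profiles(ref)
    weights = gene_weights(ref, profiles=profiles, subject_profiles=subject_profiles)
    sig = build_signature(ref, markers, weights=weights, profiles=profiles)
    gsig = group_signature(sig, ref, tree)
    est = tree_deconvolve(dataset.bulk, sig, tree, gsig)
    metrics = evaluate_recovery(est, dataset.true_proportions)
    return markers, sig, est, metrics


def tune_parameters(
    ref: SingleCellReference,
    grid: dict[str, list],
    dataset: PseudoBulkDataset | None = None,
    tree: ClusterTree | None = None,
    base_config: MarkerConfig | None = None,
    n_samples: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate a marker-selection parameter grid on a fixed pseudo-bulk set.

    ``grid`` maps any of {n_b, n_bs, n_min, n_max} to candidate values;
    unlisted parameters come from ``base_config``.  Every grid point runs
    the full pipeline (markers → signature → tree deconvolution) against
    the same pseudo-bulk dataset and is scored by Pearson r, with ties
    broken by smaller residual sum, then smaller (n_bs, n_max).
    Returns the full table and the winning parameter dict.
    """
    allowed = {"n_b", "n_bs", "n_min", "n_max"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty tuning grid")
    base = base_config or MarkerConfig(seed=seed)
    if tree is None:
        tree = default_synthetic_tree(ref.cluster_labels)
    if dataset is None:
        dataset = simulate_pseudobulk(ref, n_samples, mode="exact-mixture", seed=seed)

    names = sorted(grid)
    rows = []
    score_cache: dict[tuple, dict] = {}
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        if params.get("n_min", base.n_min) > params.get("n_max", base.n_max):
            continue
        cfg = replace(base, **params)
        # bootstrap scores depend only on (n_b, n_bs, seed): reuse across bounds
        key = (cfg.n_b, cfg.n_bs, cfg.seed)
        tables = score_cache.setdefault(key, {})
        _, _, _, metrics = _run_one(ref, cfg, dataset, tree, score_tables=tables)
        rows.append(
            {
                "n_b": cfg.n_b,
                "n_bs": cfg.n_bs,
                "n_min": cfg.n_min,
                "n_max": cfg.n_max,
                "pearson_r": metrics.pearson_r,
                "residual_sum": metrics.residual_sum,
                "total_deviance": metrics.total_deviance,
            }
        )
    if not rows:
        raise ValueError("tuning grid contained no valid (n_min <= n_max) points")
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["pearson_r", "residual_sum", "n_bs", "n_max"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    best = ranked.iloc[0].to_dict()
    return table, best
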