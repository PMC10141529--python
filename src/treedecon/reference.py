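"""Single-cell reference handling: CPM normalisation, cluster profiles,
gene reliability weights and signature matrices.

The deconvolution model is Y ≈ B P with Y the bulk expression
(genes × samples), B the signature matrix (marker genes × cell types) and
P the cell-type proportions (cell types × samples).  Everything in this
module works on the linear CPM (counts-per-million) scale: the reference
cells, the cluster profiles that become columns of B, and later the bulk
columns of Y are all normalised identically, which is what makes the
non-negative least-squares fit meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CPM_SCALE = 1e6


def normalize_cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column of a genes × samples matrix to sum to one million.

    Linear (not log) scale; gene order preserved.  Raises ``ValueError``
    naming the offending sample if a column sums to zero.
    """
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative entries")
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [str(matrix.columns[i]) for i in zero[:5]]
        raise ValueError(f"column(s) with zero total counts: {', '.join(names)}")
    out = values * (CPM_SCALE / colsums)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class SingleCellReference:
    """Annotated cell × gene count matrix used as the deconvolution reference.

    Parameters
    ----------
    counts
        Non-negative cells × genes matrix of raw UMI-like counts
        (dense ndarray or scipy sparse).
    gene_ids, cell_ids
        Ordered unique identifiers for columns / rows of ``counts``.
    clusters, subjects
        Per-cell cluster and subject (donor) labels, aligned with
        ``cell_ids``.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    clusters: np.ndarray
    subjects: np.ndarray
    _cpm_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.clusters = np.asarray(self.clusters, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts rows")
        if len(self.clusters) != n_cells or len(self.subjects) != n_cells:
            raise ValueError("cluster/subject labels must cover every cell")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        dense = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if not np.isfinite(dense).all() or (dense < 0).any():
            raise ValueError("counts must be finite and non-negative")
        sizes = pd.Series(self.clusters).value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(f"clusters with fewer than 2 cells: {list(small.index)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cluster_labels(self) -> list[str]:
        return sorted(set(self.clusters))

    @property
    def subject_labels(self) -> list[str]:
        return sorted(set(self.subjects))

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def cpm(self) -> np.ndarray:
        """Per-cell CPM matrix (cells × genes), cached after first call."""
        if self._cpm_cache is None:
            dense = self.counts_dense()
            totals = dense.sum(axis=1)
            if (totals == 0).any():
                bad = [str(c) for c in self.cell_ids[totals == 0][:5]]
                raise ValueError(f"cells with zero total counts: {', '.join(bad)}")
            self._cpm_cache = dense * (CPM_SCALE / totals)[:, None]
        return self._cpm_cache

    def subset_cells(self, mask: np.ndarray) -> "SingleCellReference":
        counts = self.counts[mask] if not sp.issparse(self.counts) else self.counts[mask]
        return SingleCellReference(
            counts=counts,
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[mask],
            clusters=self.clusters[mask],
            subjects=self.subjects[mask],
        )

    @classmethod
    def from_anndata(cls, adata, cluster_key: str = "cluster", subject_key: str = "subject"):
        """Build a reference from an :class:`anndata.AnnData` (cells × genes)."""
        return cls(
            counts=adata.X.copy(),
            gene_ids=np.asarray(adata.var_names),
            cell_ids=np.asarray(adata.obs_names),
            clusters=np.asarray(adata.obs[cluster_key]),
            subjects=np.asarray(adata.obs[subject_key]),
        )

    def to_anndata(self):
        import anndata

        obs = pd.DataFrame(
            {"cluster": self.clusters, "subject": self.subjects},
            index=self.cell_ids.astype(str),
        )
        var = pd.DataFrame(index=self.gene_ids.astype(str))
        return anndata.AnnData(X=self.counts, obs=obs, var=var)


@dataclass
class ClusterTree:
    """Two-level grouping of reference clusters for tree-guided estimation.

    ``groups`` maps group name → ordered list of member cluster labels.
    Groups must partition the cluster label set they are used with.
    """

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        flat: list[str] = []
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            flat.extend(members)
        if len(flat) != len(set(flat)):
            raise ValueError("cluster tree groups overlap")

    @property
    def cluster_labels(self) -> list[str]:
        return [c for members in self.groups.values() for c in members]

    def validate_against(self, cluster_labels: Sequence[str]) -> None:
        tree_set = set(self.cluster_labels)
        ref_set = set(cluster_labels)
        missing = tree_set - ref_set
        if missing:
            raise ValueError(f"tree clusters not in reference: {sorted(missing)}")
        uncovered = ref_set - tree_set
        if uncovered:
            raise ValueError(f"clusters not covered by tree: {sorted(uncovered)}")

    @classmethod
    def singleton(cls, cluster_labels: Sequence[str]) -> "ClusterTree":
        """Trivial tree: every cluster is its own group (flat fit)."""
        return cls(groups={str(c): [str(c)] for c in cluster_labels})


def crc_epithelial_tree() -> ClusterTree:
    """The standard grouping of the nine colorectal epithelial cell types:
    the four consensus molecular subtypes, the undifferentiated crypt
    states, and the mature enterocytes."""
    return ClusterTree(
        groups={
            "tumor_CMS": ["CMS1", "CMS2", "CMS3", "CMS4"],
            "crypt": ["stem-like/TA", "goblet", "intermediate"],
            "enterocytes": ["mature enterocytes 1", "mature enterocytes 2"],
        }
    )


def default_synthetic_tree(cluster_labels: Sequence[str]) -> ClusterTree:
    """Split sorted cluster labels into three contiguous groups.

    Group sizes mirror the 4/3/2 granularity used for the nine-type
    colorectal reference; for other K the sizes are as even as possible
    (larger groups first).
    """
    labels = sorted(str(c) for c in cluster_labels)
    k = len(labels)
    if k < 3:
        return ClusterTree.singleton(labels)
    if k == 9:
        sizes = [4, 3, 2]
    else:
        base, extra = divmod(k, 3)
        sizes = [base + (1 if i < extra else 0) for i in range(3)]
    groups: dict[str, list[str]] = {}
    start = 0
    for i, size in enumerate(sizes):
        groups[f"group{i + 1}"] = labels[start : start + size]
        start += size
    return ClusterTree(groups=groups)


def cluster_profiles(
    ref: SingleCellReference,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Mean CPM profiles per cluster and per (subject, cluster).

    Returns
    -------
    profiles
        clusters × genes DataFrame: pooled mean of per-cell CPM over all
        cells of the cluster.
    subject_profiles
        (subject, cluster) MultiIndex × genes DataFrame, one row per
        subject/cluster combination with at least one cell.
    single_subject
        Cluster labels observed in only one subject (their cross-subject
        variation cannot be estimated).
    """
    cpm = ref.cpm()
    df = pd.DataFrame(cpm, columns=ref.gene_ids)
    df["__cluster"] = ref.clusters
    df["__subject"] = ref.subjects

    profiles = df.groupby("__cluster", sort=True).mean(numeric_only=True)
    profiles.index.name = "cluster"

    subject_profiles = df.groupby(["__subject", "__cluster"], sort=True).mean(
        numeric_only=True
    )
    subject_profiles.index.names = ["subject", "cluster"]

    per_cluster_subjects = (
        subject_profiles.reset_index().groupby("cluster")["subject"].nunique()
    )
    single_subject = sorted(per_cluster_subjects[per_cluster_subjects < 2].index)
    if single_subject:
        logger.warning(
            "clusters observed in a single subject (cross-subject CV set to 0): %s",
            single_subject,
        )
    return profiles, subject_profiles, single_subject


def _nanmean_cols(arr: np.ndarray) -> np.ndarray:
    """Column-wise mean ignoring NaN; all-NaN columns yield NaN silently."""
    mask = ~np.isnan(arr)
    counts = mask.sum(axis=0)
    sums = np.where(mask, arr, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def gene_weights(
    ref: SingleCellReference,
    genes: Sequence[str] | None = None,
    profiles: pd.DataFrame | None = None,
    subject_profiles: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-gene reliability weights from cross-subject and cross-cell variation.

    w_g = 1 / (1 + CV²_subj(g) + CV²_cell(g))

    CV²_subj pools, over clusters seen in ≥2 subjects, the squared
    coefficient of variation of the subject-level cluster-mean CPM;
    CV²_cell pools the within-cluster cell-level squared CV.  Pooling is
    the unweighted mean over clusters with positive mean expression.
    Weights lie in (0, 1]; genes with zero mean everywhere receive the
    minimum observed weight so they never dominate the fit.
    """
    if profiles is None or subject_profiles is None:
        profiles, subject_profiles, _ = cluster_profiles(ref)
    if genes is None:
        genes = list(ref.gene_ids)
    genes = list(genes)
    missing = set(genes) - set(ref.gene_ids)
    if missing:
        raise KeyError(f"genes absent from reference: {sorted(missing)[:5]}")

    cpm = pd.DataFrame(ref.cpm(), columns=ref.gene_ids)[genes]
    cluster_series = pd.Series(ref.clusters, name="cluster")

    grouped = cpm.groupby(cluster_series)
    means = grouped.mean()
    stds = grouped.std(ddof=1).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2_cell_by_cluster = np.where(means.values > 0, (stds.values / means.values) ** 2, np.nan)
    cv2_cell = _nanmean_cols(cv2_cell_by_cluster)

    sp_vals = subject_profiles[genes]
    by_cluster = sp_vals.groupby(level="cluster")
    s_means = by_cluster.mean()
    s_stds = by_cluster.std(ddof=1)
    n_subj = by_cluster.size()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2_subj_by_cluster = np.where(
            (s_means.values > 0) & (n_subj.values[:, None] >= 2),
            (s_stds.fillna(0.0).values / np.where(s_means.values > 0, s_means.values, 1.0)) ** 2,
            np.nan,
        )
    cv2_subj = _nanmean_cols(cv2_subj_by_cluster)

    weights = 1.0 / (1.0 + np.nan_to_num(cv2_subj, nan=0.0) + np.nan_to_num(cv2_cell, nan=0.0))

    total_mean = cpm.mean(axis=0).values
    zero_mask = total_mean == 0
    if zero_mask.any():
        observed = weights[~zero_mask]
        floor = observed.min() if observed.size else 1.0
        weights = np.where(zero_mask, floor, weights)
    weights = np.clip(weights, np.finfo(float).tiny, 1.0)
    return pd.Series(weights, index=genes, name="weight")


@dataclass
class SignatureMatrix:
    """Signature matrix B: marker genes × cell-type columns on CPM scale.

    ``gene_weights`` carries the per-gene reliability weight w_g;
    ``gene_cluster`` records, for each marker row, the cluster it was
    selected for (after cross-cluster deduplication) — the tree-guided
    second stage uses it to restrict rows to each group's own markers.
    """

    values: pd.DataFrame
    gene_weights: pd.Series
    gene_cluster: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ValueError("signature matrix has negative entries")
        if (np.asarray(self.values).sum(axis=1) == 0).any():
            raise ValueError("signature matrix has an all-zero row")
        w = self.gene_weights.reindex(self.values.index)
        if w.isna().any() or (w <= 0).any() or not np.isfinite(w).all():
            raise ValueError("gene weights must be finite and > 0 for every marker")
        self.gene_weights = w

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cluster_labels(self) -> list[str]:
        return list(self.values.columns)


def build_signature(
    ref: SingleCellReference,
    markers: "Mapping[str, Sequence[tuple[str, float]]] | object",
    weights: pd.Series | None = None,
    profiles: pd.DataFrame | None = None,
) -> SignatureMatrix:
    """Restrict cluster CPM profiles to the marker union, attach weights.

    ``markers`` is a MarkerSet (``markers.assigned``) or a plain mapping
    cluster → [(gene, score), ...].  Rows are ordered by selecting cluster
    (cluster label order) then descending score; duplicates across clusters
    appear once.
    """
    assigned = getattr(markers, "assigned", markers)
    subject_profiles = None
    if profiles is None:
        profiles, subject_profiles, _ = cluster_profiles(ref)

    gene_set = set(ref.gene_ids)
    order: list[str] = []
    owner: dict[str, str] = {}
    missing: list[str] = []
    for cluster in sorted(assigned):
        for gene, _score in assigned[cluster]:
            if gene not in gene_set:
                missing.append(gene)
            elif gene not in owner:
                owner[gene] = cluster
                order.append(gene)
    if missing:
        raise KeyError(f"marker genes absent from reference: {sorted(set(missing))[:10]}")
    if not order:
        raise ValueError("empty marker set")

    values = profiles[order].T  # genes × clusters
    values = values.loc[:, sorted(values.columns)]
    if weights is None:
        weights = gene_weights(ref, order, profiles=profiles, subject_profiles=subject_profiles)
    else:
        weights = weights.reindex(order)
    return SignatureMatrix(
        values=values,
        gene_weights=weights,
        gene_cluster=pd.Series(owner).reindex(order),
    )


def group_signature(
    sig: SignatureMatrix, ref: SingleCellReference, tree: ClusterTree
) -> SignatureMatrix:
    """Coarse signature: one column per tree group, the pooled mean CPM
    profile over all cells of the member clusters, on the same marker rows."""
    tree.validate_against(sig.cluster_labels)
    cpm = pd.DataFrame(ref.cpm(), columns=ref.gene_ids)
    cols = {}
    for name, members in tree.groups.items():
        mask = np.isin(ref.clusters, list(members))
        if not mask.any():
            raise ValueError(f"tree group {name!r} matches no reference cells")
        cols[name] = cpm.loc[mask, sig.gene_ids].mean(axis=0).values
    values = pd.DataFrame(cols, index=sig.gene_ids)
    return SignatureMatrix(
        values=values, gene_weights=sig.gene_weights, gene_cluster=sig.gene_cluster
    )
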