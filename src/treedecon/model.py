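"""Model/Results interface tying the pipeline together.

`BulkDeconvolution` is constructed from a bulk matrix and a single-cell
reference (plus an optional cluster tree and marker configuration);
`fit()` runs marker selection, signature construction and tree-guided
weighted NNLS, and returns a `DeconvolutionResults` carrying the
proportion estimates, per-sample diagnostics and the selected markers.
"""

from __future__ import annotations

from dataclasses import asdict

import pandas as pd

from .deconvolve import (
    BulkExpressionMatrix,
    ProportionEstimate,
    RecoveryMetrics,
    evaluate_recovery,
    flat_deconvolve,
    tree_deconvolve,
)
from .markers import MarkerConfig, MarkerSet, select_all_markers
from .reference import (
    ClusterTree,
    SignatureMatrix,
    SingleCellReference,
    build_signature,
    cluster_profiles,
    gene_weights,
    group_signature,
)


class BulkDeconvolution:
    """Reference-based deconvolution of bulk RNA-seq samples.

    Parameters
    ----------
    bulk
        Genes × samples bulk expression (``BulkExpressionMatrix`` or a
        DataFrame, which is wrapped).
    reference
        Annotated single-cell reference with cluster and subject labels.
    tree
        Optional two-level cluster grouping; when omitted the fit is a
        flat (single-level) weighted NNLS.
    marker_config
        Bootstrap marker-selection settings; defaults follow the tuned
        values n_b=4, n_bs=100, bounds [28, 35].
    markers
        Pre-selected MarkerSet, skipping the bootstrap stage.
    """

    def __init__(
        self,
        bulk: BulkExpressionMatrix | pd.DataFrame,
        reference: SingleCellReference,
        tree: ClusterTree | None = None,
        marker_config: MarkerConfig | None = None,
        markers: MarkerSet | None = None,
    ) -> None:
        if isinstance(bulk, pd.DataFrame):
            bulk = BulkExpressionMatrix(values=bulk)
        self.bulk = bulk
        self.reference = reference
        self.tree = tree
        self.marker_config = marker_config or MarkerConfig()
        self.markers = markers

    @classmethod
    def from_files(
        cls,
        bulk_path,
        matrix_path,
        genes_path=None,
        cells_path=None,
        tree_path=None,
        **kwargs,
    ) -> "BulkDeconvolution":
        from . import io

        bulk = io.read_bulk(bulk_path)
        ref = io.read_reference(matrix_path, genes_path, cells_path)
        tree = io.read_tree(tree_path) if tree_path else None
        return cls(bulk, ref, tree=tree, **kwargs)

    def fit(self) -> "DeconvolutionResults":
        ref = self.reference
        markers = self.markers
        if markers is None:
            markers = select_all_markers(ref, self.marker_config)
        profiles, subject_profiles, _ = cluster_profiles(ref)
        weights = gene_weights(ref, profiles=profiles, subject_profiles=subject_profiles)
        sig = build_signature(ref, markers, weights=weights, profiles=profiles)
        if self.tree is not None:
            gsig = group_signature(sig, ref, self.tree)
            est = tree_deconvolve(self.bulk, sig, self.tree, gsig)
        else:
            gsig = None
            est = flat_deconvolve(self.bulk, sig)
        return DeconvolutionResults(
            model=self, estimate=est, markers=markers, signature=sig, group_signature=gsig
        )


class DeconvolutionResults:
    """Fitted proportions with diagnostics and provenance."""

    def __init__(
        self,
        model: BulkDeconvolution,
        estimate: ProportionEstimate,
        markers: MarkerSet,
        signature: SignatureMatrix,
        group_signature: SignatureMatrix | None,
    ) -> None:
        self.model = model
        self.estimate = estimate
        self.markers = markers
        self.signature = signature
        self.group_signature = group_signature

    @property
    def proportions(self) -> pd.DataFrame:
        """Estimated cell-type proportions, clusters × samples."""
        return self.estimate.proportions

    @property
    def residual_ss(self) -> pd.Series:
        return self.estimate.residual_ss

    @property
    def deviance(self) -> pd.Series:
        return self.estimate.deviance

    @property
    def total_deviance(self) -> float:
        return float(self.estimate.deviance.sum())

    def evaluate(self, truth: pd.DataFrame) -> RecoveryMetrics:
        """Score the fit against known proportions (pseudo-bulk truth)."""
        return evaluate_recovery(self.estimate, truth)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        est = self.estimate
        k, m = est.proportions.shape
        cfg = asdict(self.model.marker_config)
        lines = [
            "Bulk RNA-seq deconvolution (tree-guided weighted NNLS)",
            "=" * 58,
            f"samples: {m}    cell types: {k}    markers: {len(self.signature.gene_ids)}",
            f"mode: {est.provenance.get('mode', '?')}    "
            f"marker config: n_b={cfg['n_b']} n_bs={cfg['n_bs']} "
            f"bounds=[{cfg['n_min']},{cfg['n_max']}] seed={cfg['seed']}",
            f"total deviance: {est.deviance.sum():.4g} "
            f"(mean {est.deviance.mean():.4g}/sample)    "
            f"residual SS: {est.residual_ss.sum():.4g}",
            "-" * 58,
            "mean estimated proportions by cell type:",
        ]
        means = est.proportions.mean(axis=1).sort_values(ascending=False)
        for cluster, value in means.items():
            lines.append(f"  {cluster:<28s} {value:8.4f}")
        flagged = est.all_zero[est.all_zero].index.tolist()
        if flagged:
            lines.append(f"all-zero fits flagged: {flagged}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        k, m = self.estimate.proportions.shape
        return f"<DeconvolutionResults: {k} cell types x {m} samples>"
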