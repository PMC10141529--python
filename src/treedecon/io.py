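"""Readers, writers and the batch pipeline entry point.

Formats: bulk matrices as TSV/CSV (gene ids in the first column, sample
ids in the header); single-cell references as Matrix Market cell × gene
triplets with genes.tsv / cells.tsv side files, or a single dense TSV;
cluster trees as YAML or JSON mapping group name → cluster list.  All
writers produce deterministic row/column ordering; every reader/writer
pair round-trips its own output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .deconvolve import BulkExpressionMatrix
from .markers import MarkerConfig, MarkerSet
from .reference import ClusterTree, SingleCellReference

logger = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_bulk(path: str | Path) -> BulkExpressionMatrix:
    """Read a genes × samples bulk matrix from TSV/CSV.

    Duplicate gene rows are collapsed by summation (warned); negative or
    non-numeric entries raise with context.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if frame.empty:
        raise ValueError(f"{path}: empty expression table")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()][0]
        raise ValueError(f"{path}: missing/non-numeric values in column {bad!r}")
    neg = frame.lt(0)
    if neg.any().any():
        gene = frame.index[neg.any(axis=1)][0]
        raise ValueError(f"{path}: negative expression for gene {gene!r}")
    if frame.index.duplicated().any():
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("%s: %d duplicated gene rows collapsed by sum", path, n_dup)
        frame = frame.groupby(level=0, sort=False).sum()
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return BulkExpressionMatrix(values=frame)


def write_bulk(bulk: BulkExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    bulk.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_reference(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> SingleCellReference:
    """Read a single-cell reference.

    Either a Matrix Market cell × gene triplet file plus ``genes_path``
    (one gene id per line or a gene_id column) and ``cells_path`` (TSV
    with cell_id, cluster, subject columns), or a single dense TSV with
    cell_id, cluster, subject, then one column per gene.  Cells present
    in the matrix but missing from the annotation are dropped with a
    logged count; annotation rows without a matrix cell raise.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX reference requires genes_path and cells_path")
        counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
        genes_tab = pd.read_csv(genes_path, sep="\t")
        gene_ids = (
            genes_tab["gene_id"] if "gene_id" in genes_tab else genes_tab.iloc[:, 0]
        ).astype(str).to_numpy()
        cells = pd.read_csv(cells_path, sep="\t", dtype=str)
        for col in ("cell_id", "cluster", "subject"):
            if col not in cells.columns:
                raise ValueError(f"{cells_path}: missing required column {col!r}")
        if len(cells) > counts.shape[0]:
            raise ValueError(
                f"annotation has {len(cells)} cells but matrix has {counts.shape[0]} rows"
            )
        n_drop = counts.shape[0] - len(cells)
        if n_drop:
            logger.warning("%d matrix cells lack annotation rows and were dropped", n_drop)
            counts = counts[: len(cells)]
        return SingleCellReference(
            counts=counts,
            gene_ids=gene_ids,
            cell_ids=cells["cell_id"].to_numpy(dtype=object),
            clusters=cells["cluster"].to_numpy(dtype=object),
            subjects=cells["subject"].to_numpy(dtype=object),
        )
    frame = pd.read_csv(matrix_path, sep=_sep_for(matrix_path))
    for col in ("cell_id", "cluster", "subject"):
        if col not in frame.columns:
            raise ValueError(f"{matrix_path}: missing required column {col!r}")
    gene_cols = [c for c in frame.columns if c not in ("cell_id", "cluster", "subject")]
    return SingleCellReference(
        counts=frame[gene_cols].to_numpy(dtype=float),
        gene_ids=np.array(gene_cols, dtype=object),
        cell_ids=frame["cell_id"].to_numpy(dtype=object),
        clusters=frame["cluster"].to_numpy(dtype=object),
        subjects=frame["subject"].to_numpy(dtype=object),
    )


def write_reference(ref: SingleCellReference, prefix: str | Path) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + cells.tsv under ``prefix`` directory."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix / "matrix.mtx",
        "genes": prefix / "genes.tsv",
        "cells": prefix / "cells.tsv",
    }
    counts = ref.counts if sp.issparse(ref.counts) else sp.coo_matrix(ref.counts)
    scipy.io.mmwrite(paths["matrix"], counts, field="integer")
    pd.DataFrame({"gene_id": ref.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    pd.DataFrame(
        {"cell_id": ref.cell_ids, "cluster": ref.clusters, "subject": ref.subjects}
    ).to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_tree(path: str | Path) -> ClusterTree:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: tree file must map group name -> cluster list")
    return ClusterTree(groups={str(k): [str(c) for c in v] for k, v in data.items()})


def write_tree(tree: ClusterTree, path: str | Path) -> None:
    path = Path(path)
    data = {k: list(v) for k, v in tree.groups.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_markers(markers: MarkerSet, path: str | Path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path, config: MarkerConfig | None = None) -> MarkerSet:
    frame = pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene_id": str})
    return MarkerSet.from_frame(frame, config=config)


def write_proportions(proportions: pd.DataFrame, path: str | Path) -> None:
    proportions.to_csv(path, sep="\t", index_label="cluster")


def read_proportions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cluster")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Paths and settings for a batch pipeline run."""

    bulk_path: Path
    matrix_path: Path
    genes_path: Path | None
    cells_path: Path | None
    tree_path: Path | None
    out_dir: Path
    marker_config: MarkerConfig
    truth_path: Path | None = None

    def __post_init__(self) -> None:
        for name in ("bulk_path", "matrix_path", "genes_path", "cells_path",
                     "tree_path", "truth_path"):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                setattr(self, name, value)
                if not value.exists():
                    raise FileNotFoundError(f"{name}: {value}")
        self.out_dir = Path(self.out_dir)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """markers → signature → deconvolution (→ evaluation) with a manifest.

    Writes proportions.tsv, markers.tsv, diag.json and run_manifest.json
    into ``cfg.out_dir``; partial outputs are removed on failure.
    Idempotent for identical inputs and seed.
    """
    from . import __version__
    from .model import BulkDeconvolution

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "proportions": cfg.out_dir / "proportions.tsv",
        "markers": cfg.out_dir / "markers.tsv",
        "diagnostics": cfg.out_dir / "diag.json",
        "manifest": cfg.out_dir / "run_manifest.json",
    }
    try:
        model = BulkDeconvolution.from_files(
            cfg.bulk_path,
            cfg.matrix_path,
            cfg.genes_path,
            cfg.cells_path,
            cfg.tree_path,
            marker_config=cfg.marker_config,
        )
        results = model.fit()
        write_proportions(results.proportions, outputs["proportions"])
        write_markers(results.markers, outputs["markers"])
        diag = {
            "per_sample": {
                s: {
                    "residual_ss": float(results.residual_ss[s]),
                    "deviance": float(results.deviance[s]),
                    "all_zero": bool(results.estimate.all_zero[s]),
                }
                for s in results.proportions.columns
            },
            "total_deviance": results.total_deviance,
            "n_markers": len(results.signature.gene_ids),
            "provenance": results.estimate.provenance,
        }
        if cfg.truth_path is not None:
            truth = read_proportions(cfg.truth_path)
            metrics = results.evaluate(truth)
            diag["evaluation"] = {
                "pearson_r": metrics.pearson_r,
                "residual_sum": metrics.residual_sum,
                "total_deviance": metrics.total_deviance,
                "mean_deviance_per_sample": metrics.mean_deviance_per_sample,
            }
        outputs["diagnostics"].write_text(json.dumps(diag, indent=2, sort_keys=True) + "\n")

        inputs = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("bulk", cfg.bulk_path),
                ("matrix", cfg.matrix_path),
                ("genes", cfg.genes_path),
                ("cells", cfg.cells_path),
                ("tree", cfg.tree_path),
                ("truth", cfg.truth_path),
            )
            if p is not None
        }
        manifest = {
            "version": __version__,
            "inputs": inputs,
            "marker_config": {
                k: getattr(cfg.marker_config, k)
                for k in ("n_b", "n_bs", "n_min", "n_max", "cells_per_cluster_cap",
                          "dbscan_eps_mads", "dbscan_min_samples", "seed")
            },
            "seed": cfg.marker_config.seed,
        }
        outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise
    return outputs
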