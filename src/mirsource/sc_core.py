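"""Expression-matrix model, I/O, QC filtering and normalization.

The dataset container is an :class:`anndata.AnnData` with raw counts in
``X`` (sparse, cells x genes), per-cell metadata in ``obs`` (cell_type,
cell_subtype, disease_state plus derived total_counts, n_genes_detected,
mito_fraction) and per-gene metadata in ``var`` (is_mito). Normalization
writes a ``normalized`` layer: counts-per-10k library-size scaling
followed by natural log1p, i.e. ``ln(1 + c * 1e4 / total)``. Scaling
(z-scoring) is deliberately not applied before DOR or DEG statistics,
which operate on normalized or binarized values.

QC keeps a cell iff it has at least ``min_genes`` expressed genes, at
least ``min_counts`` total counts, and at most ``max_mito`` mitochondrial
fraction — boundary cells (exactly at a threshold) are kept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MITO_PATTERN = r"^MT-"

META_COLUMNS = ("cell_type", "cell_subtype", "disease_state")


@dataclass
class QCReport:
    """Per-criterion cell-removal bookkeeping (overlaps allowed)."""

    n_cells_in: int
    n_removed_genes_filter: int
    n_removed_counts_filter: int
    n_removed_mito_filter: int
    n_cells_out: int

    def to_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


def annotate_cells(adata: ad.AnnData, mito_pattern: str = MITO_PATTERN) -> ad.AnnData:
    """Compute per-cell totals, detected-gene counts and mitochondrial
    fraction in place (and ``is_mito`` in var); returns the dataset."""
    x = sp.csr_matrix(adata.X)
    pattern = re.compile(mito_pattern)
    is_mito = np.array([bool(pattern.search(g)) for g in adata.var_names])
    adata.var["is_mito"] = is_mito
    total = np.asarray(x.sum(axis=1)).ravel()
    n_det = x.getnnz(axis=1)
    mito = np.asarray(x[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros_like(total)
    adata.obs["total_counts"] = total
    adata.obs["n_genes_detected"] = n_det
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    adata.obs["mito_fraction"] = frac
    return adata


def write_dataset(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts + metadata as Matrix Market (genes x cells) plus
    features.tsv, barcodes.tsv and metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(adata.X).T.astype(int))
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs[list(META_COLUMNS)].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
    mito_pattern: str = MITO_PATTERN,
) -> ad.AnnData:
    """Assemble an AnnData from Matrix Market + sidecar TSVs.

    The matrix on disk is genes x cells (features as rows); it is
    transposed into the cells x genes container. Metadata is joined by
    barcode; a barcode missing from the metadata, duplicated, or an empty
    matrix is a hard error.
    """
    x = sp.csr_matrix(scipy.io.mmread(str(mtx_path))).T
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("empty dataset")
    if x.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"dimension mismatch: matrix {x.shape} vs {len(barcodes)} barcodes x "
            f"{len(features)} features"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode file")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "barcode" not in meta.columns:
        raise ValueError("metadata file must have a 'barcode' column")
    if meta["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in metadata")
    meta = meta.set_index("barcode")
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise ValueError(f"barcodes missing from metadata (e.g. {missing[:5]})")
    obs = meta.loc[barcodes, list(META_COLUMNS)].copy()
    obs.index.name = "barcode"
    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(features, name="symbol")))
    return annotate_cells(adata, mito_pattern)


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 250,
    min_counts: int = 100,
    max_mito: float = 0.25,
) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells.

    A cell is kept iff ``n_genes_detected >= min_genes`` and
    ``total_counts >= min_counts`` and ``mito_fraction <= max_mito``;
    cells exactly at a threshold are kept. Idempotent. If every cell is
    removed a warning is logged and an empty dataset returned.
    """
    if min_genes < 0 or min_counts < 0 or not 0 <= max_mito <= 1:
        raise ValueError("invalid QC thresholds")
    if "n_genes_detected" not in adata.obs:
        annotate_cells(adata)
    fail_genes = adata.obs["n_genes_detected"].to_numpy() < min_genes
    fail_counts = adata.obs["total_counts"].to_numpy() < min_counts
    fail_mito = adata.obs["mito_fraction"].to_numpy() > max_mito
    keep = ~(fail_genes | fail_counts | fail_mito)
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_removed_genes_filter=int(fail_genes.sum()),
        n_removed_counts_filter=int(fail_counts.sum()),
        n_removed_mito_filter=int(fail_mito.sum()),
        n_cells_out=int(keep.sum()),
    )
    if report.n_cells_out == 0:
        logger.warning("QC removed every cell")
    return adata[keep].copy(), report


def normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Add the CP10K + log1p ``normalized`` layer.

    ``normalized[c, g] = ln(1 + counts[c, g] * scale_factor /
    total_counts[c])``. Zeros stay zeros, so the sparsity pattern is
    unchanged and detection (value > 0) is identical on counts and on the
    normalized layer. A zero-total cell is an error (cannot occur after
    QC with positive thresholds).
    """
    x = sp.csr_matrix(adata.X, dtype=float)
    total = np.asarray(x.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("cannot normalize: cell(s) with zero total counts")
    norm = x.multiply(scale_factor / total[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers["normalized"] = norm
    return adata


def merge_subtype_groups(adata: ad.AnnData, level: str = "cell_subtype") -> dict[str, np.ndarray]:
    """Partition cells by a label level into group -> cell-index map.

    ``level`` is ``cell_type`` or ``cell_subtype``; merging at
    ``cell_type`` collapses subtypes. Missing/NaN labels are an error.
    """
    if level not in ("cell_type", "cell_subtype"):
        raise ValueError(f"unknown grouping level {level!r}")
    labels = adata.obs[level]
    if labels.isna().any() or (labels.astype(str) == "").any():
        raise ValueError(f"missing {level} labels")
    values = labels.astype(str).to_numpy()
    return {name: np.flatnonzero(values == name) for name in sorted(set(values))}
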