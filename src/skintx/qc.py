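"""Cell- and gene-level quality control.

Rules applied, with strict inequalities throughout:

* doublets — per sequencing lane, cells whose doublet score exceeds
  median + ``mad_multiplier`` x MAD of that lane's scores are removed
  (MAD is the raw median absolute deviation, no normal-consistency
  scaling);
* mitochondrial content — cells with mito fraction > ``max_mito_frac``;
* library complexity — cells with fewer than ``min_genes_detected``
  detected genes or total counts below ``min_total_counts``;
* gene prevalence — after cell removal, genes detected in fewer than
  ``min_cells_per_gene`` cells are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

__all__ = ["QCParams", "QCReport", "doublet_threshold", "filter_cells", "filter_genes", "run_qc"]


@dataclass
class QCParams:
    max_mito_frac: float = 0.20
    min_genes_detected: int = 400
    min_total_counts: int = 1000
    min_cells_per_gene: int = 3
    mad_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if min(self.max_mito_frac, self.min_genes_detected, self.min_total_counts,
               self.min_cells_per_gene) <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.mad_multiplier < 0:
            raise ValueError("mad_multiplier must be >= 0")


@dataclass
class QCReport:
    n_input_cells: int = 0
    n_retained_cells: int = 0
    n_input_genes: int = 0
    n_retained_genes: int = 0
    excluded_by_rule: dict[str, int] = field(default_factory=dict)
    n_excluded_union: int = 0
    lane_doublet_thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_retained_cells": self.n_retained_cells,
            "n_input_genes": self.n_input_genes,
            "n_retained_genes": self.n_retained_genes,
            "excluded_by_rule": dict(self.excluded_by_rule),
            "n_excluded_union": self.n_excluded_union,
            "lane_doublet_thresholds": dict(self.lane_doublet_thresholds),
        }


def doublet_threshold(scores, mad_multiplier: float = 4.0) -> float:
    """median + mad_multiplier x MAD of one lane's doublet scores.

    MAD is the raw median absolute deviation from the median.  Cells with a
    score strictly greater than the returned threshold are doublets.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("doublet_threshold requires a non-empty score vector")
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    return med + mad_multiplier * mad


def _counts_matrix(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    return X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)


def _mito_fraction(adata: AnnData) -> np.ndarray:
    """Per-cell mito fraction: metadata column if present, else MT- gene share."""
    if "mito_frac" in adata.obs.columns:
        return adata.obs["mito_frac"].to_numpy(dtype=float)
    if "symbol" not in adata.var.columns:
        raise ValueError(
            "missing metadata column 'mito_frac' and no gene symbols to compute it"
        )
    X = _counts_matrix(adata)
    is_mt = adata.var["symbol"].astype(str).str.startswith("MT-").to_numpy()
    total = np.asarray(X.sum(axis=1)).ravel()
    mt = np.asarray(X[:, is_mt].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mt / np.maximum(total, 1), 0.0)
    return frac


def filter_cells(
    adata: AnnData, params: QCParams | None = None, lane_key: str = "lane"
) -> tuple[AnnData, QCReport]:
    """Remove doublets (per lane) and cells failing the mito / complexity rules.

    Boundary behavior is strict exactly as stated: mito fraction > 0.20
    fails, < 400 detected genes fails, total counts < 1,000 fails; a cell
    sitting exactly on every boundary is retained.
    """
    params = params or QCParams()
    report = QCReport(n_input_cells=adata.n_obs, n_input_genes=adata.n_vars)
    if adata.n_obs == 0:
        report.excluded_by_rule = {k: 0 for k in ("doublet", "mito", "min_genes", "min_counts")}
        return adata.copy(), report

    if "doublet_score" not in adata.obs.columns:
        raise ValueError("missing metadata column 'doublet_score'")
    scores = adata.obs["doublet_score"].to_numpy(dtype=float)
    if lane_key in adata.obs.columns:
        lanes = adata.obs[lane_key].astype(str).to_numpy()
    else:
        lanes = np.array(["lane0"] * adata.n_obs)

    is_doublet = np.zeros(adata.n_obs, dtype=bool)
    for lane in pd.unique(lanes):
        in_lane = lanes == lane
        thr = doublet_threshold(scores[in_lane], params.mad_multiplier)
        report.lane_doublet_thresholds[str(lane)] = thr
        is_doublet[in_lane] = scores[in_lane] > thr

    X = _counts_matrix(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = _mito_fraction(adata)

    fail_mito = mito > params.max_mito_frac
    fail_genes = detected < params.min_genes_detected
    fail_counts = total < params.min_total_counts
    report.excluded_by_rule = {
        "doublet": int(is_doublet.sum()),
        "mito": int(fail_mito.sum()),
        "min_genes": int(fail_genes.sum()),
        "min_counts": int(fail_counts.sum()),
    }
    keep = ~(is_doublet | fail_mito | fail_genes | fail_counts)
    report.n_excluded_union = int((~keep).sum())
    report.n_retained_cells = int(keep.sum())
    report.n_retained_genes = adata.n_vars
    for rule, n in report.excluded_by_rule.items():
        logger.info("qc: rule %s excluded %d cells", rule, n)
    return adata[keep].copy(), report


def filter_genes(adata: AnnData, params: QCParams | None = None) -> AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells_per_gene`` cells."""
    params = params or QCParams()
    X = _counts_matrix(adata)
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_cells >= params.min_cells_per_gene
    logger.info("qc: removed %d genes below prevalence threshold", int((~keep).sum()))
    return adata[:, keep].copy()


def run_qc(
    adata: AnnData, params: QCParams | None = None, lane_key: str = "lane"
) -> tuple[AnnData, QCReport]:
    """Doublet + cell rules, then the gene-prevalence rule on the survivors."""
    params = params or QCParams()
    filtered, report = filter_cells(adata, params, lane_key=lane_key)
    filtered = filter_genes(filtered, params)
    report.n_retained_genes = filtered.n_vars
    return filtered, report
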