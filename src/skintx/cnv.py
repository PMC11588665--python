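"""Copy-number inference from expression and malignant-cell calling.

A simplified reference-based scheme: genes are ordered along the genome
(chromosomes 1..22 then X, then start position), log-normalized expression
is centered on a benign reference, clamped, smoothed with a fixed-length
sliding window within each chromosome, and re-centered per cell and per
gene.  Cells whose mean squared smoothed deviation exceeds the reference
mean + k s.d. are called malignant, and malignant cells are partitioned
into clones by average-linkage hierarchical clustering of their CNV
profiles at a correlation cut.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import average, fcluster
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CNVParams",
    "CNVMatrix",
    "MalignancyCall",
    "order_genes",
    "smooth_windows",
    "call_malignant",
    "dominant_clonotype",
    "DominantClonotype",
]

_CHROM_RANK = {str(c): c for c in range(1, 23)}
_CHROM_RANK["X"] = 23


@dataclass
class CNVParams:
    window_genes: int = 101          # odd sliding-window length, in genes
    clamp: float = 3.0               # max |centered log2 expression|
    score_sd_multiplier: float = 3.0  # k in threshold = ref mean + k * sd
    min_genes_per_chromosome: int | None = None  # default: window_genes
    target_sum: float = 1e4          # per-cell total for normalization
    clone_corr_cut: float = 0.5      # clones merge while correlation >= cut

    def __post_init__(self) -> None:
        if self.window_genes < 3 or self.window_genes % 2 == 0:
            raise ValueError("window_genes must be odd and >= 3")
        if self.clamp <= 0:
            raise ValueError("clamp must be positive")
        if self.score_sd_multiplier <= 0:
            raise ValueError("score_sd_multiplier must be positive")
        if self.min_genes_per_chromosome is None:
            self.min_genes_per_chromosome = self.window_genes


@dataclass
class CNVMatrix:
    """Smoothed relative copy-number values (cells x ordered genes)."""

    values: pd.DataFrame             # cells x genes, genomic order, bounded by clamp
    gene_chrom: pd.Series            # chromosome per retained gene
    reference_cells: list[str]
    dropped_chromosomes: list[str] = field(default_factory=list)


@dataclass
class MalignancyCall:
    calls: pd.DataFrame              # barcode: label {malignant, benign}, score, clone
    threshold: float
    reference_cells: list[str]


class DominantClonotype(NamedTuple):
    clonotype: str
    fraction: float
    n_missing: int


def chromosome_rank(chrom) -> int:
    key = str(chrom).removeprefix("chr")
    if key not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome label {chrom!r}")
    return _CHROM_RANK[key]


def order_genes(annotation: pd.DataFrame) -> pd.Index:
    """Sort genes by (chromosome 1..22 then X, start position), stably."""
    ranks = annotation["chrom"].map(chromosome_rank)
    order = np.lexsort(
        (np.arange(len(annotation)), annotation["start"].to_numpy(), ranks.to_numpy())
    )
    return annotation.index[order]


def _log_norm(adata: AnnData, target_sum: float) -> np.ndarray:
    """Per-cell library normalization to target_sum, then log2(x + 1)."""
    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run QC first")
    return np.log2(X / totals * target_sum + 1.0)


def smooth_windows(
    adata: AnnData,
    order: pd.Index,
    reference_cells: Sequence[str],
    params: CNVParams | None = None,
) -> CNVMatrix:
    """Reference-centered sliding-window smoothing along the genome.

    Per cell: (1) library-normalize and log2-transform; (2) subtract each
    gene's reference mean; (3) clamp to +-clamp; (4) sliding mean over
    ``window_genes`` genes within each chromosome (window truncated at
    chromosome ends); (5) subtract the cell's median smoothed value;
    (6) subtract the per-gene mean over smoothed reference cells.
    Chromosomes with fewer than ``min_genes_per_chromosome`` genes are
    dropped with a logged warning.
    """
    params = params or CNVParams()
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference_cells must be non-empty")
    missing = set(reference_cells) - set(adata.obs_names)
    if missing:
        raise ValueError(f"reference cells absent from counts: {sorted(missing)[:5]}")

    adata = adata[:, list(order)]
    chroms = adata.var["chrom"].astype(str).str.removeprefix("chr")
    counts = chroms.value_counts()
    keep_chroms = [c for c in counts.index if counts[c] >= params.min_genes_per_chromosome]
    dropped = sorted(set(counts.index) - set(keep_chroms), key=chromosome_rank)
    for c in dropped:
        logger.warning(
            "cnv: chromosome %s has %d genes (< %d), dropped from CNV analysis",
            c, counts[c], params.min_genes_per_chromosome,
        )
    mask = chroms.isin(keep_chroms).to_numpy()
    adata = adata[:, mask]
    chroms = chroms[mask]

    logX = _log_norm(adata, params.target_sum)
    ref_idx = adata.obs_names.get_indexer(reference_cells)
    centered = logX - logX[ref_idx].mean(axis=0, keepdims=True)
    np.clip(centered, -params.clamp, params.clamp, out=centered)

    smoothed = np.empty_like(centered)
    chrom_arr = chroms.to_numpy()
    for c in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == c)
        block = centered[:, cols]
        # truncated sliding mean: ratio of windowed sums to window populations
        w = params.window_genes
        ones = np.ones(block.shape[1])
        sums = uniform_filter1d(block, size=w, axis=1, mode="constant", cval=0.0) * w
        ns = uniform_filter1d(ones, size=w, mode="constant", cval=0.0) * w
        smoothed[:, cols] = sums / np.round(ns)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    smoothed -= smoothed[ref_idx].mean(axis=0, keepdims=True)
    np.clip(smoothed, -params.clamp, params.clamp, out=smoothed)

    values = pd.DataFrame(smoothed, index=adata.obs_names, columns=adata.var_names)
    return CNVMatrix(
        values=values,
        gene_chrom=pd.Series(chrom_arr, index=adata.var_names),
        reference_cells=reference_cells,
        dropped_chromosomes=dropped,
    )


def call_malignant(cnv: CNVMatrix, params: CNVParams | None = None) -> MalignancyCall:
    """Score cells, threshold on the reference distribution, cluster clones.

    Per-cell score = mean over genes of the squared smoothed CNV value.
    The malignancy threshold is mean + k s.d. of the reference cells'
    scores; reference cells are always labeled benign.  Malignant cells
    are split into clones by average-linkage clustering on 1 - Pearson
    correlation of CNV profiles, cut at correlation ``clone_corr_cut``.
    """
    params = params or CNVParams()
    if len(cnv.reference_cells) < 10:
        raise ValueError("need at least 10 reference cells to estimate the threshold")
    V = cnv.values
    scores = (V.to_numpy() ** 2).mean(axis=1)
    score_s = pd.Series(scores, index=V.index, name="score")
    ref_scores = score_s.loc[cnv.reference_cells]
    threshold = float(ref_scores.mean() + params.score_sd_multiplier * ref_scores.std(ddof=1))

    is_ref = V.index.isin(cnv.reference_cells)
    malignant = (scores > threshold) & ~is_ref

    clone = np.array([""] * len(V), dtype=object)
    mal_idx = np.flatnonzero(malignant)
    if mal_idx.size == 1:
        clone[mal_idx] = "clone1"
    elif mal_idx.size > 1:
        prof = V.to_numpy()[mal_idx]
        corr = np.corrcoef(prof)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = average(squareform(dist, checks=False))
        labels = fcluster(Z, t=1.0 - params.clone_corr_cut, criterion="distance")
        for i, lab in zip(mal_idx, labels):
            clone[i] = f"clone{lab}"

    calls = pd.DataFrame(
        {
            "label": np.where(malignant, "malignant", "benign"),
            "score": scores,
            "clone": clone,
        },
        index=V.index,
    )
    return MalignancyCall(calls=calls, threshold=threshold,
                          reference_cells=list(cnv.reference_cells))


def dominant_clonotype(clonotypes: Sequence[str] | pd.Series) -> DominantClonotype:
    """Modal clonotype and its fraction among clonotyped cells in a group.

    Cells with a missing/empty clonotype are excluded from the denominator;
    their count is reported.  Ties are broken lexicographically.
    """
    s = pd.Series(list(clonotypes), dtype=object)
    missing = s.isna() | (s.astype(str) == "")
    present = s[~missing].astype(str)
    if present.empty:
        raise ValueError("no clonotyped cells in group")
    counts = Counter(present)
    best_n = max(counts.values())
    # lexicographic tie-break: among max-count clonotypes pick the smallest name
    best = min(name for name, n in counts.items() if n == best_n)
    return DominantClonotype(best, best_n / len(present), int(missing.sum()))
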