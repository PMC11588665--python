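"""Intratumor expression programs and cross-tumor metaprograms.

Per tumor, the malignant cells' counts are log-normalized, restricted to
highly variable genes, scaled with the mitochondrial fraction regressed
out, clipped, and factorized by NMF.  Each ranked factor defines a program:
its 30 highest-weight genes plus a per-cell activity score (the factor's
max-normalized cell loadings); low-variability programs (score s.d. below
a floor) are discarded.  Programs from all tumors are then clustered on
pairwise Jaccard similarity of their gene sets, and clusters recurring in
at least two tumors become metaprograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .nmf import NMFResult, nmf_factorize

logger = logging.getLogger(__name__)

__all__ = [
    "ProgramParams",
    "ExpressionProgram",
    "Metaprogram",
    "normalize_per_tumor",
    "select_hvgs",
    "scale_regress",
    "extract_programs",
    "intratumor_programs",
    "jaccard",
    "metaprogram_cluster",
]


@dataclass
class ProgramParams:
    n_hvgs: int = 2000
    nmf_rank: int = 10
    genes_per_program: int = 30
    min_score_sd: float | None = 0.1   # None disables the s.d. filter
    scale_clip: float = 10.0
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nmf_rank < 1:
            raise ValueError("nmf_rank must be >= 1")
        if self.genes_per_program > self.n_hvgs:
            raise ValueError("genes_per_program must not exceed n_hvgs")
        if self.min_score_sd is not None and self.min_score_sd < 0:
            raise ValueError("min_score_sd must be >= 0")


@dataclass
class ExpressionProgram:
    tumor: str
    rank: int                      # 1-based rank of the source NMF factor
    genes: list[str]               # genes_per_program genes, highest weight first
    scores: np.ndarray             # per-cell activity, factor loadings / max
    score_sd: float
    cell_names: list[str] = field(default_factory=list)

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class Metaprogram:
    members: list[ExpressionProgram]
    tumors: list[str]
    consensus: pd.Series           # gene -> recurrence count, descending

    @property
    def n_members(self) -> int:
        return len(self.members)


def _dense(adata_or_matrix) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(adata_or_matrix, AnnData):
        X = adata_or_matrix.X
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        return X.astype(float), list(adata_or_matrix.obs_names), list(adata_or_matrix.var_names)
    if isinstance(adata_or_matrix, pd.DataFrame):
        return (
            adata_or_matrix.to_numpy(dtype=float),
            list(adata_or_matrix.index),
            list(adata_or_matrix.columns),
        )
    X = np.asarray(adata_or_matrix, dtype=float)
    return X, [f"cell{i}" for i in range(X.shape[0])], [f"g{j}" for j in range(X.shape[1])]


def normalize_per_tumor(counts, target_sum: float = 1e4) -> pd.DataFrame:
    """Scale each cell to ``target_sum`` total counts, then ln(x + 1)."""
    X, cells, genes = _dense(counts)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to normalize a tumor")
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        zero = [cells[i] for i in np.flatnonzero(totals.ravel() == 0)]
        raise ValueError(f"cells with zero total counts: {zero[:5]}")
    return pd.DataFrame(np.log1p(X / totals * target_sum), index=cells, columns=genes)


def select_hvgs(normalized: pd.DataFrame, n_hvgs: int = 2000, n_bins: int = 20) -> list[str]:
    """Top genes by binned dispersion of the log-normalized matrix.

    Dispersion = variance / mean, z-scored within 20 equal-width bins of the
    gene mean; constant genes are never selected.  If fewer than ``n_hvgs``
    eligible genes exist, all of them are returned (logged).
    """
    X = normalized.to_numpy(dtype=float)
    means = X.mean(axis=0)
    variances = X.var(axis=0)
    eligible = variances > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, variances / np.maximum(means, 1e-300), 0.0)
    z = np.full(X.shape[1], -np.inf)
    if eligible.any():
        bins = pd.cut(means[eligible], bins=n_bins, labels=False, duplicates="drop")
        d = disp[eligible]
        zi = np.empty_like(d)
        for b in np.unique(bins):
            in_b = bins == b
            mu, sd = d[in_b].mean(), d[in_b].std()
            zi[in_b] = (d[in_b] - mu) / sd if sd > 0 else 0.0
        z[eligible] = zi
    n_eligible = int(eligible.sum())
    if n_eligible < n_hvgs:
        logger.info("select_hvgs: only %d variable genes available (< %d)",
                    n_eligible, n_hvgs)
    order = np.lexsort((normalized.columns.to_numpy(), -z))
    picked = [normalized.columns[i] for i in order[: min(n_hvgs, n_eligible)]]
    return picked


def scale_regress(
    matrix: pd.DataFrame, mito_frac, scale_clip: float = 10.0
) -> pd.DataFrame:
    """Per gene: OLS residuals of expression on mito fraction, z-scored, clipped.

    A constant regressor degenerates to plain centering, so the output then
    equals an ordinary z-score.  Genes with zero residual variance are set
    to 0 (logged).
    """
    m = np.asarray(mito_frac, dtype=float)
    if m.shape[0] != matrix.shape[0]:
        raise ValueError("mito_frac must have one value per cell")
    X = matrix.to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(m), m])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0)
    # zero residual variance up to numerical noise relative to the gene scale
    flat = sd <= 1e-10 * np.maximum(np.abs(X).max(axis=0), 1.0)
    if flat.any():
        logger.info("scale_regress: %d genes with zero residual variance set to 0",
                    int(flat.sum()))
    sd_safe = np.where(flat, 1.0, sd)
    scaled = np.where(flat, 0.0, (resid - resid.mean(axis=0)) / sd_safe)
    np.clip(scaled, -scale_clip, scale_clip, out=scaled)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def extract_programs(
    result: NMFResult,
    gene_names: list[str],
    cell_names: list[str],
    tumor: str,
    params: ProgramParams | None = None,
) -> list[ExpressionProgram]:
    """Turn ranked NMF factors into programs; drop low-variability ones.

    A factor's program is its ``genes_per_program`` highest-weight genes
    (ties broken by gene id), scored per cell by the factor's H row scaled
    to unit maximum; programs whose score s.d. is not above ``min_score_sd``
    are discarded.
    """
    params = params or ProgramParams()
    W, H = result.W, result.H
    if len(gene_names) < params.genes_per_program:
        raise ValueError(
            f"need at least {params.genes_per_program} genes, got {len(gene_names)}"
        )
    names = np.asarray(gene_names)
    programs = []
    for j in range(W.shape[1]):
        order = np.lexsort((names, -W[:, j]))
        top = names[order[: params.genes_per_program]].tolist()
        h = H[j, :].astype(float)
        hmax = h.max()
        scores = h / hmax if hmax > 0 else np.zeros_like(h)
        sd = float(scores.std())
        programs.append(
            ExpressionProgram(
                tumor=tumor, rank=j + 1, genes=top, scores=scores, score_sd=sd,
                cell_names=list(cell_names),
            )
        )
    if params.min_score_sd is not None:
        kept = [p for p in programs if p.score_sd > params.min_score_sd]
        logger.info("extract_programs: %s: %d/%d programs pass the s.d. filter",
                    tumor, len(kept), len(programs))
        return kept
    return programs


def intratumor_programs(
    counts,
    mito_frac,
    tumor: str,
    params: ProgramParams | None = None,
) -> list[ExpressionProgram]:
    """Full per-tumor pipeline on one tumor's malignant cells.

    normalize -> HVG selection -> scale + regress out mito fraction ->
    clip negatives to 0 -> NMF at rank ``nmf_rank`` -> program extraction.
    """
    params = params or ProgramParams()
    norm = normalize_per_tumor(counts)
    hvgs = select_hvgs(norm, params.n_hvgs)
    scaled = scale_regress(norm[hvgs], mito_frac, params.scale_clip)
    A = np.maximum(scaled.to_numpy().T, 0.0)  # genes x cells, negatives -> 0
    result = nmf_factorize(
        A, k=params.nmf_rank, seed=params.seed,
        max_iter=params.nmf_max_iter, tol=params.nmf_tol,
    )
    return extract_programs(result, hvgs, list(scaled.index), tumor, params)


def jaccard(A, B) -> float:
    """|A n B| / |A u B| for two non-empty gene sets."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("jaccard requires non-empty sets")
    return len(A & B) / len(A | B)


def metaprogram_cluster(
    programs: list[ExpressionProgram], j_min: float = 0.25
) -> list[Metaprogram]:
    """Cluster programs across tumors by Jaccard similarity of gene sets.

    Average-linkage hierarchical clustering on distance 1 - Jaccard, cut at
    1 - ``j_min``; clusters spanning at least two distinct tumors become
    metaprograms with consensus genes ranked by recurrence.
    """
    if len(programs) < 2:
        raise ValueError("need at least 2 programs to cluster")
    n = len(programs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - jaccard(programs[i].gene_set,
                                                    programs[j].gene_set)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=1.0 - j_min, criterion="distance")

    metas = []
    for lab in np.unique(labels):
        members = [programs[i] for i in np.flatnonzero(labels == lab)]
        tumors = sorted({p.tumor for p in members})
        if len(tumors) < 2:
            continue
        gene_counts = pd.Series(
            [g for p in members for g in p.genes], dtype=object
        ).value_counts()
        gene_counts = gene_counts.sort_values(ascending=False)
        metas.append(Metaprogram(members=members, tumors=tumors, consensus=gene_counts))
    metas.sort(key=lambda m: (-m.n_members, m.tumors))
    return metas
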