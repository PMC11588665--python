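"""Spot-grid spatial analysis along the depth-to-surface axis.

Debris spots (every connected component except the largest) are removed,
the outermost epidermis spots define the skin surface, and each remaining
spot gets a Euclidean distance to the closest surface spot expressed in
interspot units (100 um on Visium).  Per-spot-normalized cell-type
abundances are then binned by rounded distance into mean +- s.d. depth
profiles.  Co-occurrence microenvironments come from NMF of the spot x
cell-type abundance matrix, with per-cell-type silhouette scores grading
how cleanly each type belongs to its assigned factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.metrics import silhouette_samples

from .nmf import nmf_factorize
from .simulate import SpotGrid

logger = logging.getLogger(__name__)

__all__ = [
    "AxisProfile",
    "Microenvironment",
    "infer_pitch",
    "tissue_mask",
    "surface_spots",
    "distance_to_surface",
    "normalize_abundance",
    "axis_profile",
    "microenv_nmf",
    "microenv_silhouette",
]

ADJACENCY_FACTOR = 1.2  # neighbors = spots within 1.2 x interspot distance


@dataclass
class AxisProfile:
    """Binned depth profiles: one row per (cell type, rounded distance)."""

    table: pd.DataFrame  # cell_type, bin, mean, sd, n, ci_lo, ci_hi, band_lo, band_hi

    def for_type(self, cell_type: str) -> pd.DataFrame:
        return self.table[self.table["cell_type"] == cell_type].reset_index(drop=True)


@dataclass
class Microenvironment:
    """One NMF co-occurrence factorization of the spot x cell-type matrix."""

    n_fact: int
    weights: pd.DataFrame        # cell type x factor, rows sum to 1
    assignment: pd.Series        # cell type -> argmax factor id
    silhouettes: pd.Series | None = None
    degenerate_types: list[str] = field(default_factory=list)  # all-zero abundance


def infer_pitch(positions: pd.DataFrame) -> float:
    """Interspot distance: minimal physical distance between in-tissue spots."""
    pts = positions.loc[positions["in_tissue"] == 1, ["pxl_row", "pxl_col"]].to_numpy(float)
    if len(pts) < 2:
        raise ValueError("need at least 2 in-tissue spots to infer the pitch")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    pitch = float(d[:, 1].min())
    if pitch <= 0:
        raise ValueError("duplicate spot positions; cannot infer pitch")
    return pitch


def _adjacency_components(pts: np.ndarray, radius: float) -> np.ndarray:
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        data = np.ones(len(pairs))
        graph = csr_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = csr_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def tissue_mask(grid: SpotGrid) -> SpotGrid:
    """Keep only the largest connected component of in-tissue spots.

    Connectivity links spots whose centers lie within 1.2 x the interspot
    distance.  A size tie is broken in favor of the component containing
    the lexicographically smallest barcode.
    """
    pos = grid.positions
    in_tissue = pos.index[pos["in_tissue"] == 1]
    if len(in_tissue) == 0:
        raise ValueError("no in-tissue spots")
    pts = pos.loc[in_tissue, ["pxl_row", "pxl_col"]].to_numpy(float)
    pitch = grid.pitch_um or infer_pitch(pos)
    labels = _adjacency_components(pts, ADJACENCY_FACTOR * pitch)
    sizes = np.bincount(labels)
    best = None
    for lab in np.flatnonzero(sizes == sizes.max()):
        min_bc = min(in_tissue[labels == lab])
        if best is None or min_bc < best[1]:
            best = (lab, min_bc)
    keep = in_tissue[labels == best[0]]
    n_removed = len(in_tissue) - len(keep)
    if n_removed:
        logger.info("tissue_mask: removed %d debris spots in %d components",
                    n_removed, sizes.size - 1)
    return grid.subset(list(keep))


def surface_spots(mask: SpotGrid) -> list[str]:
    """Outermost epidermis spots: epidermis-flagged with a missing neighbor.

    A spot's full neighborhood is 4 on a square lattice and 6 on a hexagonal
    one (layout detected from the array coordinates); an epidermis spot with
    fewer in-mask neighbors sits on the grid boundary or borders non-tissue
    and is therefore surface.
    """
    pos = mask.positions
    epi = pos.index[pos["epidermis"].astype(bool)]
    if len(epi) == 0:
        raise ValueError("no epidermis spots flagged")
    pts = pos[["pxl_row", "pxl_col"]].to_numpy(float)
    pitch = mask.pitch_um or infer_pitch(pos)
    tree = cKDTree(pts)
    neighbor_counts = np.array(
        [len(tree.query_ball_point(p, ADJACENCY_FACTOR * pitch)) - 1 for p in pts]
    )
    # hexagonal Visium layouts have constant (row+col) parity; square ones don't
    parity = (pos["array_row"].to_numpy(int) + pos["array_col"].to_numpy(int)) % 2
    full = 6 if len(np.unique(parity)) == 1 and len(pos) > 1 else 4
    counts = pd.Series(neighbor_counts, index=pos.index)
    return [bc for bc in epi if counts[bc] < full]


def distance_to_surface(mask: SpotGrid, surface: list[str]) -> pd.Series:
    """Distance from every spot to the closest surface spot, in interspot units."""
    if not surface:
        raise ValueError("surface spot set is empty")
    pos = mask.positions
    pitch = mask.pitch_um or infer_pitch(pos)
    surf_pts = pos.loc[surface, ["pxl_row", "pxl_col"]].to_numpy(float)
    pts = pos[["pxl_row", "pxl_col"]].to_numpy(float)
    tree = cKDTree(surf_pts)
    d, _ = tree.query(pts, k=1)
    return pd.Series(d / pitch, index=pos.index, name="distance")


def normalize_abundance(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-spot cell-type fractions; zero-total spots are dropped (logged)."""
    totals = abundance.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info("normalize_abundance: dropped %d zero-total spots", int(zero.sum()))
    kept = abundance.loc[~zero]
    return kept.div(kept.sum(axis=1), axis=0)


def _round_half_up(d: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(d, dtype=float) + 0.5).astype(int)


def axis_profile(fractions: pd.DataFrame, distances: pd.Series) -> AxisProfile:
    """Mean +- s.d. of normalized abundance per cell type and rounded distance.

    Bins are round-half-up integers of the distance (d = 1.5 -> bin 2).
    Two uncertainty bands are reported per bin: ci_lo/ci_hi = mean +- 2
    s.d./sqrt(n) (default band) and band_lo/band_hi = mean +- 2 s.d.
    """
    common = fractions.index.intersection(distances.index)
    fr = fractions.loc[common]
    bins = _round_half_up(distances.loc[common].to_numpy())
    rows = []
    for ct in fr.columns:
        vals = fr[ct].to_numpy(float)
        for b in np.unique(bins):
            v = vals[bins == b]
            mean, sd, n = float(v.mean()), float(v.std()), int(v.size)
            sem2 = 2.0 * sd / np.sqrt(n)
            rows.append(
                {
                    "cell_type": ct, "bin": int(b), "mean": mean, "sd": sd, "n": n,
                    "ci_lo": mean - sem2, "ci_hi": mean + sem2,
                    "band_lo": mean - 2.0 * sd, "band_hi": mean + 2.0 * sd,
                }
            )
    return AxisProfile(table=pd.DataFrame(rows))


def microenv_nmf(
    abundance: pd.DataFrame,
    n_fact: int,
    seed: int = 0,
    with_silhouette: bool = True,
) -> Microenvironment:
    """Co-occurrence microenvironments from NMF of spot x cell-type abundance.

    The matrix is factorized (cell types x spots orientation) at rank
    ``n_fact``; each cell type's factor weights are normalized to sum 1 and
    the type is assigned to its argmax factor.  All-zero cell types get
    uniform weights and are flagged.
    """
    A = abundance.to_numpy(dtype=float).T  # cell types x spots
    if A.min() < 0:
        raise ValueError("abundance must be nonnegative")
    if not 2 <= n_fact <= min(A.shape):
        raise ValueError(f"n_fact must lie in [2, {min(A.shape)}], got {n_fact}")
    res = nmf_factorize(A, k=n_fact, seed=seed)
    W = res.W  # cell types x factors
    row_sums = W.sum(axis=1)
    degenerate = [
        str(abundance.columns[i]) for i in np.flatnonzero(row_sums == 0)
    ]
    safe = np.where(row_sums == 0, 1.0, row_sums)
    weights = W / safe[:, None]
    weights[row_sums == 0] = 1.0 / n_fact
    wdf = pd.DataFrame(
        weights,
        index=pd.Index(abundance.columns, name="cell_type"),
        columns=[f"factor{j + 1}" for j in range(n_fact)],
    )
    assignment = pd.Series(
        wdf.columns.to_numpy()[np.argmax(weights, axis=1)], index=wdf.index,
        name="factor",
    )
    sil = None
    if with_silhouette and assignment.nunique() > 1:
        sil = microenv_silhouette(wdf, assignment)
    return Microenvironment(
        n_fact=n_fact, weights=wdf, assignment=assignment, silhouettes=sil,
        degenerate_types=degenerate,
    )


def microenv_range(
    abundance: pd.DataFrame, n_facts, seed: int = 0
) -> dict[int, Microenvironment]:
    """Fit and report every requested factor count (e.g. range(5, 31))."""
    return {k: microenv_nmf(abundance, k, seed=seed) for k in n_facts}


def microenv_silhouette(weights: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    """Silhouette s = (b - a)/max(a, b) per cell type on normalized weights.

    Euclidean distance; a = mean intra-cluster distance, b = min mean
    distance to another cluster; cell types alone in their factor get 0.
    """
    labels = assignment.reindex(weights.index)
    if labels.nunique() < 2:
        raise ValueError("silhouette requires at least 2 assigned factors")
    vals = silhouette_samples(weights.to_numpy(float), labels.to_numpy(object))
    return pd.Series(vals, index=weights.index, name="silhouette")
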