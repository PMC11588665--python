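"""Synthetic cohort and spot-grid generators with planted ground truth.

The generators emulate the statistical structure the downstream stages
assume: per-donor malignant clones carrying contiguous copy-number blocks
and a single dominant TCR clonotype, helper-lineage transcription-factor
skew, shared activity programs recurring across donors, doublet-score and
mitochondrial-fraction outliers, and spot grids with an epidermal surface
layer and depth-dependent cell-type gradients.  Every generated cell and
spot carries a truth record so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CohortConfig",
    "SpotGridConfig",
    "GradientSpec",
    "TruthLabels",
    "SpotGrid",
    "ConfigError",
    "simulate_cohort",
    "simulate_spots",
    "LINEAGE_FACTORS",
]

# helper lineage -> marker transcription factor
LINEAGE_FACTORS = {"TH1": "TBX21", "TH2": "GATA3", "TH17": "RORC"}

CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X"]

N_MITO_GENES = 13  # symbols prefixed "MT-", for the expression-based QC fallback


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class CohortConfig:
    """Study conditions for the synthetic single-cell cohort.

    Defaults are sized so that every chromosome holds more genes than the
    default CNV smoothing window (150 per chromosome vs. 101) and each
    donor's clone is large enough to score recovery.
    """

    n_donors: int = 6
    n_cells_per_donor: int = 400
    n_genes: int = 3450
    stage_split: float = 0.5          # fraction of donors labeled advanced
    clone_fraction: float = 0.5       # malignant fraction of a donor's cells
    # per-donor list of (chromosome, start-gene-index-on-chromosome,
    # length-in-genes, log2-fold); None -> 3 auto-placed blocks of 120 genes
    # at |log2FC| = 1 per donor, on donor-specific chromosomes
    cnv_blocks: list[list[tuple[str, int, int, float]]] | None = None
    lineage_skew: float | Sequence[float] = 0.6  # target TH2 fraction, per donor
    # list of (gene-set size, member-donor indices or "all", activity fraction)
    shared_programs: list[tuple[int, Sequence[int] | str, float]] = field(
        default_factory=lambda: [(30, "all", 0.3)]
    )
    doublet_outlier_fraction: float = 0.05
    mito_high_fraction: float = 0.05
    nb_dispersion: float = 0.3
    seed: int = 0

    # internal effect sizes (held fixed; see docs/methods.md)
    program_fold: float = 8.0      # mean multiplier for active program genes
    lineage_factor_mean: float = 3.0
    lineage_baseline_mean: float = 0.05

    def validate(self) -> None:
        for name in ("n_donors", "n_cells_per_donor", "n_genes"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        for name in (
            "stage_split",
            "clone_fraction",
            "doublet_outlier_fraction",
            "mito_high_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        skews = self.lineage_skews()
        if any(not 0.0 <= s <= 1.0 for s in skews):
            raise ConfigError("lineage_skew values must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.n_genes < 2 * len(CHROMOSOMES):
            raise ConfigError("n_genes too small to populate 23 chromosomes")
        for size, members, frac in self.shared_programs:
            if size <= 0 or size > self.n_genes:
                raise ConfigError("shared_programs gene-set size out of range")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("shared_programs activity fraction must lie in [0, 1]")
            if members != "all":
                if any(d < 0 or d >= self.n_donors for d in members):
                    raise ConfigError("shared_programs member donor index out of range")

    def lineage_skews(self) -> list[float]:
        if np.isscalar(self.lineage_skew):
            return [float(self.lineage_skew)] * self.n_donors
        skews = [float(s) for s in self.lineage_skew]
        if len(skews) != self.n_donors:
            raise ConfigError("lineage_skew sequence length must equal n_donors")
        return skews


@dataclass
class GradientSpec:
    """Planted depth dependence of one cell type's spot abundance.

    kind 'linear': value = max(base - slope * depth, 0)
    kind 'flat':   value = base
    """

    kind: str = "flat"
    base: float = 1.0
    slope: float = 0.0

    def evaluate(self, depth: np.ndarray) -> np.ndarray:
        if self.kind == "flat":
            return np.full_like(np.asarray(depth, dtype=float), self.base)
        if self.kind == "linear":
            return np.maximum(self.base - self.slope * np.asarray(depth, dtype=float), 0.0)
        raise ConfigError(f"unknown gradient kind {self.kind!r}")


@dataclass
class SpotGridConfig:
    """Study conditions for the synthetic spot grid (square lattice, 100 um pitch)."""

    rows: int = 20
    cols: int = 20
    epidermis_depth: int = 2
    cell_types: Sequence[str] = ("Tumor", "Fibroblast", "Bcell", "Keratinocyte")
    gradients: dict[str, GradientSpec] | None = None
    debris_size: int = 0
    noise_sd: float = 0.05
    pitch_um: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ConfigError("rows and cols must be >= 2")
        if self.epidermis_depth < 1 or self.epidermis_depth > self.rows:
            raise ConfigError("epidermis_depth must lie in [1, rows]")
        if self.debris_size < 0:
            raise ConfigError("debris_size must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for ct in (self.gradients or {}):
            if ct not in self.cell_types:
                raise ConfigError(f"gradient references unknown cell type {ct!r}")


@dataclass
class SpotGrid:
    """Spot-level data: positions (Visium tissue-positions dialect) + abundance."""

    positions: pd.DataFrame  # index barcode: in_tissue, array_row, array_col,
    #                          pxl_row, pxl_col, epidermis
    abundance: pd.DataFrame  # index barcode, one column per cell type
    pitch_um: float = 100.0

    def subset(self, barcodes: Sequence[str]) -> "SpotGrid":
        idx = pd.Index(barcodes)
        return SpotGrid(
            positions=self.positions.loc[idx].copy(),
            abundance=self.abundance.loc[idx].copy(),
            pitch_um=self.pitch_um,
        )


@dataclass
class TruthLabels:
    """Ground truth for everything the generators planted."""

    cells: pd.DataFrame | None = None       # barcode: malignant, clone_id, lineage,
    #                                         is_doublet_outlier, is_high_mito
    programs: list[dict] | None = None      # {"name", "genes", "donors", "active_cells"}
    cnv_blocks: dict[str, list] | None = None  # donor -> [(chrom, g0, length, lfc)]
    spots: pd.DataFrame | None = None       # barcode: depth + planted_<celltype> cols


def make_gene_annotation(n_genes: int) -> pd.DataFrame:
    """Deterministic annotation: 22 autosomes + X, genes evenly spaced.

    The three helper-lineage factors (TBX21, GATA3, RORC) and 13 "MT-"
    genes are placed at the end of chromosome X so auto-placed CNV blocks
    (autosomes only) never overlap them.
    """
    per = n_genes // len(CHROMOSOMES)
    extra = n_genes - per * len(CHROMOSOMES)
    chroms: list[str] = []
    starts: list[int] = []
    for i, c in enumerate(CHROMOSOMES):
        n = per + (1 if i < extra else 0)
        chroms.extend([c] * n)
        starts.extend((np.arange(n) + 1) * 10_000)
    ids = [f"ENSG{i:05d}" for i in range(n_genes)]
    symbols = [f"GENE{i:05d}" for i in range(n_genes)]
    # lineage factors then mito genes at the tail
    tail = len(LINEAGE_FACTORS) + N_MITO_GENES
    if n_genes < tail + 10:
        raise ConfigError("n_genes too small to place marker genes")
    for j, tf in enumerate(LINEAGE_FACTORS.values()):
        symbols[n_genes - tail + j] = tf
    for j in range(N_MITO_GENES):
        symbols[n_genes - N_MITO_GENES + j] = f"MT-G{j + 1}"
    ann = pd.DataFrame(
        {
            "symbol": symbols,
            "chrom": chroms,
            "start": starts,
            "end": [s + 1000 for s in starts],
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return ann


def _auto_cnv_blocks(
    config: CohortConfig, ann: pd.DataFrame, rng: np.random.Generator
) -> list[list[tuple[str, int, int, float]]]:
    """Three chromosome-scale blocks at |log2FC| = 1 per donor, autosomes only.

    Clonal aberrations in this malignancy are typically arm- to
    chromosome-level, so each donor's clone gains/loses three whole
    (donor-specific) autosomes: two gains and one loss.
    """
    blocks: list[list[tuple[str, int, int, float]]] = []
    autosomes = [c for c in CHROMOSOMES if c != "X"]
    chrom_sizes = {c: int((ann["chrom"] == c).sum()) for c in autosomes}
    for d in range(config.n_donors):
        chrs = rng.choice(autosomes, size=3, replace=False)
        donor_blocks = []
        for j, c in enumerate(chrs):
            size = chrom_sizes[str(c)]
            lfc = 1.0 if j % 2 == 0 else -1.0
            donor_blocks.append((str(c), 0, size, lfc))
        blocks.append(donor_blocks)
    return blocks


def _check_blocks(
    blocks: list[list[tuple[str, int, int, float]]], ann: pd.DataFrame
) -> None:
    sizes = ann["chrom"].value_counts().to_dict()
    for donor_blocks in blocks:
        for chrom, g0, length, _ in donor_blocks:
            if chrom not in sizes:
                raise ConfigError(f"cnv_blocks chromosome {chrom!r} not in annotation")
            if g0 < 0 or length < 1 or g0 + length > sizes[chrom]:
                raise ConfigError(
                    f"cnv_blocks block ({chrom}, {g0}, {length}) exceeds chromosome bounds"
                )


def _block_gene_indices(
    block: tuple[str, int, int, float], ann: pd.DataFrame
) -> np.ndarray:
    chrom, g0, length, _ = block
    on_chrom = np.flatnonzero((ann["chrom"] == chrom).to_numpy())
    return on_chrom[g0 : g0 + length]


def simulate_cohort(config: CohortConfig) -> tuple[AnnData, TruthLabels]:
    """Draw a truth-labeled cohort of per-donor count matrices.

    Counts follow a gamma-Poisson (negative binomial) model with log-normal
    gene means and per-cell log-normal size factors.  Malignant cells of a
    donor share one clonotype and have their CNV-block gene means scaled by
    2**log2FC; each malignant cell's planted lineage factor mean is raised;
    shared activity programs multiply their gene set's means in a random
    malignant subset of each member donor.  Identical config + seed gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = make_gene_annotation(config.n_genes)
    n_genes = config.n_genes

    # base mean expression per gene (log-normal), marker genes overridden
    base_mean = rng.lognormal(mean=-0.7, sigma=1.0, size=n_genes)
    sym = ann["symbol"].to_numpy()
    factor_idx = {tf: int(np.flatnonzero(sym == tf)[0]) for tf in LINEAGE_FACTORS.values()}
    for i in factor_idx.values():
        base_mean[i] = config.lineage_baseline_mean
    mito_idx = np.flatnonzero(np.char.startswith(sym.astype(str), "MT-"))
    base_mean[mito_idx] = 2.0
    ann["base_mean"] = base_mean

    blocks = config.cnv_blocks
    if blocks is None:
        blocks = _auto_cnv_blocks(config, ann, rng)
    if len(blocks) != config.n_donors:
        raise ConfigError("cnv_blocks must provide one block list per donor")
    _check_blocks(blocks, ann)

    # resolve shared programs to concrete gene sets
    gene_ids = ann.index.to_numpy()
    programs: list[dict] = []
    # candidate program genes: ordinary genes with a decent base mean so the
    # planted fold is visible; exclude markers and CNV-eligible tails
    candidates = np.flatnonzero(
        (base_mean > 0.3) & ~np.char.startswith(sym.astype(str), "MT-")
    )
    candidates = np.array([i for i in candidates if i not in factor_idx.values()])
    for p, (size, members, frac) in enumerate(config.shared_programs):
        idx = rng.choice(candidates, size=size, replace=False)
        member_list = list(range(config.n_donors)) if members == "all" else list(members)
        programs.append(
            {
                "name": f"program_{p}",
                "gene_indices": np.sort(idx),
                "genes": sorted(gene_ids[idx].tolist()),
                "donors": member_list,
                "activity_fraction": float(frac),
                "active_cells": [],
            }
        )

    n_adv = int(round(config.stage_split * config.n_donors))
    donor_order = rng.permutation(config.n_donors)
    stage_of = {
        int(d): ("advanced" if rank < n_adv else "early")
        for rank, d in enumerate(donor_order)
    }
    skews = config.lineage_skews()
    lineages = list(LINEAGE_FACTORS)  # TH1, TH2, TH17

    X_parts: list[sp.csr_matrix] = []
    obs_parts: list[pd.DataFrame] = []
    truth_parts: list[pd.DataFrame] = []
    r = 1.0 / config.nb_dispersion  # gamma shape; var = mu + disp * mu^2

    for d in range(config.n_donors):
        donor = f"donor{d:02d}"
        nc = config.n_cells_per_donor
        barcodes = [f"{donor}_BC{i:05d}" for i in range(nc)]
        n_mal = int(round(config.clone_fraction * nc))
        malignant = np.zeros(nc, dtype=bool)
        malignant[rng.choice(nc, size=n_mal, replace=False)] = True

        mu = np.tile(base_mean, (nc, 1))
        for block in blocks[d]:
            gi = _block_gene_indices(block, ann)
            mu[np.ix_(malignant, gi)] *= 2.0 ** block[3]

        # planted helper lineage for malignant cells
        skew = skews[d]
        probs = np.array([(1 - skew) / 2, skew, (1 - skew) / 2])
        lineage = np.array(["none"] * nc, dtype=object)
        mal_idx = np.flatnonzero(malignant)
        if mal_idx.size:
            draws = rng.choice(3, size=mal_idx.size, p=probs)
            for ci, li in zip(mal_idx, draws):
                lineage[ci] = lineages[li]
                mu[ci, factor_idx[LINEAGE_FACTORS[lineages[li]]]] = (
                    config.lineage_factor_mean
                )

        # shared activity programs: random malignant subsets of member donors
        for prog in programs:
            if d in prog["donors"] and mal_idx.size:
                n_active = int(round(prog["activity_fraction"] * mal_idx.size))
                active = rng.choice(mal_idx, size=n_active, replace=False)
                mu[np.ix_(active, prog["gene_indices"])] *= config.program_fold
                prog["active_cells"].extend(barcodes[i] for i in active)

        size_factor = rng.lognormal(mean=0.0, sigma=0.3, size=nc)
        mu *= size_factor[:, None]
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam).astype(np.int32)
        X_parts.append(sp.csr_matrix(counts))

        # doublet scores: low baseline, planted far-outlier subpopulation
        dbl = rng.beta(2.0, 40.0, size=nc)
        n_dbl = int(round(config.doublet_outlier_fraction * nc))
        dbl_idx = rng.choice(nc, size=n_dbl, replace=False)
        dbl[dbl_idx] = rng.beta(25.0, 12.0, size=n_dbl)
        is_dbl = np.zeros(nc, dtype=bool)
        is_dbl[dbl_idx] = True

        # mitochondrial fraction: baseline below the QC cut, high-mito subpop above
        mito = rng.beta(2.5, 30.0, size=nc)
        n_hi = int(round(config.mito_high_fraction * nc))
        hi_idx = rng.choice(nc, size=n_hi, replace=False)
        mito[hi_idx] = rng.beta(12.0, 18.0, size=n_hi)
        is_hi = np.zeros(nc, dtype=bool)
        is_hi[hi_idx] = True

        # clonotypes: one dominant malignant clone; diverse benign repertoire
        # with a fraction of cells lacking V(D)J information
        clonotype = np.array([""] * nc, dtype=object)
        clonotype[malignant] = f"TRB_clone_{donor}"
        ben_idx = np.flatnonzero(~malignant)
        has_tcr = rng.random(ben_idx.size) < 0.7
        pool = [f"TRB_{donor}_{j:03d}" for j in range(50)]
        picked = rng.choice(len(pool), size=int(has_tcr.sum()))
        clonotype[ben_idx[has_tcr]] = [pool[j] for j in picked]

        compartment = np.where(rng.random(nc) < 0.5, "epidermis", "dermis")
        obs_parts.append(
            pd.DataFrame(
                {
                    "donor": donor,
                    "stage": stage_of[d],
                    "compartment": compartment,
                    "doublet_score": dbl,
                    "mito_frac": mito,
                    "clonotype": clonotype,
                    "lane": donor,
                },
                index=pd.Index(barcodes, name="barcode"),
            )
        )
        truth_parts.append(
            pd.DataFrame(
                {
                    "malignant": malignant,
                    "clone_id": np.where(malignant, f"clone_{donor}", ""),
                    "lineage": lineage,
                    "is_doublet_outlier": is_dbl,
                    "is_high_mito": is_hi,
                },
                index=pd.Index(barcodes, name="barcode"),
            )
        )

    X = sp.vstack(X_parts, format="csr")
    obs = pd.concat(obs_parts)
    adata = AnnData(X=X, obs=obs, var=ann.copy())
    truth = TruthLabels(
        cells=pd.concat(truth_parts),
        programs=programs,
        cnv_blocks={f"donor{d:02d}": list(blocks[d]) for d in range(config.n_donors)},
    )
    return adata, truth


def simulate_spots(config: SpotGridConfig) -> tuple[SpotGrid, TruthLabels]:
    """Draw a truth-labeled square spot lattice with a surface layer.

    The main component is a full rows x cols lattice whose top
    ``epidermis_depth`` rows are flagged epidermis; depth of a spot is its
    row index (interspot units).  Planted abundance follows each cell type's
    gradient evaluated at that depth plus Gaussian noise, clipped at zero.
    An optional debris component of ``debris_size`` spots is placed beyond
    adjacency range of the main lattice.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gradients = dict(config.gradients or {})
    for ct in config.cell_types:
        gradients.setdefault(ct, GradientSpec("flat", base=1.0))

    rows, cols = config.rows, config.cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    array_row = rr.ravel()
    array_col = cc.ravel()
    depth = array_row.astype(float)
    barcodes = [f"SPOT_{r:03d}_{c:03d}" for r, c in zip(array_row, array_col)]
    epidermis = array_row < config.epidermis_depth

    if config.debris_size:
        # compact strip far below the lattice (gap >> adjacency radius)
        db_row = rows + 5 + np.zeros(config.debris_size, dtype=int)
        db_col = np.arange(config.debris_size)
        array_row = np.concatenate([array_row, db_row])
        array_col = np.concatenate([array_col, db_col])
        depth = np.concatenate([depth, np.zeros(config.debris_size)])
        barcodes += [f"DEBRIS_{i:03d}" for i in range(config.debris_size)]
        epidermis = np.concatenate([epidermis, np.zeros(config.debris_size, dtype=bool)])

    positions = pd.DataFrame(
        {
            "in_tissue": 1,
            "array_row": array_row,
            "array_col": array_col,
            "pxl_row": array_row * config.pitch_um,
            "pxl_col": array_col * config.pitch_um,
            "epidermis": epidermis,
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    planted = {}
    noisy = {}
    for ct in config.cell_types:
        vals = gradients[ct].evaluate(depth)
        planted[ct] = vals
        noisy[ct] = np.maximum(vals + rng.normal(0.0, config.noise_sd, size=vals.size), 0.0)
    abundance = pd.DataFrame(noisy, index=positions.index)
    truth_spots = pd.DataFrame(
        {"depth": depth, **{f"planted_{ct}": planted[ct] for ct in config.cell_types}},
        index=positions.index,
    )
    grid = SpotGrid(positions=positions, abundance=abundance, pitch_um=config.pitch_um)
    return grid, TruthLabels(spots=truth_spots)
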