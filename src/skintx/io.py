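"""Reading and writing cohort fixtures in plain-text exchange formats.

Layout written by :func:`write_fixture`::

    <dir>/matrix.mtx            MatrixMarket, genes x cells, integer
    <dir>/barcodes.tsv          one barcode per line
    <dir>/features.tsv          gene_id <TAB> symbol <TAB> Gene Expression
    <dir>/cell_metadata.csv     per-cell metadata, indexed by barcode
    <dir>/genes.tsv             BED-like: chrom, start, end, gene (0-based half-open)
    <dir>/tissue_positions.csv  Visium dialect (barcode, in_tissue, array_row,
                                array_col, pxl_row, pxl_col [, epidermis])
    <dir>/abundance.csv         per-spot cell-type abundance
    <dir>/truth.json            planted ground truth
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .simulate import SpotGrid, TruthLabels

__all__ = [
    "FixtureParseError",
    "write_fixture",
    "read_fixture",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_spot_tables",
    "write_spot_tables",
]


class FixtureParseError(ValueError):
    """Malformed fixture file; the message carries file (and line) context."""


def write_counts_mtx(directory: str | Path, adata: AnnData) -> None:
    """Write counts as MatrixMarket (genes x cells) + barcodes/features TSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    mat = sp.coo_matrix(X.T.astype(np.int64))  # genes x cells
    scipy.io.mmwrite(str(d / "matrix.mtx"), mat, field="integer")
    (d / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
    symbols = (
        adata.var["symbol"]
        if "symbol" in adata.var.columns
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    with open(d / "features.tsv", "w") as fh:
        for gid, symv in zip(adata.var_names, symbols):
            fh.write(f"{gid}\t{symv}\tGene Expression\n")


def read_counts_mtx(directory: str | Path) -> AnnData:
    """Read a genes x cells MTX triplet back into an AnnData (cells x genes)."""
    d = Path(directory)
    try:
        mat = scipy.io.mmread(str(d / "matrix.mtx"))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FixtureParseError(f"{d / 'matrix.mtx'}: {exc}") from exc
    barcodes = _read_lines(d / "barcodes.tsv")
    features = []
    for lineno, line in enumerate(_read_lines(d / "features.tsv"), start=1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FixtureParseError(
                f"{d / 'features.tsv'}: line {lineno}: expected >= 2 tab-separated fields"
            )
        features.append(parts[:2])
    ids = [f[0] for f in features]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise FixtureParseError(
            f"{d / 'features.tsv'}: duplicated gene id {dup[0]!r}"
        )
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(ids), len(barcodes)):
        raise FixtureParseError(
            f"{d / 'matrix.mtx'}: shape {mat.shape} does not match "
            f"{len(ids)} features x {len(barcodes)} barcodes"
        )
    var = pd.DataFrame(
        {"symbol": [f[1] for f in features]}, index=pd.Index(ids, name="gene_id")
    )
    return AnnData(
        X=sp.csr_matrix(mat.T.astype(np.int32)),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=var,
    )


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FixtureParseError(f"{path}: file not found")
    return [ln for ln in path.read_text().splitlines()]


def _write_gene_bed(path: Path, var: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for gid, row in var.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{gid}\n")


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like (chrom, start, end, gene) TSV into a gene-indexed frame."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FixtureParseError(f"{path}: line {lineno}: expected 4 fields")
        chrom, start, end, gene = parts
        try:
            rows.append((gene, chrom, int(start), int(end)))
        except ValueError as exc:
            raise FixtureParseError(f"{path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return df.set_index("gene_id")


def write_spot_tables(directory: str | Path, grid: SpotGrid) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pos = grid.positions.copy()
    pos["epidermis"] = pos["epidermis"].astype(int)
    pos.to_csv(d / "tissue_positions.csv")
    grid.abundance.to_csv(d / "abundance.csv")


def read_spot_tables(directory: str | Path, pitch_um: float = 100.0) -> SpotGrid:
    d = Path(directory)
    try:
        pos = pd.read_csv(d / "tissue_positions.csv", index_col=0)
        ab = pd.read_csv(d / "abundance.csv", index_col=0)
    except FileNotFoundError as exc:
        raise FixtureParseError(str(exc)) from exc
    except Exception as exc:  # noqa: BLE001
        raise FixtureParseError(f"{d}: {exc}") from exc
    required = {"in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"}
    missing = required - set(pos.columns)
    if missing:
        raise FixtureParseError(
            f"{d / 'tissue_positions.csv'}: missing columns {sorted(missing)}"
        )
    if "epidermis" in pos.columns:
        pos["epidermis"] = pos["epidermis"].astype(bool)
    else:
        pos["epidermis"] = False
    if not pos.index.equals(ab.index):
        ab = ab.reindex(pos.index)
        if ab.isna().any().any():
            raise FixtureParseError(
                f"{d / 'abundance.csv'}: barcodes do not match tissue_positions.csv"
            )
    return SpotGrid(positions=pos, abundance=ab, pitch_um=pitch_um)


def _truth_to_json(truth: TruthLabels) -> dict:
    out: dict = {}
    if truth.cells is not None:
        out["cells"] = json.loads(truth.cells.to_json(orient="index"))
        out["cell_order"] = truth.cells.index.tolist()
    if truth.programs is not None:
        out["programs"] = [
            {
                "name": p["name"],
                "genes": list(p["genes"]),
                "donors": list(p["donors"]),
                "activity_fraction": p["activity_fraction"],
                "active_cells": list(p["active_cells"]),
            }
            for p in truth.programs
        ]
    if truth.cnv_blocks is not None:
        out["cnv_blocks"] = {
            d: [[c, int(g0), int(ln), float(lfc)] for c, g0, ln, lfc in bl]
            for d, bl in truth.cnv_blocks.items()
        }
    if truth.spots is not None:
        out["spots"] = json.loads(truth.spots.to_json(orient="index"))
        out["spot_order"] = truth.spots.index.tolist()
    return out


def _truth_from_json(obj: dict) -> TruthLabels:
    truth = TruthLabels()
    if "cells" in obj:
        truth.cells = pd.DataFrame.from_dict(obj["cells"], orient="index").loc[
            obj["cell_order"]
        ]
        truth.cells.index.name = "barcode"
    if "programs" in obj:
        truth.programs = obj["programs"]
    if "cnv_blocks" in obj:
        truth.cnv_blocks = {
            d: [(c, int(g0), int(ln), float(lfc)) for c, g0, ln, lfc in bl]
            for d, bl in obj["cnv_blocks"].items()
        }
    if "spots" in obj:
        truth.spots = pd.DataFrame.from_dict(obj["spots"], orient="index").loc[
            obj["spot_order"]
        ]
        truth.spots.index.name = "barcode"
    return truth


def write_fixture(
    directory: str | Path,
    adata: AnnData | None = None,
    truth: TruthLabels | None = None,
    grid: SpotGrid | None = None,
) -> None:
    """Write all generated artifacts to plain-text files (see module docstring)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if adata is not None:
        write_counts_mtx(d, adata)
        meta_cols = [
            c
            for c in (
                "donor",
                "stage",
                "compartment",
                "doublet_score",
                "mito_frac",
                "clonotype",
                "lane",
            )
            if c in adata.obs.columns
        ]
        adata.obs[meta_cols].to_csv(d / "cell_metadata.csv")
        if {"chrom", "start", "end"} <= set(adata.var.columns):
            _write_gene_bed(d / "genes.tsv", adata.var)
    if grid is not None:
        write_spot_tables(d, grid)
    if truth is not None:
        (d / "truth.json").write_text(json.dumps(_truth_to_json(truth), indent=1))


def read_fixture(
    directory: str | Path,
) -> tuple[AnnData | None, TruthLabels | None, SpotGrid | None]:
    """Read back everything :func:`write_fixture` wrote; absent parts are None."""
    d = Path(directory)
    adata = None
    if (d / "matrix.mtx").exists():
        adata = read_counts_mtx(d)
        if (d / "cell_metadata.csv").exists():
            meta = pd.read_csv(d / "cell_metadata.csv", index_col=0)
            if not meta.index.equals(adata.obs.index):
                raise FixtureParseError(
                    f"{d / 'cell_metadata.csv'}: barcodes do not match barcodes.tsv"
                )
            if "clonotype" in meta.columns:
                meta["clonotype"] = meta["clonotype"].fillna("")
            adata.obs = meta
        if (d / "genes.tsv").exists():
            bed = read_gene_bed(d / "genes.tsv")
            if not bed.index.equals(adata.var.index):
                raise FixtureParseError(
                    f"{d / 'genes.tsv'}: gene ids do not match features.tsv"
                )
            for col in ("chrom", "start", "end"):
                adata.var[col] = bed[col]
    grid = None
    if (d / "tissue_positions.csv").exists():
        grid = read_spot_tables(d)
    truth = None
    if (d / "truth.json").exists():
        truth = _truth_from_json(json.loads((d / "truth.json").read_text()))
    return adata, truth, grid
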