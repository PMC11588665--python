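"""Helper-lineage classification, stage comparison, and pseudo-bulk analysis.

Malignant T cells are assigned to the TH1/TH2/TH17 helper lineages by the
expression of their marker transcription factors (TBX21, GATA3, RORC): a
cell takes the lineage whose factor is detected (> 0) and is the strict
maximum of the three, otherwise it stays unassigned.  Per-patient TH2
fractions are compared between early and advanced disease with a two-sided
Wilcoxon rank-sum test (exact permutation enumeration at small sizes,
tie-corrected normal approximation otherwise).  Pseudo-bulk aggregation
sums raw counts per donor, excluding donors contributing fewer than 20
cells of the requested type, and a simple donor-level differential
expression stand-in (CPM fold-change + rank-sum p + Benjamini-Hochberg)
operates on the aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .simulate import LINEAGE_FACTORS

logger = logging.getLogger(__name__)

__all__ = [
    "LineageCall",
    "StageComparison",
    "PseudoBulk",
    "RankSumResult",
    "classify_lineage",
    "lineage_fractions",
    "stage_comparison",
    "rank_sum_test",
    "pseudobulk_aggregate",
    "pseudobulk_de",
    "bh_adjust",
]

LINEAGES = tuple(LINEAGE_FACTORS)  # ("TH1", "TH2", "TH17")


@dataclass
class LineageCall:
    """Per-cell lineage labels plus the supporting factor expression."""

    calls: pd.DataFrame  # barcode: label in {TH1, TH2, TH17, unassigned} + factor cols


@dataclass
class StageComparison:
    fractions: pd.Series        # per-patient TH2 fraction (assigned cells)
    n_early: int
    n_advanced: int
    statistic: float            # Mann-Whitney U (early group)
    p_value: float


@dataclass
class PseudoBulk:
    counts: pd.DataFrame        # donor x gene summed raw counts
    n_cells: pd.Series          # contributing cells per retained donor
    excluded_donors: list[str]
    group: pd.Series | None = None  # optional donor -> group label


class RankSumResult(NamedTuple):
    statistic: float
    p_value: float
    method: str                 # "exact" or "normal"


def _factor_matrix(normalized, factors: dict[str, str]) -> pd.DataFrame:
    """Normalized expression of the three lineage factors, absent genes -> 0."""
    if isinstance(normalized, AnnData):
        X = normalized.X
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        df = pd.DataFrame(X, index=normalized.obs_names, columns=normalized.var_names)
        if "symbol" in normalized.var.columns:
            # allow lookup by symbol as well as by gene id
            sym2id = {}
            for gid, s in normalized.var["symbol"].items():
                sym2id.setdefault(str(s), gid)
            df = df.rename(
                columns={sym2id[f]: f for f in factors.values() if f in sym2id}
            )
    elif isinstance(normalized, pd.DataFrame):
        df = normalized
    else:
        raise TypeError("normalized must be an AnnData or a cells x genes DataFrame")
    out = {}
    for gene in factors.values():
        if gene in df.columns:
            out[gene] = df[gene].to_numpy(dtype=float)
        else:
            logger.info("classify_lineage: gene %s absent, treated as all-zero", gene)
            out[gene] = np.zeros(df.shape[0])
    return pd.DataFrame(out, index=df.index)


def classify_lineage(
    normalized,
    factors: dict[str, str] | None = None,
    min_expr: float = 0.0,
) -> LineageCall:
    """Assign each cell the lineage of its strictly maximal detected factor.

    ``normalized`` holds normalized expression (cells x genes, AnnData or
    DataFrame); ``factors`` maps lineage -> marker gene (default TH1:TBX21,
    TH2:GATA3, TH17:RORC).  A cell is unassigned when all three factors are
    at or below ``min_expr`` or when the maximum is tied.
    """
    factors = factors or dict(LINEAGE_FACTORS)
    F = _factor_matrix(normalized, factors)
    vals = F.to_numpy()
    order = np.argsort(-vals, axis=1)
    best = vals[np.arange(len(F)), order[:, 0]]
    second = vals[np.arange(len(F)), order[:, 1]]
    assignable = (best > min_expr) & (best > second)
    lineage_names = np.asarray(list(factors), dtype=object)
    labels = np.where(assignable, lineage_names[order[:, 0]], "unassigned")
    calls = F.copy()
    calls.insert(0, "label", labels)
    return LineageCall(calls=calls)


def lineage_fractions(
    call: LineageCall, patients: Sequence[str] | pd.Series
) -> pd.DataFrame:
    """Per-patient TH1/TH2/TH17 fractions among assigned malignant cells.

    Rows sum to 1 for patients with at least one assigned cell; patients
    with none get missing fractions.
    """
    labels = call.calls["label"]
    pat = pd.Series(np.asarray(patients, dtype=object), index=labels.index)
    rows = {}
    for p in pd.unique(pat):
        sub = labels[pat == p]
        assigned = sub[sub != "unassigned"]
        if len(assigned) == 0:
            rows[p] = {ln: np.nan for ln in LINEAGES}
        else:
            rows[p] = {ln: float((assigned == ln).mean()) for ln in LINEAGES}
    out = pd.DataFrame.from_dict(rows, orient="index")[list(LINEAGES)]
    out.index.name = "patient"
    return out


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x (ties counted half) via midranks."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def rank_sum_test(x, y, exact_max_n: int = 12) -> RankSumResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    For pooled sample sizes up to ``exact_max_n`` the p-value is computed
    by exact enumeration of all group assignments of the observed pooled
    values (valid with ties); larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = _mann_whitney_u(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = comb(n1 + n2, n1)
        for chosen in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return RankSumResult(u_obs, hits / total, "exact")

    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankSumResult(u_obs, 1.0, "normal")
    z = max((abs(u_obs - mu) - 0.5) / sqrt(var), 0.0)
    # two-sided p from the standard normal survival function
    p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))
    return RankSumResult(u_obs, p, "normal")


def stage_comparison(
    fractions: pd.DataFrame, stage: pd.Series, lineage: str = "TH2"
) -> StageComparison:
    """Compare per-patient lineage fractions between early and advanced stage."""
    frac = fractions[lineage].dropna()
    st = stage.reindex(frac.index).astype(str)
    early = frac[st == "early"].to_numpy()
    advanced = frac[st == "advanced"].to_numpy()
    res = rank_sum_test(early, advanced)
    return StageComparison(
        fractions=frac,
        n_early=len(early),
        n_advanced=len(advanced),
        statistic=res.statistic,
        p_value=res.p_value,
    )


def pseudobulk_aggregate(
    adata: AnnData,
    donor_key: str = "donor",
    cell_type: str | None = None,
    cell_type_key: str | None = None,
    min_cells: int = 20,
) -> PseudoBulk:
    """Sum raw counts per donor, dropping donors with < ``min_cells`` cells.

    When ``cell_type`` is given, only cells whose ``cell_type_key`` column
    equals it contribute; exclusion counts are logged.
    """
    obs = adata.obs
    if donor_key not in obs.columns:
        raise ValueError(f"missing metadata column {donor_key!r}")
    mask = np.ones(adata.n_obs, dtype=bool)
    if cell_type is not None:
        if cell_type_key is None or cell_type_key not in obs.columns:
            raise ValueError("cell_type_key must name an existing metadata column")
        mask = (obs[cell_type_key].astype(str) == cell_type).to_numpy()
    X = adata.X
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)
    donors = obs[donor_key].astype(str).to_numpy()

    rows, kept, excluded, ncells = [], [], [], {}
    for d in pd.unique(donors):
        sel = (donors == d) & mask
        n = int(sel.sum())
        if n < min_cells:
            excluded.append(d)
            logger.info("pseudobulk: donor %s excluded (%d < %d cells)", d, n, min_cells)
            continue
        rows.append(np.asarray(X[sel].sum(axis=0)).ravel())
        kept.append(d)
        ncells[d] = n
    if not kept:
        raise ValueError("no donor passes the minimum-cell filter")
    counts = pd.DataFrame(np.vstack(rows), index=pd.Index(kept, name="donor"),
                          columns=adata.var_names)
    return PseudoBulk(
        counts=counts,
        n_cells=pd.Series(ncells, name="n_cells"),
        excluded_donors=excluded,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg: q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pseudobulk_de(
    pb: PseudoBulk, groups: pd.Series | dict, group_a: str, group_b: str
) -> pd.DataFrame:
    """Donor-level differential expression stand-in on pseudo-bulk counts.

    Per gene: log2 fold-change of mean CPM between the groups (with a +1
    pseudocount on mean CPM), a two-sided rank-sum p-value across donor
    CPMs, and a Benjamini-Hochberg q-value.  This is a deliberately simple
    donor-replicate test, not a reimplementation of count-model (e.g.
    quasi-likelihood) differential expression.
    """
    groups = pd.Series(groups)
    donors = pb.counts.index
    ga = [d for d in donors if groups.get(d) == group_a]
    gb = [d for d in donors if groups.get(d) == group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 donors")
    totals = pb.counts.sum(axis=1)
    cpm = pb.counts.div(totals, axis=0) * 1e6
    mean_a = cpm.loc[ga].mean(axis=0)
    mean_b = cpm.loc[gb].mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pvals = np.array([
        rank_sum_test(cpm.loc[ga, g].to_numpy(), cpm.loc[gb, g].to_numpy()).p_value
        for g in pb.counts.columns
    ])
    return pd.DataFrame(
        {"log2fc": log2fc.to_numpy(), "p_value": pvals, "q_value": bh_adjust(pvals)},
        index=pb.counts.columns,
    )
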