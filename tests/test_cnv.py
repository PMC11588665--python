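import numpy as np
import pandas as pd
import pytest

from skintx.cnv import (
    CNVParams,
    call_malignant,
    dominant_clonotype,
    order_genes,
    smooth_windows,
)
from skintx.simulate import CohortConfig, simulate_cohort
from conftest import make_adata


# ---------------------------------------------------------------- gene order

def _annotation(chroms, starts):
    return pd.DataFrame(
        {"chrom": chroms, "start": starts},
        index=[f"g{i}" for i in range(len(chroms))],
    )


def test_single_chromosome_sorted_by_start():
    ann = _annotation(["1"] * 4, [40, 10, 30, 20])
    assert list(order_genes(ann)) == ["g1", "g3", "g2", "g0"]


def test_sorted_input_unchanged():
    ann = _annotation(["1", "1", "2", "X"], [10, 20, 5, 1])
    assert list(order_genes(ann)) == ["g0", "g1", "g2", "g3"]


def test_random_shuffle_matches_brute_force_sort():
    rng = np.random.default_rng(0)
    chrom_rank = {str(c): c for c in range(1, 23)} | {"X": 23}
    chroms = rng.choice(list(chrom_rank), size=50)
    starts = rng.integers(1, 10_000, size=50)
    ann = _annotation(chroms, starts)
    expected = [
        g for _, _, g in sorted(
            (chrom_rank[c], s, g) for c, s, g in zip(chroms, starts, ann.index)
        )
    ]
    assert list(order_genes(ann)) == expected


def test_unknown_chromosome_rejected():
    with pytest.raises(ValueError, match="chrY"):
        order_genes(_annotation(["1", "chrY"], [1, 2]))


# ------------------------------------------------------------------ smoothing

def _brute_force_cnv(counts, chroms, ref_rows, window, clamp, target=1e4):
    """Direct loop implementation of the 6-step smoothing pipeline."""
    X = counts.astype(float)
    logX = np.log2(X / X.sum(axis=1, keepdims=True) * target + 1.0)
    centered = logX - logX[ref_rows].mean(axis=0)
    centered = np.clip(centered, -clamp, clamp)
    sm = np.zeros_like(centered)
    for j in range(centered.shape[1]):
        same = [g for g in range(centered.shape[1]) if chroms[g] == chroms[j]]
        pos = same.index(j)
        lo, hi = max(0, pos - window // 2), min(len(same), pos + window // 2 + 1)
        win = [same[g] for g in range(lo, hi)]
        sm[:, j] = centered[:, win].mean(axis=1)
    sm = sm - np.median(sm, axis=1, keepdims=True)
    sm = sm - sm[ref_rows].mean(axis=0)
    return np.clip(sm, -clamp, clamp)


def _cnv_adata(counts, chroms):
    adata = make_adata(counts)
    adata.var["chrom"] = chroms
    adata.var["start"] = np.arange(len(chroms)) + 1
    adata.var["end"] = adata.var["start"] + 1
    return adata


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_smoothing_matches_brute_force_loop(seed):
    rng = np.random.default_rng(seed)
    n_cells, n_genes = 15, 120
    counts = rng.poisson(3.0, size=(n_cells, n_genes)) + 1
    chroms = ["1"] * 70 + ["2"] * 50
    adata = _cnv_adata(counts, chroms)
    params = CNVParams(window_genes=7, min_genes_per_chromosome=7)
    ref = [f"c{i}" for i in range(6)]
    cm = smooth_windows(adata, order_genes(adata.var), ref, params)
    expected = _brute_force_cnv(counts, chroms, list(range(6)), 7, params.clamp)
    assert np.allclose(cm.values.to_numpy(), expected, atol=1e-10)


def test_window_truncation_at_chromosome_start():
    """The first gene's window spans only the first ceil(w/2) genes."""
    rng = np.random.default_rng(3)
    counts = rng.poisson(5.0, size=(8, 40)) + 1
    adata = _cnv_adata(counts, ["1"] * 40)
    params = CNVParams(window_genes=9, min_genes_per_chromosome=9)
    ref = [f"c{i}" for i in range(4)]
    cm = smooth_windows(adata, order_genes(adata.var), ref, params)
    # brute-force oracle uses the explicitly truncated window [0, 5) for gene 0
    sm_full = _brute_force_cnv(counts, ["1"] * 40, list(range(4)), 9, 3.0)
    assert np.allclose(cm.values.to_numpy()[:, 0], sm_full[:, 0], atol=1e-10)


def test_cells_identical_to_reference_give_zero_matrix():
    counts = np.tile(np.array([5, 2, 8, 1, 3, 9, 4, 6, 7, 2] * 3), (12, 1))
    adata = _cnv_adata(counts, ["1"] * 30)
    params = CNVParams(window_genes=5, min_genes_per_chromosome=5)
    ref = [f"c{i}" for i in range(10)]
    cm = smooth_windows(adata, order_genes(adata.var), ref, params)
    assert np.abs(cm.values.to_numpy()).max() < 1e-6


def test_planted_block_interior_windows_near_plus_one():
    """A contiguous +1 log2 block longer than the window shows interior
    smoothed means near +1 (before per-cell centering shifts)."""
    rng = np.random.default_rng(7)
    base = rng.integers(20, 40, size=60).astype(int)
    ref_counts = np.tile(base, (10, 1))
    tumor = base.copy()
    tumor[20:50] = tumor[20:50] * 2  # +1 in log2
    counts = np.vstack([ref_counts, np.tile(tumor, (4, 1))])
    adata = _cnv_adata(counts, ["1"] * 60)
    params = CNVParams(window_genes=5, min_genes_per_chromosome=5)
    ref = [f"c{i}" for i in range(10)]
    cm = smooth_windows(adata, order_genes(adata.var), ref, params)
    interior = cm.values.to_numpy()[10:, 25:45]
    outside = cm.values.to_numpy()[10:, :15]
    # library normalization + per-cell median shift move the baseline, but the
    # block-vs-outside contrast stays ~1
    contrast = interior.mean() - outside.mean()
    assert contrast == pytest.approx(1.0, abs=0.15)


def test_translation_invariance_under_library_scaling():
    rng = np.random.default_rng(11)
    counts = rng.poisson(4.0, size=(10, 40)) + 1
    adata1 = _cnv_adata(counts, ["1"] * 40)
    adata2 = _cnv_adata(counts * 3, ["1"] * 40)
    params = CNVParams(window_genes=5, min_genes_per_chromosome=5)
    ref = [f"c{i}" for i in range(5)]
    cm1 = smooth_windows(adata1, order_genes(adata1.var), ref, params)
    cm2 = smooth_windows(adata2, order_genes(adata2.var), ref, params)
    assert np.allclose(cm1.values, cm2.values, atol=1e-9)


def test_small_chromosome_dropped_with_warning(caplog):
    rng = np.random.default_rng(1)
    counts = rng.poisson(4.0, size=(12, 40)) + 1
    chroms = ["1"] * 36 + ["2"] * 4
    adata = _cnv_adata(counts, chroms)
    params = CNVParams(window_genes=5, min_genes_per_chromosome=5)
    with caplog.at_level("WARNING"):
        cm = smooth_windows(adata, order_genes(adata.var), [f"c{i}" for i in range(6)], params)
    assert cm.dropped_chromosomes == ["2"]
    assert cm.values.shape[1] == 36


# ------------------------------------------------------------- malignancy call

def test_reference_only_cohort_is_all_benign(small_cohort):
    cfg, adata, truth = small_cohort
    benign = truth.cells.index[~truth.cells["malignant"]]
    sub = adata[benign].copy()
    params = CNVParams(window_genes=21, min_genes_per_chromosome=21)
    cm = smooth_windows(sub, order_genes(sub.var), list(benign), params)
    call = call_malignant(cm, params)
    assert (call.calls["label"] == "benign").all()


def test_planted_clones_recovered(default_cohort):
    cfg, adata, truth = default_cohort
    ref = list(truth.cells.index[~truth.cells["malignant"]])
    cm = smooth_windows(adata, order_genes(adata.var), ref)
    call = call_malignant(cm)
    pred = call.calls["label"] == "malignant"
    actual = truth.cells["malignant"].reindex(call.calls.index)
    tp = int((pred & actual).sum())
    precision = tp / max(int(pred.sum()), 1)
    recall = tp / int(actual.sum())
    assert precision >= 0.95
    assert recall >= 0.95
    # clone partition matches donors: one dominant clone per donor
    clones = call.calls.loc[pred & actual, "clone"]
    donors = truth.cells.loc[clones.index, "clone_id"]
    purity = pd.crosstab(clones, donors).max(axis=1).sum() / len(clones)
    assert purity >= 0.95


def test_no_planted_blocks_no_malignant_calls():
    cfg = CohortConfig(n_donors=2, n_cells_per_donor=150, n_genes=1150,
                       cnv_blocks=[[], []], shared_programs=[], seed=9)
    adata, truth = simulate_cohort(cfg)
    benign = list(truth.cells.index[~truth.cells["malignant"]])
    params = CNVParams(window_genes=21, min_genes_per_chromosome=21)
    cm = smooth_windows(adata, order_genes(adata.var), benign, params)
    call = call_malignant(cm, params)
    # "malignant" cells carry no CNV here; their scores match the reference
    non_ref = call.calls.drop(index=benign)
    assert (non_ref["label"] == "malignant").mean() < 0.05


def test_too_few_reference_cells_rejected(small_cohort):
    cfg, adata, truth = small_cohort
    some = list(adata.obs_names[:20])
    params = CNVParams(window_genes=21, min_genes_per_chromosome=21)
    cm = smooth_windows(adata[some].copy(), order_genes(adata.var), some[:5], params)
    with pytest.raises(ValueError, match="reference"):
        call_malignant(cm, params)


# ----------------------------------------------------------- dominant clonotype

def test_dominant_clonotype_unanimous():
    res = dominant_clonotype(["A"] * 7)
    assert (res.clonotype, res.fraction, res.n_missing) == ("A", 1.0, 0)


def test_dominant_clonotype_tie_breaks_lexicographically():
    res = dominant_clonotype(["B"] * 5 + ["A"] * 5)
    assert res.clonotype == "A"
    assert res.fraction == 0.5


def test_dominant_clonotype_counts_and_missing():
    labels = ["A"] * 90 + ["B"] * 10 + [""] * 4 + [None] * 2
    res = dominant_clonotype(labels)
    assert res.clonotype == "A"
    assert res.fraction == pytest.approx(0.9)
    assert res.n_missing == 6


def test_dominant_clonotype_requires_clonotyped_cells():
    with pytest.raises(ValueError):
        dominant_clonotype(["", None])
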