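import numpy as np
import pandas as pd
import pytest

from skintx.simulate import GradientSpec, SpotGrid, SpotGridConfig, simulate_spots
from skintx.spatial import (
    axis_profile,
    distance_to_surface,
    microenv_nmf,
    microenv_silhouette,
    normalize_abundance,
    surface_spots,
    tissue_mask,
)


def _grid_from_coords(coords, epidermis=(), pitch=100.0, abundance=None):
    idx = pd.Index([f"s{i}" for i in range(len(coords))], name="barcode")
    rows = np.array([r for r, c in coords])
    cols = np.array([c for r, c in coords])
    pos = pd.DataFrame(
        {
            "in_tissue": 1,
            "array_row": rows,
            "array_col": cols,
            "pxl_row": rows * pitch,
            "pxl_col": cols * pitch,
            "epidermis": [i in set(epidermis) for i in range(len(coords))],
        },
        index=idx,
    )
    ab = abundance if abundance is not None else pd.DataFrame(
        {"A": np.ones(len(coords))}, index=idx
    )
    return SpotGrid(positions=pos, abundance=ab, pitch_um=pitch)


def _bfs_components(coords, radius_units=1.2):
    """Brute-force breadth-first-search connected components."""
    n = len(coords)
    seen, comps = set(), []
    pts = np.asarray(coords, dtype=float)
    for start in range(n):
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            i = queue.pop()
            comp.append(i)
            for j in range(n):
                if j not in seen and np.linalg.norm(pts[i] - pts[j]) <= radius_units:
                    seen.add(j)
                    queue.append(j)
        comps.append(sorted(comp))
    return comps


# ------------------------------------------------------------------ tissue mask

def test_largest_component_retained():
    big = [(r, c) for r in range(5) for c in range(10)]
    debris = [(20, 0), (20, 1), (21, 0)]
    grid = _grid_from_coords(big + debris)
    mask = tissue_mask(grid)
    assert mask.positions.shape[0] == 50
    assert not any(bc.startswith("s5") and int(bc[1:]) >= 50 for bc in mask.positions.index)


def test_single_component_unchanged():
    grid = _grid_from_coords([(r, c) for r in range(3) for c in range(3)])
    mask = tissue_mask(grid)
    assert list(mask.positions.index) == list(grid.positions.index)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_components_match_bfs_oracle(seed):
    rng = np.random.default_rng(seed)
    coords = {(int(r), int(c)) for r, c in rng.integers(0, 12, size=(40, 2))}
    coords = sorted(coords)
    grid = _grid_from_coords(coords)
    comps = _bfs_components(coords)
    # tie rule: smallest minimum barcode == smallest minimum index here
    best = max(comps, key=lambda comp: (len(comp), -min(comp)))
    mask = tissue_mask(grid)
    expected = {f"s{i}" for i in best}
    assert set(mask.positions.index) == expected


def test_no_in_tissue_spots_rejected():
    grid = _grid_from_coords([(0, 0), (0, 1)])
    grid.positions["in_tissue"] = 0
    with pytest.raises(ValueError):
        tissue_mask(grid)


# ---------------------------------------------------------------- surface spots

def test_full_rectangle_top_row_epidermis_is_surface():
    coords = [(r, c) for r in range(4) for c in range(5)]
    top_row = [i for i, (r, c) in enumerate(coords) if r == 0]
    grid = _grid_from_coords(coords, epidermis=top_row)
    assert set(surface_spots(grid)) == {f"s{i}" for i in top_row}


def test_surrounded_epidermis_spot_is_not_surface():
    coords = [(r, c) for r in range(3) for c in range(3)]
    center = coords.index((1, 1))
    grid = _grid_from_coords(coords, epidermis=[center])
    assert surface_spots(grid) == []


@pytest.mark.parametrize("seed", [3, 4])
def test_surface_matches_neighbor_count_oracle(seed):
    rng = np.random.default_rng(seed)
    coords = sorted({(int(r), int(c)) for r, c in rng.integers(0, 8, size=(30, 2))})
    epi = list(range(0, len(coords), 2))
    grid = _grid_from_coords(coords, epidermis=epi)
    pts = np.asarray(coords, dtype=float)
    expected = []
    for i in epi:
        n_nb = sum(
            1
            for j in range(len(coords))
            if j != i and np.linalg.norm(pts[i] - pts[j]) <= 1.2
        )
        if n_nb < 4:
            expected.append(f"s{i}")
    assert surface_spots(grid) == expected


def test_no_epidermis_flags_rejected():
    grid = _grid_from_coords([(0, 0), (0, 1)])
    with pytest.raises(ValueError):
        surface_spots(grid)


# ----------------------------------------------------------- distance to surface

def test_surface_spot_distance_zero_and_unit_spacing():
    coords = [(0, 0), (1, 0), (2, 0)]
    grid = _grid_from_coords(coords, epidermis=[0])
    surf = surface_spots(grid)
    d = distance_to_surface(grid, surf)
    assert d["s0"] == 0.0
    assert d["s1"] == 1.0   # one interspot distance = 100 um below the surface
    assert d["s2"] == 2.0


@pytest.mark.parametrize("seed", [5, 6])
def test_distance_matches_all_pairs_minimum(seed):
    rng = np.random.default_rng(seed)
    coords = sorted({(int(r), int(c)) for r, c in rng.integers(0, 30, size=(120, 2))})
    epi = list(range(0, len(coords), 5))
    grid = _grid_from_coords(coords, epidermis=epi)
    surf = surface_spots(grid)
    d = distance_to_surface(grid, surf)
    pts = np.asarray(coords, dtype=float)
    surf_idx = [int(bc[1:]) for bc in surf]
    for i, bc in enumerate(grid.positions.index):
        brute = min(np.linalg.norm(pts[i] - pts[j]) for j in surf_idx)
        assert d[bc] == pytest.approx(brute)


# ---------------------------------------------------------- abundance profiles

def test_normalized_rows_sum_to_one():
    rng = np.random.default_rng(7)
    ab = pd.DataFrame(rng.uniform(0, 2, size=(20, 4)),
                      index=[f"s{i}" for i in range(20)], columns=list("ABCD"))
    fr = normalize_abundance(ab)
    assert np.allclose(fr.sum(axis=1), 1.0)


def test_single_type_spot_gets_fraction_one_and_zero_total_dropped():
    ab = pd.DataFrame({"A": [3.0, 0.0], "B": [0.0, 0.0]}, index=["s0", "s1"])
    fr = normalize_abundance(ab)
    assert list(fr.index) == ["s0"]
    assert fr.loc["s0", "A"] == 1.0


def test_round_half_up_binning():
    fr = pd.DataFrame({"A": [1.0, 1.0]}, index=["s0", "s1"])
    d = pd.Series([1.49, 1.5], index=["s0", "s1"])
    prof = axis_profile(fr, d).table
    assert sorted(prof["bin"]) == [1, 2]


def test_uniform_fractions_are_flat_across_bins():
    coords = [(r, c) for r in range(6) for c in range(4)]
    grid = _grid_from_coords(coords, epidermis=[i for i, (r, _) in enumerate(coords) if r == 0])
    surf = surface_spots(grid)
    d = distance_to_surface(grid, surf)
    fr = pd.DataFrame({"A": 0.25, "B": 0.75},
                      index=grid.positions.index)
    prof = axis_profile(fr, d)
    a = prof.for_type("A")
    assert np.allclose(a["mean"], 0.25) and np.allclose(a["sd"], 0.0)


def test_bin_populations_partition_spots():
    rng = np.random.default_rng(8)
    coords = sorted({(int(r), int(c)) for r, c in rng.integers(0, 10, size=(50, 2))})
    grid = _grid_from_coords(coords, epidermis=[0])
    d = distance_to_surface(grid, [f"s0"])
    fr = pd.DataFrame({"A": 1.0}, index=grid.positions.index)
    prof = axis_profile(fr, d)
    assert prof.for_type("A")["n"].sum() == len(coords)


def test_planted_linear_decay_gives_strictly_decreasing_means(gradient_grid):
    cfg, grid, truth = gradient_grid
    mask = tissue_mask(grid)
    surf = surface_spots(mask)
    d = distance_to_surface(mask, surf)
    fr = normalize_abundance(mask.abundance)
    prof = axis_profile(fr, d).for_type("Tumor")
    means = prof.sort_values("bin")["mean"].to_numpy()
    assert (np.diff(means) < 0).all()
    # Spearman correlation of bin vs mean is exactly -1 for a monotone decay
    from scipy.stats import spearmanr

    rho, _ = spearmanr(prof["bin"], prof["mean"])
    assert rho == pytest.approx(-1.0)


# ------------------------------------------------------------ microenvironments

def _block_abundance(seed=0, n_spots=90):
    """Three disjoint co-occurrence blocks of cell types across spot thirds."""
    rng = np.random.default_rng(seed)
    ab = pd.DataFrame(
        rng.uniform(0, 0.02, size=(n_spots, 6)),
        index=[f"s{i}" for i in range(n_spots)],
        columns=["T1", "T2", "F1", "F2", "B1", "B2"],
    )
    third = n_spots // 3
    ab.iloc[:third, 0:2] += rng.uniform(1, 2, size=(third, 2))
    ab.iloc[third : 2 * third, 2:4] += rng.uniform(1, 2, size=(third, 2))
    ab.iloc[2 * third :, 4:6] += rng.uniform(1, 2, size=(third, 2))
    return ab


def test_block_structure_groups_cooccurring_types():
    ab = _block_abundance()
    me = microenv_nmf(ab, n_fact=3, seed=0)
    assert me.assignment["T1"] == me.assignment["T2"]
    assert me.assignment["F1"] == me.assignment["F2"]
    assert me.assignment["B1"] == me.assignment["B2"]
    assert me.assignment.nunique() == 3
    assert np.allclose(me.weights.sum(axis=1), 1.0)
    assert (me.silhouettes > 0.5).all()


def test_all_zero_cell_type_flagged_with_uniform_weights():
    ab = _block_abundance()
    ab["DEAD"] = 0.0
    me = microenv_nmf(ab, n_fact=3, seed=0)
    assert me.degenerate_types == ["DEAD"]
    assert np.allclose(me.weights.loc["DEAD"], 1 / 3)


def test_nfact_larger_than_dims_rejected():
    ab = _block_abundance()
    with pytest.raises(ValueError, match="n_fact"):
        microenv_nmf(ab, n_fact=7)


def _brute_silhouette(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    out = np.zeros(len(X))
    for i in range(len(X)):
        same = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not same:
            out[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(len(X))
                     if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


@pytest.mark.parametrize("seed", [0, 1])
def test_silhouette_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(15, 4))
    labels = rng.choice(["x", "y", "z"], size=15)
    w = pd.DataFrame(X, index=[f"t{i}" for i in range(15)])
    s = microenv_silhouette(w, pd.Series(labels, index=w.index))
    assert np.allclose(s.to_numpy(), _brute_silhouette(X, labels), atol=1e-10)
    assert ((s >= -1) & (s <= 1)).all()


def test_equidistant_point_scores_zero():
    X = np.array([[0.0], [0.0], [2.0], [2.0], [1.0]])
    labels = ["a", "a", "b", "b", "a"]
    s = _brute_silhouette(X, labels)
    w = pd.DataFrame(X, index=[f"t{i}" for i in range(5)])
    got = microenv_silhouette(w, pd.Series(labels, index=w.index))
    assert got.iloc[4] == pytest.approx(s[4])


def test_single_cluster_rejected():
    w = pd.DataFrame(np.ones((4, 2)), index=list("abcd"))
    with pytest.raises(ValueError):
        microenv_silhouette(w, pd.Series(["only"] * 4, index=w.index))
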