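"""Neighborhood shells, enrichment ratios, and the mutual graph."""

import numpy as np
import pandas as pd
import pytest

import tmekit as tk
from tmekit.spatial import SpatialGrid
from _oracles import neighborhood_ratio_oracle, shell_neighbors_oracle


def _square_grid(side, fields: dict) -> SpatialGrid:
    """fields: type -> (side x side) array."""
    coords = pd.DataFrame(
        {
            "x": [c for r in range(side) for c in range(side)],
            "y": [r for r in range(side) for c in range(side)],
        },
        index=[f"s{r}_{c}" for r in range(side) for c in range(side)],
    ).astype(float)
    abundance = pd.DataFrame(
        {name: np.asarray(arr, float).ravel() for name, arr in fields.items()},
        index=coords.index,
    ).T
    return SpatialGrid(coords=coords, lattice="square", abundance=abundance)


def test_find_high_spots_strict_threshold():
    grid = _square_grid(3, {"t": [[0, 3.0, 3.0001], [1, 2, 2.9], [5, 0, 0]]})
    assert set(tk.find_high_spots(grid, "t")) == {"s0_2", "s2_0"}
    low = _square_grid(3, {"t": np.full((3, 3), 2.0)})
    assert len(tk.find_high_spots(low, "t")) == 0
    with pytest.raises(KeyError):
        tk.find_high_spots(grid, "nope")


def test_square_interior_three_shells_has_twelve_spots():
    grid = _square_grid(7, {"t": np.zeros((7, 7))})
    nb = tk.neighbor_shells(grid, "s3_3", n_shells=3)
    assert len(nb) == 12  # 4 at d=1, 4 at d=sqrt(2), 4 at d=2
    coords = {s: (grid.coords.loc[s, "x"], grid.coords.loc[s, "y"]) for s in grid.spot_ids}
    assert set(nb) == shell_neighbors_oracle(coords, "s3_3", 3)


def test_corner_spot_shells_match_brute_force():
    grid = _square_grid(7, {"t": np.zeros((7, 7))})
    coords = {s: (grid.coords.loc[s, "x"], grid.coords.loc[s, "y"]) for s in grid.spot_ids}
    for spot in ["s0_0", "s0_3", "s6_6"]:
        nb = set(tk.neighbor_shells(grid, spot, n_shells=3))
        assert nb == shell_neighbors_oracle(coords, spot, 3)
    # corner has fewer realized shells than the interior
    assert len(tk.neighbor_shells(grid, "s0_0", 3)) < 12


def test_shell_symmetry_for_interior_spots():
    grid = _square_grid(9, {"t": np.zeros((9, 9))})
    interior = [f"s{r}_{c}" for r in range(2, 7) for c in range(2, 7)]
    for a in interior[:5]:
        for b in tk.neighbor_shells(grid, a, 2):
            if b in interior:
                assert a in set(tk.neighbor_shells(grid, b, 2))


def test_constant_field_ratio_exactly_one():
    side = 6
    grid = _square_grid(side, {"u": np.full((side, side), 4.0)})
    prof = tk.neighborhood_enrichment(grid, "u")
    assert prof.n_high_spots == side * side
    assert prof.per_type_ratio["u"] == 1.0  # exact, not approximate


def test_five_by_five_worked_example():
    """One central high spot; frozen hand-computed observed/expected table.

    F is 4.0 at the center and zero elsewhere (the only high spot); T is
    constant 1.0; G is 2.0 on the four edge-adjacent spots of the center.
    The 3-shell neighborhood of the center holds 12 spots, so expected_G =
    12 * (8/25) and observed_G = 8, giving ratio 25/12; F contributes
    nothing to its own neighborhood (ratio 0); T gives exactly 1.
    """
    F = np.zeros((5, 5))
    F[2, 2] = 4.0
    G = np.zeros((5, 5))
    G[1, 2] = G[3, 2] = G[2, 1] = G[2, 3] = 2.0
    grid = _square_grid(5, {"F": F, "T": np.ones((5, 5)), "G": G})
    prof = tk.neighborhood_enrichment(grid, "F")
    assert prof.n_high_spots == 1
    assert prof.per_type_ratio["T"] == pytest.approx(1.0, abs=1e-15)
    assert prof.per_type_ratio["G"] == pytest.approx(25 / 12, rel=1e-12)
    assert prof.per_type_ratio["F"] == 0.0


def test_enrichment_matches_brute_force_on_generated_lattice():
    grid, _ = tk.simulate_spatial(tk.SimConfig(grid_side=12, seed=5))
    coords = {s: (grid.coords.loc[s, "x"], grid.coords.loc[s, "y"]) for s in grid.spot_ids}
    abundance = {t: grid.abundance.loc[t].to_dict() for t in grid.cell_types}
    prof = tk.neighborhood_enrichment(grid, "CoA")
    oracle = neighborhood_ratio_oracle(coords, abundance, "CoA", 3.0, 3)
    for t in grid.cell_types:
        assert prof.per_type_ratio[t] == pytest.approx(oracle[t], rel=1e-9)


def test_planted_pairs_drive_enrichment_directions():
    grid, gt = tk.simulate_spatial(tk.SimConfig(grid_side=16, seed=2))
    a, b = gt.colocalized_pairs[0]
    sa, sb = gt.segregated_pairs[0]
    assert tk.neighborhood_enrichment(grid, a).per_type_ratio[b] > 1
    assert tk.neighborhood_enrichment(grid, b).per_type_ratio[a] > 1
    assert tk.neighborhood_enrichment(grid, sa).per_type_ratio[sb] < 1
    assert tk.neighborhood_enrichment(grid, sb).per_type_ratio[sa] < 1


def test_enrichment_invariant_to_type_scaling():
    grid, _ = tk.simulate_spatial(tk.SimConfig(grid_side=10, seed=4))
    prof = tk.neighborhood_enrichment(grid, "CoA")
    scaled = SpatialGrid(
        coords=grid.coords,
        lattice=grid.lattice,
        abundance=grid.abundance.mul(
            pd.Series(3.0, index=grid.abundance.index).where(
                grid.abundance.index != "SegB", 7.0
            ),
            axis=0,
        ),
    )
    # scaling SegB (a non-focal type) leaves its enrichment ratio unchanged
    sprof = tk.neighborhood_enrichment(scaled, "CoA", threshold=9.0)
    assert sprof.per_type_ratio["SegB"] == pytest.approx(prof.per_type_ratio["SegB"], rel=1e-9)


def test_unstructured_field_ratio_near_one():
    """Spatially unstructured abundance: mean enrichment ratio ~ 1 within
    3 standard errors over 50 simulated grids."""
    rng = np.random.default_rng(8)
    vals = []
    for _ in range(50):
        field = rng.uniform(1.0, 6.0, (10, 10))
        grid = _square_grid(10, {"r": field})
        vals.append(tk.neighborhood_enrichment(grid, "r").per_type_ratio["r"])
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 1.0) <= 3 * se + 1e-3


def test_mutual_graph_rules():
    r = lambda d: pd.Series(d)
    p = {
        "A": tk.EnrichmentProfile("A", r({"A": 2.0, "B": 1.4, "C": 0.7}), 5),
        "B": tk.EnrichmentProfile("B", r({"A": 1.2, "B": 2.0, "C": 1.6}), 4),
        "C": tk.EnrichmentProfile("C", r({"A": 0.9, "B": 0.9, "C": 2.0}), 3),
    }
    g = tk.build_mutual_graph([p])
    assert set(g.edges) == {("A", "B")}  # mutuality required; no self-edges
    assert g.edges["A", "B"]["weight"] == pytest.approx((1.4 + 1.2) / 2)
    # one-directional enrichment (B->C 1.6 but C->B 0.9) makes no edge
    assert not g.has_edge("B", "C")
    with pytest.raises(ValueError):
        tk.build_mutual_graph([])


def test_mutual_graph_invariant_to_sample_order():
    grids = [tk.simulate_spatial(tk.SimConfig(grid_side=12, seed=s))[0] for s in range(3)]
    profiles = [tk.enrichment_profiles(g) for g in grids]
    g1 = tk.build_mutual_graph(profiles)
    g2 = tk.build_mutual_graph(profiles[::-1])
    assert set(g1.edges) == set(g2.edges)


def test_planted_pair_edges_across_samples():
    profiles = []
    for s in range(5):
        grid, gt = tk.simulate_spatial(tk.SimConfig(grid_side=16, seed=100 + s))
        profiles.append(tk.enrichment_profiles(grid))
    g = tk.build_mutual_graph(profiles)
    assert g.has_edge("CoA", "CoB")
    assert not g.has_edge("SegA", "SegB")
    # background types were never focal: flagged, no incident edges
    assert g.nodes["Bg1"]["no_high_spots"] and g.degree["Bg1"] == 0


def test_neighborhood_abundance_closed_forms():
    side = 6
    const = np.full((side, side), 2.5)
    focal = np.zeros((side, side))
    focal[3, 3] = 9.0
    grid = _square_grid(side, {"f": focal, "c": const, "z": np.zeros((side, side))})
    assert tk.neighborhood_abundance(grid, "f", "c") == pytest.approx(2.5, abs=1e-12)
    assert tk.neighborhood_abundance(grid, "f", "z") == 0.0
    with pytest.warns(UserWarning, match="no high spots"):
        assert np.isnan(tk.neighborhood_abundance(grid, "z", "c"))
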