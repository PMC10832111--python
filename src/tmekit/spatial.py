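"""Neighborhood enrichment on deconvolved spot-abundance maps.

Works on per-spot cell-type abundance estimates (e.g. the 5%-quantile
posterior abundances of a spatial deconvolution model) laid out on a square
or hexagonal spot lattice. "High spots" of a cell type are spots whose
abundance exceeds a threshold; neighborhoods are distance shells of the
lattice; enrichment is the observed-to-expected ratio of neighboring-spot
abundance, and cell-type pairs enriched in both directions form the edges of
a mutual-enrichment graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SpatialGrid",
    "EnrichmentProfile",
    "find_high_spots",
    "neighbor_shells",
    "neighborhood_enrichment",
    "enrichment_profiles",
    "build_mutual_graph",
    "neighborhood_abundance",
]

_DIST_DECIMALS = 6  # lattice distances equal up to fp noise are one shell


@dataclass
class SpatialGrid:
    """Spot lattice plus a cell-type x spot abundance matrix.

    ``coords`` is indexed by spot id with columns ``x``/``y`` in lattice
    units; ``abundance`` has cell types as rows and the same spot ids as
    columns.
    """

    coords: pd.DataFrame
    lattice: str
    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.coords.index.is_unique:
            raise ValueError("spot ids must be unique")
        if self.coords[["x", "y"]].duplicated().any():
            raise ValueError("spot coordinates must be unique")
        if list(self.abundance.columns) != list(self.coords.index):
            self.abundance = self.abundance.reindex(columns=self.coords.index)
        vals = self.abundance.to_numpy(float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("abundances must be finite and non-negative")

    @property
    def spot_ids(self) -> pd.Index:
        return self.coords.index

    @property
    def cell_types(self) -> pd.Index:
        return self.abundance.index


def find_high_spots(grid: SpatialGrid, cell_type: str, threshold: float = 3.0) -> pd.Index:
    """Spots whose abundance of ``cell_type`` strictly exceeds ``threshold``."""
    if cell_type not in grid.abundance.index:
        raise KeyError(f"unknown cell type: {cell_type!r}")
    row = grid.abundance.loc[cell_type]
    return row.index[row.to_numpy() > threshold]


def neighbor_shells(grid: SpatialGrid, spot: str, n_shells: int = 3) -> pd.Index:
    """Spots within the ``n_shells`` nearest distance shells of ``spot``.

    A shell is a distinct realized center-to-center distance from the focal
    spot; the focal spot itself is excluded. Near the lattice boundary the
    realized distances (hence the shells) differ from the interior ones, so
    the result is always computed from the focal spot's own distance
    spectrum.
    """
    if spot not in grid.coords.index:
        raise KeyError(f"unknown spot: {spot!r}")
    xy = grid.coords[["x", "y"]].to_numpy()
    focal = grid.coords.loc[spot, ["x", "y"]].to_numpy(float)
    d = np.round(np.hypot(xy[:, 0] - focal[0], xy[:, 1] - focal[1]), _DIST_DECIMALS)
    distinct = np.unique(d[d > 0])
    if distinct.size == 0:
        warnings.warn(f"spot {spot!r} is isolated; empty neighborhood")
        return grid.coords.index[:0]
    cutoff = distinct[: n_shells][-1]
    return grid.coords.index[(d > 0) & (d <= cutoff)]


@dataclass
class EnrichmentProfile:
    """Observed-to-expected neighborhood abundance ratios for one focal type."""

    focal_type: str
    per_type_ratio: pd.Series  # cell type -> mean observed/expected ratio
    n_high_spots: int


def _spot_ratios(
    grid: SpatialGrid, high: Iterable[str], n_shells: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-high-spot observed and expected neighborhood profiles."""
    mean_ab = grid.abundance.mean(axis=1)
    observed, expected = {}, {}
    for spot in high:
        nb = neighbor_shells(grid, spot, n_shells)
        observed[spot] = grid.abundance[nb].sum(axis=1)
        expected[spot] = len(nb) * mean_ab
    return pd.DataFrame(observed), pd.DataFrame(expected)


def neighborhood_enrichment(
    grid: SpatialGrid,
    focal_type: str,
    threshold: float = 3.0,
    n_shells: int = 3,
    aggregate: str = "mean_of_ratios",
) -> EnrichmentProfile:
    """Enrichment profile of a focal cell type.

    For each high spot of ``focal_type`` the abundance profiles of its
    neighborhood shells are summed (observed) and compared with the number
    of neighbors times the per-type mean abundance over all spots
    (expected). With ``aggregate="mean_of_ratios"`` (default) the per-spot
    observed/expected ratios are averaged over high spots;
    ``"ratio_of_sums"`` divides the summed observed by the summed expected
    instead. Cell types with zero mean abundance get a NaN ratio.
    """
    high = find_high_spots(grid, focal_type, threshold)
    if len(high) == 0:
        raise ValueError(f"cell type {focal_type!r} has no high spots at threshold {threshold}")
    observed, expected = _spot_ratios(grid, high, n_shells)
    with np.errstate(divide="ignore", invalid="ignore"):
        if aggregate == "mean_of_ratios":
            ratio = (observed / expected).mean(axis=1)
        elif aggregate == "ratio_of_sums":
            ratio = observed.sum(axis=1) / expected.sum(axis=1)
        else:
            raise ValueError(f"unknown aggregate: {aggregate!r}")
    ratio[grid.abundance.mean(axis=1) == 0] = np.nan
    return EnrichmentProfile(focal_type=focal_type, per_type_ratio=ratio, n_high_spots=len(high))


def enrichment_profiles(
    grid: SpatialGrid,
    cell_types: Sequence[str] | None = None,
    threshold: float = 3.0,
    n_shells: int = 3,
    aggregate: str = "mean_of_ratios",
) -> dict[str, EnrichmentProfile]:
    """Profiles for every cell type that has at least one high spot."""
    types = grid.cell_types if cell_types is None else cell_types
    out = {}
    for t in types:
        if len(find_high_spots(grid, t, threshold)) == 0:
            continue
        out[t] = neighborhood_enrichment(grid, t, threshold, n_shells, aggregate)
    return out


def build_mutual_graph(
    sample_profiles: Sequence[Mapping[str, EnrichmentProfile]],
    mean_abundance: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Graph of cell-type pairs enriched in each other's neighborhoods.

    ``sample_profiles`` holds one ``{focal type: EnrichmentProfile}`` mapping
    per sample. The directional score A->B is the unweighted mean over the
    samples in which A has high spots of A's ratio for B; an undirected edge
    A-B exists iff both directional scores exceed 1, with weight equal to
    their mean. Types that are never focal keep their node (flagged
    ``no_high_spots``) but cannot gain edges.
    """
    if len(sample_profiles) == 0:
        raise ValueError("at least one sample of profiles is required")
    all_types: list[str] = []
    for profiles in sample_profiles:
        for prof in profiles.values():
            for t in prof.per_type_ratio.index:
                if t not in all_types:
                    all_types.append(t)
    focal_types = sorted({t for profiles in sample_profiles for t in profiles})

    def directional(a: str, b: str) -> float:
        vals = [
            profiles[a].per_type_ratio.get(b, np.nan)
            for profiles in sample_profiles
            if a in profiles
        ]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    graph = nx.Graph()
    for t in sorted(all_types):
        attrs = {"no_high_spots": t not in focal_types}
        if mean_abundance is not None and t in mean_abundance:
            attrs["mean_abundance"] = float(mean_abundance[t])
        graph.add_node(t, **attrs)
    for i, a in enumerate(focal_types):
        for b in focal_types[i + 1 :]:
            ab, ba = directional(a, b), directional(b, a)
            if np.isfinite(ab) and np.isfinite(ba) and ab > 1.0 and ba > 1.0:
                graph.add_edge(a, b, weight=(ab + ba) / 2.0)
    return graph


def neighborhood_abundance(
    grid: SpatialGrid,
    focal_type: str,
    target_type: str,
    threshold: float = 3.0,
    n_shells: int = 3,
) -> float:
    """Mean per-neighbor abundance of ``target_type`` around the focal type's
    high spots; NaN if the focal type has no high spots."""
    if target_type not in grid.abundance.index:
        raise KeyError(f"unknown cell type: {target_type!r}")
    high = find_high_spots(grid, focal_type, threshold)
    if len(high) == 0:
        warnings.warn(f"cell type {focal_type!r} has no high spots; returning NaN")
        return float("nan")
    vals = []
    target = grid.abundance.loc[target_type]
    for spot in high:
        nb = neighbor_shells(grid, spot, n_shells)
        vals.append(target[nb].sum() / len(nb))
    return float(np.mean(vals))
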