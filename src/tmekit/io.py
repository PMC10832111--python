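"""Plain-text readers and writers for the three input modalities.

Single-cell tables travel as MTX + TSV (counts.mtx in genes x cells
orientation as is conventional for exchange, barcodes.tsv with per-cell
metadata, genes.tsv with per-gene metadata); bulk cohorts as
expression.csv + survival.csv; spatial grids as coords.csv +
abundance.csv; planted ground truth as ground_truth.json.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth
from .spatial import SpatialGrid
from .survival import CohortTable

__all__ = [
    "write_cells",
    "read_cells",
    "write_cohort",
    "read_cohort",
    "write_spatial",
    "read_spatial",
    "write_ground_truth",
    "read_ground_truth",
]


def write_cells(cells: ad.AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = cells.X if sparse.issparse(cells.X) else sparse.csr_matrix(cells.X)
    spio.mmwrite(outdir / "counts.mtx", X.T.astype(int))
    cells.obs.to_csv(outdir / "barcodes.tsv", sep="\t")
    cells.var.to_csv(outdir / "genes.tsv", sep="\t")


def read_cells(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "counts.mtx").T)
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    if "is_singlet" in obs:
        obs["is_singlet"] = obs["is_singlet"].astype(bool)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_cohort(cohort: CohortTable, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expr.to_csv(outdir / "expression.csv")
    pd.DataFrame({"os_time": cohort.os_time, "os_event": cohort.os_event}).to_csv(
        outdir / "survival.csv"
    )


def read_cohort(indir, standardize: bool = False) -> CohortTable:
    """Load a cohort; set ``standardize=True`` for raw (non z-scored) input."""
    indir = Path(indir)
    expr = pd.read_csv(indir / "expression.csv", index_col=0)
    surv = pd.read_csv(indir / "survival.csv", index_col=0)
    if standardize:
        return CohortTable.from_raw(expr, surv["os_time"], surv["os_event"])
    return CohortTable(
        expr=expr, os_time=surv["os_time"].astype(float), os_event=surv["os_event"].astype(int)
    )


def write_spatial(grid: SpatialGrid, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords = grid.coords.copy()
    coords["lattice"] = grid.lattice
    coords.to_csv(outdir / "coords.csv")
    grid.abundance.to_csv(outdir / "abundance.csv")


def read_spatial(indir) -> SpatialGrid:
    indir = Path(indir)
    coords = pd.read_csv(indir / "coords.csv", index_col=0)
    lattice = str(coords["lattice"].iloc[0]) if "lattice" in coords else "square"
    abundance = pd.read_csv(indir / "abundance.csv", index_col=0)
    return SpatialGrid(coords=coords[["x", "y"]], lattice=lattice, abundance=abundance)


def _jsonable(value):
    if isinstance(value, pd.DataFrame):
        return None  # tabular ground truth travels as its own CSV
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, list):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    return value


def write_ground_truth(gt: GroundTruth, path) -> None:
    path = Path(path)
    payload = {
        k: _jsonable(v)
        for k, v in dataclasses.asdict(gt).items()
        if not isinstance(v, pd.DataFrame)
    }
    path.write_text(json.dumps(payload, indent=1))
    if gt.cluster_profiles is not None:
        gt.cluster_profiles.to_csv(path.with_name("cluster_profiles.csv"))


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    payload = json.loads(path.read_text())
    payload["colocalized_pairs"] = [tuple(p) for p in payload.get("colocalized_pairs", [])]
    payload["segregated_pairs"] = [tuple(p) for p in payload.get("segregated_pairs", [])]
    gt = GroundTruth(**payload)
    profiles = path.with_name("cluster_profiles.csv")
    if profiles.exists():
        gt.cluster_profiles = pd.read_csv(profiles, index_col=0)
    return gt
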