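"""Synthetic data generators with recorded ground truth.

Three generators mirror the three input modalities of the tumor-
microenvironment pipeline:

* :func:`simulate_cells` — clustered negative-binomial single-cell count
  matrices with planted cluster-specific marker genes, an optional cycling
  population drawn from parent clusters, and optional planted QC failures;
* :func:`simulate_cohort` — bulk expression cohorts built as Dirichlet
  mixtures of cluster profiles, with exponential survival whose hazard jumps
  when a hidden signature score crosses a planted threshold;
* :func:`simulate_spatial` — spot lattices (square or Visium-style hex) with
  planted co-localized, segregated, and uniform cell-type abundance fields.

Every planted parameter is recorded in a :class:`GroundTruth`, so each
downstream stage has a parameter-recovery oracle without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .survival import CohortTable, standardize_expression
from .spatial import SpatialGrid

__all__ = [
    "ConfigError",
    "SimConfig",
    "GroundTruth",
    "simulate_cells",
    "simulate_cohort",
    "simulate_spatial",
]

# dedicated gene programs appended to the core gene pool
N_CYCLE_GENES = 30
N_MITO_GENES = 10
CYCLE_FOLD = 8.0

# default QC thresholds the generator plants failures against
# (kept in sync with tmekit.qc.QCConfig defaults)
_QC_MIN_UMI = 2000
_QC_MIN_GENES = 500
_QC_MAX_GENES = 7000
_QC_MAX_PCT_MITO = 10.0

# baseline survival scale: exponential with median overall survival of
# 24 months for the low-risk group
_BASELINE_MEDIAN_OS = 24.0


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults are the study conditions used throughout the test suite:
    four clusters of 250 cells over 1000 genes with 20 markers each at
    eight-fold enrichment, a 200-sample bulk cohort with a three-fold hazard
    jump at the median signature score, and a 20x20 spot lattice.
    """

    n_clusters: int = 4
    n_cells_per_cluster: int = 250
    n_genes: int = 1000
    n_markers_per_cluster: int = 20
    marker_fold_change: float = 8.0
    nb_mean: float = 2.0
    nb_dispersion: float = 0.3
    n_patients: int = 8
    cycling_fraction: float = 0.0
    qc_fail_fraction: float = 0.0
    n_samples: int = 200
    hazard_ratio: float = 3.0
    true_cutoff_quantile: float = 0.5
    censor_rate: float = 0.2
    grid_side: int = 20
    lattice: str = "square"
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_clusters": self.n_clusters,
            "n_cells_per_cluster": self.n_cells_per_cluster,
            "n_genes": self.n_genes,
            "n_markers_per_cluster": self.n_markers_per_cluster,
            "n_patients": self.n_patients,
            "n_samples": self.n_samples,
            "grid_side": self.grid_side,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        for name, value in {
            "marker_fold_change": self.marker_fold_change,
            "nb_mean": self.nb_mean,
            "nb_dispersion": self.nb_dispersion,
            "hazard_ratio": self.hazard_ratio,
        }.items():
            if not value > 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")
        for name, value in {
            "cycling_fraction": self.cycling_fraction,
            "qc_fail_fraction": self.qc_fail_fraction,
            "censor_rate": self.censor_rate,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 < self.true_cutoff_quantile < 1.0:
            raise ConfigError("true_cutoff_quantile must lie in (0, 1)")
        if self.lattice not in ("square", "hex"):
            raise ConfigError(f"lattice must be 'square' or 'hex', got {self.lattice!r}")
        n_core = self.n_genes - N_CYCLE_GENES - N_MITO_GENES
        if self.n_clusters * self.n_markers_per_cluster > n_core:
            raise ConfigError(
                "not enough genes for the requested markers: "
                f"{self.n_clusters} clusters x {self.n_markers_per_cluster} markers "
                f"> {n_core} assignable genes "
                f"({self.n_genes} genes minus {N_CYCLE_GENES} cycle "
                f"and {N_MITO_GENES} mitochondrial genes)"
            )


@dataclass
class GroundTruth:
    """Record of everything the generators planted.

    Each generator fills only the fields relevant to its modality; the rest
    stay at their empty defaults.
    """

    planted_markers: dict[str, list[str]] = field(default_factory=dict)
    cycle_genes: list[str] = field(default_factory=list)
    parent_of_cycling_cell: dict[str, str] = field(default_factory=dict)
    qc_fail_cells: dict[str, str] = field(default_factory=dict)  # cell -> criterion
    cluster_profiles: pd.DataFrame | None = None
    signature: list[str] = field(default_factory=list)
    true_cutoff: float | None = None
    high_risk_samples: list[str] = field(default_factory=list)
    colocalized_pairs: list[tuple[str, str]] = field(default_factory=list)
    segregated_pairs: list[tuple[str, str]] = field(default_factory=list)
    uniform_types: list[str] = field(default_factory=list)
    domain_map: dict[str, str] | None = None

    @property
    def qc_fail_cell_set(self) -> set[str]:
        return set(self.qc_fail_cells)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion, size=size)
    return rng.poisson(lam)


def _gene_names(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    n_core = config.n_genes - N_CYCLE_GENES - N_MITO_GENES
    core = [f"G{i:04d}" for i in range(n_core)]
    cycle = [f"CCG{i:02d}" for i in range(N_CYCLE_GENES)]
    mito = [f"MT-{i:02d}" for i in range(N_MITO_GENES)]
    return core, cycle, mito


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a clustered single-cell count matrix with planted structure.

    Returns an :class:`anndata.AnnData` (cells x genes, raw counts in ``X``)
    with populated QC metadata, plus the :class:`GroundTruth`. Marker genes
    of cluster *k* have negative-binomial mean ``nb_mean * marker_fold_change``
    inside *k* and ``nb_mean`` elsewhere; marker sets of different clusters
    are disjoint. A cycling population of ``cycling_fraction`` x (base cell
    count) extra cells is drawn from randomly chosen parent clusters with a
    shared high-expression cycle-gene program superposed. When
    ``qc_fail_fraction > 0``, that fraction of cells is modified to violate
    exactly one QC criterion each (recorded per cell), and all remaining
    cells are guaranteed to pass the default thresholds.
    """
    config.validate()
    if config.qc_fail_fraction > 0 and config.n_genes < 2 * _QC_MIN_GENES:
        raise ConfigError(
            "planting QC failures requires n_genes >= "
            f"{2 * _QC_MIN_GENES} so that passing cells can clear the "
            f"{_QC_MIN_GENES} detected-gene floor"
        )
    rng = np.random.default_rng([config.seed, 0])
    core, cycle, mito = _gene_names(config)
    genes = core + cycle + mito
    n_genes = len(genes)
    n_core = len(core)
    k = config.n_clusters
    cluster_names = [f"C{i}" for i in range(k)]

    # per-gene baseline means: log-normal spread around nb_mean for realism
    sigma = 0.5
    base = config.nb_mean * rng.lognormal(-0.5 * sigma**2, sigma, n_core + N_CYCLE_GENES)
    base = np.concatenate([base, np.full(N_MITO_GENES, 0.02 * config.nb_mean)])

    # disjoint marker sets
    marker_idx = rng.choice(n_core, size=k * config.n_markers_per_cluster, replace=False)
    planted: dict[str, list[str]] = {}
    means = np.tile(base, (k, 1))
    for c in range(k):
        idx = marker_idx[c * config.n_markers_per_cluster : (c + 1) * config.n_markers_per_cluster]
        means[c, idx] *= config.marker_fold_change
        planted[cluster_names[c]] = sorted(genes[i] for i in idx)

    n_base = k * config.n_cells_per_cluster
    blocks = [
        _nb_draw(rng, means[c], config.nb_dispersion, (config.n_cells_per_cluster, n_genes))
        for c in range(k)
    ]
    labels = np.repeat(cluster_names, config.n_cells_per_cluster).tolist()

    n_cyc = int(round(config.cycling_fraction * n_base))
    parents = rng.integers(0, k, n_cyc)
    if n_cyc:
        cyc_means = means[parents].copy()
        cyc_means[:, n_core : n_core + N_CYCLE_GENES] *= CYCLE_FOLD
        blocks.append(_nb_draw(rng, cyc_means, config.nb_dispersion, cyc_means.shape))
        labels += ["Cycling"] * n_cyc

    X = np.vstack(blocks).astype(np.int64)
    n_cells = X.shape[0]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    # the first half of the clusters form one major cell type, the rest the other
    split = max(1, math.ceil(k / 2))
    major_of = {cluster_names[c]: ("epithelial" if c < split else "fibroblast") for c in range(k)}
    majors = [
        major_of[lab] if lab != "Cycling" else major_of[cluster_names[parents[i - n_base]]]
        for i, lab in enumerate(labels)
    ]

    is_singlet = np.ones(n_cells, dtype=bool)
    qc_fail: dict[str, str] = {}
    mito_cols = np.arange(n_core + N_CYCLE_GENES, n_genes)
    if config.qc_fail_fraction > 0:
        _enforce_pass(X, mito_cols)
        n_fail = int(round(config.qc_fail_fraction * n_cells))
        fail_rows = rng.choice(n_cells, size=n_fail, replace=False)
        modes = ["umi", "genes", "mito", "doublet"]
        for j, row in enumerate(fail_rows):
            mode = modes[j % len(modes)]
            if mode == "umi":
                _plant_low_umi(X, row, rng)
            elif mode == "genes":
                _plant_low_genes(X, row, mito_cols)
            elif mode == "mito":
                _plant_high_mito(X, row, mito_cols)
            else:
                is_singlet[row] = False
            qc_fail[cell_ids[row]] = mode

    totals = X.sum(axis=1)
    detected = (X > 0).sum(axis=1)
    pct_mito = 100.0 * X[:, mito_cols].sum(axis=1) / np.maximum(totals, 1)

    obs = pd.DataFrame(
        {
            "patient_id": [f"P{i % config.n_patients:02d}" for i in range(n_cells)],
            "cluster_label": pd.Categorical(labels),
            "major_type": pd.Categorical(majors),
            "total_umi": totals,
            "n_genes_detected": detected,
            "pct_mito": pct_mito,
            "is_singlet": is_singlet,
        },
        index=cell_ids,
    )
    var = pd.DataFrame(
        {"is_mito": [g.startswith("MT-") for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )
    adata = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)

    profiles = pd.DataFrame(means.T, index=genes, columns=cluster_names)
    gt = GroundTruth(
        planted_markers=planted,
        cycle_genes=list(cycle),
        parent_of_cycling_cell={
            cell_ids[n_base + i]: cluster_names[parents[i]] for i in range(n_cyc)
        },
        qc_fail_cells=qc_fail,
        cluster_profiles=profiles,
    )
    return adata, gt


def _enforce_pass(X: np.ndarray, mito_cols: np.ndarray) -> None:
    """Deterministically nudge every cell to pass the default QC thresholds."""
    totals = X.sum(axis=1)
    for row in np.nonzero(totals <= _QC_MIN_UMI)[0]:
        factor = int(_QC_MIN_UMI // max(totals[row], 1)) + 2
        X[row] *= factor
    detected = (X > 0).sum(axis=1)
    for row in np.nonzero(detected < _QC_MIN_GENES)[0]:
        zeros = np.nonzero(X[row] == 0)[0]
        need = _QC_MIN_GENES - detected[row] + 5
        X[row, zeros[:need]] = 1
    mito_share = X[:, mito_cols].sum(axis=1) / np.maximum(X.sum(axis=1), 1)
    for row in np.nonzero(mito_share >= _QC_MAX_PCT_MITO / 100.0)[0]:
        X[row, mito_cols] = 0


def _plant_low_umi(X: np.ndarray, row: int, rng: np.random.Generator) -> None:
    """Thin counts below the UMI threshold without breaking other criteria."""
    target = int(0.7 * _QC_MIN_UMI)
    total = X[row].sum()
    x = rng.binomial(X[row], min(1.0, target / max(total, 1)))
    while x.sum() > _QC_MIN_UMI:  # vanishingly rare; thin further
        x = rng.binomial(x, 0.9)
    detected = int((x > 0).sum())
    if detected < _QC_MIN_GENES:
        zeros = np.nonzero(x == 0)[0]
        need = _QC_MIN_GENES - detected + 5
        x[zeros[:need]] = 1
        excess = x.sum() - _QC_MIN_UMI
        if excess > 0:  # keep the UMI criterion the violated one
            top = int(np.argmax(x))
            x[top] = max(1, x[top] - excess - 1)
    X[row] = x


def _plant_low_genes(X: np.ndarray, row: int, mito_cols: np.ndarray) -> None:
    """Concentrate the cell's counts on few genes, preserving the total."""
    target_genes = int(0.6 * _QC_MIN_GENES)
    x = X[row].copy()
    x[mito_cols] = 0
    total = X[row].sum()
    order = np.argsort(x)[::-1]
    keep = order[:target_genes]
    new = np.zeros_like(x)
    kept_sum = x[keep].sum()
    scale = total / max(kept_sum, 1)
    new[keep] = np.maximum((x[keep] * scale).astype(np.int64), 1)
    if new.sum() <= _QC_MIN_UMI:
        new[keep[0]] += _QC_MIN_UMI + 1 - new.sum()
    X[row] = new


def _plant_high_mito(X: np.ndarray, row: int, mito_cols: np.ndarray) -> None:
    """Raise mitochondrial content to ~20% of the cell's counts."""
    nonmito = X[row].sum() - X[row, mito_cols].sum()
    target = int(math.ceil(0.25 * nonmito)) + len(mito_cols)
    X[row, mito_cols] = target // len(mito_cols) + 1


def simulate_cohort(
    config: SimConfig,
    cluster_profiles: pd.DataFrame,
    signature: Sequence[str],
) -> tuple[CohortTable, GroundTruth]:
    """Generate a bulk cohort as a mixture of cluster profiles plus survival.

    Each sample's raw expression is a Dirichlet-weighted mixture of the
    columns of ``cluster_profiles`` (genes x clusters) plus Gaussian noise,
    then standardized per gene. Signature scores (mean standardized
    expression over ``signature``) above the ``true_cutoff_quantile``
    quantile multiply the exponential hazard by ``hazard_ratio``; censoring
    is an independent exponential whose rate gives a baseline censoring
    probability of ``censor_rate``.
    """
    config.validate()
    if len(signature) == 0:
        raise ConfigError("signature gene set must not be empty")
    missing = [g for g in signature if g not in cluster_profiles.index]
    if missing:
        raise ConfigError(f"signature genes absent from cluster_profiles: {missing[:5]}")
    if config.censor_rate >= 1.0:
        raise ConfigError("censor_rate must be < 1 (all-censored cohort is degenerate)")

    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    P = cluster_profiles.to_numpy(float)
    k = P.shape[1]
    weights = rng.dirichlet(np.ones(k), size=n)
    raw = weights @ P.T
    # heteroscedastic per-gene noise: sd = 50% of the gene's mean profile
    # level (a typical inter-tumor CV), floored so silent genes still vary
    noise_sd = 0.5 * P.mean(axis=1) + 0.05 * float(P.mean())
    raw = raw + rng.normal(0.0, 1.0, raw.shape) * noise_sd
    sample_ids = [f"S{i:03d}" for i in range(n)]
    expr = standardize_expression(
        pd.DataFrame(raw, index=sample_ids, columns=cluster_profiles.index)
    )

    present = [g for g in signature if g in expr.columns]
    scores = expr[present].mean(axis=1)
    cutoff = float(np.quantile(scores, config.true_cutoff_quantile))
    high = scores.to_numpy() > cutoff

    lam0 = math.log(2.0) / _BASELINE_MEDIAN_OS
    lam = np.where(high, lam0 * config.hazard_ratio, lam0)
    event_time = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        lam_c = lam0 * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / lam_c, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    cohort = CohortTable(
        expr=expr,
        os_time=pd.Series(os_time, index=sample_ids, name="os_time"),
        os_event=pd.Series(os_event, index=sample_ids, name="os_event"),
    )
    gt = GroundTruth(
        signature=list(signature),
        true_cutoff=cutoff,
        high_risk_samples=[s for s, h in zip(sample_ids, high) if h],
    )
    return cohort, gt


def _lattice_coords(grid_side: int, lattice: str) -> pd.DataFrame:
    rows, cols = np.mgrid[0:grid_side, 0:grid_side]
    rows = rows.ravel()
    cols = cols.ravel()
    if lattice == "hex":
        x = cols + 0.5 * (rows % 2)
        y = rows * (math.sqrt(3.0) / 2.0)
    else:
        x = cols.astype(float)
        y = rows.astype(float)
    ids = [f"s{i:04d}" for i in range(grid_side * grid_side)]
    return pd.DataFrame({"x": x, "y": y}, index=pd.Index(ids, name="spot_id"))


def simulate_spatial(config: SimConfig) -> tuple[SpatialGrid, GroundTruth]:
    """Generate a spot lattice with planted abundance fields.

    Seven cell types are planted: one exactly uniform type (constant
    abundance above the high-spot threshold), a co-localized pair sharing one
    circular domain, a segregated pair occupying two distant disjoint
    domains, and two unstructured low-abundance background types. Domain
    spots are scaled well above the default high-spot threshold of 3 and all
    non-domain abundances stay well below it.
    """
    config.validate()
    if config.grid_side < 8:
        raise ConfigError("grid_side must be >= 8")
    rng = np.random.default_rng([config.seed, 2])
    coords = _lattice_coords(config.grid_side, config.lattice)
    xy = coords[["x", "y"]].to_numpy()
    ex, ey = xy.max(axis=0)

    radius = max(1.5, config.grid_side / 7.0)
    centers = {
        "coloc": (0.25 * ex, 0.75 * ey),
        "segA": (0.25 * ex, 0.25 * ey),
        "segB": (0.75 * ex, 0.75 * ey),
    }
    in_domain = {
        name: np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) <= radius
        for name, (cx, cy) in centers.items()
    }

    n = len(coords)

    def _field(mask: np.ndarray) -> np.ndarray:
        low = rng.uniform(0.05, 0.5, n)
        high = 5.0 + rng.uniform(0.0, 1.0, n)
        return np.where(mask, high, low)

    abundance = pd.DataFrame(
        {
            "Uniform": np.full(n, 4.0),
            "CoA": _field(in_domain["coloc"]),
            "CoB": _field(in_domain["coloc"]),
            "SegA": _field(in_domain["segA"]),
            "SegB": _field(in_domain["segB"]),
            "Bg1": rng.uniform(0.1, 1.5, n),
            "Bg2": rng.uniform(0.1, 1.5, n),
        },
        index=coords.index,
    ).T

    domain_map = {}
    for i, spot in enumerate(coords.index):
        for name in ("coloc", "segA", "segB"):
            if in_domain[name][i]:
                domain_map[spot] = name
                break
        else:
            domain_map[spot] = "none"

    grid = SpatialGrid(coords=coords, lattice=config.lattice, abundance=abundance)
    gt = GroundTruth(
        colocalized_pairs=[("CoA", "CoB")],
        segregated_pairs=[("SegA", "SegB")],
        uniform_types=["Uniform"],
        domain_map=domain_map,
    )
    return grid, gt
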