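"""Cell quality-control filtering and count normalization.

Cells are kept only if their UMI total strictly exceeds ``min_umi``, their
detected-gene count lies inclusively between ``min_genes`` and
``max_genes``, their mitochondrial percentage is strictly below
``max_pct_mito``, and (optionally) they are predicted singlets. The
boundary semantics are deliberate and tested: strict on UMI and
mitochondrial content, inclusive on the detected-gene range.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
from scipy import sparse

__all__ = ["QCConfig", "filter_cells", "normalize_log", "compute_qc_metrics"]


@dataclass
class QCConfig:
    min_umi: int = 2000
    min_genes: int = 500
    max_genes: int = 7000
    max_pct_mito: float = 10.0
    require_singlet: bool = True

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if self.min_umi <= 0 or self.min_genes <= 0 or self.max_pct_mito <= 0:
            raise ValueError("QC thresholds must be positive")


def compute_qc_metrics(cells: ad.AnnData) -> ad.AnnData:
    """Populate total_umi, n_genes_detected and pct_mito from the counts."""
    X = cells.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    if "is_mito" in cells.var:
        mito = np.asarray(X[:, cells.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(totals)
    cells.obs["total_umi"] = totals.astype(int)
    cells.obs["n_genes_detected"] = detected.astype(int)
    cells.obs["pct_mito"] = 100.0 * mito / np.maximum(totals, 1)
    return cells


def filter_cells(cells: ad.AnnData, qc: QCConfig | None = None) -> ad.AnnData:
    """Return the subset of cells passing every QC criterion.

    The returned object carries a per-criterion removal tally in
    ``.uns["qc_log"]`` (criteria are counted independently, so a cell can
    appear under several). A missing QC metadata field raises a KeyError
    naming the field.
    """
    qc = qc or QCConfig()
    required = ["total_umi", "n_genes_detected", "pct_mito"]
    if qc.require_singlet:
        required.append("is_singlet")
    for fieldname in required:
        if fieldname not in cells.obs:
            raise KeyError(f"QC field {fieldname!r} missing from cell metadata")

    obs = cells.obs
    pass_umi = obs["total_umi"].to_numpy() > qc.min_umi
    genes = obs["n_genes_detected"].to_numpy()
    pass_genes = (genes >= qc.min_genes) & (genes <= qc.max_genes)
    pass_mito = obs["pct_mito"].to_numpy() < qc.max_pct_mito
    if qc.require_singlet:
        pass_singlet = obs["is_singlet"].to_numpy().astype(bool)
    else:
        pass_singlet = np.ones(cells.n_obs, dtype=bool)
    keep = pass_umi & pass_genes & pass_mito & pass_singlet

    out = cells[keep].copy()
    out.uns["qc_log"] = {
        "n_input": int(cells.n_obs),
        "n_retained": int(keep.sum()),
        "removed_low_umi": int((~pass_umi).sum()),
        "removed_gene_range": int((~pass_genes).sum()),
        "removed_high_mito": int((~pass_mito).sum()),
        "removed_doublet": int((~pass_singlet).sum()),
    }
    return out


def normalize_log(cells: ad.AnnData, target_sum: int = 10_000) -> ad.AnnData:
    """Total-count normalize to ``target_sum`` per cell and log-transform.

    Writes ``lognorm[g, c] = log(1 + target_sum * counts[g, c] / total[c])``
    into ``.layers["lognorm"]`` of a copy; the counts layer is untouched.
    A cell with zero total counts cannot be normalized and raises.
    """
    X = cells.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cannot normalize: at least one cell has zero total counts")
    out = cells.copy()
    if sparse.issparse(X):
        L = X.astype(float).multiply(target_sum / totals[:, None]).tocsr()
        L.data = np.log1p(L.data)
    else:
        L = np.log1p(np.asarray(X, float) * (target_sum / totals[:, None]))
    out.layers["lognorm"] = L
    return out
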