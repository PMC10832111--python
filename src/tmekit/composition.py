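"""Patient-level subcluster composition, hierarchical stratification, and
Shannon diversity.

Compositions are per-patient subcluster proportions computed separately
within compartments (e.g. the cancer-cell and CAF populations), so each
patient's proportions sum to 1 within each compartment. Patients are
stratified by Ward/Euclidean agglomerative clustering on the concatenated
compartment proportions, and compartment diversity is the Shannon index of
the proportion vector.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = ["composition_matrix", "cluster_patients", "shannon_index"]


def composition_matrix(
    cells: ad.AnnData,
    compartment_map: dict,
    patient_key: str = "patient_id",
    cluster_key: str = "cluster_label",
) -> pd.DataFrame:
    """Per-patient subcluster proportions, normalized within compartments.

    ``compartment_map`` maps each subcluster label to a compartment name;
    unmapped clusters are ignored. Columns are a ``(compartment, cluster)``
    MultiIndex. A patient with zero cells in a compartment gets NaN for
    that compartment's columns, recorded in
    ``result.attrs["empty_compartments"]``.
    """
    obs = cells.obs
    frame = pd.DataFrame(
        {
            "patient": obs[patient_key].astype(str),
            "cluster": obs[cluster_key].astype(str),
        }
    )
    frame["compartment"] = frame["cluster"].map(compartment_map)
    frame = frame.dropna(subset=["compartment"])
    counts = pd.crosstab(frame["patient"], [frame["compartment"], frame["cluster"]])
    counts.columns.names = ["compartment", "cluster"]

    empty = []
    blocks = []
    for comp in counts.columns.get_level_values(0).unique():
        block = counts[comp]
        totals = block.sum(axis=1)
        props = block.div(totals, axis=0)
        for patient in props.index[totals == 0]:
            empty.append((patient, comp))
        blocks.append(pd.concat({comp: props}, axis=1))
    out = pd.concat(blocks, axis=1)
    out.attrs["empty_compartments"] = empty
    return out


def cluster_patients(
    comp: pd.DataFrame,
    k: int = 3,
    method: str = "ward",
    metric: str = "euclidean",
) -> pd.Series:
    """Stratify patients by hierarchical clustering of their compositions.

    The tree (default Ward linkage on Euclidean distances over the
    concatenated compartment proportions) is cut at ``k`` groups. Patients
    with incomplete rows (an empty compartment) are excluded and labelled
    -1. Rows are sorted by patient id before linkage and groups are
    relabelled 0..k-1 by first appearance in that order, so the result does
    not depend on the input row order.
    """
    complete = comp.dropna()
    if k > len(complete):
        raise ValueError(f"k={k} exceeds the {len(complete)} patients with complete rows")
    ordered = complete.sort_index()
    Z = linkage(pdist(ordered.to_numpy(float), metric=metric), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel)
    labels = pd.Series([relabel[r] for r in raw], index=ordered.index, name="group")
    return labels.reindex(comp.index, fill_value=-1)


def shannon_index(proportions, base: float | None = None) -> float:
    """Shannon diversity H = -sum(p * log p) of a proportion vector.

    Zero proportions contribute nothing; natural log by default (pass
    ``base`` to change). The input must be non-negative and sum to 1.
    """
    p = np.asarray(list(proportions), float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h
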