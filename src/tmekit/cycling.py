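"""Parent-identity transfer for cycling cells and proliferation enrichment.

Cycling cells share a strong common cell-cycle program that masks their
cluster of origin, so parent identities are recovered by a multinomial
ridge-penalized logistic regression trained on the non-cycling cells with
cell-cycle genes excluded from the features. Enrichment of each parent
cluster among cycling cells is the ratio of its fraction in the cycling
compartment to its fraction in the non-cycling compartment, with a pooled
two-proportion z-test per cluster.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = ["transfer_labels", "cycling_enrichment"]


def transfer_labels(
    cells: ad.AnnData,
    cycling_cluster: str,
    cycle_genes=(),
    cluster_key: str = "cluster_label",
    C: float = 1.0,
    holdout: float = 0.2,
    seed: int = 0,
    layer: str = "lognorm",
) -> tuple[pd.Series, float]:
    """Predict a parent (non-cycling) cluster for every cycling cell.

    Fits a multinomial logistic regression (L2 penalty, fixed strength
    ``C``) on the log-normalized features of the non-cycling reference
    cells, with ``cycle_genes`` removed from the feature space, and reports
    the accuracy on a held-out stratified ``holdout`` fraction of the
    reference before refitting on all reference cells. Returns the
    per-cycling-cell predictions and the held-out accuracy.
    """
    labels = cells.obs[cluster_key].astype(str)
    is_cycling = (labels == cycling_cluster).to_numpy()
    if not is_cycling.any():
        raise ValueError(f"cycling cluster {cycling_cluster!r} not present")
    feature_mask = ~cells.var_names.isin(list(cycle_genes))
    X = cells.layers[layer][:, feature_mask]
    if sparse.issparse(X):
        X = X.tocsr()

    y_ref = labels[~is_cycling]
    counts = y_ref.value_counts()
    small = counts[counts < 10]
    if len(small):
        warnings.warn(f"reference clusters with < 10 cells: {sorted(small.index)}")
    if counts.size < 2:
        raise ValueError("label transfer needs at least two reference clusters")

    X_ref = X[~is_cycling]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X_ref, y_ref, test_size=holdout, random_state=seed, stratify=y_ref
    )
    model = LogisticRegression(C=C, max_iter=2000)
    model.fit(X_tr, y_tr)
    acc = float(accuracy_score(y_te, model.predict(X_te)))
    model.fit(X_ref, y_ref)
    preds = model.predict(X[is_cycling])
    return pd.Series(preds, index=cells.obs_names[is_cycling], name="parent"), acc


def cycling_enrichment(
    parent_labels,
    noncycling_labels,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-cluster enrichment of the cycling compartment with significance.

    ``enrichment`` is the cluster's fraction among cycling cells divided by
    its fraction among non-cycling cells; significance comes from a
    two-sided pooled two-proportion z-test. ``call`` is ``enriched`` when
    enrichment > 1 and p < alpha, ``depleted`` when < 1 and p < alpha, else
    ``ns``. A cluster absent from the non-cycling compartment has infinite
    enrichment and is flagged ``undefined``. No multiplicity correction is
    applied by default; pass ``correction="fdr_bh"`` (or any statsmodels
    method name) to adjust the p-values before calling.
    """
    cyc = pd.Series(parent_labels).astype(str)
    ncyc = pd.Series(noncycling_labels).astype(str)
    if cyc.empty or ncyc.empty:
        raise ValueError("both compartments must be non-empty")
    n1, n2 = len(cyc), len(ncyc)
    clusters = sorted(set(cyc) | set(ncyc))
    rows = []
    for cl in clusters:
        x1 = int((cyc == cl).sum())
        x2 = int((ncyc == cl).sum())
        f1, f2 = x1 / n1, x2 / n2
        enrich = f1 / f2 if f2 > 0 else float("inf")
        z, p = proportions_ztest([x1, x2], [n1, n2])
        rows.append(
            {
                "cluster": cl,
                "frac_cycling": f1,
                "frac_noncycling": f2,
                "enrichment": enrich,
                "z": float(z),
                "pvalue": float(p),
                "undefined": f2 == 0,
            }
        )
    out = pd.DataFrame(rows).set_index("cluster")
    pvals = out["pvalue"].to_numpy()
    if correction is not None:
        pvals = multipletests(pvals, method=correction)[1]
        out["p_adj"] = pvals
    sig = pvals < alpha
    out["call"] = np.select(
        [sig & (out["enrichment"] > 1), sig & (out["enrichment"] < 1)],
        ["enriched", "depleted"],
        default="ns",
    )
    return out
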