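"""Gap-score marker ranking, refinement against major cell types, and
gene-set signature scoring.

The specificity measure is the *gap score*: per gene, the cluster means of
log-normalized expression are divided by the top-expressing cluster's mean
(so the top value becomes 1) and the gap is 1 minus the second-highest
normalized value. A gene with a clean cluster-exclusive expression pattern
has gap 1; a gene expressed evenly across clusters has gap 0. Candidates
must additionally clear an absolute expression floor and an
expressing-fraction floor, are ranked by gap within their top cluster, and
are confirmed by a one-vs-rest Wilcoxon rank-sum test with Benjamini-
Hochberg correction.

Refinement removes markers that leak into other *major* cell types, making
the surviving ("refined") sets usable on bulk tissue expression where all
cell types are mixed.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_markers", "refine_markers", "score_gene_set", "top_gap_markers"]


def _group_stats(X, labels: pd.Series) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-cluster means and expressing fractions (clusters x genes)."""
    cats = sorted(pd.unique(labels))
    n = X.shape[0]
    onehot = sparse.csr_matrix(
        (np.ones(n), (pd.Categorical(labels, categories=cats).codes, np.arange(n))),
        shape=(len(cats), n),
    )
    sizes = np.asarray(onehot.sum(axis=1)).ravel()

    def _dense(m):
        return m.toarray() if sparse.issparse(m) else np.asarray(m)

    means = _dense(onehot @ X) / sizes[:, None]
    if sparse.issparse(X):
        B = X.copy()
        B.data = np.ones_like(B.data)
    else:
        B = (np.asarray(X) > 0).astype(float)
    fracs = _dense(onehot @ B) / sizes[:, None]
    return means, fracs, cats


def _resolve_grouping(cells: ad.AnnData, grouping) -> pd.Series:
    if isinstance(grouping, str):
        return cells.obs[grouping].astype(str)
    return pd.Series(np.asarray(grouping, dtype=object), index=cells.obs_names).astype(str)


def rank_markers(
    cells: ad.AnnData,
    grouping="cluster_label",
    min_top_mean: float = 0.4,
    min_fraction: float = 0.10,
    alpha: float = 0.05,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Rank genes by gap score and test candidates one-vs-rest.

    ``grouping`` is an ``obs`` column name or a label vector with at least
    two clusters. Returns one record per gene (genes with all-zero cluster
    means are excluded) with columns ``gene_id, cluster, top_mean,
    second_norm, gap, expr_fraction, pvalue, p_adj, candidate, final,
    refined``, sorted by cluster and descending gap. Only candidate genes
    (top mean strictly above ``min_top_mean`` and expressing fraction
    strictly above ``min_fraction``) are tested; ``final`` marks candidates
    with BH-adjusted p below ``alpha``. Ties for the top cluster break
    toward the higher expressing fraction, then the lexicographically
    smaller cluster name.
    """
    labels = _resolve_grouping(cells, grouping)
    if labels.nunique() < 2:
        raise ValueError("marker ranking requires at least two clusters")
    X = cells.layers[layer]
    means, fracs, cats = _group_stats(X, labels)
    n_genes = means.shape[1]

    top_val = means.max(axis=0)
    keep = top_val > 0  # all-zero genes carry no marker information
    top_idx = means.argmax(axis=0)
    # resolve exact ties deterministically
    for g in np.nonzero((means == top_val).sum(axis=0) > 1)[0]:
        tied = np.nonzero(means[:, g] == top_val[g])[0]
        top_idx[g] = min(tied, key=lambda c: (-fracs[c, g], cats[c]))

    masked = means.copy()
    masked[top_idx, np.arange(n_genes)] = -np.inf
    second = masked.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        second_norm = np.where(top_val > 0, second / top_val, np.nan)
    gap = 1.0 - second_norm
    expr_fraction = fracs[top_idx, np.arange(n_genes)]
    candidate = keep & (top_val > min_top_mean) & (expr_fraction > min_fraction)

    pvalues = np.full(n_genes, np.nan)
    Xd = X.toarray() if sparse.issparse(X) else np.asarray(X)
    for ci, cat in enumerate(cats):
        gidx = np.nonzero(candidate & (top_idx == ci))[0]
        if gidx.size == 0:
            continue
        in_c = (labels == cat).to_numpy()
        pvalues[gidx] = mannwhitneyu(
            Xd[np.ix_(in_c, gidx)], Xd[np.ix_(~in_c, gidx)], alternative="two-sided", axis=0
        ).pvalue

    p_adj = np.full(n_genes, np.nan)
    if candidate.any():
        p_adj[candidate] = multipletests(pvalues[candidate], method="fdr_bh")[1]

    records = pd.DataFrame(
        {
            "gene_id": cells.var_names,
            "cluster": [cats[i] for i in top_idx],
            "top_mean": top_val,
            "second_norm": second_norm,
            "gap": gap,
            "expr_fraction": expr_fraction,
            "pvalue": pvalues,
            "p_adj": p_adj,
            "candidate": candidate,
            "final": candidate & (p_adj < alpha),
            "refined": False,
        }
    )[keep]
    return records.sort_values(
        ["cluster", "gap", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def top_gap_markers(records: pd.DataFrame, cluster: str, n: int) -> list[str]:
    """Top-n candidate genes of a cluster by descending gap score."""
    sub = records[(records["cluster"] == cluster) & records["candidate"]]
    return sub.nlargest(n, "gap")["gene_id"].tolist()


def refine_markers(
    markers: pd.DataFrame,
    cells: ad.AnnData,
    major_grouping="major_type",
    leakage_ratio: float = 0.5,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Flag markers whose expression stays confined to their own major type.

    A marker is *refined* iff, in every major cell type other than the one
    containing its top cluster, the mean log-normalized expression is
    strictly below ``leakage_ratio`` times the marker's top-cluster mean.
    The cluster-to-major-type assignment is taken as the majority major
    type among the cluster's cells. Returns a copy of ``markers`` with the
    ``refined`` flag set.
    """
    majors = _resolve_grouping(cells, major_grouping)
    major_means, _, major_cats = _group_stats(cells.layers[layer], majors)
    gene_pos = {g: i for i, g in enumerate(cells.var_names)}

    cluster_labels = cells.obs["cluster_label"].astype(str)
    major_of_cluster = (
        pd.crosstab(cluster_labels, majors).idxmax(axis=1).to_dict()
    )

    out = markers.copy()
    refined = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        home = major_of_cluster.get(row.cluster)
        g = gene_pos[row.gene_id]
        ok = True
        for mi, m in enumerate(major_cats):
            if m == home:
                continue
            if not major_means[mi, g] < leakage_ratio * row.top_mean:
                ok = False
                break
        refined[i] = ok
    out["refined"] = refined
    return out


def score_gene_set(data, gene_set, layer: str = "lognorm") -> pd.Series:
    """Mean expression of a gene set per observation (cell or sample).

    ``data`` is either a sample x gene DataFrame or an AnnData (scored on
    ``layer``). Set genes absent from the matrix are dropped with a
    warning; an entirely absent set raises.
    """
    if isinstance(data, ad.AnnData):
        X = data.layers[layer] if layer in data.layers else data.X
        frame = pd.DataFrame(
            X.toarray() if sparse.issparse(X) else np.asarray(X),
            index=data.obs_names,
            columns=data.var_names,
        )
    else:
        frame = data
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in frame.columns]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if missing:
        warnings.warn(f"{len(missing)} gene(s) of the set absent and dropped: {missing[:5]}")
    return frame[present].mean(axis=1)
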