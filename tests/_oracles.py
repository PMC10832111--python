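"""Independent brute-force oracles used by the tests.

Everything here is written as plain scalar loops or direct enumeration,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def lognorm_oracle(counts: np.ndarray, target_sum: float) -> np.ndarray:
    """Scalar-loop total-count normalization + log1p (cells x genes)."""
    n, g = counts.shape
    out = np.zeros((n, g))
    for i in range(n):
        total = sum(counts[i, j] for j in range(g))
        for j in range(g):
            out[i, j] = math.log(1.0 + target_sum * counts[i, j] / total)
    return out


def marker_stats_oracle(lognorm: np.ndarray, labels: list, genes: list) -> dict:
    """Scalar-loop gap-score table: gene -> (cluster, top_mean, second_norm,
    gap, expr_fraction); genes with all-zero means are omitted. Top-cluster
    ties break by higher expressing fraction then cluster name."""
    cats = sorted(set(labels))
    out = {}
    for j, gene in enumerate(genes):
        means, fracs = {}, {}
        for c in cats:
            vals = [lognorm[i, j] for i in range(len(labels)) if labels[i] == c]
            means[c] = sum(vals) / len(vals)
            fracs[c] = sum(1 for v in vals if v != 0) / len(vals)
        top_val = max(means.values())
        if top_val == 0:
            continue
        tied = [c for c in cats if means[c] == top_val]
        top = min(tied, key=lambda c: (-fracs[c], c))
        second = max(means[c] for c in cats if c != top)
        second_norm = second / top_val
        out[gene] = (top, top_val, second_norm, 1.0 - second_norm, fracs[top])
    return out


def score_oracle(matrix: np.ndarray, cols: list, gene_set: list) -> np.ndarray:
    """Scalar-loop mean over the present set genes, per row."""
    idx = [cols.index(g) for g in gene_set if g in cols]
    return np.array(
        [sum(matrix[i, j] for j in idx) / len(idx) for i in range(matrix.shape[0])]
    )


def logrank_stat_oracle(times, events, in_a) -> float:
    """Life-table log-rank chi-square statistic, (sum(O-E))^2 / sum(V)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_a = np.asarray(in_a, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def logrank_permutation_p(times, events, in_a, n_perm: int, rng) -> float:
    """Permutation p of the log-rank statistic under group-label shuffling."""
    obs = logrank_stat_oracle(times, events, in_a)
    in_a = np.asarray(in_a, bool)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(in_a)
        if logrank_stat_oracle(times, events, perm) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def km_oracle(times, events) -> dict:
    """Product-limit estimate by explicit life table: event time -> S(t)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    surv = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / n
        out[t] = surv
    return out


def two_proportion_z_oracle(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, closed form."""
    from scipy.stats import norm

    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return z, 2 * norm.sf(abs(z))


def shell_neighbors_oracle(coords: dict, spot, n_shells: int) -> set:
    """Brute-force shell enumeration over explicit distance lists."""
    x0, y0 = coords[spot]
    dists = {}
    for s, (x, y) in coords.items():
        if s == spot:
            continue
        dists[s] = round(math.hypot(x - x0, y - y0), 6)
    shells = sorted(set(dists.values()))[:n_shells]
    return {s for s, d in dists.items() if d in shells}


def shannon_oracle(props) -> float:
    h = 0.0
    for p in props:
        if p > 0:
            h -= p * math.log(p)
    return h


def neighborhood_ratio_oracle(coords, abundance, focal, threshold, n_shells):
    """Brute-force observed/expected enrichment profile.

    coords: spot -> (x, y); abundance: type -> {spot: value}. Returns
    type -> mean over the focal type's high spots of obs/exp ratios.
    """
    spots = list(coords)
    high = [s for s in spots if abundance[focal][s] > threshold]
    means = {t: sum(vals[s] for s in spots) / len(spots) for t, vals in abundance.items()}
    ratios = {t: [] for t in abundance}
    for s in high:
        nb = shell_neighbors_oracle(coords, s, n_shells)
        for t, vals in abundance.items():
            obs = sum(vals[x] for x in nb)
            exp = len(nb) * means[t]
            ratios[t].append(obs / exp)
    return {t: sum(v) / len(v) for t, v in ratios.items()}
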