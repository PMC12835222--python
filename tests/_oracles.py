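"""Independent brute-force oracles used to freeze expected values.

Everything here is written as plainly as possible (explicit loops, direct
formulas) and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def _avg_ranks(values):
    """1-based ranks with ties averaged, via explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Direct implementation of the trimmed weighted mean of M-values."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    # reference: 75th percentile count fraction closest to the mean
    f75 = [np.quantile(counts[:, j], 0.75) / lib[j] for j in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - mean75))
    log_factors = []
    for j in range(n_samples):
        ms, as_, vs = [], [], []
        for g in range(n_genes):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                vs.append(
                    (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
                )
        if not ms or max(abs(m) for m in ms) < 1e-6:
            log_factors.append(0.0)
            continue
        n = len(ms)
        rm = _avg_ranks(ms)
        ra = _avg_ranks(as_)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
        log_factors.append(num / den if den > 0 else 0.0)
    factors = [2.0**f for f in log_factors]
    gm = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return np.array([f / gm for f in factors])


def normal_equations_fit(y: np.ndarray, x: np.ndarray):
    """Gene-by-gene OLS through explicit normal equations."""
    xtx_inv = np.linalg.inv(x.T @ x)
    betas = []
    for g in range(y.shape[0]):
        betas.append(xtx_inv @ x.T @ y[g])
    return np.array(betas)


def stepup_bh(pvals):
    """Benjamini-Hochberg by the literal step-up definition."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * n / (rank_idx + 1))
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return np.array(adj)


def spearman_matrix(values: np.ndarray):
    """Rank columns (average ties) then Pearson-correlate every pair."""
    n_genes, n_samples = values.shape
    ranks = np.column_stack(
        [_avg_ranks(list(values[:, j])) for j in range(n_samples)]
    )
    out = np.ones((n_samples, n_samples))
    for a in range(n_samples):
        for b in range(a + 1, n_samples):
            ra = ranks[:, a] - ranks[:, a].mean()
            rb = ranks[:, b] - ranks[:, b].mean()
            r = float(ra @ rb / math.sqrt((ra @ ra) * (rb @ rb)))
            out[a, b] = out[b, a] = r
    return out


def running_sum_es(gene_order, weights, members, exponent):
    """Step-by-step running-sum enrichment score."""
    members = set(members)
    n = len(gene_order)
    hits = [g in members for g in gene_order]
    nh = sum(hits)
    wsum = sum(abs(w) ** exponent for g, w in zip(gene_order, weights) if g in members)
    running = []
    total = 0.0
    for g, w, h in zip(gene_order, weights, hits):
        if h:
            total += (abs(w) ** exponent / wsum) if wsum > 0 else 1.0 / nh
        else:
            total -= 1.0 / (n - nh)
        running.append(total)
    es = max(running, key=abs)
    return es, running
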