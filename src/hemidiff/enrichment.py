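"""Preranked running-sum gene-set enrichment with permutation significance.

Given a gene list ranked by a signed significance key, the running sum
increments at set members (proportionally to |weight|^exponent normalized
over members) and decrements by 1/(N - set size) elsewhere; the
enrichment score (ES) is the signed extremum of the walk.  Significance
comes from a gene-label permutation null; FDR is Benjamini-Hochberg over
sets.  A hypergeometric over-representation test on a significant-gene
cut is provided as a cheap alternative to network-based enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection
from .de import benjamini_hochberg

__all__ = [
    "rank_genes",
    "preranked_es",
    "permutation_p",
    "enrich_collection",
    "hypergeometric_ora",
]


def rank_genes(de: pd.DataFrame, key: str = "signed_logp") -> pd.DataFrame:
    """Order a DE table for preranked enrichment.

    ``signed_logp`` ranks by sign(log2fc) * -log10(p) (significance-ranked,
    most up-significant first); ``t_mod`` ranks by the moderated t.
    """
    df = de.copy()
    if key == "signed_logp":
        df["weight"] = np.sign(df["log2fc"]) * -np.log10(df["p"])
    elif key == "t_mod":
        df["weight"] = df["t_mod"]
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    df = df.sort_values(
        ["weight", "gene_id"], ascending=[False, True], kind="stable"
    )
    return df[["gene_id", "weight"]].reset_index(drop=True)


def preranked_es(
    ranked: pd.DataFrame, gene_set: list, exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and the full running sum.

    Returns (ES, running sum over list positions).  ES is NaN when the set
    does not intersect the ranking.
    """
    genes = ranked["gene_id"].to_numpy()
    weights = ranked["weight"].to_numpy(dtype=float)
    hits = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    n = genes.size
    nh = int(hits.sum())
    if nh == 0:
        return float("nan"), np.zeros(n)
    if nh == n:
        raise ValueError("gene set covers the entire ranking")
    inc = np.abs(weights) ** exponent
    inc_sum = inc[hits].sum()
    steps = np.where(
        hits,
        (inc / inc_sum if inc_sum > 0 else np.full(n, 1.0 / nh)),
        -1.0 / (n - nh),
    )
    # when all hit weights are zero (inc_sum == 0) fall back to equal steps
    if inc_sum == 0:
        steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def permutation_p(
    ranked: pd.DataFrame,
    gene_set: list,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Gene-label permutation p-value for one set.

    Returns (ES, p, null ES draws).  p = (1 + #{|ES_perm| >= |ES|}) /
    (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, _ = preranked_es(ranked, gene_set, exponent=exponent)
    if not np.isfinite(es):
        return es, float("nan"), np.array([])
    genes = ranked["gene_id"].to_numpy()
    weights = np.abs(ranked["weight"].to_numpy(dtype=float)) ** exponent
    hits = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    n = genes.size
    nh = int(hits.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    miss_step = -1.0 / (n - nh)
    for i in range(n_perm):
        pos = rng.choice(n, size=nh, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[pos] = True
        wsum = weights[mask].sum()
        if wsum > 0:
            steps = np.where(mask, weights / wsum, miss_step)
        else:
            steps = np.where(mask, 1.0 / nh, miss_step)
        running = np.cumsum(steps)
        null[i] = running[np.argmax(np.abs(running))]
    p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
    return es, float(p), null


def enrich_collection(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """ES, normalized ES, permutation p and BH FDR for every set."""
    rows = []
    for i, name in enumerate(collection.names()):
        es, p, null = permutation_p(
            ranked,
            collection[name],
            exponent=exponent,
            n_perm=n_perm,
            seed=seed + i,
        )
        if null.size:
            denom = np.abs(null).mean()
            nes = es / denom if denom > 0 else float("nan")
        else:
            nes = float("nan")
        leading = _leading_edge(ranked, collection[name], exponent)
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p": p,
                "n_genes": len(collection[name]),
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame(rows)
    finite = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if finite.any():
        fdr[finite.to_numpy()] = benjamini_hochberg(out.loc[finite, "p"].to_numpy())
    out["fdr"] = fdr
    return out


def _leading_edge(ranked: pd.DataFrame, gene_set: list, exponent: float) -> list:
    es, running = preranked_es(ranked, gene_set, exponent=exponent)
    if not np.isfinite(es):
        return []
    peak = int(np.argmax(np.abs(running)))
    genes = ranked["gene_id"].to_numpy()
    members = set(gene_set)
    if es >= 0:
        return [g for g in genes[: peak + 1] if g in members]
    return [g for g in genes[peak:] if g in members]


def hypergeometric_ora(
    significant: list, gene_set: list, universe: list
) -> float:
    """One-sided over-representation p on the 2x2 table.

    A plain hypergeometric tail; offered as a lightweight alternative to
    network-based enrichment services.
    """
    uni = set(universe)
    sig = set(significant) & uni
    members = set(gene_set) & uni
    overlap = len(sig & members)
    return float(
        hypergeom.sf(overlap - 1, len(uni), len(members), len(sig))
    )
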