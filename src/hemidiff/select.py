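"""Rank-correlation clustering of samples and similar-subset selection.

To tame between-subject heterogeneity before the asymmetry contrast, the
pipeline clusters samples by Spearman correlation over the most variable
well-expressed genes and keeps the most cohesive all-PD cluster in which
every retained subject contributes both hemispheres.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .containers import ExpressionMatrix

__all__ = [
    "top_variable_genes",
    "rank_correlation_matrix",
    "select_similar_subset",
]


def top_variable_genes(
    expr: ExpressionMatrix, n: int = 2500, min_mean: float = 1.0
) -> list:
    """The n most variable genes among those above a mean-expression floor.

    Ties in variance break lexically by gene id so the selection is
    deterministic.
    """
    means = expr.values.mean(axis=1)
    passing = means >= min_mean
    if passing.sum() < n:
        raise ValueError(
            f"expression floor {min_mean} leaves {int(passing.sum())} genes, "
            f"need {n}"
        )
    variances = expr.values.var(axis=1, ddof=1)
    df = pd.DataFrame(
        {"gene_id": expr.gene_ids[passing], "var": variances[passing]}
    )
    df = df.sort_values(["var", "gene_id"], ascending=[False, True], kind="stable")
    return df["gene_id"].head(n).tolist()


def rank_correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Spearman correlation (mid-ranks for ties) between every sample pair."""
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a similarity matrix")
    sds = expr.values.std(axis=0)
    if np.any(sds == 0):
        flat = list(expr.sample_ids[sds == 0])
        raise ValueError(f"zero-variance samples (undefined correlation): {flat}")
    ranks = np.apply_along_axis(rankdata, 0, expr.values)
    corr = np.corrcoef(ranks.T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.sample_ids, columns=expr.sample_ids)


def _cut_by_largest_gap(z: np.ndarray, n_leaves: int) -> np.ndarray:
    """Cut the dendrogram in the largest gap between merge heights.

    When all merge heights are (near) identical there is no meaningful
    structure; everything falls into one cluster.
    """
    heights = z[:, 2]
    if heights.max() - heights.min() < 1e-8:
        return np.ones(n_leaves, dtype=int)
    hs = np.sort(heights)
    gaps = np.diff(hs)
    g = int(np.argmax(gaps))
    cut = (hs[g] + hs[g + 1]) / 2.0
    return fcluster(z, t=cut, criterion="distance")


def select_similar_subset(
    sim: pd.DataFrame,
    samples: pd.DataFrame,
    target_status: str = "PD",
    method: str = "average",
) -> list:
    """Subjects of the most cohesive all-PD cluster with both hemispheres.

    Average-linkage hierarchical clustering on distance 1 - correlation,
    cut in the largest merge-height gap.  A cluster qualifies if every
    sample in it belongs to a ``target_status`` subject whose two
    hemispheres both fall inside it; the qualifying cluster with the most
    subjects wins (ties break on the lexically smallest member sample id).
    If the cut yields a single cluster, all complete target-status
    subjects are returned.
    """
    ids = list(sim.index)
    meta = samples.set_index("sample_id").loc[ids]
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    labels = _cut_by_largest_gap(z, len(ids))

    best: list = []
    best_key = None
    for lab in np.unique(labels):
        members = [ids[i] for i in np.where(labels == lab)[0]]
        sub = meta.loc[members]
        if not (sub["status"] == target_status).all():
            continue
        counts = sub.groupby("subject_id").size()
        total = samples.groupby("subject_id").size()
        # a subject with hemispheres split across clusters is excluded
        subjects = sorted(s for s in counts.index if counts[s] == total[s] == 2)
        kept = [m for m in members if meta.loc[m, "subject_id"] in subjects]
        if not subjects:
            continue
        key = (len(subjects), min(kept))
        if best_key is None or (key[0] > best_key[0]) or (
            key[0] == best_key[0] and key[1] < best_key[1]
        ):
            best, best_key = subjects, key
    if not best or len(best) < 2:
        raise ValueError(
            f"no all-{target_status} cluster with >=2 complete subjects"
        )
    return best
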