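"""Cross-contrast gene classification and external-dataset comparison.

Genes significant in the asymmetry contrast are split by whether they are
also disease-significant and, among those, whether the two fold changes
agree in direction.  Asymmetry-significant genes that are *not* disease
genes qualify as "asymmetry-only" when the two effect sizes differ by at
least a log2 threshold; disease genes stable across hemispheres form the
complementary class.  The summary fractions (share of asymmetry genes
that are disease genes; same/opposite direction split among them) are the
headline numbers of the comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["classify_genes", "summarize_classes", "cross_dataset_compare"]

CLASSES = (
    "both_same_direction",
    "both_opposite_direction",
    "disease_only_stable",
    "asym_only_differential",
    "neither",
)


def classify_genes(
    de_disease: pd.DataFrame,
    de_asym: pd.DataFrame,
    fdr: float = 0.05,
    delta: float = 0.5,
) -> pd.DataFrame:
    """Assign each gene to one cross-contrast class.

    Requires both tables to cover the same gene universe.  Zero fold
    changes among doubly significant genes make direction undefined; such
    genes are labelled ``both_zero_direction`` and excluded from the
    same/opposite split.
    """
    d = de_disease.set_index("gene_id")
    a = de_asym.set_index("gene_id")
    if set(d.index) != set(a.index):
        diff = len(set(d.index) ^ set(a.index))
        raise ValueError(f"gene universes differ by {diff} genes")
    a = a.loc[d.index]
    dis_sig = d["fdr"] < fdr
    asym_sig = a["fdr"] < fdr
    delta_lfc = (d["log2fc"] - a["log2fc"]).abs()
    sign_prod = np.sign(d["log2fc"]) * np.sign(a["log2fc"])

    cls = pd.Series("neither", index=d.index, dtype=object)
    both = dis_sig & asym_sig
    cls[both & (sign_prod > 0)] = "both_same_direction"
    cls[both & (sign_prod < 0)] = "both_opposite_direction"
    cls[both & (sign_prod == 0)] = "both_zero_direction"
    cls[asym_sig & ~dis_sig & (delta_lfc >= delta)] = "asym_only_differential"
    cls[dis_sig & ~asym_sig] = "disease_only_stable"

    return pd.DataFrame(
        {
            "gene_id": d.index,
            "gene_class": cls.to_numpy(),
            "disease_log2fc": d["log2fc"].to_numpy(),
            "asym_log2fc": a["log2fc"].to_numpy(),
            "disease_fdr": d["fdr"].to_numpy(),
            "asym_fdr": a["fdr"].to_numpy(),
            "delta_lfc": delta_lfc.to_numpy(),
            "asym_significant": asym_sig.to_numpy(),
            "disease_significant": dis_sig.to_numpy(),
        }
    ).reset_index(drop=True)


def summarize_classes(table: pd.DataFrame) -> dict:
    """Headline fractions of the cross-contrast comparison."""
    asym_sig = table["asym_significant"]
    both = asym_sig & table["disease_significant"]
    directed = table["gene_class"].isin(
        ["both_same_direction", "both_opposite_direction"]
    )
    n_asym = int(asym_sig.sum())
    n_both = int(both.sum())
    n_directed = int(directed.sum())
    n_same = int((table["gene_class"] == "both_same_direction").sum())
    n_opposite = int((table["gene_class"] == "both_opposite_direction").sum())
    return {
        "n_asym_significant": n_asym,
        "n_both_significant": n_both,
        "frac_asym_also_disease": n_both / n_asym if n_asym else float("nan"),
        "frac_same_direction": n_same / n_directed if n_directed else float("nan"),
        "frac_opposite_direction": (
            n_opposite / n_directed if n_directed else float("nan")
        ),
        "class_counts": table["gene_class"].value_counts().to_dict(),
    }


def cross_dataset_compare(
    human_genes: pd.DataFrame,
    external_de: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    fdr: float = 0.05,
    case_insensitive: bool = True,
) -> pd.DataFrame:
    """Intersect directed human genes with an external DE table.

    ``human_genes`` needs columns ``gene_id`` and ``direction`` (sign of
    the human effect); ``external_de`` needs ``gene``, ``log2fc``, ``fdr``;
    ``ortholog_map`` is two columns (human, external).  Unmapped genes are
    dropped, not fatal.  The result holds one row per mapped gene with
    direction agreement and external significance.
    """
    for col in ("gene_id", "direction"):
        if col not in human_genes.columns:
            raise ValueError(f"human_genes missing column {col!r}")
    for col in ("gene", "log2fc", "fdr"):
        if col not in external_de.columns:
            raise ValueError(f"external_de missing column {col!r}")
    if ortholog_map.shape[1] < 2:
        raise ValueError("ortholog map needs two columns (human, external)")
    omap = ortholog_map.iloc[:, :2].copy()
    omap.columns = ["human", "external"]

    def norm(s):
        return s.str.lower() if case_insensitive else s

    human = human_genes.copy()
    human["_key"] = norm(human["gene_id"].astype(str))
    omap["_hkey"] = norm(omap["human"].astype(str))
    omap["_ekey"] = norm(omap["external"].astype(str))
    ext = external_de.copy()
    ext["_ekey"] = norm(ext["gene"].astype(str))

    merged = human.merge(omap, left_on="_key", right_on="_hkey", how="inner")
    merged = merged.merge(ext, on="_ekey", how="inner", suffixes=("", "_ext"))
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "external_gene",
                "human_direction",
                "external_log2fc",
                "external_fdr",
                "external_significant",
                "concordant",
            ]
        )
    ext_dir = np.sign(merged["log2fc"])
    concordant = ext_dir * merged["direction"] > 0
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "external_gene": merged["gene"],
            "human_direction": merged["direction"],
            "external_log2fc": merged["log2fc"],
            "external_fdr": merged["fdr"],
            "external_significant": merged["fdr"] < fdr,
            "concordant": concordant,
        }
    ).reset_index(drop=True)
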