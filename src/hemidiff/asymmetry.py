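"""Per-subject directional gene-set asymmetry scores and stratification.

For each unilateral PD subject and each gene in a set, the score is the
difference in z-scored expression between the severe and the moderate
hemisphere; the subject's summary is the mean and SD of those per-gene
differences.  The sign of the mean assigns the subject to the
``higher_in_severe`` or ``higher_in_moderate`` stratum, splitting the
cohort into the two asymmetry subtypes used for stratified contrasts.

The module-correlation report quantifies cohesion of a primary gene set
(mean pairwise Pearson correlation) and the relation of an alternative
member to the primary mean, on a named expression scale.  Correlations
are reported both as r and as the signed square sign(r)*r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "zscore_genes",
    "subject_asymmetry",
    "stratify",
    "module_correlation",
    "ModuleCorrelation",
]

STRATUM_SEVERE = "higher_in_severe"
STRATUM_MODERATE = "higher_in_moderate"
STRATUM_TIE = "tie"


def zscore_genes(
    expr: ExpressionMatrix,
    samples: pd.DataFrame | None = None,
    sample_scope: str = "all",
) -> ExpressionMatrix:
    """Standardize each gene to mean 0, SD 1 across in-scope samples.

    ``sample_scope`` is ``all`` or ``PD_only``; the latter standardizes
    across PD samples only (and returns only those columns).  Genes with
    zero SD in scope are excluded with a warning.
    """
    if sample_scope not in ("all", "PD_only"):
        raise ValueError(f"unknown sample scope {sample_scope!r}")
    if sample_scope == "PD_only":
        if samples is None:
            raise ValueError("PD_only scope needs the sample sheet")
        keep = samples.loc[samples["status"] == "PD", "sample_id"]
        expr = expr.subset_samples(list(keep))
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples in scope to z-score")
    means = expr.values.mean(axis=1, keepdims=True)
    sds = expr.values.std(axis=1, ddof=0, keepdims=True)
    flat = sds[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} zero-variance genes from z-scoring"
        )
    z = (expr.values[~flat] - means[~flat]) / sds[~flat]
    return ExpressionMatrix(
        expr.gene_ids[~flat], expr.sample_ids, z, expr.scale
    )


def subject_asymmetry(
    z: ExpressionMatrix,
    samples: pd.DataFrame,
    gene_set: list,
    set_name: str = "gene_set",
    tie_tolerance: float = 1e-9,
) -> pd.DataFrame:
    """Mean +/- SD of per-gene z differences (severe - moderate) per subject."""
    if "severity" not in samples.columns:
        raise ValueError("severity not derived")
    genes = [g for g in gene_set if g in z.gene_ids]
    missing = [g for g in gene_set if g not in z.gene_ids]
    if missing:
        warnings.warn(f"genes absent from z matrix: {missing}")
    if not genes:
        raise ValueError("no gene of the set is present in the z matrix")
    zg = z.subset_genes(genes)
    meta = samples.set_index("sample_id")
    rows = []
    for subject, grp in samples[samples["status"] == "PD"].groupby("subject_id"):
        sev = grp.loc[grp["severity"] == "severe", "sample_id"]
        mod = grp.loc[grp["severity"] == "moderate", "sample_id"]
        if len(sev) != 1 or len(mod) != 1:
            warnings.warn(f"subject {subject!r} lacks a severe/moderate pair; skipped")
            continue
        if sev.iloc[0] not in zg.sample_ids or mod.iloc[0] not in zg.sample_ids:
            warnings.warn(f"subject {subject!r} has samples outside the z scope; skipped")
            continue
        d = (
            zg.values[:, zg.sample_ids.get_loc(sev.iloc[0])]
            - zg.values[:, zg.sample_ids.get_loc(mod.iloc[0])]
        )
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        if abs(mean) < tie_tolerance:
            stratum = STRATUM_TIE
        else:
            stratum = STRATUM_SEVERE if mean > 0 else STRATUM_MODERATE
        rows.append(
            {
                "subject_id": subject,
                "score_mean": mean,
                "score_sd": sd,
                "n_genes": d.size,
                "gene_set": set_name,
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)


def stratify(scores: pd.DataFrame) -> tuple[list, list]:
    """Split subjects by asymmetry direction; ties are excluded."""
    severe = scores.loc[scores["stratum"] == STRATUM_SEVERE, "subject_id"].tolist()
    moderate = scores.loc[scores["stratum"] == STRATUM_MODERATE, "subject_id"].tolist()
    for name, lst in (("higher_in_severe", severe), ("higher_in_moderate", moderate)):
        if not lst:
            warnings.warn(f"stratum {name!r} is empty; stratified contrasts will skip it")
    return severe, moderate


@dataclass
class ModuleCorrelation:
    scale: str
    primary_cohesion_r: float
    alt_relation_r: float

    @property
    def primary_cohesion_signed_r2(self) -> float:
        r = self.primary_cohesion_r
        return float(np.sign(r) * r**2)

    @property
    def alt_relation_signed_r2(self) -> float:
        r = self.alt_relation_r
        return float(np.sign(r) * r**2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale": [self.scale],
                "primary_cohesion_r": [self.primary_cohesion_r],
                "primary_cohesion_signed_r2": [self.primary_cohesion_signed_r2],
                "alt_relation_r": [self.alt_relation_r],
                "alt_relation_signed_r2": [self.alt_relation_signed_r2],
            }
        )


def module_correlation(
    expr: ExpressionMatrix, primary: list, alt: str
) -> ModuleCorrelation:
    """Cohesion of the primary module and the alternative member's relation.

    Cohesion is the mean over all primary-primary pairs of the Pearson
    correlation across samples; the alternative relation is the Pearson
    correlation of the alternative gene with the per-sample mean of the
    primary genes.  Zero-variance genes are excluded with a warning.
    """
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples for module correlations")
    present = [g for g in primary if g in expr.gene_ids]
    if len(present) < 2:
        raise ValueError("fewer than 2 primary module genes present")
    if alt not in expr.gene_ids:
        raise ValueError(f"alternative member {alt!r} absent")
    pv = expr.subset_genes(present).values
    sds = pv.std(axis=1)
    if np.any(sds == 0):
        warnings.warn("excluding zero-variance primary genes from cohesion")
        pv = pv[sds > 0]
        if pv.shape[0] < 2:
            raise ValueError("fewer than 2 primary genes with variance")
    cc = np.corrcoef(pv)
    iu = np.triu_indices_from(cc, k=1)
    cohesion = float(cc[iu].mean())
    primary_mean = pv.mean(axis=0)
    av = expr.subset_genes([alt]).values[0]
    if av.std() == 0 or primary_mean.std() == 0:
        raise ValueError("zero variance in alternative member or primary mean")
    alt_r = float(np.corrcoef(av, primary_mean)[0, 1])
    return ModuleCorrelation(
        scale=expr.scale, primary_cohesion_r=cohesion, alt_relation_r=alt_r
    )
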