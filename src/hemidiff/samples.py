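"""Sample-sheet validation, severity derivation and the design factor.

A cohort consists of subjects each contributing a left and a right
hemisphere library.  For Parkinson's disease (PD) subjects the clinical
side of motor symptom onset orients the pair: one hemisphere is labelled
``severe`` and the other ``moderate``.  Because dopaminergic loss is more
pronounced in the hemisphere contralateral to motor onset, the default
onset rule maps a right-onset subject's *left* hemisphere to ``severe``;
the rule is configurable (``ipsilateral``) since cohorts may record onset
differently.  Bilateral-onset subjects receive no severity label and are
excluded from asymmetry contrasts.

The design factor used downstream is a means-model "combined category":
for PD samples the concatenation status.sex.onset_side.hemisphere, for
controls status.sex.hemisphere (controls have no onset side).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "OnsetRule",
    "validate_samples",
    "derive_severity",
    "build_combined_category",
    "center_covariates",
]

HEMISPHERES = ("left", "right")
ONSET_SIDES = ("left", "right", "bilateral")

REQUIRED_COLUMNS = [
    "sample_id",
    "subject_id",
    "hemisphere",
    "status",
    "onset_side",
    "sex",
]

COVARIATE_COLUMNS = ["age", "duration", "rin", "library_size", "nuclei_per_mg", "pmi"]


class SampleValidationError(ValueError):
    pass


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of the sample sheet.

    Each subject must contribute exactly one left and one right sample;
    PD rows must carry an onset side; controls must not.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise SampleValidationError(f"sample sheet missing columns: {missing}")
    samples = samples.copy()
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise SampleValidationError(f"duplicate sample ids: {dup[:5]}")
    bad_hemi = ~samples["hemisphere"].isin(HEMISPHERES)
    if bad_hemi.any():
        raise SampleValidationError(
            f"invalid hemisphere values: {samples.loc[bad_hemi, 'hemisphere'].unique().tolist()}"
        )
    bad_status = ~samples["status"].isin(("PD", "control"))
    if bad_status.any():
        raise SampleValidationError(
            f"invalid status values: {samples.loc[bad_status, 'status'].unique().tolist()}"
        )
    for subject, grp in samples.groupby("subject_id"):
        hemis = sorted(grp["hemisphere"].tolist())
        if hemis != ["left", "right"]:
            raise SampleValidationError(
                f"subject {subject!r} has hemispheres {hemis}, expected one left and one right"
            )
        if grp["status"].nunique() != 1:
            raise SampleValidationError(f"subject {subject!r} has mixed status")
    is_pd = samples["status"] == "PD"
    onset = samples["onset_side"]
    pd_missing = is_pd & (onset.isna() | (onset == "NA"))
    if pd_missing.any():
        bad = samples.loc[pd_missing, "sample_id"].tolist()
        raise SampleValidationError(f"PD samples missing onset_side: {bad[:5]}")
    pd_bad = is_pd & ~onset.isin(ONSET_SIDES) & ~onset.isna()
    if pd_bad.any():
        raise SampleValidationError(
            f"invalid onset_side values: {samples.loc[pd_bad, 'onset_side'].unique().tolist()}"
        )
    return samples


class OnsetRule:
    """How the recorded onset side maps hemispheres to severity."""

    CONTRALATERAL = "contralateral"
    IPSILATERAL = "ipsilateral"
    VALID = (CONTRALATERAL, IPSILATERAL)


def derive_severity(samples: pd.DataFrame, rule: str = OnsetRule.CONTRALATERAL) -> pd.DataFrame:
    """Label each PD hemisphere ``severe`` or ``moderate``.

    Under the default ``contralateral`` rule the hemisphere opposite the
    onset side is severe.  Controls and bilateral-onset subjects get NA;
    bilateral subjects are additionally flagged ``excluded_asymmetry``.
    """
    if rule not in OnsetRule.VALID:
        raise ValueError(f"unknown onset rule {rule!r}")
    samples = validate_samples(samples)
    opposite = {"left": "right", "right": "left"}
    severity = []
    excluded = []
    for _, row in samples.iterrows():
        if row["status"] != "PD" or row["onset_side"] == "bilateral":
            severity.append("NA")
            excluded.append(row["status"] == "PD")
            continue
        if rule == OnsetRule.CONTRALATERAL:
            severe_hemi = opposite[row["onset_side"]]
        else:
            severe_hemi = row["onset_side"]
        severity.append("severe" if row["hemisphere"] == severe_hemi else "moderate")
        excluded.append(False)
    out = samples.copy()
    out["severity"] = severity
    out["excluded_asymmetry"] = excluded
    return out


def build_combined_category(samples: pd.DataFrame) -> pd.Series:
    """Means-model factor: status.sex.onset_side.hemisphere (PD) or
    status.sex.hemisphere (control)."""
    if "severity" not in samples.columns:
        raise SampleValidationError("severity not derived; call derive_severity first")
    labels = []
    for _, row in samples.iterrows():
        if row["status"] == "PD":
            onset = row["onset_side"]
            if pd.isna(onset) or onset == "NA":
                raise SampleValidationError(
                    f"PD sample {row['sample_id']!r} has unresolved onset_side"
                )
            labels.append(f"PD.{row['sex']}.{onset}.{row['hemisphere']}")
        else:
            labels.append(f"control.{row['sex']}.{row['hemisphere']}")
    return pd.Series(labels, index=samples.index, name="combined_category")


def center_covariates(samples: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Center continuous covariates; library size is log-transformed first.

    Returns a DataFrame of centered covariate columns aligned to the sample
    sheet.  Columns absent from the sheet are skipped silently; columns with
    zero variance are dropped (they would be collinear with the means model).
    """
    columns = list(columns) if columns is not None else COVARIATE_COLUMNS
    out = {}
    for col in columns:
        if col not in samples.columns:
            continue
        x = samples[col].astype(float).to_numpy()
        if col == "library_size":
            x = np.log(x)
        x = x - np.nanmean(x)
        if np.nanstd(x) == 0:
            continue
        out[col] = x
    return pd.DataFrame(out, index=samples.index)
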