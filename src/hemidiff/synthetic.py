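"""Synthetic paired-hemisphere RNA-seq cohorts with planted structure.

The generator emulates the statistical skeleton of a bilateral brain-bank
cohort: each subject contributes a left and a right neuronal-nuclei
library; Parkinson's (PD) subjects carry a side of symptom onset that
orients their hemispheres into ``severe`` and ``moderate``.  Counts are
gamma-Poisson (negative binomial) draws around a log-linear mean built
from

* a log-normal per-gene baseline,
* a per-gene, per-subject random effect (biological between-subject
  variation shared by the two hemispheres),
* a disease effect for a planted fraction of genes,
* a lateralized effect, oriented by severity, for a planted fraction of
  genes — applied half up in the severe hemisphere and half down in the
  moderate one so the severe-minus-moderate contrast equals the planted
  log2 fold change,
* a co-regulated module (default 8 genes) whose per-subject asymmetry
  direction can flip for a configurable fraction of subjects, plus one
  alternative member anti-correlated with the module mean,
* k nuisance batch factors with gene-wise Gaussian loadings,
* a log-normal library-size offset.

Every subject is generated from its own counter-based substream of the
global seed, so a subject's data is reproducible when the cohort grows.
A companion truth table records per-gene classes and effects, per-sample
batch factor values and per-subject module directions for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .samples import OnsetRule, derive_severity

__all__ = ["CohortSpec", "SimTruth", "simulate_cohort", "simulate_twogroup"]

GENE_CLASSES = (
    "disease_only",
    "asym_only",
    "both_concordant",
    "both_discordant",
    "module_primary",
    "module_alt",
    "null",
)


class SpecValidationError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    Effect sizes are in log2 units; ``dispersion`` is the negative-binomial
    dispersion (variance = mu + dispersion * mu^2); ``libsize_log_sd`` is a
    natural-log SD.  Defaults mirror a small bilateral brain-bank study:
    14 PD and 10 control subjects, ~2000 genes, unit log2 effects, modest
    subject heterogeneity and two technical batch factors.
    """

    n_pd_subjects: int = 14
    n_ctrl_subjects: int = 10
    n_genes: int = 2000
    frac_disease_genes: float = 0.10
    frac_asym_genes: float = 0.075
    frac_asym_only_genes: float = 0.025
    disease_lfc: float = 1.0
    asym_lfc: float = 1.0
    module_size: int = 8
    alt_member_anticorr: float = -0.6
    module_activity_sd: float = 1.5
    subject_sd: float = 0.3
    dispersion: float = 0.1
    libsize_log_sd: float = 0.25
    n_batch_factors: int = 2
    batch_sd: float = 0.5
    frac_sign_flip_subjects: float = 0.0
    n_bilateral_subjects: int = 0
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    module_base_log2: float = 8.0
    onset_rule: str = OnsetRule.CONTRALATERAL
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_disease_genes",
            "frac_asym_genes",
            "frac_asym_only_genes",
            "frac_sign_flip_subjects",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_disease_genes + self.frac_asym_only_genes > 1.0:
            raise SpecValidationError(
                "frac_disease_genes + frac_asym_only_genes exceeds 1"
            )
        if self.frac_asym_only_genes > self.frac_asym_genes:
            raise SpecValidationError(
                "frac_asym_only_genes cannot exceed frac_asym_genes"
            )
        if self.dispersion <= 0:
            raise SpecValidationError("dispersion must be > 0")
        if self.module_size < 2:
            raise SpecValidationError("module_size must be >= 2")
        if not -1.0 <= self.alt_member_anticorr <= 1.0:
            raise SpecValidationError("alt_member_anticorr must be in [-1, 1]")
        for name in ("n_pd_subjects", "n_ctrl_subjects"):
            if getattr(self, name) < 1:
                raise SpecValidationError(f"{name} must be >= 1")
        if self.n_bilateral_subjects < 0:
            raise SpecValidationError("n_bilateral_subjects must be >= 0")
        if self.n_genes < self.module_size + 1:
            raise SpecValidationError("n_genes too small for the module")
        if self.onset_rule not in OnsetRule.VALID:
            raise SpecValidationError(f"unknown onset_rule {self.onset_rule!r}")


@dataclass
class SimTruth:
    """Planted parameters of one simulated cohort."""

    genes: pd.DataFrame  # gene_id, class_true, disease_lfc_true, asym_lfc_true
    samples: pd.DataFrame  # sample_id, batch_f1..fk
    subjects: pd.DataFrame  # subject_id, module_direction_true
    module_primary: list = field(default_factory=list)
    module_alt: str = ""

    def genes_of_class(self, *classes) -> list:
        mask = self.genes["class_true"].isin(classes)
        return self.genes.loc[mask, "gene_id"].tolist()


def _gene_truth(spec: CohortSpec, rng: np.random.Generator):
    """Assign baselines, classes and signed effects to genes."""
    n = spec.n_genes
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=n)
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(n)], dtype=object)
    classes = np.full(n, "null", dtype=object)
    dis_lfc = np.zeros(n)
    asym_lfc = np.zeros(n)

    # module occupies the last module_size + 1 slots, at a high baseline so
    # count noise does not swamp the shared activity
    m = spec.module_size
    mod_idx = np.arange(n - m - 1, n - 1)
    alt_idx = n - 1
    classes[mod_idx] = "module_primary"
    classes[alt_idx] = "module_alt"
    base[mod_idx] = spec.module_base_log2
    base[alt_idx] = spec.module_base_log2
    gene_ids[mod_idx] = [f"MODP{i + 1:02d}" for i in range(m)]
    gene_ids[alt_idx] = "MODALT"

    free = np.arange(n - m - 1)
    n_dis = int(round(spec.frac_disease_genes * n))
    n_asym = int(round(spec.frac_asym_genes * n))
    n_asym_only = int(round(spec.frac_asym_only_genes * n))
    n_both = max(n_asym - n_asym_only, 0)
    n_dis_only = max(n_dis - n_both, 0)
    need = n_dis_only + n_both + n_asym_only
    if need > free.size:
        raise SpecValidationError("effect-gene fractions exceed available genes")
    chosen = rng.choice(free, size=need, replace=False)
    dis_only = chosen[:n_dis_only]
    both = chosen[n_dis_only : n_dis_only + n_both]
    asym_only = chosen[n_dis_only + n_both :]

    sd = rng.choice([-1.0, 1.0], size=n)
    sa = rng.choice([-1.0, 1.0], size=n)
    classes[dis_only] = "disease_only"
    dis_lfc[dis_only] = sd[dis_only] * spec.disease_lfc
    classes[asym_only] = "asym_only"
    asym_lfc[asym_only] = sa[asym_only] * spec.asym_lfc
    dis_lfc[both] = sd[both] * spec.disease_lfc
    asym_lfc[both] = sa[both] * spec.asym_lfc
    concordant = sd[both] * sa[both] > 0
    classes[both] = np.where(concordant, "both_concordant", "both_discordant")
    # degenerate magnitudes collapse classes to what is actually planted
    both_classes = ["both_concordant", "both_discordant"]
    if spec.disease_lfc == 0 and spec.asym_lfc == 0:
        classes[np.isin(classes, ["disease_only", "asym_only", *both_classes])] = "null"
    elif spec.disease_lfc == 0:
        classes[np.isin(classes, ["disease_only"])] = "null"
        classes[np.isin(classes, both_classes)] = "asym_only"
    elif spec.asym_lfc == 0:
        classes[np.isin(classes, ["asym_only"])] = "null"
        classes[np.isin(classes, both_classes)] = "disease_only"
    dis_lfc[np.isin(classes, ["null", "asym_only"])] = 0.0
    asym_lfc[np.isin(classes, ["null", "disease_only"])] = 0.0

    batch_loadings = rng.normal(
        0.0, spec.batch_sd, size=(n, spec.n_batch_factors)
    ) if spec.n_batch_factors > 0 else np.zeros((n, 0))

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class_true": classes,
            "disease_lfc_true": dis_lfc,
            "asym_lfc_true": asym_lfc,
            "base_log2": base,
        }
    )
    return genes, batch_loadings, mod_idx, alt_idx


def simulate_cohort(
    spec: CohortSpec, invert_onset: bool = False
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Generate a paired-hemisphere cohort and its truth tables.

    ``invert_onset`` regenerates the identical cohort with every recorded
    side of onset swapped, which flips the sign of every planted
    lateralized effect while leaving all other draws untouched.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    gene_ss, cohort_ss = root.spawn(2)
    gene_rng = np.random.default_rng(gene_ss)
    genes, batch_loadings, mod_idx, alt_idx = _gene_truth(spec, gene_rng)
    base = genes["base_log2"].to_numpy()
    dis = genes["disease_lfc_true"].to_numpy()
    asym = genes["asym_lfc_true"].to_numpy()

    n_pd = spec.n_pd_subjects
    n_ctrl = spec.n_ctrl_subjects
    subject_ids = [f"PD{i + 1:02d}" for i in range(n_pd)] + [
        f"C{i + 1:02d}" for i in range(n_ctrl)
    ]
    statuses = ["PD"] * n_pd + ["control"] * n_ctrl

    rows = []
    subj_rows = []
    cols = []
    col_ids = []
    subject_batch = []
    subject_streams = root.spawn(2 + n_pd + n_ctrl)[2:]
    for si, (subject, status) in enumerate(zip(subject_ids, statuses)):
        srng = np.random.default_rng(subject_streams[si])
        sex = "male" if srng.random() < 0.5 else "female"
        age = float(np.clip(srng.normal(76.0, 8.0), 50.0, 95.0))
        pmi = float(np.clip(srng.normal(12.0, 5.0), 2.0, 30.0))
        if status == "PD":
            bilateral = si < spec.n_bilateral_subjects
            onset = "bilateral" if bilateral else (
                "left" if srng.random() < 0.5 else "right"
            )
            if invert_onset and onset != "bilateral":
                onset = "right" if onset == "left" else "left"
            duration = float(np.clip(srng.normal(10.0, 5.0), 1.0, 25.0))
            braak = float(srng.choice([1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0]))
            direction = -1.0 if srng.random() < spec.frac_sign_flip_subjects else 1.0
        else:
            onset = "NA"
            duration = 0.0
            braak = 0.0
            direction = 1.0
        subj_rows.append(
            {"subject_id": subject, "module_direction_true": direction}
        )
        # batch is subject-level: both hemisphere libraries of a subject are
        # prepared together, as a paired design would run them
        subject_batch.append(srng.normal(0.0, 1.0, size=spec.n_batch_factors))
        subject_effect = srng.normal(0.0, spec.subject_sd, size=spec.n_genes)
        module_u = srng.normal(0.0, spec.module_activity_sd)
        module_v = srng.normal(0.0, spec.module_activity_sd)
        for hemi in ("left", "right"):
            sample_id = f"{subject}_{hemi[0].upper()}"
            rin = float(np.clip(srng.normal(7.0, 0.8), 5.0, 10.0))
            nuclei = float(srng.lognormal(np.log(5000.0), 0.4))
            libsize_offset = srng.normal(0.0, spec.libsize_log_sd)
            rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "hemisphere": hemi,
                    "status": status,
                    "onset_side": onset,
                    "sex": sex,
                    "age": age,
                    "duration": duration,
                    "rin": rin,
                    "nuclei_per_mg": nuclei,
                    "pmi": pmi,
                    "braak": braak,
                    "_libsize_offset": libsize_offset,
                }
            )
            col_ids.append(sample_id)
            cols.append((srng, subject_effect, module_u, module_v, direction))

    samples = pd.DataFrame(rows)
    samples = derive_severity(samples, rule=spec.onset_rule)

    # block-randomized technical design: batch factors are balanced within
    # every subject-level design cell (status x sex x onset side), so they
    # load on no group-mean contrast and act purely as shared noise
    if spec.n_batch_factors > 0:
        b = np.vstack(subject_batch)
        subj_meta = samples.drop_duplicates("subject_id").set_index("subject_id")
        cells = [
            f"{subj_meta.loc[s, 'status']}.{subj_meta.loc[s, 'sex']}."
            f"{subj_meta.loc[s, 'onset_side']}"
            for s in subject_ids
        ]
        a = np.column_stack(
            [[c == lv for c in cells] for lv in sorted(set(cells))]
        ).astype(float)
        b = b - a @ np.linalg.lstsq(a, b, rcond=None)[0]
        batch_values = [b[si] for si in range(len(statuses)) for _ in range(2)]
    else:
        batch_values = [np.zeros(0) for _ in col_ids]

    counts = np.zeros((spec.n_genes, len(col_ids)), dtype=np.int64)
    for j, (srng, subject_effect, module_u, module_v, direction) in enumerate(cols):
        row = samples.iloc[j]
        log2_mu = base + subject_effect
        if row["status"] == "PD":
            log2_mu = log2_mu + dis
        sev = row["severity"]
        sev_sign = {"severe": 1.0, "moderate": -1.0}.get(sev, 0.0)
        log2_mu = log2_mu + 0.5 * sev_sign * asym
        # shared module activity: subject latent plus oriented asymmetry
        m_signal = module_u + 0.5 * sev_sign * direction * spec.asym_lfc
        rho = spec.alt_member_anticorr
        alt_signal = rho * m_signal + np.sqrt(max(1.0 - rho**2, 0.0)) * module_v
        log2_mu[mod_idx] = log2_mu[mod_idx] + m_signal
        log2_mu[alt_idx] = log2_mu[alt_idx] + alt_signal
        if spec.n_batch_factors > 0:
            log2_mu = log2_mu + batch_loadings @ batch_values[j]
        mu = 2.0 ** log2_mu * np.exp(samples.iloc[j]["_libsize_offset"])
        shape = 1.0 / spec.dispersion
        lam = srng.gamma(shape, mu * spec.dispersion)
        counts[:, j] = srng.poisson(lam)

    cm = CountMatrix(pd.Index(genes["gene_id"]), pd.Index(col_ids), counts)
    samples = samples.drop(columns=["_libsize_offset"])
    samples["library_size"] = cm.library_sizes()

    truth_samples = pd.DataFrame(
        np.array(batch_values).reshape(len(col_ids), spec.n_batch_factors),
        columns=[f"batch_f{k + 1}" for k in range(spec.n_batch_factors)],
    )
    truth_samples.insert(0, "sample_id", col_ids)
    truth = SimTruth(
        genes=genes.drop(columns=["base_log2"]),
        samples=truth_samples,
        subjects=pd.DataFrame(subj_rows),
        module_primary=list(genes["gene_id"].iloc[mod_idx]),
        module_alt=str(genes["gene_id"].iloc[alt_idx]),
    )
    return cm, samples, truth


def simulate_twogroup(
    n_cells_per_group: int,
    module_lfc: float,
    seed: int,
    n_genes: int = 500,
    module_size: int = 8,
    dispersion: float = 0.3,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Small two-group dataset: ``aggregate`` vs ``non_aggregate`` units.

    Emulates the cross-validation input where neurons bearing protein
    aggregates are contrasted with unaffected neighbours: module genes are
    shifted by ``module_lfc`` in the aggregate group, everything else is
    exchangeable noise.
    """
    if n_cells_per_group < 2:
        raise SpecValidationError("n_cells_per_group must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = rng.normal(4.0, 1.5, size=n_genes)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    for i in range(module_size):
        gene_ids[n_genes - module_size + i] = f"MODP{i + 1:02d}"
        base[n_genes - module_size + i] = 7.0
    groups = ["aggregate"] * n_cells_per_group + ["non_aggregate"] * n_cells_per_group
    sample_ids = [f"cell{i + 1:04d}" for i in range(2 * n_cells_per_group)]
    counts = np.zeros((n_genes, len(sample_ids)), dtype=np.int64)
    shape = 1.0 / dispersion
    for j, group in enumerate(groups):
        log2_mu = base.copy()
        if group == "aggregate":
            log2_mu[n_genes - module_size :] += module_lfc
        mu = 2.0 ** log2_mu
        lam = rng.gamma(shape, mu * dispersion)
        counts[:, j] = rng.poisson(lam)
    cm = CountMatrix(pd.Index(gene_ids), pd.Index(sample_ids), counts)
    meta = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return cm, meta
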