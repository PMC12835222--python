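"""End-to-end orchestration: config, staged execution, run manifest.

A run executes, in order: (optional) cohort simulation -> loading ->
severity derivation -> two-stage differential expression on the full
cohort -> similarity-based subset selection -> two-stage DE on the subset
-> per-subject module asymmetry scores and stratification -> per-stratum
DE -> cross-contrast gene classification -> preranked enrichment.  Every
stage writes plain TSV/JSON under the run directory and the manifest
records a config snapshot and SHA-256 checksums of all outputs, so two
runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import asymmetry as asym_mod
from . import classify as classify_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import select as select_mod
from .containers import GeneSetCollection
from .de import DEConfig, run_two_stage
from .samples import OnsetRule, derive_severity
from .synthetic import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "hemidiff_run"
    counts_path: str | None = None
    samples_path: str | None = None
    gene_sets_path: str | None = None
    counts_format: str | None = None
    simulate: bool = False
    cohort: dict = field(default_factory=dict)
    onset_rule: str = OnsetRule.CONTRALATERAL
    seed: int = 0
    # stage parameters
    cpm_filter: float = 1.0
    n_control_genes: int = 2000
    k_factors: int = 5
    prior_count: float = 0.5
    fdr: float = 0.05
    voom_span: float = 0.5
    n_top_genes: int = 2500
    expression_floor: float = 1.0
    linkage: str = "average"
    zscore_scope: str = "PD_only"
    asym_gene_set: str = "module_primary"
    tie_tolerance: float = 1e-9
    delta_lfc: float = 0.5
    enrich_exponent: float = 1.0
    n_perm: int = 200
    min_stratum_subjects: int = 2

    def validate(self) -> None:
        if not self.simulate:
            for name in ("counts_path", "samples_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when simulate is false")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p}")
        if self.gene_sets_path is not None and not Path(self.gene_sets_path).exists():
            raise FileNotFoundError(f"gene_sets_path: no such file {self.gene_sets_path}")
        if self.onset_rule not in OnsetRule.VALID:
            raise ValueError(f"unknown onset_rule {self.onset_rule!r}")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.k_factors < 0:
            raise ValueError("k_factors must be >= 0")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    def de_config(self) -> DEConfig:
        return DEConfig(
            cpm_filter=self.cpm_filter,
            n_control_genes=self.n_control_genes,
            k_factors=self.k_factors,
            prior_count=self.prior_count,
            fdr_threshold=self.fdr,
            voom_span=self.voom_span,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_de(de: pd.DataFrame, path: Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    # ---- inputs -------------------------------------------------------
    truth = None
    if config.simulate:
        spec = CohortSpec(
            **{"seed": config.seed, "onset_rule": config.onset_rule, **config.cohort}
        )
        counts, samples, truth = simulate_cohort(spec)
        cpath = out / "counts.tsv.gz"
        spath = out / "samples.tsv"
        io_mod.write_counts(counts, cpath, format="tsv")
        io_mod.write_samples(samples, spath)
        truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        truth.subjects.to_csv(out / "truth_subjects.tsv", sep="\t", index=False)
        record("simulate", cpath, spath, out / "truth_genes.tsv",
               out / "truth_subjects.tsv")
    else:
        counts = io_mod.read_counts(config.counts_path, format=config.counts_format)
        samples = io_mod.read_samples(config.samples_path)
        manifest["inputs"] = {
            "counts": _sha256(Path(config.counts_path)),
            "samples": _sha256(Path(config.samples_path)),
        }

    samples = derive_severity(samples, rule=config.onset_rule)
    spath = out / "samples_severity.tsv"
    io_mod.write_samples(samples, spath)
    record("severity", spath)

    if config.gene_sets_path is not None:
        collection = io_mod.read_gmt(config.gene_sets_path)
    elif truth is not None:
        collection = GeneSetCollection(
            sets={
                "module_primary": list(truth.module_primary),
                "module_with_alt": list(truth.module_primary) + [truth.module_alt],
            },
            descriptions={
                "module_primary": "planted co-regulated module",
                "module_with_alt": "module plus alternative member",
            },
        )
    else:
        collection = None

    # ---- full-cohort DE ----------------------------------------------
    de_cfg = config.de_config()
    full = run_two_stage(counts, samples, de_cfg)
    p_dis = out / "de_full_disease.tsv"
    p_asym = out / "de_full_asymmetry.tsv"
    _write_de(full.de_disease, p_dis)
    _write_de(full.de_asymmetry, p_asym)
    if full.nuisance is not None:
        full.nuisance.to_frame().to_csv(
            out / "nuisance_factors.tsv", sep="\t", index=False, float_format="%.10g"
        )
        record("de_full", p_dis, p_asym, out / "nuisance_factors.tsv")
    else:
        record("de_full", p_dis, p_asym)

    # ---- subset selection --------------------------------------------
    genes_top = select_mod.top_variable_genes(
        full.logcpm, n=min(config.n_top_genes, full.logcpm.n_genes),
        min_mean=config.expression_floor,
    )
    pd_samples = samples.loc[samples["status"] == "PD", "sample_id"]
    sim = select_mod.rank_correlation_matrix(
        full.logcpm.subset_genes(genes_top).subset_samples(list(pd_samples))
    )
    sim.to_csv(out / "similarity.tsv", sep="\t", float_format="%.10g")
    try:
        subset_subjects = select_mod.select_similar_subset(
            sim, samples, method=config.linkage
        )
    except ValueError as exc:
        logger.warning("subset selection fell back to all PD subjects: %s", exc)
        subset_subjects = sorted(
            samples.loc[samples["status"] == "PD", "subject_id"].unique()
        )
    (out / "subset_subjects.txt").write_text("\n".join(subset_subjects) + "\n")
    record("select", out / "similarity.tsv", out / "subset_subjects.txt")

    # ---- subset DE ----------------------------------------------------
    keep = samples["subject_id"].isin(subset_subjects) | (
        samples["status"] == "control"
    )
    sub_samples = samples.loc[keep].reset_index(drop=True)
    sub_counts = counts.subset_samples(list(sub_samples["sample_id"]))
    subset = run_two_stage(sub_counts, sub_samples, de_cfg)
    p_sdis = out / "de_subset_disease.tsv"
    p_sasym = out / "de_subset_asymmetry.tsv"
    _write_de(subset.de_disease, p_sdis)
    _write_de(subset.de_asymmetry, p_sasym)
    record("de_subset", p_sdis, p_sasym)

    # ---- asymmetry scores and stratification -------------------------
    scores = None
    strata: dict = {}
    if collection is not None and config.asym_gene_set in collection:
        z = asym_mod.zscore_genes(
            full.logcpm, samples, sample_scope=config.zscore_scope
        )
        scores = asym_mod.subject_asymmetry(
            z,
            samples,
            collection[config.asym_gene_set],
            set_name=config.asym_gene_set,
            tie_tolerance=config.tie_tolerance,
        )
        scores.to_csv(out / "asymmetry_scores.tsv", sep="\t", index=False,
                      float_format="%.10g")
        record("asymmetry", out / "asymmetry_scores.tsv")
        severe_subj, moderate_subj = asym_mod.stratify(scores)
        strata = {"higher_in_severe": severe_subj, "higher_in_moderate": moderate_subj}
        for name, subjects in strata.items():
            if len(subjects) < config.min_stratum_subjects:
                logger.warning(
                    "stratum %s has %d subjects (<%d); skipped",
                    name, len(subjects), config.min_stratum_subjects,
                )
                continue
            keep = samples["subject_id"].isin(subjects) | (
                samples["status"] == "control"
            )
            st_samples = samples.loc[keep].reset_index(drop=True)
            st_counts = counts.subset_samples(list(st_samples["sample_id"]))
            st = run_two_stage(st_counts, st_samples, de_cfg)
            pd_path = out / f"de_stratum_{name}_disease.tsv"
            pa_path = out / f"de_stratum_{name}_asymmetry.tsv"
            _write_de(st.de_disease, pd_path)
            _write_de(st.de_asymmetry, pa_path)
            record(f"de_stratum_{name}", pd_path, pa_path)
    else:
        logger.warning("no gene set %r available; asymmetry scoring skipped",
                       config.asym_gene_set)

    # ---- cross-contrast classification --------------------------------
    classes = classify_mod.classify_genes(
        subset.de_disease, subset.de_asymmetry, fdr=config.fdr,
        delta=config.delta_lfc,
    )
    classes.to_csv(out / "gene_classes.tsv", sep="\t", index=False,
                   float_format="%.10g")
    summary = classify_mod.summarize_classes(classes)
    (out / "class_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    record("classify", out / "gene_classes.tsv", out / "class_summary.json")

    # ---- enrichment ----------------------------------------------------
    if collection is not None:
        ranked = enrich_mod.rank_genes(subset.de_asymmetry)
        enr = enrich_mod.enrich_collection(
            ranked, collection, exponent=config.enrich_exponent,
            n_perm=config.n_perm, seed=config.seed,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.10g")
        record("enrich", out / "enrichment.tsv")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
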