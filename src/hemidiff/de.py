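"""Moderated linear-model differential expression with nuisance factors.

The workflow mirrors the standard limma/voom chain for bulk RNA-seq, with
a residual-factor correction stage in the middle:

1. fit a means-model ("combined category") linear model with clinical
   covariates to log2-CPM, using mean-variance precision weights;
2. rank genes by the disease contrast and keep the *least* different ones
   as empirical control genes;
3. estimate k unwanted-variation factors as the leading sample-space
   singular vectors of the control-gene residuals of a reduced model;
4. refit with the factors appended and test contrasts with
   empirical-Bayes moderated t statistics and Benjamini-Hochberg FDR.

Contrasts are expressed as vectors over design columns: the disease
contrast averages the PD levels minus the control levels with equal
weight per level, and the asymmetry contrast averages severe levels
minus moderate levels within PD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, ExpressionMatrix
from .normalize import log_cpm, tmm_factors
from .samples import build_combined_category, center_covariates

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "FitResult",
    "ModerationPrior",
    "NuisanceFactors",
    "DEConfig",
    "TwoStageResult",
    "build_design",
    "fit_model",
    "precision_weights",
    "moderate",
    "test_contrast",
    "benjamini_hochberg",
    "select_least_different",
    "estimate_nuisance",
    "disease_contrast",
    "asymmetry_contrast",
    "run_two_stage",
]

DE_COLUMNS = ["gene_id", "contrast", "log2fc", "t_mod", "p", "fdr", "ave_expr"]

REDUCED_COVARIATES = ["duration", "age"]


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    columns: list
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("design shape does not match columns/samples")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def check_full_rank(self) -> None:
        if self.rank < len(self.columns):
            # name the columns involved in the deficiency via pivoted QR
            _, r, piv = _qr_pivoted(self.matrix)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(self.matrix.shape) * np.finfo(float).eps
            bad = [self.columns[j] for j in piv[diag < tol]]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _qr_pivoted(x):
    import scipy.linalg

    q, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    return q, r, piv


def build_design(
    samples: pd.DataFrame,
    nuisance: "NuisanceFactors | None" = None,
    covariates: list | None = None,
) -> DesignMatrix:
    """Means-model design: one column per combined-category level, plus
    centered covariates and optional unwanted-variation factors."""
    cats = build_combined_category(samples)
    levels = sorted(cats.unique())
    dummies = np.column_stack([(cats == lv).to_numpy(float) for lv in levels])
    cov = center_covariates(samples, columns=covariates)
    blocks = [dummies]
    names = list(levels)
    if not cov.empty:
        blocks.append(cov.to_numpy(float))
        names.extend(cov.columns)
    if nuisance is not None and nuisance.k > 0:
        if not pd.Index(samples["sample_id"]).equals(nuisance.sample_ids):
            raise ValueError("nuisance factor samples do not match sample sheet")
        blocks.append(nuisance.values)
        names.extend(f"ruv_{i + 1}" for i in range(nuisance.k))
    design = DesignMatrix(
        np.hstack(blocks), names, pd.Index(samples["sample_id"])
    )
    design.check_full_rank()
    return design


@dataclass
class FitResult:
    coefficients: np.ndarray  # genes x p
    sigma2: np.ndarray  # genes
    df_resid: int
    residuals: np.ndarray  # genes x samples
    cov_unscaled: np.ndarray  # genes x p x p, (X'WX)^-1
    design: DesignMatrix
    gene_ids: pd.Index
    ave_expr: np.ndarray


def fit_model(
    expr: ExpressionMatrix, design: DesignMatrix, weights: np.ndarray | None = None
) -> FitResult:
    """Gene-wise (weighted) least squares against a shared design."""
    if expr.scale != "log2cpm":
        raise ValueError("statistical fitting runs on the log2cpm scale only")
    if not expr.sample_ids.equals(design.sample_ids):
        raise ValueError("expression and design sample sets differ")
    if not np.all(np.isfinite(expr.values)):
        raise ValueError("expression matrix contains non-finite values")
    design.check_full_rank()
    x = design.matrix
    y = expr.values
    n, p = x.shape
    if weights is None:
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = y @ x @ xtx_inv
        cov = np.broadcast_to(xtx_inv, (expr.n_genes, p, p)).copy()
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != y.shape:
            raise ValueError("weights shape must match expression matrix")
        if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
            raise ValueError("weights must be positive and finite")
        xtwx = np.einsum("sp,gs,sq->gpq", x, weights, x, optimize=True)
        xtwy = np.einsum("sp,gs,gs->gp", x, weights, y, optimize=True)
        cov = np.linalg.inv(xtwx)
        beta = np.einsum("gpq,gq->gp", cov, xtwy)
    fitted = beta @ x.T
    resid = y - fitted
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    if weights is None:
        rss = np.sum(resid**2, axis=1)
    else:
        rss = np.sum(weights * resid**2, axis=1)
    sigma2 = rss / df
    return FitResult(
        coefficients=beta,
        sigma2=sigma2,
        df_resid=df,
        residuals=resid,
        cov_unscaled=cov,
        design=design,
        gene_ids=expr.gene_ids,
        ave_expr=expr.values.mean(axis=1),
    )


def precision_weights(
    counts: CountMatrix,
    design: DesignMatrix,
    factors=None,
    span: float = 0.5,
    prior: float = 0.5,
) -> np.ndarray:
    """Mean-variance trend precision weights (observation-level).

    Fits sqrt residual SD against average log2 count with lowess, predicts
    the SD at each observation's fitted log2 count and returns the inverse
    squared prediction.  With too few genes for a stable trend the weights
    fall back to ones with a warning.
    """
    if factors is None:
        factors = tmm_factors(counts)
    expr = log_cpm(counts, factors, prior=prior)
    if counts.n_genes < 50:
        warnings.warn("too few genes for a mean-variance trend; using unit weights")
        return np.ones_like(expr.values)
    fit = fit_model(expr, design)
    eff = counts.library_sizes().astype(float) * factors.factors
    # average log2 count of each gene (shift log-CPM back to count scale)
    sx = fit.ave_expr + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(fit.sigma2))
    smooth = lowess(sy, sx, frac=span, return_sorted=True)
    fitted_logcpm = fit.coefficients @ design.matrix.T
    fitted_logcount = fitted_logcpm + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, smooth[:, 0], smooth[:, 1])
    pred = np.clip(pred, 1e-6, None)
    return 1.0 / pred**4


@dataclass
class ModerationPrior:
    s2_prior: float
    df_prior: float  # may be inf

    def __post_init__(self) -> None:
        if self.s2_prior <= 0:
            raise ValueError("prior variance must be positive")
        if not self.df_prior > 0:
            raise ValueError("prior degrees of freedom must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: int, min_df_prior: float = 0.5):
    """Method-of-moments fit of a scaled F prior to log sample variances."""
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("not enough positive residual variances to moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        df_prior = max(df_prior, min_df_prior)
        s2_prior = np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return ModerationPrior(float(s2_prior), float(df_prior))


@dataclass
class Moderation:
    prior: ModerationPrior
    s2_post: np.ndarray
    df_total: float


def moderate(fit: FitResult, min_df_prior: float = 0.5) -> Moderation:
    """Empirical-Bayes shrinkage of residual variances toward the prior."""
    prior = estimate_prior(fit.sigma2, fit.df_resid, min_df_prior=min_df_prior)
    d0, s0 = prior.df_prior, prior.s2_prior
    d = fit.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma2, s0)
    else:
        s2_post = (d0 * s0 + d * fit.sigma2) / (d0 + d)
    return Moderation(prior=prior, s2_post=s2_post, df_total=d0 + d)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_contrast(
    fit: FitResult, moderation: Moderation, contrast: np.ndarray, name: str
) -> pd.DataFrame:
    """Moderated t test of a contrast vector over the design columns."""
    c = np.asarray(contrast, dtype=float)
    p_cols = len(fit.design.columns)
    if c.shape != (p_cols,):
        raise ValueError(f"contrast length {c.size} != design columns {p_cols}")
    lfc = fit.coefficients @ c
    cvar = np.einsum("p,gpq,q->g", c, fit.cov_unscaled, c)
    se = np.sqrt(np.clip(cvar, 0, None) * moderation.s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df = moderation.df_total
    if np.isinf(df):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "contrast": name,
            "log2fc": lfc,
            "t_mod": t,
            "p": pvals,
            "fdr": benjamini_hochberg(pvals),
            "ave_expr": fit.ave_expr,
        }
    )


def select_least_different(de: pd.DataFrame, n: int = 2000) -> list:
    """The n genes least perturbed by the contrast: largest p, ties broken
    by smallest |moderated t|, then gene id."""
    df = de.copy()
    df["_abs_t"] = df["t_mod"].abs()
    df = df.sort_values(
        ["p", "_abs_t", "gene_id"], ascending=[False, True, True], kind="stable"
    )
    if len(df) < n:
        warnings.warn(
            f"only {len(df)} genes available for control selection (asked {n})"
        )
        n = len(df)
    return df["gene_id"].head(n).tolist()


@dataclass
class NuisanceFactors:
    """Sample-space factors estimated from control-gene residuals."""

    values: np.ndarray  # samples x k, orthonormal columns
    sample_ids: pd.Index
    control_genes: list
    singular_values: np.ndarray

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"ruv_{i + 1}" for i in range(self.k)]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


def estimate_nuisance(
    expr: ExpressionMatrix,
    reduced_design: DesignMatrix,
    control_genes: list,
    k: int = 5,
) -> NuisanceFactors:
    """Leading sample-space singular vectors of control-gene residuals.

    Fits the reduced model to all genes, restricts the residual matrix to
    the control genes, and takes the first k left singular vectors of the
    samples x controls residual matrix.  Columns are orthonormal with a
    deterministic sign convention (largest-magnitude element positive).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fit = fit_model(expr, reduced_design)
    ctrl = pd.Index(control_genes)
    idx = expr.gene_ids.get_indexer(ctrl)
    if (idx < 0).any():
        missing = list(ctrl[idx < 0][:5])
        raise ValueError(f"control genes absent from expression matrix: {missing}")
    resid = fit.residuals[idx]  # controls x samples
    admissible = min(reduced_design.n_samples - reduced_design.rank, len(ctrl))
    if k > admissible:
        raise ValueError(
            f"k={k} exceeds admissible residual rank {admissible}"
        )
    if np.allclose(resid, 0.0, atol=1e-12):
        raise ValueError("control-gene residuals are identically zero")
    u, s, _ = np.linalg.svd(resid.T, full_matrices=False)
    w = u[:, :k].copy()
    for j in range(k):
        col = w[:, j]
        lead = np.argmax(np.abs(col))
        if col[lead] < 0:
            w[:, j] = -col
    return NuisanceFactors(
        values=w,
        sample_ids=expr.sample_ids,
        control_genes=list(ctrl),
        singular_values=s[:k],
    )


def _level_columns(columns) -> list:
    return [c for c in columns if c.startswith("PD.") or c.startswith("control.")]


def _level_weights(columns, pos_levels, neg_levels, sizes, weighting):
    c = np.zeros(len(columns))
    cols = list(columns)
    for sign, group in ((1.0, pos_levels), (-1.0, neg_levels)):
        if weighting == "equal":
            w = {lv: 1.0 / len(group) for lv in group}
        elif weighting == "size":
            total = sum(sizes[lv] for lv in group)
            w = {lv: sizes[lv] / total for lv in group}
        else:
            raise ValueError(f"unknown contrast weighting {weighting!r}")
        for lv in group:
            c[cols.index(lv)] = sign * w[lv]
    return c


def disease_contrast(
    columns, samples: pd.DataFrame | None = None, weighting: str = "size"
) -> np.ndarray:
    """Average of PD levels minus control levels.

    ``size`` weighting (default) weights each level by its sample count,
    matching the plain group-mean difference; ``equal`` weights every
    level identically.  Size weighting is the stabler choice when design
    cells are small: a singleton level would otherwise dominate the
    contrast variance.
    """
    pd_levels = [c for c in columns if c.startswith("PD.")]
    ctrl_levels = [c for c in columns if c.startswith("control.")]
    if not pd_levels or not ctrl_levels:
        raise ValueError("design lacks PD or control levels")
    if weighting == "size":
        if samples is None:
            raise ValueError("size weighting needs the sample sheet")
        sizes = build_combined_category(samples).value_counts().to_dict()
    else:
        sizes = {}
    return _level_weights(columns, pd_levels, ctrl_levels, sizes, weighting)


def asymmetry_contrast(
    columns, samples: pd.DataFrame, weighting: str = "size"
) -> np.ndarray:
    """Average of severe levels minus moderate levels within PD.

    Level severity is read off the sample sheet: every sample in a PD
    combined-category level shares one severity, because the level encodes
    both onset side and hemisphere.  With ``size`` weighting every
    unilateral subject contributes the same magnitude to both sides, so
    subject-level effects cancel exactly in the contrast.
    """
    if "severity" not in samples.columns:
        raise ValueError("severity not derived")
    cats = build_combined_category(samples)
    level_sev: dict = {}
    for cat, sev in zip(cats, samples["severity"]):
        if not cat.startswith("PD.") or sev not in ("severe", "moderate"):
            continue
        prev = level_sev.setdefault(cat, sev)
        if prev != sev:
            raise ValueError(f"level {cat!r} mixes severities")
    severe = [c for c in columns if level_sev.get(c) == "severe"]
    moderate = [c for c in columns if level_sev.get(c) == "moderate"]
    if not severe or not moderate:
        raise ValueError("no severe/moderate levels present in design")
    sizes = cats.value_counts().to_dict() if weighting == "size" else {}
    return _level_weights(columns, severe, moderate, sizes, weighting)


@dataclass
class DEConfig:
    cpm_filter: float = 1.0
    min_samples: int | None = None
    n_control_genes: int = 2000
    k_factors: int = 5
    prior_count: float = 0.5
    fdr_threshold: float = 0.05
    voom_span: float = 0.5
    use_weights: bool = True


@dataclass
class TwoStageResult:
    de_disease: pd.DataFrame
    de_asymmetry: pd.DataFrame
    stage1_disease: pd.DataFrame
    stage1_asymmetry: pd.DataFrame
    nuisance: NuisanceFactors | None
    control_genes: list
    factors: "object"
    logcpm: ExpressionMatrix
    kept_genes: list
    final_fit: FitResult = None
    final_moderation: Moderation = None


def filter_by_cpm(
    counts: CountMatrix, threshold: float = 1.0, min_samples: int | None = None,
    samples: pd.DataFrame | None = None,
) -> CountMatrix:
    """Keep genes with CPM above threshold in at least min_samples samples.

    ``min_samples`` defaults to the smallest combined-category level size
    (floor 2) so a gene expressed only in one design cell survives.
    """
    raw_cpm = counts.counts / counts.library_sizes().astype(float)[None, :] * 1e6
    if min_samples is None:
        if samples is not None:
            cats = build_combined_category(samples)
            min_samples = max(2, int(cats.value_counts().min()))
        else:
            min_samples = 2
    keep = (raw_cpm > threshold).sum(axis=1) >= min_samples
    if keep.sum() == 0:
        raise ValueError("CPM filter removed every gene")
    return CountMatrix(
        counts.gene_ids[keep], counts.sample_ids, counts.counts[keep]
    )


def _fit_and_test(counts, samples, design, config, factors):
    weights = (
        precision_weights(counts, design, factors=factors, span=config.voom_span,
                          prior=config.prior_count)
        if config.use_weights
        else None
    )
    expr = log_cpm(counts, factors, prior=config.prior_count)
    fit = fit_model(expr, design, weights=weights)
    mod = moderate(fit)
    de_dis = test_contrast(
        fit, mod, disease_contrast(design.columns, samples), "disease"
    )
    de_asym = test_contrast(
        fit, mod, asymmetry_contrast(design.columns, samples), "asymmetry"
    )
    return fit, mod, de_dis, de_asym, expr


def run_two_stage(
    counts: CountMatrix, samples: pd.DataFrame, config: DEConfig | None = None
) -> TwoStageResult:
    """Full two-stage workflow on one cohort.

    Stage 1 fits the clinical model alone and selects the least
    disease-different genes as empirical controls; the correcting factors
    estimated from their residuals enter the final model, which yields the
    disease and asymmetry tables.
    """
    config = config or DEConfig()
    samples = samples.reset_index(drop=True)
    if not pd.Index(samples["sample_id"]).equals(counts.sample_ids):
        samples = (
            samples.set_index("sample_id").loc[counts.sample_ids].reset_index()
        )
    counts = filter_by_cpm(counts, config.cpm_filter, config.min_samples, samples)
    logger.info("CPM filter kept %d genes", counts.n_genes)
    factors = tmm_factors(counts)
    design0 = build_design(samples)
    fit0, mod0, de0_dis, de0_asym, expr = _fit_and_test(
        counts, samples, design0, config, factors
    )
    if config.k_factors <= 0:
        logger.info("k_factors=0: single-stage fit")
        return TwoStageResult(
            de_disease=de0_dis,
            de_asymmetry=de0_asym,
            stage1_disease=de0_dis,
            stage1_asymmetry=de0_asym,
            nuisance=None,
            control_genes=[],
            factors=factors,
            logcpm=expr,
            kept_genes=list(counts.gene_ids),
            final_fit=fit0,
            final_moderation=mod0,
        )
    controls = select_least_different(de0_dis, config.n_control_genes)
    reduced = build_design(samples, covariates=REDUCED_COVARIATES)
    admissible = min(reduced.n_samples - reduced.rank, len(controls)) - 1
    k = min(config.k_factors, max(admissible, 1))
    if k < config.k_factors:
        logger.warning(
            "reducing k_factors from %d to admissible %d", config.k_factors, k
        )
    nuisance = estimate_nuisance(expr, reduced, controls, k=k)
    design1 = build_design(samples, nuisance=nuisance)
    fit1, mod1, de1_dis, de1_asym, _ = _fit_and_test(
        counts, samples, design1, config, factors
    )
    logger.info(
        "final model: %d disease / %d asymmetry genes at FDR<%g",
        int((de1_dis["fdr"] < config.fdr_threshold).sum()),
        int((de1_asym["fdr"] < config.fdr_threshold).sum()),
        config.fdr_threshold,
    )
    return TwoStageResult(
        de_disease=de1_dis,
        de_asymmetry=de1_asym,
        stage1_disease=de0_dis,
        stage1_asymmetry=de0_asym,
        nuisance=nuisance,
        control_genes=controls,
        factors=factors,
        logcpm=expr,
        kept_genes=list(counts.gene_ids),
        final_fit=fit1,
        final_moderation=mod1,
    )
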