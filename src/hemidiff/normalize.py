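"""Between-sample scaling normalization and expression scales.

Scaling uses the trimmed mean of M-values (TMM): for each sample, genewise
log2 ratios (M) against a reference sample are doubly trimmed — by the M
values themselves and by average log intensity (A) — and the surviving M
values are combined in a weighted mean, weights being the inverse binomial
(delta-method) variance of each M.  The reference is the sample whose
upper-quartile count fraction is closest to the cohort mean.  Factors are
rescaled so their geometric mean is one.

Downstream statistics run on log2 counts-per-million with a pseudo-count;
an exp-scale "corrected" matrix with fitted nuisance structure removed is
provided for display and correlation analyses only.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .containers import CountMatrix, ExpressionMatrix, NormFactors

__all__ = ["tmm_factors", "cpm", "log_cpm", "corrected_counts"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 scaling factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 0.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    po = o / lib_obs
    pr = r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # inverse asymptotic variance of M under binomial sampling
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    denom = np.sum(1.0 / w[sel])
    if not np.any(sel) or denom == 0:
        return 0.0
    f = np.sum(m[sel] / w[sel]) / denom
    if not np.isfinite(f):
        return 0.0
    return f


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for each sample."""
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.library_sizes().astype(float)
    zero = lib == 0
    if zero.any():
        bad = list(counts.sample_ids[zero])
        raise ValueError(f"samples with zero total count: {bad}")
    x = counts.counts.astype(float)
    # reference: 75th-percentile count fraction closest to the mean fraction
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(counts.n_samples)
        ]
    )
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        counts.sample_ids, factors, str(counts.sample_ids[ref_idx])
    )


def _effective_libsizes(counts: CountMatrix, factors: NormFactors) -> np.ndarray:
    if not counts.sample_ids.equals(factors.sample_ids):
        raise ValueError("sample sets of counts and factors differ")
    return counts.library_sizes().astype(float) * factors.factors


def cpm(counts: CountMatrix, factors: NormFactors) -> ExpressionMatrix:
    """Counts per million on effective (TMM-scaled) library sizes."""
    eff = _effective_libsizes(counts, factors)
    vals = counts.counts / eff[None, :] * 1e6
    return ExpressionMatrix(counts.gene_ids, counts.sample_ids, vals, "cpm")


def log_cpm(
    counts: CountMatrix, factors: NormFactors, prior: float = 0.5
) -> ExpressionMatrix:
    """log2((count + prior) / (effective libsize + 2 prior) * 1e6)."""
    if prior <= 0:
        raise ValueError("prior pseudo-count must be positive")
    eff = _effective_libsizes(counts, factors)
    vals = np.log2((counts.counts + prior) / (eff[None, :] + 2 * prior) * 1e6)
    return ExpressionMatrix(counts.gene_ids, counts.sample_ids, vals, "log2cpm")


def corrected_counts(
    expr: ExpressionMatrix, nuisance: np.ndarray, loadings: np.ndarray | None = None
) -> ExpressionMatrix:
    """Exp-scale expression with fitted nuisance structure removed.

    ``nuisance`` is the samples x k factor matrix estimated from control-gene
    residuals.  Loadings default to the per-gene least-squares projection of
    log expression on the factors; passing precomputed loadings overrides
    the fit.  The result is for display and correlation only — inference
    always runs on the log2cpm scale with the factors as model covariates.
    Projection makes the operation idempotent: residuals are orthogonal to
    the factors, so a second pass fits zero loadings.
    """
    if expr.scale != "log2cpm":
        raise ValueError("corrected_counts expects log2cpm input")
    w = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if w.shape[0] != expr.n_samples:
        raise ValueError(
            f"nuisance factor rows ({w.shape[0]}) != samples ({expr.n_samples})"
        )
    if loadings is None:
        # fit with an intercept so the factors explain variation around the
        # gene mean, but subtract only the factor part
        aug = np.column_stack([np.ones(w.shape[0]), w])
        coef, *_ = np.linalg.lstsq(aug, expr.values.T, rcond=None)
        loadings = coef[1:]
    else:
        loadings = np.asarray(loadings, dtype=float)
        if loadings.shape != (w.shape[1], expr.n_genes):
            raise ValueError("loadings shape must be (k, n_genes)")
    corrected_log = expr.values - (w @ loadings).T
    return ExpressionMatrix(
        expr.gene_ids, expr.sample_ids, 2.0 ** corrected_log, "corrected"
    )
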