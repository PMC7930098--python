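"""Transform raw counts into regression-ready quantities.

The total-count response is ``y_trc = log(Y_total / (2 L))`` and the
allelic-imbalance response is ``y_asc = log(asc1 / asc2)`` with weights
``w = (1/asc1 + 1/asc2)^-1`` (inverse of the count-level error variance,
up to the common scale sigma^2).  Filters and the weight cap follow the
defaults used for large cohort analyses.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import GeneCounts

log = logging.getLogger(__name__)


@dataclasses.dataclass
class FilterConfig:
    """Thresholds for sample- and gene-level count filters.

    asc_sample_min_reads: a sample enters the allelic-imbalance regression
        only with strictly more than this many reads on *both* haplotypes.
    asc_outlier_max: samples with an allele-specific count above this on
        either haplotype are treated as alignment artifacts and dropped.
    trc_zero_impute: zero total counts are replaced by this value before
        taking logs.
    gene_*: gene-level inclusion criteria (counted with >=).
    min_asc_samples_for_meta: minimum valid samples for the allelic
        component to participate in the combined test.
    """

    asc_sample_min_reads: int = 15
    asc_outlier_max: int = 1000
    trc_zero_impute: int = 1
    gene_min_asc_samples: int = 15
    gene_asc_reads_per_hap: int = 50
    gene_min_trc_samples: int = 500
    gene_trc_min_reads: int = 100
    min_asc_samples_for_meta: int = 15

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclasses.dataclass
class PreparedGene:
    """Regression inputs for one gene; full-length arrays with masks."""

    y_trc: np.ndarray
    trc_mask: np.ndarray
    y_asc: np.ndarray
    w: np.ndarray
    asc_mask: np.ndarray

    @property
    def n_trc(self) -> int:
        return int(self.trc_mask.sum())

    @property
    def n_asc(self) -> int:
        return int(self.asc_mask.sum())


def compute_trc(counts: GeneCounts, cfg: FilterConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """log(Y_total / (2 L)) with zero counts imputed to ``trc_zero_impute``."""
    cfg = cfg or FilterConfig()
    y = np.maximum(counts.total, cfg.trc_zero_impute).astype(float)
    y_trc = np.log(y / (2.0 * counts.libsize))
    mask = np.isfinite(y_trc)
    return y_trc, mask


def compute_asc(counts: GeneCounts, cfg: FilterConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allelic log-ratio, raw inverse-variance weights and validity mask.

    A sample is valid iff both haplotype counts exceed
    ``asc_sample_min_reads`` and neither exceeds ``asc_outlier_max``.
    Entries outside the mask are NaN.
    """
    cfg = cfg or FilterConfig()
    a1 = counts.asc1.astype(float)
    a2 = counts.asc2.astype(float)
    mask = ((counts.asc1 > cfg.asc_sample_min_reads)
            & (counts.asc2 > cfg.asc_sample_min_reads)
            & (np.maximum(counts.asc1, counts.asc2) <= cfg.asc_outlier_max))
    y = np.full(counts.n_samples, np.nan)
    w = np.full(counts.n_samples, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        y[mask] = np.log(a1[mask] / a2[mask])
        w[mask] = 1.0 / (1.0 / a1[mask] + 1.0 / a2[mask])
    return y, w, mask


def cap_weights(raw_w: np.ndarray, n: int) -> np.ndarray:
    """Cap weights at K = min(10, n/10) times the smallest weight.

    Limits the leverage of samples with very deep allele-specific
    coverage.  ``n`` is the cohort sample size; for tiny cohorts the cap
    is floored at 1 (all weights equalized).
    """
    raw_w = np.asarray(raw_w, dtype=float)
    if raw_w.size == 0:
        return raw_w.copy()
    if np.any(raw_w <= 0):
        raise ValueError("weights must be positive")
    k = max(1.0, min(10.0, n / 10.0))
    return np.minimum(raw_w, k * raw_w.min())


def gene_passes_asc_filters(counts: GeneCounts, cfg: FilterConfig | None = None) -> bool:
    """Gene-level inclusion: enough deep allele-specific and total samples."""
    cfg = cfg or FilterConfig()
    n_asc = int(((counts.asc1 >= cfg.gene_asc_reads_per_hap)
                 & (counts.asc2 >= cfg.gene_asc_reads_per_hap)).sum())
    n_trc = int((counts.total >= cfg.gene_trc_min_reads).sum())
    return n_asc >= cfg.gene_min_asc_samples and n_trc >= cfg.gene_min_trc_samples


def adjust_covariates(y_trc: np.ndarray, covariates: pd.DataFrame | np.ndarray,
                      p_threshold: float = 0.05) -> np.ndarray:
    """Two-stage covariate adjustment of the total-count response.

    Stage 1 regresses y on all covariates jointly and keeps those with a
    two-sided coefficient p below ``p_threshold``; stage 2 regresses y on
    the kept covariates and returns the residuals.  With no covariate
    kept, y is simply centered.  Allelic-imbalance values are never
    adjusted: individual-level effects cancel in the log-ratio.
    """
    y = np.asarray(y_trc, dtype=float)
    C = pd.DataFrame(covariates)
    n, k = C.shape
    if n != y.shape[0]:
        raise ValueError("covariate rows must match samples")
    if n <= k + 1:
        raise ValueError(f"need n > K + 1 samples ({n} <= {k + 1})")

    # constant columns carry no information once an intercept is fit
    keep_cols = [c for c in C.columns if C[c].nunique() > 1]
    if len(keep_cols) < k:
        log.warning("dropping %d constant covariate columns", k - len(keep_cols))
    C = C[keep_cols]
    if C.shape[1] == 0:
        return y - y.mean()

    X1 = sm.add_constant(C.to_numpy(dtype=float))
    fit1 = sm.OLS(y, X1).fit()
    selected = [c for c, p in zip(C.columns, fit1.pvalues[1:]) if p < p_threshold]
    if not selected:
        return y - y.mean()

    X2 = C[selected].to_numpy(dtype=float)
    # drop collinear columns so stage 2 has full rank
    q, r = np.linalg.qr(X2 - X2.mean(axis=0))
    indep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not indep.all():
        log.warning("dropping %d collinear covariate columns", int((~indep).sum()))
        X2 = X2[:, indep]
    fit2 = sm.OLS(y, sm.add_constant(X2)).fit()
    return np.asarray(fit2.resid)


def prepare_gene(counts: GeneCounts, cfg: FilterConfig | None = None,
                 covariates: pd.DataFrame | np.ndarray | None = None) -> PreparedGene:
    """Full preprocessing for one gene: responses, weights, masks."""
    cfg = cfg or FilterConfig()
    y_trc, trc_mask = compute_trc(counts, cfg)
    if covariates is not None:
        y_trc = y_trc.copy()
        y_trc[trc_mask] = adjust_covariates(
            y_trc[trc_mask], pd.DataFrame(covariates).iloc[np.flatnonzero(trc_mask)])
    y_asc, raw_w, asc_mask = compute_asc(counts, cfg)
    w = np.full_like(raw_w, np.nan)
    w[asc_mask] = cap_weights(raw_w[asc_mask], counts.n_samples)
    return PreparedGene(y_trc=y_trc, trc_mask=trc_mask,
                        y_asc=y_asc, w=w, asc_mask=asc_mask)
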