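"""Two-step multi-SNP preparation: variance components, then stacking.

Multi-SNP solvers (fine-mapping, penalized prediction) expect a single
homoskedastic linear model y = X beta + e.  The two count-derived
regressions have different error scales, so we first estimate the
residual variance of each block by REML -- treating the genetic effect
as a random effect with kernel K = X X'/p, as in EMMA-style mixed
models -- and then center/scale each block so its rows have unit error
variance.  The scaled blocks are stacked into one augmented dataset in
which the same beta vector solves both blocks.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import linalg, optimize

from .io_formats import PhasedGenotypes
from .preprocess import PreparedGene

log = logging.getLogger(__name__)


@dataclasses.dataclass
class VarianceEstimates:
    """REML variance components for the two blocks.

    sigma2_trc is the residual variance of the total-count equation
    (individual baseline variation plus count noise); sigma2_asc is the
    common scale of the weighted allelic-imbalance errors.
    """

    sigma2_trc: float
    sigma2_asc: float
    sigma2_g_trc: float = 0.0
    sigma2_g_asc: float = 0.0
    trc_at_boundary: bool = False
    asc_at_boundary: bool = False


@dataclasses.dataclass
class AugmentedData:
    """Stacked, variance-standardized data from both blocks.

    ``block`` labels each row "trc" or "asc"; ``sample_idx`` maps rows
    back to cohort samples.  The trc-block centering constants and block
    scales are kept so fitted coefficients (which are on the original
    beta scale in both codings) can be turned into predictions on the
    raw log-abundance scale.
    """

    y: np.ndarray
    X: np.ndarray
    block: np.ndarray  # (rows,) of {"trc", "asc"}
    sample_idx: np.ndarray
    variant_ids: list[str]
    y_trc_mean: float
    x_trc_mean: np.ndarray
    sigma_trc: float
    sigma_asc: float

    @property
    def trc_rows(self) -> np.ndarray:
        return self.block == "trc"

    @property
    def asc_rows(self) -> np.ndarray:
        return self.block == "asc"


def _reml_loglik(log_delta: float, eigvals: np.ndarray, etas2: np.ndarray) -> float:
    delta = np.exp(log_delta)
    m = eigvals.size
    denom = eigvals + delta
    ss = float(np.sum(etas2 / denom))
    return 0.5 * (m * np.log(m / (2.0 * np.pi)) - m
                  - m * np.log(ss) - float(np.sum(np.log(denom))))


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray | None = None,
    intercept: bool = True,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
    n_grid: int = 64,
) -> tuple[float, float, bool]:
    """REML estimates of (sigma2_g, sigma2_e) for y ~ N(mu, sg2*K + se2*D).

    K = Xc Xc'/p with columns of X centered when an intercept is present;
    D = diag(1/w) (identity when w is None).  Rows are pre-whitened by
    sqrt(w), the restricted kernel is eigendecomposed once, and the REML
    log-likelihood is maximized over the ratio delta = se2/sg2 by a
    log-grid pre-scan followed by bounded Brent refinement.  Returns
    (sigma2_g, sigma2_e, at_boundary); invariant to row order.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X must have the same number of rows")
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")

    sw = np.ones(n) if w is None else np.sqrt(np.asarray(w, dtype=float))
    ys = y * sw
    Xc = X - X.mean(axis=0) if intercept else X
    Xs = Xc * sw[:, None]
    K = (Xs @ Xs.T) / max(p, 1)

    if intercept:
        # restrict to the complement of the (whitened) intercept direction
        Q = linalg.null_space(sw[None, :])  # (n, n-1), orthonormal
        M = Q.T @ K @ Q
        eta = Q.T @ ys
    else:
        M = K
        eta = ys
    eigvals, U = linalg.eigh(M)
    eigvals = np.clip(eigvals, 0.0, None)
    etas2 = (U.T @ eta) ** 2

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    ll = np.array([_reml_loglik(g, eigvals, etas2) for g in grid])
    i = int(np.argmax(ll))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(t, eigvals, etas2),
        bounds=(a, b), method="bounded")
    log_delta = float(res.x)
    at_boundary = log_delta <= lo + 1e-3 or log_delta >= hi - 1e-3
    if at_boundary:
        log.debug("REML ratio estimate at search boundary (log delta=%.2f)",
                  log_delta)

    delta = float(np.exp(log_delta))
    m = eigvals.size
    sigma2_g = float(np.sum(etas2 / (eigvals + delta))) / m
    sigma2_e = delta * sigma2_g
    return sigma2_g, sigma2_e, at_boundary


def estimate_gene_variances(prep: PreparedGene, geno: PhasedGenotypes,
                            min_asc_samples: int = 15) -> VarianceEstimates:
    """Estimate both blocks' residual variances for one gene.

    The allelic block needs enough valid samples; otherwise its variance
    is left NaN and downstream augmentation uses the trc block only.
    """
    x_trc = geno.dosage_trc()
    tmask = prep.trc_mask & np.all(np.isfinite(x_trc), axis=1)
    sg_t, se_t, bd_t = estimate_variance_components(
        prep.y_trc[tmask], x_trc[tmask], w=None, intercept=True)

    x_asc = geno.dosage_asc()
    amask = prep.asc_mask & np.all(np.isfinite(x_asc), axis=1)
    if int(amask.sum()) >= max(min_asc_samples, 10):
        sg_a, se_a, bd_a = estimate_variance_components(
            prep.y_asc[amask], x_asc[amask], w=prep.w[amask], intercept=False)
    else:
        sg_a, se_a, bd_a = 0.0, np.nan, False
    return VarianceEstimates(sigma2_trc=se_t, sigma2_asc=se_a,
                             sigma2_g_trc=sg_t, sigma2_g_asc=sg_a,
                             trc_at_boundary=bd_t, asc_at_boundary=bd_a)


def build_augmented(prep: PreparedGene, geno: PhasedGenotypes,
                    var: VarianceEstimates,
                    include_asc: bool = True) -> AugmentedData:
    """Center, scale and stack the two blocks into one homoskedastic model.

    trc rows: (y - mean, X - column means) / sigma_trc, genotype coded
    (X1+X2)/2.  asc rows: (y, X) * sqrt(w)/sigma_asc, genotype coded
    X1-X2, no centering (the model has no intercept).  An empty or
    unusable asc block yields the scaled trc block alone.
    """
    if not np.isfinite(var.sigma2_trc) or var.sigma2_trc <= 0:
        raise ValueError("positive trc variance estimate required")
    sigma_trc = float(np.sqrt(var.sigma2_trc))

    x_trc = geno.dosage_trc()
    tmask = prep.trc_mask & np.all(np.isfinite(x_trc), axis=1)
    tidx = np.flatnonzero(tmask)
    y_t = prep.y_trc[tidx]
    X_t = x_trc[tidx]
    y_mean = float(y_t.mean())
    x_mean = X_t.mean(axis=0)
    y_rows = [(y_t - y_mean) / sigma_trc]
    X_rows = [(X_t - x_mean) / sigma_trc]
    blocks = [np.full(tidx.size, "trc")]
    sample_idx = [tidx]

    sigma_asc = np.nan
    use_asc = (include_asc and np.isfinite(var.sigma2_asc) and var.sigma2_asc > 0)
    if use_asc:
        sigma_asc = float(np.sqrt(var.sigma2_asc))
        x_asc = geno.dosage_asc()
        amask = prep.asc_mask & np.all(np.isfinite(x_asc), axis=1)
        aidx = np.flatnonzero(amask)
        if aidx.size:
            scale = np.sqrt(prep.w[aidx]) / sigma_asc
            y_rows.append(prep.y_asc[aidx] * scale)
            X_rows.append(x_asc[aidx] * scale[:, None])
            blocks.append(np.full(aidx.size, "asc"))
            sample_idx.append(aidx)

    return AugmentedData(
        y=np.concatenate(y_rows),
        X=np.vstack(X_rows),
        block=np.concatenate(blocks),
        sample_idx=np.concatenate(sample_idx),
        variant_ids=list(geno.variant_ids),
        y_trc_mean=y_mean,
        x_trc_mean=x_mean,
        sigma_trc=sigma_trc,
        sigma_asc=sigma_asc,
    )


def prepare_augmented(prep: PreparedGene, geno: PhasedGenotypes,
                      include_asc: bool = True,
                      min_asc_samples: int = 15) -> tuple[AugmentedData, VarianceEstimates]:
    """Convenience wrapper: estimate variances, then stack the blocks."""
    var = estimate_gene_variances(prep, geno, min_asc_samples=min_asc_samples)
    aug = build_augmented(prep, geno, var, include_asc=include_asc)
    return aug, var
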