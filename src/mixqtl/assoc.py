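"""Single-variant association: the mixQTL test and its components.

The total-count regression (OLS with intercept, genotype coded
(X1+X2)/2) and the allelic-imbalance regression (weighted least squares
through the origin, genotype coded X1-X2) are fit separately and
combined by fixed-effect inverse-variance meta-analysis.  The two
responses carry approximately independent information on the shared
log allelic fold change beta, which is what makes the simple
meta-analytic combination valid.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .io_formats import PhasedGenotypes
from .preprocess import FilterConfig, PreparedGene


@dataclasses.dataclass
class AssocResult:
    """Per-variant estimates for each component and the combined test.

    ``method`` records which components informed the headline result:
    "meta" when both were available, otherwise "trc" or "asc".
    """

    variant_id: str
    gene_id: str = ""
    beta_trc: float = math.nan
    se_trc: float = math.nan
    p_trc: float = math.nan
    beta_asc: float = math.nan
    se_asc: float = math.nan
    p_asc: float = math.nan
    beta_meta: float = math.nan
    se_meta: float = math.nan
    p_meta: float = math.nan
    n_trc: int = 0
    n_asc: int = 0
    method: str = "trc"


def fit_trc(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of the log total-count abundance on genotype, with intercept.

    Returns (beta, se, p, n); NaNs for a monomorphic variant.  The p-value
    is two-sided from t(n-2).  Samples with NaN in y or x are dropped.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = y.size
    if n < 3:
        return math.nan, math.nan, math.nan, n
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return math.nan, math.nan, math.nan, n
    beta = float(xc @ (y - y.mean())) / sxx
    resid = y - y.mean() - beta * xc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        return beta, 0.0, 0.0, n
    p = 2.0 * stats.t.sf(abs(beta / se), df)
    return beta, se, float(p), n


def fit_asc(y: np.ndarray, x: np.ndarray, w: np.ndarray
            ) -> tuple[float, float, float, int]:
    """Weighted least squares through the origin for the allelic log-ratio.

    beta = sum(w x y) / sum(w x^2); the residual scale sigma^2 is
    estimated from all valid samples (including homozygous ones, whose
    fitted value is zero) with n-1 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(w)
    y, x, w = y[ok], x[ok], w[ok]
    n = y.size
    if n < 2 or not np.any(x != 0):
        return math.nan, math.nan, math.nan, n
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / sxx
    resid = y - x * beta
    df = n - 1
    sigma2 = float(np.sum(w * resid * resid)) / df
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        return beta, 0.0, 0.0, n
    p = 2.0 * stats.t.sf(abs(beta / se), df)
    return beta, se, float(p), n


def meta_combine(beta1: float, se1: float, beta2: float, se2: float
                 ) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance combination of two independent estimates.

    Falls back to the defined component when the other is NaN; the
    combined p-value is two-sided Normal.
    """
    ok1 = np.isfinite(beta1) and np.isfinite(se1) and se1 > 0
    ok2 = np.isfinite(beta2) and np.isfinite(se2) and se2 > 0
    if not ok1 and not ok2:
        return math.nan, math.nan, math.nan
    if ok1 and ok2:
        v1, v2 = 1.0 / se1**2, 1.0 / se2**2
        beta = (v1 * beta1 + v2 * beta2) / (v1 + v2)
        se = 1.0 / math.sqrt(v1 + v2)
    elif ok1:
        beta, se = beta1, se1
    else:
        beta, se = beta2, se2
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
    return float(beta), float(se), float(p)


def run_cis_scan(gene: PreparedGene, geno: PhasedGenotypes,
                 cfg: FilterConfig | None = None,
                 gene_id: str = "") -> list[AssocResult]:
    """Nominal pass over every variant in the cis-window of one gene.

    The total-count component is always attempted; the allelic component
    only when enough valid samples carry informative (heterozygous)
    genotypes.  Samples with a missing genotype are excluded per variant.
    """
    cfg = cfg or FilterConfig()
    x_trc_all = geno.dosage_trc()
    x_asc_all = geno.dosage_asc()
    results: list[AssocResult] = []
    for j, vid in enumerate(geno.variant_ids):
        res = AssocResult(variant_id=vid, gene_id=gene_id)
        xt = np.where(gene.trc_mask, x_trc_all[:, j], np.nan)
        res.beta_trc, res.se_trc, res.p_trc, res.n_trc = fit_trc(gene.y_trc, xt)

        xa = np.where(gene.asc_mask, x_asc_all[:, j], np.nan)
        n_asc_valid = int(np.sum(np.isfinite(xa) & np.isfinite(gene.y_asc)))
        if n_asc_valid >= cfg.min_asc_samples_for_meta and np.nansum(np.abs(xa)) > 0:
            res.beta_asc, res.se_asc, res.p_asc, res.n_asc = fit_asc(
                gene.y_asc, xa, gene.w)
        else:
            res.n_asc = n_asc_valid

        res.beta_meta, res.se_meta, res.p_meta = meta_combine(
            res.beta_trc, res.se_trc, res.beta_asc, res.se_asc)
        has_trc = np.isfinite(res.beta_trc)
        has_asc = np.isfinite(res.beta_asc)
        res.method = "meta" if (has_trc and has_asc) else ("asc" if has_asc else "trc")
        results.append(res)
    return results


def permute_gene(gene: PreparedGene, seed: int) -> PreparedGene:
    """Permute phenotypes against genotypes while preserving marginals.

    One shared permutation is applied to the total-count response (with
    its mask) and an independent one to the allelic-imbalance response,
    weights and mask.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = gene.y_trc.shape[0]
    p1 = rng.permutation(n)
    p2 = rng.permutation(n)
    return PreparedGene(
        y_trc=gene.y_trc[p1], trc_mask=gene.trc_mask[p1],
        y_asc=gene.y_asc[p2], w=gene.w[p2], asc_mask=gene.asc_mask[p2],
    )
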