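"""Penalized multi-SNP prediction of expression (mixPred).

An elastic-net path is fit on the augmented rows (total-count and
allelic blocks jointly).  Because both blocks encode the same effect
vector beta, the fitted coefficients are directly the per-allele log
fold changes; predictions are made on the total-count scale,
intercept + (X1+X2)/2 . beta.  The penalty is selected by internal
k-fold cross-validation scored on total-count rows only, since the
deployable prediction target lives on that scale.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .io_formats import PhasedGenotypes
from .variance_scaling import AugmentedData

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PredModel:
    """Sparse per-variant weights on the allelic (log fold change) scale."""

    weights: np.ndarray
    intercept: float
    variant_ids: list[str]
    alpha_mix: float
    lambda_: float
    cv_mse: np.ndarray | None = None
    lambda_path: np.ndarray | None = None


def _lambda_grid(y: np.ndarray, X: np.ndarray, alpha_mix: float,
                 n_lambda: int, eps: float = 1e-3) -> np.ndarray:
    n = y.size
    lam_max = np.max(np.abs(X.T @ y)) / (n * max(alpha_mix, 1e-3))
    if lam_max <= 0:
        return np.array([1.0])
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambda)


def fit_mixpred(aug: AugmentedData, alpha_mix: float = 0.5, n_lambda: int = 100,
                cv_folds: int = 5, seed: int = 0,
                lambdas: np.ndarray | None = None) -> PredModel:
    """Elastic net on the augmented data with CV-selected penalty.

    Folds are drawn over cohort samples, so a sample's total-count and
    allelic rows always land in the same fold.  Validation error is the
    mean squared error on held-out total-count rows.
    """
    y, X = aug.y, aug.X
    n_rows = y.size
    if n_rows < 20:
        raise ValueError(f"need at least 20 rows, got {n_rows}")
    if not np.any(y != 0):
        return PredModel(weights=np.zeros(X.shape[1]), intercept=aug.y_trc_mean,
                         variant_ids=list(aug.variant_ids), alpha_mix=alpha_mix,
                         lambda_=np.inf)

    lams = (np.asarray(lambdas, dtype=float) if lambdas is not None
            else _lambda_grid(y, X, alpha_mix, n_lambda))
    mse = np.zeros(lams.size)
    best = 0
    if lams.size > 1:
        samples = np.unique(aug.sample_idx)
        kf = KFold(n_splits=min(cv_folds, samples.size), shuffle=True,
                   random_state=seed)
        counts = np.zeros(lams.size)
        trc_rows = aug.trc_rows
        for _, val_samples in kf.split(samples):
            val = np.isin(aug.sample_idx, samples[val_samples])
            train = ~val
            val_trc = val & trc_rows
            if val_trc.sum() == 0 or train.sum() < 2:
                continue
            _, coefs, _ = enet_path(X[train], y[train], l1_ratio=alpha_mix,
                                    alphas=lams, eps=1e-3)
            pred = X[val_trc] @ coefs  # (n_val, n_lambda)
            mse += np.mean((pred - y[val_trc, None]) ** 2, axis=0) * val_trc.sum()
            counts += val_trc.sum()
        mse /= np.maximum(counts, 1)
        best = int(np.argmin(mse))

    model = ElasticNet(alpha=lams[best], l1_ratio=alpha_mix,
                       fit_intercept=False, max_iter=5000)
    model.fit(X, y)
    weights = np.asarray(model.coef_, dtype=float)
    intercept = aug.y_trc_mean - float(aug.x_trc_mean @ weights)
    return PredModel(weights=weights, intercept=intercept,
                     variant_ids=list(aug.variant_ids), alpha_mix=alpha_mix,
                     lambda_=float(lams[best]), cv_mse=mse, lambda_path=lams)


def predict(model: PredModel, geno: PhasedGenotypes) -> np.ndarray:
    """Predicted log total-count abundance, intercept + (X1+X2)/2 . beta.

    Variants absent from ``geno`` are dropped with a warning; missing
    genotypes propagate NaN for the affected samples.
    """
    pos = {v: j for j, v in enumerate(geno.variant_ids)}
    x = geno.dosage_trc()
    yhat = np.full(geno.n_samples, model.intercept, dtype=float)
    n_missing = 0
    for k, vid in enumerate(model.variant_ids):
        if model.weights[k] == 0.0:
            continue
        j = pos.get(vid)
        if j is None:
            n_missing += 1
            continue
        yhat = yhat + x[:, j] * model.weights[k]
    if n_missing:
        log.warning("%d model variants absent from genotypes; weights dropped",
                    n_missing)
    return yhat


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(stats.pearsonr(a[ok], b[ok])[0])


def crossval_evaluate(counts, geno: PhasedGenotypes, k_folds: int = 5,
                      repeats: int = 2, seed: int = 0,
                      filter_cfg=None, covariates=None):
    """Inverted k-fold evaluation: train on ONE fold, test on the rest.

    Larger k therefore means a smaller training set.  Each repeat
    reshuffles the fold assignment.  Returns a DataFrame with one row
    per (repeat, fold, method) holding the held-out Pearson correlation
    between predicted and observed log total-count abundance for the
    joint model (mixPred) and the total-count-only model (trcPred).
    """
    import pandas as pd

    from .preprocess import prepare_gene
    from .variance_scaling import prepare_augmented

    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = counts.n_samples
    rows = []
    for rep in range(repeats):
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed + rep)
        for fold, (rest_idx, train_idx) in enumerate(kf.split(np.arange(n))):
            # note the inversion: the small split trains, the rest tests
            c_tr = counts.subset_samples(train_idx)
            g_tr = geno.subset_samples(train_idx)
            g_te = geno.subset_samples(rest_idx)
            cov_tr = (pd.DataFrame(covariates).iloc[train_idx]
                      if covariates is not None else None)
            prep = prepare_gene(c_tr, filter_cfg, covariates=cov_tr)
            y_te, _ = _test_response(counts, rest_idx, filter_cfg, covariates)
            for method, use_asc in (("mixPred", True), ("trcPred", False)):
                try:
                    aug, _ = prepare_augmented(prep, g_tr, include_asc=use_asc)
                    model = fit_mixpred(aug, seed=seed + rep)
                    r = _pearson(predict(model, g_te), y_te)
                except ValueError:
                    r = np.nan
                rows.append({"repeat": rep, "fold": fold, "method": method,
                             "r": r, "n_train": len(train_idx)})
    return pd.DataFrame(rows)


def _test_response(counts, idx, filter_cfg, covariates):
    from .preprocess import adjust_covariates, compute_trc

    c = counts.subset_samples(idx)
    y, mask = compute_trc(c, filter_cfg)
    if covariates is not None:
        import pandas as pd
        y = adjust_covariates(y, pd.DataFrame(covariates).iloc[idx])
    return y, mask
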