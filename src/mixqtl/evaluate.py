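"""Simulation-study harness: calibration, power, fine-mapping, prediction.

Each suite simulates replicate genes under stated conditions, runs the
corresponding method(s) and summarizes rejection rates, detections,
credible-set sizes or held-out prediction accuracy with Wilson binomial
intervals.  All suites are exactly reproducible given their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .assoc import run_cis_scan
from .mixfine import IbssConfig, ibss_fit
from .mixpred import _pearson, fit_mixpred, predict
from .preprocess import FilterConfig, prepare_gene
from .simulator import SimConfig, simulate_dataset
from .variance_scaling import build_augmented, estimate_gene_variances

DEFAULT_GRID = [
    {"n_samples": n, "theta": t, "afc": a}
    for n in (100, 500) for t in (5e-5, 1e-6) for a in (1.0, 1.25, 2.0)
]


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def single_variant_pvalues(ds, filter_cfg: FilterConfig | None = None
                           ) -> dict[str, float]:
    """p-values of the three tests at the (first) causal variant."""
    cfg = filter_cfg or FilterConfig()
    prep = prepare_gene(ds.counts, cfg)
    j = int(ds.causal_idx[0])
    res = run_cis_scan(prep, ds.geno.subset_variants([j]), cfg)[0]
    return {"trcQTL": res.p_trc, "ascQTL": res.p_asc, "mixQTL": res.p_meta,
            "beta_meta": res.beta_meta, "beta_trc": res.beta_trc,
            "beta_asc": res.beta_asc}


def type1_power_suite(grid: list[dict] | None = None, alpha: float = 0.05,
                      n_rep: int = 200, seed: int = 0,
                      filter_cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Rejection fraction at nominal ``alpha`` per grid cell and method.

    Cells with afc = 1 measure type I error; others measure power at the
    causal variant.  An undefined component p-value never counts as a
    rejection.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    rows = []
    for c, cell in enumerate(grid):
        seeds = _child_seeds(seed + 7919 * c, n_rep)
        rej = {"mixQTL": 0, "trcQTL": 0, "ascQTL": 0}
        for r in range(n_rep):
            cfg = SimConfig(seed=int(seeds[r]), **cell)
            pv = single_variant_pvalues(simulate_dataset(cfg), filter_cfg)
            for m in rej:
                if np.isfinite(pv[m]) and pv[m] < alpha:
                    rej[m] += 1
        for m, k in rej.items():
            lo, hi = _wilson(k, n_rep)
            rows.append({**cell, "method": m, "metric": "rejection_rate",
                         "estimate": k / n_rep, "ci_low": lo, "ci_high": hi,
                         "n_replicates": n_rep, "alpha": alpha})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class FineMapReplicate:
    method: str
    replicate: int
    is_null: bool
    pip: np.ndarray
    causal: np.ndarray  # boolean truth per variant
    detected: int  # causal variants at PIP > 0.5
    cs_sizes_causal: list[int]  # sizes of credible sets containing a causal
    n_cs: int


def finemap_suite(n_rep: int = 100, n_null: int = 100, n_samples: int = 500,
                  theta: float = 5e-5, h2: float = 0.4, n_causal: int = 1,
                  n_variants: int = 200, seed: int = 0,
                  ibss_cfg: IbssConfig | None = None,
                  filter_cfg: FilterConfig | None = None
                  ) -> tuple[pd.DataFrame, list[FineMapReplicate]]:
    """Paired mixFine / trcFine evaluation on shared replicates.

    Signal replicates draw ``n_causal`` causal variants at heritability
    ``h2``; null replicates carry no genetic effect and contribute to
    the PIP calibration pool.  Returns a summary table plus the
    per-replicate records (PIPs, detections, credible-set sizes).
    """
    ibss_cfg = ibss_cfg or IbssConfig()
    fcfg = filter_cfg or FilterConfig()
    seeds = _child_seeds(seed, n_rep + n_null)
    records: list[FineMapReplicate] = []
    for r in range(n_rep + n_null):
        is_null = r >= n_rep
        cfg = SimConfig(n_samples=n_samples, theta=theta,
                        h2=0.0 if is_null else h2,
                        n_causal=n_causal, n_cis_variants=n_variants,
                        seed=int(seeds[r]))
        ds = simulate_dataset(cfg)
        causal = np.zeros(n_variants, dtype=bool)
        if not is_null:
            causal[ds.causal_idx] = True
        prep = prepare_gene(ds.counts, fcfg)
        var = estimate_gene_variances(prep, ds.geno)
        for method, use_asc in (("mixFine", True), ("trcFine", False)):
            aug = build_augmented(prep, ds.geno, var, include_asc=use_asc)
            fit = ibss_fit(aug, cfg=ibss_cfg)
            sizes = [len(cs.variants) for cs in fit.credible_sets
                     if causal[cs.variants].any()]
            records.append(FineMapReplicate(
                method=method, replicate=r, is_null=is_null, pip=fit.pip,
                causal=causal, detected=int((fit.pip[causal] > 0.5).sum()),
                cs_sizes_causal=sizes, n_cs=len(fit.credible_sets)))

    rows = []
    for method in ("mixFine", "trcFine"):
        recs = [x for x in records if x.method == method and not x.is_null]
        null_recs = [x for x in records if x.method == method and x.is_null]
        n_causal_tot = sum(int(x.causal.sum()) for x in recs)
        det = sum(x.detected for x in recs)
        lo, hi = _wilson(det, max(n_causal_tot, 1))
        sizes = [s for x in recs for s in x.cs_sizes_causal]
        rows.append({"method": method, "metric": "detection_rate_pip0.5",
                     "estimate": det / max(n_causal_tot, 1),
                     "ci_low": lo, "ci_high": hi, "n_replicates": len(recs)})
        rows.append({"method": method, "metric": "mean_cs_size_causal",
                     "estimate": float(np.mean(sizes)) if sizes else np.nan,
                     "ci_low": np.nan, "ci_high": np.nan,
                     "n_replicates": len(sizes)})
        n_cs_null = sum(x.n_cs for x in null_recs)
        rows.append({"method": method, "metric": "null_credible_sets",
                     "estimate": n_cs_null, "ci_low": np.nan, "ci_high": np.nan,
                     "n_replicates": len(null_recs)})
    return pd.DataFrame(rows), records


def prediction_suite(n_rep: int = 50, n_samples: int = 500, theta: float = 5e-5,
                     h2: float = 0.4, n_causal: int = 1, n_variants: int = 200,
                     train_frac: float = 0.8, repeats: int = 2, seed: int = 0,
                     filter_cfg: FilterConfig | None = None
                     ) -> pd.DataFrame:
    """Held-out Pearson r for mixPred vs trcPred on shared replicates.

    Each replicate is split into train/test (``train_frac`` training,
    repeated ``repeats`` times with fresh splits); models are trained on
    the training split only and scored on the held-out log total-count
    abundance.
    """
    fcfg = filter_cfg or FilterConfig()
    seeds = _child_seeds(seed, n_rep)
    rows = []
    for r in range(n_rep):
        cfg = SimConfig(n_samples=n_samples, theta=theta, h2=h2,
                        n_causal=n_causal, n_cis_variants=n_variants,
                        seed=int(seeds[r]))
        ds = simulate_dataset(cfg)
        rng = np.random.default_rng(int(seeds[r]) + 1)
        for rep in range(repeats):
            perm = rng.permutation(n_samples)
            n_train = int(round(train_frac * n_samples))
            tr, te = perm[:n_train], perm[n_train:]
            c_tr = ds.counts.subset_samples(tr)
            g_tr = ds.geno.subset_samples(tr)
            g_te = ds.geno.subset_samples(te)
            prep = prepare_gene(c_tr, fcfg)
            from .preprocess import compute_trc
            y_te, _ = compute_trc(ds.counts.subset_samples(te), fcfg)
            var = estimate_gene_variances(prep, g_tr)
            for method, use_asc in (("mixPred", True), ("trcPred", False)):
                aug = build_augmented(prep, g_tr, var, include_asc=use_asc)
                model = fit_mixpred(aug, seed=int(seeds[r]))
                rows.append({"replicate": r, "split": rep, "method": method,
                             "r": _pearson(predict(model, g_te), y_te),
                             "n_train": n_train, "theta": theta, "h2": h2})
    return pd.DataFrame(rows)
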