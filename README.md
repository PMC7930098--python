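# mixqtl

cis-eQTL mapping, fine-mapping and genetic prediction of gene expression
that combine **total** and **allele-specific** RNA-seq read counts.

Standard eQTL pipelines regress a normalized expression value on genotype
and ignore the within-individual information carried by allele-specific
expression (ASE): when an individual is heterozygous for a cis-regulatory
variant, the imbalance between reads from its two gene haplotypes measures
the regulatory effect directly, free of between-individual confounding.
Methods that model both sources jointly at the count level exist but do
not scale to cohorts of hundreds to thousands of RNA-seq samples.  This
package implements the log-linear approximation that makes the joint
analysis scale: it is aimed at statistical geneticists running cis-QTL
scans, fine-mapping, or building expression prediction models on
haplotype-resolved count data.

## Model

For gene haplotype *h* of individual *i*, with library size *L*ᵢ, baseline
abundance *θ*₀,ᵢ and allelic dosage *X*ᵢʰ ∈ {0, 1}, the haplotypic read
count is modeled multiplicatively,

    Yᵢʰ = Lᵢ · θ₀,ᵢ · exp(β Xᵢʰ) · noise,

where exp(β) is the **allelic fold change (aFC)** of the alternative
allele.  Under weak effects this linearizes into two approximately
independent regressions on the observed quantities:

    allelic imbalance:   log(Yᵢ⁽¹⁾ / Yᵢ⁽²⁾)   =  (Xᵢ¹ − Xᵢ²) β + εᵢᵃˢᶜ,   εᵢᵃˢᶜ ~ N(0, σ²/wᵢ)
    total read count:    log(Yᵢᵗᵒᵗᵃˡ / 2Lᵢ)  ≈  μ₀ + ((Xᵢ¹+Xᵢ²)/2) β + z̃ᵢ,   z̃ᵢ ~ N(0, σ̃₀²)

with count-level weights wᵢ = (1/Yᵢ⁽¹⁾ + 1/Yᵢ⁽²⁾)⁻¹, so that count
variance scales with the mean.  On top of these two equations the package
provides:

- **mixQTL** — single-variant scan: OLS on the total-count equation, WLS
  through the origin on the allelic equation, combined by inverse-variance
  meta-analysis (`assoc`).
- **mixFine** — multi-SNP fine-mapping: each block is variance-standardized
  (residual variances estimated by EMMA-style REML) and stacked into one
  augmented homoskedastic dataset, on which a sum-of-single-effects (IBSS)
  solver yields per-variant posterior inclusion probabilities and 95%
  credible sets (`variance_scaling`, `mixfine`).
- **mixPred** — elastic-net prediction of log expression trained on the
  same augmented data (`mixpred`).
- a generative simulator of phased genotypes and haplotype-resolved counts
  (`simulator`) and an evaluation harness for type I error, power,
  PIP calibration, credible-set size and prediction accuracy (`evaluate`).

## Worked example

```python
import numpy as np
from mixqtl import (SimConfig, simulate_dataset, prepare_gene,
                    run_cis_scan, prepare_augmented, ibss_fit)

cfg = SimConfig(n_samples=500, theta=5e-5, afc=1.5, n_cis_variants=50, seed=42)
ds = simulate_dataset(cfg)

prep = prepare_gene(ds.counts)
results = run_cis_scan(prep, ds.geno, gene_id="simgene")
top = min(results, key=lambda r: r.p_meta)
print(top.variant_id, top.beta_meta, np.exp(top.beta_meta))

aug, var = prepare_augmented(prep, ds.geno)
fit = ibss_fit(aug)
print(fit.pip[ds.causal_idx[0]], [list(cs.variants) for cs in fit.credible_sets])
```

Output:

```
causal variant: var00006 (true log aFC = 0.4055)
samples with usable allele-specific counts: 385/500
top hit: var00006  beta_meta=0.4018 se=0.0081  p=0.000e+00  method=meta
estimated aFC = 1.494 (simulated 1.5)
fine-mapping: PIP at causal = 1.000, 1 credible set(s): [[6]]
```

The simulated gene has one causal variant with aFC 1.5 (log aFC 0.405)
among 50 cis-variants.  The scan recovers it as the top association with
an estimated aFC of 1.49; `method=meta` indicates both the total-count
and allelic components informed the estimate.  Fine-mapping assigns the
causal variant a posterior inclusion probability of 1.0 and a singleton
95% credible set.

The same pipeline is available from the shell — `mixqtl simulate`,
`mixqtl scan`, `mixqtl finemap`, `mixqtl predict-train`,
`mixqtl predict-eval`, `mixqtl evaluate` — operating on phased VCF and
TSV count matrices; the simulator writes exactly the formats the other
commands read.  Run `mixqtl --help` for options.

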