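"""Generative simulator for phased genotypes and haplotype-resolved counts.

Three steps: (1) lay out polymorphic sites uniformly across the gene
body and draw per-haplotype alleles so a site is heterozygous with
probability 2f(1-f); (2) draw a Negative Binomial library size, a Beta
baseline abundance theta_0 and haplotypic counts Y^h ~ NB with mean
L * theta_0 * exp(beta X^h); (3) read out allele-specific counts as the
reads overlapping at least one heterozygous site, with reads placed
uniformly along the gene body.  Total count is the sum of the two
haplotypic counts.

The simulator also draws a panel of candidate cis-variants (independent
sites by default, or rows of a user-supplied phased haplotype panel)
among which the causal variants live, so its output feeds the mapping,
fine-mapping and prediction code directly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import GeneAnnotation, GeneCounts, PhasedGenotypes


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated gene.

    theta is the expected baseline abundance E(theta_0); with the
    default library size of 94 million reads, theta = 5e-5 corresponds
    to roughly 50 reads per million.  The genetic effect is specified
    either as an allelic fold change ``afc`` (exp(beta) per causal
    variant) or as a target cis-heritability ``h2`` of the log
    total-count abundance.  ``nb_phi`` is the variance-to-mean ratio of
    the haplotypic counts, keeping count variance proportional to the
    mean as the error model assumes.
    """

    n_samples: int = 500
    mean_libsize: float = 94e6
    libsize_nb_size: float = 15.0
    theta: float = 5e-5
    beta_conc: float = 20.0
    afc: float | None = None
    h2: float | None = None
    n_causal: int = 1
    n_sites: float = 10.0
    maf: tuple[float, float] = (0.05, 0.3)
    gene_length: int = 2000
    read_length: int = 76
    nb_phi: float = 2.0
    n_cis_variants: int = 1
    tss: int = 1_000_000
    cis_window: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.maf[0] <= self.maf[1] <= 0.5):
            raise ValueError("maf range must lie in (0, 0.5]")
        if self.h2 is not None and not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")
        if self.afc is not None and self.afc <= 0:
            raise ValueError("afc must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_cis_variants:
            raise ValueError("need 0 <= n_causal <= n_cis_variants")
        if self.read_length >= self.gene_length:
            raise ValueError("read_length must be smaller than gene_length")


@dataclasses.dataclass
class GeneBodyConfig:
    """Polymorphic sites within the gene body (readout machinery)."""

    positions: np.ndarray  # sorted, 0-based within the gene body
    freqs: np.ndarray
    hap1: np.ndarray  # (n, s)
    hap2: np.ndarray


@dataclasses.dataclass
class SimulatedDataset:
    geno: PhasedGenotypes
    counts: GeneCounts
    annotation: GeneAnnotation
    causal_idx: np.ndarray
    beta: np.ndarray  # (p,) true effects on the cis-variant panel
    theta0: np.ndarray
    alpha: np.ndarray  # realized allele-specific fraction per sample
    sites: GeneBodyConfig
    hap_counts: tuple[np.ndarray, np.ndarray] | None = None


def simulate_gene_config(cfg: SimConfig, rng: np.random.Generator) -> GeneBodyConfig:
    """Step 1: site positions, frequencies and per-haplotype alleles."""
    s = int(rng.poisson(cfg.n_sites))
    positions = np.sort(rng.integers(0, cfg.gene_length, size=s))
    freqs = rng.uniform(cfg.maf[0], cfg.maf[1], size=s)
    hap1 = (rng.random((cfg.n_samples, s)) < freqs).astype(np.int8)
    hap2 = (rng.random((cfg.n_samples, s)) < freqs).astype(np.int8)
    return GeneBodyConfig(positions=positions, freqs=freqs, hap1=hap1, hap2=hap2)


def asc_fraction(het_positions: np.ndarray, gene_length: int,
                 read_length: int) -> float:
    """Probability that a uniformly placed read covers >= 1 het site.

    Read starts are the integers 0 .. gene_length - read_length; a read
    starting at s covers positions [s, s + read_length).
    """
    if het_positions.size == 0:
        return 0.0
    n_starts = gene_length - read_length + 1
    last = gene_length - read_length
    a = np.clip(het_positions - read_length + 1, 0, None)
    b = np.minimum(het_positions, last)
    keep = b >= a
    a, b = a[keep], b[keep]
    if a.size == 0:
        return 0.0
    # merge the (sorted) per-site start windows and total their length
    covered = 0
    cur_a, cur_b = int(a[0]), int(b[0])
    for k in range(1, a.size):
        if a[k] > cur_b + 1:
            covered += cur_b - cur_a + 1
            cur_a, cur_b = int(a[k]), int(b[k])
        else:
            cur_b = max(cur_b, int(b[k]))
    covered += cur_b - cur_a + 1
    return covered / n_starts


def _alphas(sites: GeneBodyConfig, cfg: SimConfig) -> np.ndarray:
    het = sites.hap1 != sites.hap2
    return np.array([
        asc_fraction(sites.positions[het[i]], cfg.gene_length, cfg.read_length)
        for i in range(het.shape[0])
    ])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative Binomial with Var = phi * mean (Poisson when phi <= 1)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 1.0:
        return rng.poisson(mean)
    size = mean / (phi - 1.0)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size[pos], 1.0 / phi)
    return out


def simulate_counts(cfg: SimConfig, x1: np.ndarray, x2: np.ndarray,
                    beta: np.ndarray, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Step 2: library sizes, baseline abundances and haplotypic counts.

    Returns (libsize, theta0, y_hap1, y_hap2).  theta_0 is drawn as
    2*theta*Beta(c/2, c/2) so its mean is ``theta`` with concentration
    ``beta_conc`` controlling between-individual spread.
    """
    n = cfg.n_samples
    size = cfg.libsize_nb_size
    libsize = rng.negative_binomial(size, size / (size + cfg.mean_libsize), n)
    libsize = np.maximum(libsize, 1)
    c = cfg.beta_conc
    theta0 = 2.0 * cfg.theta * rng.beta(c / 2.0, c / 2.0, n)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x1 = np.asarray(x1, dtype=float).reshape(n, -1)
    x2 = np.asarray(x2, dtype=float).reshape(n, -1)
    mu1 = libsize * theta0 * np.exp(x1 @ beta)
    mu2 = libsize * theta0 * np.exp(x2 @ beta)
    y1 = _nb_draw(rng, mu1, cfg.nb_phi)
    y2 = _nb_draw(rng, mu2, cfg.nb_phi)
    return libsize, theta0, y1, y2


def readout_asc(y1: np.ndarray, y2: np.ndarray, alpha: np.ndarray,
                rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step 3: allele-specific readout by uniform read placement.

    Each of the Y^h reads is allele-specific independently with the
    per-sample coverage probability alpha (the chance a uniformly
    placed read overlaps a heterozygous site), so the gene-level
    allele-specific count is Binomial(Y^h, alpha).  Total = Y^1 + Y^2.
    """
    asc1 = rng.binomial(y1, alpha)
    asc2 = rng.binomial(y2, alpha)
    return asc1, asc2, y1 + y2


def _draw_panel(cfg: SimConfig, rng: np.random.Generator,
                panel: tuple[np.ndarray, np.ndarray] | None
                ) -> tuple[np.ndarray, np.ndarray]:
    p = cfg.n_cis_variants
    if panel is not None:
        h1, h2 = panel
        if h1.shape[0] < cfg.n_samples or h1.shape[1] < p:
            raise ValueError("haplotype panel too small for the requested shape")
        rows = rng.choice(h1.shape[0], cfg.n_samples, replace=False)
        cols = np.sort(rng.choice(h1.shape[1], p, replace=False))
        return h1[np.ix_(rows, cols)].astype(np.int8), h2[np.ix_(rows, cols)].astype(np.int8)
    freqs = rng.uniform(cfg.maf[0], cfg.maf[1], size=p)
    h1 = (rng.random((cfg.n_samples, p)) < freqs).astype(np.int8)
    h2 = (rng.random((cfg.n_samples, p)) < freqs).astype(np.int8)
    return h1, h2


def simulate_dataset(cfg: SimConfig,
                     haplotype_panel: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> SimulatedDataset:
    """Compose the three steps into a dataset the analysis code consumes.

    Reproducible given ``cfg.seed``.  When ``haplotype_panel`` is given
    (two n x p arrays of phased alleles), cis-variants are sampled from
    it instead of being drawn independently, preserving real LD.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = simulate_gene_config(cfg, rng)
    alpha = _alphas(sites, cfg)

    # candidate cis-variants; redraw if a causal variant is monomorphic
    for _ in range(100):
        h1, h2 = _draw_panel(cfg, rng, haplotype_panel)
        causal = np.sort(rng.choice(cfg.n_cis_variants, cfg.n_causal, replace=False))
        x_trc = (h1[:, causal].astype(float) + h2[:, causal].astype(float)) / 2.0
        if cfg.n_causal == 0 or all(np.var(x_trc[:, k]) > 0
                                    for k in range(cfg.n_causal)):
            break
    else:
        raise RuntimeError("could not draw polymorphic causal variants")

    beta = np.zeros(cfg.n_cis_variants)
    if cfg.n_causal > 0:
        if cfg.h2 is not None:
            b = rng.standard_normal(cfg.n_causal)
            g = x_trc @ b
            var_g = float(np.var(g))
            # noise on the log total-count scale: baseline spread + count noise
            var_log_theta0 = _beta_log_variance(cfg.beta_conc)
            count_noise = cfg.nb_phi / (2.0 * cfg.mean_libsize * cfg.theta)
            noise = var_log_theta0 + count_noise
            if cfg.h2 > 0 and var_g > 0:
                b *= np.sqrt(cfg.h2 / (1.0 - cfg.h2) * noise / var_g)
            else:
                b[:] = 0.0
            beta[causal] = b
        else:
            afc = 1.0 if cfg.afc is None else cfg.afc
            beta[causal] = np.log(afc)

    libsize, theta0, y1, y2 = simulate_counts(
        cfg, h1[:, causal], h2[:, causal], beta[causal], rng)
    asc1, asc2, total = readout_asc(y1, y2, alpha, rng)

    positions = np.sort(rng.choice(
        np.arange(max(1, cfg.tss - cfg.cis_window), cfg.tss + cfg.cis_window + 1),
        size=cfg.n_cis_variants, replace=False))
    geno = PhasedGenotypes(
        variant_ids=[f"var{j:05d}" for j in range(cfg.n_cis_variants)],
        positions=positions, hap1=h1, hap2=h2,
        samples=[f"S{i:04d}" for i in range(cfg.n_samples)], chrom="1")
    counts = GeneCounts(total=total, asc1=asc1, asc2=asc2, libsize=libsize,
                        samples=list(geno.samples))
    ann = GeneAnnotation("simgene", "1", cfg.tss, "+")
    return SimulatedDataset(geno=geno, counts=counts, annotation=ann,
                            causal_idx=causal, beta=beta, theta0=theta0,
                            alpha=alpha, sites=sites, hap_counts=(y1, y2))


def _beta_log_variance(conc: float) -> float:
    """Variance of log theta_0 when theta_0 = 2*theta*Beta(c/2, c/2)."""
    from scipy.special import polygamma
    a = conc / 2.0
    return float(polygamma(1, a) - polygamma(1, 2.0 * a))
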