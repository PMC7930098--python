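"""Readers and writers for the formats the suite touches.

Phased genotypes come from VCF (phased ``GT`` fields), counts and
annotation from plain TSV matrices.  Coordinates are 1-based inclusive
throughout, following the VCF convention.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing haplotype allele


@dataclasses.dataclass
class GeneAnnotation:
    """Gene location: the transcription start site anchors the cis-window."""

    gene_id: str
    chrom: str
    tss: int  # 1-based genomic coordinate
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclasses.dataclass
class PhasedGenotypes:
    """Per-haplotype allele dosages (0/1) for each sample x variant.

    ``hap1``/``hap2`` hold the left/right allele of the phased genotype;
    missing alleles are stored as -1.
    """

    variant_ids: list[str]
    positions: np.ndarray  # (p,) int, 1-based
    hap1: np.ndarray  # (n_samples, p) int8
    hap2: np.ndarray  # (n_samples, p) int8
    samples: list[str] | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        if self.hap1.shape != self.hap2.shape:
            raise ValueError("hap1 and hap2 must have the same shape")
        if self.hap1.shape[1] != len(self.variant_ids):
            raise ValueError("number of variant ids does not match matrix width")

    @property
    def n_samples(self) -> int:
        return self.hap1.shape[0]

    @property
    def n_variants(self) -> int:
        return self.hap1.shape[1]

    def subset_variants(self, idx) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        return PhasedGenotypes(
            variant_ids=[self.variant_ids[i] for i in np.atleast_1d(idx)],
            positions=self.positions[idx],
            hap1=self.hap1[:, idx],
            hap2=self.hap2[:, idx],
            samples=self.samples,
            chrom=self.chrom,
        )

    def subset_samples(self, idx) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        samples = [self.samples[i] for i in idx] if self.samples is not None else None
        return PhasedGenotypes(
            variant_ids=list(self.variant_ids),
            positions=self.positions,
            hap1=self.hap1[idx],
            hap2=self.hap2[idx],
            samples=samples,
            chrom=self.chrom,
        )

    def dosage_trc(self) -> np.ndarray:
        """(X1 + X2)/2 coding; NaN where either allele is missing."""
        x = (self.hap1.astype(float) + self.hap2.astype(float)) / 2.0
        x[(self.hap1 == MISSING) | (self.hap2 == MISSING)] = np.nan
        return x

    def dosage_asc(self) -> np.ndarray:
        """X1 - X2 coding; NaN where either allele is missing."""
        x = self.hap1.astype(float) - self.hap2.astype(float)
        x[(self.hap1 == MISSING) | (self.hap2 == MISSING)] = np.nan
        return x


@dataclasses.dataclass
class GeneCounts:
    """Total, haplotype-resolved allele-specific counts and library sizes."""

    total: np.ndarray
    asc1: np.ndarray
    asc2: np.ndarray
    libsize: np.ndarray
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=np.int64)
        self.asc1 = np.asarray(self.asc1, dtype=np.int64)
        self.asc2 = np.asarray(self.asc2, dtype=np.int64)
        self.libsize = np.asarray(self.libsize, dtype=np.int64)
        for name in ("total", "asc1", "asc2"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative values in {name}")
        if (self.libsize <= 0).any():
            raise ValueError("library sizes must be positive")
        # Real pipelines occasionally violate asc1+asc2 <= total; warn only.
        bad = int((self.asc1 + self.asc2 > self.total).sum())
        if bad:
            log.warning("asc1 + asc2 exceeds total for %d samples", bad)

    @property
    def n_samples(self) -> int:
        return self.total.shape[0]

    def subset_samples(self, idx) -> "GeneCounts":
        idx = np.asarray(idx)
        samples = [self.samples[i] for i in idx] if self.samples is not None else None
        return GeneCounts(
            total=self.total[idx],
            asc1=self.asc1[idx],
            asc2=self.asc2[idx],
            libsize=self.libsize[idx],
            samples=samples,
        )


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def _parse_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_phased_vcf(path: str, region: str | None = None) -> PhasedGenotypes:
    """Load phased biallelic SNVs from a VCF file.

    Unphased or multiallelic records are skipped (counted in the log);
    missing alleles are stored as -1.  ``region`` is ``chrom:start-end``
    with 1-based inclusive bounds.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region is not None else None

    ids: list[str] = []
    positions: list[int] = []
    h1: list[np.ndarray] = []
    h2: list[np.ndarray] = []
    n_skipped = 0
    chrom_seen = "1"

    # Random access needs an index; plain-text VCFs are streamed and filtered.
    records: Iterable = vcf(region) if (region and str(path).endswith(".gz")) else vcf
    for v in records:
        if want is not None and not str(path).endswith(".gz"):
            if v.CHROM != want[0] or not (want[1] <= v.POS <= want[2]):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(v.genotypes)  # (n, 3): allele1, allele2, phased flag
        if gts.shape[1] < 3 or not gts[:, 2].all():
            n_skipped += 1
            continue
        a1 = gts[:, 0].astype(np.int8)
        a2 = gts[:, 1].astype(np.int8)
        a1[a1 < 0] = MISSING
        a2[a2 < 0] = MISSING
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        positions.append(v.POS)
        h1.append(a1)
        h2.append(a2)
        chrom_seen = v.CHROM

    if n_skipped:
        log.info("skipped %d unphased/multiallelic records", n_skipped)
    n = len(samples)
    hap1 = np.column_stack(h1) if h1 else np.empty((n, 0), dtype=np.int8)
    hap2 = np.column_stack(h2) if h2 else np.empty((n, 0), dtype=np.int8)
    return PhasedGenotypes(ids, np.asarray(positions, dtype=np.int64), hap1, hap2,
                           samples=samples, chrom=chrom_seen)


def write_phased_vcf(geno: PhasedGenotypes, path: str) -> None:
    """Write genotypes as a minimal phased VCF (A/G placeholder alleles)."""
    samples = geno.samples or [f"S{i}" for i in range(geno.n_samples)]
    order = np.argsort(geno.positions, kind="stable")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={geno.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in order:
            gts = []
            for i in range(geno.n_samples):
                a1, a2 = geno.hap1[i, j], geno.hap2[i, j]
                gts.append(f"{'.' if a1 == MISSING else a1}|{'.' if a2 == MISSING else a2}")
            fh.write(f"{geno.chrom}\t{geno.positions[j]}\t{geno.variant_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def cis_window(ann: GeneAnnotation, geno: PhasedGenotypes,
               window: int = 1_000_000) -> PhasedGenotypes:
    """Variants with tss - window <= pos <= tss + window (inclusive).

    The window is symmetric around the TSS regardless of strand.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    keep = np.flatnonzero((geno.positions >= ann.tss - window)
                          & (geno.positions <= ann.tss + window))
    return geno.subset_variants(keep)


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def read_count_tables(total_path: str, asc1_path: str, asc2_path: str,
                      libsize_path: str) -> dict[str, GeneCounts]:
    """Load count matrices (genes x samples) and align sample columns by ID.

    Samples are intersected across tables (warning when some are dropped);
    genes present only in the total table get zero allele-specific vectors.
    """
    total = _read_matrix(total_path)
    asc1 = _read_matrix(asc1_path)
    asc2 = _read_matrix(asc2_path)
    lib = pd.read_csv(libsize_path, sep="\t", index_col=0).iloc[:, 0]

    shared = [s for s in total.columns if s in set(asc1.columns)
              and s in set(asc2.columns) and s in set(lib.index)]
    if not shared:
        raise ValueError(
            "no shared sample IDs across tables; total has "
            f"{list(total.columns)[:5]}..., libsize has {list(lib.index)[:5]}...")
    dropped = set(total.columns) - set(shared)
    if dropped:
        log.warning("dropping %d samples absent from some tables", len(dropped))

    lib = lib.loc[shared]
    out: dict[str, GeneCounts] = {}
    zeros = np.zeros(len(shared), dtype=np.int64)
    for gene in total.index:
        a1 = asc1.loc[gene, shared].to_numpy() if gene in asc1.index else zeros
        a2 = asc2.loc[gene, shared].to_numpy() if gene in asc2.index else zeros
        out[gene] = GeneCounts(
            total=total.loc[gene, shared].to_numpy(),
            asc1=a1, asc2=a2,
            libsize=lib.to_numpy(),
            samples=list(shared),
        )
    return out


def read_annotation(path: str) -> list[GeneAnnotation]:
    """TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    return [GeneAnnotation(r.gene_id, str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples(index=False)]


def read_covariates(path: str) -> pd.DataFrame:
    """TSV of samples x covariates with a header row and sample-id index."""
    return pd.read_csv(path, sep="\t", index_col=0)


ASSOC_COLUMNS = [
    "gene_id", "variant_id", "n_trc", "n_asc",
    "beta_trc", "se_trc", "p_trc",
    "beta_asc", "se_asc", "p_asc",
    "beta_meta", "se_meta", "p_meta",
    "method",
]


def write_assoc(results: Sequence, path: str) -> None:
    """Write association results as TSV; undefined components become NA."""
    rows = []
    for r in results:
        rows.append({c: getattr(r, c, None) for c in ASSOC_COLUMNS})
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_assoc(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
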