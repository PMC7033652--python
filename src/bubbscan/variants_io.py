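"""Variant/genotype containers, window grids and standard-format readers.

All coordinates are held 0-based half-open internally.  VCF (1-based) and
GFF3 (1-based closed) are converted on import; BED is taken as-is.  Keeping a
single convention prevents off-by-one drift between the window statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage / haplotype sentinel


@dataclass
class VariantTable:
    """Per-site metadata for a set of biallelic SNPs.

    Positions are stored 1-based (as printed in VCF); ``pos0`` gives the
    0-based coordinate used by the window machinery.  Positions must be
    strictly increasing within each chromosome.
    """

    chrom: np.ndarray  # str array, one entry per site
    pos: np.ndarray    # int array, 1-based
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def pos0(self) -> np.ndarray:
        return self.pos - 1

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx])


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid dosages, optionally with phased haplotypes.

    ``dosages`` holds entries in {0,1,2} with -1 for missing.  When phased
    input is available ``haplotypes`` holds the 2*samples x sites {0,1}
    matrix; haplotype pairs always collapse to the dosage entries.
    """

    dosages: np.ndarray                      # (n_samples, n_sites) int8
    samples: list[str]
    haplotypes: np.ndarray | None = None     # (2*n_samples, n_sites) int8
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list length does not match dosage rows")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * self.dosages.shape[0], self.dosages.shape[1]):
                raise ValueError("haplotypes must be (2*samples, sites)")
            collapsed = self.haplotypes[0::2] + self.haplotypes[1::2]
            if not np.array_equal(collapsed, self.dosages):
                raise ValueError("haplotype pairs do not collapse to dosages")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def require_haplotypes(self) -> np.ndarray:
        if self.haplotypes is None:
            raise ValueError(
                "phased haplotypes requested but the genotypes are unphased; "
                "phase upstream or load a phased VCF"
            )
        return self.haplotypes

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ref_count, alt_count) over called alleles.

        Missing dosages are excluded site-wise rather than imputed.
        """
        called = self.dosages != MISSING
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return total - alt, alt

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        hap = None if self.haplotypes is None else self.haplotypes[:, idx]
        return GenotypeMatrix(self.dosages[:, idx], list(self.samples), hap,
                              dict(self.populations))


@dataclass(frozen=True, order=True)
class Window:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad window [{self.start},{self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 0-based half-open after import."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


def make_windows(contig_lengths: dict[str, int], size: int = 50_000,
                 step: int = 20_000) -> list[Window]:
    """Sliding window grid: 50-kb windows every 20 kb by default.

    Windows start at 0 and advance by ``step`` while the start is inside the
    contig; the final window is truncated at the contig end.  ``size == step``
    gives the non-overlapping tiling used by the composite-likelihood scan.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    windows: list[Window] = []
    for chrom, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {chrom} has non-positive length")
        if length <= size:
            windows.append(Window(chrom, 0, length))
            continue
        for start in range(0, length, step):
            windows.append(Window(chrom, start, min(start + size, length)))
    return windows


def snps_in_window(variants: VariantTable, window: Window) -> slice:
    """Index range of sites with 0-based position in [start, end).

    Assumes the table is position-sorted per chromosome; binary search.
    """
    on_chrom = np.flatnonzero(variants.chrom == window.chrom)
    if on_chrom.size == 0:
        return slice(0, 0)
    pos0 = variants.pos0[on_chrom]
    lo = int(np.searchsorted(pos0, window.start, side="left"))
    hi = int(np.searchsorted(pos0, window.end, side="left"))
    return slice(int(on_chrom[0]) + lo, int(on_chrom[0]) + hi)


def read_vcf(path: str, region: tuple[str, int, int] | None = None,
             samples: list[str] | None = None) -> tuple[VariantTable, GenotypeMatrix]:
    """Load biallelic SNPs from a VCF into (VariantTable, GenotypeMatrix).

    Multi-allelic and non-SNP records are skipped (count logged).  Fully
    phased GT columns ("|" separators) yield haplotypes as well as dosages;
    any "/" genotype leaves the matrix unphased.

    Parameters
    ----------
    region : optional (chrom, start0, end0) half-open filter.
    samples : optional subset of sample names, in VCF order.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, samples=samples, gts012=True)
    names = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    skipped = 0
    phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        if region is not None:
            chrom, start0, end0 = region
            if rec.CHROM != chrom or not (start0 <= rec.POS - 1 < end0):
                continue
        gts = rec.genotype.array()  # (n, ploidy+1): allele, allele, phased flag
        a0 = gts[:, 0].astype(np.int16)
        a1 = gts[:, 1].astype(np.int16)
        dos = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        if phased and not np.all(gts[:, 2] == 1):
            phased = False
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dosage_rows.append(dos)
        hap_rows.append(np.stack([a0, a1], axis=1).reshape(-1).astype(np.int8))
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    variants = VariantTable(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                            np.array(refs, dtype=object), np.array(alts, dtype=object))
    n_sites = variants.n_sites
    dosages = (np.stack(dosage_rows, axis=1) if n_sites
               else np.empty((len(names), 0), dtype=np.int8))
    haplotypes = None
    if phased and n_sites and not np.any(dosages == MISSING):
        haplotypes = np.stack(hap_rows, axis=1)
    geno = GenotypeMatrix(dosages, names, haplotypes)
    return variants, geno


def read_gff_genes(path: str) -> list[GeneModel]:
    """Gene features from GFF3; 1-based closed converted to 0-based half-open."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            gid = attrs.get("ID", attrs.get("gene_id", f"gene_{lineno}"))
            genes.append(GeneModel(gid, fields[0], start1 - 1, end1, fields[6]))
    return genes


def read_bed(path: str) -> list[GeneModel]:
    """BED4+ intervals, already 0-based half-open."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            genes.append(GeneModel(name, fields[0], start, end, strand))
    return genes


def write_window_table(rows: pd.DataFrame, path: str) -> None:
    rows.to_csv(path, sep="\t", index=False)
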