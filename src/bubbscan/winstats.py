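"""Windowed nucleotide diversity, the pi ln-ratio and Weir-Cockerham F_ST.

Window values follow the sliding-window conventions of the standard VCF
tooling: pi is the sum of per-site heterozygosity estimates divided by the
window span in bp; the window F_ST is the "weighted" ratio of summed
variance components sum(a)/sum(a+b+c).  Windows with no usable SNPs are
reported as NaN and excluded from ranking downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants_io import MISSING, GenotypeMatrix, VariantTable, Window, snps_in_window


def site_pi(ref_count: int | np.ndarray, alt_count: int | np.ndarray) -> np.ndarray:
    """Per-site diversity 2*c_ref*c_alt / (n*(n-1)) over called alleles.

    Sites with fewer than 2 called alleles are undefined (NaN).
    """
    r = np.asarray(ref_count, dtype=float)
    a = np.asarray(alt_count, dtype=float)
    if np.any(r < 0) or np.any(a < 0):
        raise ValueError("allele counts must be non-negative")
    n = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * r * a / (n * (n - 1)), np.nan)
    return pi


def window_pi(geno: GenotypeMatrix, variants: VariantTable, window: Window) -> float:
    """Sum of site_pi over in-window sites, divided by the window span in bp.

    A truncated end window uses its actual span.  Empty windows give 0.
    """
    sl = snps_in_window(variants, window)
    ref, alt = geno.allele_counts()
    pis = site_pi(ref[sl], alt[sl])
    return float(np.nansum(pis)) / window.span


def ln_ratio_pi(pi_other: float, pi_target: float) -> float:
    """ln(pi_other / pi_target); large positive = diversity loss in target.

    Either diversity being 0 makes the ratio undefined (NaN); such windows
    are excluded from ranking.
    """
    if pi_other < 0 or pi_target < 0:
        raise ValueError("pi values must be non-negative")
    if pi_other == 0 or pi_target == 0:
        return float("nan")
    return float(np.log(pi_other / pi_target))


def _pop_site_summaries(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (called diploids n_i, alt frequency p_i, observed het h_i)."""
    called = geno.dosages != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, geno.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, (geno.dosages == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def wc_fst_site(geno1: GenotypeMatrix, geno2: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components per site, r=2 populations.

    Returns arrays (a, b, c): among-population, among-individual-within-
    population and within-individual components.  Sites monomorphic across
    both populations, or with a population of fewer than 2 called alleles
    (i.e. no called diploid), are NaN in all three.
    Heterozygosity uses observed genotype counts; no HWE assumption.
    """
    n1, p1, h1 = _pop_site_summaries(geno1)
    n2, p2, h2 = _pop_site_summaries(geno2)
    r = 2.0
    usable = (n1 >= 1) & (n2 >= 1)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        usable &= (pbar > 0) & (pbar < 1) & (nbar > 1)
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def wc_fst_window(geno1: GenotypeMatrix, geno2: GenotypeMatrix,
                  variants: VariantTable, window: Window) -> float:
    """Weighted window F_ST: sum(a) / sum(a+b+c) over usable in-window sites.

    NaN when the window has no usable site.  Negative values are retained.
    """
    sl = snps_in_window(variants, window)
    a, b, c = wc_fst_site(geno1.take_sites(np.arange(sl.start, sl.stop)),
                          geno2.take_sites(np.arange(sl.start, sl.stop)))
    return _ratio_of_sums(a, b, c)


def _ratio_of_sums(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ok = ~np.isnan(a)
    if not np.any(ok):
        return float("nan")
    denom = np.sum(a[ok] + b[ok] + c[ok])
    if denom == 0:
        return float("nan")
    return float(np.sum(a[ok]) / denom)


def genomewide_fst(geno1: GenotypeMatrix, geno2: GenotypeMatrix) -> float:
    """Weighted Weir-Cockerham F_ST over all sites."""
    a, b, c = wc_fst_site(geno1, geno2)
    return _ratio_of_sums(a, b, c)


def _window_frame(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
    })


def fst_scan(geno1: GenotypeMatrix, geno2: GenotypeMatrix, variants: VariantTable,
             windows: list[Window]) -> pd.DataFrame:
    """Per-window weighted F_ST table (chrom, start, end, n_snps, value)."""
    a, b, c = wc_fst_site(geno1, geno2)
    out = _window_frame(windows)
    vals, counts = [], []
    for w in windows:
        sl = snps_in_window(variants, w)
        vals.append(_ratio_of_sums(a[sl], b[sl], c[sl]))
        counts.append(int(np.sum(~np.isnan(a[sl]))))
    out["n_snps"] = counts
    out["value"] = vals
    return out


def pi_scan(geno: GenotypeMatrix, variants: VariantTable,
            windows: list[Window]) -> pd.DataFrame:
    """Per-window nucleotide diversity table."""
    ref, alt = geno.allele_counts()
    pis = site_pi(ref, alt)
    out = _window_frame(windows)
    vals, counts = [], []
    for w in windows:
        sl = snps_in_window(variants, w)
        vals.append(float(np.nansum(pis[sl])) / w.span)
        counts.append(int(np.sum(~np.isnan(pis[sl]))))
    out["n_snps"] = counts
    out["value"] = vals
    return out


def ln_ratio_scan(geno_other: GenotypeMatrix, geno_target: GenotypeMatrix,
                  variants: VariantTable, windows: list[Window]) -> pd.DataFrame:
    """Per-window ln(pi_other/pi_target); positive = diversity loss in target."""
    other = pi_scan(geno_other, variants, windows)
    target = pi_scan(geno_target, variants, windows)
    out = other.copy()
    out["n_snps"] = np.minimum(other["n_snps"], target["n_snps"])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((other["value"] > 0) & (target["value"] > 0),
                         np.log(other["value"] / target["value"]), np.nan)
    out["value"] = ratio
    return out
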