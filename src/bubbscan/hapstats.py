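"""Extended haplotype homozygosity (EHH), iES and the XP-EHH scan.

EHH at extension x is the probability that two random haplotypes are
identical at every SNP from the core out to x; the all-haplotype variant
used here (no partition by core allele) is the one integrated into iES for
the cross-population test.  XP-EHH is ln(iES_A / iES_B) per site,
standardised genome-wide to mean 0 / sd 1, then averaged per window.

Defaults follow the usual haplotype-scan settings: EHH truncated below 0.05,
inter-SNP gaps over 200 kb stop the extension, and curves extend at most
1 Mb from the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import GenotypeMatrix, VariantTable, Window, snps_in_window

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_MAX_EXTEND = 1_000_000


@dataclass
class EhhCurve:
    """One-sided EHH decay curve from a core site."""

    core: int
    direction: str                 # "left" or "right"
    distances: np.ndarray          # bp from the core, starting at 0
    values: np.ndarray             # EHH, starting at 1.0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class XpehhResult:
    """Per-site XP-EHH scores with the genome-wide standardisation used."""

    raw: np.ndarray                # ln(iES_A / iES_B); NaN where unscored
    normalized: np.ndarray
    mean: float
    sd: float


def _check_hap(hap: np.ndarray) -> np.ndarray:
    hap = np.asarray(hap)
    if hap.ndim != 2:
        raise ValueError("haplotype matrix must be 2-D")
    if hap.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    if np.any(hap < 0):
        raise ValueError("missing haplotype alleles are not supported; "
                         "phase/impute upstream")
    return hap


def _side_curve(hap: np.ndarray, core: int, pos0: np.ndarray, step: int,
                cutoff: float, max_extend: float, max_gap: float) -> tuple[np.ndarray, np.ndarray]:
    """Walk outward from the core, refining haplotype groups site by site.

    The core site's alleles enter the identity from the first extension step;
    EHH at distance 0 is 1 by definition (empty interval).
    """
    n = hap.shape[0]
    denom = n * (n - 1) / 2.0
    dists = [0.0]
    vals = [1.0]
    _, ids = np.unique(hap[:, core], return_inverse=True)
    j = core + step
    prev = core
    while 0 <= j < hap.shape[1]:
        gap = abs(pos0[j] - pos0[prev])
        dist = abs(pos0[j] - pos0[core])
        if gap > max_gap or dist > max_extend:
            break
        key = ids * 2 + hap[:, j]
        _, ids, counts = np.unique(key, return_inverse=True, return_counts=True)
        ehh = float(np.sum(counts * (counts - 1)) / 2.0 / denom)
        dists.append(float(dist))
        vals.append(ehh)
        if ehh < cutoff:
            break
        prev = j
        j += step
    return np.asarray(dists), np.asarray(vals)


def ehh(hap: np.ndarray, core: int, direction: str, cutoff: float = DEFAULT_CUTOFF,
        max_extend: float = DEFAULT_MAX_EXTEND, max_gap: float = DEFAULT_MAX_GAP,
        pos0: np.ndarray | None = None) -> EhhCurve:
    """One-sided EHH curve from ``core`` over phased haplotypes.

    ``pos0`` gives bp coordinates per site; site indices are used when absent.
    The walk stops when EHH drops below ``cutoff`` (that point is recorded),
    at an inter-SNP gap above ``max_gap``, or beyond ``max_extend`` bp.
    """
    hap = _check_hap(hap)
    if pos0 is None:
        pos0 = np.arange(hap.shape[1], dtype=float)
    step = {"left": -1, "right": 1}[direction]
    d, v = _side_curve(hap, core, np.asarray(pos0, dtype=float), step,
                       cutoff, max_extend, max_gap)
    return EhhCurve(core, direction, d, v)


def _side_integral(dists: np.ndarray, vals: np.ndarray) -> float:
    return float(np.trapezoid(vals, dists)) if dists.size > 1 else 0.0


def ies(hap: np.ndarray, core: int, cutoff: float = DEFAULT_CUTOFF,
        max_extend: float = DEFAULT_MAX_EXTEND, max_gap: float = DEFAULT_MAX_GAP,
        pos0: np.ndarray | None = None) -> float:
    """Two-sided trapezoidal integral of the EHH curve, in bp; >= 0.

    The segment reaching the first below-cutoff point is included, then the
    curve is truncated.
    """
    left = ehh(hap, core, "left", cutoff, max_extend, max_gap, pos0)
    right = ehh(hap, core, "right", cutoff, max_extend, max_gap, pos0)
    return _side_integral(left.distances, left.values) + \
        _side_integral(right.distances, right.values)


def xpehh_raw(hapA: np.ndarray, hapB: np.ndarray, variants: VariantTable,
              cutoff: float = DEFAULT_CUTOFF, max_extend: float = DEFAULT_MAX_EXTEND,
              max_gap: float = DEFAULT_MAX_GAP) -> np.ndarray:
    """Unstandardised per-site XP-EHH: ln(iES_A/iES_B); NaN where either
    iES is 0.  Both matrices must cover the same site set."""
    from ._ehh_kernel import ies_all

    hapA = _check_hap(hapA)
    hapB = _check_hap(hapB)
    if hapA.shape[1] != hapB.shape[1]:
        raise ValueError("populations must share the same site set")
    pos0 = variants.pos0.astype(float)
    ies_a = ies_all(np.ascontiguousarray(hapA, dtype=np.int8), pos0,
                    cutoff, float(max_extend), float(max_gap))
    ies_b = ies_all(np.ascontiguousarray(hapB, dtype=np.int8), pos0,
                    cutoff, float(max_extend), float(max_gap))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where((ies_a > 0) & (ies_b > 0), np.log(ies_a / ies_b), np.nan)


def xpehh_scan(hapA: np.ndarray, hapB: np.ndarray, variants: VariantTable,
               cutoff: float = DEFAULT_CUTOFF, max_extend: float = DEFAULT_MAX_EXTEND,
               max_gap: float = DEFAULT_MAX_GAP) -> XpehhResult:
    """XP-EHH over every site: raw = ln(iES_A/iES_B), standardised genome-wide.

    Sites where either iES is 0 are skipped; normalisation uses a single
    genome-wide bin (mean 0, sd 1 over the scored set).
    """
    raw = xpehh_raw(hapA, hapB, variants, cutoff, max_extend, max_gap)
    scored = ~np.isnan(raw)
    if scored.sum() < 2:
        raise ValueError("fewer than 2 scored sites; cannot standardise")
    mean = float(np.mean(raw[scored]))
    sd = float(np.std(raw[scored]))
    if sd == 0:
        raise ValueError("zero variance of raw scores; cannot standardise")
    norm = (raw - mean) / sd
    return XpehhResult(raw, norm, mean, sd)


def window_mean_xpehh(result: XpehhResult, variants: VariantTable,
                      windows: list[Window]) -> pd.DataFrame:
    """Arithmetic mean of normalised scores per window; NaN when unscored."""
    rows = []
    for w in windows:
        sl = snps_in_window(variants, w)
        vals = result.normalized[sl]
        vals = vals[~np.isnan(vals)]
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "n_snps": int(vals.size),
            "value": float(np.mean(vals)) if vals.size else float("nan"),
        })
    return pd.DataFrame(rows)


def xpehh_window_scan(genoA: GenotypeMatrix, genoB: GenotypeMatrix,
                      variants: VariantTable, windows: list[Window],
                      **kwargs) -> pd.DataFrame:
    """Convenience: per-site XP-EHH then per-window averaging."""
    res = xpehh_scan(genoA.require_haplotypes(), genoB.require_haplotypes(),
                     variants, **kwargs)
    return window_mean_xpehh(res, variants, windows)
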