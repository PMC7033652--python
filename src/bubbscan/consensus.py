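"""Empirical-threshold significance and the multi-method candidate caller.

Each scan statistic is converted to rank-based empirical P-values within the
scanned genome (P(w) = fraction of defined windows with a value at least as
extreme, ties counted inclusively).  Windows with P strictly below the
threshold (default 0.005, i.e. the top 0.5%) are significant; overlapping
significant windows are merged per method, and a merged union region is a
candidate iff at least ``min_methods`` distinct methods contribute a
significant window overlapping it.  Book-ended intervals (touching ends) do
not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants_io import GeneModel

DEFAULT_THRESHOLD = 0.005


@dataclass
class MethodScan:
    """One statistic's window table with ranks and empirical P-values."""

    method: str
    table: pd.DataFrame  # chrom, start, end, n_snps, value [, rank, pvalue]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"scan table missing columns: {sorted(missing)}")


@dataclass
class CandidateRegion:
    """A merged candidate interval with its supporting methods and genes."""

    chrom: str
    start: int
    end: int
    methods: frozenset[str]
    genes: list[str] = field(default_factory=list)


def empirical_pvalues(scan: MethodScan, tail: str = "upper") -> MethodScan:
    """Attach rank-based empirical P-values over the defined windows.

    Upper tail: P(w) = #{defined windows with value >= value(w)} / N_defined;
    the lower tail mirrors this.  Undefined (NaN) windows carry no P.
    """
    values = scan.table["value"].to_numpy(dtype=float)
    defined = ~np.isnan(values)
    if not np.any(defined):
        raise ValueError(f"{scan.method}: no defined window values")
    v = values[defined]
    order = np.sort(v)
    n = v.size
    pvals = np.full(values.size, np.nan)
    ranks = np.full(values.size, np.nan)
    if tail == "upper":
        count = n - np.searchsorted(order, values[defined], side="left")
    elif tail == "lower":
        count = np.searchsorted(order, values[defined], side="right")
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    pvals[defined] = count / n
    ranks[defined] = count
    out = scan.table.copy()
    out["rank"] = ranks
    out["pvalue"] = pvals
    return MethodScan(scan.method, out)


def significant_windows(scan: MethodScan,
                        threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Windows with empirical P strictly below the threshold."""
    if "pvalue" not in scan.table.columns:
        raise ValueError("run empirical_pvalues first")
    return scan.table[scan.table["pvalue"] < threshold]


def merge_significant(windows: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Merge overlapping (>= 1 bp) intervals per chromosome.

    Book-ended windows (end == next start) are kept separate.
    """
    merged: list[tuple[str, int, int]] = []
    if len(windows) == 0:
        return merged
    df = windows.sort_values(["chrom", "start", "end"])
    cur = None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (chrom, cur[1], max(cur[2], end))
        else:
            if cur is not None:
                merged.append(cur)
            cur = (chrom, int(start), int(end))
    merged.append(cur)
    return merged


def candidate_regions(scans: list[MethodScan], threshold: float = DEFAULT_THRESHOLD,
                      min_methods: int = 2, tail: str = "upper") -> list[CandidateRegion]:
    """Regions where >= min_methods methods are simultaneously significant.

    All methods' merged significant intervals are unioned and re-merged; a
    union region is kept iff at least ``min_methods`` distinct methods have a
    significant window overlapping it (overlap with the union region, not
    pairwise mutual overlap).
    """
    if len(scans) < 2:
        raise ValueError("consensus needs at least 2 method scans")
    per_method: dict[str, list[tuple[str, int, int]]] = {}
    for scan in scans:
        if "pvalue" not in scan.table.columns:
            scan = empirical_pvalues(scan, tail=tail)
        sig = significant_windows(scan, threshold)
        per_method[scan.method] = merge_significant(sig)
    pooled = [iv for ivs in per_method.values() for iv in ivs]
    if not pooled:
        return []
    union = merge_significant(pd.DataFrame(pooled, columns=["chrom", "start", "end"]))
    regions = []
    for chrom, start, end in union:
        support = frozenset(
            m for m, ivs in per_method.items()
            if any(c == chrom and s < end and start < e for c, s, e in ivs)
        )
        if len(support) >= min_methods:
            regions.append(CandidateRegion(chrom, start, end, support))
    return regions


def genes_in_regions(regions: list[CandidateRegion],
                     genes: list[GeneModel]) -> tuple[list[CandidateRegion], int]:
    """Annotate regions with genes overlapping by >= 1 bp; count distinct ids.

    Half-open intervals: a gene merely touching a region end is not counted.
    """
    annotated = []
    seen: set[str] = set()
    for r in regions:
        hits = [g.gene_id for g in genes
                if g.chrom == r.chrom and g.start < r.end and r.start < g.end]
        seen.update(hits)
        annotated.append(CandidateRegion(r.chrom, r.start, r.end, r.methods, hits))
    return annotated, len(seen)


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "methods": ",".join(sorted(r.methods)),
        "n_methods": len(r.methods),
        "genes": ",".join(r.genes),
    } for r in regions])
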