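"""End-to-end composite scan: four statistics -> empirical P -> consensus.

The object population is the one screened for sweeps; the reference
population provides the contrast.  F_ST, the pi ln-ratio and the window-mean
XP-EHH run on the sliding 50-kb/20-kb grid; XP-CLR runs on its own
non-overlapping 50-kb tiling.  Each method is thresholded at the top 0.5%
(empirical P < 0.005) and regions supported by at least two methods are the
candidates.
"""

from __future__ import annotations

import pandas as pd

from .consensus import CandidateRegion, MethodScan, candidate_regions, empirical_pvalues
from .hapstats import xpehh_window_scan
from .variants_io import GenotypeMatrix, VariantTable, make_windows
from .winstats import fst_scan, ln_ratio_scan
from .xpclr import xpclr_scan


def sweep_scan_pipeline(geno_ref: GenotypeMatrix, geno_obj: GenotypeMatrix,
                        variants: VariantTable, contig_lengths: dict[str, int],
                        window_size: int = 50_000, window_step: int = 20_000,
                        threshold: float = 0.005, min_methods: int = 2,
                        methods: tuple[str, ...] = ("fst", "ln_ratio", "xpehh", "xpclr"),
                        recomb_rate: float = 1e-8,
                        ) -> tuple[list[CandidateRegion], dict[str, pd.DataFrame]]:
    """Run the selected scan statistics and call consensus candidate regions.

    Returns (regions, per-method window tables with empirical P attached).
    """
    windows = make_windows(contig_lengths, size=window_size, step=window_step)
    scans: list[MethodScan] = []
    if "fst" in methods:
        scans.append(MethodScan("fst", fst_scan(geno_ref, geno_obj, variants, windows)))
    if "ln_ratio" in methods:
        scans.append(MethodScan("ln_ratio",
                                ln_ratio_scan(geno_ref, geno_obj, variants, windows)))
    if "xpehh" in methods:
        scans.append(MethodScan("xpehh",
                                xpehh_window_scan(geno_obj, geno_ref, variants, windows)))
    if "xpclr" in methods:
        scans.append(MethodScan("xpclr",
                                xpclr_scan(geno_ref, geno_obj, variants, contig_lengths,
                                           window_size=window_size,
                                           recomb_rate=recomb_rate)))
    scans = [empirical_pvalues(s, tail="upper") for s in scans]
    regions = candidate_regions(scans, threshold=threshold, min_methods=min_methods)
    return regions, {s.method: s.table for s in scans}
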