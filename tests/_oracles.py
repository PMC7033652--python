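"""Independent brute-force oracles shared across test modules."""

import numpy as np
import pandas as pd

from bubbscan.consensus import MethodScan


def wc_reference(counts1, counts2):
    """Scalar Weir & Cockerham (1984) components from genotype counts.

    Independent transcription of the estimator: counts are (hom-ref, het,
    hom-alt) per population; returns (a, b, c) or None for unusable sites.
    """
    r = 2
    ns, ps, hs = [], [], []
    for n00, n01, n11 in (counts1, counts2):
        n = n00 + n01 + n11
        if n < 1:
            return None
        ns.append(n)
        ps.append((n01 + 2 * n11) / (2 * n))
        hs.append(n01 / n)
    nbar = sum(ns) / r
    if nbar <= 1:
        return None
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    if pbar in (0.0, 1.0):
        return None
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def consensus_fuzz_case(rng):
    """Random multi-method window set + the expected candidate regions from
    a brute-force oracle (exhaustive tie counting, fixed-point pairwise
    interval merging, direct overlap support checks)."""
    n_methods = rng.integers(2, 5)
    n_windows = rng.integers(1, 12)
    size = int(rng.integers(2, 6))
    threshold = float(rng.choice([0.005, 0.1, 0.3, 0.6]))
    scans = []
    sig_windows = {}
    for k in range(n_methods):
        starts = np.sort(rng.choice(30, size=n_windows, replace=False))
        values = rng.integers(0, 5, size=n_windows).astype(float)
        scans.append(MethodScan(f"m{k}", pd.DataFrame({
            "chrom": "1", "start": starts, "end": starts + size,
            "n_snps": 1, "value": values})))
        pv = np.array([np.mean(values >= v) for v in values])
        sig_windows[f"m{k}"] = [(int(s), int(s) + size)
                                for s, p in zip(starts, pv) if p < threshold]
    pool = [iv for ivs in sig_windows.values() for iv in ivs]
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                (s1, e1), (s2, e2) = pool[i], pool[j]
                if s1 < e2 and s2 < e1:
                    pool[i] = (min(s1, s2), max(e1, e2))
                    pool.pop(j)
                    changed = True
                    break
            if changed:
                break
    expected = []
    for s, e in sorted(set(pool)):
        support = {m for m, ivs in sig_windows.items()
                   if any(ws < e and s < we for ws, we in ivs)}
        if len(support) >= 2:
            expected.append((s, e, frozenset(support)))
    return scans, threshold, expected
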