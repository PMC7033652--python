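"""Synthetic two-population panels with known truth.

The generators emulate the statistical structure the scan assumes rather than
running a full coalescent: drift-differentiated allele frequencies
(Balding-Nichols), hard sweeps built by copying a single core haplotype with
recombinational escape, two-clade Y-chromosome haplotypes with missingness,
and MSMC-format coalescence-rate tracks with a known split time.  Every
generator is deterministic under a fixed seed and returns a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import MISSING, GenotypeMatrix, VariantTable


@dataclass
class SimConfig:
    """Parameters of the two-population simulators.

    F is the Balding-Nichols drift parameter (plays the role of the
    between-type divergence of the panel); sweep_freq is the frequency of the
    swept core haplotype in the object population.  sweep_gens controls the
    recombinational escape scale of the sweep (breakpoints fall at
    Exponential(mean 1/(recomb_rate*sweep_gens)) bp from sweep_pos).
    """

    n_snps: int = 2500
    n1: int = 50
    n2: int = 50
    F: float = 0.1
    anc_beta: tuple[float, float] = (0.8, 0.8)
    region_len: int = 5_000_000
    recomb_rate: float = 1e-8
    mut_rate: float = 1e-3
    sweep_pos: int | None = None
    sweep_freq: float = 0.0
    sweep_gens: float = 200.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 diploids per population")
        if not (0 <= self.F < 1):
            raise ValueError("F must lie in [0,1)")
        for name in ("recomb_rate", "mut_rate", "missing_rate", "sweep_freq"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0,1]")
        if self.missing_rate >= 1:
            raise ValueError("missing_rate must be < 1")
        if any(b <= 0 for b in self.anc_beta):
            raise ValueError("anc_beta shapes must be positive")
        if self.n_snps < 1 or self.region_len < 1:
            raise ValueError("n_snps and region_len must be positive")
        if self.sweep_pos is not None and not (0 <= self.sweep_pos < self.region_len):
            raise ValueError("sweep_pos outside region")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    anc_freq: np.ndarray | None = None
    pop_freqs: tuple[np.ndarray, np.ndarray] | None = None
    sweep_interval: tuple[int, int] | None = None
    clades: np.ndarray | None = None


def _positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Distinct sorted 1-based positions across the region."""
    pos0 = rng.choice(cfg.region_len, size=cfg.n_snps, replace=False)
    pos0.sort()
    return pos0 + 1


def _variant_table(cfg: SimConfig, pos: np.ndarray) -> VariantTable:
    n = pos.size
    return VariantTable(np.array(["1"] * n, dtype=object), pos,
                        np.array(["A"] * n, dtype=object),
                        np.array(["C"] * n, dtype=object))


def _bn_freqs(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = rng.beta(cfg.anc_beta[0], cfg.anc_beta[1], size=cfg.n_snps)
    if cfg.F == 0:
        return p, p.copy(), p.copy()
    scale = (1 - cfg.F) / cfg.F
    p1 = rng.beta(p * scale, (1 - p) * scale)
    p2 = rng.beta(p * scale, (1 - p) * scale)
    return p, p1, p2


def _apply_missing(dos: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        dos = dos.copy()
        dos[rng.random(dos.shape) < rate] = MISSING
    return dos


def simulate_balding_nichols(cfg: SimConfig) -> tuple[VariantTable, GenotypeMatrix, GenotypeMatrix, SimTruth]:
    """Neutral drift-only panel under the Balding-Nichols model.

    Each SNP draws an ancestral frequency p ~ Beta(anc_beta), then each
    population independently draws p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
    (p_k = p exactly when F = 0) and genotypes are Binomial(2, p_k).
    """
    if cfg.sweep_pos is not None:
        raise ValueError("neutral generator takes no sweep; use simulate_sweep_region")
    rng = np.random.default_rng(cfg.seed)
    pos = _positions(cfg, rng)
    p, p1, p2 = _bn_freqs(cfg, rng)
    d1 = rng.binomial(2, p1, size=(cfg.n1, cfg.n_snps)).astype(np.int8)
    d2 = rng.binomial(2, p2, size=(cfg.n2, cfg.n_snps)).astype(np.int8)
    d1 = _apply_missing(d1, cfg.missing_rate, rng)
    d2 = _apply_missing(d2, cfg.missing_rate, rng)
    g1 = GenotypeMatrix(d1, [f"p1_{i}" for i in range(cfg.n1)])
    g2 = GenotypeMatrix(d2, [f"p2_{i}" for i in range(cfg.n2)])
    truth = SimTruth(anc_freq=p, pop_freqs=(p1, p2))
    return _variant_table(cfg, pos), g1, g2, truth


def _copy_haplotypes(panel: np.ndarray, n_hap: int, pos0: np.ndarray,
                     recomb_rate: float, mut_rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Build haplotypes by mutation-recombination copying from a panel.

    Each output haplotype copies a panel template site by site; at each
    inter-SNP gap it switches to a fresh template with probability
    1 - exp(-recomb_rate * gap) (single-crossover copying per tract), and each
    copied allele flips with probability mut_rate.
    """
    n_panel, n_snps = panel.shape
    tmpl = rng.integers(n_panel, size=n_hap)
    out = np.empty((n_hap, n_snps), dtype=np.int8)
    out[:, 0] = panel[tmpl, 0]
    gaps = np.diff(pos0)
    switch_p = 1.0 - np.exp(-recomb_rate * gaps)
    switch = rng.random((n_hap, n_snps - 1)) < switch_p[None, :]
    new_tmpl = rng.integers(n_panel, size=(n_hap, n_snps - 1))
    for j in range(1, n_snps):
        sw = switch[:, j - 1]
        tmpl = np.where(sw, new_tmpl[:, j - 1], tmpl)
        out[:, j] = panel[tmpl, j]
    flips = rng.random(out.shape) < mut_rate
    out[flips] = 1 - out[flips]
    return out


def simulate_sweep_region(cfg: SimConfig) -> tuple[VariantTable, GenotypeMatrix, GenotypeMatrix, SimTruth]:
    """Two-population phased haplotypes with an optional hard sweep in pop 2.

    Background haplotypes in both populations are built by
    mutation-recombination copying from Balding-Nichols founder panels.  In
    the object population (pop 2) a fraction ``sweep_freq`` of haplotypes copy
    one fixed core haplotype around ``sweep_pos``; each carrier escapes the
    core beyond breakpoints drawn at exponentially distributed bp distances
    (mean 1/(recomb_rate*sweep_gens)) left and right of the sweep site.  The
    truth interval is the region where at least half the carriers still carry
    the core (median breakpoints); with no carriers it is empty.
    """
    if cfg.sweep_pos is None:
        raise ValueError("sweep generator requires sweep_pos; use cfg.sweep_pos")
    if cfg.sweep_freq == 1.0 and min(cfg.n1, cfg.n2) < 2:
        raise ValueError("sweep_freq=1 needs at least 2 samples")
    rng = np.random.default_rng(cfg.seed)
    pos = _positions(cfg, rng)
    pos0 = pos - 1
    _, p1, p2 = _bn_freqs(cfg, rng)
    panel1 = (rng.random((max(2 * cfg.n1, 40), cfg.n_snps)) < p1).astype(np.int8)
    panel2 = (rng.random((max(2 * cfg.n2, 40), cfg.n_snps)) < p2).astype(np.int8)
    hap1 = _copy_haplotypes(panel1, 2 * cfg.n1, pos0, cfg.recomb_rate, cfg.mut_rate, rng)
    hap2 = _copy_haplotypes(panel2, 2 * cfg.n2, pos0, cfg.recomb_rate, cfg.mut_rate, rng)

    sweep_interval = None
    n_carriers = int(round(cfg.sweep_freq * 2 * cfg.n2))
    if n_carriers > 0:
        core = panel2[0]
        carriers = rng.choice(2 * cfg.n2, size=n_carriers, replace=False)
        scale = 1.0 / (cfg.recomb_rate * cfg.sweep_gens)
        left = cfg.sweep_pos - rng.exponential(scale, size=n_carriers)
        right = cfg.sweep_pos + rng.exponential(scale, size=n_carriers)
        for h, lo, hi in zip(carriers, left, right):
            mask = (pos0 >= lo) & (pos0 <= hi)
            hap2[h, mask] = core[mask]
        lo_med = int(max(0, np.median(left)))
        hi_med = int(min(cfg.region_len, np.median(right)))
        sweep_interval = (lo_med, max(hi_med, lo_med + 1))

    def as_geno(hap: np.ndarray, prefix: str) -> GenotypeMatrix:
        dos = (hap[0::2] + hap[1::2]).astype(np.int8)
        return GenotypeMatrix(dos, [f"{prefix}_{i}" for i in range(hap.shape[0] // 2)],
                              haplotypes=hap)

    truth = SimTruth(pop_freqs=(p1, p2), sweep_interval=sweep_interval)
    return _variant_table(cfg, pos), as_geno(hap1, "ref"), as_geno(hap2, "obj"), truth


def simulate_y_matrix(n_males: int, clade_sizes: tuple[int, ...],
                      n_private_snps: int, missing_rate: float = 0.0,
                      seed: int = 0) -> tuple[np.ndarray, SimTruth]:
    """Male haploid {0,1,missing} matrix with clade-private derived alleles.

    Each clade carries ``n_private_snps`` private derived alleles; all other
    entries are ancestral.  Missingness is applied independently per
    site x sample.  Returns (males x sites matrix, truth with clade labels).
    """
    if sum(clade_sizes) != n_males:
        raise ValueError("clade sizes must sum to n_males")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    n_sites = n_private_snps * len(clade_sizes)
    calls = np.zeros((n_males, n_sites), dtype=np.int8)
    labels = np.empty(n_males, dtype=object)
    row = 0
    for k, size in enumerate(clade_sizes):
        cols = slice(k * n_private_snps, (k + 1) * n_private_snps)
        calls[row:row + size, cols] = 1
        labels[row:row + size] = f"clade{k + 1}"
        row += size
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return calls, SimTruth(clades=labels)


def simulate_msmc_track(split_time_scaled: float = 4e-4, n_segments: int = 20,
                        lam_within: float = 1000.0, seed: int = 0,
                        noise: float = 0.0) -> tuple[pd.DataFrame, float]:
    """MSMC-style 3-lambda track whose rCCR falls through 0.5 at a known time.

    Segment boundaries are log-spaced in scaled time; the cross-coalescence
    rate follows a logistic decline centred on ``split_time_scaled`` so the
    0.5 crossing of 2*lam01/(lam00+lam11) sits at the split (up to segment
    discretisation).  Returns (track, true scaled split time).
    """
    rng = np.random.default_rng(seed)
    bounds = np.concatenate([[0.0], np.geomspace(split_time_scaled / 30,
                                                 split_time_scaled * 30, n_segments)])
    left, right = bounds[:-1], bounds[1:]
    mid = np.where(left > 0, np.sqrt(np.maximum(left, 1e-12) * right), right / 2)
    rccr = 1.0 / (1.0 + (mid / split_time_scaled) ** 3)
    if noise > 0:
        rccr = np.clip(rccr * (1 + noise * rng.standard_normal(rccr.size)), 0, 1.2)
    lam00 = np.full(mid.size, lam_within)
    lam11 = np.full(mid.size, lam_within)
    lam01 = rccr * (lam00 + lam11) / 2
    track = pd.DataFrame({
        "time_index": np.arange(mid.size),
        "left_time_boundary": left,
        "right_time_boundary": right,
        "lambda_00": lam00,
        "lambda_01": lam01,
        "lambda_11": lam11,
    })
    return track, split_time_scaled


def write_sim_vcf(variants: VariantTable, genos: list[GenotypeMatrix], path: str) -> None:
    """Write a VCF 4.2 with GT; phased "|" when all matrices carry haplotypes."""
    samples: list[str] = []
    for g in genos:
        samples.extend(g.samples)
    phased = all(g.haplotypes is not None for g in genos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(variants.chrom):
            last = variants.pos[variants.chrom == chrom].max() if variants.n_sites else 1
            fh.write(f"##contig=<ID={chrom},length={int(last) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(variants.n_sites):
            cols = [str(variants.chrom[j]), str(int(variants.pos[j])), ".",
                    str(variants.ref[j]), str(variants.alt[j]), ".", "PASS", ".", "GT"]
            for g in genos:
                if phased:
                    hap = g.haplotypes
                    for i in range(g.n_samples):
                        cols.append(f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}")
                else:
                    for d in g.dosages[:, j]:
                        if d == MISSING:
                            cols.append("./.")
                        else:
                            cols.append(["0/0", "0/1", "1/1"][d])
            fh.write("\t".join(cols) + "\n")


def write_truth_bed(truth: SimTruth, path: str, chrom: str = "1") -> None:
    with open(path, "w") as fh:
        if truth.sweep_interval is not None:
            lo, hi = truth.sweep_interval
            fh.write(f"{chrom}\t{lo}\t{hi}\tsweep\n")


def write_msmc_track(track: pd.DataFrame, path: str) -> None:
    track.to_csv(path, sep="\t", index=False)
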