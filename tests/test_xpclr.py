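"""Composite likelihood ratio: limits, quadrature accuracy, LD weighting and
sweep response on simulations."""

import numpy as np
import pytest
from scipy import stats

from bubbscan.simulate import SimConfig, simulate_balding_nichols, simulate_sweep_region
from bubbscan.variants_io import GenotypeMatrix
from bubbscan.xpclr import (XpclrModel, escape_probability, estimate_omega,
                            neutral_loglik, snp_weights, sweep_loglik, xpclr_scan)


class TestOmega:
    def test_identical_frequencies_floor(self):
        p = np.linspace(0.1, 0.9, 50)
        assert estimate_omega(p, p, 1000, 1000) == pytest.approx(1e-4)

    def test_no_polymorphic_sites_error(self):
        with pytest.raises(ValueError):
            estimate_omega(np.zeros(5), np.zeros(5), 10, 10)

    def test_replicate_concentration(self):
        """omega-hat is reproducible across seeds (Monte-Carlo oracle)."""
        vals = []
        for seed in range(15):
            cfg = SimConfig(n_snps=1500, F=0.1, n1=50, n2=50,
                            region_len=1_500_000, seed=seed)
            _, g1, g2, t = simulate_balding_nichols(cfg)
            r1, a1 = g1.allele_counts()
            r2, a2 = g2.allele_counts()
            vals.append(estimate_omega(a1 / (r1 + a1), a2 / (r2 + a2), 50, 50))
        vals = np.array(vals)
        assert vals.std() / vals.mean() < 0.2


class TestNeutralLoglik:
    def test_quadrature_matches_dense_grid(self):
        """64-node Gauss-Legendre within 1e-6 of a brute-force Riemann
        integral on a 200k-point grid (plus identical edge masses)."""
        for alt2, n2, p1, omega in [(3, 10, 0.3, 0.05), (18, 10, 0.9, 0.02),
                                    (0, 15, 0.2, 0.1), (30, 15, 0.5, 0.01)]:
            grid = np.linspace(1e-9, 1 - 1e-9, 200_000)
            sigma = np.sqrt(omega * p1 * (1 - p1))
            dens = stats.norm.pdf(grid, p1, sigma)
            pmf = stats.binom.pmf(alt2, 2 * n2, grid)
            brute = np.trapezoid(dens * pmf, grid)
            brute += stats.norm.cdf(0, p1, sigma) * (alt2 == 0)
            brute += stats.norm.sf(1, p1, sigma) * (alt2 == 2 * n2)
            assert neutral_loglik(alt2, n2, p1, omega) == pytest.approx(
                np.log(brute), abs=1e-6)

    def test_allele_relabeling_symmetry(self):
        n2 = 12
        for alt2, p1 in [(3, 0.2), (20, 0.7)]:
            assert neutral_loglik(alt2, n2, p1, 0.05) == pytest.approx(
                neutral_loglik(2 * n2 - alt2, n2, 1 - p1, 0.05), abs=1e-10)

    def test_maximised_when_frequencies_agree(self):
        """At tiny omega the likelihood of an observed count is maximised by
        the matching reference frequency (numeric scan oracle)."""
        n2, alt2 = 20, 16  # observed frequency 0.4
        p_grid = np.linspace(0.05, 0.95, 19)
        lls = [neutral_loglik(alt2, n2, p, 1e-4) for p in p_grid]
        assert p_grid[int(np.argmax(lls))] == pytest.approx(0.4, abs=0.051)


class TestSweepLoglik:
    def test_smallest_s_recovers_neutral(self):
        for alt2, p1 in [(4, 0.3), (0, 0.6), (24, 0.5)]:
            neutral = neutral_loglik(alt2, 12, p1, 0.05)
            sweep = sweep_loglik(alt2, 12, p1, 0.05, s=1e-8, r_dist=1e-4)
            assert sweep == pytest.approx(neutral, abs=1e-8)

    def test_infinite_distance_recovers_neutral(self):
        neutral = neutral_loglik(5, 12, 0.4, 0.05)
        sweep = sweep_loglik(5, 12, 0.4, 0.05, s=0.05, r_dist=1e9)
        assert sweep == pytest.approx(neutral, abs=1e-10)

    def test_escape_probability_monotone_in_s(self):
        r = 1e-3
        s_grid = np.geomspace(1e-5, 1e-1, 20)
        esc = np.array([escape_probability(r, s) for s in s_grid])
        assert np.all(np.diff(esc) <= 0)          # saturates at 1 for tiny s
        unsat = esc < 1.0
        assert np.all(np.diff(esc[unsat]) < 0)    # strictly decreasing once off 1

    def test_fixation_favoured_under_strong_sweep(self):
        """A nearly fixed object count is more likely under a strong nearby
        sweep than under drift alone."""
        alt2, n2, p1 = 24, 12, 0.5
        assert sweep_loglik(alt2, n2, p1, 0.02, s=0.05, r_dist=1e-5) > \
            neutral_loglik(alt2, n2, p1, 0.02)


class TestSnpWeights:
    def test_three_duplicates_share_weight(self, rng):
        col = rng.integers(0, 3, size=30)
        dos = np.stack([col, col, col], axis=1)
        assert np.allclose(snp_weights(dos), 1 / 3)

    def test_independent_snps_full_weight(self, rng):
        dos = rng.integers(0, 3, size=(200, 5))
        # shuffle columns independently to break any chance correlation
        for j in range(5):
            rng.shuffle(dos[:, j])
        w = snp_weights(dos, r2_threshold=0.95)
        assert np.allclose(w, 1.0)

    def test_chained_correlation_greedy_grouping(self):
        """A~B and B~C but A!~C: B joins A's group (leader comparison), C
        starts a new group -> weights (1/2, 1/2, 1), matching a brute-force
        walk of the greedy rule."""
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0] * 3)
        b = a.copy()
        c = a.copy()
        c[:6] = [2, 2, 1, 1, 0, 0]  # decorrelate from a, keep some link to b
        b[0] = 1  # slight perturbation keeps r2(a,b) >= .95 but r2(a,c) < .95
        dos = np.stack([a, b, c], axis=1)
        r2_ab = np.corrcoef(a, b)[0, 1] ** 2
        r2_ac = np.corrcoef(a, c)[0, 1] ** 2
        assert r2_ab >= 0.95 and r2_ac < 0.95
        w = snp_weights(dos, r2_threshold=0.95)
        assert list(w) == [0.5, 0.5, 1.0]


class TestScan:
    def test_object_equals_reference_floor(self):
        cfg = SimConfig(n_snps=500, F=0.1, n1=30, n2=30,
                        region_len=500_000, seed=2)
        v, g1, _, _ = simulate_balding_nichols(cfg)
        g2 = GenotypeMatrix(g1.dosages.copy(), [f"c{i}" for i in range(30)])
        out = xpclr_scan(g1, g2, v, {"1": 500_000},
                         model=XpclrModel(omega=0.05))
        assert np.all(out["value"].to_numpy() == 0.0)

    def test_allele_relabeling_invariance(self):
        cfg = SimConfig(n_snps=300, F=0.1, n1=25, n2=25,
                        region_len=300_000, seed=3)
        v, g1, g2, _ = simulate_balding_nichols(cfg)
        out = xpclr_scan(g1, g2, v, {"1": 300_000}, model=XpclrModel(omega=0.05))
        flip = lambda g: GenotypeMatrix(
            np.where(g.dosages >= 0, 2 - g.dosages, -1).astype(np.int8), g.samples)
        out_flipped = xpclr_scan(flip(g1), flip(g2), v, {"1": 300_000},
                                 model=XpclrModel(omega=0.05))
        assert np.allclose(out["value"], out_flipped["value"], atol=1e-6)

    def test_neutral_genome_median_near_zero(self):
        cfg = SimConfig(n_snps=1000, F=0.1, n1=40, n2=40,
                        region_len=1_000_000, seed=4)
        v, g1, g2, _ = simulate_balding_nichols(cfg)
        out = xpclr_scan(g1, g2, v, {"1": 1_000_000})
        assert np.nanmedian(out["value"]) < 2.0

    def test_sweep_window_ranks_high(self):
        """The truth-overlapping window carries a top CLR on sweep data."""
        cfg = SimConfig(n_snps=600, F=0.05, n1=30, n2=30, region_len=1_000_000,
                        sweep_pos=500_000, sweep_freq=0.9, seed=6)
        v, ref, obj, truth = simulate_sweep_region(cfg)
        out = xpclr_scan(ref, obj, v, {"1": 1_000_000})
        lo, hi = truth.sweep_interval
        overlap = (out["start"] < hi) & (lo < out["end"])
        assert out.loc[overlap, "value"].max() >= \
            np.nanquantile(out["value"], 0.9)

    def test_empty_window_flagged(self):
        cfg = SimConfig(n_snps=100, F=0.1, n1=20, n2=20,
                        region_len=100_000, seed=7)
        v, g1, g2, _ = simulate_balding_nichols(cfg)
        out = xpclr_scan(g1, g2, v, {"1": 200_000}, model=XpclrModel(omega=0.05))
        assert np.isnan(out["value"].iloc[-1])  # second 50-kb tile is empty
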