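# Methods

## Scope and data model

The package implements a two-population selective-sweep scan (four window
statistics with a rank-based consensus caller), a Y-chromosome haplogroup
workflow and MSMC output rescaling.  Upstream steps — read alignment,
variant calling, phasing, and the MSMC coalescent HMM itself — are out of
scope; their outputs (phased biallelic SNP VCFs, MSMC final tables) are the
package's inputs.

All coordinates are 0-based half-open internally; VCF (1-based) and GFF3
(1-based closed) are converted on import.  Missing dosages are excluded
site-wise from allele counts, never imputed.  Windows are 50 kb sliding
every 20 kb (both CLI-settable); the composite-likelihood scan uses a
non-overlapping 50-kb tiling.  A contig shorter than the window size yields
a single full-contig window; otherwise every start below the contig length
is kept and the final window truncated, so contig ends remain scannable.

## Window statistics

**π.** Per site 2·c_ref·c_alt/(n(n−1)) over called alleles (undefined below
two called alleles); the window value is the site sum divided by the window
span in bp.  Normalising by span rather than by callable-site count follows
the common sliding-window convention of the standard VCF tooling; windows
without usable SNPs are reported undefined and excluded from ranking.

**π ln-ratio.** ln(π_other/π_target); windows where either π is 0 are
flagged undefined rather than yielding ±∞.  The statistic is antisymmetric
under swapping populations.

**F_ST.** Weir & Cockerham (1984) components a, b, c for r = 2 populations
from per-population sample sizes, allele frequencies and *observed*
heterozygosities (no Hardy–Weinberg assumption).  Sites monomorphic across
both populations or with an uncalled population are skipped; the window
value is the weighted ratio Σa/Σ(a+b+c).  Negative window values are
retained — clipping would distort empirical ranks.

**XP-EHH.** EHH at extension x is the probability two random haplotypes are
identical at every SNP from the core through x (the all-haplotype variant,
EHH(0) = 1 on the empty interval).  The curve stops below 0.05, at an
inter-SNP gap over 200 kb, or 1 Mb from the core — the cited tool's default
settings, since nothing more specific is available.  iES is the two-sided
trapezoidal integral in bp, including the segment that reaches the first
below-cutoff point.  The per-site score ln(iES_obj/iES_ref) is standardised
in a single genome-wide bin (the tool's cross-population default; no
frequency binning) and averaged per window.  The upper tail of the signed
window mean, with the object population in the numerator, feeds the
threshold: positive scores mean longer haplotypes — a sweep — in the object
population.  Missing haplotype alleles are rejected; real data must be
phased upstream, and the simulators emit complete haplotypes.  A compiled
(numba) kernel walks all cores in one pass; it is asserted equal to the
pure-Python reference implementation in the test suite.

**XP-CLR.** The drift null models the object-population frequency as
q ~ Normal(p₁, ω·p₁(1−p₁)) truncated to [0,1] with the truncated mass as
point masses at the edges; ω is estimated genome-wide by method of moments
(mean of (p₁−p₂)²/(p̄(1−p̄)) over polymorphic sites minus the binomial
sampling term 1/(2n₁)+1/(2n₂), floored at 10⁻⁴).  The sweep alternative is
a per-lineage hitchhiking mixture: with escape probability
c = 1−exp(−r/s) a lineage keeps the drifted frequency; otherwise it carries
the swept core's allele, giving post-sweep frequency c·q + (1−c)·X with
X ~ Bernoulli(q).  Both s → 0⁺ and r → ∞ recover the neutral likelihood
exactly.  This compact mixture deliberately stands in for the full
hitchhiking model: it is validated by its limits and by simulation
behaviour (monotone response to sweep frequency, truth-window localisation),
not by numeric identity with any particular executable.

Numerics: 64-node Gauss–Legendre quadrature mapped onto p₁ ± 10σ clipped to
[0,1], so narrow drift densities at small ω stay resolved; verified against
a 200,000-point brute-force integral to 10⁻⁶.  The s grid is log-spaced over
[10⁻⁵, 10⁻¹] Morgans plus a near-zero sentinel.  r is bp distance to the
window centre times a uniform recombination rate (default 1 cM/Mb,
CLI-settable).  SNPs whose dosage r² with a group leader reaches 0.95 share
weight 1/k (greedy left-to-right grouping, deterministic for chained
correlations); windows over 600 SNPs are thinned uniformly by position.
The window statistic 2·max_s Σ wᵢ(ℓ_sweep−ℓ_neutral) is floored at 0, with
sub-10⁻⁹ gains treated as 0 so identical populations score exactly 0.

## Consensus

Empirical P-values are genome-wide ranks: P(w) = #{defined windows with
value ≥ value(w)}/N, ties counted inclusively; significance is strict
P < 0.005, matching the top-0.5% usage, with both the threshold and the
strictness switchable.  Overlap always means ≥ 1 bp — book-ended intervals
never merge, in per-method merging, in the cross-method union, and in gene
annotation.  A union region is a candidate when ≥ 2 distinct methods have a
significant window overlapping it (overlap with the union region, not
pairwise mutual overlap — the simplest reading of co-location).  Mixed
window grids (sliding vs non-overlapping) need no resampling because
overlap is computed on bp intervals.

## Uniparental workflow

Site filters: any female call, any heterozygous male call, or a male call
rate below 95% removes the site.  The three filters commute and attrition is
reported per filter.  The source description "genotyping rate < 5%" is read
as removing sites with call rate below 95%; the literal reading would retain
nearly everything and is taken as a typo, exposed as `max_missing` (default
0.05).  Distances are mismatch fractions over sites called in both
haplotypes.  Neighbour-joining is the canonical Studier–Keppler update with
ties broken to the lowest index pair; negative branch lengths are clamped
to 0 with the length moved to the sibling edge, preserving path lengths
(exactness on additive metrics is asserted, and the tree cross-checked
against an independent NJ implementation).  Haplogroups are the two sides
of the longest internal edge (or the outgroup edge when an outgroup is
given); a tree with no positive-length internal edge triggers a warning and
falls back to the first bipartition.  Only k = 2 is implemented — matching
the two-haplogroup structure the workflow targets; named mtDNA lineage
nomenclature is out of scope.  Frequencies are per-group percentages
rounded to 2 decimals, summing to 100 within rounding.

## Demography

years = (scaled time/μ)·g anchored at each segment's left boundary (the
usual step-plot convention; both boundaries are exported);
N_e = 1/(2λ₀₀μ); rCCR = 2λ₀₁/(λ₀₀+λ₁₁), not clipped at 1 since estimates
can slightly exceed it.  Crossings of a level (default 0.5) are linearly
interpolated scanning from recent to ancient; all crossings are returned
with the most recent first, and an exact hit at a segment anchor returns
that anchor.  Defaults μ = 1.26×10⁻⁸ per generation and g = 6 years are the
buffalo-panel constants.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical *structure* the analyses assume,
not a full coalescent process:

- **Balding–Nichols panels** — ancestral frequencies p ~ Beta(0.8, 0.8),
  population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) independently per
  population (exactly p at F = 0, avoiding the degenerate Beta), genotypes
  Binomial(2, p_k).  F plays the role of the between-type divergence; the
  genome-wide weighted F_ST of such panels is centred on F.
- **Sweep regions** — background haplotypes copy founder panels site by
  site, switching templates at each inter-SNP gap with probability
  1−exp(−r·gap) (single-crossover copying, the simplest mechanism that
  yields distance-decaying haplotype sharing) and flipping each copied
  allele with probability 10⁻³.  A fraction `sweep_freq` of object-population
  haplotypes copy one fixed core haplotype around `sweep_pos`, escaping
  beyond breakpoints drawn Exponential with mean 1/(r·sweep_gens) bp on each
  side (default sweep_gens = 200, giving a ~500-kb mean tract at 1 cM/Mb —
  a strong recent sweep at desk scale).  The recorded truth interval spans
  the median carrier breakpoints: the region where at least half the
  carriers still carry the core.
- **Y matrices** — clades defined by private derived alleles, independent
  site×sample missingness matching the downstream per-site call-rate filter
  semantics.
- **MSMC tracks** — log-spaced segment boundaries with a logistic rCCR
  decline centred on a known scaled split time.

Default panel sizes (n = 50 + 50 diploids, 2,500 SNPs over 5 Mb, F = 0.05
between populations for sweep scans) keep a full 4-method replicate under a
few seconds while leaving every statistic well inside its asymptotic
regime.  What passing tests show: the estimators are arithmetically correct,
the scan localises strong hard sweeps, and the consensus logic is exact.
What they do not show: behaviour under demographic confounding, soft or old
sweeps, unphased or sparse data, ascertainment bias, or genome-scale
multiple-testing burdens — none of which the generators emulate.

## Known limitations

- XP-CLR scores are not numerically comparable to the original executable's
  (documented stand-in model, uniform recombination map).
- The empirical-threshold consensus always flags the top 0.5% per method,
  including on wholly neutral genomes; the neutral false-call rate is
  reported by the acceptance script, not asserted away.
- Haplogroup assignment assumes a two-clade structure; star-like trees fall
  back with a warning.
- The sweep simulator draws a single core haplotype (hard sweeps only) and
  the MSMC track generator emulates output shape, not coalescent inference.
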