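# Methods

This note documents the models and numerical choices behind canyonpool:
what the synthetic cohorts emulate, how the estimators and the sweep HMM
are defined, and where the design was genuinely open.

## The study design being emulated

The package targets pool-seq contrasts of two locally adapted populations
("slopes"): per slope, 9 isofemale lines, each pooled to n = 40 haploid
genomes and sequenced to a mean depth of 73×. Sites are biallelic SNPs
with per-line (ref, alt) read depths; allele frequencies are estimated
from read counts, never from genotype calls. Default filters keep sites
with genotyping quality > 30 and depth in [10, 250], and drop SNPs within
10 bp of an indel (boundary inclusive — a SNP exactly 10 bp away is
removed). All internal coordinates are 1-based inclusive; BED conversion
happens only at the I/O boundary.

## Synthetic cohort generator

### Frequency model

Population alternate-allele frequencies are drawn from the neutral site
frequency spectrum ξ_i ∝ 1/i over derived-allele counts i = 1..n−1 of
n = 40 haploids. Interslope structure is a *site-level mixture*: with
probability `migration_mix` both slopes share one draw; otherwise each
slope receives an independent draw whose allele orientation is flipped
(p → 1−p) with probability ½. Two properties motivated this exact form:

- the marginal per-slope spectrum stays neutral, so genome-wide Tajima's
  D is centred on zero away from sweeps (an arithmetic frequency blend of
  a shared and a private draw would concentrate mass at intermediate
  frequencies and push D systematically positive);
- the orientation flip preserves the folded spectrum — heterozygosity,
  segregating-site counts and D are all invariant under p → 1−p — while
  letting the slopes sit at opposite frequency extremes. Without it the
  mean per-SNP F_ST is capped near 0.15 because independent draws from a
  rare-skewed spectrum are usually rare *on the same side*; with it the
  attainable range extends to ≈ 0.29, comfortably bracketing the target
  regime of 0.17. Biologically the flip reflects that which allele is
  "reference" is arbitrary with respect to each deme's private history.

Observation is two-stage: the pool frequency is Binomial(40, p)/40 per
line, coverage is Poisson(73), and alternate reads are
Binomial(coverage, pool frequency). All sites appear in every line's
table (joint genotyping), including sites where a line's pool carries no
alternate allele.

### Divergence calibration

`calibrate_divergence(target, config)` bisects `migration_mix` until the
genome-wide mean per-SNP F_ST (averaged over ≥ 3 seeds, simulated *with*
the config's planted sweeps, since the empirical genome-wide average
includes swept regions) is within 0.02 of the target. Targets below the
pure-sampling floor (≈ 0.01 at full sharing) or above the independence
ceiling raise `CalibrationError`. With the defaults, a target of 0.17
calibrates to `migration_mix` ≈ 0.5 and reproduces windowed means of
0.172 across seeds.

### Planted sweeps

A sweep interval carries a `diversity_reduction` factor r ∈ (0, 1] and a
slope ("NFS", "SFS" or "both"). Inside the interval, for each affected
slope: a fraction 1−r of sites is fixed for the reference allele, and the
rest have frequencies pushed toward the *nearer* extreme, q → q^γ for
q < ½ and the mirror transform otherwise, with γ = 1/r. r = 1 is an exact
no-op. Pushing toward the nearer extreme (rather than a random side) is
deliberate: a power-law tilt cannot carry a rare allele to near-fixation
without crossing intermediate frequencies, where it would *raise*
heterozygosity; the nearer-extreme form reproduces the post-hitchhiking
phenotype — reduced site density, rare-skewed survivors, strongly negative
Tajima's D and depressed heterozygosity in the swept slope — which is both
what real swept windows look like and what the HMM's Selection state
models. With r = 0.3 the default cohorts show genome-wide D ≈ −0.5 on the
swept slope versus ≈ 0 on the other.

### TEs, second species

Each TE family plants `n_sites` insertion sites; a site is "shared" with
probability `sharing_prob`, in which case carriers are drawn on both
slopes (each line with probability 0.7, at least one per slope), otherwise
on one random slope only. Default families span the observed range from a
nearly fixed, old family (88% shared) to recently invading families (6–7%
shared).

The second species copies `shared_species_fraction` (default 1%) of the
first species' sites with the same allele pair and jittered frequencies;
its major allele matches the first species' with probability
`species_cooccurrence` (0.85), and 30% of shared sites copy the interslope
frequency difference (`species_convergent_fraction`). Private sites of the
second species get independent neutral frequencies whose orientation is
solved at generation time so that major-allele coincidence expected under
independence equals `species_background_coincidence` (0.34) — the planted
fold enrichment is therefore 0.85/0.34 ≈ 2.5, recovered as ≈ 2.3–2.4
after read sampling erodes sites near the 0.5 boundary.

### What the generator does not emulate

No linkage (sites are independent draws, so windowed statistics have less
variance than coalescent data and there are no hitchhiking shoulders); no
recombination maps, indels, or read-level artifacts; equal detection
sensitivity across lines for TEs (the depth-normalization of real TE
calling is emulated, not implemented); a single chromosome arm. Passing
tests therefore demonstrate correctness of the estimators and the
inference machinery under the stated sampling model, not robustness to
demographic confounding or linked selection in real data.

## Estimators

Statistics use the classical formulas on pooled frequency estimates with
the small-sample factor n/(n−1), n = 40 pool haplotypes. Slope-level
frequencies are depth-weighted across lines (unweighted per-line means
available by flag). Windows are non-overlapping 5-kb tiles by default
(100-bp reanalysis via `--window`); genes use their own sites, never
window means. Missing values propagate as NaN — an empty window or a gene
with fewer than 3 segregating sites reports missing D rather than zero.
The exact pooled-sampling bias corrections of dedicated pool-seq tools are
intentionally out of scope; with 40-haplotype pools at 73× the residual
bias in D is ≈ −0.015, an order of magnitude below the window-to-window
spread.

## Sweep HMM

States are Neutral, Intermediate and Selection with spectra over
i = 1..n−1: ξ_i ∝ 1/i (Neutral); ξ_i ∝ (1/i)·exp(−γ·min(i, n−i)/n)
renormalized (Selection, default tilt γ = 8, concentrating mass at both
extremes as after hitchhiking); and their normalized elementwise geometric
mean (Intermediate). Emission log-probabilities integrate binomial read
sampling over the spectrum, log Σ ξ_i·B(alt | depth, i/n), computed in log
space. Transitions switch with probability k = 1e-10 per site to each
other state; the initial distribution is uniform. Sites outside coverage
[5, 250] are excluded before decoding.

Viterbi segmentation is authoritative for regions (runs of ≥ 3 Selection
sites, reported as [first, last] site position, never merged across
interruptions); forward–backward posteriors are attached as diagnostics.
The decoding kernels are numba-compiled; they are checked against
exhaustive path enumeration in the test suite. The per-line Watterson θ is
estimated and recorded with each line's parameters but does not enter the
emissions, which are conditioned on segregating sites. Under the default
cohorts the per-site log-likelihood drift is ≈ −0.4 nats under neutrality
and ≈ +0.4 inside sweeps, so with |log k| ≈ 23 a state switch needs ~60
consistent sites and false regions are vanishingly rare while 100-kb
planted sweeps (≈ 4,000 sites) are recovered essentially exactly.

Alleles are treated as unfolded with the alternate allele as derived;
synthetic truth is generated accordingly. Application to real data would
require outgroup polarization.

## Scores, transspecies, TEs

A gene is "in" a line's sweep region on ≥ 1 bp overlap of the gene span
(full containment available by flag — overlap matches how multi-gene
regions are counted). Score = N − S; positive is NFS-prevalent; the
prevalence threshold (default 6) applies symmetrically to both signs. Gene
correlations are Spearman, mid-ranked ties, two-sided p; the primary
covariates are the interslope differences ΔD = D_NFS − D_SFS and
Δhet (computed in the same orientation as the score), with mean
heterozygosity also reported.

"Major allele" means frequency > 0.5; exact ties are excluded. The
co-occurrence background is the set of sites polymorphic in exactly one
species, with the expectation m_A·m_B + (1−m_A)(1−m_B) from the two
background alt-major fractions. The slope-divergent filter requires
nonsynonymous effect, opposite major alleles between slopes within each
species, and the same allele major on the same slope across species;
Fisher tests use haploid-equivalent counts (frequency × 2 × lines,
rounded) because raw read counts would overstate the effective sample.

Coding effects substitute the alternate allele into the reference codon
(strand-aware, standard nuclear code) of the first transcript containing
the site. TE site identity across lines is exact-position by default
(`merge_window` available for jittered real calls); two-sided Fisher
p-values follow the "sum of probabilities ≤ observed" convention, with
the family-vs-background sharing table constructed as
[[s, t−s], [S−s, (T−t)−(S−s)]].

## Problem sizes

The shipped tests and the reproduction script use 1 Mb single-arm cohorts
(~43,000 SNPs, 18 line tables) for end-to-end checks, 150–500 kb for
module-level checks, and 3–5 seeds for simulation-based measurements;
these sizes give stable statistics (SEs an order of magnitude below the
asserted margins) while keeping the full suite fast.
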