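# Methods

This note documents the models, estimators, numerical conventions and
design choices behind each module, and what the synthetic-data tests do
and do not demonstrate about real data.

## Data model and missing data

All genetic analyses operate on an equal-length alignment over
`{A,C,G,T,N,-}`. A single *missing policy* is applied consistently:
`complete-deletion` (default) removes every column containing `N` or `-`
in any record before an analysis; `strict` compares characters as given.
Complete deletion mirrors the default of the classical population-genetics
packages this pipeline is modelled on; the choice matters whenever
missingness is non-random, and both policies are exposed everywhere.
Sequences are stored upper-case; `U` is mapped to `T` with a warning.
Haplotype tables are ordered by decreasing count with ties broken by first
occurrence, so all downstream outputs are deterministic.

## Diversity statistics

* Gene diversity h = n/(n−1)·(1 − Σpᵢ²), variance by Nei's (1987)
  formula V(h) = 2/(n(n−1))·{2(n−2)(Σpᵢ³ − (Σpᵢ²)²) + Σpᵢ² − (Σpᵢ²)²}.
* θπ is the mean pairwise difference over all n(n−1)/2 pairs; its
  reported s.d. is the total coalescent variance
  V = b₁θ + b₂θ² evaluated at θ̂ = θπ, with b₁ = (n+1)/(3(n−1)) and
  b₂ = 2(n²+n+3)/(9n(n−1)). π = θπ/L.
* Watterson's θs = S/a₁ with a₁ = Σ_{i<n} 1/i. Its s.d. uses the S-based
  plug-in V = (a₁²S + a₂S²)/(a₁²(a₁²+a₂)); this (rather than
  V = θ/a₁ + a₂θ²/a₁²) is the convention that reproduces the standard
  software's printed uncertainties. Note that published tables computed
  with n-dependent subtleties can disagree at the third decimal; for
  S=11, n=40 the harmonic-sum value is 2.586, and the implementation
  always returns the harmonic-sum value.

## Neutrality tests

Tajima's D uses the 1989 constants (a₁,a₂,b₁,b₂,c₁,c₂,e₁,e₂) and is
undefined at S = 0 (guarded error). Fu's Fs computes
S′ = Pr(K ≥ k_obs | θ = θπ, n) from the Ewens sampling formula with
unsigned Stirling numbers of the first kind evaluated in log space by the
recurrence |s(n+1,k)| = |s(n,k−1)| + n·|s(n,k)|, which stays finite far
beyond n = 55; the tail and its complement are both accumulated in log
space so the log-odds Fs = ln(S′/(1−S′)) is accurate when S′ is near 0 or
1 (the exact limits return ∓∞ as flagged values).

P-values come from neutral constant-size coalescent simulations with θ
fixed at the observed θπ (the cited packages' convention, rather than
conditioning on S), 1000 replicates by default, seeded. The null
simulations use the infinite-sites model while observed statistics come
from finite observed alignments — a deliberate, documented asymmetry: the
null is the model under which the tests were derived, and at mtDNA-scale
divergence the finite-sites correction is negligible relative to
Monte-Carlo error. D's p-value is one-tailed on the side of the observed
sign; Fs's p-value is the fraction of simulated Fs ≤ observed.

## Mismatch distributions and expansion dating

The sudden-expansion model treats a pair of sequences as coalescing in a
population of scaled size θ₁ for the last τ units of mutational time and
θ₀ before that; with F̂_j(θ) = θʲ/(1+θ)^{j+1} the geometric equilibrium,

    F_j(τ,θ₀,θ₁) = F̂_j(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{i≤j} τ^{j−i}/(j−i)! [F̂_i(θ₀) − F̂_i(θ₁)]

(verified in the tests against direct numerical integration of the
piecewise-exponential coalescence density). Fitting minimises the SSD
between observed relative frequencies and F_j over the observed support:
a deterministic coarse grid (τ linear up to ~2×mean, θ₀ and θ₁
log-spaced, θ₁ capped at 99999.0 to reproduce the boundary behaviour of
the standard software) followed by Nelder–Mead refinement with fixed
start order (SSD tolerance 1e−9, parameter tolerance 1e−4), so point
estimates are reproducible bit-for-bit. The parametric bootstrap
re-simulates histograms from the fitted model (multinomial over pairwise
differences — an approximation that treats pairs as independent, standard
for this test), re-fits, and yields p(SSD), p(raggedness) and 2.5/97.5
percentile CIs. Harpending's raggedness is the sum of squared successive
differences of the relative frequencies padded with zero beyond both
ends.

Expansion dating uses t = τ/(2µ) with µ = L × rate × generation-time per
sequence per generation. The default rate is the combined mitochondrial
1.3%/bp/Myr (per-gene values 1.38%/1.22% available), generation time 1
year; printed values truncate fractional years, and both truncated and
exact values are emitted.

## AMOVA ΦST and isolation by distance

ΦST comes from one-level AMOVA on the matrix of pairwise sequence
differences — the quantity most field studies print as "F_ST from
pairwise differences". Because a difference count is a squared Euclidean
distance, SS(total) = Σ_{i<j} d_ij/n and SS(within) = Σ_pops Σ_{i<j∈pop}
d_ij/n_pop enter directly; variance components use the unequal-size
coefficient n′ = (n − Σn_p²/n)/(P−1), and ΦST = σ²_a/(σ²_a+σ²_w).
Negative components are retained (flagged), not truncated, matching
published tables that print small negative values. Permutation tests
shuffle individuals among populations, include the observed arrangement
in numerator and denominator, and default to 10,000 permutations
(seeded). Pairwise tables apply the same machinery per population pair
with no multiple-testing correction.

Geographic distances are haversine on a 6371-km sphere;
population-to-population distance is the mean over cross-population
sample pairs. The Mantel statistic is the Pearson correlation of
lower-triangle entries, untransformed (no log), one-tailed (r_perm ≥
r_obs) under simultaneous row/column permutation; for ≤ 5 populations all
permutations are enumerated exactly, which the permutation path is tested
against. Latitudinal bands for India close the printed gaps downward:
[10,20), [20,29), [29,35].

## Median-joining networks

The network algorithm iterates (1) the ε-relaxed minimum-spanning network
under Hamming distance (an edge of weight w joins nodes not already
connected by admitted edges of weight < w − ε; ε defaults to 0, giving
the union of all MSTs), (2) addition of novel quasi-median vectors — the
per-site majority consensus of each triple (u,v,w) in which v and w are
both MSN neighbours of u; sites where all three states differ branch into
one vector per state, capped at 2 such sites per triple to bound the
combinatorics — until no new vectors arise, then prunes median vectors of
degree ≤ 2 and recomputes until stable, so surviving medians are genuine
branch points. All ties break on node index (observed haplotypes in input
order, medians in creation order). Characters are equally weighted.

## Trees

Jukes–Cantor d = −(3/4)·ln(1 − 4p/3) with a saturation guard at p ≥ 3/4
naming the offending pair. Neighbor joining follows the standard
Q-criterion with deterministic tie-breaks (lexicographically smallest
label pair); negative branch lengths are clamped to zero with the deficit
moved to the adjacent branch and counted. Bootstrap supports use site
resampling under the same missing policy (replicates resample the
retained columns; saturated replicates are skipped and counted) and are
written as internal node labels in Newick. Trees for populations of
mostly identical sequences are built on one representative per haplotype.
Likelihood-based tree search and model selection are out of scope; the
distance pathway carries the monophyly conclusions this package targets.

## BIOCLIM envelope model

Per variable, the envelope is [quantile(q), quantile(1−q)] of the
training presence values with q = 0.025 by default (linear-interpolation
quantiles; the choice moves bounds by less than one inter-point gap).
Scoring uses the training percentile P with midpoint rank convention:
s = 1 − 2|P − 0.5| inside the envelope, 0 outside; cell suitability is
the minimum over variables. The historical GUI's exact scoring is not
documented anywhere, so this standard tent-percentile-min formulation is
fixed here, and the raw in/out-of-envelope Boolean grid is emitted
alongside for comparison. Variable pre-filtering removes, greedily from
the most-correlated pair down, the lower-priority member of any pair with
|r| > 0.7 (priority = caller-supplied order, since keeping climatic
extremes is a judgment call the model cannot make). Pseudo-absences are
drawn uniformly without replacement from valid cells of the full analysis
extent. AUC is the Mann–Whitney statistic with ties counted half
(invariant to monotone transforms of the scores); the replicate protocol
draws ten independent 75/25 presence splits and fresh pseudo-absence sets
of size equal to the presence count. Maximum-entropy modelling is out of
scope; externally produced suitability grids can be read for side-by-side
comparison only.

## Coalescent simulator

Genealogies come from msprime with haploid samples (mtDNA). θ is
per-sequence: θ = 2N_e·u with u the per-sequence per-generation rate; the
simulator fixes the reference size so that the requested θ values are
reproduced exactly in expectation (E[θπ] = θ, verified to 3 SE in tests).
The sudden-expansion demography places the size change at t = τ/(2u)
generations, so fitted τ values are directly comparable to the simulated
truth; θ₀ = 0 is represented by a 1000-fold size reduction. The
two-island demography uses scaled migration M = 2Nm with a merger T·2N
generations back. Mutations are finite-sites HKY (default transition bias
κ = 4, in the range typical of mitochondrial protein-coding data) over L
discrete sites with a random ancestral background, so multiple hits,
multi-state sites and transition excess occur as in real data;
infinite-sites Jukes–Cantor mode exists for oracle tests. Everything is
bit-reproducible from (parameters, seed).

What the synthetic tests show: that every estimator recovers the truth of
the model it assumes, at realistic sample sizes (n = 50, L = 601 for the
expansion study; 12+12 for the island study; 140 presences for the niche
study). What they do not show: robustness to recombination (absent in
mtDNA, so irrelevant here), selection, sequencing error, alignment error,
or spatially biased presence sampling — all of which affect real data and
none of which the generators emulate.

## Pipeline sizes and determinism

Default statistical settings are 1000 neutrality simulations (as in the
standard workflow), 10,000 AMOVA/Mantel permutations, 1000 bootstrap
replicates. The bundled synthetic runs and the calibration study use
smaller replicate counts (stated in each driver) chosen to keep a full
desk run in minutes while leaving Monte-Carlo error well inside the
asserted tolerances; the type-I calibration scores 2000 fresh replicates
against critical values estimated from 2000 null replicates drawn from
the same constant-size family, rather than nesting a full simulated
p-value inside every replicate. All randomness flows from explicit seeds
(no wall-clock defaults); reruns with the same config are byte-identical,
which the test suite asserts on the report files.

## Known limitations

* Fu's Fs p-values are simulated, not exact; for very large |Fs| the
  simulated p saturates at 0 or 1.
* The mismatch bootstrap treats the n(n−1)/2 pairwise differences as
  independent draws; true pairs share a genealogy, so bootstrap CIs are
  mildly anti-conservative (the same approximation as the standard tool).
* The median-joining quasi-median cap (2 fully ambiguous sites per
  triple) can omit medians in extremely homoplastic data.
* The BIOCLIM scoring reproduces the standard formulation, not the exact
  pixel values of any particular historical implementation.
* AMOVA here is one-level (populations within total); hierarchical
  group/population designs are not implemented.
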