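# Methods

`mtpopgen` implements the standard mitochondrial phylogeography workflow for
haploid, non-recombining sequence data sampled from multiple localities:
molecular diversity, population structure (pairwise Φ_ST and hierarchical
AMOVA with permutation significance), median-joining haplotype networks with
inverse-origin site weighting, mismatch-distribution demographic inference
with neutrality tests and expansion dating, model-based haplogroup
clustering, and a structured-coalescent generator that produces data with
known truth for validation. This note records the models, the conventions
and defaults, and the places where a genuine design choice had to be made.

## Data model and filtering

All statistics operate on an equal-length alignment after **complete
deletion** of gap/N columns: any column containing `-` or `N` in any
retained sequence is removed, so every pairwise comparison uses the same
analysed length *L*. A pairwise-deletion mode exists for the p-distance
(`drop_gap_sites(..., mode="none")` plus the distance module's per-pair
masking) but is not the default, because haplotype identity and the
mismatch histogram require one consistent site set. Haplotype identity is
exact string equality after filtering. Localities sampled below `min_n = 5`
individuals are excluded from population-level statistics (diversity tables
still report them, flagged).

## Diversity

* S — count of columns with ≥ 2 observed nucleotides.
* h — Nei's unbiased haplotype diversity, h = n/(n−1)·(1 − Σ pᵢ²).
* d — mean number of pairwise differences; π = d/L exactly, and both are
  reported together so the identity is auditable.
* Localities with n < 2 yield flagged-undefined (NaN) rows rather than
  zeros, so regional averages are never silently deflated. The pooled row
  is a pooled-sample statistic, not an average of per-locality values (an
  averaging mode is a one-liner on the emitted table).

## Distances

Tamura–Nei (1993) with empirical base frequencies estimated from the pooled
alignment. With a gamma shape α the correction term −ln(x) is replaced by
α(x^(−1/α) − 1) (term substitution). The best-fitting model and α for any
particular dataset are inputs (`SubstitutionModelConfig`); the default is
TN93 with α = 0.5, recorded in the run manifest. Saturated pairs (a
non-positive logarithm argument) raise a flagged error listing the pairs,
with an explicit fall-back to the p-distance available — saturation is
never silently clamped. The gamma-corrected distance is non-increasing in α
and always ≥ the p-distance; both properties are tested.

## AMOVA, Φ statistics, permutation tests

The hierarchical analysis of molecular variance follows the Excoffier
sum-of-squares formulation with unbalanced-design coefficients. One
convention deserves emphasis: the **molecular distance already is the
squared distance**. In the per-site 0/1 embedding of sequence data the
squared Euclidean distance between two haplotypes equals their number of
differing sites, so the distance matrix entries (pairwise differences, or
their TN93 correction) enter the sums of squares directly. Squaring them
again would inflate between-population terms nonlinearly and makes the
Φ_ST estimator inconsistent with coalescent expectations (we verified this
against the island-model closed form). `amova(..., square_distances=True)`
exists for genuinely Euclidean inputs.

Variance components use the standard unbalanced coefficients; negative
components are reported as computed, flagged, and kept in denominators
(truncating them to zero would silently bias the indices). Fixation
indices: Φ_CT = σ²ₐ/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c),
Φ_ST = (σ²ₐ+σ²_b)/σ²_T, which satisfy
(1−Φ_ST) = (1−Φ_CT)(1−Φ_SC) identically.

Permutation nulls match each index: whole populations among groups for
Φ_CT; individuals among populations within their group for Φ_SC;
individuals among populations for Φ_ST. p = (b+1)/(B+1) with B = 10,000 by
default, so p is never zero. Pairwise Φ_ST matrices get
Benjamini–Hochberg FDR adjustment across pairs (statsmodels backend; the
step-up definition is enforced by a brute-force oracle in the tests).

When Φ_ST is summarised **across simulation replicates** the package's
tests use a ratio of sums of variance components (the Weir–Cockerham
multi-locus convention) rather than a mean of per-replicate ratios: the
ratio estimator is Jensen-biased downward (≈0.03 at 2Nm = 0.25 with 20
samples per deme), while the ratio of sums is consistent — it reproduces
F_ST = 1/(1+2Nm) within Monte-Carlo error at 2Nm ∈ {0.25, 1, 4}.

## Median-joining networks

Construction follows the Bandelt scheme: the ε-relaxed minimum spanning
network under weighted Hamming distance (an edge (u,v) is kept iff
d(u,v) ≤ δ(u,v) + ε, δ the minimax path value), quasi-median generation
from node triplets (sitewise majority; sites where all three states differ
branch over the three states), greedy insertion of the candidate that most
reduces the total network cost (minimum-spanning-tree weight over the node
set; ties broken lexicographically by sequence, so the build is
deterministic), and pruning of median vectors of degree ≤ 2, which by the
triangle inequality can never reduce the cost. For small inputs all node
triplets are considered, which on every fixture with ≤ 6 haplotypes and
≤ 8 sites reproduces the exact Steiner minimal tree found by a
Dreyfus–Wagner search over the full quasi-median universe (test oracle).

Site weighting: after a first pass with uniform weights, each site's number
of origins r (distinct network edges on which it mutates) is counted and
the site is reweighted to 90 for r ≤ 1 and 90/r otherwise; the network is
rebuilt under the new weights (two passes by default). The origin count
uses the complete pass-1 network including median vectors. ε defaults
to 0. The iteration count and the origin-counting substrate are
conventions — they follow common practice with weighted network builds, and
data without homoplasy are a fixed point of the procedure (tested).

## Mismatch distributions and demographic inference

The sudden-expansion model: a haploid population at equilibrium with scaled
size θ₀ jumps to θ₁ at time τ (in units of 1/(2u) generations, u the locus
mutation rate) before sampling. The expected probability of i pairwise
differences combines the geometric equilibrium form
F̂(i,θ) = θ^i/(1+θ)^(i+1) with a Poisson kernel in τ; the implementation is
validated against the τ = 0 (geometric) and θ₀ = 0, θ₁ → ∞ (Poisson)
limits and an independent transcription of the closed form.

Fitting minimises the SSD between observed relative frequencies and model
probabilities over the support up to the largest observed difference count
(zero-padding the histogram therefore cannot change the SSD). The search is
multi-start Nelder–Mead in a sigmoid-bounded space, τ ∈ [0, 4·max_diff],
θ ∈ [0, 10·d̂], with method-of-moments warm starts; θ₁ is free by default
and can be pinned (`pin_theta1`) for the reduced variant. The SSD
goodness-of-fit p-value and the 95% τ CI come from a parametric bootstrap:
B coalescent samples of matched size are simulated under the fitted model,
each refitted (warm-started at the parent parameters), with
p = (b+1)/(B+1) for b simulated SSDs ≥ observed and a percentile CI for τ.
B = 10,000 by default, reduced in tests. Percentile (not basic) intervals
are used — they are the convention of this literature and calibrated better
in our coverage experiments. Note that the closed-form expectation is
itself an approximation to the coalescent: with modest θ₁ the fitted τ is
biased upward, so calibration experiments plant a pronounced expansion
(θ₀ ≪ θ₁, θ₁ ≫ τ), which is the regime the model is meant for.

Neutrality tests: Tajima's D with the canonical a₁…e₂ constants, and Fu's
Fs = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ = d̂) from the Ewens sampling
distribution. The Stirling numbers of the first kind are accumulated in
log space, which keeps n ≥ 320 stable in double precision (verified
against exact rational arithmetic for n ≤ 8 to 1e-12). Significance for
both tests comes from simulating a neutral constant-size coalescent null at
θ = d̂ (1000 replicates by default, lower-tail p), so the pipeline needs no
lookup tables. S = 0 yields flagged-undefined statistics.

Expansion dating: t = τ/(2u) generations with u = µs; µ is the divergence
rate per site per year times the generation time. Defaults follow the
bivalve mtDNA literature: 0.52% per site per Myr, 2-year generation time,
and the rate is **not** halved by default — `halve_rate=True` switches to
the per-lineage convention and exactly doubles every date; both conventions
are exposed because published applications are ambiguous about which was
used, and τ itself is rarely printed, so the chain cannot be audited from
the outside. CI endpoints transform identically to the point estimate.

## Haplogroup clustering

A deliberately transparent surrogate for linkage-aware Bayesian clustering:
partitions of haplotypes are scored by the marginal likelihood of an
independent-polymorphic-sites Dirichlet-multinomial (symmetric prior
α = 0.25 per nucleotide, haplotypes weighted by their frequency), searched
by randomised greedy reassignment with `runs × replicates` restarts
(10 × 6 by default, mirroring the usual run design) over K = 1..22. K is
selected by the maximum marginal likelihood — the model's own Occam factor
is the only complexity penalty. The module's validated claim is
planted-partition recovery (ARI = 1 on groups separated by ≥ 10 fixed
differences, 20 seeds); membership of any particular published clustering
is *not* claimed, since codon-linkage likelihoods are not reproduced here.

## Synthetic data

The generator wraps msprime: haploid samples (`ploidy=1`) from `demes`
island-model populations, optional instantaneous size change, finite-sites
JC69 or HKY mutations on a random root sequence. Conventions:

* θ = 2Nu per locus, so a single equilibrium deme has E[d] = θ and
  E[S] = θ·a₁ (both verified against 2000-replicate Monte-Carlo means).
* `migration` is the effective scaled rate M defined so that
  F_ST = 1/(1+M) for **any** deme count: the per-lineage emigration rate is
  M(d−1)/(2Nd). For two demes this absorbs the (d−1)/d correction that the
  infinite-island formula ignores.
* `expansion=(τ, θ₀, θ₁)` is in mutational units and round-trips exactly
  with the mismatch module's parameterisation (the size change is placed at
  τ/(2u) generations).
* Finite-sites mutation is used deliberately so homoplasy exists and the
  network reweighting rule has something to do; infinite-sites behaviour is
  approached by raising the sequence length.

What the generator does **not** emulate: recombination, selection,
sequencing error, alignment ambiguity, and sampling heterogeneity beyond
deme sample sizes. Tests passing on synthetic data therefore validate the
estimators under the stated models, not robustness to real-data artefacts.

## Pipeline and reproducibility

`run_full_analysis` derives one child seed per stage from the global seed
by hashing the stage name (SHA-256, reduced below 2³¹), so disabling a
stage never shifts another stage's random stream; two runs from the same
config are byte-identical (tested). Every stage writes plain-text tables in
the conventional layouts plus a JSON manifest (package version, config
echo, stage seeds, dropped individuals/localities). Stage failures are
isolated and recorded; independent stages continue.

## Problem sizes used in the validation suite

Simulation-backed checks run at desk scale, chosen to keep the full suite
in the tens of minutes while leaving Monte-Carlo error well below the
tolerances tested: 2000 replicates for the Watterson/θ and Tajima-null
means, 500 replicates per migration rate for island-model Φ_ST recovery,
and 100 outer replicates with B = 200 bootstrap resamples for τ CI
coverage (n = 50, τ* = 4, θ₀ = 0.5, θ₁ = 50, L = 800). Production runs
should use the defaults (B = 10,000 bootstrap and permutation replicates).

## Known limitations

* The Rogers–Harpending curve is an approximation; τ̂ from SSD fits is
  upward-biased when θ₁ is not ≫ θ₀ (≈18% at θ₁ = 20, ≈8% at θ₁ = 50 in
  our experiments). The bootstrap inherits and therefore largely corrects
  for this in CI coverage, but point estimates should be read accordingly.
* Gamma-corrected TN93 uses term substitution; site-rate integration would
  differ in the third decimal for typical divergences.
* The clustering surrogate ignores linkage between sites; haplogroup
  boundaries on weakly separated data will differ from linkage-aware
  methods.
* No Bayesian skyline inference, no model selection across substitution
  models, and no de novo alignment: aligned input is assumed.
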