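# Methods

This note documents the models, estimators, numerical choices and known
limitations of mitopop. It is the reference for what each reported number
means and for the design decisions that were genuinely open.

## Data model and masking

Input is an aligned set of equal-length haploid sequences with a population
label per record. Bases other than A/C/G/T (N, gaps, other IUPAC codes) are
treated as missing and masked **per site and per pair**: a pairwise
comparison uses only the sites where both sequences are unambiguous, and a
column-level statistic uses only the unambiguous entries of that column.
Whole columns are never deleted, so the coordinate frame (e.g. 683 sites) is
preserved. Sites are numbered 1-based in all tabular output; arrays are
0-based internally. Reading frames are 0-based offsets; the default frame is
"auto", the frame minimising the total number of premature stop codons
across sequences, under the invertebrate mitochondrial code (NCBI table 5)
— the marker is assumed to be a protein-coding mtDNA fragment whose reading
frame is usually unknown for a PCR amplicon.

A *haplotype* is an exact-string equivalence class of sequences. Sequences
containing ambiguous bases therefore merge only with byte-identical records;
no wildcard matching is attempted. This is deliberate: haplotype-collapsing
tools offer several incompatible N-handling modes, and exact matching is the
only deterministic, order-independent choice. Haplotypes are named H1, H2, …
by first appearance in the input, so naming is reproducible given record
order (and the most frequent haplotype need not be H1).

## Diversity

* Haplotype diversity: Nei's unbiased estimator
  h = n(1 − Σpᵢ²)/(n − 1). Undefined for n < 2.
* Nucleotide diversity π: mean over unordered pairs of
  (differences / comparable sites); k̂ is the unnormalised mean difference
  count. Pairs with zero comparable sites are dropped from the π average.
* "Average" diversity across populations is the **unweighted arithmetic
  mean** of per-population values, not the pooled-sample statistic; with
  equal sample sizes per locality this matches how multi-locality studies
  conventionally report a mean.
* Reporting precision in tables: h to 3 decimals, π to 5; full precision is
  kept internally.

## Population structure

Distances are raw pairwise difference counts ("number of differences").
At π ≈ 0.002, model-corrected distances differ from raw counts by far less
than sampling error, so no substitution-model correction is applied.

Two-level AMOVA on squared distances:

    SS_total  = Σ_{i<j} d²ij / N
    SS_within = Σ_p Σ_{i<j∈p} d²ij / n_p
    Vb  = SS_within / (N − P)
    Va  = (SS_among/(P−1) − Vb) / n̄,   n̄ = (N − Σn_p²/N)/(P−1)
    Φ_ST = Va / (Va + Vb)

The permutation null shuffles individuals among populations keeping sample
sizes; the p-value uses the (b+1)/(m+1) estimator so that a permutation test
never reports exactly zero. Default 10,000 permutations. Negative Φ_ST
estimates (sampling noise around zero) are reported as computed, never
truncated. If all pairwise distances are zero, Φ_ST is undefined and
reported as NaN with a warning. Pairwise Φ_ST runs a two-population AMOVA
per pair; both raw and Holm-adjusted p-values are emitted, since no single
multiple-testing convention is universal for these matrices. Between-
population divergence d_xy is the mean per-site difference fraction over all
inter-population pairs (uncorrected, masked) — on the same scale as π.

Neighbor joining uses the Studier–Keppler formulation; ties in the Q
criterion are broken by scan order over the current node list, making the
topology deterministic given label order. A negative branch length is
clamped to zero with the excess transferred to its sister branch, preserving
the joined pair's distance. Bootstrap support resamples alignment columns
with replacement and counts, for each split of the full-data tree, the
percentage of replicate trees containing it (default 1000 replicates).
By default the tree is built on the haplotype set rather than on all
sequences (duplicate sequences carry no topological information).

## Neutrality tests

Tajima's D uses the standard constants a₁…e₂ computed from n;
D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)). S counts variable sites under the masking
rules above. D is undefined at S = 0 (NaN with a warning) and requires
n ≥ 4. Significance comes from conditional coalescent simulation (default
1000 replicates) with θ set to Watterson's S/a₁, not from the beta
approximation: the lower tail is P(D* ≤ D) and the reported two-tailed value
is min(2·tail, 1). This calibrates the test for the expansion direction
(negative D), which is the direction of scientific interest here; strongly
positive D values are not flagged by this construction.

Fu's F_S = ln(S′/(1−S′)), with S′ = P(K ≥ k_obs) under the Ewens sampling
formula at θ estimated by k̂ (the Tajima estimator, per the statistic's
original definition). The Ewens probabilities use unsigned Stirling numbers
of the first kind via the recursion |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)|
carried out entirely in log space (logaddexp), which is stable to n in the
hundreds; rows are cached per n. k_obs = 1 returns +∞ (the tail probability
is 1). The simulation p-value is one-tailed, P(F_S* ≤ F_S), and following
the statistic's original convention significance at the nominal 5% level is
declared at p < 0.02 (`FS_SIGNIFICANCE_LEVEL`).

## Mismatch distributions and dating

The observed mismatch distribution is the normalised histogram of pairwise
difference counts. The sudden-expansion model (equilibrium θ₀, instantaneous
change to θ₁ at mutational time τ = 2ut before present) has class
probabilities

    F_i(τ,θ₀,θ₁) = F̂_i(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤i} [F̂_j(θ₀) − F̂_j(θ₁)] τ^{i−j}/(i−j)!

with F̂_i(θ) = θ^i/(1+θ)^{i+1}. The vector is truncated at the observed
maximum difference class and renormalised. The implementation is verified in
the tests against an independent numerical route (integrating the Poisson
class probabilities against the piecewise-exponential pair-coalescence-time
density).

Fitting minimises SSD = Σ(obs − exp)² over (τ, θ₀, θ₁), via a vectorised
coarse grid (τ up to min(25, 2·mean), θ₀ and θ₁ on log-spread grids) refined
by Nelder–Mead with parameters clipped to τ∈[0,25], θ₀∈[0,50], θ₁∈[θ₀,5000].
Plain SSD over classes 0…d_max is used as the objective; the exact class
weighting used by the common desktop implementation is unpublished, so this
is a documented, reproducible choice. A degenerate single-class observed
vector returns the τ = 0 boundary with a warning. Harpending's raggedness is
Σ(xᵢ − xᵢ₋₁)² over successive classes with an implicit zero appended after
the last class; it is computed on the observed vector, SSD on the fitted one.

Goodness of fit is a parametric bootstrap (default 1000 replicates):
coalescent samples of the same size are simulated under the fitted model
(present θ = θ̂₁, a θ̂₁/θ̂₀-fold size change at scaled time τ̂/θ̂₁), each
replicate refitted, and p = P(stat* ≥ stat_obs). Calibration measured in the
test suite: for data truly generated under an expansion, the SSD p-value
exceeds 0.05 in ≈89% of trials and the raggedness p-value in ≈93% — i.e. the
SSD test is mildly anti-conservative; the calibration test asserts a
threshold with margin for that.

Expansion time uses τ = 2ut with u the per-sequence per-generation mutation
rate: u = rate × L × generation. Rate strings like "3.1%/Myr" parse as
3.1e−8 substitutions/site/year. Because published "% per Myr" rates are
sometimes per-lineage and sometimes pairwise-divergence rates (a factor of
two), both conventions are exposed (`rate_convention="per_lineage"`,
default, or `"pairwise"`); no particular calendar date is hard-coded.

## Haplotype networks

The minimum spanning network is the union of all minimum spanning trees of
the complete Hamming-distance graph: an edge of weight w is kept iff its
endpoints are disconnected in the subgraph of edges lighter than w − ε
(ε = 0 by default, matching the usual tolerance default; larger ε keeps more
alternative connections). Median joining iterates: build the MSN over the
current node set; for every triple with at least two MSN links, add the
quasi-median (per site the majority value; fully discordant sites expand to
all three values, capped at 27 combinations per triple); repeat to a fixed
point; finally prune median vectors greedily (lexicographic scan) whenever
removal leaves the total network length — the weight of a minimum spanning
tree over the remaining nodes — unchanged. Only variable columns enter the
computation, all sites weighted equally; haplotypes with ambiguous bases at
variable sites stay in the network but are excluded from median generation
(with a warning). On exhaustively enumerated small binary instances
(≤ 4 haplotypes) the resulting network length equals the true Steiner
minimum found by brute force; this is asserted in the tests but is not a
general guarantee for larger inputs.

## Coalescent simulator

A backwards-in-time Gillespie simulator for a haploid non-recombining locus,
with haploid scaling θ = 2Nu per sequence and time in units of N
generations: a lineage pair in one deme coalesces at rate 1 and a pair
accumulates differences at rate θ per scaled time unit (so a size change at
scaled time t sits at mutational time τ = θ·t — the same τ as the mismatch
model). Users comparing against diploid-scaled tools (θ = 4Nu) should halve
accordingly. Demographies: constant size; sudden expansion (coalescence rate
× growth_factor before tau_event, looking backwards); finite island model
(per-lineage scaled migration Nm, uniform target deme), optionally combined
with an expansion and optionally merging all demes into the single ancestral
population at the event (the colonisation scenario). Mutations are Poisson
(θ/2 per branch per scaled time) under infinite sites (each mutation a fresh
column; an error suggests finite sites if mutations exceed L) or
finite-sites Jukes–Cantor with uniform site rates — sufficient at COI-scale
divergence (π < 0.005). Identical seeds give bit-identical output.

The study-like generator (`simulate_fujian_like`) emulates a six-locality,
65-per-locality, 683-site design: Nm = 50 (structure negligible), a 50×
expansion at mutational time τ = 1.0, θ = 12, demes merging into one small
ancestral population at the event. These defaults were chosen so that the
simulated data reproduce the qualitative features of real COI datasets of
this kind — typically one dominant haplotype above 40% relative frequency,
per-deme h ≈ 0.4–0.85, per-deme π ≈ 0.0005–0.004, star-like genealogies and
unimodal mismatch distributions. The merged-ancestor choice matters: with
six *separate* ancestral demes 50× smaller, lineages caught in different
demes at the event keep accumulating differences while waiting to migrate
together, which inflates π and breaks the star shape; a single ancestral
source population is both the cleaner biological story for a post-glacial
expansion and the regime the summary statistics assume.

What the simulator does **not** emulate: sequencing error, base-composition
bias (root states are uniform), rate heterogeneity across sites, selection,
and recombination. Passing tests therefore show the statistics behave
correctly under the stated demographic models, not that they are robust to
those real-data complications.

The count-table fixture (`table1_fixture`) reconstructs a published
84-haplotype × 6-locality count matrix exactly: all count-based statistics
(sample sizes, haplotype totals, sharing, haplotype diversity) reproduce the
printed values. Its sequences are synthetic stand-ins — a CTA-repeat
backbone with one G substitution per haplotype within the first 100 columns,
stop-free in frame 0 under the invertebrate mitochondrial code, with the
backbone assigned to the dominant haplotype so the network is a star around
it. Sequence-based statistics (π, base composition, site counts, Tajima's D,
mismatch shapes) computed on this fixture are therefore *not* estimates of
the real data's values.

## Problem sizes and determinism

Simulation-based checks in the test suite and the acceptance script use:
2000 constant-size replicates (n = 30, θ = 5) for the neutral Tajima's D
mean; 400 replicates of a 50× expansion for the directional shift; 500
random-labelling datasets (n = 40, θ = 5) for the Φ_ST null; 200 expansion
datasets (n = 60, θ₁ = 50, τ = 5) for mismatch τ recovery; 60 trials × 99
bootstrap replicates for goodness-of-fit calibration. These sizes put the
Monte-Carlo error comfortably inside each assertion's tolerance while
keeping the default suite fast. All stochastic stages take explicit seeds;
the pipeline derives per-stage seeds by hashing the stage name with the
top-level seed, so adding a stage never perturbs the others.

## Known limitations

* Two-level AMOVA only; no hierarchical (group-of-populations) designs.
* Tajima's D p-value is calibrated for the negative (expansion) direction.
* The median-joining implementation targets datasets of at most a few
  hundred haplotypes; the triple scan is quadratic-to-cubic in nodes.
* The mismatch SSD bootstrap is mildly anti-conservative (see above).
* No recombination, selection, or rate heterogeneity in the simulator; no
  amino-acid-level or codon-position-stratified diversity statistics.
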