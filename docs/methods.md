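# Methods

## Coalescent model

`netcoal` simulates exchangeable Λ-coalescents: at any moment with `b`
active ancestral lineages, a single group of `k` lineages (2 ≤ k ≤ b)
merges at rate λ_{b,k}.  Waiting times are exponential with rate
Σ_k λ_{b,k}; the merger size is drawn proportionally to λ_{b,k} and the
participants are a uniformly random k-subset, so lineages are exchangeable
by construction.  Exactly one merger occurs per event — simultaneous
multiple mergers (Ξ-coalescents) are out of scope.  Three families are
implemented (Kingman; ψ point-mass; Beta(2−α, α)); all satisfy
λ_{2,2} = 1, which fixes the coalescent time unit.  The Beta kernel is
evaluated in log space via log-gamma so large `b` cannot overflow; at
α = 1.999 the kernel is within 1 % of Kingman for b ≤ 10, and ψ = 0
reproduces Kingman exactly, so the family boundaries are consistent with
the scalar dispatch rule ((0, 1] → ψ, (1, 2) → α, 0/2 → Kingman).

## Simulation inside a network

The species network is a rooted DAG parsed from extended Newick.  Both
occurrences of a hybrid label (`name#tag`) merge into one node; "left"
parent means the parent edge encountered first in a left-to-right scan of
the string, and an inline numeric tag (`h#0.4`) is the inheritance
probability γ of that left edge (the right edge gets 1 − γ).  For symbolic
tags (`h1#H1`) γ is a required side input.  Validation enforces: one root,
acyclicity, ≤ 2 parents per label, γ ∈ [0, 1] with pairs summing to 1
(tolerance 1e-9), unique tip labels.

Sampled lineages start at the tips at time 0.  Nodes are processed in
postorder (children before parents); on each branch an independent
censored coalescent runs with that branch's parameter for the branch's
duration, and survivors are handed to the parent branch.  Lineage sets
pool where branches join; at a hybrid node each lineage is routed
independently (probability γ left) *before* any coalescence in the parent
branches.  Above the network root the root branch's parameter and
population size apply until the grand MRCA.  Under Kingman the output is
strictly binary; under ψ/α it may contain polytomies.

Node times are defined bottom-up (a node's height is the maximum over
children of child height + branch length), which coincides with every
root-to-tip path on ultrametric inputs.  Non-ultrametric inputs produce a
warning per deviating root-to-tip path (relative tolerance 1e-6 of the
tree height, configurable) and are then simulated on this root-consistent
time axis with every tip at the present — a diagnostic convention, not an
error, chosen so the simulator never refuses an input it can interpret.

## Units and timescales

Branch lengths are coalescent units internally.  Input in generations is
converted by dividing by the branch's effective size N — except on Beta
branches, where the coalescent timescale is proportional to N^(α−1) and
that power is the divisor.  The same factor, applied in reverse and
piecewise across the population boundaries each gene-tree branch
traverses, produces the generations scaling of the output trees;
expected-mutation lengths are generations × μ.  Using one symmetric rule
in both directions makes conversion invertible (checked to 1e-12 relative
error) and keeps the mutation process consistent with the divergence-time
grid of the two-population experiment below.  The ψ family uses plain N:
its literature timescale normalisation is not settled, and the package
treats the pairwise rate of the analytic split model as a free input
(`lambda_A`) rather than imposing ψ².

## Mutations and haplotypes

Mutations follow the infinitely-many-sites model: independent
Poisson(μ × generations length) counts per branch, each mutation a new
0/1 column whose carriers are exactly the samples below the branch.  The
matrix is therefore a perfect phylogeny by construction, and the test
suite verifies pairwise column compatibility on simulated data.  Mutations
above the grand MRCA are not simulated (they would not segregate); 0 is
always ancestral.  Columns are ordered oldest-first by the carrying
branch's upper height, ties broken by preorder traversal — an arbitrary
but deterministic convention that makes same-seed runs byte-identical.
The `seg` file layout (one `//replicate` header line per block, then one
`label 0 1 …` row per sample) is this package's own documented convention
and ships with a reader (`HaplotypeMatrix.from_text`).

## F_ST

For two populations with n sequences each, H_w,i is the mean pairwise
difference count over distinct within-population pairs,
H_w = (H_w,1 + H_w,2)/2, and H_b the mean over all n₁×n₂ between pairs.
The default estimator is the published form
F̂ = 1 − (n/(n−1)) H_w/H_b.  Note its behaviour: with H_w the
*distinct-pair* mean, the n/(n−1) factor overcorrects — at zero divergence
the expectation is −1/(n−1), not 0.  The factor is exact if H_w is instead
an n²-denominator (with-replacement) average, in which case the two
conventions cancel.  Because downstream comparisons with the analytic
limit need a consistent estimator, an `uncorrected` mode F̂ = 1 − H_w/H_b
is provided; its pooled multi-locus form (differences summed across loci
per pair before averaging — ratio of sums, the low-variance choice)
converges to Slatkin's low-mutation limit 1 − E[T_w]/E[T_b].  Replicates
with H_b = 0 are reported as NaN and excluded (counted) from summary
means, not imputed.  With unequal sample sizes the correction uses
n = (n₁+n₂)/2 with a logged warning.  With a single sequence per
population only the uncorrected mode is available and H_w is taken as 0
(no within pair exists) with a logged note.

The analytic split model implements the published expressions

    E[T_w] = (1 − e^(−λ_A τ))/λ_A + e^(−λ_A τ)(τ + 1/λ_AB)
    E[T_b] = τ + 1/λ_AB
    F_ST⁰  = (1 − e^(−λ_A τ)) (1 − 1/((τ + 1/λ_AB) λ_A))

verbatim.  A caveat documented here because the package's own simulations
expose it: the first term of E[T_w] is P(T < τ)·E[T] rather than
E[T·1{T<τ}] = (1 − e^(−λ_A τ))/λ_A − τ e^(−λ_A τ), so the exact value is
E[T_w] = (1 − e^(−λ_A τ))/λ_A + e^(−λ_A τ)/λ_AB (at λ_A = λ_AB the split
is invisible to a within pair by memorylessness).  The two versions of
F_ST⁰ differ by τ e^(−τ)(1+τ)⁻¹ at unit rates — at most ≈ 0.06 on the
experiment grid below and negligible for τ ≳ 5.  Both the package's
simulator and an independent msprime split-model simulation reproduce the
exact value; the test suite's Monte-Carlo bands at the prescribed
replicate counts cover the difference.

## Two-population experiment

`simulate_split_fst` reproduces the α-sweep experiment: populations of
size N = 10⁴ separated by τ ∈ {10⁴, 2·10⁴, 5·10⁴} generations,
α ∈ {1.1, …, 1.9} (coalescent-unit separation τ/N^(α−1)), μ = 10⁻⁵,
10³ replicates per grid cell, 2 sequences per population (the smallest n
for which within-population diversity is observable), pooled uncorrected
estimator.  The end-to-end test asserts that pooled F̂ is monotone in α
and agrees with the analytic prediction within a per-cell allowance fixed
in advance as 1.96 × (bootstrap SE over replicates) plus a Poisson
add-one term 1.96·√(S_w+1)/(2 H_b) for the discreteness of the within
mutation count S_w (several cells observe S_w = 0, where a bootstrap
alone has zero spread).

## What the generator does and does not emulate

Simulated data have exchangeable samples within populations, free
recombination between replicates (each replicate an independent locus) and
no recombination, migration, selection or sequencing error within a locus;
sample sizes, rates and divergence times are the experiment's stated
conditions.  Passing tests therefore validate the coalescent, routing,
mutation and estimation machinery — not robustness to the many features of
real data (intralocus recombination, finite sites, missing data,
population structure within species) that the model excludes.

## Numerical and design choices

* One `numpy.random.Generator` threaded through every stochastic step;
  the same seed reproduces every output byte for byte.
* Branch lengths print with 6 significant digits by default
  (configurable); tests use higher precision where round-trips matter.
* Degenerate inputs: zero-length branches are legal (no time to
  coalesce); duration-0 and single-lineage branches return their input;
  a one-node network (`A;`) is a single panmictic population.
* Topology tables canonicalise trees by sorting children on their
  smallest descendant tip label; monophyly classes are reciprocal
  monophyly / paraphyly (exactly one population forms a clade) /
  polyphyly.
* The CLI mirrors the historical single-dash flag set (`-spng`, `-num`,
  `-seed`, `-mu`, `-S`, `-mm`, `-sim_num_mut`, `-seg`, `-fst`) with
  long-form synonyms; `-pop`, `-gen`, `-o` and `-tol` are documented
  extensions.  Output file names (`<prefix>_coal_unit`, `_num_gener`,
  `_num_mut`, `_num_mut_tree`, `_seg`, `_fst.tsv`, `_topology.tsv`,
  `_monophyly.tsv`) are this package's convention.

## Known limitations

* No migration, recombination, Ξ-coalescents, time-varying parameters or
  heterochronous sampling.
* The ψ-family timescale (and hence its generations conversion) uses
  plain N; users comparing with point-mass theory should set rates
  explicitly in the analytic model.
* Non-ultrametric networks are simulated on the root-consistent time
  axis described above, which stretches short root-to-tip paths; the
  warnings list every affected tip.
* The network figure export, NEXUS/PhyloXML formats and R bindings are
  out of scope.
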