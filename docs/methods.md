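# Methods

## The ZCNT model

A copy number profile p ∈ {0,…,B}^m records the integer number of copies of
each of m genomic bins in one cell.  A CNT event c_{s,t,b} adds b ∈ {+1,−1}
to every *non-zero* entry in the interval [s,t]; once a locus reaches zero
copies it is frozen.  The zero-agnostic (ZCNT) event drops the freeze: it
adds b to every entry in [s,t], so profiles live in Z^m and intermediate
values may be negative.  Zero-skipping is the biologically correct rule — a
deleted locus cannot be re-amplified — but it couples loci in a way that
makes distances asymmetric and parsimony intractable.  The zero-agnostic
relaxation buys a metric with a closed form, at the price of permitting
biologically impossible events; the package therefore also *measures* how
often fitted ancestral genomes actually exploit that freedom (see
"CNT-violation diagnostics").

### Delta profiles

The delta map sends p to the vector of adjacent differences padded with a
baseline β at both ends of each chromosome:

    Δ(p) = (p₁−β, p₂−p₁, …, p_m−p_{m−1}, β−p_m),   β = 2 (diploid) by default.

Each chromosome segment of Δ(p) sums to zero (the *balancing condition*),
and Δ is a bijection between Z^m and balanced integer vectors (inverse:
cumulative sums).  A ZCNT event on bins [s,t] acts on Δ(p) by adding b at
boundary s and subtracting b at boundary t+1 — two coordinates only.  Hence
ZCNT transformations commute, and the minimum number of events between two
profiles is

    d(p,p′) = ½‖Δ(p) − Δ(p′)‖₁,

a metric (each event moves the L1 difference by at most 2; a greedy pairing
of surplus boundaries achieves the bound).  The difference of two balanced
vectors is balanced and a balanced integer vector has even L1 norm, so d is
always a non-negative integer.

Chromosomes are handled by applying the delta map independently per
chromosome with baseline padding at both chromosome ends; distances and
parsimony objectives sum over chromosomes.  (Only chromosome junctions
distinguish this from concatenating everything into one vector.)

ZCNT is *not* an upper-bound-preserving relaxation of CNT distances: one
zero-skipping CNT event acts on a union of intervals and may need several
ZCNT events to emulate.  Example: (1,0,1) → (2,0,2) is one CNT
amplification but two ZCNT events.  Empirically (exhaustively at m=3,
entries ≤3) d_ZCNT > d_CNT only for pairs whose CNT path bridges interior
zeros; for zero-free profiles d_ZCNT ≤ d_CNT.  The `cnt_zcnt_comparison`
statistics quantify the relative difference |d_CNT/d_ZCNT − 1| (with the
symmetrized CNT distance σ′ = (σ(u,v)+σ(v,u))/2); pairs with d_ZCNT = 0 are
excluded and counted.

### BFS oracles

`bfs_min_events` computes minimum event counts by breadth-first search over
profile space, guarded to toy scale (≤6 bins, entries ≤5, ≤12 events).
ZCNT intermediate values are clamped to [−max_events, B+max_events] — valid
because each event moves an entry by exactly 1.  For CNT, reachability is
exactly zero-set containment (zeros of the source must be zeros of the
target); the box [0, B+max_events] cannot cut an optimal path of length
≤ max_events.  These oracles exist to validate the closed form and to
compute toy-scale CNT distances; CNT distances at realistic scale must be
supplied externally.

## Small parsimony

Given a tree with cells at the leaves, find balanced integer delta labels
for the internal vertices minimizing J = Σ_edges ‖ℓ(u)−ℓ(v)‖₁.  Scores are
reported both as this L1 sum and in event units (J/2, integral for integer
balanced labelings).

**Unbalanced relaxation (exact, O(nm)).**  Dropping the balancing condition
decouples the coordinates; each becomes an L1 small parsimony problem whose
optimum uses only integer labels within the leaf range.  A bottom-up pass
stores, per vertex, the subtree cost as a function of the vertex's label
over that range; a child is absorbed through a min-plus distance transform
(two linear sweeps), which is exact for any vertex degree, so multifurcating
trees are solved as-is rather than resolved.  The top-down pass breaks ties
toward the zero delta at the root and toward the parent's value below it,
keeping ancestral states as close to diploid as optimality allows.  (The
tree-search scorer uses an equivalent interval/Wagner formulation,
vectorized across coordinates, on binary trees.)

**LP relaxation.**  Dropping integrality instead gives a linear program:
per-edge per-coordinate absolute values split into slack variables,
balancing as per-chromosome equality rows, solved with HiGHS.  The reported
score is the fractional optimum; the attached labels stay fractional.

**Exact ILP.**  The same program with integrality on the vertex labels.
Vertex labels are boxed to [min leaf delta − s, max leaf delta + s] with
s = max(2, largest |vertex discrepancy| of the unbalanced solution); after
solving, active bounds trigger a re-solve with a doubled box, so the box is
never binding at the reported optimum.  LP/ILP scores are compared at 1e−6.

**Balancing repair and the factor-2 guarantee.**  The *discrepancy* of a
vertex label is the sum of its delta entries per chromosome (zero iff
balanced).  Repair subtracts each vertex's discrepancy from the final
(right-telomere) boundary coordinate of each chromosome segment —
equivalent to extending events to the chromosome end — leaving leaves
untouched.  Per edge only that coordinate moves, so the cost increase is at
most |disc(u)−disc(v)| ≤ ‖ℓ(u)−ℓ(v)‖₁ per chromosome; the repaired cost is
therefore at most twice the unbalanced cost.  Since any leaf-consistent
labeling costs at least its total |discrepancy| and the unbalanced optimum
lower-bounds the true optimum, unbalanced + repair is a linear-time
2-approximation.  Every solve reports the relaxation ordering
unbalanced ≤ LP ≤ ILP ≤ repaired ≤ 2·unbalanced, which the test suite
checks on simulated batches.  The repair coordinate (right telomere) is our
choice among several valid ones; it preserves all interior breakpoints and
yields the provable per-edge bound.

**Canonical event decomposition.**  For one edge, the delta difference
w = Δ(child) − Δ(parent) is expanded into ±1 unit charges at boundary
positions; positive and negative charges are paired in left-to-right order,
each pair becoming one interval event (amplification when the + charge
precedes the − charge, deletion otherwise).  The number of events equals
the ZCNT distance exactly, and amplifications are scheduled before
deletions so intermediate profiles dip no lower than necessary.  This is
one minimum-length realization among many; violation counts below depend
mildly on it.

**CNT-violation diagnostics.**  For a labeling in copy-number space:
(a) maximal runs of negative entries in ancestral profiles per chromosome,
normalized by the edge count; (b) the minimum ancestral entry; (c) canonical
amplification events covering a locus at or below zero at application time,
normalized by edges; (d) the fraction of all events violating CNT semantics
(amplifying *or* deleting a locus at or below zero — deletions at zero are
also forbidden under zero-skipping).

## The median problem

For profiles p₁…p_n, the profile r minimizing Σᵢ d(r,pᵢ) is found per
chromosome by a DP over A[j,k] = minimal partial L1 cost of a length-j
prefix of Δ(r) with prefix sum (discrepancy) k; entries of Δ(r) range over
[−B′,B′] with B′ = max(B, 2, max|Δ| observed), slightly wider than the
maximum input copy number B for safety at low ploidy.  Boundary condition:
the empty prefix has discrepancy 0 at cost 0 and is infeasible otherwise
(A[0,0]=0, A[0,k≠0]=∞ — the prefix-sum semantics admits no other reading).
The answer sits at A[L,0], enforcing balance; backpointers reconstruct r,
with ties broken toward the delta value nearest zero.  Discrepancy is
bounded by B′·j at column j.  Runtime O(n·m²·B²).  For n=2 the optimum
equals the pairwise distance and an input profile attains it.

## Large parsimony search

Pipeline: pairwise ZCNT distance matrix → neighbor joining (Saitou–Nei,
deterministic lowest-index tie-breaking) → NNI hill climbing → final
balanced labeling.  The search scores candidate topologies with the
unbalanced relaxation — orders of magnitude faster than the balanced
solvers and empirically almost perfectly rank-concordant with them — while
the final reported labeling is balanced (repair heuristic by default, exact
ILP on request).

Defaults: best-improvement NNI; after each converged climb, a random NNI
walk of length ⌈0.2·n⌉ followed by a re-climb, keeping the best tree seen;
up to 50 perturbation rounds; a single integer seed drives all randomness.
These schedule choices are deliberately simple and exposed in
`SearchConfig`; the accepted-score trace is non-increasing by construction
and identical runs are byte-for-byte reproducible.

Rooting: with `root_at_diploid` a pseudo-cell named `diploid` carrying the
all-baseline profile joins the distance matrix and the search; the final
tree is re-rooted at it, so the root label is exactly the normal genome
(the leaf-data constraint pins it).  Evaluation metrics drop this
pseudo-leaf before comparing trees.  Pinning adds the diploid edge to the
objective, so the pinned score is never below the unpinned one.

## Simulator

Ground truth generator: random binary topologies by iterative uniform
pair-joining; evolution from an all-diploid root with a Poisson number of
events per edge (default mean 3), uniform chromosome choice, uniform
interval endpoints (a geometric length option mimics focal events),
amplification probability 0.5, applied with CNT semantics by default so
simulated data never violates the zero-skipping constraint; an optional
maximum-copy cap rejects events that would exceed it.  The event log and
all ancestral profiles are kept, and replaying the log reproduces every
vertex profile exactly.

What the simulator does *not* emulate: whole-genome doubling,
chromothripsis, sequencing noise or segmentation error — inputs are assumed
to be correctly called integer profiles.  Passing tests therefore show
correctness of the algorithms under the stated generative model, not
robustness to real-world calling noise.  Under CNT semantics a logged event
is not always a single ZCNT event (zero-skipping may split it), so
event counts upper-bound per-edge ZCNT distances only under the simulator's
ZCNT mode; tests distinguish the two.

Problem sizes used in the shipped checks (chosen to exercise every code
path at desk scale): exhaustive distance validation on all 4096 ordered
pairs at m=3, entries ≤3; 50 simulated phylogenies with n=10, m=30 for the
relaxation/approximation batch; n=12, m=120 over 10 seeds for the search
comparison.

## Numerical and degenerate-input notes

- All distances and integer-labeling scores are exact integer arithmetic in
  float containers; LP comparisons use 1e−6 tolerances.
- Identical cells give zero distance matrices; neighbor joining breaks the
  resulting ties deterministically by lowest index pair.
- Profiles with a single bin, single chromosomes, and polytomies are all
  legal inputs; trees rooted at a leaf (the diploid root) are handled by
  constraining vertices by name rather than by degree.
- Observed (input) profiles must be non-negative integers; ancestral and
  median profiles may be negative by design.

## Known limitations

- CNT distances are only available through the toy-scale BFS oracle; real-
  scale CNT comparisons require externally computed distances.
- The NNI neighborhood is the only rearrangement move (no SPR/TBR), and the
  perturbation schedule is a simple fixed-strength random walk.
- The ILP scales to hundreds of integer variables comfortably but is not
  intended for thousands of cells; the repair heuristic is the scalable
  path and is within a provable factor 2 (empirically ≈1.2–1.35 on the
  simulated batches the acceptance script runs).
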