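# Methods

## The model

A causal biological network (CBN) is a directed acyclic graph G = ⟨V, E⟩
over biological signal variables X₁…Xₙ (brain regions, phosphoproteins,
genes).  G factorizes the joint distribution as
P(X₁,…,Xₙ) = ∏ᵢ P(Xᵢ | Pa(Xᵢ)), and structure learning is cast as
score-and-search: find the DAG maximizing the K2 metric

    f(G : D) = ∑ᵢ ∑ⱼ [ log Γ(rᵢ) − log Γ(Nᵢⱼ + rᵢ) + ∑ₖ log Γ(Nᵢⱼₖ + 1) ],

the log marginal likelihood of the structure under independent uniform
Dirichlet parameter priors, where rᵢ is the cardinality of node i, j runs
over the parent configurations realized in the discrete data D, Nᵢⱼₖ counts
samples with child level k under configuration j, and Nᵢⱼ = ∑ₖ Nᵢⱼₖ.  A
uniform structure prior is assumed and dropped as an additive constant.
Configurations never realized contribute a factor of exactly one, so the
sum ranges over realized configurations only; this is lossless and keeps
the cost independent of the Cartesian product of parent cardinalities.
All arithmetic is in log-gamma space (a lookup table over integer counts on
the hot path); factorials are never formed.

## The search

The optimizer is a parallel ant colony system.  Each of N colonies owns one
data set.  Within a colony, each of Num ants grows a DAG from the empty
graph, one arc at a time.  An arc u → c is a candidate if it is absent,
keeps the graph acyclic, and has positive heuristic

    η(u → c) = (1 + Inf(u, c)) · [f(c | Pa(c) ∪ {u}) − f(c | Pa(c))],

the mutual-information-weighted local K2 gain.  Selection follows the
pseudo-random proportional rule: with probability q₀ the ant exploits
(argmax of τ·η^β; ties go to the smallest (parent, child) index pair),
otherwise it samples an arc with probability ∝ τ^α·η^β.  The exponent
asymmetry between the two rules (no α in exploitation) is deliberate and
kept exactly as the rules are conventionally printed.  Each selected arc is
immediately evaporated toward the initial level, τ ← (1−ρ)τ + ρτ₀.
Because every accepted arc strictly increases the network score and the
candidate set shrinks monotonically under the acyclicity constraint,
construction terminates.

The iteration-best ant's network is refined by first-improvement hill
climbing over single-arc additions, deletions and reversals (a reversal is
accepted on the combined score delta of both endpoint children and only if
it keeps the graph acyclic), sweeping until no move improves or `lstep`
sweeps have run.  The colony's best-so-far network G⁺ then receives a
global deposit τ ← (1−ρ)τ + ρ/|f(G⁺ : D)| on its arcs; all other entries
are unchanged (substituting the no-deposit branch into the update leaves
them fixed, so it is implemented as a no-op).

After every iteration the colonies synchronize: the pheromone matrix of the
colony whose G⁺ scores highest overwrites every colony's matrix (ties go to
the lowest colony index).  After NC iterations the N colony-best networks
are fused by majority vote: arc u → c enters the final network iff at least
`consensus_fraction · N` colonies learned it (exactly half passes).  The
vote can produce orientation conflicts and, in principle, cycles, which the
original rule leaves unaddressed; here the orientation with the larger
count wins (an exact tie keeps neither), and any residual cycle is broken
by discarding arcs in ascending vote order.  The result is always a DAG.

Determinism and parallelism: every ant's random stream is derived from
(base seed, colony index, iteration, ant index), so results are
bit-identical between serial and thread-parallel execution and independent
of scheduling order.

### Parameters

| name | default | role |
|------|---------|------|
| α    | 1.2     | pheromone exponent in the exploration rule |
| β    | 2.0     | heuristic exponent in both rules |
| ρ    | 0.35    | evaporation rate, in (0, 1] |
| q₀   | 0.75    | exploitation probability, in [0, 1) |
| τ₀   | 0.1     | initial pheromone level |
| Num  | 20      | ants per colony per iteration |
| NC   | 10      | iterations (= fusion barriers) |
| lstep | 20     | local-search sweep cap |
| consensus_fraction | 0.5 | vote threshold for the final network |

The α/β/ρ/q₀/NC/Num defaults are the configuration under which the
algorithm is reported stable; we keep them fixed in all benchmark runs.
The global deposit ρ/|f| is tiny relative to τ₀ = 0.1 on realistic data
(|f| is thousands of nats), so pheromone acts as a weak tie-breaker rather
than a strong memory; experiments with τ₀ rescaled to the deposit magnitude
changed benchmark accuracy by less than one F1 point, so the plain default
is kept.

## Discretization — the load-bearing design choice

The K2 metric needs categorical data; biological signals are continuous.
How they are reduced to levels turns out to decide what the method can and
cannot recover, so both options are spelled out:

**equal_frequency** cuts each column at its own sample quantiles (boundary
ties to the lower bin).  It is scale-free and right for columns measured in
unrelated units.  But marginal standardization has a hard consequence for
linear systems with a shared noise scale: after each variable is reduced to
its own quantiles, a dependent Gaussian pair is *exchangeable* — the
discretized joint distribution of (X, Y) is symmetric in X and Y — so no
pairwise statistic, K2 included, carries any information about edge
direction.  Only collider patterns remain, and empirically they are diluted
to near coin-flip orientation accuracy on dense graphs.

**shared_scale** (the default) applies a signed log1p compression and cuts
equal-width bins on one scale shared by all columns of a data set, so a
column's realized levels reflect its amplitude relative to the rest of the
system.  In a linear SEM with unit noise variance everywhere, variance
accumulates along the causal order — Var(child) = 1 + ∑ w²·Var(parent) —
so amplitude rank is exactly the causal order signal (the same property
that makes equal-variance Gaussian SEMs identifiable at all, and that
continuous methods exploit through residual variances).  The signed-log
compression keeps deep, high-variance nodes from swallowing the shared
scale; a non-constant column that still falls inside a single shared bin is
split at its own median so it always carries at least two levels.  K2 then
prefers the low-amplitude → high-amplitude orientation through its
cardinality asymmetry, which in controlled two-node experiments follows the
coding's level gradient almost deterministically.

Columns with at most `n_bins` distinct values are passed through by
rank-coding under either method, so already-discrete inputs are not
distorted.  Each colony discretizes its own data set; nothing is pooled.

The corollary: with `shared_scale`, passing tests show the method recovers
amplitude-ordered linear systems; they do not show it can orient edges in
data whose channels have been independently normalized (there the
information provably is not in the data, and `equal_frequency` behaviour —
skeleton without reliable orientation — is what real mixed-unit inputs
should be expected to give).

## The synthetic benchmark

`simulate` draws a strictly upper-triangular binary adjacency with
independent Bernoulli(0.5) entries, weights uniform on
[−1.5, −0.5] ∪ [0.5, 1.5] (fair-coin sign × Unif[0.5, 1.5] magnitude,
equivalent to uniform on the union), and samples x = Wᵀx + λ by triangular
solve with unit-variance noise — Gaussian, or standardized Gumbel
(location −γ√6/π, scale √6/π) for the non-Gaussian family.  One benchmark
bundle shares a single truth and a single uniformly random column
permutation across its N sub-data sets (one biological system observed
repeatedly); only the noise differs, with sub-data set k seeded as
(seed, k).  The truth is exported in observed (permuted) coordinates, so
evaluation never sees the hidden topological order.

What the generator does not emulate: haemodynamic convolution or temporal
autocorrelation of fMRI, cytometry measurement noise or gating artefacts,
interventions, hidden confounders, or cyclic feedback.  Benchmark numbers
therefore speak to the score-and-search machinery, not to those
real-data complications.

Density matters when reading results.  Bernoulli(0.5) truths are dense:
expected in-degree grows linearly with v (≈ v/4 on average, up to v−1),
so a 30-node truth has ≈ 220 edges and parent sets far larger than any
discrete score can populate from 200 samples per sub-data set — the
K2 optimum at that sample size is a much sparser graph, and recall is
structurally capped.  The 5-node instances (≈ 5 edges) are the regime
where full recovery is statistically possible, and there the pipeline's
mean F1 ≈ 0.75 and mean SHD ≈ 1.8 over ten seeds (see
`scripts/acceptance.py`, which recomputes these).

## Problem sizes used in checks

Acceptance-style runs average 10 seeds at v = 5 and v = 10, 3 seeds at
v = 30, 5 seeds for the (v = 10, N = 50) SHD instance, and 3 seeds at
v = 50, which stands in for the 100-node instance; these counts are the
package's balance between sampling error and a desk-scale run.

## Numerical choices and degenerate inputs

* Scores are compared with plain floating-point `>`; construction requires
  strictly positive heuristic, so zero-gain arcs are never added.
* Argmax ties in exploitation break to the smallest (parent, child) pair —
  deterministic and seed-independent.  Colony-score ties at fusion break to
  the lowest colony index.
* The global deposit guards against a zero best score (impossible on real
  data, where log-marginal likelihoods are negative) by substituting the
  smallest positive float magnitude.
* A constant column discretizes to a single level with a warning; its
  local score is exactly zero for any parent set and it can never gain or
  give an informative arc.
* Declared cardinalities may exceed observed level counts when a
  `DiscreteDataset` is built directly (a variable may have possible values
  unseen in a small sample); the discretizer itself only emits realized
  levels.
* Exploration sampling falls back to argmax if the proportional weights
  overflow or vanish.

## Known limitations

* Orientation on marginally-standardized data is limited to what collider
  structure identifies; see the discretization section.
* Dense truths (expected degree ≫ affordable parent-set size at the given
  sample count) cap recall for any discrete score; the consensus vote then
  returns the well-supported sparse core.
* The consensus threshold is a hard vote; it has no notion of edge
  confidence beyond the colony count.
* No pheromone bounds (max–min style) and no conditional-independence
  pruning of candidates; both are deliberate non-goals.
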