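# Methods

`fwalign` quantifies how much of a food web's *topological organisation*
survives a press perturbation, even when many of the individual trophic
links do not. It was built around a paired mesocosm design — four
replicate control/drought pairs of stream food webs — but the machinery
is generic: any two node-labelled directed resource→consumer networks
sharing a species namespace can be analysed.

## The alignment model

Both webs of a pair are projected onto undirected simple graphs
(an edge wherever a feeding link exists in either direction;
cannibalistic self-loops dropped). A *global alignment* is an injective
map `f : V1 → V2` from the smaller graph into the larger. Its quality
is the Symmetric Substructure Score

    S3 = |f(E1)| / ( |E1| + |E(G2[f(V1)])| − |f(E1)| )

conserved edges over the union of edges present in the aligned region
of either graph. Because the denominator includes the edges of the
subgraph of `G2` *induced* by the image of `f`, the score penalises
mapping a sparse region onto a dense one as much as the reverse; it is
1 exactly when the image of `E1` coincides with the induced edge set,
and (by convention, logged) 1 when both aligned regions are edgeless.

### Search

Maximising `S3` over injections is a hard combinatorial problem; the
search is a memetic genetic algorithm over permutations of `G2`'s node
list, the map read off the first `|V1|` positions:

- **Fitness**: `S3`, evaluated in a vectorised batch against a boolean
  adjacency matrix. An experimental `node_conservation` fitness
  (degree-difference similarity) is provided; reported scores are
  always `S3`.
- **Selection**: elitist — the top `elite_fraction` (default 0.5)
  survive; offspring are produced by cycle crossover of uniformly
  sampled elite parents with per-child transposition mutation
  (probability 0.2).
- **Local search**: periodically (every 10 generations, and every
  generation with extra random restarts on graphs of ≤ 15 nodes) the
  incumbent is refined by first-improvement hill climbing over position
  swaps until no swap raises the score. This memetic step is what makes
  the scaled-down settings reliable: with it, the search matched the
  exhaustive oracle's optimum on 150/150 random small instances.
- **Seeding**: besides random permutations, the initial population
  contains a degree-sorted greedy match and — when the two graphs share
  node labels, as paired webs sampled from one species pool do — the
  shared-label map. Seeding only warm-starts the search; with elitism
  the reported score can never fall below a seed's score. It can be
  disabled (`label_seeding=False`), and all oracle-equivalence testing
  runs on graphs with disjoint label sets so the search itself is
  exercised.

Default parameters mirror the reference configuration (population
15000, 2000 generations, elite fraction 0.5, 30 replicate runs
averaged); the pipeline's working defaults are population 500, 300
generations, 5 runs, which on 74-node webs costs roughly 10–15 s per
run on one core. Replicate runs are seeded by spawning a root seed, so
every result is a pure function of inputs and seed. With elitism the
best-so-far trace is non-decreasing; the run stops early only at a
perfect score (or after an optional stagnation patience, off by
default).

An exhaustive oracle (`brute_force_align`, guarded to `|V1| ≤ 8`)
enumerates every injective map in lexicographic order and is the
ground truth for correctness tests.

## Null model and significance

The null hypothesis is that an observed `S3` could arise from webs
with the same degree sequence but random structure. The perturbed web
is randomized by attempted double-edge swaps (default `10·|E|`
attempts; swaps creating self-loops or multi-edges are rejected, so
the degree sequence is preserved exactly). The randomizer is written
in-package with attempt semantics so that swap-free graphs (e.g. stars)
are returned unchanged rather than failing. Thirty randomized webs are
aligned to the control with the same GA settings as the observed
alignment, and significance is the z-score `(x − μ)/σ` with `σ` the
sample SD over replicates (zero `σ` yields an undefined z, reported as
+inf with a warning).

## Rewiring classification

Species carry the same identifiers in both webs, so directed link
identity is the `(resource, consumer)` pair; the alignment is needed
only for topology, never for matching links. The drought web's links
partition exactly into **conserved** (present in both), **rewired**
(drought-only with a surviving consumer — a dietary shift, attributed
to the consumer endpoint), and **invader** links (drought-only with a
consumer absent from the control); the control web's links partition
into conserved and **lost**. Per-species records report the rewired
count and its proportion of the drought diet (the control-diet
denominator is available by option), plus drought-minus-control changes
in degree, eigenvector centrality and PageRank.

## Node metrics

Degree, eigenvector centrality and PageRank are computed on the same
undirected graph used for alignment (the resource/consumer split in
reports is an attribute filter, not a directed computation). PageRank
uses damping 0.85 and uniform teleport to tolerance 1e-9; eigenvector
centrality is the power-iteration principal eigenvector normalized to
unit Euclidean norm (the max-entry-1 convention would rescale
regression slopes but nothing else). On disconnected graphs the
eigenvector is computed on the largest component with zeros elsewhere
and a warning, since the iteration has no unique limit across
components.

## Aligned binary matrices

Control species are ordered deterministically: four sub-groups
(aligned-survived, aligned-extinct, non-aligned-survived,
non-aligned-extinct), resources before consumers within each, detritus
(no recorded body mass) in the first entries, then decomposers, primary
producers, detritivores, herbivores and predators, each by ascending
body mass with id tiebreaks (descending mass by option; a non-detritus
species missing mass falls back to id order with a warning). Each
drought species occupies the matrix entry of its aligned control
counterpart; drought species with no aligned counterpart are appended
after all control positions in ascending degree order. The two 0/1
matrices share a position index and can be overlaid cell by cell; a
long-format cell table carries the link class of every edge.

## Statistical models

Three families of linear mixed-effects models, fitted by REML through
statsmodels' `MixedLM`:

1. metric ~ treatment, random intercept for species nested within web
   pair (surviving species of both webs);
2. metric change ~ number of rewired links, crossed random intercepts
   for pair and species;
3. proportion of links rewired ~ control-web degree / eigenvector
   centrality / PageRank, crossed random intercepts for pair and
   species, identity scale by default (logit by option).

Wald F statistics use Satterthwaite denominator degrees of freedom
computed in-package by the delta method on
`g(θ) = c'(X'V(θ)⁻¹X)⁻¹c` with the REML expected information of the
variance parameters; the implementation agrees with `lmerTest` (slope
to ~0.1%, df to a few percent) and is cross-checked against it in the
test suite through `Rscript`. The reported r² is the marginal
(fixed-effects) coefficient of determination. A constant response is
reported as a null effect (F = 0, p = 1); a constant predictor or a
single-row table is an error.

## Synthetic study generator

The generator exists so every pipeline stage can be validated against
known ground truth. Control webs are niche-model webs: species receive
uniform niche values, feeding intervals sized to a target connectance
(beta-distributed range fractions), and eat everything inside their
interval (cannibalism excluded). Basal species are relabelled —
two detritus classes (no body mass), up to two decomposers, the rest
primary producers — and consumers split into detritivores, herbivores
and predators by niche terciles; body mass grows log-linearly with
niche value; fluxes are lognormal (g m⁻² yr⁻¹).

Defaults are the reference dataset's scale: 74 trophic elements,
connectance `98/74²` (≈ 98 directed links per web, eight webs pooling
to ≈ 783), four pairs. Sparse niche draws are usually disconnected, so
minor components are reattached by one rare feeding link each, bounded
so realized connectance stays within ±20% of target; at extreme
sparsity (where a spanning tree alone would exceed the band) remaining
components are left disconnected with a warning.

The drought perturbation: (i) `13 ± 1.9` consumer extinctions
(sampled, clipped); (ii) each surviving link dropped independently
with probability 0.3 (diet contraction); (iii) rewired links added
until the expected *share of drought links that are conserved* is 0.60
— the calibration is placed on this share because adding rewired and
invader links changes the denominator that a drop-step-only
calibration would assume fixed; (iv) invading consumers (count derived
from the 92% shared-species target, ≈ 5 per web) with small preferential
diets; (v) fluxes scaled by 0.7, so drought totals fall below the
aligned control region's. Rewired links target resources that already
support many consumers, reproducing the observed rise in eigenvector
centrality and PageRank among rewiring survivors — a modelling choice,
not an observed mechanism.

Rewiring propensity is per surviving diet link, `∝ degree^(−bias)`, so
a consumer's event rate is `(surviving diet) · degree^(−bias)`: at
`specialist_bias = 0` the expected rewired count is proportional to the
denominator of `prop_rewired` and the proportion is flat in degree
(generator null), while positive bias makes specialists rewire
proportionally more, monotonically steeper in the bias. Rewired links
are never drawn from control pairs, so the generator's rewired set is
recovered *exactly* by the classifier — the pipeline's strongest
ground-truth check.

What the generator does **not** emulate: gut-content sampling effort,
body-size-structured diet selection, seasonal/temporal dynamics, or
the empirical webs' exact per-web S and L (only pooled scale). Passing
tests therefore demonstrate correctness of the machinery and
recoverability of planted effects at realistic scale — not that the
empirical effect sizes themselves are reproduced, which requires the
original data tables.

## Numerical and convention choices

- Connectance is `L/S²` on the directed web, self-loops included
  (`L/[S(S−1)]` is a documented alternative).
- Undirected projection: edge iff a link exists in either direction.
- `S3 = 1` for doubly edgeless aligned regions, logged.
- Brute-force ties broken by lexicographically first image sequence;
  replicated-run ties by first run.
- z-scores use sample SD (ddof = 1) over null replicates.
- Satterthwaite df clipped to `[1, n − p]`; variance components floored
  at zero; a degenerate information matrix falls back to residual df.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; derived seeds are reduced mod
  2³¹.

## Problem sizes used in the shipped checks

Unit tests run on 30-node webs and tiny graphs; oracle equivalence on
50 random pairs with `|V1| ≤ 8`; self-alignment on twenty 74-node webs
at population 500 / 300 generations; turnover recovery on 50 default-
scale pairs; the specialist-bias sign tests on twenty 4-pair studies
per bias setting. The full-scale empirical reproduction check needs the
original study's web tables under `data/empirical/` and is otherwise
reported as unmet.

## Known limitations

- Exact numerical replication of the original Magna++ aligner is not
  claimed: its node-conservation objective is not publicly specified.
  Correctness is instead established against the exhaustive oracle and
  planted-solution bounds.
- Alignment is unweighted; flux weights enter only region summaries.
- The niche-model generator produces interval diets, which are more
  contiguous than gut-content diets.
- Mixed-model estimation inherits statsmodels' REML optimizer; for very
  small tables variance components may hit the zero boundary, where
  Satterthwaite df approaches the residual df.
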