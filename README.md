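# fwalign

Topological alignment and rewiring analysis of paired food webs.

When a press perturbation such as drought removes consumers from a
stream food web, the surviving species can re-assemble their diets so
thoroughly that most individual trophic links change while the web's
*global topological organisation* barely moves. `fwalign` is a toolkit
for quantifying exactly that phenomenon in a paired
(control vs perturbed) experimental design:

- **Global network alignment.** For each pair it searches for the
  injective node map `f : V1 → V2` (smaller web into larger) maximising
  the Symmetric Substructure Score

  `S³ = |f(E1)| / (|E1| + |E(G2[f(V1)])| − |f(E1)|)`

  — conserved edges over the union of edges in the aligned region of
  either web — using a seeded, elitist, memetic genetic algorithm over
  permutations, with an exhaustive oracle for small instances.
- **Significance.** Degree-preserving (double-edge-swap) randomizations
  of the perturbed web are aligned to the control and the observed
  score is expressed as `z = (x − μ)/σ` against the null ensemble.
- **Rewiring.** Each pair's directed links are partitioned exactly into
  conserved / lost / rewired (dietary shifts of surviving consumers) /
  invader links, with per-species rewiring proportions and changes in
  degree, eigenvector centrality and PageRank.
- **Aligned binary matrices.** Deterministic role-and-body-mass
  ordering of the control web, with every perturbed-web species placed
  at the entry of its aligned counterpart, for cell-by-cell overlay.
- **Mixed-effects statistics.** Treatment comparisons, rewiring
  regressions and specialism regressions with REML estimation and
  Satterthwaite degrees of freedom.
- **Synthetic studies.** A niche-model generator with a parameterised
  drought perturbation (consumer extinctions, link loss, degree-biased
  rewiring, invaders, flux down-scaling) and exact ground-truth
  records, so the whole pipeline is testable without any data download.

See `docs/methods.md` for the model, parameters, and design choices.

## Worked example

Generate a small synthetic study (two control/drought pairs of 30
trophic elements) and run the full pipeline with reduced search
settings:

```sh
fwalign simulate --out demo/study --pairs 2 --species 30 --seed 11
fwalign run --input-dir demo/study --out demo/report \
        --pop 200 --gens 150 --runs 3 --null-n 10 --seed 11
```

which prints

```
wrote 2 pairs to demo/study
S3 over pairs: 0.512 +/- 0.017; mean z=1.4
```

and writes per-pair bundles (alignment map, null scores, link classes,
metrics, per-species rewiring, aligned matrices) plus pooled tables and
`summary.yaml`. In this run the two drought webs kept 92.5% of their
species and only 60.0% of their links relative to the controls
(`mean_prop_shared_species`, `mean_prop_shared_links` in the summary) —
the generator's planted turnover — yet the best alignments recover
51% topological similarity, above the degree-preserving null mean of
0.445. The z separation grows with web size and search effort: at the
default 74-element scale the same pipeline yields observed scores near
0.56 against null means near 0.40, and tight null SDs (hence very large
z) are reached at the full search settings
(`--paper-settings`: population 15000, 2000 generations, 30 runs),
which cost hours per pair on one core.

The two headline per-species results are reproduced on synthetic data
by the stats layer: metric changes increase with the number of rewired
links (rewiring regression), and the *proportion* of links rewired
decreases with control-web degree when the generator's
`specialist_bias > 0` (specialism regression) — specialists rewire
proportionally more.

Everything is also callable as a library:

```python
from fwalign import (GAParams, align_replicated, classify_links,
                     GeneratorParams, generate_study)

pairs, _ = generate_study(GeneratorParams(n_pairs=1, seed=11))
control, drought = pairs[0].control, pairs[0].drought
rep = align_replicated(drought.to_undirected(), control.to_undirected(),
                       GAParams(population_size=500, generations=300,
                                elite_fraction=0.5, n_runs=5, seed=0))
print(rep.mean, rep.sd)
cls = classify_links(control, drought)
assert cls.rewired == pairs[0].truth.rewired   # exact ground-truth recovery
```

## Data formats

Node tables (`web_id, species_id, name, functional_role, body_mass,
is_consumer`) and link tables (`web_id, resource_id, consumer_id,
flux`) as CSV/TSV; fluxes in g m⁻² yr⁻¹. `functional_role` is one of
detritus, decomposer, primary_producer, detritivore, herbivore,
predator; body mass may be missing only for detritus. Round-tripping
through `write_foodweb`/`read_foodweb` is exact.
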