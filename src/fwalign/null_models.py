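"""Degree-preserving null models and z-score significance.

The null hypothesis is that the observed alignment score between a
control web and its perturbed counterpart could arise from webs with
the same degree sequence but otherwise random structure. Randomized
versions of the perturbed web are produced by repeated double-edge
swaps (reject any swap that would create a self-loop or multi-edge),
each aligned to the control, and the observed S^3 is expressed as

    z = (x - mu) / sigma

against the mean and standard deviation of the null scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import GAParams, ga_align

logger = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    scores: list[float]
    mu: float
    sigma: float
    observed: float | None = None
    z: float | None = None
    n_replicates: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_replicates = len(self.scores)


def degree_preserving_randomize(
    G: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Randomize a simple undirected graph by attempted double-edge swaps.

    ``n_swaps`` is the number of swap *attempts* (default 10 |E|, a
    common mixing heuristic); attempts that would introduce a self-loop
    or a multi-edge are rejected, so the output is simple and has
    exactly the original degree sequence. Graphs with fewer than two
    edges are returned unchanged with a warning.
    """
    H = G.copy()
    m = H.number_of_edges()
    if m < 2:
        logger.warning("graph has %d edge(s); no degree-preserving swap exists", m)
        return H
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    rng = np.random.default_rng(seed)
    edges = list(H.edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,c),(b,d)
        if len({a, b, c, d}) < 4:
            continue
        if H.has_edge(a, c) or H.has_edge(b, d):
            continue
        H.remove_edge(a, b)
        H.remove_edge(c, d)
        H.add_edge(a, c)
        H.add_edge(b, d)
        edges[i] = (a, c)
        edges[j] = (b, d)
    return H


def null_alignment_scores(
    control: nx.Graph,
    drought: nx.Graph,
    n: int = 30,
    ga: GAParams | None = None,
    seed: int = 0,
    observed: float | None = None,
    randomize_both: bool = False,
) -> NullEnsemble:
    """Align ``n`` degree-preserving randomizations of the perturbed web.

    Only the perturbed (drought) web is randomized by default; the GA
    settings default to those used for the observed alignment so the
    null scores are comparable. The smaller graph of each pair is
    aligned into the larger. Sigma is the sample SD over replicates; a
    zero sigma makes z undefined and is reported as +inf with a warning.
    """
    if ga is None:
        ga = GAParams(population_size=200, generations=150, elite_fraction=0.5,
                      n_runs=1, seed=seed)
    root = np.random.SeedSequence(seed)
    scores: list[float] = []
    for child in root.spawn(n):
        s1, s2 = child.generate_state(2) % (2**31)
        rand_d = degree_preserving_randomize(drought, seed=int(s1))
        g_small, g_large = (rand_d, control)
        if g_small.number_of_nodes() > g_large.number_of_nodes():
            g_small, g_large = g_large, g_small
        if randomize_both:
            g_large = degree_preserving_randomize(g_large, seed=int(s1) + 1)
        params = GAParams(
            population_size=ga.population_size,
            generations=ga.generations,
            elite_fraction=ga.elite_fraction,
            n_runs=1,
            seed=int(s2),
            objective=ga.objective,
            mutation_rate=ga.mutation_rate,
            local_search_interval=ga.local_search_interval,
            patience=ga.patience,
            label_seeding=ga.label_seeding,
        )
        scores.append(ga_align(g_small, g_large, params).alignment.s3)
    mu = float(np.mean(scores))
    sigma = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    ens = NullEnsemble(scores=scores, mu=mu, sigma=sigma, observed=observed)
    if observed is not None:
        ens.z = z_score(observed, ens)
    return ens


def z_score(x: float, ensemble: NullEnsemble) -> float:
    """Standardized deviation of ``x`` from the null ensemble."""
    if ensemble.sigma == 0:
        logger.warning("null ensemble has zero SD; z-score is undefined (+inf)")
        return math.inf if x != ensemble.mu else 0.0
    return (x - ensemble.mu) / ensemble.sigma
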