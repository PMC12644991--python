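"""Global alignment of two undirected graphs under the S^3 score.

An alignment is an injective map ``f`` from the node set of the smaller
graph G1 into the larger graph G2. Its quality is the Symmetric
Substructure Score

    S3 = |f(E1)| / (|E1| + |E(G2[f(V1)])| - |f(E1)|)

i.e. conserved edges over the union of edges present in the aligned
region of either graph. The denominator counts edges of the subgraph of
G2 induced by the image of f, so the score penalises mapping a sparse
region onto a dense one as much as the reverse.

The search is a memetic genetic algorithm over permutations of G2's
node list (the first |V1| positions read off the map), with elitist
selection, cycle crossover, transposition mutation, and periodic
swap-based hill climbing of the incumbent. When the two graphs share
node labels — as paired food webs sampled from the same species pool
do — the initial population is seeded with the shared-label map, which
warm-starts the search without constraining it. An exhaustive oracle
for tiny instances supports validation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Node = Hashable


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """An injective node map V1 -> V2 with its conserved edges and score."""

    mapping: dict[Node, Node]
    conserved_edges: frozenset[frozenset[Node]]
    s3: float
    g1_nodes: tuple[Node, ...] = ()
    g2_nodes: tuple[Node, ...] = ()

    def image(self) -> set[Node]:
        return set(self.mapping.values())

    def is_identity_on(self, nodes) -> bool:
        return all(self.mapping.get(v) == v for v in nodes)


@dataclass
class GAParams:
    """Genetic-algorithm settings.

    Defaults mirror the reference configuration (population 15000,
    2000 generations, elite fraction 0.5, 30 replicate runs); pipelines
    typically scale these down. ``objective`` selects the fitness used
    during the search; reported scores are always S^3.
    """

    population_size: int = 15000
    generations: int = 2000
    elite_fraction: float = 0.5
    n_runs: int = 30
    seed: int = 0
    objective: str = "edge_s3"  # or "node_conservation" (experimental)
    mutation_rate: float = 0.2
    local_search_interval: int = 10
    patience: Optional[int] = None
    label_seeding: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise AlignmentError("population_size must be >= 2")
        if not 0 < self.elite_fraction <= 1:
            raise AlignmentError("elite_fraction must be in (0, 1]")
        if int(self.elite_fraction * self.population_size) < 1:
            raise AlignmentError("elite_fraction * population_size must be >= 1")
        if self.generations < 1 or self.n_runs < 1:
            raise AlignmentError("generations and n_runs must be positive")
        if self.objective not in {"edge_s3", "node_conservation"}:
            raise AlignmentError(f"unknown objective {self.objective!r}")


# ----------------------------------------------------------------------
# Scoring


def _check_pair(G1: nx.Graph, G2: nx.Graph) -> None:
    if G1.number_of_nodes() > G2.number_of_nodes():
        raise AlignmentError(
            "G1 must be the smaller graph "
            f"(|V1|={G1.number_of_nodes()} > |V2|={G2.number_of_nodes()})"
        )


def s3_score(G1: nx.Graph, G2: nx.Graph, f: Mapping[Node, Node]) -> float:
    """Symmetric Substructure Score of the alignment ``f``.

    ``f`` must be total on V1 and injective. When both the aligned
    region of G1 and the induced subgraph of G2 are edgeless the score
    is 1 by convention (vacuously perfect agreement) and a debug message
    is logged.
    """
    _check_pair(G1, G2)
    missing = [v for v in G1.nodes if v not in f]
    if missing:
        raise AlignmentError(f"alignment is not total on V1; missing {missing[:5]}")
    image = [f[v] for v in G1.nodes]
    if len(set(image)) != len(image):
        raise AlignmentError("alignment is not injective")
    unknown = [u for u in image if u not in G2]
    if unknown:
        raise AlignmentError(f"alignment maps onto nodes not in G2: {unknown[:5]}")

    conserved = sum(1 for u, v in G1.edges if G2.has_edge(f[u], f[v]))
    induced = G2.subgraph(image).number_of_edges()
    e1 = G1.number_of_edges()
    denom = e1 + induced - conserved
    if denom == 0:
        logger.debug("S3 of edgeless aligned regions: returning 1.0 by convention")
        return 1.0
    return conserved / denom


def conserved_edge_set(
    G1: nx.Graph, G2: nx.Graph, f: Mapping[Node, Node]
) -> frozenset[frozenset[Node]]:
    return frozenset(
        frozenset((u, v)) for u, v in G1.edges if G2.has_edge(f[u], f[v])
    )


# ----------------------------------------------------------------------
# Indexed problem representation shared by the GA and the oracle


class _Problem:
    """Arrays for fast permutation-based S^3 evaluation."""

    def __init__(self, G1: nx.Graph, G2: nx.Graph):
        _check_pair(G1, G2)
        self.nodes1: list[Node] = sorted(G1.nodes, key=str)
        self.nodes2: list[Node] = sorted(G2.nodes, key=str)
        self.n1 = len(self.nodes1)
        self.n2 = len(self.nodes2)
        idx1 = {v: i for i, v in enumerate(self.nodes1)}
        self.idx2 = {v: i for i, v in enumerate(self.nodes2)}
        self.e1 = G1.number_of_edges()
        eu, ev = [], []
        for u, v in G1.edges:
            eu.append(idx1[u])
            ev.append(idx1[v])
        self.eu = np.asarray(eu, dtype=np.intp)
        self.ev = np.asarray(ev, dtype=np.intp)
        self.A2 = np.zeros((self.n2, self.n2), dtype=bool)
        for u, v in G2.edges:
            i, j = self.idx2[u], self.idx2[v]
            self.A2[i, j] = self.A2[j, i] = True
        pi, pj = np.triu_indices(self.n1, k=1)
        self.pi = pi.astype(np.intp)
        self.pj = pj.astype(np.intp)
        self.deg1 = np.zeros(self.n1)
        for v, d in G1.degree():
            self.deg1[idx1[v]] = d
        self.deg2 = np.zeros(self.n2)
        for v, d in G2.degree():
            self.deg2[self.idx2[v]] = d
        self.max_deg = max(1.0, self.deg1.max(initial=0), self.deg2.max(initial=0))

    # -- batch scoring -------------------------------------------------
    def s3_batch(self, perms: np.ndarray) -> np.ndarray:
        """S^3 for each permutation row (first n1 entries = image)."""
        F = perms[:, : self.n1]
        if self.e1:
            conserved = self.A2[F[:, self.eu], F[:, self.ev]].sum(axis=1)
        else:
            conserved = np.zeros(len(perms), dtype=np.intp)
        induced = self.A2[F[:, self.pi], F[:, self.pj]].sum(axis=1)
        denom = self.e1 + induced - conserved
        out = np.ones(len(perms), dtype=float)
        nz = denom > 0
        out[nz] = conserved[nz] / denom[nz]
        return out

    def node_conservation_batch(self, perms: np.ndarray) -> np.ndarray:
        """Degree-difference similarity, averaged over mapped nodes.

        Experimental proxy for node-based objectives: 1 - |deg(u) -
        deg(f(u))| / max_deg, averaged. Reported scores remain S^3.
        """
        F = perms[:, : self.n1]
        diff = np.abs(self.deg1[None, :] - self.deg2[F])
        return 1.0 - (diff / self.max_deg).mean(axis=1)

    def s3_single(self, perm: np.ndarray) -> float:
        return float(self.s3_batch(perm[None, :])[0])

    def to_alignment(self, perm: np.ndarray, G1: nx.Graph, G2: nx.Graph) -> Alignment:
        f = {self.nodes1[i]: self.nodes2[perm[i]] for i in range(self.n1)}
        return Alignment(
            mapping=f,
            conserved_edges=conserved_edge_set(G1, G2, f),
            s3=s3_score(G1, G2, f),
            g1_nodes=tuple(self.nodes1),
            g2_nodes=tuple(self.nodes2),
        )


# ----------------------------------------------------------------------
# Exhaustive oracle

_BRUTE_FORCE_MAX_V1 = 8
_BRUTE_FORCE_MAX_MAPS = 5_000_000


def brute_force_align(G1: nx.Graph, G2: nx.Graph) -> Alignment:
    """Globally S^3-optimal alignment by enumerating every injective map.

    Guarded to |V1| <= 8 (the search is factorial). Ties are broken by
    the lexicographically first image sequence over the sorted node
    lists, making the result deterministic.
    """
    prob = _Problem(G1, G2)
    if prob.n1 > _BRUTE_FORCE_MAX_V1:
        raise AlignmentError(
            f"brute_force_align is limited to |V1| <= {_BRUTE_FORCE_MAX_V1}, got {prob.n1}"
        )
    n_maps = math.perm(prob.n2, prob.n1)
    if n_maps > _BRUTE_FORCE_MAX_MAPS:
        raise AlignmentError(
            f"brute_force_align would enumerate {n_maps} maps (> {_BRUTE_FORCE_MAX_MAPS})"
        )

    best_perm: Optional[np.ndarray] = None
    best_score = -1.0
    batch: list[tuple[int, ...]] = []

    def flush() -> None:
        nonlocal best_perm, best_score
        if not batch:
            return
        arr = np.array(batch, dtype=np.intp)
        scores = prob.s3_batch(arr)
        k = int(np.argmax(scores))  # first max = lexicographic tie-break
        if scores[k] > best_score:
            best_score = float(scores[k])
            best_perm = arr[k]
        batch.clear()

    for image in itertools.permutations(range(prob.n2), prob.n1):
        batch.append(image)
        if len(batch) >= 100_000:
            flush()
    flush()
    assert best_perm is not None
    full = _complete_perm(best_perm, prob.n2)
    return prob.to_alignment(full, G1, G2)


def _complete_perm(prefix: np.ndarray, n2: int) -> np.ndarray:
    rest = [i for i in range(n2) if i not in set(int(x) for x in prefix)]
    return np.concatenate([np.asarray(prefix, dtype=np.intp), np.asarray(rest, dtype=np.intp)])


# ----------------------------------------------------------------------
# Genetic algorithm


def _cycle_crossover(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cycle crossover: alternate cycles of the two parent permutations."""
    n = len(p1)
    child = np.full(n, -1, dtype=np.intp)
    pos1 = np.empty(n, dtype=np.intp)
    pos1[p1] = np.arange(n)
    take_p1 = rng.random() < 0.5
    for start in range(n):
        if child[start] >= 0:
            continue
        src = p1 if take_p1 else p2
        i = start
        while child[i] < 0:
            child[i] = src[i]
            i = pos1[p2[i]]  # within a cycle, p1 and p2 hold the same value set
        take_p1 = not take_p1
    return child


def _seed_perms(
    prob: _Problem, pop: int, rng: np.random.Generator, label_seeding: bool
) -> np.ndarray:
    """Initial population: random permutations plus informed seeds.

    Seeds: (a) the shared-label map (each G1 node mapped to the G2 node
    carrying the same label, when any labels are shared), (b) a
    degree-sorted greedy match. Remaining positions filled randomly.
    """
    perms = np.empty((pop, prob.n2), dtype=np.intp)
    for i in range(pop):
        perms[i] = rng.permutation(prob.n2)

    seeds: list[np.ndarray] = []
    if label_seeding:
        shared = [v for v in prob.nodes1 if v in prob.idx2]
        if shared:
            prefix = np.full(prob.n1, -1, dtype=np.intp)
            used = set()
            for i, v in enumerate(prob.nodes1):
                if v in prob.idx2:
                    prefix[i] = prob.idx2[v]
                    used.add(prob.idx2[v])
            free = [j for j in range(prob.n2) if j not in used]
            for _ in range(min(3, pop // 2 if pop >= 6 else 1)):
                fill = rng.permutation(len(free))
                p = prefix.copy()
                k = 0
                for i in range(prob.n1):
                    if p[i] < 0:
                        p[i] = free[fill[k]]
                        k += 1
                tail = [free[fill[j]] for j in range(k, len(free))]
                seeds.append(np.concatenate([p, np.asarray(tail, dtype=np.intp)]))
    order1 = np.argsort(-prob.deg1, kind="stable")
    order2 = np.argsort(-prob.deg2, kind="stable")
    greedy = np.empty(prob.n2, dtype=np.intp)
    inv = np.empty(prob.n1, dtype=np.intp)
    inv[order1] = np.arange(prob.n1)
    greedy[: prob.n1] = order2[inv]
    greedy[prob.n1 :] = order2[prob.n1 :]
    seeds.append(greedy)

    for i, s in enumerate(seeds[: max(0, pop - 1)]):
        perms[i] = s
    return perms


def _local_search(prob: _Problem, perm: np.ndarray, max_passes: int = 20) -> tuple[np.ndarray, float]:
    """First-improvement hill climbing over position swaps.

    Considers swaps of two mapped positions and swaps of a mapped with
    an unmapped position; repeats passes until no swap improves S^3 or
    the pass budget is exhausted.
    """
    perm = perm.copy()
    score = prob.s3_single(perm)
    n1, n2 = prob.n1, prob.n2
    for _ in range(max_passes):
        improved = False
        for i in range(n1):
            for j in range(i + 1, n2):
                perm[i], perm[j] = perm[j], perm[i]
                s = prob.s3_single(perm)
                if s > score + 1e-12:
                    score = s
                    improved = True
                else:
                    perm[i], perm[j] = perm[j], perm[i]
        if not improved or score >= 1.0:
            break
    return perm, score


@dataclass
class GAResult:
    alignment: Alignment
    trace: list[float] = field(default_factory=list)  # best S^3 per generation


def ga_align(G1: nx.Graph, G2: nx.Graph, params: GAParams) -> GAResult:
    """Run the memetic GA once; deterministic given ``params.seed``.

    With elitism the best-so-far S^3 recorded in the trace is
    non-decreasing. The search stops early once a perfect score is
    reached, or after ``params.patience`` generations without
    improvement when patience is set.
    """
    prob = _Problem(G1, G2)
    rng = np.random.default_rng(params.seed)
    pop = params.population_size
    n_elite = max(1, int(params.elite_fraction * pop))

    perms = _seed_perms(prob, pop, rng, params.label_seeding)
    fitness_fn = (
        prob.s3_batch if params.objective == "edge_s3" else prob.node_conservation_batch
    )

    best_perm = perms[0].copy()
    best_s3 = prob.s3_single(best_perm)
    trace: list[float] = []
    stall = 0

    for gen in range(params.generations):
        fitness = fitness_fn(perms)
        s3s = fitness if params.objective == "edge_s3" else prob.s3_batch(perms)
        order = np.argsort(-fitness, kind="stable")
        perms = perms[order]
        s3s = s3s[order]

        gen_best = int(np.argmax(s3s))
        if s3s[gen_best] > best_s3 + 1e-12:
            best_s3 = float(s3s[gen_best])
            best_perm = perms[gen_best].copy()
            stall = 0
        else:
            stall += 1

        small = prob.n2 <= 15
        interval = 1 if small else params.local_search_interval
        if interval and (gen % interval == 0 or gen == params.generations - 1):
            # refine the incumbent plus, on small problems, random restarts
            # to escape shallow swap-local optima
            starts = [perms[0]]
            if small:
                starts.append(perms[int(rng.integers(0, pop))])
                starts.append(rng.permutation(prob.n2).astype(np.intp))
            for k_start, start in enumerate(starts):
                refined, s = _local_search(prob, start)
                if s > best_s3 + 1e-12:
                    best_s3, best_perm = s, refined.copy()
                    stall = 0
                perms[min(n_elite, pop - 1) - 1 - k_start] = refined

        trace.append(best_s3)
        if best_s3 >= 1.0:
            break
        if params.patience is not None and stall >= params.patience:
            break

        children = np.empty_like(perms[n_elite:])
        parents = rng.integers(0, n_elite, size=(len(children), 2))
        for k in range(len(children)):
            child = _cycle_crossover(perms[parents[k, 0]], perms[parents[k, 1]], rng)
            if rng.random() < params.mutation_rate:
                i, j = rng.integers(0, prob.n2, size=2)
                child[i], child[j] = child[j], child[i]
            children[k] = child
        perms[n_elite:] = children

    refined, s = _local_search(prob, best_perm)
    if s > best_s3:
        best_s3, best_perm = s, refined
        trace.append(best_s3)
    return GAResult(alignment=prob.to_alignment(best_perm, G1, G2), trace=trace)


@dataclass
class ReplicatedAlignment:
    scores: list[float]
    mean: float
    sd: float
    best: Alignment


def align_replicated(G1: nx.Graph, G2: nx.Graph, params: GAParams) -> ReplicatedAlignment:
    """Average the stochastic search over ``params.n_runs`` independent runs.

    Run seeds are spawned deterministically from ``params.seed``. The SD
    is the sample standard deviation over runs (0 when n_runs = 1); the
    best alignment is the highest-scoring run, first run on ties.
    """
    scores: list[float] = []
    best: Optional[Alignment] = None
    root = np.random.SeedSequence(params.seed)
    for child in root.spawn(params.n_runs):
        run_params = GAParams(
            population_size=params.population_size,
            generations=params.generations,
            elite_fraction=params.elite_fraction,
            n_runs=1,
            seed=int(child.generate_state(1)[0] % (2**31)),
            objective=params.objective,
            mutation_rate=params.mutation_rate,
            local_search_interval=params.local_search_interval,
            patience=params.patience,
            label_seeding=params.label_seeding,
        )
        result = ga_align(G1, G2, run_params)
        scores.append(result.alignment.s3)
        if best is None or result.alignment.s3 > best.s3:
            best = result.alignment
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    assert best is not None
    return ReplicatedAlignment(scores=scores, mean=mean, sd=sd, best=best)


def write_alignment(alignment: Alignment, path, params: Optional[GAParams] = None) -> None:
    """Write the node map as TSV with header comments recording the score."""
    deg = {}
    for e in alignment.conserved_edges:
        for v in e:
            deg[v] = deg.get(v, 0) + 1
    with open(path, "w") as fh:
        fh.write(f"# s3={alignment.s3!r}\n")
        if params is not None:
            fh.write(
                f"# pop={params.population_size} gens={params.generations} "
                f"elite={params.elite_fraction} runs={params.n_runs} seed={params.seed}\n"
            )
        fh.write("g1_node\tg2_node\tconserved_degree\n")
        for v in alignment.g1_nodes:
            fh.write(f"{v}\t{alignment.mapping[v]}\t{deg.get(v, 0)}\n")
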