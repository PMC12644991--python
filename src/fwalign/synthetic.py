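"""Synthetic control/drought web pairs with known ground truth.

The control webs are niche-model food webs: every species receives a
niche value in [0, 1], a feeding range drawn to hit a target
connectance, and a range centre below its own niche value; it eats
every species inside its range. Basal species are relabelled into
detrital and producer roles, body mass increases stochastically with
niche value, and per-link biomass fluxes are lognormal.

The drought perturbation encodes the turnover structure the pipeline
is meant to detect: a sampled number of consumer extinctions, random
loss of surviving consumers' links, degree-dependent rewiring
(specialists — low-degree consumers — rewire proportionally more when
``specialist_bias`` is positive), a few invading consumers, and
down-scaled fluxes. Rewired links are drawn preferentially toward
resources that already support many consumers, which raises the
interconnectedness of surviving consumers. Every stochastic choice is
recorded in a ground-truth record so downstream classification and
regression can be validated exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .foodweb import FoodWeb, SpeciesRecord, TrophicLink
from .io import write_foodweb


logger = logging.getLogger(__name__)


class GeneratorError(RuntimeError):
    pass


@dataclass
class GeneratorParams:
    """Study-level generator settings.

    Defaults emulate the reference dataset's scale: webs of 74 trophic
    elements with roughly 98 directed links each (eight webs pooling to
    roughly 783 links), four control/drought pairs, 92% of drought
    species shared with the control, 60% of drought links conserved,
    and 13 +/- 1.9 consumer extinctions per web. ``specialist_bias``
    controls how steeply the probability of rewiring falls with control
    degree (0 = uniform); ``n_invaders=None`` derives the invader count
    from ``p_species_survival``.
    """

    S: int = 74
    C_target: float = 98 / 74**2
    n_pairs: int = 4
    p_species_survival: float = 0.92
    p_link_conserved: float = 0.60
    n_consumer_extinctions_mean: float = 13.0
    n_consumer_extinctions_sd: float = 1.9
    specialist_bias: float = 1.0
    p_link_drop: float = 0.30
    n_invaders: Optional[int] = None
    flux_scale_drought: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 10:
            raise GeneratorError("S must be >= 10")
        for name in ("p_species_survival", "p_link_conserved", "p_link_drop"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise GeneratorError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.C_target < 0.5:
            raise GeneratorError("C_target must be in (0, 0.5)")
        if self.specialist_bias < 0:
            raise GeneratorError("specialist_bias must be >= 0")


@dataclass
class GroundTruth:
    survivor_map: dict[str, str]
    extinct: frozenset[str]
    invaders: frozenset[str]
    rewired: frozenset[tuple[str, str]]
    rewiring_weights: dict[str, float]
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticPair:
    control: FoodWeb
    drought: FoodWeb
    truth: GroundTruth


# ----------------------------------------------------------------------
# Niche-model control webs


def _sample_niche_links(S: int, C: float, rng: np.random.Generator):
    niche = np.sort(rng.uniform(0, 1, size=S))
    beta = 1.0 / (2.0 * C) - 1.0
    ranges = niche * rng.beta(1.0, beta, size=S)
    centres = rng.uniform(ranges / 2.0, np.minimum(niche, 1.0 - ranges / 2.0))
    links = []
    for i in range(S):
        lo, hi = centres[i] - ranges[i] / 2.0, centres[i] + ranges[i] / 2.0
        for j in range(S):
            if j != i and lo <= niche[j] <= hi:  # cannibalism excluded
                links.append((j, i))
    return niche, links


def niche_model_web(
    S: int,
    C_target: float,
    seed: int = 0,
    web_id: str = "web",
    treatment: str = "control",
    block: int = 1,
    max_attempts: int = 100,
) -> FoodWeb:
    """Draw one niche-model web with roles, masses, and fluxes.

    Draws are retried (up to ``max_attempts``) until the web has at
    least one consumer, at least two basal species (for the two
    detrital entries), and realized connectance within +/-20% of the
    target. Sparse draws are frequently disconnected; instead of
    rejecting those outright, each minor component is reattached by one
    extra link into a main-component consumer (a rare feeding link),
    provided connectance stays inside the tolerance band.
    """
    root = np.random.SeedSequence(seed)
    for attempt_seq in root.spawn(max_attempts):
        rng = np.random.default_rng(attempt_seq)
        niche, links = _sample_niche_links(S, C_target, rng)

        consumers = {c for (_, c) in links}
        basal = [i for i in range(S) if i not in consumers]
        if not consumers or len(basal) < 2:
            continue

        # reattach minor components through one extra link each
        adj: dict[int, set[int]] = {i: set() for i in range(S)}
        for r, c in links:
            adj[r].add(c)
            adj[c].add(r)
        seen: set[int] = set()
        components: list[list[int]] = []
        for i in range(S):
            if i in seen:
                continue
            stack, comp = [i], []
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                comp.append(v)
                stack.extend(adj[v])
            components.append(sorted(comp))
        components.sort(key=len, reverse=True)
        main = set(components[0])
        main_consumers = sorted(main & consumers)
        if not main_consumers:
            continue
        max_links = int(1.2 * C_target * S * S)
        unrepaired = 0
        for comp in components[1:]:
            if len(links) >= max_links:
                unrepaired += 1
                continue
            resource = min(comp, key=lambda v: niche[v])
            consumer = int(rng.choice(main_consumers))
            links.append((resource, consumer))
            main |= set(comp)
        if unrepaired:
            logger.warning(
                "web %s: %d component(s) left disconnected — full connectivity "
                "needs more links than the connectance band allows",
                web_id, unrepaired,
            )

        L = len(links)
        realized_C = L / S**2
        if not (0.8 * C_target <= realized_C <= 1.2 * C_target):
            continue

        ids = [f"sp{i + 1:02d}" for i in range(S)]
        log_mass = rng.normal(6.0 * niche, 0.5)
        species = []
        n_decomposers = min(2, len(basal) - 2)
        for rank, i in enumerate(sorted(basal, key=lambda v: niche[v])):
            if rank < 2:
                role, mass = "detritus", None
            elif rank < 2 + n_decomposers:
                role, mass = "decomposer", float(np.exp(log_mass[i]))
            else:
                role, mass = "primary_producer", float(np.exp(log_mass[i]))
            species.append(SpeciesRecord(ids[i], name=f"taxon {ids[i]}",
                                         functional_role=role, body_mass=mass))
        cons_sorted = sorted(consumers, key=lambda v: niche[v])
        third = max(1, math.ceil(len(cons_sorted) / 3))
        for rank, i in enumerate(cons_sorted):
            role = ("detritivore", "herbivore", "predator")[min(rank // third, 2)]
            species.append(SpeciesRecord(ids[i], name=f"taxon {ids[i]}",
                                         functional_role=role,
                                         body_mass=float(np.exp(log_mass[i]))))

        link_records = [
            TrophicLink(ids[r], ids[c], flux=float(rng.lognormal(-1.0, 1.0)))
            for (r, c) in sorted(links)
        ]
        return FoodWeb(web_id=web_id, treatment=treatment, block=block,
                       species=species, links=link_records)
    raise GeneratorError(
        f"no acceptable niche-model draw in {max_attempts} attempts "
        f"(S={S}, C_target={C_target})"
    )


# ----------------------------------------------------------------------
# Drought perturbation


def apply_drought(
    control: FoodWeb,
    params: GeneratorParams,
    seed: int = 0,
    web_id: Optional[str] = None,
) -> SyntheticPair:
    """Perturb a control web into its drought counterpart, with truth.

    Steps: (i) sampled consumer extinctions; (ii) independent loss of
    surviving links; (iii) degree-dependent rewiring sized so the
    expected share of drought links that are conserved equals
    ``p_link_conserved``; (iv) invading consumers; (v) flux rescaling.
    """
    rng = np.random.default_rng(seed)
    consumers = sorted(control.consumer_ids())
    n_ext = int(np.clip(round(rng.normal(params.n_consumer_extinctions_mean,
                                         params.n_consumer_extinctions_sd)),
                        1, None))
    if n_ext >= len(consumers):
        raise GeneratorError(
            f"extinction request ({n_ext}) >= consumer count ({len(consumers)})"
        )
    extinct = {str(s) for s in rng.choice(consumers, size=n_ext, replace=False)}
    survivors = [sid for sid in control.species if sid not in extinct]
    survivor_set = set(survivors)

    # (ii) link loss among survivors
    conserved: list[TrophicLink] = []
    for link in control.links.values():
        if link.resource_id in survivor_set and link.consumer_id in survivor_set:
            if rng.random() >= params.p_link_drop:
                conserved.append(link)

    # (iv) invaders (count first, links after rewiring targets are known)
    n_surviving_nodes = len(survivors)
    if params.n_invaders is None:
        p = params.p_species_survival
        n_inv = int(round(n_surviving_nodes * (1.0 - p) / p))
    else:
        n_inv = params.n_invaders
    invader_ids = [f"inv{k + 1:02d}" for k in range(n_inv)]

    invader_diets: dict[str, set[str]] = {}
    drought_consumers_of: dict[str, set[str]] = {sid: set() for sid in survivors}
    for link in conserved:
        drought_consumers_of[link.resource_id].add(link.consumer_id)

    def preferential_resource(exclude: set[str]) -> Optional[str]:
        candidates = [s for s in survivors if s not in exclude]
        if not candidates:
            return None
        weights = np.array(
            [1.0 + len(drought_consumers_of[s]) for s in candidates], dtype=float
        )
        return str(rng.choice(candidates, p=weights / weights.sum()))

    n_invader_links = 0
    for inv in invader_ids:
        diet_size = 1 + int(rng.poisson(1.0))
        diet: set[str] = set()
        for _ in range(diet_size):
            pick = preferential_resource(diet | {inv})
            if pick is None:
                break
            diet.add(pick)
            drought_consumers_of[pick].add(inv)
        invader_diets[inv] = diet
        n_invader_links += len(diet)

    # (iii) rewiring sized to hit the conserved-link share in expectation
    n_conserved = len(conserved)
    target_new = round(n_conserved * (1.0 - params.p_link_conserved)
                       / params.p_link_conserved)
    n_rewired_target = max(0, int(target_new) - n_invader_links)

    surviving_consumers = sorted(
        set(consumers) - extinct, key=lambda s: s
    )
    # per-link rewiring propensity ~ degree^(-bias): each *surviving* diet
    # link of consumer i is a rewiring opportunity, so the consumer-level
    # event rate is (surviving diet size) * degree^(-bias). At bias = 0 the
    # expected rewired count is proportional to the drought diet that forms
    # the denominator of prop_rewired, leaving the proportion flat in
    # degree; bias > 0 makes specialists rewire proportionally more.
    drought_diet: dict[str, set[str]] = {sid: set() for sid in surviving_consumers}
    for link in conserved:
        drought_diet.setdefault(link.consumer_id, set()).add(link.resource_id)
    control_pairs = control.link_pairs()

    control_degree = {sid: len(control.diet(sid)) for sid in surviving_consumers}
    weights = np.array(
        [max(1, len(drought_diet[sid]))
         * control_degree[sid] ** (-params.specialist_bias)
         for sid in surviving_consumers],
        dtype=float,
    )
    weight_map = {sid: float(w) for sid, w in zip(surviving_consumers, weights)}

    rewired: set[tuple[str, str]] = set()
    attempts = 0
    while len(rewired) < n_rewired_target and attempts < 50 * (n_rewired_target + 1):
        attempts += 1
        consumer = str(rng.choice(surviving_consumers,
                                  p=weights / weights.sum()))
        exclude = drought_diet[consumer] | {consumer}
        exclude |= {r for (r, c) in control_pairs if c == consumer}
        resource = preferential_resource(exclude)
        if resource is None:
            continue
        rewired.add((resource, consumer))
        drought_diet[consumer].add(resource)
        drought_consumers_of[resource].add(consumer)

    # assemble the drought web
    scale = params.flux_scale_drought
    links: list[TrophicLink] = [
        TrophicLink(l.resource_id, l.consumer_id,
                    flux=None if l.flux is None else l.flux * scale)
        for l in conserved
    ]
    for (r, c) in sorted(rewired):
        links.append(TrophicLink(r, c, flux=float(rng.lognormal(-1.0, 1.0)) * scale))
    for inv in invader_ids:
        for r in sorted(invader_diets[inv]):
            links.append(TrophicLink(r, inv, flux=float(rng.lognormal(-1.0, 1.0)) * scale))

    # survivors may have lost their whole diet; leave the consumer flag to
    # be recomputed from the drought link table
    species = [
        SpeciesRecord(rec.species_id, rec.name, rec.functional_role, rec.body_mass)
        for rec in (control.species[sid] for sid in survivors)
    ]
    for inv in invader_ids:
        species.append(SpeciesRecord(
            inv, name=f"invader {inv}",
            functional_role=str(rng.choice(["detritivore", "herbivore", "predator"])),
            body_mass=float(rng.lognormal(2.0, 1.0)),
        ))

    drought = FoodWeb(
        web_id=web_id or f"{control.web_id}_drought",
        treatment="drought",
        block=control.block,
        species=species,
        links=links,
    )
    truth = GroundTruth(
        survivor_map={sid: sid for sid in survivors},
        extinct=frozenset(extinct),
        invaders=frozenset(invader_ids),
        rewired=frozenset(rewired),
        rewiring_weights=weight_map,
        params={"seed": int(seed), "n_extinct": n_ext, "n_invaders": n_inv},
    )
    return SyntheticPair(control=control, drought=drought, truth=truth)


# ----------------------------------------------------------------------
# Whole-study generation


def generate_study(
    params: GeneratorParams, outdir: Optional[Path] = None
) -> tuple[list[SyntheticPair], dict]:
    """Generate ``n_pairs`` control/drought pairs plus a manifest.

    With ``outdir`` set, webs are written under ``webs/`` in the node
    and link table formats, ground truth under ``truth/``, and the
    manifest (parameters and derived seeds) as ``manifest.yaml``;
    regeneration from the same parameters is byte-identical.
    """
    root = np.random.SeedSequence(params.seed)
    pairs: list[SyntheticPair] = []
    pair_seeds: list[tuple[int, int]] = []
    for b, child in enumerate(root.spawn(params.n_pairs), start=1):
        s_web, s_drought = (int(x) for x in child.generate_state(2) % (2**31))
        control = niche_model_web(
            params.S, params.C_target, seed=s_web,
            web_id=f"C{b}", treatment="control", block=b,
        )
        pair = apply_drought(control, params, seed=s_drought, web_id=f"D{b}")
        pairs.append(pair)
        pair_seeds.append((s_web, s_drought))

    manifest = {
        "params": {
            "S": params.S,
            "C_target": params.C_target,
            "n_pairs": params.n_pairs,
            "p_species_survival": params.p_species_survival,
            "p_link_conserved": params.p_link_conserved,
            "n_consumer_extinctions_mean": params.n_consumer_extinctions_mean,
            "n_consumer_extinctions_sd": params.n_consumer_extinctions_sd,
            "specialist_bias": params.specialist_bias,
            "p_link_drop": params.p_link_drop,
            "n_invaders": params.n_invaders,
            "flux_scale_drought": params.flux_scale_drought,
            "seed": params.seed,
        },
        "pair_seeds": [list(s) for s in pair_seeds],
        "webs": [
            {"block": p.control.block, "control": p.control.web_id,
             "drought": p.drought.web_id}
            for p in pairs
        ],
    }

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "webs").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        for pair in pairs:
            for web in (pair.control, pair.drought):
                write_foodweb(
                    web,
                    outdir / "webs" / f"{web.web_id}_nodes.csv",
                    outdir / "webs" / f"{web.web_id}_links.csv",
                )
            truth_doc = {
                "survivors": sorted(pair.truth.survivor_map),
                "extinct": sorted(pair.truth.extinct),
                "invaders": sorted(pair.truth.invaders),
                "rewired": sorted(list(e) for e in pair.truth.rewired),
                "rewiring_weights": {
                    k: float(v) for k, v in sorted(pair.truth.rewiring_weights.items())
                },
                "params": pair.truth.params,
            }
            with open(outdir / "truth" / f"pair{pair.control.block}.yaml", "w") as fh:
                yaml.safe_dump(truth_doc, fh, sort_keys=True)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return pairs, manifest
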