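"""Data model for node-attributed trophic networks.

A food web is a directed network whose links point from a resource to the
consumer that eats it, optionally weighted by biomass flux (g m^-2 yr^-1).
Nodes are "trophic elements": living species plus non-living resource
classes such as amorphous detritus. Topological comparison between webs
is done on the derived undirected simple graph, so cannibalistic
self-loops are kept in the directed data model but excluded from that
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

logger = logging.getLogger(__name__)

#: Roles that do not consume any live organisms or materials.
RESOURCE_ROLES = frozenset({"detritus", "decomposer", "primary_producer"})
#: Invertebrate consumer roles.
CONSUMER_ROLES = frozenset({"detritivore", "herbivore", "predator"})
FUNCTIONAL_ROLES = RESOURCE_ROLES | CONSUMER_ROLES

TREATMENTS = ("control", "drought")


class FoodWebError(ValueError):
    """Raised when a web violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One trophic element.

    ``body_mass`` may be missing (None) only for detritus, which has no
    recorded body mass. ``is_consumer`` is True iff the species has at
    least one resource link in its web; it is recomputed on web
    construction.
    """

    species_id: str
    name: str = ""
    functional_role: str = "predator"
    body_mass: Optional[float] = None
    is_consumer: bool = False

    def __post_init__(self) -> None:
        if self.functional_role not in FUNCTIONAL_ROLES:
            raise FoodWebError(
                f"species {self.species_id!r}: unknown functional_role "
                f"{self.functional_role!r}; expected one of {sorted(FUNCTIONAL_ROLES)}"
            )
        if self.body_mass is not None and not self.body_mass > 0:
            raise FoodWebError(
                f"species {self.species_id!r}: body_mass must be positive, "
                f"got {self.body_mass}"
            )
        if self.body_mass is None and self.functional_role != "detritus":
            raise FoodWebError(
                f"species {self.species_id!r}: missing body_mass is allowed "
                f"only for detritus (role={self.functional_role!r})"
            )


@dataclass(frozen=True)
class TrophicLink:
    """A directed resource -> consumer feeding link with optional flux."""

    resource_id: str
    consumer_id: str
    flux: Optional[float] = None

    def __post_init__(self) -> None:
        if self.flux is not None and self.flux < 0:
            raise FoodWebError(
                f"link {self.resource_id}->{self.consumer_id}: flux must be "
                f"non-negative, got {self.flux}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.resource_id, self.consumer_id)


class FoodWeb:
    """A validated food web: species set plus directed trophic links.

    ``is_consumer`` flags on the stored records are recomputed from the
    link table (a consumer is a node with at least one resource); a
    conflicting flag supplied by the caller triggers a warning and is
    overridden. Resource-role species (detritus, decomposers, primary
    producers) must not appear as consumers.
    """

    def __init__(
        self,
        web_id: str,
        treatment: str,
        block: int,
        species: Iterable[SpeciesRecord],
        links: Iterable[TrophicLink],
    ) -> None:
        if treatment not in TREATMENTS:
            raise FoodWebError(
                f"web {web_id!r}: treatment must be one of {TREATMENTS}, got {treatment!r}"
            )
        self.web_id = str(web_id)
        self.treatment = treatment
        self.block = int(block)

        self.species: dict[str, SpeciesRecord] = {}
        for rec in species:
            if rec.species_id in self.species:
                raise FoodWebError(
                    f"web {web_id!r}: duplicate species_id {rec.species_id!r}"
                )
            self.species[rec.species_id] = rec
        if not self.species:
            raise FoodWebError(f"web {web_id!r}: species set is empty")

        self.links: dict[tuple[str, str], TrophicLink] = {}
        for link in links:
            for endpoint, kind in ((link.resource_id, "resource"), (link.consumer_id, "consumer")):
                if endpoint not in self.species:
                    raise FoodWebError(
                        f"web {web_id!r}: link {link.resource_id}->{link.consumer_id} "
                        f"references unknown {kind} id {endpoint!r}"
                    )
            if link.pair in self.links:
                raise FoodWebError(
                    f"web {web_id!r}: duplicate link {link.resource_id}->{link.consumer_id}"
                )
            self.links[link.pair] = link

        consumers = {c for (_, c) in self.links}
        fixed: dict[str, SpeciesRecord] = {}
        for sid, rec in self.species.items():
            is_consumer = sid in consumers
            if is_consumer and rec.functional_role in RESOURCE_ROLES:
                raise FoodWebError(
                    f"web {web_id!r}: species {sid!r} has role "
                    f"{rec.functional_role!r} but consumes other species"
                )
            if rec.is_consumer != is_consumer:
                if rec.is_consumer:  # only warn on an explicit wrong flag
                    logger.warning(
                        "web %r: is_consumer flag for %r disagrees with the "
                        "link table; recomputed value %s is used",
                        web_id, sid, is_consumer,
                    )
                fixed[sid] = SpeciesRecord(
                    species_id=rec.species_id,
                    name=rec.name,
                    functional_role=rec.functional_role,
                    body_mass=rec.body_mass,
                    is_consumer=is_consumer,
                )
        self.species.update(fixed)

    # ------------------------------------------------------------------
    @property
    def S(self) -> int:
        """Number of trophic elements."""
        return len(self.species)

    @property
    def L(self) -> int:
        """Number of directed trophic links (self-loops included)."""
        return len(self.links)

    @property
    def connectance(self) -> float:
        """Directed connectance L / S^2."""
        return self.L / self.S**2

    def consumer_ids(self) -> set[str]:
        return {sid for sid, rec in self.species.items() if rec.is_consumer}

    def resource_ids(self) -> set[str]:
        return {sid for sid, rec in self.species.items() if not rec.is_consumer}

    def diet(self, consumer_id: str) -> set[str]:
        """Resource ids consumed by ``consumer_id``."""
        return {r for (r, c) in self.links if c == consumer_id}

    def link_pairs(self) -> set[tuple[str, str]]:
        return set(self.links)

    def has_fluxes(self) -> bool:
        return all(l.flux is not None for l in self.links.values()) and bool(self.links)

    def total_flux(self) -> Optional[float]:
        if not self.has_fluxes():
            return None
        return sum(l.flux for l in self.links.values())

    # ------------------------------------------------------------------
    def to_undirected(self) -> nx.Graph:
        """Project onto the undirected simple graph used for alignment.

        An edge {u, v} is present iff a trophic link exists in either
        direction. Cannibalistic self-loops are dropped with a warning.
        """
        G = nx.Graph()
        G.add_nodes_from(self.species)
        for (r, c) in self.links:
            if r == c:
                logger.warning(
                    "web %r: cannibalistic link %s->%s excluded from the "
                    "undirected projection", self.web_id, r, c,
                )
                continue
            G.add_edge(r, c)
        return G

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return (
            self.web_id == other.web_id
            and self.treatment == other.treatment
            and self.block == other.block
            and self.species == other.species
            and self.links == other.links
        )

    def __repr__(self) -> str:
        return (
            f"FoodWeb({self.web_id!r}, {self.treatment!r}, block={self.block}, "
            f"S={self.S}, L={self.L})"
        )


@dataclass
class WebSummary:
    web_id: str
    S: int
    L: int
    connectance: float
    n_consumers: int
    n_resources: int
    total_flux: Optional[float] = field(default=None)


def web_summary(web: FoodWeb) -> WebSummary:
    """Headline descriptors: size, links, connectance, consumer split."""
    n_cons = len(web.consumer_ids())
    return WebSummary(
        web_id=web.web_id,
        S=web.S,
        L=web.L,
        connectance=web.connectance,
        n_consumers=n_cons,
        n_resources=web.S - n_cons,
        total_flux=web.total_flux(),
    )
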