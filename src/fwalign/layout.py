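"""Aligned binary matrices for a control/perturbed web pair.

Control species are ordered deterministically into four sub-groups —
aligned-survived, aligned-extinct, non-aligned-survived,
non-aligned-extinct — with resources before consumers inside each
sub-group. Resources run detritus (no recorded body mass, so the two
detrital classes occupy the first entries), then decomposers, then
primary producers by ascending body mass; consumers run detritivores,
herbivores, predators, each by ascending body mass. Each perturbed-web
species is then placed at the matrix entry of its aligned control
counterpart, so the two binary matrices can be overlaid cell by cell;
perturbed-web species with no aligned counterpart (including invaders)
are appended after all control positions in ascending degree order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import Alignment
from .foodweb import FoodWeb
from .rewiring import LinkClassification

logger = logging.getLogger(__name__)

_ROLE_ORDER = {
    "detritus": 0,
    "decomposer": 1,
    "primary_producer": 2,
    "detritivore": 3,
    "herbivore": 4,
    "predator": 5,
}


@dataclass
class MatrixLayout:
    ordered_control_ids: list[str]
    ordered_drought_ids: list[Optional[str]]  # None = no aligned counterpart
    group_labels: list[str]  # per control position
    appended_drought_ids: list[str]  # unmatched drought species, tail order


def _control_drought_pairs(
    control: FoodWeb, drought: FoodWeb, alignment: Alignment
) -> dict[str, str]:
    """Map control node -> aligned drought node, whichever side was G1."""
    vc, vd = set(control.species), set(drought.species)
    domain, image = set(alignment.mapping), alignment.image()
    if domain <= vd and image <= vc:
        return {c: d for d, c in alignment.mapping.items()}
    if domain <= vc and image <= vd:
        return dict(alignment.mapping)
    raise ValueError("alignment does not connect the given control/drought pair")


def _species_sort_key(web: FoodWeb, ascending_mass: bool = True):
    warned = []

    def key(sid: str):
        rec = web.species[sid]
        role = _ROLE_ORDER[rec.functional_role]
        if rec.body_mass is None and rec.functional_role != "detritus":
            if sid not in warned:
                logger.warning(
                    "species %r lacks body mass; ordering falls back to id", sid
                )
                warned.append(sid)
            return (role, 1, 0.0, sid)
        mass = rec.body_mass if rec.body_mass is not None else 0.0
        if not ascending_mass:
            mass = -mass
        return (role, 0, mass, sid)

    return key


def order_control_species(
    control: FoodWeb,
    drought: FoodWeb,
    alignment: Alignment,
    ascending_mass: bool = True,
) -> MatrixLayout:
    """Deterministic matrix ordering for a pair; a pure function of inputs."""
    pairs = _control_drought_pairs(control, drought, alignment)
    vd = set(drought.species)
    aligned = set(pairs)
    key = _species_sort_key(control, ascending_mass)

    ordered: list[str] = []
    labels: list[str] = []
    for aligned_flag, group in ((True, "aligned"), (False, "non-aligned")):
        for survived_flag, fate in ((True, "survived"), (False, "extinct")):
            members = [
                sid for sid in control.species
                if (sid in aligned) == aligned_flag and (sid in vd) == survived_flag
            ]
            for sid in sorted(members, key=key):
                ordered.append(sid)
                side = "consumer" if control.species[sid].is_consumer else "resource"
                labels.append(f"{group}-{fate}/{side}")

    drought_row: list[Optional[str]] = [pairs.get(sid) for sid in ordered]
    placed = {d for d in drought_row if d is not None}
    Gd = drought.to_undirected()
    tail = sorted(vd - placed, key=lambda s: (Gd.degree(s), s))
    return MatrixLayout(
        ordered_control_ids=ordered,
        ordered_drought_ids=drought_row,
        group_labels=labels,
        appended_drought_ids=tail,
    )


def binary_matrices(
    layout: MatrixLayout, control: FoodWeb, drought: FoodWeb
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric 0/1 adjacency matrices in layout order.

    Both matrices share the position index: entry i of the perturbed
    matrix holds the species aligned to the control species at entry i,
    with unmatched perturbed species in the appended tail positions.
    """
    n_c = len(layout.ordered_control_ids)
    n = n_c + len(layout.appended_drought_ids)
    Gc = control.to_undirected()
    Gd = drought.to_undirected()

    Mc = np.zeros((n, n), dtype=np.int8)
    pos_c = {sid: i for i, sid in enumerate(layout.ordered_control_ids)}
    for u, v in Gc.edges:
        i, j = pos_c[u], pos_c[v]
        Mc[i, j] = Mc[j, i] = 1

    Md = np.zeros((n, n), dtype=np.int8)
    pos_d = {
        sid: i for i, sid in enumerate(layout.ordered_drought_ids) if sid is not None
    }
    pos_d.update(
        {sid: n_c + k for k, sid in enumerate(layout.appended_drought_ids)}
    )
    for u, v in Gd.edges:
        i, j = pos_d[u], pos_d[v]
        Md[i, j] = Md[j, i] = 1
    return Mc, Md


def matrix_long_table(
    layout: MatrixLayout,
    control: FoodWeb,
    drought: FoodWeb,
    cls: Optional[LinkClassification] = None,
) -> pd.DataFrame:
    """Long-format (row, col, web, value, link_class) cells for plotting.

    One row per undirected edge of each web (upper triangle of the
    corresponding binary matrix), annotated with the link class of the
    underlying directed link when a classification is supplied.
    """
    n_c = len(layout.ordered_control_ids)
    pos_c = {sid: i for i, sid in enumerate(layout.ordered_control_ids)}
    pos_d = {
        sid: i for i, sid in enumerate(layout.ordered_drought_ids) if sid is not None
    }
    pos_d.update({sid: n_c + k for k, sid in enumerate(layout.appended_drought_ids)})

    def klass(web: FoodWeb, u: str, v: str) -> str:
        if cls is None:
            return ""
        for (r, c) in ((u, v), (v, u)):
            if (r, c) in web.links:
                for label, links in (
                    ("conserved", cls.conserved),
                    ("lost", cls.lost),
                    ("rewired", cls.rewired),
                    ("invader", cls.invader_links),
                ):
                    if (r, c) in links:
                        return label
        return ""

    rows = []
    for web, pos, tag in ((control, pos_c, "control"), (drought, pos_d, "drought")):
        for u, v in web.to_undirected().edges:
            i, j = sorted((pos[u], pos[v]))
            rows.append(
                {"row": i, "col": j, "web": tag, "value": 1,
                 "link_class": klass(web, u, v)}
            )
    return pd.DataFrame(rows, columns=["row", "col", "web", "value", "link_class"])
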