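"""Link classification and rewiring quantification across a web pair.

Species carry the same identifiers in both webs of a pair, so link
identity is the directed (resource, consumer) pair — the alignment is
needed only for topological comparison, not for matching links. Links
present only in the perturbed web are *rewired* when their consumer
survived from the control (a dietary shift) and *invader* links when
the consumer is new to the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .alignment import Alignment
from .foodweb import FoodWeb

LinkPair = tuple[str, str]


@dataclass
class TurnoverRecord:
    prop_shared_species: float
    prop_shared_links: float
    n_extinct_consumers: int
    n_invaders: int


@dataclass
class LinkClassification:
    """Partition of both webs' links.

    {conserved, rewired, invader_links} partitions the perturbed web's
    links; {conserved, lost} partitions the control web's links.
    """

    conserved: frozenset[LinkPair]
    lost: frozenset[LinkPair]
    rewired: frozenset[LinkPair]
    invader_links: frozenset[LinkPair]


def species_turnover(control: FoodWeb, drought: FoodWeb) -> TurnoverRecord:
    """Species and link overlap, consumer extinctions, and invaders.

    Shared proportions are relative to the perturbed (drought) web:
    the fraction of its species / directed links also present in the
    control. Extinct consumers are control consumers absent from the
    drought web; invaders are drought species absent from the control.
    """
    vc, vd = set(control.species), set(drought.species)
    ec, ed = control.link_pairs(), drought.link_pairs()
    return TurnoverRecord(
        prop_shared_species=len(vd & vc) / len(vd),
        prop_shared_links=(len(ed & ec) / len(ed)) if ed else 1.0,
        n_extinct_consumers=len(control.consumer_ids() - vd),
        n_invaders=len(vd - vc),
    )


def classify_links(control: FoodWeb, drought: FoodWeb) -> LinkClassification:
    ec, ed = control.link_pairs(), drought.link_pairs()
    vc = set(control.species)
    conserved = ec & ed
    lost = ec - ed
    drought_only = ed - ec
    rewired = {(r, c) for (r, c) in drought_only if c in vc}
    invader = drought_only - rewired
    return LinkClassification(
        conserved=frozenset(conserved),
        lost=frozenset(lost),
        rewired=frozenset(rewired),
        invader_links=frozenset(invader),
    )


def link_class_table(cls: LinkClassification) -> pd.DataFrame:
    """Long-format table of every link with its class label."""
    rows = []
    for label, links in (
        ("conserved", cls.conserved),
        ("lost", cls.lost),
        ("rewired", cls.rewired),
        ("invader", cls.invader_links),
    ):
        rows.extend(
            {"resource_id": r, "consumer_id": c, "link_class": label}
            for (r, c) in sorted(links)
        )
    return pd.DataFrame(rows, columns=["resource_id", "consumer_id", "link_class"])


def rewiring_per_species(
    control: FoodWeb,
    drought: FoodWeb,
    cls: Optional[LinkClassification] = None,
    metrics_c: Optional[pd.DataFrame] = None,
    metrics_d: Optional[pd.DataFrame] = None,
    denominator: str = "drought",
) -> pd.DataFrame:
    """Per-surviving-consumer rewiring tallies and metric changes.

    One row per consumer present in both webs with at least one drought
    diet link. ``prop_rewired`` divides the consumer's rewired-link
    count by its drought diet size (set ``denominator='control'`` for
    the control diet size instead). Metric deltas are drought minus
    control values when per-web metric tables are supplied.
    """
    if cls is None:
        cls = classify_links(control, drought)
    if denominator not in {"drought", "control"}:
        raise ValueError("denominator must be 'drought' or 'control'")

    survivors = control.consumer_ids() & drought.consumer_ids()
    rewired_by_consumer: dict[str, int] = {}
    for (_, c) in cls.rewired:
        rewired_by_consumer[c] = rewired_by_consumer.get(c, 0) + 1

    def metric_of(table: Optional[pd.DataFrame], sid: str, col: str) -> Optional[float]:
        if table is None:
            return None
        hit = table.loc[table["species_id"] == sid, col]
        return float(hit.iloc[0]) if len(hit) else None

    rows = []
    for sid in sorted(survivors):
        n_c = len(control.diet(sid))
        n_d = len(drought.diet(sid))
        if n_d == 0:
            continue
        n_rew = rewired_by_consumer.get(sid, 0)
        denom = n_d if denominator == "drought" else n_c
        row: dict[str, object] = {
            "species_id": sid,
            "n_links_control": n_c,
            "n_links_drought": n_d,
            "n_rewired": n_rew,
            "prop_rewired": n_rew / denom if denom else 0.0,
        }
        for name, col in (
            ("delta_degree", "degree"),
            ("delta_eigencentrality", "eigencentrality"),
            ("delta_pagerank", "pagerank"),
        ):
            mc = metric_of(metrics_c, sid, col)
            md = metric_of(metrics_d, sid, col)
            row[name] = (md - mc) if (mc is not None and md is not None) else None
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AlignedRegionSummary:
    connectance_whole_c: float
    connectance_aligned_c: float
    n_aligned: int
    total_flux_aligned_c: Optional[float]
    total_flux_d: Optional[float]


def aligned_region_summary(
    control: FoodWeb, drought: FoodWeb, alignment: Alignment
) -> AlignedRegionSummary:
    """Connectance and flux totals for the aligned region of the control.

    The aligned control nodes are those hit by the alignment (the image
    when the control is the larger graph, the domain when it is the
    smaller). Connectance of the region counts directed control links
    with both endpoints aligned, over k^2. Flux totals are reported only
    when every relevant link carries a flux.
    """
    vc = set(control.species)
    domain = set(alignment.mapping)
    image = alignment.image()
    if image <= vc:          # control is the larger graph G2 (usual case)
        aligned_c = image
    elif domain <= vc:       # control is the smaller graph G1
        aligned_c = domain
    else:
        aligned_c = (image | domain) & vc
    if not aligned_c:
        raise ValueError("alignment touches no control species")

    k = len(aligned_c)
    links_in_region = [
        l for l in control.links.values()
        if l.resource_id in aligned_c and l.consumer_id in aligned_c
    ]
    region_flux: Optional[float] = None
    if links_in_region and all(l.flux is not None for l in links_in_region):
        region_flux = sum(l.flux for l in links_in_region)
    return AlignedRegionSummary(
        connectance_whole_c=control.connectance,
        connectance_aligned_c=len(links_in_region) / k**2,
        n_aligned=k,
        total_flux_aligned_c=region_flux,
        total_flux_d=drought.total_flux(),
    )
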