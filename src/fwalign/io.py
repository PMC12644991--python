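"""Delimited-text I/O for food webs and analysis tables.

Node table columns: ``web_id, species_id, name, functional_role,
body_mass, is_consumer``. Link table columns: ``web_id, resource_id,
consumer_id, flux``. ``web_id`` is optional on input (used as a filter
when present); files with a ``.tsv`` extension are tab-delimited,
anything else comma-delimited. Body mass and flux are written with
Python's shortest round-tripping float representation, so a write/read
cycle preserves them exactly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .foodweb import FoodWeb, FoodWebError, SpeciesRecord, TrophicLink

PathLike = Union[str, Path]

NODE_COLUMNS = ["web_id", "species_id", "name", "functional_role", "body_mass", "is_consumer"]
LINK_COLUMNS = ["web_id", "resource_id", "consumer_id", "flux"]


def _sep(path: PathLike) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path: PathLike, required: list[str], optional: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FoodWebError(f"{path}: missing required column(s) {missing}")
    for col in optional:
        if col not in df.columns:
            df[col] = ""
    return df


def _opt_float(raw: str, what: str, row: int, path: PathLike) -> Optional[float]:
    raw = raw.strip()
    if raw == "" or raw.lower() in {"na", "nan", "none"}:
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise FoodWebError(f"{path} row {row}: bad {what} value {raw!r}") from exc
    if math.isnan(value):
        return None
    return value


def read_foodweb(
    node_table: PathLike,
    link_table: PathLike,
    web_id: Optional[str] = None,
    treatment: str = "control",
    block: int = 1,
) -> FoodWeb:
    """Read and validate one web from a node table and a link table.

    If ``web_id`` is given and the files carry a ``web_id`` column, only
    the matching rows are used; otherwise all rows are taken. Errors name
    the offending file row (1-based, excluding the header).
    """
    nodes = _read_table(node_table, ["species_id"], ["web_id", "name", "functional_role", "body_mass", "is_consumer"])
    links = _read_table(link_table, ["resource_id", "consumer_id"], ["web_id", "flux"])
    if web_id is not None:
        if nodes["web_id"].str.len().gt(0).any():
            nodes = nodes[nodes["web_id"] == str(web_id)]
        if links["web_id"].str.len().gt(0).any():
            links = links[links["web_id"] == str(web_id)]
    if nodes.empty:
        raise FoodWebError(f"{node_table}: no species rows for web {web_id!r}")

    species = []
    for idx, row in nodes.iterrows():
        try:
            species.append(
                SpeciesRecord(
                    species_id=row["species_id"].strip(),
                    name=row["name"].strip(),
                    functional_role=(row["functional_role"].strip() or "predator"),
                    body_mass=_opt_float(row["body_mass"], "body_mass", idx + 1, node_table),
                    is_consumer=row["is_consumer"].strip().lower() in {"true", "1", "yes"},
                )
            )
        except FoodWebError as exc:
            raise FoodWebError(f"{node_table} row {idx + 1}: {exc}") from exc

    link_records = []
    for idx, row in links.iterrows():
        try:
            link_records.append(
                TrophicLink(
                    resource_id=row["resource_id"].strip(),
                    consumer_id=row["consumer_id"].strip(),
                    flux=_opt_float(row["flux"], "flux", idx + 1, link_table),
                )
            )
        except FoodWebError as exc:
            raise FoodWebError(f"{link_table} row {idx + 1}: {exc}") from exc

    return FoodWeb(
        web_id=str(web_id) if web_id is not None else str(nodes["web_id"].iloc[0] or "web"),
        treatment=treatment,
        block=block,
        species=species,
        links=link_records,
    )


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def write_foodweb(web: FoodWeb, node_table: PathLike, link_table: PathLike) -> None:
    """Write a web to the two delimited files read by :func:`read_foodweb`."""
    nodes = pd.DataFrame(
        [
            {
                "web_id": web.web_id,
                "species_id": rec.species_id,
                "name": rec.name,
                "functional_role": rec.functional_role,
                "body_mass": _fmt(rec.body_mass),
                "is_consumer": rec.is_consumer,
            }
            for rec in sorted(web.species.values(), key=lambda r: r.species_id)
        ],
        columns=NODE_COLUMNS,
    )
    links = pd.DataFrame(
        [
            {
                "web_id": web.web_id,
                "resource_id": link.resource_id,
                "consumer_id": link.consumer_id,
                "flux": _fmt(link.flux),
            }
            for link in sorted(web.links.values(), key=lambda l: l.pair)
        ],
        columns=LINK_COLUMNS,
    )
    nodes.to_csv(node_table, sep=_sep(node_table), index=False)
    links.to_csv(link_table, sep=_sep(link_table), index=False)


def export_graphml(web: FoodWeb, path: PathLike) -> None:
    """Export the undirected projection for external graph viewers."""
    G = web.to_undirected()
    for sid, rec in web.species.items():
        G.nodes[sid]["name"] = rec.name
        G.nodes[sid]["functional_role"] = rec.functional_role
        G.nodes[sid]["is_consumer"] = rec.is_consumer
        if rec.body_mass is not None:
            G.nodes[sid]["body_mass"] = rec.body_mass
    nx.write_graphml(G, path)
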