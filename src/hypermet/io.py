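"""Readers and writers for the interchange formats.

Formats
-------
* Reaction TSV: 4 tab-separated columns ``id  substrates  products
  reversible`` with metabolite ids separated by ``;``.  The reversible
  flag is parsed and then ignored (direction semantics beyond the
  tail/head split are not modelled).  A species appearing on both sides
  of a reaction cancels topologically and is dropped from both sides
  with a warning; reactions reduced below cardinality 2 are skipped.
* Hypergraph JSON: ``{"directed": bool, "nodes": [...], "hyperedges":
  [...]}`` where an undirected hyperedge is an array of node ids (or an
  object ``{"id": ..., "nodes": [...]}``) and a directed hyperedge is
  ``{"tail": [...], "head": [...], "id": ...}``.
* Edge-list TSV: two columns of node ids, one row per edge,
  lexicographically sorted; an optional ``#nodes:`` header line
  preserves isolated nodes.
* Incidence TSV: dense matrix with hyperedge ids as the header row and
  node ids in the first column.

Warnings and diagnostics go to the logging system (stderr by default);
data only ever goes to the requested files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .core import Hyperedge, Hypergraph, HypergraphError, IncidenceMatrix, SimpleGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRecord",
    "read_reactions",
    "read_hypergraph",
    "write_hypergraph",
    "read_edge_list",
    "write_edge_list",
    "write_incidence_matrix",
]


@dataclass(frozen=True)
class ReactionRecord:
    """One parsed reaction line (before hypergraph conversion)."""

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool


def _parse_side(field: str) -> tuple[str, ...]:
    return tuple(dict.fromkeys(s.strip() for s in field.split(";") if s.strip()))


def read_reactions(path) -> Hypergraph:
    """Parse a reaction TSV into a directed hypergraph.

    Tail = substrates, head = products.  Species on both sides are
    dropped from both (logged); reactions reduced below cardinality 2
    are skipped (logged); duplicate reactions -- identical (tail, head)
    pairs -- are collapsed (logged).  The undirected view is available
    via ``Hypergraph.flattened``.
    """
    path = Path(path)
    records: list[ReactionRecord] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise HypergraphError(
                    f"{path.name}:{lineno}: expected 3 or 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rid = fields[0].strip()
            if not rid:
                raise HypergraphError(f"{path.name}:{lineno}: empty reaction id")
            if rid in seen_ids:
                raise HypergraphError(f"{path.name}:{lineno}: duplicate reaction id {rid!r}")
            seen_ids.add(rid)
            subs = _parse_side(fields[1])
            prods = _parse_side(fields[2])
            if not subs or not prods:
                raise HypergraphError(
                    f"{path.name}:{lineno}: reaction {rid!r} has an empty side"
                )
            rev = fields[3].strip().upper() in ("R", "1", "TRUE", "YES") if len(fields) == 4 else False
            records.append(ReactionRecord(rid, subs, prods, rev))

    edges: list[Hyperedge] = []
    keys: set = set()
    nodes: dict[str, None] = {}
    for rec in records:
        both = set(rec.substrates) & set(rec.products)
        subs = tuple(s for s in rec.substrates if s not in both)
        prods = tuple(p for p in rec.products if p not in both)
        if both:
            logger.warning(
                "reaction %s: species %s appear on both sides; dropped from both",
                rec.id, sorted(both),
            )
        if not subs or not prods or len(subs) + len(prods) < 2:
            logger.warning(
                "reaction %s reduced below cardinality 2 after cancellation; skipped", rec.id
            )
            continue
        edge = Hyperedge.directed(subs, prods, id=rec.id)
        if edge.key() in keys:
            logger.warning("reaction %s duplicates an earlier reaction; collapsed", rec.id)
            continue
        keys.add(edge.key())
        edges.append(edge)
        for v in edge.members:
            nodes.setdefault(v)
    return Hypergraph(tuple(nodes), edges, directed=True)


def write_hypergraph(H: Hypergraph, path) -> None:
    """Serialize H to the hypergraph JSON interchange format."""
    payload: dict = {"directed": H.directed, "nodes": list(H.nodes), "hyperedges": []}
    if H.allow_duplicate_hyperedges:
        payload["allow_duplicate_hyperedges"] = True
    for i, e in enumerate(H.hyperedges):
        auto_id = f"E{i + 1}"
        if e.is_directed:
            payload["hyperedges"].append(
                {"tail": list(e.tail), "head": list(e.head), "id": e.id}
            )
        elif e.id != auto_id:
            payload["hyperedges"].append({"id": e.id, "nodes": list(e.members)})
        else:
            payload["hyperedges"].append(list(e.members))
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_hypergraph(path) -> Hypergraph:
    """Read a hypergraph from the JSON interchange format.

    Round-trips exactly with ``write_hypergraph``, including node and
    hyperedge order.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise HypergraphError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise HypergraphError("hypergraph JSON must be an object")
    for field in ("directed", "nodes", "hyperedges"):
        if field not in payload:
            raise HypergraphError(f"hypergraph JSON is missing required field {field!r}")
    directed = payload["directed"]
    if not isinstance(directed, bool):
        raise HypergraphError("field 'directed' must be a boolean")
    nodes = payload["nodes"]
    if not isinstance(nodes, list) or not all(isinstance(v, str) for v in nodes):
        raise HypergraphError("field 'nodes' must be an array of strings")
    edges: list[Hyperedge] = []
    for i, item in enumerate(payload["hyperedges"]):
        if isinstance(item, list):
            if directed:
                raise HypergraphError(
                    f"hyperedge {i}: plain arrays are undirected, but 'directed' is true"
                )
            edges.append(Hyperedge.undirected(item))
        elif isinstance(item, dict):
            if "tail" in item or "head" in item:
                if not directed:
                    raise HypergraphError(
                        f"hyperedge {i}: tail/head given but 'directed' is false"
                    )
                if "tail" not in item or "head" not in item:
                    raise HypergraphError(f"hyperedge {i}: needs both 'tail' and 'head'")
                edges.append(
                    Hyperedge.directed(item["tail"], item["head"], id=item.get("id"))
                )
            elif "nodes" in item:
                if directed:
                    raise HypergraphError(f"hyperedge {i}: missing 'tail'/'head'")
                edges.append(Hyperedge.undirected(item["nodes"], id=item.get("id")))
            else:
                raise HypergraphError(f"hyperedge {i}: object needs 'nodes' or 'tail'+'head'")
        else:
            raise HypergraphError(f"hyperedge {i}: must be an array or an object")
    return Hypergraph(
        nodes, edges, directed=directed,
        allow_duplicate_hyperedges=bool(payload.get("allow_duplicate_hyperedges", False)),
    )


def write_edge_list(G: SimpleGraph, path) -> None:
    """Two-column TSV of edges, lexicographically sorted; isolated nodes
    are preserved in a ``#nodes:`` header comment."""
    lines = ["#nodes:\t" + "\t".join(G.nodes)]
    lines += [f"{u}\t{w}" for u, w in G.edges]  # already sorted
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path) -> SimpleGraph:
    """Read a two-column edge TSV (with optional ``#nodes:`` header)."""
    path = Path(path)
    nodes: list[str] | None = None
    edges: list[tuple[str, str]] = []
    seen: dict[str, None] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#nodes:"):
                nodes = [v for v in line.split("\t")[1:] if v]
                continue
            if line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HypergraphError(
                    f"{path.name}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            u, w = fields[0].strip(), fields[1].strip()
            edges.append((u, w))
            seen.setdefault(u)
            seen.setdefault(w)
    if nodes is None:
        nodes = list(seen)
    return SimpleGraph(nodes, edges)


def write_incidence_matrix(M: IncidenceMatrix, path) -> None:
    """Dense TSV: header row of hyperedge ids, first column of node ids."""
    lines = ["node\t" + "\t".join(M.edge_order)]
    for i, v in enumerate(M.node_order):
        lines.append(v + "\t" + "\t".join(str(int(x)) for x in M.matrix[i]))
    Path(path).write_text("\n".join(lines) + "\n")
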