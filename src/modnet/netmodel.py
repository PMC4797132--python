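"""Attributed undirected graph model with hyper-edges and group (compound) nodes.

The :class:`Network` is the universal substrate of the package: an undirected,
simple graph (no self-loops, no parallel edges) whose nodes and edges carry
typed attributes, extended with two constructs beyond plain graphs:

* **hyper-edges** — relations among two or more participants with free-form
  roles (e.g. enzyme / substrate / product), used to describe reactions that
  binary interactions cannot express.  They are data only: clustering, layout
  forces and shortest paths ignore them.
* **groups** — compound nodes containing member nodes, the vehicle for
  displaying clusters.  Group member sets are pairwise disjoint.

Nodes may carry a *role* of ``"seed"`` (an altered gene anchoring subnetwork
extraction) or ``"linker"`` (a non-seed gene on a shortest path between
seeds); a node is never both, and seed wins on conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ArityError, ConflictError, IntegrityError, NodeLookupError

GROUP_SHAPES = ("rectangle", "circle", "convex_hull")
ROLES = ("seed", "linker")


@dataclass
class HyperEdge:
    id: str
    participants: list[tuple[str, str]]  # (node id, role)
    attrs: dict = field(default_factory=dict)


@dataclass
class Group:
    id: str
    label: str
    members: set[str]
    shape: str = "convex_hull"
    style: dict = field(default_factory=dict)


def _clean_id(node_id) -> str:
    nid = str(node_id).strip()
    if not nid:
        raise IntegrityError("node id must be a non-empty string")
    return nid


class Network:
    """Undirected attributed graph with hyper-edges and disjoint groups.

    Wraps a :class:`networkx.Graph` (exposed as :attr:`graph`) so that
    standard graph algorithms apply directly, while enforcing the model's
    invariants (simple, undirected, referential integrity, group
    disjointness) at the mutation surface.
    """

    def __init__(self, name: str = "network"):
        self.name = name
        self.graph = nx.Graph()
        self.hyperedges: dict[str, HyperEdge] = {}
        self.groups: dict[str, Group] = {}
        #: declared attribute schema: attribute name -> python type name
        self.schema: dict[str, str] = {}
        self._hyper_counter = 0
        self._group_counter = 0

    # ------------------------------------------------------------------ nodes
    def add_node(self, node_id, **attrs) -> str:
        nid = _clean_id(node_id)
        self._declare(attrs)
        self.graph.add_node(nid, **attrs)
        return nid

    def has_node(self, node_id) -> bool:
        return self.graph.has_node(str(node_id).strip())

    def nodes(self) -> Iterator[str]:
        return iter(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_attrs(self, node_id) -> dict:
        self._require(node_id)
        return self.graph.nodes[node_id]

    def set_role(self, node_id, role: str | None) -> None:
        """Flag a node as seed or linker.  Seed wins over linker on conflict."""
        self._require(node_id)
        if role is not None and role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        current = self.graph.nodes[node_id].get("__role")
        if current == "seed" and role == "linker":
            return  # seed wins
        if role is None:
            self.graph.nodes[node_id].pop("__role", None)
        else:
            self.graph.nodes[node_id]["__role"] = role

    def role(self, node_id) -> str | None:
        self._require(node_id)
        return self.graph.nodes[node_id].get("__role")

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("__role") == role}

    def remove_node(self, node_id) -> None:
        """Remove a node, its incident edges, any hyperedge it participates in,
        and its group membership (empty groups are dropped)."""
        self._require(node_id)
        self.graph.remove_node(node_id)
        dead = [h.id for h in self.hyperedges.values()
                if any(p == node_id for p, _ in h.participants)]
        for hid in dead:
            del self.hyperedges[hid]
        for gid in list(self.groups):
            g = self.groups[gid]
            g.members.discard(node_id)
            if not g.members:
                del self.groups[gid]

    # ------------------------------------------------------------------ edges
    def add_edge(self, u, v, weight: float = 1.0, score: float | None = None, **attrs) -> None:
        """Add an undirected edge.  Self-loops are rejected; a duplicate of an
        existing edge keeps the maximum score (and the new weight/attrs)."""
        u, v = _clean_id(u), _clean_id(v)
        if u == v:
            raise IntegrityError(f"self-loop on {u!r} not allowed")
        for n in (u, v):
            if not self.graph.has_node(n):
                self.graph.add_node(n)
        self._declare(attrs)
        if self.graph.has_edge(u, v):
            old = self.graph.edges[u, v].get("score")
            if score is None or (old is not None and old > score):
                score = old
        data = dict(attrs, weight=float(weight))
        if score is not None:
            data["score"] = float(score)
        self.graph.add_edge(u, v, **data)

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    def edges(self, data: bool = False):
        return self.graph.edges(data=data)

    def edge_attrs(self, u, v) -> dict:
        if not self.graph.has_edge(u, v):
            raise IntegrityError(f"no edge {u!r}-{v!r}")
        return self.graph.edges[u, v]

    def remove_edge(self, u, v) -> None:
        if not self.graph.has_edge(u, v):
            raise IntegrityError(f"no edge {u!r}-{v!r}")
        self.graph.remove_edge(u, v)

    def degree(self, node_id) -> int:
        """Binary-edge degree; hyperedges are excluded by contract."""
        self._require(node_id)
        return self.graph.degree[node_id]

    def neighbors(self, node_id) -> set[str]:
        self._require(node_id)
        return set(self.graph.neighbors(node_id))

    # ------------------------------------------------------------- hyperedges
    def add_hyperedge(self, participants: Iterable[tuple[str, str]],
                      hyper_id: str | None = None, **attrs) -> HyperEdge:
        parts = [(str(p).strip(), str(r)) for p, r in participants]
        if len(parts) < 2:
            raise ArityError(f"hyperedge needs >= 2 participants, got {len(parts)}")
        for p, r in parts:
            if not self.graph.has_node(p):
                raise IntegrityError(f"hyperedge participant {p!r} not in network")
            if not r:
                raise IntegrityError("hyperedge roles must be non-empty strings")
        if hyper_id is None:
            self._hyper_counter += 1
            hyper_id = f"h{self._hyper_counter}"
        if hyper_id in self.hyperedges:
            raise ConflictError(f"hyperedge id {hyper_id!r} already used")
        he = HyperEdge(id=hyper_id, participants=parts, attrs=dict(attrs))
        self.hyperedges[hyper_id] = he
        return he

    # ----------------------------------------------------------------- groups
    def add_group(self, members: Iterable[str], label: str = "",
                  shape: str = "convex_hull", group_id: str | None = None,
                  style: Mapping | None = None) -> Group:
        members = {str(m).strip() for m in members}
        if not members:
            raise IntegrityError("group members must be non-empty")
        if shape not in GROUP_SHAPES:
            raise ValueError(f"shape must be one of {GROUP_SHAPES}, got {shape!r}")
        for m in members:
            if not self.graph.has_node(m):
                raise IntegrityError(f"group member {m!r} not in network")
        grouped = self.grouped_nodes()
        overlap = members & grouped
        if overlap:
            raise ConflictError(f"nodes already grouped: {sorted(overlap)}")
        if group_id is None:
            self._group_counter += 1
            group_id = f"g{self._group_counter}"
        if group_id in self.groups:
            raise ConflictError(f"group id {group_id!r} already used")
        grp = Group(id=group_id, label=label or group_id, members=members,
                    shape=shape, style=dict(style or {}))
        self.groups[group_id] = grp
        return grp

    def remove_group(self, group_id: str) -> None:
        if group_id not in self.groups:
            raise IntegrityError(f"no group {group_id!r}")
        del self.groups[group_id]

    def grouped_nodes(self) -> set[str]:
        out: set[str] = set()
        for g in self.groups.values():
            out |= g.members
        return out

    def group_of(self, node_id) -> str | None:
        for gid, g in self.groups.items():
            if node_id in g.members:
                return gid
        return None

    # ------------------------------------------------------------------ misc
    def subgraph(self, node_ids: Iterable[str], name: str | None = None) -> "Network":
        """Induced subnetwork on ``node_ids`` (groups/hyperedges restricted)."""
        keep = {n for n in node_ids if self.graph.has_node(n)}
        sub = Network(name or f"{self.name}__sub")
        sub.schema = dict(self.schema)
        for n in sorted(keep):  # sorted: byte-stable serialization across runs
            sub.graph.add_node(n, **dict(self.graph.nodes[n]))
        for u, v, d in self.graph.edges(data=True):
            if u in keep and v in keep:
                sub.graph.add_edge(u, v, **dict(d))
        for h in self.hyperedges.values():
            if all(p in keep for p, _ in h.participants):
                sub.hyperedges[h.id] = HyperEdge(h.id, list(h.participants), dict(h.attrs))
        for g in self.groups.values():
            m = g.members & keep
            if m:
                sub.groups[g.id] = Group(g.id, g.label, m, g.shape, dict(g.style))
        return sub

    def copy(self) -> "Network":
        return self.subgraph(self.nodes(), name=self.name)

    def check_integrity(self) -> None:
        """Raise IntegrityError/ConflictError if any model invariant is broken."""
        for h in self.hyperedges.values():
            if len(h.participants) < 2:
                raise ArityError(f"hyperedge {h.id} has < 2 participants")
            for p, _ in h.participants:
                if not self.graph.has_node(p):
                    raise IntegrityError(f"hyperedge {h.id} references missing node {p!r}")
        seen: set[str] = set()
        for g in self.groups.values():
            if not g.members:
                raise IntegrityError(f"group {g.id} is empty")
            for m in g.members:
                if not self.graph.has_node(m):
                    raise IntegrityError(f"group {g.id} references missing node {m!r}")
            if g.members & seen:
                raise ConflictError(f"group {g.id} overlaps another group")
            seen |= g.members
        for u, v in self.graph.edges:
            if u == v:
                raise IntegrityError(f"self-loop on {u!r}")

    def _require(self, node_id) -> None:
        if not self.graph.has_node(node_id):
            raise NodeLookupError(f"unknown node {node_id!r}")

    def _declare(self, attrs: Mapping) -> None:
        for k, val in attrs.items():
            self.schema.setdefault(k, type(val).__name__)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Network {self.name!r}: {self.n_nodes} nodes, {self.n_edges} edges, "
                f"{len(self.hyperedges)} hyperedges, {len(self.groups)} groups>")


def networks_equal(a: Network, b: Network, rel_tol: float = 1e-9) -> bool:
    """Structural equality of two networks up to attribute-value formatting."""
    import math

    def close(x, y):
        if isinstance(x, float) or isinstance(y, float):
            try:
                return math.isclose(float(x), float(y), rel_tol=rel_tol, abs_tol=1e-12)
            except (TypeError, ValueError):
                return False
        return x == y

    if set(a.nodes()) != set(b.nodes()):
        return False
    for n in a.nodes():
        da, db = dict(a.graph.nodes[n]), dict(b.graph.nodes[n])
        if set(da) != set(db) or not all(close(da[k], db[k]) for k in da):
            return False
    ea = {frozenset((u, v)) for u, v in a.graph.edges}
    eb = {frozenset((u, v)) for u, v in b.graph.edges}
    if ea != eb:
        return False
    for u, v in a.graph.edges:
        da, db = dict(a.graph.edges[u, v]), dict(b.graph.edges[u, v])
        if set(da) != set(db) or not all(close(da[k], db[k]) for k in da):
            return False
    ga = {(g.label, g.shape, frozenset(g.members)) for g in a.groups.values()}
    gb = {(g.label, g.shape, frozenset(g.members)) for g in b.groups.values()}
    if ga != gb:
        return False
    ha = {(h.id, tuple(sorted(h.participants))) for h in a.hyperedges.values()}
    hb = {(h.id, tuple(sorted(h.participants))) for h in b.hyperedges.values()}
    return ha == hb
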