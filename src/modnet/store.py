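"""Persisted background interaction sources.

A *background network* is a large, named interaction source (a STRING-like
confidence network, a curated pathway net, ...) imported once and then
queried repeatedly: filter edges by confidence score, pull the neighborhood
of a gene list, extract seed subnetworks.  Each source lives in its own
subdirectory of a store directory as a GraphML file plus a JSON manifest, so
it is locally available on the next run without re-importing.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from . import io
from .errors import ConflictError, ConfigurationError, FormatError
from .netmodel import Network

log = logging.getLogger(__name__)

FORMATS = ("sif", "tsv", "graphml")


@dataclass
class BackgroundStore:
    """One named, persisted background interaction source."""

    source_name: str
    network: Network
    score_column: str | None
    storage_path: Path
    created: str

    @property
    def manifest(self) -> dict:
        return {
            "source_name": self.source_name,
            "score_column": self.score_column,
            "created": self.created,
            "n_nodes": self.network.n_nodes,
            "n_edges": self.network.n_edges,
        }


def _source_dir(store_dir, name: str) -> Path:
    return Path(store_dir) / name


def import_source(path, name: str, fmt: str, store_dir,
                  score_column: str | int | None = None) -> BackgroundStore:
    """Parse ``path`` in the declared format and persist it under ``name``."""
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    sdir = _source_dir(store_dir, name)
    if (sdir / "manifest.json").exists():
        raise ConflictError(f"source name {name!r} already used in {store_dir}")
    if fmt == "sif":
        net = io.read_sif(path, name=name)
        score_attr = None
    elif fmt == "tsv":
        net = io.read_tsv(path, score_column=score_column, name=name)
        score_attr = "score" if score_column is not None else None
    else:
        net = io.read_graphml(path)
        net.name = name
        score_attr = "score" if score_column is not None else None
    sdir.mkdir(parents=True, exist_ok=True)
    io.write_graphml(net, sdir / "network.graphml")
    store = BackgroundStore(
        source_name=name, network=net, score_column=score_attr,
        storage_path=sdir,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    (sdir / "manifest.json").write_text(json.dumps(store.manifest, indent=1) + "\n")
    log.info("imported source %s: %d nodes, %d edges", name, net.n_nodes, net.n_edges)
    return store


def open_source(name: str, store_dir) -> BackgroundStore:
    sdir = _source_dir(store_dir, name)
    mpath = sdir / "manifest.json"
    if not mpath.exists():
        raise ConfigurationError(f"no source named {name!r} in {store_dir}")
    meta = json.loads(mpath.read_text())
    net = io.read_graphml(sdir / "network.graphml")
    return BackgroundStore(source_name=name, network=net,
                           score_column=meta.get("score_column"),
                           storage_path=sdir, created=meta.get("created", ""))


def list_sources(store_dir) -> list[dict]:
    store_dir = Path(store_dir)
    out = []
    if store_dir.is_dir():
        for mpath in sorted(store_dir.glob("*/manifest.json")):
            out.append(json.loads(mpath.read_text()))
    return out


def delete_source(name: str, store_dir) -> None:
    sdir = _source_dir(store_dir, name)
    if not (sdir / "manifest.json").exists():
        raise ConfigurationError(f"no source named {name!r} in {store_dir}")
    for f in sdir.iterdir():
        f.unlink()
    sdir.rmdir()


def subnetwork_by_score(store: BackgroundStore, min_score: float) -> Network:
    """Edges with score strictly greater than ``min_score``; isolated nodes dropped."""
    if store.score_column is None:
        raise ConfigurationError(
            f"source {store.source_name!r} has no score column declared")
    net = store.network
    keep_edges = [(u, v) for u, v, d in net.graph.edges(data=True)
                  if d.get("score") is not None and d["score"] > min_score]
    sub = Network(f"{net.name}__score_gt_{min_score:g}")
    sub.schema = dict(net.schema)
    for u, v in keep_edges:
        for n in (u, v):
            if not sub.graph.has_node(n):
                sub.graph.add_node(n, **dict(net.graph.nodes[n]))
        sub.graph.add_edge(u, v, **dict(net.graph.edges[u, v]))
    return sub


def expand(store: BackgroundStore, ids, depth: int = 1) -> Network:
    """Induced subgraph on ``ids`` plus every node within graph distance
    ``depth`` of any of them.  Unknown ids warn and are ignored."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    g = store.network.graph
    known = {str(i).strip() for i in ids if g.has_node(str(i).strip())}
    unknown = {str(i).strip() for i in ids} - known
    if unknown:
        log.warning("expand: %d unknown ids ignored: %s", len(unknown),
                    sorted(unknown)[:10])
    reach: set[str] = set(known)
    for seed in known:
        lengths = nx.single_source_shortest_path_length(g, seed, cutoff=depth)
        reach |= set(lengths)
    return store.network.subgraph(reach, name=f"{store.source_name}__expand{depth}")
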