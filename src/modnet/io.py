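"""Reading and writing networks.

Formats:

* **GraphML** (via networkx) — the lossless persistence format.  Group
  membership is stored as a ``__group`` node attribute plus a graph-level
  JSON blob for group labels/shapes/styles; coordinates travel as ``x``/``y``
  node attributes.  GraphML has no hyperedge standard, so hyperedges are
  serialized to a sidecar JSON file (``<stem>.hyper.json``) next to the
  GraphML file.
* **SIF** — ``A <relation> B [C ...]`` whitespace-separated interaction lines.
* **TSV** — ``source  target  [score]  [attrs...]`` with a header-detection
  heuristic: if the first row's score column is non-numeric, it is a header.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .errors import FormatError
from .netmodel import Group, Network

_META_KEYS = ("__name", "__schema", "__groups")


# --------------------------------------------------------------------- GraphML
def write_graphml(net: Network, path) -> None:
    path = Path(path)
    g = net.graph.copy()
    for gid, grp in net.groups.items():
        for m in grp.members:
            g.nodes[m]["__group"] = gid
    g.graph["__name"] = net.name
    g.graph["__schema"] = json.dumps(net.schema, sort_keys=True)
    g.graph["__groups"] = json.dumps(
        {gid: {"label": grp.label, "shape": grp.shape, "style": grp.style}
         for gid, grp in sorted(net.groups.items())}, sort_keys=True)
    nx.write_graphml(g, path, named_key_ids=True)
    sidecar = _sidecar(path)
    if net.hyperedges:
        payload = [{"id": h.id, "participants": [list(p) for p in h.participants],
                    "attrs": h.attrs} for h in net.hyperedges.values()]
        sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif sidecar.exists():
        sidecar.unlink()


def read_graphml(path) -> Network:
    path = Path(path)
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # malformed XML / keys
        raise FormatError(f"cannot parse GraphML {path}: {exc}") from exc
    net = Network(g.graph.get("__name", path.stem))
    net.schema = json.loads(g.graph.get("__schema", "{}"))
    group_meta = json.loads(g.graph.get("__groups", "{}"))
    members: dict[str, set[str]] = {}
    for n, d in g.nodes(data=True):
        d = dict(d)
        gid = d.pop("__group", None)
        net.graph.add_node(str(n), **d)
        if gid is not None:
            members.setdefault(gid, set()).add(str(n))
    for u, v, d in g.edges(data=True):
        net.graph.add_edge(str(u), str(v), **dict(d))
    for gid, meta in group_meta.items():
        if gid in members:
            net.groups[gid] = Group(id=gid, label=meta.get("label", gid),
                                    members=members[gid],
                                    shape=meta.get("shape", "convex_hull"),
                                    style=dict(meta.get("style", {})))
    sidecar = _sidecar(path)
    if sidecar.exists():
        for h in json.loads(sidecar.read_text()):
            net.add_hyperedge([tuple(p) for p in h["participants"]],
                              hyper_id=h["id"], **h.get("attrs", {}))
    net.check_integrity()
    return net


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hyper.json") if path.suffix != ".graphml" \
        else path.with_suffix(".hyper.json")


# ------------------------------------------------------------------------- SIF
def read_sif(path, name: str | None = None) -> Network:
    path = Path(path)
    net = Network(name or path.stem)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            net.add_node(fields[0])
        elif len(fields) >= 3:
            src, _rel, targets = fields[0], fields[1], fields[2:]
            for t in targets:
                if t != src:
                    net.add_edge(src, t)
        else:
            raise FormatError(f"SIF line needs 1 or >=3 fields, got {len(fields)}",
                              line=lineno)
    return net


# ------------------------------------------------------------------------- TSV
def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_tsv(path, score_column: str | int | None = None,
             name: str | None = None) -> Network:
    """Read a ``source  target  [score]  [extra...]`` interaction TSV.

    ``score_column`` may be a column index (0-based) or, when a header row is
    present, a column name.  Header detection: the first row is a header if
    its score column (or, without one, its first column used as an edge
    endpoint elsewhere-numeric heuristic does not apply — then only an exact
    ``source\\ttarget`` match) is non-numeric.
    """
    path = Path(path)
    net = Network(name or path.stem)
    lines = [ln for ln in path.read_text().splitlines()]
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            rows.append((lineno, raw.rstrip("\n").split("\t")))
    if not rows:
        return net
    header: list[str] | None = None
    first = rows[0][1]
    score_idx: int | None = None
    if isinstance(score_column, int):
        score_idx = score_column
    # header heuristic: non-numeric value in the score column of row 1
    if score_column is not None:
        probe = score_idx if score_idx is not None else 2
        if probe < len(first) and not _is_number(first[probe]):
            header = first
            rows = rows[1:]
    elif [c.lower() for c in first[:2]] == ["source", "target"]:
        header = first
        rows = rows[1:]
    if isinstance(score_column, str):
        if header is None or score_column not in header:
            raise FormatError(f"score column {score_column!r} not found in header")
        score_idx = header.index(score_column)
    elif score_column is not None and score_idx is None:
        score_idx = 2
    extra_names = None
    if header is not None:
        extra_names = {i: h for i, h in enumerate(header)
                       if i > 1 and i != score_idx}
    for lineno, fields in rows:
        if len(fields) < 2 or (score_idx is not None and len(fields) <= score_idx):
            raise FormatError("too few columns", line=lineno)
        u, v = fields[0].strip(), fields[1].strip()
        if not u or not v or u == v:
            raise FormatError(f"bad endpoints {fields[:2]!r}", line=lineno)
        attrs = {}
        score = None
        if score_idx is not None:
            tok = fields[score_idx]
            if not _is_number(tok):
                raise FormatError(f"non-numeric score {tok!r}", line=lineno)
            score = float(tok)
        for i, tok in enumerate(fields):
            if i <= 1 or i == score_idx:
                continue
            key = extra_names.get(i, f"col{i}") if extra_names else f"col{i}"
            attrs[key] = float(tok) if _is_number(tok) else tok
        net.add_edge(u, v, score=score, **attrs)
    return net


def write_tsv(net: Network, path, score: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tscore\tweight\n" if score else "source\ttarget\tweight\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            w = d.get("weight", 1.0)
            if score:
                s = d.get("score", "")
                fh.write(f"{u}\t{v}\t{s}\t{w}\n")
            else:
                fh.write(f"{u}\t{v}\t{w}\n")
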