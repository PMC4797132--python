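"""Data-to-visual mapping and multi-condition overlay export.

A :class:`VisualMapping` is a monotone linear map from a numeric data
attribute (alteration frequency, expression, correlation, ...) to a visual
channel: node size, node color, edge width or edge color.  Color ranges are
2–3 hex sRGB anchors interpolated linearly in RGB; a 3-anchor gradient is a
diverging map whose middle anchor sits at the domain midpoint.

:func:`overlay_series` renders one styled frame per experimental condition
on a single, shared coordinate set, with one shared value domain across all
conditions so that styles are comparable between frames — the serial /
animated overlay of multiple profiles on an identical network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import to_hex, to_rgb

from .netmodel import Network

NODE_TARGETS = ("node_size", "node_color")
EDGE_TARGETS = ("edge_width", "edge_color")
NEUTRAL_COLOR = "#c0c0c0"


@dataclass
class VisualMapping:
    source_attr: str
    target: str  # node_size | node_color | edge_width | edge_color
    domain: tuple[float, float] | str = "auto"
    range: tuple[float, float] | tuple[str, ...] = (10.0, 30.0)
    out_of_domain: str = "clamp"  # clamp | hide

    def __post_init__(self):
        if self.target not in NODE_TARGETS + EDGE_TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.out_of_domain not in ("clamp", "hide"):
            raise ValueError("out_of_domain must be 'clamp' or 'hide'")
        if self.domain != "auto":
            lo, hi = self.domain
            if not lo < hi:
                raise ValueError("domain min must be < max")
        if self.is_color:
            if not (2 <= len(self.range) <= 3):
                raise ValueError("color range needs 2 or 3 anchors")
        else:
            lo, hi = self.range
            if not float(lo) <= float(hi):
                raise ValueError("size range must be non-decreasing")

    @property
    def is_color(self) -> bool:
        return self.target.endswith("color")

    @property
    def on_nodes(self) -> bool:
        return self.target in NODE_TARGETS


@dataclass
class ConditionSeries:
    """Per-node values under an ordered list of experimental conditions."""

    conditions: list[str]
    values: pd.DataFrame  # nodes x conditions

    def __post_init__(self):
        missing = [c for c in self.conditions if c not in self.values.columns]
        if missing:
            raise ValueError(f"conditions missing from value table: {missing}")
        self.values = self.values[self.conditions]

    @classmethod
    def from_tsv(cls, path) -> "ConditionSeries":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(conditions=list(df.columns), values=df)


def _interp_color(anchors: tuple[str, ...], t: float) -> str:
    """Piecewise-linear RGB interpolation over 2 or 3 hex anchors, t in [0,1]."""
    rgb = [np.array(to_rgb(a)) for a in anchors]
    if len(rgb) == 2:
        c = rgb[0] + t * (rgb[1] - rgb[0])
    else:
        if t <= 0.5:
            c = rgb[0] + (t / 0.5) * (rgb[1] - rgb[0])
        else:
            c = rgb[1] + ((t - 0.5) / 0.5) * (rgb[2] - rgb[1])
    return to_hex(np.clip(c, 0, 1))


def apply_mapping(net: Network, mapping: VisualMapping,
                  values: pd.Series | None = None,
                  domain_override: tuple[float, float] | None = None) -> pd.DataFrame:
    """Map a data attribute to a style column.

    Returns a table indexed by element id (node id, or ``u|v`` for edges)
    with columns ``value``, ``style`` and ``flag`` (absent / hidden / '').
    ``values`` overrides the attribute lookup (used by overlays).
    """
    if mapping.on_nodes:
        ids = sorted(net.nodes())
        if values is not None:
            raw = [values.get(i, np.nan) for i in ids]
        else:
            raw = [net.graph.nodes[i].get(mapping.source_attr, np.nan) for i in ids]
    else:
        pairs = sorted(net.graph.edges)
        ids = [f"{u}|{v}" for u, v in pairs]
        raw = [net.graph.edges[u, v].get(mapping.source_attr, np.nan) for u, v in pairs]
    vals = pd.to_numeric(pd.Series(raw, index=ids), errors="coerce")

    if domain_override is not None:
        lo, hi = domain_override
    elif mapping.domain == "auto":
        finite = vals.dropna()
        if finite.empty:
            lo, hi = 0.0, 1.0
        else:
            lo, hi = float(finite.min()), float(finite.max())
    else:
        lo, hi = mapping.domain
    constant = not lo < hi

    styles, flags = [], []
    for v in vals:
        if pd.isna(v):
            styles.append(NEUTRAL_COLOR if mapping.is_color else np.nan)
            flags.append("absent")
            continue
        if constant:
            t = 0.5  # degenerate domain: midpoint for every element
        else:
            t = (float(v) - lo) / (hi - lo)
        flag = ""
        if t < 0 or t > 1:
            if mapping.out_of_domain == "hide":
                styles.append(NEUTRAL_COLOR if mapping.is_color else np.nan)
                flags.append("hidden")
                continue
            flag = "clamped"
            t = min(1.0, max(0.0, t))
        if mapping.is_color:
            styles.append(_interp_color(tuple(mapping.range), t))
        else:
            r0, r1 = float(mapping.range[0]), float(mapping.range[1])
            styles.append(r0 + t * (r1 - r0))
        flags.append(flag)
    if constant and not vals.dropna().empty:
        warnings.warn(f"attribute {mapping.source_attr!r} is constant; all "
                      "elements mapped to the range midpoint")
    return pd.DataFrame({"value": vals, "style": styles, "flag": flags}, index=ids)


def overlay_series(net: Network, series: ConditionSeries, mapping: VisualMapping,
                   coords) -> dict[str, pd.DataFrame]:
    """One styled frame per condition on identical coordinates.

    The value domain is shared across *all* conditions (global min/max when
    the mapping's domain is "auto"), so the same style means the same value
    in every frame.  Each frame table carries ``x``/``y`` columns copied
    from ``coords`` (a LayoutState or an id -> (x, y) mapping).
    """
    if not mapping.on_nodes:
        raise ValueError("overlay_series requires a node target")
    cmap = coords.coords if hasattr(coords, "coords") else dict(coords)
    missing = [n for n in net.nodes() if n not in cmap]
    if missing:
        raise ValueError(f"coordinates missing for {len(missing)} nodes")
    if mapping.domain == "auto":
        pool = series.values[series.conditions].to_numpy(dtype=float)
        finite = pool[np.isfinite(pool)]
        shared = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
        if shared[0] == shared[1]:
            shared = (shared[0] - 0.5, shared[1] + 0.5)
    else:
        shared = tuple(mapping.domain)

    frames: dict[str, pd.DataFrame] = {}
    for cond in series.conditions:
        col = series.values[cond]
        col.index = col.index.astype(str)
        frame = apply_mapping(net, mapping, values=col, domain_override=shared)
        if (frame["flag"] == "absent").all():
            warnings.warn(f"condition {cond!r} has no values; neutral frame")
        frame["x"] = [cmap[i][0] for i in frame.index]
        frame["y"] = [cmap[i][1] for i in frame.index]
        frames[cond] = frame
    return frames


def condition_matrix(series: ConditionSeries,
                     node_order: list[str] | None = None) -> pd.DataFrame:
    """Genes x conditions matrix, rows in the given (e.g. cluster) order."""
    if not series.conditions:
        raise ValueError("condition series is empty")
    df = series.values[series.conditions]
    if node_order is not None:
        order = [n for n in node_order if n in df.index]
        rest = [n for n in df.index if n not in set(order)]
        df = df.loc[order + rest]
    return df.copy()


def write_frames(frames: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write per-condition frame TSVs plus a styles.json manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for cond, frame in frames.items():
        p = out_dir / f"frame_{cond}.tsv"
        frame.to_csv(p, sep="\t")
        written.append(p)
    manifest = {"conditions": list(frames), "files": [p.name for p in written]}
    (out_dir / "styles.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return written
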