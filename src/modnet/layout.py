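"""Group-aware force-directed layout with an animation-friendly stepper.

A spring-electrical model: edges act as springs toward a rest length,
every node pair repels with an inverse-square force, and two group terms
implement "members of the same group attract, members of different groups
repel" — each grouped node is additionally pulled toward its group's
centroid (scaled by ``group_attraction_gain``) and repulsion between nodes
of *different* groups is multiplied by ``group_repulsion_gain``.  Damped
velocity integration; the run is deterministic given (network, params,
seed), and the iteration loop is exposed so callers can advance a layout a
few steps at a time, change parameters mid-run, and collect animation
frames.

Coordinates are abstract units, translated after each run so the global
centroid sits at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IntegrityError
from .netmodel import Network


@dataclass
class LayoutParams:
    spring_constant: float = 0.1
    rest_length: float = 50.0
    repulsion_constant: float = 5000.0
    group_attraction_gain: float = 3.0
    group_repulsion_gain: float = 2.0
    damping: float = 0.9
    step_size: float = 0.2
    max_iter: int = 500
    convergence_tol: float = 1e-3  # mean displacement per node
    seed: int = 0

    def __post_init__(self):
        for f in ("spring_constant", "rest_length", "repulsion_constant", "step_size"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        if not (0 < self.damping < 1):
            raise ValueError("damping must be in (0, 1)")
        for f in ("group_attraction_gain", "group_repulsion_gain"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


@dataclass
class LayoutState:
    """Node coordinates plus the integrator state needed to continue the run."""

    coords: dict[str, tuple[float, float]]
    iteration: int
    converged: bool
    group_geometry: dict[str, dict] = field(default_factory=dict)
    _velocity: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)
    _node_order: tuple[str, ...] = ()

    def positions(self) -> np.ndarray:
        return np.array([self.coords[n] for n in self._node_order])


def _init_state(net: Network, params: LayoutParams) -> LayoutState:
    nodes = tuple(sorted(net.nodes()))
    rng = np.random.default_rng(params.seed)
    n = len(nodes)
    radius = params.rest_length * max(1.0, np.sqrt(n))
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    coords = {nd: (float(x), float(y)) for nd, (x, y) in zip(nodes, pos)}
    vel = {nd: (0.0, 0.0) for nd in nodes}
    return LayoutState(coords=coords, iteration=0, converged=(n <= 1),
                       _velocity=vel, _node_order=nodes)


def _forces(pos: np.ndarray, net: Network, params: LayoutParams,
            nodes: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
    n = len(nodes)
    idx = {nd: i for i, nd in enumerate(nodes)}
    F = np.zeros_like(pos)

    # pairwise repulsion ~ C / d^2, scaled up across different groups
    diff = pos[:, None, :] - pos[None, :, :]          # i - j
    d2 = (diff ** 2).sum(axis=2)
    coincident = (d2 < 1e-12) & ~np.eye(n, dtype=bool)
    if coincident.any():  # deterministic jitter for coincident points
        jitter = rng.uniform(-0.5, 0.5, pos.shape)
        pos = pos + jitter
        diff = pos[:, None, :] - pos[None, :, :]
        d2 = (diff ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    gid = np.zeros(n, dtype=int)  # 0 = ungrouped
    for g_i, g in enumerate(net.groups.values(), start=1):
        for m in g.members:
            if m in idx:
                gid[idx[m]] = g_i
    scale = np.ones((n, n))
    both = (gid[:, None] > 0) & (gid[None, :] > 0)
    scale[both & (gid[:, None] != gid[None, :])] = params.group_repulsion_gain
    mag = params.repulsion_constant * scale / d2
    F += ((mag / np.sqrt(d2))[:, :, None] * diff).sum(axis=1)

    # springs along edges toward rest_length
    for u, v in net.graph.edges:
        i, j = idx[u], idx[v]
        dvec = pos[j] - pos[i]
        dist = float(np.hypot(*dvec))
        if dist < 1e-9:
            continue
        f = params.spring_constant * (dist - params.rest_length) * dvec / dist
        F[i] += f
        F[j] -= f

    # group-centroid attraction
    for g in net.groups.values():
        members = [idx[m] for m in sorted(g.members) if m in idx]
        if len(members) < 2:
            continue
        centroid = pos[members].mean(axis=0)
        for i in members:
            F[i] += params.group_attraction_gain * params.spring_constant * \
                (centroid - pos[i])
    return F


def step_layout(state: LayoutState, net: Network, params: LayoutParams,
                n: int) -> LayoutState:
    """Advance exactly ``n`` iterations with the parameters given *now*.

    Splitting a run into several calls with constant parameters reproduces a
    single longer run exactly (the integrator continues from the uncentered
    positions it carries); passing different parameters mid-run is the
    dynamic-reconfiguration contract.
    """
    state = _continuable(state)
    nodes = state._node_order
    if set(nodes) != set(net.nodes()):
        raise IntegrityError("layout state does not match the network's node set")
    pos = np.array([state.coords[nd] for nd in nodes], dtype=float)
    vel = np.array([state._velocity[nd] for nd in nodes], dtype=float)
    iteration, converged = state.iteration, state.converged
    mean_disp = np.inf
    for _ in range(n):
        if converged:
            break
        rng = np.random.default_rng((params.seed, iteration))
        F = _forces(pos, net, params, nodes, rng)
        vel = params.damping * (vel + params.step_size * F)
        disp = params.step_size * vel
        pos = pos + disp
        iteration += 1
        mean_disp = float(np.abs(disp).sum(axis=1).mean()) if len(nodes) else 0.0
        if mean_disp <= params.convergence_tol:
            converged = True
    centered = pos - (pos.mean(axis=0) if len(nodes) else 0.0)
    coords = {nd: (float(x), float(y)) for nd, (x, y) in zip(nodes, centered)}
    new = LayoutState(coords=coords, iteration=iteration, converged=converged,
                      _velocity={nd: (float(vx), float(vy))
                                 for nd, (vx, vy) in zip(nodes, vel)},
                      _node_order=nodes)
    # keep raw (uncentered) positions for exact continuation
    new._raw = {nd: (float(x), float(y)) for nd, (x, y) in zip(nodes, pos)}
    new.group_geometry = {gid: group_outline(new, net.groups[gid])
                          for gid in net.groups}
    return new


def _continuable(state: LayoutState) -> LayoutState:
    raw = getattr(state, "_raw", None)
    if raw is None:
        return state
    return LayoutState(coords=dict(raw), iteration=state.iteration,
                       converged=state.converged, _velocity=dict(state._velocity),
                       _node_order=state._node_order)


def run_layout(net: Network, params: LayoutParams | None = None) -> LayoutState:
    """Run the layout to convergence (mean displacement <= tol) or max_iter."""
    params = params or LayoutParams()
    if net.n_nodes == 0:
        raise ValueError("cannot lay out an empty network")
    state = _init_state(net, params)
    if net.n_nodes == 1:
        only = state._node_order[0]
        state.coords[only] = (0.0, 0.0)
        return state
    return step_layout(state, net, params, params.max_iter)


def frames(net: Network, params: LayoutParams | None = None,
           every: int = 25) -> list[LayoutState]:
    """Snapshots every ``every`` iterations plus the final state."""
    params = params or LayoutParams()
    if every < 1:
        raise ValueError("every must be >= 1")
    state = _init_state(net, params)
    out: list[LayoutState] = []
    while state.iteration < params.max_iter and not state.converged:
        n = min(every, params.max_iter - state.iteration)
        state = step_layout(state, net, params, n)
        out.append(state)
    if not out or out[-1] is not state:
        out.append(state)
    return out


def group_outline(state: LayoutState, group, padding: float = 10.0) -> dict:
    """Outline geometry for one group: rectangle, circle or convex hull."""
    pts = np.array([state.coords[m] for m in sorted(group.members)
                    if m in state.coords])
    if pts.size == 0:
        raise IntegrityError(f"group {group.id} has no laid-out members")
    centroid = pts.mean(axis=0)
    geo: dict = {"shape": group.shape, "centroid": tuple(map(float, centroid))}
    if group.shape == "rectangle":
        lo = pts.min(axis=0) - padding
        hi = pts.max(axis=0) + padding
        geo["outline"] = [(float(lo[0]), float(lo[1])), (float(hi[0]), float(lo[1])),
                          (float(hi[0]), float(hi[1])), (float(lo[0]), float(hi[1]))]
    elif group.shape == "circle":
        radius = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).max()) + padding
        geo["radius"] = radius
        angles = np.linspace(0, 2 * np.pi, 33)[:-1]
        geo["outline"] = [(float(centroid[0] + radius * np.cos(a)),
                           float(centroid[1] + radius * np.sin(a))) for a in angles]
    else:  # convex hull
        if len(pts) == 1:
            geo["outline"] = [(float(pts[0, 0]), float(pts[0, 1]))]
        elif len(pts) == 2:
            geo["outline"] = [tuple(map(float, p)) for p in pts]
        else:
            from scipy.spatial import ConvexHull, QhullError
            try:
                hull = ConvexHull(pts)
                verts = pts[hull.vertices]
            except QhullError:  # collinear points
                order = np.lexsort((pts[:, 1], pts[:, 0]))
                verts = pts[[order[0], order[-1]]]
            if padding:
                dist = np.sqrt(((verts - centroid) ** 2).sum(axis=1, keepdims=True))
                verts = centroid + (verts - centroid) * \
                    (1 + padding / np.maximum(dist, 1e-9))
            geo["outline"] = [tuple(map(float, p)) for p in verts]
    return geo
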