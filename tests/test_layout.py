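import math

import numpy as np
import pytest

from modnet import (LayoutParams, Network, frames, group_outline, run_layout,
                    step_layout)
from modnet.errors import IntegrityError
from modnet.layout import LayoutState, _init_state


def _centroid_stats(state, members):
    pos = np.array([state.coords[m] for m in members])
    c = pos.mean(axis=0)
    return c, float(np.mean(np.linalg.norm(pos - c, axis=1)))


def separation_ratio(state, g1, g2):
    c1, r1 = _centroid_stats(state, g1)
    c2, r2 = _centroid_stats(state, g2)
    return float(np.linalg.norm(c1 - c2)) / np.mean([r1, r2])


class TestRunLayout:
    def test_single_node_at_origin(self):
        net = Network()
        net.add_node("only")
        state = run_layout(net)
        assert state.coords["only"] == (0.0, 0.0)
        assert state.converged and state.iteration == 0

    def test_spring_equilibrium_reaches_rest_length(self):
        net = Network()
        net.add_edge("A", "B")
        params = LayoutParams(repulsion_constant=1e-9, seed=3,
                              rest_length=50.0, max_iter=2000)
        state = run_layout(net, params)
        d = math.dist(state.coords["A"], state.coords["B"])
        assert state.converged
        assert abs(d - 50.0) / 50.0 < 0.01

    def test_centroid_normalized_to_origin(self, grouped_cliques):
        state = run_layout(grouped_cliques, LayoutParams(seed=1, max_iter=60))
        pos = np.array(list(state.coords.values()))
        assert np.allclose(pos.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.isfinite(pos))

    def test_determinism_bitwise(self, grouped_cliques):
        p = LayoutParams(seed=42, max_iter=80)
        a = run_layout(grouped_cliques, p)
        b = run_layout(grouped_cliques, p)
        assert a.coords == b.coords and a.iteration == b.iteration

    def test_group_separation_exceeds_intra_radius(self, grouped_cliques):
        state = run_layout(grouped_cliques, LayoutParams(seed=42, max_iter=200))
        c1, r1 = _centroid_stats(state, sorted("ABCDE"))
        c2, r2 = _centroid_stats(state, sorted("VWXYZ"))
        assert np.linalg.norm(c1 - c2) > np.mean([r1, r2])


class TestStepLayout:
    def test_zero_steps_is_identity(self, grouped_cliques):
        p = LayoutParams(seed=5)
        s0 = run_layout(grouped_cliques, LayoutParams(seed=5, max_iter=40))
        s1 = step_layout(s0, grouped_cliques, p, 0)
        assert s0.coords == s1.coords and s0.iteration == s1.iteration

    def test_split_run_equivalence(self, grouped_cliques):
        p = LayoutParams(seed=42, max_iter=100)
        full = run_layout(grouped_cliques, p)
        s = _init_state(grouped_cliques, p)
        for _ in range(4):
            s = step_layout(s, grouped_cliques, p, 25)
        assert full.coords == s.coords
        assert full.iteration == s.iteration

    def test_mismatched_node_set_is_error(self, grouped_cliques, barbell):
        s = _init_state(grouped_cliques, LayoutParams())
        with pytest.raises(IntegrityError):
            step_layout(s, barbell, LayoutParams(), 1)

    def test_raising_group_attraction_tightens_groups(self, grouped_cliques):
        base = LayoutParams(seed=7, convergence_tol=1e-12)
        s = _init_state(grouped_cliques, base)
        s = step_layout(s, grouped_cliques, base, 50)
        _, r_before = _centroid_stats(s, sorted("ABCDE"))
        boosted = LayoutParams(seed=7, group_attraction_gain=12.0,
                               convergence_tol=1e-12)
        s2 = step_layout(s, grouped_cliques, boosted, 50)
        _, r_after = _centroid_stats(s2, sorted("ABCDE"))
        assert r_after < r_before


class TestFrames:
    def test_frame_cadence(self, barbell):
        p = LayoutParams(seed=1, max_iter=10, convergence_tol=0.0)
        seq = frames(barbell, p, every=5)
        assert [f.iteration for f in seq] == [5, 10]

    def test_every_beyond_max_iter_single_frame(self, barbell):
        p = LayoutParams(seed=1, max_iter=10, convergence_tol=0.0)
        seq = frames(barbell, p, every=99)
        assert len(seq) == 1 and seq[0].iteration == 10

    def test_final_frame_matches_run_layout(self, grouped_cliques):
        p = LayoutParams(seed=42, max_iter=60)
        seq = frames(grouped_cliques, p, every=25)
        full = run_layout(grouped_cliques, p)
        assert seq[-1].coords == full.coords


class TestGroupOutline:
    def _state(self, points):
        coords = {f"n{i}": tuple(map(float, p)) for i, p in enumerate(points)}
        return LayoutState(coords=coords, iteration=0, converged=True,
                           _node_order=tuple(coords))

    def _group(self, n, shape):
        from modnet.netmodel import Group
        return Group(id="g", label="g", members={f"n{i}" for i in range(n)},
                     shape=shape)

    def test_convex_hull_of_triangle(self):
        state = self._state([(0, 0), (2, 0), (0, 2)])
        geo = group_outline(state, self._group(3, "convex_hull"), padding=0)
        assert sorted(geo["outline"]) == [(0.0, 0.0), (0.0, 2.0), (2.0, 0.0)]

    def test_rectangle_bounding_box(self):
        state = self._state([(0, 0), (2, 0), (0, 2)])
        geo = group_outline(state, self._group(3, "rectangle"), padding=0)
        assert sorted(geo["outline"]) == [(0.0, 0.0), (0.0, 2.0),
                                          (2.0, 0.0), (2.0, 2.0)]

    def test_singleton_circle_with_padding(self):
        state = self._state([(1, 1)])
        geo = group_outline(state, self._group(1, "circle"), padding=5)
        assert geo["centroid"] == (1.0, 1.0)
        assert geo["radius"] == pytest.approx(5.0)

    def test_hull_contains_all_members(self, grouped_cliques):
        state = run_layout(grouped_cliques, LayoutParams(seed=9, max_iter=50))
        geo = state.group_geometry
        from matplotlib.path import Path as MplPath
        for gid, g in grouped_cliques.groups.items():
            outline = geo[gid]["outline"]
            if len(outline) >= 3:
                path = MplPath(outline)
                pts = [state.coords[m] for m in g.members]
                assert path.contains_points(pts, radius=1e-6).all()
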