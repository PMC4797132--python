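import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modnet import (AlterationTable, ExtractionParams, Network, extract_paths,
                    filter_linkers, linker_pvalue, select_seeds,
                    weight_by_correlation)
from oracles import hypergeom_tail_exact, pearson_exact


def _table(rows):
    return AlterationTable(pd.DataFrame(rows, columns=["gene", "mut_freq",
                                                       "cna_freq"]))


class TestSelectSeeds:
    @pytest.mark.parametrize("mut,cna,selected", [
        (0.03, 0.00, True),    # mutation branch: 0.03 > 0.02
        (0.02, 0.00, False),   # boundary: strict inequality
        (0.01, 0.05, True),    # CNA branch: 0.05 > 0.03
        (0.00, 0.03, False),   # CNA boundary: strict
        (0.00, 0.00, False),
    ])
    def test_threshold_logic(self, mut, cna, selected):
        seeds = select_seeds(_table([("g", mut, cna)]))
        assert (("g" in seeds) is selected)

    def test_empty_result_warns_not_raises(self):
        with pytest.warns(UserWarning):
            assert select_seeds(_table([("g", 0.0, 0.0)])) == set()

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            select_seeds(_table([]))


class TestExtractPaths:
    def test_unique_shortest_path_linker_included(self):
        net = Network()
        net.add_edge("A", "L1")
        net.add_edge("L1", "B")
        out = extract_paths(net, {"A", "B"}, d=2)
        assert set(out.nodes()) == {"A", "L1", "B"}
        assert out.role("L1") == "linker"
        assert out.role("A") == "seed"

    def test_longer_paths_excluded_when_direct_edge_exists(self):
        net = Network()
        net.add_edge("A", "B")
        net.add_edge("A", "L1")
        net.add_edge("L1", "B")
        out = extract_paths(net, {"A", "B"}, d=2)
        assert set(out.nodes()) == {"A", "B"}
        assert out.n_edges == 1

    def test_tied_shortest_paths_all_included(self):
        net = Network()
        for u, v in [("A", "L1"), ("L1", "B"), ("A", "L2"), ("L2", "B")]:
            net.add_edge(u, v)
        out = extract_paths(net, {"A", "B"}, d=2)
        assert set(out.nodes()) == {"A", "L1", "L2", "B"}

    def test_pairs_beyond_distance_threshold_contribute_nothing(self):
        net = Network()
        for u, v in [("A", "x"), ("x", "y"), ("y", "B")]:
            net.add_edge(u, v)
        out = extract_paths(net, {"A", "B"}, d=2)  # distance is 3
        assert set(out.nodes()) == {"A", "B"} and out.n_edges == 0

    def test_output_is_subgraph_and_keeps_all_present_seeds(self):
        rng = np.random.default_rng(5)
        net = Network()
        nodes = [f"n{i}" for i in range(30)]
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.uniform() < 0.12:
                    net.add_edge(nodes[i], nodes[j])
        seeds = {"n0", "n5", "n11", "n17", "n23"}
        present = {s for s in seeds if net.has_node(s)}
        out = extract_paths(net, seeds, d=2)
        assert present <= set(out.nodes())
        for u, v in out.edges():
            assert net.has_edge(u, v)

    def test_fewer_than_two_seeds_warns(self):
        net = Network()
        net.add_edge("A", "B")
        with pytest.warns(UserWarning):
            out = extract_paths(net, {"A"}, d=2)
        assert set(out.nodes()) == {"A"}


class TestLinkerPvalue:
    def test_worked_example(self):
        # (N=20, s=5, k=6, x=4): exact tail is 540/38760
        expected = hypergeom_tail_exact(20, 5, 6, 4)
        assert expected == pytest.approx(540 / 38760)
        assert linker_pvalue(20, 5, 6, 4) == pytest.approx(float(expected), abs=1e-12)

    def test_x_zero_is_one(self):
        assert linker_pvalue(25, 7, 5, 0) == 1.0

    def test_degenerate_universe(self):
        assert linker_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            linker_pvalue(10, 4, 5, 5)  # x > min(k, s)
        with pytest.raises(ValueError):
            linker_pvalue(10, 11, 5, 2)  # s > N

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_bigint_oracle(self, data):
        N = data.draw(st.integers(2, 30))
        s = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, min(s, k)))
        assert linker_pvalue(N, s, k, x) == pytest.approx(
            float(hypergeom_tail_exact(N, s, k, x)), abs=1e-10)

    def test_monotone_nonincreasing_in_x(self):
        N, s, k = 28, 9, 11
        ps = [linker_pvalue(N, s, k, x) for x in range(min(s, k) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestFilterLinkers:
    def _toy(self):
        """Background of 20 nodes where linker LL touches 4 of 5 seeds with
        degree 6: p = 540/38760 ~ 0.0139, above alpha 0.01."""
        bg = Network()
        seeds = [f"S{i}" for i in range(5)]
        others = [f"o{i}" for i in range(14)]
        for n in seeds + others:
            bg.add_node(n)
        for s in seeds[:4]:
            bg.add_edge("LL", s)
        bg.add_edge("LL", "o0")
        bg.add_edge("LL", "o1")
        # extracted net: all 5 seeds plus the candidate linker
        net = bg.subgraph(["LL"] + seeds)
        for s in seeds:
            net.set_role(s, "seed")
        net.set_role("LL", "linker")
        return net, bg

    def test_marginal_linker_removed_at_alpha_001(self):
        net, bg = self._toy()
        out = filter_linkers(net, bg, alpha=0.01)
        assert not out.has_node("LL")
        rec = out.linker_records[0]
        assert (rec.global_degree, rec.seed_links) == (6, 4)
        assert rec.p_value == pytest.approx(540 / 38760, abs=1e-12)

    def test_alpha_one_is_identity(self):
        net, bg = self._toy()
        out = filter_linkers(net, bg, alpha=1.0)
        assert set(out.nodes()) == set(net.nodes())

    def test_seeds_never_removed(self):
        net, bg = self._toy()
        out = filter_linkers(net, bg, alpha=1e-9)
        assert out.nodes_with_role("seed") == net.nodes_with_role("seed")

    def test_no_linkers_unchanged(self):
        bg = Network()
        bg.add_edge("A", "B")
        net = bg.copy()
        net.set_role("A", "seed")
        net.set_role("B", "seed")
        out = filter_linkers(net, bg, alpha=0.01)
        assert set(out.nodes()) == {"A", "B"}
        assert out.linker_records == []

    def test_linker_set_shrinks_as_alpha_decreases(self):
        net, bg = self._toy()
        kept = [set(filter_linkers(net, bg, alpha=a).nodes_with_role("linker"))
                for a in (1.0, 0.05, 0.0139, 0.001)]
        for bigger, smaller in zip(kept, kept[1:]):
            assert smaller <= bigger


class TestWeightByCorrelation:
    def _net(self):
        net = Network()
        net.add_edge("a", "b")
        net.add_edge("b", "c")
        net.add_edge("c", "d")
        return net

    def test_perfect_and_anti_correlation(self):
        net = self._net()
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 3], [3, 2, 1], [5, 5, 5]],
                            index=["a", "b", "c", "d"])
        out = weight_by_correlation(net, expr)
        assert out.edge_attrs("a", "b")["weight"] == pytest.approx(1.0)
        assert out.edge_attrs("b", "c")["weight"] == pytest.approx(-1.0)
        assert out.edge_attrs("b", "c")["similarity"] == pytest.approx(1.0)

    def test_exact_value_against_rational_oracle(self):
        x, y = (1, 2, 3, 4), (1, 2, 3, 10)
        expected = pearson_exact(x, y)  # = 0.8854377448471461
        assert expected == pytest.approx(0.8854377448471461, abs=1e-12)
        net = Network()
        net.add_edge("a", "b")
        expr = pd.DataFrame([x, y], index=["a", "b"])
        out = weight_by_correlation(net, expr)
        assert out.edge_attrs("a", "b")["weight"] == pytest.approx(expected,
                                                                   abs=1e-12)

    def test_zero_variance_gene_gives_zero_weight(self):
        net = self._net()
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 3], [3, 2, 1], [5, 5, 5]],
                            index=["a", "b", "c", "d"])
        with pytest.warns(UserWarning):
            out = weight_by_correlation(net, expr)
        assert out.edge_attrs("c", "d")["weight"] == 0.0
        assert out.edge_attrs("c", "d")["zero_variance"] is True

    def test_missing_gene_flagged(self):
        net = self._net()
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 4], [2, 1, 0]],
                            index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            out = weight_by_correlation(net, expr)
        assert out.edge_attrs("c", "d")["weight"] == 1.0
        assert out.edge_attrs("c", "d")["weight_missing"] is True

    def test_requires_three_samples(self):
        net = self._net()
        expr = pd.DataFrame([[1, 2]], index=["a"])
        with pytest.raises(ValueError):
            weight_by_correlation(net, expr)
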