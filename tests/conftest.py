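import itertools
import textwrap

import pytest

from modnet import Network


@pytest.fixture
def barbell():
    """Two triangles joined by a single bridge edge."""
    net = Network("barbell")
    for u, v in [("A", "B"), ("B", "C"), ("A", "C"),
                 ("D", "E"), ("E", "F"), ("D", "F"), ("C", "D")]:
        net.add_edge(u, v)
    return net


@pytest.fixture
def two_cliques():
    """Two disjoint 4-cliques."""
    net = Network("cliques")
    for u, v in itertools.combinations("ABCD", 2):
        net.add_edge(u, v)
    for u, v in itertools.combinations("WXYZ", 2):
        net.add_edge(u, v)
    return net


@pytest.fixture
def clique_pendant():
    """A 4-clique plus one pendant vertex hanging off it."""
    net = Network("clique_pendant")
    for u, v in itertools.combinations("ABCD", 2):
        net.add_edge(u, v)
    net.add_edge("D", "E")
    return net


@pytest.fixture
def grouped_cliques():
    """Two 5-cliques, each registered as a group (disconnected)."""
    net = Network("grouped")
    for u, v in itertools.combinations("ABCDE", 2):
        net.add_edge(u, v)
    for u, v in itertools.combinations("VWXYZ", 2):
        net.add_edge(u, v)
    net.add_group(set("ABCDE"), label="left")
    net.add_group(set("VWXYZ"), label="right")
    return net


@pytest.fixture
def tiny_obo(tmp_path):
    p = tmp_path / "tiny.obo"
    p.write_text(textwrap.dedent("""\
        format-version: 1.2
        ontology: tiny

        [Term]
        id: GO:0000001
        name: root process
        namespace: biological_process

        [Term]
        id: GO:0000002
        name: branch process
        namespace: biological_process
        is_a: GO:0000001 ! root process

        [Term]
        id: GO:0000003
        name: leaf process
        namespace: biological_process
        is_a: GO:0000002 ! branch process

        [Term]
        id: GO:0000008
        name: other branch
        namespace: molecular_function
        is_a: GO:0000001 ! root process

        [Term]
        id: GO:0000009
        name: obsolete thing
        is_obsolete: true
        """))
    return p


@pytest.fixture
def tiny_annotations(tmp_path):
    """Ten genes: g0-2 on the leaf, g3-5 on the branch, g6-9 on the root."""
    p = tmp_path / "ann.tsv"
    rows = [f"g{i}\tGO:0000003" for i in range(3)]
    rows += [f"g{i}\tGO:0000002" for i in range(3, 6)]
    rows += [f"g{i}\tGO:0000001" for i in range(6, 10)]
    p.write_text("".join(r + "\n" for r in rows))
    return p
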