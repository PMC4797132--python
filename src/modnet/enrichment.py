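"""Gene Ontology over-representation analysis (ORA) for node sets.

Given an ontology (is_a DAG), a gene-annotation file and a query gene set
(typically the members of one network module), each term ``t`` is tested
for enrichment with the upper-tail hypergeometric probability

    p(t) = sum_{i=x}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

where ``N`` is the universe size, ``K`` the number of universe genes
annotated (after propagation to ancestors) to ``t``, ``n`` the effective
query size and ``x`` the overlap.  Annotations are propagated over ``is_a``
edges only; the default universe is every gene with at least one propagated
annotation.  P-values are Benjamini–Hochberg adjusted by default.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .errors import FormatError
from .stats import adjust_pvalues, hypergeom_tail

log = logging.getLogger(__name__)


@dataclass
class OntologyDAG:
    """Terms plus the is_a parent relation (acyclic)."""

    terms: dict[str, tuple[str, str]]      # id -> (name, namespace)
    parents: dict[str, set[str]]           # child -> is_a parents

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for p in self.parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out


@dataclass
class AnnotationMap:
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    universe: set[str]


@dataclass
class EnrichmentResult:
    """Per-term test results, sorted by raw p ascending."""

    table: pd.DataFrame  # term, name, x, n, K, N, p_raw, p_adjusted

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] < alpha]


def load_ontology(obo_path) -> OntologyDAG:
    """Parse an OBO file; obsolete terms are excluded, is_a cycles rejected."""
    graph = obonet.read_obo(obo_path, ignore_obsolete=True)
    dag = nx.DiGraph((c, p) for c, p, rel in graph.edges(keys=True) if rel == "is_a")
    if not nx.is_directed_acyclic_graph(dag):
        raise FormatError(f"is_a cycle in ontology {obo_path}")
    terms = {t: (d.get("name", t), d.get("namespace", ""))
             for t, d in graph.nodes(data=True)}
    parents = {t: set(dag.successors(t)) for t in dag.nodes if t in terms}
    return OntologyDAG(terms=terms, parents=parents)


def load_annotations(path, dag: OntologyDAG,
                     evidence_filter: set[str] | None = None) -> AnnotationMap:
    """Read gene→term annotations from GAF 2.x or a 2-column term/gene TSV.

    Rows referencing unknown (e.g. obsolete) terms are skipped with a
    warning; the propagation closure over is_a ancestors is computed; the
    universe is every annotated gene.
    """
    path = Path(path)
    direct: dict[str, set[str]] = {}
    skipped = 0
    for row in _annotation_rows(path, evidence_filter):
        gene, term = row
        if term not in dag.terms:
            skipped += 1
            continue
        direct.setdefault(term, set()).add(gene)
    if skipped:
        log.warning("skipped %d annotation rows with unknown/obsolete terms", skipped)
    propagated: dict[str, set[str]] = {t: set(gs) for t, gs in direct.items()}
    for term, genes in direct.items():
        for anc in dag.ancestors(term):
            if anc in dag.terms:
                propagated.setdefault(anc, set()).update(genes)
    universe = set().union(*propagated.values()) if propagated else set()
    return AnnotationMap(direct=direct, propagated=propagated, universe=universe)


def _annotation_rows(path: Path, evidence_filter):
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) >= 15:  # GAF 2.x
                if fields[3].strip().upper() == "NOT":
                    continue
                if evidence_filter and fields[6] not in evidence_filter:
                    continue
                yield fields[2].strip(), fields[4].strip()  # symbol, term id
            elif len(fields) == 2:
                a, b = fields[0].strip(), fields[1].strip()
                # term column identified by the GO:-style prefix
                if a.upper().startswith("GO:") or ":" in a and ":" not in b:
                    yield b, a
                else:
                    yield a, b
            else:
                raise FormatError(f"annotation row with {len(fields)} columns "
                                  f"(expected 2 or >=15)")


def overrepresentation(query, ann: AnnotationMap,
                       universe_override: set[str] | None = None,
                       adjust: str = "bh",
                       min_term_size: int = 3,
                       dag: OntologyDAG | None = None,
                       namespace: str | None = None) -> EnrichmentResult:
    """Hypergeometric ORA of ``query`` against the annotation universe."""
    universe = set(universe_override) if universe_override is not None else set(ann.universe)
    query = {str(q).strip() for q in query}
    effective = query & universe
    dropped = query - effective
    if dropped:
        warnings.warn(f"{len(dropped)} query genes absent from the universe were "
                      "dropped")
    if not effective:
        raise ValueError("query has no genes in the universe")
    N, n = len(universe), len(effective)
    rows = []
    for term in sorted(ann.propagated):
        if namespace and dag is not None and dag.terms.get(term, ("", ""))[1] != namespace:
            continue
        genes = ann.propagated[term] & universe
        K = len(genes)
        if K < min_term_size:
            continue
        x = len(genes & effective)
        p = hypergeom_tail(N=N, K=K, n=n, x=x)
        name = dag.terms[term][0] if dag is not None and term in dag.terms else term
        rows.append((term, name, x, n, K, N, p))
    df = pd.DataFrame(rows, columns=["term", "name", "x", "n", "K", "N", "p_raw"])
    df["p_adjusted"] = adjust_pvalues(df["p_raw"].to_numpy(), method=adjust)
    df = df.sort_values(["p_raw", "term"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table=df)
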