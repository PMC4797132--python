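"""Seed-driven subnetwork discovery.

The case-study construction this module implements:

1. **Seed selection** — genes recurrently altered in a patient cohort:
   somatic-mutation frequency strictly above ``mut_freq_min`` (default 0.02)
   OR copy-number-aberration frequency strictly above ``cna_freq_min``
   (default 0.03).
2. **Shortest-path extraction** — from a score-thresholded background
   network, take the union over all seed pairs within graph distance
   ``max_distance`` (default 2) of every node and edge on *any* shortest
   path between them.  Non-seed nodes picked up this way are *linkers*.
3. **Linker significance** — a linker with global degree ``k`` touching
   ``x`` seeds out of ``s`` in a background of ``N`` genes is kept only if
   the upper-tail hypergeometric probability of ``x`` or more seed contacts
   is below ``linker_alpha`` (default 0.01); optionally Benjamini–Hochberg
   adjusted across all candidate linkers.
4. **Correlation weighting** — each surviving edge gets the Pearson
   correlation of its endpoint genes' expression across samples as a signed
   weight; |r| is stored separately as the similarity used by clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netmodel import Network
from .stats import adjust_pvalues, hypergeom_tail

log = logging.getLogger(__name__)


@dataclass
class AlterationTable:
    """Per-gene alteration frequencies in a patient cohort."""

    table: pd.DataFrame  # columns: gene, mut_freq, cna_freq
    n_patients: int | None = None

    def __post_init__(self):
        required = {"gene", "mut_freq", "cna_freq"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"alteration table missing columns {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in alteration table")
        freqs = self.table[["mut_freq", "cna_freq"]].to_numpy(dtype=float)
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("alteration frequencies must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "AlterationTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class LinkerRecord:
    """Hypergeometric evidence for one candidate linker gene."""

    gene: str
    global_degree: int   # k: degree in the background network
    seed_links: int      # x: background neighbors that are seeds
    p_value: float
    p_adjusted: float | None = None


@dataclass
class ExtractionParams:
    max_distance: int = 2
    linker_alpha: float = 0.01
    min_score: float = 900.0
    mut_freq_min: float = 0.02
    cna_freq_min: float = 0.03
    adjust: str = "none"  # 'none' or 'bh'

    def __post_init__(self):
        if self.max_distance < 1:
            raise ValueError("max_distance must be >= 1")
        if not (0 < self.linker_alpha <= 1):
            raise ValueError("linker_alpha must be in (0, 1]")
        for f in ("mut_freq_min", "cna_freq_min"):
            v = getattr(self, f)
            if not (0 <= v <= 1):
                raise ValueError(f"{f} must be in [0, 1]")
        if self.adjust not in ("none", "bh"):
            raise ValueError("adjust must be 'none' or 'bh'")


def select_seeds(tab: AlterationTable,
                 params: ExtractionParams | None = None) -> set[str]:
    """Genes with mut_freq > mut_freq_min OR cna_freq > cna_freq_min (strict)."""
    params = params or ExtractionParams()
    if tab.table.empty:
        raise ValueError("alteration table is empty")
    df = tab.table
    mask = (df["mut_freq"] > params.mut_freq_min) | (df["cna_freq"] > params.cna_freq_min)
    seeds = set(df.loc[mask, "gene"].astype(str))
    if not seeds:
        warnings.warn("no genes pass the alteration thresholds; empty seed set")
    return seeds


def extract_paths(background: Network, seeds, d: int = 2) -> Network:
    """Union of all shortest paths between seed pairs at distance <= d.

    Returns the subnetwork of ``background`` containing every node and edge
    lying on any shortest path between two surviving seeds whose graph
    distance is at most ``d``.  Seeds absent from the background are dropped
    with a warning; non-seed nodes in the result are flagged ``linker``.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    g = background.graph
    seeds = {str(s).strip() for s in seeds}
    surviving = sorted(s for s in seeds if g.has_node(s))
    dropped = seeds - set(surviving)
    if dropped:
        log.warning("extract_paths: %d seeds absent from background", len(dropped))
    if len(surviving) < 2:
        warnings.warn("fewer than 2 seeds present in background; seeds-only network")
        out = background.subgraph(surviving, name="extracted")
        for s in surviving:
            out.set_role(s, "seed")
        return out

    dist = {s: nx.single_source_shortest_path_length(g, s, cutoff=d)
            for s in surviving}
    keep_nodes: set[str] = set(surviving)
    keep_edges: set[frozenset] = set()
    for a, b in combinations(surviving, 2):
        da, db = dist[a], dist[b]
        if b not in da:
            continue  # distance > d contributes nothing
        D = da[b]
        on_path = [v for v in da if v in db and da[v] + db[v] == D]
        keep_nodes.update(on_path)
        on_set = set(on_path)
        for u in on_path:
            for v in g.neighbors(u):
                if v in on_set and da[u] + 1 + db[v] == D:
                    keep_edges.add(frozenset((u, v)))
    out = background.subgraph(keep_nodes, name="extracted")
    # restrict edges to those on a shortest path
    for u, v in list(out.graph.edges):
        if frozenset((u, v)) not in keep_edges:
            out.graph.remove_edge(u, v)
    for n in out.nodes():
        out.set_role(n, "seed" if n in seeds else "linker")
    return out


def linker_pvalue(N: int, s: int, k: int, x: int) -> float:
    """P(a degree-k gene touches >= x of s seeds by chance) in an N-gene net.

    Upper-tail hypergeometric probability
    ``p = sum_{i=x}^{min(k,s)} C(s,i) C(N-s, k-i) / C(N,k)``.
    """
    return hypergeom_tail(N=N, K=s, n=k, x=x)


def filter_linkers(net: Network, background: Network, alpha: float = 0.01,
                   adjust: str = "none") -> Network:
    """Drop linker-flagged nodes whose (adjusted) seed-contact p-value >= alpha.

    The sampling frame is the (score-filtered) background network: ``N`` is
    its node count, ``k`` each linker's degree in it, ``s`` the number of
    seeds present in it and ``x`` the linker's background neighbors that are
    seeds.  Seed nodes are never removed.  The tested records are attached
    to the result as ``result.linker_records``.
    """
    out = net.copy()
    seeds = {s for s in net.nodes_with_role("seed") if background.has_node(s)}
    linkers = sorted(net.nodes_with_role("linker"))
    N = background.n_nodes
    s = len(seeds)
    records: list[LinkerRecord] = []
    for gene in linkers:
        k = background.degree(gene)
        x = len(background.neighbors(gene) & seeds)
        records.append(LinkerRecord(gene=gene, global_degree=k, seed_links=x,
                                    p_value=linker_pvalue(N, s, k, x)))
    adjusted = adjust_pvalues([r.p_value for r in records], method=adjust)
    for r, pa in zip(records, adjusted):
        r.p_adjusted = float(pa)
        if r.p_adjusted >= alpha:
            out.remove_node(r.gene)
    out.linker_records = records  # type: ignore[attr-defined]
    return out


def weight_by_correlation(net: Network, expr: pd.DataFrame) -> Network:
    """Set each edge weight to the Pearson r of its endpoints' expression.

    ``expr`` is genes x samples.  The signed r becomes the edge ``weight``;
    |r| is stored as ``similarity`` for clustering.  Edges with an endpoint
    missing from ``expr`` keep weight 1.0 and are flagged
    ``weight_missing``; a zero-variance endpoint yields weight 0 with a
    warning (r undefined).
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to compute correlations")
    out = net.copy()
    mat = expr.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(expr.index.astype(str))}
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    n_missing = n_flat = 0
    for u, v in out.graph.edges:
        d = out.graph.edges[u, v]
        if u not in index or v not in index:
            d["weight"] = 1.0
            d["similarity"] = 1.0
            d["weight_missing"] = True
            n_missing += 1
            continue
        i, j = index[u], index[v]
        if norms[i] == 0 or norms[j] == 0:
            d["weight"] = 0.0
            d["similarity"] = 0.0
            d["zero_variance"] = True
            n_flat += 1
            continue
        r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
        r = min(1.0, max(-1.0, r))
        d["weight"] = r
        d["similarity"] = abs(r)
    if n_missing:
        warnings.warn(f"{n_missing} edges had endpoints missing from the "
                      "expression matrix; weight left at 1.0")
    if n_flat:
        warnings.warn(f"{n_flat} edges touched zero-variance genes; weight set to 0")
    out.schema.setdefault("weight", "float")
    out.schema.setdefault("similarity", "float")
    return out


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df
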