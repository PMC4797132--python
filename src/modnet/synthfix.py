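"""Deterministic synthetic fixtures emulating a multi-omics module study.

Two generators cover every input the pipeline consumes, with no downloads:

* :func:`planted_network` — a planted-partition (stochastic-block) graph:
  known module labels, within-module edge probability ``p_in``, cross-module
  probability ``p_out``, uniform confidence scores on each edge.  The ground
  truth for clustering-recovery tests.
* :func:`simulate_omics` — expression from a per-module one-factor model
  (gene = sqrt(rho) * module factor + sqrt(1-rho) * noise, so within-module
  pairwise correlation targets ``rho``), per-condition mean shifts for the
  overlay stage, and an alteration table in which a chosen fraction of the
  genes of designated "altered" modules receive mutation/CNA frequencies
  above the selection thresholds while all other genes stay below them.

All randomness flows from a single seeded generator per call; identical
configs give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import AlterationTable
from .netmodel import Network
from .vismap import ConditionSeries


@dataclass
class PlantedConfig:
    n_modules: int = 5
    module_sizes: list[int] = field(default_factory=lambda: [20] * 5)
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0
    score_distribution: tuple[float, float] = (800.0, 1000.0)

    def __post_init__(self):
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        for p in (self.p_in, self.p_out):
            if not (0 <= p <= 1):
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out and self.p_in < 1:
            raise ValueError("p_in must exceed p_out for a recoverable fixture")


@dataclass
class OmicsSimConfig:
    n_samples: int = 100
    rho: float = 0.6              # target within-module pairwise correlation
    noise_sd: float = 1.0
    altered_modules: list[int] = field(default_factory=lambda: [0, 1, 2])
    altered_fraction: float = 0.8
    mut_freq_range: tuple[float, float] = (0.05, 0.25)
    cna_freq_range: tuple[float, float] = (0.05, 0.30)
    background_mut_max: float = 0.015
    background_cna_max: float = 0.025
    conditions: list[str] = field(default_factory=lambda: [
        "proneural", "neural", "classical", "mesenchymal"])
    condition_shift_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.altered_fraction <= 1):
            raise ValueError("altered_fraction must lie in [0, 1]")
        for lo, hi in (self.mut_freq_range, self.cna_freq_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("frequency ranges must be ordered within [0, 1]")


def planted_network(cfg: PlantedConfig) -> tuple[Network, dict[str, int]]:
    """Planted-partition network plus the node -> module label map."""
    rng = np.random.default_rng(cfg.seed)
    labels: dict[str, int] = {}
    net = Network("planted")
    names: list[str] = []
    for m, size in enumerate(cfg.module_sizes):
        for i in range(size):
            name = f"M{m}G{i:02d}"
            names.append(name)
            labels[name] = m
            net.add_node(name)
    n = len(names)
    lo, hi = cfg.score_distribution
    for i in range(n):
        for j in range(i + 1, n):
            p = cfg.p_in if labels[names[i]] == labels[names[j]] else cfg.p_out
            if rng.uniform() < p:
                score = float(rng.uniform(lo, hi))
                net.add_edge(names[i], names[j], score=score)
    return net, labels


def simulate_omics(net: Network, labels: dict[str, int], cfg: OmicsSimConfig
                   ) -> tuple[pd.DataFrame, AlterationTable, ConditionSeries]:
    """Expression matrix, alteration table and condition series for a fixture."""
    genes = sorted(net.nodes())
    missing = [g for g in genes if g not in labels]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} nodes")
    rng = np.random.default_rng(cfg.seed)
    modules = sorted(set(labels.values()))

    # one latent factor per (module, sample); correlated expression within module
    factors = {m: rng.normal(size=cfg.n_samples) for m in modules}
    a, b = np.sqrt(cfg.rho), np.sqrt(1.0 - cfg.rho)
    expr = np.empty((len(genes), cfg.n_samples))
    for gi, g in enumerate(genes):
        noise = rng.normal(size=cfg.n_samples)
        expr[gi] = cfg.noise_sd * (a * factors[labels[g]] + b * noise)
    expr_df = pd.DataFrame(expr, index=genes,
                           columns=[f"S{j:03d}" for j in range(cfg.n_samples)])

    # alteration frequencies: designated modules carry the recurrent alterations
    mut = rng.uniform(0.0, cfg.background_mut_max, len(genes))
    cna = rng.uniform(0.0, cfg.background_cna_max, len(genes))
    altered = set(cfg.altered_modules)
    for m in modules:
        if m not in altered:
            continue
        member_idx = [i for i, g in enumerate(genes) if labels[g] == m]
        n_alt = int(round(cfg.altered_fraction * len(member_idx)))
        chosen = rng.choice(member_idx, size=n_alt, replace=False)
        half = len(chosen) // 2
        mut[chosen[:half]] = rng.uniform(*cfg.mut_freq_range, half)
        cna[chosen[half:]] = rng.uniform(*cfg.cna_freq_range, len(chosen) - half)
    alt = AlterationTable(pd.DataFrame(
        {"gene": genes, "mut_freq": np.round(mut, 4), "cna_freq": np.round(cna, 4)}),
        n_patients=cfg.n_samples)

    # per-condition mean expression with module-specific shifts
    shifts = {(m, c): rng.normal(scale=cfg.condition_shift_sd)
              for m in modules for c in cfg.conditions}
    cond = pd.DataFrame(
        {c: [float(expr_df.loc[g].mean() + shifts[(labels[g], c)]) for g in genes]
         for c in cfg.conditions}, index=genes)
    series = ConditionSeries(conditions=list(cfg.conditions), values=cond)
    return expr_df, alt, series


# ------------------------------------------------------------------- presets
def gbm_like_configs(seed: int = 0) -> tuple[PlantedConfig, OmicsSimConfig]:
    """The end-to-end study fixture: 5 modules x 20 genes, 3 altered modules.

    The raw p_in is set so that the *post-filter* within-module edge
    probability lands at 0.3, the density regime at which planted modules
    of this size are recoverable: the pipeline's confidence filter
    (score > 900 over scores ~ U(800, 1000)) removes half the edges, so
    p_in = 0.6 raw -> 0.3 effective.  This also mirrors real confidence
    networks, where high-confidence subnetworks of true complexes stay dense.
    """
    planted = PlantedConfig(n_modules=5, module_sizes=[20] * 5,
                            p_in=0.6, p_out=0.02, seed=seed,
                            score_distribution=(800.0, 1000.0))
    omics = OmicsSimConfig(seed=seed + 1)
    return planted, omics


def write_fixture_dir(out_dir, seed: int = 0) -> dict[str, Path]:
    """Materialize the gbm-like preset as plain-text files for the CLI."""
    from . import io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pcfg, ocfg = gbm_like_configs(seed)
    net, labels = planted_network(pcfg)
    expr, alt, series = simulate_omics(net, labels, ocfg)
    paths = {
        "interactions": out_dir / "interactions.tsv",
        "alterations": out_dir / "alterations.tsv",
        "expression": out_dir / "expression.tsv",
        "conditions": out_dir / "conditions.tsv",
        "labels": out_dir / "labels.tsv",
    }
    io.write_tsv(net, paths["interactions"])
    alt.to_tsv(paths["alterations"])
    expr.to_csv(paths["expression"], sep="\t", index_label="gene")
    series.values.to_csv(paths["conditions"], sep="\t", index_label="gene")
    with open(paths["labels"], "w") as fh:
        fh.write("gene\tmodule\n")
        for g in sorted(labels):
            fh.write(f"{g}\t{labels[g]}\n")
    return paths
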