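"""End-to-end, file-based analysis pipeline.

Stages run in order — seeds → extract → filter → weight → cluster → groups →
enrich → layout → overlay — each reading the previous stage's file output
and writing its own, so any stage can be rerun or inspected in isolation.
A machine-readable run log records every stage's parameters and the SHA-256
checksum of each output; rerunning an identical config reproduces identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import clustering, discovery, enrichment, io, layout, vismap
from .clustering import MCLParams, MCODEParams
from .discovery import AlterationTable, ExtractionParams
from .errors import ConfigurationError, StageError
from .layout import LayoutParams
from .netmodel import Network
from .vismap import ConditionSeries, VisualMapping

log = logging.getLogger(__name__)

STAGES = ("seeds", "extract", "filter", "weight", "cluster", "groups",
          "enrich", "layout", "overlay")

_SECTIONS = {"inputs", "output", "extraction", "clustering", "layout",
             "enrichment", "mapping"}


@dataclass
class PipelineConfig:
    network_tsv: Path
    alterations_tsv: Path
    expression_tsv: Path
    out_dir: Path
    conditions_tsv: Path | None = None
    obo: Path | None = None
    annotations: Path | None = None
    score_column: str | None = "score"
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    algo: str = "mcl"
    mcl: MCLParams = field(default_factory=MCLParams)
    mcode: MCODEParams = field(default_factory=MCODEParams)
    top_k: int | None = None
    layout_params: LayoutParams = field(default_factory=LayoutParams)
    enrich_adjust: str = "bh"
    min_term_size: int = 3
    mapping: VisualMapping = field(default_factory=lambda: VisualMapping(
        source_attr="expression", target="node_color",
        range=("#2166ac", "#f7f7f7", "#b2182b")))

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        unknown = set(raw) - _SECTIONS
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        try:
            inputs = raw["inputs"]
            out_dir = Path(raw["output"]["dir"])
        except KeyError as exc:
            raise ConfigurationError(f"missing required config key: {exc}") from exc
        base = Path(path).parent

        def _p(name, required=True):
            if name not in inputs:
                if required:
                    raise ConfigurationError(f"missing inputs.{name}")
                return None
            q = Path(inputs[name])
            return q if q.is_absolute() else base / q

        def _section(name, cls_, **extra):
            data = dict(raw.get(name, {}))
            data.update(extra)
            known = cls_.__dataclass_fields__
            bad = set(data) - set(known)
            if bad:
                raise ConfigurationError(f"unknown keys in [{name}]: {sorted(bad)}")
            return cls_(**data)

        clus = dict(raw.get("clustering", {}))
        algo = clus.pop("algo", "mcl")
        if algo not in ("mcl", "mcode"):
            raise ConfigurationError(f"clustering.algo must be mcl|mcode, got {algo!r}")
        top_k = clus.pop("top_k", None)
        params_cls = MCLParams if algo == "mcl" else MCODEParams
        bad = set(clus) - set(params_cls.__dataclass_fields__)
        if bad:
            raise ConfigurationError(f"unknown keys in [clustering]: {sorted(bad)}")
        cfg = cls(
            network_tsv=_p("network"),
            alterations_tsv=_p("alterations"),
            expression_tsv=_p("expression"),
            conditions_tsv=_p("conditions", required=False),
            obo=_p("obo", required=False),
            annotations=_p("annotations", required=False),
            score_column=inputs.get("score_column", "score"),
            out_dir=out_dir if out_dir.is_absolute() else base / out_dir,
            extraction=_section("extraction", ExtractionParams),
            algo=algo, top_k=top_k,
            layout_params=_section("layout", LayoutParams),
            enrich_adjust=raw.get("enrichment", {}).get("adjust", "bh"),
            min_term_size=raw.get("enrichment", {}).get("min_term_size", 3),
        )
        if algo == "mcl":
            cfg.mcl = params_cls(**clus)
        else:
            cfg.mcode = params_cls(**clus)
        enr = set(raw.get("enrichment", {})) - {"adjust", "min_term_size"}
        if enr:
            raise ConfigurationError(f"unknown keys in [enrichment]: {sorted(enr)}")
        mp = raw.get("mapping", {})
        if mp:
            cfg.mapping = VisualMapping(
                source_attr=mp.get("source_attr", "expression"),
                target=mp.get("target", "node_color"),
                domain=tuple(mp["domain"]) if "domain" in mp else "auto",
                range=tuple(mp.get("range", ("#2166ac", "#f7f7f7", "#b2182b"))),
                out_of_domain=mp.get("out_of_domain", "clamp"))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing intermediates and a run log to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []

    def record(stage: str, params: dict, outputs: list[Path]):
        run_log.append({"stage": stage, "parameters": params,
                        "outputs": {p.name: _sha256(p) for p in outputs}})
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1) + "\n")
        log.info("stage %s done (%d outputs)", stage, len(outputs))

    def guard(stage):
        def deco(fn):
            def wrapped(*a, **k):
                try:
                    return fn(*a, **k)
                except Exception as exc:
                    raise StageError(stage, str(exc)) from exc
            return wrapped
        return deco

    # ---- seeds
    @guard("seeds")
    def stage_seeds():
        tab = AlterationTable.from_tsv(config.alterations_tsv)
        seeds = discovery.select_seeds(tab, config.extraction)
        p = out / "01_seeds.txt"
        p.write_text("".join(f"{s}\n" for s in sorted(seeds)))
        record("seeds", {"mut_freq_min": config.extraction.mut_freq_min,
                         "cna_freq_min": config.extraction.cna_freq_min}, [p])
        return seeds

    # ---- extract (score filter + shortest paths)
    @guard("extract")
    def stage_extract(seeds):
        background = io.read_tsv(config.network_tsv,
                                 score_column=config.score_column)
        filtered = Network(background.name + "__filtered")
        filtered.schema = dict(background.schema)
        for u, v, d in background.graph.edges(data=True):
            s = d.get("score")
            if s is None or s > config.extraction.min_score:
                for n_ in (u, v):
                    if not filtered.graph.has_node(n_):
                        filtered.graph.add_node(n_, **dict(background.graph.nodes[n_]))
                filtered.graph.add_edge(u, v, **dict(d))
        net = discovery.extract_paths(filtered, seeds,
                                      d=config.extraction.max_distance)
        p = out / "02_extracted.graphml"
        io.write_graphml(net, p)
        record("extract", {"min_score": config.extraction.min_score,
                           "max_distance": config.extraction.max_distance}, [p])
        return filtered, net

    # ---- linker filter
    @guard("filter")
    def stage_filter(filtered, net):
        kept = discovery.filter_linkers(net, filtered,
                                        alpha=config.extraction.linker_alpha,
                                        adjust=config.extraction.adjust)
        p = out / "03_filtered.graphml"
        io.write_graphml(kept, p)
        recs = getattr(kept, "linker_records", [])
        tsv = out / "03_linker_tests.tsv"
        with open(tsv, "w") as fh:
            fh.write("gene\tglobal_degree\tseed_links\tp_value\tp_adjusted\n")
            for r in recs:
                fh.write(f"{r.gene}\t{r.global_degree}\t{r.seed_links}\t"
                         f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\n")
        record("filter", {"alpha": config.extraction.linker_alpha,
                          "adjust": config.extraction.adjust}, [p, tsv])
        return kept

    # ---- correlation weighting
    @guard("weight")
    def stage_weight(net):
        expr = discovery.read_expression(config.expression_tsv)
        weighted = discovery.weight_by_correlation(net, expr)
        p = out / "04_weighted.graphml"
        io.write_graphml(weighted, p)
        record("weight", {"n_samples": int(expr.shape[1])}, [p])
        return weighted, expr

    # ---- clustering
    @guard("cluster")
    def stage_cluster(net):
        if config.algo == "mcl":
            result = clustering.mcl(net, config.mcl)
            params = asdict(config.mcl)
        else:
            result = clustering.mcode(net, config.mcode)
            params = asdict(config.mcode)
        p = out / "05_clusters.tsv"
        with open(p, "w") as fh:
            fh.write("cluster_id\tnode_id\tscore\n")
            for i, (c, s) in enumerate(zip(result.clusters, result.scores), 1):
                for nd in sorted(c):
                    fh.write(f"cluster_{i}\t{nd}\t{s:.6g}\n")
        record("cluster", dict(params, algo=config.algo), [p])
        return result

    # ---- group promotion
    @guard("groups")
    def stage_groups(net, result):
        clustering.clusters_to_groups(net, result, top_k=config.top_k)
        p = out / "06_grouped.graphml"
        io.write_graphml(net, p)
        record("groups", {"top_k": config.top_k}, [p])
        return net

    # ---- enrichment (optional: needs ontology + annotations)
    @guard("enrich")
    def stage_enrich(net):
        p = out / "07_enrichment.tsv"
        if config.obo is None or config.annotations is None:
            p.write_text("group\tterm\tname\tx\tn\tK\tN\tp_raw\tp_adjusted\n")
            record("enrich", {"skipped": "no ontology/annotations configured"}, [p])
            return None
        dag = enrichment.load_ontology(config.obo)
        ann = enrichment.load_annotations(config.annotations, dag)
        rows = []
        for gid, grp in sorted(net.groups.items()):
            try:
                res = enrichment.overrepresentation(
                    grp.members, ann, adjust=config.enrich_adjust,
                    min_term_size=config.min_term_size, dag=dag)
            except ValueError:
                continue
            t = res.table.copy()
            t.insert(0, "group", gid)
            rows.append(t)
        import pandas as pd
        table = pd.concat(rows, ignore_index=True) if rows else None
        if table is None:
            p.write_text("group\tterm\tname\tx\tn\tK\tN\tp_raw\tp_adjusted\n")
        else:
            table.to_csv(p, sep="\t", index=False)
        record("enrich", {"adjust": config.enrich_adjust,
                          "min_term_size": config.min_term_size}, [p])
        return table

    # ---- layout
    @guard("layout")
    def stage_layout(net):
        state = layout.run_layout(net, config.layout_params)
        for nd, (x, y) in state.coords.items():
            net.graph.nodes[nd]["x"] = x
            net.graph.nodes[nd]["y"] = y
        net.schema.setdefault("x", "float")
        net.schema.setdefault("y", "float")
        p = out / "08_layout.graphml"
        io.write_graphml(net, p)
        geo = out / "08_group_outlines.json"
        geo.write_text(json.dumps(state.group_geometry, indent=1, sort_keys=True,
                                  default=list) + "\n")
        record("layout", {"seed": config.layout_params.seed,
                          "max_iter": config.layout_params.max_iter,
                          "iterations": state.iteration,
                          "converged": state.converged}, [p, geo])
        return state

    # ---- overlay
    @guard("overlay")
    def stage_overlay(net, state, expr):
        frame_dir = out / "09_overlay"
        if config.conditions_tsv is not None:
            series = ConditionSeries.from_tsv(config.conditions_tsv)
        else:  # fall back: mean expression as a single condition
            import pandas as pd
            series = ConditionSeries(
                conditions=["mean_expression"],
                values=pd.DataFrame({"mean_expression": expr.mean(axis=1)}))
        frames = vismap.overlay_series(net, series, config.mapping, state)
        written = vismap.write_frames(frames, frame_dir)
        heat = out / "09_heatmap.tsv"
        order = [nd for g in sorted(net.groups.values(), key=lambda g: g.id)
                 for nd in sorted(g.members)]
        vismap.condition_matrix(series, node_order=order).to_csv(
            heat, sep="\t", index_label="gene")
        record("overlay", {"conditions": series.conditions},
               written + [frame_dir / "styles.json", heat])

    seeds = stage_seeds()
    filtered, extracted = stage_extract(seeds)
    kept = stage_filter(filtered, extracted)
    weighted, expr = stage_weight(kept)
    result = stage_cluster(weighted)
    grouped = stage_groups(weighted, result)
    stage_enrich(grouped)
    state = stage_layout(grouped)
    stage_overlay(grouped, state, expr)
    return out
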