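"""End-to-end orchestration: config validation, staged run, run report.

Stage order mirrors the analysis chain: ingest -> component screen ->
network statistics -> transaction build + Apriori mining -> rule filter ->
EWM/TOPSIS ranking -> bidirectional-target screening -> optional classifier
evaluation, gene-set intersection, docking/enrichment read-and-report.
Mandatory-stage failure aborts with a partial manifest; optional stages
record their failure and the run continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import arm, io, mcda, network, screening
from .errors import ClassBalanceError, ConfigError, FctfError, ParameterError, StageError

logger = logging.getLogger("fctf.pipeline")


@dataclass
class PipelineConfig:
    components: str = ""
    targets: str = ""
    functions: str = ""
    interactions: str | None = None
    docking: str | None = None
    enrichment: str | None = None
    gene_sets: list[str] = field(default_factory=list)

    min_content_pct: float = 1.0
    min_probability: float = 0.0
    min_interaction_score: float = 0.9
    docking_threshold: float = -5.0

    min_support: float = 0.20
    min_confidence: float = 0.35
    min_lift: float = 1.0
    min_leverage: float = 0.0
    min_conviction: float = 0.0
    transaction_mode: str = "both"
    max_itemset_size: int = 2

    min_ct: int = 2
    min_tf: int = 2
    classifier_seed: int = 17
    classifier_folds: int = 5
    run_classifiers: bool = True

    venn_categories: list[str] = field(default_factory=list)
    out_dir: str = "fctf_out"

    def rule_thresholds(self) -> arm.RuleThresholds:
        return arm.RuleThresholds(
            self.min_support, self.min_confidence, self.min_lift,
            self.min_leverage, self.min_conviction,
        )


_REQUIRED_PATHS = ("components", "targets", "functions")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config; unknown keys are rejected, defaults applied.

    Support/confidence thresholds given as percents (> 1) normalise to
    fractions, so ``min_support: 20`` and ``min_support: 0.2`` agree.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparsable config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    config = PipelineConfig(**raw)
    for key in _REQUIRED_PATHS:
        value = getattr(config, key)
        if not value:
            raise ConfigError(f"missing required input path: {key}")
        if not Path(value).exists():
            raise ConfigError(f"{key} path does not exist: {value}")
    for key in ("interactions", "docking", "enrichment"):
        value = getattr(config, key)
        if value and not Path(value).exists():
            raise ConfigError(f"{key} path does not exist: {value}")
    for value in config.gene_sets:
        if not Path(value).exists():
            raise ConfigError(f"gene-set path does not exist: {value}")
    if config.min_support > 1:
        config.min_support /= 100.0
    if config.min_confidence > 1:
        config.min_confidence /= 100.0
    if config.transaction_mode not in ("components", "functions", "both"):
        raise ConfigError(f"unknown transaction_mode {config.transaction_mode!r}")
    return config


@dataclass
class StageRecord:
    stage: str
    status: str  # ok | skipped | failed
    loaded: int = 0
    emitted: int = 0
    seconds: float = 0.0
    detail: str = ""


@dataclass
class RunReport:
    parameters: dict[str, Any]
    stages: list[StageRecord] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    ok: bool = True

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "ok": self.ok,
            "parameters": self.parameters,
            "stages": [vars(s) for s in self.stages],
            "manifest": self.manifest,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> RunReport:
    """Execute the full chain, writing each stage's outputs before the next."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters={k: v for k, v in vars(config).items()})
    written: list[Path] = []

    def record(stage: str, status: str, loaded=0, emitted=0, seconds=0.0, detail=""):
        report.stages.append(StageRecord(stage, status, loaded, emitted, round(seconds, 4), detail))

    def mandatory(stage: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except FctfError as exc:
            record(stage, "failed", detail=str(exc))
            report.ok = False
            _finish(report, out, written)
            raise StageError(f"mandatory stage {stage!r} failed: {exc}") from exc
        return result, time.perf_counter() - start

    # --- ingest -----------------------------------------------------------
    def _ingest():
        library = io.read_component_library(config.components)
        predictions = io.load_predictions(
            config.targets, min_probability_exclusive=config.min_probability
        )
        functions = io.load_functions(config.functions)
        return library, predictions, functions

    (library, predictions, functions), dt = mandatory("ingest", _ingest)
    record("ingest", "ok", loaded=len(library) + len(predictions) + len(functions),
           emitted=len(library) + len(predictions) + len(functions), seconds=dt)

    # --- component screen -------------------------------------------------
    def _screen():
        screened = io.screen_components(library, config.min_content_pct)
        names = {c.name for c in screened}
        kept = [p for p in predictions if p.component in names]
        return screened, kept

    (screened, predictions_s), dt = mandatory("screen", _screen)
    io.write_component_library(screened, out / "components.screened.tsv")
    io.write_predictions(predictions_s, out / "predictions.screened.tsv")
    written += [out / "components.screened.tsv", out / "predictions.screened.tsv"]
    record("screen", "ok", loaded=len(library), emitted=len(screened), seconds=dt)

    # --- network ----------------------------------------------------------
    def _network():
        net = network.build_network(screened, predictions_s, functions)
        tables = {
            layer: network.degree(net, layer)
            for layer in ("component", "target_ct", "target_tf", "category")
        }
        return net, tables

    (net, degree_tables), dt = mandatory("network", _network)
    for layer, table in degree_tables.items():
        path = out / f"degree.{layer}.tsv"
        with path.open("w") as handle:
            handle.write("node\tdegree\n")
            for node, deg in table.entries:
                handle.write(f"{node}\t{deg}\n")
        written.append(path)
    record("network", "ok", loaded=len(net.ct_edges) + len(net.tf_edges),
           emitted=sum(len(t.entries) for t in degree_tables.values()), seconds=dt)

    # optional Venn stage
    if config.venn_categories:
        start = time.perf_counter()
        try:
            result = network.category_overlap(functions, config.venn_categories)
            path = out / "venn.json"
            path.write_text(json.dumps(result.to_json_dict(), indent=2))
            written.append(path)
            record("venn", "ok", loaded=len(functions),
                   emitted=len(result.region_counts), seconds=time.perf_counter() - start)
        except FctfError as exc:
            record("venn", "failed", detail=str(exc), seconds=time.perf_counter() - start)
    else:
        record("venn", "skipped", detail="no venn_categories configured")

    # --- mine + filter ----------------------------------------------------
    def _mine():
        tx = arm.build_transactions(predictions_s, functions, mode=config.transaction_mode)
        itemsets = arm.mine_frequent_itemsets(
            tx, config.min_support, config.max_itemset_size
        )
        rules = arm.derive_rules(itemsets, tx)
        return tx, itemsets, rules

    (tx, itemsets, rules), dt = mandatory("mine", _mine)
    record("mine", "ok", loaded=tx.N, emitted=len(rules), seconds=dt)

    def _filter():
        return arm.filter_rules(rules, config.rule_thresholds())

    filtered, dt = mandatory("filter", _filter)
    arm.write_rules(filtered, out / "rules.tsv")
    written.append(out / "rules.tsv")
    roles = arm.item_role_frequencies(filtered)
    roles.to_csv(out / "rule_item_roles.tsv", sep="\t", index=False)
    written.append(out / "rule_item_roles.tsv")
    record("filter", "ok", loaded=len(rules), emitted=len(filtered), seconds=dt)

    # --- rank (optional: needs >= 2 surviving rules) ----------------------
    start = time.perf_counter()
    if len(filtered) >= 2:
        ranking = mcda.rank_rules(filtered)
        ranking.table.to_csv(out / "ranked_rules.tsv", sep="\t", index=False)
        (out / "weights.json").write_text(
            json.dumps(ranking.weights.to_json_dict(), indent=2)
        )
        written += [out / "ranked_rules.tsv", out / "weights.json"]
        record("rank", "ok", loaded=len(filtered), emitted=len(ranking.table),
               seconds=time.perf_counter() - start)
    else:
        record("rank", "skipped", loaded=len(filtered),
               detail="fewer than 2 rules passed the filter")

    # --- bidirectional screening -----------------------------------------
    def _bidirectional():
        return screening.bidirectional_targets(
            predictions_s, functions, config.min_ct, config.min_tf
        )

    bidirectional, dt = mandatory("screen-targets", _bidirectional)
    path = out / "bidirectional_targets.tsv"
    with path.open("w") as handle:
        handle.write("target\tdegree_ct\tdegree_tf\tbidirectional\n")
        for b in bidirectional:
            handle.write(f"{b.target}\t{b.degree_ct}\t{b.degree_tf}\t{int(b.bidirectional)}\n")
    written.append(path)
    record("screen-targets", "ok", loaded=len(bidirectional),
           emitted=sum(b.bidirectional for b in bidirectional), seconds=dt)

    # --- classifiers (optional) -------------------------------------------
    start = time.perf_counter()
    if config.run_classifiers:
        try:
            features, labels = screening.build_feature_table(bidirectional, filtered)
            reports = screening.evaluate_classifiers(
                features, labels, seed=config.classifier_seed, folds=config.classifier_folds
            )
            for model_report in reports:
                path = out / f"classifier.{model_report.model}.json"
                path.write_text(model_report.to_json())
                written.append(path)
            record("classify", "ok", loaded=len(labels), emitted=len(reports),
                   seconds=time.perf_counter() - start)
        except (ClassBalanceError, ParameterError) as exc:
            record("classify", "failed", detail=str(exc),
                   seconds=time.perf_counter() - start)
    else:
        record("classify", "skipped", detail="disabled in config")

    # --- gene-set intersection (optional) ---------------------------------
    start = time.perf_counter()
    if config.gene_sets:
        try:
            sets: dict[str, set[str]] = {}
            for gene_set_path in config.gene_sets:
                p = Path(gene_set_path)
                if p.suffix.lower() == ".gmt":
                    sets.update(screening.read_gmt(p))
                else:
                    sets[p.stem] = screening.read_symbol_list(p)
            targets_list = network.unique_targets(predictions_s)
            venn_result, core = screening.intersect_gene_sets(targets_list, sets)
            key_map = (
                screening.map_targets_to_components(core, predictions_s, sets)
                if core else screening.KeyTargetMap()
            )
            path = out / "key_targets.json"
            path.write_text(json.dumps(
                {"venn": venn_result.to_json_dict(), "core": core,
                 "back_map": key_map.to_json_dict()}, indent=2))
            written.append(path)
            record("intersect", "ok", loaded=len(sets), emitted=len(core),
                   seconds=time.perf_counter() - start)
        except FctfError as exc:
            record("intersect", "failed", detail=str(exc),
                   seconds=time.perf_counter() - start)
    else:
        record("intersect", "skipped", detail="no gene sets configured")

    # --- docking / enrichment read-and-report (optional) ------------------
    for stage, loader, filename in (
        ("docking", lambda: io.load_docking(config.docking, config.docking_threshold), "docking.tsv"),
        ("enrichment", lambda: io.select_enrichment_terms(io.load_enrichment(config.enrichment)), "enrichment.selected.tsv"),
    ):
        start = time.perf_counter()
        source = getattr(config, stage)
        if not source:
            record(stage, "skipped", detail=f"no {stage} table configured")
            continue
        try:
            records = loader()
            path = out / filename
            with path.open("w") as handle:
                if stage == "docking":
                    handle.write("target\tcomponent\tvina_score\tfavorable\n")
                    for r in records:
                        handle.write(f"{r.target}\t{r.component}\t{r.vina_score}\t{int(r.favorable)}\n")
                else:
                    handle.write("term_id\tontology\tp_value\tgene_count\n")
                    for t in records:
                        handle.write(f"{t.term_id}\t{t.ontology}\t{t.p_value}\t{t.gene_count}\n")
            written.append(path)
            record(stage, "ok", loaded=len(records), emitted=len(records),
                   seconds=time.perf_counter() - start)
        except FctfError as exc:
            record(stage, "failed", detail=str(exc), seconds=time.perf_counter() - start)

    if config.interactions:
        start = time.perf_counter()
        try:
            edges = io.load_interactions(config.interactions, config.min_interaction_score)
            n_nodes, n_edges, table = network.interaction_summary(edges)
            path = out / "interaction_summary.json"
            path.write_text(json.dumps(
                {"nodes": n_nodes, "edges": n_edges,
                 "degree": [[node, deg] for node, deg in table.entries]}, indent=2))
            written.append(path)
            record("interactions", "ok", loaded=len(edges), emitted=n_nodes,
                   seconds=time.perf_counter() - start)
        except FctfError as exc:
            record("interactions", "failed", detail=str(exc),
                   seconds=time.perf_counter() - start)
    else:
        record("interactions", "skipped", detail="no interaction table configured")

    _finish(report, out, written)
    return report


def _finish(report: RunReport, out: Path, written: list[Path]) -> None:
    for path in written:
        if path.exists():
            report.manifest[path.name] = _sha256(path)
    (out / "run_report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
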