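"""Tabular ingestion of the component-target-function data model.

Readers accept CSV/TSV snapshots exported from chemistry and target
databases (component libraries with per-method relative contents,
component->target prediction tables, target->disease catalogs, STRING
interaction exports, docking-result tables, enrichment-term tables) and
normalise them into plain dataclasses.  Every reader takes a ``dialect``
mapping so arbitrary export column headers can be ingested without code
changes, and every screening filter uses a *strict* inequality: boundary
values are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DialectError, ParameterError, ValidationError

logger = logging.getLogger("fctf.io")

#: Controlled vocabulary of chemical classes for component records.
CHEMICAL_CATEGORIES = (
    "terpene",
    "alcohol",
    "aldehyde",
    "ester",
    "acid",
    "ketone",
    "amino_acid",
    "other",
)

ONTOLOGIES = ("BP", "MF", "CC", "KEGG")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class ComponentRecord:
    """One chemical component with its per-detection-method relative contents.

    ``contents`` maps detection-method name -> relative content in percent;
    ``mean_content`` averages only the methods in which the component was
    actually detected.
    """

    name: str
    category: str
    contents: dict[str, float] = field(default_factory=dict)

    @property
    def mean_content(self) -> float:
        if not self.contents:
            return 0.0
        return sum(self.contents.values()) / len(self.contents)

    @property
    def max_content(self) -> float:
        if not self.contents:
            return 0.0
        return max(self.contents.values())


@dataclass(frozen=True)
class TargetPrediction:
    """A predicted component->target edge with a probability score."""

    component: str
    target: str
    probability: float
    smiles: str | None = None


@dataclass(frozen=True)
class FunctionAssociation:
    """A target->disease edge with its disease-category label."""

    target: str
    disease: str
    category: str
    source: str | None = None


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected protein-protein edge with a combined score in [0, 1].

    Endpoints are stored in canonical (sorted) order.
    """

    protein_a: str
    protein_b: str
    combined_score: float


@dataclass(frozen=True)
class DockingRecord:
    """One docking result; ``favorable`` iff vina_score < threshold (strict)."""

    target: str
    component: str
    vina_score: float
    favorable: bool
    pdb_id: str | None = None
    cavity_size: float | None = None


@dataclass(frozen=True)
class EnrichmentTerm:
    """A precomputed enrichment term (GO BP/MF/CC or KEGG)."""

    term_id: str
    description: str
    ontology: str
    p_value: float
    gene_count: int


# ---------------------------------------------------------------------------
# Low-level table reading
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    import csv

    try:
        if delimiter is None:
            frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            frame = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except csv.Error:  # sniffer cannot find a delimiter in a blank/1-field file
        if not path.read_text().strip():
            return pd.DataFrame()
        frame = pd.read_csv(path, sep="\t", dtype=str)
    return frame


def _resolve_columns(
    frame: pd.DataFrame,
    required: Sequence[str],
    optional: Sequence[str],
    dialect: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map logical column names to actual headers via the dialect config."""
    dialect = dict(dialect or {})
    resolved: dict[str, str] = {}
    lower = {c.lower().strip(): c for c in frame.columns}
    for logical in list(required) + list(optional):
        actual = dialect.get(logical, logical)
        if actual in frame.columns:
            resolved[logical] = actual
        elif actual.lower() in lower:
            resolved[logical] = lower[actual.lower()]
        elif logical in required:
            raise ConfigError(
                f"required column {logical!r} (mapped to {actual!r}) "
                f"not found among {list(frame.columns)}"
            )
    return resolved


def _parse_float(value: object, what: str, row: int) -> float:
    try:
        out = float(str(value).strip())
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric {what}: {value!r}") from None
    if math.isnan(out):
        raise ValidationError(f"row {row}: missing {what}")
    return out


def normalize_symbol(symbol: str) -> str:
    """Gene symbols are upper-cased for join stability."""
    return str(symbol).strip().upper()


def normalize_component(name: str) -> str:
    """Component names are lower-cased for join stability."""
    return str(name).strip().lower()


def normalize_disease(name: str) -> str:
    """Disease names compare case-insensitively after whitespace collapse."""
    return " ".join(str(name).split()).lower()


# ---------------------------------------------------------------------------
# Component library
# ---------------------------------------------------------------------------

def read_component_library(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[ComponentRecord]:
    """Read a long-format component table (name, category, method, content).

    Rows sharing a (case-normalised) name are merged into one record whose
    ``contents`` map holds one entry per detection method; record order is
    the input order of first appearance.
    """
    frame = _read_table(path, delimiter)
    if frame.empty:
        raise ValidationError(f"empty component library: {path}")
    cols = _resolve_columns(frame, ["name", "category", "method", "content"], [], dialect)

    records: dict[str, ComponentRecord] = {}
    for i in range(len(frame)):
        row = frame.iloc[i]
        name = normalize_component(row[cols["name"]])
        category = str(row[cols["category"]]).strip().lower()
        method = str(row[cols["method"]]).strip()
        content = _parse_float(row[cols["content"]], "content", i + 2)
        if content < 0:
            raise ValidationError(f"row {i + 2}: negative relative content {content}")
        record = records.get(name)
        if record is None:
            record = ComponentRecord(name=name, category=category)
            records[name] = record
        record.contents[method] = content
    logger.info("component library: %d rows -> %d records", len(frame), len(records))
    return list(records.values())


def screen_components(
    library: Sequence[ComponentRecord],
    min_content_pct: float = 1.0,
) -> list[ComponentRecord]:
    """Retain components whose *maximum* per-method content exceeds the cut.

    A component counts as abundant if it exceeds the threshold under any
    single detection method; the comparison is strict, so a content exactly
    at the threshold is dropped.  Idempotent by construction.
    """
    if min_content_pct < 0:
        raise ParameterError(f"min_content_pct must be >= 0, got {min_content_pct}")
    kept = [c for c in library if c.max_content > min_content_pct]
    logger.info(
        "component screen (> %g%%): %d -> %d", min_content_pct, len(library), len(kept)
    )
    return kept


# ---------------------------------------------------------------------------
# Target predictions
# ---------------------------------------------------------------------------

def load_predictions(
    path: str | Path,
    min_probability_exclusive: float = 0.0,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    library: Sequence[ComponentRecord] | None = None,
) -> list[TargetPrediction]:
    """Load component->target predictions, keeping probability > threshold.

    Duplicate (component, target) pairs collapse to the maximum probability.
    When a screened ``library`` is supplied, predictions for components
    absent from it raise a warning but are kept.
    """
    frame = _read_table(path, delimiter)
    if frame.empty:
        return []
    cols = _resolve_columns(frame, ["component", "target", "probability"], ["smiles"], dialect)
    known = {c.name for c in library} if library is not None else None

    best: dict[tuple[str, str], TargetPrediction] = {}
    for i in range(len(frame)):
        row = frame.iloc[i]
        probability = _parse_float(row[cols["probability"]], "probability", i + 2)
        if not 0.0 <= probability <= 1.0:
            raise ValidationError(
                f"row {i + 2}: probability {probability} outside [0, 1]"
            )
        if probability <= min_probability_exclusive:
            continue
        component = normalize_component(row[cols["component"]])
        target = normalize_symbol(row[cols["target"]])
        smiles = str(row[cols["smiles"]]) if "smiles" in cols and pd.notna(row[cols["smiles"]]) else None
        if known is not None and component not in known:
            logger.warning("prediction row %d: unknown component %r", i + 2, component)
        key = (component, target)
        if key not in best or probability > best[key].probability:
            best[key] = TargetPrediction(component, target, probability, smiles)
    logger.info("predictions: %d rows -> %d edges", len(frame), len(best))
    return list(best.values())


# ---------------------------------------------------------------------------
# Function catalog
# ---------------------------------------------------------------------------

def load_functions(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[FunctionAssociation]:
    """Load the target->disease catalog, deduplicated on (target, disease)."""
    frame = _read_table(path, delimiter)
    if frame.empty:
        return []
    cols = _resolve_columns(frame, ["target", "disease", "category"], ["source"], dialect)

    seen: dict[tuple[str, str], FunctionAssociation] = {}
    for i in range(len(frame)):
        row = frame.iloc[i]
        disease_raw = row[cols["disease"]]
        if pd.isna(disease_raw) or not str(disease_raw).strip():
            logger.warning("function row %d: blank disease name, dropped", i + 2)
            continue
        target = normalize_symbol(row[cols["target"]])
        disease = normalize_disease(disease_raw)
        category = " ".join(str(row[cols["category"]]).split()).lower()
        source = (
            str(row[cols["source"]]) if "source" in cols and pd.notna(row[cols["source"]]) else None
        )
        seen.setdefault((target, disease), FunctionAssociation(target, disease, category, source))
    vocabulary = sorted({a.category for a in seen.values()})
    logger.info(
        "functions: %d rows -> %d associations; categories: %s",
        len(frame), len(seen), ", ".join(vocabulary),
    )
    return list(seen.values())


def category_vocabulary(functions: Iterable[FunctionAssociation]) -> list[str]:
    """Sorted controlled vocabulary of disease categories in a catalog."""
    return sorted({a.category for a in functions})


# ---------------------------------------------------------------------------
# STRING interaction edges
# ---------------------------------------------------------------------------

def load_interactions(
    path: str | Path,
    min_score: float = 0.9,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[InteractionEdge]:
    """Load a STRING-style edge list, keeping combined score > min_score.

    Scores on the raw 0-1000 scale are detected (any value > 1) and divided
    by 1000; a column mixing both scales is rejected.  Self-loops are
    removed, endpoints canonicalised (sorted), and parallel edges collapsed
    to the maximum score.
    """
    frame = _read_table(path, delimiter)
    if frame.empty:
        return []
    dialect = dict(dialect or {})
    dialect.setdefault("protein_a", "node1")
    dialect.setdefault("protein_b", "node2")
    cols = _resolve_columns(frame, ["protein_a", "protein_b", "combined_score"], [], dialect)

    raw: list[tuple[str, str, float]] = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        score = _parse_float(row[cols["combined_score"]], "combined_score", i + 2)
        a = normalize_symbol(row[cols["protein_a"]])
        b = normalize_symbol(row[cols["protein_b"]])
        raw.append((a, b, score))

    scores = [s for _, _, s in raw]
    if any(s > 1.0 for s in scores):
        if any(s <= 1.0 for s in scores):
            raise DialectError(
                "combined_score column mixes values <= 1 with values in (1, 1000]; "
                "cannot decide between fraction and millesimal dialects"
            )
        raw = [(a, b, s / 1000.0) for a, b, s in raw]

    best: dict[tuple[str, str], float] = {}
    dropped_loops = 0
    for a, b, s in raw:
        if a == b:
            dropped_loops += 1
            continue
        key = (min(a, b), max(a, b))
        if s > best.get(key, -1.0):
            best[key] = s
    edges = [
        InteractionEdge(a, b, s) for (a, b), s in best.items() if s > min_score
    ]
    logger.info(
        "interactions: %d rows, %d self-loops removed, %d edges > %g",
        len(frame), dropped_loops, len(edges), min_score,
    )
    return edges


# ---------------------------------------------------------------------------
# Docking results
# ---------------------------------------------------------------------------

def load_docking(
    path: str | Path,
    threshold: float = -5.0,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[DockingRecord]:
    """Load docking scores; favorable iff binding energy < threshold kcal/mol."""
    frame = _read_table(path, delimiter)
    if frame.empty:
        return []
    cols = _resolve_columns(
        frame, ["target", "component", "vina_score"], ["pdb_id", "cavity_size"], dialect
    )
    records = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        vina = _parse_float(row[cols["vina_score"]], "vina_score", i + 2)
        cavity = (
            _parse_float(row[cols["cavity_size"]], "cavity_size", i + 2)
            if "cavity_size" in cols and pd.notna(row[cols["cavity_size"]])
            else None
        )
        pdb = str(row[cols["pdb_id"]]) if "pdb_id" in cols and pd.notna(row[cols["pdb_id"]]) else None
        records.append(
            DockingRecord(
                target=normalize_symbol(row[cols["target"]]),
                component=normalize_component(row[cols["component"]]),
                vina_score=vina,
                favorable=vina < threshold,
                pdb_id=pdb,
                cavity_size=cavity,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Enrichment terms
# ---------------------------------------------------------------------------

def load_enrichment(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[EnrichmentTerm]:
    frame = _read_table(path, delimiter)
    if frame.empty:
        return []
    cols = _resolve_columns(
        frame, ["term_id", "description", "ontology", "p_value", "gene_count"], [], dialect
    )
    terms = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        p = _parse_float(row[cols["p_value"]], "p_value", i + 2)
        n = int(_parse_float(row[cols["gene_count"]], "gene_count", i + 2))
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"row {i + 2}: p_value {p} outside [0, 1]")
        if n < 1:
            raise ValidationError(f"row {i + 2}: gene_count {n} < 1")
        terms.append(
            EnrichmentTerm(
                term_id=str(row[cols["term_id"]]).strip(),
                description=str(row[cols["description"]]).strip(),
                ontology=str(row[cols["ontology"]]).strip().upper(),
                p_value=p,
                gene_count=n,
            )
        )
    return terms


def select_enrichment_terms(
    terms: Sequence[EnrichmentTerm],
    alpha: float = 0.01,
    top_n: int = 20,
) -> list[EnrichmentTerm]:
    """Per ontology: terms with p < alpha (strict), top ``top_n`` by p.

    Ties in p break by descending gene_count, then term_id.  The result is
    a flat list ordered by ontology (BP, MF, CC, KEGG, then others) and rank
    within ontology.
    """
    order = {o: i for i, o in enumerate(ONTOLOGIES)}
    selected: list[EnrichmentTerm] = []
    ontologies = sorted(
        {t.ontology for t in terms}, key=lambda o: (order.get(o, len(order)), o)
    )
    for ontology in ontologies:
        pool = [t for t in terms if t.ontology == ontology and t.p_value < alpha]
        pool.sort(key=lambda t: (t.p_value, -t.gene_count, t.term_id))
        selected.extend(pool[:top_n])
    return selected


# ---------------------------------------------------------------------------
# Writers (round-trip support and pipeline outputs)
# ---------------------------------------------------------------------------

def write_component_library(library: Sequence[ComponentRecord], path: str | Path) -> None:
    rows = [
        {"name": c.name, "category": c.category, "method": m, "content": v}
        for c in library
        for m, v in c.contents.items()
    ]
    pd.DataFrame(rows, columns=["name", "category", "method", "content"]).to_csv(
        path, sep="\t", index=False
    )


def write_predictions(predictions: Sequence[TargetPrediction], path: str | Path) -> None:
    rows = [
        {"component": p.component, "target": p.target, "probability": p.probability,
         "smiles": p.smiles or ""}
        for p in predictions
    ]
    pd.DataFrame(rows, columns=["component", "target", "probability", "smiles"]).to_csv(
        path, sep="\t", index=False
    )


def write_functions(functions: Sequence[FunctionAssociation], path: str | Path) -> None:
    rows = [
        {"target": a.target, "disease": a.disease, "category": a.category,
         "source": a.source or ""}
        for a in functions
    ]
    pd.DataFrame(rows, columns=["target", "disease", "category", "source"]).to_csv(
        path, sep="\t", index=False
    )
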