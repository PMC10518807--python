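"""Parsing of the two source dialects and record-level qualification.

Parsing is deliberately lossless: every input row becomes an
:class:`~kinicurate.records.ActivityRecord`, including rows with malformed
values or non-qualifying measurement types.  All filtering happens in
:func:`qualify`, which is a total function — a record either becomes an
active/inactive candidate or is discarded with a named reason, and the
:class:`~kinicurate.records.QualificationReport` accounts for every row
exactly once.

Qualification rules
-------------------
* measurement type must be IC50, Ki or Kd;
* ChEMBL-dialect records additionally need the SINGLE PROTEIN target
  category, confidence score 9, no blacklisted activity comment and no
  active/inactive label conflicting with the 10 µM threshold;
* BindingDB-dialect records must come from single-chain targets;
* units must normalize to nM (µM/mM/M values are converted, not discarded);
* relation "=" with value ≤ 10,000 nM → active candidate, "=" above the
  threshold → inactive candidate; ">"/">>" with value ≥ 10,000 nM →
  qualitative inactive candidate; every other relation is uninformative.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .records import (
    QUALIFYING_TYPES,
    ActivityRecord,
    MeasurementType,
    Organism,
    QualificationReport,
    Relation,
    Source,
)

DEFAULT_THRESHOLD_NM = 10_000.0

DEFAULT_COMMENT_BLACKLIST = (
    "uncertain",
    "potential transcription error",
    "outside typical range",
)

_UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "mm": 1e6,
    "m": 1e9,
}

_TYPE_ALIASES = {
    "ic50": MeasurementType.IC50,
    "ki": MeasurementType.KI,
    "kd": MeasurementType.KD,
}

_RELATION_ALIASES = {
    "=": Relation.EQ,
    ">": Relation.GT,
    ">>": Relation.GTGT,
    "<": Relation.LT,
}


class ConfigurationError(Exception):
    """A structural problem with the input file (e.g. missing column)."""


@dataclass
class QualifyConfig:
    threshold_nM: float = DEFAULT_THRESHOLD_NM
    comment_blacklist: tuple[str, ...] = DEFAULT_COMMENT_BLACKLIST
    required_confidence: int = 9
    required_target_category: str = "SINGLE PROTEIN"


@dataclass
class QualifyResult:
    QUALIFIED_ACTIVE_CANDIDATE = "QUALIFIED_ACTIVE_CANDIDATE"
    QUALIFIED_INACTIVE_CANDIDATE = "QUALIFIED_INACTIVE_CANDIDATE"
    DISCARD = "DISCARD"

    outcome: str
    reason: str | None = None

    @property
    def qualified(self) -> bool:
        return self.outcome != self.DISCARD


def load_dialect_presets(path: Path | None = None) -> dict[str, dict[str, str]]:
    """Load the column-mapping presets ("chembl", "bindingdb")."""
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    ref = importlib.resources.files("kinicurate.data") / "dialects.yaml"
    return yaml.safe_load(ref.read_text())


def load_kinase_table(path: Path) -> dict[str, dict]:
    """Read the kinase annotation TSV (uniprot_id, pref_name, organism)."""
    table: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"uniprot_id", "pref_name", "organism"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ConfigurationError(
                f"kinase table is missing required column(s): {sorted(missing)}"
            )
        for row in reader:
            org = _parse_organism(row["organism"])
            table[row["uniprot_id"]] = {
                "pref_name": row["pref_name"],
                "organism": org,
            }
    return table


def _parse_organism(text: str) -> Organism | None:
    t = (text or "").strip().lower()
    if t in {"human", "homo sapiens"}:
        return Organism.HUMAN
    if t in {"mouse", "mus musculus"}:
        return Organism.MOUSE
    return None


def _parse_float(text: str | None) -> float | None:
    if text is None:
        return None
    try:
        v = float(text)
    except (TypeError, ValueError):
        return None
    return v


def _parse_type(text: str | None) -> tuple[MeasurementType, str]:
    raw = (text or "").strip()
    return _TYPE_ALIASES.get(raw.lower(), MeasurementType.OTHER), raw


def _parse_relation(text: str | None) -> Relation:
    raw = (text or "").strip().strip("'\"")
    return _RELATION_ALIASES.get(raw, Relation.OTHER)


def _open_rows(table_path: Path, columns: dict[str, str]) -> Iterator[dict]:
    with open(table_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"{table_path}: empty input file", stacklevel=3)
            return
        missing = set(columns.values()) - set(reader.fieldnames)
        if missing:
            raise ConfigurationError(
                f"{table_path}: missing required column(s): {sorted(missing)}"
            )
        yield from reader


def parse_chembl_dialect(
    table_path: Path,
    kinase_table: dict[str, dict],
    columns: dict[str, str] | None = None,
) -> Iterator[ActivityRecord]:
    """Parse a ChEMBL-dialect export into a stream of records."""
    cols = columns or load_dialect_presets()["chembl"]
    for row in _open_rows(Path(table_path), cols):
        mtype, raw_type = _parse_type(row.get(cols["measurement_type"]))
        uniprot = (row.get(cols["uniprot"]) or "").strip()
        ann = kinase_table.get(uniprot)
        label = (row.get(cols["activity_label"]) or "").strip().lower() or None
        yield ActivityRecord(
            record_id=str(row.get(cols["record_id"], "")),
            source=Source.CHEMBL_DIALECT,
            compound_smiles=(row.get(cols["smiles"]) or "").strip(),
            kinase_uniprot=uniprot,
            organism=ann["organism"] if ann else None,
            measurement_type=mtype,
            relation=_parse_relation(row.get(cols["relation"])),
            value_nM=_parse_float(row.get(cols["value"])),
            units=(row.get(cols["units"]) or "").strip() or None,
            target_category=(row.get(cols["target_category"]) or "").strip() or None,
            confidence_score=_parse_int(row.get(cols["confidence_score"])),
            activity_comment=(row.get(cols["activity_comment"]) or "").strip() or None,
            activity_label=label if label in {"active", "inactive"} else None,
            raw_type=raw_type,
        )


def parse_bindingdb_dialect(
    table_path: Path,
    kinase_table: dict[str, dict],
    columns: dict[str, str] | None = None,
) -> Iterator[ActivityRecord]:
    """Parse a BindingDB-dialect export into a stream of records.

    Fields absent from this dialect (confidence score, target category,
    comments, labels) are set to ``None``; qualification treats absence as a
    pass for those ChEMBL-only filters.
    """
    cols = columns or load_dialect_presets()["bindingdb"]
    for row in _open_rows(Path(table_path), cols):
        mtype, raw_type = _parse_type(row.get(cols["measurement_type"]))
        uniprot = (row.get(cols["uniprot"]) or "").strip()
        ann = kinase_table.get(uniprot)
        yield ActivityRecord(
            record_id=str(row.get(cols["record_id"], "")),
            source=Source.BINDINGDB_DIALECT,
            compound_smiles=(row.get(cols["smiles"]) or "").strip(),
            kinase_uniprot=uniprot,
            organism=ann["organism"] if ann else None,
            measurement_type=mtype,
            relation=_parse_relation(row.get(cols["relation"])),
            value_nM=_parse_float(row.get(cols["value"])),
            units="nM",
            n_chains=_parse_int(row.get(cols["n_chains"])),
            raw_type=raw_type,
        )


def _parse_int(text: str | None) -> int | None:
    try:
        return int(float(text))  # tolerate "9.0"
    except (TypeError, ValueError):
        return None


def normalize_units(record: ActivityRecord) -> ActivityRecord | None:
    """Convert the value to nM in place; return None for unknown units."""
    if record.value_nM is None:
        return record
    unit = (record.units or "nM").strip().lower()
    factor = _UNIT_TO_NM.get(unit)
    if factor is None:
        return None
    if factor != 1.0:
        record.value_nM = record.value_nM * factor
        record.units = "nM"
    return record


def qualify(record: ActivityRecord, config: QualifyConfig | None = None) -> QualifyResult:
    """Classify one parsed record as active/inactive candidate or discard.

    Total and order-independent: the outcome depends only on the record's
    own fields.
    """
    cfg = config or QualifyConfig()

    if not record.compound_smiles:
        return QualifyResult(QualifyResult.DISCARD, "missing_smiles")
    if record.organism is None:
        return QualifyResult(QualifyResult.DISCARD, "unknown_kinase")
    if record.measurement_type not in QUALIFYING_TYPES:
        return QualifyResult(QualifyResult.DISCARD, "excluded_type")

    if record.source is Source.CHEMBL_DIALECT:
        if (record.target_category or "").upper() != cfg.required_target_category:
            return QualifyResult(QualifyResult.DISCARD, "not_single_protein")
        if record.confidence_score != cfg.required_confidence:
            return QualifyResult(QualifyResult.DISCARD, "low_confidence")
        comment = (record.activity_comment or "").lower()
        if comment and any(phrase in comment for phrase in cfg.comment_blacklist):
            return QualifyResult(QualifyResult.DISCARD, "comment_blacklist")
    elif record.source is Source.BINDINGDB_DIALECT:
        if record.n_chains is not None and record.n_chains != 1:
            return QualifyResult(QualifyResult.DISCARD, "multi_chain_target")

    if record.value_nM is None:
        return QualifyResult(QualifyResult.DISCARD, "unparseable_value")
    if normalize_units(record) is None:
        return QualifyResult(QualifyResult.DISCARD, "bad_units")

    rel, value = record.relation, record.value_nM
    if rel is Relation.EQ:
        outcome = (
            QualifyResult.QUALIFIED_ACTIVE_CANDIDATE
            if value <= cfg.threshold_nM
            else QualifyResult.QUALIFIED_INACTIVE_CANDIDATE
        )
    elif rel in (Relation.GT, Relation.GTGT):
        if value >= cfg.threshold_nM:
            outcome = QualifyResult.QUALIFIED_INACTIVE_CANDIDATE
        else:
            return QualifyResult(QualifyResult.DISCARD, "uninformative_relation")
    else:  # LT or OTHER: no verifiable point potency or activity class
        return QualifyResult(QualifyResult.DISCARD, "uninformative_relation")

    if record.activity_label is not None:
        labelled_active = record.activity_label == "active"
        classified_active = outcome == QualifyResult.QUALIFIED_ACTIVE_CANDIDATE
        if labelled_active != classified_active:
            return QualifyResult(QualifyResult.DISCARD, "label_conflict")

    return QualifyResult(outcome)


@dataclass
class QualifiedSet:
    """The output of a qualification pass over one or more input streams."""

    records: list[ActivityRecord] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    report: QualificationReport = field(default_factory=QualificationReport)


def qualify_stream(
    records: Iterable[ActivityRecord], config: QualifyConfig | None = None
) -> QualifiedSet:
    """Qualify a record stream, keeping candidates and full bookkeeping."""
    out = QualifiedSet()
    for record in records:
        out.report.n_read += 1
        result = qualify(record, config)
        if result.qualified:
            out.report.n_qualified += 1
            out.records.append(record)
            out.outcomes.append(result.outcome)
        else:
            out.report.discard(result.reason)
    return out
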