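"""Interchange formats: JSON event documents, TSV import, timeline and
rule serialization, YAML configuration.

JSON is the canonical format (causal links nest naturally); TSV is a
convenience importer.  ``raw_time`` strings are stored verbatim — a TAP
displays the original expression, never a normalised date — and all
resolved timestamps are ISO-8601.  Documents are schema-validated with
named error locations; unknown fields are rejected.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml
from pydantic import (BaseModel, ConfigDict, Field, ValidationError,
                      field_validator)

from .model import (ClinicalEvent, PatientTimeline, VStructure,
                    semantic_type)
from .patterns import (DurationBounds, MiningResult, PatternSignature,
                       PhenotypeRule, SignatureMode)
from .renderer import RenderConfig
from .temporal import (AnchorKind, CalendarInterval, Dialect, FuzzyModifier,
                       Granularity, TemporalAnchor, Unit)

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "EventRecord",
    "InterchangeDocument",
    "PatientRecord",
    "document_from_patients",
    "load_config",
    "read_events",
    "read_rules",
    "read_timeline",
    "to_clinical_events",
    "write_events",
    "write_rules",
    "write_timeline",
]

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    """A document failed schema validation; message names the location."""


class EventRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    event_id: str = Field(min_length=1)
    text: str
    semantic_type: str
    appearance_index: int = Field(ge=0)
    raw_time: str = ""
    causal_links: list[str] = Field(default_factory=list)

    @field_validator("semantic_type")
    @classmethod
    def _known_tag(cls, value: str) -> str:
        try:
            semantic_type(value)
        except KeyError:
            raise ValueError(f"unknown semantic tag {value!r}")
        return value


class PatientRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str = Field(min_length=1)
    anchor_date: Optional[date] = None
    events: list[EventRecord] = Field(default_factory=list)


class InterchangeDocument(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: str
    patients: list[PatientRecord] = Field(default_factory=list)

    @field_validator("schema_version")
    @classmethod
    def _supported(cls, value: str) -> str:
        if value != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {value!r}; "
                f"this reader supports {SCHEMA_VERSION!r}")
        return value


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(part) for part in loc)


def _wrap_validation_error(exc: ValidationError) -> SchemaError:
    lines = [f"at {_pointer(err['loc'])}: {err['msg']}"
             for err in exc.errors()]
    return SchemaError("schema violation: " + "; ".join(lines))


def _validate_document(payload: Any) -> InterchangeDocument:
    try:
        doc = InterchangeDocument.model_validate(payload)
    except ValidationError as exc:
        raise _wrap_validation_error(exc) from None
    seen: set[tuple[str, str]] = set()
    for patient in doc.patients:
        for ev in patient.events:
            key = (patient.patient_id, ev.event_id)
            if key in seen:
                raise SchemaError(
                    f"duplicate event_id {ev.event_id!r} for patient "
                    f"{patient.patient_id!r}")
            seen.add(key)
    return doc


_TSV_COLUMNS = ["patient_id", "event_id", "appearance_index",
                "semantic_type", "text", "raw_time", "causal_links"]


def read_events(path: "str | Path", format: str = "json"
                ) -> InterchangeDocument:
    """Read and schema-validate an events document (``json`` or ``tsv``).

    Errors carry a JSON-pointer (JSON) or row/column (TSV) location.
    """
    path = Path(path)
    if format == "json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from None
        return _validate_document(payload)
    if format == "tsv":
        return _read_events_tsv(path)
    raise ValueError(f"unknown format {format!r}; expected 'json' or 'tsv'")


def _read_events_tsv(path: Path) -> InterchangeDocument:
    patients: dict[str, list[dict]] = {}
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in _TSV_COLUMNS
                   if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(
                f"TSV header missing column(s): {', '.join(missing)}")
        for row_no, row in enumerate(reader, start=2):
            tag = row["semantic_type"]
            try:
                semantic_type(tag)
            except KeyError:
                raise SchemaError(
                    f"row {row_no}, column semantic_type: unknown semantic "
                    f"tag {tag!r}") from None
            try:
                index = int(row["appearance_index"])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"row {row_no}, column appearance_index: not an "
                    f"integer: {row['appearance_index']!r}") from None
            links = [part for part in (row["causal_links"] or "").split(";")
                     if part]
            patients.setdefault(row["patient_id"], []).append({
                "event_id": row["event_id"],
                "text": row["text"],
                "semantic_type": tag,
                "appearance_index": index,
                "raw_time": row["raw_time"] or "",
                "causal_links": links,
            })
    payload = {"schema_version": SCHEMA_VERSION,
               "patients": [{"patient_id": pid, "events": events}
                            for pid, events in patients.items()]}
    return _validate_document(payload)


def write_events(document: InterchangeDocument, path: "str | Path") -> None:
    Path(path).write_text(
        json.dumps(document.model_dump(mode="json"), indent=2,
                   ensure_ascii=False) + "\n", encoding="utf-8")


def to_clinical_events(patient: PatientRecord) -> list[ClinicalEvent]:
    return [ClinicalEvent(ev.event_id, ev.text, ev.semantic_type,
                          ev.appearance_index, ev.raw_time,
                          set(ev.causal_links))
            for ev in patient.events]


def document_from_patients(
        patients: Sequence[tuple[str, Optional[date],
                                 Sequence[ClinicalEvent]]]
) -> InterchangeDocument:
    return InterchangeDocument(
        schema_version=SCHEMA_VERSION,
        patients=[PatientRecord(
            patient_id=pid, anchor_date=anchor,
            events=[EventRecord(
                event_id=ev.event_id, text=ev.text,
                semantic_type=ev.semantic_type,
                appearance_index=ev.appearance_index,
                raw_time=ev.raw_time,
                causal_links=sorted(ev.causal_links))
                for ev in events])
            for pid, anchor, events in patients])


# ---------------------------------------------------------------------------
# timelines

def _event_to_dict(ev: ClinicalEvent) -> dict:
    return {"event_id": ev.event_id, "text": ev.text,
            "semantic_type": ev.semantic_type,
            "appearance_index": ev.appearance_index,
            "raw_time": ev.raw_time,
            "causal_links": sorted(ev.causal_links)}


def _event_from_dict(data: dict) -> ClinicalEvent:
    try:
        record = EventRecord.model_validate(data)
    except ValidationError as exc:
        raise _wrap_validation_error(exc) from None
    return ClinicalEvent(record.event_id, record.text, record.semantic_type,
                         record.appearance_index, record.raw_time,
                         set(record.causal_links))


def _tap_to_dict(tap: TemporalAnchor) -> dict:
    interval = None
    if tap.interval is not None:
        interval = {"earliest": tap.interval.earliest.isoformat(),
                    "latest": tap.interval.latest.isoformat()}
    return {"raw_text": tap.raw_text, "kind": tap.kind.value,
            "granularity": tap.granularity.value,
            "fuzzy_modifier": tap.fuzzy_modifier.value,
            "open_start": tap.open_start, "interval": interval}


def _tap_from_dict(data: dict) -> TemporalAnchor:
    interval = None
    if data.get("interval") is not None:
        interval = CalendarInterval(
            datetime.fromisoformat(data["interval"]["earliest"]),
            datetime.fromisoformat(data["interval"]["latest"]))
    return TemporalAnchor(
        raw_text=data["raw_text"], kind=AnchorKind(data["kind"]),
        granularity=Granularity(data["granularity"]),
        fuzzy_modifier=FuzzyModifier(data["fuzzy_modifier"]),
        open_start=bool(data["open_start"]), interval=interval)


def write_timeline(timeline: PatientTimeline, path: "str | Path") -> None:
    """Serialise a timeline losslessly (verbatim raw_time included)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": timeline.patient_id,
        "anchor_date": (timeline.anchor_date.isoformat()
                        if timeline.anchor_date else None),
        "structures": [{
            "structure_id": v.structure_id,
            "visit_only": v.visit_only,
            "tap": _tap_to_dict(v.tap),
            "problems": [_event_to_dict(ev) for ev in v.problems],
            "actions": [_event_to_dict(ev) for ev in v.actions],
            "visits": [_event_to_dict(ev) for ev in v.visits],
        } for v in timeline.structures],
    }
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False)
                          + "\n", encoding="utf-8")


def read_timeline(path: "str | Path") -> PatientTimeline:
    """Read a timeline document; inverse of :func:`write_timeline`."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(payload, dict):
        raise SchemaError("timeline document must be a JSON object")
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {version!r}; "
            f"this reader supports {SCHEMA_VERSION!r}")
    known = {"schema_version", "patient_id", "anchor_date", "structures"}
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(
            f"unknown field(s) in timeline document: "
            f"{', '.join(sorted(unknown))}")
    try:
        structures = []
        for s in payload["structures"]:
            structures.append(VStructure(
                structure_id=s["structure_id"],
                tap=_tap_from_dict(s["tap"]),
                problems=[_event_from_dict(e) for e in s["problems"]],
                actions=[_event_from_dict(e) for e in s["actions"]],
                visits=[_event_from_dict(e) for e in s["visits"]],
                visit_only=bool(s.get("visit_only", False))))
        anchor = (date.fromisoformat(payload["anchor_date"])
                  if payload.get("anchor_date") else None)
        return PatientTimeline(payload["patient_id"], structures, anchor)
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(f"malformed timeline document: {exc}") from None


# ---------------------------------------------------------------------------
# mined rules

def _signature_to_dict(sig: PatternSignature) -> dict:
    return {"mode": sig.mode.value,
            "blocks": [[[list(problems), list(actions)]
                        for problems, actions in block]
                       for block in sig.blocks]}


def _signature_from_dict(data: dict) -> PatternSignature:
    blocks = tuple(
        tuple((tuple(problems), tuple(actions))
              for problems, actions in block)
        for block in data["blocks"])
    return PatternSignature(blocks, SignatureMode(data["mode"]))


def _rule_to_dict(rule: PhenotypeRule) -> dict:
    constraint = None
    if rule.temporal_constraint is not None:
        constraint = {"min_units": rule.temporal_constraint.min_units,
                      "max_units": rule.temporal_constraint.max_units,
                      "unit": rule.temporal_constraint.unit.value}
    return {"include": _signature_to_dict(rule.include),
            "exclude_preceding": [_signature_to_dict(s)
                                  for s in rule.exclude_preceding],
            "temporal_constraint": constraint}


def _rule_from_dict(data: dict) -> PhenotypeRule:
    constraint = None
    if data.get("temporal_constraint") is not None:
        c = data["temporal_constraint"]
        constraint = DurationBounds(c["min_units"], c["max_units"],
                                    Unit(c["unit"]))
    return PhenotypeRule(
        include=_signature_from_dict(data["include"]),
        exclude_preceding=tuple(_signature_from_dict(s)
                                for s in data.get("exclude_preceding", [])),
        temporal_constraint=constraint)


def write_rules(results: Sequence[MiningResult], path: "str | Path") -> None:
    payload = {"schema_version": SCHEMA_VERSION,
               "rules": [{
                   **_rule_to_dict(r.rule),
                   "support_target": r.support_target,
                   "support_background": r.support_background,
                   "confusion": {"tp": r.confusion[0], "fp": r.confusion[1],
                                 "fn": r.confusion[2], "tn": r.confusion[3]},
               } for r in results]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_rules(path: "str | Path") -> list[PhenotypeRule]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version "
            f"{payload.get('schema_version')!r}")
    return [_rule_from_dict(item) for item in payload["rules"]]


# ---------------------------------------------------------------------------
# configuration

def load_config(path: "str | Path") -> dict:
    """Load the YAML configuration (dialect / render / simulate sections)."""
    with Path(path).open(encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise SchemaError("config must be a YAML mapping")
    return data


def dialect_from_config(config: dict) -> Dialect:
    section = config.get("dialect", {}) or {}
    return Dialect(
        century_pivot=int(section.get("century_pivot", 30)),
        lexicon={str(k).casefold(): str(v)
                 for k, v in (section.get("lexicon") or {}).items()})


def render_config_from_config(config: dict) -> RenderConfig:
    section = dict(config.get("render", {}) or {})
    valid = set(RenderConfig.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise SchemaError(
            f"unknown render option(s): {', '.join(sorted(unknown))}")
    return RenderConfig(**section)
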