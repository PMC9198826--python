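"""Patient records, quality-control filtering, and chronological tokenization.

A :class:`PatientRecord` is the structured form of one inpatient chart:
demographics, time-stamped clinical facts grouped into the standard chart
sections, and the physician's reference prescriptions (drug-id sets) at each
order time.  :func:`extract_tokens` converts a record into the chronological
token sequence the embedding and classification stages consume, truncated at
an evaluation cutoff so the model only ever sees information available at
prediction time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SECTIONS", "ClinicalFact", "Order", "PatientRecord", "TokenSequence",
    "qc_filter", "extract_tokens", "write_records_jsonl", "read_records_jsonl",
    "CUTOFF_ALIASES", "parse_cutoff",
]

# The chart sections facts may come from, in chart order.  Demography is
# synthesised from the record header rather than stored as facts but keeps
# rank 0 so demographic tokens always lead the sequence.
SECTIONS = (
    "demography",
    "chief_complaints",
    "recent_medical_history",
    "past_medical_history",
    "present_illness",
    "body_check",
    "treatment_process",
    "physician_orders",
    "nursing_notes",
    "examination_reports",
    "laboratory_reports",
)
_SECTION_RANK = {s: i for i, s in enumerate(SECTIONS)}

# standard token alphabet; anything else counts as a nonstandard description
_STANDARD_TOKEN = re.compile(r"^[a-z0-9_:.=+-]+$")

SPECIAL_CIRCUMSTANCES = ("chemotherapy", "post_operation", "fracture_setting_removal")

CUTOFF_ALIASES = {"admission": 0.0, "24h": 24.0, "48h": 48.0, "72h": 72.0, "168h": 168.0}


def parse_cutoff(text: str) -> float:
    """Map a cutoff spelling (``admission``, ``24h`` or plain hours) to hours."""
    if text in CUTOFF_ALIASES:
        return CUTOFF_ALIASES[text]
    return float(text.rstrip("h"))


@dataclass
class ClinicalFact:
    t_hours: float
    section: str
    name: str
    value: str | None = None
    unit: str | None = None

    def __post_init__(self):
        if self.section not in _SECTION_RANK:
            raise ValueError(f"unknown chart section {self.section!r}")


@dataclass
class Order:
    t_hours: float
    drug_ids: list[str]


@dataclass
class PatientRecord:
    patient_id: str
    demographics: dict | None
    facts: list[ClinicalFact] = field(default_factory=list)
    orders: list[Order] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def order_at(self, t_hours: float) -> Order | None:
        for o in self.orders:
            if o.t_hours == t_hours:
                return o
        return None


@dataclass
class TokenSequence:
    tokens: list[str]
    t_hours: list[float]

    def __post_init__(self):
        if len(self.tokens) != len(self.t_hours):
            raise ValueError("tokens and t_hours must have equal length")
        if any(b < a for a, b in zip(self.t_hours, self.t_hours[1:])):
            raise ValueError("t_hours must be non-decreasing")

    def __len__(self) -> int:
        return len(self.tokens)


# -- quality control -------------------------------------------------------

_REQUIRED_DEMOGRAPHICS = ("sex", "age", "height", "weight", "bmi")


def qc_reason(record: PatientRecord) -> str | None:
    """Return the discard reason for a record, or None if it is clean.

    The four discard conditions: missing basic pages (incomplete), internally
    inconsistent duplicate facts, nonstandard descriptions, and special
    circumstances (chemotherapy, post-operation, fracture-setting removal).
    """
    if record.demographics is None or any(
        k not in record.demographics for k in _REQUIRED_DEMOGRAPHICS
    ):
        return "incomplete"
    if not any(f.t_hours == 0.0 for f in record.facts):
        return "incomplete"
    seen: dict[tuple, str | None] = {}
    for f in record.facts:
        key = (f.t_hours, f.section, f.name)
        if key in seen and seen[key] != f.value:
            return "inconsistent"
        seen[key] = f.value
    for f in record.facts:
        if f.name == "special_circumstance" or (
            f.value is not None and f.value in SPECIAL_CIRCUMSTANCES
        ):
            return "special_circumstance"
        for tok in (f.name, f.value, f.unit):
            if tok is not None and not _STANDARD_TOKEN.match(tok):
                return "nonstandard"
    return None


def qc_filter(
    records: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Split records into (kept, discarded-with-reason) per the QC rules."""
    kept: list[PatientRecord] = []
    discarded: list[tuple[PatientRecord, str]] = []
    for r in records:
        reason = qc_reason(r)
        if reason is None:
            kept.append(r)
        else:
            discarded.append((r, reason))
    return kept, discarded


# -- tokenization ----------------------------------------------------------

def _bin_numeric(name: str, x: float) -> str:
    # demographics are binned into coarse, clinically conventional bands so
    # the vocabulary stays finite
    if name == "age":
        return f"age_{int(x) // 10 * 10}s"
    if name == "height":
        return f"height_{int(x) // 10 * 10}"
    if name == "weight":
        return f"weight_{int(x) // 10 * 10}"
    if name == "bmi":
        if x < 18.5:
            return "bmi_low"
        if x < 25:
            return "bmi_normal"
        return "bmi_high"
    return f"{name}_{x}"


def demographic_tokens(demo: dict) -> list[str]:
    toks = [f"sex_{demo['sex']}"]
    for k in ("age", "height", "weight", "bmi"):
        toks.append(_bin_numeric(k, float(demo[k])))
    return toks


def fact_tokens(fact: ClinicalFact) -> list[str]:
    """1-3 tokens per fact: name, name-qualified binned value, unit."""
    toks = [fact.name]
    if fact.value is not None:
        toks.append(f"{fact.name}:{fact.value}")
    if fact.unit is not None:
        toks.append(fact.unit)
    return toks


def extract_tokens(
    record: PatientRecord,
    cutoff_hours: float,
    include_prior_orders: bool = True,
) -> TokenSequence:
    """Chronological token sequence for one record up to `cutoff_hours`.

    Demographics are emitted first (t=0).  Facts at ``t_hours <= cutoff``
    contribute their tokens; prescriptions issued strictly before the cutoff
    are included as medicines-taken tokens (the order being predicted at the
    cutoff itself is never included).  Simultaneous facts are ordered by
    chart-section rank, then by name, so truncation at an earlier cutoff
    always yields a prefix of a later one.
    """
    if cutoff_hours < 0:
        raise ValueError("cutoff_hours must be >= 0")
    items: list[tuple[float, int, str, int, list[str]]] = []
    if record.demographics is not None:
        items.append((0.0, 0, "", 0, demographic_tokens(record.demographics)))
    for i, f in enumerate(record.facts):
        if f.t_hours <= cutoff_hours:
            items.append((f.t_hours, _SECTION_RANK[f.section], f.name, i, fact_tokens(f)))
    if include_prior_orders:
        for o in record.orders:
            if o.t_hours < cutoff_hours:
                toks = [f"taken:{d}" for d in sorted(o.drug_ids)]
                items.append((o.t_hours, _SECTION_RANK["physician_orders"], "", 0, toks))
    items.sort(key=lambda it: it[:4])
    tokens: list[str] = []
    times: list[float] = []
    for t, _, _, _, toks in items:
        tokens.extend(toks)
        times.extend([t] * len(toks))
    return TokenSequence(tokens=tokens, t_hours=times)


# -- JSONL I/O -------------------------------------------------------------

def write_records_jsonl(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r), sort_keys=True) + "\n")


def read_records_jsonl(path: str | Path) -> Iterator[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            yield PatientRecord(
                patient_id=d["patient_id"],
                demographics=d["demographics"],
                facts=[ClinicalFact(**f) for f in d["facts"]],
                orders=[Order(**o) for o in d["orders"]],
                meta=d.get("meta", {}),
            )
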