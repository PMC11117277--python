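"""Raw admission records and their CSV serialization.

A :class:`RawPatientRecord` is one hospital admission *before* eligibility
filtering: demographics, day-offset drug and procedure events, admission labs,
functional scores, and outcome days. Day offsets count from the admission date
(day 0). The optional ``hidden_confounder`` field is simulation truth carried
by the synthetic generator; analysis stages never read it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from typing import Optional

from .exceptions import ParseError, RecordValidationError

#: infection-source levels
SOURCES = ("community", "nursing", "hospital")


@dataclass
class RawPatientRecord:
    patient_id: str
    age: float
    sex: str  # "male" | "female"
    admission_day: int = 0
    drug_events: list[tuple[str, int]] = field(default_factory=list)
    procedure_events: list[tuple[str, int]] = field(default_factory=list)
    # admission labs (None = not measured)
    bun: Optional[float] = None        # mg/dL
    albumin: Optional[float] = None    # g/dL
    # functional scores (None = not recorded)
    barthel: Optional[int] = None      # 0-100
    hugh_jones: Optional[int] = None   # 1-5
    jcs: Optional[int] = None          # Japan Coma Scale, 0 = alert
    # binary flags
    dialysis: bool = False
    immunodeficiency: bool = False
    prior_antibiotics_90d: bool = False
    residence_healthcare_facility: bool = False
    source_of_infection: str = "community"
    oxygen_on_admission: bool = False
    # outcome days (None = did not occur within follow-up)
    death_day: Optional[int] = None
    surgery_day: Optional[int] = None
    lost_to_followup_day: Optional[int] = None
    transfer_day: Optional[int] = None
    # simulation truth, never read by analysis stages
    hidden_confounder: Optional[int] = None

    def validate(self) -> None:
        """Raise :class:`RecordValidationError` on out-of-range raw values."""
        if self.age < 0:
            raise RecordValidationError(f"{self.patient_id}: negative age {self.age}")
        if self.sex not in ("male", "female"):
            raise RecordValidationError(f"{self.patient_id}: bad sex {self.sex!r}")
        if self.source_of_infection not in SOURCES:
            raise RecordValidationError(
                f"{self.patient_id}: bad source {self.source_of_infection!r}"
            )
        if self.barthel is not None and not 0 <= self.barthel <= 100:
            raise RecordValidationError(
                f"{self.patient_id}: Barthel index {self.barthel} outside 0-100"
            )
        if self.hugh_jones is not None and not 1 <= self.hugh_jones <= 5:
            raise RecordValidationError(
                f"{self.patient_id}: Hugh-Jones class {self.hugh_jones} outside 1-5"
            )
        if self.jcs is not None and self.jcs < 0:
            raise RecordValidationError(f"{self.patient_id}: negative JCS {self.jcs}")
        for name in ("bun", "albumin"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RecordValidationError(f"{self.patient_id}: negative {name} {v}")
        for code, day in self.drug_events + self.procedure_events:
            if day < 0:
                raise RecordValidationError(
                    f"{self.patient_id}: negative day offset for {code}"
                )
        for name in ("death_day", "surgery_day", "lost_to_followup_day", "transfer_day"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RecordValidationError(f"{self.patient_id}: negative {name} {v}")


_COLUMNS = [
    "patient_id", "age", "sex", "admission_day", "drug_events", "procedure_events",
    "bun", "albumin", "barthel", "hugh_jones", "jcs",
    "dialysis", "immunodeficiency", "prior_antibiotics_90d",
    "residence_healthcare_facility", "source_of_infection", "oxygen_on_admission",
    "death_day", "surgery_day", "lost_to_followup_day", "transfer_day",
    "hidden_confounder",
]

_INT_FIELDS = {"admission_day", "barthel", "hugh_jones", "jcs",
               "death_day", "surgery_day", "lost_to_followup_day", "transfer_day",
               "hidden_confounder"}
_FLOAT_FIELDS = {"age", "bun", "albumin"}
_BOOL_FIELDS = {"dialysis", "immunodeficiency", "prior_antibiotics_90d",
                "residence_healthcare_facility", "oxygen_on_admission"}


def _events_to_str(events: list[tuple[str, int]]) -> str:
    return ";".join(f"{code}:{day}" for code, day in events)


def _events_from_str(s: str, row: int) -> list[tuple[str, int]]:
    if not s:
        return []
    out = []
    for item in s.split(";"):
        try:
            code, day = item.rsplit(":", 1)
            out.append((code, int(day)))
        except ValueError as exc:
            raise ParseError(f"row {row}: malformed event {item!r}") from exc
    return out


def write_raw_csv(records: list[RawPatientRecord], path) -> None:
    """Write records to CSV; missing values become empty fields, events are
    semicolon-delimited ``code:day`` pairs."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            row = []
            for col in _COLUMNS:
                v = getattr(rec, col)
                if col in ("drug_events", "procedure_events"):
                    row.append(_events_to_str(v))
                elif v is None:
                    row.append("")
                elif col in _BOOL_FIELDS:
                    row.append(int(v))
                elif col == "age":
                    row.append(repr(float(v)))
                else:
                    row.append(v)
            writer.writerow(row)


def read_raw_csv(path) -> list[RawPatientRecord]:
    """Read records written by :func:`write_raw_csv` (lossless round-trip).

    Raises :class:`ParseError` naming the 1-based data row on malformed input.
    """
    records: list[RawPatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _COLUMNS:
            raise ParseError(f"unexpected header {header!r}")
        for i, row in enumerate(reader, start=1):
            if len(row) != len(_COLUMNS):
                raise ParseError(f"row {i}: expected {len(_COLUMNS)} fields, got {len(row)}")
            kwargs = {}
            for col, raw in zip(_COLUMNS, row):
                if col in ("drug_events", "procedure_events"):
                    kwargs[col] = _events_from_str(raw, i)
                    continue
                if raw == "":
                    if col in ("patient_id", "sex", "source_of_infection"):
                        raise ParseError(f"row {i}: missing required field {col}")
                    kwargs[col] = None
                    continue
                try:
                    if col in _INT_FIELDS:
                        kwargs[col] = int(raw)
                    elif col in _FLOAT_FIELDS:
                        kwargs[col] = float(raw)
                    elif col in _BOOL_FIELDS:
                        kwargs[col] = bool(int(raw))
                    else:
                        kwargs[col] = raw
                except ValueError as exc:
                    raise ParseError(f"row {i}: bad value {raw!r} for {col}") from exc
            # booleans default False when blank
            for b in _BOOL_FIELDS:
                if kwargs.get(b) is None:
                    kwargs[b] = False
            if kwargs.get("admission_day") is None:
                kwargs["admission_day"] = 0
            records.append(RawPatientRecord(**kwargs))
    return records
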