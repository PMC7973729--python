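"""Event-log handling: pathway extraction, pathway tables and file formats.

A raw event log records one row per (patient, activity, timestamp).  Per
patient, events are sorted by timestamp (stably, so same-day activities keep
their input order) and the activity codes are concatenated into a pathway
string; identical strings are aggregated with multiplicities.  The case-study
data records each activity at most once per patient, so de-duplication
(keeping the first occurrence) is on by default but optional.

File formats are plain CSV throughout: event logs as
``patient_id,activity,timestamp``, pathway tables as
``pathway,multiplicity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import ActivityCatalog, CatalogError, Pathway

__all__ = [
    "EventRecord",
    "PathwayTable",
    "extract_pathways",
    "read_event_log",
    "export_heatmap_table",
]


@dataclass(frozen=True)
class EventRecord:
    """One dated care activity for one patient."""

    patient_id: str
    activity: str
    timestamp: pd.Timestamp


class PathwayTable:
    """Unique pathway strings with multiplicities (patients per pathway)."""

    def __init__(self, rows: Iterable[tuple[str, int]]):
        self.rows: list[tuple[str, int]] = []
        for pathway, mult in rows:
            if not pathway:
                raise ValueError("pathway strings must be non-empty")
            if mult < 1:
                raise ValueError(f"multiplicity must be positive for {pathway!r}")
            self.rows.append((pathway, int(mult)))

    @classmethod
    def from_strings(cls, pathways: Sequence[str]) -> "PathwayTable":
        return cls((p, 1) for p in pathways)

    @property
    def pathways(self) -> list[str]:
        return [p for p, _ in self.rows]

    @property
    def n_patients(self) -> int:
        return sum(m for _, m in self.rows)

    def as_pathway_objects(self) -> list[Pathway]:
        return [Pathway(codes=p, multiplicity=m) for p, m in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PathwayTable) and self.rows == other.rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["pathway", "multiplicity"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PathwayTable":
        df = pd.read_csv(path, dtype={"pathway": str})
        if "pathway" not in df.columns:
            raise ValueError("pathway table must have a 'pathway' column")
        mult = df["multiplicity"] if "multiplicity" in df.columns else 1
        df = df.assign(multiplicity=mult)
        return cls(zip(df["pathway"], df["multiplicity"].astype(int)))

    def __repr__(self) -> str:
        return f"PathwayTable({len(self)} pathways, {self.n_patients} patients)"


def read_event_log(path: str | Path, date_format: str | None = None) -> list[EventRecord]:
    """Read a CSV event log with columns ``patient_id,activity,timestamp``.

    Timestamps are parsed as ISO-8601 by default; pass ``date_format`` (e.g.
    ``"%d/%m/%Y"``) for other conventions.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "activity": str})
    required = {"patient_id", "activity", "timestamp"}
    if not required.issubset(df.columns):
        raise ValueError(f"event log must have columns {sorted(required)}")
    stamps = pd.to_datetime(df["timestamp"], format=date_format)
    return [
        EventRecord(patient_id=p, activity=a, timestamp=t)
        for p, a, t in zip(df["patient_id"], df["activity"], stamps)
    ]


def extract_pathways(
    events: Sequence[EventRecord],
    catalog: ActivityCatalog,
    dedupe: bool = True,
) -> PathwayTable:
    """Turn an event log into a pathway table.

    Per patient, events are sorted by timestamp with a stable sort (input
    order breaks ties) and their codes concatenated.  With ``dedupe`` only
    the first occurrence of a repeated activity is kept.  Identical pathway
    strings are aggregated with multiplicities; patients appear in order of
    first occurrence in the log.
    """
    for rec in events:
        if rec.activity not in catalog:
            raise CatalogError(
                f"unresolvable activity {rec.activity!r} for patient {rec.patient_id!r}"
            )
    per_patient: dict[str, list[tuple[pd.Timestamp, int, str]]] = {}
    for pos, rec in enumerate(events):
        per_patient.setdefault(rec.patient_id, []).append((rec.timestamp, pos, rec.activity))
    counts: dict[str, int] = {}
    for pid, items in per_patient.items():
        items.sort(key=lambda t: (t[0], t[1]))
        codes: list[str] = []
        for _, _, act in items:
            if dedupe and act in codes:
                continue
            codes.append(act)
        s = "".join(codes)
        counts[s] = counts.get(s, 0) + 1
    return PathwayTable(counts.items())


def export_heatmap_table(table: PathwayTable) -> pd.DataFrame:
    """Long-format per-position export for heatmap-style displays.

    One row per (patient, position, activity), pathways repeated per
    multiplicity and sorted alphabetically; positions are 1-based.  Rendering
    is left to the caller.
    """
    records = []
    patient = 0
    expanded = sorted(
        (p for p, m in table.rows for _ in range(m)),
    )
    for pathway in expanded:
        for pos, code in enumerate(pathway, start=1):
            records.append((patient, pos, code))
        patient += 1
    return pd.DataFrame(records, columns=["patient", "position", "activity"])
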