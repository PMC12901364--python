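"""Event-log data model, readers/writers and healthcare data-quality validation.

The event log is the universal currency between pipeline stages: a set of
traces, each an ordered sequence of (case, activity, timestamp) events.
Clinical time series arrive as hourly measurement tables in the PhysioNet
Challenge 2019 pipe-separated dialect and are converted to event logs by the
state models in :mod:`careflow.states`.

Validation follows clinical data-quality practice: mandatory attributes
(case id, activity, timestamp), strict chronological ordering within a
trace, rejection of duplicate event signatures, admission-before-discharge
consistency where both timestamps exist, and physiological range constraints
(e.g. a body temperature above 45 °C is a measurement artifact, not a
fever). Violating rows are dropped and itemized, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, FormatError

#: Column list of the PhysioNet Challenge 2019 hourly PSV dialect.
PHYSIONET_COLUMNS = [
    "HR", "O2Sat", "Temp", "SBP", "MAP", "DBP", "Resp", "EtCO2",
    "BaseExcess", "HCO3", "FiO2", "pH", "PaCO2", "SaO2", "AST", "BUN",
    "Alkalinephos", "Calcium", "Chloride", "Creatinine", "Bilirubin_direct",
    "Glucose", "Lactate", "Magnesium", "Phosphate", "Potassium",
    "Bilirubin_total", "TroponinI", "Hct", "Hgb", "PTT", "WBC",
    "Fibrinogen", "Platelets", "Age", "Gender", "Unit1", "Unit2",
    "HospAdmTime", "ICULOS", "SepsisLabel",
]

#: Upper physiological bound for core body temperature; values above are
#: measurement artifacts.
TEMP_ARTIFACT_MAX = 45.0


@dataclass(frozen=True)
class Event:
    case_id: str
    activity: str
    timestamp: object  # numeric hour index or pandas Timestamp

    def signature(self) -> tuple:
        return (self.case_id, self.activity, self.timestamp)


@dataclass
class Trace:
    """One case's chronologically ordered events."""

    case_id: str
    events: list[Event]

    def __post_init__(self) -> None:
        if not self.events:
            raise DegenerateInputError(f"trace {self.case_id!r} has no events")
        if any(e.case_id != self.case_id for e in self.events):
            raise FormatError(f"trace {self.case_id!r} mixes case ids")
        ts = [e.timestamp for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise FormatError(f"trace {self.case_id!r} is not chronologically ordered")

    @property
    def activities(self) -> tuple[str, ...]:
        return tuple(e.activity for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class EventLog:
    traces: list[Trace]
    metadata: dict = field(default_factory=dict)

    @property
    def activity_universe(self) -> set[str]:
        return {e.activity for t in self.traces for e in t.events}

    @property
    def case_ids(self) -> list[str]:
        return [t.case_id for t in self.traces]

    def __post_init__(self) -> None:
        ids = self.case_ids
        if len(ids) != len(set(ids)):
            raise FormatError("case ids are not unique across traces")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


@dataclass
class ClinicalRecordTable:
    """Per-patient hourly measurements with a binary sepsis label.

    ``data`` holds one row per hour with an ``ICULOS`` hour index (1-based),
    measurement columns (NaN = not measured) and ``SepsisLabel``.
    ``latent_states`` is populated by the synthetic cohort generator and
    carries the ground-truth state per row for recovery tests.
    """

    patient_id: str
    data: pd.DataFrame
    latent_states: list[str] | None = None
    issues: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        hours = self.data["ICULOS"].to_numpy()
        if len(hours) and not np.all(np.diff(hours) > 0):
            raise FormatError(f"patient {self.patient_id!r}: hour index not strictly increasing")
        lab = self.data["SepsisLabel"].to_numpy()
        if len(lab):
            onset = np.argmax(lab == 1) if (lab == 1).any() else len(lab)
            if (lab[onset:] != 1).any():
                raise FormatError(f"patient {self.patient_id!r}: sepsis label is not absorbing")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ValidationReport:
    n_checked: int
    violations: list[tuple]  # (rule_id, case_id, detail)
    n_rejected: int

    def __post_init__(self) -> None:
        if self.n_rejected > self.n_checked:
            raise ValueError("n_rejected exceeds n_checked")

    def to_dict(self) -> dict:
        return {
            "n_checked": self.n_checked,
            "n_rejected": self.n_rejected,
            "violations": [
                {"rule_id": r, "case_id": c, "detail": d} for r, c, d in self.violations
            ],
        }


DEFAULT_COLUMN_MAP = {"case": "case_id", "activity": "activity", "timestamp": "timestamp"}


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Numeric timestamps stay numeric; otherwise parse as datetimes."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric
    if numeric.notna().any() and numeric.isna().sum() < len(raw):
        # mixed numeric column with a few bad cells: keep numeric reading
        return numeric
    return pd.to_datetime(raw, errors="coerce", format="mixed")


def read_event_log_csv(path, column_map: Mapping[str, str] | None = None) -> EventLog:
    """Read a CSV event log into one trace per case.

    Events within a case are sorted ascending by timestamp with a stable
    secondary order (input row order breaks ties). Rows with unparsable
    timestamps and exact duplicate (case, activity, timestamp) signatures
    are dropped and itemized in ``metadata["violations"]``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, dtype={cmap["case"]: str, cmap["activity"]: str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty event-log file") from exc
    missing = [cmap[k] for k in ("case", "activity", "timestamp") if cmap[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mapped column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: event-log file has a header but no rows")

    violations: list[tuple] = []
    ts = _parse_timestamps(df[cmap["timestamp"]])
    bad = ts.isna() | df[cmap["case"]].isna() | df[cmap["activity"]].isna()
    for i in df.index[bad]:
        violations.append(("unparsable_row", str(df.at[i, cmap["case"]]), f"row {i}"))
    df = df.loc[~bad].copy()
    df["_ts"] = ts.loc[df.index]

    sig = list(zip(df[cmap["case"]], df[cmap["activity"]], df["_ts"]))
    dup_mask = pd.Series(sig, index=df.index).duplicated()
    for i in df.index[dup_mask]:
        violations.append(
            ("duplicate_signature", df.at[i, cmap["case"]],
             f"{df.at[i, cmap['activity']]}@{df.at[i, cmap['timestamp']]}")
        )
    df = df.loc[~dup_mask]
    if df.empty:
        raise FormatError(f"{path}: no valid rows after parsing")

    traces = []
    for case_id in df[cmap["case"]].drop_duplicates():
        sub = df[df[cmap["case"]] == case_id].sort_values("_ts", kind="stable")
        traces.append(Trace(case_id, [
            Event(case_id, a, t)
            for a, t in zip(sub[cmap["activity"]], sub["_ts"])
        ]))
    return EventLog(traces, metadata={"source": str(path), "violations": violations})


def write_event_log_csv(log: EventLog, path) -> None:
    """Write an event log back to CSV; read→write→read is the identity."""
    if not log.traces:
        raise DegenerateInputError("refusing to write an empty event log")
    rows = [
        {"case_id": e.case_id, "activity": e.activity, "timestamp": e.timestamp}
        for t in log.traces for e in t.events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_physionet_psv(path) -> ClinicalRecordTable:
    """Read one patient's hourly table in the PhysioNet Challenge 2019 dialect.

    The header must match the challenge column list exactly. Non-numeric
    cells become missing values and are reported on the returned table's
    ``issues`` list rather than raising.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="|")
    if list(df.columns) != PHYSIONET_COLUMNS:
        raise FormatError(f"{path}: header does not match the PhysioNet column list")
    issues = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.lower() != "nan")
        for i in df.index[bad]:
            issues.append(("non_numeric_cell", path.stem, f"{col} row {i}"))
        df[col] = coerced
    df["SepsisLabel"] = df["SepsisLabel"].fillna(0).astype(int)
    df["ICULOS"] = df["ICULOS"].astype(int)
    return ClinicalRecordTable(patient_id=path.stem, data=df, issues=issues)


# ---------------------------------------------------------------------------
# Validation rules
# ---------------------------------------------------------------------------

def _rule_mandatory_fields(log: EventLog) -> list[tuple]:
    out = []
    for t in log.traces:
        for e in t.events:
            if not str(e.case_id) or not str(e.activity) or e.timestamp is None \
                    or str(e.activity).strip() == "" or (
                        isinstance(e.activity, float) and np.isnan(e.activity)):
                out.append(("mandatory_fields", t.case_id, f"event {e!r}"))
    return out


def _rule_chronological_order(log: EventLog) -> list[tuple]:
    # Trace construction enforces ordering; this rule re-checks defensively.
    out = []
    for t in log.traces:
        ts = [e.timestamp for e in t.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            out.append(("chronological_order", t.case_id, "events out of order"))
    return out


def _rule_duplicate_signature(log: EventLog) -> list[tuple]:
    out = []
    for t in log.traces:
        seen = set()
        for e in t.events:
            s = e.signature()
            if s in seen:
                out.append(("duplicate_signature", t.case_id, f"{e.activity}@{e.timestamp}"))
            seen.add(s)
    return out


def _rule_admission_before_discharge(log: EventLog) -> list[tuple]:
    out = []
    for t in log.traces:
        adm = [e.timestamp for e in t.events if e.activity.lower() == "admission"]
        dis = [e.timestamp for e in t.events if e.activity.lower() == "discharge"]
        if adm and dis and min(dis) < min(adm):
            out.append(("admission_before_discharge", t.case_id,
                        f"discharge {min(dis)} precedes admission {min(adm)}"))
    return out


def _rule_physiological_range(tables: Sequence[ClinicalRecordTable]) -> list[tuple]:
    out = []
    for tab in tables:
        if "Temp" in tab.data:
            temp = tab.data["Temp"]
            for i in tab.data.index[temp > TEMP_ARTIFACT_MAX]:
                out.append(("physiological_range", tab.patient_id,
                            f"Temp={temp[i]} > {TEMP_ARTIFACT_MAX} at hour "
                            f"{tab.data.at[i, 'ICULOS']}"))
        numeric = tab.data.select_dtypes("number")
        if np.isinf(numeric.to_numpy(dtype=float, na_value=np.nan)).any():
            out.append(("physiological_range", tab.patient_id, "non-finite measurement"))
    return out


def _rule_hour_order(tables: Sequence[ClinicalRecordTable]) -> list[tuple]:
    out = []
    for tab in tables:
        hours = tab.data["ICULOS"].to_numpy()
        if len(hours) and not np.all(np.diff(hours) > 0):
            out.append(("hour_order", tab.patient_id, "ICULOS not strictly increasing"))
    return out


EVENT_RULES: dict[str, Callable] = {
    "mandatory_fields": _rule_mandatory_fields,
    "chronological_order": _rule_chronological_order,
    "duplicate_signature": _rule_duplicate_signature,
    "admission_before_discharge": _rule_admission_before_discharge,
}

RECORD_RULES: dict[str, Callable] = {
    "physiological_range": _rule_physiological_range,
    "hour_order": _rule_hour_order,
}


def validate_records(records, rules: Iterable[str] | None = None) -> ValidationReport:
    """Apply registered data-quality rules and itemize every violation.

    ``records`` is either an :class:`EventLog` (structural rules) or a
    sequence of :class:`ClinicalRecordTable` (clinical-plausibility rules).
    Flagged items are reported for exclusion downstream, never repaired.
    """
    if isinstance(records, EventLog):
        registry, n = EVENT_RULES, len(records.traces)
    else:
        records = list(records)
        registry, n = RECORD_RULES, len(records)
    selected = list(rules) if rules is not None else list(registry)
    unknown = [r for r in selected if r not in registry]
    if unknown:
        raise ConfigurationError(f"unknown validation rule(s): {unknown}")
    violations: list[tuple] = []
    for rule_id in selected:
        violations.extend(registry[rule_id](records))
    rejected = {c for _, c, _ in violations}
    return ValidationReport(n_checked=n, violations=violations, n_rejected=len(rejected))


def filter_cases(log: EventLog, predicate: Callable[[Trace], bool]) -> EventLog:
    """Keep exactly the traces satisfying ``predicate``; empty results are legal."""
    kept = [t for t in log.traces if predicate(t)]
    meta = dict(log.metadata)
    meta.update(n_retained=len(kept), n_excluded=len(log.traces) - len(kept))
    if not kept:
        meta["empty_result"] = True
    return EventLog(kept, metadata=meta)
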