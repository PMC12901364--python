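"""Disease-progression state models and the clinical event-log pipeline.

Two models turn hourly measurement tables into clinical-state event logs:

* **infection** — SIRS temperature bands (hypothermia < 36 °C, normal
  36–37.5 °C closed, fever > 37.5 °C) crossed with a leukocytosis/
  leukopenia infection flag (WBC > 12 or < 4 ×10³ cells/µL), giving six
  combined states plus the absorbing "Sepsis" label taken from the dataset
  (Sepsis-3), 7 activities in all.
* **organ** — per-organ dysfunction flags (troponin I > 0.04 ng/mL cardiac,
  creatinine > 1.3 mg/dL renal, AST > 40 IU/L hepatic) aggregated to
  "Low Risk", three single-organ, three two-organ and one "Multiorgan
  Damage" state plus "Sepsis", 9 activities in all.

Event-log construction runs five stages: (1) validation and quality
checking, (2) hourly state classification with last-observation-carried-
forward for sparsely measured labs, (3) temporal-order verification,
(4) cohort filtering — patients lacking any required variable over the whole
stay are excluded, (5) collapse of consecutive repeats into state-transition
traces, truncated at sepsis onset when the label is absorbing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateInputError, SpecificationError
from .eventlog import (
    TEMP_ARTIFACT_MAX,
    ClinicalRecordTable,
    Event,
    EventLog,
    Trace,
    validate_records,
)

LOW_TEMP, NORMAL_TEMP, HIGH_TEMP = "Low Temperature", "Normal Temperature", "High Temperature"
SEPSIS = "Sepsis"

DEFAULT_THRESHOLDS = {
    "temp_low": 36.0,       # °C, below → hypothermia
    "temp_high": 37.5,      # °C, above → fever
    "wbc_high": 12.0,       # 10³ cells/µL, above → leukocytosis
    "wbc_low": 4.0,         # 10³ cells/µL, below → leukopenia
    "troponin": 0.04,       # ng/mL, above → cardiac dysfunction
    "creatinine": 1.3,      # mg/dL, above → renal dysfunction
    "ast": 40.0,            # IU/L, above → hepatic dysfunction
}

INFECTION_LABELS = [
    LOW_TEMP, NORMAL_TEMP, HIGH_TEMP,
    f"Infection + {LOW_TEMP}", f"Infection + {NORMAL_TEMP}",
    f"Infection + {HIGH_TEMP}", SEPSIS,
]
ORGAN_LABELS = [
    "Low Risk", "Cardiac Damage", "Renal Damage", "Liver Damage",
    "Renal + Cardiac Damage", "Liver + Cardiac Damage", "Renal + Liver Damage",
    "Multiorgan Damage", SEPSIS,
]


@dataclass
class StateModelSpec:
    model_id: str  # "infection" | "organ"
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    required_variables: list[str] | None = None
    sepsis_absorbing: bool = True

    def __post_init__(self) -> None:
        if self.model_id not in ("infection", "organ"):
            raise SpecificationError(f"unknown model_id {self.model_id!r}")
        t = self.thresholds
        if t["temp_low"] >= t["temp_high"] or t["wbc_low"] >= t["wbc_high"]:
            raise SpecificationError("threshold bands are inverted")
        if any(v <= 0 for v in t.values()):
            raise SpecificationError("thresholds must be positive")
        if self.required_variables is None:
            self.required_variables = (
                ["Temp", "WBC"] if self.model_id == "infection"
                else ["Creatinine", "TroponinI", "AST"]
            )

    @property
    def label_universe(self) -> list[str]:
        return INFECTION_LABELS if self.model_id == "infection" else ORGAN_LABELS

    @classmethod
    def from_config(cls, path) -> "StateModelSpec":
        """Load a model spec from a YAML or JSON config file."""
        text = Path(path).read_text()
        cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(cfg.get("thresholds", {}))
        return cls(model_id=cfg["model_id"], thresholds=thresholds,
                   required_variables=cfg.get("required_variables"),
                   sepsis_absorbing=cfg.get("sepsis_absorbing", True))


def classify_temperature(temp: float, thresholds: dict | None = None) -> str:
    """Three-way SIRS partition; the normal band [36.0, 37.5] is closed."""
    t = thresholds or DEFAULT_THRESHOLDS
    if temp < t["temp_low"]:
        return LOW_TEMP
    if temp > t["temp_high"]:
        return HIGH_TEMP
    return NORMAL_TEMP


def infection_flag(wbc: float, thresholds: dict | None = None) -> bool:
    """True iff the white-cell count indicates leukocytosis or leukopenia."""
    t = thresholds or DEFAULT_THRESHOLDS
    return wbc > t["wbc_high"] or wbc < t["wbc_low"]


def infection_activity(temp_state: str, infected: bool, sepsis: bool) -> str:
    """Combined infection/temperature activity label; sepsis takes precedence."""
    if sepsis:
        return SEPSIS
    if infected:
        return f"Infection + {temp_state}"
    return temp_state


_PAIR_LABELS = {
    ("cardiac", "renal"): "Renal + Cardiac Damage",
    ("cardiac", "hepatic"): "Liver + Cardiac Damage",
    ("hepatic", "renal"): "Renal + Liver Damage",
}
_SINGLE_LABELS = {"cardiac": "Cardiac Damage", "renal": "Renal Damage",
                  "hepatic": "Liver Damage"}


def organ_activity(troponin: float, creatinine: float, ast: float,
                   sepsis: bool, thresholds: dict | None = None) -> str:
    """Aggregate per-organ dysfunction flags into one of 9 activity labels."""
    if sepsis:
        return SEPSIS
    t = thresholds or DEFAULT_THRESHOLDS
    flags = []
    if troponin > t["troponin"]:
        flags.append("cardiac")
    if creatinine > t["creatinine"]:
        flags.append("renal")
    if ast > t["ast"]:
        flags.append("hepatic")
    if not flags:
        return "Low Risk"
    if len(flags) == 1:
        return _SINGLE_LABELS[flags[0]]
    if len(flags) == 2:
        return _PAIR_LABELS[tuple(sorted(flags))]
    return "Multiorgan Damage"


def collapse_consecutive(labels: list) -> list:
    """Drop consecutive repeats, keeping each run's first occurrence."""
    out = []
    for x in labels:
        if not out or out[-1] != x:
            out.append(x)
    return out


@dataclass
class StateSequence:
    patient_id: str
    states: list[tuple[int, str]]  # (hour, activity) after collapsing repeats


_ORGAN_BY_FLAGS = [
    # index = cardiac + 2·renal + 4·hepatic
    "Low Risk", "Cardiac Damage", "Renal Damage", "Renal + Cardiac Damage",
    "Liver Damage", "Liver + Cardiac Damage", "Renal + Liver Damage",
    "Multiorgan Damage",
]


def _hourly_labels(spec: StateModelSpec, values: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorized per-hour activity labels (sepsis handled by the caller)."""
    t = spec.thresholds
    if spec.model_id == "infection":
        temp, wbc = values["Temp"], values["WBC"]
        temp_state = np.select([temp < t["temp_low"], temp > t["temp_high"]],
                               [LOW_TEMP, HIGH_TEMP], default=NORMAL_TEMP)
        infected = (wbc > t["wbc_high"]) | (wbc < t["wbc_low"])
        return np.where(infected,
                        np.char.add("Infection + ", temp_state.astype(str)),
                        temp_state)
    flags = ((values["TroponinI"] > t["troponin"]).astype(int)
             + 2 * (values["Creatinine"] > t["creatinine"]).astype(int)
             + 4 * (values["AST"] > t["ast"]).astype(int))
    return np.array(_ORGAN_BY_FLAGS, dtype=object)[flags]


def classify_patient(table: ClinicalRecordTable, spec: StateModelSpec) -> StateSequence:
    """Hourly classification with LOCF, collapsed to state transitions.

    Values flagged as artifacts (Temp > 45 °C) are treated as missing.
    Each variable carries its last observation forward after its first
    measurement; hours before every required variable has been observed at
    least once emit no state. With an absorbing sepsis label the sequence
    ends with a single "Sepsis" event at onset.
    """
    df = table.data
    carried = {}
    for var in spec.required_variables:
        s = df[var]
        if var == "Temp":
            s = s.where(~(s > TEMP_ARTIFACT_MAX))
        carried[var] = s.ffill().to_numpy(dtype=float)
    complete = np.logical_and.reduce(
        [~np.isnan(carried[v]) for v in spec.required_variables])
    hours = df["ICULOS"].to_numpy()
    sepsis = df["SepsisLabel"].to_numpy() == 1

    n = len(df)
    cutoff = int(np.argmax(sepsis)) if (spec.sepsis_absorbing and sepsis.any()) else n
    labels = _hourly_labels(spec, carried)
    raw = [(int(hours[i]), str(labels[i])) for i in range(cutoff) if complete[i]]
    if spec.sepsis_absorbing and cutoff < n:
        raw.append((int(hours[cutoff]), SEPSIS))

    collapsed: list[tuple[int, str]] = []
    for hour, label in raw:
        if not collapsed or collapsed[-1][1] != label:
            collapsed.append((hour, label))
    return StateSequence(patient_id=table.patient_id, states=collapsed)


def build_event_log(records: list[ClinicalRecordTable],
                    spec: StateModelSpec) -> tuple[EventLog, dict]:
    """Run the five-stage pipeline from hourly tables to an event log.

    Returns the log plus a per-stage report: validation violations, patients
    in/excluded at cohort filtering, event and unique-trace counts.
    """
    report: dict = {"patients_in": len(records)}

    # (1) validation and quality checking
    vreport = validate_records(records)
    report["validation"] = vreport.to_dict()

    # (4, checked first since it gates classification) cohort inclusion:
    # at least one recorded value of every required variable over the stay
    included, excluded = [], []
    for tab in records:
        if all(tab.data[v].notna().any() for v in spec.required_variables):
            included.append(tab)
        else:
            excluded.append(tab.patient_id)
    report["patients_excluded_missing_variables"] = len(excluded)
    report["excluded_ids"] = excluded

    # (2) hourly classification with LOCF + (5) collapse and sepsis truncation
    traces = []
    for tab in included:
        seq = classify_patient(tab, spec)
        if seq.states:
            traces.append(Trace(tab.patient_id, [
                Event(tab.patient_id, label, hour) for hour, label in seq.states
            ]))
    report["patients_kept"] = len(traces)

    if not traces:
        raise DegenerateInputError(
            f"no usable traces after filtering; stage report: {report}")

    log = EventLog(traces, metadata={"model_id": spec.model_id,
                                     "stage_report": report})

    # (3) temporal-order verification on the constructed log
    order_check = validate_records(log, rules=["chronological_order"])
    report["temporal_order_violations"] = len(order_check.violations)

    # (5) variant analysis summary
    variants = {t.activities for t in traces}
    report["n_events"] = sum(len(t) for t in traces)
    report["n_unique_traces"] = len(variants)
    bad = log.activity_universe - set(spec.label_universe)
    if bad:
        raise SpecificationError(f"labels outside the model universe: {bad}")
    return log, report
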