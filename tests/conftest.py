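import numpy as np
import pandas as pd
import pytest

from careflow import (
    CohortSpec,
    Event,
    EventLog,
    StateModelSpec,
    Trace,
    infection_cohort_spec,
    simulate_cohort,
)
from careflow.eventlog import PHYSIONET_COLUMNS, ClinicalRecordTable


def make_log(sequences, case_prefix="c"):
    """Event log from plain label sequences, hourly integer timestamps."""
    traces = []
    for i, seq in enumerate(sequences):
        cid = f"{case_prefix}{i}"
        traces.append(Trace(cid, [Event(cid, a, h + 1) for h, a in enumerate(seq)]))
    return EventLog(traces)


def random_log(rng, n_traces=20, labels=("A", "B", "C", "D", "E"),
               max_len=8):
    seqs = []
    for _ in range(n_traces):
        length = int(rng.integers(1, max_len + 1))
        seqs.append([labels[i] for i in rng.integers(0, len(labels), size=length)])
    return make_log(seqs)


def make_patient(patient_id, temp=None, wbc=None, sepsis=None, n_hours=None,
                 troponin=None, creatinine=None, ast=None):
    """Hourly clinical table with only the named variables filled in."""
    cols = {"Temp": temp, "WBC": wbc, "TroponinI": troponin,
            "Creatinine": creatinine, "AST": ast}
    n = n_hours or max(len(v) for v in cols.values() if v is not None)
    df = pd.DataFrame(np.nan, index=range(n), columns=PHYSIONET_COLUMNS)
    for name, values in cols.items():
        if values is not None:
            df[name] = list(values) + [np.nan] * (n - len(values))
    df["ICULOS"] = range(1, n + 1)
    df["SepsisLabel"] = list(sepsis) if sepsis is not None else 0
    df["SepsisLabel"] = df["SepsisLabel"].astype(int)
    return ClinicalRecordTable(patient_id=patient_id, data=df)


@pytest.fixture(scope="session")
def recovery_spec():
    """Study-scale generator settings for Markov parameter recovery."""
    return infection_cohort_spec(n_patients=2000, missingness_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def recovery_cohort(recovery_spec):
    return simulate_cohort(recovery_spec)


@pytest.fixture(scope="session")
def recovery_log(recovery_cohort):
    from careflow import build_event_log
    log, report = build_event_log(recovery_cohort, StateModelSpec("infection"))
    return log, report


@pytest.fixture(scope="session")
def small_cohort():
    spec = infection_cohort_spec(n_patients=40, missingness_rate=0.3, seed=7)
    return spec, simulate_cohort(spec)


@pytest.fixture
def tiny_spec():
    """Two-state spec small enough for exhaustive reasoning."""
    return CohortSpec(
        n_patients=3, horizon_hours=6,
        state_names=["Normal Temperature", "High Temperature"],
        transition_matrix=np.array([[0.5, 0.5], [0.5, 0.5]]),
        emission_ranges={
            "Normal Temperature": {"Temp": (36.2, 37.4), "WBC": (5, 11)},
            "High Temperature": {"Temp": (37.6, 39.5), "WBC": (5, 11)},
        },
        missingness_rate=0.0, seed=42,
    )
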