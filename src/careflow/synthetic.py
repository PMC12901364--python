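"""Synthetic PhysioNet-style hourly cohorts from a known Markov ground truth.

Every downstream stage (PSV parsing, state classification, event-log
construction, process discovery, conformance) is testable without any
download: patients evolve on a latent clinical-state Markov chain sampled
hourly, each state emits measurements uniformly within threshold-consistent
intervals, scheduled measurements go missing at a configurable rate, and a
per-state hazard moves patients into an absorbing sepsis label, after which
the record stops — mirroring hourly ICU tables that run up to sepsis onset
or discharge.

The generator keeps its ground truth: each table carries the latent state
per row, and :func:`truth_summary` exposes the exact transition matrix, so
parameter-recovery tests can compare discovered transition frequencies
against what actually generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpecificationError
from .eventlog import PHYSIONET_COLUMNS, ClinicalRecordTable

MODELED_VARIABLES = ["Temp", "WBC", "TroponinI", "Creatinine", "AST"]


@dataclass
class CohortSpec:
    """Generator specification: states, dynamics, emissions, missingness.

    ``transition_matrix`` is row-stochastic over ``state_names`` per hour;
    ``emission_ranges[state][variable]`` is a closed interval consistent with
    the classification thresholds of the state it represents;
    ``sepsis_hazard[state]`` is the per-hour probability of entering the
    absorbing sepsis state. The initial distribution defaults to the first
    state with probability 1 (the dominant single entry point seen in
    clinical process maps) and is configurable.
    """

    n_patients: int
    horizon_hours: int
    state_names: list[str]
    transition_matrix: np.ndarray
    emission_ranges: dict[str, dict[str, tuple[float, float]]]
    missingness_rate: float = 0.0
    sepsis_hazard: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.state_names)
        if self.n_patients <= 0:
            raise SpecificationError("n_patients must be positive")
        if self.horizon_hours <= 0:
            raise SpecificationError("horizon_hours must be positive")
        if self.transition_matrix.shape != (k, k):
            raise SpecificationError("transition_matrix shape does not match states")
        if (self.transition_matrix < 0).any() or \
                not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise SpecificationError("transition_matrix rows must be non-negative and sum to 1")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise SpecificationError("missingness_rate must lie in [0, 1]")
        for s, h in self.sepsis_hazard.items():
            if s not in self.state_names or not 0.0 <= h <= 1.0:
                raise SpecificationError(f"invalid sepsis hazard for state {s!r}")
        for s in self.state_names:
            for var, (lo, hi) in self.emission_ranges.get(s, {}).items():
                if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                    raise SpecificationError(f"bad emission interval {s!r}/{var!r}")
        if self.initial_distribution is None:
            init = np.zeros(k)
            init[0] = 1.0
            self.initial_distribution = init
        else:
            self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
            if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-9):
                raise SpecificationError("initial_distribution must sum to 1")


def simulate_cohort(spec: CohortSpec) -> list[ClinicalRecordTable]:
    """Simulate ``spec.n_patients`` hourly tables; identical spec ⇒ identical output.

    Each patient draws from an independent substream seeded by
    ``(spec.seed, patient_index)`` so the first n patients are stable when
    ``n_patients`` grows.
    """
    idx = {s: i for i, s in enumerate(spec.state_names)}
    tables = []
    for p in range(spec.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, p]))
        state = spec.state_names[int(rng.choice(len(spec.state_names),
                                                p=spec.initial_distribution))]
        rows, latent = [], []
        for hour in range(1, spec.horizon_hours + 1):
            septic = rng.random() < spec.sepsis_hazard.get(state, 0.0)
            row = {c: np.nan for c in PHYSIONET_COLUMNS}
            for var in MODELED_VARIABLES:
                interval = spec.emission_ranges.get(state, {}).get(var)
                if interval is None:
                    continue
                value = rng.uniform(interval[0], interval[1])
                if rng.random() >= spec.missingness_rate:
                    row[var] = value
            row["ICULOS"] = hour
            row["SepsisLabel"] = int(septic)
            rows.append(row)
            latent.append(state)
            if septic:
                break
            state = spec.state_names[int(rng.choice(len(spec.state_names),
                                                    p=spec.transition_matrix[idx[state]]))]
        df = pd.DataFrame(rows, columns=PHYSIONET_COLUMNS)
        df["ICULOS"] = df["ICULOS"].astype(int)
        df["SepsisLabel"] = df["SepsisLabel"].astype(int)
        tables.append(ClinicalRecordTable(patient_id=f"p{p:06d}", data=df,
                                          latent_states=latent))
    return tables


def export_physionet_style(cohort: list[ClinicalRecordTable], directory) -> list[Path]:
    """Write one pipe-separated ``.psv`` per patient in the challenge dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for tab in cohort:
        path = directory / f"{tab.patient_id}.psv"
        tab.data.to_csv(path, sep="|", index=False, na_rep="NaN")
        paths.append(path)
    return paths


def truth_summary(spec: CohortSpec) -> pd.DataFrame:
    """The generator's exact per-state hourly transition probabilities."""
    return pd.DataFrame(spec.transition_matrix, index=spec.state_names,
                        columns=spec.state_names)


def collapsed_truth(spec: CohortSpec) -> pd.DataFrame:
    """Transition probabilities of the chain after collapsing self-loops.

    Collapsing consecutive repeats conditions each row on leaving the state:
    P*(i→j) = P(i→j) / (1 − P(i→i)) for j ≠ i. A state with a self-loop of
    probability 1 never leaves; its row is all zeros.
    """
    P = spec.transition_matrix.copy()
    out = np.zeros_like(P)
    for i in range(len(P)):
        stay = P[i, i]
        if stay < 1.0:
            out[i] = P[i] / (1.0 - stay)
            out[i, i] = 0.0
    return pd.DataFrame(out, index=spec.state_names, columns=spec.state_names)


def latent_transition_counts(cohort: list[ClinicalRecordTable],
                             state_names: list[str]) -> pd.DataFrame:
    """Count ground-truth hourly transitions in the simulator's truth log."""
    counts = pd.DataFrame(0, index=state_names, columns=state_names)
    for tab in cohort:
        path = tab.latent_states or []
        for a, b in zip(path, path[1:]):
            counts.at[a, b] += 1
    return counts


def infection_cohort_spec(n_patients: int = 200, horizon_hours: int = 48,
                          missingness_rate: float = 0.3, seed: int = 0) -> CohortSpec:
    """Default cohort emulating the infection/SIRS progression model.

    Six latent states combine SIRS temperature bands (<36, 36–37.5, >37.5 °C)
    with a leukocytosis infection flag (WBC > 12 ×10³ cells/µL); emission
    intervals sit strictly inside the corresponding classification bands.
    Hazards make sepsis rarest from normothermia and most likely from
    infection states.
    """
    normal_panel = {"TroponinI": (0.005, 0.03), "Creatinine": (0.6, 1.2), "AST": (10, 35)}
    states = [
        "Normal Temperature", "High Temperature", "Low Temperature",
        "Infection + High Temperature", "Infection + Normal Temperature",
        "Infection + Low Temperature",
    ]
    temp = {"Normal Temperature": (36.2, 37.4), "High Temperature": (37.6, 39.5),
            "Low Temperature": (34.5, 35.9)}
    emissions = {}
    for s in states:
        base = s.replace("Infection + ", "")
        wbc = (12.5, 25.0) if s.startswith("Infection") else (5.0, 11.0)
        emissions[s] = {"Temp": temp[base], "WBC": wbc, **normal_panel}
    matrix = np.array([
        [0.70, 0.12, 0.03, 0.05, 0.08, 0.02],
        [0.15, 0.65, 0.01, 0.15, 0.03, 0.01],
        [0.20, 0.02, 0.70, 0.01, 0.02, 0.05],
        [0.05, 0.10, 0.01, 0.65, 0.17, 0.02],
        [0.10, 0.03, 0.01, 0.12, 0.70, 0.04],
        [0.05, 0.01, 0.10, 0.02, 0.12, 0.70],
    ])
    hazard = {"Normal Temperature": 0.001, "High Temperature": 0.004,
              "Low Temperature": 0.004, "Infection + High Temperature": 0.012,
              "Infection + Normal Temperature": 0.008,
              "Infection + Low Temperature": 0.012}
    return CohortSpec(n_patients=n_patients, horizon_hours=horizon_hours,
                      state_names=states, transition_matrix=matrix,
                      emission_ranges=emissions, missingness_rate=missingness_rate,
                      sepsis_hazard=hazard, seed=seed)


def organ_cohort_spec(n_patients: int = 200, horizon_hours: int = 48,
                      missingness_rate: float = 0.3, seed: int = 0) -> CohortSpec:
    """Default cohort emulating the organ-damage progression model.

    Latent states span no dysfunction ("Low Risk"), single-organ damage
    (troponin I > 0.04 ng/mL cardiac, creatinine > 1.3 mg/dL renal,
    AST > 40 IU/L hepatic), one two-organ combination and three-organ
    ("Multiorgan") damage.
    """
    states = ["Low Risk", "Cardiac Damage", "Renal Damage", "Liver Damage",
              "Renal + Cardiac Damage", "Multiorgan Damage"]
    trp = {"lo": (0.005, 0.03), "hi": (0.05, 0.5)}
    crt = {"lo": (0.6, 1.2), "hi": (1.4, 3.5)}
    ast = {"lo": (10, 35), "hi": (45, 200)}
    vitals = {"Temp": (36.2, 37.4), "WBC": (5.0, 11.0)}
    flags = {  # (cardiac, renal, hepatic)
        "Low Risk": (0, 0, 0), "Cardiac Damage": (1, 0, 0),
        "Renal Damage": (0, 1, 0), "Liver Damage": (0, 0, 1),
        "Renal + Cardiac Damage": (1, 1, 0), "Multiorgan Damage": (1, 1, 1),
    }
    emissions = {
        s: {**vitals,
            "TroponinI": trp["hi" if c else "lo"],
            "Creatinine": crt["hi" if r else "lo"],
            "AST": ast["hi" if h else "lo"]}
        for s, (c, r, h) in flags.items()
    }
    matrix = np.array([
        [0.80, 0.08, 0.05, 0.03, 0.02, 0.02],
        [0.10, 0.70, 0.02, 0.02, 0.10, 0.06],
        [0.10, 0.03, 0.72, 0.02, 0.08, 0.05],
        [0.10, 0.03, 0.02, 0.75, 0.02, 0.08],
        [0.02, 0.08, 0.06, 0.01, 0.68, 0.15],
        [0.02, 0.03, 0.03, 0.03, 0.09, 0.80],
    ])
    hazard = {"Low Risk": 0.0005, "Cardiac Damage": 0.004, "Renal Damage": 0.003,
              "Liver Damage": 0.003, "Renal + Cardiac Damage": 0.008,
              "Multiorgan Damage": 0.02}
    return CohortSpec(n_patients=n_patients, horizon_hours=horizon_hours,
                      state_names=states, transition_matrix=matrix,
                      emission_ranges=emissions, missingness_rate=missingness_rate,
                      sepsis_hazard=hazard, seed=seed)
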