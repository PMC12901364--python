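"""Process discovery: directly-follows graphs, variants and process matrices.

The directly-follows graph (DFG) counts, for every ordered activity pair
(a, b), how often b immediately follows a across all traces, together with
trace start/end counts and per-activity case coverage (share of traces
containing the activity — the percentage annotation on process-map nodes).
The process matrix is the DFG's square-matrix form, the aggregate artifact
handed to report generation; no patient-level rows leave this module.

The heuristics-miner dependency measure (a − b)/(a + b + 1) quantifies how
one-directional a directly-follows relation is, tolerant of noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .eventlog import EventLog


@dataclass
class DFG:
    activities: list[str]  # first-appearance order
    edge_counts: dict[tuple[str, str], int]
    start_counts: dict[str, int]
    end_counts: dict[str, int]
    case_coverage: dict[str, float]
    n_traces: int

    def successors(self, a: str) -> set[str]:
        return {b for (x, b) in self.edge_counts if x == a}


@dataclass
class VariantTable:
    """Distinct activity sequences with counts, sorted by count then lexically."""

    rows: list[tuple[tuple[str, ...], int, float]]
    n_traces: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(" → ".join(v), c, s) for v, c, s in self.rows],
            columns=["variant", "count", "share"],
        )


@dataclass
class ProcessMatrix:
    activities: list[str]
    counts: np.ndarray  # square, counts[i, j] = directly-follows count
    starts: np.ndarray
    ends: np.ndarray
    n_traces: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        """Row-normalized transition frequencies; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    def to_json(self) -> str:
        return json.dumps({
            "activities": self.activities,
            "matrix": self.counts.tolist(),
            "starts": self.starts.tolist(),
            "ends": self.ends.tolist(),
            "n_traces": self.n_traces,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProcessMatrix":
        d = json.loads(text)
        return cls(d["activities"], np.array(d["matrix"]), np.array(d["starts"]),
                   np.array(d["ends"]), d.get("n_traces", 0))


def discover_dfg(log: EventLog) -> DFG:
    """Count directly-follows pairs, trace starts/ends and case coverage."""
    if not log.traces:
        raise DegenerateInputError("cannot discover a DFG from an empty log")
    activities: list[str] = []
    seen = set()
    edges: dict[tuple[str, str], int] = {}
    starts: dict[str, int] = {}
    ends: dict[str, int] = {}
    containing: dict[str, int] = {}
    for trace in log.traces:
        acts = trace.activities
        for a in acts:
            if a not in seen:
                seen.add(a)
                activities.append(a)
        starts[acts[0]] = starts.get(acts[0], 0) + 1
        ends[acts[-1]] = ends.get(acts[-1], 0) + 1
        for a, b in zip(acts, acts[1:]):
            edges[(a, b)] = edges.get((a, b), 0) + 1
        for a in set(acts):
            containing[a] = containing.get(a, 0) + 1
    n = len(log.traces)
    coverage = {a: containing[a] / n for a in activities}
    return DFG(activities, edges, starts, ends, coverage, n)


def trace_variants(log: EventLog) -> VariantTable:
    """One row per distinct sequence, count-descending, ties lexicographic."""
    if not log.traces:
        raise DegenerateInputError("cannot tabulate variants of an empty log")
    counts: dict[tuple[str, ...], int] = {}
    for t in log.traces:
        counts[t.activities] = counts.get(t.activities, 0) + 1
    n = len(log.traces)
    rows = sorted(((v, c, c / n) for v, c in counts.items()),
                  key=lambda r: (-r[1], r[0]))
    return VariantTable(rows=rows, n_traces=n)


def to_process_matrix(dfg: DFG) -> ProcessMatrix:
    """Lossless square-matrix form of the DFG, first-appearance ordering."""
    idx = {a: i for i, a in enumerate(dfg.activities)}
    k = len(dfg.activities)
    counts = np.zeros((k, k), dtype=int)
    for (a, b), c in dfg.edge_counts.items():
        counts[idx[a], idx[b]] = c
    starts = np.array([dfg.start_counts.get(a, 0) for a in dfg.activities])
    ends = np.array([dfg.end_counts.get(a, 0) for a in dfg.activities])
    return ProcessMatrix(list(dfg.activities), counts, starts, ends, dfg.n_traces)


def matrix_to_dfg(pm: ProcessMatrix) -> DFG:
    """Inverse of :func:`to_process_matrix`."""
    edges = {
        (pm.activities[i], pm.activities[j]): int(pm.counts[i, j])
        for i in range(len(pm.activities)) for j in range(len(pm.activities))
        if pm.counts[i, j] > 0
    }
    starts = {a: int(s) for a, s in zip(pm.activities, pm.starts) if s > 0}
    ends = {a: int(e) for a, e in zip(pm.activities, pm.ends) if e > 0}
    return DFG(list(pm.activities), edges, starts, ends, {}, pm.n_traces)


def dependency_measure(count_ab: int, count_ba: int) -> float:
    """Heuristics-miner dependency score (a − b)/(a + b + 1) in (−1, 1)."""
    return (count_ab - count_ba) / (count_ab + count_ba + 1)


def dependency_matrix(dfg: DFG) -> pd.DataFrame:
    acts = dfg.activities
    out = pd.DataFrame(0.0, index=acts, columns=acts)
    for a in acts:
        for b in acts:
            out.at[a, b] = dependency_measure(dfg.edge_counts.get((a, b), 0),
                                              dfg.edge_counts.get((b, a), 0))
    return out


def filter_edges(dfg: DFG, min_count: int) -> DFG:
    """Optional frequency filter; discovery applies no pruning by default."""
    edges = {e: c for e, c in dfg.edge_counts.items() if c >= min_count}
    return DFG(dfg.activities, edges, dict(dfg.start_counts),
               dict(dfg.end_counts), dict(dfg.case_coverage), dfg.n_traces)


def to_dot(dfg: DFG, rankdir: str = "TB") -> str:
    """Deterministic DOT rendering: edge labels are absolute counts, node
    labels carry case-coverage percentages to 2 decimals (e.g. "97.18%")."""
    lines = [f'digraph dfg {{\n  rankdir={rankdir};\n  node [shape=box];']
    ids = {a: f"n{i}" for i, a in enumerate(dfg.activities)}
    for a in dfg.activities:
        pct = dfg.case_coverage.get(a, 0.0) * 100
        lines.append(f'  {ids[a]} [label="{a}\\n{pct:.2f}%"];')
    for (a, b), c in sorted(dfg.edge_counts.items(),
                            key=lambda kv: (dfg.activities.index(kv[0][0]),
                                            dfg.activities.index(kv[0][1]))):
        lines.append(f'  {ids[a]} -> {ids[b]} [label="{c}"];')
    lines.append("}")
    return "\n".join(lines)
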