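"""Model-quality metrics: token-replay fitness, escaping-arcs precision, F1.

The replay substrate is a state-machine workflow net derived from a DFG:
one place per activity ("a just executed") plus a single-token source and a
sink; a visible transition per activity, wired so that activity b can fire
from place a exactly when the edge (a, b) was observed; invisible start/end
transitions route the source token to observed start activities and observed
end activities to the sink. Invisible transitions are excluded from enabled
sets and token tallies.

Fitness replays every trace, inserting missing tokens where a firing is not
enabled and counting tokens left over at the end:

    F = ½(1 − Σm/Σc) + ½(1 − Σr/Σp)

aggregated over the whole log (sum the tallies, then apply the formula).

Precision follows the escaping-arcs idea: walk the observed prefixes,
compare what the model enables next against what the log actually does
next, and penalize enabled-but-never-observed continuations. Prefixes are
abstracted to their last activity, matching the memorylessness of the DFG
net; under this abstraction a log always has precision 1 on its own DFG
net, while a flower model (everything always enabled) is punished in
proportion to how constrained the real behavior is.

F1 = 2·(Precision·Fitness)/(Precision + Fitness), the harmonic mean, with
F1(0, 0) = 0 by convention.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .discovery import DFG
from .errors import DegenerateInputError, SpecificationError
from .eventlog import EventLog

SOURCE, SINK = "__source__", "__sink__"


@dataclass
class PetriNet:
    """State-machine workflow net used for replay.

    ``transitions`` lists (name, label, visible) triples; ``arcs`` connect
    places to transitions and vice versa. ``edges``/``starts``/``ends``
    carry the replay semantics; for a flower net every activity is enabled
    from every marking.
    """

    places: list[str]
    transitions: list[tuple[str, str | None, bool]]
    arcs: list[tuple[str, str]]
    activities: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    starts: set[str] = field(default_factory=set)
    ends: set[str] = field(default_factory=set)
    flower: bool = False

    def enabled_after(self, last_activity: str | None) -> set[str]:
        """Activities the model allows after an observed prefix, abstracted
        to the prefix's last activity (None = before the first event)."""
        if self.flower:
            return set(self.activities)
        if last_activity is None:
            return set(self.starts)
        return {b for (a, b) in self.edges if a == last_activity}

    def to_dot(self) -> str:
        lines = ["digraph net {", "  rankdir=LR;"]
        for p in self.places:
            lines.append(f'  "{p}" [shape=circle,label=""];')
        for name, label, visible in self.transitions:
            style = "" if visible else ",style=dashed"
            lines.append(f'  "{name}" [shape=box,label="{label or ""}"{style}];')
        for a, b in self.arcs:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def _place(a: str) -> str:
    return f"p_{a}"


def dfg_to_state_net(dfg: DFG) -> PetriNet:
    """State-machine net: a transition labeled b with input place of a
    exists iff the edge (a, b) was observed; start/end transitions are wired
    from the start/end count support."""
    if not dfg.activities:
        raise DegenerateInputError("cannot build a net from an empty DFG")
    places = [SOURCE, SINK] + [_place(a) for a in dfg.activities]
    transitions = [(f"t_{a}", a, True) for a in dfg.activities]
    arcs = [(_place(a), f"t_{b}") for (a, b) in sorted(dfg.edge_counts)] + \
           [(f"t_{a}", _place(a)) for a in dfg.activities]
    starts = {a for a, c in dfg.start_counts.items() if c > 0}
    ends = {a for a, c in dfg.end_counts.items() if c > 0}
    for a in sorted(starts):
        transitions.append((f"start_{a}", None, False))
        arcs += [(SOURCE, f"start_{a}"), (f"start_{a}", f"t_{a}")]
    for a in sorted(ends):
        transitions.append((f"end_{a}", None, False))
        arcs += [(_place(a), f"end_{a}"), (f"end_{a}", SINK)]
    return PetriNet(places, transitions, arcs, list(dfg.activities),
                    edges=set(dfg.edge_counts), starts=starts, ends=ends)


def make_flower_net(activities: list[str]) -> PetriNet:
    """Flower model: every activity enabled in any order — perfect fitness,
    low precision on any structured log."""
    if not activities:
        raise DegenerateInputError("flower net needs at least one activity")
    places = [SOURCE, "center", SINK]
    transitions = [(f"t_{a}", a, True) for a in activities]
    arcs = [("center", f"t_{a}") for a in activities] + \
           [(f"t_{a}", "center") for a in activities]
    transitions += [("start", None, False), ("end", None, False)]
    arcs += [(SOURCE, "start"), ("start", "center"), ("center", "end"), ("end", SINK)]
    return PetriNet(places, transitions, arcs, list(activities), flower=True)


@dataclass
class ReplayResult:
    produced: int
    consumed: int
    missing: int
    remaining: int
    per_trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.produced, self.consumed, self.missing, self.remaining) < 0:
            raise ValueError("token tallies must be non-negative")
        if self.missing > self.consumed:
            raise ValueError("missing tokens cannot exceed consumed tokens")

    @property
    def fitness(self) -> float:
        if self.consumed == 0 or self.produced == 0:
            return 0.0
        return 0.5 * (1 - self.missing / self.consumed) + \
            0.5 * (1 - self.remaining / self.produced)

    @property
    def perfect(self) -> bool:
        return self.missing == 0 and self.remaining == 0


def _replay_trace(net: PetriNet, acts: tuple[str, ...]) -> dict:
    """Token game for one trace; missing tokens are inserted to continue."""
    marking: Counter = Counter({SOURCE: 1})
    p, c, m = 1, 0, 0
    last_produced: str | None = None
    known = set(net.activities)
    for b in acts:
        target = "center" if net.flower else _place(b)
        if net.flower:
            candidates = ["center"] if marking["center"] > 0 else []
            if not candidates and b in known and marking[SOURCE] > 0:
                candidates = [SOURCE]
            if b not in known:
                candidates = []
        else:
            feeders = [_place(a) for (a, x) in net.edges if x == b]
            candidates = [pl for pl in feeders if marking[pl] > 0]
            if last_produced in candidates:  # prefer the live token's place
                candidates = [last_produced] + [x for x in candidates if x != last_produced]
            if b in net.starts and marking[SOURCE] > 0:
                candidates.append(SOURCE)
        if candidates:
            marking[candidates[0]] -= 1
        else:
            m += 1  # missing token inserted at b's input, immediately consumed
        c += 1
        marking[target] += 1
        p += 1
        last_produced = target
    # final consumption: the sink must receive the last token
    c += 1
    last = acts[-1] if acts else None
    final_place = "center" if net.flower else (_place(last) if last else None)
    ok_end = net.flower or (last in net.ends)
    if final_place and ok_end and marking[final_place] > 0:
        marking[final_place] -= 1
    else:
        m += 1
    r = sum(v for v in marking.values() if v > 0)
    return {"produced": p, "consumed": c, "missing": m, "remaining": r,
            "trace": acts}


def token_replay_fitness(net: PetriNet, log: EventLog) -> ReplayResult:
    """Replay every trace and aggregate token tallies over the whole log."""
    if not log.traces:
        raise DegenerateInputError("cannot replay an empty log")
    per_trace = [_replay_trace(net, t.activities) for t in log.traces]
    return ReplayResult(
        produced=sum(t["produced"] for t in per_trace),
        consumed=sum(t["consumed"] for t in per_trace),
        missing=sum(t["missing"] for t in per_trace),
        remaining=sum(t["remaining"] for t in per_trace),
        per_trace=per_trace,
    )


def escaping_arcs_precision(net: PetriNet, log: EventLog) -> float:
    """P = 1 − Σ w(s)·|escaping(s)| / Σ w(s)·|enabled(s)| over observed
    prefix states s (abstracted to the last activity), weighted by
    occurrence. Escaping = enabled by the model but never observed next."""
    if not log.traces:
        raise DegenerateInputError("cannot compute precision on an empty log")
    if not set(net.activities) & log.activity_universe:
        raise DegenerateInputError("model and log alphabets are disjoint; "
                                   "precision undefined")
    observed_next: dict[str | None, set[str]] = {}
    state_weight: Counter = Counter()
    for t in log.traces:
        prev: str | None = None
        for b in t.activities:
            observed_next.setdefault(prev, set()).add(b)
            state_weight[prev] += 1
            prev = b
    num = den = 0
    for state, w in state_weight.items():
        enabled = net.enabled_after(state)
        if not enabled:
            continue
        escaping = enabled - observed_next[state]
        num += w * len(escaping)
        den += w * len(enabled)
    if den == 0:
        raise DegenerateInputError("model enables nothing along the log; "
                                   "precision undefined")
    return 1.0 - num / den


def f1_score(fitness: float, precision: float) -> float:
    """Harmonic mean of fitness and precision; 0 when both are 0."""
    for name, v in (("fitness", fitness), ("precision", precision)):
        if not 0.0 <= v <= 1.0:
            raise SpecificationError(f"{name} must lie in [0, 1], got {v}")
    if fitness == 0.0 and precision == 0.0:
        return 0.0
    return 2.0 * precision * fitness / (precision + fitness)


@dataclass
class ConformanceResult:
    fitness: float
    precision: float
    f1: float
    replay: ReplayResult | None = None

    def to_json(self) -> str:
        return json.dumps({"fitness": self.fitness, "precision": self.precision,
                           "f1": self.f1}, indent=2)


def evaluate_conformance(dfg: DFG, log: EventLog) -> ConformanceResult:
    """Fitness, precision and F1 of a DFG's state net against a log."""
    net = dfg_to_state_net(dfg)
    replay = token_replay_fitness(net, log)
    precision = escaping_arcs_precision(net, log)
    return ConformanceResult(fitness=replay.fitness, precision=precision,
                             f1=f1_score(replay.fitness, precision),
                             replay=replay)
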