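"""Structured report generation over aggregated process-mining artifacts.

Prompt assembly follows a five-component structure — role definition, task
specification, context provision (audience, disease-state logic and the
valid-state constraint list with its reversibility note), output-format
requirements and quality criteria. The payload is the serialized process
matrix plus summary statistics only: raw patient-level rows never leave the
pipeline, so prompts and reports are privacy-safe by construction.

Reports follow a fixed six-section Markdown skeleton (Executive Summary,
Introduction, Process Map Analysis, Data Summary Tables, Hypothesis
Generation, Conclusion); the Data Summary Tables section carries the
mandatory Case Summary / Activity Summary / Trace Summary sub-structure.

Interpreter backends satisfy a small contract (identity, generate, cost);
a fully deterministic template backend renders reference reports without
any external service, and the orchestrator collects reports from several
backends, extracts structured findings and splits them into quorum-backed
consensus versus preserved divergent findings with provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

from .discovery import ProcessMatrix, VariantTable
from .errors import ConfigurationError, DegenerateInputError, OrchestrationError

SECTION_HEADINGS = [
    "Executive Summary", "Introduction", "Process Map Analysis",
    "Data Summary Tables", "Hypothesis Generation", "Conclusion",
]


@dataclass
class CaseConfig:
    """Audience, disease context and the constrained state list for a case."""

    case_id: str
    audience: str
    disease_context: str
    valid_states: list[str]
    reversible_transitions: bool = True

    def __post_init__(self) -> None:
        if not self.valid_states:
            raise ConfigurationError("case config requires a non-empty state list")


@dataclass
class PromptBundle:
    role_definition: str
    task_specification: str
    context_provision: str
    output_format_requirements: str
    quality_criteria: str
    payload: str

    def __post_init__(self) -> None:
        for name in ("role_definition", "task_specification", "context_provision",
                     "output_format_requirements", "quality_criteria"):
            if not getattr(self, name).strip():
                raise ConfigurationError(f"prompt component {name} is empty")

    @property
    def text(self) -> str:
        return "\n\n".join([
            self.role_definition, self.task_specification, self.context_provision,
            self.output_format_requirements, self.quality_criteria, self.payload,
        ])


@dataclass
class ReportDocument:
    sections: list[tuple[str, str]]
    metadata: dict = field(default_factory=dict)

    def check(self) -> None:
        """Raise unless the section headings are exactly the required six,
        in order."""
        headings = [h for h, _ in self.sections]
        if headings != SECTION_HEADINGS:
            raise ConfigurationError(
                f"report sections must be {SECTION_HEADINGS}, got {headings}")

    @property
    def is_valid(self) -> bool:
        try:
            self.check()
            return True
        except ConfigurationError:
            return False

    def section(self, heading: str) -> str:
        for h, body in self.sections:
            if h == heading:
                return body
        raise KeyError(heading)

    def to_markdown(self) -> str:
        parts = []
        for h, body in self.sections:
            parts.append(f"## {h}\n\n{body.strip()}\n")
        return "\n".join(parts)


@runtime_checkable
class InterpreterBackend(Protocol):
    """Contract every report interpreter satisfies.

    ``identity`` names the backend; ``generate`` maps a prompt bundle to a
    report document; ``cost_per_mtok`` is the (input, output) price per 10⁶
    tokens. Live API adapters implement the same contract but are never
    exercised in tests.
    """

    identity: str
    cost_per_mtok: tuple[float, float]

    def generate(self, bundle: PromptBundle) -> ReportDocument: ...


def summarize_matrix(matrix: ProcessMatrix,
                     variants: VariantTable | None = None) -> dict:
    """Aggregate statistics for the payload: counts only, no patient rows."""
    stats = {
        "n_activities": len(matrix.activities),
        "n_traces": matrix.n_traces,
        "n_transitions_observed": int((matrix.counts > 0).sum()),
        "total_transition_count": int(matrix.counts.sum()),
    }
    if variants is not None:
        stats["n_variants"] = len(variants.rows)
        stats["top_variants"] = [
            {"variant": list(v), "count": c, "share": round(s, 4)}
            for v, c, s in variants.rows[:5]
        ]
    return stats


def assemble_prompt(case_config: CaseConfig, matrix: ProcessMatrix,
                    stats: dict | None = None) -> PromptBundle:
    """Deterministic five-component prompt over the process matrix."""
    states = "; ".join(f"({i + 1}) {s}" for i, s in enumerate(case_config.valid_states))
    reversibility = ("Transitions between these states are reversible."
                     if case_config.reversible_transitions else
                     "Transitions between these states are one-directional.")
    stats = stats if stats is not None else summarize_matrix(matrix)
    payload = json.dumps({"process_matrix": json.loads(matrix.to_json()),
                          "summary_statistics": stats}, indent=2, sort_keys=True)
    return PromptBundle(
        role_definition=(
            "You are an expert process mining analyst applied to epidemiology, "
            "skilled at communicating complex data to clinical stakeholders."),
        task_specification=(
            "Synthesize the provided process matrix and summary statistics "
            f"for case {case_config.case_id} into a comprehensive report."),
        context_provision=(
            f"Audience: {case_config.audience}. "
            f"Disease context: {case_config.disease_context}. "
            f"The only valid states are: {states}. {reversibility} "
            "Do not fabricate states absent from this list."),
        output_format_requirements=(
            "Respond in strict Markdown with exactly these sections, in "
            "order: " + ", ".join(SECTION_HEADINGS) + ". The Data Summary "
            "Tables section must contain Case Summary, Activity Summary and "
            "Trace Summary subsections."),
        quality_criteria=(
            "Maintain a professional, collaborative tone; use bullet points "
            "and bold text for key findings; keep every number consistent "
            "with the supplied matrix."),
        payload=payload,
    )


def render_template_report(matrix: ProcessMatrix, variants: VariantTable,
                           case_config: CaseConfig) -> ReportDocument:
    """Deterministic non-LLM reference report; numbers come straight from
    the matrix and variant table."""
    if len(matrix.activities) == 0 or matrix.n_traces == 0:
        raise DegenerateInputError("cannot render a report from an empty matrix")
    freq = matrix.counts.sum(axis=1) + matrix.ends
    case_summary = (f"Case Summary\n\n- Case: {case_config.case_id}\n"
                    f"- Traces analysed: {matrix.n_traces}\n"
                    f"- Distinct activities: {len(matrix.activities)}")
    activity_lines = [
        f"- {a}: {int(matrix.counts[i].sum() + matrix.ends[i])} occurrences as "
        f"source, starts {int(matrix.starts[i])}, ends {int(matrix.ends[i])}"
        for i, a in enumerate(matrix.activities)
    ]
    trace_lines = [
        f"- {' → '.join(v)}: {c} cases ({s:.2%})" for v, c, s in variants.rows[:5]
    ]
    top = matrix.counts.flatten()
    strongest = ""
    if top.max() > 0:
        i, j = divmod(int(top.argmax()), len(matrix.activities))
        strongest = (f"The most frequent transition is "
                     f"{matrix.activities[i]} → {matrix.activities[j]} "
                     f"({int(matrix.counts[i, j])} occurrences).")
    sections = [
        ("Executive Summary",
         f"Process analysis of case {case_config.case_id} over "
         f"{matrix.n_traces} patient traces and {len(matrix.activities)} "
         f"clinical states. {strongest}"),
        ("Introduction",
         f"This report summarizes directly-follows process discovery for "
         f"{case_config.disease_context}, intended for "
         f"{case_config.audience}. Valid states: "
         + ", ".join(case_config.valid_states) + "."),
        ("Process Map Analysis",
         "Transition structure derived from the process matrix. "
         + (strongest or "No transitions observed.")),
        ("Data Summary Tables",
         case_summary + "\n\nActivity Summary\n\n" + "\n".join(activity_lines)
         + "\n\nTrace Summary\n\n" + "\n".join(trace_lines)),
        ("Hypothesis Generation",
         "Hypothesis: observed transition frequencies reflect the underlying "
         "clinical progression dynamics; high-frequency transitions warrant "
         "closer monitoring."),
        ("Conclusion",
         f"The discovered process map over {len(matrix.activities)} states "
         "provides an interpretable summary of cohort-level progression."),
    ]
    doc = ReportDocument(sections=sections,
                         metadata={"case_id": case_config.case_id,
                                   "backend": "template"})
    doc.check()
    return doc


@dataclass
class TemplateBackend:
    """Deterministic backend rendering the reference report from the payload."""

    identity: str = "template"
    cost_per_mtok: tuple[float, float] = (0.0, 0.0)
    case_config: CaseConfig | None = None
    variants: VariantTable | None = None

    def generate(self, bundle: PromptBundle) -> ReportDocument:
        payload = json.loads(bundle.payload)
        matrix = ProcessMatrix.from_json(json.dumps(payload["process_matrix"]))
        cfg = self.case_config or CaseConfig(
            "case", "clinical stakeholders", "disease progression",
            list(matrix.activities))
        variants = self.variants or VariantTable(rows=[], n_traces=matrix.n_traces)
        return render_template_report(matrix, variants, cfg)


@dataclass
class ScriptedBackend:
    """Test double emitting a fixed set of findings inside a valid skeleton."""

    identity: str
    findings: list[str]
    cost_per_mtok: tuple[float, float] = (0.0, 0.0)
    valid: bool = True

    def generate(self, bundle: PromptBundle) -> ReportDocument:
        body = "\n".join(f"- {f}" for f in self.findings)
        sections = [(h, body if h == "Data Summary Tables" else f"Narrative for {h}.")
                    for h in SECTION_HEADINGS]
        if not self.valid:
            sections = sections[::-1]
        return ReportDocument(sections=sections, metadata={"backend": self.identity})


def normalize_finding(text: str) -> str:
    """Voting key: lowercase, collapse whitespace, round numbers to 2
    significant figures. Semantic matching is deliberately not attempted."""

    def _round(match: re.Match) -> str:
        value = float(match.group(0))
        if value == 0:
            return "0"
        rounded = float(f"{value:.2g}")
        return f"{rounded:g}"

    text = re.sub(r"-?\d+\.?\d*", _round, text.strip().lower())
    return re.sub(r"\s+", " ", text)


def extract_findings(doc: ReportDocument) -> list[str]:
    """Tabulated statements from Data Summary Tables plus tagged hypotheses."""
    findings = []
    for line in doc.section("Data Summary Tables").splitlines():
        line = line.strip()
        if line.startswith("- "):
            findings.append(line[2:])
    for line in doc.section("Hypothesis Generation").splitlines():
        line = line.strip()
        if line.lower().startswith("hypothesis"):
            findings.append(line)
    return findings


@dataclass
class ConsensusSummary:
    consensus_findings: list[dict]
    divergent_findings: list[dict]
    agreement_rate: float

    def to_json(self) -> str:
        return json.dumps({
            "consensus_findings": self.consensus_findings,
            "divergent_findings": self.divergent_findings,
            "agreement_rate": self.agreement_rate,
        }, indent=2)


def orchestrate(bundle: PromptBundle, backends: list,
                quorum: int = 2) -> tuple[list[ReportDocument], ConsensusSummary]:
    """Collect structurally valid reports and split findings by quorum.

    Findings shared (after normalization) by at least ``quorum`` backends
    become consensus; the rest are preserved as divergent with provenance —
    divergences are uncertainty indicators, not noise to discard.
    """
    if not backends:
        raise ConfigurationError("orchestration requires at least one backend")
    if quorum < 1 or quorum > len(backends):
        raise ConfigurationError("quorum must lie in [1, number of backends]")
    reports, rejected = [], []
    per_backend: dict[str, list[str]] = {}
    for backend in backends:
        doc = backend.generate(bundle)
        if not doc.is_valid:
            rejected.append(backend.identity)
            continue
        reports.append(doc)
        per_backend[backend.identity] = extract_findings(doc)
    if not reports:
        raise OrchestrationError(f"all backends structurally invalid: {rejected}")

    support: dict[str, dict] = {}
    for identity, findings in per_backend.items():
        for f in findings:
            key = normalize_finding(f)
            entry = support.setdefault(key, {"finding": f, "backends": []})
            if identity not in entry["backends"]:
                entry["backends"].append(identity)
    consensus, divergent = [], []
    for key in sorted(support):
        entry = support[key]
        record = {"finding": entry["finding"], "backends": entry["backends"],
                  "support": len(entry["backends"])}
        (consensus if record["support"] >= quorum else divergent).append(record)
    total = len(support)
    rate = len(consensus) / total if total else 0.0
    summary = ConsensusSummary(consensus_findings=consensus,
                               divergent_findings=divergent,
                               agreement_rate=rate)
    return reports, summary
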