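import json

import pytest

from careflow import (
    CaseConfig,
    OrchestrationError,
    ScriptedBackend,
    TemplateBackend,
    assemble_prompt,
    build_event_log,
    discover_dfg,
    orchestrate,
    render_template_report,
    to_process_matrix,
    trace_variants,
)
from careflow.errors import ConfigurationError, DegenerateInputError
from careflow.reporting import (
    SECTION_HEADINGS,
    ReportDocument,
    extract_findings,
    normalize_finding,
    summarize_matrix,
)
from careflow.states import StateModelSpec

from conftest import make_log


@pytest.fixture
def case_i_config():
    return CaseConfig(
        case_id="case-i", audience="clinical and epidemiological stakeholders",
        disease_context="sepsis progression",
        valid_states=["low temperature", "normal temperature",
                      "high temperature", "infection", "sepsis"])


@pytest.fixture
def matrix_and_variants():
    log = make_log([["A", "B", "C"], ["A", "B"], ["A", "C"]])
    return to_process_matrix(discover_dfg(log)), trace_variants(log)


class TestAssemblePrompt:
    def test_contains_constrained_states_and_reversibility(self, case_i_config,
                                                           matrix_and_variants):
        bundle = assemble_prompt(case_i_config, matrix_and_variants[0])
        assert "(4) infection" in bundle.context_provision
        assert "(5) sepsis" in bundle.context_provision
        assert "reversible" in bundle.context_provision
        assert "Markdown" in bundle.output_format_requirements

    def test_deterministic(self, case_i_config, matrix_and_variants):
        a = assemble_prompt(case_i_config, matrix_and_variants[0])
        b = assemble_prompt(case_i_config, matrix_and_variants[0])
        assert a.text == b.text

    def test_missing_state_list_rejected(self):
        with pytest.raises(ConfigurationError):
            CaseConfig("c", "aud", "ctx", [])

    def test_payload_is_aggregate_only_no_patient_ids(self, small_cohort,
                                                      case_i_config):
        _, cohort = small_cohort
        log, _ = build_event_log(cohort, StateModelSpec("infection"))
        matrix = to_process_matrix(discover_dfg(log))
        bundle = assemble_prompt(case_i_config, matrix)
        for tab in cohort:
            assert tab.patient_id not in bundle.text

    def test_empty_component_rejected(self, case_i_config, matrix_and_variants):
        bundle = assemble_prompt(case_i_config, matrix_and_variants[0])
        with pytest.raises(ConfigurationError):
            type(bundle)(role_definition=" ",
                         task_specification=bundle.task_specification,
                         context_provision=bundle.context_provision,
                         output_format_requirements=bundle.output_format_requirements,
                         quality_criteria=bundle.quality_criteria,
                         payload=bundle.payload)


class TestTemplateReport:
    def test_six_sections_in_order(self, case_i_config, matrix_and_variants):
        doc = render_template_report(*matrix_and_variants, case_i_config)
        assert [h for h, _ in doc.sections] == SECTION_HEADINGS

    def test_data_summary_totals_match_inputs(self, case_i_config,
                                              matrix_and_variants):
        matrix, variants = matrix_and_variants
        doc = render_template_report(matrix, variants, case_i_config)
        body = doc.section("Data Summary Tables")
        assert f"Traces analysed: {matrix.n_traces}" in body
        assert "Case Summary" in body and "Activity Summary" in body \
            and "Trace Summary" in body
        total = sum(c for _, c, _ in variants.rows)
        assert total == matrix.n_traces

    def test_byte_identical_determinism(self, case_i_config, matrix_and_variants):
        a = render_template_report(*matrix_and_variants, case_i_config)
        b = render_template_report(*matrix_and_variants, case_i_config)
        assert a.to_markdown() == b.to_markdown()

    def test_empty_matrix_rejected(self, case_i_config):
        from careflow.discovery import ProcessMatrix
        import numpy as np
        empty = ProcessMatrix([], np.zeros((0, 0)), np.array([]), np.array([]), 0)
        with pytest.raises(DegenerateInputError):
            render_template_report(empty, trace_variants(make_log([["A"]])),
                                   case_i_config)

    def test_schema_checker_rejects_permuted_sections(self, case_i_config,
                                                      matrix_and_variants):
        doc = render_template_report(*matrix_and_variants, case_i_config)
        permuted = ReportDocument(sections=doc.sections[::-1])
        assert not permuted.is_valid
        with pytest.raises(ConfigurationError):
            permuted.check()


class TestOrchestrate:
    def bundle(self, matrix_and_variants, case_i_config):
        return assemble_prompt(case_i_config, matrix_and_variants[0])

    def test_identical_backends_agree_fully(self, matrix_and_variants,
                                            case_i_config):
        bundle = self.bundle(matrix_and_variants, case_i_config)
        backends = [ScriptedBackend(f"m{i}", ["X is high", "Y is low"])
                    for i in range(3)]
        reports, summary = orchestrate(bundle, backends, quorum=2)
        assert len(reports) == 3
        assert summary.agreement_rate == 1.0
        assert summary.divergent_findings == []

    def test_quorum_voting_splits_findings(self, matrix_and_variants,
                                           case_i_config):
        bundle = self.bundle(matrix_and_variants, case_i_config)
        backends = [ScriptedBackend("A", ["X", "Y"]),
                    ScriptedBackend("B", ["X"]),
                    ScriptedBackend("C", ["X", "Z"])]
        _, summary = orchestrate(bundle, backends, quorum=2)
        consensus = {f["finding"] for f in summary.consensus_findings}
        divergent = {f["finding"] for f in summary.divergent_findings}
        assert consensus == {"X"} and divergent == {"Y", "Z"}
        assert summary.agreement_rate == pytest.approx(1 / 3)
        # divergent findings keep their provenance
        sources = {f["finding"]: f["backends"] for f in summary.divergent_findings}
        assert sources["Y"] == ["A"] and sources["Z"] == ["C"]

    def test_quorum_one_makes_everything_consensus(self, matrix_and_variants,
                                                   case_i_config):
        bundle = self.bundle(matrix_and_variants, case_i_config)
        backends = [ScriptedBackend("A", ["X"]), ScriptedBackend("B", ["Y"])]
        _, summary = orchestrate(bundle, backends, quorum=1)
        assert summary.agreement_rate == 1.0

    def test_invalid_backends_rejected_and_reported(self, matrix_and_variants,
                                                    case_i_config):
        bundle = self.bundle(matrix_and_variants, case_i_config)
        with pytest.raises(OrchestrationError, match="bad"):
            orchestrate(bundle, [ScriptedBackend("bad", ["X"], valid=False)],
                        quorum=1)

    def test_quorum_bounds_checked(self, matrix_and_variants, case_i_config):
        bundle = self.bundle(matrix_and_variants, case_i_config)
        with pytest.raises(ConfigurationError):
            orchestrate(bundle, [ScriptedBackend("A", ["X"])], quorum=2)
        with pytest.raises(ConfigurationError):
            orchestrate(bundle, [], quorum=1)

    def test_template_backends_agree_on_everything(self, small_cohort,
                                                   case_i_config):
        _, cohort = small_cohort
        log, _ = build_event_log(cohort, StateModelSpec("infection"))
        matrix = to_process_matrix(discover_dfg(log))
        variants = trace_variants(log)
        cfg = CaseConfig("case-i", "clinicians", "sepsis progression",
                         list(matrix.activities))
        bundle = assemble_prompt(cfg, matrix)
        backends = [TemplateBackend(identity=f"t{i}", case_config=cfg,
                                    variants=variants) for i in range(3)]
        reports, summary = orchestrate(bundle, backends, quorum=3)
        assert summary.agreement_rate == 1.0
        for doc in reports:
            doc.check()
            for tab in cohort:
                assert tab.patient_id not in doc.to_markdown()


class TestFindingNormalization:
    def test_case_and_whitespace_collapse(self):
        assert normalize_finding("  X   is\tHIGH ") == "x is high"

    def test_numbers_rounded_to_two_significant_figures(self):
        assert normalize_finding("rate 0.3456") == normalize_finding("rate 0.3467")
        assert normalize_finding("n = 14940") == normalize_finding("n = 14900")
        assert normalize_finding("rate 0.34") != normalize_finding("rate 0.36")

    def test_extract_findings_reads_tables_and_hypotheses(self):
        backend = ScriptedBackend("A", ["alpha", "beta"])
        doc = backend.generate.__call__(None)  # bundle unused by the double
        found = extract_findings(doc)
        assert "alpha" in found and "beta" in found


def test_summarize_matrix_counts(matrix_and_variants):
    matrix, variants = matrix_and_variants
    stats = summarize_matrix(matrix, variants)
    assert stats["n_traces"] == 3
    assert stats["n_activities"] == 3
    assert stats["n_variants"] == len(variants.rows)
    json.dumps(stats)  # serializable
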