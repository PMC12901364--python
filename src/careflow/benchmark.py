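"""Published LLM-evaluation benchmark tables used as worked-example inputs.

Per-case mean scores (1–4 scale across four proof-of-concept cases:
infection, organ dysfunction, GFR, kidney outcomes) and per-report costs in
USD for the language models evaluated in the framework's technical
validation study. These are *inputs* to the evaluation arithmetic — overall
means, ranks and performance-to-cost ratios are always recomputed, never
stored.
"""

from __future__ import annotations

import numpy as np

from .evaluation import performance_cost_ratio, round_half_up

#: model -> per-case mean scores (case I..IV) on the 1-4 scale
PER_CASE_SCORES: dict[str, tuple[float, float, float, float]] = {
    "claude-sonnet-4": (3.56, 3.72, 3.73, 3.86),
    "gemini-2.5-pro": (3.53, 3.56, 3.70, 3.20),
    "qwen-2.5-72b": (3.26, 3.06, 3.61, 3.48),
    "grok-4": (3.07, 3.17, 3.16, 3.20),
    "gpt-4.1": (3.11, 3.03, 2.85, 3.65),
    "deepseek-r1": (3.01, 3.19, 2.74, 3.52),
    "llama-3.1-70b": (3.10, 3.17, 3.07, 2.75),
    "gemma-2-27b": (2.32, 2.54, 2.55, 2.76),
}

#: model -> overall mean as printed in the benchmark (for most models this
#: equals the rounded mean of the per-case scores; for a few the published
#: value was evidently computed before rounding and differs by ≤0.02)
PRINTED_OVERALL_MEANS: dict[str, float] = {
    "claude-sonnet-4": 3.72,
    "gemini-2.5-pro": 3.49,
    "qwen-2.5-72b": 3.35,
    "grok-4": 3.15,
    "gpt-4.1": 3.15,
    "deepseek-r1": 3.10,
    "llama-3.1-70b": 3.02,
    "gemma-2-27b": 2.54,
}

#: model -> cost per report in USD
COST_PER_REPORT: dict[str, float] = {
    "deepseek-r1": 0.02,
    "gemini-2.5-pro": 0.11,
    "claude-sonnet-4": 0.26,
    "grok-4": 0.61,
    "gpt-4.1": 1.13,
    "llama-3.1-70b": 0.001,
    "gemma-2-27b": 0.001,
    "qwen-2.5-72b": 0.001,
}

N_REPORTS = 20


def overall_mean(model: str) -> float:
    """Unweighted mean of the four per-case means, rounded half-up to 2 dp."""
    return round_half_up(float(np.mean(PER_CASE_SCORES[model])))


def cost_ratio(model: str) -> int:
    """Performance-to-cost ratio from the published mean and per-report cost."""
    return performance_cost_ratio(PRINTED_OVERALL_MEANS[model],
                                  COST_PER_REPORT[model])


def total_cost(model: str, n_reports: int = N_REPORTS) -> float:
    return round(COST_PER_REPORT[model] * n_reports, 2)
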