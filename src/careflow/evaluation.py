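"""Multi-rater evaluation: weighted rubric, Fleiss κ, Cronbach α, cost ratios.

Reports are scored by several raters on six weighted criteria using an
integer 1–4 scale. The layer computes weighted per-report scores, per-case
and overall means with ranks, chance-corrected inter-rater agreement
(Fleiss κ, an extension of Cohen's κ to ≥2 raters), internal-consistency
reliability across cases (Cronbach α) and performance-to-cost ratios.

κ = (p₀ − pₑ)/(1 − pₑ) with p₀ the observed agreement proportion and pₑ the
agreement expected by chance; α = (k/(k−1))·(1 − Σσᵢ²/σₜ²) over k items with
sample variances. Raters whose scores never vary carry no agreement
information and can be excluded (and are logged when they are).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, SpecificationError

#: (criterion, weight) in rubric order; weights sum to 1.
DEFAULT_CRITERIA = [
    ("Clinical accuracy", 0.25),
    ("Process mining understanding", 0.20),
    ("Actionable insights", 0.20),
    ("Statistical interpretation", 0.15),
    ("Report structure & clarity", 0.10),
    ("Evidence-based reasoning", 0.10),
]


@dataclass
class Rubric:
    criteria: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_CRITERIA))
    scale_min: int = 1
    scale_max: int = 4

    def __post_init__(self) -> None:
        weights = [w for _, w in self.criteria]
        if any(w <= 0 for w in weights):
            raise ConfigurationError("rubric weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("rubric weights must sum to 1")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.criteria]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.criteria])


def round_half_up(value: float, digits: int = 2) -> float:
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def weighted_score(scores, rubric: Rubric | None = None) -> float:
    """Σ weightᵢ·scoreᵢ over the rubric's criteria, in rubric order."""
    rubric = rubric or Rubric()
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(rubric.criteria):
        raise ConfigurationError(
            f"expected {len(rubric.criteria)} criterion scores, got {len(scores)}")
    if (scores < rubric.scale_min).any() or (scores > rubric.scale_max).any():
        raise SpecificationError("scores outside the rubric scale")
    return float(rubric.weights @ scores)


def fleiss_kappa(ratings, categories=(1, 2, 3, 4)) -> float:
    """Fleiss κ on an items × raters matrix of categorical scores.

    κ = (p₀ − pₑ)/(1 − pₑ); κ = 1 at perfect agreement. Missing cells are an
    error — no imputation.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateInputError("need ≥2 items and ≥2 raters")
    if np.isnan(table).any():
        raise DegenerateInputError("missing cell in ratings matrix")
    if not np.isin(table, np.asarray(categories, dtype=float)).all():
        raise SpecificationError(f"scores must lie in categories {categories}")
    n_items, n_raters = table.shape
    counts = np.stack([(table == c).sum(axis=1) for c in categories], axis=1)
    p_i = (np.square(counts).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p0 = p_i.mean()
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    pe = float(np.square(p_j).sum())
    if p0 == 1.0:
        return 1.0
    return float((p0 - pe) / (1.0 - pe))


def cronbach_alpha(item_scores) -> float:
    """Cronbach α = (k/(k−1))·(1 − Σσᵢ²/σₜ²) on a subjects × k-items array."""
    table = np.asarray(item_scores, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise DegenerateInputError("need at least 2 items")
    if np.isnan(table).any():
        raise DegenerateInputError("missing cell in item scores")
    k = table.shape[1]
    item_var = table.var(axis=0, ddof=1)
    total_var = table.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateInputError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def performance_cost_ratio(overall_mean: float, cost_per_report: float) -> int:
    """round(overall mean / per-report cost) to the nearest integer."""
    if cost_per_report <= 0:
        raise SpecificationError("cost per report must be positive")
    return int(math.floor(overall_mean / cost_per_report + 0.5))


@dataclass
class EvaluationResult:
    table: pd.DataFrame          # per-model per-case means, overall, rank, CI
    kappa: dict                  # per-criterion plus pooled κ
    alpha: float | None
    ratios: dict
    excluded_raters: list[str]

    def to_json(self) -> str:
        return json.dumps({
            "table": self.table.reset_index().to_dict(orient="records"),
            "kappa": self.kappa,
            "alpha": self.alpha,
            "ratios": self.ratios,
            "excluded_raters": self.excluded_raters,
        }, indent=2, default=str)

    def to_markdown(self) -> str:
        lines = ["| Model | " + " | ".join(self.table.columns) + " |",
                 "|" + "---|" * (len(self.table.columns) + 1)]
        for model, row in self.table.iterrows():
            lines.append("| " + str(model) + " | "
                         + " | ".join(str(v) for v in row) + " |")
        return "\n".join(lines)


def read_ratings_csv(path) -> pd.DataFrame:
    """Long-format ratings: report_id, model, case, rater, criterion, score."""
    df = pd.read_csv(path)
    required = {"model", "case", "rater", "criterion", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"ratings file lacks columns {sorted(missing)}")
    return df


def exclude_degenerate_raters(ratings: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop raters whose scores have zero variance across all reports."""
    excluded = [str(r) for r, g in ratings.groupby("rater")
                if g["score"].nunique() == 1]
    return ratings[~ratings["rater"].astype(str).isin(excluded)], excluded


def _bootstrap_ci(case_means: np.ndarray, seed: int = 0,
                  n_boot: int = 2000) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(case_means), size=(n_boot, len(case_means)))
    means = case_means[idx].mean(axis=1)
    return (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))


def summarize_evaluation(ratings: pd.DataFrame, rubric: Rubric | None = None,
                         costs: dict | None = None,
                         drop_degenerate_raters: bool = False,
                         ci_seed: int = 0) -> EvaluationResult:
    """Aggregate a complete model × case × rater × criterion ratings grid.

    Per-case means are weighted criterion scores averaged over raters; the
    overall mean is the unweighted mean of the per-case means, rounded
    half-up to 2 decimals; ranks order models by overall mean descending.
    κ is computed per criterion over pooled reports plus a pooled variant;
    α treats the cases as the k items with models as subjects.
    """
    rubric = rubric or Rubric()
    excluded: list[str] = []
    if drop_degenerate_raters:
        ratings, excluded = exclude_degenerate_raters(ratings)

    models = list(dict.fromkeys(ratings["model"]))
    cases = sorted(ratings["case"].unique())
    raters = sorted(ratings["rater"].unique())
    holes = []
    for model in models:
        for case in cases:
            for rater in raters:
                sub = ratings[(ratings["model"] == model)
                              & (ratings["case"] == case)
                              & (ratings["rater"] == rater)]
                have = set(sub["criterion"])
                if have != set(rubric.names):
                    holes.append((model, case, rater))
    if holes:
        raise ConfigurationError(f"incomplete ratings grid at {holes[:5]}"
                                 + ("…" if len(holes) > 5 else ""))

    per_case = pd.DataFrame(index=models, columns=cases, dtype=float)
    for model in models:
        for case in cases:
            scores = []
            for rater in raters:
                sub = ratings[(ratings["model"] == model)
                              & (ratings["case"] == case)
                              & (ratings["rater"] == rater)]
                ordered = sub.set_index("criterion").loc[rubric.names, "score"]
                scores.append(weighted_score(ordered.to_numpy(), rubric))
            per_case.at[model, case] = float(np.mean(scores))

    overall = per_case.mean(axis=1).map(round_half_up)
    rank = overall.rank(ascending=False, method="min").astype(int)
    cis = {m: _bootstrap_ci(per_case.loc[m].to_numpy(), seed=ci_seed)
           for m in models}

    table = per_case.copy()
    table["overall_mean"] = overall
    table["rank"] = rank
    table["ci_low"] = [round_half_up(cis[m][0]) for m in models]
    table["ci_high"] = [round_half_up(cis[m][1]) for m in models]

    # κ per criterion: items = model × case reports, raters as columns
    categories = tuple(range(rubric.scale_min, rubric.scale_max + 1))
    kappa: dict = {}
    for criterion in rubric.names:
        sub = ratings[ratings["criterion"] == criterion]
        matrix = sub.pivot_table(index=["model", "case"], columns="rater",
                                 values="score").to_numpy()
        kappa[criterion] = (fleiss_kappa(matrix, categories)
                            if matrix.shape[0] >= 2 and matrix.shape[1] >= 2
                            else None)
    pooled = ratings.pivot_table(index=["model", "case", "criterion"],
                                 columns="rater", values="score").to_numpy()
    kappa["pooled"] = (fleiss_kappa(pooled, categories)
                       if pooled.shape[0] >= 2 and pooled.shape[1] >= 2 else None)

    alpha = None
    if len(cases) >= 2 and len(models) >= 2:
        totals_var = per_case.to_numpy().sum(axis=1).var(ddof=1)
        if totals_var > 0:
            alpha = cronbach_alpha(per_case.to_numpy())

    ratios = {}
    if costs:
        for model in models:
            if model in costs:
                ratios[model] = performance_cost_ratio(float(overall[model]),
                                                       costs[model])
    return EvaluationResult(table=table, kappa=kappa, alpha=alpha,
                            ratios=ratios, excluded_raters=excluded)
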