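"""Two-stage Taguchi optimization driver.

Stage 1 screens all factors on a coarse orthogonal array, analyses the
per-run means and SN ratios, pools minor factors, predicts the response at
the recommended setting and validates it with confirmation runs.  Numeric
factors judged worth refining are then re-leveled around the stage-1
winner with half the coarse spacing, and stage 2 repeats the analysis on
the refined design.  Confirmation pass/fail is advisory: it is recorded in
the report but never aborts the procedure.

Every objective evaluation is seeded deterministically from the stage
seed, the run and the replicate index, so a whole two-stage campaign is
reproducible bit-for-bit from a single integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import (
    AdditivePrediction,
    AnovaTable,
    ConfidenceInterval,
    ResponseTable,
    anova,
    auto_pool,
    confidence_halfwidth,
    predict_additive,
    response_table,
    select_best_levels,
    significant_factors,
)
from .design import (
    ExperimentPlan,
    FactorSpec,
    default_assignment,
    get_array,
    make_plan,
    smallest_array_for,
)
from .objectives import Objective, ObjectiveError
from .quality import RunSummary, summarize_runs

__all__ = [
    "StageConfig",
    "RefinementRule",
    "RefinementError",
    "EvaluationRecord",
    "StageResult",
    "ConfirmationResult",
    "BudgetReport",
    "TSTOReport",
    "evaluation_seed",
    "run_stage",
    "refine_factors",
    "confirm",
    "run_tsto",
    "experiment_budget",
]


class RefinementError(ValueError):
    """Refined levels cannot be constructed (e.g. integer step rounds to 0)."""


@dataclass
class StageConfig:
    """Configuration of one Taguchi stage."""

    factors: Sequence[FactorSpec]
    array_id: str
    assignment: Mapping[str, int] | None = None
    replicates: int = 3
    sn_type: str = "ltb"
    sn_target: float | None = None
    screening_alpha: float = 0.1
    ci_alpha: float = 0.05
    retain_top_k: int = 2
    pooled_override: set[str] | None = None
    confirmation_r: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.confirmation_r < 1:
            raise ValueError("confirmation_r must be >= 1")

    def build_plan(self) -> ExperimentPlan:
        array = get_array(self.array_id)
        assignment = self.assignment or default_assignment(self.factors, array)
        return make_plan(self.factors, array, assignment)


@dataclass
class RefinementRule:
    """How stage-2 levels are derived from the stage-1 winner.

    Each refinable numeric factor is re-leveled to ``center +/- step`` with
    ``center`` the stage-1 best level and ``step = step_fraction x`` the
    stage-1 level spacing (integer factors: step rounded to the nearest
    positive integer).  Categorical factors are fixed at their best level,
    as are structural factors whose best level is the lowest offered.
    ``bounds`` optionally clips refined levels per factor (lo, hi); a clip
    is reported with a warning.
    """

    step_fraction: float = 0.5
    bounds: Mapping[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )


@dataclass(frozen=True)
class EvaluationRecord:
    """One logged objective evaluation."""

    stage: int
    run: int  # 0 marks confirmation runs
    replicate: int
    assignment: Mapping[str, Any]
    seed: int
    response: float


@dataclass
class StageResult:
    """Everything one stage produced."""

    config: StageConfig
    stage_index: int
    plan: ExperimentPlan
    results: dict[int, tuple[float, ...]]
    summary: RunSummary
    response_mean: ResponseTable
    response_sn: ResponseTable
    anova_mean: AnovaTable
    anova_sn: AnovaTable
    pooled: set[str]
    significant: set[str]
    best_levels: dict[str, Any]
    prediction_mean: AdditivePrediction
    prediction_sn: AdditivePrediction
    ci_mean: ConfidenceInterval
    ci_sn: ConfidenceInterval
    evaluations: list[EvaluationRecord]

    @property
    def retained(self) -> list[str]:
        return [n for n in self.plan.factor_names if n not in self.pooled]


@dataclass
class ConfirmationResult:
    """Confirmation runs at a recommended setting, judged against the
    predicted mean/SN confidence intervals."""

    setting: dict[str, Any]
    values: tuple[float, ...]
    mean: float
    sd: float
    sn: float
    ci_mean: ConfidenceInterval
    ci_sn: ConfidenceInterval
    evaluations: list[EvaluationRecord]

    @property
    def mean_within(self) -> bool:
        return self.ci_mean.contains(self.mean)

    @property
    def sn_within(self) -> bool:
        return self.ci_sn.contains(self.sn)

    @property
    def passed(self) -> bool:
        return self.mean_within and self.sn_within


def evaluation_seed(base_seed: int, stage: int, run: int, replicate: int) -> int:
    """Deterministic per-evaluation seed below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), stage, run, replicate])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_stage(
    config: StageConfig, objective: Objective, stage_index: int = 1
) -> StageResult:
    """Execute one full stage: evaluate the design, then analyse it."""
    plan = config.build_plan()
    results: dict[int, tuple[float, ...]] = {}
    evaluations: list[EvaluationRecord] = []
    for run in plan.runs:
        setting = plan.setting(run)
        vals = []
        for rep in range(config.replicates):
            seed = evaluation_seed(config.seed, stage_index, run, rep)
            try:
                resp = float(objective(setting, rep, seed))
            except ObjectiveError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate run context
                raise ObjectiveError(
                    f"objective failed on run {run} replicate {rep}: {exc}"
                ) from exc
            vals.append(resp)
            evaluations.append(
                EvaluationRecord(stage_index, run, rep, setting, seed, resp)
            )
        results[run] = tuple(vals)
    summary = summarize_runs(plan, results, config.sn_type, config.sn_target)
    rt_mean = response_table(plan, summary.per_run_mean, kind="mean")
    rt_sn = response_table(plan, summary.per_run_sn, kind="sn")
    if config.pooled_override is not None:
        pooled = set(config.pooled_override)
    else:
        pooled = auto_pool(plan, summary.per_run_mean, config.retain_top_k)
    an_mean = anova(plan, summary.per_run_mean, pooled)
    an_sn = anova(plan, summary.per_run_sn, pooled)
    significant = significant_factors(an_mean, config.screening_alpha)
    best = select_best_levels(rt_mean, rt_sn)
    retained = [n for n in plan.factor_names if n not in pooled]
    chosen = {n: best[n] for n in retained}
    pred_mean = predict_additive(rt_mean, chosen)
    pred_sn = predict_additive(rt_sn, chosen)
    ci_mean = confidence_halfwidth(
        an_mean,
        plan.n_runs,
        retained,
        config.confirmation_r,
        config.ci_alpha,
        center=pred_mean.value,
    )
    ci_sn = confidence_halfwidth(
        an_sn,
        plan.n_runs,
        retained,
        config.confirmation_r,
        config.ci_alpha,
        center=pred_sn.value,
    )
    return StageResult(
        config=config,
        stage_index=stage_index,
        plan=plan,
        results=results,
        summary=summary,
        response_mean=rt_mean,
        response_sn=rt_sn,
        anova_mean=an_mean,
        anova_sn=an_sn,
        pooled=pooled,
        significant=significant,
        best_levels=best,
        prediction_mean=pred_mean,
        prediction_sn=pred_sn,
        ci_mean=ci_mean,
        ci_sn=ci_sn,
        evaluations=evaluations,
    )


def confirm(
    best: Mapping[str, Any],
    objective: Objective,
    r: int,
    ci_mean: ConfidenceInterval,
    ci_sn: ConfidenceInterval,
    seed: int = 0,
    stage_index: int = 1,
    sn_type: str = "ltb",
    sn_target: float | None = None,
) -> ConfirmationResult:
    """Run ``r`` confirmation evaluations at ``best`` and judge them
    against the predicted intervals."""
    from .quality import ReplicatedResponse

    if r < 1:
        raise ValueError("r must be >= 1")
    setting = dict(best)
    vals = []
    evaluations = []
    for rep in range(r):
        seed_i = evaluation_seed(seed, stage_index, 0, rep)
        try:
            resp = float(objective(setting, rep, seed_i))
        except Exception as exc:  # noqa: BLE001
            raise ObjectiveError(
                f"confirmation evaluation {rep} failed: {exc}"
            ) from exc
        vals.append(resp)
        evaluations.append(
            EvaluationRecord(stage_index, 0, rep, setting, seed_i, resp)
        )
    rr = ReplicatedResponse(0, tuple(vals))
    return ConfirmationResult(
        setting=setting,
        values=rr.values,
        mean=rr.mean,
        sd=rr.sd,
        sn=rr.sn(sn_type, sn_target),
        ci_mean=ci_mean,
        ci_sn=ci_sn,
        evaluations=evaluations,
    )


def refine_factors(
    stage1: StageResult, rule: RefinementRule | None = None
) -> tuple[list[FactorSpec], dict[str, Any]]:
    """Derive the stage-2 factor list and the fixed-factor record.

    Categorical factors are fixed at their stage-1 best level.  Structural
    factors whose best level is the lowest offered are fixed (shrinking
    them further would sacrifice capacity).  Every other numeric factor is
    re-leveled to 3 refined levels around its winner; extrapolation past
    the stage-1 range is allowed unless a bound clips it.
    """
    rule = rule or RefinementRule()
    refined: list[FactorSpec] = []
    fixed: dict[str, Any] = {}
    for f in stage1.plan.factors:
        best = stage1.best_levels[f.name]
        if not f.is_numeric:
            fixed[f.name] = best
            continue
        if f.structural and _eq_num(best, f.levels[0]):
            fixed[f.name] = best
            continue
        spacing = (float(f.levels[-1]) - float(f.levels[0])) / (f.n_levels - 1)
        step = spacing * rule.step_fraction
        if f.role == "numeric-integer":
            step = int(np.floor(step + 0.5))  # round half up, not to even
            if step < 1:
                raise RefinementError(
                    f"factor {f.name!r}: integer refinement step rounds to 0"
                )
        center = float(best)
        levels = [center - step, center, center + step]
        lo, hi = rule.bounds.get(f.name, (None, None))
        clipped = False
        if lo is not None and levels[0] < lo:
            levels[0] = float(lo)
            clipped = True
        if hi is not None and levels[-1] > hi:
            levels[-1] = float(hi)
            clipped = True
        if clipped:
            warnings.warn(
                f"factor {f.name!r}: refined levels clipped to bounds "
                f"({lo}, {hi}) -> {levels}",
                stacklevel=2,
            )
        if not (levels[0] < levels[1] < levels[2]):
            raise RefinementError(
                f"factor {f.name!r}: refined levels {levels} not strictly increasing"
            )
        if f.role == "numeric-integer":
            levels = [int(v) for v in levels]
        refined.append(FactorSpec(f.name, f.role, tuple(levels), f.structural))
    return refined, fixed


def _eq_num(a: Any, b: Any) -> bool:
    try:
        return np.isclose(float(a), float(b), rtol=0, atol=1e-12)
    except (TypeError, ValueError):
        return a == b


@dataclass
class BudgetReport:
    """Experiment-count arithmetic: orthogonal array vs full factorial."""

    full_factorial: int
    array_experiments: int
    reduction_factor: float


def experiment_budget(
    level_counts: Sequence[int], replicates: int, array_runs: int
) -> BudgetReport:
    """Full factorial = product(levels) x replicates; array = runs x
    replicates; reduction = their ratio."""
    full = int(np.prod([int(k) for k in level_counts])) * replicates
    arr = array_runs * replicates
    return BudgetReport(full, arr, full / arr)


@dataclass
class TSTOReport:
    """Complete two-stage campaign: both stages, both confirmations, the
    stage-2 fixed factors, and the comparison table."""

    stage1: StageResult
    confirmation1: ConfirmationResult
    stage2: StageResult
    confirmation2: ConfirmationResult
    fixed: dict[str, Any]
    comparison: pd.DataFrame
    budget1: BudgetReport
    budget2: BudgetReport

    @property
    def evaluations(self) -> list[EvaluationRecord]:
        return (
            self.stage1.evaluations
            + self.confirmation1.evaluations
            + self.stage2.evaluations
            + self.confirmation2.evaluations
        )

    @property
    def best_setting(self) -> dict[str, Any]:
        setting = dict(self.fixed)
        setting.update(self.stage2.best_levels)
        return setting


def _comparison_table(
    stage1: StageResult,
    conf1: ConfirmationResult,
    stage2: StageResult,
    conf2: ConfirmationResult,
    fixed: Mapping[str, Any],
) -> pd.DataFrame:
    """Comparison table: each stage's recommended setting and confirmed
    mean/SD/SN, plus an improvement row of raw stage-2 minus stage-1
    differences (for SD a negative improvement means less scatter)."""
    factor_names = stage1.plan.factor_names
    row1: dict[str, Any] = {"stage": stage1.plan.array.identifier}
    row1.update({n: stage1.best_levels[n] for n in factor_names})
    row1.update(mean=conf1.mean, sd=conf1.sd, sn=conf1.sn)
    row2: dict[str, Any] = {"stage": stage2.plan.array.identifier}
    for n in factor_names:
        row2[n] = stage2.best_levels.get(n, fixed.get(n))
    row2.update(mean=conf2.mean, sd=conf2.sd, sn=conf2.sn)
    imp: dict[str, Any] = {"stage": "improvement"}
    imp.update({n: None for n in factor_names})
    imp.update(
        mean=conf2.mean - conf1.mean,
        sd=conf2.sd - conf1.sd,
        sn=conf2.sn - conf1.sn,
    )
    return pd.DataFrame([row1, row2, imp])


def run_tsto(
    config1: StageConfig,
    rule: RefinementRule | None = None,
    objective: Objective | None = None,
    stage2_array_id: str | None = None,
) -> TSTOReport:
    """Run the full two-stage procedure.

    Stage 2 uses L9(3^4) when exactly three 3-level factors advance (the
    canonical case); otherwise the smallest catalog array that fits is
    selected, with a warning.
    """
    if objective is None:
        raise ValueError("an objective is required")
    stage1 = run_stage(config1, objective, stage_index=1)
    conf1 = confirm(
        stage1.best_levels,
        objective,
        config1.confirmation_r,
        stage1.ci_mean,
        stage1.ci_sn,
        seed=config1.seed,
        stage_index=1,
        sn_type=config1.sn_type,
        sn_target=config1.sn_target,
    )
    refined, fixed = refine_factors(stage1, rule)
    if not refined:
        raise RefinementError("no numeric factors left to refine for stage 2")
    if stage2_array_id is not None:
        array2 = get_array(stage2_array_id)
    elif len(refined) == 3 and all(f.n_levels == 3 for f in refined):
        array2 = get_array("L9(3^4)")
    else:
        array2 = smallest_array_for(refined)
        warnings.warn(
            f"non-canonical refined factor set ({len(refined)} factors); "
            f"selected {array2.identifier}",
            stacklevel=2,
        )
    config2 = StageConfig(
        factors=refined,
        array_id=array2.identifier,
        assignment=default_assignment(refined, array2),
        replicates=config1.replicates,
        sn_type=config1.sn_type,
        sn_target=config1.sn_target,
        screening_alpha=config1.screening_alpha,
        ci_alpha=config1.ci_alpha,
        retain_top_k=config1.retain_top_k,
        confirmation_r=config1.confirmation_r,
        seed=config1.seed,
    )

    def fixed_objective(assignment, replicate, seed):
        full = dict(fixed)
        full.update(assignment)
        return objective(full, replicate, seed)

    stage2 = run_stage(config2, fixed_objective, stage_index=2)
    best2 = dict(fixed)
    best2.update(stage2.best_levels)
    conf2 = confirm(
        best2,
        objective,
        config2.confirmation_r,
        stage2.ci_mean,
        stage2.ci_sn,
        seed=config2.seed,
        stage_index=2,
        sn_type=config2.sn_type,
        sn_target=config2.sn_target,
    )
    comparison = _comparison_table(stage1, conf1, stage2, conf2, fixed)
    budget1 = experiment_budget(
        [f.n_levels for f in config1.factors],
        config1.replicates,
        stage1.plan.n_runs,
    )
    budget2 = experiment_budget(
        [f.n_levels for f in refined], config2.replicates, stage2.plan.n_runs
    )
    return TSTOReport(
        stage1=stage1,
        confirmation1=conf1,
        stage2=stage2,
        confirmation2=conf2,
        fixed=fixed,
        comparison=comparison,
        budget1=budget1,
        budget2=budget2,
    )
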