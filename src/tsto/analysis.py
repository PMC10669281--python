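"""Main-effects analysis: response tables, pooled ANOVA, additive
prediction and confirmation confidence intervals.

All analysis operates on one summary response per run (the per-run mean or
the per-run SN ratio), not on raw replicates; total degrees of freedom are
therefore ``runs - 1``.  The main effect of a factor is the spread of its
level means (max minus min); factors are ranked by effect.  Minor factors
are pooled into the ANOVA error term to obtain a usable error variance, and
the additive model predicts the response at a chosen setting as the grand
mean plus the selected factors' level-mean deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentPlan

__all__ = [
    "ResponseTable",
    "AnovaRow",
    "AnovaTable",
    "AdditivePrediction",
    "ConfidenceInterval",
    "PoolingError",
    "DegenerateVarianceError",
    "response_table",
    "anova",
    "auto_pool",
    "f_quantile",
    "f_pvalue",
    "significant_factors",
    "predict_additive",
    "confidence_halfwidth",
    "select_best_levels",
]


class PoolingError(ValueError):
    """Pooling choice leaves no error degrees of freedom."""


class DegenerateVarianceError(ValueError):
    """All responses identical: no variance to decompose."""


@dataclass
class ResponseTable:
    """Per-factor level means, effects and ranks for one response kind.

    ``kind`` is ``"mean"`` or ``"sn"``.  ``level_means[name]`` lists the
    means in level order (index 0 = level 1).  ``effect`` is max - min of a
    factor's level means; rank 1 marks the largest effect, ties broken by
    factor declaration order.
    """

    kind: str
    grand_mean: float
    factors: tuple[str, ...]
    levels: dict[str, tuple[Any, ...]]
    level_means: dict[str, tuple[float, ...]]
    effect: dict[str, float] = field(init=False)
    rank: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.effect = {
            f: float(max(m) - min(m)) for f, m in self.level_means.items()
        }
        order = sorted(
            self.factors, key=lambda f: (-self.effect[f], self.factors.index(f))
        )
        self.rank = {f: i + 1 for i, f in enumerate(order)}

    def level_mean(self, factor: str, level_value: Any) -> float:
        levels = self.levels[factor]
        for i, lv in enumerate(levels):
            if _eq(lv, level_value):
                return self.level_means[factor][i]
        raise KeyError(f"factor {factor!r} has no level {level_value!r} in {levels}")

    def best_level(self, factor: str) -> Any:
        means = self.level_means[factor]
        return self.levels[factor][int(np.argmax(means))]

    def to_frame(self) -> pd.DataFrame:
        n_levels = max(len(v) for v in self.level_means.values())
        data: dict[str, list] = {}
        for f in self.factors:
            col = list(self.level_means[f]) + [np.nan] * (
                n_levels - len(self.level_means[f])
            )
            col += [self.effect[f], self.rank[f]]
            data[f] = col
        idx = [f"level_{i + 1}" for i in range(n_levels)] + ["effect", "rank"]
        return pd.DataFrame(data, index=idx)


def _eq(a: Any, b: Any) -> bool:
    try:
        return bool(np.isclose(float(a), float(b), rtol=0, atol=1e-12))
    except (TypeError, ValueError):
        return a == b


def _responses(plan: ExperimentPlan, per_run: Mapping[int, float]) -> np.ndarray:
    missing = [r for r in plan.runs if r not in per_run]
    if missing:
        raise ValueError(f"missing response for runs {missing}")
    return np.array([float(per_run[r]) for r in plan.runs])


def response_table(
    plan: ExperimentPlan, per_run_response: Mapping[int, float], kind: str = "mean"
) -> ResponseTable:
    """Level means, effects and ranks for every factor of the plan."""
    y = _responses(plan, per_run_response)
    level_means: dict[str, tuple[float, ...]] = {}
    levels: dict[str, tuple[Any, ...]] = {}
    for f in plan.factors:
        means = []
        for li in range(1, f.n_levels + 1):
            runs = plan.runs_at_level(f.name, li)
            if not runs:
                raise ValueError(
                    f"factor {f.name!r} level {li} has no runs in the design"
                )
            means.append(float(np.mean([y[r - 1] for r in runs])))
        level_means[f.name] = tuple(means)
        levels[f.name] = f.levels
    return ResponseTable(
        kind=kind,
        grand_mean=float(y.mean()),
        factors=tuple(plan.factor_names),
        levels=levels,
        level_means=level_means,
    )


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None = None
    f: float | None = None
    p: float | None = None
    pooled: bool = False


@dataclass
class AnovaTable:
    """Pooled one-response-per-run ANOVA.

    The error term absorbs the pooled factors' sums of squares together
    with the residual from unassigned array columns, so
    ``sum(unpooled SS) + error SS == total SS`` holds exactly.
    """

    rows: list[AnovaRow]
    error_df: int
    error_ss: float
    total_df: int
    total_ss: float
    r_squared: float
    r_squared_adj: float

    @property
    def error_ms(self) -> float:
        return self.error_ss / self.error_df

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def unpooled(self) -> list[AnovaRow]:
        return [r for r in self.rows if not r.pooled]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "source": r.source + (" *" if r.pooled else ""),
                "df": r.df,
                "ss": r.ss,
                "ms": r.ms,
                "F": r.f,
                "p": r.p,
            }
            for r in self.rows
        ]
        recs.append(
            {
                "source": "error",
                "df": self.error_df,
                "ss": self.error_ss,
                "ms": self.error_ms,
                "F": None,
                "p": None,
            }
        )
        recs.append(
            {
                "source": "total",
                "df": self.total_df,
                "ss": self.total_ss,
                "ms": None,
                "F": None,
                "p": None,
            }
        )
        return pd.DataFrame.from_records(recs)


def anova(
    plan: ExperimentPlan,
    per_run_response: Mapping[int, float],
    pooled: set[str] | frozenset[str] = frozenset(),
) -> AnovaTable:
    """Main-effects ANOVA with the given factors pooled into error.

    Factor SS is ``(runs per level) * sum((level mean - grand mean)^2)``;
    the error SS is the total SS minus the unpooled factors' SS, absorbing
    both pooled-factor SS and residual from unused columns.
    """
    pooled = set(pooled)
    unknown = pooled - set(plan.factor_names)
    if unknown:
        raise ValueError(f"pooled names not in plan: {sorted(unknown)}")
    if not (set(plan.factor_names) - pooled):
        raise PoolingError("at least one factor must remain unpooled")
    y = _responses(plan, per_run_response)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    if sst == 0.0:
        raise DegenerateVarianceError("all responses are identical")
    total_df = plan.n_runs - 1
    rows: list[AnovaRow] = []
    ss_unpooled = 0.0
    df_unpooled = 0
    for f in plan.factors:
        per_level = plan.n_runs // f.n_levels
        lm = np.array(
            [
                np.mean([y[r - 1] for r in plan.runs_at_level(f.name, li)])
                for li in range(1, f.n_levels + 1)
            ]
        )
        ss = float(per_level * ((lm - grand) ** 2).sum())
        df = f.n_levels - 1
        rows.append(AnovaRow(f.name, df, ss, pooled=f.name in pooled))
        if f.name not in pooled:
            ss_unpooled += ss
            df_unpooled += df
    error_df = total_df - df_unpooled
    if error_df < 1:
        raise PoolingError(
            f"error degrees of freedom {error_df} < 1; pool more factors"
        )
    error_ss = sst - ss_unpooled
    ms_error = error_ss / error_df
    for r in rows:
        if not r.pooled:
            r.ms = r.ss / r.df
            if ms_error > 0:
                r.f = r.ms / ms_error
                r.p = f_pvalue(r.f, r.df, error_df)
            else:
                # perfect fit (zero residual): infinitely significant
                r.f = float("inf") if r.ms > 0 else float("nan")
                r.p = 0.0 if r.ms > 0 else float("nan")
    r2 = ss_unpooled / sst
    r2_adj = 1.0 - (error_ss / error_df) / (sst / total_df)
    return AnovaTable(
        rows=rows,
        error_df=error_df,
        error_ss=error_ss,
        total_df=total_df,
        total_ss=sst,
        r_squared=r2,
        r_squared_adj=r2_adj,
    )


def auto_pool(
    plan: ExperimentPlan,
    per_run_response: Mapping[int, float],
    retain_top_k: int = 2,
) -> set[str]:
    """Pool all but the ``retain_top_k`` largest-SS factors into error."""
    full = anova(plan, per_run_response, pooled=frozenset())
    by_ss = sorted(full.rows, key=lambda r: -r.ss)
    retained = {r.source for r in by_ss[:retain_top_k]}
    return set(plan.factor_names) - retained


def f_quantile(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail F quantile: P(F >= q) = alpha."""
    _check_f_args(alpha, df1, df2)
    return float(stats.f.isf(alpha, df1, df2))


def f_pvalue(f_value: float, df1: int, df2: int) -> float:
    """Upper-tail F probability: P(F >= f_value)."""
    _check_f_args(0.5, df1, df2)
    return float(stats.f.sf(f_value, df1, df2))


def _check_f_args(alpha: float, df1: int, df2: int) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1},{df2})")


def significant_factors(table: AnovaTable, alpha: float = 0.1) -> set[str]:
    """Unpooled factors whose (unrounded) p-value is below ``alpha``."""
    return {r.source for r in table.unpooled if r.p is not None and r.p < alpha}


@dataclass
class AdditivePrediction:
    """Additive-model prediction: grand mean plus selected level-mean
    deviations.  With no contributing factors the prediction is the grand
    mean itself."""

    grand_mean: float
    contributions: dict[str, tuple[Any, float]]  # factor -> (level, level mean)

    @property
    def value(self) -> float:
        return self.grand_mean + sum(
            lm - self.grand_mean for _, lm in self.contributions.values()
        )


def predict_additive(
    rt: ResponseTable, chosen: Mapping[str, Any]
) -> AdditivePrediction:
    """Predict the response at ``chosen`` (factor -> level value) using only
    those factors' main effects."""
    contributions = {}
    for name, level in chosen.items():
        if name not in rt.level_means:
            raise KeyError(f"factor {name!r} not in response table")
        contributions[name] = (level, rt.level_mean(name, level))
    return AdditivePrediction(rt.grand_mean, contributions)


@dataclass
class ConfidenceInterval:
    """Confirmation-experiment CI for a predicted response.

    ``half_width = sqrt(F(alpha; 1, nu2) * Ve * (1/n_eff + 1/r))`` where
    ``Ve`` is the pooled error variance with ``nu2`` degrees of freedom,
    ``n_eff = total runs / (1 + sum DF of prediction factors)`` and ``r``
    is the confirmation replicate count.
    """

    alpha: float
    f_critical: float
    error_variance: float
    error_df: int
    n_eff: float
    r: int
    half_width: float
    center: float | None = None

    @property
    def interval(self) -> tuple[float, float]:
        if self.center is None:
            raise ValueError("no center (predicted value) attached")
        return (self.center - self.half_width, self.center + self.half_width)

    def contains(self, observed: float) -> bool:
        lo, hi = self.interval
        return lo <= observed <= hi


def confidence_halfwidth(
    table: AnovaTable,
    total_runs: int,
    prediction_factors: Sequence[str],
    r: int,
    alpha: float = 0.05,
    center: float | None = None,
) -> ConfidenceInterval:
    """CI half-width for a prediction built from ``prediction_factors``."""
    if r < 1:
        raise ValueError(f"confirmation count r must be >= 1, got {r}")
    ve = table.error_ms
    if ve < 0:
        raise DegenerateVarianceError(f"pooled error variance {ve} < 0")
    df_sum = sum(table.row(f).df for f in prediction_factors)
    n_eff = total_runs / (1 + df_sum)
    fcrit = f_quantile(alpha, 1, table.error_df)
    half = float(np.sqrt(fcrit * ve * (1.0 / n_eff + 1.0 / r)))
    return ConfidenceInterval(
        alpha=alpha,
        f_critical=fcrit,
        error_variance=ve,
        error_df=table.error_df,
        n_eff=n_eff,
        r=r,
        half_width=half,
        center=center,
    )


def select_best_levels(
    rt_mean: ResponseTable, rt_sn: ResponseTable
) -> dict[str, Any]:
    """Best level per factor: maximize the mean-response level mean; break
    exact ties by the higher SN level mean, then by the lower level index."""
    best: dict[str, Any] = {}
    for f in rt_mean.factors:
        means = rt_mean.level_means[f]
        sns = rt_sn.level_means[f]
        order = sorted(
            range(len(means)), key=lambda i: (-means[i], -sns[i], i)
        )
        best[f] = rt_mean.levels[f][order[0]]
    return best
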