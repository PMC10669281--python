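"""Replicate summarization and Taguchi signal-to-noise ratios.

The SN ratio condenses the replicate responses of one run into a single
decibel-scale quality statistic.  Three orientations exist:

* nominal-the-better (NTB): ``-10 log10( sum((y_i - m)^2) / n )`` — penalizes
  deviation from a target ``m``;
* smaller-the-better (STB): ``-10 log10( sum(y_i^2) / n )`` — zero is ideal;
* larger-the-better (LTB):  ``-10 log10( sum(1/y_i^2) / n )`` — rewards large
  positive responses (the orientation used for classifier accuracy).

Higher SN always means better and more stable quality.  Logarithms are base
10 per the decibel convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ExperimentPlan

__all__ = [
    "SNDomainError",
    "sn_larger_the_better",
    "sn_smaller_the_better",
    "sn_nominal_the_better",
    "sn_ratio",
    "ReplicatedResponse",
    "RunSummary",
    "summarize_runs",
]

SN_TYPES = ("ltb", "stb", "ntb")


class SNDomainError(ValueError):
    """Input outside the domain of the requested SN ratio."""


def _as_array(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise SNDomainError(f"{what}: empty replicate list")
    return arr


def sn_larger_the_better(values: Sequence[float]) -> float:
    """LTB SN ratio in dB; all replicates must be strictly positive."""
    arr = _as_array(values, "larger-the-better SN")
    if np.any(arr <= 0):
        raise SNDomainError(
            "larger-the-better SN requires strictly positive responses"
        )
    return float(-10.0 * np.log10(np.mean(1.0 / arr**2)))


def sn_smaller_the_better(values: Sequence[float]) -> float:
    """STB SN ratio in dB; all-zero input is ideal and returns +inf."""
    arr = _as_array(values, "smaller-the-better SN")
    msq = float(np.mean(arr**2))
    if msq == 0.0:
        return math.inf
    return float(-10.0 * np.log10(msq))


def sn_nominal_the_better(values: Sequence[float], target: float) -> float:
    """NTB SN ratio in dB; replicates exactly on target return +inf."""
    arr = _as_array(values, "nominal-the-better SN")
    msd = float(np.mean((arr - target) ** 2))
    if msd == 0.0:
        return math.inf
    return float(-10.0 * np.log10(msd))


def sn_ratio(
    values: Sequence[float], sn_type: str, target: float | None = None
) -> float:
    """Dispatch on SN orientation (``ltb`` | ``stb`` | ``ntb``)."""
    if sn_type == "ltb":
        return sn_larger_the_better(values)
    if sn_type == "stb":
        return sn_smaller_the_better(values)
    if sn_type == "ntb":
        if target is None:
            raise SNDomainError("nominal-the-better SN requires a target")
        return sn_nominal_the_better(values, target)
    raise SNDomainError(f"unknown SN type {sn_type!r}; expected one of {SN_TYPES}")


@dataclass(frozen=True)
class ReplicatedResponse:
    """Replicate responses of one experiment run."""

    run: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError(f"run {self.run}: at least one replicate required")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample standard deviation (denominator n-1); 0 for one replicate."""
        if self.n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))

    def sn(self, sn_type: str = "ltb", target: float | None = None) -> float:
        return sn_ratio(self.values, sn_type, target)


@dataclass
class RunSummary:
    """Per-run summary of a whole design plus grand means.

    ``table`` carries one row per run: realized factor values, replicates,
    mean, sample SD and SN.  The grand SD is the mean of the per-run sample
    SDs (the replicate-noise level averaged over the design), not a pooled
    SD.
    """

    table: pd.DataFrame
    sn_type: str
    grand_mean: float
    grand_sd: float
    grand_sn: float

    @property
    def per_run_mean(self) -> dict[int, float]:
        return self.table["mean"].to_dict()

    @property
    def per_run_sn(self) -> dict[int, float]:
        return self.table["sn"].to_dict()


def summarize_runs(
    plan: ExperimentPlan,
    results: Mapping[int, Sequence[float]],
    sn_type: str = "ltb",
    target: float | None = None,
) -> RunSummary:
    """Summarize replicated results over a plan.

    Every plan run must have a result row and replicate counts must agree
    across runs (the design is balanced).
    """
    missing = [r for r in plan.runs if r not in results]
    if missing:
        raise ValueError(f"missing results for runs {missing}")
    counts = {len(results[r]) for r in plan.runs}
    if len(counts) != 1:
        raise ValueError(f"unequal replicate counts across runs: {sorted(counts)}")
    design = plan.realized_design()
    reps = sorted(counts)[0]
    rows = []
    for r in plan.runs:
        rr = ReplicatedResponse(r, tuple(results[r]))
        row = dict(design.loc[r])
        row.update({f"rep_{i + 1}": rr.values[i] for i in range(reps)})
        row.update(mean=rr.mean, sd=rr.sd, sn=rr.sn(sn_type, target))
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, plan.n_runs + 1, name="run"))
    return RunSummary(
        table=table,
        sn_type=sn_type,
        grand_mean=float(table["mean"].mean()),
        grand_sd=float(table["sd"].mean()),
        grand_sn=float(table["sn"].mean()),
    )
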