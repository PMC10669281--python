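"""Orthogonal-array experiment design.

A Taguchi orthogonal array ``L_a(b^c)`` is a fractional-factorial design
with ``a`` runs and ``c`` columns, each column taking ``b`` levels, balanced
so that every pair of columns contains each ordered level combination
equally often (strength-2 orthogonality).  Assigning factors to columns
yields an experiment plan whose main effects are estimable from far fewer
runs than a full factorial.

The catalog stores each array as a literal 1-based integer matrix; arrays
are not generated algorithmically.  The L18 entry is the canonical variant
whose columns reproduce, under the usual factor-to-column assignment, the
published mixed-level designs this package is validated against.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "OrthogonalArray",
    "ExperimentPlan",
    "OrthogonalityReport",
    "CatalogError",
    "AssignmentError",
    "get_array",
    "list_arrays",
    "verify_orthogonality",
    "make_plan",
    "smallest_array_for",
]

ROLES = ("categorical", "numeric-continuous", "numeric-integer")


class CatalogError(KeyError):
    """Unknown orthogonal-array identifier."""


class AssignmentError(ValueError):
    """Invalid factor-to-column assignment."""


@dataclass(frozen=True)
class FactorSpec:
    """A tunable factor: its name, role and ordered levels.

    ``structural`` marks factors (e.g. network depth) that are fixed rather
    than refined when their best level sits at the low boundary.
    """

    name: str
    role: str
    levels: tuple
    structural: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if not 2 <= len(self.levels) <= 3:
            raise ValueError(
                f"factor {self.name!r} needs 2 or 3 levels, got {len(self.levels)}"
            )
        if self.role.startswith("numeric"):
            vals = [float(v) for v in self.levels]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"numeric factor {self.name!r} levels must be strictly increasing"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def is_numeric(self) -> bool:
        return self.role.startswith("numeric")


@dataclass(frozen=True)
class OrthogonalArray:
    """An ``L_a(b^c)`` array: 1-based level indices, one row per run."""

    identifier: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("matrix must be a non-empty 2-D integer array")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_levels(self, column: int) -> int:
        """Number of levels carried by 1-based ``column``."""
        return int(self.matrix[:, column - 1].max())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix,
            index=pd.RangeIndex(1, self.n_runs + 1, name="run"),
            columns=[f"col_{j}" for j in range(1, self.n_columns + 1)],
        )
        return df


def _mat(rows: Sequence[Sequence[int]]) -> np.ndarray:
    return np.array(rows, dtype=int)


# Literal catalog.  L18 is the mixed 2x3 array whose columns 2-7 carry six
# 3-level factors; column 1 is the 2-level column and column 8 the spare
# 3-level column (both usually left unassigned and absorbed into error).
_CATALOG: dict[str, OrthogonalArray] = {}


def _register(identifier: str, rows: Sequence[Sequence[int]]) -> None:
    _CATALOG[identifier] = OrthogonalArray(identifier, _mat(rows))


_register(
    "L4(2^3)",
    [
        [1, 1, 1],
        [1, 2, 2],
        [2, 1, 2],
        [2, 2, 1],
    ],
)

_register(
    "L8(2^7)",
    [
        [1, 1, 1, 1, 1, 1, 1],
        [1, 1, 1, 2, 2, 2, 2],
        [1, 2, 2, 1, 1, 2, 2],
        [1, 2, 2, 2, 2, 1, 1],
        [2, 1, 2, 1, 2, 1, 2],
        [2, 1, 2, 2, 1, 2, 1],
        [2, 2, 1, 1, 2, 2, 1],
        [2, 2, 1, 2, 1, 1, 2],
    ],
)

_register(
    "L9(3^4)",
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
)

_register(
    "L18(2^1x3^7)",
    [
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 2, 2, 2, 2, 2, 2],
        [1, 1, 3, 3, 3, 3, 3, 3],
        [1, 2, 1, 1, 2, 2, 3, 3],
        [1, 2, 2, 2, 3, 3, 1, 1],
        [1, 2, 3, 3, 1, 1, 2, 2],
        [1, 3, 1, 2, 1, 3, 2, 3],
        [1, 3, 2, 3, 2, 1, 3, 1],
        [1, 3, 3, 1, 3, 2, 1, 2],
        [2, 1, 1, 3, 3, 2, 2, 1],
        [2, 1, 2, 1, 1, 3, 3, 2],
        [2, 1, 3, 2, 2, 1, 1, 3],
        [2, 2, 1, 2, 3, 1, 3, 2],
        [2, 2, 2, 3, 1, 2, 1, 3],
        [2, 2, 3, 1, 2, 3, 2, 1],
        [2, 3, 1, 3, 2, 3, 1, 2],
        [2, 3, 2, 1, 3, 1, 2, 3],
        [2, 3, 3, 2, 1, 2, 3, 1],
    ],
)


def _normalize_id(identifier: str) -> str:
    return re.sub(r"[^a-z0-9]", "", identifier.lower())


_LOOKUP = {_normalize_id(k): k for k in _CATALOG}
# common aliases: bare run counts
_LOOKUP.update(
    {"l4": "L4(2^3)", "l8": "L8(2^7)", "l9": "L9(3^4)", "l18": "L18(2^1x3^7)"}
)


def list_arrays() -> list[str]:
    """Canonical identifiers of all catalog arrays."""
    return sorted(_CATALOG, key=lambda k: _CATALOG[k].n_runs)


def get_array(identifier: str) -> OrthogonalArray:
    """Fetch a catalog array by identifier.

    Identifiers are matched loosely: ``L9(3^4)``, ``L9_3_4`` and ``L9`` all
    resolve to the same entry.
    """
    key = _LOOKUP.get(_normalize_id(identifier))
    if key is None:
        raise CatalogError(
            f"unknown orthogonal array {identifier!r}; available: {list_arrays()}"
        )
    return _CATALOG[key]


@dataclass
class OrthogonalityReport:
    """Balance diagnostics for an array: per-column level counts, per-pair
    ordered-combination counts, and any violations found."""

    column_counts: dict[int, dict[int, int]]
    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]]
    violations: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations


def verify_orthogonality(array: OrthogonalArray) -> OrthogonalityReport:
    """Check single-column balance and pairwise (strength-2) balance.

    Every level index must appear equally often within each column, and for
    any two columns every ordered pair of level indices must appear equally
    often.  Returns a report rather than raising: callers decide severity.
    """
    m = array.matrix
    a, c = m.shape
    column_counts: dict[int, dict[int, int]] = {}
    violations: list[str] = []
    for j in range(c):
        col = m[:, j]
        b = int(col.max())
        counts = Counter(int(v) for v in col)
        column_counts[j + 1] = dict(sorted(counts.items()))
        expected = {lvl: a // b for lvl in range(1, b + 1)}
        if a % b != 0 or dict(counts) != expected:
            violations.append(
                f"column {j + 1}: level counts {dict(counts)} != {expected}"
            )
    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]] = {}
    for i in range(c):
        bi = int(m[:, i].max())
        for j in range(i + 1, c):
            bj = int(m[:, j].max())
            counts = Counter(zip(m[:, i].tolist(), m[:, j].tolist()))
            pair_counts[(i + 1, j + 1)] = dict(sorted(counts.items()))
            expected_n = a / (bi * bj)
            cells = {
                (u, v) for u in range(1, bi + 1) for v in range(1, bj + 1)
            }
            if set(counts) != cells or any(
                n != expected_n for n in counts.values()
            ):
                violations.append(
                    f"columns ({i + 1},{j + 1}): pair counts unbalanced "
                    f"(expected each of {len(cells)} pairs {expected_n} times)"
                )
    return OrthogonalityReport(column_counts, pair_counts, violations)


@dataclass(frozen=True)
class ExperimentPlan:
    """Factors mapped onto array columns, with the realized run settings."""

    array: OrthogonalArray
    factors: tuple[FactorSpec, ...]
    assignment: Mapping[str, int]  # factor name -> 1-based column

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def n_runs(self) -> int:
        return self.array.n_runs

    @property
    def runs(self) -> range:
        return range(1, self.n_runs + 1)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def unused_columns(self) -> list[int]:
        used = set(self.assignment.values())
        return [j for j in range(1, self.array.n_columns + 1) if j not in used]

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def level_index(self, run: int, name: str) -> int:
        """1-based level index of factor ``name`` in ``run``."""
        col = self.assignment[name]
        return int(self.array.matrix[run - 1, col - 1])

    def setting(self, run: int) -> dict[str, Any]:
        """Realized factor values for one run."""
        return {
            f.name: f.levels[self.level_index(run, f.name) - 1]
            for f in self.factors
        }

    def realized_design(self) -> pd.DataFrame:
        """All run settings as a DataFrame indexed by run (1-based)."""
        rows = [self.setting(r) for r in self.runs]
        return pd.DataFrame(
            rows, index=pd.RangeIndex(1, self.n_runs + 1, name="run")
        )

    def runs_at_level(self, name: str, level_index: int) -> list[int]:
        """Runs where factor ``name`` sits at 1-based ``level_index``."""
        col = self.assignment[name]
        mask = self.array.matrix[:, col - 1] == level_index
        return [int(r) for r in np.flatnonzero(mask) + 1]

    def to_csv(self, path) -> None:
        self.realized_design().to_csv(path)

    def matches(self, run: int, setting: Mapping[str, Any]) -> bool:
        own = self.setting(run)
        return all(_values_equal(own[k], setting[k]) for k in own)


def _values_equal(a: Any, b: Any) -> bool:
    try:
        return np.isclose(float(a), float(b), rtol=0, atol=1e-12)
    except (TypeError, ValueError):
        return a == b


def make_plan(
    factors: Sequence[FactorSpec],
    array: OrthogonalArray,
    assignment: Mapping[str, int],
) -> ExperimentPlan:
    """Assign factors to array columns, validating the mapping.

    Each factor must land on a distinct column whose level count equals the
    factor's level count (no dummy treatment), and every factor needs an
    assignment.
    """
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise AssignmentError(f"duplicate factor names in {names}")
    missing = [n for n in names if n not in assignment]
    if missing:
        raise AssignmentError(f"factors without column assignment: {missing}")
    cols = [assignment[n] for n in names]
    if len(set(cols)) != len(cols):
        raise AssignmentError(f"duplicate column assignments: {cols}")
    for f in factors:
        col = assignment[f.name]
        if not 1 <= col <= array.n_columns:
            raise AssignmentError(
                f"factor {f.name!r}: column {col} outside 1..{array.n_columns}"
            )
        b = array.column_levels(col)
        if f.n_levels != b:
            raise AssignmentError(
                f"factor {f.name!r} has {f.n_levels} levels but column {col} "
                f"of {array.identifier} carries {b}"
            )
    return ExperimentPlan(array, tuple(factors), {n: assignment[n] for n in names})


def smallest_array_for(factors: Sequence[FactorSpec]) -> OrthogonalArray:
    """Smallest catalog array that can host all factors on distinct columns
    of matching level count."""
    need = Counter(f.n_levels for f in factors)
    for ident in list_arrays():
        arr = get_array(ident)
        have = Counter(
            arr.column_levels(j) for j in range(1, arr.n_columns + 1)
        )
        if all(have.get(k, 0) >= v for k, v in need.items()):
            return arr
    raise CatalogError(
        f"no catalog array hosts level counts {dict(need)}; available: {list_arrays()}"
    )


def default_assignment(
    factors: Sequence[FactorSpec], array: OrthogonalArray
) -> dict[str, int]:
    """Greedy left-to-right assignment of factors to matching columns."""
    taken: set[int] = set()
    out: dict[str, int] = {}
    for f in factors:
        for j in range(1, array.n_columns + 1):
            if j not in taken and array.column_levels(j) == f.n_levels:
                out[f.name] = j
                taken.add(j)
                break
        else:
            raise AssignmentError(
                f"no free {f.n_levels}-level column for factor {f.name!r} "
                f"in {array.identifier}"
            )
    return out
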