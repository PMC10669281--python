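"""Objective functions evaluated by the optimization driver.

An objective maps ``(factor assignment, replicate index, seed)`` to a
response in ``(0, 1]`` (larger is better) and must be deterministic given
those three arguments.  Three concrete objectives are provided:

* :class:`LookupObjective` replays a fixed table of recorded responses —
  used to push previously collected experiment results through the full
  analysis chain;
* :class:`SyntheticAdditiveObjective` is a test harness with a known
  optimum: baseline plus per-factor additive level effects plus optional
  Gaussian noise;
* :class:`MLPObjective` trains a scikit-learn multilayer perceptron on a
  tabular binary-outcome dataset and returns held-out test accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Protocol, Sequence

import numpy as np

from .design import ExperimentPlan, FactorSpec

__all__ = [
    "Objective",
    "ObjectiveError",
    "LookupObjective",
    "SyntheticAdditiveObjective",
    "MLPHyperparameters",
    "MLPObjective",
]

RESPONSE_FLOOR = 1e-6  # keeps larger-the-better SN defined


class ObjectiveError(RuntimeError):
    """Objective evaluation failed or was queried off its domain."""


class Objective(Protocol):
    """Contract: deterministic response in (0, 1] for a factor setting."""

    def __call__(
        self, assignment: Mapping[str, Any], replicate: int, seed: int
    ) -> float: ...


def _key(assignment: Mapping[str, Any]) -> tuple:
    """Hashable, float-tolerant key for a factor assignment."""
    items = []
    for name in sorted(assignment):
        v = assignment[name]
        try:
            v = round(float(v), 10)
        except (TypeError, ValueError):
            pass
        items.append((name, v))
    return tuple(items)


class LookupObjective:
    """Replay recorded responses for the settings of a known design.

    ``tables`` maps a setting key to the list of replicate responses
    recorded at that setting.  Extra settings (e.g. confirmation runs at a
    predicted-best combination that is off the design) are added with
    :meth:`add`.
    """

    def __init__(self) -> None:
        self._tables: dict[tuple, list[float]] = {}

    @classmethod
    def from_plan(
        cls, plan: ExperimentPlan, responses: Mapping[int, Sequence[float]]
    ) -> "LookupObjective":
        obj = cls()
        for run in plan.runs:
            if run not in responses:
                raise ObjectiveError(f"no recorded responses for run {run}")
            obj.add(plan.setting(run), responses[run])
        return obj

    def add(
        self, assignment: Mapping[str, Any], values: Sequence[float]
    ) -> "LookupObjective":
        self._tables[_key(assignment)] = [float(v) for v in values]
        return self

    def __call__(
        self, assignment: Mapping[str, Any], replicate: int, seed: int
    ) -> float:
        values = self._tables.get(_key(assignment))
        if values is None:
            # confirmation settings may include factors fixed after screening:
            # fall back to the unique recorded setting consistent on shared keys
            matches = [
                v
                for k, v in self._tables.items()
                if dict(k).items() <= dict(_key(assignment)).items()
            ]
            if len(matches) == 1:
                values = matches[0]
            else:
                raise ObjectiveError(
                    f"no recorded responses for setting {dict(assignment)!r}"
                )
        if not 0 <= replicate < len(values):
            raise ObjectiveError(
                f"replicate {replicate} outside recorded range 0..{len(values) - 1}"
            )
        return values[replicate]


@dataclass
class SyntheticAdditiveObjective:
    """Known-optimum additive response with optional Gaussian noise.

    The noiseless response at a setting is ``baseline + sum of the chosen
    levels' effects``, clipped to ``(0, 1]``.  Noise of standard deviation
    ``sigma`` is added per evaluation, seeded solely by the ``seed``
    argument so identical (setting, replicate, seed) triples repeat
    exactly.
    """

    factors: Sequence[FactorSpec]
    baseline: float
    effects: Mapping[str, Mapping[Any, float]]  # factor -> level value -> effect
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self._effect_keys = {
            name: {_scalar_key(lv): e for lv, e in table.items()}
            for name, table in self.effects.items()
        }

    def _effect(self, name: str, level: Any) -> float:
        table = self._effect_keys.get(name)
        if table is None:
            raise ObjectiveError(f"no effects declared for factor {name!r}")
        k = _scalar_key(level)
        if k not in table:
            raise ObjectiveError(f"factor {name!r}: no effect for level {level!r}")
        return table[k]

    def noiseless(self, assignment: Mapping[str, Any]) -> float:
        val = self.baseline + sum(
            self._effect(n, v) for n, v in assignment.items() if n in self._effect_keys
        )
        return float(np.clip(val, RESPONSE_FLOOR, 1.0))

    def __call__(
        self, assignment: Mapping[str, Any], replicate: int, seed: int
    ) -> float:
        val = self.noiseless(assignment)
        if self.sigma > 0:
            rng = np.random.default_rng(seed)
            val += rng.normal(0.0, self.sigma)
        return float(np.clip(val, RESPONSE_FLOOR, 1.0))

    def true_optimum(self) -> tuple[dict[str, Any], float]:
        """Argmax setting of the additive model and its noiseless value."""
        best: dict[str, Any] = {}
        for f in self.factors:
            if f.name not in self._effect_keys:
                continue
            best[f.name] = max(f.levels, key=lambda lv: self._effect(f.name, lv))
        return best, self.noiseless(best)


def _scalar_key(v: Any) -> Any:
    try:
        return round(float(v), 10)
    except (TypeError, ValueError):
        return v


@dataclass(frozen=True)
class MLPHyperparameters:
    """Multilayer-perceptron hyperparameters: all hidden layers share one
    width; momentum applies only where the backend defines it (sgd)."""

    hidden_layers: int = 1
    hidden_nodes: int = 8
    activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_nodes < 1:
            raise ValueError("hidden_layers and hidden_nodes must be >= 1")
        if not (0 < self.learning_rate < 1) or not (0 < self.momentum < 1):
            raise ValueError("learning_rate and momentum must lie in (0, 1)")
        if self.activation not in ("logistic", "tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer not in ("lbfgs", "sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def from_assignment(cls, assignment: Mapping[str, Any]) -> "MLPHyperparameters":
        return cls(
            hidden_layers=int(assignment.get("hidden_layers", 1)),
            hidden_nodes=int(assignment.get("hidden_nodes", 8)),
            activation=str(assignment.get("activation", "relu")),
            optimizer=str(assignment.get("optimizer", "adam")),
            learning_rate=float(assignment.get("learning_rate", 0.001)),
            momentum=float(assignment.get("momentum_rate", 0.9)),
        )


@dataclass
class MLPObjective:
    """Train an MLP classifier and score held-out accuracy.

    Replicates share one train/test split (``split_seed``); the per-call
    ``seed`` varies only the weight initialization, so replicate scatter
    reflects training randomness alone.  Non-convergence is logged as a
    warning and the reached accuracy still returned.
    """

    dataset: Any  # pandas DataFrame with feature columns + outcome column
    outcome: str = "cardio"
    split_seed: int = 0
    test_fraction: float = 0.2
    max_iter: int = 200
    _split_cache: tuple | None = field(default=None, repr=False)

    def _split(self):
        if self._split_cache is None:
            from .data import split_and_normalize

            train, test = split_and_normalize(
                self.dataset,
                seed=self.split_seed,
                test_fraction=self.test_fraction,
                outcome=self.outcome,
            )
            for part, label in ((train, "train"), (test, "test")):
                if part[self.outcome].nunique() < 2:
                    raise ObjectiveError(
                        f"{label} partition contains a single outcome class"
                    )
            self._split_cache = (train, test)
        return self._split_cache

    def __call__(
        self, assignment: Mapping[str, Any], replicate: int, seed: int
    ) -> float:
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.neural_network import MLPClassifier

        hp = MLPHyperparameters.from_assignment(assignment)
        train, test = self._split()
        feats = [c for c in train.columns if c != self.outcome]
        kwargs: dict[str, Any] = dict(
            hidden_layer_sizes=(hp.hidden_nodes,) * hp.hidden_layers,
            activation=hp.activation,
            solver=hp.optimizer,
            max_iter=self.max_iter,
            random_state=int(seed) % (2**31),
        )
        if hp.optimizer in ("sgd", "adam"):
            kwargs["learning_rate_init"] = hp.learning_rate
        if hp.optimizer == "sgd":
            kwargs["momentum"] = hp.momentum
        clf = MLPClassifier(**kwargs)
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "always", category=ConvergenceWarning, module="sklearn"
            )
            clf.fit(train[feats].to_numpy(), train[self.outcome].to_numpy())
        acc = float(
            clf.score(test[feats].to_numpy(), test[self.outcome].to_numpy())
        )
        return max(acc, RESPONSE_FLOOR)
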