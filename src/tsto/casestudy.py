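"""Bundled worked example: ANN tuning for cardiovascular-risk prediction.

A published case study tuned six multilayer-perceptron hyperparameters
(hidden layers, activation, optimizer, learning rate, momentum rate,
hidden nodes) for a cardiovascular-disease risk classifier, recording test
accuracy for every run of a coarse L18 screening design (3 replicates),
five confirmation runs, a refined L9 design around the screening winner
(3 replicates), and five final confirmation runs.  Those recorded
accuracies are reproduced here verbatim so the complete two-stage analysis
chain — SN ratios, response tables, pooled ANOVA, additive predictions and
confirmation confidence intervals — can be recomputed and checked without
retraining any network.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import ExperimentPlan, FactorSpec, get_array, make_plan
from .objectives import LookupObjective

__all__ = [
    "STAGE1_FACTORS",
    "STAGE1_ASSIGNMENT",
    "STAGE1_RESULTS",
    "STAGE1_CONFIRMATION",
    "STAGE1_BEST",
    "STAGE2_FACTORS",
    "STAGE2_ASSIGNMENT",
    "STAGE2_RESULTS",
    "STAGE2_CONFIRMATION",
    "STAGE2_BEST",
    "stage1_plan",
    "stage2_plan",
    "lookup_objective",
    "generate_fixtures",
]

STAGE1_FACTORS = (
    FactorSpec("hidden_layers", "numeric-integer", (4, 8, 12), structural=True),
    FactorSpec("activation", "categorical", ("logistic", "tanh", "relu")),
    FactorSpec("optimizer", "categorical", ("lbfgs", "sgd", "adam")),
    FactorSpec("learning_rate", "numeric-continuous", (0.2, 0.3, 0.4)),
    FactorSpec("momentum_rate", "numeric-continuous", (0.7, 0.8, 0.9)),
    FactorSpec("hidden_nodes", "numeric-integer", (4, 8, 12)),
)

# Six 3-level factors on columns 2-7 of L18(2^1x3^7); columns 1 and 8 unused.
STAGE1_ASSIGNMENT = {
    "hidden_layers": 2,
    "activation": 3,
    "optimizer": 4,
    "learning_rate": 5,
    "momentum_rate": 6,
    "hidden_nodes": 7,
}

# Recorded test accuracies, 3 replicates per L18 run.
STAGE1_RESULTS: dict[int, tuple[float, float, float]] = {
    1: (0.4951, 0.4951, 0.4951),
    2: (0.7389, 0.7382, 0.7262),
    3: (0.4951, 0.5049, 0.4951),
    4: (0.4951, 0.4951, 0.4951),
    5: (0.7404, 0.7405, 0.7331),
    6: (0.4951, 0.4951, 0.4951),
    7: (0.4951, 0.5049, 0.5049),
    8: (0.4951, 0.4951, 0.5136),
    9: (0.7341, 0.7414, 0.4951),
    10: (0.4951, 0.4951, 0.4951),
    11: (0.7361, 0.7386, 0.7372),
    12: (0.7389, 0.7381, 0.7404),
    13: (0.5049, 0.4951, 0.4951),
    14: (0.4951, 0.5049, 0.4951),
    15: (0.7416, 0.7412, 0.7404),
    16: (0.4951, 0.4951, 0.4951),
    17: (0.7441, 0.7418, 0.7423),
    18: (0.7384, 0.7240, 0.7431),
}

# Screening winner and its five recorded confirmation accuracies.
STAGE1_BEST = {
    "hidden_layers": 4,
    "activation": "tanh",
    "optimizer": "sgd",
    "learning_rate": 0.3,
    "momentum_rate": 0.9,
    "hidden_nodes": 8,
}
STAGE1_CONFIRMATION = (0.7398, 0.7392, 0.7394, 0.7369, 0.7361)

# Refined stage: numeric factors re-leveled around the screening winner
# (winner +/- half the coarse level spacing), the rest fixed.
STAGE2_FACTORS = (
    FactorSpec("learning_rate", "numeric-continuous", (0.25, 0.3, 0.35)),
    FactorSpec("momentum_rate", "numeric-continuous", (0.85, 0.9, 0.95)),
    FactorSpec("hidden_nodes", "numeric-integer", (6, 8, 10)),
)
STAGE2_FIXED = {
    "hidden_layers": 4,
    "activation": "tanh",
    "optimizer": "sgd",
}

# Three factors on columns 1-3 of L9(3^4); column 4 unused.
STAGE2_ASSIGNMENT = {"learning_rate": 1, "momentum_rate": 2, "hidden_nodes": 3}

STAGE2_RESULTS: dict[int, tuple[float, float, float]] = {
    1: (0.7390, 0.7379, 0.7417),
    2: (0.7392, 0.7381, 0.7376),
    3: (0.7348, 0.7414, 0.7398),
    4: (0.7348, 0.7411, 0.7399),
    5: (0.7399, 0.7341, 0.7400),
    6: (0.7357, 0.7360, 0.7395),
    7: (0.7418, 0.7349, 0.7388),
    8: (0.7376, 0.7301, 0.7374),
    9: (0.7420, 0.7374, 0.7291),
}

STAGE2_BEST = {"learning_rate": 0.25, "momentum_rate": 0.85, "hidden_nodes": 10}
STAGE2_CONFIRMATION = (0.7401, 0.7410, 0.7439, 0.7415, 0.7407)


def stage1_plan() -> ExperimentPlan:
    """The coarse L18 screening plan of the case study."""
    return make_plan(STAGE1_FACTORS, get_array("L18(2^1x3^7)"), STAGE1_ASSIGNMENT)


def stage2_plan() -> ExperimentPlan:
    """The refined L9 plan of the case study."""
    return make_plan(STAGE2_FACTORS, get_array("L9(3^4)"), STAGE2_ASSIGNMENT)


def lookup_objective() -> LookupObjective:
    """Replay objective covering both designs and both confirmation
    settings, so the full two-stage driver can re-run the case study."""
    obj = LookupObjective.from_plan(stage1_plan(), STAGE1_RESULTS)
    for run, values in STAGE2_RESULTS.items():
        setting = dict(STAGE2_FIXED)
        setting.update(stage2_plan().setting(run))
        obj.add(setting, values)
    obj.add(STAGE1_BEST, STAGE1_CONFIRMATION)
    best2 = dict(STAGE2_FIXED)
    best2.update(STAGE2_BEST)
    obj.add(best2, STAGE2_CONFIRMATION)
    return obj


def generate_fixtures(out_dir) -> list[Path]:
    """Write the case-study designs and recorded accuracies as CSVs.

    Emits stage-1 and stage-2 design+results tables (one row per run:
    realized factor values and replicate accuracies) and the two
    confirmation-run tables.  Returns the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for label, plan, results in (
        ("stage1", stage1_plan(), STAGE1_RESULTS),
        ("stage2", stage2_plan(), STAGE2_RESULTS),
    ):
        df = plan.realized_design()
        reps = len(next(iter(results.values())))
        for i in range(reps):
            df[f"rep_{i + 1}"] = [results[r][i] for r in plan.runs]
        path = out / f"{label}_design_results.csv"
        df.to_csv(path)
        written.append(path)

    for label, values in (
        ("stage1", STAGE1_CONFIRMATION),
        ("stage2", STAGE2_CONFIRMATION),
    ):
        path = out / f"{label}_confirmation.csv"
        pd.DataFrame(
            {"rep": range(1, len(values) + 1), "accuracy": values}
        ).to_csv(path, index=False)
        written.append(path)
    return written
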