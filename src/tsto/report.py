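"""Report writing: CSV bundles, display rounding, run manifests.

Two variants of each table are emitted: a full-precision CSV (the
authoritative record) and a ``*_display.csv`` rounded the way such tables
are conventionally printed — accuracy-scale values to 4 decimals, SN
ratios to 3, p-values to 3 — so diffs against published tables are
meaningful.  The manifest is a JSON snapshot (config, seeds, every logged
evaluation) sufficient to re-run a command identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd

from .driver import ConfirmationResult, StageResult, TSTOReport

__all__ = ["write_stage_reports", "write_tsto_reports", "write_manifest"]

_ACC_DECIMALS = 4
_SN_DECIMALS = 3
_P_DECIMALS = 3


def _display_round(df: pd.DataFrame, sn: bool = False) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if col in ("p",):
            out[col] = out[col].round(_P_DECIMALS)
        elif sn or col in ("sn", "SN"):
            out[col] = out[col].round(_SN_DECIMALS)
        else:
            out[col] = out[col].round(_ACC_DECIMALS)
    return out


def _write_pair(df: pd.DataFrame, path: Path, index: bool, sn: bool = False) -> list[Path]:
    df.to_csv(path, index=index)
    disp = path.with_name(path.stem + "_display.csv")
    _display_round(df, sn=sn).to_csv(disp, index=index)
    return [path, disp]


def write_stage_reports(
    result: StageResult, out_dir, prefix: str = "stage1"
) -> list[Path]:
    """Write one stage's summary, response tables, ANOVA tables and
    prediction record.  Returns the file inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    files += _write_pair(result.summary.table, out / f"{prefix}_summary.csv", True)
    files += _write_pair(
        result.response_mean.to_frame(), out / f"{prefix}_response_mean.csv", True
    )
    files += _write_pair(
        result.response_sn.to_frame(), out / f"{prefix}_response_sn.csv", True, sn=True
    )
    files += _write_pair(
        result.anova_mean.to_frame(), out / f"{prefix}_anova_mean.csv", False
    )
    files += _write_pair(
        result.anova_sn.to_frame(), out / f"{prefix}_anova_sn.csv", False
    )
    pred = pd.DataFrame(
        [
            {
                "quantity": "mean",
                "predicted": result.prediction_mean.value,
                "ci_half_width": result.ci_mean.half_width,
                "lower": result.ci_mean.interval[0],
                "upper": result.ci_mean.interval[1],
            },
            {
                "quantity": "sn",
                "predicted": result.prediction_sn.value,
                "ci_half_width": result.ci_sn.half_width,
                "lower": result.ci_sn.interval[0],
                "upper": result.ci_sn.interval[1],
            },
        ]
    )
    files += _write_pair(pred, out / f"{prefix}_prediction.csv", False)
    best = pd.DataFrame([result.best_levels])
    best.to_csv(out / f"{prefix}_best_levels.csv", index=False)
    files.append(out / f"{prefix}_best_levels.csv")
    return files


def _confirmation_frame(conf: ConfirmationResult) -> pd.DataFrame:
    row: dict[str, Any] = {
        f"rep_{i + 1}": v for i, v in enumerate(conf.values)
    }
    row.update(
        mean=conf.mean,
        sd=conf.sd,
        sn=conf.sn,
        mean_within_ci=conf.mean_within,
        sn_within_ci=conf.sn_within,
    )
    return pd.DataFrame([row])


def write_tsto_reports(report: TSTOReport, out_dir) -> list[Path]:
    """Write the full two-stage bundle: per-stage reports, confirmations,
    the comparison table and a plain-text narrative log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = write_stage_reports(report.stage1, out, "stage1")
    files += write_stage_reports(report.stage2, out, "stage2")
    files += _write_pair(
        _confirmation_frame(report.confirmation1),
        out / "stage1_confirmation.csv",
        False,
    )
    files += _write_pair(
        _confirmation_frame(report.confirmation2),
        out / "stage2_confirmation.csv",
        False,
    )
    files += _write_pair(report.comparison, out / "comparison.csv", False)
    log = out / "narrative.log"
    log.write_text(_narrative(report), encoding="utf-8")
    files.append(log)
    return files


def _narrative(report: TSTOReport) -> str:
    lines = []
    s1, s2 = report.stage1, report.stage2
    lines.append(f"Stage 1: {s1.plan.array.identifier}, {s1.plan.n_runs} runs x "
                 f"{s1.config.replicates} replicates")
    lines.append(f"  retained factors: {s1.retained}; pooled: {sorted(s1.pooled)}")
    lines.append(f"  significant (alpha={s1.config.screening_alpha}): "
                 f"{sorted(s1.significant)}")
    lines.append(f"  best levels: {s1.best_levels}")
    lines.append(
        f"  predicted mean {s1.prediction_mean.value:.4f} +/- "
        f"{s1.ci_mean.half_width:.4f}; predicted SN "
        f"{s1.prediction_sn.value:.3f} +/- {s1.ci_sn.half_width:.4f} dB"
    )
    c1 = report.confirmation1
    lines.append(
        f"  confirmation: mean {c1.mean:.4f} ({'in' if c1.mean_within else 'OUT of'} CI), "
        f"SN {c1.sn:.3f} dB ({'in' if c1.sn_within else 'OUT of'} CI)"
    )
    lines.append(f"Fixed after stage 1: {report.fixed}")
    lines.append(f"Stage 2: {s2.plan.array.identifier}, {s2.plan.n_runs} runs x "
                 f"{s2.config.replicates} replicates")
    lines.append(f"  best levels: {s2.best_levels}")
    lines.append(
        f"  predicted mean {s2.prediction_mean.value:.4f} +/- "
        f"{s2.ci_mean.half_width:.4f}; predicted SN "
        f"{s2.prediction_sn.value:.3f} +/- {s2.ci_sn.half_width:.4f} dB"
    )
    c2 = report.confirmation2
    lines.append(
        f"  confirmation: mean {c2.mean:.4f} ({'in' if c2.mean_within else 'OUT of'} CI), "
        f"SN {c2.sn:.3f} dB ({'in' if c2.sn_within else 'OUT of'} CI)"
    )
    b1, b2 = report.budget1, report.budget2
    lines.append(
        f"Budget: stage 1 {b1.array_experiments} vs full factorial "
        f"{b1.full_factorial} (reduction {b1.reduction_factor:g}); stage 2 "
        f"{b2.array_experiments} vs {b2.full_factorial} "
        f"(reduction {b2.reduction_factor:g})"
    )
    imp = report.comparison.iloc[-1]
    lines.append(
        f"Improvement (stage 2 - stage 1): mean {imp['mean']:+.4f}, "
        f"SD {imp['sd']:+.4f}, SN {imp['sn']:+.4f} dB"
    )
    return "\n".join(lines) + "\n"


def write_manifest(report: TSTOReport, path) -> Path:
    """JSON manifest: seeds, arrays, per-evaluation log, file inventory."""
    path = Path(path)
    payload = {
        "seed": report.stage1.config.seed,
        "arrays": {
            "stage1": report.stage1.plan.array.identifier,
            "stage2": report.stage2.plan.array.identifier,
        },
        "fixed": report.fixed,
        "best_setting": report.best_setting,
        "evaluations": [
            {
                "stage": e.stage,
                "run": e.run,
                "replicate": e.replicate,
                "assignment": dict(e.assignment),
                "seed": e.seed,
                "response": e.response,
            }
            for e in report.evaluations
        ],
        "budget": {
            "stage1": asdict(report.budget1),
            "stage2": asdict(report.budget2),
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
    return path
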