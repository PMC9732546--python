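"""End-to-end efficacy pipeline and report generation.

``run_efficacy`` chains, for every treated arm against the control arm:
RTV series -> TGI series -> optimal TGI (with the >= 50% meaningful-effect
flag) -> Mann-Whitney on the individual RTVs at the optimal day -> per-mouse
RTVV/ORR responder classification and the pooled ORR table with Fisher
comparisons between treated arms -> RTVx2 / RTVx4 progression events with
Kaplan-Meier curves and the Mantel-Cox log-rank test. Every number in the
report equals what the stage functions return when called individually
(composition contract), and the serialized report is byte-identical across
runs on the same inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import NotEvaluableError, ValidationError
from .growth import (
    OrrTableRow,
    ResponseRecord,
    Study,
    StudyArm,
    TgiResult,
    last_common_day,
    optimal_tgi,
    orr_table,
    rtv_at,
    tgi_series,
)
from .stats import TestResult, compare_orr, mann_whitney
from .survival import (
    KMCurve,
    LogrankResult,
    SurvivalRecord,
    arm_event_times,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger("pdxefficacy")

FOLD_THRESHOLDS = (2, 4)


@dataclass(frozen=True)
class FoldSurvival:
    """Time-to-RTVxfold analysis of one treated arm against control."""

    fold: int
    treated_records: tuple[SurvivalRecord, ...]
    control_records: tuple[SurvivalRecord, ...]
    km_treated: KMCurve
    km_control: KMCurve
    logrank: LogrankResult


@dataclass(frozen=True)
class ArmEfficacy:
    """All efficacy endpoints of one treated arm."""

    arm: str
    tgi_series: tuple[TgiResult, ...]
    optimal: TgiResult
    rtv_test: TestResult  # Mann-Whitney on individual RTVs at the optimal day
    orr_row: OrrTableRow
    survival: tuple[FoldSurvival, ...]


@dataclass(frozen=True)
class EfficacyReport:
    control_arm: str
    arms: tuple[ArmEfficacy, ...]
    orr_comparisons: tuple[tuple[str, str, TestResult], ...]
    provenance: dict = field(compare=False)


def _study_hash(study: Study) -> str:
    payload = []
    for arm in sorted(study.arms, key=lambda a: a.name):
        for c in sorted(arm.curves, key=lambda c: c.mouse_id):
            for m in c.measurements:
                payload.append(f"{arm.name},{c.mouse_id},{m.day},{m.volume!r}")
    digest = hashlib.sha256("\n".join(payload).encode()).hexdigest()
    return digest


def run_efficacy(
    study: Study,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
) -> EfficacyReport:
    """Run the complete efficacy analysis of a study.

    Requires a control arm plus at least one treated arm. The Fisher ORR
    comparison is computed for every pair of treated arms.
    """
    config = config or AnalysisConfig()
    control = study.control_arm
    treated = study.treated_arms
    if not treated:
        raise ValidationError("study has no treated arm")

    arm_results: list[ArmEfficacy] = []
    for arm in treated:
        series = tuple(tgi_series(arm, control, config.min_evaluable_per_arm))
        best = optimal_tgi(arm, control, config.min_evaluable_per_arm)
        rtvs_t = [rtv_at(c, best.day) for c in arm.curves if c.measured_on(best.day)]
        rtvs_c = [rtv_at(c, best.day) for c in control.curves if c.measured_on(best.day)]
        rtv_test = mann_whitney(rtvs_t, rtvs_c, exact_max_n=config.exact_test_max_n)
        day = (
            config.evaluation_day
            if config.evaluation_day is not None
            else last_common_day(arm, control)
        )
        (orr_row,) = orr_table([arm], control, evaluation_day=day)
        folds = []
        for fold in FOLD_THRESHOLDS:
            rec_t = tuple(arm_event_times(arm, fold))
            rec_c = tuple(arm_event_times(control, fold))
            folds.append(
                FoldSurvival(
                    fold=fold,
                    treated_records=rec_t,
                    control_records=rec_c,
                    km_treated=km_estimate(rec_t),
                    km_control=km_estimate(rec_c),
                    logrank=logrank_test(rec_t, rec_c),
                )
            )
        arm_results.append(
            ArmEfficacy(
                arm=arm.name,
                tgi_series=series,
                optimal=best,
                rtv_test=rtv_test,
                orr_row=orr_row,
                survival=tuple(folds),
            )
        )

    comparisons = []
    for i in range(len(arm_results)):
        for j in range(i + 1, len(arm_results)):
            ra, rb = arm_results[i].orr_row, arm_results[j].orr_row
            table = [
                [ra.n_responders, ra.n_non_responders],
                [rb.n_responders, rb.n_non_responders],
            ]
            comparisons.append((ra.arm, rb.arm, compare_orr(table)))

    provenance = {
        "input_hash": _study_hash(study),
        "config": config.to_dict(),
        "seed": seed,
        "version": __version__,
        "n_mice": {a.name: a.n_mice for a in study.arms},
    }
    return EfficacyReport(
        control_arm=control.name,
        arms=tuple(arm_results),
        orr_comparisons=tuple(comparisons),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    """P-value formatted to 3 significant figures."""
    return f"{p:.3g}"


def report_to_dict(report: EfficacyReport) -> dict:
    """Plain-type (JSON-serializable) view of a report."""
    d = dataclasses.asdict(report)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def write_report(report: EfficacyReport, outdir, fmt: str = "tabular") -> list[Path]:
    """Serialize a report deterministically.

    ``fmt="tabular"`` writes report.json (the full lossless record) plus
    tgi.csv, responses.csv, survival.csv and tests.csv; ``fmt="summary"``
    writes a plain-text summary.txt; ``fmt="all"`` writes both. Returns the
    paths written. Outputs are byte-identical across runs on equal reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt not in ("tabular", "summary", "all"):
        raise ValidationError(f"unknown report format {fmt!r}")

    if fmt in ("tabular", "all"):
        p = outdir / "report.json"
        p.write_text(
            json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(p)

        tgi_rows = [
            {
                "arm": a.arm, "day": r.day,
                "rtv_treated_median": repr(r.rtv_treated_median),
                "rtv_control_median": repr(r.rtv_control_median),
                "tgi_percent": repr(r.tgi_percent),
                "meaningful": int(r.meaningful),
                "optimal": int(r == a.optimal),
            }
            for a in report.arms
            for r in a.tgi_series
        ]
        p = outdir / "tgi.csv"
        pd.DataFrame(tgi_rows).to_csv(p, index=False, lineterminator="\n")
        written.append(p)

        resp_rows = [
            {
                "arm": a.arm, "mouse_id": r.mouse_id,
                "rtvv": repr(r.rtvv), "orr": repr(r.orr),
                "responder": int(r.responder),
                "evaluation_day": r.evaluation_day,
                "used_last_available": int(r.used_last_available),
            }
            for a in report.arms
            for r in a.orr_row.records
        ]
        p = outdir / "responses.csv"
        pd.DataFrame(resp_rows).to_csv(p, index=False, lineterminator="\n")
        written.append(p)

        surv_rows = [
            {
                "comparison_arm": a.arm, "mouse_id": r.mouse_id, "arm": r.arm_label,
                "fold": fs.fold, "time_days": r.time, "event": int(r.event),
            }
            for a in report.arms
            for fs in a.survival
            for r in (*fs.treated_records, *fs.control_records)
        ]
        p = outdir / "survival.csv"
        pd.DataFrame(surv_rows).to_csv(p, index=False, lineterminator="\n")
        written.append(p)

        test_rows = []
        for a in report.arms:
            test_rows.append(
                {
                    "comparison": f"{a.arm} vs {report.control_arm}",
                    "test": "mann-whitney-rtv",
                    "statistic": repr(a.rtv_test.statistic),
                    "p": _fmt_p(a.rtv_test.p_two_sided),
                    "method": a.rtv_test.method,
                }
            )
            for fs in a.survival:
                test_rows.append(
                    {
                        "comparison": f"{a.arm} vs {report.control_arm}",
                        "test": f"logrank-rtvx{fs.fold}",
                        "statistic": repr(fs.logrank.chi_square),
                        "p": _fmt_p(fs.logrank.p),
                        "method": "mantel-cox",
                    }
                )
        for arm_a, arm_b, res in report.orr_comparisons:
            test_rows.append(
                {
                    "comparison": f"{arm_a} vs {arm_b}",
                    "test": "fisher-orr",
                    "statistic": repr(res.statistic),
                    "p": _fmt_p(res.p_two_sided),
                    "method": res.method,
                }
            )
        p = outdir / "tests.csv"
        pd.DataFrame(test_rows).to_csv(p, index=False, lineterminator="\n")
        written.append(p)

    if fmt in ("summary", "all"):
        p = outdir / "summary.txt"
        p.write_text(summarize(report), encoding="utf-8")
        written.append(p)
    return written


def read_report(outdir) -> dict:
    """Load the lossless JSON form written by :func:`write_report`."""
    with open(Path(outdir) / "report.json", "r", encoding="utf-8") as fh:
        return json.load(fh)


def summarize(report: EfficacyReport) -> str:
    """Plain-text study summary."""
    lines = [
        "PDX efficacy report",
        f"control arm: {report.control_arm}",
        "",
    ]
    for a in report.arms:
        flag = (
            "meaningful (TGI >= 50%)" if a.optimal.meaningful
            else "not meaningful (TGI < 50%)"
        )
        lines += [
            f"arm {a.arm}:",
            f"  optimal TGI {a.optimal.tgi_percent:.1f}% at day {a.optimal.day} "
            f"-- {flag}",
            f"  Mann-Whitney on individual RTVs at day {a.optimal.day}: "
            f"U={a.rtv_test.statistic:g}, p={_fmt_p(a.rtv_test.p_two_sided)} "
            f"({a.rtv_test.method})",
            f"  responders (ORR < -0.5): {a.orr_row.n_responders}/"
            f"{a.orr_row.n_mice} ({a.orr_row.responder_pct}%) "
            f"at day {a.orr_row.evaluation_day}",
        ]
        for fs in a.survival:
            lines.append(
                f"  RTVx{fs.fold} progression, log-rank vs control: "
                f"chi2={fs.logrank.chi_square:.3f}, p={_fmt_p(fs.logrank.p)}"
            )
        lines.append("")
    for arm_a, arm_b, res in report.orr_comparisons:
        lines.append(
            f"ORR {arm_a} vs {arm_b}: Fisher exact p={_fmt_p(res.p_two_sided)}"
        )
    lines.append("")
    return "\n".join(lines)
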