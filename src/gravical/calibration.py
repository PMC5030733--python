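"""Three-stage gravimetric calibration engine.

Stage 1 — *screening*: every candidate liquid class dispenses a probe volume
(300 µL by default) once per tip; the class with the best precision (lowest
%CV, ties broken by smallest |%DEV|, then input order) is recommended.

Stage 2 — *adjustment*: for each subclass of the selected class, three test
volumes (minimum, midpoint, maximum of the range) are dispensed once per tip
(n = 8 per volume).  If any volume misses its accuracy limit, an ordinary
least-squares line through (theoretical volume, mean measured volume) gives
slope ``a₂`` and intercept ``b₂``, and the working factor/offset are updated

    new factor = a₁ / a₂
    new offset = (b₁ − b₂) / a₂

and the round repeats, up to a configurable attempt cap (4 by default).
The factor update inverts the latent slope in a single step on a noiseless
linear instrument; the offset update is an iteration that contracts its
error by |1 − p| per round toward the fixed point −q/p (it converges for
0 < p < 2).  The update is applied as written above even though an exact
one-step offset inverse exists (``b₁ − (a₁/a₂)·b₂``); matching the
established procedure takes precedence, and the iteration converges fast in
the practically relevant regime (p near 1).

Stage 3 — *confirmation*: the adjusted subclass is re-measured with two
replicates per tip (n = 16 per volume) and gated on accuracy *and*
precision; only a confirmed subclass is persisted to the master XML.
Adjustment itself gates on accuracy only, since the pipetting parameters
that drive precision are fixed per subclass and not tuned here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from gravical.errors import GravicalError, InvariantError
from gravical.gravimetry import LiquidSpec
from gravical.instrument_sim import (
    VirtualInstrument,
    measure_volumes,
    run_protocol,
)
from gravical.liquidclass import (
    LiquidClass,
    Subclass,
    derive_test_volumes,
    select_subclass,
    write_liquid_class_xml,
)
from gravical.qc_stats import (
    AcceptanceCriteria,
    AcceptanceResult,
    VolumeSummary,
    default_criteria,
    evaluate_acceptance,
    summarize_volume_set,
)


@dataclass(frozen=True)
class ResponseFit:
    """OLS line through (theoretical volume, mean measured volume)."""

    a2: float  # slope, dimensionless
    b2: float  # intercept, µL
    r2: float


def fit_response_line(
    theoretical: Sequence[float], measured_means: Sequence[float]
) -> ResponseFit:
    """Least-squares fit of mean measured volumes against theoretical volumes.

    Raises
    ------
    InvariantError
        On length mismatch or fewer than two distinct theoretical volumes.
    """
    x = np.asarray(theoretical, dtype=float)
    y = np.asarray(measured_means, dtype=float)
    if x.size != y.size:
        raise InvariantError(f"length mismatch: {x.size} theoretical vs {y.size} measured")
    if np.unique(x).size < 2:
        raise InvariantError("need at least 2 distinct theoretical volumes to fit a line")
    res = stats.linregress(x, y)
    return ResponseFit(a2=float(res.slope), b2=float(res.intercept), r2=float(res.rvalue**2))


def update_factor_offset(
    a1: float, b1: float, a2: float, b2: float
) -> tuple[float, float]:
    """Factor/offset update from the current values and the response fit.

    ``new_factor = a1/a2``; ``new_offset = (b1 − b2)/a2``.

    Raises
    ------
    InvariantError
        If the fitted slope ``a2`` is zero.
    """
    if a2 == 0:
        raise InvariantError("fitted slope a2 is zero; cannot update factor/offset")
    return a1 / a2, (b1 - b2) / a2


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningReport:
    """Per-class probe summaries and the recommended class name."""

    probe_volume: float
    summaries: tuple[tuple[str, VolumeSummary], ...]  # (class name, summary)
    recommended: str


def recommend_class(summaries: Sequence[tuple[str, VolumeSummary]]) -> str:
    """Recommendation rule: lowest %CV, then smallest |%DEV|, then input order."""
    if not summaries:
        raise InvariantError("no screening summaries to rank")
    best = min(
        enumerate(summaries),
        key=lambda item: (item[1][1].pct_cv, abs(item[1][1].pct_dev), item[0]),
    )
    return best[1][0]


def screen_liquid_classes(
    instrument: VirtualInstrument,
    classes: Sequence[LiquidClass],
    liquid: LiquidSpec,
    probe_volume: float = 300.0,
) -> ScreeningReport:
    """Stage 1: probe each candidate class once per tip and rank by precision."""
    summaries: list[tuple[str, VolumeSummary]] = []
    for lc in classes:
        records = run_protocol(instrument, lc, liquid, [probe_volume], replicates_per_tip=1)
        summaries.append((lc.name, summarize_volume_set(records)))
    return ScreeningReport(
        probe_volume=probe_volume,
        summaries=tuple(summaries),
        recommended=recommend_class(summaries),
    )


# ---------------------------------------------------------------------------
# Adjustment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttemptRecord:
    """One adjustment round: the tried factor/offset and what it measured."""

    factor: float
    offset: float
    summaries: tuple[VolumeSummary, ...]
    accuracy_results: tuple[AcceptanceResult, ...]
    fit: ResponseFit | None  # None when the round passed (no update computed)


@dataclass(frozen=True)
class AdjustmentResult:
    """Outcome of the iterative factor/offset adjustment of one subclass."""

    subclass_idx: int
    test_volumes: tuple[int, int, int]
    attempts_used: int
    history: tuple[AttemptRecord, ...]
    converged: bool
    final_factor: float
    final_offset: float


def adjust_subclass(
    instrument: VirtualInstrument,
    lc: LiquidClass,
    subclass: Subclass,
    liquid: LiquidSpec,
    criteria: AcceptanceCriteria | None = None,
    max_attempts: int = 4,
    cap: float = 900.0,
) -> AdjustmentResult:
    """Stage 2: iterate factor/offset updates until accuracy criteria are met.

    Each attempt dispenses the subclass's three test volumes once per tip
    (n = 8 per volume) with the current working factor/offset, gates every
    volume's |%DEV| against the criteria, and on failure refits the response
    line and updates the working values.  Non-convergence within
    *max_attempts* is a result state, not an error.
    """
    if max_attempts < 1:
        raise InvariantError("max_attempts must be >= 1")
    if criteria is None:
        criteria = default_criteria(lc.name)
    sc_idx = lc.subclass_index(subclass)
    volumes = derive_test_volumes(subclass, cap=cap)

    working = subclass
    history: list[AttemptRecord] = []
    converged = False
    for _attempt in range(max_attempts):
        records = measure_volumes(
            instrument, working, liquid, list(volumes), replicates_per_tip=1
        )
        summaries = tuple(
            summarize_volume_set([r for r in records if r.target_volume == v])
            for v in volumes
        )
        results = tuple(
            evaluate_acceptance(s, criteria, sc_idx, vol_idx)
            for vol_idx, s in enumerate(summaries, start=1)
        )
        if all(r.accuracy_passed for r in results):
            history.append(
                AttemptRecord(working.factor, working.offset, summaries, results, fit=None)
            )
            converged = True
            break
        fit = fit_response_line(volumes, [s.mean for s in summaries])
        history.append(
            AttemptRecord(working.factor, working.offset, summaries, results, fit=fit)
        )
        new_factor, new_offset = update_factor_offset(
            working.factor, working.offset, fit.a2, fit.b2
        )
        working = working.with_calibration(new_factor, new_offset)

    return AdjustmentResult(
        subclass_idx=sc_idx,
        test_volumes=volumes,
        attempts_used=len(history),
        history=tuple(history),
        converged=converged,
        final_factor=history[-1].factor if converged else working.factor,
        final_offset=history[-1].offset if converged else working.offset,
    )


# ---------------------------------------------------------------------------
# Confirmation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfirmationResult:
    """Outcome of the n = 16 confirmation run of an adjusted subclass."""

    subclass_idx: int
    test_volumes: tuple[int, int, int]
    summaries: tuple[VolumeSummary, ...]
    results: tuple[AcceptanceResult, ...]
    passed: bool


def confirm_subclass(
    instrument: VirtualInstrument,
    lc: LiquidClass,
    subclass: Subclass,
    liquid: LiquidSpec,
    criteria: AcceptanceCriteria | None = None,
    cap: float = 900.0,
) -> ConfirmationResult:
    """Stage 3: re-measure with 2 replicates per tip and gate on both limits.

    *subclass* carries the adjusted factor/offset.  A pass makes it eligible
    for persistence into the master liquid-class XML.
    """
    if criteria is None:
        criteria = default_criteria(lc.name)
    sc_idx = lc.subclass_index(subclass)
    volumes = derive_test_volumes(subclass, cap=cap)
    records = measure_volumes(
        instrument, subclass, liquid, list(volumes), replicates_per_tip=2
    )
    summaries = tuple(
        summarize_volume_set([r for r in records if r.target_volume == v]) for v in volumes
    )
    results = tuple(
        evaluate_acceptance(s, criteria, sc_idx, vol_idx)
        for vol_idx, s in enumerate(summaries, start=1)
    )
    return ConfirmationResult(
        subclass_idx=sc_idx,
        test_volumes=volumes,
        summaries=summaries,
        results=results,
        passed=all(r.passed for r in results),
    )


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubclassSession:
    """Adjustment + confirmation trace of one subclass."""

    subclass_idx: int
    adjustment: AdjustmentResult
    confirmation: ConfirmationResult | None  # None when adjustment failed
    persisted: bool


@dataclass(frozen=True)
class SessionReport:
    """Structured log of one end-to-end calibration session."""

    liquid: LiquidSpec
    screening: ScreeningReport
    selected_class: str
    subclasses: tuple[SubclassSession, ...]
    calibrated_class: LiquidClass | None
    all_passed: bool


_REPORT_COLUMNS = [
    "stage",
    "liquid_class",
    "subclass",
    "attempt",
    "target_volume",
    "n",
    "mean",
    "min",
    "max",
    "dev_pct_signed",
    "dev_pct_abs",
    "cv_pct",
    "factor",
    "offset",
    "pass",
]


def _summary_row(
    stage: str,
    lc_name: str,
    sc_idx,
    attempt,
    s: VolumeSummary,
    factor,
    offset,
    passed,
) -> dict:
    return {
        "stage": stage,
        "liquid_class": lc_name,
        "subclass": sc_idx,
        "attempt": attempt,
        "target_volume": s.target,
        "n": s.n,
        "mean": f"{s.mean:.4f}",
        "min": f"{s.min:.4f}",
        "max": f"{s.max:.4f}",
        "dev_pct_signed": f"{s.pct_dev:.4f}",
        "dev_pct_abs": f"{abs(s.pct_dev):.4f}",
        "cv_pct": f"{s.pct_cv:.4f}",
        "factor": f"{factor:.6g}" if factor is not None else "",
        "offset": f"{offset:.6g}" if offset is not None else "",
        "pass": str(bool(passed)).lower(),
    }


def session_report_rows(report: SessionReport) -> list[dict]:
    """Flatten a session report into CSV-ready rows (stable column order)."""
    rows: list[dict] = []
    for name, s in report.screening.summaries:
        rows.append(
            _summary_row("screening", name, "", "", s, None, None, name == report.selected_class)
        )
    for sub in report.subclasses:
        adj = sub.adjustment
        for attempt_no, att in enumerate(adj.history, start=1):
            for s, res in zip(att.summaries, att.accuracy_results):
                rows.append(
                    _summary_row(
                        "adjustment",
                        report.selected_class,
                        adj.subclass_idx,
                        attempt_no,
                        s,
                        att.factor,
                        att.offset,
                        res.accuracy_passed,
                    )
                )
        if sub.confirmation is not None:
            conf = sub.confirmation
            for s, res in zip(conf.summaries, conf.results):
                rows.append(
                    _summary_row(
                        "confirmation",
                        report.selected_class,
                        conf.subclass_idx,
                        "",
                        s,
                        adj.final_factor,
                        adj.final_offset,
                        res.passed,
                    )
                )
    return rows


def write_session_report(report: SessionReport, path: str | Path) -> None:
    """Write the session report as CSV with the documented column set."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_REPORT_COLUMNS)
        writer.writeheader()
        writer.writerows(session_report_rows(report))


def calibrate_liquid(
    instrument: VirtualInstrument,
    classes: Sequence[LiquidClass],
    liquid: LiquidSpec,
    criteria: "AcceptanceCriteria | Callable[[str], AcceptanceCriteria] | None" = None,
    out_xml: str | Path | None = None,
    out_report: str | Path | None = None,
    probe_volume: float = 300.0,
    max_attempts: int = 4,
    cap: float = 900.0,
) -> SessionReport:
    """Run the full screen → adjust → confirm workflow for one liquid.

    Every subclass of the recommended class is adjusted and confirmed in
    turn; failures are recorded and the remaining subclasses still run.
    Confirmed factor/offset values are collected into a calibrated copy of
    the class named ``<liquid>_<class>`` and, if *out_xml* is given, written
    to that file; *out_report* receives the CSV session log.
    """
    screening = screen_liquid_classes(instrument, classes, liquid, probe_volume)
    selected = next(lc for lc in classes if lc.name == screening.recommended)
    if callable(criteria):
        criteria = criteria(selected.name)
    if criteria is None:
        criteria = default_criteria(selected.name)

    calibrated = LiquidClass(f"{liquid.name}_{selected.name}", selected.subclasses)
    sessions: list[SubclassSession] = []
    any_persisted = False
    for idx, sc in enumerate(selected.subclasses, start=1):
        adj = adjust_subclass(
            instrument, selected, sc, liquid, criteria, max_attempts=max_attempts, cap=cap
        )
        conf: ConfirmationResult | None = None
        persisted = False
        if adj.converged:
            adjusted_sc = sc.with_calibration(adj.final_factor, adj.final_offset)
            conf = confirm_subclass(instrument, selected, adjusted_sc, liquid, criteria, cap=cap)
            if conf.passed:
                calibrated = calibrated.with_subclass(idx, adjusted_sc)
                persisted = True
                any_persisted = True
        sessions.append(SubclassSession(idx, adj, conf, persisted))

    all_passed = all(s.persisted for s in sessions)
    report = SessionReport(
        liquid=liquid,
        screening=screening,
        selected_class=selected.name,
        subclasses=tuple(sessions),
        calibrated_class=calibrated if any_persisted else None,
        all_passed=all_passed,
    )
    if out_xml is not None and report.calibrated_class is not None:
        write_liquid_class_xml([report.calibrated_class], out_xml)
    if out_report is not None:
        write_session_report(report, out_report)
    return report
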