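"""Accuracy/precision statistics and the acceptance-criteria engine.

Accuracy of a dispense series is the signed percentage deviation of the mean
measured volume ``V_A`` from the intended volume ``V_O``::

    %DEV = (V_A − V_O) / V_O × 100

Precision is the coefficient of variation across tips and replicates::

    %CV = σ / x̄ × 100

with the sample standard deviation (n−1 denominator, the metrological
convention).  Acceptance is gated per (subclass, volume index) on
``|%DEV| ≤ max_abs_dev`` and ``%CV ≤ max_cv``, both inclusive; the signed
deviation is retained in summaries and reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from gravical.errors import ConfigurationError, InvariantError
from gravical.instrument_sim import MeasurementRecord


@dataclass(frozen=True)
class VolumeSummary:
    """Per-target-volume statistics of a gravimetric series."""

    target: float  # V_O, µL
    n: int
    mean: float  # µL
    min: float  # µL
    max: float  # µL
    sd: float  # µL
    pct_dev: float  # signed %
    pct_cv: float  # %


def percent_dev(v_a: float, v_o: float) -> float:
    """Signed accuracy: ``(V_A − V_O) / V_O × 100``.

    Raises
    ------
    InvariantError
        If the intended volume ``V_O`` is non-positive.
    """
    if v_o <= 0:
        raise InvariantError(f"intended volume must be > 0 µL, got {v_o}")
    return (v_a - v_o) / v_o * 100.0


def percent_cv(values: Sequence[float]) -> float:
    """Precision: sample SD (n−1) over mean, in percent.

    Raises
    ------
    InvariantError
        For fewer than two values or a zero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvariantError(f"%CV needs at least 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise InvariantError("%CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def summarize_volume_set(records: Sequence[MeasurementRecord]) -> VolumeSummary:
    """Summary statistics of all records sharing one target volume.

    Accuracy is computed from the mean measured volume (the accuracy *of the
    mean*), precision across all individual measurements.

    Raises
    ------
    InvariantError
        On fewer than two records or mixed target volumes.
    """
    if len(records) < 2:
        raise InvariantError("need at least 2 records to summarize a volume")
    targets = {r.target_volume for r in records}
    if len(targets) != 1:
        raise InvariantError(f"records mix target volumes: {sorted(targets)}")
    target = records[0].target_volume
    va = np.array([r.measured_volume for r in records], dtype=float)
    mean = float(va.mean())
    return VolumeSummary(
        target=target,
        n=len(records),
        mean=mean,
        min=float(va.min()),
        max=float(va.max()),
        sd=float(va.std(ddof=1)),
        pct_dev=percent_dev(mean, target),
        pct_cv=percent_cv(va),
    )


# ---------------------------------------------------------------------------
# Acceptance criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CriteriaCell:
    """Limits for one (subclass, volume index): |%DEV| and %CV caps."""

    max_abs_dev: float  # %
    max_cv: float  # %

    def __post_init__(self) -> None:
        if self.max_abs_dev <= 0 or self.max_cv <= 0:
            raise InvariantError("criteria limits must be > 0")


@dataclass(frozen=True)
class AcceptanceCriteria:
    """Per-(subclass 1–3, volume 1–3) acceptance limits for one liquid class."""

    cells: dict[tuple[int, int], CriteriaCell]

    def cell(self, subclass_idx: int, volume_idx: int) -> CriteriaCell:
        try:
            return self.cells[(subclass_idx, volume_idx)]
        except KeyError:
            raise ConfigurationError(
                f"no acceptance criteria configured for subclass {subclass_idx}, "
                f"volume {volume_idx}"
            ) from None


# Printed acceptance limits per liquid class: (subclass, volume) -> (dev%, cv%).
# The serum row is the only fully specified one; gaps in other rows fall back
# to the serum value at the same position.
_BUILTIN_CRITERIA: dict[str, dict[tuple[int, int], tuple[float, float]]] = {
    "serum": {
        (1, 1): (15.0, 3.0),
        (1, 2): (10.0, 3.0),
        (1, 3): (8.0, 3.0),
        (2, 1): (7.0, 3.0),
        (2, 2): (2.0, 1.0),
        (2, 3): (1.0, 0.75),
        (3, 1): (1.0, 0.75),
        (3, 2): (0.5, 0.75),
        (3, 3): (0.5, 0.75),
    },
    "DMSO": {
        (2, 1): (10.0, 3.0),
        (2, 2): (4.0, 1.0),
        (2, 3): (2.0, 0.75),
    },
    "water": {
        (2, 1): (7.0, 3.0),
        (2, 2): (1.0, 1.0),
        (2, 3): (0.5, 0.75),
        (3, 1): (0.5, 0.75),
    },
}


def default_criteria(liquid_class: str = "serum") -> AcceptanceCriteria:
    """Built-in acceptance limits for *liquid_class*.

    Classes without a specified row of their own (and unspecified cells of
    partially specified rows) inherit the serum limits at the same
    (subclass, volume) position.
    """
    base = _BUILTIN_CRITERIA["serum"]
    row = _BUILTIN_CRITERIA.get(liquid_class, {})
    cells = {
        key: CriteriaCell(*row.get(key, base[key])) for key in base
    }
    return AcceptanceCriteria(cells=cells)


def load_criteria_csv(path: str | Path, liquid_class: str) -> AcceptanceCriteria:
    """Load acceptance limits for *liquid_class* from a criteria CSV.

    Expected columns: ``liquid_class, subclass, volume_index,
    max_abs_dev_pct, max_cv_pct``.  Cells absent from the file fall back to
    the built-in serum limits.
    """
    overrides: dict[tuple[int, int], tuple[float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"liquid_class", "subclass", "volume_index", "max_abs_dev_pct", "max_cv_pct"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConfigurationError(
                f"{path}: criteria CSV must have columns {sorted(required)}"
            )
        for row in reader:
            if row["liquid_class"].strip() != liquid_class:
                continue
            try:
                key = (int(row["subclass"]), int(row["volume_index"]))
                overrides[key] = (
                    float(row["max_abs_dev_pct"]),
                    float(row["max_cv_pct"]),
                )
            except ValueError as exc:
                raise ConfigurationError(f"{path}: bad criteria row {row!r}") from exc
    base = _BUILTIN_CRITERIA["serum"]
    cells = {key: CriteriaCell(*overrides.get(key, base[key])) for key in base}
    return AcceptanceCriteria(cells=cells)


@dataclass(frozen=True)
class LimitCheck:
    """One limit comparison within an acceptance evaluation."""

    quantity: str  # "abs_dev" or "cv"
    value: float
    limit: float
    passed: bool


@dataclass(frozen=True)
class AcceptanceResult:
    """Outcome of gating one volume summary against its criteria cell."""

    passed: bool
    accuracy_passed: bool
    precision_passed: bool
    checks: tuple[LimitCheck, ...]


def evaluate_acceptance(
    summary: VolumeSummary,
    criteria: AcceptanceCriteria,
    subclass_idx: int,
    volume_idx: int,
) -> AcceptanceResult:
    """Gate a summary: pass iff ``|%DEV| ≤ max_abs_dev`` and ``%CV ≤ max_cv``.

    Both comparisons are inclusive (a value exactly at the limit passes).

    Raises
    ------
    ConfigurationError
        If no criteria cell exists for the (subclass, volume) position.
    """
    if not (1 <= subclass_idx <= 3 and 1 <= volume_idx <= 3):
        raise ConfigurationError(
            f"subclass/volume indices must be in 1–3, got ({subclass_idx}, {volume_idx})"
        )
    cell = criteria.cell(subclass_idx, volume_idx)
    dev_check = LimitCheck(
        "abs_dev", abs(summary.pct_dev), cell.max_abs_dev,
        abs(summary.pct_dev) <= cell.max_abs_dev,
    )
    cv_check = LimitCheck("cv", summary.pct_cv, cell.max_cv, summary.pct_cv <= cell.max_cv)
    return AcceptanceResult(
        passed=dev_check.passed and cv_check.passed,
        accuracy_passed=dev_check.passed,
        precision_passed=cv_check.passed,
        checks=(dev_check, cv_check),
    )
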