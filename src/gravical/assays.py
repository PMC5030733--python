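"""Adjuvant assay analytics: Langmuir adsorption capacity, kinetic surface
phosphophilicity, and plate reproducibility statistics.

**Langmuir adsorption capacity.**  For a protein adsorbing onto an aluminum
adjuvant, the Langmuir isotherm ``q = Cmax·K·c / (1 + K·c)`` (``c``:
equilibrium protein concentration in the supernatant, µg/mL; ``q``: mg
protein adsorbed per mg adjuvant; ``K``: affinity, mL/µg) linearizes to

    c / q = c / Cmax + 1 / (K·Cmax)

so an OLS regression of ``y = c/q`` on ``x = c`` has slope ``1/Cmax``: the
adsorption capacity is the inverse slope.  Dimensionally, ``x`` is µg/mL and
``y`` is (µg/mL)/(mg/mg), so the slope is (mg/mg)⁻¹ and ``1/slope`` carries
mg protein per mg adjuvant.  A fit is accepted only when R² > 0.99.

**Kinetic surface phosphophilicity.**  Free surface hydroxyl groups of
aluminum hydroxide catalyze hydrolysis of a fluorogenic phosphate substrate
(DiFMUP); fluorescence grows linearly in time over the monitored hour.  The
catalytic rate is the OLS slope of fluorescence vs time minus the background
hydrolysis rate (substrate without adjuvant); the trace must satisfy
R² > 0.99.  Rates are reported relative to a raw-material reference (≡ 1).

**Plate statistics.**  Intra- and inter-run reproducibility of plate-format
measurements (capacities, rates) as per-group and pooled mean/SD/%CV with
sample (n−1) statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gravical.errors import GravicalError, InvariantError

R2_GATE = 0.99


# ---------------------------------------------------------------------------
# Plate-reader OD corrections
# ---------------------------------------------------------------------------


def beta_casein_concentration(
    a280: float,
    a320: float,
    a975: float,
    a900: float,
    buffer_a280: float,
    std_slope: float,
    ref_nir: float,
) -> float:
    """Protein concentration (µg/mL) from plate-reader optical densities.

    Light scattering is removed by subtracting the 320 nm reading from the
    280 nm reading; the buffer blank is subtracted as well.  The well path
    length is normalized via the water near-infrared absorption peak: the
    975 nm − 900 nm difference, relative to ``ref_nir`` (the same difference
    for a 1 cm path), scales the corrected absorbance to unit path length.
    Division by the standard-curve slope (OD per µg/mL) yields concentration.

    Raises
    ------
    InvariantError
        If ``std_slope`` or ``ref_nir`` is non-positive, or the NIR
        difference is non-positive (no measurable path length).
    """
    if std_slope <= 0:
        raise InvariantError(f"standard-curve slope must be > 0, got {std_slope}")
    if ref_nir <= 0:
        raise InvariantError(f"reference NIR absorbance must be > 0, got {ref_nir}")
    nir = a975 - a900
    if nir <= 0:
        raise InvariantError(
            f"a975 − a900 must be > 0 for path-length correction, got {nir}"
        )
    corrected = (a280 - a320 - buffer_a280) * ref_nir / nir
    return corrected / std_slope


# ---------------------------------------------------------------------------
# Langmuir isotherm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsothermPoint:
    """One adsorption-isotherm point: supernatant concentration and uptake."""

    c_eq: float  # µg/mL remaining in supernatant
    q_ads: float  # mg adsorbed per mg adjuvant

    def __post_init__(self) -> None:
        if self.c_eq < 0:
            raise InvariantError(f"c_eq must be >= 0, got {self.c_eq}")
        if self.q_ads <= 0:
            raise InvariantError(f"q_ads must be > 0 for linearization, got {self.q_ads}")


@dataclass(frozen=True)
class LangmuirFit:
    """Linearized Langmuir regression: Cmax = 1/slope, gated on R² > 0.99."""

    cmax: float  # mg/mg
    slope: float
    intercept: float
    r2: float
    valid: bool  # r2 > R2_GATE


def langmuir_linearize(points: Sequence[IsothermPoint]) -> tuple[np.ndarray, np.ndarray]:
    """Linearized coordinates: ``x = c_eq``, ``y = c_eq / q_ads``."""
    x = np.array([p.c_eq for p in points], dtype=float)
    y = np.array([p.c_eq / p.q_ads for p in points], dtype=float)
    return x, y


def langmuir_fit(points: Sequence[IsothermPoint]) -> LangmuirFit:
    """OLS fit of the linearized isotherm; adsorption capacity = 1/slope.

    Raises
    ------
    InvariantError
        On fewer than three points or a non-positive fitted slope (which
        would imply no finite capacity).
    """
    if len(points) < 3:
        raise InvariantError(f"Langmuir fit needs >= 3 points, got {len(points)}")
    x, y = langmuir_linearize(points)
    res = stats.linregress(x, y)
    slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    if slope <= 0:
        raise InvariantError(f"non-positive Langmuir slope {slope:.4g}: no finite capacity")
    return LangmuirFit(
        cmax=1.0 / slope,
        slope=slope,
        intercept=intercept,
        r2=r2,
        valid=r2 > R2_GATE,
    )


def generate_isotherm(
    cmax: float,
    k: float,
    c_eq: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[IsothermPoint]:
    """Synthetic isotherm from the Langmuir forward model.

    ``q = cmax·k·c / (1 + k·c)``, with optional Gaussian noise of absolute
    SD *noise_sd* (mg/mg) on ``q``.  *rng* may be a Generator or a seed.
    """
    if cmax <= 0 or k <= 0:
        raise InvariantError("cmax and k must be > 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    points = []
    for c in c_eq:
        q = cmax * k * c / (1.0 + k * c)
        if noise_sd > 0:
            q += gen.normal(0.0, noise_sd)
        points.append(IsothermPoint(c_eq=float(c), q_ads=float(q)))
    return points


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticTrace:
    """A fluorescence time course with an associated background rate."""

    times: tuple[float, ...]  # min
    fluorescence: tuple[float, ...]  # arbitrary units
    background_rate: float = 0.0  # units/min

    def __init__(
        self,
        times: Sequence[float],
        fluorescence: Sequence[float],
        background_rate: float = 0.0,
    ):
        t = tuple(float(v) for v in times)
        f = tuple(float(v) for v in fluorescence)
        if len(t) != len(f):
            raise InvariantError(f"times and fluorescence differ: {len(t)} vs {len(f)}")
        if len(t) < 3:
            raise InvariantError(f"kinetic trace needs >= 3 points, got {len(t)}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InvariantError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "background_rate", float(background_rate))


@dataclass(frozen=True)
class KineticFit:
    """Background-subtracted catalytic rate with its regression quality."""

    rate: float  # units/min, background subtracted
    r2: float
    valid: bool  # r2 > R2_GATE


def kinetic_rate(trace: KineticTrace) -> KineticFit:
    """Catalytic rate: OLS slope of fluorescence vs time minus background."""
    res = stats.linregress(trace.times, trace.fluorescence)
    r2 = float(res.rvalue**2)
    return KineticFit(
        rate=float(res.slope) - trace.background_rate,
        r2=r2,
        valid=r2 > R2_GATE,
    )


def relative_phosphophilicity(rate: float, reference_rate: float) -> float:
    """Catalytic rate relative to the raw-material reference (reference ≡ 1).

    Raises
    ------
    InvariantError
        If the reference rate is non-positive.
    """
    if reference_rate <= 0:
        raise InvariantError(f"reference rate must be > 0, got {reference_rate}")
    return rate / reference_rate


# ---------------------------------------------------------------------------
# Plate statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateMatrix:
    """A labeled rectangular plate of scalar measurements."""

    name: str
    data: pd.DataFrame  # index = row labels, columns = column labels

    def __post_init__(self) -> None:
        if self.data.empty:
            raise InvariantError(f"plate {self.name!r} is empty")
        if self.data.isna().any().any():
            raise InvariantError(f"plate {self.name!r} is ragged or has missing cells")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise InvariantError(f"plate {self.name!r} has non-numeric cells")


def read_plate_csv(path: str | Path, name: str | None = None) -> PlateMatrix:
    """Read a plate CSV: header of column labels, first column of row labels."""
    df = pd.read_csv(path, index_col=0)
    return PlateMatrix(name=name or Path(path).stem, data=df)


def read_isotherm_csv(path: str | Path) -> list[IsothermPoint]:
    """Read an isotherm CSV with columns ``c_eq`` and ``q_ads``."""
    df = pd.read_csv(path)
    if not {"c_eq", "q_ads"}.issubset(df.columns):
        raise GravicalError(f"{path}: isotherm CSV needs columns c_eq, q_ads")
    return [IsothermPoint(float(r.c_eq), float(r.q_ads)) for r in df.itertuples()]


def read_kinetic_csv(path: str | Path, background_rate: float = 0.0) -> KineticTrace:
    """Read a kinetic CSV with columns ``time_min`` and ``fluorescence``."""
    df = pd.read_csv(path)
    if not {"time_min", "fluorescence"}.issubset(df.columns):
        raise GravicalError(f"{path}: kinetic CSV needs columns time_min, fluorescence")
    return KineticTrace(df["time_min"].tolist(), df["fluorescence"].tolist(), background_rate)


def _group_stats(name: str, values: np.ndarray) -> dict:
    if values.size < 2:
        raise InvariantError(f"group {name!r} has fewer than 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return {
        "group": name,
        "n": int(values.size),
        "mean": mean,
        "sd": sd,
        "cv_pct": sd / mean * 100.0 if mean != 0 else np.nan,
    }


def plate_statistics(
    plates: Sequence[PlateMatrix],
    group_by: Literal["plate", "row", "column"] = "plate",
) -> pd.DataFrame:
    """Per-group and pooled mean/SD/%CV of one or more plates.

    ``group_by="plate"`` summarizes each plate over all its wells (intra-run
    statistics); ``"row"`` / ``"column"`` group by the shared row or column
    labels across plates.  A final ``pooled`` row summarizes every value of
    every plate (inter-run statistics).  Sample statistics (n−1) throughout.
    """
    if not plates:
        raise InvariantError("no plates given")
    rows: list[dict] = []
    if group_by == "plate":
        for plate in plates:
            rows.append(_group_stats(plate.name, plate.data.to_numpy().ravel()))
    elif group_by == "row":
        for label in plates[0].data.index:
            vals = np.concatenate(
                [p.data.loc[label].to_numpy(dtype=float).ravel() for p in plates]
            )
            rows.append(_group_stats(str(label), vals))
    elif group_by == "column":
        for label in plates[0].data.columns:
            vals = np.concatenate(
                [p.data[label].to_numpy(dtype=float).ravel() for p in plates]
            )
            rows.append(_group_stats(str(label), vals))
    else:
        raise InvariantError(f"group_by must be plate|row|column, got {group_by!r}")
    pooled = np.concatenate([p.data.to_numpy(dtype=float).ravel() for p in plates])
    rows.append(_group_stats("pooled", pooled))
    return pd.DataFrame(rows).set_index("group")
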