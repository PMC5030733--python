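"""Virtual 8-tip liquid handler.

The simulator is the synthetic stand-in for hardware that makes the
calibration loop testable.  Its latent physics is the linear response the
factor/offset calibration implicitly inverts: a commanded plunger volume
``c`` delivers ``p·c + q`` µL, plus an additive per-tip bias and Gaussian
noise whose SD combines a proportional term (``noise_cv × volume``) with an
absolute floor (``noise_floor_sd``, dominating below ~100 µL) in quadrature.
Delivered masses pass through the balance model (tare before every dispense,
finite resolution), so measured volumes inherit balance quantization.

The default noise level (``noise_cv = 0.004``, ``noise_floor_sd = 0.4`` µL)
is reverse-engineered from the precision a well-maintained fixed-tip
workstation shows in practice — %CV around 0.2–0.5% at hundreds of µL and a
few percent at 3–16 µL — since no direct noise measurement is available; it
is a documented, overridable default, not a measured constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gravical.errors import ConfigurationError, InvariantError, RangeError
from gravical.gravimetry import (
    BalanceState,
    EnvironmentRecord,
    LiquidSpec,
    balance_read,
    mass_from_volume,
    tare,
    volume_from_mass,
)
from gravical.liquidclass import LiquidClass, Subclass, select_subclass

N_TIPS = 8


@dataclass(frozen=True)
class TrueResponse:
    """True delivered volume as a linear function of commanded volume."""

    p: float = 1.0  # slope, dimensionless
    q: float = 0.0  # intercept, µL

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise InvariantError(f"response slope p must be > 0, got {self.p}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One gravimetric dispense: command, mass, and the derived volume."""

    tip: int
    target_volume: float  # V_O, µL
    commanded_volume: float  # µL
    mass: float  # mg, as read from the balance
    density: float  # g/mL
    measured_volume: float  # V_A = mass / density, µL
    environment: EnvironmentRecord | None = None


@dataclass
class VirtualInstrument:
    """An 8-channel pipettor with linear true response, tip bias and noise.

    Parameters
    ----------
    response:
        Latent linear response (slope ``p``, intercept ``q`` µL).
    tip_bias:
        Eight additive per-tip volume offsets (µL).
    noise_cv:
        Proportional component of the dispense noise (SD / volume).
    noise_floor_sd:
        Absolute noise component (µL), combined in quadrature.
    evaporation_rate:
        Mass loss (mg/s) between dispense and balance settling; off by
        default.  ``settle_time`` is the settling interval in seconds.
    balance:
        Balance model used for every weighing.
    rng_seed:
        Seed of the instrument's single shared random stream.
    """

    response: TrueResponse = field(default_factory=TrueResponse)
    tip_bias: tuple[float, ...] = (0.0,) * N_TIPS
    noise_cv: float = 0.004
    noise_floor_sd: float = 0.4
    evaporation_rate: float = 0.0
    settle_time: float = 5.0
    balance: BalanceState = field(default_factory=BalanceState)
    rng_seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.tip_bias = tuple(float(b) for b in self.tip_bias)
        if len(self.tip_bias) != N_TIPS:
            raise InvariantError(f"tip_bias must have exactly {N_TIPS} entries")
        if self.noise_cv < 0 or self.noise_floor_sd < 0:
            raise InvariantError("noise_cv and noise_floor_sd must be >= 0")
        if self.evaporation_rate < 0 or self.settle_time < 0:
            raise InvariantError("evaporation_rate and settle_time must be >= 0")
        self._rng = np.random.default_rng(self.rng_seed)


def commanded_volume(target: float, factor: float, offset: float) -> float:
    """Plunger volume commanded for a target: ``factor × target + offset``.

    Raises
    ------
    InvariantError
        If *factor* is non-positive or the command comes out ≤ 0
        (a non-physical instruction).
    """
    if factor <= 0:
        raise InvariantError(f"factor must be > 0, got {factor}")
    cmd = factor * target + offset
    if cmd <= 0:
        raise InvariantError(
            f"commanded volume {cmd:.4g} µL (target {target}, factor {factor}, "
            f"offset {offset}) is non-physical"
        )
    return cmd


def simulate_dispense(sim: VirtualInstrument, tip: int, commanded: float) -> float:
    """True volume (µL) delivered by *tip* for a commanded plunger volume.

    Deterministic part: ``p × commanded + q + tip_bias[tip]``.  Noise SD is
    ``sqrt((noise_cv × V)² + noise_floor_sd²)`` with ``V`` the deterministic
    delivered volume; the result is clamped at 0.
    """
    if not 1 <= tip <= N_TIPS:
        raise InvariantError(f"tip must be in 1–{N_TIPS}, got {tip}")
    if commanded <= 0:
        raise InvariantError(f"commanded volume must be > 0, got {commanded}")
    v = sim.response.p * commanded + sim.response.q + sim.tip_bias[tip - 1]
    sd = math.hypot(sim.noise_cv * v, sim.noise_floor_sd)
    if sd > 0:
        v += sim._rng.normal(0.0, sd)
    return max(v, 0.0)


def _weigh_dispense(
    sim: VirtualInstrument,
    tip: int,
    target: float,
    cmd: float,
    liquid: LiquidSpec,
    environment: EnvironmentRecord | None,
) -> MeasurementRecord:
    """Dispense once, weigh on a freshly tared balance, derive the volume."""
    tare(sim.balance, 0.0)  # vessel exchanged / balance reset between dispenses
    delivered = simulate_dispense(sim, tip, cmd)
    true_mass = mass_from_volume(delivered, liquid)
    true_mass = max(true_mass - sim.evaporation_rate * sim.settle_time, 0.0)
    mass = max(balance_read(sim.balance, true_mass), 0.0)
    return MeasurementRecord(
        tip=tip,
        target_volume=target,
        commanded_volume=cmd,
        mass=mass,
        density=liquid.density,
        measured_volume=volume_from_mass(mass, liquid),
        environment=environment,
    )


def measure_volumes(
    sim: VirtualInstrument,
    sc: Subclass,
    liquid: LiquidSpec,
    volumes: list[float],
    replicates_per_tip: int = 1,
    environment: EnvironmentRecord | None = None,
) -> list[MeasurementRecord]:
    """Gravimetric series for one subclass: each volume, each tip, each replicate.

    The subclass's factor/offset compute the command; dispensing proceeds one
    tip at a time (tips 1–8 within each replicate), the balance tared before
    every dispense.
    """
    if replicates_per_tip < 1:
        raise InvariantError("replicates_per_tip must be >= 1")
    records: list[MeasurementRecord] = []
    for target in volumes:
        cmd = commanded_volume(target, sc.factor, sc.offset)
        for _rep in range(replicates_per_tip):
            for tip in range(1, N_TIPS + 1):
                records.append(_weigh_dispense(sim, tip, target, cmd, liquid, environment))
    return records


def run_protocol(
    sim: VirtualInstrument,
    lc: LiquidClass,
    liquid: LiquidSpec,
    volumes: list[float],
    replicates_per_tip: int = 1,
    environment: EnvironmentRecord | None = None,
) -> list[MeasurementRecord]:
    """Full gravimetric protocol against a liquid class.

    For each target volume the covering subclass is selected and its
    factor/offset applied; the result holds
    ``len(volumes) × 8 × replicates_per_tip`` records.

    Raises
    ------
    RangeError
        If any volume is outside the class coverage.
    """
    records: list[MeasurementRecord] = []
    for target in volumes:
        sc = select_subclass(lc, target)
        records.extend(
            measure_volumes(sim, sc, liquid, [target], replicates_per_tip, environment)
        )
    return records


# ---------------------------------------------------------------------------
# key = value configuration files
# ---------------------------------------------------------------------------

_FLOAT_KEYS = {
    "p",
    "q",
    "noise_cv",
    "noise_floor_sd",
    "evaporation_rate",
    "settle_time",
    "balance_resolution",
    "balance_noise_sd",
}


def load_instrument_config(path: str | Path, seed: int | None = None) -> VirtualInstrument:
    """Build a :class:`VirtualInstrument` from a ``key = value`` config file.

    Recognized keys: ``p``, ``q``, ``tip_bias`` (eight comma-separated µL
    values), ``noise_cv``, ``noise_floor_sd``, ``evaporation_rate``,
    ``settle_time``, ``balance_resolution``, ``balance_noise_sd``, ``seed``.
    Lines starting with ``#`` are comments.  A *seed* argument overrides the
    file's ``seed`` key.
    """
    values: dict[str, object] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _FLOAT_KEYS and key not in ("seed", "tip_bias"):
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            if key in _FLOAT_KEYS:
                values[key] = float(val)
            elif key == "seed":
                values[key] = int(val)
            else:
                values[key] = tuple(float(v) for v in val.split(","))
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: bad value for {key!r}: {val!r}") from exc

    rng_seed = seed if seed is not None else int(values.get("seed", 0))
    balance = BalanceState(
        resolution=float(values.get("balance_resolution", 0.1)),
        noise_sd=float(values.get("balance_noise_sd", 0.0)),
        rng_seed=rng_seed + 1,
    )
    return VirtualInstrument(
        response=TrueResponse(
            p=float(values.get("p", 1.0)), q=float(values.get("q", 0.0))
        ),
        tip_bias=values.get("tip_bias", (0.0,) * N_TIPS),
        noise_cv=float(values.get("noise_cv", 0.004)),
        noise_floor_sd=float(values.get("noise_floor_sd", 0.4)),
        evaporation_rate=float(values.get("evaporation_rate", 0.0)),
        settle_time=float(values.get("settle_time", 5.0)),
        balance=balance,
        rng_seed=rng_seed,
    )
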