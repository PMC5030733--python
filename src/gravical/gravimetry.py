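"""Mass ↔ volume conversion and an analytical-balance abstraction.

Gravimetric volume verification rests on one identity: since
1 g/mL = 1 mg/µL, a dispensed mass in mg divided by the liquid density in
g/mL is the dispensed volume in µL.  The balance model adds the two
behaviours of a real analytical balance that matter for calibration at small
volumes: finite readability (readings quantized to the instrument
resolution, 0.1 mg by default) and tare semantics (readings are relative to
the load present at the last tare).  Optional Gaussian read noise is seeded
for reproducibility.

No air-buoyancy correction is applied; evaporation is handled (optionally)
by the virtual instrument, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gravical.errors import InvariantError

log = logging.getLogger("gravical.balance")


@dataclass(frozen=True)
class LiquidSpec:
    """A pipetted liquid: name, density ρ (g/mL) and optional temperature (°C)."""

    name: str
    density: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvariantError(f"density must be > 0 g/mL, got {self.density}")


@dataclass(frozen=True)
class EnvironmentRecord:
    """Ambient conditions logged alongside a measurement (informational only)."""

    temperature: float | None = None  # °C
    humidity: float | None = None  # %RH
    pressure: float | None = None  # hPa

    def __post_init__(self) -> None:
        if self.temperature is not None and not -40 <= self.temperature <= 80:
            raise InvariantError(f"implausible temperature {self.temperature} °C")
        if self.humidity is not None and not 0 <= self.humidity <= 100:
            raise InvariantError(f"implausible humidity {self.humidity} %RH")
        if self.pressure is not None and not 300 <= self.pressure <= 1200:
            raise InvariantError(f"implausible pressure {self.pressure} hPa")


@dataclass
class BalanceState:
    """An analytical balance with finite resolution, read noise and a tare.

    Parameters
    ----------
    resolution:
        Readability in mg; readings are rounded to the nearest multiple.
    noise_sd:
        Standard deviation (mg) of Gaussian noise added before rounding.
        Zero (the default) makes reads deterministic.
    tare_offset:
        True mass (mg) on the pan at the last tare; reads are net of it.
    rng_seed:
        Seed of the balance's private random stream.
    """

    resolution: float = 0.1
    noise_sd: float = 0.0
    tare_offset: float = 0.0
    rng_seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise InvariantError(f"resolution must be > 0 mg, got {self.resolution}")
        if self.noise_sd < 0:
            raise InvariantError(f"noise_sd must be >= 0 mg, got {self.noise_sd}")
        self._rng = np.random.default_rng(self.rng_seed)


def volume_from_mass(mass: float, liquid: LiquidSpec) -> float:
    """Convert a dispensed mass (mg) to a volume (µL) via the liquid density.

    Raises
    ------
    InvariantError
        If *mass* is negative.
    """
    if mass < 0:
        raise InvariantError(f"mass must be >= 0 mg, got {mass}")
    return mass / liquid.density


def mass_from_volume(volume: float, liquid: LiquidSpec) -> float:
    """Convert a volume (µL) to the mass (mg) it weighs at the liquid density."""
    if volume < 0:
        raise InvariantError(f"volume must be >= 0 µL, got {volume}")
    return volume * liquid.density


def balance_read(state: BalanceState, true_mass: float) -> float:
    """Read the balance with *true_mass* (mg) on the pan.

    Returns the net mass (true mass minus tare, plus read noise) rounded to
    the balance resolution.  With ``noise_sd = 0`` the read is deterministic.
    """
    net = true_mass - state.tare_offset
    if state.noise_sd > 0:
        net += state._rng.normal(0.0, state.noise_sd)
    reading = round(net / state.resolution) * state.resolution
    log.debug("balance read: %.4f mg", reading)
    return reading


def tare(state: BalanceState, current_true_mass: float) -> BalanceState:
    """Tare (zero) the balance at the current load.

    Subsequent reads of the same true mass return 0 (up to noise and
    rounding).  The state is updated in place and returned, so the call can
    be used either imperatively or functionally; taring twice at the same
    load is idempotent.
    """
    state.tare_offset = current_true_mass
    return state
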