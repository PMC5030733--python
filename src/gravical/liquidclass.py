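"""Liquid-class data model and XML persistence.

A *liquid class* bundles everything an automated pipettor needs to know to
handle one liquid: per-volume-range *subclasses*, each carrying aspiration /
dispense parameters (speeds, delay, air gaps) and the two calibration
constants of the command transform ``Y = a·X + b`` — *factor* ``a`` (slope)
and *offset* ``b`` (intercept, µL) — that map a target volume ``X`` to the
plunger volume ``Y`` actually commanded.

Volume ranges follow a half-open convention ``[vmin, vmax)``: a shared
endpoint (e.g. 15.01 µL) belongs to the *upper* subclass, which makes
subclass selection unique on contiguous ranges.

The module ships the five predefined free-dispense classes of a standard
fixed-tip worktable (water, serum, DMSO, ethanol, liquid system) and a small
documented XML dialect for persisting calibrated classes.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from gravical.errors import InvariantError, RangeError, XMLFormatError

#: Span of target volumes (µL) every liquid class must cover.
COVERAGE_MIN = 3.00
COVERAGE_MAX = 1000.01


@dataclass(frozen=True)
class PipettingParams:
    """Aspiration and dispense settings of one subclass.

    Air gaps separate liquids inside the tip during aspiration: the system
    trailing air gap (``stag``) isolates the system fluid from the sample,
    the leading air gap (``lag``) sits between the two, and the trailing air
    gap (``tag``) is drawn after the sample at the tip opening.

    Units: speeds in µL/s, ``delay`` in ms, air gaps in µL.
    """

    aspirate_speed: float
    delay: float
    stag: float
    lag: float
    tag: float
    dispense_speed: float = 600.0
    breakoff_speed: float = 150.0

    def __post_init__(self) -> None:
        for name in ("aspirate_speed", "dispense_speed", "breakoff_speed"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("delay", "stag", "lag", "tag"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class Subclass:
    """One volume range of a liquid class with its calibration constants."""

    vmin: float
    vmax: float
    params: PipettingParams
    factor: float
    offset: float

    def __post_init__(self) -> None:
        if not 0 < self.vmin < self.vmax:
            raise InvariantError(
                f"subclass range must satisfy 0 < vmin < vmax, got [{self.vmin}, {self.vmax})"
            )
        if self.factor <= 0:
            raise InvariantError(f"factor must be > 0, got {self.factor}")

    def contains(self, volume: float) -> bool:
        """Whether *volume* falls in the half-open range [vmin, vmax)."""
        return self.vmin <= volume < self.vmax

    def with_calibration(self, factor: float, offset: float) -> "Subclass":
        """Copy of this subclass with new factor/offset."""
        return replace(self, factor=factor, offset=offset)


@dataclass(frozen=True)
class LiquidClass:
    """A named, ordered set of contiguous subclasses covering 3–1000 µL."""

    name: str
    subclasses: tuple[Subclass, ...]

    def __init__(self, name: str, subclasses: Sequence[Subclass]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "subclasses", tuple(subclasses))
        self._validate()

    def _validate(self) -> None:
        if not self.name:
            raise InvariantError("liquid class needs a non-empty name")
        scs = self.subclasses
        if not scs:
            raise InvariantError(f"liquid class {self.name!r} has no subclasses")
        for lower, upper in zip(scs, scs[1:]):
            if not math.isclose(lower.vmax, upper.vmin, abs_tol=1e-9):
                raise InvariantError(
                    f"liquid class {self.name!r}: subclass ranges must be sorted and "
                    f"contiguous, but [{lower.vmin}, {lower.vmax}) is followed by "
                    f"[{upper.vmin}, {upper.vmax})"
                )
        if scs[0].vmin > COVERAGE_MIN + 1e-9 or scs[-1].vmax < COVERAGE_MAX - 1e-9:
            raise InvariantError(
                f"liquid class {self.name!r}: subclasses cover "
                f"[{scs[0].vmin}, {scs[-1].vmax}) but must cover "
                f"[{COVERAGE_MIN}, {COVERAGE_MAX})"
            )

    def subclass_index(self, sc: Subclass) -> int:
        """1-based index of *sc* within this class (matched by volume range)."""
        for i, candidate in enumerate(self.subclasses, start=1):
            if math.isclose(candidate.vmin, sc.vmin) and math.isclose(candidate.vmax, sc.vmax):
                return i
        raise InvariantError(f"subclass [{sc.vmin}, {sc.vmax}) not part of class {self.name!r}")

    def with_subclass(self, index: int, sc: Subclass) -> "LiquidClass":
        """Copy of this class with the 1-based *index* subclass replaced."""
        scs = list(self.subclasses)
        scs[index - 1] = sc
        return LiquidClass(self.name, scs)


def builtin_default_classes() -> list[LiquidClass]:
    """The five predefined free-dispense liquid classes of a fixed-tip worktable.

    Factors/offsets and aspiration parameters are the vendor defaults for
    water, serum, DMSO, ethanol and the system liquid.  Dispense and
    break-off speeds are shared across all classes (600 and 150 µL/s).
    """

    def sc(vmin, vmax, asp, delay, stag, lag, tag, factor, offset):
        return Subclass(
            vmin=vmin,
            vmax=vmax,
            params=PipettingParams(
                aspirate_speed=asp, delay=delay, stag=stag, lag=lag, tag=tag
            ),
            factor=factor,
            offset=offset,
        )

    dmso = LiquidClass(
        "DMSO",
        [
            sc(3.00, 15.01, 20, 200, 10, 10, 5, 1.063, 0.10),
            sc(15.01, 200.01, 100, 200, 20, 0, 10, 1.100, -0.30),
            sc(200.01, 1000.01, 150, 300, 20, 0, 10, 1.002, 19.30),
        ],
    )
    water = LiquidClass(
        "water",
        [
            sc(3.00, 15.01, 20, 200, 10, 10, 5, 1.045, 0.20),
            sc(15.01, 500.01, 150, 200, 20, 0, 10, 1.042, -0.04),
            sc(500.01, 1000.01, 150, 200, 20, 0, 10, 1.000, 20.26),
        ],
    )
    serum = LiquidClass(
        "serum",
        [
            sc(3.00, 15.01, 20, 200, 10, 20, 10, 1.074, 0.30),
            sc(15.01, 300.01, 100, 200, 20, 0, 10, 1.060, 0.43),
            sc(300.01, 1000.01, 100, 200, 20, 0, 10, 1.007, 16.63),
        ],
    )
    ethanol = LiquidClass(
        "ethanol",
        [sc(3.00, 1000.01, 100, 200, 20, 0, 10, 1.063, 3.4)],
    )
    liquid_system = LiquidClass(
        "liquid-system",
        [sc(3.00, 1000.01, 150, 200, 0, 0, 10, 1.000, 0.0)],
    )
    return [water, serum, dmso, ethanol, liquid_system]


def select_subclass(lc: LiquidClass, volume: float) -> Subclass:
    """Return the unique subclass of *lc* whose [vmin, vmax) contains *volume*.

    Raises
    ------
    RangeError
        If *volume* falls outside the class coverage.
    """
    for sc in lc.subclasses:
        if sc.contains(volume):
            return sc
    raise RangeError(
        f"volume {volume} µL is outside liquid class {lc.name!r} "
        f"(valid span [{lc.subclasses[0].vmin}, {lc.subclasses[-1].vmax}) µL)"
    )


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def derive_test_volumes(sc: Subclass, cap: float = 900.0) -> tuple[int, int, int]:
    """Minimum, intermediate and maximum calibration volumes for a subclass.

    ``v1 = ceil(vmin)``; ``v3 = min(floor(vmax), cap)``; ``v2`` is the
    half-up-rounded midpoint.  The default 900 µL cap keeps the maximum test
    volume inside what a 1 mL syringe can deliver together with its air gaps.

    Raises
    ------
    InvariantError
        If the capped range degenerates (``v1 >= v3``).
    """
    v1 = math.ceil(sc.vmin - 1e-9)
    v3 = min(math.floor(sc.vmax + 1e-9), int(cap))
    if v1 >= v3:
        raise InvariantError(
            f"subclass range [{sc.vmin}, {sc.vmax}) with cap {cap} leaves no "
            f"usable test volumes (v1={v1}, v3={v3})"
        )
    v2 = _round_half_up((v1 + v3) / 2)
    return v1, v2, v3


# ---------------------------------------------------------------------------
# XML persistence
#
# Dialect: root <liquid_classes>; one <liquid_class name="..."> per class;
# one <subclass vmin vmax factor offset> per range, containing
# <aspiration aspirate_speed delay stag lag tag/> and
# <dispense dispense_speed breakoff_speed/>.  Volumes µL, speeds µL/s,
# delay ms.  Numbers are serialized with repr() so they round-trip exactly.
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def _require_attr(elem: ET.Element, name: str, path: str) -> float:
    raw = elem.get(name)
    if raw is None:
        raise XMLFormatError(f"{path}: missing required attribute {name!r}")
    try:
        return float(raw)
    except ValueError as exc:
        raise XMLFormatError(f"{path}@{name}: not a number: {raw!r}") from exc


def _require_child(elem: ET.Element, tag: str, path: str) -> ET.Element:
    child = elem.find(tag)
    if child is None:
        raise XMLFormatError(f"{path}: missing required child element <{tag}>")
    return child


def write_liquid_class_xml(classes: Iterable[LiquidClass], path: str | Path) -> None:
    """Serialize *classes* to the documented XML dialect at *path*."""
    root = ET.Element("liquid_classes")
    for lc in classes:
        lc_el = ET.SubElement(root, "liquid_class", name=lc.name)
        for sc in lc.subclasses:
            sc_el = ET.SubElement(
                lc_el,
                "subclass",
                vmin=_fmt(sc.vmin),
                vmax=_fmt(sc.vmax),
                factor=_fmt(sc.factor),
                offset=_fmt(sc.offset),
            )
            ET.SubElement(
                sc_el,
                "aspiration",
                aspirate_speed=_fmt(sc.params.aspirate_speed),
                delay=_fmt(sc.params.delay),
                stag=_fmt(sc.params.stag),
                lag=_fmt(sc.params.lag),
                tag=_fmt(sc.params.tag),
            )
            ET.SubElement(
                sc_el,
                "dispense",
                dispense_speed=_fmt(sc.params.dispense_speed),
                breakoff_speed=_fmt(sc.params.breakoff_speed),
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def read_liquid_class_xml(path: str | Path) -> list[LiquidClass]:
    """Parse a liquid-class XML document and validate all invariants.

    Raises
    ------
    XMLFormatError
        On malformed XML or schema violations (message names the element).
    InvariantError
        When parsed values violate the data-model invariants.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise XMLFormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "liquid_classes":
        raise XMLFormatError(f"{path}: root element must be <liquid_classes>, got <{root.tag}>")

    classes: list[LiquidClass] = []
    for i, lc_el in enumerate(root):
        lc_path = f"liquid_classes/liquid_class[{i + 1}]"
        if lc_el.tag != "liquid_class":
            raise XMLFormatError(f"{lc_path}: unexpected element <{lc_el.tag}>")
        name = lc_el.get("name")
        if not name:
            raise XMLFormatError(f"{lc_path}: missing required attribute 'name'")
        subclasses = []
        for j, sc_el in enumerate(lc_el):
            sc_path = f"{lc_path}/subclass[{j + 1}]"
            if sc_el.tag != "subclass":
                raise XMLFormatError(f"{sc_path}: unexpected element <{sc_el.tag}>")
            asp = _require_child(sc_el, "aspiration", sc_path)
            dsp = _require_child(sc_el, "dispense", sc_path)
            params = PipettingParams(
                aspirate_speed=_require_attr(asp, "aspirate_speed", sc_path + "/aspiration"),
                delay=_require_attr(asp, "delay", sc_path + "/aspiration"),
                stag=_require_attr(asp, "stag", sc_path + "/aspiration"),
                lag=_require_attr(asp, "lag", sc_path + "/aspiration"),
                tag=_require_attr(asp, "tag", sc_path + "/aspiration"),
                dispense_speed=_require_attr(dsp, "dispense_speed", sc_path + "/dispense"),
                breakoff_speed=_require_attr(dsp, "breakoff_speed", sc_path + "/dispense"),
            )
            subclasses.append(
                Subclass(
                    vmin=_require_attr(sc_el, "vmin", sc_path),
                    vmax=_require_attr(sc_el, "vmax", sc_path),
                    params=params,
                    factor=_require_attr(sc_el, "factor", sc_path),
                    offset=_require_attr(sc_el, "offset", sc_path),
                )
            )
        classes.append(LiquidClass(name, subclasses))
    return classes
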