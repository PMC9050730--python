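"""Resistor-network modelling of washers in series.

Both the pressure-driven flow and the AC electric field that triggers
droplet–washer coalescence distribute through the same channel network,
so each washing unit is modelled as a resistor ``R_wash`` (injection
plus removal channel in series) connected to its neighbours through the
wash-stream resistance ``R_H`` and waste-stream resistance ``R_L``.
Uniform, simultaneous operation of ``N`` washers requires the
inter-washer resistances to be negligible compared to the resistance
within a washer:

    N * (R_H + R_L) / R_wash < 0.01

evaluated independently for the hydraulic and electrical variants; a
device passes only when every supplied variant passes.

Hydraulic resistances use the exact rectangular-duct solution

    R = 12 mu L / (w h^3) * [1 - (192 h)/(pi^5 w)
        * sum_{n odd} tanh(n pi w / (2 h)) / n^5]^(-1)

with ``h`` the smaller cross-sectional dimension; the series is
truncated once terms fall below 1e-12 relative. Electrical resistance
of a conductivity-``sigma`` electrolyte column is ``R = L / (sigma w h)``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

__all__ = [
    "ChannelGeom",
    "ResistorNetwork",
    "DesignRuleReport",
    "channel_resistance",
    "washer_resistance",
    "design_rule",
    "evaluate_networks",
    "rectangular_duct_factor",
    "WATER_VISCOSITY_PA_S",
    "DEFAULT_THRESHOLD",
]

#: water-like dynamic viscosity, Pa*s (configuration default, not a constant of the model)
WATER_VISCOSITY_PA_S = 1e-3
#: default design-rule threshold; empirical, configurable per report
DEFAULT_THRESHOLD = 0.01

KINDS = ("hydraulic", "electrical")


@dataclasses.dataclass(frozen=True)
class ChannelGeom:
    """Rectangular channel geometry in micrometers.

    By convention ``width >= height``; a swapped pair is accepted with a
    warning (the duct solution is symmetric once ``h`` is taken as the
    smaller dimension).
    """

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"channel {name} must be positive")
        if self.width < self.height:
            warnings.warn(
                f"channel width {self.width} < height {self.height}; "
                "treating the larger dimension as the width",
                stacklevel=3,
            )


@dataclasses.dataclass(frozen=True)
class ResistorNetwork:
    """Resistance network of ``N`` identical washers in series."""

    R_wash: float
    R_H: float
    R_L: float
    N: int = 1
    kind: str = "hydraulic"
    R_inject: float | None = None
    R_remove: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.R_wash <= 0:
            raise ValueError("R_wash must be positive")
        for name in ("R_H", "R_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_components(
        cls, R_inject: float, R_remove: float, R_H: float, R_L: float,
        N: int = 1, kind: str = "hydraulic",
    ) -> "ResistorNetwork":
        return cls(
            R_wash=washer_resistance(R_inject, R_remove),
            R_H=R_H, R_L=R_L, N=N, kind=kind,
            R_inject=R_inject, R_remove=R_remove,
        )


@dataclasses.dataclass(frozen=True)
class DesignRuleReport:
    """Outcome of the serial-operation design rule for one network."""

    ratio: float
    passed: bool
    kind: str
    threshold: float


def rectangular_duct_factor(width: float, height: float, rtol: float = 1e-12,
                            max_terms: int | None = None) -> float:
    """Series correction factor of the exact rectangular-duct solution.

    Returns ``1 - (192 h)/(pi^5 w) * sum_{n odd} tanh(n pi w/(2 h))/n^5``
    with ``h = min(width, height)``. The sum is truncated once a term
    falls below ``rtol`` relative to the running total (or after
    ``max_terms`` odd terms when given, for oracle-style evaluation).
    """
    w, h = max(width, height), min(width, height)
    total = 0.0
    n = 1
    count = 0
    while True:
        term = math.tanh(n * math.pi * w / (2.0 * h)) / n**5
        total += term
        count += 1
        if max_terms is not None:
            if count >= max_terms:
                break
        elif term < rtol * total:
            break
        n += 2
    return 1.0 - (192.0 * h) / (math.pi**5 * w) * total


def channel_resistance(geom: ChannelGeom, transport: float, kind: str) -> float:
    """Resistance of one rectangular channel.

    ``transport`` is the dynamic viscosity (Pa*s) for ``kind="hydraulic"``
    (result in Pa*s/m^3) or the electrolyte conductivity (S/m) for
    ``kind="electrical"`` (result in ohm). Geometry is in micrometers.
    """
    if transport <= 0:
        raise ValueError("transport coefficient (viscosity or conductivity) must be positive")
    L = geom.length * 1e-6
    w = max(geom.width, geom.height) * 1e-6
    h = min(geom.width, geom.height) * 1e-6
    if kind == "hydraulic":
        return 12.0 * transport * L / (w * h**3) / rectangular_duct_factor(w, h)
    if kind == "electrical":
        return L / (transport * w * h)
    raise ValueError(f"unknown resistance kind {kind!r}; expected one of {KINDS}")


def washer_resistance(R_inject: float, R_remove: float) -> float:
    """Series composition of the washing path through one unit.

    The wash flow traverses the injection channel, the droplet and the
    removal channel; the intradroplet contribution is neglected, so
    ``R_wash = R_inject + R_remove``.
    """
    if R_inject < 0 or R_remove < 0:
        raise ValueError("component resistances must be non-negative")
    if R_inject == 0 and R_remove == 0:
        raise ValueError("at least one of R_inject, R_remove must be positive")
    return R_inject + R_remove


def design_rule(network: ResistorNetwork, threshold: float = DEFAULT_THRESHOLD) -> DesignRuleReport:
    """Evaluate ``N (R_H + R_L) / R_wash < threshold`` for one network."""
    if network.R_wash == 0:
        raise ValueError("R_wash must be positive to evaluate the design rule")
    ratio = network.N * (network.R_H + network.R_L) / network.R_wash
    return DesignRuleReport(
        ratio=ratio, passed=bool(ratio < threshold),
        kind=network.kind, threshold=threshold,
    )


def evaluate_networks(
    networks: list[ResistorNetwork], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[DesignRuleReport], bool]:
    """Evaluate the design rule per variant; overall pass requires all.

    Typically called with the hydraulic and electrical networks of one
    device, mirroring the requirement that both the fluidic and the
    electrical resistances satisfy the rule.
    """
    if not networks:
        raise ValueError("need at least one resistor network")
    reports = [design_rule(net, threshold) for net in networks]
    return reports, all(r.passed for r in reports)
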