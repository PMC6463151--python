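"""Dimensional scale analysis for embryonic-heart flows.

All simulations in this package are dimensionless (lengths in units where the
AV-canal width is 0.8, velocities in units of the peak inflow speed, density
1).  This module holds the dimensional numbers used to place a real embryonic
zebrafish ventricle on that dimensionless map, and the conversion block used
when reporting dimensional quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "reynolds_number",
    "dimensionless_frequency",
    "womersley_number",
    "ZEBRAFISH_4DPF",
    "ZebrafishScales",
]


def reynolds_number(rho: float, length: float, velocity: float, mu: float) -> float:
    """Re = rho * U * L / mu, the ratio of inertial to viscous forces."""
    if mu <= 0 or rho <= 0 or length <= 0:
        raise ValueError("rho, length and mu must be positive")
    return rho * length * velocity / mu


def dimensionless_frequency(length: float, frequency: float, velocity: float) -> float:
    """f~ = L f / U: beat frequency relative to the advective rate U/L."""
    if velocity <= 0 or length <= 0:
        raise ValueError("length and velocity must be positive")
    return length * frequency / velocity


def womersley_number(length: float, frequency: float, nu: float) -> float:
    """Wo = (L/2) sqrt(2 pi f / nu).

    Definition used here: half-width L/2 as the radius-like scale and the
    angular frequency 2 pi f.  Several variants circulate (full width, plain
    f); this one is stated explicitly wherever Wo is reported, and Wo is a
    diagnostic only -- nothing in the solver depends on it.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    return 0.5 * length * math.sqrt(2.0 * math.pi * frequency / nu)


@dataclass(frozen=True)
class ZebrafishScales:
    """Dimensional scales for a ~4 dpf embryonic zebrafish ventricle."""

    rho: float  # blood density, kg/m^3
    mu: float  # dynamic viscosity, kg/(m s)
    length: float  # ventricle width, m
    velocity: float  # characteristic blood speed, m/s
    frequency: float  # heart rate, beats/s

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    @property
    def reynolds(self) -> float:
        return reynolds_number(self.rho, self.length, self.velocity, self.mu)

    @property
    def f_nd(self) -> float:
        return dimensionless_frequency(self.length, self.frequency, self.velocity)

    @property
    def womersley(self) -> float:
        return womersley_number(self.length, self.frequency, self.nu)


#: Literature values for a 4 dpf wild-type zebrafish ventricle:
#: V = 0.75 cm/s, rho = 1025 kg/m^3, mu = 0.0015 kg/(m s), L = 208 um,
#: f = 3.95 beats/s.  Gives Re = 1.07 and f~ = 0.11.
ZEBRAFISH_4DPF = ZebrafishScales(
    rho=1025.0, mu=0.0015, length=208e-6, velocity=0.0075, frequency=3.95
)
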