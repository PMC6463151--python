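"""Closed-form flows and constructed fields used as independent test oracles.

Every numerical claim the solver and metrics modules make is checked against
one of these: Poiseuille channel flow (profiles and wall shear), the decaying
Taylor-Green vortex array (full nonlinear Navier-Stokes solution), solid-body
rotation (stream-function topology), uniform flow (interpolation partition of
unity), and sums of Gaussian stream-function bumps with known vortex centers
and senses (ground truth for the vortex detector).

Each flow evaluates ``(u, v, p, psi)`` at arbitrary points and carries an
analytic residual of the governing equations it claims to satisfy, so the
oracles audit themselves without reference to the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AnalyticFlow",
    "make_uniform",
    "make_poiseuille",
    "make_taylor_green",
    "make_solid_rotation",
    "make_constructed_psi",
    "VortexGroundTruth",
]

Array = np.ndarray
Field2 = Callable[[Array, Array, float], Array]


@dataclass
class AnalyticFlow:
    """A closed-form incompressible flow with self-auditing residuals.

    ``residual(x, y, t)`` returns ``(rx, ry, div)``: the two momentum
    residuals (for the stated kinematic viscosity ``nu``) and the divergence,
    all evaluated from analytic derivatives, so they vanish to round-off for
    a correct implementation.
    """

    name: str
    nu: float
    u: Field2
    v: Field2
    p: Field2
    psi: Field2
    residual: Callable[[Array, Array, float], tuple[Array, Array, Array]]
    params: dict = field(default_factory=dict)

    def velocity(self, x: Array, y: Array, t: float = 0.0) -> tuple[Array, Array]:
        return self.u(x, y, t), self.v(x, y, t)

    def max_residual(self, x: Array, y: Array, t: float = 0.0) -> float:
        rx, ry, div = self.residual(x, y, t)
        return float(max(np.abs(rx).max(), np.abs(ry).max(), np.abs(div).max()))


def make_uniform(cx: float = 1.0, cy: float = 0.0, nu: float = 1.0) -> AnalyticFlow:
    """Uniform flow (cx, cy): the trivial steady Navier-Stokes solution."""

    def u(x, y, t):
        return np.full_like(np.asarray(x, float), cx)

    def v(x, y, t):
        return np.full_like(np.asarray(x, float), cy)

    def p(x, y, t):
        return np.zeros_like(np.asarray(x, float))

    def psi(x, y, t):
        return cx * np.asarray(y, float) - cy * np.asarray(x, float)

    def residual(x, y, t):
        z = np.zeros_like(np.asarray(x, float))
        return z, z, z

    return AnalyticFlow("uniform", nu, u, v, p, psi, residual, {"cx": cx, "cy": cy})


def make_poiseuille(
    width: float, vmax: float, y0: float = 0.0, mu: float = 1.0
) -> AnalyticFlow:
    """Plane Poiseuille flow in the channel y0 <= y <= y0 + width.

    u(y) = 4 Vmax (y - y0)(y0 + w - y) / w^2, driven by the constant pressure
    gradient dp/dx = -8 mu Vmax / w^2.  The wall shear stress magnitude is
    ``4 mu Vmax / w`` at both walls (available as ``params["wall_shear"]``).
    """
    if width <= 0:
        raise ValueError("channel width must be positive")
    w = float(width)

    def u(x, y, t):
        eta = np.asarray(y, float) - y0
        return 4.0 * vmax * eta * (w - eta) / w**2

    def v(x, y, t):
        return np.zeros_like(np.asarray(x, float))

    def p(x, y, t):
        return (-8.0 * mu * vmax / w**2) * np.asarray(x, float)

    def psi(x, y, t):
        eta = np.asarray(y, float) - y0
        return 4.0 * vmax / w**2 * (w * eta**2 / 2.0 - eta**3 / 3.0)

    def residual(x, y, t):
        # steady, unidirectional: x-momentum = -dp/dx + mu u'' ; rest zero
        xa = np.asarray(x, float)
        dpdx = -8.0 * mu * vmax / w**2
        d2u = -8.0 * vmax / w**2
        rx = np.full_like(xa, -dpdx + mu * d2u)
        z = np.zeros_like(xa)
        return rx, z, z

    return AnalyticFlow(
        "poiseuille",
        mu,
        u,
        v,
        p,
        psi,
        residual,
        {"width": w, "vmax": vmax, "y0": y0, "mu": mu, "wall_shear": 4.0 * mu * vmax / w},
    )


def make_taylor_green(k: float, amplitude: float, nu: float) -> AnalyticFlow:
    """Decaying Taylor-Green vortex array (kx = ky = k).

    u = A cos(kx) sin(ky) e^{-2 nu k^2 t}, v = -A sin(kx) cos(ky) e^{...},
    an exact solution of the full nonlinear Navier-Stokes equations.  Kinetic
    energy decays as exp(-4 nu k^2 t); ``params["decay_rate"] = 4 nu k^2``.
    """
    A = float(amplitude)

    def env(t):
        return np.exp(-2.0 * nu * k**2 * t)

    def u(x, y, t):
        return A * np.cos(k * np.asarray(x, float)) * np.sin(k * np.asarray(y, float)) * env(t)

    def v(x, y, t):
        return -A * np.sin(k * np.asarray(x, float)) * np.cos(k * np.asarray(y, float)) * env(t)

    def p(x, y, t):
        return (
            -(A**2)
            / 4.0
            * (np.cos(2 * k * np.asarray(x, float)) + np.cos(2 * k * np.asarray(y, float)))
            * env(t) ** 2
        )

    def psi(x, y, t):
        return -(A / k) * np.cos(k * np.asarray(x, float)) * np.cos(k * np.asarray(y, float)) * env(t)

    def residual(x, y, t):
        xa = np.asarray(x, float)
        ya = np.asarray(y, float)
        e = env(t)
        cx, sx = np.cos(k * xa), np.sin(k * xa)
        cy, sy = np.cos(k * ya), np.sin(k * ya)
        uu = A * cx * sy * e
        vv = -A * sx * cy * e
        ut = -2.0 * nu * k**2 * uu
        vt = -2.0 * nu * k**2 * vv
        ux = -A * k * sx * sy * e
        uy = A * k * cx * cy * e
        vx = -A * k * cx * cy * e
        vy = A * k * sx * sy * e
        px = A**2 / 2.0 * k * np.sin(2 * k * xa) * e**2
        py = A**2 / 2.0 * k * np.sin(2 * k * ya) * e**2
        lap_u = -2.0 * k**2 * uu
        lap_v = -2.0 * k**2 * vv
        rx = ut + uu * ux + vv * uy + px - nu * lap_u
        ry = vt + uu * vx + vv * vy + py - nu * lap_v
        div = ux + vy
        return rx, ry, div

    return AnalyticFlow(
        "taylor_green",
        nu,
        u,
        v,
        p,
        psi,
        residual,
        {"k": k, "amplitude": A, "decay_rate": 4.0 * nu * k**2},
    )


def make_solid_rotation(
    omega: float, center: tuple[float, float] = (0.0, 0.0), nu: float = 1.0
) -> AnalyticFlow:
    """Solid-body rotation at angular velocity omega about ``center``.

    Counterclockwise for omega > 0; psi = -omega r^2 / 2 has its single
    interior extremum (a maximum for omega > 0) at the rotation center.
    """
    xc, yc = center

    def u(x, y, t):
        return -omega * (np.asarray(y, float) - yc)

    def v(x, y, t):
        return omega * (np.asarray(x, float) - xc)

    def p(x, y, t):
        r2 = (np.asarray(x, float) - xc) ** 2 + (np.asarray(y, float) - yc) ** 2
        return 0.5 * omega**2 * r2

    def psi(x, y, t):
        r2 = (np.asarray(x, float) - xc) ** 2 + (np.asarray(y, float) - yc) ** 2
        return -0.5 * omega * r2

    def residual(x, y, t):
        xa = np.asarray(x, float)
        ya = np.asarray(y, float)
        # u.grad(u) = (-omega^2 (x-xc), -omega^2 (y-yc)); grad p cancels it
        rx = -(omega**2) * (xa - xc) + omega**2 * (xa - xc)
        ry = -(omega**2) * (ya - yc) + omega**2 * (ya - yc)
        div = np.zeros_like(xa)
        return rx, ry, div

    return AnalyticFlow(
        "solid_rotation", nu, u, v, p, psi, residual, {"omega": omega, "center": center}
    )


@dataclass(frozen=True)
class VortexGroundTruth:
    """Known vortex content of a constructed stream function."""

    centers: tuple[tuple[float, float], ...]
    senses: tuple[str, ...]  # "ccw" | "cw"
    depths: tuple[float, ...]  # |psi extremum - background|

    def __len__(self) -> int:
        return len(self.centers)


def make_constructed_psi(
    vortices: Sequence[tuple[float, float, float, float]],
) -> tuple[Callable[[Array, Array], Array], VortexGroundTruth]:
    """Sum of Gaussian stream-function bumps with known vortex content.

    ``vortices`` is a sequence of ``(x0, y0, amplitude, sigma)``.  Positive
    amplitude gives a psi maximum, i.e. a counterclockwise vortex.  Supports
    must not overlap: centers closer than 3*(sigma_i + sigma_j) raise.

    Returns ``(psi_fn, truth)`` where ``psi_fn(x, y)`` evaluates the field.
    """
    vs = [tuple(map(float, v)) for v in vortices]
    for i in range(len(vs)):
        if vs[i][3] <= 0:
            raise ValueError("sigma must be positive")
        for j in range(i + 1, len(vs)):
            d = np.hypot(vs[i][0] - vs[j][0], vs[i][1] - vs[j][1])
            if d < 3.0 * (vs[i][3] + vs[j][3]):
                raise ValueError("overlapping vortex supports")

    def psi_fn(x: Array, y: Array) -> Array:
        xa = np.asarray(x, float)
        ya = np.asarray(y, float)
        out = np.zeros(np.broadcast(xa, ya).shape)
        for x0, y0, amp, sig in vs:
            out = out + amp * np.exp(-((xa - x0) ** 2 + (ya - y0) ** 2) / (2 * sig**2))
        return out

    truth = VortexGroundTruth(
        centers=tuple((v[0], v[1]) for v in vs),
        senses=tuple("ccw" if v[2] > 0 else "cw" for v in vs),
        depths=tuple(abs(v[2]) for v in vs),
    )
    return psi_fn, truth
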