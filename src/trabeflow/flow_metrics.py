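"""Flow analysis: stream functions, vortices, transects, wall shear stress.

Streamlines of a 2D incompressible flow are level curves of the stream
function psi, with u = d(psi)/dy and v = -d(psi)/dx.  A vortex is an
interior extremum of psi surrounded by a closed level curve lying entirely
in the fluid; its rotation sense follows from the extremum sign (maximum =
counterclockwise).  Vortices are classified as *intertrabecular* when their
center falls in the near-wall region between adjacent trabecula crests
(within hT + rT of the smooth wall) and *intracardial* when it lies in the
open chamber.

Wall shear stress is the viscous tangential traction mu * d(u_t)/dn at the
wall, estimated by quadratic extrapolation of the tangential velocity
sampled at offsets 2h, 3h and 4h along the inward normal -- outside the
diffuse immersed wall -- to the effective no-slip plane (the tethered wall
itself is treated as exactly at rest).  TAWSS is the magnitude of the
time-averaged WSS vector over one cycle; the oscillatory shear index
OSI = 0.5 (1 - |<WSS>| / <|WSS|>) measures misalignment of instantaneous
and mean shear, from 0 (unidirectional) to 0.5 (perfectly reversing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.fft as sfft
from matplotlib.path import Path as MplPath
from scipy.ndimage import binary_erosion, map_coordinates, maximum_filter, minimum_filter
from scipy.spatial import cKDTree
from shapely import contains_xy

from .geometry import BoundaryCurve, fluid_polygon
from .ib_solver import FluidGrid, FluidState, divergence, vorticity

__all__ = [
    "StreamFunctionField",
    "Vortex",
    "VortexReport",
    "Transect",
    "ShearRecord",
    "ChamberMasks",
    "stream_function",
    "region_masks",
    "detect_vortices",
    "velocity_transect",
    "wall_flow_reversal",
    "wall_shear_stress",
    "tawss_osi",
    "region_average",
    "trace_particle",
    "is_nonmonotone_near_wall",
]


# ---------------------------------------------------------------------------
# stream function
# ---------------------------------------------------------------------------


@dataclass
class StreamFunctionField:
    """Stream function on the grid, gauged to zero on the lower channel wall."""

    psi: np.ndarray
    grid: FluidGrid
    gauge: float = 0.0

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _bilinear(self.grid, self.psi, x, y)


def _bilinear(grid: FluidGrid, f: np.ndarray, x, y) -> np.ndarray:
    cx = np.asarray(x, float) / grid.h
    cy = np.asarray(y, float) / grid.h
    return map_coordinates(f, [np.atleast_1d(cx), np.atleast_1d(cy)], order=1, mode="grid-wrap")


def stream_function(
    state: FluidState,
    grid: FluidGrid,
    curve: BoundaryCurve | None = None,
    div_tol: float = 1e-6,
) -> StreamFunctionField:
    """Solve for psi from the vorticity of a divergence-free field.

    The periodic fluctuation satisfies the discrete Poisson problem
    (Dx^2 + Dy^2) psi' = -omega (centered-difference operators, solved
    exactly in Fourier space); the mean flow contributes the linear part
    u_mean y - v_mean x.  Gauged so psi averages to zero on the lower
    channel wall (or over the domain when no boundary is given).

    Raises if the centered divergence of the input exceeds ``div_tol``
    (relative to max |u| / h).
    """
    u, v = state.u, state.v
    div = divergence(grid, u, v)
    scale = max(float(np.abs(u).max()), float(np.abs(v).max()), 1e-14) / grid.h
    if float(np.abs(div).max()) > div_tol * scale:
        raise ValueError("input velocity field is not discretely divergence-free")

    u_mean = float(u.mean())
    v_mean = float(v.mean())
    om = vorticity(grid, u, v)
    nx, ny, h = grid.nx, grid.ny, grid.h
    kx = np.fft.fftfreq(nx) * nx
    ky = np.fft.rfftfreq(ny) * ny
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    d2 = -(np.sin(2 * np.pi * KX / nx) ** 2 + np.sin(2 * np.pi * KY / ny) ** 2) / h**2
    # null modes of the centered-difference Laplacian (mean and Nyquist
    # rows/columns, where sin vanishes to round-off) carry no resolvable
    # vorticity and are dropped
    live = np.abs(d2) > 1e-9 / h**2
    oh = sfft.rfft2(om)
    ph = np.where(live, -oh / np.where(live, d2, 1.0), 0.0)
    psi = sfft.irfft2(ph, s=om.shape)
    X, Y = grid.meshgrid()
    psi = psi + u_mean * Y - v_mean * X

    gauge = 0.0
    if curve is not None:
        wall = curve.points[curve.component == 0]
        if len(wall):
            gauge = float(np.mean(_bilinear(grid, psi, wall[:, 0], wall[:, 1])))
    else:
        gauge = float(psi.mean())
    return StreamFunctionField(psi - gauge, grid, gauge)


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------


@dataclass
class ChamberMasks:
    """Boolean grid masks of the fluid subregions of an idealized chamber."""

    fluid: np.ndarray
    cavity: np.ndarray
    intracardial: np.ndarray
    intertrabecular: dict[str, np.ndarray]
    cavity_area: float
    #: near-wall band flanking the trabecular field (within hT + rT of the
    #: smooth wall, within ~2 rT of the outermost crests, outside the
    #: valleys): hosts micro-eddies at the trabecula feet that are neither
    #: intertrabecular nor chamber-interior vortices
    wall_band: np.ndarray | None = None

    def any_intertrabecular(self) -> np.ndarray:
        out = np.zeros_like(self.cavity)
        for m in self.intertrabecular.values():
            out |= m
        return out


def region_masks(curve: BoundaryCurve, grid: FluidGrid) -> ChamberMasks:
    """Build fluid / cavity / intertrabecular / intracardial masks.

    The intertrabecular region between adjacent trabecula crests is the
    near-wall band within hT + rT of the smooth elliptical wall, bounded in
    arc length by the crest positions; the two flanking segments (before the
    first and after the last crest) are included under their own labels.
    The intracardial region is the rest of the cavity.
    """
    poly = fluid_polygon(curve)
    X, Y = grid.meshgrid()
    fluid = contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)

    y_top = curve.meta["y_top"]
    cavity = fluid & (Y > y_top)
    cavity_area = float(cavity.sum()) * grid.h**2

    inter: dict[str, np.ndarray] = {}
    wall_band = None
    crest_s = np.asarray(curve.meta.get("crest_s", []))
    hT = curve.meta.get("hT", 0.0)
    rT = curve.meta.get("rT", 0.0)
    if len(crest_s) and hT > 0:
        s_ref, x_ref, y_ref = curve.meta["arc_ref"]
        tree = cKDTree(np.column_stack([x_ref, y_ref]))
        pts = np.column_stack([X[cavity], Y[cavity]])
        dist, idx = tree.query(pts)
        s_pts = s_ref[idx]
        near = dist <= (hT + rT)
        n_before = np.searchsorted(crest_s, s_pts)
        flat_idx = np.flatnonzero(cavity.ravel())
        n_trab = len(crest_s)
        # only the true valleys between adjacent crests; the smooth flanks
        # outside the trabecular field belong to the chamber wall
        for k in range(1, n_trab):
            sel = near & (n_before == k)
            if not sel.any():
                continue
            m = np.zeros(grid.nx * grid.ny, dtype=bool)
            m[flat_idx[sel]] = True
            inter[f"intertrabecular[{k}]"] = m.reshape(X.shape)
        # flanking near-wall strip just outside the outermost crests
        flank = (
            near
            & (s_pts > crest_s[0] - 2.0 * rT)
            & (s_pts < crest_s[-1] + 2.0 * rT)
            & ((n_before == 0) | (n_before == n_trab))
        )
        if flank.any():
            m = np.zeros(grid.nx * grid.ny, dtype=bool)
            m[flat_idx[flank]] = True
            wall_band = m.reshape(X.shape)

    intracardial = cavity.copy()
    for m in inter.values():
        intracardial &= ~m
    if wall_band is not None:
        intracardial &= ~wall_band
    return ChamberMasks(fluid, cavity, intracardial, inter, cavity_area, wall_band)


# ---------------------------------------------------------------------------
# vortex detection
# ---------------------------------------------------------------------------


@dataclass
class Vortex:
    center: tuple[float, float]
    cls: str  # "intracardial" | "intertrabecular[k]"
    sense: str  # "ccw" | "cw"
    extent_frac: float  # closed-contour area / cavity area
    depth: float  # |psi extremum - detection level|


@dataclass
class VortexReport:
    vortices: list[Vortex] = field(default_factory=list)
    phase: float | None = None

    def __len__(self) -> int:
        return len(self.vortices)

    @property
    def intracardial(self) -> list[Vortex]:
        return [v for v in self.vortices if v.cls == "intracardial"]

    @property
    def intertrabecular(self) -> list[Vortex]:
        return [v for v in self.vortices if v.cls.startswith("intertrabecular")]

    def classify(self) -> str:
        ic, it = bool(self.intracardial), bool(self.intertrabecular)
        if ic and it:
            return "both"
        if ic:
            return "intracardial-only"
        if it:
            return "intertrabecular-only"
        return "none"

    def max_intracardial_extent(self) -> float:
        return max((v.extent_frac for v in self.intracardial), default=0.0)


def _closed_contours_at(
    psi: np.ndarray, level: float, fluid: np.ndarray, h: float
) -> list[np.ndarray]:
    """Closed psi-contours at ``level`` lying entirely in the fluid (x, y coords)."""
    from skimage.measure import find_contours

    out = []
    for c in find_contours(psi, level):
        # smallest closed marching-squares loop (one cell) has 4 vertices
        # plus the repeated endpoint
        if len(c) < 5 or not np.allclose(c[0], c[-1]):
            continue
        ii = np.clip(np.round(c[:, 0]).astype(int), 0, fluid.shape[0] - 1)
        jj = np.clip(np.round(c[:, 1]).astype(int), 0, fluid.shape[1] - 1)
        if not fluid[ii, jj].all():
            continue
        out.append(c * h)
    return out


def _contour_containing(contours: list[np.ndarray], pt: tuple[float, float]):
    for c in contours:
        if MplPath(c).contains_point(pt):
            return c
    return None


def _polygon_area(c: np.ndarray) -> float:
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def detect_vortices(
    psi_field: StreamFunctionField,
    masks: ChamberMasks,
    curve: BoundaryCurve,
    min_area_cells: float = 9.0,
    probe_frac: float = 1e-7,
    corner_margin: float = 0.12,
    phase: float | None = None,
) -> VortexReport:
    """Find and classify closed-streamline vortices in the chamber.

    A candidate is a strict interior local extremum of psi within the
    (slightly eroded) cavity -- in 2D incompressible flow such an extremum
    can only sit at the core of a recirculation or in discretization noise
    near the immersed wall.  The two are separated topologically, not by
    amplitude (groove vortices in nearly stagnant fluid carve only a minute
    streamfunction depth, of the same order as wall noise):

    * the *innermost* contour, just off the extremum (``probe_frac`` of the
      fluid psi span), must close inside the fluid with at least 80% of its
      vertices clear of the one-cell wall fringe -- real vortex cores are
      interior, kernel-noise cores sit on the wall;
    * a log-spaced bisection toward the opposite end of the fluid psi range
      then finds the *outermost* level whose contour still closes entirely
      inside the fluid around the candidate;
    * that outermost contour must enclose at least ``min_area_cells`` grid
      cells, i.e. the recirculation must be resolved rather than a
      kernel-scale wiggle.

    Rotation sense follows the extremum sign (maximum = counterclockwise);
    classification follows the region mask containing the center; extent is
    the outermost closed-contour area as a fraction of the cavity area;
    ``depth`` is the psi difference between the extremum and the outermost
    closed level.
    """
    grid = psi_field.grid
    psi = psi_field.psi
    h = grid.h

    search = binary_erosion(masks.cavity, iterations=1)
    if not search.any():
        return VortexReport([], phase)

    meta = curve.meta
    if corner_margin > 0 and {"xc", "aV", "y_top"} <= meta.keys():
        # the 90-degree mouth junctions host sub-resolution Stokes corner
        # eddies and the largest marker jitter; neither is a chamber vortex
        X, Y = grid.meshgrid()
        for sx in (-1.0, 1.0):
            cx = meta["xc"] + sx * meta["aV"]
            search &= (X - cx) ** 2 + (Y - meta["y_top"]) ** 2 > corner_margin**2

    report = VortexReport([], phase)
    fluid = masks.fluid
    interior = binary_erosion(fluid, iterations=1)

    def closed_contour_at(level: float, center, need_interior: bool) -> np.ndarray | None:
        from skimage.measure import find_contours

        for c in find_contours(psi, level):
            if len(c) < 5 or not np.allclose(c[0], c[-1]):
                continue
            ii = np.clip(np.round(c[:, 0]).astype(int), 0, fluid.shape[0] - 1)
            jj = np.clip(np.round(c[:, 1]).astype(int), 0, fluid.shape[1] - 1)
            if not fluid[ii, jj].all():
                continue
            if need_interior and interior[ii, jj].mean() < 0.8:
                continue  # core sits in the wall fringe: kernel noise
            cxy = c * h
            if MplPath(cxy).contains_point(center):
                return cxy
        return None

    cand = []
    mx = (psi == maximum_filter(psi, size=3, mode="wrap")) & search
    mn = (psi == minimum_filter(psi, size=3, mode="wrap")) & search
    for i, j in np.argwhere(mx):
        cand.append((i, j, +1))
    for i, j in np.argwhere(mn):
        cand.append((i, j, -1))

    accepted: list[tuple[np.ndarray, int]] = []
    cavity_pts: np.ndarray | None = None
    # deepest-first ordering so merged cores resolve to the dominant extremum
    cand.sort(key=lambda c: -abs(psi[c[0], c[1]]))
    psi_lo = float(psi[fluid].min())
    psi_hi = float(psi[fluid].max())
    for i, j, sgn in cand:
        center = (i * h, j * h)
        if any(s == sgn and MplPath(c).contains_point(center) for c, s in accepted):
            continue
        ref = float(psi[i, j])
        span = abs(ref - (psi_lo if sgn > 0 else psi_hi))
        if span <= 0:
            continue
        # innermost probe: a closed, interior core contour must exist
        best = closed_contour_at(ref - sgn * probe_frac * span, center, True)
        if best is None:
            continue
        lo, hi = probe_frac, 1.0
        for _ in range(20):
            mid = math.sqrt(lo * hi)  # log-spaced: eddy depths span decades
            cc = closed_contour_at(ref - sgn * mid * span, center, False)
            if cc is not None:
                best = cc
                lo = mid
            else:
                hi = mid
        area = _polygon_area(best)
        if area < min_area_cells * h**2:
            continue
        # extent: fraction of the *cavity* the vortex occupies -- a swirl
        # whose contour reaches into the channel must not count channel area
        if cavity_pts is None:
            cavity_pts = np.argwhere(masks.cavity) * h
        inside = MplPath(best).contains_points(cavity_pts)
        extent = float(inside.sum()) * h**2 / max(masks.cavity_area, 1e-300)
        depth = lo * span

        cls = "intracardial"
        for name, m in masks.intertrabecular.items():
            if m[i, j]:
                cls = name
                break
        else:
            if not masks.cavity[i, j]:
                continue  # extremum in the channel; not a chamber vortex
            if masks.wall_band is not None and masks.wall_band[i, j]:
                cls = "wall"  # foot eddy at the trabecular field's flank
        report.vortices.append(
            Vortex(center, cls, "ccw" if sgn > 0 else "cw", float(extent), float(depth))
        )
        accepted.append((best, sgn))
    return report


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------


@dataclass
class Transect:
    p0: tuple[float, float]
    p1: tuple[float, float]
    frac: np.ndarray  # 0 at p0 .. 1 at p1
    speed: np.ndarray  # |u|
    u_horizontal: np.ndarray


def velocity_transect(
    state: FluidState,
    grid: FluidGrid,
    p0: Sequence[float],
    p1: Sequence[float],
    n: int = 200,
) -> Transect:
    """Velocity magnitude and horizontal component along the segment p0-p1."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    for p in (p0, p1):
        if not (0 <= p[0] <= grid.lx and 0 <= p[1] <= grid.ly):
            raise ValueError(f"transect endpoint {p} outside the domain")
    frac = np.linspace(0.0, 1.0, n)
    x = p0[0] + frac * (p1[0] - p0[0])
    y = p0[1] + frac * (p1[1] - p0[1])
    uu = _bilinear(grid, state.u, x, y)
    vv = _bilinear(grid, state.v, x, y)
    return Transect(tuple(p0), tuple(p1), frac, np.hypot(uu, vv), uu)


def is_nonmonotone_near_wall(tr: Transect, hT: float, vchar: float = 1.0) -> bool:
    """Deep-valley signature: a local speed minimum about hT from the wall,
    an interior rise inside the valley, then decay to ~0 at the wall."""
    length = float(np.hypot(tr.p1[0] - tr.p0[0], tr.p1[1] - tr.p0[1]))
    d_wall = (1.0 - tr.frac) * length  # distance from the wall endpoint
    zone = d_wall <= 3.0 * hT
    if zone.sum() < 5:
        return False
    s = tr.speed[zone]  # ordered toward the wall
    runmin = np.minimum.accumulate(s)  # minimum seen so far moving wallward
    rise = s - runmin  # any later rise above that dip
    k = int(np.argmax(rise))
    wall_ok = tr.speed[-1] <= 0.05 * max(tr.speed.max(), 1e-14)
    return bool(
        rise[k] > 0.1 * max(runmin[k], 1e-14) and rise[k] > 1e-4 * vchar and wall_ok
    )


# ---------------------------------------------------------------------------
# wall shear stress and derived indices
# ---------------------------------------------------------------------------


@dataclass
class ShearRecord:
    """Per-boundary-point WSS vectors over time (one cycle for OSI)."""

    wss: np.ndarray  # (n_times, n_points, 2)
    times: np.ndarray
    valid: np.ndarray  # (n_points,) probes stayed in the fluid
    labels: np.ndarray
    spacing: np.ndarray


def wall_shear_stress(
    state: FluidState,
    curve: BoundaryCurve,
    grid: FluidGrid,
    mu: float,
    fluid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """WSS vector at every boundary point, with a validity flag.

    The immersed wall is diffuse over the delta-kernel support (~2h), so
    probing inside it underestimates the shear.  Instead the tangential
    velocity is sampled at offsets 2h, 3h and 4h along the inward normal
    (outside the smear), the exact quadratic through the three samples is
    constructed, its zero crossing nearest the wall taken as the effective
    no-slip plane, and the slope is evaluated there.  For a parabolic
    profile this recovers the analytic wall shear exactly, independent of
    the kernel's effective wall shift.  Points whose probes leave the fluid
    (deep concavities) are flagged invalid and must be excluded from
    averages.
    """
    h = grid.h
    pts = curve.target_points
    nrm = curve.normals
    tan = np.column_stack([-nrm[:, 1], nrm[:, 0]])
    # orient tangents along the traversal direction
    nxt = np.roll(pts, -1, axis=0) - pts
    flip = np.sign(np.sum(tan * nxt, axis=1))
    flip[flip == 0] = 1.0
    tan = tan * flip[:, None]

    offs = np.array([2.0, 3.0, 4.0]) * h
    ut = np.empty((3, len(pts)))
    inside = np.ones((3, len(pts)), dtype=bool)
    for i, d in enumerate(offs):
        p = pts + d * nrm
        uu = _bilinear(grid, state.u, p[:, 0], p[:, 1])
        vv = _bilinear(grid, state.v, p[:, 0], p[:, 1])
        ut[i] = uu * tan[:, 0] + vv * tan[:, 1]
        if fluid is not None:
            inside[i] = _bilinear(grid, fluid.astype(float), p[:, 0], p[:, 1]) > 0.5
    valid = inside.all(axis=0)

    # exact quadratic u(n) = c0 + c1 n + c2 n^2 through the three samples
    n1, n2, n3 = offs
    denom = (n1 - n2) * (n1 - n3) * (n2 - n3)
    c2 = (n3 * (ut[1] - ut[0]) + n2 * (ut[0] - ut[2]) + n1 * (ut[2] - ut[1])) / denom
    c1 = (
        n3**2 * (ut[0] - ut[1]) + n2**2 * (ut[2] - ut[0]) + n1**2 * (ut[1] - ut[2])
    ) / denom
    c0 = ut[0] - c1 * n1 - c2 * n1**2
    # effective no-slip plane: quadratic root nearest the nominal wall,
    # constrained to the kernel-smear zone [-h, 2h]; fall back to n=0
    with np.errstate(invalid="ignore"):
        disc = c1**2 - 4.0 * c2 * c0
    n0 = np.zeros(len(pts))
    best = np.full(len(pts), np.inf)
    ok = (disc >= 0) & (np.abs(c2) > 1e-300)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sgn in (-1.0, 1.0):
        root = np.where(ok, (-c1 + sgn * sq) / (2.0 * np.where(ok, c2, 1.0)), np.nan)
        pick = ok & (root >= -h) & (root <= 2.0 * h) & (np.abs(root) < best)
        n0 = np.where(pick, root, n0)
        best = np.where(pick, np.abs(root), best)
    dudn = c1 + 2.0 * c2 * n0
    wss = mu * dudn[:, None] * tan
    return wss, valid


def tawss_osi(record: ShearRecord) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged WSS magnitude and oscillatory shear index per point.

    TAWSS = |<WSS>| (magnitude of the time-mean vector);
    OSI = 0.5 (1 - |<WSS>| / <|WSS|>), defined as 0 where the mean
    magnitude vanishes.  OSI is clamped to [0, 0.5] against round-off.
    """
    mean_vec = record.wss.mean(axis=0)
    mean_mag = np.linalg.norm(record.wss, axis=2).mean(axis=0)
    tawss = np.linalg.norm(mean_vec, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - np.where(mean_mag > 0, tawss / np.where(mean_mag > 0, mean_mag, 1.0), 1.0))
    return tawss, np.clip(osi, 0.0, 0.5)


def region_average(
    values: np.ndarray,
    labels: np.ndarray,
    spacing: np.ndarray,
    region: str,
    valid: np.ndarray | None = None,
) -> np.ndarray | float:
    """Arc-length-weighted mean of per-point values over a labelled region.

    ``region`` is matched as a label prefix ("trabecula" collects all
    trabecula[k]).  ``values`` may be (n_points,) or (n_times, n_points);
    the weighted mean is taken over the point axis.
    """
    sel = np.char.startswith(labels.astype(str), region)
    if valid is not None:
        sel &= valid
    if not sel.any():
        raise ValueError(f"region {region!r} matches no (valid) boundary points")
    w = spacing[sel]
    vals = np.asarray(values, float)
    if vals.ndim == 1:
        return float(np.sum(vals[sel] * w) / np.sum(w))
    return np.sum(vals[:, sel] * w[None, :], axis=1) / np.sum(w)


def wall_flow_reversal(
    state: FluidState,
    curve: BoundaryCurve,
    grid: FluidGrid,
    rel_tol: float = 0.02,
    floor: float = 1e-3,
    corner_margin: float = 0.15,
) -> bool:
    """Reversed near-wall tangential flow along the cavity arc.

    Samples the tangential velocity one grid spacing inside the wall on the
    cavity points, excluding ``corner_margin`` of arc next to the mouth
    corners (their Stokes corner eddies are sub-resolution and not the
    chamber-scale reversal of interest).  Reversal requires a contiguous
    negative stretch longer than twice the delta-kernel support (8h of arc
    length) with velocities below ``-max(rel_tol * max(u_t), floor)`` --
    coherence beyond the kernel scale separates real recirculation from
    spreading/interpolation noise.
    """
    sel = ~curve.select("channel-wall")
    if not sel.any():
        return False
    pts = curve.target_points[sel]
    nrm = curve.normals[sel]
    spc = curve.spacing[sel]
    tan = np.column_stack([-nrm[:, 1], nrm[:, 0]])
    nxt = np.roll(curve.target_points, -1, axis=0)[sel] - pts
    flip = np.sign(np.sum(tan * nxt, axis=1))
    flip[flip == 0] = 1.0
    tan *= flip[:, None]

    # drop points near the two mouth corners (arc ends)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    keep = (s > corner_margin) & (s < s[-1] - corner_margin)
    if keep.sum() < 8:
        return False
    pts, nrm, tan, spc = pts[keep], nrm[keep], tan[keep], spc[keep]

    probe = pts + grid.h * nrm
    uu = _bilinear(grid, state.u, probe[:, 0], probe[:, 1])
    vv = _bilinear(grid, state.v, probe[:, 0], probe[:, 1])
    ut = uu * tan[:, 0] + vv * tan[:, 1]
    thresh = -max(rel_tol * float(ut.max()), floor)
    neg = ut < thresh
    run = best = 0.0
    for flag, ds in zip(neg, spc):
        run = run + ds if flag else 0.0
        best = max(best, run)
    return best >= 8.0 * grid.h


def trace_particle(
    grid: FluidGrid,
    u: np.ndarray,
    v: np.ndarray,
    x0: Sequence[float],
    dt: float,
    n_steps: int,
) -> np.ndarray:
    """RK4 passive-particle trace through a frozen velocity field.

    Independent check on the stream-function vortex detector: a particle
    seeded in a closed-streamline region returns near its starting point.
    """
    def vel(p):
        return np.array(
            [
                float(_bilinear(grid, u, p[0], p[1])[0]),
                float(_bilinear(grid, v, p[0], p[1])[0]),
            ]
        )

    traj = np.empty((n_steps + 1, 2))
    p = np.array(x0, float)
    traj[0] = p
    for i in range(n_steps):
        k1 = vel(p)
        k2 = vel(p + 0.5 * dt * k1)
        k3 = vel(p + 0.5 * dt * k2)
        k4 = vel(p + dt * k3)
        p = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[i + 1] = p
    return traj
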