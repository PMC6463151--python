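"""Boundary geometry for idealized and synthetic trabeculated ventricles.

The idealized model is a cavity-flow geometry: a straight channel (the
atrioventricular canal continuing into the sinus venosus) with a half-
elliptical ventricular cavity opening into its upper wall.  Trabeculae are
smooth bumps superimposed on the elliptical arc, protruding into the cavity
along the local inward normal, with the perturbed-Gaussian profile

    Trab(x) = hT (1 - (x/rT)^2) exp(-(x / (0.7 rT))^8),   clamped to 0 for |x| >= rT,

where hT and rT are the trabecula height and radius.  Six equally arc-length-
spaced trabeculae, symmetric about the cavity midline, are the default.

Coordinates are dimensionless with the channel width wAV = 0.8 length units.
The channel axis is x, increasing left to right: inflow enters on the left
(AV side) and leaves on the right (SV side).  The domain is periodic in both
directions; boundaries are discretized as ordered Lagrangian point sets with
per-point region labels, ready for the immersed-boundary solver.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString, Polygon

__all__ = [
    "GeometryError",
    "GeometryParams",
    "SyntheticVentricleSpec",
    "BoundaryCurve",
    "trabecula_profile",
    "build_idealized_chamber",
    "build_synthetic_ventricle",
    "fluid_polygon",
    "DEFAULT_DOMAIN",
]

#: Default periodic domain extents (Lx, Ly).  The channel plus cavity occupy
#: 1.6 units of height, leaving 0.2 of clearance above the cavity apex and
#: below the lower channel wall; horizontally the cavity (2 aV = 2.0 wide)
#: leaves 1.0 >= wAV of clearance to the periodic seam on either side.
DEFAULT_DOMAIN = (4.0, 2.0)


class GeometryError(ValueError):
    """Invalid or degenerate boundary geometry."""


@dataclass(frozen=True)
class GeometryParams:
    """Idealized chamber dimensions (dimensionless length units).

    Defaults follow the reference idealized model: semi-major axis aV = 1.0,
    semi-minor axis (chamber depth) bV = 0.8, channel widths
    wAV = wSV = 0.8, trabecula radius rT = 0.10.  ``hT`` is the trabecula
    height, the main morphological control; ``hT / bV`` in [0, 0.16] spans
    from smooth to twice the biologically relevant relative height of 0.08.
    """

    aV: float = 1.0
    bV: float = 0.8
    wAV: float = 0.8
    wSV: float = 0.8
    rT: float = 0.10
    hT: float = 0.0
    n_trab: int = 6
    #: crest-to-crest arc spacing of the trabeculae.  Real trabeculae are
    #: adjacent muscular ridges, so the default packs the bumps close
    #: together (2.5 rT apart; the effective bump support is ~1.5 rT, so
    #: the groove floors between them stay about one bump-width wide),
    #: making the grooves true notches while keeping them wider than the
    #: regularized-delta support of the immersed walls.  Spreading six
    #: bumps evenly over the whole elliptical arc would flatten the
    #: corrugation steepness below the threshold at which groove
    #: recirculation can occur in slow flow.
    trab_pitch: float = 0.25
    ds_frac: float = 0.5  # Lagrangian spacing as a fraction of grid spacing

    def __post_init__(self) -> None:
        for name in ("aV", "bV", "wAV", "wSV", "rT"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.hT < 0:
            raise GeometryError("hT must be non-negative")
        if self.hT >= self.bV:
            raise GeometryError("hT must be smaller than the chamber depth bV")
        if self.wAV != self.wSV:
            raise GeometryError("idealized model requires wAV == wSV")
        if self.n_trab < 0:
            raise GeometryError("n_trab must be non-negative")

    @property
    def ht_rel(self) -> float:
        """Dimensionless trabecula height hT / bV."""
        return self.hT / self.bV

    def with_ht_rel(self, ht_rel: float) -> "GeometryParams":
        return replace(self, hT=ht_rel * self.bV)


def trabecula_profile(x, hT: float, rT: float):
    """Height of the trabecula surface above the smooth wall at offset ``x``.

    Evaluates hT (1 - (x/rT)^2) exp(-(x/(0.7 rT))^8), clamped to zero for
    |x| >= rT (the raw expression dips slightly negative beyond rT, and
    trabeculae protrude into, never out of, the wall).  Even in x, maximal
    (= hT) at x = 0.
    """
    if rT <= 0:
        raise GeometryError("rT must be positive")
    if hT < 0:
        raise GeometryError("hT must be non-negative")
    xa = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        prof = hT * (1.0 - (xa / rT) ** 2) * np.exp(-((xa / (0.7 * rT)) ** 8))
    prof = np.where(np.abs(xa) >= rT, 0.0, np.maximum(prof, 0.0))
    return prof if prof.ndim else float(prof)


@dataclass(frozen=True)
class SyntheticVentricleSpec:
    """Spec for a synthetic, realistic-like ventricle outline.

    Stands in for traced embryo ventricle geometries (which are not
    published): a closed smooth-spline outline with inlet (AV canal) and
    outlet (SV) gaps and ``n_trab`` inward trabecular protrusions whose
    depths are drawn from N(depth_mean, depth_sd), clipped non-negative.
    Depths are expressed as fractions of the chamber width.  Deterministic
    for a fixed seed.
    """

    n_trab: int = 6
    depth_mean: float = 0.08
    depth_sd: float = 0.02
    smoothness: int = 24  # spline control-point count
    radius: float = 1.0
    # low-order radial perturbation; kept small enough that an unperturbed
    # (depth_mean = 0) outline stays convex
    irregularity: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean < 0 or self.depth_sd < 0:
            raise GeometryError("trabecula depths must be non-negative")
        if self.n_trab < 0:
            raise GeometryError("n_trab must be non-negative")
        if self.smoothness < 8:
            raise GeometryError("need at least 8 spline control points")


@dataclass
class BoundaryCurve:
    """Discretized boundary: ordered Lagrangian points with region labels.

    ``points`` are current positions, ``target_points`` the tether-spring
    rest positions (identical at construction).  ``normals`` point into the
    fluid.  ``labels`` tag each point with exactly one region
    (``channel-wall``, ``chamber-wall``, ``trabecula[k]`` or
    ``intertrabecular[k]``); ``component`` identifies the polyline each point
    belongs to (0 = lower channel wall, 1 = upper wall + cavity).
    ``spacing`` is the local arc length attributed to each point (the
    quadrature weight for force spreading and region averages).
    """

    points: np.ndarray
    normals: np.ndarray
    labels: np.ndarray
    target_points: np.ndarray
    spacing: np.ndarray
    component: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ds(self) -> float:
        return float(self.meta.get("ds", np.median(self.spacing)))

    def select(self, prefix: str) -> np.ndarray:
        """Boolean mask of points whose label starts with ``prefix``."""
        return np.char.startswith(self.labels.astype(str), prefix)

    def region_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def interior_valleys(self) -> list[str]:
        """Intertrabecular labels strictly between two trabeculae."""
        n = int(self.meta.get("n_trab", 0))
        present = set(self.region_names())
        return [
            f"intertrabecular[{k}]"
            for k in range(1, n)
            if f"intertrabecular[{k}]" in present
        ]

    # ---- plain-text vertex file I/O -------------------------------------

    def save_vertex_file(self, path: str | Path) -> None:
        """Write ``x y label`` per line with a ``#``-prefixed header."""
        buf = io.StringIO()
        buf.write("# trabeflow boundary vertex file\n")
        for key in ("aV", "bV", "wAV", "rT", "hT", "n_trab", "ds", "domain"):
            if key in self.meta:
                buf.write(f"# {key} = {self.meta[key]}\n")
        for (x, y), lab in zip(self.points, self.labels):
            buf.write(f"{x:.10g} {y:.10g} {lab}\n")
        Path(path).write_text(buf.getvalue())


def _resample_closed(
    pts: np.ndarray, ds: float, lx_period: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly resample a (periodically) closed dense polyline.

    Returns (resampled points, source arc positions).  If ``lx_period`` is
    given the closing segment wraps in x by that period (a wall crossing the
    periodic seam); otherwise the curve closes on itself directly.
    """
    d = np.diff(pts, axis=0)
    closing = pts[0] - pts[-1]
    if lx_period is not None:
        closing = closing.copy()
        closing[0] = (closing[0] + 0.5 * lx_period) % lx_period - 0.5 * lx_period
    seg = np.hypot(*np.vstack([d, closing[None]]).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(4, int(round(total / ds)))
    s_new = np.arange(n) * total / n
    x_end = pts[-1, 0] + closing[0]
    y_end = pts[-1, 1] + closing[1]
    x = np.interp(s_new, s, np.concatenate([pts[:, 0], [x_end]]))
    y = np.interp(s_new, s, np.concatenate([pts[:, 1], [y_end]]))
    if lx_period is not None:
        x = x % lx_period
    return np.column_stack([x, y]), s_new


def _polyline_normals(
    pts: np.ndarray, side: str, lx_period: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tangents/normals of a periodically-closed polyline by central differences.

    ``side`` picks which rotation of the tangent is the inward (fluid-side)
    normal: "left" = (-ty, tx), "right" = (ty, -tx).
    """
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    d = nxt - prv
    d[:, 0] = (d[:, 0] + 0.5 * lx_period) % lx_period - 0.5 * lx_period
    norm = np.hypot(d[:, 0], d[:, 1])
    t = d / norm[:, None]
    if side == "left":
        n = np.column_stack([-t[:, 1], t[:, 0]])
    else:
        n = np.column_stack([t[:, 1], -t[:, 0]])
    return t, n


def _spacing_weights(pts: np.ndarray, lx_period: float) -> np.ndarray:
    nxt = np.roll(pts, -1, axis=0)
    d = nxt - pts
    d[:, 0] = (d[:, 0] + 0.5 * lx_period) % lx_period - 0.5 * lx_period
    seg = np.hypot(d[:, 0], d[:, 1])
    return 0.5 * (seg + np.roll(seg, 1))


def _ellipse_arc(params: GeometryParams, xc: float, y_top: float, n: int = 8192):
    """Dense half-ellipse samples from the left mouth (theta=pi) to the right
    mouth (theta=0), with cumulative arc length and inward (into-cavity)
    normals of the smooth arc."""
    theta = np.linspace(np.pi, 0.0, n)
    x = xc + params.aV * np.cos(theta)
    y = y_top + params.bV * np.sin(theta)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # outward normal of the ellipse ~ (b cos, a sin); inward = opposite
    nx = -params.bV * np.cos(theta)
    ny = -params.aV * np.sin(theta)
    nn = np.hypot(nx, ny)
    return x, y, s, np.column_stack([nx / nn, ny / nn])


def build_idealized_chamber(
    params: GeometryParams,
    grid_spacing: float,
    domain: tuple[float, float] = DEFAULT_DOMAIN,
) -> BoundaryCurve:
    """Discretize the channel-plus-cavity boundary of the idealized model.

    The half-elliptical cavity opens into the upper channel wall, centered in
    x; ``params.n_trab`` trabeculae are placed at equal arc-length spacing
    along the elliptical arc, symmetric about the cavity midline, each
    protruding along the local inward normal with the ``trabecula_profile``
    shape.  Labels partition the boundary; interior valleys between adjacent
    trabeculae are ``intertrabecular[1..n-1]``, the two flanking arc segments
    ``intertrabecular[0]`` and ``intertrabecular[n]``.
    """
    lx, ly = domain
    ds = params.ds_frac * grid_spacing
    if 2.0 * params.aV + 2.0 * params.wAV > lx:
        raise GeometryError("domain too short: need >= wAV clearance beside the cavity")
    if params.wAV + params.bV >= ly:
        raise GeometryError("domain too shallow for channel plus cavity")
    y_bot = 0.5 * (ly - params.wAV - params.bV)
    y_top = y_bot + params.wAV
    xc = 0.5 * lx

    ex, ey, es, enorm = _ellipse_arc(params, xc, y_top)
    total_arc = es[-1]
    crest_s = np.array([])
    if params.n_trab > 0 and params.hT > 0:
        pitch = params.trab_pitch
        if pitch < 2.0 * params.rT - 1e-12:
            raise GeometryError(
                f"trabecula overlap: arc pitch {pitch:.3f} < 2 rT = {2 * params.rT:.3f}"
            )
        span = (params.n_trab - 1) * pitch
        if span + 2.0 * params.rT > total_arc:
            raise GeometryError("trabecular field longer than the cavity arc")
        # centered on the arc midpoint, symmetric about the cavity midline
        crest_s = 0.5 * (total_arc - span) + np.arange(params.n_trab) * pitch

    # displace dense arc along inward normals by the summed bump profile
    bump = np.zeros_like(es)
    for sk in crest_s:
        bump += trabecula_profile(es - sk, params.hT, params.rT)
    arc_pts = np.column_stack([ex, ey]) + bump[:, None] * enorm

    # dense upper component: wall -> cavity arc -> wall (left to right)
    n_wall_l = max(8, int((xc - params.aV) / (ds / 4)))
    wall_l = np.column_stack(
        [np.linspace(0.0, xc - params.aV, n_wall_l, endpoint=False), np.full(n_wall_l, y_top)]
    )
    n_wall_r = max(8, int((lx - xc - params.aV) / (ds / 4)))
    wall_r = np.column_stack(
        [np.linspace(xc + params.aV, lx, n_wall_r, endpoint=False) + (ds / 4), np.full(n_wall_r, y_top)]
    )
    dense_top = np.vstack([wall_l, arc_pts, wall_r])
    # dense labels, resolved on the smooth-arc parameter s
    dense_lab = np.array(
        ["channel-wall"] * len(wall_l) + ["chamber-wall"] * len(arc_pts) + ["channel-wall"] * len(wall_r),
        dtype=object,
    )
    if len(crest_s):
        arc_lab = np.empty(len(es), dtype=object)
        n_before = np.searchsorted(crest_s, es)
        for i, (si, nb) in enumerate(zip(es, n_before)):
            dk = np.abs(crest_s - si)
            k = int(np.argmin(dk))
            # a point belongs to a trabecula where the bump substantively
            # displaces it; the valley between adjacent crests is whatever
            # the bump profiles leave undisturbed
            if bump[i] > 0.05 * params.hT:
                arc_lab[i] = f"trabecula[{k}]"
            elif 0 < int(nb) < params.n_trab:
                arc_lab[i] = f"intertrabecular[{int(nb)}]"
            else:
                arc_lab[i] = "chamber-wall"  # flanking smooth arc
        dense_lab[len(wall_l) : len(wall_l) + len(arc_pts)] = arc_lab

    if not LineString(dense_top).is_simple:
        raise GeometryError("boundary self-intersects; reduce hT")

    top_pts, top_src = _resample_closed(dense_top, ds, lx_period=lx)
    # map resampled points back to dense source arc positions for labels
    dense_seg = np.hypot(*np.diff(dense_top, axis=0).T)
    dense_s = np.concatenate([[0.0], np.cumsum(dense_seg)])
    idx = np.clip(np.searchsorted(dense_s, top_src), 0, len(dense_lab) - 1)
    top_lab = dense_lab[idx]

    n_bot = max(8, int(round(lx / ds)))
    bot_pts = np.column_stack(
        [np.arange(n_bot) * lx / n_bot, np.full(n_bot, y_bot)]
    )
    bot_lab = np.array(["channel-wall"] * n_bot, dtype=object)

    # fluid lies below the upper component ("right" of left-to-right travel)
    # and above the lower wall ("left")
    _, top_norm = _polyline_normals(top_pts, "right", lx)
    _, bot_norm = _polyline_normals(bot_pts, "left", lx)

    points = np.vstack([bot_pts, top_pts])
    normals = np.vstack([bot_norm, top_norm])
    labels = np.concatenate([bot_lab, top_lab])
    spacing = np.concatenate(
        [_spacing_weights(bot_pts, lx), _spacing_weights(top_pts, lx)]
    )
    comp = np.concatenate([np.zeros(n_bot, int), np.ones(len(top_pts), int)])

    meta = {
        "kind": "idealized",
        "aV": params.aV,
        "bV": params.bV,
        "wAV": params.wAV,
        "rT": params.rT,
        "hT": params.hT,
        "n_trab": params.n_trab,
        "ds": ds,
        "domain": (lx, ly),
        "xc": xc,
        "y_top": y_top,
        "y_bot": y_bot,
        "crest_s": crest_s,
        "arc_total": total_arc,
        "arc_ref": (es[::8].copy(), ex[::8].copy(), ey[::8].copy()),
        "params": params,
    }
    return BoundaryCurve(points, normals, labels, points.copy(), spacing, comp, meta)


def fluid_polygon(curve: BoundaryCurve) -> Polygon:
    """Shapely polygon of the wetted (channel + cavity) fluid region."""
    if curve.meta.get("kind") != "idealized":
        raise GeometryError("fluid_polygon is defined for idealized chambers")
    lx, _ = curve.meta["domain"]
    bot = curve.points[curve.component == 0]
    top = curve.points[curve.component == 1]
    bot = bot[np.argsort(bot[:, 0])]
    # traversal order is construction order; roll so the component starts
    # near x = 0 before closing the ring through the domain edges
    start = int(np.argmin(top[:, 0]))
    top_o = np.roll(top, -start, axis=0)
    ring = np.vstack([bot, top_o[::-1]])
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def build_channel(
    params: GeometryParams,
    grid_spacing: float,
    domain: tuple[float, float] = DEFAULT_DOMAIN,
) -> BoundaryCurve:
    """A plain straight channel (no cavity): two tethered walls wAV apart.

    Used for solver validation against plane Poiseuille flow.
    """
    lx, ly = domain
    ds = params.ds_frac * grid_spacing
    y_bot = 0.5 * (ly - params.wAV - params.bV)
    y_top = y_bot + params.wAV
    n = max(8, int(round(lx / ds)))
    xs = np.arange(n) * lx / n
    bot = np.column_stack([xs, np.full(n, y_bot)])
    top = np.column_stack([xs, np.full(n, y_top)])
    points = np.vstack([bot, top])
    normals = np.vstack(
        [np.tile([0.0, 1.0], (n, 1)), np.tile([0.0, -1.0], (n, 1))]
    )
    labels = np.array(["channel-wall"] * (2 * n), dtype=object)
    spacing = np.full(2 * n, lx / n)
    comp = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    meta = {
        "kind": "channel",
        "wAV": params.wAV,
        "aV": params.aV,
        "ds": ds,
        "domain": (lx, ly),
        "y_top": y_top,
        "y_bot": y_bot,
        "hT": 0.0,
        "rT": params.rT,
        "n_trab": 0,
        "params": params,
    }
    return BoundaryCurve(points, normals, labels, points.copy(), spacing, comp, meta)


# ---------------------------------------------------------------------------
# synthetic realistic-like ventricles
# ---------------------------------------------------------------------------


def _synthetic_outline(spec: SyntheticVentricleSpec, depth_sd: float, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One candidate outline; returns (points, labels, curvature)."""
    n_dense = 2048
    phi_ctrl = np.linspace(0.0, 2 * np.pi, spec.smoothness, endpoint=False)
    # low-order (m <= 4) radial perturbation keeps the base outline convex
    pert = np.zeros(spec.smoothness)
    for m in (2, 3, 4):
        pert += rng.normal(0, 1.0 / m**2) * np.cos(
            m * phi_ctrl + rng.uniform(0, 2 * np.pi)
        )
    r_ctrl = spec.radius * (1.0 + spec.irregularity * pert)
    phi_knots = np.concatenate([phi_ctrl, [2 * np.pi]])
    r_knots = np.concatenate([r_ctrl, [r_ctrl[0]]])
    spline = CubicSpline(phi_knots, r_knots, bc_type="periodic")
    phi = np.linspace(0.0, 2 * np.pi, n_dense, endpoint=False)
    r = spline(phi)

    # trabecular field on the wall opposite the inlet/outlet gaps; gaps sit
    # around phi = pi +/- and phi = 0 +/- (AV canal left, SV right)
    gap_half = 0.35
    labels = np.array(["chamber-wall"] * n_dense, dtype=object)
    depths = np.maximum(rng.normal(spec.depth_mean, depth_sd, spec.n_trab), 0.0)
    width = 2.0 * spec.radius  # chamber width scale for depth fractions
    if spec.n_trab > 0 and spec.depth_mean > 0:
        lo, hi = gap_half + 0.25, np.pi - gap_half - 0.25
        centers = lo + (np.arange(spec.n_trab) + 0.5) * (hi - lo) / spec.n_trab
        half_w = 0.45 * (hi - lo) / spec.n_trab
        for k, (c, dep) in enumerate(zip(centers, depths)):
            win = np.abs(phi - c) <= half_w
            bumpshape = np.cos(0.5 * np.pi * (phi[win] - c) / half_w) ** 2
            r[win] -= dep * width * bumpshape
            labels[win] = f"trabecula[{k}]"
        for k in range(spec.n_trab - 1):
            win = (phi > centers[k] + half_w) & (phi < centers[k + 1] - half_w)
            labels[win] = f"intertrabecular[{k + 1}]"

    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    # curvature of the closed polyline (for protrusion counting)
    dp = np.gradient(pts, axis=0)
    ddp = np.gradient(dp, axis=0)
    cross = dp[:, 0] * ddp[:, 1] - dp[:, 1] * ddp[:, 0]
    kappa = cross / np.maximum(np.hypot(dp[:, 0], dp[:, 1]) ** 3, 1e-30)

    # cut inlet (AV) and outlet (SV) gaps
    keep = ~(
        (np.minimum(np.abs(phi - np.pi), 2 * np.pi - np.abs(phi - np.pi)) < gap_half)
        | (np.minimum(phi, 2 * np.pi - phi) < gap_half)
    )
    return pts[keep], labels[keep], kappa[keep]


def build_synthetic_ventricle(
    spec: SyntheticVentricleSpec, grid_spacing: float = 0.02, max_retries: int = 5
) -> BoundaryCurve:
    """Generate a synthetic ventricle outline per ``spec``.

    Deterministic for a fixed seed.  If the perturbed outline self-
    intersects, regeneration is attempted with the depth spread halved; after
    ``max_retries`` failures a :class:`GeometryError` is raised.
    """
    ds = max(grid_spacing * 0.5, 1e-4)
    depth_sd = spec.depth_sd
    for attempt in range(max_retries):
        rng = np.random.default_rng(spec.seed + 1000 * attempt)
        pts, labels, kappa = _synthetic_outline(spec, depth_sd, rng)
        if LineString(pts).is_simple:
            break
        depth_sd *= 0.5
    else:
        raise GeometryError("could not generate a simple synthetic outline")

    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(16, int(round(s[-1] / ds)))
    s_new = np.linspace(0.0, s[-1], n)
    x = np.interp(s_new, s, pts[:, 0])
    y = np.interp(s_new, s, pts[:, 1])
    idx = np.clip(np.searchsorted(s, s_new), 0, len(labels) - 1)
    new_pts = np.column_stack([x, y])
    d = np.gradient(new_pts, axis=0)
    t = d / np.maximum(np.hypot(d[:, 0], d[:, 1])[:, None], 1e-30)
    normals = np.column_stack([t[:, 1], -t[:, 0]])  # inward for ccw outline
    # ccw outline traversed with interior on the left -> inward is (-ty, tx);
    # orientation check via signed area
    area2 = np.sum(pts[:-1, 0] * pts[1:, 1] - pts[1:, 0] * pts[:-1, 1])
    if area2 > 0:
        normals = -normals
    spacing = np.full(n, s[-1] / max(n - 1, 1))
    meta = {
        "kind": "synthetic",
        "spec": spec,
        "ds": ds,
        "n_trab": spec.n_trab,
        "curvature": kappa,
        "hT": spec.depth_mean * 2.0 * spec.radius,
        "rT": 0.0,
    }
    return BoundaryCurve(
        new_pts, normals, labels[idx], new_pts.copy(), spacing, np.zeros(n, int), meta
    )


def count_protrusions(curve: BoundaryCurve, min_prominence: float = 3.0) -> int:
    """Count inward protrusions of a synthetic outline via curvature extrema.

    A protrusion is a contiguous run of strongly convex-outward curvature
    (sign opposite to the mean outline curvature) book-ended by concave
    intervals; for cos^2 bumps this matches the bump count.
    """
    kappa = curve.meta.get("curvature")
    if kappa is None:
        raise GeometryError("curvature record only available for synthetic outlines")
    med = np.median(kappa)
    strong = kappa * np.sign(med) < -min_prominence * abs(med)
    if not strong.any():
        return 0
    edges = np.diff(strong.astype(int))
    n_runs = int(np.sum(edges == 1)) + int(strong[0])
    return n_runs
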