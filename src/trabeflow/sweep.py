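"""Parameter sweep over (Re, trabecula height, inflow mode) and bifurcation maps.

The headline analysis: for each cell of the parameter grid, run the chamber
simulation to (periodic) steady state, detect and classify vortices, and
record a flow-structure class:

    none | intertrabecular-only | intracardial-only | both

Steady cells are classified from the converged state; pulsatile cells are
classified per phase snapshot of the final cycle, with a cycle-level
roll-up ("vortex at any phase").  ``onset_threshold`` refines a critical
Reynolds number by bisection between simulated values.  Cells are cached on
disk keyed by a hash of the resolved cell configuration, so sweeps are
resumable and rerunning an identical spec touches no solver.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryParams, build_idealized_chamber
from .ib_solver import (
    ConvergenceError,
    DEFAULT_PHASES,
    FlowParams,
    FluidState,
    IBParams,
    SolverError,
    grid_for_tier,
    run_pulsatile,
    run_steady,
)
from .flow_metrics import (
    ChamberMasks,
    VortexReport,
    detect_vortices,
    region_masks,
    stream_function,
)

__all__ = [
    "SweepSpec",
    "CaseResult",
    "BifurcationTable",
    "run_case",
    "run_sweep",
    "onset_threshold",
    "summarize",
    "STEADY_RE_SET",
    "PULSATILE_RE_SET",
    "HT_REL_SET",
]

#: Simulated Reynolds numbers for the steady sweep.
STEADY_RE_SET = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0)
#: Simulated Reynolds numbers for the pulsatile sweep.
PULSATILE_RE_SET = (0.1, 1.0, 10.0, 100.0)
#: Dimensionless trabecula heights hT/bV (0 to twice the biological 0.08).
HT_REL_SET = (0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16)

#: Deceleration-phase snapshots (end-of-pulse) used for transient-vortex calls.
DECELERATION_PHASES = (0.80, 0.90, 0.95, 1.00)


@dataclass(frozen=True)
class SweepSpec:
    """Axes and numerics of a sweep."""

    re_values: tuple[float, ...] = STEADY_RE_SET
    ht_rel_values: tuple[float, ...] = HT_REL_SET
    mode: str = "steady"
    phases: tuple[float, ...] = DEFAULT_PHASES
    tier: str = "coarse"
    steady_tol: float = 5e-3
    max_time: float = 60.0
    n_cycles: int = 4

    def __post_init__(self) -> None:
        if not self.re_values or not self.ht_rel_values:
            raise ValueError("sweep axes must be non-empty")

    def cells(self):
        for ht in self.ht_rel_values:
            for re in self.re_values:
                yield re, ht


@dataclass
class CaseResult:
    """One simulated cell: per-phase vortex reports plus run diagnostics."""

    re: float
    ht_rel: float
    mode: str
    tier: str
    reports: dict[float | str, VortexReport]
    converged: bool
    max_deviation_frac: float
    k_tether: float
    dt: float
    states: dict[float | str, FluidState] = field(default_factory=dict)
    masks: ChamberMasks | None = None

    def rollup(self) -> str:
        """Cycle-level class: a vortex type counts if present at any phase."""
        ic = any(bool(r.intracardial) for r in self.reports.values())
        it = any(bool(r.intertrabecular) for r in self.reports.values())
        if ic and it:
            return "both"
        if ic:
            return "intracardial-only"
        if it:
            return "intertrabecular-only"
        return "none"

    def intertrabecular_at(self, phases: Sequence[float]) -> bool:
        keys = [k for k in self.reports if isinstance(k, float) and any(abs(k - p) < 1e-9 for p in phases)]
        return any(bool(self.reports[k].intertrabecular) for k in keys)

    def max_intracardial_extent(self, open_inflow_only: bool = False) -> float:
        """Largest intracardial vortex extent over the recorded snapshots.

        With ``open_inflow_only`` the cycle-boundary snapshot (phase 1.0,
        where the pulsatile inflow is exactly zero) is skipped: extent is
        amplitude-blind, and the closed contours of the vanishing residual
        field at that instant sprawl over the chamber without representing
        a flow structure of the cycle.
        """
        vals = []
        for ph, r in self.reports.items():
            if open_inflow_only and isinstance(ph, float) and not (0.0 < ph < 1.0):
                continue
            vals.append(r.max_intracardial_extent())
        return max(vals, default=0.0)


def default_horizon(re: float) -> float:
    """Steady-run integration horizon (time units) by Reynolds number.

    Low-Re flows settle within a few advective/viscous times; at Re above
    ~5 the cavity vortex develops on the slower advective-recirculation
    scale, so those runs integrate longer.  The tether-marker micro-drift
    at stress concentrations sets a residual noise floor, so runs are
    integrated to a fixed physics-based horizon rather than to a machine
    tolerance (the realized residual is recorded alongside the result).
    """
    if re <= 1.0:
        return 12.0
    if re <= 30.0:
        return 50.0
    return 60.0


def run_case(
    re: float,
    ht_rel: float,
    mode: str,
    tier: str = "coarse",
    phases: Sequence[float] = DEFAULT_PHASES,
    steady_tol: float = 5e-3,
    max_time: float | None = None,
    n_cycles: int = 4,
    geometry: GeometryParams | None = None,
    ib: IBParams | None = None,
    keep_states: bool = False,
) -> CaseResult:
    """Simulate one (Re, hT/bV, mode) cell and classify its vortices."""
    if max_time is None:
        max_time = default_horizon(re)
    grid = grid_for_tier(tier)
    params = (geometry or GeometryParams()).with_ht_rel(ht_rel)
    curve = build_idealized_chamber(params, grid.h, domain=(grid.lx, grid.ly))
    masks = region_masks(curve, grid)
    reports: dict[float | str, VortexReport] = {}
    states: dict[float | str, FluidState] = {}

    if mode == "steady":
        flow = FlowParams(re=re, mode="steady")
        res = run_steady(
            curve, flow, grid, ib, tol=steady_tol, max_time=max_time, strict=False
        )
        psi = stream_function(res.state, grid, curve)
        reports["steady"] = detect_vortices(psi, masks, curve)
        if keep_states:
            states["steady"] = res.state
        converged = res.converged
        dev, k, dt = res.max_deviation_frac, res.k_tether, res.dt
    elif mode == "pulsatile":
        flow = FlowParams(re=re, mode="pulsatile", n_cycles=n_cycles)
        res = run_pulsatile(curve, flow, grid, ib, phases=phases)
        for ph, st in res.snapshots:
            psi = stream_function(st, grid, curve)
            reports[float(ph)] = detect_vortices(psi, masks, curve, phase=ph)
            if keep_states:
                states[float(ph)] = st
        converged = res.periodic
        dev, k, dt = res.max_deviation_frac, res.k_tether, res.dt
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return CaseResult(
        re, ht_rel, mode, tier, reports, converged, dev, k, dt, states,
        masks if keep_states else None,
    )


# ---------------------------------------------------------------------------
# sweep driver with on-disk cell cache
# ---------------------------------------------------------------------------


def _cell_key(spec: SweepSpec, re: float, ht: float) -> str:
    payload = {
        "re": re,
        "ht_rel": ht,
        "mode": spec.mode,
        "phases": list(spec.phases),
        "tier": spec.tier,
        "steady_tol": spec.steady_tol,
        "max_time": spec.max_time,
        "n_cycles": spec.n_cycles,
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _case_record(case: CaseResult) -> dict:
    rows = []
    for ph, rep in case.reports.items():
        rows.append(
            {
                "phase": ph,
                "cls": rep.classify(),
                "n_intracardial": len(rep.intracardial),
                "n_intertrabecular": len(rep.intertrabecular),
                "max_ic_extent": rep.max_intracardial_extent(),
                "senses": [v.sense for v in rep.vortices],
            }
        )
    return {
        "re": case.re,
        "ht_rel": case.ht_rel,
        "mode": case.mode,
        "tier": case.tier,
        "rollup": case.rollup(),
        "converged": case.converged,
        "max_deviation_frac": case.max_deviation_frac,
        "k_tether": case.k_tether,
        "dt": case.dt,
        "phases": rows,
    }


@dataclass
class BifurcationTable:
    """Per-cell flow-structure classes over the sweep, as a tidy DataFrame."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)
    n_computed: int = 0
    n_cached: int = 0

    def cell(self, re: float, ht_rel: float) -> pd.DataFrame:
        sel = (np.isclose(self.df.re, re)) & (np.isclose(self.df.ht_rel, ht_rel))
        return self.df[sel]

    def rollup_class(self, re: float, ht_rel: float) -> str:
        rows = self.cell(re, ht_rel)
        if rows.empty:
            raise KeyError(f"cell (Re={re}, hT/bV={ht_rel}) not in table")
        return str(rows.iloc[0]["rollup"])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def run_sweep(
    spec: SweepSpec,
    cache_dir: str | Path | None = None,
    geometry: GeometryParams | None = None,
    ib: IBParams | None = None,
    progress: Callable[[str], None] | None = None,
) -> BifurcationTable:
    """Run (or resume) the sweep; per-cell solver failures are recorded and
    the sweep continues."""
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    n_computed = n_cached = 0
    for re, ht in spec.cells():
        key = _cell_key(spec, re, ht)
        record = None
        if cache:
            f = cache / f"cell_{key}.json"
            if f.exists():
                try:
                    record = json.loads(f.read_text())
                    if record.get("_key") != key:
                        record = None  # corrupted / stale entry: recompute
                except (json.JSONDecodeError, OSError):
                    record = None
        if record is None:
            if progress:
                progress(f"simulating Re={re} hT/bV={ht} ({spec.mode})")
            try:
                case = run_case(
                    re,
                    ht,
                    spec.mode,
                    tier=spec.tier,
                    phases=spec.phases,
                    steady_tol=spec.steady_tol,
                    max_time=spec.max_time,
                    n_cycles=spec.n_cycles,
                    geometry=geometry,
                    ib=ib,
                )
                record = _case_record(case)
            except (SolverError, ConvergenceError, ValueError) as err:
                record = {
                    "re": re,
                    "ht_rel": ht,
                    "mode": spec.mode,
                    "tier": spec.tier,
                    "rollup": "failed",
                    "converged": False,
                    "error": str(err),
                    "phases": [],
                }
            record["_key"] = key
            n_computed += 1
            if cache:
                (cache / f"cell_{key}.json").write_text(json.dumps(record))
        else:
            n_cached += 1
        base = {k: record.get(k) for k in ("re", "ht_rel", "mode", "tier", "rollup", "converged")}
        if record["phases"]:
            for ph in record["phases"]:
                rows.append({**base, **ph})
        else:
            rows.append({**base, "phase": None, "cls": record["rollup"]})
    df = pd.DataFrame(rows)
    meta = {"spec": asdict(spec), "tier": spec.tier}
    return BifurcationTable(df, meta, n_computed, n_cached)


def onset_threshold(
    values: Sequence[float],
    condition: Callable[[float], bool],
    tol: float,
) -> float:
    """Critical parameter value by bisection.

    ``values`` must bracket a change of ``condition`` (False below, True
    above, monotone over the scanned range).  The bracketing pair from the
    simulated set is refined by bisection -- each midpoint evaluation runs
    ``condition``, i.e. a full simulation -- until the bracket half-width is
    at most ``tol``; the final bracket midpoint is returned.
    """
    vals = sorted(values)
    flags = [condition(v) for v in vals]
    if all(flags) or not any(flags):
        raise ValueError("condition does not change across the scanned axis")
    hi_idx = flags.index(True)
    if hi_idx == 0:
        raise ValueError("condition already true at the smallest value")
    lo, hi = vals[hi_idx - 1], vals[hi_idx]
    while (hi - lo) > 2.0 * tol:
        mid = 0.5 * (lo + hi)
        if condition(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


_CLASS_CODES = {
    "none": 0,
    "intertrabecular-only": 1,
    "intracardial-only": 2,
    "both": 3,
    "failed": -1,
}


def summarize(
    table: BifurcationTable,
    csv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Phase-diagram matrix of roll-up class codes over (Re, hT/bV).

    Idempotent for a fixed table.  Codes: 0 none, 1 intertrabecular-only,
    2 intracardial-only, 3 both, -1 failed.
    """
    cells = table.df.drop_duplicates(subset=["re", "ht_rel"])
    pivot = (
        cells.assign(code=cells["rollup"].map(_CLASS_CODES))
        .pivot(index="re", columns="ht_rel", values="code")
        .sort_index()
    )
    if csv_path:
        pivot.to_csv(csv_path)
    if plot_path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(
            pivot.values, origin="lower", aspect="auto", cmap="viridis", vmin=-1, vmax=3
        )
        ax.set_xticks(range(len(pivot.columns)), [f"{c:g}" for c in pivot.columns])
        ax.set_yticks(range(len(pivot.index)), [f"{r:g}" for r in pivot.index])
        ax.set_xlabel("hT / bV")
        ax.set_ylabel("Re")
        ax.set_title("vortex class (0 none, 1 intertrab, 2 intracardial, 3 both)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return pivot
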