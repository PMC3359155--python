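"""Bifurcation diagrams of the switch in the degradation rate and k5.

Steady-state branches of X_T are tracked over a parameter grid by re-solving
the fixed points at every grid value (warm-started at the full/reduced3
levels).  Saddle-node points are detected where the fixed-point count
changes by two and refined by bisection in the parameter.  The continuation
is plain dense-grid root tracking rather than pseudo-arclength: every model
level exposes a cheap, robust root solve, so the transparent method wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ParameterSet
from .reduction import InversionFit, fit_inversion
from .fixed_points import (
    _BASAL_ATOL,
    FixedPointSet,
    solve_fixed_points,
)

__all__ = [
    "BifurcationDiagram",
    "sweep",
    "bistable_range",
    "diagram_agreement",
    "quasistatic_sweep",
]

_BRANCH_JUMP = 0.25     # |dXT| / (1 + XT) branch-matching threshold


def _set_param(params: ParameterSet, name: str, value: float) -> ParameterSet:
    if name in ("lam", "lambda"):
        return params.replace(lambda1=value, lambda2=value)
    return params.replace(**{name: value})


def _distinct_count(fps: FixedPointSet) -> int:
    xts: list[float] = []
    for p in fps.points:
        if not any(abs(p.XT - x) <= max(_BASAL_ATOL, 1e-6 * x) for x in xts):
            xts.append(p.XT)
    return len(xts)


@dataclass
class BifurcationDiagram:
    """Fixed-point branches of X_T versus one swept parameter."""

    parameter: str
    unit: str
    grid: np.ndarray
    sets: list[FixedPointSet]
    saddle_nodes: list[float]
    model_level: str

    def counts(self) -> np.ndarray:
        return np.array([_distinct_count(s) for s in self.sets])

    def branch(self, which: str) -> pd.DataFrame:
        """One branch ('upper', 'lower', 'unstable') across the grid."""
        rows = []
        for g, s in zip(self.grid, self.sets):
            if which in ("upper", "lower"):
                pts = s.stable()
                if not pts:
                    continue
                pt = max(pts, key=lambda p: p.XT) if which == "upper" \
                    else min(pts, key=lambda p: p.XT)
                # a mono-stable point belongs to whichever branch it continues
                if which == "upper" and len(pts) == 1 and _distinct_count(s) == 1 \
                        and pt.XT < _BASAL_ATOL:
                    continue
            else:
                pts = s.unstable()
                if not pts:
                    continue
                pt = max(pts, key=lambda p: p.XT)
            rows.append({"param_value": g, "XT": pt.XT,
                         "stability": pt.stability})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, s in zip(self.grid, self.sets):
            for i, p in enumerate(s.points):
                rows.append({"param_value": g, "branch_id": i, "XT": p.XT,
                             "stability": p.stability,
                             "model_level": self.model_level})
        return pd.DataFrame(rows)


def _refine_saddle(params: ParameterSet, name: str, lo: float, hi: float,
                   lo_count: int, model_level: str,
                   fit: InversionFit | None, rel_tol: float = 1e-3) -> float:
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        c = _distinct_count(
            solve_fixed_points(_set_param(params, name, mid), model_level, fit=fit))
        if c == lo_count:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sweep(params: ParameterSet, parameter: str, grid: np.ndarray,
          model_level: str = "quartic", fit: InversionFit | None = None,
          refine: bool = True) -> BifurcationDiagram:
    """Track all fixed-point branches over a parameter grid.

    ``parameter`` is a ParameterSet field name, or "lam" to move both
    degradation rates together.  For the one_d level a single inversion fit
    sized for the largest upper state on the grid is reused across the
    sweep unless one is supplied.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty sweep grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly ascending")
    if model_level == "one_d" and fit is None:
        widest = max(
            (_set_param(params, parameter, g) for g in grid),
            key=lambda p: _upper_estimate(p),
        )
        fit = fit_inversion(widest)
    sets = [solve_fixed_points(_set_param(params, parameter, g), model_level,
                               fit=fit)
            for g in grid]
    counts = [_distinct_count(s) for s in sets]
    saddles = []
    for i in range(len(grid) - 1):
        if abs(counts[i + 1] - counts[i]) >= 2:
            saddles.append(
                _refine_saddle(params, parameter, grid[i], grid[i + 1],
                               counts[i], model_level, fit)
                if refine else 0.5 * (grid[i] + grid[i + 1]))
    unit = "s^-1" if parameter in ("lam", "lambda", "lambda1", "lambda2") \
        else "uM^-1 s^-1"
    return BifurcationDiagram(parameter=parameter, unit=unit, grid=grid,
                              sets=sets, saddle_nodes=saddles,
                              model_level=model_level)


def _upper_estimate(params: ParameterSet) -> float:
    """Cheap upper-state estimate c/lambda for sizing fit domains."""
    from .model_core import derive_constants
    d = derive_constants(params)
    return d.c / params.lam if params.lam > 0 else 0.0


def bistable_range(diagram: BifurcationDiagram) -> tuple[float, float, float] | None:
    """The contiguous swept-parameter interval with three fixed points.

    Returns (lo, hi, width_in_decades), or None if the diagram is
    mono-stable everywhere.  Decade width is measured on the grid's
    bistable extremes; when several bistable islands exist the widest
    contiguous one is reported.
    """
    if diagram.grid.size < 2:
        raise ValueError("bistable_range needs a diagram with >= 2 grid points")
    mask = diagram.counts() >= 3
    if not mask.any():
        return None
    best = (0, -1)
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    lo, hi = float(diagram.grid[best[0]]), float(diagram.grid[best[1]])
    decades = math.log10(hi / lo) if lo > 0 else float("inf")
    return lo, hi, decades


def diagram_agreement(diagrams: list[BifurcationDiagram],
                      match_tol: float = 0.15) -> dict:
    """Branch-wise comparison of diagrams sharing one grid.

    The verdict is "match" when the upper, lower and unstable branches of
    every diagram agree with the first diagram's within ``match_tol``
    relative (absolute near the basal state) wherever both exist.
    """
    if len(diagrams) < 2:
        raise ValueError("need at least two diagrams to compare")
    ref = diagrams[0]
    for d in diagrams[1:]:
        if d.parameter != ref.parameter or not np.array_equal(d.grid, ref.grid):
            raise ValueError("diagrams must share the swept parameter and grid")
    per_branch = {}
    for which in ("upper", "lower", "unstable"):
        worst = 0.0
        bref = ref.branch(which).set_index("param_value")["XT"]
        for d in diagrams[1:]:
            bd = d.branch(which).set_index("param_value")["XT"]
            common = bref.index.intersection(bd.index)
            for g in common:
                x0, x1 = bref.loc[g], bd.loc[g]
                disc = abs(x1 - x0) if x0 < _BASAL_ATOL else abs(x1 - x0) / x0
                worst = max(worst, float(disc))
        per_branch[which] = worst
    verdict = "match" if all(v <= match_tol for v in per_branch.values()) \
        else "mismatch"
    return {"per_branch": per_branch, "verdict": verdict,
            "max_discrepancy": max(per_branch.values())}


def quasistatic_sweep(params: ParameterSet, parameter: str, grid: np.ndarray,
                      model_level: str = "reduced3", direction: str = "forward",
                      fit: InversionFit | None = None) -> pd.DataFrame:
    """Hysteresis probe: track the realized state while stepping a parameter.

    At each grid value the system is integrated to equilibrium from the
    state realized at the previous value; jumps between branches occur at
    (approximately) the saddle-node parameters.  Returns a table of
    (param_value, XT_settled).
    """
    from .dynamics import StimulusProtocol, integrate, up_state_initial

    grid = np.asarray(grid, dtype=float)
    order = grid if direction == "forward" else grid[::-1]
    p0 = _set_param(params, parameter, order[0])
    fps0 = solve_fixed_points(p0, "quartic")
    if direction == "forward":
        try:
            y = up_state_initial(p0, model_level, fps=fps0)
            # start settled on the upper branch
            proto = StimulusProtocol(t_on=1.0, duration=10.0, U_stim=10.0)
            y = integrate(p0, y, proto, 50.0 / p0.lam, model_level,
                          fit=fit, n_eval=16).final_state
        except ValueError:
            y = None
    else:
        y = None
    if y is None:
        from .dynamics import basal_initial
        y = basal_initial(p0, model_level)
    null_proto = StimulusProtocol(t_on=0.0, duration=0.0, U_stim=1e-6,
                                  U_baseline=1e-6)
    rows = []
    for g in order:
        pg = _set_param(params, parameter, g)
        traj = integrate(pg, y, null_proto, 30.0 / pg.lam, model_level,
                         fit=fit, n_eval=16)
        y = traj.final_state
        rows.append({"param_value": float(g), "XT": float(traj.xt[-1])})
    return pd.DataFrame(rows)
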