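"""Time-domain simulation of the loop through Ca4CaM stimulus protocols.

A square Ca4CaM pulse transiently activates the kinase; whether the system
then settles into the up- or down-regulated state depends on which side of
the separatrix (the unstable fixed point) the slow variables end up on.
Because maximal synthesis is capped at ``c`` (about 1e-2 uM/s at the
reference configuration), climbing from the basal level to the upper state
takes on the order of 1/lambda; simulations therefore integrate for tens of
degradation time constants.

A quantitative constraint worth knowing when designing protocols: starting
from the resting state (total kinase ~1e-4 uM) no 10-second Ca4CaM pulse of
*any* amplitude can recruit enough phospho-CPEB1 to cross the separatrix --
the pulse can at most phosphorylate the kinase already present, and that
pool is four orders of magnitude too small.  Up-state runs therefore start
from a supra-threshold pool of *inactive* kinase (see
:func:`up_state_initial`); the pulse then supplies the activation seed that
ignites autophosphorylation and locks the loop on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import ParameterSet, _full_rhs_raw, total_camkii
from .reduction import InversionFit, fit_inversion, one_d_rhs, reduced3_rhs
from .fixed_points import FixedPointSet, solve_fixed_points

__all__ = [
    "StimulusProtocol",
    "Trajectory",
    "integrate",
    "basal_initial",
    "up_state_initial",
    "switching_threshold",
    "time_to_half_max",
]

_RTOL = 1e-8
_ATOL = 1e-12   # uM; the basal state sits six decades below the upper state


@dataclass(frozen=True)
class StimulusProtocol:
    """A square Ca4CaM pulse: U = U_stim on [t_on, t_on + duration)."""

    t_on: float = 10.0
    duration: float = 10.0
    U_stim: float = 10.0
    U_baseline: float = 1e-6

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not (self.U_stim >= self.U_baseline >= 0):
            raise ValueError("need U_stim >= U_baseline >= 0")

    def U(self, t: float) -> float:
        if self.t_on <= t < self.t_on + self.duration:
            return self.U_stim
        return self.U_baseline

    def edges(self, t_end: float) -> list[float]:
        cuts = [0.0, self.t_on, self.t_on + self.duration, t_end]
        return sorted({t for t in cuts if 0.0 <= t <= t_end})


@dataclass
class Trajectory:
    """An integrated time course at one model level."""

    t: np.ndarray
    y: np.ndarray                  # shape (n_states, n_times)
    model_level: str
    protocol: StimulusProtocol
    params: ParameterSet

    @property
    def xt(self) -> np.ndarray:
        if self.model_level == "full":
            return self.y[0] + self.y[1] + 2.0 * self.y[3] + self.y[4]
        return self.y[0]           # reduced3 and one_d carry XT first

    @property
    def final_state(self) -> np.ndarray:
        return self.y[:, -1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"full": ["X", "XP", "YP", "C1", "C2", "C3"],
                "reduced3": ["XT", "XP", "YP"],
                "one_d": ["XT"]}[self.model_level]
        df = pd.DataFrame(self.y.T, columns=cols)
        df.insert(0, "t", self.t)
        df["XT"] = self.xt
        return df


def _rhs_for_level(params: ParameterSet, model_level: str,
                   fit: InversionFit | None) -> Callable:
    if model_level == "full":
        return lambda t, y, U: _full_rhs_raw(y, params, U)
    if model_level == "reduced3":
        return lambda t, y, U: reduced3_rhs(y, params, U)
    if model_level == "one_d":
        if fit is None:
            raise ValueError("one_d integration needs an InversionFit")
        # Ca4CaM does not enter the 1-D balance; U is accepted and ignored
        return lambda t, y, U: np.array(
            [one_d_rhs(min(max(y[0], 0.0), fit.domain_hi), params, fit)])
    raise ValueError(f"unknown model level {model_level!r}")


def basal_initial(params: ParameterSet, model_level: str) -> np.ndarray:
    """The resting (down-state) initial condition."""
    if model_level == "full":
        return np.array([params.Xbasal, params.XPbasal, 0.0, 0.0, 0.0, 0.0])
    if model_level == "reduced3":
        return np.array([params.Xbasal + params.XPbasal, params.XPbasal, 0.0])
    if model_level == "one_d":
        return np.array([params.Xbasal + params.XPbasal])
    raise ValueError(f"unknown model level {model_level!r}")


def up_state_initial(params: ParameterSet, model_level: str,
                     pool_factor: float = 2.0,
                     fps: FixedPointSet | None = None) -> np.ndarray:
    """A supra-threshold pool of inactive kinase for up-state runs.

    The pool is ``pool_factor`` times the separatrix X_T (quartic level),
    delivered entirely as free, inactive X; the stimulus pulse must still
    activate it before the loop can latch.
    """
    if fps is None:
        fps = solve_fixed_points(params, "quartic")
    unstable = fps.unstable()
    if not unstable:
        raise ValueError("system is not bistable: no separatrix to clear")
    pool = pool_factor * max(p.XT for p in unstable)
    if model_level == "full":
        return np.array([pool, params.XPbasal, 0.0, 0.0, 0.0, 0.0])
    if model_level == "reduced3":
        return np.array([pool, params.XPbasal, 0.0])
    if model_level == "one_d":
        return np.array([pool])
    raise ValueError(f"unknown model level {model_level!r}")


def integrate(params: ParameterSet, y0: Sequence[float],
              protocol: StimulusProtocol, t_end: float,
              model_level: str = "full", fit: InversionFit | None = None,
              n_eval: int = 400, rtol: float = _RTOL,
              atol: float = _ATOL) -> Trajectory:
    """Integrate one model level through a stimulus protocol.

    The pulse edges are integration breakpoints (the stiff integrator never
    smooths across the discontinuity in U).  States are clipped to zero
    from below within a -1e-9 uM numerical slack; a larger excursion aborts
    the run.
    """
    if t_end <= protocol.t_on + protocol.duration and protocol.duration > 0:
        raise ValueError("t_end must exceed the end of the stimulus pulse")
    rhs = _rhs_for_level(params, model_level, fit)
    y = np.asarray(y0, dtype=float)
    edges = protocol.edges(t_end)
    ts, ys = [np.array([0.0])], [y[:, None]]
    for left, right in zip(edges[:-1], edges[1:]):
        if right <= left:
            continue
        U = protocol.U(0.5 * (left + right))
        n_seg = max(int(n_eval * (right - left) / t_end), 10)
        t_eval = np.linspace(left, right, n_seg)
        sol = solve_ivp(rhs, (left, right), y, args=(U,), method="LSODA",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{left}, {right}] s: {sol.message}")
        if sol.y.min() < -1e-9:
            raise RuntimeError(
                f"state went negative ({sol.y.min():.3g}) on [{left}, {right}] s")
        ts.append(sol.t[1:])
        ys.append(np.clip(sol.y[:, 1:], 0.0, None))
        y = np.clip(sol.y[:, -1], 0.0, None)
    t = np.concatenate(ts)
    return Trajectory(t=t, y=np.concatenate(ys, axis=1),
                      model_level=model_level, protocol=protocol, params=params)


def _settles_up(params: ParameterSet, y0: np.ndarray,
                protocol: StimulusProtocol, model_level: str,
                fit: InversionFit | None, separatrix_xt: float,
                t_end: float) -> bool:
    traj = integrate(params, y0, protocol, t_end, model_level, fit=fit, n_eval=16)
    return float(traj.xt[-1]) > separatrix_xt


def switching_threshold(params: ParameterSet, model_level: str = "reduced3",
                        family: str = "pool",
                        protocol: StimulusProtocol | None = None,
                        lo: float = 0.0, hi: float = 1e3,
                        rel_tol: float = 0.01,
                        fit: InversionFit | None = None) -> float | None:
    """Minimal stimulus that reaches the upper basin, by bisection.

    ``family`` selects the swept protocol parameter: "pool" scales the
    initial inactive-kinase pool (uM), "amplitude" the pulse U_stim (uM),
    "duration" the pulse length (s).  Returns None when the system is
    mono-stable, and raises if even the upper bracket end fails to switch
    (as every amplitude does from the basal state; see the module note).
    """
    fps = solve_fixed_points(params, "quartic")
    if not fps.bistable:
        return None
    separatrix = max(p.XT for p in fps.unstable())
    if model_level == "one_d" and fit is None:
        fit = fit_inversion(params)
    if protocol is None:
        protocol = StimulusProtocol()
    t_end = 30.0 / params.lam

    def run(value: float) -> bool:
        if family == "pool":
            y0 = basal_initial(params, model_level).copy()
            y0[0] = value
            proto = protocol
        elif family == "amplitude":
            y0 = basal_initial(params, model_level)
            proto = replace(protocol, U_stim=max(value, protocol.U_baseline))
        elif family == "duration":
            y0 = basal_initial(params, model_level)
            proto = replace(protocol, duration=value)
        else:
            raise ValueError(f"unknown protocol family {family!r}")
        return _settles_up(params, y0, proto, model_level, fit, separatrix, t_end)

    if run(lo):
        return lo
    if not run(hi):
        raise ValueError(
            f"{family} sweep never switches up to {hi}; no threshold in range")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if run(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def time_to_half_max(traj: Trajectory) -> float:
    """First time X_T crosses halfway between its initial and final values."""
    xt = traj.xt
    half = 0.5 * (xt[0] + xt[-1])
    above = np.where(xt >= half)[0] if xt[-1] > xt[0] else np.where(xt <= half)[0]
    if len(above) == 0:
        return float("inf")
    return float(traj.t[above[0]])
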