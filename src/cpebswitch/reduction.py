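"""Staged reductions of the polyadenylation loop.

Three nested approximations connect the six-variable mass-action model to a
single synthesis-degradation balance:

1. *Pseudo-steady-state* elimination of the three complexes gives a 3-ODE
   model in (X_T, X_P, Y_P), with free CPEB1 approximated by Y = Y_T - Y_P
   and free kinase recovered algebraically from the composition.
2. Setting the phospho-CPEB1 and phospho-kinase equations to steady state
   collapses the X_P dynamics onto a nullcline X_T = f(X_P), whose numeric
   inversion h = f^-1 (a degree-9 zero-intercept polynomial fit) yields
3. a single ODE dX_T/dt = G'(X_T) - F(X_T) with the saturating synthesis
   function G'(X_T) = c h(X_T) / (h(X_T) + P7/a) and linear degradation
   F(X_T) = lambda X_T.

The fixed points of level 3 are the graphical intersections of G' and F;
level 2's fixed points are the roots of a quartic polynomial in X_P (see
:mod:`cpebswitch.fixed_points`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import (
    DerivedConstants,
    DomainError,
    InfeasibleCompositionError,
    InvalidParameterError,
    ParameterSet,
    derive_constants,
)

__all__ = [
    "ReducedState",
    "InversionFit",
    "pssa_complexes",
    "yp_nullcline",
    "x_free",
    "reduced3_rhs",
    "xt_of_xp",
    "xt_of_xp_closed_form",
    "xt_of_xp_printed",
    "fit_inversion",
    "synthesis_rate",
    "one_d_rhs",
    "curve_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ReducedState:
    """State of the 3-ODE model: total, phospho-kinase and phospho-CPEB1."""

    XT: float
    XP: float
    YP: float

    def as_array(self) -> np.ndarray:
        return np.array([self.XT, self.XP, self.YP])


def pssa_complexes(X: float, XP: float, Y: float, YP: float,
                   params: ParameterSet) -> tuple[float, float, float]:
    """Complex concentrations under the pseudo-steady-state assumption.

    C1 = k1 X X_P/(k2+k3), C2 = k5 Y X_P/(k55+k6), C3 = k8 Y_P T/(k88+k9).
    """
    if min(X, XP, Y, YP) < 0:
        raise ValueError("concentrations must be non-negative")
    d = derive_constants(params)
    return (d.M * X * XP, d.N * Y * XP,
            params.k8 * YP * params.T / (params.k88 + params.k9))


def yp_nullcline(XP: float, params: ParameterSet,
                 d: DerivedConstants | None = None) -> float:
    """Steady-state phospho-CPEB1 at a given phospho-kinase level.

    Y_P = a Y_T X_P / (k7 P + a X_P): a saturating curve with half-maximum at
    X_P = P7/a and asymptote Y_T.
    """
    if XP < 0:
        raise ValueError("XP must be non-negative")
    if d is None:
        d = derive_constants(params)
    denom = d.P7 + d.a * XP
    if denom == 0:
        raise DomainError("k7*P + a*XP == 0: phospho-CPEB1 level is undetermined")
    return d.a * params.YT * XP / denom


def _x_free_raw(XT: float, XP: float, params: ParameterSet,
                YP: float, d: DerivedConstants) -> float:
    # X (1 + 2 M XP) = XT - XP - N (YT - YP) XP, from XT = X + XP + 2C1 + C2
    return (XT - XP - d.N * (params.YT - YP) * XP) / (1.0 + 2.0 * d.M * XP)


def x_free(XT: float, XP: float, params: ParameterSet,
           YP: float | None = None) -> float:
    """Free, inactive kinase for a given composition.

    With ``YP=None`` the phospho-CPEB1 level is taken on its nullcline, which
    is the form used in the steady-state elimination; passing the dynamical
    ``YP`` gives the 3-ODE model's instantaneous closure.
    """
    if not (XT >= XP >= 0):
        raise ValueError(f"need XT >= XP >= 0, got XT={XT}, XP={XP}")
    d = derive_constants(params)
    if YP is None:
        YP = yp_nullcline(XP, params, d)
    X = _x_free_raw(XT, XP, params, YP, d)
    if X < 0:
        raise InfeasibleCompositionError(
            f"composition XT={XT}, XP={XP} leaves negative free kinase ({X:.3g})"
        )
    return X


def reduced3_rhs(state, params: ParameterSet, U: float) -> np.ndarray:
    """Right-hand side of the 3-ODE reduced model (uM/s).

    dX_T/dt = k9 C3 - lambda X_T balances synthesis against degradation of
    the *total* pool (the key approximation: bound kinase degrades too);
    dY_P/dt = -k7 P Y_P + a (Y_T - Y_P) X_P; the X_P equation keeps the
    activation/autophosphorylation/deactivation fluxes with the complexes
    eliminated.  Free kinase that the composition cannot support is floored
    at zero (the trajectory is then steered back into the feasible wedge).
    """
    lam = params.lam
    XT, XP, YP = np.asarray(state, dtype=float)
    d = derive_constants(params)
    X = max(_x_free_raw(XT, XP, params, YP, d), 0.0)
    C3 = params.k8 * YP * params.T / (params.k88 + params.k9)
    dXT = params.k9 * C3 - lam * XT
    dYP = -d.P7 * YP + d.a * (params.YT - YP) * XP
    dXP = X * (d.a1 * XP + params.k10 * U) - d.DI * XP
    return np.array([dXT, dXP, dYP])


def xt_of_xp_closed_form(XP: float, params: ParameterSet,
                         U: float | None = None) -> float:
    """X_P-nullcline value of X_T, by direct algebraic elimination.

    X_T = I1 + I2 + I3 + I4 with I1 = DI X_P/(a1 X_P + a2) the free kinase,
    I2 = 2 M X_P I1 the autophosphorylation complex, I3 = X_P, and
    I4 = N (Y_T - Y_P) X_P the CPEB1 complex with Y_P on its nullcline.
    """
    if XP < 0:
        raise ValueError("XP must be non-negative")
    if XP == 0:
        return 0.0
    d = derive_constants(params, U)
    denom = d.a1 * XP + d.a2
    if denom == 0:
        raise DomainError("a1*XP + k10*U == 0: free kinase undetermined")
    X = d.DI * XP / denom
    YP = yp_nullcline(XP, params, d)
    return X * (1.0 + 2.0 * d.M * XP) + XP + d.N * (params.YT - YP) * XP


def xt_of_xp(XP: float, params: ParameterSet, U: float | None = None) -> float:
    """X_P-nullcline value of X_T, by bracketed numeric elimination.

    Solves dX_P/dt = 0 of the reduced model (with Y_P on its nullcline) for
    X_T with a bracketed one-dimensional root search.  The closed form is
    used as the seed and cross-check; a disagreement above 0.1% relative is
    logged, never averaged.
    """
    if XP < 0:
        raise ValueError("XP must be non-negative")
    if XP == 0:
        return 0.0
    if U is None:
        U = params.U_basal
    d = derive_constants(params, U)
    YP = yp_nullcline(XP, params, d)

    def dxp_dt(XT: float) -> float:
        X = _x_free_raw(XT, XP, params, YP, d)
        return X * (d.a1 * XP + d.a2) - d.DI * XP

    guess = xt_of_xp_closed_form(XP, params, U)
    lo = max(0.0, 0.5 * guess - 1.0)
    hi = 2.0 * guess + 1.0
    # dxp_dt is strictly increasing in XT; widen the bracket if needed
    for _ in range(60):
        if dxp_dt(lo) < 0 < dxp_dt(hi):
            break
        lo = max(0.0, lo - (hi - lo))
        hi = 2.0 * hi + 1.0
    else:
        raise DomainError(f"no bracketing root of dXP/dt=0 for XP={XP}")
    root = brentq(dxp_dt, lo, hi, xtol=1e-14, rtol=1e-14)
    if abs(root - guess) > 1e-3 * max(abs(root), 1e-12):
        logger.warning(
            "xt_of_xp: numeric elimination (%.6g) and closed form (%.6g) "
            "disagree at XP=%.6g", root, guess, XP,
        )
    return float(root)


def xt_of_xp_printed(XP: float, params: ParameterSet,
                     U: float | None = None) -> float:
    """Diagnostic variant of the X_T = f(X_P) map, term-for-term as published.

    The I4 term's denominator here reads ``k6/d1 + X_P/P7``; exact
    elimination gives ``k6/d1 + k6 X_P/P7`` (a dropped factor k6 in the
    second summand), so this variant deviates slightly.  Kept only to
    quantify that deviation; disagreements above 1% are logged.
    """
    if XP < 0:
        raise ValueError("XP must be non-negative")
    if XP == 0:
        return 0.0
    d = derive_constants(params, U)
    denom = d.a1 * XP + d.a2
    if denom == 0:
        raise DomainError("a1*XP + k10*U == 0")
    i1 = d.DI * XP / denom
    i2 = d.DI * XP ** 2 / (params.k3 * XP / 2.0 + params.k3 * d.a2 / (2.0 * d.a1))
    i3 = XP
    i4 = XP * params.YT / (params.k6 / d.d1 + XP / d.P7)
    value = i1 + i2 + i3 + i4
    exact = xt_of_xp_closed_form(XP, params, U)
    if abs(value - exact) > 0.01 * max(abs(exact), 1e-12):
        logger.warning(
            "printed X_T=f(X_P) deviates from elimination by %.3g%% at XP=%.6g",
            100.0 * abs(value - exact) / max(abs(exact), 1e-12), XP,
        )
    return value


@dataclass
class InversionFit:
    """Degree-9 zero-intercept polynomial inversion X_P = h(X_T).

    ``coefficients`` are a_1..a_9 of h(X_T) = sum_i a_i (X_T/scale)^i where
    ``scale`` keeps the Vandermonde basis conditioned.  ``domain_lo`` marks
    where the fitted inverse becomes reliable: below it (the basal shoulder
    and the knee of f) the fit is known to degrade, exactly as a low-order
    polynomial must at a near-ramp function.  h(0) = 0 holds exactly because
    the basis has no constant term.
    """

    coefficients: np.ndarray
    scale: float
    domain_lo: float
    domain_hi: float
    max_abs_residual: float
    grid_size: int

    def __call__(self, XT) -> np.ndarray | float:
        u = np.asarray(XT, dtype=float) / self.scale
        out = np.zeros_like(u)
        for c in self.coefficients[::-1]:       # Horner on u, zero intercept
            out = u * (out + c)
        return out if out.ndim else float(out)

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["coefficients"] = list(self.coefficients)
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InversionFit":
        data = json.loads(Path(path).read_text())
        data["coefficients"] = np.asarray(data["coefficients"], dtype=float)
        return cls(**data)


_FIT_DEGREE = 9
_ROUND_TRIP_TOL = 0.02


def fit_inversion(params: ParameterSet, domain_hi: float | None = None,
                  grid_size: int = 500) -> InversionFit:
    """Least-squares inversion of X_T = f(X_P) on [0, domain_hi].

    The grid mixes a geometric and a linear ladder of X_P values (half
    each), which concentrates samples around the knee of f where the
    inverse is hardest; the fit is unweighted with basis X_T^1..X_T^9.  When
    ``domain_hi`` is omitted it defaults to 1.5x the largest steady-state
    X_T, so the fit covers the whole physiological branch structure.
    """
    if grid_size < 50:
        raise ValueError("grid_size must be >= 50")
    if domain_hi is None:
        from .fixed_points import solve_fixed_points  # deferred: cyclic module pair
        fps = solve_fixed_points(params, "quartic")
        if not fps.points:
            raise DomainError("cannot infer a fit domain: no fixed points found")
        domain_hi = 1.5 * max(pt.XT for pt in fps.points)
    if domain_hi <= 0:
        raise ValueError("domain_hi must be positive")

    xp_hi = brentq(lambda x: xt_of_xp(x, params) - domain_hi, 1e-9, 1e9)
    half = grid_size // 2
    xps = np.unique(np.concatenate([
        [0.0],
        np.geomspace(1e-4, xp_hi, half),
        np.linspace(xp_hi / (grid_size - half), xp_hi, grid_size - half),
    ]))
    xts = np.array([xt_of_xp(x, params) for x in xps])
    scale = float(xts.max())
    u = xts / scale
    V = np.vander(u, _FIT_DEGREE + 1, increasing=True)[:, 1:]
    cond = np.linalg.cond(V)
    if cond > 1e12:
        logger.warning("inversion fit basis poorly conditioned (cond=%.3g)", cond)
    coef, *_ = np.linalg.lstsq(V, xps, rcond=None)
    fitted = V @ coef
    resid = np.abs(fitted - xps)

    # validity floor: smallest XT above which the round trip f(h(XT)) ~ XT
    # stays within tolerance all the way to the top of the domain
    ok = np.array([
        abs(xt_of_xp(max(h, 0.0), params) - xt) <= _ROUND_TRIP_TOL * xt
        if xt > 0 else True
        for h, xt in zip(fitted, xts)
    ])
    bad = np.where(~ok)[0]
    lo_idx = (bad.max() + 1) if bad.size else 1
    domain_lo = float(xts[lo_idx]) if lo_idx < len(xts) else float(xts[-1])

    return InversionFit(
        coefficients=np.asarray(coef), scale=scale,
        domain_lo=domain_lo, domain_hi=float(domain_hi),
        max_abs_residual=float(resid.max()), grid_size=int(len(xps)),
    )


def synthesis_rate(XT, params: ParameterSet, fit: InversionFit):
    """Synthesis function G'(X_T) = c h(X_T)/(h(X_T) + P7/a) (uM/s).

    ``h`` is clamped below at zero: small negative excursions of the
    polynomial fit would otherwise produce a negative synthesis rate, which
    the underlying kinetics cannot.
    """
    d = derive_constants(params)
    h = np.maximum(np.asarray(fit(XT), dtype=float), 0.0)
    K = d.P7 / d.a
    return d.c * h / (h + K)


def one_d_rhs(XT: float, params: ParameterSet, fit: InversionFit) -> float:
    """Single-ODE dynamics dX_T/dt = G'(X_T) - lambda X_T (uM/s)."""
    lam = params.lam
    if not (0.0 <= XT <= fit.domain_hi):
        raise DomainError(
            f"XT={XT} outside the inversion-fit domain [0, {fit.domain_hi}]"
        )
    return float(synthesis_rate(XT, params, fit)) - lam * XT


def curve_table(params: ParameterSet, fit: InversionFit,
                n: int = 200) -> pd.DataFrame:
    """Sampled G'/F curves and nullcline, for CSV export and plotting."""
    lam = params.lam
    xts = np.linspace(0.0, fit.domain_hi, n)
    g = synthesis_rate(xts, params, fit)
    return pd.DataFrame({
        "XT": xts,
        "XP": np.maximum(fit(xts), 0.0),
        "G_prime": g,
        "F": lam * xts,
    })
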