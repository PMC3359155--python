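"""Steady states of the polyadenylation loop at every model level.

At steady state the reduced system collapses to a single polynomial
condition in X_P.  Eliminating Y_P (its nullcline), X (the X_P nullcline)
and X_T (the synthesis-degradation balance) and clearing the two rational
denominators (a1 X_P + a2) and (a X_P + P7) yields

    X_P * [ lambda ( DI (1 + 2 M X_P)(a X_P + P7)
                     + (a1 X_P + a2)(a X_P + P7) X_P-term
                     + N Y_T P7 (a1 X_P + a2) )
            - c a (a1 X_P + a2) ] = 0,

a cubic multiplied by X_P.  The quartic form used throughout this package
retains the common factor (a X_P + P7) of the two rational terms before
cancellation, which raises the degree to four without changing any
non-negative root: the extra root sits at X_P = -P7/a < 0.  The constant
term is identically zero, so X_P = 0 (the basal state) is always a
solution.  Real non-negative roots are mapped to X_T through the
X_P-nullcline and classified by the sign of the flow across them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy.optimize import brentq, root

from .model_core import (
    InvalidParameterError,
    ParameterSet,
    derive_constants,
    _full_rhs_raw,
)
from .reduction import (
    InversionFit,
    fit_inversion,
    one_d_rhs,
    reduced3_rhs,
    xt_of_xp,
    yp_nullcline,
)

__all__ = [
    "ModelLevel",
    "SteadyPolynomial",
    "FixedPoint",
    "FixedPointSet",
    "steady_state_polynomial",
    "printed_z_coefficients",
    "compare_printed_quartic",
    "solve_fixed_points",
    "classify_stability",
    "compare_levels",
]

logger = logging.getLogger(__name__)

ModelLevel = Literal["full", "reduced3", "one_d", "quartic"]
MODEL_LEVELS: tuple[str, ...] = ("full", "reduced3", "one_d", "quartic")

_STABILITY_TOL = 1e-10      # |leading eigenvalue| below this -> marginal
_IMAG_TOL = 1e-9            # relative imaginary tolerance for polynomial roots
_RESIDUAL_TOL = 1e-9        # uM/s, max |rhs| at an accepted root
_BASAL_ATOL = 0.5           # uM, absolute dedup tolerance on the basal branch


@dataclass
class SteadyPolynomial:
    """Quartic steady-state polynomial in X_P (ascending coefficients).

    ``provenance`` records whether the coefficients come from the exact
    algebraic elimination ("eliminated") or from the published z-coefficient
    formulas ("printed-z"); the latter contain an undefined symbol and are
    kept for diagnostics only.
    """

    coefficients: np.ndarray
    provenance: str = "eliminated"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise ValueError("steady-state polynomial must have degree 4")
        if self.coefficients[0] != 0.0:
            raise ValueError("constant term must be identically zero")

    @property
    def degree(self) -> int:
        return 4

    def __call__(self, xp):
        return P.polyval(xp, self.coefficients)

    def real_nonnegative_roots(self) -> np.ndarray:
        coeffs = self.coefficients
        lead = np.max(np.abs(coeffs))
        if lead == 0:
            raise InvalidParameterError("steady-state polynomial is identically zero")
        if abs(coeffs[-1]) < 1e-300 * lead:
            logger.warning("degenerate leading coefficient; solving lower degree")
            coeffs = np.trim_zeros(coeffs, "b")
        r = P.polyroots(coeffs)
        keep = np.abs(r.imag) <= _IMAG_TOL * np.maximum(np.abs(r), 1.0)
        r = np.real(r[keep])
        r = r[r >= -1e-12]
        r[r < 0] = 0.0
        return np.unique(np.sort(r))


def steady_state_polynomial(params: ParameterSet,
                            U: float | None = None) -> SteadyPolynomial:
    """Exact elimination of the reduced steady state into a quartic in X_P."""
    lam = params.lam
    d = derive_constants(params, U)
    den1 = np.array([d.a2, d.a1])          # a1 XP + a2
    den2 = np.array([d.P7, d.a])           # a XP + P7
    q2 = P.polyadd(d.DI * P.polymul([1.0, 2.0 * d.M], den2),
                   P.polymul(den1, den2))
    q2 = P.polyadd(q2, d.N * params.YT * d.P7 * den1)
    q2 = P.polysub(lam * q2, d.c * d.a * den1)
    cubic = P.polymul([0.0, 1.0], q2)      # X_P = 0 always a root
    if d.P7 > 0:
        quart = P.polymul(cubic, den2 / d.P7)   # retained common factor
    else:
        quart = P.polymul(cubic, [1.0, 0.0])    # degenerate: pad degree
    quart = np.pad(quart, (0, 5 - len(quart)))[:5]
    quart[0] = 0.0
    return SteadyPolynomial(quart, provenance="eliminated")


def printed_z_coefficients(params: ParameterSet, F: float,
                           U: float | None = None) -> dict[str, float]:
    """The published z1..z14 ladder, with the undefined symbol F supplied.

    The published quartic coefficients contain a symbol F that is never
    defined; this evaluates the ladder verbatim for a candidate value so
    that :func:`compare_printed_quartic` can report how far every plausible
    reading lands from the exact elimination.
    """
    d = derive_constants(params, U)
    if U is None:
        U = params.U_basal
    k10U = params.k10 * U
    z = {}
    z["z1"] = d.a * d.c * d.M * params.k3 * d.P7
    z["z2"] = d.a * d.c * k10U * d.P7
    z["z3"] = d.a ** 2 * d.c * d.M * params.k3
    z["z4"] = d.a ** 2 * d.c * F * k10U
    z["z5"] = 2 * d.P4 * d.M * F + 2 * d.M * params.k1010 * F + F * d.M * params.k3
    z["z6"] = (2 * d.P4 * d.P7 * d.M + 2 * d.M * d.P7 * params.k1010
               + F * d.P4 + F * params.k1010 + d.M * params.k3 * d.P7
               + F * k10U + d.N * d.M * params.k3 * params.YT)
    z["z7"] = (d.P7 * d.P4 + d.P7 * params.k1010 + k10U * d.P7
               + d.N * k10U * d.P7 * params.YT)
    z["z8"] = d.a * z["z5"]
    z["z9"] = d.a * z["z6"] + d.P7 * z["z5"] - z["z3"]
    z["z10"] = d.a * z["z7"] + d.P7 * z["z6"] - z["z1"] - z["z4"]
    z["z11"] = d.P7 * z["z7"] - z["z2"]
    for k in ("z12", "z13", "z14"):
        src = {"z12": "z9", "z13": "z10", "z14": "z11"}[k]
        z[k] = z[src] / z["z8"] if z["z8"] != 0 else float("nan")
    return z


def compare_printed_quartic(params: ParameterSet,
                            candidates: dict[str, float] | None = None) -> pd.DataFrame:
    """Root-level comparison of printed-z quartics against the elimination.

    Each candidate interpretation of the undefined symbol F is substituted,
    the resulting monic quartic rooted, and the non-negative roots compared
    with the eliminated polynomial's.  Mismatches are logged and returned,
    never silently reconciled.
    """
    d = derive_constants(params)
    if candidates is None:
        candidates = {"F=1": 1.0, "F=P7": d.P7, "F=P4": d.P4,
                      "F=a": d.a, "F=DI": d.DI}
    exact = steady_state_polynomial(params).real_nonnegative_roots()
    rows = []
    for label, F in candidates.items():
        z = printed_z_coefficients(params, F)
        coeffs = np.array([0.0, z["z14"], z["z13"], z["z12"], 1.0])
        try:
            roots = SteadyPolynomial(coeffs, provenance="printed-z").real_nonnegative_roots()
        except (ValueError, InvalidParameterError):
            roots = np.array([])
        agree = (len(roots) == len(exact)
                 and np.allclose(roots, exact, rtol=1e-3, atol=1e-9))
        if not agree:
            logger.warning("printed-z quartic with %s disagrees with elimination "
                           "(roots %s vs %s)", label, roots, exact)
        rows.append({"candidate": label, "n_roots": len(roots),
                     "roots": roots, "matches_elimination": agree})
    return pd.DataFrame(rows)


@dataclass
class FixedPoint:
    """A steady state with its stability classification."""

    XT: float
    XP: float
    YP: float
    stability: str
    leading_eigenvalue: float
    model_level: str
    state: np.ndarray | None = field(default=None, repr=False)


@dataclass
class FixedPointSet:
    """Fixed points of one model level, ascending in X_T."""

    points: list[FixedPoint]
    params: ParameterSet
    model_level: str

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.XT)

    def stable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stability == "stable"]

    def unstable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stability == "unstable"]

    @property
    def bistable(self) -> bool:
        return len(self.stable()) >= 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model_level": p.model_level, "XT": p.XT, "XP": p.XP, "YP": p.YP,
             "stability": p.stability, "leading_eigenvalue": p.leading_eigenvalue}
            for p in self.points
        ])


def _numeric_jacobian(fun, y0: np.ndarray, rel: float = 1e-7) -> np.ndarray:
    n = len(y0)
    J = np.empty((n, n))
    for j in range(n):
        h = rel * max(abs(y0[j]), 1e-6)
        yp = y0.copy(); yp[j] += h
        ym = y0.copy(); ym[j] -= h
        J[:, j] = (fun(yp) - fun(ym)) / (2.0 * h)
    return J


def _label(leading: float) -> str:
    if leading < -_STABILITY_TOL:
        return "stable"
    if leading > _STABILITY_TOL:
        return "unstable"
    return "marginal"


def classify_stability(fp: FixedPoint, params: ParameterSet,
                       fit: InversionFit | None = None) -> FixedPoint:
    """(Re)classify a fixed point by local linearization at its level.

    1-D level: central-difference slope of dX_T/dt.  reduced3/full: largest
    real part of the numerically differentiated Jacobian's spectrum.
    quartic: slope of the synthesis-degradation balance along the
    X_P-nullcline manifold (the flow the polynomial encodes).
    """
    level = fp.model_level
    if level == "one_d":
        if fit is None:
            fit = fit_inversion(params)
        h = 1e-4 * max(fp.XT, 1.0)
        lo, hi = max(fp.XT - h, 0.0), min(fp.XT + h, fit.domain_hi)
        lead = (one_d_rhs(hi, params, fit) - one_d_rhs(lo, params, fit)) / (hi - lo)
    elif level == "quartic":
        lam = params.lam
        d = derive_constants(params)

        def balance(xp: float) -> float:
            return d.c * d.a * xp / (d.a * xp + d.P7) - lam * xt_of_xp(xp, params)

        h = 1e-5 * max(fp.XP, 1e-3)
        dxt = max(xt_of_xp(fp.XP + h, params) - xt_of_xp(max(fp.XP - h, 0.0), params),
                  1e-300)
        lead = (balance(fp.XP + h) - balance(max(fp.XP - h, 0.0))) / dxt
    elif level == "reduced3":
        y0 = np.array([fp.XT, fp.XP, fp.YP])
        J = _numeric_jacobian(lambda y: reduced3_rhs(y, params, params.U_basal), y0)
        lead = float(np.max(np.linalg.eigvals(J).real))
    elif level == "full":
        y0 = np.asarray(fp.state, dtype=float)
        J = _numeric_jacobian(lambda y: _full_rhs_raw(y, params, params.U_basal), y0)
        lead = float(np.max(np.linalg.eigvals(J).real))
    else:
        raise ValueError(f"unknown model level {level!r}")
    fp.leading_eigenvalue = float(lead)
    fp.stability = _label(lead)
    return fp


def _quartic_points(params: ParameterSet) -> list[FixedPoint]:
    poly = steady_state_polynomial(params)
    pts = []
    for xp in poly.real_nonnegative_roots():
        xt = xt_of_xp(xp, params)
        fp = FixedPoint(XT=xt, XP=float(xp), YP=yp_nullcline(float(xp), params),
                        stability="marginal", leading_eigenvalue=0.0,
                        model_level="quartic")
        pts.append(classify_stability(fp, params))
    return pts


def _one_d_points(params: ParameterSet, fit: InversionFit) -> list[FixedPoint]:
    lam = params.lam

    def f(xt: float) -> float:
        return one_d_rhs(xt, params, fit)

    pts = [FixedPoint(XT=0.0, XP=0.0, YP=0.0, stability="marginal",
                      leading_eigenvalue=0.0, model_level="one_d")]
    grid = np.linspace(1e-6, fit.domain_hi, 2000)
    vals = np.array([f(g) for g in grid])
    sign = np.sign(vals)
    for i in np.where(sign[:-1] * sign[1:] < 0)[0]:
        xt = brentq(f, grid[i], grid[i + 1], xtol=1e-12)
        xp = max(float(fit(xt)), 0.0)
        pts.append(FixedPoint(XT=float(xt), XP=xp, YP=yp_nullcline(xp, params),
                              stability="marginal", leading_eigenvalue=0.0,
                              model_level="one_d"))
    return [classify_stability(p, params, fit) for p in pts]


def _reduced3_points(params: ParameterSet) -> list[FixedPoint]:
    pts = []
    for seed in _quartic_points(params):
        y0 = np.array([seed.XT, seed.XP, seed.YP])
        sol = root(lambda y: reduced3_rhs(y, params, params.U_basal), y0,
                   method="hybr", tol=1e-13)
        y = sol.x
        resid = np.max(np.abs(reduced3_rhs(y, params, params.U_basal)))
        if not sol.success and resid > _RESIDUAL_TOL:
            logger.warning("reduced3 root solve failed from seed XT=%.4g", seed.XT)
            continue
        if resid > _RESIDUAL_TOL:
            continue
        fp = FixedPoint(XT=float(y[0]), XP=float(max(y[1], 0.0)),
                        YP=float(max(y[2], 0.0)), stability="marginal",
                        leading_eigenvalue=0.0, model_level="reduced3")
        pts.append(classify_stability(fp, params))
    return _dedup(pts)


def _full_seed_states(params: ParameterSet) -> list[np.ndarray]:
    d = derive_constants(params)
    seeds = [np.array([params.Xbasal, params.XPbasal, 0.0, 0.0, 0.0, 0.0])]
    xp_grid = [pt.XP for pt in _quartic_points(params) if pt.XP > 0]
    xp_grid += list(np.geomspace(1e-3, 300.0, 8))
    for xp in xp_grid:
        X = (d.DI + params.lambda1) * xp / (d.a1 * xp + d.a2) if (d.a1 * xp + d.a2) > 0 else 0.0
        YP = yp_nullcline(xp, params, d)
        Y = max(params.YT - YP, 0.0)
        C1 = d.M * X * xp
        C2 = d.N * Y * xp
        C3 = params.k8 * YP * params.T / (params.k88 + params.k9)
        # re-balance CPEB1 conservation across YP and the complexes
        tot = YP + C2 + C3
        if tot > params.YT > 0:
            shrink = params.YT / tot
            YP, C2, C3 = YP * shrink, C2 * shrink, C3 * shrink
        seeds.append(np.array([X, xp, YP, C1, C2, C3]))
    return seeds


def _full_points(params: ParameterSet) -> list[FixedPoint]:
    from .model_core import total_camkii

    pts = []
    for y0 in _full_seed_states(params):
        sol = root(lambda y: _full_rhs_raw(y, params, params.U_basal), y0,
                   method="hybr", tol=1e-13)
        y = sol.x
        if np.any(y < -1e-9):
            continue
        y = np.maximum(y, 0.0)
        resid = np.max(np.abs(_full_rhs_raw(y, params, params.U_basal)))
        if resid > _RESIDUAL_TOL:
            continue
        fp = FixedPoint(XT=total_camkii(y), XP=float(y[1]), YP=float(y[2]),
                        stability="marginal", leading_eigenvalue=0.0,
                        model_level="full", state=y)
        pts.append(classify_stability(fp, params))
    pts = _dedup(pts)
    if not pts:
        logger.warning("no full-model fixed point converged from any seed")
    return pts


def _dedup(pts: list[FixedPoint]) -> list[FixedPoint]:
    out: list[FixedPoint] = []
    for p in sorted(pts, key=lambda q: q.XT):
        if any(abs(p.XT - q.XT) <= max(_BASAL_ATOL, 1e-6 * q.XT) for q in out):
            continue
        out.append(p)
    return out


def solve_fixed_points(params: ParameterSet, model_level: str,
                       fit: InversionFit | None = None) -> FixedPointSet:
    """Locate and classify every steady state at one model level.

    quartic: polynomial roots mapped to X_T.  one_d: bracketed sign changes
    of the synthesis-degradation balance (plus the exact root at X_T = 0).
    reduced3/full: damped multi-start Newton-type root searches seeded from
    the quartic roots, the basal state and a saturated ladder; every
    returned point satisfies max|rhs| < 1e-9 uM/s.
    """
    if model_level == "quartic":
        pts = _quartic_points(params)
    elif model_level == "one_d":
        if fit is None:
            fit = fit_inversion(params)
        pts = _one_d_points(params, fit)
    elif model_level == "reduced3":
        pts = _reduced3_points(params)
    elif model_level == "full":
        pts = _full_points(params)
    else:
        raise ValueError(f"unknown model level {model_level!r}")
    return FixedPointSet(points=pts, params=params, model_level=model_level)


def compare_levels(params: ParameterSet,
                   fit: InversionFit | None = None) -> dict:
    """Fixed points at all four levels plus per-branch discrepancies.

    Branches are matched by stability and rank in X_T against the quartic
    level; the returned table lists the relative X_T discrepancy of each
    level's branch (absolute, on the basal branch).
    """
    if fit is None:
        fit = fit_inversion(params)
    sets = {lvl: solve_fixed_points(params, lvl, fit=fit) for lvl in MODEL_LEVELS}
    ref = sets["quartic"].points
    rows = []
    for i, rp in enumerate(ref):
        for lvl in MODEL_LEVELS:
            pts = sets[lvl].points
            match = min(pts, key=lambda p: abs(p.XT - rp.XT)) if pts else None
            if match is None:
                rows.append({"branch": i, "ref_XT": rp.XT, "model_level": lvl,
                             "XT": np.nan, "discrepancy": np.nan,
                             "stability": "absent"})
                continue
            if rp.XT < _BASAL_ATOL:
                disc = abs(match.XT - rp.XT)
            else:
                disc = abs(match.XT - rp.XT) / rp.XT
            rows.append({"branch": i, "ref_XT": rp.XT, "model_level": lvl,
                         "XT": match.XT, "discrepancy": disc,
                         "stability": match.stability})
    table = pd.DataFrame(rows)
    return {
        "sets": sets,
        "table": table,
        "max_discrepancy": float(table["discrepancy"].max()),
    }
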