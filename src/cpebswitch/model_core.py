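"""Full mass-action model of the CPEB1-alphaCaMKII polyadenylation loop.

The loop couples two proteins: alphaCaMKII (``X``, inactive; ``X_P``, active
and phosphorylated) and its translational regulator CPEB1 (``Y``,
unphosphorylated; ``Y_P``, phosphorylated).  Six elementary reactions close a
positive feedback: Ca4CaM activates X (R1), active kinase autophosphorylates
through the dimer complex C1 (R2), a phosphatase pool P deactivates X_P (R3),
X_P phosphorylates CPEB1 through the complex C2 (R4), the phosphatase
dephosphorylates Y_P (R5), and Y_P bound to the translation machinery T (the
complex C3) drives synthesis of new, inactive X (R6).  Free X and X_P relax
toward basal levels at the degradation rates lambda2 and lambda1; complexes
do not degrade.

The six dynamical variables are X, X_P, Y_P, C1, C2 and C3; free CPEB1 is
carried implicitly by the exact conservation Y = Y_T - Y_P - C2 - C3.  The
total kinase concentration, the switch readout, is
``X_T = X + X_P + 2 C1 + C2``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "InvalidParameterError",
    "InfeasibleCompositionError",
    "DomainError",
    "ParameterSet",
    "DerivedConstants",
    "FullState",
    "derive_constants",
    "full_rhs",
    "total_camkii",
    "parameter_schema",
]


class InvalidParameterError(ValueError):
    """A rate constant or concentration violates the model's invariants."""


class InfeasibleCompositionError(ValueError):
    """A (X_T, X_P) composition leaves no room for free, inactive kinase."""


class DomainError(ValueError):
    """An input lies outside the validity domain of an approximation."""


_FIELD_UNITS = {
    "k1": "uM^-1 s^-1", "k2": "s^-1", "k3": "s^-1", "k4": "uM^-1 s^-1",
    "k5": "uM^-1 s^-1", "k55": "s^-1", "k6": "s^-1", "k7": "uM^-1 s^-1",
    "k8": "uM^-1 s^-1", "k88": "s^-1", "k9": "s^-1", "k10": "uM^-1 s^-1",
    "k1010": "s^-1", "lambda1": "s^-1", "lambda2": "s^-1",
    "P": "uM", "T": "uM", "YT": "uM", "U_basal": "uM",
    "Xbasal": "uM", "XPbasal": "uM",
}


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and free concentrations of the loop.

    Rates follow the reaction scheme: ``k1/k2`` bind/release the X.X_P
    autophosphorylation complex C1 and ``k3`` is its catalytic step;
    ``k4``/``k7`` are the phosphatase rates on X_P and Y_P (second order,
    paired with the phosphatase concentration ``P``); ``k5/k55/k6`` govern
    CPEB1 phosphorylation through C2; ``k8/k88/k9`` govern translation
    through C3 with machinery concentration ``T``; ``k10/k1010`` are Ca4CaM
    activation and its reversal.  ``lambda1``/``lambda2`` are the degradation
    rates of free X_P and X.  ``YT`` is total CPEB1 and ``U_basal`` the
    resting Ca4CaM concentration.
    """

    k1: float = 0.085
    k2: float = 0.143
    k3: float = 500.0
    k4: float = 0.0012
    k5: float = 0.0072
    k55: float = 20.0
    k6: float = 0.962
    k7: float = 0.012
    k8: float = 0.08
    k88: float = 10.0
    k9: float = 0.08
    k10: float = 0.001
    k1010: float = 0.8
    lambda1: float = 1e-4
    lambda2: float = 1e-4
    P: float = 0.01
    T: float = 1.0
    YT: float = 1.0
    U_basal: float = 1e-6
    Xbasal: float = 1e-4
    XPbasal: float = 0.0

    def __post_init__(self) -> None:
        for name in _FIELD_UNITS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise InvalidParameterError(f"{name} must be a number, got {value!r}")
            if not math.isfinite(value) or value < 0:
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {value!r}"
                )

    @property
    def lam(self) -> float:
        """The single degradation rate of the reduced models.

        The reduced levels assume free and bound kinase degrade at one rate;
        they are only meaningful when ``lambda1 == lambda2``.
        """
        if self.lambda1 != self.lambda2:
            raise InvalidParameterError(
                "reduced models require lambda1 == lambda2 "
                f"(got {self.lambda1} != {self.lambda2})"
            )
        return self.lambda1

    def replace(self, **changes: float) -> "ParameterSet":
        if "lam" in changes:
            lam = changes.pop("lam")
            changes.setdefault("lambda1", lam)
            changes.setdefault("lambda2", lam)
        return dataclasses.replace(self, **changes)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ParameterSet":
        unknown = set(data) - set(_FIELD_UNITS)
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise InvalidParameterError(f"malformed parameter file {path}: {exc}")
        if not isinstance(data, dict):
            raise InvalidParameterError(f"parameter file {path} must hold an object")
        return cls.from_dict(data)


def parameter_schema() -> dict:
    """The JSON schema (with units) shipped with the package."""
    text = resources.files("cpebswitch").joinpath("data/parameter_schema.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class DerivedConstants:
    """Lumped constants of the pseudo-steady-state reduction.

    ``a`` is the effective CPEB1 phosphorylation rate ``k5 k6/(k55+k6)``
    (uM^-1 s^-1); ``N = k5/(k55+k6)`` and ``M = k1/(k2+k3)`` (uM^-1) are the
    C2 and C1 binding factors; ``b = k9 k8 T/(k88+k9)`` (s^-1) is the
    synthesis rate per unit phospho-CPEB1 and ``c = b YT`` (uM s^-1) its
    saturated maximum; ``P7 = k7 P`` and ``P4 = k4 P`` (s^-1) are the
    pseudo-first-order phosphatase rates; ``a1 = k3 k1/(k2+k3)`` is the
    autophosphorylation gain, ``a2 = k10 U`` the Ca4CaM drive,
    ``DI = P4 + k1010`` the X_P loss rate and ``d1`` an alias of ``a``.
    """

    a: float
    b: float
    c: float
    M: float
    N: float
    P7: float
    P4: float
    a1: float
    a2: float
    DI: float
    d1: float


def derive_constants(params: ParameterSet, U: float | None = None) -> DerivedConstants:
    """Lump the rate constants of the reduction; ``U`` defaults to resting Ca4CaM."""
    if U is None:
        U = params.U_basal
    if U < 0 or not math.isfinite(U):
        raise InvalidParameterError(f"U must be finite and >= 0, got {U}")
    for denom, label in [
        (params.k55 + params.k6, "k55 + k6"),
        (params.k2 + params.k3, "k2 + k3"),
        (params.k88 + params.k9, "k88 + k9"),
    ]:
        if denom == 0:
            raise InvalidParameterError(f"zero denominator: {label} == 0")
    a = params.k5 * params.k6 / (params.k55 + params.k6)
    N = params.k5 / (params.k55 + params.k6)
    M = params.k1 / (params.k2 + params.k3)
    b = params.k9 * params.k8 * params.T / (params.k88 + params.k9)
    c = b * params.YT
    P7 = params.k7 * params.P
    P4 = params.k4 * params.P
    a1 = params.k3 * params.k1 / (params.k2 + params.k3)
    a2 = params.k10 * U
    return DerivedConstants(
        a=a, b=b, c=c, M=M, N=N, P7=P7, P4=P4, a1=a1, a2=a2,
        DI=P4 + params.k1010, d1=a,
    )


@dataclass
class FullState:
    """The six dynamical concentrations of the full model (uM)."""

    X: float
    XP: float
    YP: float
    C1: float
    C2: float
    C3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.XP, self.YP, self.C1, self.C2, self.C3])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FullState":
        return cls(*(float(v) for v in np.asarray(y)))

    def free_cpeb(self, params: ParameterSet) -> float:
        """Free, unphosphorylated CPEB1 by exact conservation."""
        return params.YT - self.YP - self.C2 - self.C3


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, FullState):
        return state.as_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError(f"full-model state must have 6 components, got shape {y.shape}")
    return y


def _full_rhs_raw(y: np.ndarray, params: ParameterSet, U: float) -> np.ndarray:
    """Unvalidated right-hand side; used by the integrator."""
    X, XP, YP, C1, C2, C3 = y
    Y = params.YT - YP - C2 - C3
    v1f = params.k10 * X * U           # R1 forward: X + Ca4CaM -> XP
    v1r = params.k1010 * XP            # R1 reverse
    v2f = params.k1 * X * XP           # R2 binding: X + XP -> C1
    v2r = params.k2 * C1               # R2 unbinding
    v2c = params.k3 * C1               # R2 catalysis: C1 -> 2 XP
    v3 = params.k4 * XP * params.P     # R3: XP + P -> X + P
    v4f = params.k5 * Y * XP           # R4 binding: Y + XP -> C2
    v4r = params.k55 * C2
    v4c = params.k6 * C2               # R4 catalysis: C2 -> YP + XP
    v5 = params.k7 * YP * params.P     # R5: YP + P -> Y + P
    v6f = params.k8 * YP * params.T    # R6 binding: YP + T -> C3
    v6r = params.k88 * C3
    v6c = params.k9 * C3               # R6 catalysis: C3 -> YP + X + T
    dX = (-v2f + v2r + v3 + v6c - v1f + v1r
          - params.lambda2 * (X - params.Xbasal))
    dXP = (-v2f + v2r + 2.0 * v2c - v3 + v4r + v4c - v4f + v1f - v1r
           - params.lambda1 * (XP - params.XPbasal))
    dYP = -v5 + v4c - v6f + v6r + v6c
    dC1 = v2f - v2r - v2c
    dC2 = v4f - v4r - v4c
    dC3 = v6f - v6r - v6c
    return np.array([dX, dXP, dYP, dC1, dC2, dC3])


def full_rhs(state, params: ParameterSet, U: float) -> np.ndarray:
    """Time derivative (uM/s) of the six-variable mass-action model.

    ``U`` is the instantaneous Ca4CaM concentration, an exogenous input.
    """
    y = _as_state_array(state)
    if np.any(~np.isfinite(y)):
        raise ValueError("state contains non-finite components")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    if U < 0 or not math.isfinite(U):
        raise ValueError(f"U must be finite and >= 0, got {U}")
    dy = _full_rhs_raw(y, params, U)
    if np.any(~np.isfinite(dy)):
        raise FloatingPointError("full_rhs produced non-finite derivatives")
    return dy


def total_camkii(state) -> float:
    """Total kinase concentration X_T = X + X_P + 2 C1 + C2 (uM)."""
    y = _as_state_array(state)
    return float(y[0] + y[1] + 2.0 * y[3] + y[4])
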