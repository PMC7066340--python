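"""Equilibrium algebra and stability of the vulnerability model.

Setting the rescaled system to zero and eliminating x = 1 - y - z and
z = c*mu / (beta + mu - delta*y) reduces the equilibrium problem to a cubic
in the low-vulnerability fraction y,

    A y^3 + B y^2 + C y + D = 0,      A = eps*delta,

whose root positivity is screened through Vieta's formulas (sum S1 = -B/A,
second symmetric sum S2 = C/A, product P = -D/A, all required > 0 for three
positive roots).  The derivation assumes x + y + z = 1, i.e. entry
probabilities summing to 1.

Stability is assessed at the disease-free equilibrium (x, y, z) = (0, 0, 1):
the Jacobian there is block-triangular with closed-form eigenvalues
-(mu+alpha), -mu and -(mu+beta+delta), all negative for positive parameters.
Two reproduction-number quantities are carried side by side, because the
source analysis prints two mutually inconsistent definitions: the literal
``r0_literal = -mu + beta + delta`` and the bound ``r0_bound =
delta*(mu+alpha)/eps`` implied by its S1 > 0 manipulation.  The report takes
no position on which is "the" R0 and flags the case where r0_literal >= 1
while the equilibrium is nevertheless stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estimation import ModelParameters

__all__ = [
    "DegenerateCubicError",
    "SingularDenominatorError",
    "CubicCoefficients",
    "VietaSums",
    "EquilibriumRoot",
    "StabilityReport",
    "cubic_coefficients",
    "vieta",
    "positivity_conditions",
    "solve_equilibrium_y",
    "equilibrium_z",
    "jacobian_dfe",
    "closed_form_eigenvalues",
    "stability_analysis",
]

_REAL_ROOT_IMAG_TOL = 1e-9


class DegenerateCubicError(ValueError):
    """The leading cubic coefficient eps*delta vanishes."""


class SingularDenominatorError(ZeroDivisionError):
    """beta + mu - delta*y is (numerically) zero in the z back-substitution."""

    def __init__(self, delta_y: float):
        self.delta_y = delta_y
        super().__init__(
            f"beta + mu - delta*y is singular (delta*y = {delta_y})"
        )


@dataclass(frozen=True)
class CubicCoefficients:
    A: float
    B: float
    C: float
    D: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)

    def residual(self, y: float) -> float:
        return self.A * y**3 + self.B * y**2 + self.C * y + self.D


@dataclass(frozen=True)
class VietaSums:
    S1: float  # sum of roots
    S2: float  # second elementary symmetric sum
    P: float  # product of roots


@dataclass(frozen=True)
class EquilibriumRoot:
    y: float
    admissible: bool
    residual: float


@dataclass
class StabilityReport:
    jacobian: np.ndarray
    eigenvalues: tuple[float, float, float]
    r0_literal: float
    r0_bound: float | None
    stable: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "jacobian": self.jacobian.tolist(),
            "eigenvalues": list(self.eigenvalues),
            "r0_literal": self.r0_literal,
            "r0_bound": self.r0_bound,
            "stable": self.stable,
            "notes": list(self.notes),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Equilibrium cubic
# ---------------------------------------------------------------------------


def cubic_coefficients(p: ModelParameters) -> CubicCoefficients:
    """Coefficients of the equilibrium cubic in y (unit-simplex assumption)."""
    mu, a, c = p.mu, p.a, p.c
    d, e, al, be = p.delta, p.epsilon, p.alpha, p.beta
    A = e * d
    B = -(mu * d + e * d + e * be + al * d + mu * e)
    C = (
        mu * d - a * mu * d + mu**2 + mu * be + e * mu + e * be
        + al * d + al * mu + al * be - c * e * mu
    )
    D = (
        a * mu**2 + a * mu * be - mu**2 - mu * be - al * mu - al * be
        + c * mu**2 + c * mu * al
    )
    return CubicCoefficients(A, B, C, D)


def vieta(c: CubicCoefficients) -> VietaSums:
    """Symmetric functions of the cubic's roots from its coefficients."""
    if c.A == 0:
        raise DegenerateCubicError("leading coefficient A = eps*delta is zero")
    return VietaSums(S1=-c.B / c.A, S2=c.C / c.A, P=-c.D / c.A)


def positivity_conditions(p: ModelParameters) -> tuple[bool, bool, bool]:
    """Strict positivity of S1, S2 and P — necessary for three positive roots."""
    if p.epsilon * p.delta == 0:
        raise DegenerateCubicError(
            "positivity conditions undefined: eps*delta = 0"
        )
    v = vieta(cubic_coefficients(p))
    return (v.S1 > 0, v.S2 > 0, v.P > 0)


def solve_equilibrium_y(
    p: ModelParameters, admissible_upper: float = 1.0
) -> list[EquilibriumRoot]:
    """Real roots of the equilibrium cubic, sorted ascending.

    Roots are computed as companion-matrix eigenvalues; complex roots with
    |imag| < 1e-9 are treated as real.  A root is flagged admissible when it
    lies in [0, ``admissible_upper``] (default the unit interval; pass
    ``a+b+c`` when working with unnormalized entry probabilities).

    A vanishing leading coefficient degrades gracefully to the quadratic or
    linear problem.
    """
    coeffs = cubic_coefficients(p)
    poly = np.array(coeffs.as_tuple(), dtype=float)
    # strip leading (near-)zeros: degenerate cubic -> quadratic -> linear
    nonzero = np.nonzero(poly != 0.0)[0]
    if nonzero.size == 0:
        raise DegenerateCubicError("all cubic coefficients vanish")
    poly = poly[nonzero[0]:]
    if poly.size == 1:
        return []
    roots = np.roots(poly)
    real_roots = sorted(
        float(r.real) for r in roots if abs(r.imag) < _REAL_ROOT_IMAG_TOL
    )
    return [
        EquilibriumRoot(
            y=r,
            admissible=(0.0 <= r <= admissible_upper),
            residual=float(coeffs.residual(r)),
        )
        for r in real_roots
    ]


def equilibrium_z(y: float, p: ModelParameters) -> float:
    """Back-substituted complete-mental-health fraction c*mu/(beta+mu-delta*y)."""
    denom = p.beta + p.mu - p.delta * y
    if abs(denom) < 1e-12:
        raise SingularDenominatorError(p.delta * y)
    return p.c * p.mu / denom


# ---------------------------------------------------------------------------
# Jacobian and stability at the disease-free equilibrium
# ---------------------------------------------------------------------------


def jacobian_dfe(p: ModelParameters) -> np.ndarray:
    """Jacobian of the rescaled system at (x, y, z) = (0, 0, 1)."""
    # epsilon does not appear: its terms carry x*y or x factors, zero at the DFE
    mu, d, al, be = p.mu, p.delta, p.alpha, p.beta
    return np.array(
        [
            [-mu - al, 0.0, 0.0],
            [al, -mu - d, be],
            [0.0, d, -mu - be],
        ]
    )


def closed_form_eigenvalues(p: ModelParameters) -> tuple[float, float, float]:
    """Eigenvalues -(mu+alpha), -mu, -(mu+beta+delta) of the DFE Jacobian."""
    return (-(p.mu + p.alpha), -p.mu, -(p.mu + p.beta + p.delta))


def stability_analysis(p: ModelParameters) -> StabilityReport:
    """Stability report at the disease-free equilibrium (0, 0, 1)."""
    J = jacobian_dfe(p)
    eigs = closed_form_eigenvalues(p)
    r0_literal = -p.mu + p.beta + p.delta
    notes = [
        "r0_literal = -mu + beta + delta, the literal printed definition",
    ]
    if p.epsilon > 0:
        r0_bound = p.delta * (p.mu + p.alpha) / p.epsilon
        notes.append(
            "r0_bound = delta*(mu+alpha)/eps, the bound implied by S1 > 0"
        )
    else:
        r0_bound = None
        notes.append("r0_bound undefined: eps = 0")
    stable = all(ev < 0 for ev in eigs)
    if stable and r0_literal >= 1:
        notes.append(
            "inconsistency: all eigenvalues negative (stable) although "
            f"r0_literal = {r0_literal:.4f} >= 1; the source analysis ties "
            "stability to R0 < 1, which the literal definition violates here"
        )
    return StabilityReport(
        jacobian=J,
        eigenvalues=eigs,
        r0_literal=r0_literal,
        r0_bound=r0_bound,
        stable=stable,
        notes=notes,
    )
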