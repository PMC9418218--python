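"""Dimensionless time-fractional bioheat model and its Laplace-domain solution.

The dimensionless temperature theta(y, t) on the slab y in [0, 1] obeys the
Caputo-fractional reaction–diffusion equation

    D_t^alpha theta = D d2theta/dy2 - c theta + s,      0 < alpha <= 1,

with Dirichlet boundary values at both faces and a uniform initial state.
The coefficients collect the physics:

    D = (r_k / r_cp) (1 + 4R/3)    effective diffusion (conductivity ratio
                                   of the nanofluid, Rosseland radiation R)
    c = gamma - lam / r_cp         blood-perfusion sink minus metabolic gain
    s = gamma + beta / r_cp        perfusion supply plus porous-matrix source

where r_cp = (rho cp)_nf/(rho cp)_b and r_k = k_nf/k_b are the nanofluid
property ratios. Taking the Laplace transform in time (Caputo:
L{D_t^alpha f} = q^alpha F - q^(alpha-1) f(0)) turns the PDE into a
two-point ODE whose closed form is a cosh/sinh combination around the
particular solution

    F_p(q) = (theta_init q^alpha + s) / (q (q^alpha + c)).

Time-domain values come from numerically inverting this transform
(:mod:`fracbioheat.laplace_inversion`).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

from .materials import NanofluidMixture

__all__ = [
    "TherapyParams",
    "PDECoefficients",
    "assemble_coefficients",
    "laplace_particular",
    "laplace_solution",
    "laplace_solution_dy",
    "steady_state",
    "LaplaceField",
]


@dataclass(frozen=True)
class TherapyParams:
    """Dimensionless control parameters of a hyperthermia run.

    Parameters
    ----------
    alpha : float
        Caputo fractional order in (0, 1]; alpha = 1 recovers the classical
        first-order-in-time bioheat equation, alpha < 1 adds thermal memory.
    R : float
        Rosseland radiation parameter (>= 0); enters only through the
        enhanced diffusion factor (1 + 4R/3).
    gamma : float
        Blood-perfusion parameter (>= 0).
    lam : float
        Metabolic heat-source parameter (>= 0).
    beta : float
        Porous-structure parameter (>= 0).
    theta_init, theta_left, theta_right : float
        Uniform initial value and the fixed boundary values at y = 0 and
        y = 1. Defaults follow the published transform-domain convention of
        carrying the physical temperatures (37, 37, 45); a physical
        zero-to-one mode (0, 0, 1) differs only by an affine map.
    """

    alpha: float = 0.8
    R: float = 0.5
    gamma: float = 1.0
    lam: float = 0.5
    beta: float = 0.5
    theta_init: float = 37.0
    theta_left: float = 37.0
    theta_right: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} must lie in (0, 1]")
        for field in ("R", "gamma", "lam", "beta"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be nonnegative")


@dataclass(frozen=True)
class PDECoefficients:
    """Assembled coefficients of D_t^alpha theta = D theta_yy - c theta + s."""

    D: float
    c: float
    s: float

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"diffusion coefficient D={self.D} must be positive")


def assemble_coefficients(
    params: TherapyParams, mix: NanofluidMixture
) -> PDECoefficients:
    """Build (D, c, s) from the dimensionless groups and nanofluid ratios.

    With no particles and no radiation (phi = 0, R = 0) both property ratios
    are 1 and D = 1 exactly.
    """
    r_cp = mix.heat_capacity_ratio
    r_k = mix.conductivity_ratio
    D = (r_k / r_cp) * (1.0 + 4.0 * params.R / 3.0)
    c = params.gamma - params.lam / r_cp
    s = params.gamma + params.beta / r_cp
    return PDECoefficients(D=D, c=c, s=s)


def _q_alpha(q: complex, alpha: float) -> complex:
    """Principal-branch q^alpha; contours keep Re q > 0 so no cut is crossed."""
    return complex(q) ** alpha


def laplace_particular(
    q: complex, coeff: PDECoefficients, params: TherapyParams
) -> complex:
    """Spatially uniform particular solution F_p(q) of the transformed ODE.

    F_p(q) = (theta_init q^alpha + s) / (q (q^alpha + c)). When
    s = c * theta_init this collapses to theta_init / q — the transform of
    the constant equilibrium state.
    """
    qa = _q_alpha(q, params.alpha)
    denom = qa + coeff.c
    if denom == 0:
        raise ZeroDivisionError(f"resonant pole q^alpha + c = 0 at q={q}")
    return (params.theta_init * qa + coeff.s) / (q * denom)


def _mu(q: complex, coeff: PDECoefficients, params: TherapyParams) -> complex:
    """Spatial decay rate mu = sqrt((q^alpha + c)/D), principal branch."""
    return cmath.sqrt((_q_alpha(q, params.alpha) + coeff.c) / coeff.D)


def _sinh_ratio(z1: complex, z2: complex) -> complex:
    """sinh(z1)/sinh(z2) for 0 <= Re z1 <= Re z2, without overflow.

    Uses sinh(z) = exp(z)(1 - exp(-2z))/2 so only decaying exponentials are
    ever evaluated for large |Re z|.
    """
    e2 = 1.0 - cmath.exp(-2.0 * z2)
    if e2 == 0:
        raise ZeroDivisionError(f"sinh vanished at z={z2}")
    return cmath.exp(z1 - z2) * (1.0 - cmath.exp(-2.0 * z1)) / e2


def _cosh_sinh_ratio(z1: complex, z2: complex) -> complex:
    """cosh(z1)/sinh(z2) for 0 <= Re z1 <= Re z2, without overflow."""
    e2 = 1.0 - cmath.exp(-2.0 * z2)
    if e2 == 0:
        raise ZeroDivisionError(f"sinh vanished at z={z2}")
    return cmath.exp(z1 - z2) * (1.0 + cmath.exp(-2.0 * z1)) / e2


def laplace_solution(
    y: float, q: complex, coeff: PDECoefficients, params: TherapyParams
) -> complex:
    """Closed-form transform of the temperature at position y.

    Algebraically equal to A cosh(y mu) + B sinh(y mu) + F_p with
    A = theta_left/q - F_p and B = (theta_right/q - F_p - A cosh mu)/sinh mu,
    but evaluated in the two-boundary form

        F_p + (theta_left/q - F_p) sinh((1-y) mu)/sinh(mu)
            + (theta_right/q - F_p) sinh(y mu)/sinh(mu)

    which is exact at both walls and overflow-safe for |mu| up to ~700.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"position y={y} outside [0, 1]")
    mu = _mu(q, coeff, params)
    fp = laplace_particular(q, coeff, params)
    left = params.theta_left / q - fp
    right = params.theta_right / q - fp
    val = (
        fp
        + left * _sinh_ratio((1.0 - y) * mu, mu)
        + right * _sinh_ratio(y * mu, mu)
    )
    if not (math.isfinite(val.real) and math.isfinite(val.imag)):
        raise ArithmeticError(f"non-finite transform value at y={y}, q={q}")
    return val


def laplace_solution_dy(
    y: float, q: complex, coeff: PDECoefficients, params: TherapyParams
) -> complex:
    """Spatial derivative of the transform, mu (A sinh(y mu) + B cosh(y mu))."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"position y={y} outside [0, 1]")
    mu = _mu(q, coeff, params)
    fp = laplace_particular(q, coeff, params)
    left = params.theta_left / q - fp
    right = params.theta_right / q - fp
    val = mu * (
        -left * _cosh_sinh_ratio((1.0 - y) * mu, mu)
        + right * _cosh_sinh_ratio(y * mu, mu)
    )
    if not (math.isfinite(val.real) and math.isfinite(val.imag)):
        raise ArithmeticError(f"non-finite transform derivative at y={y}, q={q}")
    return val


@dataclass(frozen=True)
class LaplaceField:
    """Bundle of the transform evaluator and its spatial derivative.

    Satisfies value(0, q) = theta_left/q and value(1, q) = theta_right/q to
    machine precision for every q with Re q > 0.
    """

    coeff: PDECoefficients
    params: TherapyParams

    def value(self, y: float, q: complex) -> complex:
        return laplace_solution(y, q, self.coeff, self.params)

    def dvalue_dy(self, y: float, q: complex) -> complex:
        return laplace_solution_dy(y, q, self.coeff, self.params)


def steady_state(
    y: float, coeff: PDECoefficients, params: TherapyParams
) -> float:
    """Long-time limit: solution of D theta'' - c theta + s = 0 with the
    boundary values of the run.

    For c > 0 this is s/c plus a sinh interpolation of the boundary
    excesses; for c = 0 it degenerates to a parabola. c < 0 (metabolic gain
    beating perfusion) has no bounded long-time limit in general and is
    evaluated through the trigonometric analogue, raising near its poles.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"position y={y} outside [0, 1]")
    if coeff.c == 0.0:
        # D theta'' + s = 0: parabola through the two boundary values.
        lin = params.theta_left + (params.theta_right - params.theta_left) * y
        return lin + 0.5 * coeff.s / coeff.D * y * (1.0 - y)
    omega = cmath.sqrt(complex(coeff.c) / coeff.D)
    base = coeff.s / coeff.c
    denom = cmath.sinh(omega)
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            f"steady state degenerate: sinh(sqrt(c/D)) ~ 0 for c={coeff.c}"
        )
    val = (
        base
        + (params.theta_left - base) * cmath.sinh((1.0 - y) * omega) / denom
        + (params.theta_right - base) * cmath.sinh(y * omega) / denom
    )
    return val.real


def steady_state_dy(
    y: float, coeff: PDECoefficients, params: TherapyParams
) -> float:
    """Spatial derivative of the steady-state profile (for wall-flux checks)."""
    if coeff.c == 0.0:
        slope = params.theta_right - params.theta_left
        return slope + 0.5 * coeff.s / coeff.D * (1.0 - 2.0 * y)
    omega = cmath.sqrt(complex(coeff.c) / coeff.D)
    base = coeff.s / coeff.c
    denom = cmath.sinh(omega)
    val = omega * (
        -(params.theta_left - base) * cmath.cosh((1.0 - y) * omega) / denom
        + (params.theta_right - base) * cmath.cosh(y * omega) / denom
    )
    return val.real
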