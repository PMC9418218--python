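"""Implicit Caputo-L1 finite-difference solver for the fractional bioheat
equation — the independent oracle for the Laplace-transform path.

The Caputo derivative of order alpha in (0, 1] is discretised by the L1
scheme: with uniform step dt and sigma = dt^(-alpha)/Gamma(2-alpha),

    D_t^alpha u(t_n) ~ sigma * sum_{j=0}^{n-1} b_j (u^{n-j} - u^{n-j-1}),
    b_j = (j+1)^(1-alpha) - j^(1-alpha).

Space uses second-order central differences; the fully implicit step solves
a constant tridiagonal system, unconditionally stable for D > 0, c >= 0.
At alpha = 1 the weights collapse to (1, 0, 0, ...) and the scheme is
exactly backward Euler. The full history sum is retained (no short-memory
truncation); at desk-scale step counts the O(nt^2) cost is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .fields import TemperatureField
from .materials import NanofluidMixture
from .model_core import PDECoefficients, TherapyParams

__all__ = [
    "FDGrid",
    "caputo_l1_weights",
    "solve_fd",
    "solve_fd_dimensional",
    "DimensionalSetup",
]


@dataclass(frozen=True)
class FDGrid:
    """Uniform space-time grid on [0, 1] x [0, nt*dt]."""

    ny: int
    nt: int
    dt: float

    def __post_init__(self) -> None:
        if self.ny < 3:
            raise ValueError("need at least 3 spatial points (2 boundaries + 1)")
        if self.nt < 1 or self.dt <= 0:
            raise ValueError("need nt >= 1 time steps of positive size")

    @property
    def dy(self) -> float:
        return 1.0 / (self.ny - 1)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.ny)

    @property
    def t(self) -> np.ndarray:
        return self.dt * np.arange(self.nt + 1)


def caputo_l1_weights(alpha: float, n: int) -> np.ndarray:
    """L1 weights b_j = (j+1)^(1-alpha) - j^(1-alpha), j = 0..n-1.

    b_0 = 1 for every alpha; at alpha = 1 all later weights vanish (no
    memory); for alpha < 1 the weights decay like j^(-alpha).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha={alpha} must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    j = np.arange(n, dtype=float)
    lower = j ** (1.0 - alpha)
    lower[0] = 0.0  # 0^(1-alpha) = 0 also in the alpha -> 1 limit (not 0^0 = 1)
    return (j + 1.0) ** (1.0 - alpha) - lower


def _step_matrix(
    ny: int, dy: float, lhs_diag: float, D: float
) -> np.ndarray:
    """Banded (ab) form of the implicit tridiagonal operator with pinned
    boundary rows."""
    r = D / dy**2
    ab = np.zeros((3, ny))
    ab[0, 1:] = -r  # superdiagonal
    ab[1, :] = lhs_diag + 2.0 * r
    ab[2, :-1] = -r  # subdiagonal
    # Dirichlet rows
    ab[1, 0] = ab[1, -1] = 1.0
    ab[0, 1] = 0.0
    ab[2, -2] = 0.0
    return ab


def solve_fd(
    params: TherapyParams, coeff: PDECoefficients, grid: FDGrid
) -> TemperatureField:
    """March the L1/implicit scheme and return the full (y, t) field.

    Each step solves

        (sigma + c + 2D/dy^2) u_i - (D/dy^2)(u_{i-1} + u_{i+1})
            = sigma * (history) + s

    on interior nodes, with the boundary rows pinned to theta_left and
    theta_right, starting from the uniform initial state theta_init.
    """
    alpha = params.alpha
    sigma = grid.dt ** (-alpha) / math.gamma(2.0 - alpha)
    b = caputo_l1_weights(alpha, grid.nt)

    U = np.empty((grid.nt + 1, grid.ny))
    U[0] = params.theta_init
    U[0, 0] = params.theta_init  # initial row keeps the uniform state
    U[0, -1] = params.theta_init

    ab = _step_matrix(grid.ny, grid.dy, sigma + coeff.c, coeff.D)

    for n in range(1, grid.nt + 1):
        # sigma * sum b_j (u^{n-j} - u^{n-j-1}) = sigma*(u^n - hist_rhs)
        # hist_rhs = sum_{j=1}^{n-1} (b_{j-1}-b_j) u^{n-j} + b_{n-1} u^0
        if n == 1 or alpha == 1.0:
            hist = U[n - 1]  # at alpha=1 all memory weights vanish
        else:
            w = b[: n - 1] - b[1:n]  # weights for u^{n-1} ... u^{1}
            hist = w @ U[n - 1 : 0 : -1] + b[n - 1] * U[0]
        rhs = sigma * hist + coeff.s
        rhs[0] = params.theta_left
        rhs[-1] = params.theta_right
        U[n] = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(U[n])):
            raise ArithmeticError(
                f"instability at step {n}: dt={grid.dt}, dy={grid.dy}, "
                f"alpha={alpha}, D={coeff.D}, c={coeff.c}"
            )

    meta = {
        "method": "fd_l1_implicit",
        "settings": {"ny": grid.ny, "nt": grid.nt, "dt": grid.dt, "alpha": alpha},
    }
    return TemperatureField(values=U.T, y_grid=grid.y, t_grid=grid.t, metadata=meta)


@dataclass(frozen=True)
class DimensionalSetup:
    """Dimensional inputs of the integer-order governing equation.

    Used to arbitrate the nondimensionalization: a dimensional solve, once
    rescaled, must overlay the dimensionless solve built from the derived
    groups (``gamma``, ``lam``, ``beta`` properties below).

    Parameters
    ----------
    a : float
        Slab thickness, m.
    omega_b : float
        Blood perfusion rate, s^-1.
    Qm : float
        Metabolic heat-source coefficient, W m^-3 K^-1 (multiplies theta -
        theta0).
    eps_over_K : float
        Lumped porous-matrix source epsilon/K, W m^-3.
    theta0, thetab : float
        Reference (initial) and blood temperatures, deg C; also the scale
        of the dimensionless temperature (theta - theta0)/(thetab - theta0).
    R : float
        Radiation parameter entering (1 + 4R/3).
    """

    mix: NanofluidMixture
    a: float
    omega_b: float
    Qm: float
    eps_over_K: float
    theta0: float = 37.0
    thetab: float = 45.0
    R: float = 0.0

    @property
    def alpha1(self) -> float:
        """Base-fluid thermal diffusivity k_b/(rho_b cp_b), m^2 s^-1."""
        return self.mix.base.k / self.mix.base.rho_cp

    @property
    def gamma(self) -> float:
        return self.a**2 * self.omega_b / self.alpha1

    @property
    def lam(self) -> float:
        return self.a**2 * self.Qm / self.mix.base.k

    @property
    def beta(self) -> float:
        return self.a**2 * self.eps_over_K / (
            self.mix.base.k * (self.thetab - self.theta0)
        )

    def time_scale(self) -> float:
        """Dimensional seconds per unit of dimensionless time, a^2/alpha1."""
        return self.a**2 / self.alpha1


def solve_fd_dimensional(
    setup: DimensionalSetup,
    ny: int,
    nt: int,
    dt_star: float,
    theta_left: float = 37.0,
    theta_right: float = 45.0,
) -> TemperatureField:
    """Backward-Euler solve of the dimensional (integer-order) equation

        (rho cp)_nf theta_t = k_nf (1+4R/3) theta_yy
            + omega_b (rho cp)_nf (theta_b - theta) + eps/K
            + Qm (theta - theta0)

    on y* in [0, a] with Dirichlet boundary temperatures. Returned grids are
    dimensional (metres, seconds); the caller rescales for comparison.
    """
    mix = setup.mix
    rho_cp = mix.rho_cp
    k_eff = mix.k * (1.0 + 4.0 * setup.R / 3.0)
    kappa = k_eff / rho_cp
    dy_star = setup.a / (ny - 1)

    # raw-theta form: theta_t = kappa theta_yy - c_dim theta + s_dim
    c_dim = setup.omega_b - setup.Qm / rho_cp
    s_dim = (
        setup.omega_b * setup.thetab
        + (setup.eps_over_K - setup.Qm * setup.theta0) / rho_cp
    )

    sigma = 1.0 / dt_star
    ab = _step_matrix(ny, dy_star, sigma + c_dim, kappa)

    U = np.empty((nt + 1, ny))
    U[0] = setup.theta0
    for n in range(1, nt + 1):
        rhs = sigma * U[n - 1] + s_dim
        rhs[0] = theta_left
        rhs[-1] = theta_right
        U[n] = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(U[n])):
            raise ArithmeticError(f"dimensional solve unstable at step {n}")

    meta = {"method": "fd_dimensional_backward_euler",
            "settings": {"ny": ny, "nt": nt, "dt_star": dt_star, "a": setup.a}}
    return TemperatureField(
        values=U.T,
        y_grid=np.linspace(0.0, setup.a, ny),
        t_grid=dt_star * np.arange(nt + 1),
        metadata=meta,
    )
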