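"""Built-in validation: analytic transform-pair suite and the Laplace vs
finite-difference cross-check matrix.

The analytic suite inverts known Laplace pairs with both Durbin's and
Zakian's methods and compares against the closed forms. Tolerances are
method capabilities, not fitted numbers: Durbin with the default contour
resolves every pair to 1e-4; Zakian's five-term rational approximation is
essentially exact (~1e-7) on transforms with only poles (rational in q) but
degrades to ~1e-3 on transforms carrying a branch point (fractional powers,
exp(-sqrt(q))), which is why the model solver defaults to Durbin and keeps
Zakian as a cross-check.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import erfc, gamma

from .fd_oracle import FDGrid, solve_fd
from .laplace_inversion import InversionSettings, durbin_invert, invert_field, zakian_invert
from .materials import MATERIALS, SHAPES, NanofluidMixture
from .model_core import LaplaceField, TherapyParams, assemble_coefficients

__all__ = ["ANALYTIC_PAIRS", "AnalyticPair", "run_inversion_suite", "cross_validate"]


@dataclass(frozen=True)
class AnalyticPair:
    """A known transform pair F(q) <-> f(t) with per-method tolerances."""

    name: str
    F: Callable[[complex], complex]
    f: Callable[[float], float]
    times: tuple[float, ...]
    durbin_tol: float
    zakian_tol: float
    branch_point: bool = False


_ALPHA_FRAC = 0.5

ANALYTIC_PAIRS: tuple[AnalyticPair, ...] = (
    AnalyticPair(
        "constant: 1/q", lambda q: 1.0 / q, lambda t: 1.0,
        (0.1, 0.5, 1.0, 2.0), 1e-4, 1e-6,
    ),
    AnalyticPair(
        "ramp: 1/q^2", lambda q: 1.0 / q**2, lambda t: t,
        (0.1, 0.5, 1.0, 2.0), 1e-4, 1e-6,
    ),
    AnalyticPair(
        "exp decay: 1/(q+1)", lambda q: 1.0 / (q + 1.0), lambda t: math.exp(-t),
        (0.1, 0.5, 1.0, 2.0), 1e-4, 1e-6,
    ),
    AnalyticPair(
        "saturating growth: 1/(q(q+1))",
        lambda q: 1.0 / (q * (q + 1.0)),
        lambda t: 1.0 - math.exp(-t),
        (0.1, 0.5, 1.0, 2.0), 1e-4, 1e-6,
    ),
    AnalyticPair(
        "sine: 1/(q^2+1)",
        lambda q: 1.0 / (q * q + 1.0),
        lambda t: math.sin(t),
        (0.5, 1.0, math.pi / 2, 2.0), 1e-4, 1e-6,
    ),
    AnalyticPair(
        f"fractional: 1/q^(1+{_ALPHA_FRAC})",
        lambda q: q ** -(1.0 + _ALPHA_FRAC),
        lambda t: t**_ALPHA_FRAC / gamma(1.0 + _ALPHA_FRAC),
        (0.1, 0.5, 1.0, 2.0), 1e-4, 5e-3, branch_point=True,
    ),
    AnalyticPair(
        "diffusion wall: exp(-sqrt(q))/q",
        lambda q: cmath.exp(-cmath.sqrt(q)) / q,
        lambda t: float(erfc(0.5 / math.sqrt(t))),
        (0.1, 0.5, 1.0, 2.0), 1e-4, 5e-3, branch_point=True,
    ),
)


def run_inversion_suite(
    settings: InversionSettings | None = None,
    pairs: tuple[AnalyticPair, ...] = ANALYTIC_PAIRS,
) -> pd.DataFrame:
    """Invert every analytic pair with both methods; return the error table.

    Columns: pair, method, t, value, expected, abs_err, tol, passed.
    """
    settings = settings or InversionSettings()
    rows = []
    for pair in pairs:
        times = np.asarray(pair.times, dtype=float)
        durbin_vals = durbin_invert(pair.F, times, settings)
        for t, val in zip(times, durbin_vals):
            expected = pair.f(float(t))
            err = abs(val - expected)
            rows.append(
                {"pair": pair.name, "method": "durbin", "t": float(t),
                 "value": float(val), "expected": expected, "abs_err": err,
                 "tol": pair.durbin_tol, "passed": err <= pair.durbin_tol}
            )
        for t in times:
            val = zakian_invert(pair.F, float(t), settings)
            expected = pair.f(float(t))
            err = abs(val - expected)
            rows.append(
                {"pair": pair.name, "method": "zakian", "t": float(t),
                 "value": float(val), "expected": expected, "abs_err": err,
                 "tol": pair.zakian_tol, "passed": err <= pair.zakian_tol}
            )
    return pd.DataFrame(rows)


def cross_validate(
    alphas: tuple[float, ...] = (0.7, 1.0),
    phis: tuple[float, ...] = (0.0, 0.04),
    Rs: tuple[float, ...] = (0.0, 0.5),
    t_slices: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0),
    ny: int = 21,
    fd_ny: int = 101,
    fd_nt: int = 400,
    tol: float = 1e-2,
    settings: InversionSettings | None = None,
    quick: bool = False,
) -> pd.DataFrame:
    """Laplace-inversion solution vs the L1 finite-difference oracle.

    For every (alpha, phi, R) combination the two independently computed
    fields are compared on a shared 21-point y-grid at four time slices;
    one row per combination reports the max-absolute discrepancy.
    """
    settings = settings or InversionSettings()
    if quick:
        alphas, phis, Rs = alphas[:1], phis[:1], Rs[:1]
        fd_ny, fd_nt = 41, 200

    mix0 = NanofluidMixture(
        base=MATERIALS["blood"], particle=MATERIALS["gold"],
        phi=0.0, shape=SHAPES["platelet"],
    )
    t_max = max(t_slices)
    dt = t_max / fd_nt
    # FD time indices for the requested slices must be exact grid nodes
    slice_idx = [int(round(ts / dt)) for ts in t_slices]
    if any(abs(i * dt - ts) > 1e-12 for i, ts in zip(slice_idx, t_slices)):
        raise ValueError("t_slices must be multiples of t_max/fd_nt")
    stride = (fd_ny - 1) // (ny - 1)
    if stride * (ny - 1) != fd_ny - 1:
        raise ValueError("fd_ny - 1 must be a multiple of ny - 1")

    y = np.linspace(0.0, 1.0, ny)
    rows = []
    for alpha in alphas:
        # the incompatible hot-wall corner (theta jumps 37 -> 45 at t=0)
        # makes the first slice discretisation-limited; refine the time grid
        # there — cheaply for the memoryless alpha=1 scheme, moderately for
        # the O(nt^2) fractional history
        refine = 8 if alpha == 1.0 else 4
        for phi in phis:
            for R in Rs:
                params = TherapyParams(alpha=alpha, R=R)
                mix = mix0.with_phi(phi)
                coeff = assemble_coefficients(params, mix)
                lap = invert_field(
                    LaplaceField(coeff, params), y, np.asarray(t_slices), settings
                )
                fd = solve_fd(
                    params, coeff,
                    FDGrid(ny=fd_ny, nt=fd_nt * refine, dt=dt / refine),
                )
                fd_vals = fd.values[::stride, :][:, [i * refine for i in slice_idx]]
                err = float(np.abs(lap.values - fd_vals).max())
                rows.append(
                    {"alpha": alpha, "phi": phi, "R": R,
                     "max_abs_err": err, "tol": tol, "passed": err <= tol}
                )
    return pd.DataFrame(rows)
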