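"""Numerical inverse Laplace transforms: Durbin's Fourier series and Zakian's
rational approximation.

Durbin's method evaluates the Bromwich integral by the trapezoidal rule on a
shifted contour Re q = a,

    f(t) ~ (e^{a t} / T) [ 1/2 Re F(a)
           + sum_{k=1}^{N} Re F(a + i k pi / T) cos(k pi t / T)
                         - Im F(a + i k pi / T) sin(k pi t / T) ],

with T a small multiple of the largest time of interest (the implied series
period is 2T; aliasing decays like exp(-2aT)). Transforms of functions with
a nonzero initial value decay only like f(0+)/q, so the series tail
converges like 1/N; the implementation therefore subtracts the asymptote
c0/q with c0 = lim qF(q) (estimated at a large real frequency), inverts the
remainder — which decays at least one power faster — and adds the constant
c0 back exactly. By default the remaining oscillatory series is summed with
Wynn's epsilon algorithm applied to the complex partial sums (the classical
Honig–Hirdes refinement of Durbin's method), which removes the residual
truncation error of wall boundary-layer transforms; what is left is the
contour aliasing floor ~ exp(-2aT). Zakian's
method approximates the delta function by a five-term rational expansion,

    f(t) ~ (2 / t) sum_{i=1}^{5} Re[ K_i F(alpha_i / t) ],

with fixed conjugate-pair constants (alpha_i, K_i). Durbin converges slowly
but uniformly and handles oscillatory transforms; Zakian is cheap and very
accurate on smooth, non-oscillatory transients but degrades on oscillatory
or slowly decaying ones — the two together provide an internal cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fields import TemperatureField
from .model_core import LaplaceField

__all__ = [
    "ZAKIAN_CONSTANTS",
    "InversionSettings",
    "zakian_invert",
    "durbin_invert",
    "invert_field",
]

#: Zakian's standard five-term constants (alpha_i, K_i). Only the upper
#: half-plane member of each conjugate pair is listed; the real part in the
#: summation formula accounts for its conjugate. Checked by the 1/q -> 1
#: identity test.
ZAKIAN_CONSTANTS: tuple[tuple[complex, complex], ...] = (
    (12.83767675 + 1.666063445j, -36902.08210 + 196990.4257j),
    (12.22613209 + 5.012718792j, 61277.02524 - 95408.62551j),
    (10.93430308 + 8.409673116j, -28916.56288 + 18169.18531j),
    (8.776434715 + 11.92185389j, 4655.361138 - 1.901528642j),
    (5.225453361 + 15.72952905j, -118.7414011 - 141.3036911j),
)


@dataclass(frozen=True)
class InversionSettings:
    """Tuning of the numerical inversion.

    ``durbin_shift_times_tmax`` is the dimensionless product a*T of the
    contour shift and the series period; larger values suppress aliasing
    (error ~ exp(-2 a T)) at the cost of amplifying round-off through the
    e^{a t} factor. ``durbin_period_factor`` sets T = factor * t_max.
    """

    method: str = "durbin"
    durbin_shift_times_tmax: float = 6.0
    durbin_terms: int = 2000
    durbin_period_factor: float = 2.0
    durbin_warn_ratio: float = 1e-8
    durbin_acceleration: bool = True
    durbin_accel_window: int = 16
    zakian_constants: tuple[tuple[complex, complex], ...] = ZAKIAN_CONSTANTS

    def __post_init__(self) -> None:
        if self.method not in ("durbin", "zakian"):
            raise ValueError(f"unknown inversion method {self.method!r}")
        if self.durbin_terms < 10:
            raise ValueError("durbin_terms must be >= 10")
        if self.durbin_period_factor <= 1.0:
            raise ValueError("durbin_period_factor must exceed 1")
        for node, _ in self.zakian_constants:
            if complex(node).real <= 0:
                raise ValueError("all Zakian nodes must have positive real part")


def zakian_invert(
    F: Callable[[complex], complex],
    t: float,
    settings: InversionSettings | None = None,
) -> float:
    """Invert the transform F at a single time t > 0 by Zakian's formula."""
    if t <= 0:
        raise ValueError(f"Zakian inversion needs t > 0, got t={t}")
    settings = settings or InversionSettings()
    acc = 0.0
    for node, weight in settings.zakian_constants:
        try:
            acc += (weight * F(node / t)).real
        except Exception as exc:  # add (node, t) context, keep the cause
            raise RuntimeError(
                f"transform evaluation failed at q={node / t} (t={t})"
            ) from exc
    return 2.0 * acc / t


def _wynn_epsilon(S: np.ndarray, scale: float) -> complex:
    """Best even-column Wynn-epsilon estimate of the limit of partial sums S.

    Degenerate differences (constant tails, exactly summed series) stop the
    recursion; the estimate from the last completed even column is returned.
    Diverging table entries are rejected against ``scale``, the magnitude of
    the quantity being summed.
    """
    e_prev = np.zeros(len(S) + 1, dtype=complex)
    e_cur = np.asarray(S, dtype=complex)
    best = e_cur[-1]
    col = 0
    while len(e_cur) >= 2:
        d = np.diff(e_cur)
        if np.any(np.abs(d) < 1e-14 * scale):
            break
        nxt = e_prev[1 : len(e_cur)] + 1.0 / d
        e_prev, e_cur = e_cur, nxt
        col += 1
        if col % 2 == 0 and np.isfinite(e_cur[-1]) and abs(e_cur[-1]) < 1e6 * scale:
            best = e_cur[-1]
    return best


def durbin_invert(
    F: Callable[[complex], complex],
    t_grid: Sequence[float] | np.ndarray,
    settings: InversionSettings | None = None,
    t_max: float | None = None,
) -> np.ndarray:
    """Invert the transform F on a grid of times by Durbin's Fourier series.

    All grid times must lie in (0, t_max]; the contour is shared across the
    grid so F is evaluated once per frequency node. A warning is issued when
    the last retained term is still large relative to the partial sum
    (non-convergence of the series).
    """
    settings = settings or InversionSettings()
    t = np.asarray(t_grid, dtype=float)
    if t.ndim == 0:
        t = t[None]
    if np.any(t <= 0):
        raise ValueError("Durbin inversion needs all times > 0")
    tmax = float(t_max) if t_max is not None else float(t.max())
    if np.any(t > tmax * (1 + 1e-12)):
        raise ValueError("grid times must not exceed t_max")
    T = settings.durbin_period_factor * tmax
    a = settings.durbin_shift_times_tmax / T
    N = settings.durbin_terms

    # Tail subtraction: c0 = lim q F(q) = f(0+); the remainder transform
    # decays at least one power of q faster, restoring series convergence.
    q_big = 1e8
    c0 = float((q_big * F(complex(q_big))).real)
    if abs(c0) < 1e-9:
        c0 = 0.0

    k = np.arange(N + 1)
    q = a + 1j * k * np.pi / T
    Fq = np.array([F(complex(qk)) - c0 / complex(qk) for qk in q], dtype=complex)

    if settings.durbin_acceleration:
        m = min(settings.durbin_accel_window, N // 2)
        partial = np.empty(t.size)
        for j, tj in enumerate(t):
            cterms = Fq * np.exp(1j * k * (np.pi / T) * tj)
            cterms[0] *= 0.5
            S = np.cumsum(cterms)
            scale = max(float(np.abs(S[-1])), float(np.abs(cterms).max()), 1e-300)
            partial[j] = _wynn_epsilon(S[N - 2 * m :], scale).real
        return c0 + np.exp(a * t) / T * partial

    phase = np.outer(t, k * np.pi / T)  # (nt, N+1)
    terms = Fq.real[None, :] * np.cos(phase) - Fq.imag[None, :] * np.sin(phase)
    partial = 0.5 * terms[:, 0] + terms[:, 1:].sum(axis=1)
    tail = np.abs(terms[:, -1]).max()
    scale = max(np.abs(partial).max(), 1e-300)
    if tail > settings.durbin_warn_ratio * scale:
        warnings.warn(
            f"Durbin series slow to converge: last-term magnitude {tail:.3e} "
            f"exceeds {settings.durbin_warn_ratio:g} of the partial sum "
            f"({scale:.3e}); increase durbin_terms",
            RuntimeWarning,
            stacklevel=2,
        )
    return c0 + np.exp(a * t) / T * partial


def invert_field(
    fld: LaplaceField,
    y_grid: Sequence[float] | np.ndarray,
    t_grid: Sequence[float] | np.ndarray,
    settings: InversionSettings | None = None,
    derivative: bool = False,
) -> TemperatureField:
    """Invert the model transform on a (y, t) product grid.

    t = 0 is never inverted (both formulas are singular there); when present
    in ``t_grid`` the initial value is written directly from the parameters.
    """
    settings = settings or InversionSettings()
    y = np.asarray(y_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if y.ndim != 1 or t.ndim != 1 or y.size == 0 or t.size == 0:
        raise ValueError("y_grid and t_grid must be non-empty 1-D arrays")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")

    evaluator = fld.dvalue_dy if derivative else fld.value
    positive = t > 0
    t_pos = t[positive]
    values = np.empty((y.size, t.size), dtype=float)

    for i, yi in enumerate(y):
        F = lambda q, _y=float(yi): evaluator(_y, q)  # noqa: E731
        try:
            if settings.method == "zakian":
                values[i, positive] = [
                    zakian_invert(F, float(tj), settings) for tj in t_pos
                ]
            else:
                if t_pos.size:
                    values[i, positive] = durbin_invert(F, t_pos, settings)
        except Exception as exc:
            raise RuntimeError(
                f"inversion failed at y={yi} (method={settings.method})"
            ) from exc

    if np.any(~positive):
        # flat initial state: theta_init everywhere, zero gradient
        values[:, ~positive] = 0.0 if derivative else fld.params.theta_init

    meta = {
        "method": settings.method,
        "derivative": derivative,
        "settings": {
            "durbin_shift_times_tmax": settings.durbin_shift_times_tmax,
            "durbin_terms": settings.durbin_terms,
            "durbin_period_factor": settings.durbin_period_factor,
        },
    }
    return TemperatureField(values=values, y_grid=y, t_grid=t, metadata=meta)
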