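"""Shared test oracle: dense-matrix backward-Euler integration of the
semi-discrete bioheat system, independent of the production solver."""

import numpy as np


def backward_euler_dense(params, coeff, grid):
    ny, dy, dt = grid.ny, grid.dy, grid.dt
    A = np.zeros((ny, ny))
    r = coeff.D / dy**2
    for i in range(1, ny - 1):
        A[i, i - 1] = -r
        A[i, i] = 1.0 / dt + coeff.c + 2 * r
        A[i, i + 1] = -r
    A[0, 0] = A[-1, -1] = 1.0
    u = np.full(ny, params.theta_init)
    out = [u.copy()]
    for _ in range(grid.nt):
        rhs = u / dt + coeff.s
        rhs[0] = params.theta_left
        rhs[-1] = params.theta_right
        u = np.linalg.solve(A, rhs)
        out.append(u.copy())
    return np.array(out).T
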