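"""Small-matrix batched numerics used by the multi-state likelihood.

The panel likelihood needs ``exp(dt * Q)`` for thousands of per-subject 4x4
intensity matrices per objective evaluation; a vectorised scaling-and-squaring
Pade approximant over the whole stack keeps that cost in fused LAPACK/BLAS
calls instead of a Python loop.
"""

from __future__ import annotations

import numpy as np

# Pade [7/7] numerator coefficients (Higham); theta_7 is the 1-norm bound below
# which the unscaled approximant is accurate to double precision.
_B7 = (17297280.0, 8648640.0, 1995840.0, 277200.0, 25200.0, 1512.0, 56.0, 1.0)
_THETA7 = 0.95


def expm_batch(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of square matrices, shape (..., d, d).

    Scaling-and-squaring with a Pade [7/7] approximant; the scaling power is
    chosen from the largest 1-norm in the stack so the whole batch squares in
    lockstep.
    """
    A = np.asarray(A, dtype=float)
    single = A.ndim == 2
    if single:
        A = A[None]
    d = A.shape[-1]
    norms = np.abs(A).sum(axis=-2).max(axis=-1)  # 1-norm per matrix
    eta = float(norms.max()) if norms.size else 0.0
    s = max(0, int(np.ceil(np.log2(eta / _THETA7)))) if eta > _THETA7 else 0
    As = A / (2.0 ** s)

    I = np.broadcast_to(np.eye(d), As.shape)
    A2 = As @ As
    A4 = A2 @ A2
    A6 = A4 @ A2
    b = _B7
    U = As @ (b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * I)
    V = b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * I
    R = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        R = R @ R
    return R[0] if single else R


def numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    Steps are absolute (parameters here are log intensities and log hazard
    ratios, all O(1)).
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)
    # diagonal terms
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
    # off-diagonal terms
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = step
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H
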