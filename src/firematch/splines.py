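"""Cubic regression spline bases with curvature penalties.

The basis is the knot-value parameterization of a natural cubic spline:
coefficients are the function's values at k knots, the spline interpolates
them with natural (zero second derivative) boundary conditions, and the
quadratic penalty is the integrated squared second derivative.  The penalty
null space is exactly the linear functions, so infinite smoothing collapses
a term to a straight line rather than to zero.  Outside the knot range the
basis extrapolates linearly (with a warning), matching the natural-spline
boundary behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasisSpec", "cr_knots", "cr_basis", "sum_to_zero"]


@dataclass
class SplineBasisSpec:
    """Knots and constraint for one smooth term."""

    covariate: str
    knots: np.ndarray
    k: int = 10
    #: null-space basis of the sum-to-zero constraint (k × (k−1)), set when
    #: the constraint is absorbed
    Z: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError(f"knots for {self.covariate!r} must be strictly increasing")


def cr_knots(x: np.ndarray, k: int = 10) -> np.ndarray:
    """Default knots: k quantiles of the observed values.

    Near-coincident quantiles (heavily tied data) are merged so knot
    spacings stay bounded away from zero and the curvature penalty stays
    numerically sane.
    """
    x = np.asarray(x, dtype=float)
    q = np.quantile(x, np.linspace(0, 1, k))
    span = q[-1] - q[0]
    if span <= 0:
        raise ValueError("cannot place knots on constant data")
    knots = [q[0]]
    for v in q[1:]:
        if v - knots[-1] > 1e-4 * span:
            knots.append(v)
    if len(knots) < 3:
        raise ValueError("need at least 3 distinct knot locations")
    return np.asarray(knots)


def _penalty_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """B (tridiagonal) and D (second-difference) of the natural-spline system.

    Second derivatives at interior knots solve B δ = D β for knot values β;
    the curvature penalty is S = Dᵀ B⁻¹ D.
    """
    h = np.diff(knots)
    k = len(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    return B, D


def cr_basis(x: np.ndarray, spec: SplineBasisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the cubic regression spline basis and its penalty.

    Returns the n × k basis matrix (column j = cardinal function that is 1
    at knot j, 0 at the others) and the k × k curvature penalty.  Values
    outside the knot range get the linear extrapolant of the boundary.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    knots = spec.knots
    k = len(knots)
    B, D = _penalty_matrices(knots)
    Binv = np.linalg.inv(B)
    # F maps knot values to second derivatives at all k knots (0 at ends)
    F = np.zeros((k, k))
    F[1:-1, :] = Binv @ D
    S = D.T @ Binv @ D

    outside = (x < knots[0]) | (x > knots[-1])
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} value(s) outside knot range for "
            f"{spec.covariate!r}; extrapolating linearly"
        )
    xc = np.clip(x, knots[0], knots[-1])

    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    lo = (knots[j + 1] - xc) / h
    hi = (xc - knots[j]) / h
    cneg = ((knots[j + 1] - xc) ** 3 / h - h * (knots[j + 1] - xc)) / 6.0
    cpos = ((xc - knots[j]) ** 3 / h - h * (xc - knots[j])) / 6.0

    n = len(x)
    X = np.zeros((n, k))
    rows = np.arange(n)
    np.add.at(X, (rows, j), lo)
    np.add.at(X, (rows, j + 1), hi)
    X += cneg[:, None] * F[j, :] + cpos[:, None] * F[j + 1, :]

    if np.any(outside):
        # first derivative of the basis at the clamped boundary point
        dlo = -1.0 / h
        dhi = 1.0 / h
        dcneg = (-3.0 * (knots[j + 1] - xc) ** 2 / h + h) / 6.0
        dcpos = (3.0 * (xc - knots[j]) ** 2 / h - h) / 6.0
        dX = np.zeros((n, k))
        np.add.at(dX, (rows, j), dlo)
        np.add.at(dX, (rows, j + 1), dhi)
        dX += dcneg[:, None] * F[j, :] + dcpos[:, None] * F[j + 1, :]
        X[outside] += (x - xc)[outside, None] * dX[outside]
    return X, S


def sum_to_zero(
    X: np.ndarray, S: np.ndarray, Z: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero (mean-centering) identifiability constraint.

    Finds an orthonormal null-space basis Z of the constraint 1ᵀXβ = 0 and
    reparameterizes: columns drop from k to k−1 and the penalty transforms
    to ZᵀSZ.  Pass a stored ``Z`` to reproduce a training-time constraint at
    prediction time.
    """
    if Z is None:
        c = X.mean(axis=0)[None, :]
        # null space of the 1×k constraint via full SVD
        _, _, vt = np.linalg.svd(c, full_matrices=True)
        Z = vt[1:, :].T
    return X @ Z, Z.T @ S @ Z, Z
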