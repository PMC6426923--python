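"""B-spline coefficient-function bases for varying-coefficient models.

A coefficient function beta_j(t) over the dementia-severity axis t
(CDR-SB units) is represented as a linear combination of L B-spline
basis functions, beta_j(t) = sum_l gamma_jl B_l(t).  The default
configuration uses L = 4 cubic basis functions with no interior knots,
i.e. the space of cubic polynomials on the observed severity range
expressed in the (nonnegative, partition-of-unity) Bernstein-like
B-spline coordinates.

The functional group-LASSO penalty sqrt(int beta_j(t)^2 dt) is a
quadratic form gamma' Omega gamma with Gram matrix
Omega_lm = int B_l(t) B_m(t) dt; `PenaltyGram` carries Omega and its
Cholesky factor R (Omega = R'R), which the solver uses to reduce each
block to a Euclidean-norm group penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class BSplineBasis:
    """A B-spline basis on a severity domain [t_min, t_max].

    Parameters
    ----------
    degree : spline degree (3 = cubic).
    knots : full (clamped) knot vector, length L + degree + 1.
    """

    degree: int
    knots: np.ndarray

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def design_matrix(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at t; rows sum to one on the domain."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(
                f"evaluation points outside basis domain [{lo}, {hi}]"
            )
        tc = np.clip(t, lo, hi)
        out = BSpline.design_matrix(tc, self.knots, self.degree).toarray()
        return out

    def penalty_gram(self, n_quad: int = 64) -> "PenaltyGram":
        """Omega_lm = int_domain B_l(t) B_m(t) dt by Gauss-Legendre quadrature.

        Products of degree-d splines are piecewise polynomials of degree
        2d; 64 nodes per domain are far beyond exact for the default
        (no-interior-knot) configuration.
        """
        lo, hi = self.domain
        # integrate per knot span so interior knots are handled exactly
        spans = np.unique(self.knots[(self.knots >= lo) & (self.knots <= hi)])
        omega = np.zeros((self.n_basis, self.n_basis))
        xg, wg = np.polynomial.legendre.leggauss(n_quad)
        for a, b in zip(spans[:-1], spans[1:]):
            if b <= a:
                continue
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            B = self.design_matrix(mid + half * xg)  # (n_quad, L)
            omega += half * (B.T * wg) @ B
        return PenaltyGram(omega=omega)


@dataclass(frozen=True)
class PenaltyGram:
    """Gram matrix of the basis under the L2(dt) inner product."""

    omega: np.ndarray
    cholesky: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if not np.allclose(omega, omega.T, atol=1e-12):
            raise ValueError("penalty Gram matrix must be symmetric")
        try:
            # upper-triangular R with omega = R'R
            r = np.linalg.cholesky(omega).T
        except np.linalg.LinAlgError as exc:
            raise ValueError("penalty Gram matrix must be positive definite") from exc
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "cholesky", r)

    def functional_norm(self, gamma: np.ndarray) -> float:
        """sqrt(int beta(t)^2 dt) = ||R gamma||_2 for beta = sum gamma_l B_l."""
        return float(np.linalg.norm(self.cholesky @ np.asarray(gamma, float)))


def build_basis(t_values: np.ndarray, L: int = 4, degree: int = 3) -> BSplineBasis:
    """Build a clamped B-spline basis with L functions spanning the data.

    With the defaults (L = 4, cubic) there are no interior knots: the span
    is the full cubic-polynomial space on [min t, max t].  For L > degree+1
    interior knots are placed at quantiles of the observed severities so
    each span carries data.

    Raises
    ------
    ValueError
        if L < degree + 1 or the severities are degenerate (all equal).
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two severity values to build a basis")
    lo, hi = float(np.min(t)), float(np.max(t))
    if hi - lo <= 0:
        raise ValueError("all severity values identical; basis domain degenerate")
    if L < degree + 1:
        raise ValueError(f"L={L} requires at least degree+1={degree + 1} basis functions")
    n_interior = L - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    return BSplineBasis(degree=degree, knots=knots)


@dataclass(frozen=True)
class CoefficientFunction:
    """A severity-dependent coefficient beta(t) = sum_l gamma_l B_l(t)."""

    gamma: np.ndarray
    basis: BSplineBasis
    name: str = ""

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.basis.design_matrix(np.atleast_1d(t)) @ self.gamma

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.gamma == 0.0))
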