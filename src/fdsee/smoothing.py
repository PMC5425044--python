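"""Cubic B-spline least-squares smoothing of SEE traces.

Each subject's noisy minute-by-minute series is represented as a smooth
function f(t) = sum_k c_k phi_k(t) where phi_k are B-spline basis functions of
a given order (4 = cubic) on equally spaced interior knots.  Smoothness is
controlled primarily through the number of basis functions K — the default
workflow fits by unpenalized least squares and selects K with a greedy
("myopic") walk up a candidate ladder using generalized cross-validation —
with an optional roughness penalty lambda * int (f^(m))^2 for robustness.

All inner products (Gram and penalty matrices) use Gauss-Legendre quadrature
per knot span with order+1 nodes, which is exact for the piecewise
polynomials involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, solve

__all__ = [
    "SplineBasis",
    "SmoothCurveSet",
    "make_bspline_basis",
    "evaluate_basis",
    "fit_curves",
    "select_K_myopic",
    "evaluate_curves",
    "mean_curve",
    "DomainError",
    "SmoothingError",
]


class DomainError(ValueError):
    """Evaluation requested outside the basis domain."""


class SmoothingError(RuntimeError):
    """The (penalized) least-squares system could not be solved."""


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis on a closed time domain with its Gram matrix.

    ``knots`` is the full knot vector (boundary knots at full multiplicity);
    ``gram[j, k] = int phi_j phi_k`` over the domain.
    """

    domain: tuple[float, float]
    order: int
    K: int
    knots: np.ndarray
    gram: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return self.order - 1

    def same_as(self, other: "SplineBasis") -> bool:
        return (
            self.order == other.order
            and self.K == other.K
            and np.allclose(self.knots, other.knots)
        )


def _gauss_legendre_grid(knots: np.ndarray, n_nodes: int):
    """Gauss-Legendre nodes/weights tiled over each distinct knot span."""
    x0, w0 = np.polynomial.legendre.leggauss(n_nodes)
    spans = np.unique(knots)
    a, b = spans[:-1], spans[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    nodes = (mid[:, None] + half[:, None] * x0[None, :]).ravel()
    weights = (half[:, None] * w0[None, :]).ravel()
    return nodes, weights


def make_bspline_basis(domain, K: int, order: int = 4) -> SplineBasis:
    """Build a B-spline basis with K functions and equally spaced interior knots."""
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError(f"degenerate domain [{lo}, {hi}]")
    if K < order:
        raise ValueError(f"K={K} must be >= order={order}")
    n_interior = K - order
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(order, lo), interior, np.full(order, hi)])
    gram = _inner_product_matrix(knots, K, order, deriv=0)
    return SplineBasis(domain=(lo, hi), order=order, K=K, knots=knots, gram=gram)


def _design(knots: np.ndarray, K: int, order: int, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    spl = BSpline(knots, np.eye(K), order - 1, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(np.asarray(x, dtype=float))
    # extrapolate=False yields NaN at the right boundary for some scipy
    # versions; clamp evaluation into the closed domain instead
    if np.isnan(out).any():
        spl2 = BSpline(knots, np.eye(K), order - 1, extrapolate=True)
        if deriv:
            spl2 = spl2.derivative(deriv)
        x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
        out = spl2(x)
    return out


def _inner_product_matrix(knots, K, order, deriv: int) -> np.ndarray:
    nodes, weights = _gauss_legendre_grid(knots, order + 1)
    Phi = _design(knots, K, order, nodes, deriv=deriv)
    return Phi.T @ (weights[:, None] * Phi)


def evaluate_basis(basis: SplineBasis, x, deriv: int = 0) -> np.ndarray:
    """len(x) x K design matrix of the basis (or its ``deriv``-th derivative)."""
    x = np.asarray(x, dtype=float)
    lo, hi = basis.domain
    if (x < lo - 1e-9).any() or (x > hi + 1e-9).any():
        raise DomainError(f"evaluation points outside domain [{lo}, {hi}]")
    return _design(basis.knots, basis.K, basis.order, x, deriv=deriv)


def penalty_matrix(basis: SplineBasis, m: int = 2) -> np.ndarray:
    """K x K matrix of int phi_j^(m) phi_k^(m) (roughness penalty Gram)."""
    return _inner_product_matrix(basis.knots, basis.K, basis.order, deriv=m)


@dataclass
class SmoothCurveSet:
    """Fitted coefficient matrix representing n smooth curves on one basis."""

    basis: SplineBasis
    coef: np.ndarray  # n x K
    subject_ids: list[str]
    lam: float = 0.0
    penalty_order: int = 2
    rss: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.coef.shape[0]


def fit_curves(cohort, basis: SplineBasis, lam: float = 0.0, penalty_order: int = 2) -> SmoothCurveSet:
    """Fit every subject's SEE series by (penalized) least squares.

    Minimizes (1/T) sum_t (y_t - f(t))^2 + lam * int (f^(m))^2 per subject.
    With lam = 0 this requires T >= K observed minutes.
    """
    from .data_io import Cohort  # cycle-free: typing only

    profiles = list(cohort)
    if not profiles:
        raise ValueError("empty cohort")
    grid0 = profiles[0].time
    shared = all(np.array_equal(p.time, grid0) for p in profiles)

    def _solve(Phi, Y, T):
        A = Phi.T @ Phi / T
        if lam > 0:
            A = A + lam * penalty_matrix(basis, penalty_order)
        try:
            return solve(A, Phi.T @ Y / T, assume_a="pos")
        except LinAlgError as exc:
            raise SmoothingError(
                "singular penalized system; raise lambda or lower K"
            ) from exc

    if shared:
        T = grid0.size
        if lam == 0 and T < basis.K:
            raise SmoothingError(
                f"lambda=0 needs >= K={basis.K} observed minutes, got {T}"
            )
        Phi = evaluate_basis(basis, grid0)
        Y = np.vstack([p.see for p in profiles]).T  # T x n
        C = _solve(Phi, Y, T).T  # n x K
        resid = Y - Phi @ C.T
        rss = (resid**2).sum(axis=0)
    else:
        rows, rss_list = [], []
        for p in profiles:
            T = p.time.size
            if lam == 0 and T < basis.K:
                raise SmoothingError(
                    f"subject {p.subject_id}: lambda=0 needs >= K={basis.K} "
                    f"observed minutes, got {T}"
                )
            Phi = evaluate_basis(basis, p.time)
            c = _solve(Phi, p.see, T)
            rows.append(c)
            rss_list.append(((p.see - Phi @ c) ** 2).sum())
        C = np.vstack(rows)
        rss = np.array(rss_list)

    return SmoothCurveSet(
        basis=basis,
        coef=C,
        subject_ids=[p.subject_id for p in profiles],
        lam=lam,
        penalty_order=penalty_order,
        rss=rss,
    )


def _mean_gcv(cohort, K: int, order: int) -> float:
    """Mean per-subject GCV of the unpenalized K-basis fit."""
    profiles = list(cohort)
    tmin = min(p.time[0] for p in profiles)
    tmax = max(p.time[-1] for p in profiles)
    basis = make_bspline_basis((tmin, tmax), K, order)
    curves = fit_curves(cohort, basis, lam=0.0)
    gcvs = []
    for p, rss in zip(profiles, curves.rss):
        T = p.time.size
        gcvs.append((rss / T) / (1.0 - K / T) ** 2)
    return float(np.mean(gcvs))


def select_K_myopic(
    cohort,
    candidates=(10, 20, 40, 80, 120),
    order: int = 4,
    rel_tol: float = 0.05,
):
    """Greedy ("myopic") basis-size selection over an increasing ladder.

    Walks the candidate Ks in order, computing the mean GCV across subjects of
    the unpenalized fit; stops the first time the relative improvement over
    the previous rung falls below ``rel_tol`` and returns that previous K.
    Returns ``(K, trace)`` where trace is a list of (K, mean_gcv) pairs.
    """
    candidates = sorted(candidates)
    T_min = min(p.time.size for p in cohort)
    usable = []
    for K in candidates:
        if K < order:
            raise ValueError(f"candidate K={K} below order={order}")
        if K > T_min:
            warnings.warn(
                f"candidate K={K} exceeds shortest series length {T_min}; skipped"
            )
            continue
        usable.append(K)
    if not usable:
        raise ValueError("no usable candidate K")

    trace: list[tuple[int, float]] = []
    prev_K, prev_gcv = None, None
    for K in usable:
        g = _mean_gcv(cohort, K, order)
        trace.append((K, g))
        if prev_gcv is not None:
            # a numerically zero criterion means the fit is already exact
            if prev_gcv < 1e-20:
                return prev_K, trace
            improvement = (prev_gcv - g) / prev_gcv
            if improvement < rel_tol:
                return prev_K, trace
        prev_K, prev_gcv = K, g
    return prev_K, trace


def evaluate_curves(curveset: SmoothCurveSet, grid) -> np.ndarray:
    """n x len(grid) matrix of fitted curve values."""
    Phi = evaluate_basis(curveset.basis, grid)
    return curveset.coef @ Phi.T


def mean_curve(curveset: SmoothCurveSet, mask=None) -> np.ndarray:
    """Mean curve in coefficient space (equals the pointwise mean by linearity).

    ``mask`` optionally selects a subset of subjects (boolean or index array).
    """
    C = curveset.coef if mask is None else curveset.coef[np.asarray(mask)]
    if C.shape[0] == 0:
        raise ValueError("mask selects no subjects")
    return C.mean(axis=0)
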