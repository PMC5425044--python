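"""Functional principal component analysis in B-spline coordinates.

For curves f_i(t) = c_i' phi(t) with basis Gram matrix W, the covariance
operator's eigenproblem reduces to the symmetric matrix problem

    W^(1/2) [Cc' Cc / (n-1)] W^(1/2) u = mu u,      b = W^(-1/2) u,

where Cc is the centered coefficient matrix and b holds an eigenfunction's
basis coordinates.  Eigenfunctions are orthonormal in L2, eigenvalues are the
variances of the corresponding FPC scores

    z_hi = int xi_h(t) [f_i(t) - fbar(t)] dt = b_h' W c_i^c ,

computed exactly in coefficient space.  A VARIMAX rotation of the retained
components (applied to their values on an equally spaced grid) is available
for interpretability; it preserves orthonormality and total retained variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import SmoothCurveSet, SplineBasis, evaluate_basis

__all__ = ["FPCAResult", "fpca", "compute_scores", "varimax_rotate"]


@dataclass
class FPCAResult:
    """Eigenfunctions, eigenvalues, variance proportions and FPC scores."""

    basis: SplineBasis
    mean_coef: np.ndarray  # K
    eig_coef: np.ndarray  # H x K, rows are eigenfunction coordinates
    eigenvalues: np.ndarray  # H, nonincreasing for the unrotated solution
    eigenvalues_all: np.ndarray = field(repr=False)
    var_prop: np.ndarray = None  # H, over ALL positive eigenvalues
    scores: np.ndarray = None  # n x H
    rotation: np.ndarray = None  # H x H orthogonal (identity if unrotated)
    rotated: bool = False

    @property
    def H(self) -> int:
        return self.eig_coef.shape[0]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues_all.sum())


def _gram_sqrt(W: np.ndarray):
    evals, Q = np.linalg.eigh(W)
    if evals.min() <= 0:
        raise np.linalg.LinAlgError("basis Gram matrix is not positive definite")
    s = np.sqrt(evals)
    return (Q * s) @ Q.T, (Q / s) @ Q.T  # W^{1/2}, W^{-1/2}


def _basis_integrals(basis: SplineBasis) -> np.ndarray:
    """Vector of int phi_k(t) dt (exact: Gram column sums against constant)."""
    # constant function 1 has coefficients all-ones in a B-spline basis
    return basis.gram @ np.ones(basis.K)


def _fix_signs(eig_coef: np.ndarray, scores: np.ndarray | None, basis: SplineBasis):
    """Deterministic sign rule: int xi_h >= 0; tie broken by midpoint value."""
    integrals = eig_coef @ _basis_integrals(basis)
    mid = 0.5 * (basis.domain[0] + basis.domain[1])
    mid_vals = (eig_coef @ evaluate_basis(basis, [mid]).T).ravel()
    sign = np.where(np.abs(integrals) > 1e-10, np.sign(integrals), np.sign(mid_vals))
    sign = np.where(sign == 0, 1.0, sign)
    eig_coef = eig_coef * sign[:, None]
    if scores is not None:
        scores = scores * sign[None, :]
    return eig_coef, scores, sign


def fpca(curveset: SmoothCurveSet, H: int = 8) -> FPCAResult:
    """Functional PCA of a smooth curve set, retaining H components."""
    C = curveset.coef
    n, K = C.shape
    if n < 2:
        raise ValueError("FPCA needs at least 2 curves")
    if H > min(n - 1, K):
        raise ValueError(f"H={H} exceeds min(n-1, K) = {min(n - 1, K)}")
    W = curveset.basis.gram
    Whalf, Winvhalf = _gram_sqrt(W)
    mean_coef = C.mean(axis=0)
    Cc = C - mean_coef
    M = Whalf @ (Cc.T @ Cc / (n - 1)) @ Whalf
    evals, U = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    U = U[:, order]
    n_keep_all = min(n - 1, K)
    eigenvalues_all = evals[:n_keep_all]

    B = (Winvhalf @ U[:, :H]).T  # H x K
    scores = Cc @ W @ B.T  # n x H
    B, scores, _ = _fix_signs(B, scores, curveset.basis)

    total = eigenvalues_all.sum()
    return FPCAResult(
        basis=curveset.basis,
        mean_coef=mean_coef,
        eig_coef=B,
        eigenvalues=evals[:H],
        eigenvalues_all=eigenvalues_all,
        var_prop=evals[:H] / total,
        scores=scores,
        rotation=np.eye(H),
        rotated=False,
    )


def compute_scores(curveset: SmoothCurveSet, result: FPCAResult) -> np.ndarray:
    """FPC scores of ``curveset`` against the components in ``result``.

    Exact in coefficient space: z = (c - mean_coef)' W b.  Uses the rotated
    components when ``result`` is rotated.
    """
    if not curveset.basis.same_as(result.basis):
        raise ValueError("curve set and FPCA result use different bases")
    Cc = curveset.coef - result.mean_coef
    return Cc @ result.basis.gram @ result.eig_coef.T


def _varimax(L: np.ndarray, max_iter: int = 1000, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal rotation maximizing the raw VARIMAX criterion of L @ R."""
    p, k = L.shape
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        G = L.T @ (Lr**3 - Lr * (Lr**2).sum(axis=0, keepdims=True) / p)
        u, s, vt = np.linalg.svd(G)
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d <= d_old * (1 + tol):
            break
        d_old = d
    return R


def varimax_rotate(result: FPCAResult, H_keep: int = 2, grid_size: int = 101) -> FPCAResult:
    """VARIMAX-rotate the first ``H_keep`` components.

    The criterion is evaluated on the component values over ``grid_size``
    equally spaced points (Kaiser normalization off).  Rotated components stay
    L2-orthonormal; per-component variances become the sample variances of the
    rotated scores (their sum equals the sum of the first H_keep eigenvalues).
    Components are re-ordered by decreasing rotated variance.
    """
    if H_keep < 1:
        raise ValueError("H_keep must be >= 1")
    if H_keep > result.H:
        raise ValueError(f"H_keep={H_keep} exceeds retained components {result.H}")
    basis = result.basis
    grid = np.linspace(basis.domain[0], basis.domain[1], grid_size)
    L = (result.eig_coef[:H_keep] @ evaluate_basis(basis, grid).T).T  # grid x H
    R = _varimax(L)

    B_rot = R.T @ result.eig_coef[:H_keep]
    scores_rot = result.scores[:, :H_keep] @ R
    var_rot = scores_rot.var(axis=0, ddof=1)
    order = np.argsort(var_rot)[::-1]
    B_rot, scores_rot, var_rot = B_rot[order], scores_rot[:, order], var_rot[order]
    R = R[:, order]
    B_rot, scores_rot, sign = _fix_signs(B_rot, scores_rot, basis)
    R = R * sign[None, :]

    total = result.eigenvalues_all.sum()
    return FPCAResult(
        basis=basis,
        mean_coef=result.mean_coef,
        eig_coef=B_rot,
        eigenvalues=var_rot,
        eigenvalues_all=result.eigenvalues_all,
        var_prop=var_rot / total,
        scores=scores_rot,
        rotation=R,
        rotated=True,
    )
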