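"""Two-group inference on mean SEE curves and FPC scores.

Four procedures:

* pointwise permutation test — Welch t at every grid point with single-step
  max-|t| (Westfall-Young) family-wise adjustment;
* functional F-test — ratio of integrated between-group to pooled
  within-group squared deviations;
* adaptive Neyman test — the standardized mean-difference curve is rotated
  into (cosine) Fourier coordinates and the Neyman statistic adaptively
  truncates the number of coefficients entering the chi-square sum;
* Hotelling T^2 on FPC scores (two-group MANOVA), with its exact F reference.

The three functional tests are calibrated by label permutation (seeded),
never by asymptotics; permutation p-values use (1 + #{perm >= obs}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.fft import dct

from .smoothing import SmoothCurveSet, evaluate_curves

__all__ = [
    "FunctionalTestResult",
    "pointwise_permutation_test",
    "functional_F_test",
    "adaptive_neyman_test",
    "hotelling_t2",
]


@dataclass
class FunctionalTestResult:
    method: str
    statistic: float | np.ndarray
    p_value: float | np.ndarray
    B: int | None = None
    seed: int | None = None
    grid: np.ndarray | None = None
    raw_p: np.ndarray | None = None  # pointwise test only

    @property
    def significant(self) -> bool:
        p = np.min(self.p_value)
        return bool(p < 0.05)


def _prepare(curves, groups, grid):
    """Evaluate curves on the grid and encode groups as a 0/1 vector."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"exactly two groups required, got {labels!r}")
    g = (groups == labels[1]).astype(float)
    if isinstance(curves, SmoothCurveSet):
        if grid is None:
            lo, hi = curves.basis.domain
            grid = np.arange(np.ceil(lo), np.floor(hi) + 1)
        Y = evaluate_curves(curves, grid)
    else:
        Y = np.asarray(curves, dtype=float)
        if grid is None:
            grid = np.arange(1, Y.shape[1] + 1)
        grid = np.asarray(grid, dtype=float)
        if Y.shape[1] != grid.size:
            raise ValueError("grid length does not match curve matrix")
    if Y.shape[0] != g.size:
        raise ValueError("group labels do not match number of curves")
    n1 = int(g.sum())
    n2 = int(g.size - n1)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    return Y, g, np.asarray(grid, dtype=float)


def _permuted_labels(g: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B x n matrix of label permutations (group sizes preserved)."""
    keys = rng.random((B, g.size))
    return g[np.argsort(keys, axis=1)]


def _group_moments(S: np.ndarray, Y: np.ndarray):
    """Per-permutation group means and variances at each grid point.

    S is a B x n matrix of 0/1 labels; returns m1, m2, v1, v2 (each B x G).
    """
    n = Y.shape[0]
    n1 = S[0].sum()
    n2 = n - n1
    Y2 = Y**2
    sum1 = S @ Y
    ss1 = S @ Y2
    sum_tot = Y.sum(axis=0)
    ss_tot = Y2.sum(axis=0)
    m1 = sum1 / n1
    m2 = (sum_tot - sum1) / n2
    v1 = (ss1 - n1 * m1**2) / (n1 - 1)
    v2 = (ss_tot - ss1 - n2 * m2**2) / (n2 - 1)
    return m1, m2, np.clip(v1, 0.0, None), np.clip(v2, 0.0, None)


def _check_B(B: int):
    if B < 100:
        import warnings

        warnings.warn(f"B={B} permutations is small; p-values will be coarse")


def pointwise_permutation_test(
    curves, groups, grid=None, B: int = 10_000, seed: int = 0
) -> FunctionalTestResult:
    """Welch t at every grid point with max-|t| family-wise adjustment.

    The adjusted p-value at time t is the fraction of label permutations whose
    maximum |t| over the whole grid exceeds the observed |t(t)| — single-step
    Westfall-Young, controlling the family-wise error rate.
    """
    _check_B(B)
    Y, g, grid = _prepare(curves, groups, grid)
    rng = np.random.default_rng(seed)
    n1, n2 = g.sum(), g.size - g.sum()

    def _welch(S):
        m1, m2, v1, v2 = _group_moments(S, Y)
        se = np.sqrt(v1 / n1 + v2 / n2)
        return (m1 - m2) / se

    t_obs = _welch(g[None, :])[0]
    S = _permuted_labels(g, B, rng)
    t_perm = np.abs(_welch(S))
    max_t = t_perm.max(axis=1)  # B
    abs_obs = np.abs(t_obs)
    adj_p = (1 + (max_t[:, None] >= abs_obs[None, :]).sum(axis=0)) / (B + 1)
    raw_p = (1 + (t_perm >= abs_obs[None, :]).sum(axis=0)) / (B + 1)
    return FunctionalTestResult(
        method="pointwise_perm",
        statistic=t_obs,
        p_value=adj_p,
        raw_p=raw_p,
        B=B,
        seed=seed,
        grid=grid,
    )


def functional_F_test(
    curves, groups, grid=None, B: int = 10_000, seed: int = 0
) -> FunctionalTestResult:
    """Integrated F: between-group vs pooled within-group squared deviation.

    F = [int sum_g n_g (mbar_g - mbar)^2 dt / (G-1)]
        / [int sum_i (y_i - mbar_{g(i)})^2 dt / (n-G)],
    with trapezoid quadrature on the grid and a permutation p-value.
    """
    _check_B(B)
    Y, g, grid = _prepare(curves, groups, grid)
    rng = np.random.default_rng(seed)
    n = g.size
    n1, n2 = g.sum(), n - g.sum()
    # trapezoid quadrature weights on a (possibly uneven) grid
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2

    def _F(S):
        m1, m2, v1, v2 = _group_moments(S, Y)
        grand = Y.mean(axis=0)
        between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
        # within-group SS from the (nonnegative) group variances directly:
        # subtracting 'between' from the total cancels catastrophically when
        # the groups are nearly perfectly separated
        within = (n1 - 1) * v1 + (n2 - 1) * v2
        num = (between * w).sum(axis=1) / 1.0  # G - 1 = 1
        den = (within * w).sum(axis=1) / (n - 2)
        with np.errstate(divide="ignore"):
            return num / den

    F_obs = float(_F(g[None, :])[0])
    S = _permuted_labels(g, B, rng)
    F_perm = _F(S)
    p = float((1 + (F_perm >= F_obs).sum()) / (B + 1))
    return FunctionalTestResult(
        method="functional_F", statistic=F_obs, p_value=p, B=B, seed=seed, grid=grid
    )


def adaptive_neyman_test(
    curves, groups, grid=None, B: int = 10_000, seed: int = 0
) -> FunctionalTestResult:
    """Adaptive Neyman test on the Fourier-rotated standardized difference.

    The pooled-SE standardized difference curve is transformed by an
    orthonormal discrete cosine transform; the statistic is

        T_AN = max_{1<=m<=M} (1/sqrt(2m)) sum_{j<=m} (X_j^2 - 1),

    adaptively choosing how many low-frequency coefficients to pool.  The
    p-value is by permutation of the same statistic.
    """
    _check_B(B)
    Y, g, grid = _prepare(curves, groups, grid)
    if grid.size < 16:
        raise ValueError("adaptive Neyman test needs a grid of length >= 16")
    rng = np.random.default_rng(seed)
    n = g.size
    n1, n2 = g.sum(), n - g.sum()
    scale = np.sqrt(1 / n1 + 1 / n2)
    m_idx = np.arange(1, grid.size + 1)

    def _tan(S):
        m1, m2, v1, v2 = _group_moments(S, Y)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n - 2)
        z = (m1 - m2) / (np.sqrt(sp2) * scale)
        X = dct(z, axis=1, norm="ortho")
        cum = np.cumsum(X**2 - 1.0, axis=1)
        return (cum / np.sqrt(2.0 * m_idx)[None, :]).max(axis=1)

    T_obs = float(_tan(g[None, :])[0])
    S = _permuted_labels(g, B, rng)
    T_perm = _tan(S)
    p = float((1 + (T_perm >= T_obs).sum()) / (B + 1))
    return FunctionalTestResult(
        method="adaptive_neyman", statistic=T_obs, p_value=p, B=B, seed=seed, grid=grid
    )


def hotelling_t2(scores: np.ndarray, groups, H: int | None = None) -> FunctionalTestResult:
    """Two-sample Hotelling T^2 on the first H FPC score columns.

    Uses the exact F reference: T^2 (n1+n2-H-1) / (H (n1+n2-2)) ~ F_{H, n1+n2-H-1}.
    Invariant to any invertible linear map of the score columns, in particular
    to VARIMAX rotation.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    if H is None:
        H = scores.shape[1]
    X = scores[:, :H]
    x1 = X[groups == labels[0]]
    x2 = X[groups == labels[1]]
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 + n2 - 2 <= H:
        raise ValueError(f"n1+n2-2={n1 + n2 - 2} must exceed H={H}")
    d = x1.mean(axis=0) - x2.mean(axis=0)
    Sp = ((n1 - 1) * np.cov(x1, rowvar=False, ddof=1).reshape(H, H)
          + (n2 - 1) * np.cov(x2, rowvar=False, ddof=1).reshape(H, H)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(Sp, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; try a smaller H"
        ) from exc
    T2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    dof2 = n1 + n2 - H - 1
    F = T2 * dof2 / (H * (n1 + n2 - 2))
    p = float(stats.f.sf(F, H, dof2))
    return FunctionalTestResult(method="hotelling", statistic=T2, p_value=p)
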