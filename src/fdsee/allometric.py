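"""Allometric (power-law) normalisation of SEE for body size.

Energy expenditure scales multiplicatively with body size, so per-subject
mean SEE is modelled as

    SEE = exp(alpha + beta * sex) * weight^b1 * height^b2 * age^b3 * eps,

linearised by natural log and fitted by ordinary least squares.  On the study
population the weight-only model carries essentially all the signal with an
exponent near 0.5, so the default adjustment divides each subject's whole SEE
series by weight^0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .data_io import Cohort

__all__ = [
    "AllometricFit",
    "fit_allometric",
    "weight_adjust",
    "choose_exponent",
    "SingularFitError",
    "InsufficientDataError",
]

_VALID_TERMS = ("sex", "weight", "height", "age")


class SingularFitError(ValueError):
    """Collinear or degenerate design matrix."""


class InsufficientDataError(ValueError):
    """Too few subjects for the requested number of terms."""


@dataclass(frozen=True)
class AllometricFit:
    """OLS fit of ln(mean SEE) on the selected log-covariates.

    ``coef`` holds only the included terms (sex enters linearly as 0/1; the
    continuous covariates enter as natural logs, so their coefficients are
    power-law exponents).
    """

    intercept: float
    coef: dict[str, float]
    pvalues: dict[str, float]
    adj_r_squared: float
    residual_sd: float
    n: int

    @property
    def weight_exponent(self) -> float:
        return self.coef["weight"]


def fit_allometric(cohort: Cohort, terms: Sequence[str] = ("weight",)) -> AllometricFit:
    """Regress ln(per-subject mean SEE) on the requested terms by OLS."""
    terms = list(terms)
    for t in terms:
        if t not in _VALID_TERMS:
            raise ValueError(f"unknown term {t!r}; choose from {_VALID_TERMS}")
    cov = cohort.covariates()
    n = len(cov)
    if n <= len(terms) + 1:
        raise InsufficientDataError(
            f"n={n} subjects cannot identify {len(terms)} terms plus intercept"
        )
    y = np.log([p.mean_see for p in cohort.profiles])
    X = {}
    for t in terms:
        v = cov[t].to_numpy(dtype=float)
        if t == "sex":
            X[t] = v
        else:
            if (v <= 0).any():
                raise ValueError(f"covariate {t} must be positive for log transform")
            X[t] = np.log(v)
    design = (
        sm.add_constant(np.column_stack([X[t] for t in terms]), has_constant="add")
        if terms
        else np.ones((n, 1))
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularFitError("collinear design (e.g., a constant covariate)")
    res = sm.OLS(y, design).fit()
    coef = {t: float(res.params[i + 1]) for i, t in enumerate(terms)}
    pvals = {t: float(res.pvalues[i + 1]) for i, t in enumerate(terms)}
    return AllometricFit(
        intercept=float(res.params[0]),
        coef=coef,
        pvalues=pvals,
        adj_r_squared=float(res.rsquared_adj),
        residual_sd=float(np.sqrt(res.scale)),
        n=n,
    )


def choose_exponent(fit: AllometricFit, canonical: float = 0.5, tol: float = 0.05) -> float:
    """Round the fitted weight exponent to the canonical 0.5 when it is close.

    When |b1 - canonical| < tol the canonical value is used (the study's
    convention); otherwise the fitted exponent is kept.
    """
    b1 = fit.weight_exponent
    return canonical if abs(b1 - canonical) < tol else b1


def weight_adjust(cohort: Cohort, exponent: float = 0.5) -> Cohort:
    """Divide each subject's SEE series by weight**exponent.

    Covariates are untouched; the exponent is recorded in provenance.  Because
    the operation is a per-subject scalar multiplication it commutes exactly
    with any linear smoother.
    """
    if not np.isfinite(exponent):
        raise ValueError("exponent must be finite")
    out = Cohort(
        [dc_replace(p, see=p.see / p.weight**exponent) for p in cohort.profiles],
        provenance=list(cohort.provenance),
    )
    out.log(f"weight_adjust(exponent={exponent})")
    return out
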