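"""Obese vs non-obese classification from SEE features with repeated K-fold CV.

Features are either the full smoothed curves evaluated on the minute grid
(p = 405) or the first H FPC scores, optionally with anthropometric covariates
appended.  Performance is the Monte-Carlo mean over M random unstratified
K-fold partitions of the per-run mean fold accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fpca import FPCAResult
from .smoothing import SmoothCurveSet, evaluate_curves

__all__ = ["FeatureSet", "CVResult", "build_features", "repeated_kfold_cv"]

CLASSIFIERS = ("logistic", "svm", "rf")


@dataclass
class FeatureSet:
    matrix: np.ndarray  # n x p
    feature_kind: str  # "full_grid" | "fpc_scores"
    subject_ids: list[str] | None = None
    covariates_appended: tuple[str, ...] = ()

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CVResult:
    classifier: str
    K_folds: int
    M_runs: int
    rates: np.ndarray  # per-run mean fold accuracy
    seed: int
    feature_kind: str = ""

    @property
    def mc_mean_rate(self) -> float:
        return float(self.rates.mean())


def build_features(
    source,
    kind: str,
    H: int | None = None,
    covariates: Sequence[str] = (),
    cohort=None,
    grid=None,
) -> FeatureSet:
    """Assemble the classifier input matrix.

    ``kind='full_grid'`` evaluates a :class:`SmoothCurveSet` on the integer
    minute grid of its domain (p = 405 for the study window);
    ``kind='fpc_scores'`` takes the first H (unrotated) score columns of a
    :class:`FPCAResult`.  Covariates named in ``covariates`` are pulled from
    ``cohort`` and appended as extra columns.
    """
    if kind == "full_grid":
        if not isinstance(source, SmoothCurveSet):
            raise TypeError("full_grid features require a SmoothCurveSet")
        if grid is None:
            lo, hi = source.basis.domain
            grid = np.arange(np.ceil(lo), np.floor(hi) + 1)
        X = evaluate_curves(source, grid)
        ids = source.subject_ids
    elif kind == "fpc_scores":
        if not isinstance(source, FPCAResult):
            raise TypeError("fpc_scores features require an FPCAResult")
        if H is None:
            H = source.H
        if H > source.H:
            raise ValueError(f"H={H} exceeds available components {source.H}")
        X = source.scores[:, :H]
        ids = None
    else:
        raise ValueError(f"unknown feature kind {kind!r}")

    covariates = tuple(covariates)
    if covariates:
        if cohort is None:
            raise ValueError("covariates requested but no cohort supplied")
        cov = cohort.covariates()
        extra = cov[list(covariates)].to_numpy(dtype=float)
        X = np.column_stack([X, extra])
    return FeatureSet(
        matrix=np.asarray(X, dtype=float),
        feature_kind=kind,
        subject_ids=ids,
        covariates_appended=covariates,
    )


def _make_classifier(name: str, rng: np.random.Generator, rf_trees: int):
    if name == "logistic":
        # C=inf => unpenalized maximum likelihood
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=rf_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
        )
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def repeated_kfold_cv(
    features,
    labels,
    classifier: str = "logistic",
    K: int = 10,
    M: int = 1000,
    seed: int = 0,
    standardize: bool | None = None,
    rf_trees: int = 500,
    stratified: bool = False,
) -> CVResult:
    """Monte-Carlo repeated K-fold cross-validated classification rate.

    Each of the M runs draws a fresh random unstratified partition of the
    subjects into K near-equal folds; the run's rate is the mean fold accuracy
    and all M rates are returned.  Fully reproducible from ``seed``.

    ``standardize`` defaults to True for logistic/SVM on full-grid features
    (fitted on the training folds only) and False otherwise.
    """
    if isinstance(features, FeatureSet):
        X = features.matrix
        kind = features.feature_kind
    else:
        X = np.asarray(features, dtype=float)
        kind = "fpc_scores"
    y = np.asarray(labels)
    n, p = X.shape
    if np.unique(y).size != 2:
        raise ValueError("exactly two classes required")
    if standardize is None:
        standardize = kind == "full_grid" and classifier in ("logistic", "svm")

    min_train = n - int(np.ceil(n / K))
    if classifier == "logistic" and p >= min_train:
        raise ValueError(
            f"full-data logistic not identifiable: p={p} >= smallest training "
            f"set size {min_train}"
        )

    rng = np.random.default_rng(seed)
    rates = np.empty(M)
    for m in range(M):
        if stratified:
            order = []
            for lab in np.unique(y):
                idx = np.flatnonzero(y == lab)
                order.append(rng.permutation(idx))
            perm = np.concatenate(order)
            folds = [perm[k::K] for k in range(K)]
        else:
            perm = rng.permutation(n)
            folds = np.array_split(perm, K)
        accs = []
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
            Xtr, Xte = X[train_idx], X[test_idx]
            if standardize:
                scaler = StandardScaler().fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            clf = _make_classifier(classifier, rng, rf_trees)
            clf.fit(Xtr, y[train_idx])
            accs.append(float((clf.predict(Xte) == y[test_idx]).mean()))
        rates[m] = np.mean(accs)
    return CVResult(
        classifier=classifier,
        K_folds=K,
        M_runs=M,
        rates=rates,
        seed=seed,
        feature_kind=kind,
    )
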