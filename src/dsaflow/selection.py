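"""Iterative sparse representation (ISR) feature scoring and selection.

Sparse representation of a binary label vector on a standardized feature
matrix is realized as L1-penalized least squares,

    w = argmin ||y - Xw||^2 + lambda * ||w||_1,

solved by coordinate descent.  ISR repeats the fit K times on
class-stratified subsamples of fraction rho and averages the absolute
coefficients: score_j = mean_k |w_kj|.  The averaged coefficient magnitude
is the importance of feature j; the fraction of iterations in which a
feature's coefficient is nonzero is its selection frequency.  Temporal and
radiomics features compete in one pool on equal footing because the matrix
is standardized column-wise before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold


@dataclass
class ISRResult:
    """Per-feature importance scores and selection frequencies.

    ``ranking`` is a permutation of feature indices sorted by nonincreasing
    score, ties broken by lower index; zero-variance features carry score 0
    and sort last among the zeros by index.
    """

    scores: np.ndarray
    frequency: np.ndarray
    ranking: np.ndarray
    feature_names: list[str]
    config: dict = field(default_factory=dict)


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(
            f"ISR needs exactly two label classes, got {list(classes)}"
        )
    return np.where(y == classes[1], 1.0, -1.0)


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the L1 solution is identically zero."""
    return 2.0 * float(np.abs(X.T @ y).max())


def resolve_lambda(X: np.ndarray, y: np.ndarray, lam, seed: int = 0) -> float:
    """Resolve a penalty spec into a number.

    ``lam`` may be a number (used as-is), ``"auto"`` (5-fold
    cross-validated prediction error, chosen once on the given table), or
    ``"max_frac:<f>"`` (the fraction f of the all-zero penalty lambda_max,
    a cheap deterministic heuristic used by the modelling pipeline).
    """
    if isinstance(lam, (int, float)):
        return float(lam)
    if lam == "auto":
        n = len(y)
        cv = KFold(5, shuffle=True, random_state=seed)
        fit = LassoCV(cv=cv, fit_intercept=False, max_iter=20000).fit(X, y)
        return 2.0 * n * float(fit.alpha_)
    if isinstance(lam, str) and lam.startswith("max_frac:"):
        return float(lam.split(":", 1)[1]) * _lambda_max(X, y)
    raise ValueError(f"unrecognized lambda spec {lam!r}")


def _lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coordinate-descent solution of ||y - Xw||^2 + lam * ||w||_1.

    Narrow problems are solved to near machine precision; wide (p > 50)
    ranking problems use a looser duality tolerance, which does not change
    which coefficients are large.
    """
    n = len(y)
    alpha = lam / (2.0 * n)
    tol = 1e-10 if X.shape[1] <= 50 else 1e-3
    model = Lasso(alpha=alpha, fit_intercept=False, max_iter=20000, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_


def isr_scores(
    features,
    labels,
    K: int = 100,
    rho: float = 0.8,
    lam="auto",
    seed: int = 0,
) -> ISRResult:
    """Score every feature by iterative sparse representation.

    Features are standardized to zero mean and unit variance on the full
    table; zero-variance columns are dropped with score 0.  Each of the K
    iterations draws a class-stratified subsample of fraction ``rho``
    without replacement and solves the L1-penalized least-squares problem;
    scores are the averaged absolute coefficients.  Deterministic given
    ``seed``.
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X_full = features.to_numpy(dtype=float)
    else:
        X_full = np.asarray(features, dtype=float)
        names = [f"feature_{j}" for j in range(X_full.shape[1])]
    if np.isnan(X_full).any():
        raise ValueError("feature table contains missing values")
    y = _encode_labels(labels)
    n, p = X_full.shape
    counts = [int((y == v).sum()) for v in (-1.0, 1.0)]
    if min(counts) < 2:
        raise ValueError("need at least 2 cases per class")
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"subsample fraction rho must lie in (0, 1], got {rho}")
    sub_counts = [int(round(rho * c)) for c in counts]
    if min(sub_counts) < 1:
        raise ValueError(
            f"rho={rho} leaves a class empty in the subsample (class sizes {counts})"
        )

    mu = X_full.mean(axis=0)
    sd = X_full.std(axis=0)
    keep = sd > 0
    X = (X_full[:, keep] - mu[keep]) / sd[keep]

    lam_value = resolve_lambda(X, y, lam, seed=seed)

    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(y == v) for v in (-1.0, 1.0)]
    abs_sum = np.zeros(X.shape[1])
    nz_count = np.zeros(X.shape[1])
    for _ in range(K):
        take = np.concatenate(
            [rng.choice(idx, size=m, replace=False)
             for idx, m in zip(idx_by_class, sub_counts)]
        )
        w = _lasso_fit(X[take], y[take], lam_value)
        abs_sum += np.abs(w)
        nz_count += (w != 0).astype(float)

    scores = np.zeros(p)
    freq = np.zeros(p)
    scores[keep] = abs_sum / K
    freq[keep] = nz_count / K
    ranking = np.lexsort((np.arange(p), -scores))
    return ISRResult(
        scores=scores,
        frequency=freq,
        ranking=ranking,
        feature_names=names,
        config={"K": K, "rho": rho, "lambda": lam_value, "seed": seed},
    )


def select_features(
    result: ISRResult,
    m,
    features=None,
    labels=None,
    seed: int = 0,
    grid: tuple[int, ...] = (5, 10, 20, 30, 50),
) -> np.ndarray:
    """Pick the top-m features by ISR score (ties by lower index).

    ``m="cv"`` chooses m from ``grid`` by 5-fold cross-validated AUC of a
    linear SVM on the candidate subsets (``features`` and ``labels`` must
    then be supplied).  If every score is zero there is no informative
    ranking; a warning is emitted and the first m features by index are
    returned.
    """
    p = len(result.scores)
    if m == "cv":
        if features is None or labels is None:
            raise ValueError("m='cv' needs the feature table and labels")
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X = (features.to_numpy(dtype=float)
             if isinstance(features, pd.DataFrame) else np.asarray(features, float))
        y = _encode_labels(labels)
        best_m, best_auc = None, -np.inf
        for cand in grid:
            if cand > p:
                continue
            cols = select_features(result, cand)
            clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
            cv = StratifiedKFold(5, shuffle=True, random_state=seed)
            auc = cross_val_score(
                clf, X[:, cols], y, cv=cv, scoring="roc_auc"
            ).mean()
            if auc > best_auc:
                best_m, best_auc = cand, auc
        if best_m is None:
            raise ValueError("no grid entry fits the feature count")
        return select_features(result, best_m)

    m = int(m)
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    if m > p:
        raise ValueError(f"m={m} exceeds the {p} scored features")
    if np.all(result.scores == 0):
        warnings.warn(
            "all ISR scores are zero: no informative ranking, returning the "
            "first features by index",
            stacklevel=2,
        )
        return np.arange(m)
    return np.sort(result.ranking[:m])
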