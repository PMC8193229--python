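"""SVM diagnosis/grading models and the clinical evaluation protocol.

The evaluation protocol mirrors small-cohort radiomics practice: cases are
split 7:3 into a cross-validation cohort and an untouched independent test
cohort (stratified by class); model evaluation on the cross-validation
cohort uses leave-one-out (LOO): for every held-out case, feature
standardization, ISR feature selection and the SVM fit are re-run on the
remaining cases only, so no information leaks from the held-out case into
selection or fitting.  Metrics are ACC/SENS/SPEC and the Mann-Whitney AUC
with a stratified percentile-bootstrap 95% CI.

Three feature sets are compared: the five binary temporal features, the
1,750 radiomics features, and their concatenation; grading (high = IV-V
vs. low = I-III) uses the same machinery on AVM cases only, under the
cross-validation protocol.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import radiomics, temporal
from .dataio import read_detection_table, read_frame_stack, write_feature_table
from .selection import isr_scores, select_features


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Equals the trapezoidal area under the empirical ROC curve.  Requires
    both classes present.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ClassificationMetrics:
    """ACC/SENS/SPEC/AUC with a bootstrap 95% CI on the AUC."""

    acc: float
    sens: float
    spec: float
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d


def classification_metrics(
    predicted,
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassificationMetrics:
    """Confusion-matrix metrics plus AUC with a stratified bootstrap CI.

    The positive class is label 1 (AVM for diagnosis, high grade for
    grading); SENS = TP/(TP+FN), SPEC = TN/(TN+FP).  The CI resamples
    positives and negatives separately (percentile interval).
    """
    y = np.asarray(labels).astype(bool)
    p = np.asarray(predicted).astype(bool)
    s = np.asarray(scores, dtype=float)
    tp = int((p & y).sum())
    tn = int((~p & ~y).sum())
    fp = int((p & ~y).sum())
    fn = int((~p & y).sum())
    auc = roc_auc(s, y)

    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        boots[b] = roc_auc(s[idx], y[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ClassificationMetrics(
        acc=(tp + tn) / len(y),
        sens=tp / max(tp + fn, 1),
        spec=tn / max(tn + fp, 1),
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


# --------------------------------------------------------------------------
# classifier with in-fold selection
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Tunable parameters of the selection + SVM pipeline.

    ``n_features`` caps the ISR-selected subset (selection is skipped when
    the feature pool is already that small).  ``isr_lambda`` follows
    :func:`dsaflow.selection.resolve_lambda`; the default is a cheap
    deterministic fraction of the all-zero penalty, re-resolved inside
    every training fold.  ``c_grid`` is searched by inner stratified CV on
    the training fold; a single-entry grid skips the search.
    """

    kernel: str = "linear"
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    n_features: int = 10
    isr_k: int = 20
    isr_rho: float = 0.8
    isr_lambda: object = "max_frac:0.1"
    inner_cv: int = 3
    tau: float = 0.5
    n_boot: int = 2000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_grid"] = list(self.c_grid)
        return d


def _fit_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ModelConfig,
    seed: int,
    fixed_columns: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Fit standardize->ISR-select->SVM on the training cases only.

    Returns decision-function scores for the test rows and a record of the
    fitted choices (selected columns, C).  ``fixed_columns`` bypasses
    in-fold ISR selection with a precomputed subset.
    """
    scaler = StandardScaler().fit(X_train)
    Xt = scaler.transform(X_train)
    Xs = scaler.transform(X_test)

    p = X_train.shape[1]
    if fixed_columns is not None:
        cols = np.asarray(fixed_columns)
    elif p > config.n_features:
        res = isr_scores(
            Xt, y_train, K=config.isr_k, rho=config.isr_rho,
            lam=config.isr_lambda, seed=seed,
        )
        cols = select_features(res, config.n_features)
    else:
        cols = np.arange(p)
    Xt, Xs = Xt[:, cols], Xs[:, cols]

    grid = list(config.c_grid)
    if len(grid) > 1 and min(np.bincount(y_train.astype(int))) >= config.inner_cv:
        best_c, best_auc = grid[0], -np.inf
        skf = StratifiedKFold(config.inner_cv, shuffle=True, random_state=seed)
        for c in grid:
            aucs = []
            for tr, va in skf.split(Xt, y_train):
                clf = SVC(kernel=config.kernel, C=c).fit(Xt[tr], y_train[tr])
                s = clf.decision_function(Xt[va])
                if len(np.unique(y_train[va])) == 2:
                    aucs.append(roc_auc(s, y_train[va]))
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            if mean_auc > best_auc:
                best_c, best_auc = c, mean_auc
    else:
        best_c = grid[0]

    clf = SVC(kernel=config.kernel, C=best_c).fit(Xt, y_train)
    return clf.decision_function(Xs), {"C": best_c, "columns": cols.tolist()}


def loo_cv(
    features,
    labels,
    config: ModelConfig | None = None,
    seed: int = 0,
    selection_scope: str = "fold",
) -> tuple[ClassificationMetrics, np.ndarray]:
    """Leave-one-out cross-validation with in-fold selection (no leakage).

    Returns the metrics over the held-out decision scores (predicted label
    = positive score) and the per-case score vector.

    ``selection_scope="fold"`` (default) reruns ISR selection on the n-1
    training cases of every fold.  ``"cohort"`` selects once on all n
    cases and holds the subset fixed — optimistically biased, offered only
    for sensitivity analysis of the selection protocol.
    """
    config = config or ModelConfig()
    X = (features.to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame) else np.asarray(features, float))
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 4:
        raise ValueError(f"LOO needs at least 4 cases, got {n}")
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("LOO needs at least 2 cases of each class")
    if selection_scope not in ("fold", "cohort"):
        raise ValueError("selection_scope must be 'fold' or 'cohort'")
    fixed = None
    if selection_scope == "cohort" and X.shape[1] > config.n_features:
        Xs_all = StandardScaler().fit_transform(X)
        res = isr_scores(Xs_all, y, K=config.isr_k, rho=config.isr_rho,
                         lam=config.isr_lambda, seed=seed)
        fixed = select_features(res, config.n_features)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        s, _ = _fit_score(X[mask], y[mask], X[i: i + 1], config, seed=seed,
                          fixed_columns=fixed)
        scores[i] = s[0]
    metrics = classification_metrics(
        scores > 0, scores, y, n_boot=config.n_boot, seed=seed
    )
    return metrics, scores


def split_evaluate(
    features,
    labels,
    config: ModelConfig | None = None,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[ClassificationMetrics, ClassificationMetrics]:
    """7:3 protocol: LOO on the CV cohort, one shot on the untouched test.

    The stratified split keeps class ratios within one case; the model is
    refit on the full CV cohort before scoring the test cohort once.
    """
    config = config or ModelConfig()
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    X = (features.to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame) else np.asarray(features, float))
    y = np.asarray(labels).astype(int)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=test_fraction, stratify=y, random_state=seed
    )
    for part, name in ((idx_train, "cross-validation"), (idx_test, "test")):
        if min(np.bincount(y[part], minlength=2)) < 2:
            raise ValueError(f"split leaves fewer than 2 cases per class in the {name} cohort")
    cv_metrics, _ = loo_cv(X[idx_train], y[idx_train], config, seed=seed)
    s_test, _ = _fit_score(X[idx_train], y[idx_train], X[idx_test], config, seed=seed)
    test_metrics = classification_metrics(
        s_test > 0, s_test, y[idx_test], n_boot=config.n_boot, seed=seed
    )
    return cv_metrics, test_metrics


# --------------------------------------------------------------------------
# end-to-end cohort pipelines
# --------------------------------------------------------------------------

FEATURE_SETS = ("temporal", "radiomics", "combined")


def compute_cohort_features(
    cohort_dir: str | Path,
    tau: float = 0.5,
    detector: str = "truth",
    cache: bool = True,
) -> pd.DataFrame:
    """Detections -> T1-T5 and key-frame radiomics for every cohort case.

    ``detector="truth"`` uses the ground-truth annotation table;
    ``"reference"`` runs the template-layout reference detector on the
    rendered frames.  The resulting table (metadata + 5 temporal + 1,750
    radiomics columns) is cached as CSV in the cohort directory.
    """
    cohort_dir = Path(cohort_dir)
    cache_path = cohort_dir / f"features_{detector}.csv"
    if cache and cache_path.exists():
        from .dataio import read_feature_table

        return read_feature_table(cache_path)

    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    truth = read_detection_table(cohort_dir / "truth_boxes.csv")
    rows = []
    for _, rec in manifest.iterrows():
        case_id = rec["case_id"]
        stack = read_frame_stack(
            cohort_dir / "cases" / case_id, rec["frame_interval_ms"]
        )
        if detector == "truth":
            det = truth[truth["case_id"] == case_id]
        elif detector == "reference":
            from .detection import reference_detect

            det = reference_detect(stack)
        else:
            raise ValueError(f"unknown detector {detector!r}")
        ev = temporal.structure_events(det, tau)
        tl = temporal.classify_phases(ev, det, tau, n_frames=stack.n_frames)
        tvec = temporal.temporal_features(ev, tl)
        key = temporal.select_key_frames(ev, stack.n_frames)
        rad = radiomics.case_radiomics_vector(stack, key)
        row = dict(zip(temporal.TEMPORAL_FEATURE_NAMES, (float(v) for v in tvec)))
        row.update(rad.to_dict())
        rows.append(row)

    feats = pd.DataFrame(rows)
    if cache:
        write_feature_table(
            manifest["case_id"], manifest["diagnosis"], manifest["grade_class"],
            feats, cache_path,
        )
    out = feats.copy()
    out.insert(0, "grade_class", manifest["grade_class"].to_numpy())
    out.insert(0, "diagnosis", manifest["diagnosis"].to_numpy())
    out.insert(0, "case_id", manifest["case_id"].to_numpy())
    return out


def _feature_columns(table: pd.DataFrame, feature_set: str) -> list[str]:
    tcols = list(temporal.TEMPORAL_FEATURE_NAMES)
    rcols = [c for c in table.columns
             if c not in ("case_id", "diagnosis", "grade_class") and c not in tcols]
    if feature_set == "temporal":
        return tcols
    if feature_set == "radiomics":
        return rcols
    if feature_set == "combined":
        return tcols + rcols
    raise ValueError(f"feature_set must be one of {FEATURE_SETS}, got {feature_set!r}")


def run_diagnosis_pipeline(
    cohort_dir: str | Path,
    feature_set: str = "combined",
    config: ModelConfig | None = None,
    seed: int = 0,
    detector: str = "truth",
    out_path: str | Path | None = None,
) -> dict:
    """End-to-end AVM diagnosis on a cohort directory.

    Runs detections -> phases -> temporal features and key-frame radiomics,
    restricts to the requested feature set, and evaluates with both the LOO
    and the 7:3 split protocol.  Positive class: AVM.
    """
    config = config or ModelConfig()
    table = compute_cohort_features(cohort_dir, tau=config.tau, detector=detector)
    cols = _feature_columns(table, feature_set)
    y = (table["diagnosis"] == "AVM").astype(int).to_numpy()
    X = table[cols]
    loo_metrics, loo_scores = loo_cv(X, y, config, seed=seed)
    cv_metrics, test_metrics = split_evaluate(X, y, config, seed=seed)
    report = {
        "task": "diagnosis",
        "feature_set": feature_set,
        "detector": detector,
        "n_cases": int(len(y)),
        "n_avm": int(y.sum()),
        "seed": seed,
        "config": config.to_dict(),
        "loo": loo_metrics.to_dict(),
        "split_cv": cv_metrics.to_dict(),
        "split_test": test_metrics.to_dict(),
        "loo_scores": loo_scores.tolist(),
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report


def run_grading_pipeline(
    cohort_dir: str | Path,
    config: ModelConfig | None = None,
    seed: int = 0,
    detector: str = "truth",
    out_path: str | Path | None = None,
) -> dict:
    """AVM grading (high IV-V vs. low I-III) on the cohort's AVM cases.

    Cross-validation (LOO) protocol only; reports the combined and the
    radiomics-only feature sets side by side.  Positive class: high grade.
    """
    config = config or ModelConfig()
    table = compute_cohort_features(cohort_dir, tau=config.tau, detector=detector)
    avm = table[table["diagnosis"] == "AVM"].reset_index(drop=True)
    if len(avm) == 0 or avm["grade_class"].isin(["none"]).any():
        raise ValueError("grading needs AVM cases with grade_class low/high")
    y = (avm["grade_class"] == "high").astype(int).to_numpy()
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("grading needs both high- and low-grade AVM cases")
    report: dict = {
        "task": "grading",
        "detector": detector,
        "n_cases": int(len(y)),
        "n_high": int(y.sum()),
        "seed": seed,
        "config": config.to_dict(),
    }
    for fs in ("combined", "radiomics"):
        metrics, scores = loo_cv(avm[_feature_columns(avm, fs)], y, config, seed=seed)
        report[fs] = {"loo": metrics.to_dict(), "loo_scores": scores.tolist()}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report


def permutation_null_auc(
    features,
    labels,
    config: ModelConfig | None = None,
    n_permutations: int = 3,
    seed: int = 0,
) -> list[float]:
    """LOO AUCs under label permutation (the no-signal null)."""
    config = config or ModelConfig()
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        m, _ = loo_cv(features, y[perm], config, seed=seed)
        aucs.append(m.auc)
    return aucs
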