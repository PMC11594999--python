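"""Fisher linear discriminant analysis with stepwise feature selection.

The two-class discriminant direction w maximises the Fisher criterion

    J(w) = (w' S_B w) / (w' S_W w),

where S_B and S_W are the between- and within-class scatter matrices; for
two classes the maximiser has the closed form w ∝ S_W^{-1} (mu_1 - mu_0).
Classification assumes Gaussian classes with a shared (pooled) covariance,
so the decision rule is a threshold on the projection z = w'x placed where
the two class posteriors (with training priors) are equal.

Feature selection follows the classical stepwise discriminant procedure:
forward entry and backward removal driven by partial Wilks' lambda
F statistics, with SPSS-style default thresholds F-to-enter = 3.84 and
F-to-remove = 2.71.

Validation utilities implement leave-one-out at the cell or patient level
(the *entire* procedure, including stepwise selection, is refit inside
every fold) and repeated stratified 50/50 hold-out with macro F-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDAModel",
    "ValidationReport",
    "fit_lda",
    "stepwise_select",
    "loo_validate",
    "holdout_validate",
    "f_score",
    "aggregate_per_patient",
]


@dataclass
class LDAModel:
    """Fitted two-class Fisher discriminant."""

    w: np.ndarray  # unit-length discriminant direction, oriented towards class 1
    classes_: np.ndarray  # the two labels, [negative, positive]
    class_means: np.ndarray  # (2, d)
    priors: np.ndarray  # (2,)
    S_W: np.ndarray
    S_B: np.ndarray
    threshold: float  # decision point on the projection z = w.x
    selected_features: list[str] = field(default_factory=list)
    ridge: float = 0.0

    def project(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w

    def predict(self, X):
        z = self.project(X)
        return np.where(z > self.threshold, self.classes_[1], self.classes_[0])

    def fisher_criterion(self, w=None) -> float:
        w = self.w if w is None else np.asarray(w, dtype=float)
        denom = float(w @ self.S_W @ w)
        if denom == 0.0:
            return float("inf")
        return float(w @ self.S_B @ w) / denom


def _scatter(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    mu = X.mean(axis=0)
    d = X.shape[1]
    S_W = np.zeros((d, d))
    S_B = np.zeros((d, d))
    means = []
    for c in classes:
        Xi = X[y == c]
        mi = Xi.mean(axis=0)
        means.append(mi)
        Xc = Xi - mi
        S_W += Xc.T @ Xc
        diff = (mi - mu)[:, None]
        S_B += Xi.shape[0] * (diff @ diff.T)
    return np.array(means), S_W, S_B


def fit_lda(X, y, feature_names: list[str] | None = None) -> LDAModel:
    """Fit the two-class Fisher discriminant with a pooled-covariance rule.

    A singular within-class scatter falls back to ridge regularisation
    S_W + eps*I with eps = 1e-8 * trace(S_W)/d, recorded on the model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    n, d = X.shape
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")

    means, S_W, S_B = _scatter(X, y, classes)
    ridge = 0.0
    S_W_r = S_W
    # closed-form two-class solution of the generalized eigenproblem
    delta = means[1] - means[0]
    try:
        w = np.linalg.solve(S_W_r, delta)
        if not np.isfinite(w).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        ridge = 1e-8 * max(np.trace(S_W), 1.0) / d
        S_W_r = S_W + ridge * np.eye(d)
        w = np.linalg.solve(S_W_r, delta)
    norm = np.linalg.norm(w)
    if norm == 0 or not np.isfinite(norm):
        # identical class means: direction undefined, fall back to delta axis
        w = np.zeros(d)
        w[0] = 1.0
    else:
        w = w / norm
    if w @ delta < 0:
        w = -w

    priors = counts / n
    pooled = S_W / max(n - 2, 1)
    m0, m1 = float(means[0] @ w), float(means[1] @ w)
    s2 = float(w @ pooled @ w)
    if m1 == m0:
        threshold = m0
    elif s2 == 0.0:
        threshold = 0.5 * (m0 + m1)
    else:
        threshold = 0.5 * (m0 + m1) - s2 * np.log(priors[1] / priors[0]) / (m1 - m0)

    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(d)]
    return LDAModel(
        w=w,
        classes_=classes,
        class_means=means,
        priors=priors,
        S_W=S_W,
        S_B=S_B,
        threshold=float(threshold),
        selected_features=names,
        ridge=ridge,
    )


# ---------------------------------------------------------------------------
# stepwise selection on partial Wilks' lambda F statistics


def _wilks_lambda(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    """Wilks' lambda det(W)/det(T) restricted to the given columns."""
    if not cols:
        return 1.0
    Xs = X[:, cols]
    classes = np.unique(y)
    _, W, _ = _scatter(Xs, y, classes)
    Xc = Xs - Xs.mean(axis=0)
    T = Xc.T @ Xc
    sW, ldW = np.linalg.slogdet(W)
    sT, ldT = np.linalg.slogdet(T)
    if sT <= 0:
        return np.nan  # degenerate total scatter (collinear/constant features)
    if sW <= 0:
        return 0.0
    return float(np.exp(ldW - ldT))


def _partial_f(lam_small: float, lam_big: float, n: int, p_small: int, g: int = 2) -> float:
    """F statistic for the change in Wilks' lambda when one feature is added."""
    if not np.isfinite(lam_big) or lam_big <= 0:
        return np.nan
    df2 = n - g - p_small
    if df2 < 1:
        return np.nan
    return (lam_small / lam_big - 1.0) * df2 / (g - 1)


def stepwise_select(
    X,
    y,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    feature_names: list[str] | None = None,
    max_steps: int = 100,
) -> tuple[list[str], LDAModel]:
    """Forward/backward stepwise discriminant feature selection.

    Returns the ordered list of selected feature names and an LDA model
    refit on that subset.  If nothing passes F-to-enter the selection is
    empty and a chance-level single-feature model is returned with a
    warning.
    """
    if f_enter <= f_remove:
        raise ValueError("f_enter must exceed f_remove")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, d = X.shape
    if d < 1:
        raise ValueError("need at least one candidate feature")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(d)]

    selected: list[int] = []
    lam_cur = 1.0
    for _ in range(max_steps):
        changed = False
        # forward entry
        best_j, best_f, best_lam = None, -np.inf, None
        for j in range(d):
            if j in selected:
                continue
            lam_j = _wilks_lambda(X, y, selected + [j])
            fj = _partial_f(lam_cur, lam_j, n, len(selected))
            if np.isfinite(fj) and fj > best_f:
                best_j, best_f, best_lam = j, fj, lam_j
        if best_j is not None and best_f >= f_enter:
            selected.append(best_j)
            lam_cur = best_lam
            changed = True
        # backward removal
        while len(selected) > 1:
            worst_j, worst_f, worst_lam = None, np.inf, None
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = _wilks_lambda(X, y, rest)
                fj = _partial_f(lam_rest, lam_cur, n, len(rest))
                if np.isfinite(fj) and fj < worst_f:
                    worst_j, worst_f, worst_lam = j, fj, lam_rest
            if worst_j is not None and worst_f < f_remove:
                selected.remove(worst_j)
                lam_cur = worst_lam
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        warnings.warn("no feature passed F-to-enter; returning chance-level model", stacklevel=2)
        model = fit_lda(X[:, [0]], y, feature_names=[names[0]])
        model.w = np.zeros(1)
        model.selected_features = []
        return [], model

    sel_names = [names[j] for j in selected]
    model = fit_lda(X[:, selected], y, feature_names=sel_names)
    return sel_names, model


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    level: str = "cell"
    accuracy: float | None = None  # resubstitution
    accuracy_loo: float | None = None
    per_repeat_accuracy: list[float] = field(default_factory=list)
    f_score_mean: float | None = None
    f_score_sd: float | None = None
    confusion: np.ndarray | None = None  # rows = true, cols = predicted
    selected_features: list[str] = field(default_factory=list)
    skipped_folds: int = 0

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "accuracy": self.accuracy,
            "accuracy_loo": self.accuracy_loo,
            "per_repeat_accuracy": list(self.per_repeat_accuracy),
            "f_score_mean": self.f_score_mean,
            "f_score_sd": self.f_score_sd,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "selected_features": list(self.selected_features),
            "skipped_folds": self.skipped_folds,
        }


def _fit_and_predict(Xtr, ytr, Xte, stepwise: bool, names, f_enter, f_remove):
    if stepwise:
        sel, model = stepwise_select(Xtr, ytr, f_enter=f_enter, f_remove=f_remove, feature_names=names)
        if not sel:
            # chance-level: predict the majority training class
            classes, counts = np.unique(ytr, return_counts=True)
            return np.full(Xte.shape[0], classes[np.argmax(counts)]), []
        idx = [names.index(s) for s in sel]
        return model.predict(Xte[:, idx]), sel
    model = fit_lda(Xtr, ytr, feature_names=names)
    return model.predict(Xte), list(names)


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=int)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            cm[i, j] = int(np.sum((y_true == ci) & (y_pred == cj)))
    return cm


def f_score(confusion, averaging: str = "macro") -> float:
    """Macro (or per-class) F1 from a 2x2 confusion matrix (rows = true)."""
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    fs = []
    for k in (0, 1):
        tp = cm[k, k]
        fp = cm[1 - k, k]
        fn = cm[k, 1 - k]
        if tp == 0:
            fs.append(0.0)
            continue
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        fs.append(2 * prec * rec / (prec + rec))
    if averaging == "macro":
        return float(np.mean(fs))
    if averaging == "per_class":
        return fs
    raise ValueError(f"unknown averaging {averaging!r}")


def loo_validate(
    X,
    y,
    unit_ids=None,
    *,
    stepwise: bool = False,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    feature_names: list[str] | None = None,
    level: str = "cell",
) -> ValidationReport:
    """Leave-one-unit-out validation, refitting the full procedure per fold.

    ``unit_ids`` groups rows into validation units (e.g. patients); by
    default every row is its own unit.  Folds whose training remainder
    contains a single class are skipped and counted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = X.shape[0]
    units = np.arange(n) if unit_ids is None else np.asarray(unit_ids)
    uniq = np.unique(units)
    if uniq.size < 3:
        raise ValueError("need >= 3 validation units")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    classes = np.unique(y)

    full_pred, sel = _fit_and_predict(X, y, X, stepwise, names, f_enter, f_remove)
    resub = float(np.mean(full_pred == y))

    hits, total, skipped = 0, 0, 0
    y_true_all, y_pred_all = [], []
    for u in uniq:
        test = units == u
        train = ~test
        if np.unique(y[train]).size < 2:
            skipped += 1
            continue
        pred, _ = _fit_and_predict(X[train], y[train], X[test], stepwise, names, f_enter, f_remove)
        hits += int(np.sum(pred == y[test]))
        total += int(test.sum())
        y_true_all.append(y[test])
        y_pred_all.append(pred)

    cm = _confusion(np.concatenate(y_true_all), np.concatenate(y_pred_all), classes)
    return ValidationReport(
        level=level,
        accuracy=resub,
        accuracy_loo=hits / total if total else float("nan"),
        confusion=cm,
        selected_features=sel,
        skipped_folds=skipped,
    )


def holdout_validate(
    X,
    y,
    train_fraction: float = 0.5,
    repeats: int = 10,
    seed: int = 0,
    *,
    stepwise: bool = False,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    feature_names: list[str] | None = None,
    level: str = "cell",
) -> ValidationReport:
    """Repeated stratified hold-out (default 50%/50%, 10 repeats).

    Reports per-repeat accuracy and the mean +/- SD of accuracy and macro
    F-score across repeats; deterministic for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    rng = np.random.default_rng(seed)

    accs, fss = [], []
    cm_total = np.zeros((2, 2), dtype=int)
    sel_last: list[str] = []
    for _ in range(repeats):
        train = np.zeros(X.shape[0], dtype=bool)
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            k = int(round(train_fraction * idx.size))
            k = max(2, min(k, idx.size - 1))  # >=2 to fit, >=1 left to test
            train[idx[:k]] = True
        if np.unique(y[train]).size < 2 or np.unique(y[~train]).size < 1:
            raise ValueError("degenerate hold-out split")
        pred, sel_last = _fit_and_predict(X[train], y[train], X[~train], stepwise, names, f_enter, f_remove)
        cm = _confusion(y[~train], pred, classes)
        cm_total += cm
        accs.append(float(np.trace(cm) / cm.sum()))
        fss.append(f_score(cm, "macro"))

    return ValidationReport(
        level=level,
        accuracy=float(np.mean(accs)),
        per_repeat_accuracy=accs,
        f_score_mean=float(np.mean(fss)),
        f_score_sd=float(np.std(fss, ddof=0)),
        confusion=cm_total,
        selected_features=sel_last,
    )


def aggregate_per_patient(cell_features: pd.DataFrame, patient_col: str = "patient_id") -> pd.DataFrame:
    """Average per-cell features into one row per patient.

    Numeric columns are arithmetic means over the patient's cells;
    non-numeric columns (group, subtype, ...) must be constant within a
    patient and are carried through; ``n_cells`` records the count.
    """
    if patient_col not in cell_features.columns:
        raise ValueError(f"missing patient column {patient_col!r}")
    df = cell_features.copy()
    num_cols = [c for c in df.columns if c != patient_col and pd.api.types.is_numeric_dtype(df[c])]
    other = [c for c in df.columns if c != patient_col and c not in num_cols and c != "cell_id"]

    grouped = df.groupby(patient_col, sort=True)
    out = grouped[num_cols].mean()
    out["n_cells"] = grouped.size()
    for c in other:
        vals = grouped[c].nunique()
        if (vals > 1).any():
            raise ValueError(f"column {c!r} not constant within patient")
        out[c] = grouped[c].first()
    return out.reset_index()
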