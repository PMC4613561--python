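"""Model validation: 7-fold cross-validation, CV-ANOVA and ROC analysis.

Q2 is the cross-validated analogue of R2Y: 1 - PRESS / SS_tot, where PRESS
pools squared prediction errors of held-out samples over stratified folds,
each fold's model (including its scaling parameters) being refit on the
training portion only. CV-ANOVA turns the same quantities into an F-test:
the variation explained by cross-validated prediction (SS_tot - PRESS) is
compared against the residual PRESS with degrees of freedom counted from the
model size, giving a p-value for the whole discriminant model. ROC curves
are computed from the cross-validated predicted y values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .chemometrics import OPLSDAModel, encode_classes, fit_oplsda, predict, _as_matrix
from .errors import ValidationError


@dataclass
class CVResult:
    """Per-sample cross-validated predictions and the derived Q2."""

    fold_assignment: np.ndarray  # sample -> fold in 0..K-1
    y_pred_cv: np.ndarray
    y_true: np.ndarray  # 0/1 encoding
    PRESS: float
    SS_tot: float
    Q2: float
    K: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": self.fold_assignment,
            "y_true": self.y_true,
            "y_pred_cv": self.y_pred_cv,
        })


@dataclass
class CVANOVAResult:
    F: float
    df1: float
    df2: float
    p: float


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def youden_point(self) -> tuple[float, float, float]:
        """(threshold, sensitivity, specificity) maximizing Youden's J."""
        j = self.sensitivity + self.specificity - 1.0
        i = int(np.argmax(j))
        return float(self.thresholds[i]), float(self.sensitivity[i]), float(self.specificity[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def stratified_folds(y01: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class the indices are shuffled by a seeded RNG and dealt
    one at a time to the currently least-filled fold (ties broken by fold
    index), so folds stay balanced overall and within class; K = n reduces
    to leave-one-out. When a class has fewer members than K some folds
    simply receive none of that class (graceful degradation).
    """
    n = y01.size
    if K < 2:
        raise ValidationError("K must be >= 2")
    if K > n:
        raise ValidationError(f"K={K} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=int)
    fill = np.zeros(K, dtype=int)
    for cls in np.unique(y01):
        idx = np.nonzero(y01 == cls)[0]
        for i in rng.permutation(idx):
            f = int(np.argmin(fill))
            folds[i] = f
            fill[f] += 1
    return folds


def cross_validate(
    X,
    y,
    n_ortho: int = 1,
    K: int = 7,
    seed: int = 0,
    scaling: str = "unit_variance",
    folds: np.ndarray | None = None,
) -> CVResult:
    """Stratified K-fold cross-validation of the OPLS-DA model.

    Scaling parameters and the model are refit on each training portion
    only, so no information from held-out samples leaks into the fit.
    A precomputed ``folds`` assignment (values in 0..K-1) overrides the
    seeded stratified construction.
    """
    M = _as_matrix(X)
    y01, _ = encode_classes(y)
    if folds is None:
        folds = stratified_folds(y01, K, seed)
    else:
        folds = np.asarray(folds, dtype=int)
        if folds.size != y01.size or folds.min() < 0 or folds.max() >= K:
            raise ValidationError("folds must assign every sample to 0..K-1")
    y_pred = np.empty_like(y01, dtype=float)
    for f in range(K):
        test = folds == f
        if not test.any():
            continue
        train = ~test
        model = fit_oplsda(M[train], y01[train], n_ortho=n_ortho, scaling=scaling)
        y_pred[test] = predict(model, M[test])
    press = float(((y01 - y_pred) ** 2).sum())
    ss_tot = float(((y01 - y01.mean()) ** 2).sum())
    return CVResult(
        fold_assignment=folds, y_pred_cv=y_pred, y_true=y01,
        PRESS=press, SS_tot=ss_tot, Q2=1.0 - press / ss_tot, K=K,
    )


def model_df(n_ortho: int) -> int:
    """Parameter count convention for CV-ANOVA: one predictive component,
    a score/loading pair per orthogonal component, plus the intercept.
    This follows the component-counting convention of the CV-ANOVA method;
    it is a convention, not a quantity stated by the original analysis."""
    return 1 + 2 * n_ortho + 1


def cv_anova(cv: CVResult, df_model: int | None = None, n_ortho: int = 1) -> CVANOVAResult:
    """F-test of the cross-validated predictions against total Y variation.

    SS_reg = SS_tot - PRESS; F = (SS_reg/df1) / (PRESS/df2) with
    df1 = df_model and df2 = n - df1 - 1. F is floored at 0 (p = 1) when the
    cross-validated predictions explain nothing; a perfect CV prediction
    (PRESS = 0) yields p = 0.
    """
    if df_model is None:
        df_model = model_df(n_ortho)
    n = cv.y_true.size
    df1 = float(df_model)
    df2 = float(n - df_model - 1)
    if df2 <= 0:
        raise ValidationError(f"df2 = {df2} <= 0 (n too small for df_model={df_model})")
    ss_reg = cv.SS_tot - cv.PRESS
    if cv.PRESS <= 0:
        return CVANOVAResult(F=np.inf, df1=df1, df2=df2, p=0.0)
    if ss_reg <= 0:
        return CVANOVAResult(F=0.0, df1=df1, df2=df2, p=1.0)
    F = (ss_reg / df1) / (cv.PRESS / df2)
    return CVANOVAResult(F=F, df1=df1, df2=df2, p=float(stats.f.sf(F, df1, df2)))


def roc_curve(y_true, y_pred) -> ROCCurve:
    """ROC from predicted y values; trapezoidal AUC.

    Thresholds sweep the unique predicted values; ties are handled so that
    the area equals the normalized Mann-Whitney U statistic
    (#{pos > neg} + 0.5 #{ties}) / (n1 * n0).
    """
    y01, _ = encode_classes(y_true)
    y_pred = np.asarray(y_pred, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y01, y_pred)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def choose_n_ortho(
    X,
    y,
    max_ortho: int = 5,
    K: int = 7,
    seed: int = 0,
    min_gain: float = 0.01,
) -> tuple[int, list[float]]:
    """Pick the orthogonal-component count by cross-validated Q2.

    Components are added while Q2 improves by at least ``min_gain``;
    returns the chosen count and the Q2 path (index = n_ortho).
    """
    q2s: list[float] = []
    best = 0
    for k in range(max_ortho + 1):
        try:
            q2 = cross_validate(X, y, n_ortho=k, K=K, seed=seed).Q2
        except Exception:
            break
        q2s.append(q2)
        if k > 0 and q2 - q2s[best] < min_gain:
            break
        if q2 >= q2s[best]:
            best = k
    return best, q2s


def model_summary(model: OPLSDAModel, cv: CVResult, anova: CVANOVAResult,
                  roc: ROCCurve) -> dict:
    """Flat summary mirroring a model-quality table row."""
    thr, sens, spec = roc.youden_point()
    return {
        "n": int(cv.y_true.size),
        "n_ortho": model.n_ortho,
        "R2X": model.R2X,
        "R2Y": model.R2Y,
        "Q2": cv.Q2,
        "cv_anova_F": anova.F,
        "cv_anova_p": anova.p,
        "auc": roc.auc,
        "sensitivity": sens,
        "specificity": spec,
        "youden_threshold": thr,
    }
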