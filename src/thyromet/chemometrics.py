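"""Mean-centered PCA and unit-variance-scaled OPLS-DA.

OPLS-DA follows the orthogonal-projections-to-latent-structures algorithm
for a single response: the predictive weight ``w`` is the (normalized)
covariance direction X'y; each orthogonal component removes from X the
systematic variation orthogonal to ``w`` before the final predictive score
``t = Xw`` and the regression scalar ``b = t'y / t't`` are formed. The class
vector y in {0, 1} is mean-centered, matching the single-Y discriminant
convention; X is unit-variance scaled by default.

With zero orthogonal components and a single response, the predictive
component coincides with one-component PLS1 — a property used as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import RankError, SchemaError, ValidationError
from .preprocess import BucketTable

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, BucketTable):
        return X.matrix
    return np.asarray(X, dtype=float)


@dataclass
class ScalingParams:
    """Column scaling: x -> (x - mean) / sd (sd = 1 in mean-center mode)."""

    means: np.ndarray
    sds: np.ndarray | None
    mode: str  # "mean_center" | "unit_variance"

    @classmethod
    def fit(cls, X: np.ndarray, mode: str) -> "ScalingParams":
        if mode not in ("mean_center", "unit_variance"):
            raise ValidationError(f"unknown scaling mode {mode!r}")
        means = X.mean(axis=0)
        sds = None
        if mode == "unit_variance":
            sds = X.std(axis=0, ddof=1)
            if np.any(sds <= _ZERO_VAR_TOL):
                raise ValidationError("zero-variance variable in unit_variance scaling")
        return cls(means=means, sds=sds, mode=mode)

    def apply(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.means
        return Xc if self.sds is None else Xc / self.sds

    def invert(self, X: np.ndarray) -> np.ndarray:
        return (X if self.sds is None else X * self.sds) + self.means


@dataclass
class PCAModel:
    """Rank-k PCA of the mean-centered matrix (via SVD)."""

    loadings: np.ndarray  # variables x components, orthonormal columns
    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    center: np.ndarray

    def transform(self, X) -> np.ndarray:
        return (_as_matrix(X) - self.center) @ self.loadings


def fit_pca(X, n_components: int | None = None) -> PCAModel:
    """Mean-center PCA; deterministic sign (largest-|loading| entry positive).

    Used on the normalized bucket matrix to inspect group clustering and
    potential outliers before supervised modelling.
    """
    M = _as_matrix(X)
    n, p = M.shape
    max_k = min(n - 1, p)
    if n_components is None:
        n_components = min(max_k, 10)
    if not 1 <= n_components <= max_k:
        raise ValidationError(f"n_components must be in [1, {max_k}]")
    center = M.mean(axis=0)
    Xc = M - center
    total = (Xc**2).sum()
    if total <= 1e-30:  # exactly-constant matrix (identical rows handled fine)
        raise ValidationError("matrix has zero variance after centering")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    loadings = Vt[:k].T
    # sign convention: in each component the largest-magnitude loading is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = U[:, :k] * s[:k] * flip
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=(s[:k] ** 2) / (s**2).sum(),
        center=center,
    )


@dataclass
class OPLSDAModel:
    """Fitted OPLS-DA discriminant for a two-class comparison.

    ``w``/``t``/``p_load`` are the predictive weights, scores and loadings;
    ``W_o``/``T_o``/``P_o`` hold the orthogonal components column-wise;
    ``b`` is the regression scalar of centered y on t. ``kept`` maps the
    model's variables back into the training table's columns (zero-variance
    buckets are dropped before scaling).
    """

    w: np.ndarray
    t: np.ndarray
    p_load: np.ndarray
    W_o: np.ndarray
    T_o: np.ndarray
    P_o: np.ndarray
    b: float
    scaling: ScalingParams
    y_mean: float
    kept: np.ndarray  # boolean mask over original variables
    n_ortho: int
    R2X: float
    R2Y: float
    R2X_pred: float
    R2X_ortho: float
    classes: tuple = (0, 1)

    @property
    def y_fitted(self) -> np.ndarray:
        return self.b * self.t + self.y_mean

    def to_json(self, path: str | Path) -> None:
        def arr(a):
            return np.asarray(a).tolist()

        payload = {
            "w": arr(self.w), "t": arr(self.t), "p_load": arr(self.p_load),
            "W_o": arr(self.W_o), "T_o": arr(self.T_o), "P_o": arr(self.P_o),
            "b": self.b, "y_mean": self.y_mean, "kept": arr(self.kept.astype(int)),
            "n_ortho": self.n_ortho, "R2X": self.R2X, "R2Y": self.R2Y,
            "R2X_pred": self.R2X_pred, "R2X_ortho": self.R2X_ortho,
            "classes": list(self.classes),
            "scaling": {"means": arr(self.scaling.means),
                        "sds": None if self.scaling.sds is None else arr(self.scaling.sds),
                        "mode": self.scaling.mode},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "OPLSDAModel":
        d = json.loads(Path(path).read_text())
        sc = ScalingParams(
            means=np.asarray(d["scaling"]["means"]),
            sds=None if d["scaling"]["sds"] is None else np.asarray(d["scaling"]["sds"]),
            mode=d["scaling"]["mode"],
        )
        return cls(
            w=np.asarray(d["w"]), t=np.asarray(d["t"]), p_load=np.asarray(d["p_load"]),
            W_o=np.asarray(d["W_o"]), T_o=np.asarray(d["T_o"]), P_o=np.asarray(d["P_o"]),
            b=d["b"], scaling=sc, y_mean=d["y_mean"],
            kept=np.asarray(d["kept"], dtype=bool), n_ortho=d["n_ortho"],
            R2X=d["R2X"], R2Y=d["R2Y"], R2X_pred=d["R2X_pred"], R2X_ortho=d["R2X_ortho"],
            classes=tuple(d["classes"]),
        )


def encode_classes(y) -> tuple[np.ndarray, tuple]:
    """Encode a two-class label vector as 0/1 (sorted label order)."""
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {classes}")
    y01 = (y == classes[1]).astype(float)
    counts = [(y01 == v).sum() for v in (0, 1)]
    if min(counts) < 2:
        raise ValidationError("each class needs >= 2 samples")
    return y01, classes


def fit_oplsda(
    X,
    y,
    n_ortho: int = 1,
    scaling: str = "unit_variance",
) -> OPLSDAModel:
    """Fit OPLS-DA of a two-class y on X with ``n_ortho`` orthogonal components.

    The component sign is fixed so that the predictive score correlates
    positively with y (class 1 scores high). Zero-variance variables are
    dropped with a warning before scaling.
    """
    M = _as_matrix(X)
    y01, classes = encode_classes(y)
    if M.shape[0] != y01.size:
        raise ValidationError("X rows and y length differ")
    if n_ortho < 0:
        raise ValidationError("n_ortho must be >= 0")
    rank_cap = min(M.shape[0] - 1, M.shape[1])
    if n_ortho >= rank_cap:
        raise RankError(f"n_ortho={n_ortho} >= usable rank bound {rank_cap}")

    sds = M.std(axis=0, ddof=1)
    kept = sds > _ZERO_VAR_TOL
    if not kept.all():
        logger.warning("dropping %d zero-variance variable(s) before scaling",
                       int((~kept).sum()))
    if not kept.any():
        raise ValidationError("all variables have zero variance")
    sc = ScalingParams.fit(M[:, kept], scaling)
    Xs = sc.apply(M[:, kept])
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    ss_x_total = float((Xs**2).sum())

    w = Xs.T @ yc
    nw = np.linalg.norm(w)
    if nw <= 0:
        raise ValidationError("X carries no covariance with y")
    w = w / nw

    p_var = Xs.shape[1]
    W_o = np.zeros((p_var, n_ortho))
    T_o = np.zeros((Xs.shape[0], n_ortho))
    P_o = np.zeros((p_var, n_ortho))
    Xd = Xs
    for i in range(n_ortho):
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _ZERO_VAR_TOL:
            raise RankError("predictive score collapsed during deflation")
        p = Xd.T @ t / tt
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo <= 1e-10:
            raise RankError(f"no orthogonal variation left for component {i + 1}")
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        tot = float(t_o @ t_o)
        if tot <= _ZERO_VAR_TOL:
            raise RankError(f"orthogonal score {i + 1} has zero variance")
        p_o = Xd.T @ t_o / tot
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, i], T_o[:, i], P_o[:, i] = w_o, t_o, p_o

    t = Xd @ w
    tt = float(t @ t)
    if tt <= _ZERO_VAR_TOL:
        raise RankError("predictive score has zero variance")
    if float(t @ yc) < 0:  # sign convention: t correlates positively with y
        w, t = -w, -t
    p_load = Xd.T @ t / tt
    b = float(t @ yc) / tt

    ss_pred = tt * float(p_load @ p_load)
    ss_ortho = float(sum((T_o[:, i] @ T_o[:, i]) * (P_o[:, i] @ P_o[:, i])
                         for i in range(n_ortho)))
    ss_y = float(yc @ yc)
    return OPLSDAModel(
        w=w, t=t, p_load=p_load, W_o=W_o, T_o=T_o, P_o=P_o, b=b,
        scaling=sc, y_mean=y_mean, kept=kept, n_ortho=n_ortho,
        R2X=(ss_pred + ss_ortho) / ss_x_total,
        R2Y=(b * b * tt) / ss_y,
        R2X_pred=ss_pred / ss_x_total,
        R2X_ortho=ss_ortho / ss_x_total,
        classes=classes,
    )


def predict(model: OPLSDAModel, X_new) -> np.ndarray:
    """Predicted y values (on the 0/1 scale) for new samples.

    New data is scaled with the training parameters, filtered through the
    stored orthogonal components and projected on the predictive weights.
    """
    M = _as_matrix(X_new)
    if M.ndim == 1:
        M = M[None, :]
    if M.shape[1] == model.kept.size:
        M = M[:, model.kept]
    elif M.shape[1] != int(model.kept.sum()):
        raise SchemaError(
            f"X_new has {M.shape[1]} variables, model expects "
            f"{model.kept.size} (or {int(model.kept.sum())} after drop)")
    Xs = model.scaling.apply(M)
    for i in range(model.n_ortho):
        t_o = Xs @ model.W_o[:, i]
        Xs = Xs - np.outer(t_o, model.P_o[:, i])
    return model.b * (Xs @ model.w) + model.y_mean


def predict_class(model: OPLSDAModel, X_new) -> np.ndarray:
    """Hard class assignment at the centered midpoint threshold."""
    yhat = predict(model, X_new)
    labels = np.asarray(model.classes, dtype=object)
    return labels[(yhat >= 0.5).astype(int)]
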