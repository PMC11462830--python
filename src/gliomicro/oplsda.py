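"""Orthogonal partial least squares discriminant analysis (OPLS-DA) with
VIP scores, cross-validated Q2Y, and a label-permutation overfitting test.

The decomposition follows the standard OPLS scheme: the class label is
dummy-coded +/-1 and centered; X is mean-centered and (by default)
unit-variance scaled; variation in X orthogonal to y is removed
sequentially, and a single-component PLS is fitted to the filtered X.
With ``n_ortho=0`` the model coincides exactly with PLS1.

Model quality statistics use the chemometrics conventions: R2Y is the
explained fraction of label variance on the training data, Q2Y is
1 - PRESS/SS with out-of-fold predictions from stratified k-fold
cross-validation (7 folds by default), and the permutation test refits
the model on label permutations and regresses the permuted R2Y/Q2Y on
the absolute label correlation, reporting the two intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y

from .cohort_stats import ROCResult, roc_analysis

__all__ = ["OPLSDA", "fit_oplsda", "vip", "cross_validate", "permutation_test",
           "ValidationReport"]


class OPLSDA(BaseEstimator, ClassifierMixin):
    """OPLS-DA with one predictive and ``n_ortho`` orthogonal components.

    Parameters
    ----------
    n_ortho : int or "auto"
        Number of y-orthogonal components to remove.  "auto" adds
        components while cross-validated Q2Y improves by more than
        ``q2_tol`` (capped at ``max_ortho``).
    scale : bool
        Unit-variance scaling of the columns (default True).
    cv_folds, q2_tol, max_ortho, random_state : auto-selection and
        cross-validation controls.

    Attributes (after ``fit``)
    --------------------------
    w_pred_ : (p,) unit predictive weight vector
    p_pred_, q_ : predictive loadings (x and y side)
    w_ortho_, p_ortho_ : (k, p) orthogonal weights / loadings
    scores_ : (n,) predictive scores; scores_ortho_ : (n, k)
    r2y_ : explained label variance; vip_ : per-variable VIP
    """

    def __init__(self, n_ortho=1, scale: bool = True, cv_folds: int = 7,
                 q2_tol: float = 0.01, max_ortho: int = 3, random_state=None):
        self.n_ortho = n_ortho
        self.scale = scale
        self.cv_folds = cv_folds
        self.q2_tol = q2_tol
        self.max_ortho = max_ortho
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _encode(self, y):
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("OPLS-DA is a binary method")
        return classes, np.where(y == classes[1], 1.0, -1.0)

    def _resolve_n_ortho(self, X, y_num):
        if self.n_ortho != "auto":
            return int(self.n_ortho)
        best_k, best_q2 = 0, -np.inf
        for k in range(0, self.max_ortho + 1):
            q2 = _q2(X, y_num, k, self.scale, self.cv_folds, self.random_state)
            if q2 > best_q2 + (self.q2_tol if k > 0 else 0.0):
                best_k, best_q2 = k, q2
            else:
                break
        return best_k

    # -- core -------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[0] < 6:
            raise ValueError("need at least 6 samples")
        self.classes_, y_num = self._encode(y)
        k = self._resolve_n_ortho(X, y_num)
        if k >= min(X.shape):
            raise ValueError("n_ortho must be below the rank of X")

        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        if np.any(sd == 0):
            warnings.warn("constant column(s) carry no weight in the model")
            sd = np.where(sd == 0, 1.0, sd)
        self.x_std_ = sd
        self.y_mean_ = y_num.mean()

        Xc = (X - self.x_mean_) / self.x_std_
        yc = y_num - self.y_mean_

        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        w_ortho, p_ortho, t_ortho = [], [], []
        Xd = Xc
        for _ in range(k):
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            wo = p - (w @ p) * w
            nrm = np.linalg.norm(wo)
            if nrm < 1e-12:
                break
            wo = wo / nrm
            to = Xd @ wo
            po = Xd.T @ to / (to @ to)
            Xd = Xd - np.outer(to, po)
            w_ortho.append(wo)
            p_ortho.append(po)
            t_ortho.append(to)

        t = Xd @ w
        self.w_pred_ = w
        self.p_pred_ = Xd.T @ t / (t @ t)
        self.q_ = float(yc @ t / (t @ t))
        self.scores_ = t
        self.scores_ortho_ = np.column_stack(t_ortho) if t_ortho else np.zeros((len(t), 0))
        p_feat = X.shape[1]
        self.w_ortho_ = (np.array(w_ortho) if w_ortho else np.zeros((0, p_feat)))
        self.p_ortho_ = (np.array(p_ortho) if p_ortho else np.zeros((0, p_feat)))
        self.n_ortho_ = len(w_ortho)

        resid = yc - t * self.q_
        ss = float(yc @ yc)
        self.r2y_ = 1.0 - float(resid @ resid) / ss if ss > 0 else 0.0
        self.vip_ = np.sqrt(X.shape[1]) * np.abs(w)
        self._y_num_train = y_num
        return self

    def _filter(self, X):
        Xc = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        for wo, po in zip(self.w_ortho_, self.p_ortho_):
            to = Xc @ wo
            Xc = Xc - np.outer(to, po)
        return Xc

    def transform(self, X):
        """Predictive score t of new samples."""
        return self._filter(X) @ self.w_pred_

    def decision_function(self, X):
        return self.transform(X) * self.q_ + self.y_mean_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def fit_oplsda(X, y, n_ortho=1, scaling: bool = True) -> OPLSDA:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_ortho=n_ortho, scale=scaling).fit(X, y)


def vip(model: OPLSDA) -> np.ndarray:
    """Predictive-component VIP; the mean of squared VIPs equals 1."""
    return model.vip_


def _q2(X, y_num, n_ortho, scale, folds, seed):
    X = np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for tr, te in skf.split(X, y_num):
        m = OPLSDA(n_ortho=n_ortho, scale=scale).fit(X[tr], y_num[tr])
        yhat = m.decision_function(X[te])
        y_te = np.where(y_num[te] == m.classes_[1], 1.0, -1.0)
        press += float(np.sum((y_te - yhat) ** 2))
    ss = float(np.sum((y_num - y_num.mean()) ** 2))
    return 1.0 - press / ss


def cross_validate(X, y, folds: int = 7, n_ortho=1, scale: bool = True,
                   seed: int = 0) -> float:
    """Cross-validated Q2Y = 1 - PRESS/SS with stratified folds."""
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    counts = [np.sum(y == c) for c in classes]
    if folds < 2 or folds > min(counts):
        raise ValueError("fold count must be >= 2 and <= the smaller class size")
    y_num = np.where(np.asarray(y) == classes[1], 1.0, -1.0)
    return _q2(X, y_num, n_ortho, scale, folds, seed)


def cv_scores(X, y, folds: int = 7, n_ortho=1, scale: bool = True, seed: int = 0):
    """Out-of-fold decision values (for a cross-validated score ROC)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    out = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        m = OPLSDA(n_ortho=n_ortho, scale=scale).fit(X[tr], y[tr])
        out[te] = m.decision_function(X[te])
    return out


@dataclass
class ValidationReport:
    r2y: float
    q2y: float
    r2y_perm: np.ndarray
    q2y_perm: np.ndarray
    perm_correlations: np.ndarray
    r2y_intercept: float
    q2y_intercept: float
    roc_train: ROCResult
    roc_cv: ROCResult
    vip: np.ndarray = field(default_factory=lambda: np.zeros(0))


def permutation_test(X, y, n_perm: int = 200, seed: int = 0, n_ortho=1,
                     scale: bool = True, folds: int = 7) -> ValidationReport:
    """Label-permutation overfitting test.

    For each permutation the model is refitted and (R2Y, Q2Y) recorded
    against the absolute correlation between permuted and true labels;
    straight lines through those points (including the unpermuted model
    at correlation 1) give the reported intercepts.  The report also
    carries the unpermuted model's training-score and cross-validated
    score ROCs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6283]))
    model = OPLSDA(n_ortho=n_ortho, scale=scale).fit(X, y)
    q2 = cross_validate(X, y, folds=folds, n_ortho=n_ortho, scale=scale, seed=seed)
    y_bin = (y == model.classes_[1]).astype(int)
    roc_train = roc_analysis(model.decision_function(X), y_bin)
    roc_cv = roc_analysis(cv_scores(X, y, folds=folds, n_ortho=n_ortho,
                                    scale=scale, seed=seed), y_bin)

    y_num = np.where(y == model.classes_[1], 1.0, -1.0)
    r2s, q2s, cors = [], [], []
    for _ in range(int(n_perm)):
        yp = rng.permutation(y)
        m = OPLSDA(n_ortho=n_ortho, scale=scale).fit(X, yp)
        r2s.append(m.r2y_)
        q2s.append(cross_validate(X, yp, folds=folds, n_ortho=n_ortho,
                                  scale=scale, seed=seed))
        yp_num = np.where(yp == model.classes_[1], 1.0, -1.0)
        c = np.corrcoef(yp_num, y_num)[0, 1]
        cors.append(abs(c))
    r2s, q2s, cors = (np.array(v) for v in (r2s, q2s, cors))
    cx = np.concatenate([cors, [1.0]])
    r2_int = float(np.polyfit(cx, np.concatenate([r2s, [model.r2y_]]), 1)[1]) \
        if n_perm > 0 else model.r2y_
    q2_int = float(np.polyfit(cx, np.concatenate([q2s, [q2]]), 1)[1]) \
        if n_perm > 0 else q2
    return ValidationReport(r2y=model.r2y_, q2y=q2, r2y_perm=r2s, q2y_perm=q2s,
                            perm_correlations=cors, r2y_intercept=r2_int,
                            q2y_intercept=q2_int, roc_train=roc_train,
                            roc_cv=roc_cv, vip=model.vip_)
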