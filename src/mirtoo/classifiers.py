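"""Nearest shrunken centroids and L1-penalized multinomial regression.

Both classifiers are implemented from scratch and exposed statsmodels-style:
a Model object is built from a training matrix and labels, ``fit()`` returns
a Results object carrying the estimates, diagnostics and ``summary()``, and
prediction hangs off the Results.

Nearest shrunken centroids (NSC)
    Class centroids are standardized deviations from the overall centroid,
    d_kj = (xbar_kj - xbar_j) / (m_k (s_j + s0)) with m_k = sqrt(1/n_k - 1/n),
    pooled within-class SD s_j and offset s0 = median_j s_j. Soft
    thresholding d'_kj = sign(d) max(|d| - delta, 0) moves centroids toward
    the overall centroid; a feature is *used* when d'_kj is nonzero for some
    class. With delta = 0 nothing shrinks and the rule is a diagonal-
    covariance Gaussian discriminant with variances (s_j + s0)^2.

Multinomial lasso
    Minimizes (1/n) * multinomial negative log-likelihood
    + lambda * sum_kj |beta_kj| (intercepts unpenalized) in the symmetric
    parameterization, by glmnet-style cyclic coordinate descent on per-class
    quadratic approximations, with step halving to keep the penalized
    objective non-increasing. Features are standardized internally;
    coefficients are reported on the standardized scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_SERIAL_VERSION = 1


class ClassifierError(ValueError):
    pass


def _check_training(X: np.ndarray, y: np.ndarray, min_per_class: int = 2):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassifierError("need at least two classes")
    small = classes[counts < min_per_class]
    if small.size:
        raise ClassifierError(
            f"classes with fewer than {min_per_class} samples: {small.tolist()}"
        )
    if np.isnan(X).any():
        raise ClassifierError("training matrix contains missing values")
    return classes, counts


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_array(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ClassifierError(f"missing features: {missing}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    names = feature_names if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    if len(names) != X.shape[1]:
        raise ClassifierError("feature count mismatch")
    return X, list(names)


# ===================================================================== NSC
class NearestShrunkenCentroids:
    """NSC model specification: training data plus shrinkage threshold.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Training features (classifier-ready, e.g. log2 normalized counts).
    y : length-n labels
        Merged prediction-class labels.
    delta : float
        Shrinkage threshold (0 keeps every feature).
    priors : mapping or None
        Class priors; default empirical frequencies. "uniform" for equal.
    """

    def __init__(self, X, y, delta: float = 0.0, priors=None):
        self.X, self.feature_names = _as_array(X)
        self.y = np.asarray(list(y))
        if len(self.y) != self.X.shape[0]:
            raise ClassifierError("X and y lengths differ")
        if delta < 0:
            raise ClassifierError("delta must be >= 0")
        self.delta = float(delta)
        self.priors = priors

    def fit(self) -> "NSCResults":
        X, y = self.X, self.y
        classes, counts = _check_training(X, y)
        n, p = X.shape
        K = len(classes)
        centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
        overall = X.mean(axis=0)
        # pooled within-class variance, n - K denominator
        ss = np.zeros(p)
        for k, c in enumerate(classes):
            d = X[y == c] - centroids[k]
            ss += (d * d).sum(axis=0)
        s = np.sqrt(ss / (n - K))
        s0 = float(np.median(s))
        m = np.sqrt(1.0 / counts - 1.0 / n)
        denom = m[:, None] * (s + s0)[None, :]
        d_kj = (centroids - overall) / denom
        shrunk = np.sign(d_kj) * np.maximum(np.abs(d_kj) - self.delta, 0.0)
        shrunk_centroids = overall + denom * shrunk
        if self.priors is None:
            priors = counts / n
        elif self.priors == "uniform":
            priors = np.full(K, 1.0 / K)
        else:
            priors = np.array([self.priors[c] for c in classes], dtype=float)
            priors = priors / priors.sum()
        return NSCResults(
            model=self,
            classes=list(classes),
            centroids=centroids,
            overall_centroid=overall,
            s=s,
            s0=s0,
            m=m,
            delta=self.delta,
            priors=priors,
            d=d_kj,
            shrunken_d=shrunk,
            shrunken_centroids=shrunk_centroids,
        )


@dataclass
class NSCResults:
    """Fitted NSC classifier: shrunken centroids, dispersions, priors."""

    model: NearestShrunkenCentroids | None
    classes: list
    centroids: np.ndarray
    overall_centroid: np.ndarray
    s: np.ndarray
    s0: float
    m: np.ndarray
    delta: float
    priors: np.ndarray
    d: np.ndarray
    shrunken_d: np.ndarray
    shrunken_centroids: np.ndarray
    feature_names: list = field(default=None)

    def __post_init__(self):
        if self.feature_names is None and self.model is not None:
            self.feature_names = list(self.model.feature_names)

    @property
    def features_used(self) -> np.ndarray:
        """Boolean mask: features with a nonzero shrunken deviation somewhere."""
        return (self.shrunken_d != 0).any(axis=0)

    @property
    def n_features_used(self) -> int:
        return int(self.features_used.sum())

    def discriminant(self, X) -> np.ndarray:
        """delta_k(x) = sum_j (x_j - c'_kj)^2 / (s_j + s0)^2 - 2 log pi_k."""
        X, _ = _as_array(X, self.feature_names)
        w = (self.s + self.s0) ** 2
        diff = X[:, None, :] - self.shrunken_centroids[None, :, :]
        dist = (diff * diff / w[None, None, :]).sum(axis=2)
        return dist - 2.0 * np.log(self.priors)[None, :]

    def predict_proba(self, X) -> pd.DataFrame:
        """Softmax of -discriminant/2 (overflow-safe); rows sum to 1."""
        single = not isinstance(X, pd.DataFrame) and np.asarray(X).ndim == 1
        delta = self.discriminant(X)
        probs = _softmax_rows(-0.5 * delta)
        idx = None
        if isinstance(X, pd.DataFrame):
            idx = X.index
        out = pd.DataFrame(probs, columns=self.classes, index=idx)
        return out.iloc[0] if single else out

    def predict(self, X):
        proba = self.predict_proba(X)
        if isinstance(proba, pd.Series):
            return proba.idxmax()
        return proba.idxmax(axis=1).to_numpy()

    def summary(self) -> str:
        lines = [
            "Nearest shrunken centroids",
            f"  classes: {len(self.classes)}  features: {len(self.feature_names)}",
            f"  delta: {self.delta:g}   s0 (median pooled SD): {self.s0:.4g}",
            f"  features used: {self.n_features_used}",
            "  priors:",
        ]
        for c, pi in zip(self.classes, self.priors):
            lines.append(f"    {c:>10}  {pi:.3f}")
        return "\n".join(lines)

    # --------------------------------------------------------- persistence
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "mirtoo-nsc",
            "version": _SERIAL_VERSION,
            "classes": [str(c) for c in self.classes],
            "feature_names": self.feature_names,
            "delta": self.delta,
            "s0": self.s0,
            "centroids": self.centroids.tolist(),
            "overall_centroid": self.overall_centroid.tolist(),
            "s": self.s.tolist(),
            "m": self.m.tolist(),
            "priors": self.priors.tolist(),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NSCResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format") != "mirtoo-nsc":
            raise ClassifierError("not a serialized NSC model")
        centroids = np.array(doc["centroids"])
        overall = np.array(doc["overall_centroid"])
        s = np.array(doc["s"])
        m = np.array(doc["m"])
        delta = float(doc["delta"])
        denom = m[:, None] * (s + float(doc["s0"]))[None, :]
        d = (centroids - overall) / denom
        shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        return cls(
            model=None,
            classes=doc["classes"],
            centroids=centroids,
            overall_centroid=overall,
            s=s,
            s0=float(doc["s0"]),
            m=m,
            delta=delta,
            priors=np.array(doc["priors"]),
            d=d,
            shrunken_d=shrunk,
            shrunken_centroids=overall + denom * shrunk,
            feature_names=doc["feature_names"],
        )


# =============================================================== lasso
def _soft(u: float, t: float) -> float:
    return np.sign(u) * max(abs(u) - t, 0.0)


class MultinomialLasso:
    """L1-penalized multinomial logistic regression (symmetric form).

    Objective: (1/n) * NLL(beta0, beta) + lam * sum_kj |beta_kj|.
    Features are standardized internally (mean 0, SD 1, population SD);
    coefficients live on the standardized scale.
    """

    def __init__(self, X, y, lam: float = 0.019):
        self.X_raw, self.feature_names = _as_array(X)
        self.y = np.asarray(list(y))
        if len(self.y) != self.X_raw.shape[0]:
            raise ClassifierError("X and y lengths differ")
        if lam < 0:
            raise ClassifierError("lambda must be >= 0")
        self.lam = float(lam)

    def fit(
        self,
        max_iter: int = 10_000,
        tol: float = 1e-6,
        inner_sweeps: int = 50,
        min_weight: float = 1e-5,
        track_objective: bool = False,
    ) -> "LassoResults":
        X_raw, y, lam = self.X_raw, self.y, self.lam
        classes, counts = _check_training(X_raw, y, min_per_class=1)
        n, p = X_raw.shape
        K = len(classes)
        mean = X_raw.mean(axis=0)
        scale = X_raw.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X_raw - mean) / scale
        Y = (y[:, None] == classes[None, :]).astype(float)

        beta0 = np.log(counts / n)  # start at intercept-only solution
        beta = np.zeros((K, p))
        eta = np.tile(beta0, (n, 1))
        X2 = X * X
        objective_trace: list[float] = []

        def objective(b0, b):
            sc = X @ b.T + b0
            lse = sc.max(axis=1)
            lse = lse + np.log(np.exp(sc - lse[:, None]).sum(axis=1))
            nll = (lse - (Y * sc).sum(axis=1)).mean()
            return nll + lam * np.abs(b).sum()

        obj = objective(beta0, beta)
        if track_objective:
            objective_trace.append(obj)
        converged = False
        n_outer = 0
        for n_outer in range(1, max_iter + 1):
            max_change = 0.0
            for k in range(K):
                P = _softmax_rows(eta)
                pk = P[:, k]
                w = np.maximum(pk * (1 - pk), min_weight)
                z = eta[:, k] + (Y[:, k] - pk) / w
                b0_old, b_old = beta0[k], beta[k].copy()
                b0, b = b0_old, b_old.copy()
                r = z - X @ b - b0  # working residual
                wsum = w.sum()
                v_all = (w @ X2) / n  # curvature per coordinate

                def cd_sweep(cols) -> float:
                    nonlocal b0, r
                    db0 = (w * r).sum() / wsum
                    b0 += db0
                    r -= db0
                    change = abs(db0)
                    for j in cols:
                        v = v_all[j]
                        u = (X[:, j] @ (w * r)) / n + v * b[j]
                        bj_new = _soft(u, lam) / v
                        if bj_new != b[j]:
                            r -= X[:, j] * (bj_new - b[j])
                            change = max(change, abs(bj_new - b[j]))
                            b[j] = bj_new
                    return change

                # full sweeps establish the active set; cheap active-only
                # sweeps (glmnet-style) polish it
                for _ in range(inner_sweeps):
                    if cd_sweep(range(p)) < 0.1 * tol:
                        break
                    active = np.flatnonzero(b)
                    for _ in range(inner_sweeps):
                        if cd_sweep(active) < 0.1 * tol:
                            break
                # step halving keeps the penalized objective non-increasing
                step = 1.0
                while step > 1e-10:
                    beta0_try = beta0.copy()
                    beta_try = beta.copy()
                    beta0_try[k] = b0_old + step * (b0 - b0_old)
                    beta_try[k] = b_old + step * (b - b_old)
                    obj_try = objective(beta0_try, beta_try)
                    if obj_try <= obj + 1e-12:
                        break
                    step *= 0.5
                else:
                    beta0_try, beta_try, obj_try = beta0, beta, obj
                change = max(
                    abs(beta0_try[k] - b0_old),
                    float(np.max(np.abs(beta_try[k] - b_old), initial=0.0)),
                )
                max_change = max(max_change, change)
                beta0, beta, obj = beta0_try, beta_try, obj_try
                eta = X @ beta.T + beta0
                if track_objective:
                    objective_trace.append(obj)
            if max_change < tol:
                converged = True
                break
        if not converged:
            warnings.warn("multinomial lasso did not converge", RuntimeWarning)
        return LassoResults(
            model=self,
            classes=list(classes),
            beta0=beta0,
            beta=beta,
            lam=lam,
            converged=converged,
            n_iter=n_outer,
            x_mean=mean,
            x_scale=scale,
            feature_names=list(self.feature_names),
            objective_trace=objective_trace,
        )


@dataclass
class LassoResults:
    """Fitted multinomial lasso: intercepts, sparse coefficient matrix."""

    model: MultinomialLasso | None
    classes: list
    beta0: np.ndarray
    beta: np.ndarray
    lam: float
    converged: bool
    n_iter: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    feature_names: list
    objective_trace: list = field(default_factory=list)

    @property
    def features_used(self) -> np.ndarray:
        return (self.beta != 0).any(axis=0)

    @property
    def n_features_used(self) -> int:
        return int(self.features_used.sum())

    def _standardize(self, X) -> np.ndarray:
        X, _ = _as_array(X, self.feature_names)
        return (X - self.x_mean) / self.x_scale

    def decision_scores(self, X) -> np.ndarray:
        return self._standardize(X) @ self.beta.T + self.beta0

    def predict_proba(self, X) -> pd.DataFrame:
        single = not isinstance(X, pd.DataFrame) and np.asarray(X).ndim == 1
        probs = _softmax_rows(self.decision_scores(X))
        idx = X.index if isinstance(X, pd.DataFrame) else None
        out = pd.DataFrame(probs, columns=self.classes, index=idx)
        return out.iloc[0] if single else out

    def predict(self, X):
        proba = self.predict_proba(X)
        if isinstance(proba, pd.Series):
            return proba.idxmax()
        return proba.idxmax(axis=1).to_numpy()

    def kkt_violation(self) -> float:
        """Max violation of the subgradient optimality conditions.

        For each (k, j): zero coefficients need |g_kj| <= lambda, active
        ones need g_kj = -lambda * sign(beta_kj), where g is the gradient of
        the mean negative log-likelihood. Returns the largest excess.
        """
        if self.model is None:
            raise ClassifierError("KKT check needs the training data")
        X = (self.model.X_raw - self.x_mean) / self.x_scale
        y = self.model.y
        classes = np.array(self.classes)
        Y = (y[:, None] == classes[None, :]).astype(float)
        P = _softmax_rows(X @ self.beta.T + self.beta0)
        G = (P - Y).T @ X / X.shape[0]  # K x p gradient of mean NLL
        active = self.beta != 0
        viol_zero = np.maximum(np.abs(G) - self.lam, 0.0)
        viol_zero[active] = 0.0
        viol_active = np.abs(G + self.lam * np.sign(self.beta))
        viol_active[~active] = 0.0
        g0 = (P - Y).mean(axis=0)  # unpenalized intercept gradient
        return float(
            max(viol_zero.max(initial=0.0), viol_active.max(initial=0.0),
                np.abs(g0).max(initial=0.0))
        )

    def summary(self) -> str:
        lines = [
            "Multinomial lasso (coordinate descent, symmetric parameterization)",
            f"  classes: {len(self.classes)}  features: {len(self.feature_names)}",
            f"  lambda: {self.lam:g}   converged: {self.converged} "
            f"({self.n_iter} outer iterations)",
            f"  features used (nonzero in some class): {self.n_features_used}",
            f"  nonzero coefficients: {int((self.beta != 0).sum())}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "mirtoo-lasso",
            "version": _SERIAL_VERSION,
            "classes": [str(c) for c in self.classes],
            "feature_names": self.feature_names,
            "lambda": self.lam,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "beta0": self.beta0.tolist(),
            "beta": self.beta.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LassoResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format") != "mirtoo-lasso":
            raise ClassifierError("not a serialized lasso model")
        return cls(
            model=None,
            classes=doc["classes"],
            beta0=np.array(doc["beta0"]),
            beta=np.array(doc["beta"]),
            lam=float(doc["lambda"]),
            converged=bool(doc["converged"]),
            n_iter=int(doc["n_iter"]),
            x_mean=np.array(doc["x_mean"]),
            x_scale=np.array(doc["x_scale"]),
            feature_names=doc["feature_names"],
        )


# ====================================================== threshold selection
def cross_validate_threshold(
    X,
    y,
    grid,
    n_folds: int = 10,
    kind: str = "nsc",
    seed: int = 0,
    **fit_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Pick the shrinkage/penalty threshold by stratified K-fold CV.

    Returns ``(best, curve)`` where ``curve`` has columns threshold /
    cv_error. The minimizer is returned; ties go to the *larger* threshold
    (the sparser model). Classes with fewer samples than folds reduce the
    fold count (with a warning).
    """
    from sklearn.model_selection import StratifiedKFold

    X, names = _as_array(X)
    y = np.asarray(list(y))
    grid = sorted(float(g) for g in grid)
    _, counts = np.unique(y, return_counts=True)
    max_folds = int(counts.min())
    if n_folds < 2:
        raise ClassifierError("n_folds must be >= 2")
    if max_folds < n_folds:
        warnings.warn(
            f"smallest class has {max_folds} samples; reducing folds "
            f"{n_folds} -> {max_folds}"
        )
        n_folds = max_folds
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(grid))
    total = 0
    for train_idx, test_idx in skf.split(X, y):
        total += len(test_idx)
        for gi, g in enumerate(grid):
            if kind == "nsc":
                res = NearestShrunkenCentroids(
                    X[train_idx], y[train_idx], delta=g
                ).fit()
            elif kind == "lasso":
                res = MultinomialLasso(X[train_idx], y[train_idx], lam=g).fit(
                    **fit_kwargs
                )
            else:
                raise ClassifierError(f"unknown classifier kind {kind!r}")
            pred = res.predict(X[test_idx])
            errors[gi] += int((pred != y[test_idx]).sum())
    curve = pd.DataFrame({"threshold": grid, "cv_error": errors / total})
    best_err = curve["cv_error"].min()
    best = curve.loc[curve["cv_error"] == best_err, "threshold"].max()
    return float(best), curve
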