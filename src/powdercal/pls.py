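"""Partial least squares regression (PLS1) via NIPALS.

Single-response PLS on mean-centered data, no variance scaling: the
calibration operates on raw reflectance, so magnitude information is
retained.  The fitted regression coefficient vector on the original
(uncentered) variables doubles as the variable-importance signal for
CARS wavelength selection.

Two entry points:

* :class:`PLSModel` — ``PLSModel(y, X).fit(n_lv=...)`` returns a
  :class:`PLSResults` carrying weights, loadings, coefficients and
  diagnostics, with ``predict``, ``summary`` and JSON round-tripping.
* module-level helpers :func:`fit_plsr`, :func:`predict_plsr`,
  :func:`select_n_lv` for functional use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "PLSResults",
    "fit_plsr",
    "predict_plsr",
    "select_n_lv",
    "cv_rmsecv_by_lv",
    "RankDeficiencyWarning",
]

#: A latent variable whose score norm falls below this fraction of the
#: first score norm is treated as numerically rank-deficient.
SCORE_NORM_RTOL = 1e-12


class RankDeficiencyWarning(UserWarning):
    """Requested more latent variables than the data's numerical rank."""


class PLSModel:
    """PLS1 regression model of a response on a spectral matrix.

    Parameters
    ----------
    endog : ndarray, shape (n,)
        Response (reference concentration, % by mass).
    exog : ndarray, shape (n, p)
        Predictor matrix (reflectance spectra).
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError(f"endog has {y.size} rows, exog has {X.shape[0]}")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("NaN in inputs")
        if np.ptp(y) == 0.0:
            raise ValueError("endog is constant; nothing to regress")
        self.endog = y
        self.exog = X

    @classmethod
    def from_dataset(cls, dataset) -> "PLSModel":
        return cls(dataset.np_percent, dataset.reflectance)

    @property
    def max_rank(self) -> int:
        return min(self.exog.shape[0] - 1, self.exog.shape[1])

    def fit(self, n_lv: int = 2) -> "PLSResults":
        """Fit with ``n_lv`` latent variables by NIPALS.

        If ``n_lv`` exceeds the numerical rank the decomposition is
        truncated with a :class:`RankDeficiencyWarning`.
        """
        if n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        requested = min(int(n_lv), self.max_rank)
        if requested < n_lv:
            warnings.warn(
                f"n_lv={n_lv} exceeds min(n-1, p)={self.max_rank}; truncating",
                RankDeficiencyWarning,
                stacklevel=2,
            )

        x_mean = self.exog.mean(axis=0)
        y_mean = float(self.endog.mean())
        Xc = self.exog - x_mean
        yc = self.endog - y_mean

        n, p = Xc.shape
        W = np.zeros((p, requested))
        P = np.zeros((p, requested))
        q = np.zeros(requested)
        T = np.zeros((n, requested))
        first_norm = None
        a = 0
        for a in range(requested):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn == 0.0:
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            tn = np.sqrt(tt)
            if first_norm is None:
                first_norm = tn
            if tn <= SCORE_NORM_RTOL * (first_norm or 1.0):
                break
            pvec = Xc.T @ t / tt
            qa = float(yc @ t) / tt
            Xc = Xc - np.outer(t, pvec)
            yc = yc - qa * t
            W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
            a += 1
        n_kept = a
        if n_kept == 0:
            raise ValueError("no latent variable could be extracted (X'y is zero)")
        if n_kept < requested:
            warnings.warn(
                f"numerical rank reached after {n_kept} latent variables "
                f"(requested {n_lv})",
                RankDeficiencyWarning,
                stacklevel=2,
            )
        W, P, q, T = W[:, :n_kept], P[:, :n_kept], q[:n_kept], T[:, :n_kept]

        # Per-LV coefficient vectors on centered data: B_k = W_k (P_k'W_k)^-1 q_k,
        # using the leading k x k block for the k-LV sub-model (nested models).
        PtW = P.T @ W
        coefs = np.zeros((self.exog.shape[1], n_kept))
        for k in range(1, n_kept + 1):
            coefs[:, k - 1] = W[:, :k] @ np.linalg.solve(PtW[:k, :k], q[:k])

        return PLSResults(
            model=self,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=W,
            loadings=P,
            y_loadings=q,
            scores=T,
            coefs_per_lv=coefs,
            n_lv=n_kept,
        )


@dataclass
class PLSResults:
    """Fitted PLS1 decomposition.

    ``params`` is the coefficient vector b on the original (uncentered)
    variables and ``intercept`` the matching b0, so predictions are
    ``b0 + X @ b``; the score-path prediction agrees to 1e-8 relative.
    """

    model: PLSModel | None
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray | None
    coefs_per_lv: np.ndarray
    n_lv: int

    @property
    def params(self) -> np.ndarray:
        return self.coefs_per_lv[:, self.n_lv - 1]

    @property
    def intercept(self) -> float:
        return self.y_mean - float(self.x_mean @ self.params)

    def predict(self, exog: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Predict via b0 + X·b (optionally with a smaller LV count)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"exog has {X.shape[1]} columns, model was trained with {self.x_mean.size}"
            )
        k = self.n_lv if n_lv is None else n_lv
        if not 1 <= k <= self.n_lv:
            raise ValueError(f"n_lv must be in [1, {self.n_lv}]")
        b = self.coefs_per_lv[:, k - 1]
        b0 = self.y_mean - float(self.x_mean @ b)
        return b0 + X @ b

    def predict_via_scores(self, exog: np.ndarray) -> np.ndarray:
        """Prediction through the score path (projection then y-loadings)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        Xc = X - self.x_mean
        yhat = np.full(X.shape[0], self.y_mean)
        for a in range(self.n_lv):
            t = Xc @ self.weights[:, a]
            yhat += self.y_loadings[a] * t
            Xc = Xc - np.outer(t, self.loadings[:, a])
        return yhat

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("training data not retained")
        return self.predict(self.model.exog)

    @property
    def rmsec(self) -> float:
        if self.model is None:
            raise ValueError("training data not retained")
        resid = self.model.endog - self.fittedvalues
        return float(np.sqrt(np.mean(resid**2)))

    def summary(self) -> str:
        lines = [
            "PLS1 regression (NIPALS, mean-centered)",
            f"  samples:          {self.model.exog.shape[0] if self.model else 'n/a'}",
            f"  variables:        {self.x_mean.size}",
            f"  latent variables: {self.n_lv}",
            f"  intercept:        {self.intercept:.6g}",
        ]
        if self.model is not None:
            lines.append(f"  RMSEC:            {self.rmsec:.6g}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kind": "pls1",
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefs_per_lv": self.coefs_per_lv.tolist(),
            "n_lv": self.n_lv,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PLSResults":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        doc = json.loads(text)
        if doc.get("kind") != "pls1":
            raise ValueError("not a serialized PLS1 model")
        return cls(
            model=None,
            x_mean=np.array(doc["x_mean"]),
            y_mean=float(doc["y_mean"]),
            weights=np.array(doc["weights"]),
            loadings=np.array(doc["loadings"]),
            y_loadings=np.array(doc["y_loadings"]),
            scores=None,
            coefs_per_lv=np.array(doc["coefs_per_lv"]),
            n_lv=int(doc["n_lv"]),
        )


# -- functional surface ---------------------------------------------------

def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSResults:
    """Fit a PLS1 model with ``n_lv`` latent variables."""
    return PLSModel(y, X).fit(n_lv=n_lv)


def predict_plsr(model: PLSResults, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous folds after a seeded shuffle."""
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def cv_rmsecv_by_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """k-fold RMSECV for every LV count 1..max_lv (one fit per fold).

    NIPALS yields nested sub-models, so each fold is fitted once at the
    largest LV count and evaluated at every smaller count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, n)
    cap = min(max_lv, n - int(np.ceil(n / folds)) - 1, X.shape[1])
    cap = max(cap, 1)
    sse = np.zeros(cap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankDeficiencyWarning)
        for test_idx in _fold_indices(n, folds, seed):
            train = np.setdiff1d(np.arange(n), test_idx)
            res = PLSModel(y[train], X[train]).fit(n_lv=cap)
            for k in range(1, res.n_lv + 1):
                resid = y[test_idx] - res.predict(X[test_idx], n_lv=k)
                sse[k - 1] += float(resid @ resid)
            # folds truncated below cap contribute their deepest model
            for k in range(res.n_lv + 1, cap + 1):
                resid = y[test_idx] - res.predict(X[test_idx], n_lv=res.n_lv)
                sse[k - 1] += float(resid @ resid)
    return np.sqrt(sse / n)


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """LV count minimizing k-fold RMSECV; ties broken toward fewer LVs."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    rmsecv = cv_rmsecv_by_lv(X, y, max_lv=max_lv, folds=folds, seed=seed)
    return int(np.argmin(rmsecv)) + 1
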