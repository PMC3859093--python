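"""Least-squares support vector machine regression with an RBF kernel.

Training solves one linear (KKT) system instead of a quadratic program:

    [ 0   1ᵀ        ] [ b ]   [ 0 ]
    [ 1   Ω + I/γ   ] [ α ] = [ y ],    Ω_ij = exp(−‖x_i − x_j‖² / σ²),

with regularization γ > 0 and kernel width σ² > 0.  Predictions are
ŷ(x) = Σ_i α_i K(x, x_i) + b.  Hyperparameters are picked by grid search
minimizing leave-one-out RMSECV; the LOO residuals come from a
closed-form identity (e_i = α_i / (A⁻¹)_{ii}) that is validated in the
test suite against the normative naive refit loop.

Spectra enter unscaled; the σ² grid is wide enough to absorb magnitude
differences between bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LSSVMModel",
    "LSSVMResults",
    "HyperGrid",
    "rbf_kernel",
    "kernel_matrix",
    "fit_lssvm",
    "grid_search_lssvm",
    "loo_rmsecv",
    "loo_rmsecv_naive",
    "default_grid",
]


def rbf_kernel(u: np.ndarray, v: np.ndarray, sigma2: float) -> float:
    """exp(−‖u − v‖² / σ²); lies in (0, 1]."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"vector lengths differ: {u.size} vs {v.size}")
    d = u - v
    return float(np.exp(-(d @ d) / sigma2))


def kernel_matrix(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """Pairwise RBF kernel between the rows of A and B."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    sq = cdist(np.atleast_2d(A), np.atleast_2d(B), metric="sqeuclidean")
    return np.exp(-sq / sigma2)


@dataclass(frozen=True)
class HyperGrid:
    """Candidate (γ, σ²) values for the grid search; all positive."""

    gamma_values: tuple[float, ...]
    sigma2_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.gamma_values or not self.sigma2_values:
            raise ValueError("grid axes must be non-empty")
        if min(self.gamma_values) <= 0 or min(self.sigma2_values) <= 0:
            raise ValueError("all grid values must be > 0")


def default_grid(points_per_axis: int = 8) -> HyperGrid:
    """γ and σ² log-spaced over 1e-1 … 1e6."""
    vals = tuple(np.logspace(-1, 6, points_per_axis))
    return HyperGrid(vals, vals)


class LSSVMModel:
    """LS-SVM regression of a response on a spectral matrix.

    ``LSSVMModel(y, X).fit()`` grid-searches (γ, σ²) by leave-one-out
    RMSECV; ``fit(gamma=…, sigma2=…)`` fits at fixed hyperparameters.
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
        self.endog = y
        self.exog = X

    @classmethod
    def from_dataset(cls, dataset) -> "LSSVMModel":
        return cls(dataset.np_percent, dataset.reflectance)

    def fit(
        self,
        gamma: float | None = None,
        sigma2: float | None = None,
        grid: HyperGrid | None = None,
        refine: bool = True,
    ) -> "LSSVMResults":
        if (gamma is None) != (sigma2 is None):
            raise ValueError("give both gamma and sigma2, or neither")
        rmsecv = None
        if gamma is None:
            gamma, sigma2, rmsecv = grid_search_lssvm(
                self.exog, self.endog, grid or default_grid(), refine=refine
            )
        alpha, b = _solve_kkt(self.exog, self.endog, gamma, sigma2)
        return LSSVMResults(
            model=self,
            alpha=alpha,
            bias=b,
            gamma=float(gamma),
            sigma2=float(sigma2),
            X_train=self.exog,
            rmsecv=rmsecv,
        )


def _kkt_matrix(X: np.ndarray, gamma: float, sigma2: float) -> np.ndarray:
    n = X.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = kernel_matrix(X, X, sigma2) + np.eye(n) / gamma
    return A


def _solve_kkt(
    X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float
) -> tuple[np.ndarray, float]:
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be > 0")
    A = _kkt_matrix(X, gamma, sigma2)
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular KKT system at gamma={gamma:g}, sigma2={sigma2:g}; "
            "decrease gamma (larger ridge 1/gamma) — no jitter is applied silently"
        ) from exc
    return sol[1:], float(sol[0])


@dataclass
class LSSVMResults:
    """Fitted LS-SVM: support values α, bias b, hyperparameters, data.

    KKT structure implies Σ α_i = 0 and training residuals e_i = α_i / γ.
    """

    model: LSSVMModel | None
    alpha: np.ndarray
    bias: float
    gamma: float
    sigma2: float
    X_train: np.ndarray
    rmsecv: float | None = None

    def predict(self, exog: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"exog has {X.shape[1]} columns, model was trained with "
                f"{self.X_train.shape[1]}"
            )
        return kernel_matrix(X, self.X_train, self.sigma2) @ self.alpha + self.bias

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.X_train)

    def summary(self) -> str:
        lines = [
            "LS-SVM regression (RBF kernel)",
            f"  samples:  {self.X_train.shape[0]}",
            f"  gamma:    {self.gamma:.6g}",
            f"  sigma2:   {self.sigma2:.6g}",
            f"  bias:     {self.bias:.6g}",
        ]
        if self.rmsecv is not None:
            lines.append(f"  LOO RMSECV: {self.rmsecv:.6g}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kind": "lssvm",
            "alpha": self.alpha.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "X_train": self.X_train.tolist(),
            "rmsecv": self.rmsecv,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LSSVMResults":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        doc = json.loads(text)
        if doc.get("kind") != "lssvm":
            raise ValueError("not a serialized LS-SVM model")
        return cls(
            model=None,
            alpha=np.array(doc["alpha"]),
            bias=float(doc["bias"]),
            gamma=float(doc["gamma"]),
            sigma2=float(doc["sigma2"]),
            X_train=np.array(doc["X_train"]),
            rmsecv=doc.get("rmsecv"),
        )


# -- functional surface and cross-validation ------------------------------

def fit_lssvm(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> LSSVMResults:
    """Fit at fixed (γ, σ²) by solving the KKT system once."""
    return LSSVMModel(y, X).fit(gamma=gamma, sigma2=sigma2)


def loo_rmsecv(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    """Leave-one-out RMSECV via the closed-form identity e_i = α_i / (A⁻¹)_ii.

    A is the KKT matrix; the identity gives each held-out residual from a
    single factorization.  Validated against :func:`loo_rmsecv_naive`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    A = _kkt_matrix(X, gamma, sigma2)
    Ainv = np.linalg.inv(A)
    sol = Ainv @ np.concatenate([[0.0], y])
    alpha = sol[1:]
    diag = np.diag(Ainv)[1:]
    resid = alpha / diag
    return float(np.sqrt(np.mean(resid**2)))


def loo_rmsecv_naive(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    """Normative leave-one-out RMSECV: n refits, each omitting one sample."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    errors = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        alpha, b = _solve_kkt(X[keep], y[keep], gamma, sigma2)
        pred = kernel_matrix(X[i : i + 1], X[keep], sigma2) @ alpha + b
        errors[i] = y[i] - pred[0]
    return float(np.sqrt(np.mean(errors**2)))


def _search_points(
    X: np.ndarray, y: np.ndarray, points: list[tuple[float, float]]
) -> tuple[float, float, float]:
    best: tuple[float, float, float] | None = None
    for gamma, sigma2 in points:
        try:
            r = loo_rmsecv(X, y, gamma, sigma2)
        except np.linalg.LinAlgError:
            continue
        if not np.isfinite(r):
            continue
        # ties: smaller RMSECV, then smaller gamma, then smaller sigma2
        key = (r, gamma, sigma2)
        if best is None or key < best:
            best = key
    if best is None:
        raise np.linalg.LinAlgError("every grid point produced a singular KKT system")
    r, gamma, sigma2 = best
    return gamma, sigma2, r


def grid_search_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperGrid | None = None,
    refine: bool = True,
) -> tuple[float, float, float]:
    """Pick (γ, σ²) minimizing leave-one-out RMSECV over the grid.

    Ties break toward smaller γ then smaller σ².  With ``refine``, one
    pass at 3x finer log-spacing is run around the coarse optimum.
    Returns ``(gamma, sigma2, rmsecv)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 samples for leave-one-out grid search")
    grid = grid or default_grid()

    points = sorted(
        {(float(g), float(s)) for g in grid.gamma_values for s in grid.sigma2_values}
    )
    gamma, sigma2, rmsecv = _search_points(X, y, points)

    if refine and len(points) > 1:
        g_step = _axis_step(sorted(set(grid.gamma_values)))
        s_step = _axis_step(sorted(set(grid.sigma2_values)))
        g_ref = [gamma * g_step ** (k / 3.0) for k in range(-3, 4)]
        s_ref = [sigma2 * s_step ** (k / 3.0) for k in range(-3, 4)]
        refined = sorted({(g, s) for g in g_ref for s in s_ref})
        gamma, sigma2, rmsecv = _search_points(X, y, refined)
    return gamma, sigma2, rmsecv


def _axis_step(values: list[float]) -> float:
    """Multiplicative spacing of a (log-spaced) axis; 10 for a single value."""
    if len(values) < 2:
        return 10.0
    ratios = [b / a for a, b in zip(values[:-1], values[1:])]
    return float(np.median(ratios))
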