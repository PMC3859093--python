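"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

CARS couples Monte Carlo subsampling with PLS regression to whittle a
full spectrum down to a small informative wavelength subset.  Each of N
sampling runs performs four steps:

1. Monte Carlo sampling — draw a fraction of the calibration samples
   without replacement and fit a PLS model on the currently retained
   variables.
2. Enforced reduction (EDF) — keep only the top ⌈r_i·p⌉ variables by
   normalized absolute regression coefficient, where the retained
   fraction decays exponentially, r_i = a·e^(−k·i), from r_1 = 1 down to
   r_N = 2/p.
3. Adaptive reweighted sampling (ARS) — draw ⌈r_i·p⌉ variables with
   replacement, with probability proportional to coefficient magnitude
   ("survival of the fittest"); variables drawn at least once survive.
4. Evaluation — record the k-fold RMSECV of a PLS model on the surviving
   subset over the whole calibration set.

The subset with the smallest RMSECV across runs is the selection.  The
prediction set never enters this procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import PLSModel, RankDeficiencyWarning, cv_rmsecv_by_lv

__all__ = ["CARSConfig", "CARSResult", "edf_retained_fraction", "run_cars"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CARSConfig:
    """CARS settings.

    n_runs
        Number of sampling runs N.
    mc_ratio
        Fraction of calibration samples drawn (without replacement) per run.
    cv_folds
        Fold count for the RMSECV that scores each run's subset.
    max_lv
        Cap on latent variables for the inner PLS models; the count used
        is chosen by inner cross-validation each run.
    """

    n_runs: int = 50
    mc_ratio: float = 0.8
    cv_folds: int = 5
    max_lv: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0.0 < self.mc_ratio < 1.0:
            raise ValueError("mc_ratio must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")


@dataclass
class CARSResult:
    """Traces and optimum of one CARS computation.

    retained_counts and rmsecv_trace have one entry per run;
    coefficient_paths is (n_runs, p) with exact zeros once a variable has
    been eliminated.  ``selected_variables`` are column indices into the
    matrix CARS was run on.
    """

    retained_counts: np.ndarray
    rmsecv_trace: np.ndarray
    coefficient_paths: np.ndarray
    best_run: int
    selected_variables: np.ndarray
    n_lv_trace: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv_trace[self.best_run])


def edf_retained_fraction(i: int, p: int, n_runs: int) -> float:
    """Exponentially decreasing retained fraction r_i = a·e^(−k·i).

    With a = (p/2)^(1/(N−1)) and k = ln(p/2)/(N−1), so that r_1 = 1 and
    r_N = 2/p.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 1 <= i <= n_runs:
        raise ValueError(f"run index {i} outside 1..{n_runs}")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * i))


def _choose_n_lv(X: np.ndarray, y: np.ndarray, config: CARSConfig, seed: int) -> int:
    cap = min(config.max_lv, X.shape[1], X.shape[0] - 1)
    if cap <= 1:
        return 1
    rmsecv = cv_rmsecv_by_lv(X, y, max_lv=cap, folds=config.cv_folds, seed=seed)
    return int(np.argmin(rmsecv)) + 1


def run_cars(X: np.ndarray, y: np.ndarray, config: CARSConfig | None = None) -> CARSResult:
    """Run CARS on a calibration set; fully reproducible from config.seed."""
    config = config or CARSConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n < config.cv_folds:
        raise ValueError(f"need at least cv_folds={config.cv_folds} samples, got {n}")

    rng = np.random.default_rng(config.seed)
    n_mc = int(np.ceil(config.mc_ratio * n))
    retained = np.arange(p)
    # one fold assignment for all runs, so RMSECV is comparable across runs
    cv_seed = int(rng.integers(2**31 - 1))

    retained_counts = np.zeros(config.n_runs, dtype=int)
    rmsecv_trace = np.zeros(config.n_runs)
    coefficient_paths = np.zeros((config.n_runs, p))
    n_lv_trace = np.zeros(config.n_runs, dtype=int)
    subsets: list[np.ndarray] = []

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankDeficiencyWarning)
        for run in range(1, config.n_runs + 1):
            # (1) Monte Carlo sample of calibration rows
            mc = rng.choice(n, size=n_mc, replace=False)
            Xmc = X[np.sort(mc)][:, retained]
            ymc = y[np.sort(mc)]

            # (2) PLS on retained variables; LV count by inner CV once per run
            inner_seed = int(rng.integers(2**31 - 1))
            n_lv = _choose_n_lv(Xmc, ymc, config, inner_seed)
            res = PLSModel(ymc, Xmc).fit(n_lv=n_lv)

            # (3) normalized absolute-coefficient weights
            b = res.params
            absb = np.abs(b)
            total = absb.sum()
            weights = absb / total if total > 0 else np.full(absb.size, 1.0 / absb.size)

            # (4) EDF: deterministic top-⌈r_i·p⌉ by weight (ties by index);
            # the schedule is absolute in the original variable count p
            n_draws = int(np.ceil(edf_retained_fraction(run, p, config.n_runs) * p))
            order = np.argsort(-weights, kind="stable")
            edf_idx = np.sort(order[: min(n_draws, retained.size)])

            # (5) ARS: ⌈r_i·p⌉ weighted draws with replacement among survivors
            w_surv = weights[edf_idx]
            w_surv = w_surv / w_surv.sum()
            draws = rng.choice(edf_idx.size, size=n_draws, replace=True, p=w_surv)
            survivors = edf_idx[np.unique(draws)]
            if survivors.size < 2:
                logger.warning(
                    "CARS run %d: retained set degenerated to %d variable(s); "
                    "keeping best 2 by weight",
                    run,
                    survivors.size,
                )
                survivors = np.sort(order[:2])
            new_retained = retained[survivors]

            # (6) score the surviving subset on the full calibration set
            cap = min(config.max_lv, new_retained.size, n - 1)
            curve = cv_rmsecv_by_lv(
                X[:, new_retained], y, max_lv=cap, folds=config.cv_folds, seed=cv_seed
            )
            best_lv = int(np.argmin(curve)) + 1
            score_fit = PLSModel(y, X[:, new_retained]).fit(n_lv=best_lv)

            retained = new_retained
            retained_counts[run - 1] = retained.size
            rmsecv_trace[run - 1] = float(curve[best_lv - 1])
            coefficient_paths[run - 1, retained] = score_fit.params
            n_lv_trace[run - 1] = score_fit.n_lv
            subsets.append(retained.copy())

    # ties: later run wins (fewer variables — parsimony)
    best_run = int(
        config.n_runs - 1 - np.argmin(rmsecv_trace[::-1])
    )
    return CARSResult(
        retained_counts=retained_counts,
        rmsecv_trace=rmsecv_trace,
        coefficient_paths=coefficient_paths,
        best_run=best_run,
        selected_variables=subsets[best_run],
        n_lv_trace=n_lv_trace,
    )
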