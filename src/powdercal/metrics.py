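"""Model evaluation statistics and the calibration/prediction split.

A fitted calibration is summarized by a :class:`RegressionReport`:
Pearson correlations (r_C, r_P), coefficients of determination
(R²_C, R²_P, computed as 1 − SS_res/SS_tot on the respective set), root
mean square errors (RMSEC, RMSEP, and cross-validated RMSECV), and the
residual predictive deviation RPD = sd(prediction-set reference) / RMSEP
using the sample (n−1) standard deviation.  RPD reads: ≥ 3 usable for
most applications, ≥ 2.5 usable for screening.

Robustness is judged by the |RMSECV − RMSEP| gap; a gap above ~2–3 % by
mass flags overfitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .dataset import SpectralDataset

__all__ = [
    "RegressionReport",
    "split_calibration_prediction",
    "regression_report",
    "robustness_gap",
    "rpd_interpretation",
    "OVERFIT_GAP_THRESHOLD",
]

#: |RMSECV − RMSEP| (% by mass) above which a model is flagged as overfit.
OVERFIT_GAP_THRESHOLD = 2.0


@dataclass
class RegressionReport:
    """Evaluation statistics for one fitted calibration model."""

    r_c: float
    r2_c: float
    rmsec: float
    r_p: float
    r2_p: float
    rmsep: float
    rmsecv: float | None
    rpd: float
    n_cal: int
    n_pred: int
    n_lv: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RegressionReport":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def split_calibration_prediction(
    dataset: SpectralDataset,
    n_cal_per_treatment: int = 15,
    seed: int = 0,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Per-treatment seeded split: first ``n_cal_per_treatment`` shuffled
    samples to calibration, the rest to prediction.

    The two outputs are disjoint and jointly exhaustive.  With the
    standard 20-sample treatments and the default 15, this is the
    15-calibration / 5-prediction split.
    """
    rng = np.random.default_rng(seed)
    cal_rows: list[np.ndarray] = []
    pred_rows: list[np.ndarray] = []
    for t in np.unique(dataset.treatment_id):
        rows = np.flatnonzero(dataset.treatment_id == t)
        if rows.size < n_cal_per_treatment + 1:
            raise ValueError(
                f"treatment {t} has {rows.size} samples; need at least "
                f"{n_cal_per_treatment + 1} for a {n_cal_per_treatment}/rest split"
            )
        perm = rng.permutation(rows.size)
        cal_rows.append(rows[np.sort(perm[:n_cal_per_treatment])])
        pred_rows.append(rows[np.sort(perm[n_cal_per_treatment:])])
    cal_idx = np.concatenate(cal_rows)
    pred_idx = np.concatenate(pred_rows)
    return dataset.select_rows(cal_idx), dataset.select_rows(pred_idx)


def _rmse(ref: np.ndarray, hat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((ref - hat) ** 2)))


def _r2(ref: np.ndarray, hat: np.ndarray) -> float:
    ss_res = float(np.sum((ref - hat) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def regression_report(
    y_cal_ref: np.ndarray,
    y_cal_hat: np.ndarray,
    y_pred_ref: np.ndarray,
    y_pred_hat: np.ndarray,
    rmsecv: float | None = None,
    n_lv: int | None = None,
) -> RegressionReport:
    """Compute the full statistic suite from paired reference/prediction
    vectors on the calibration and prediction sets.

    Raises ``ValueError`` if a reference vector has zero variance
    (correlation undefined).
    """
    vectors = {
        "y_cal_ref": np.asarray(y_cal_ref, dtype=float).ravel(),
        "y_cal_hat": np.asarray(y_cal_hat, dtype=float).ravel(),
        "y_pred_ref": np.asarray(y_pred_ref, dtype=float).ravel(),
        "y_pred_hat": np.asarray(y_pred_hat, dtype=float).ravel(),
    }
    cr, ch, pr, ph = vectors.values()
    if cr.size != ch.size or pr.size != ph.size:
        raise ValueError("reference/prediction vectors must be paired")
    if cr.size < 2 or pr.size < 2:
        raise ValueError("each set needs at least 2 samples")
    for name in ("y_cal_ref", "y_pred_ref"):
        if np.ptp(vectors[name]) == 0.0:
            raise ValueError(f"{name} has zero variance; correlation is undefined")

    rmsep = _rmse(pr, ph)
    sd_pred = float(np.std(pr, ddof=1))
    return RegressionReport(
        r_c=float(stats.pearsonr(cr, ch).statistic),
        r2_c=_r2(cr, ch),
        rmsec=_rmse(cr, ch),
        r_p=float(stats.pearsonr(pr, ph).statistic),
        r2_p=_r2(pr, ph),
        rmsep=rmsep,
        rmsecv=None if rmsecv is None else float(rmsecv),
        rpd=float(np.inf) if rmsep == 0.0 else sd_pred / rmsep,
        n_cal=cr.size,
        n_pred=pr.size,
        n_lv=n_lv,
    )


def robustness_gap(report: RegressionReport) -> float:
    """|RMSECV − RMSEP|, the overfitting indicator."""
    if report.rmsecv is None:
        raise ValueError("report has no RMSECV; robustness gap is undefined")
    return abs(report.rmsecv - report.rmsep)


def rpd_interpretation(rpd: float) -> str:
    """Conventional reading of an RPD value."""
    if rpd >= 3.0:
        return "usable for most applications"
    if rpd >= 2.5:
        return "usable for screening"
    return "not reliable for quantification"
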