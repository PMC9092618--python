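"""Fit, internal, and external validation statistics for QSPR models.

Implements the classical battery used to judge regression QSPR models:
fit statistics (R2, adjusted R2, s, F), leave-one-out Q2 (computed by
the PLS engine), external predictivity (R2pred = Q2F1, Q2F2, Lin's
concordance correlation coefficient), the rm2 metric family built from
origin-forced correlations, the Golbraikh-Tropsha acceptability
checklist, and a trimmed mean-absolute-error quality classification.

Acceptance thresholds: 0.5 for Q2, rm2-family means, R2pred and Q2F2;
0.750 for CCC; 0.2 as the ceiling for delta-rm2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "external_metrics",
    "rm2_metrics",
    "golbraikh_tropsha",
    "mae_criteria",
    "fit_stats",
    "ValidationReport",
    "THRESHOLDS",
]

THRESHOLDS = {
    "q2": 0.5,
    "rm2": 0.5,
    "r2pred": 0.5,
    "q2f2": 0.5,
    "ccc": 0.750,
    "delta_rm2_max": 0.2,
}

# trimmed-MAE classification constants (fraction of the training response range)
MAE_GOOD = (0.10, 0.20)   # MAE <= 0.10*range and MAE + 3*SD <= 0.20*range
MAE_BAD = (0.15, 0.25)    # MAE >  0.15*range or  MAE + 3*SD >  0.25*range
MAE_TRIM_FRACTION = 0.05


class MetricError(ValueError):
    pass


def _as1d(*arrays) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float).ravel() for a in arrays]
    n = len(out[0])
    if any(len(a) != n for a in out):
        raise MetricError("input vectors must have equal length")
    return out


def external_metrics(obs_test, pred_test, mean_y_train: float) -> tuple[float, float, float, float]:
    """External predictivity: (R2pred, Q2F2, CCC, RMSEP).

    R2pred (a.k.a. Q2F1) normalizes the test SSE by deviations from the
    training mean, Q2F2 by deviations from the test mean.  CCC is Lin's
    concordance correlation (population-moment, n-denominator form).
    """
    y, p = _as1d(obs_test, pred_test)
    if len(y) < 3:
        raise MetricError("need at least 3 test observations")
    sse = float(np.sum((y - p) ** 2))
    den1 = float(np.sum((y - mean_y_train) ** 2))
    den2 = float(np.sum((y - y.mean()) ** 2))
    if den1 == 0 or den2 == 0:
        raise MetricError("zero deviance denominator in external metrics")
    r2pred = 1.0 - sse / den1
    q2f2 = 1.0 - sse / den2
    sx2 = float(np.mean((y - y.mean()) ** 2))
    sy2 = float(np.mean((p - p.mean()) ** 2))
    sxy = float(np.mean((y - y.mean()) * (p - p.mean())))
    ccc = 2.0 * sxy / (sx2 + sy2 + (y.mean() - p.mean()) ** 2)
    rmsep = math.sqrt(sse / len(y))
    return r2pred, q2f2, ccc, rmsep


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise MetricError("constant vector cannot be min-max scaled")
    return (v - lo) / (hi - lo)


def rm2_metrics(obs, pred, scaled: bool = True) -> dict[str, float]:
    """The rm2 metric family from observed/predicted vectors.

    r2 is the squared Pearson correlation; r0_2 forces the regression of
    observed on predicted through the origin (r0p_2 swaps the axes);
    k and kp are the corresponding origin-forced slopes.  rm2 shrinks r2
    by the asymmetry between free and origin-forced fits.  By default
    both vectors are independently min-max scaled to [0, 1] first
    (``scaled=False`` gives the raw-scale variant used by the
    Golbraikh-Tropsha checks).
    """
    y, p = _as1d(obs, pred)
    if len(y) < 2:
        raise MetricError("need at least 2 observations")
    if y.std() == 0 or p.std() == 0:
        raise MetricError("constant vector in rm2 metrics")
    if scaled:
        y, p = _minmax(y), _minmax(p)
    r = float(np.corrcoef(y, p)[0, 1])
    r2 = r * r
    k = float(np.sum(y * p) / np.sum(p * p))
    kp = float(np.sum(y * p) / np.sum(y * y))
    r0_2 = 1.0 - float(np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2))
    r0p_2 = 1.0 - float(np.sum((p - kp * y) ** 2) / np.sum((p - p.mean()) ** 2))
    rm2 = r2 * (1.0 - math.sqrt(abs(r2 - r0_2)))
    rm2p = r2 * (1.0 - math.sqrt(abs(r2 - r0p_2)))
    return {
        "r2": r2,
        "r0_2": r0_2,
        "r0p_2": r0p_2,
        "k": k,
        "kp": kp,
        "rm2": rm2,
        "rm2p": rm2p,
        "rm2_avg": 0.5 * (rm2 + rm2p),
        "delta_rm2": abs(rm2 - rm2p),
    }


@dataclass
class GTVerdict:
    r2: float
    ratio: float       # (r2 - r0_2)/r2
    ratio_prime: float  # (r2 - r0p_2)/r2
    k: float
    kp: float
    pass_r2: bool
    pass_ratio: bool
    pass_slope: bool
    passed: bool


def golbraikh_tropsha(obs_test, pred_test) -> GTVerdict:
    """Golbraikh-Tropsha external acceptability checklist (raw scale).

    Criteria: r2 > 0.6; (r2 - r0_2)/r2 < 0.1 or the axis-swapped ratio
    < 0.1; at least one origin-forced slope within (0.85, 1.15).
    """
    m = rm2_metrics(obs_test, pred_test, scaled=False)
    r2 = m["r2"]
    ratio = (r2 - m["r0_2"]) / r2
    ratio_p = (r2 - m["r0p_2"]) / r2
    pass_r2 = r2 > 0.6
    pass_ratio = (ratio < 0.1) or (ratio_p < 0.1)
    pass_slope = (0.85 < m["k"] < 1.15) or (0.85 < m["kp"] < 1.15)
    return GTVerdict(
        r2=r2, ratio=ratio, ratio_prime=ratio_p, k=m["k"], kp=m["kp"],
        pass_r2=pass_r2, pass_ratio=pass_ratio, pass_slope=pass_slope,
        passed=pass_r2 and pass_ratio and pass_slope,
    )


def _n_trim(n: int, fraction: float = MAE_TRIM_FRACTION) -> int:
    # round half up
    return int(math.floor(n * fraction + 0.5))


def mae_trimmed_stats(abs_errors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trimmed MAE and SD of absolute errors, vectorized over rows.

    The 5% largest absolute errors (count rounded half up) are dropped;
    the mean and SD (n-1 denominator) of the remainder are returned.
    Accepts a 1-D vector or a (models x samples) matrix.
    """
    e = np.atleast_2d(np.asarray(abs_errors, dtype=float))
    n = e.shape[1]
    drop = _n_trim(n)
    keep = n - drop
    if keep < 2:
        raise MetricError("too few errors left after trimming")
    s = np.sort(e, axis=1)[:, :keep]
    mae = s.mean(axis=1)
    sd = s.std(axis=1, ddof=1)
    return mae, sd


def mae_class_from_stats(mae: float, sd: float, y_range: float) -> str:
    if y_range <= 0:
        raise MetricError("training response range must be positive")
    hi = mae + 3.0 * sd
    if mae <= MAE_GOOD[0] * y_range and hi <= MAE_GOOD[1] * y_range:
        return "good"
    if mae > MAE_BAD[0] * y_range or hi > MAE_BAD[1] * y_range:
        return "bad"
    return "moderate"


def mae_criteria(abs_errors, training_response_range: float) -> tuple[str, dict[str, float]]:
    """Classify prediction quality as good / moderate / bad.

    After dropping the 5% largest absolute errors, quality is judged
    relative to the training response range: good when MAE <= 0.1*range
    and MAE + 3*SD <= 0.2*range; bad when MAE > 0.15*range or
    MAE + 3*SD > 0.25*range; moderate otherwise.
    """
    e = np.asarray(abs_errors, dtype=float).ravel()
    if len(e) < 5:
        raise MetricError("need at least 5 errors for the MAE criteria")
    mae, sd = mae_trimmed_stats(e)
    cls = mae_class_from_stats(float(mae[0]), float(sd[0]), training_response_range)
    return cls, {"mae": float(mae[0]), "sd": float(sd[0]),
                 "mae_plus_3sd": float(mae[0] + 3 * sd[0]),
                 "n_dropped": _n_trim(len(e))}


def fit_stats(obs_train, fitted, n_params: int) -> tuple[float, float, float, float]:
    """Training-fit statistics (R2, adjusted R2, s, F ratio).

    ``n_params`` is the number of predictors p (intercept excluded);
    adjusted R2 and s use n - p - 1 residual degrees of freedom.
    """
    y, f = _as1d(obs_train, fitted)
    n = len(y)
    p = n_params
    if n <= p + 1:
        raise MetricError(f"need n > p + 1 (got n={n}, p={p})")
    sse = float(np.sum((y - f) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise MetricError("zero-variance response")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    s = math.sqrt(sse / (n - p - 1))
    ssr = sst - sse
    f_ratio = (ssr / p) / (sse / (n - p - 1)) if sse > 0 else math.inf
    return r2, r2_adj, s, f_ratio


@dataclass
class ValidationReport:
    """Full statistics battery with pass/fail verdicts.

    Mirrors the conventional reporting order: fit statistics, LOO-based
    internal validation, then external (test-set) validation.
    """

    n_train: int
    n_test: int
    n_descriptors: int
    lv: Optional[int]
    r2: float
    r2_adj: float
    s: float
    f_ratio: float
    q2_loo: float
    rm2_loo_avg: float
    delta_rm2_loo: float
    mae_class_train: str
    r2pred: float
    q2f2: float
    ccc: float
    rmsep: float
    rm2_test_avg: float
    delta_rm2_test: float
    mae_class_test: str
    gt: GTVerdict
    verdicts: dict[str, bool] = field(default_factory=dict)

    def evaluate_verdicts(self) -> dict[str, bool]:
        self.verdicts = {
            "q2_loo": self.q2_loo > THRESHOLDS["q2"],
            "rm2_loo": self.rm2_loo_avg > THRESHOLDS["rm2"],
            "delta_rm2_loo": self.delta_rm2_loo < THRESHOLDS["delta_rm2_max"],
            "r2pred": self.r2pred > THRESHOLDS["r2pred"],
            "q2f2": self.q2f2 > THRESHOLDS["q2f2"],
            "ccc": self.ccc > THRESHOLDS["ccc"],
            "rm2_test": self.rm2_test_avg > THRESHOLDS["rm2"],
            "delta_rm2_test": self.delta_rm2_test < THRESHOLDS["delta_rm2_max"],
            "golbraikh_tropsha": self.gt.passed,
        }
        return self.verdicts

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=float)

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        gt = d.pop("gt")
        d.pop("verdicts")
        d.update({f"gt_{k}": v for k, v in gt.items()})
        return pd.DataFrame([d])
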