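"""Per-subject non-Gaussianity gate.

The orientation stage relies on skewed marginals; applying it to
(near-)Gaussian data yields orientations at chance. The gate therefore
tests, per subject, whether the observed parcels' |skewness| values
exceed those of matched Gaussian surrogate series, using a one-tailed
Wilcoxon rank-sum test: p parcels give p observed |skewness| values,
compared against |skewness| of p freshly drawn standard-normal series
of the same length. Both signs of skewness indicate usable asymmetry,
hence the absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .synth import gaussian_surrogates

__all__ = ["GateResult", "sample_skewness", "gate_subject"]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class GateResult:
    """Outcome of the skewness gate for one subject."""

    per_parcel_abs_skewness: np.ndarray
    surrogate_abs_skewness: np.ndarray
    statistic: float
    p_value: float
    alpha: float
    passed: bool
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": float(self.alpha),
            "passed": bool(self.passed),
            "n_parcels": int(len(self.per_parcel_abs_skewness)),
            "n_excluded": int(self.n_excluded),
        }


def sample_skewness(series) -> float:
    """Moment-form skewness m3 / m2^(3/2) (biased estimator).

    The small-sample bias factor is shared by observed and surrogate
    series of equal length, so the rank-sum comparison is unaffected.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < 3:
        raise DegenerateDataError("need at least 3 observations")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 < _VAR_FLOOR:
        raise DegenerateDataError("series is (near-)constant; skewness undefined")
    return float(np.mean(xc**3) / m2**1.5)


def gate_subject(ts, alpha: float = 0.05, seed: int = 0) -> GateResult:
    """One-tailed rank-sum gate: observed |skew| > Gaussian surrogate |skew|.

    Parcels with (near-)zero variance are excluded from the comparison
    with a logged warning; the surrogate set is sized to the parcels
    actually compared.
    """
    x = ts.to_numpy() if isinstance(ts, pd.DataFrame) else np.asarray(ts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("time series must be 2-D with at least 2 parcels")
    n, p = x.shape
    obs = []
    n_excluded = 0
    for j in range(p):
        try:
            obs.append(abs(sample_skewness(x[:, j])))
        except DegenerateDataError:
            n_excluded += 1
            logger.warning("parcel %d excluded from gate: degenerate series", j)
    if len(obs) < 2:
        raise DegenerateDataError("fewer than 2 non-degenerate parcels")
    obs = np.asarray(obs)
    sur = gaussian_surrogates(len(obs), n, seed=seed)
    sur_skew = np.abs(stats.skew(sur, axis=0, bias=True))
    res = stats.ranksums(obs, sur_skew, alternative="greater")
    passed = bool(res.pvalue < alpha)
    return GateResult(
        per_parcel_abs_skewness=obs,
        surrogate_abs_skewness=sur_skew,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        passed=passed,
        n_excluded=n_excluded,
    )
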