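"""Signal-relationship diagnostics: Pearson correlation and time-lagged
cross-correlation (TLCC).

TLCC evaluates the Pearson coefficient of two series as a function of an
integer lag applied to the second series; its argmax estimates the temporal
offset between them (used, e.g., to check radar-vs-BP clock alignment).
Each lag's coefficient is a genuine Pearson on the overlapping support
(overlap truncation, no zero padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "TLCCResult", "pearson", "tlcc"]


@dataclass
class CorrelationResult:
    rho: float
    n: int


@dataclass
class TLCCResult:
    lags: np.ndarray         # integer sample offsets
    rho_at_lag: np.ndarray
    best_lag: int
    best_rho: float

    def to_frame(self) -> pd.DataFrame:
        """(lag, rho) curve, e.g. for CSV export / plotting."""
        return pd.DataFrame({"lag": self.lags, "rho": self.rho_at_lag})


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    rho = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(rho=rho, n=int(x.size))


def tlcc(x: np.ndarray, y: np.ndarray, max_lag: int) -> TLCCResult:
    """Time-lagged cross-correlation over lags in [-max_lag, max_lag].

    A positive best lag means ``y`` lags ``x`` by that many samples
    (x[t] aligns with y[t + lag]).  Ties are broken toward the smallest
    absolute lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(x.size, y.size)
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < half the series length")
    lags = np.arange(-max_lag, max_lag + 1)
    rhos = np.empty(lags.size)
    for j, k in enumerate(lags):
        if k >= 0:
            xs, ys = x[: n - k], y[k: n]
        else:
            xs, ys = x[-k: n], y[: n + k]
        if xs.size < 3:
            raise ValueError("overlap shorter than 3 samples at extreme lag")
        rhos[j] = stats.pearsonr(xs, ys).statistic
    # argmax with ties broken toward |lag| -> sort candidates by (-rho, |lag|)
    order = np.lexsort((np.abs(lags), -rhos))
    best = order[0]
    return TLCCResult(lags=lags, rho_at_lag=rhos,
                      best_lag=int(lags[best]), best_rho=float(rhos[best]))
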