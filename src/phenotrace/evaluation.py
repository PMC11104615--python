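"""Reconstruction fidelity on short and long timescales via STL.

Seasonal-Trend decomposition using LOESS splits a series additively into
trend + seasonal + residual. Long-timescale reconstruction error compares the
trends of the original and reconstructed trace; short-timescale error compares
their seasonal + residual parts (transients live there). Errors are normalised
by the standard deviation of the original channel series so pooled
distributions are comparable to a standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import STL

#: default seasonal smoother length; sufficient to isolate transient signals
SEASONAL_SMOOTHER = 35
#: STL needs a nominal period; 35 resampled steps (~8.4 min of imaging) puts
#: few-minute transients into seasonal+residual while slow decays stay in trend
DEFAULT_PERIOD = 35


@dataclass
class STLResult:
    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray

    @property
    def short(self) -> np.ndarray:
        """Short-timescale part: seasonal + residual."""
        return self.seasonal + self.residual


def stl_decompose(
    series: np.ndarray,
    seasonal_smoother: int = SEASONAL_SMOOTHER,
    period: int = DEFAULT_PERIOD,
) -> STLResult:
    """Additive STL decomposition of one series.

    ``seasonal_smoother`` is rounded up to the next odd integer if even, as
    LOESS windows must be odd. The residual is defined as
    ``series − trend − seasonal`` so additivity holds to machine precision.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if y.size <= 2 * period:
        raise ValueError(f"series length {y.size} must exceed 2×period ({2 * period})")
    if seasonal_smoother % 2 == 0:
        seasonal_smoother += 1
    res = STL(y, period=period, seasonal=seasonal_smoother).fit()
    trend = np.asarray(res.trend)
    seasonal = np.asarray(res.seasonal)
    residual = y - trend - seasonal
    return STLResult(trend=trend, seasonal=seasonal, residual=residual)


def timescale_error(
    x: np.ndarray,
    x_hat: np.ndarray,
    seasonal_smoother: int = SEASONAL_SMOOTHER,
    period: int = DEFAULT_PERIOD,
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Normalised long- and short-timescale errors per channel.

    ``x`` and ``x_hat`` are (channels, T). For each channel both series are
    STL-decomposed; the long error is the trend difference and the short
    error the (seasonal + residual) difference, each divided by the standard
    deviation of the original channel series. Channels with zero variance are
    reported as raw differences (s = 1) and flagged.

    Returns ``(long_errors, short_errors, zero_variance_flags)`` with error
    arrays of shape (channels, T).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have equal shapes")
    long_err = np.empty_like(x)
    short_err = np.empty_like(x)
    flags = []
    for c in range(x.shape[0]):
        s = float(np.std(x[c]))
        flagged = s == 0.0
        if flagged:
            s = 1.0
        dx = stl_decompose(x[c], seasonal_smoother, period)
        dh = stl_decompose(x_hat[c], seasonal_smoother, period)
        long_err[c] = (dx.trend - dh.trend) / s
        short_err[c] = (dx.short - dh.short) / s
        flags.append(flagged)
    return long_err, short_err, flags


def error_table(
    X: np.ndarray,
    X_hat: np.ndarray,
    cell_ids: np.ndarray | None = None,
    seasonal_smoother: int = SEASONAL_SMOOTHER,
    period: int = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """Pooled tidy error table over cells: columns cell_id, channel, timescale, value."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(len(X))
    rows = []
    for i in range(len(X)):
        le, se, _ = timescale_error(X[i], X_hat[i], seasonal_smoother, period)
        for c in range(X.shape[1]):
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids[i],
                        "channel": c,
                        "timescale": "long",
                        "value": le[c],
                    }
                )
            )
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids[i],
                        "channel": c,
                        "timescale": "short",
                        "value": se[c],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
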