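"""Raw frames/traces to the fixed-size matrix the VAE consumes.

Pipeline order follows the imaging workflow: image-level grid background
subtraction first, then per-trace moving-average smoothing (window 10) and
linear resampling to 750 uniformly spaced time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import CHANNELS, CellTrace

TARGET_LENGTH = 750
SMOOTH_WINDOW = 10
GRID = 8
N_LOWEST = 20


def background_subtract(image: np.ndarray, grid: int = GRID, n_lowest: int = N_LOWEST) -> np.ndarray:
    """Subtract a per-subset background estimate from a square image.

    The image is divided into a ``grid × grid`` array of subsets (64 × 64 px
    for a 512 × 512 frame); within each subset the mean of its ``n_lowest``
    lowest non-zero pixel values is subtracted and the result clamped at zero.
    Subsets with fewer than ``n_lowest`` non-zero pixels use all of them;
    all-zero subsets are left unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    n = image.shape[0]
    if n % grid != 0:
        raise ValueError(f"image side {n} not divisible by grid {grid}")
    step = n // grid
    out = image.copy()
    for gy in range(grid):
        for gx in range(grid):
            sub = out[gy * step : (gy + 1) * step, gx * step : (gx + 1) * step]
            nonzero = sub[sub > 0]
            if nonzero.size == 0:
                continue
            lowest = np.sort(nonzero)[:n_lowest]
            sub -= lowest.mean()
    return np.clip(out, 0.0, None)


def moving_average(trace: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving mean with windows shrunk at the boundaries.

    Interior samples average ``window`` values; near the edges the window is
    clipped to the available samples so output length equals input length.
    """
    y = np.asarray(trace, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = y.shape[-1]
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return y.copy()
    lo_off = (window - 1) // 2
    hi_off = window // 2
    idx = np.arange(n)
    lo = np.clip(idx - lo_off, 0, n)
    hi = np.clip(idx + hi_off + 1, 0, n)
    csum = np.cumsum(y, axis=-1)
    csum = np.concatenate([np.zeros(y.shape[:-1] + (1,)), csum], axis=-1)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def resample(
    timestamps: np.ndarray, values: np.ndarray, n: int = TARGET_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto ``n`` uniform points spanning the series.

    Returns ``(new_timestamps, new_values)``; endpoints are preserved exactly.
    """
    t = np.asarray(timestamps, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("resampling requires at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    grid = np.linspace(t[0], t[-1], n)
    if y.ndim == 1:
        return grid, np.interp(grid, t, y)
    return grid, np.stack([np.interp(grid, t, row) for row in y])


@dataclass
class TraceMatrix:
    """Resampled dataset: cells × 3 channels × 750 points plus metadata."""

    data: np.ndarray  # (n, 3, TARGET_LENGTH)
    time: np.ndarray  # (TARGET_LENGTH,) hours
    cell_ids: np.ndarray
    positions: np.ndarray | None = None  # (n, 2) μm
    sites: np.ndarray | None = None
    channel_order: tuple[str, ...] = CHANNELS
    labels: np.ndarray | None = field(default=None)  # ground truth if synthetic

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.time):
            raise ValueError("data must be (cells, channels, time) aligned with the grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.cell_ids) != len(self.data):
            raise ValueError("cell_ids misaligned with data")

    def __len__(self) -> int:
        return len(self.data)


def assemble(
    traces: list[CellTrace],
    window: int = SMOOTH_WINDOW,
    n_points: int = TARGET_LENGTH,
    labels: np.ndarray | None = None,
) -> TraceMatrix:
    """Smooth then resample each trace and stack into a :class:`TraceMatrix`."""
    if not traces:
        return TraceMatrix(
            data=np.empty((0, len(CHANNELS), n_points)),
            time=np.linspace(0, 1, n_points),
            cell_ids=np.empty(0, dtype=int),
            positions=np.empty((0, 2)),
            sites=np.empty(0, dtype=object),
            labels=labels,
        )
    n_ch = traces[0].values.shape[0]
    if any(tr.values.shape[0] != n_ch for tr in traces):
        raise ValueError("all traces must share the same channel set")
    data = np.empty((len(traces), n_ch, n_points))
    grid = None
    for i, tr in enumerate(traces):
        smoothed = moving_average(tr.values, window=window)
        grid, data[i] = resample(tr.time, smoothed, n=n_points)
    return TraceMatrix(
        data=data,
        time=grid,
        cell_ids=np.array([tr.cell_id for tr in traces]),
        positions=np.array([tr.position for tr in traces], dtype=float),
        sites=np.array([tr.site for tr in traces]),
        labels=labels,
    )
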