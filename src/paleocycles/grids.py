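"""Regular calendar-time series on a descending cal BP grid.

All regular series in the package (SPDs, growth rates, stability indices,
forcings) share one container, :class:`GridSeries`.  The grid is stored from
older to younger: ``t0`` is the cal BP age of the first bin and successive
bins step *forward in time*, i.e. towards smaller cal BP (0 BP = 1950 CE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSeries", "aggregate", "resample_to"]


@dataclass(eq=False)
class GridSeries:
    """A uniform-step series over calendar time.

    Parameters
    ----------
    t0
        cal BP of the first (oldest) bin centre.
    step
        Grid step in years; positive.  Bin ``i`` sits at ``t0 - i*step``.
    values
        One value per bin; ``NaN`` marks bins where the quantity is
        undefined (never silently zero).
    label
        Free-text description carried through transformations.
    normalized
        Whether the series has been scaled to unit standard deviation.
    """

    t0: float
    step: float
    values: np.ndarray
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """cal BP age of every bin, descending (old to young)."""
        return self.t0 - self.step * np.arange(len(self.values))

    @property
    def t_end(self) -> float:
        return self.t0 - self.step * (len(self.values) - 1)

    def copy(self, **changes) -> "GridSeries":
        out = replace(self, **changes)
        out.values = np.array(out.values, dtype=float, copy=True)
        return out

    @classmethod
    def from_times(cls, times, values, label: str = "") -> "GridSeries":
        """Build from explicit times; times must be uniform and descending."""
        times = np.asarray(times, dtype=float)
        if len(times) < 2:
            raise ValueError("need at least two time points")
        steps = np.diff(times)
        if not np.allclose(steps, steps[0]) or steps[0] >= 0:
            raise ValueError("times must be uniformly descending in cal BP")
        return cls(t0=float(times[0]), step=float(-steps[0]),
                   values=np.asarray(values, dtype=float), label=label)

    def restrict(self, window: tuple[float, float]) -> "GridSeries":
        """Clip to a ``(old, young)`` cal BP window (inclusive)."""
        old, young = max(window), min(window)
        t = self.times
        mask = (t <= old + 1e-9) & (t >= young - 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} does not intersect the grid")
        idx = np.flatnonzero(mask)
        return GridSeries(t0=float(t[idx[0]]), step=self.step,
                          values=self.values[idx].copy(), label=self.label,
                          normalized=self.normalized)

    def value_at(self, t, extrapolate: bool = False) -> np.ndarray:
        """Linear interpolation at arbitrary cal BP age(s)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tt = self.times[::-1]           # ascending for np.interp
        vv = self.values[::-1]
        out = np.interp(t, tt, vv, left=np.nan, right=np.nan)
        if extrapolate:
            out = np.interp(t, tt, vv)
        return out if out.shape != (1,) else out[0]


def aggregate(series: GridSeries, width: float) -> GridSeries:
    """Average consecutive bins into slices of ``width`` years.

    ``width`` must be an integer multiple of the input step.  Used to go
    from the fine internal calibration grid (5 a) to the 100 a analysis
    slices.  Slice value is the mean of the member bins; a slice is NaN
    only if all its members are NaN.
    """
    k = width / series.step
    if abs(k - round(k)) > 1e-9:
        raise ValueError("slice width must be a multiple of the grid step")
    k = int(round(k))
    if k == 1:
        return series.copy()
    n = len(series) // k
    if n == 0:
        raise ValueError("series shorter than one slice")
    block = series.values[: n * k].reshape(n, k)
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(block, axis=1)
    # slice centre: mean age of member bins
    t0 = series.t0 - series.step * (k - 1) / 2.0
    return GridSeries(t0=t0, step=width, values=vals, label=series.label,
                      normalized=series.normalized)


def resample_to(times, values, grid: GridSeries) -> GridSeries:
    """Linearly interpolate an irregular ``(cal BP, value)`` series onto
    the grid of ``grid``; NaN outside the input support."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times)
    out = np.interp(grid.times[::-1], times[order], values[order],
                    left=np.nan, right=np.nan)[::-1]
    return GridSeries(t0=grid.t0, step=grid.step, values=out)
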