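"""Relative growth rates and the smoothing/detrending/normalization chain.

The relative growth rate (RGR) of an SPD is the per-annum fractional
change ``{SPD(t+Δt) − SPD(t)} / {SPD(t)·Δt}``, with t+Δt one step *younger*
(forward in time).  Before any comparative statistic, series are bandpass
filtered: a distance-decaying (triangular) kernel of 130 a length removes
high frequencies, subtracting a 1500 a moving average removes the
millennial trend, and division by the standard deviation puts series on a
common scale.
"""

from __future__ import annotations

import numpy as np

from .grids import GridSeries

__all__ = ["rgr", "preprocess", "occupation_boom_bust_density"]


def rgr(spd: GridSeries, dt: float = 100.0) -> GridSeries:
    """Relative growth rate of an SPD.

    ``dt`` must be a multiple of the grid step.  Bins where the SPD is
    zero (or where the forward value is unavailable) are NaN-flagged.
    Scale-invariant: multiplying the SPD by a constant leaves RGR
    unchanged.
    """
    k = dt / spd.step
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("dt must be a positive multiple of the grid step")
    k = int(round(k))
    v = spd.values
    out = np.full(len(v), np.nan)
    if len(v) > k:
        cur = v[:-k]
        nxt = v[k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:-k] = (nxt - cur) / (cur * dt)
        out[:-k][cur <= 0] = np.nan
    return GridSeries(t0=spd.t0, step=spd.step, values=out,
                      label=f"RGR({spd.label})")


def _triangular_smooth(values: np.ndarray, step: float,
                       smooth_len: float) -> np.ndarray:
    """NaN-aware weighted average with triangular weights of half-width
    ``smooth_len`` years (weight 1 at lag 0, linearly decaying to 0)."""
    half = int(np.floor(smooth_len / step))
    if half < 1:
        return values.copy()
    lags = np.arange(-half, half + 1)
    w = 1.0 - np.abs(lags) * step / smooth_len
    w = np.clip(w, 0.0, None)
    mask = np.isfinite(values)
    v = np.where(mask, values, 0.0)
    num = np.convolve(v, w, mode="same")
    den = np.convolve(mask.astype(float), w, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[~mask] = np.nan          # undefined bins stay undefined
    out[den <= 0] = np.nan
    return out


def _moving_average(values: np.ndarray, step: float, win: float) -> np.ndarray:
    """Centred moving average over ``win`` years, window truncated at the
    series ends; NaNs ignored inside the window."""
    half = max(int(np.floor(win / (2 * step))), 1)
    n = len(values)
    out = np.full(n, np.nan)
    mask = np.isfinite(values)
    v = np.where(mask, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    ccnt = np.concatenate([[0.0], np.cumsum(mask.astype(float))])
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        cnt = ccnt[hi] - ccnt[lo]
        if cnt > 0:
            out[i] = (csum[hi] - csum[lo]) / cnt
    return out


def preprocess(series: GridSeries, smooth_len: float = 130.0,
               detrend_win: float = 1500.0, normalize: bool = True) -> GridSeries:
    """Smooth, detrend, centre and (optionally) scale a series.

    Order of operations: triangular smoothing of 130 a length, subtraction
    of the 1500 a moving-average trend, removal of the residual mean, and
    division by the standard deviation when ``normalize`` is on.  NaN bins
    propagate.
    """
    sm = _triangular_smooth(series.values, series.step, smooth_len)
    trend = _moving_average(sm, series.step, detrend_win)
    out = sm - trend
    valid = np.isfinite(out)
    if valid.sum() < 2:
        raise ValueError("preprocess: fewer than two defined bins")
    out = out - np.nanmean(out)
    if normalize:
        sd = np.nanstd(out)
        scale = float(np.nanmax(np.abs(series.values))) if \
            np.isfinite(series.values).any() else 0.0
        if sd <= 1e-10 * max(scale, 1e-30):
            raise ValueError("preprocess: zero variance, cannot normalize")
        out = out / sd
    return GridSeries(t0=series.t0, step=series.step, values=out,
                      label=series.label, normalized=normalize)


def occupation_boom_bust_density(series_list, threshold: float = 0.5,
                                 grid: GridSeries | None = None,
                                 smooth_len: float = 130.0,
                                 detrend_win: float = 1500.0) -> GridSeries:
    """Boom-minus-bust event density from independent occupation series.

    Each occupation-density series (its own time support) is converted to
    a relative change rate, preprocessed per series, and thresholded:
    rate > +threshold marks a boom (+1), rate < −threshold a bust (−1).
    Event series are summed across records and divided by the number of
    records covering each bin, so the density lies in [−1, 1].
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no occupation series given")
    if grid is None:
        oldest = max(s.t0 for s in series_list)
        youngest = min(s.t_end for s in series_list)
        step = series_list[0].step
        n = int(np.floor((oldest - youngest) / step)) + 1
        grid = GridSeries(t0=oldest, step=step, values=np.zeros(n))

    total = np.zeros(len(grid))
    cover = np.zeros(len(grid))
    for s in series_list:
        rate = rgr(s, dt=s.step)
        proc = preprocess(rate, smooth_len, detrend_win, normalize=True)
        events = np.zeros(len(proc))
        events[proc.values > threshold] = 1.0
        events[proc.values < -threshold] = -1.0
        on_grid = np.interp(grid.times[::-1], proc.times[::-1],
                            events[::-1], left=np.nan, right=np.nan)[::-1]
        # nearest-bin snap: event indicators should not be diluted by interp
        covered = np.isfinite(on_grid)
        total[covered] += on_grid[covered]
        cover[covered] += 1.0
    with np.errstate(invalid="ignore"):
        dens = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)
    return GridSeries(t0=grid.t0, step=grid.step, values=dens,
                      label="boom-bust density")
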