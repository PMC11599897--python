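"""Proxy stacking by PCA, the climate-stability index, and comparison forcings.

After chronology alignment the proxy ensemble is reduced to its leading
principal components.  The climate-stability index is the sign-reversed,
normalized sum of the absolute temporal derivatives of the first five
smoothed components: it is high whenever the shared climate state changes
slowly — regardless of whether conditions are warm, cold, wet or dry —
and low during rapid transitions.  The solar forcing enters sign-reversed
(low irradiance historically coincides with high stability), and annual
tree-ring tables provide a local homogeneity proxy via the across-tree
spread of ring widths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .grids import GridSeries, resample_to
from .growth import preprocess, _triangular_smooth

__all__ = [
    "PCResult",
    "principal_components",
    "stability_index",
    "merge_segments",
    "prepare_forcing",
    "treering_homogeneity",
]

log = logging.getLogger(__name__)

MERGE_OLD = 6200.0   # cal BP, blend zone between early and late segments
MERGE_YOUNG = 5800.0


@dataclass
class PCResult:
    """Leading principal components of a weighted proxy ensemble."""

    times: np.ndarray                # cal BP, descending
    scores: np.ndarray               # (n_times, n_pc)
    loadings: np.ndarray             # (n_records, n_pc)
    explained_variance_ratio: np.ndarray
    record_ids: list

    @property
    def step(self) -> float:
        return float(self.times[0] - self.times[1])

    def component(self, c: int) -> GridSeries:
        return GridSeries(t0=float(self.times[0]), step=self.step,
                          values=self.scores[:, c], label=f"PC{c + 1}")


def _record_matrix(records, step: float, max_gap: float):
    """Interpolate standardized records onto a common grid; drop records
    with an internal sampling gap larger than ``max_gap`` years."""
    kept, kept_idx = [], []
    for i, r in enumerate(records):
        gaps = np.diff(r.times)
        if len(gaps) and gaps.max() > max_gap:
            log.info("PCA: dropping %s (coverage gap %.0f a)", r.id, gaps.max())
            continue
        kept.append(r)
        kept_idx.append(i)
    if not kept:
        raise ValueError("no records survive the coverage-gap screen")
    oldest = min(r.span[1] for r in kept)
    youngest = max(r.span[0] for r in kept)
    if oldest - youngest < 4 * step:
        raise ValueError("records share too little common support")
    n = int(np.floor((oldest - youngest) / step)) + 1
    times = oldest - step * np.arange(n)
    cols = []
    for r in kept:
        v = r.standardized()
        cols.append(np.interp(times[::-1], r.times, v)[::-1])
    return times, np.column_stack(cols), kept, kept_idx


def principal_components(records, weights=None, n_pc: int = 5,
                         step: float = 20.0, max_gap: float = 500.0) -> PCResult:
    """PCA of an aligned, convergence-weighted proxy ensemble.

    Records are standardized, interpolated to a common ``step``-year grid
    over the span they all share, multiplied by their alignment weights
    ``w_j`` (so poorly synchronized records contribute little), and
    decomposed.  Explained-variance fractions come out non-increasing.
    """
    records = list(records)
    if weights is None:
        weights = np.array([r.weight if r.weight > 0 else 1.0 / len(records)
                            for r in records])
    weights = np.asarray(weights, dtype=float)
    times, mat, kept, kept_idx = _record_matrix(records, step, max_gap)
    w = weights[kept_idx]
    if len(kept) < n_pc:
        n_pc = len(kept)
    X = mat * w[np.newaxis, :]
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(X)
    return PCResult(times=times, scores=scores,
                    loadings=pca.components_.T,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    record_ids=[r.id for r in kept])


def stability_index(pcs: PCResult, n_pc: int = 5,
                    smooth_len: float = 130.0) -> GridSeries:
    """Climate stability from the leading components of one segment.

    Each component is smoothed with the standard 130 a triangular
    kernel; the absolute central-difference derivatives of the first
    ``n_pc`` components are summed, normalized to zero mean and unit
    standard deviation, and sign-reversed: a high index means a slowly
    changing climate state.  Invariant to the (arbitrary) sign of each
    component.
    """
    step = pcs.step
    k = min(n_pc, pcs.scores.shape[1])
    change = np.zeros(pcs.scores.shape[0])
    for c in range(k):
        sm = _triangular_smooth(pcs.scores[:, c], step, smooth_len)
        change += np.abs(np.gradient(sm, -step))
    sd = np.nanstd(change)
    if sd <= 0:
        raise ValueError("degenerate components: change signal has zero variance")
    idx = -(change - np.nanmean(change)) / sd
    return GridSeries(t0=float(pcs.times[0]), step=step, values=idx,
                      label="climate stability", normalized=True)


def merge_segments(early: GridSeries, late: GridSeries,
                   blend_old: float = MERGE_OLD,
                   blend_young: float = MERGE_YOUNG) -> GridSeries:
    """Merge an early- and a late-segment index with a linear cross-fade
    over the 5.8–6.2 ka BP junction.

    Older than ``blend_old`` the early index is used, younger than
    ``blend_young`` the late one; in between the weight shifts linearly.
    """
    if abs(early.step - late.step) > 1e-9:
        raise ValueError("segments must share the grid step")
    step = early.step
    t0 = max(early.t0, late.t0)
    t_end = min(early.t_end, late.t_end)
    n = int(np.floor((t0 - t_end) / step)) + 1
    times = t0 - step * np.arange(n)
    ve = np.interp(times[::-1], early.times[::-1], early.values[::-1],
                   left=np.nan, right=np.nan)[::-1]
    vl = np.interp(times[::-1], late.times[::-1], late.values[::-1],
                   left=np.nan, right=np.nan)[::-1]
    w_early = np.clip((times - blend_young) / (blend_old - blend_young), 0.0, 1.0)
    out = np.where(np.isnan(ve), vl,
                   np.where(np.isnan(vl), ve,
                            w_early * ve + (1 - w_early) * vl))
    return GridSeries(t0=float(times[0]), step=step, values=out,
                      label=early.label, normalized=early.normalized)


def prepare_forcing(times_or_series, values=None, grid: GridSeries | None = None,
                    smooth_len: float = 130.0,
                    detrend_win: float = 1500.0) -> GridSeries:
    """Sign-reversed, preprocessed solar-irradiance forcing.

    Accepts a :class:`GridSeries` or an irregular ``(times, values)``
    pair (resampled onto ``grid``).  Output is ``−preprocess(TSI)`` with
    normalization on: minima of solar irradiance become maxima of the
    comparison forcing.
    """
    if isinstance(times_or_series, GridSeries):
        series = times_or_series
    else:
        if grid is None:
            raise ValueError("a target grid is required for irregular input")
        series = resample_to(times_or_series, values, grid)
        if np.isnan(series.values).any():
            raise ValueError("forcing does not cover the analysis window")
    proc = preprocess(series, smooth_len, detrend_win, normalize=True)
    return GridSeries(t0=proc.t0, step=proc.step, values=-proc.values,
                      label="-TSI", normalized=True)


def treering_homogeneity(widths: pd.DataFrame, smooth_len: float = 130.0,
                         detrend_win: float = 1500.0,
                         min_trees: int = 2) -> GridSeries:
    """Environmental homogeneity from an annual ring-width table.

    ``widths`` is indexed by cal BP year with one column per tree.  The
    across-tree standard deviation per year is preprocessed and
    sign-flipped: identical growth across trees (low spatial variance)
    reads as high homogeneity.  Years with fewer than ``min_trees``
    measurements are excluded.
    """
    counts = widths.notna().sum(axis=1)
    sub = widths.loc[counts >= min_trees]
    if sub.empty:
        raise ValueError("no year has enough trees")
    if (counts < min_trees).any():
        log.info("treering_homogeneity: excluded %d year(s) with <%d trees",
                 int((counts < min_trees).sum()), min_trees)
    years = sub.index.to_numpy(dtype=float)
    order = np.argsort(years)[::-1]          # descending cal BP
    sd = sub.std(axis=1, ddof=1).to_numpy(dtype=float)[order]
    years = years[order]
    step = float(np.round(np.median(-np.diff(years))))
    series = GridSeries(t0=float(years[0]), step=step, values=sd,
                        label="tree-ring spread")
    proc = preprocess(series, smooth_len, detrend_win, normalize=True)
    return GridSeries(t0=proc.t0, step=proc.step, values=-proc.values,
                      label="tree-ring homogeneity", normalized=True)
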