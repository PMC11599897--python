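"""Time-variable regionalization of growth rates and spatial synchrony.

Where date density permits, growth-rate estimation is down-scaled from
the continent to statistically homogeneous regions.  For each 400 a time
slice, spatial permutation tests on a 4°×4° grid flag cells whose local
growth deviates from the continent-wide expectation; the signed scores
and cell coordinates feed a k-means whose cluster count is chosen by
minimizing the within-cluster sum of squares times a penalty
``1 + exp{−10(N_min/N* − 1)}`` that discourages regions with too few
dates (N* = 120 cell-slice dates keeps regions above the sample size
needed for a robust SPD).  Regional series are then combined into an
area-weighted continental average — a low-density region of equal area
counts as much as a dense one — and compared across space via
distance-binned correlations and window-growing phase overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .calibration import CalibrationCurve, spd, _cell_of, _cell_area_km2
from .grids import GridSeries, aggregate
from .growth import rgr
from .synchrony import phase_overlap

__all__ = [
    "CellScore",
    "RegionPartition",
    "local_deviation_scores",
    "cluster_weighting_factor",
    "cluster_regions",
    "regional_mean_rgr",
    "spatial_autocorrelation",
    "synchrony_vs_extent",
    "great_circle_km",
]

log = logging.getLogger(__name__)

N_STAR = 120            # scaling of the minimum-cluster-size penalty
CRITICAL_P = 0.05
CRITICAL_Q = 0.05
MIN_CELL_DATES = 10
EARTH_RADIUS_KM = 6371.0


@dataclass
class CellScore:
    """Permutation-test outcome for one 4°×4° cell in one slice."""

    cell: tuple[int, int]
    lon: float           # cell centre
    lat: float
    n_dates: int
    deviation: float     # cell RGR minus global RGR over the slice
    p: float
    q: float
    score: float         # signed combined score, 0 unless p and q < .05


@dataclass
class RegionPartition:
    """Regions of one 400 a slice, projected on a 0.1° grid."""

    slice_window: tuple[float, float]          # (old, young) cal BP
    cell_assignment: dict                      # 0.1° cell -> region label
    region_cells: dict                         # label -> list of 4° cells
    region_dates: dict                         # label -> date count
    region_area: dict                          # label -> km²
    k: int
    n_min: int
    weighted_withinss: float
    extras: dict = field(default_factory=dict)


def slice_windows(oldest: float = 9800.0, youngest: float = 3000.0,
                  width: float = 400.0):
    """The 400 a slice tiling of the study period, oldest first:
    (9.8–9.4, 9.4–9.0, ..., 3.4–3.0 ka BP)."""
    out = []
    t = oldest
    while t - width >= youngest - 1e-9:
        out.append((t, t - width))
        t -= width
    return out


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    """Haversine distance in km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _slice_growth(dens_sum: np.ndarray, t: np.ndarray, step: float,
                  slice_window, dt: float = 100.0) -> float:
    """Mean RGR over a slice from a summed density on the fine grid."""
    series = GridSeries(t0=float(t[0]), step=step, values=dens_sum)
    coarse = rgr(aggregate(series, dt), dt=dt)
    old, young = max(slice_window), min(slice_window)
    m = (coarse.times <= old) & (coarse.times >= young) & \
        np.isfinite(coarse.values)
    if not m.any():
        return np.nan
    return float(coarse.values[m].mean())


def local_deviation_scores(dates, curve: CalibrationCurve, slice_window,
                           n_perm: int = 999, seed: int | None = None,
                           cell_deg: float = 4.0, step: float = 5.0,
                           dt: float = 100.0,
                           min_cell_dates: int = MIN_CELL_DATES):
    """Permutation test for local growth-rate deviations in one slice.

    Sites — not individual dates — are the exchangeable units: the test
    statistic per cell is the mean slice RGR of the cell's summed date
    density minus the global value, and the null distribution is built
    by randomly reassigning whole sites to cells (holding the number of
    sites per cell fixed).  Per-cell p-values are two-sided permutation
    ranks; q-values come from the Benjamini–Hochberg step-up over the
    slice.  The combined score ``(1−p) + (1−q)``, signed by the
    deviation, is nonzero only where both p and q fall below .05.
    """
    rng = np.random.default_rng(seed)
    dates = list(dates)
    old, young = max(slice_window), min(slice_window)
    # pad the calibration window so the forward difference is defined
    window = (old + 2 * dt, max(young - 2 * dt, curve.support[0]))

    # per-site summed calibrated density (sites move as blocks)
    from .calibration import calibrate_date, _cal_grid
    t = _cal_grid(curve, window, step)
    site_ids, site_cell, site_dens, site_count = [], [], [], []
    by_site: dict[str, list] = {}
    for d in dates:
        by_site.setdefault(d.site_id, []).append(d)
    for sid, ds in by_site.items():
        dens = np.zeros(len(t))
        for d in ds:
            dens += calibrate_date(d.c14_age, d.c14_sd, curve,
                                   window=window, step=step).values
        site_ids.append(sid)
        site_cell.append(_cell_of(ds[0].lon, ds[0].lat, cell_deg))
        site_dens.append(dens)
        site_count.append(len(ds))
    site_dens = np.asarray(site_dens)
    site_count = np.asarray(site_count)
    cells = sorted(set(site_cell))
    cell_index = {c: k for k, c in enumerate(cells)}
    assign = np.array([cell_index[c] for c in site_cell])

    counts = np.array([site_count[assign == k].sum() for k in range(len(cells))])
    active = [k for k in range(len(cells)) if counts[k] >= min_cell_dates]
    dropped = len(cells) - len(active)
    if dropped:
        log.info("local_deviation_scores: excluded %d cell(s) with <%d dates",
                 dropped, min_cell_dates)
    if len(active) < 2:
        raise ValueError("need at least 2 populated cells")

    def cell_stats(a):
        out = np.full(len(cells), np.nan)
        for k in active:
            m = a == k
            if m.any():
                out[k] = _slice_growth(site_dens[m].sum(axis=0), t, step,
                                       slice_window, dt)
        return out

    global_rgr = _slice_growth(site_dens.sum(axis=0), t, step,
                               slice_window, dt)
    obs = cell_stats(assign) - global_rgr

    exceed = np.zeros(len(cells))
    valid = np.zeros(len(cells))
    for _ in range(n_perm):
        perm = rng.permutation(assign)
        dev = cell_stats(perm) - global_rgr
        for k in active:
            if np.isfinite(dev[k]) and np.isfinite(obs[k]):
                valid[k] += 1
                if abs(dev[k]) >= abs(obs[k]):
                    exceed[k] += 1

    results = []
    pvals, keys = [], []
    for k in active:
        if not np.isfinite(obs[k]) or valid[k] == 0:
            continue
        p = (exceed[k] + 1.0) / (valid[k] + 1.0)
        pvals.append(p)
        keys.append(k)
    if not pvals:
        raise ValueError("no cell yielded a defined statistic")
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for k, p, q in zip(keys, pvals, qvals):
        score = 0.0
        if p < CRITICAL_P and q < CRITICAL_Q:
            score = np.sign(obs[k]) * ((1.0 - p) + (1.0 - q))
        lon = (cells[k][0] + 0.5) * cell_deg
        lat = (cells[k][1] + 0.5) * cell_deg
        results.append(CellScore(cell=cells[k], lon=lon, lat=lat,
                                 n_dates=int(counts[k]),
                                 deviation=float(obs[k]), p=float(p),
                                 q=float(q), score=float(score)))
    return results


def cluster_weighting_factor(n_min: float, n_star: float = N_STAR) -> float:
    """Penalty ``1 + exp{−10(N_min/N* − 1)}`` applied to the within-cluster
    sum of squares; equals 2 at N_min = N* and tends to 1 for large
    clusters."""
    return float(1.0 + np.exp(-10.0 * (n_min / n_star - 1.0)))


def cluster_regions(scores, slice_window, n_star: float = N_STAR,
                    k_range=range(2, 13), n_restarts: int = 25,
                    seed: int | None = None, cell_deg: float = 4.0,
                    fine_deg: float = 0.1) -> RegionPartition:
    """Choose and fit the region partition for one slice.

    Feature vector per populated 4° cell: (signed score, lon, lat), each
    standardized so statistics and geography are commensurate.  For every
    k in ``k_range`` a seeded k-means with ``n_restarts`` restarts is
    fitted; the k minimizing ``withinss × cluster_weighting_factor(N_min)``
    wins, with N_min the date count of the smallest cluster.  The winning
    partition is projected onto a ``fine_deg`` grid by containment in the
    parent 4° cell.
    """
    scores = list(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 scored cells")
    feats = np.array([[s.score, s.lon, s.lat] for s in scores])
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    X = (feats - mu) / sd
    n_dates = np.array([s.n_dates for s in scores])

    best = None
    for k in k_range:
        if k > len(scores):
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        n_min = min(n_dates[labels == c].sum() for c in range(k))
        weighted = km.inertia_ * cluster_weighting_factor(n_min, n_star)
        if best is None or weighted < best[0]:
            best = (weighted, k, labels, n_min)
    if best is None:
        raise ValueError("k range exhausted without a valid partition")
    weighted, k, labels, n_min = best

    region_cells: dict[int, list] = {}
    region_dates: dict[int, int] = {}
    region_area: dict[int, float] = {}
    cell_assignment: dict[tuple[int, int], int] = {}
    ratio = int(round(cell_deg / fine_deg))
    for s, lab in zip(scores, labels):
        lab = int(lab)
        region_cells.setdefault(lab, []).append(s.cell)
        region_dates[lab] = region_dates.get(lab, 0) + s.n_dates
        region_area[lab] = region_area.get(lab, 0.0) + _cell_area_km2(s.cell, cell_deg)
        fx0 = s.cell[0] * ratio
        fy0 = s.cell[1] * ratio
        for fx in range(fx0, fx0 + ratio):
            for fy in range(fy0, fy0 + ratio):
                cell_assignment[(fx, fy)] = lab
    log.info("cluster_regions %s: k=%d, N_min=%d", slice_window, k, n_min)
    return RegionPartition(slice_window=tuple(slice_window),
                           cell_assignment=cell_assignment,
                           region_cells=region_cells,
                           region_dates=region_dates,
                           region_area=region_area,
                           k=k, n_min=int(n_min),
                           weighted_withinss=float(weighted))


def regional_mean_rgr(partition: RegionPartition, dates,
                      curve: CalibrationCurve, window,
                      step: float = 5.0, dt: float = 100.0,
                      cell_deg: float = 4.0):
    """Per-region growth rates and their area-weighted average.

    Returns ``(regional, continental)`` where ``regional`` maps region
    label to its RGR series over ``window`` and ``continental`` is
    ``Σ area_r·RGR_r / Σ area_r`` per time step, skipping regions whose
    RGR is undefined in that bin (logged via NaN-awareness).
    """
    cell_to_region = {}
    for lab, cells in partition.region_cells.items():
        for c in cells:
            cell_to_region[c] = lab
    groups: dict[int, list] = {}
    for d in dates:
        lab = cell_to_region.get(_cell_of(d.lon, d.lat, cell_deg))
        if lab is not None:
            groups.setdefault(lab, []).append(d)

    regional: dict[int, GridSeries] = {}
    for lab, ds in groups.items():
        s = aggregate(spd(ds, curve, window=window, step=step), dt)
        regional[lab] = rgr(s, dt=dt)
    if not regional:
        raise ValueError("no region contains any date")

    labs = sorted(regional)
    areas = np.array([partition.region_area[l] for l in labs])
    mat = np.vstack([regional[l].values for l in labs])
    w = areas[:, None] * np.isfinite(mat)
    with np.errstate(invalid="ignore"):
        cont = np.nansum(np.where(np.isfinite(mat), mat, 0.0) * areas[:, None],
                         axis=0) / w.sum(axis=0)
    cont[w.sum(axis=0) == 0] = np.nan
    ref = regional[labs[0]]
    continental = GridSeries(t0=ref.t0, step=ref.step, values=cont,
                             label="area-weighted RGR")
    return regional, continental


def _region_centroid(partition: RegionPartition, lab,
                     cell_deg: float = 4.0) -> tuple[float, float]:
    cells = partition.region_cells[lab]
    lons = [(c[0] + 0.5) * cell_deg for c in cells]
    lats = [(c[1] + 0.5) * cell_deg for c in cells]
    return float(np.mean(lons)), float(np.mean(lats))


def spatial_autocorrelation(regional: dict, partition: RegionPartition,
                            bin_km: float = 500.0, max_km: float = 5000.0,
                            cell_deg: float = 4.0):
    """Mean pairwise correlation of regional growth series per
    inter-centroid distance bin.  Returns (bin centres km, mean r,
    pair counts); empty bins are NaN."""
    labs = sorted(regional)
    if len(labs) < 3:
        raise ValueError("need at least 3 regions")
    cent = {l: _region_centroid(partition, l, cell_deg) for l in labs}
    edges = np.arange(0.0, max_km + bin_km, bin_km)
    sums = np.zeros(len(edges) - 1)
    cnts = np.zeros(len(edges) - 1, dtype=int)
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            va, vb = regional[a].values, regional[b].values
            m = np.isfinite(va) & np.isfinite(vb)
            if m.sum() < 8:
                continue
            if va[m].std() == 0 or vb[m].std() == 0:
                continue
            r = np.corrcoef(va[m], vb[m])[0, 1]
            dist = great_circle_km(*cent[a], *cent[b])
            k = int(np.searchsorted(edges, dist, side="right")) - 1
            if 0 <= k < len(sums):
                sums[k] += r
                cnts[k] += 1
    with np.errstate(invalid="ignore"):
        mean_r = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centres = (edges[:-1] + edges[1:]) / 2.0
    return centres, mean_r, cnts


def synchrony_vs_extent(regional: dict, partition: RegionPartition,
                        forcing: GridSeries, windows,
                        preprocess_fn=None, cell_deg: float = 4.0):
    """Phase overlap of the area-averaged growth rate with a forcing as
    the spatial window grows.

    ``windows`` is an iterable of (lon_min, lon_max, lat_min, lat_max)
    boxes, typically nested; regions enter a window by centroid.  The
    growth average is area-weighted within the window, optionally passed
    through ``preprocess_fn`` before the overlap.  Windows containing no
    region are skipped.
    """
    results = []
    for box in windows:
        lon0, lon1, lat0, lat1 = box
        labs = []
        for l in regional:
            lon, lat = _region_centroid(partition, l, cell_deg)
            if lon0 <= lon <= lon1 and lat0 <= lat <= lat1:
                labs.append(l)
        if not labs:
            log.info("synchrony_vs_extent: window %s empty, skipped", box)
            continue
        areas = np.array([partition.region_area[l] for l in labs])
        mat = np.vstack([regional[l].values for l in labs])
        w = areas[:, None] * np.isfinite(mat)
        with np.errstate(invalid="ignore"):
            avg = np.nansum(np.where(np.isfinite(mat), mat, 0.0)
                            * areas[:, None], axis=0) / w.sum(axis=0)
        avg[w.sum(axis=0) == 0] = np.nan
        ref = regional[labs[0]]
        series = GridSeries(t0=ref.t0, step=ref.step, values=avg)
        if preprocess_fn is not None:
            series = preprocess_fn(series)
        ov = phase_overlap(series, forcing)
        results.append({"window": box, "n_regions": len(labs),
                        "area_km2": float(areas.sum()), "overlap": ov})
    return results
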