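"""Synthetic study data: dated samples, calibration curves, proxies, forcing.

The generators emulate the statistical structure each pipeline stage
assumes, so the whole chain runs and is tested without any download: a
population trajectory whose relative growth rate carries multicentennial
cycles (default periods 360, 500 and 680 a); radiocarbon dates drawn in
proportion to that trajectory, mapped through a wiggly but monotone
calibration curve and blurred by lab error, at sites clustered in space;
a proxy ensemble sharing one latent climate signal but corrupted by
smooth independent chronological distortions of at most ±150 a plus
noise; and a solar-like forcing optionally coupled to the latent.

Everything is reproducible from ``(seed, scenario)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import CalibrationCurve, RadiocarbonDate
from .grids import GridSeries
from .proxy_align import ProxyRecord

__all__ = [
    "SyntheticScenario",
    "make_calibration_curve",
    "make_population",
    "sample_dates",
    "make_proxies",
    "make_forcing",
]


@dataclass
class SyntheticScenario:
    """All knobs of one synthetic study, serializable with its outputs."""

    seed: int = 0
    window: tuple = (9800.0, 3000.0)          # cal BP (old, young)
    cycle_periods: tuple = (360.0, 500.0, 680.0)
    cycle_amplitudes: tuple = (0.0012, 0.0012, 0.0012)   # a⁻¹ RGR amplitude
    trend_rate: float = 0.0003                # a⁻¹ long-term growth
    n_dates: int = 20000
    n_sites: int = 250
    n_clusters: int = 8                       # spatial site clusters
    cluster_sd_deg: float = 1.5
    lon_range: tuple = (-10.0, 30.0)
    lat_range: tuple = (36.0, 60.0)
    lab_sd: float = 30.0                      # ¹⁴C a measurement error
    curve_wiggle_amp: float = 20.0            # ¹⁴C a
    curve_wiggle_len: float = 500.0           # a correlation length
    curve_sigma: float = 5.0                  # ¹⁴C a curve error
    n_proxies: int = 12
    distortion_cap: float = 150.0             # a, chronology error bound
    proxy_noise_sd: float = 0.5               # in latent SD units
    proxy_spacing: float = 40.0               # a mean sampling interval
    forcing_periods: tuple = (360.0, 500.0, 680.0)
    forcing_noise_sd: float = 0.3
    forcing_coupling: float = 0.0             # correlation with the latent
    grid_step: float = 5.0

    def to_dict(self) -> dict:
        return asdict(self)


def _smooth_noise(rng, t: np.ndarray, corr_len: float) -> np.ndarray:
    """Unit-variance smooth random series via interpolated control points."""
    span = abs(t[0] - t[-1])
    n_ctrl = max(int(span / corr_len) + 2, 4)
    ctrl_t = np.linspace(min(t[0], t[-1]) - corr_len,
                         max(t[0], t[-1]) + corr_len, n_ctrl)
    ctrl_v = rng.standard_normal(n_ctrl)
    v = np.interp(t, ctrl_t, ctrl_v)
    sd = v.std()
    return v / sd if sd > 0 else v


def make_calibration_curve(scenario: SyntheticScenario) -> CalibrationCurve:
    """Identity curve plus smooth random wiggles, kept strictly monotone.

    Wiggle draws that would break monotonicity of the cal→¹⁴C mapping
    are rejected and redrawn (with a final amplitude back-off as a
    safety valve for extreme settings).
    """
    rng = np.random.default_rng(scenario.seed)
    old, young = max(scenario.window), min(scenario.window)
    pad = 600.0
    grid = np.arange(young - pad, old + pad, 10.0)
    amp = scenario.curve_wiggle_amp
    for attempt in range(50):
        wig = amp * _smooth_noise(rng, grid, scenario.curve_wiggle_len) \
            if amp > 0 else np.zeros_like(grid)
        mu = grid + wig
        if np.all(np.diff(mu) > 0):
            break
        if attempt >= 25:
            amp *= 0.8
    else:
        raise ValueError("could not generate a monotone curve")
    sigma = np.full_like(grid, scenario.curve_sigma)
    return CalibrationCurve(grid, mu, sigma)


def make_population(scenario: SyntheticScenario):
    """True growth rate and the implied population trajectory.

    ``RGR(t) = trend + Σ A_p sin(2π·t/p + φ_p)`` with phases drawn from
    the seed; the population is the cumulative exponential of RGR along
    forward time.  Returns ``(population, true_rgr)`` on the scenario
    grid.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    old, young = max(scenario.window), min(scenario.window)
    step = scenario.grid_step
    n = int(np.floor((old - young) / step)) + 1
    t = old - step * np.arange(n)
    growth = np.full(n, scenario.trend_rate)
    for p, a in zip(scenario.cycle_periods, scenario.cycle_amplitudes):
        phi = rng.uniform(0, 2 * np.pi)
        growth += a * np.sin(2 * np.pi * t / p + phi)
    # integrate forward in time (decreasing cal BP)
    log_pop = np.concatenate([[0.0], np.cumsum(growth[:-1]) * step])
    if log_pop.max() - log_pop.min() > 50:
        raise ValueError("population overflow: reduce amplitudes or trend")
    pop = np.exp(log_pop - log_pop.max())
    return (GridSeries(t0=float(t[0]), step=step, values=pop, label="population"),
            GridSeries(t0=float(t[0]), step=step, values=growth, label="true RGR"))


def _site_layout(rng, scenario: SyntheticScenario):
    """Clustered site coordinates: mixture of 2-D Gaussians."""
    centers = np.column_stack([
        rng.uniform(*scenario.lon_range, scenario.n_clusters),
        rng.uniform(*scenario.lat_range, scenario.n_clusters)])
    which = rng.integers(0, scenario.n_clusters, scenario.n_sites)
    coords = centers[which] + rng.normal(0, scenario.cluster_sd_deg,
                                         (scenario.n_sites, 2))
    coords[:, 0] = np.clip(coords[:, 0], -179.9, 179.9)
    coords[:, 1] = np.clip(coords[:, 1], -89.9, 89.9)
    return coords


def sample_dates(population: GridSeries, curve: CalibrationCurve,
                 scenario: SyntheticScenario) -> list[RadiocarbonDate]:
    """Draw radiocarbon dates in proportion to the population trajectory.

    Calendar ages are sampled by inverse transform on the population
    density, mapped through the curve, and blurred with Gaussian lab
    error; each date is attached to a random site from a clustered
    layout.
    """
    if scenario.n_dates < 1:
        raise ValueError("n_dates must be at least 1")
    rng = np.random.default_rng(scenario.seed + 2)
    t = population.times
    p = np.clip(population.values, 0, None)
    if p.sum() <= 0:
        raise ValueError("population is identically zero")
    cdf = np.cumsum(p)
    cdf = cdf / cdf[-1]
    u = rng.random(scenario.n_dates)
    idx = np.searchsorted(cdf, u)
    # jitter within the bin so ages are continuous
    cal_ages = t[np.minimum(idx, len(t) - 1)] + \
        rng.uniform(-population.step / 2, population.step / 2, scenario.n_dates)
    c14 = curve.mu(cal_ages) + rng.normal(0, scenario.lab_sd, scenario.n_dates)
    coords = _site_layout(rng, scenario)
    site_of = rng.integers(0, scenario.n_sites, scenario.n_dates)
    dates = []
    for i in range(scenario.n_dates):
        s = site_of[i]
        dates.append(RadiocarbonDate(
            lab_id=f"SYN-{i:06d}", c14_age=float(c14[i]),
            c14_sd=float(scenario.lab_sd),
            lon=float(coords[s, 0]), lat=float(coords[s, 1]),
            site_id=f"site{s:04d}"))
    return dates


def _latent_signal(rng, t: np.ndarray, periods) -> np.ndarray:
    out = np.zeros_like(t)
    for p in periods:
        phi = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * t / p + phi)
    out += 0.4 * _smooth_noise(rng, t, 1000.0)
    return (out - out.mean()) / out.std()


def make_proxies(scenario: SyntheticScenario):
    """A proxy ensemble sharing one latent signal.

    Each record reads the latent at chronologically distorted times —
    ``value_k = loading · latent(T_k + δ(T_k)) + ε_k`` — with δ a smooth
    random drift bounded by ``distortion_cap`` (spline-like, emulating
    age-model error rather than white jitter) and ε white noise.
    Returns ``(records, latent GridSeries, true distortion per record)``
    so alignment recovery can be scored against the truth.
    """
    if scenario.n_proxies < 3:
        raise ValueError("need at least 3 proxies")
    if scenario.distortion_cap < 0:
        raise ValueError("distortion cap must be non-negative")
    rng = np.random.default_rng(scenario.seed + 3)
    old, young = max(scenario.window), min(scenario.window)
    fine_t = old - 5.0 * np.arange(int((old - young) / 5.0) + 1)
    latent_vals = _latent_signal(rng, fine_t, scenario.forcing_periods)
    latent = GridSeries(t0=float(fine_t[0]), step=5.0, values=latent_vals,
                        label="latent climate")

    records, distortions = [], []
    for i in range(scenario.n_proxies):
        n_pts = int((old - young) / scenario.proxy_spacing)
        times = np.sort(young + (old - young) *
                        (np.arange(n_pts) + rng.uniform(0.2, 0.8, n_pts)) / n_pts)
        times = np.unique(times)
        raw = scenario.distortion_cap * _smooth_noise(rng, times, 1500.0) * 0.6
        delta = np.clip(raw, -scenario.distortion_cap, scenario.distortion_cap)
        loading = rng.uniform(0.6, 1.4) * rng.choice([-1.0, 1.0], p=[0.2, 0.8])
        vals = loading * latent.value_at(np.clip(times + delta, young, old),
                                         extrapolate=True)
        vals = np.asarray(vals) + rng.normal(0, scenario.proxy_noise_sd,
                                             len(times))
        records.append(ProxyRecord(id=f"proxy{i:02d}", times=times, values=vals))
        distortions.append(delta)
    return records, latent, distortions


def make_forcing(scenario: SyntheticScenario,
                 latent: GridSeries | None = None) -> GridSeries:
    """Solar-like forcing: sinusoids at the configured periods plus red
    noise, optionally mixed with the proxy latent at the configured
    coupling (coupling 1 with zero noise reproduces the latent up to
    scale)."""
    rng = np.random.default_rng(scenario.seed + 4)
    old, young = max(scenario.window), min(scenario.window)
    step = scenario.grid_step
    n = int(np.floor((old - young) / step)) + 1
    t = old - step * np.arange(n)
    own = _latent_signal(rng, t, scenario.forcing_periods)
    if scenario.forcing_noise_sd > 0:
        ar = np.zeros(n)
        e = rng.normal(0, 1, n)
        for i in range(1, n):
            ar[i] = 0.9 * ar[i - 1] + e[i]
        ar = (ar - ar.mean()) / ar.std()
        own = own + scenario.forcing_noise_sd * ar
        own = (own - own.mean()) / own.std()
    c = scenario.forcing_coupling
    if latent is not None and c != 0:
        lat = latent.value_at(t, extrapolate=True)
        lat = (lat - lat.mean()) / lat.std()
        own = c * lat + np.sqrt(max(1 - c ** 2, 0.0)) * own
    return GridSeries(t0=float(t[0]), step=step, values=own, label="forcing")
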