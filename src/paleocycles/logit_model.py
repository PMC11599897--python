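"""Logistic boom/bust regression: endogenous lag plus exogenous climate terms.

Booms and busts are defined by the sign of the (preprocessed) relative
growth rate.  Three model variants predict the probability of a boom at
each 100 a slice:

* ``1V`` — endogenous only: the growth rate itself, shifted back in time
  by 350 a before 7 ka BP and 210 a thereafter (a boom follows a bust
  after a finite lag, and vice versa);
* ``2V`` — exogenous only: the climate-stability index and the
  sign-reversed solar irradiance;
* ``3V`` — all three inputs.

The hindcast reported downstream is the probability of a boom minus that
of a bust, ``2·p̂ − 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .grids import GridSeries

__all__ = [
    "VARIANT_INPUTS",
    "LogitModel",
    "label_boom_bust",
    "lagged_rgr",
    "fit_boom_bust_logit",
    "predict_boom_minus_bust",
]

log = logging.getLogger(__name__)

LAG_BREAK = 7000.0   # cal BP; older slices use the longer lag
LAG_EARLY = 350.0    # years, before 7 ka BP
LAG_LATE = 210.0     # years, after 7 ka BP

#: design of each model variant
VARIANT_INPUTS = {
    "1V": ("lagged_rgr",),
    "2V": ("stability", "tsi"),
    "3V": ("lagged_rgr", "stability", "tsi"),
}


@dataclass
class LogitModel:
    variant: str
    input_names: tuple
    params: np.ndarray        # intercept first, then one per input
    bse: np.ndarray           # standard errors, same order
    llf: float                # log-likelihood at the optimum
    n_obs: int
    ridge: bool = False       # whether the separation fallback was used
    diagnostics: dict = field(default_factory=dict)


def label_boom_bust(rgr: GridSeries) -> GridSeries:
    """Binary labels from the sign of the growth rate: boom = 1 where
    RGR > 0, bust = 0 where RGR < 0; exact zeros (and NaNs) stay NaN so
    they are dropped from fitting."""
    v = rgr.values
    out = np.full(len(v), np.nan)
    out[v > 0] = 1.0
    out[v < 0] = 0.0
    return GridSeries(t0=rgr.t0, step=rgr.step, values=out,
                      label="boom/bust")


def lagged_rgr(rgr: GridSeries, break_time: float = LAG_BREAK,
               lag_early: float = LAG_EARLY,
               lag_late: float = LAG_LATE) -> GridSeries:
    """Growth rate read at an earlier (older) time.

    The value at slice t is RGR at ``t + lag`` cal BP, with the lag
    switching from ``lag_early`` to ``lag_late`` at ``break_time``;
    linear interpolation between slices, NaN where the lagged time falls
    outside the series support.
    """
    t = rgr.times
    lag = np.where(t > break_time, lag_early, lag_late)
    src = t + lag
    tt = rgr.times[::-1]
    vv = rgr.values[::-1]
    out = np.interp(src, tt, vv, left=np.nan, right=np.nan)
    # NaN bins in the source poison interpolation only locally; mask
    # any lagged read that lands within one step of an undefined bin
    if np.isnan(rgr.values).any():
        bad = rgr.times[np.isnan(rgr.values)]
        for tb in bad:
            out[np.abs(src - tb) < rgr.step] = np.nan
    return GridSeries(t0=rgr.t0, step=rgr.step, values=out,
                      label="lagged RGR")


def _design(variant: str, inputs: dict) -> tuple[np.ndarray, tuple]:
    if variant not in VARIANT_INPUTS:
        raise ValueError(f"unknown variant {variant!r}")
    names = VARIANT_INPUTS[variant]
    missing = [n for n in names if n not in inputs]
    if missing:
        raise KeyError(f"variant {variant} requires input(s) {missing}")
    cols = [np.asarray(inputs[n].values, dtype=float) for n in names]
    return np.column_stack(cols), names


def _ridge_irls(X: np.ndarray, y: np.ndarray, alpha: float = 1e-6,
                max_iter: int = 100, tol: float = 1e-10):
    """Ridge-stabilized iteratively reweighted least squares for the
    logistic likelihood; used when the MLE does not exist (separation)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = X.T @ (X * w[:, None]) + alpha * np.eye(p)
        new = np.linalg.solve(A, X.T @ (w * z))
        if np.abs(new - beta).max() < tol:
            beta = new
            break
        beta = new
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + alpha * np.eye(X.shape[1]))
    return beta, np.sqrt(np.diag(cov)), llf


def fit_boom_bust_logit(variant: str, inputs: dict,
                        labels: GridSeries) -> LogitModel:
    """Maximum-likelihood logistic fit of boom probability.

    ``inputs`` maps input names (``lagged_rgr``, ``stability``, ``tsi``)
    to preprocessed series on the label grid; bins where any input or
    the label is undefined are dropped listwise.  Perfect separation
    triggers a ridge-stabilized refit (penalty 10⁻⁶) with a warning.
    """
    X, names = _design(variant, inputs)
    y = np.asarray(labels.values, dtype=float)
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    Xm = sm.add_constant(X[mask], has_constant="add")
    ym = y[mask]
    if len(ym) < Xm.shape[1] + 2:
        raise ValueError("too few defined bins to fit")
    ridge = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(ym, Xm).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False) or \
                not np.all(np.isfinite(res.bse)):
            raise RuntimeError("non-finite fit")
        params, bse, llf = res.params, res.bse, float(res.llf)
    except Exception:
        log.warning("fit_boom_bust_logit(%s): separation or non-convergence, "
                    "ridge-stabilized refit", variant)
        params, bse, llf = _ridge_irls(Xm, ym)
        ridge = True
    return LogitModel(variant=variant, input_names=names,
                      params=np.asarray(params), bse=np.asarray(bse),
                      llf=llf, n_obs=int(mask.sum()), ridge=ridge)


def predict_boom_minus_bust(model: LogitModel, inputs: dict) -> GridSeries:
    """Hindcast ``2·p̂ − 1`` on the input grid: +1 certain boom, −1
    certain bust, NaN where any input is undefined."""
    X, _ = _design(model.variant, inputs)
    grid = inputs[model.input_names[0]]
    out = np.full(X.shape[0], np.nan)
    mask = np.all(np.isfinite(X), axis=1)
    eta = model.params[0] + X[mask] @ model.params[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    out[mask] = 2.0 * p - 1.0
    return GridSeries(t0=grid.t0, step=grid.step, values=out,
                      label=f"{model.variant} hindcast")
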