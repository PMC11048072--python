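"""Convert sampled fed-batch measurements into cell-specific rates.

Pipeline: robust outlier replacement (moving-median / MAD rule) ->
LOWESS smoothing (tricube-weighted local linear regression, one pass) ->
interval mass balances converting concentrations [mmol/L] to specific rates
q [umol/g_DW/h] with feed and bolus correction. Consumption is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .kinetics import FeedSchedule

__all__ = [
    "CultureTimeSeries",
    "SpecificFluxSeries",
    "PreprocessError",
    "DW_PER_CELL",
    "remove_outliers",
    "smooth_lowess",
    "smooth_series",
    "concentrations_to_fluxes",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_flux_csv",
]

#: default cell dry weight [g/cell]
DW_PER_CELL = 250e-12


class PreprocessError(ValueError):
    pass


@dataclass
class CultureTimeSeries:
    """Offline fed-batch measurements on a common sampling grid.

    time [h] strictly increasing; concentrations [mmol/L]; vcd [cells/L];
    viability fraction; titer [g/L]; volume [L].
    """

    time: np.ndarray
    concentrations: pd.DataFrame
    vcd: np.ndarray
    viability: np.ndarray
    titer: np.ndarray
    volume: np.ndarray
    feed: FeedSchedule | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise PreprocessError("time must be strictly increasing")
        n = len(self.time)
        for name in ("vcd", "viability", "titer", "volume"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise PreprocessError(f"{name} length != time length")
            setattr(self, name, arr)
        if len(self.concentrations) != n:
            raise PreprocessError("concentrations length != time length")
        if np.any(self.vcd < 0):
            raise PreprocessError("vcd must be >= 0")
        if np.any((self.viability < 0) | (self.viability > 1)):
            raise PreprocessError("viability must lie in [0, 1]")
        if np.any(self.volume <= 0):
            raise PreprocessError("volume must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def copy(self) -> "CultureTimeSeries":
        return CultureTimeSeries(
            self.time.copy(),
            self.concentrations.copy(),
            self.vcd.copy(),
            self.viability.copy(),
            self.titer.copy(),
            self.volume.copy(),
            self.feed,
        )


@dataclass
class SpecificFluxSeries:
    """Cell-specific rates on interval midpoints.

    q [umol/g_DW/h] per metabolite (consumption negative), mu [1/h],
    qp [mg/g_DW/h].
    """

    time: np.ndarray
    q: pd.DataFrame
    mu: np.ndarray
    qp: np.ndarray


# ---------------------------------------------------------------------------
# outlier handling


def _moving_median(y: np.ndarray, window: int = 5) -> np.ndarray:
    # odd-reflection padding keeps linear trends unbiased at the edges
    half = window // 2
    left = 2 * y[0] - y[1 : half + 1][::-1]
    right = 2 * y[-1] - y[-half - 1 : -1][::-1]
    yp = np.concatenate([left, y, right])
    out = np.empty_like(y)
    for i in range(len(y)):
        out[i] = np.median(yp[i : i + window])
    return out


def flag_outliers(y: np.ndarray, z_max: float = 4.0, window: int = 5) -> np.ndarray:
    """Hampel identifier: flag points deviating more than z_max robust SDs
    (window-local MAD scale) from the moving median."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise PreprocessError("need >= 5 points for outlier detection")
    half = window // 2
    left = 2 * y[0] - y[1 : half + 1][::-1]
    right = 2 * y[-1] - y[-half - 1 : -1][::-1]
    yp = np.concatenate([left, y, right])
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        w = yp[i : i + window]
        m = np.median(w)
        scale = 1.4826 * np.median(np.abs(w - m))
        if scale <= 0:
            continue  # locally constant window: nothing to flag
        flagged[i] = abs(y[i] - m) > z_max * scale
    return flagged


def _replace_flagged(t: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return y.copy()
    out = y.copy()
    good = ~mask
    out[mask] = np.interp(t[mask], t[good], y[good])
    return out


def remove_outliers(
    series: CultureTimeSeries, z_max: float = 4.0, window: int = 5
) -> tuple[CultureTimeSeries, int]:
    """Replace spike outliers by interpolation; returns (cleaned, n_replaced)."""
    out = series.copy()
    n_replaced = 0
    for col in out.concentrations.columns:
        y = out.concentrations[col].to_numpy(dtype=float)
        mask = flag_outliers(y, z_max, window)
        n_replaced += int(mask.sum())
        out.concentrations[col] = _replace_flagged(out.time, y, mask)
    for name in ("vcd", "titer"):
        y = getattr(out, name)
        mask = flag_outliers(y, z_max, window)
        n_replaced += int(mask.sum())
        setattr(out, name, _replace_flagged(out.time, y, mask))
    return out, n_replaced


# ---------------------------------------------------------------------------
# LOWESS


def smooth_lowess(t: np.ndarray, y: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated at the input times.

    One pass, no robustifying reweighting (series are short).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise PreprocessError("need >= 3 points for LOWESS")
    if not 0 < frac <= 1:
        raise PreprocessError("frac must be in (0, 1]")
    if int(frac * len(t)) < 2:
        raise PreprocessError("frac too small: local window has < 2 points")
    return _sm_lowess(y, t, frac=frac, it=0, return_sorted=False)


def smooth_series(series: CultureTimeSeries, frac: float = 0.5) -> CultureTimeSeries:
    """LOWESS-smooth all concentration columns, vcd and titer."""
    out = series.copy()
    for col in out.concentrations.columns:
        out.concentrations[col] = smooth_lowess(
            out.time, out.concentrations[col].to_numpy(dtype=float), frac
        )
    out.vcd = np.maximum(smooth_lowess(out.time, out.vcd, frac), 0.0)
    out.titer = np.maximum(smooth_lowess(out.time, out.titer, frac), 0.0)
    return out


# ---------------------------------------------------------------------------
# concentration -> flux conversion


def concentrations_to_fluxes(
    series: CultureTimeSeries,
    dw_per_cell: float = DW_PER_CELL,
) -> SpecificFluxSeries:
    """Interval mass balances on smoothed series.

    For each sampling interval [t_k, t_k+1]:
        q = [d(C V)/dt - F C_feed - boluses/dt] / (X_dw V)    [mmol/g_DW/h]
    reported in umol/g_DW/h at the interval midpoint. X_dw V is the mean
    biomass [g] over the interval; mu and qp follow analogously from vcd
    and titer.
    """
    t = series.time
    V = series.volume
    feed = series.feed or FeedSchedule()
    n = len(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    dt = np.diff(t)

    x_dw = series.vcd * dw_per_cell  # g/L
    grams = 0.5 * (x_dw[:-1] * V[:-1] + x_dw[1:] * V[1:])
    if np.any(grams <= 0):
        raise PreprocessError("zero biomass in an interval; cannot form specific rates")

    def bolus_amount(name: str) -> np.ndarray:
        amounts = np.zeros(n - 1)
        for b in feed.boluses:
            k = np.searchsorted(t, b.time, side="left") - 1
            if 0 <= k < n - 1:
                amounts[k] += b.volume * b.composition.get(name, 0.0)
        return amounts

    qcols = {}
    for col in series.concentrations.columns:
        c = series.concentrations[col].to_numpy(dtype=float)
        cv = c * V
        dcv = np.diff(cv) / dt  # mmol/h
        f_in = np.array([feed.rate(tm) for tm in t_mid]) * feed.feed_conc(col)
        b_in = bolus_amount(col) / dt
        qcols[col] = (dcv - f_in - b_in) / grams * 1000.0  # umol/g/h

    xtot = x_dw * V
    mu = np.diff(np.log(np.maximum(xtot, 1e-300))) / dt
    pv = series.titer * V  # g
    qp = np.diff(pv) / dt / grams * 1000.0  # mg/g/h

    return SpecificFluxSeries(
        time=t_mid, q=pd.DataFrame(qcols, index=t_mid), mu=mu, qp=qp
    )


# ---------------------------------------------------------------------------
# tidy CSV I/O


def write_timeseries_csv(series: CultureTimeSeries, path) -> None:
    rows = []
    units = {"vcd": "cells/L", "viability": "fraction", "titer": "g/L", "volume": "L"}
    for k, tk in enumerate(series.time):
        for col in series.concentrations.columns:
            rows.append((tk, f"conc:{col}", series.concentrations[col].iloc[k], "mmol/L"))
        for name, unit in units.items():
            rows.append((tk, name, getattr(series, name)[k], unit))
    pd.DataFrame(rows, columns=["time_h", "variable", "value", "unit"]).to_csv(
        path, index=False
    )


def read_timeseries_csv(path, feed: FeedSchedule | None = None) -> CultureTimeSeries:
    df = pd.read_csv(path)
    wide = df.pivot(index="time_h", columns="variable", values="value").sort_index()
    conc_cols = [c for c in wide.columns if c.startswith("conc:")]
    conc = wide[conc_cols].rename(columns={c: c.split(":", 1)[1] for c in conc_cols})
    return CultureTimeSeries(
        time=wide.index.to_numpy(),
        concentrations=conc.reset_index(drop=True),
        vcd=wide["vcd"].to_numpy(),
        viability=wide["viability"].to_numpy(),
        titer=wide["titer"].to_numpy(),
        volume=wide["volume"].to_numpy(),
        feed=feed,
    )


def write_flux_csv(flux: SpecificFluxSeries, path) -> None:
    rows = []
    for k, tk in enumerate(flux.time):
        for col in flux.q.columns:
            rows.append((tk, f"q:{col}", flux.q[col].iloc[k], "umol/gDW/h"))
        rows.append((tk, "mu", flux.mu[k], "1/h"))
        rows.append((tk, "qp", flux.qp[k], "mg/gDW/h"))
    pd.DataFrame(rows, columns=["time_h", "variable", "value", "unit"]).to_csv(
        path, index=False
    )
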