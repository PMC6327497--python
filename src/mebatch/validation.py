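"""Proteome mass fractions and lag-scanned cross-correlation.

Predicted proteome dynamics are compared against measured expression
time courses by (i) converting the simulation to protein mass fractions,
(ii) log2-transforming and resampling both sides onto a common uniform
grid, and (iii) scanning a lag window for the offset maximizing the
median per-protein Pearson correlation.  A positive best lag means the
measurements trail the simulation (predicted dynamics are faster than
observed).

Cross-correlation convention: for lag ``l`` (an integer multiple of the
grid interval) the correlation pairs (x_t, y_{t+l}) over the overlapping
support, with means and variances computed on that overlap (plain sample
Pearson correlation of the two shifted windows).  Conventions differ
between libraries; this one is pinned by the property suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "XCorrResult",
    "mass_fractions_translation",
    "mass_fractions_concentration",
    "log2_expression",
    "resample_profiles",
    "lagged_crosscorr",
    "best_common_lag",
]

DEFAULT_LAG_RANGE = (-1.7, 1.7)   # hours
DEFAULT_INTERVAL = 0.1            # hours
LOG2_FLOOR = 1e-6                 # mass fractions can be exactly 0


@dataclass
class XCorrResult:
    lags: np.ndarray                    # scanned lag grid, h
    median_by_lag: pd.Series            # median correlation per lag
    best_lag: float                     # h
    corr_at_best: pd.Series             # per-protein correlation at best lag
    median: float                       # median of corr_at_best


def _fractions(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    if np.any(values < 0):
        raise ValueError("abundances must be non-negative")
    if not np.all(weights > 0):
        raise ValueError("molecular weights must be positive")
    mass = values * weights
    total = mass.sum()
    if total <= 0:
        raise ValueError("all abundances are zero: mass fractions undefined")
    return mass / total


def mass_fractions_translation(v_trsl: Mapping[str, float] | pd.Series,
                               w: Mapping[str, float] | pd.Series) -> pd.Series:
    """f_j = v_trsl_j * w_j / sum_k v_trsl_k * w_k (free-proteome mode)."""
    v = pd.Series(v_trsl, dtype=float)
    wts = pd.Series(w, dtype=float).reindex(v.index)
    return pd.Series(_fractions(v.to_numpy(), wts.to_numpy()), index=v.index)


def mass_fractions_concentration(p: Mapping[str, float] | pd.Series,
                                 w: Mapping[str, float] | pd.Series) -> pd.Series:
    """f_j = p_j * w_j / sum_k p_k * w_k (inertia mode, p is a variable)."""
    return mass_fractions_translation(p, w)


def log2_expression(frame: pd.DataFrame | pd.Series,
                    floor: float = LOG2_FLOOR):
    """log2 transform with a floor for exact zeros."""
    return np.log2(frame.clip(lower=floor))


def resample_profiles(a: pd.Series | pd.DataFrame,
                      b: pd.Series | pd.DataFrame,
                      interval: float | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linearly interpolate two time-indexed profiles onto a common grid.

    The grid interval defaults to the smaller native sampling interval of
    the two inputs; the grid covers the overlap of their time supports.
    A series' native interval is its median time step, which is robust to
    occasional shortened steps from event-clipped simulation grids.
    """
    a = a.to_frame() if isinstance(a, pd.Series) else a
    b = b.to_frame() if isinstance(b, pd.Series) else b
    ta = a.index.to_numpy(dtype=float)
    tb = b.index.to_numpy(dtype=float)
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("each profile needs at least 2 timepoints")
    t0 = max(ta[0], tb[0])
    t1 = min(ta[-1], tb[-1])
    if t1 <= t0:
        raise ValueError("profiles have no overlapping time support")
    if interval is None:
        interval = float(min(np.median(np.diff(ta)), np.median(np.diff(tb))))
    n = int(np.floor((t1 - t0) / interval + 1e-9)) + 1
    grid = t0 + interval * np.arange(n)

    def _interp(df: pd.DataFrame, t: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {c: np.interp(grid, t, df[c].to_numpy(dtype=float))
             for c in df.columns}, index=grid)

    return _interp(a, ta), _interp(b, tb)


def lagged_crosscorr(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series,
                     lags: Sequence[int]) -> dict[int, float]:
    """Pearson correlation of (x_t, y_{t+l}) for each integer grid lag l.

    Zero variance of either window makes the correlation undefined for
    that lag; it is reported as NaN (missing), never as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share the grid")
    n = len(x)
    out: dict[int, float] = {}
    for lag in lags:
        lag = int(lag)
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        if len(xs) < 2:
            out[lag] = np.nan
            continue
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
        out[lag] = float(xs @ ys / denom) if denom > 0 else np.nan
    return out


def best_common_lag(sim: pd.DataFrame, measured: pd.DataFrame,
                    lag_range: tuple[float, float] = DEFAULT_LAG_RANGE,
                    interval: float | None = None) -> XCorrResult:
    """Scan a lag window for the offset maximizing the median correlation.

    ``sim`` holds simulated (log2) expression profiles and ``measured``
    the measured ones (log2-transformed upstream), both time-indexed with
    proteins as columns.  Both are resampled onto a common uniform grid,
    then one common lag over ``lag_range`` (default -1.7..1.7 h) is
    chosen to maximize the median per-protein correlation; proteins with
    undefined correlation at a lag are ignored in that median.  Ties go
    to the smallest |lag| (then to the negative one).
    """
    shared = [c for c in sim.columns if c in set(measured.columns)]
    if not shared:
        raise ValueError("no shared proteins between simulation and data")
    s, m = resample_profiles(sim[shared], measured[shared], interval)
    dt = float(s.index[1] - s.index[0])
    k_min = int(np.ceil(lag_range[0] / dt - 1e-9))
    k_max = int(np.floor(lag_range[1] / dt + 1e-9))
    ks = list(range(k_min, k_max + 1))

    per_protein = {
        prot: lagged_crosscorr(s[prot], m[prot], ks) for prot in shared
    }
    medians = {}
    for k in ks:
        vals = [per_protein[p][k] for p in shared]
        vals = [v for v in vals if np.isfinite(v)]
        medians[k] = float(np.median(vals)) if vals else np.nan
    med = pd.Series(medians)
    if med.isna().all():
        raise ValueError("correlation undefined at every lag")
    best = max((k for k in ks if np.isfinite(med[k])),
               key=lambda k: (med[k], -abs(k), -k))
    corr_best = pd.Series({p: per_protein[p][best] for p in shared})
    finite = corr_best[np.isfinite(corr_best)]
    lags_h = np.array(ks, dtype=float) * dt
    med.index = lags_h
    return XCorrResult(lags=lags_h, median_by_lag=med,
                       best_lag=float(best * dt), corr_at_best=corr_best,
                       median=float(np.median(finite)))
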