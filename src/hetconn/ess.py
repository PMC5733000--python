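"""Effective sample size of temporally dependent timeseries, and thinning.

An fMRI parcel timeseries is autocorrelated in time, so its ``N`` rows are
worth fewer than ``N`` independent observations.  The effective sample size
of component ``j`` is

    ESS_j = N / (1 + 2 * sum_t rho_j(t)),

with ``rho_j(t)`` the lag-``t`` autocorrelation, and the overall ESS is the
conservative minimum over components.  The infinite sum is truncated with
Geyer's initial-positive-sequence rule: consecutive lag pairs are summed and
accumulation stops at the first non-positive pair sum, which keeps the
estimator from drowning in autocorrelation noise at large lags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .data_io import TimeseriesMatrix

__all__ = [
    "EssResult",
    "sample_autocorrelation",
    "effective_sample_size",
    "study_ess",
    "thin",
]

DEFAULT_MAX_LAG = 2000


@dataclass(frozen=True)
class EssResult:
    """Effective sample size of one multivariate timeseries.

    ``n_effective`` is ``floor(min_j ESS_j)`` clamped to ``[1, N]``;
    ``per_component_ess`` keeps the unclamped per-parcel values.
    """

    n_effective: int
    per_component_ess: np.ndarray
    max_lag_used: int


def sample_autocorrelation(series: Sequence[float], max_lag: int) -> np.ndarray:
    """Sample autocorrelations at lags ``1..max_lag`` (FFT-based).

    A constant series has undefined autocorrelation; NaNs are returned and
    interpreted downstream as perfect dependence (ESS of 1).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with N >= 3")
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the series length")
    if np.ptp(x) == 0.0:
        return np.full(max_lag, np.nan)
    rho = _sm_acf(x, nlags=max_lag, fft=True)[1:]
    return np.clip(rho, -1.0, 1.0)


def _ess_from_acf(rho: np.ndarray, n: int) -> float:
    """Plug autocorrelations (lags 1..L) into the ESS formula.

    Uses Geyer pairing on (rho_0 + rho_1), (rho_2 + rho_3), ... where
    rho_0 = 1; the running sum stops before the first non-positive pair.
    Exposed separately so closed-form autocorrelation functions can be
    plugged in directly.
    """
    if not np.all(np.isfinite(rho)):
        return 1.0
    padded = np.concatenate([[1.0], rho])
    if padded.size % 2 == 1:
        padded = np.concatenate([padded, [0.0]])
    pair_sums = padded[0::2] + padded[1::2]
    keep = np.nonzero(pair_sums <= 0.0)[0]
    stop = keep[0] if keep.size else pair_sums.size
    tau = max(2.0 * np.sum(pair_sums[:stop]) - 1.0, 1.0 / n)
    return n / tau


def effective_sample_size(
    ts: TimeseriesMatrix, max_lag: int | None = None
) -> EssResult:
    """Component-wise ESS with the minimum taken over parcels.

    Expects a centered series with ``N >= 10``.  A degenerate (constant)
    component forces ``n_effective = 1``; negative autocorrelation can push a
    component's ESS above ``N``, in which case it is clamped to ``N`` because
    thinning cannot exceed the available time points.
    """
    n = ts.n_timepoints
    if n < 10:
        raise ValueError("need at least 10 time points for ESS estimation")
    lag = min(max_lag if max_lag is not None else DEFAULT_MAX_LAG, n - 1)
    per = np.array(
        [
            _ess_from_acf(sample_autocorrelation(ts.values[:, j], lag), n)
            for j in range(ts.n_parcels)
        ]
    )
    n_eff = int(np.floor(np.min(per)))
    return EssResult(
        n_effective=int(np.clip(n_eff, 1, n)),
        per_component_ess=per,
        max_lag_used=lag,
    )


def study_ess(
    series: Sequence[TimeseriesMatrix], max_lag: int | None = None
) -> int:
    """Study-wide thinning count: the minimum ``n_effective`` over subjects."""
    if not series:
        raise ValueError("no timeseries supplied")
    return min(effective_sample_size(ts, max_lag).n_effective for ts in series)


def thin(ts: TimeseriesMatrix, n: int) -> TimeseriesMatrix:
    """Keep ``n`` evenly spaced rows starting at the first time point.

    Row ``i`` of the result is row ``floor(i * N / n)`` of the input, so the
    subsample spans the run while preserving temporal order.
    """
    big_n = ts.n_timepoints
    if not 1 <= n <= big_n:
        raise ValueError(f"thinning count {n} outside [1, {big_n}]")
    idx = (np.arange(n) * big_n) // n
    return replace(ts, values=ts.values[idx])
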