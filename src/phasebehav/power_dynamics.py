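"""Time-lagged cross-correlation between the band-power time courses of two
area clusters.

A directed power-power (amplitude-envelope) interaction shows up as a lagged
peak: if the fronto-central beta envelope leads the occipital one by L ms, the
correlation between fronto-central power at window w and occipital power at
window w + L/step peaks at lag +L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import PowerTimecourse
from .inference import nearest_rank_percentile

__all__ = ["LagCorrelation", "lagged_power_correlation"]


@dataclass
class LagCorrelation:
    lags_ms: np.ndarray
    r: np.ndarray
    peak_lag_ms: float
    lo_threshold: np.ndarray | None = None   # per-lag (max-corrected, constant)
    hi_threshold: np.ndarray | None = None
    n_surrogates: int = 0


def _pooled_corr(a: np.ndarray, b: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """r(lag) pooling (trial x overlapping-window) points; a leads b at
    positive lags."""
    n_win = a.shape[0]
    out = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            aw = a[: n_win - lag]
            bw = b[lag:]
        else:
            aw = a[-lag:]
            bw = b[: n_win + lag]
        x = aw.ravel()
        y = bw.ravel()
        out[i] = np.corrcoef(x, y)[0, 1]
    return out


def lagged_power_correlation(pc_a: PowerTimecourse, pc_b: PowerTimecourse,
                             log_transform: bool = True,
                             n_surrogates: int = 0,
                             rng: np.random.Generator | None = None,
                             step_ms: float = 4.0) -> LagCorrelation:
    """Cross-correlation of two cluster power time courses as a function of
    window lag.

    Powers are averaged over each input's sites, log-transformed by default
    (stabilizes the variance of the skewed power distribution), and correlated
    across pooled (trial, window) points for every lag from -(W-1) to W-1
    windows.  ``peak_lag_ms`` is the argmax lag in ms (positive: the first
    operand leads).  With ``n_surrogates`` > 0, trial-shuffled surrogates of
    the second operand provide max-corrected two-sided thresholds.
    """
    if pc_a.power.shape[1] != pc_b.power.shape[1] or \
            not np.allclose(pc_a.window_centers, pc_b.window_centers):
        raise ValueError("power time courses must share the window layout")
    a = pc_a.power.mean(axis=0)           # window x trial
    b = pc_b.power.mean(axis=0)
    if log_transform:
        a = np.log(a)
        b = np.log(b)
    n_win = a.shape[0]
    lags = np.arange(-(n_win - 1), n_win)
    r = _pooled_corr(a, b, lags)
    peak = float(lags[int(np.nanargmax(r))] * step_ms)

    lo = hi = None
    if n_surrogates > 0:
        rng = np.random.default_rng() if rng is None else rng
        mins = np.empty(n_surrogates)
        maxs = np.empty(n_surrogates)
        for s in range(n_surrogates):
            perm = rng.permutation(b.shape[1])
            rs = _pooled_corr(a, b[:, perm], lags)
            mins[s] = rs.min()
            maxs[s] = rs.max()
        lo = np.full(len(lags), nearest_rank_percentile(mins, 2.5))
        hi = np.full(len(lags), nearest_rank_percentile(maxs, 97.5))
    return LagCorrelation(lags_ms=lags * step_ms, r=r, peak_lag_ms=peak,
                          lo_threshold=lo, hi_threshold=hi,
                          n_surrogates=n_surrogates)
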