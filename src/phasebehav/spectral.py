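"""Fourier analysis of epochs: Hann-tapered zero-padded FFT, power spectra,
aperiodic (1/f) removal, and sliding-window band power.

All spectral estimates share one convention: the epoch is multiplied by a Hann
taper of its own length, zero-padded to 1 s, and Fourier transformed, which
puts every spectrum on a 1 Hz grid; analyses use the 1–95 Hz range unless a
caller asks for the full grid (needed for spectral factorization) or for the
>100 Hz artifact scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .synthgen import SessionRecording
from .preprocess import EpochSet

__all__ = [
    "SpectralFrame",
    "PowerSpectrum",
    "PowerTimecourse",
    "fft_epochs",
    "power_spectra",
    "remove_aperiodic",
    "sliding_band_power",
    "PAD_SECONDS",
    "DEFAULT_FREQ_RANGE",
]

PAD_SECONDS = 1.0
DEFAULT_FREQ_RANGE = (1.0, 95.0)


@dataclass
class SpectralFrame:
    """Complex Fourier coefficients, site x frequency x trial."""

    coeff: np.ndarray
    freqs: np.ndarray             # Hz, strictly increasing
    taper: str = "hann"
    epoch_window: tuple = (-200.0, 0.0)

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.coeff)):
            raise ValueError("non-finite Fourier coefficients")

    def select(self, fmin: float, fmax: float) -> "SpectralFrame":
        m = (self.freqs >= fmin) & (self.freqs <= fmax)
        return SpectralFrame(self.coeff[:, m, :], self.freqs[m],
                             self.taper, self.epoch_window)

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 0.5:
            raise ValueError(f"frequency {f} Hz not on the grid")
        return i

    @property
    def n_trials(self) -> int:
        return self.coeff.shape[2]


@dataclass
class PowerSpectrum:
    power: np.ndarray             # site x frequency (x trial if not averaged)
    freqs: np.ndarray
    aperiodic_removed: bool = False
    #: per-site (offset, exponent) of the log-log aperiodic fit, if removed
    aperiodic_params: np.ndarray | None = None

    def __post_init__(self):
        if not self.aperiodic_removed and np.any(self.power < 0):
            raise ValueError("raw power must be nonnegative")


@dataclass
class PowerTimecourse:
    power: np.ndarray             # site x window x trial
    window_centers: np.ndarray    # ms relative to change onset
    band: tuple                   # (lo Hz, hi Hz)

    def __post_init__(self):
        if self.power.shape[1] != len(self.window_centers):
            raise ValueError("one center per window required")


# ---------------------------------------------------------------------------

def _taper_pad_fft(x: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-taper the time axis (next-to-last), zero-pad to 1 s, rfft."""
    n = x.shape[-2]
    pad_n = int(round(PAD_SECONDS * sample_rate))
    if n > pad_n:
        raise ValueError("epoch longer than the 1 s padding target")
    w = hann(n, sym=False)
    spec = np.fft.rfft(x * w[..., :, None], n=pad_n, axis=-2)
    freqs = np.fft.rfftfreq(pad_n, d=1.0 / sample_rate)
    return spec, freqs


def fft_epochs(epochs: EpochSet, fmin: float | None = DEFAULT_FREQ_RANGE[0],
               fmax: float | None = DEFAULT_FREQ_RANGE[1]) -> SpectralFrame:
    """Per site and trial: Hann taper, zero-pad to 1 s, FFT.

    The 1 s padding at 1 kHz puts coefficients on an exact 1 Hz grid; by
    default the 1–95 Hz bins are retained.  Pass ``fmin=None`` to keep the
    full 0–Nyquist grid (required by the Granger-causality stage) or e.g.
    ``fmin=101, fmax=200`` for the high-frequency artifact scan.
    """
    if not np.all(np.isfinite(epochs.signal)):
        raise ValueError("non-finite samples in epochs")
    spec, freqs = _taper_pad_fft(epochs.signal, epochs.sample_rate)
    frame = SpectralFrame(spec, freqs, taper="hann", epoch_window=epochs.window)
    if fmin is None:
        return frame
    return frame.select(fmin, 95.0 if fmax is None else fmax)


def power_spectra(frame: SpectralFrame, average: bool = True) -> PowerSpectrum:
    """Squared coefficient magnitudes; optionally averaged over trials."""
    p = np.abs(frame.coeff) ** 2
    if average:
        p = p.mean(axis=2)
    return PowerSpectrum(power=p, freqs=frame.freqs.copy())


def remove_aperiodic(spec: PowerSpectrum, threshold_sd: float = 2.5,
                     max_iter: int = 10) -> PowerSpectrum:
    """Fit and subtract the aperiodic (1/f) component in log-log space.

    Fixed-mode (knee-free) fit: log10(power) is regressed on log10(f) by
    ordinary least squares, iteratively excluding bins whose residual exceeds
    ``threshold_sd`` residual SDs above the fit (oscillatory peak bins), until
    the exclusion mask stabilizes.  The returned spectrum holds the residual
    in log10-power units (the flattened spectrum), so values may be negative;
    the fitted (offset, exponent) per site is stored in ``aperiodic_params``.
    """
    if spec.power.ndim != 2:
        raise ValueError("remove_aperiodic expects a trial-averaged spectrum")
    power = spec.power
    usable = power > 0
    if np.any(usable.sum(axis=1) < 10):
        raise ValueError("fewer than 10 usable (positive-power) bins")
    logf = np.log10(spec.freqs)
    resid = np.empty_like(power)
    params = np.empty((power.shape[0], 2))
    for s in range(power.shape[0]):
        m = usable[s]
        logp = np.log10(power[s, m])
        x = logf[m]
        mask = np.ones(len(x), dtype=bool)
        coef = None
        for _ in range(max_iter):
            coef = np.polyfit(x[mask], logp[mask], 1)
            r = logp - np.polyval(coef, x)
            sd = r[mask].std()
            new_mask = r <= threshold_sd * (sd if sd > 0 else np.inf)
            if new_mask.sum() < 10 or np.array_equal(new_mask, mask):
                break
            mask = new_mask
        fit_all = np.polyval(coef, logf)
        full = np.full(power.shape[1], np.nan)
        full[m] = np.log10(power[s, m]) - fit_all[m]
        resid[s] = full
        params[s] = (coef[1], -coef[0])     # (offset, exponent)
    return PowerSpectrum(power=resid, freqs=spec.freqs.copy(),
                         aperiodic_removed=True, aperiodic_params=params)


def sliding_band_power(rec: SessionRecording, band: tuple = (14.0, 16.0),
                       keep: np.ndarray | None = None, n_windows: int = 50,
                       window_ms: float = 200.0, step_ms: float = 4.0,
                       start_ms: float = -400.0) -> PowerTimecourse:
    """Band power in sliding pre-change windows.

    Default layout: 50 windows of 200 ms shifted in 4 ms steps, the first
    covering [-400, -200] ms and the last [-200, 0] ms relative to the target
    change.  Each window is Hann tapered, zero-padded to 1 s, Fourier
    transformed, and |coeff|^2 averaged over the band's bins (default
    14–16 Hz, the band of the lagged beta-power interaction).
    """
    lo, hi = band
    if lo < 1.0 or hi > 95.0 or hi < lo:
        raise ValueError("band must lie within 1–95 Hz")
    fs = rec.sample_rate
    n_win = int(round(window_ms * fs / 1000.0))
    trial_index = np.arange(rec.n_trials) if keep is None else np.flatnonzero(keep)

    starts_ms = start_ms + step_ms * np.arange(n_windows)
    centers = starts_ms + window_ms / 2.0
    power = np.empty((rec.n_channels, n_windows, len(trial_index)))
    w = hann(n_win, sym=False)
    pad_n = int(round(PAD_SECONDS * fs))
    freqs = np.fft.rfftfreq(pad_n, d=1.0 / fs)
    bsel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    # zero-padding leaves the DFT a plain projection of the tapered window
    # onto the padded grid's exponentials; evaluate only the band bins
    n_ar = np.arange(n_win)
    basis = np.exp(-2j * np.pi * freqs[bsel][None, :] * n_ar[:, None] / fs) \
        * w[:, None]
    change_samp = np.round(rec.change_time * fs / 1000.0).astype(int)
    for k in range(n_windows):
        segs = np.empty((rec.n_channels, n_win, len(trial_index)))
        for j, tr in enumerate(trial_index):
            s0 = change_samp[tr] + int(round(starts_ms[k] * fs / 1000.0))
            if s0 < 0:
                raise ValueError(f"trial {tr} does not cover the window layout")
            segs[:, :, j] = rec.signal[:, s0:s0 + n_win, tr]
        spec = np.einsum("cnt,nb->cbt", segs, basis)
        power[:, k, :] = (np.abs(spec) ** 2).mean(axis=1)
    return PowerTimecourse(power=power, window_centers=centers, band=band)
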