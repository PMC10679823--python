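"""Single-trial phase relations, goodness of phase relation (GPR), and the
phase/power-to-behavior correlations.

The GPR of a trial is the cosine of the deviation of that trial's interareal
phase relation from the site pair's mean phase relation: +1 at the typical
phase relation, -1 opposite to it.  Averaging rotated phase relations over
site pairs (area-pair, cluster, and population levels) before taking the
cosine suppresses estimation noise and strengthens the GPR-RT correlation
without the inflation that trial binning would cause.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .spectral import SpectralFrame, PowerSpectrum
from .connectivity import ppc_spectrum

__all__ = [
    "PhaseRelationSeries",
    "GPRSeries",
    "phase_relations",
    "rotated_deviations",
    "gpr_series",
    "gpr_rt_correlation",
    "cross_cluster_gpr_correlation",
    "power_rt_correlation",
    "rt_quintile_ppc_contrast",
    "pearson_rows",
    "wrap_angle",
]

LEVELS = ("site-pair", "area-pair", "cluster", "population")


def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = (np.asarray(x) + np.pi) % (2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of y with each row-slice of x along the last axis.

    Degenerate (zero-variance) slices yield NaN rather than an error, since
    they are a legitimate limit (e.g. kappa -> infinity makes GPR constant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=-1))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return np.where(denom > 0, r, np.nan)


@dataclass
class PhaseRelationSeries:
    """Per-trial phase relation of one site pair at one frequency."""

    phi: np.ndarray           # radians, in (-pi, pi]
    rotated: bool
    mean_phase: float         # angle of the mean resultant vector (radians)
    pair: tuple = (0, 1)
    freq: float = np.nan

    def __post_init__(self):
        if np.any((self.phi <= -np.pi) | (self.phi > np.pi)):
            raise ValueError("phase relations must lie in (-pi, pi]")
        if self.rotated:
            resultant = np.exp(1j * self.phi).mean()
            if np.abs(np.angle(resultant)) > 1e-9 and np.abs(resultant) > 1e-12:
                raise ValueError("rotated series must have circular mean 0")


@dataclass
class GPRSeries:
    """Per-trial goodness of phase relation at some pooling level."""

    gpr: np.ndarray           # (n_freq, n_trials), each value in [-1, 1]
    freqs: np.ndarray
    level: str
    bands: tuple = ()

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if np.any(np.abs(self.gpr) > 1 + 1e-12):
            raise ValueError("GPR is a cosine and must lie in [-1, 1]")


# ---------------------------------------------------------------------------

def rotated_deviations(frame: SpectralFrame, pairs: list,
                       freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotated phase relations for many pairs and frequencies at once.

    Returns (deviations, mean_phases) with shapes
    (n_pairs, n_freqs, n_trials) and (n_pairs, n_freqs).  The deviation of a
    trial is its phase relation minus the pair's mean phase relation (angle of
    the mean resultant vector), wrapped to (-pi, pi].
    """
    fidx = np.array([frame.freq_index(f) for f in np.atleast_1d(freqs)])
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    z = frame.coeff[ia][:, fidx, :] * np.conj(frame.coeff[ib][:, fidx, :])
    if np.any(np.abs(z) == 0):
        bad = np.argwhere(np.abs(z) == 0)[0]
        raise ValueError(f"zero-amplitude coefficient in trial {bad[2]}: "
                         "phase undefined")
    phi = np.angle(z)
    mean_phase = np.angle(np.exp(1j * phi).mean(axis=2))
    dev = wrap_angle(phi - mean_phase[:, :, None])
    return dev, mean_phase


def phase_relations(frame: SpectralFrame, pair: tuple, freq: float,
                    rotate: bool = True) -> PhaseRelationSeries:
    """Phase-relation series of one site pair at one frequency.

    phi_t = angle(coeff_a(t) * conj(coeff_b(t))); the rotated series is
    wrap(phi - mean_phase) so its circular mean is zero.
    """
    dev, mean_phase = rotated_deviations(frame, [pair], np.array([freq]))
    if rotate:
        return PhaseRelationSeries(phi=dev[0, 0], rotated=True,
                                   mean_phase=float(mean_phase[0, 0]),
                                   pair=pair, freq=freq)
    z = frame.coeff[pair[0], frame.freq_index(freq), :] * \
        np.conj(frame.coeff[pair[1], frame.freq_index(freq), :])
    return PhaseRelationSeries(phi=wrap_angle(np.angle(z)), rotated=False,
                               mean_phase=float(mean_phase[0, 0]),
                               pair=pair, freq=freq)


def gpr_series(deviations: np.ndarray, level: str = "site-pair",
               freqs: np.ndarray | None = None, bands: tuple = (),
               circular_mean: bool = False) -> GPRSeries:
    """GPR from rotated deviations.

    ``deviations`` is (n_members, n_freq, n_trials): the rotated phase
    relations of the member site pairs.  At the site-pair level the single
    member's cosine is taken directly; at higher levels the rotated relations
    are first averaged over members per trial — by default as the arithmetic
    mean of the wrapped angles (the rotated deviations concentrate near zero,
    where this coincides with the circular mean; set ``circular_mean`` for the
    resultant-angle variant) — and the cosine of the average is the pooled GPR.
    """
    dev = np.asarray(deviations)
    if dev.ndim == 2:
        dev = dev[None]
    if dev.shape[0] == 0:
        raise ValueError("empty member set")
    if circular_mean:
        pooled = np.angle(np.exp(1j * dev).mean(axis=0))
    else:
        pooled = dev.mean(axis=0)
    gpr = np.cos(pooled)
    if freqs is None:
        freqs = np.arange(gpr.shape[0], dtype=float)
    return GPRSeries(gpr=gpr, freqs=np.asarray(freqs, dtype=float),
                     level=level, bands=bands)


def gpr_rt_correlation(gpr, rt: np.ndarray) -> np.ndarray:
    """Pearson correlation between GPR and RT across trials, per frequency.

    ``gpr`` is a GPRSeries or a list of them (site-pair level); for a list the
    correlation spectra are averaged over the members (site pairs).  Returns
    the correlation spectrum; zero-variance GPR yields NaN ("missing").
    """
    if isinstance(gpr, GPRSeries):
        if len(rt) < 10:
            raise ValueError("need at least 10 trials")
        return pearson_rows(gpr.gpr, rt)
    spectra = np.stack([gpr_rt_correlation(g, rt) for g in gpr])
    return np.nanmean(spectra, axis=0)


def cross_cluster_gpr_correlation(gpr_a: np.ndarray, gpr_b: np.ndarray,
                                  condition: np.ndarray,
                                  n_rand: int = 1000,
                                  rng: np.random.Generator | None = None) -> dict:
    """Across-trial Pearson correlation of two cluster-level GPR series,
    per condition, plus a permutation test on the IN-OUT difference."""
    from .inference import condition_permutation_test

    gpr_a = np.asarray(gpr_a, dtype=float)
    gpr_b = np.asarray(gpr_b, dtype=float)
    if gpr_a.shape != gpr_b.shape or len(gpr_a) != len(condition):
        raise ValueError("GPR series and condition labels must share trials")
    out = {}
    for cond in ("IN", "OUT"):
        m = condition == cond
        r, p = _stats.pearsonr(gpr_a[m], gpr_b[m])
        out[cond] = {"r": float(r), "p": float(p), "n": int(m.sum())}

    def stat(indices):
        return float(np.corrcoef(gpr_a[indices], gpr_b[indices])[0, 1])

    diff, z, p = condition_permutation_test(stat, condition, n_rand=n_rand,
                                            rng=rng)
    out["difference"] = {"in_minus_out": diff, "z": z, "p": p}
    return out


def power_rt_correlation(power: PowerSpectrum, rt: np.ndarray) -> np.ndarray:
    """Power-RT control: Pearson correlation between single-trial band power
    and RT per site and frequency, averaged over sites."""
    if power.power.ndim != 3:
        raise ValueError("per-trial power (site x freq x trial) required")
    r = pearson_rows(power.power, rt)          # site x freq
    return np.nanmean(r, axis=0)


def rt_quintile_ppc_contrast(frame: SpectralFrame, rt: np.ndarray, pairs: list,
                             n_bins: int = 5, compare: tuple = (0, -1)):
    """PPC contrast between fast- and slow-RT trials.

    Trials are sorted by RT and divided into ``n_bins`` equal bins (the
    remainder, n mod n_bins, is dropped from the slow end); PPC is computed
    separately on the first (fast) and last (slow) bin and the difference
    averaged over site pairs.  Returns (ppc_fast, ppc_slow, mean difference
    spectrum).
    """
    n = len(rt)
    if n < 10:
        raise ValueError("need at least 10 trials")
    order = np.argsort(rt, kind="stable")
    binsize = n // n_bins
    if binsize < 2:
        raise ValueError("bin size below 2: too few trials for quintiles")
    order = order[: binsize * n_bins]
    bins = order.reshape(n_bins, binsize)
    fast = bins[compare[0]]
    slow = bins[compare[1]]
    ppc_fast = ppc_spectrum(frame, pairs, trials=fast)
    ppc_slow = ppc_spectrum(frame, pairs, trials=slow)
    diff = (ppc_fast.ppc - ppc_slow.ppc).mean(axis=0)
    return ppc_fast, ppc_slow, diff
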