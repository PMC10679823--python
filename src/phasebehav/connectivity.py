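"""Pairwise phase consistency, site-/area-pair selection, cluster definition,
and peak-frequency alignment.

PPC is the bias-free phase-locking estimator: the average cosine of all
pairwise differences between per-trial relative phases.  It is computed here
through the algebraic identity

    PPC = (|sum_t exp(i theta_t)|^2 - N) / (N (N - 1)),

which equals the explicit O(N^2) pairwise-cosine average.  Site pairs are
screened for recording artifacts (>100 Hz PPC) and selected by a pooled
mean+3SD threshold; area pairs whose average PPC crosses the same kind of
threshold are grouped into clusters by connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .spectral import SpectralFrame

__all__ = [
    "PPCSpectrum",
    "SelectionResult",
    "PeakAlignment",
    "Cluster",
    "ppc_spectrum",
    "select_site_pairs",
    "define_clusters",
    "peak_align",
    "inter_areal_pairs",
    "BAND_RANGES",
    "BAND_HALFWIDTHS",
]

#: band search ranges (Hz), consistent with beta peaks at 16–18 Hz and gamma
#: peaks at 63–74 Hz
BAND_RANGES = {"beta": (10.0, 30.0), "gamma": (40.0, 95.0)}
#: alignment half-widths (Hz): spectra are re-indexed to peak +/- halfwidth
BAND_HALFWIDTHS = {"beta": 15.0, "gamma": 20.0}

SELECTION_SD_FACTOR = 3.0
ARTIFACT_SD_FACTOR = 5.0


@dataclass
class PPCSpectrum:
    ppc: np.ndarray               # site-pair x frequency, in [-1, 1]
    freqs: np.ndarray
    pairs: list                   # list of (site_a, site_b) index tuples
    pair_meta: pd.DataFrame       # columns site_a, site_b, area_a, area_b
    n_trials: int

    def __post_init__(self):
        if self.n_trials < 2:
            raise ValueError("PPC requires at least 2 trials")
        if np.any(self.ppc > 1.0 + 1e-12):
            raise ValueError("PPC cannot exceed 1")


@dataclass
class SelectionResult:
    artifact_excluded: np.ndarray     # bool per site pair
    selected: np.ndarray              # bool per site pair
    threshold_value: float            # mean + 3 SD of the pooled PPC values
    stats: tuple                      # (mean, SD) of the pooled PPC

    def __post_init__(self):
        if np.any(self.artifact_excluded & self.selected):
            raise ValueError("artifact-excluded pairs cannot be selected")


@dataclass
class PeakAlignment:
    subject_id: str
    band: str
    peak_freq: float
    halfwidth: float

    def aligned_freqs(self, fmin: float = 1.0, fmax: float = 95.0) -> np.ndarray:
        """Integer frequency bins spanning peak +/- halfwidth, clipped to the
        analysis range."""
        lo = max(fmin, self.peak_freq - self.halfwidth)
        hi = min(fmax, self.peak_freq + self.halfwidth)
        return np.arange(np.ceil(lo), np.floor(hi) + 1.0)


@dataclass
class Cluster:
    areas: tuple
    band: str
    peak_freq: float


# ---------------------------------------------------------------------------

def inter_areal_pairs(meta: pd.DataFrame, areas_a=None, areas_b=None) -> list:
    """All site-index pairs whose areas differ (optionally restricted to two
    area groups).  Pairs are ordered (lower site index, higher site index)."""
    area = meta["area"].to_numpy()
    n = len(meta)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if area[i] == area[j]:
                continue
            if areas_a is not None:
                ok = (area[i] in areas_a and area[j] in areas_b) or \
                     (area[i] in areas_b and area[j] in areas_a)
                if not ok:
                    continue
            pairs.append((i, j))
    return pairs


def ppc_spectrum(frame: SpectralFrame, pairs: list,
                 meta: pd.DataFrame | None = None,
                 trials: np.ndarray | None = None) -> PPCSpectrum:
    """PPC per site pair per frequency via the algebraic identity.

    The relative phase of trial t is the angle of
    coeff_a(f, t) * conj(coeff_b(f, t)); PPC is the mean cosine of all
    pairwise differences of these phases across trials, computed as
    (|sum of unit phasors|^2 - N) / (N (N-1)).
    """
    coeff = frame.coeff if trials is None else frame.coeff[:, :, trials]
    n = coeff.shape[2]
    if n < 2:
        raise ValueError("PPC requires at least 2 trials")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    z = coeff[ia] * np.conj(coeff[ib])            # pair x freq x trial
    mag = np.abs(z)
    if np.any(mag == 0):
        raise ValueError("zero-amplitude coefficient: relative phase undefined")
    u = z / mag
    resultant = np.abs(u.sum(axis=2)) ** 2
    ppc = (resultant - n) / (n * (n - 1))
    if meta is not None:
        area = meta["area"].to_numpy()
        pair_meta = pd.DataFrame(
            {"site_a": ia, "site_b": ib, "area_a": area[ia], "area_b": area[ib]}
        )
    else:
        pair_meta = pd.DataFrame({"site_a": ia, "site_b": ib,
                                  "area_a": "", "area_b": ""})
    return PPCSpectrum(ppc=ppc, freqs=frame.freqs.copy(), pairs=list(pairs),
                       pair_meta=pair_meta, n_trials=n)


def ppc_pairwise_bruteforce(phases: np.ndarray) -> float:
    """Explicit O(N^2) pairwise-cosine average (oracle for the identity)."""
    n = len(phases)
    acc = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            acc += np.cos(phases[j] - phases[k])
    return 2.0 * acc / (n * (n - 1))


def select_site_pairs(ppc: PPCSpectrum, ppc_high: PPCSpectrum) -> SelectionResult:
    """Artifact screening then threshold selection.

    A pair is artifact-excluded if its PPC at any frequency above 100 Hz
    exceeds mean+5SD of all >100 Hz PPC values of the same area pair.  Among
    the remaining pairs, a pair is selected if its 1–95 Hz PPC exceeds, at any
    frequency, mean+3SD of all PPC values pooled over the remaining inter-areal
    site pairs and all frequencies.
    """
    if ppc.pairs != ppc_high.pairs:
        raise ValueError("both spectra must cover the identical pair set")
    n_pairs = ppc.ppc.shape[0]

    key = list(zip(ppc.pair_meta["area_a"], ppc.pair_meta["area_b"]))
    excluded = np.zeros(n_pairs, dtype=bool)
    for ap in set(key):
        rows = np.array([k == ap for k in key])
        vals = ppc_high.ppc[rows].ravel()
        thr = vals.mean() + ARTIFACT_SD_FACTOR * vals.std()
        excluded[rows] = (ppc_high.ppc[rows] > thr).any(axis=1)

    pooled = ppc.ppc[~excluded].ravel()
    mean, sd = float(pooled.mean()), float(pooled.std())
    if sd <= 1e-12 * max(abs(mean), 1.0):
        raise ValueError("degenerate threshold: pooled PPC values are identical")
    thr = mean + SELECTION_SD_FACTOR * sd
    selected = (~excluded) & (ppc.ppc > thr).any(axis=1)
    return SelectionResult(artifact_excluded=excluded, selected=selected,
                           threshold_value=thr, stats=(mean, sd))


def define_clusters(avg_ppc: np.ndarray, area_pairs: list,
                    freqs: np.ndarray) -> list[Cluster]:
    """Group areas into clusters of supra-threshold average coupling.

    ``avg_ppc`` is area-pair x frequency (average over the selected site pairs
    of each area pair).  Pairs exceeding mean+3SD of all pooled values at any
    frequency are retained; connected components of the retained pairs (areas
    as nodes) form clusters, each labeled by the band of its strongest
    supra-threshold peak.
    """
    pooled = avg_ppc.ravel()
    sd = pooled.std()
    thr = pooled.mean() + SELECTION_SD_FACTOR * sd if sd > 0 else np.inf
    supra = (avg_ppc > thr).any(axis=1)
    if not supra.any():
        warnings.warn("no supra-threshold area pair: no clusters defined")
        return []
    areas = sorted({a for p in area_pairs for a in p})
    index = {a: i for i, a in enumerate(areas)}
    rows = [index[area_pairs[k][0]] for k in np.flatnonzero(supra)]
    cols = [index[area_pairs[k][1]] for k in np.flatnonzero(supra)]
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)),
                     shape=(len(areas), len(areas)))
    n_comp, labels = connected_components(adj, directed=False)

    clusters = []
    for c in range(n_comp):
        members = tuple(a for a in areas if labels[index[a]] == c)
        if len(members) < 2:
            continue   # isolated areas with no supra-threshold pair
        k_pairs = [k for k in np.flatnonzero(supra)
                   if area_pairs[k][0] in members and area_pairs[k][1] in members]
        spec = avg_ppc[k_pairs].mean(axis=0)
        peak = float(freqs[int(np.argmax(spec))])
        band = "gamma" if BAND_RANGES["gamma"][0] <= peak else "beta"
        clusters.append(Cluster(areas=members, band=band, peak_freq=peak))
    return clusters


def peak_align(avg_ppc: np.ndarray, freqs: np.ndarray, band: str,
               subject_id: str = "unknown") -> PeakAlignment:
    """Individual peak frequency: argmax of the average PPC within the band's
    search range (ties break toward the lower frequency)."""
    lo, hi = BAND_RANGES[band]
    m = (freqs >= lo) & (freqs <= hi)
    if not m.any():
        raise ValueError(f"spectrum does not cover the {band} search range")
    sub = avg_ppc[m]
    fsub = freqs[m]
    peak = float(fsub[int(np.argmax(sub))])
    if peak in (fsub[0], fsub[-1]):
        warnings.warn(f"{band} peak {peak:g} Hz lies on the search-range "
                      "boundary; possible truncation")
    return PeakAlignment(subject_id=subject_id, band=band, peak_freq=peak,
                         halfwidth=BAND_HALFWIDTHS[band])
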