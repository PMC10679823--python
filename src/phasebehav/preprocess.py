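"""Preprocessing: bipolar derivation, trial cleaning/selection, signal
conditioning, and epoch extraction.

The stages follow the standard ECoG/LFP hygiene for interareal coherence
analysis: local bipolar re-referencing removes the common recording reference,
trials with excessive variance or invalid behavioral structure are discarded,
line noise is projected out per trial, each trial is linearly detrended, and
every site is z-normalized over all retained data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .synthgen import SessionRecording

__all__ = [
    "TrialMask",
    "EpochSet",
    "EmptySelectionError",
    "bipolar_derive",
    "clean_and_select_trials",
    "condition_signal",
    "extract_epochs",
    "EPOCH_WINDOWS",
]

#: analysis windows (ms before the target change)
EPOCH_WINDOWS = {"power-ppc-gpr": 200.0, "gc": 400.0}

REASONS = ("artifact-variance", "distractor-first", "change-before-800ms",
           "error-trial")

#: minimal cue-to-change interval for a trial to enter the analysis (ms)
MIN_CUE_TO_CHANGE_MS = 800.0

#: a trial is an artifact if its variance exceeds this multiple of the mean
#: trial variance of the same site
ARTIFACT_VARIANCE_FACTOR = 5.0


class EmptySelectionError(RuntimeError):
    """No trial survived the selection rules."""


@dataclass
class TrialMask:
    keep: np.ndarray          # bool per trial
    reason: np.ndarray        # primary rejection reason or '' for kept trials

    def __post_init__(self):
        if len(self.keep) != len(self.reason):
            raise ValueError("keep and reason must have equal length")
        bad = set(self.reason[~self.keep]) - set(REASONS)
        if bad:
            raise ValueError(f"unknown rejection reasons: {bad}")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial_id": np.arange(len(self.keep)), "keep": self.keep,
             "reason": self.reason}
        )


@dataclass
class EpochSet:
    """Fixed-length windows cut relative to each trial's change onset."""

    signal: np.ndarray        # site x time x trial
    window: tuple             # (start ms, end ms) relative to change onset
    sample_rate: float
    trial_index: np.ndarray   # indices into the parent recording's trials

    def __post_init__(self):
        length = self.window[1] - self.window[0]
        if length not in (200.0, 400.0):
            raise ValueError("epoch window length must be 200 or 400 ms")

    @property
    def n_trials(self) -> int:
        return self.signal.shape[2]


# ---------------------------------------------------------------------------

def bipolar_derive(rec: SessionRecording) -> SessionRecording:
    """Difference neighboring electrodes on the same lane.

    The output channel i of a lane is electrode i+1 minus electrode i (fixed
    sign convention: higher within-lane index minus lower).  Any signal common
    to all electrodes — in particular the shared recording reference — cancels
    exactly.  Lanes with fewer than two electrodes contribute no sites.
    """
    if rec.derivation != "unipolar":
        raise ValueError("bipolar_derive expects a unipolar recording")
    meta = rec.channel_meta
    sites = []
    rows = []
    for lane, idx in meta.groupby("lane").groups.items():
        idx = meta.loc[idx].sort_values("electrode").index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            sites.append(rec.signal[b] - rec.signal[a])
            r = meta.loc[a]
            rows.append({"area": r["area"], "cluster": r["cluster"],
                         "lane": lane, "electrode": int(r["electrode"])})
    if not sites:
        raise ValueError("no lane has >= 2 electrodes; bipolar derivation impossible")
    return SessionRecording(
        signal=np.stack(sites), sample_rate=rec.sample_rate, rt=rec.rt,
        condition=rec.condition, cue_time=rec.cue_time,
        change_time=rec.change_time, target_first=rec.target_first,
        correct=rec.correct, channel_meta=pd.DataFrame(rows),
        subject_id=rec.subject_id, derivation="bipolar",
    )


def clean_and_select_trials(rec: SessionRecording,
                            variance_scope: str = "any-site") -> TrialMask:
    """Keep a trial iff it passes all four rules.

    Rules (order-independent for the mask): variance on every site at most
    five times that site's mean trial variance; the target change occurred
    first; the change came at least 800 ms after cue onset; the trial was
    correct.  The variance baseline is the per-site mean over all trials of
    the session, computed once (no iteration).  ``variance_scope`` is
    'any-site' (a single bad site rejects the trial) or 'all-sites'.
    """
    var = rec.signal.var(axis=1)                       # site x trial
    baseline = var.mean(axis=1, keepdims=True)
    over = var > ARTIFACT_VARIANCE_FACTOR * baseline
    if variance_scope == "any-site":
        artifact = over.any(axis=0)
    elif variance_scope == "all-sites":
        artifact = over.all(axis=0)
    else:
        raise ValueError("variance_scope must be 'any-site' or 'all-sites'")

    late_enough = (rec.change_time - rec.cue_time) >= MIN_CUE_TO_CHANGE_MS
    keep = (~artifact) & rec.target_first & late_enough & rec.correct

    reason = np.full(len(keep), "", dtype=object)
    # primary reason: first failing rule in the documented order
    reason[~rec.correct] = "error-trial"
    reason[~late_enough] = "change-before-800ms"
    reason[~rec.target_first] = "distractor-first"
    reason[artifact] = "artifact-variance"
    reason[keep] = ""

    if not keep.any():
        raise EmptySelectionError("no trial survived the selection rules")
    return TrialMask(keep=keep, reason=np.asarray(reason, dtype=object))


def _project_out(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares removal of the design columns from the time axis of
    x (channels x time x trials)."""
    pinv = np.linalg.pinv(design)                       # (k, T)
    coef = np.einsum("kt,ctr->ckr", pinv, x)
    return x - np.einsum("tk,ckr->ctr", design, coef)


def condition_signal(rec: SessionRecording, keep: np.ndarray | None = None,
                     steps: tuple = ("line", "detrend", "normalize"),
                     line_freqs: tuple = (50.0, 100.0, 150.0)) -> SessionRecording:
    """Line-noise removal, linear detrending, and per-site z-normalization.

    'line': per trial, the best-fitting sinusoids at the line frequencies are
    removed by projecting the full trial onto the corresponding cosine/sine
    pair (discrete-Fourier-transform method; exact for an integer number of
    cycles).  'detrend': per-trial linear detrend, which includes demeaning.
    'normalize': per site, subtract the mean and divide by the SD of all used
    data of that site; ``keep`` restricts "used data" to the retained trials
    (statistics from kept trials are applied to every trial).
    """
    x = rec.signal.astype(float, copy=True)
    n_samp = rec.n_samples
    t = np.arange(n_samp) / rec.sample_rate

    if "line" in steps:
        cols = []
        for f in line_freqs:
            cols += [np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]
        x = _project_out(x, np.column_stack(cols))
    if "detrend" in steps:
        x = _linear_detrend(x, axis=1, type="linear")
    if "normalize" in steps:
        used = x if keep is None else x[:, :, keep]
        mean = used.mean(axis=(1, 2), keepdims=True)
        sd = used.std(axis=(1, 2), keepdims=True)
        dead = np.flatnonzero(sd.ravel() == 0)
        if dead.size:
            raise ValueError(f"zero-variance site(s): {dead.tolist()}")
        x = (x - mean) / sd

    return SessionRecording(
        signal=x, sample_rate=rec.sample_rate, rt=rec.rt,
        condition=rec.condition, cue_time=rec.cue_time,
        change_time=rec.change_time, target_first=rec.target_first,
        correct=rec.correct, channel_meta=rec.channel_meta,
        subject_id=rec.subject_id, derivation=rec.derivation,
    )


def extract_epochs(rec: SessionRecording, purpose: str = "power-ppc-gpr",
                   keep: np.ndarray | None = None) -> EpochSet:
    """Cut the pre-change analysis window from every (retained) trial.

    Window is the last 200 ms before the target change for power/PPC/GPR and
    the last 400 ms for GC; it never includes post-change samples.
    """
    if purpose not in EPOCH_WINDOWS:
        raise ValueError(f"purpose must be one of {sorted(EPOCH_WINDOWS)}")
    win_ms = EPOCH_WINDOWS[purpose]
    n_win = int(round(win_ms * rec.sample_rate / 1000.0))
    trial_index = np.arange(rec.n_trials) if keep is None else np.flatnonzero(keep)

    out = np.empty((rec.n_channels, n_win, len(trial_index)))
    for k, tr in enumerate(trial_index):
        end = int(round(rec.change_time[tr] * rec.sample_rate / 1000.0))
        start = end - n_win
        if start < 0:
            raise ValueError(f"trial {tr} too short for a {win_ms:.0f} ms epoch")
        out[:, :, k] = rec.signal[:, start:end, tr]
    return EpochSet(signal=out, window=(-win_ms, 0.0),
                    sample_rate=rec.sample_rate, trial_index=trial_index)
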