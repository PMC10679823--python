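"""Synthetic multi-area LFP sessions with known ground truth.

Generates trial-epoched multi-channel recordings that carry the statistical
structure the analysis pipeline is designed to detect: an occipital cluster of
areas oscillating in the gamma band and a fronto-central cluster oscillating in
the beta band, with within-cluster phase coupling, trial-wise von Mises phase
jitter, a shared per-trial phase deviation that lengthens reaction times in the
attend-IN condition, a lagged beta-band driver from the fronto-central to the
occipital cluster, 1/f background noise, 50/100/150 Hz line noise, a shared
recording-reference artifact, and occasional high-variance artifact trials.

The generator is validation scaffolding: it makes every pipeline stage testable
against known parameters, and makes no biophysical claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "AreaSpec",
    "SimConfig",
    "GroundTruth",
    "SessionRecording",
    "build_grid",
    "simulate_session",
    "oracle_statistics",
    "DEFAULT_AREAS",
]

OCCIPITAL = "occipital"
FRONTOCENTRAL = "frontocentral"
CONDITIONS = ("IN", "OUT")


@dataclass(frozen=True)
class AreaSpec:
    """One recorded area: name, cluster membership, and electrode layout.

    Electrodes are divided evenly over ``n_lanes`` lanes; bipolar derivation
    later differentiates neighboring electrodes within a lane, so an area
    contributes sites only if at least one lane holds >= 2 electrodes.
    """

    name: str
    cluster: str = "none"
    n_electrodes: int = 4
    n_lanes: int = 1


#: Default grid: 4 occipital + 5 fronto-central areas, 4 electrodes each,
#: one lane per area. Area order encodes the anatomical hierarchy (low -> high).
DEFAULT_AREAS: tuple[AreaSpec, ...] = (
    AreaSpec("V1", OCCIPITAL),
    AreaSpec("V2", OCCIPITAL),
    AreaSpec("V4", OCCIPITAL),
    AreaSpec("DP", OCCIPITAL),
    AreaSpec("S1", FRONTOCENTRAL),
    AreaSpec("A5", FRONTOCENTRAL),
    AreaSpec("F1", FRONTOCENTRAL),
    AreaSpec("F2", FRONTOCENTRAL),
    AreaSpec("F4", FRONTOCENTRAL),
)


@dataclass
class SimConfig:
    """Generative parameters for one synthetic session.

    Units: frequencies in Hz, times in ms, amplitudes in arbitrary units on
    the scale of the (unit-SD) background noise.
    """

    n_trials_per_condition: int = 300
    sample_rate: float = 1000.0
    trial_duration: float = 1400.0
    areas: tuple[AreaSpec, ...] = DEFAULT_AREAS
    gamma_freq: float = 70.0
    beta_freq: float = 16.0
    #: attend-IN shifts the beta peak slightly upward (Hz)
    beta_freq_attend_shift: float = 1.0
    #: per-channel von Mises phase-jitter concentration, per condition;
    #: larger kappa -> tighter phase locking (stronger PPC)
    phase_jitter_kappa: dict = field(default_factory=lambda: {"IN": 8.0, "OUT": 4.0})
    #: concentration of the shared per-trial phase deviation that drives RT
    shared_deviation_kappa: float = 4.0
    #: RT model: baseline + effect*(1 - cos(deviation)) - slope*(gain - 1) + noise
    rt_baseline: float = 300.0
    rt_effect: float = 90.0
    rt_noise_sd: float = 30.0
    coupling_gain_rt_slope: float = 40.0
    #: fronto-central beta power envelope leads the occipital copy by this lag
    power_lag: float = 32.0
    gamma_amp: float = 2.0
    beta_amp: float = 2.0
    #: amplitude of the lagged beta copy received by occipital channels
    occ_beta_amp: float = 0.3
    #: phase-jitter concentration of the occipital beta copy (noisy
    #: transmission channel)
    occ_beta_jitter_kappa: float = 4.0
    #: phase-incoherent lagged power component: follows the fronto-central
    #: beta envelope at the same lag but with random carrier phase, so it
    #: drives the power-power correlation without adding phase coupling
    occ_beta_lagpow_amp: float = 0.45
    #: intrinsic occipital beta rhythm, independent per channel; competes with
    #: the received copy so inter-cluster coherence stays moderate and grows
    #: with the coupling gain
    occ_beta_noise_amp: float = 0.3
    #: log-SD of the slow multiplicative beta envelope and its smoothing scale
    envelope_log_sd: float = 0.4
    envelope_smooth_ms: float = 30.0
    #: log-SD of the per-trial beta coupling gain
    gain_log_sd: float = 0.5
    noise_amp: float = 1.0
    aperiodic_exponent: float = 1.5
    line_noise_amp: float = 0.3
    common_reference_amp: float = 1.0
    artifact_trial_fraction: float = 0.05
    distractor_first_fraction: float = 0.10
    early_change_fraction: float = 0.05
    error_trial_fraction: float = 0.06
    cue_time: float = 100.0
    change_min: float = 900.0
    change_max: float = 1300.0
    subject_id: str = "synthetic-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_condition < 2:
            raise ValueError("n_trials_per_condition must be >= 2")
        highest = max(self.gamma_freq, self.beta_freq + self.beta_freq_attend_shift)
        if self.sample_rate <= 2 * highest:
            raise ValueError(
                f"sample_rate {self.sample_rate} must exceed twice the highest "
                f"oscillation frequency ({highest} Hz)"
            )
        for cond in CONDITIONS:
            if self.phase_jitter_kappa[cond] < 0:
                raise ValueError("phase_jitter_kappa must be >= 0")
        if not 0 <= self.artifact_trial_fraction < 1:
            raise ValueError("artifact_trial_fraction must be in [0, 1)")
        if any(a.n_electrodes <= 0 for a in self.areas):
            raise ValueError("every area needs at least one electrode")
        if self.change_max + 50 > self.trial_duration:
            raise ValueError("trial_duration too short for the change-time range")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["areas"] = [asdict(a) for a in self.areas]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "areas" in d:
            d["areas"] = tuple(AreaSpec(**a) for a in d["areas"])
        return cls(**d)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SessionRecording:
    """Trial-epoched multi-channel recording.

    ``signal`` is channels x time x trials (a.u.).  ``channel_meta`` has one
    row per channel with columns area, cluster, lane, electrode (lane is a
    session-global lane id; electrode the within-lane index).
    """

    signal: np.ndarray
    sample_rate: float
    rt: np.ndarray                 # ms, per trial
    condition: np.ndarray          # 'IN' / 'OUT'
    cue_time: np.ndarray           # ms, per trial
    change_time: np.ndarray        # ms, per trial
    target_first: np.ndarray       # bool per trial
    correct: np.ndarray            # bool per trial
    channel_meta: pd.DataFrame
    subject_id: str = "unknown"
    derivation: str = "unipolar"

    def __post_init__(self):
        n_trials = self.signal.shape[2]
        if len(self.rt) != n_trials:
            raise ValueError("rt length must equal the number of trials")
        if np.any(self.rt[self.correct] <= 0):
            raise ValueError("completed trials must have rt > 0")
        if len(self.channel_meta) != self.signal.shape[0]:
            raise ValueError("channel_meta must have one row per channel")
        if self.channel_meta["area"].isna().any():
            raise ValueError("every channel needs an area label")

    @property
    def n_trials(self) -> int:
        return self.signal.shape[2]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class GroundTruth:
    """Generative latents of one simulated session (one record per trial)."""

    shared_deviation: dict          # cluster -> per-trial deviation (radians)
    coupling_gain: np.ndarray       # per-trial beta gain (dimensionless)
    power_lag: float                # ms
    condition: np.ndarray
    channel_jitter: np.ndarray      # channels x trials (radians)
    deviation_weight: np.ndarray    # per channel, in {0, 1}
    artifact: np.ndarray            # bool per trial
    rt_params: dict

    def pair_deviation_weight(self, meta: pd.DataFrame, site_a: int, site_b: int) -> float:
        """Signed deviation weight carried by a site pair's phase relation.

        Site weights equal the (common) weight of their constituent channels;
        a pair carries the shared deviation iff the two sites sit on opposite
        halves of a cluster's hierarchy.
        """
        return float(self.deviation_weight[site_a] - self.deviation_weight[site_b])

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x
        d = {
            "shared_deviation": {k: v.tolist() for k, v in self.shared_deviation.items()},
            "coupling_gain": self.coupling_gain.tolist(),
            "power_lag": self.power_lag,
            "condition": self.condition.tolist(),
            "channel_jitter": self.channel_jitter.tolist(),
            "deviation_weight": self.deviation_weight.tolist(),
            "artifact": self.artifact.tolist(),
            "rt_params": {k: conv(v) for k, v in self.rt_params.items()},
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def build_grid(config: SimConfig) -> pd.DataFrame:
    """Per-channel (area, cluster, lane, electrode) table for the config's areas.

    Electrodes are split as evenly as possible over each area's lanes; lanes
    never span areas.  Raises on an area with zero electrodes.
    """
    rows = []
    lane_id = 0
    for area in config.areas:
        if area.n_electrodes <= 0:
            raise ValueError(f"area {area.name} has no electrodes")
        n_lanes = max(1, area.n_lanes)
        base, extra = divmod(area.n_electrodes, n_lanes)
        for lane in range(n_lanes):
            n_in_lane = base + (1 if lane < extra else 0)
            for e in range(n_in_lane):
                rows.append(
                    {"area": area.name, "cluster": area.cluster,
                     "lane": lane_id, "electrode": e}
                )
            lane_id += 1
    return pd.DataFrame(rows)


def n_bipolar_sites(channel_meta: pd.DataFrame) -> int:
    """Number of neighboring-electrode pairs: sum over lanes of (n_lane - 1)."""
    return int(sum(max(0, n - 1) for n in channel_meta.groupby("lane").size()))


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _von_mises(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    if np.isinf(kappa):
        return np.zeros(size)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size)
    return rng.vonmises(0.0, kappa, size)


def _one_over_f_noise(rng, exponent, n_ch, n_samp, n_trials, sample_rate):
    """White noise spectrally shaped to power ~ 1/f**exponent, unit SD."""
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sample_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_ch, n_trials, n_samp))
    spec = np.fft.rfft(white, axis=-1) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _area_deviation_weights(areas: tuple[AreaSpec, ...]) -> dict:
    """Per-area weight h in [0, 1], graded along each cluster's hierarchy.

    The shared per-trial deviation enters a channel's phase as h * s_t, so an
    inter-areal pair between areas with weights h_a, h_b expresses the
    deviation with weight h_a - h_b: every inter-areal pair carries part of
    the signal, adjacent areas less, distant areas more — mirroring graded
    interareal coupling strengths.
    """
    h = {}
    for cluster in (OCCIPITAL, FRONTOCENTRAL):
        names = [a.name for a in areas if a.cluster == cluster]
        n = len(names)
        for i, name in enumerate(names):
            h[name] = (n - 1 - i) / (n - 1) if n > 1 else 0.0
    return h


def _deviation_weights(meta: pd.DataFrame, areas: tuple[AreaSpec, ...]) -> np.ndarray:
    h = _area_deviation_weights(areas)
    return np.array([h.get(a, 0.0) for a in meta["area"]])


def simulate_session(config: SimConfig) -> tuple[SessionRecording, GroundTruth]:
    """Generate one session plus its generative latents.

    Deterministic for a fixed config (identical seeds give bit-identical
    arrays).  See the module docstring for the signal model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = build_grid(config)
    n_ch = len(meta)
    fs = config.sample_rate
    n_samp = int(round(config.trial_duration * fs / 1000.0))
    n_per = config.n_trials_per_condition
    n_trials = 2 * n_per

    # -- trial structure -----------------------------------------------------
    condition = np.array(["IN"] * n_per + ["OUT"] * n_per)
    rng.shuffle(condition)
    is_in = condition == "IN"

    early = rng.random(n_trials) < config.early_change_fraction
    target_first = rng.random(n_trials) >= config.distractor_first_fraction
    correct = rng.random(n_trials) >= config.error_trial_fraction
    artifact = rng.random(n_trials) < config.artifact_trial_fraction

    cue = np.full(n_trials, config.cue_time)
    change = np.where(
        early,
        rng.uniform(config.cue_time + 400.0, config.cue_time + 780.0, n_trials),
        rng.uniform(config.change_min, config.change_max, n_trials),
    )
    change = np.round(change)  # integer ms = integer samples at 1 kHz

    # -- latents -------------------------------------------------------------
    kappa_s = config.shared_deviation_kappa
    s_shared = _von_mises(rng, kappa_s, n_trials)
    s_indep_occ = _von_mises(rng, kappa_s, n_trials)
    s_indep_fc = _von_mises(rng, kappa_s, n_trials)
    # IN: one deviation shared between clusters; OUT: independent per cluster
    s_occ = np.where(is_in, s_shared, s_indep_occ)
    s_fc = np.where(is_in, s_shared, s_indep_fc)

    sig_g = config.gain_log_sd
    gain = np.exp(rng.normal(-0.5 * sig_g**2, sig_g, n_trials))

    # RT: linked to the signal latents in IN; to independent surrogate draws
    # (same marginals) in OUT
    s_rt_surrogate = _von_mises(rng, kappa_s, n_trials)
    gain_rt_surrogate = np.exp(rng.normal(-0.5 * sig_g**2, sig_g, n_trials))
    s_for_rt = np.where(is_in, s_occ, s_rt_surrogate)
    g_for_rt = np.where(is_in, gain, gain_rt_surrogate)
    rt = (
        config.rt_baseline
        + config.rt_effect * (1.0 - np.cos(s_for_rt))
        - config.coupling_gain_rt_slope * (g_for_rt - 1.0)
        + rng.normal(0.0, config.rt_noise_sd, n_trials)
    )
    rt = np.maximum(rt, 50.0)

    # -- per-channel phase structure -----------------------------------------
    occ_ch = (meta["cluster"] == OCCIPITAL).to_numpy()
    fc_ch = (meta["cluster"] == FRONTOCENTRAL).to_numpy()
    w = _deviation_weights(meta, config.areas)

    # fixed channel offsets: random area base + pi/2 steps along each lane,
    # so bipolar differences retain the oscillation
    area_base = {a.name: rng.uniform(-np.pi, np.pi) for a in config.areas}
    delta = np.array(
        [area_base[r.area] + (np.pi / 2) * r.electrode for r in meta.itertuples()]
    )

    # von Mises jitter per channel per trial at the trial's concentration
    jitter = np.empty((n_ch, n_trials))
    for cond in CONDITIONS:
        m = condition == cond
        jitter[:, m] = _von_mises(
            rng, config.phase_jitter_kappa[cond], (n_ch, int(m.sum()))
        )
    jitter_beta = np.empty((n_ch, n_trials))
    for cond in CONDITIONS:
        m = condition == cond
        jitter_beta[:, m] = _von_mises(
            rng, config.phase_jitter_kappa[cond], (n_ch, int(m.sum()))
        )

    t = np.arange(n_samp) / fs  # seconds
    signal = np.zeros((n_ch, n_samp, n_trials))

    # -- occipital gamma -----------------------------------------------------
    phi_gamma = rng.uniform(-np.pi, np.pi, n_trials)
    theta_occ = (delta[occ_ch, None] + w[occ_ch, None] * s_occ[None, :]
                 + jitter[occ_ch, :])          # (n_occ, n_trials)
    phase = (2 * np.pi * config.gamma_freq) * t[None, :, None] \
        + phi_gamma[None, None, :] + theta_occ[:, None, :]
    signal[occ_ch] += config.gamma_amp * np.cos(phase)
    del phase

    # -- beta source with slow multiplicative envelope, lagged copy ----------
    lag_samp = int(round(config.power_lag * fs / 1000.0))
    n_ext = n_samp + lag_samp
    z = rng.standard_normal((n_trials, n_ext))
    z = gaussian_filter1d(z, sigma=config.envelope_smooth_ms * fs / 1000.0, axis=-1)
    zsd = z.std(axis=-1, keepdims=True)
    zsd[zsd == 0] = 1.0
    env = np.exp(config.envelope_log_sd * z / zsd)       # (n_trials, n_ext)

    phi_beta = rng.uniform(-np.pi, np.pi, n_trials)
    f_beta = np.where(is_in, config.beta_freq + config.beta_freq_attend_shift,
                      config.beta_freq)
    t_ext = (np.arange(n_ext) - lag_samp) / fs           # so t_ext[lag:] == t
    carrier = env * np.exp(
        1j * (2 * np.pi * f_beta[:, None] * t_ext[None, :] + phi_beta[:, None])
    )                                                     # (n_trials, n_ext)
    u_now = carrier[:, lag_samp:]                         # U(t)
    u_lag = carrier[:, :n_samp]                           # U(t - lag)

    theta_fc = (delta[fc_ch, None] + w[fc_ch, None] * s_fc[None, :]
                + jitter_beta[fc_ch, :])
    signal[fc_ch] += config.beta_amp * gain[None, None, :] * np.real(
        u_now.T[None, :, :] * np.exp(1j * theta_fc[:, None, :])
    )
    occ_beta_jitter = _von_mises(rng, config.occ_beta_jitter_kappa,
                                 (int(occ_ch.sum()), n_trials))
    theta_occ_beta = delta[occ_ch, None] + occ_beta_jitter
    signal[occ_ch] += config.occ_beta_amp * gain[None, None, :] * np.real(
        u_lag.T[None, :, :] * np.exp(1j * theta_occ_beta[:, None, :])
    )

    # incoherent lagged power: same delayed envelope, random carrier phase
    # per channel and trial, independent of the coupling gain
    if config.occ_beta_lagpow_amp > 0:
        n_occ = int(occ_ch.sum())
        env_lag = np.abs(u_lag)                          # (n_trials, n_samp)
        phi_inc = rng.uniform(-np.pi, np.pi, (n_occ, n_trials))
        signal[occ_ch] += config.occ_beta_lagpow_amp * env_lag.T[None, :, :] * \
            np.cos(2 * np.pi * f_beta[None, None, :] * t[None, :, None]
                   + phi_inc[:, None, :])
    del carrier, u_now, u_lag

    # intrinsic occipital beta: independent envelope and phase per channel,
    # so it adds no interareal beta coupling but competes with the received
    # fronto-central copy in the beta band
    if config.occ_beta_noise_amp > 0:
        n_occ = int(occ_ch.sum())
        z2 = rng.standard_normal((n_occ, n_trials, n_samp))
        z2 = gaussian_filter1d(z2, sigma=config.envelope_smooth_ms * fs / 1000.0,
                               axis=-1)
        z2sd = z2.std(axis=-1, keepdims=True)
        z2sd[z2sd == 0] = 1.0
        env2 = np.exp(config.envelope_log_sd * z2 / z2sd)
        phi2 = rng.uniform(-np.pi, np.pi, (n_occ, n_trials))
        intrinsic = env2 * np.cos(
            2 * np.pi * f_beta[None, :, None] * t[None, None, :]
            + phi2[:, :, None])
        signal[occ_ch] += config.occ_beta_noise_amp * \
            np.transpose(intrinsic, (0, 2, 1))
        del z2, env2, intrinsic

    # -- background, line noise, common reference ----------------------------
    noise = _one_over_f_noise(rng, config.aperiodic_exponent, n_ch, n_samp,
                              n_trials, fs)
    signal += config.noise_amp * np.transpose(noise, (0, 2, 1))
    del noise

    for f_line, rel in ((50.0, 1.0), (100.0, 0.6), (150.0, 0.4)):
        ch_gain = rng.uniform(0.5, 1.5, n_ch)
        phi_line = rng.uniform(-np.pi, np.pi, n_trials)
        signal += (config.line_noise_amp * rel) * ch_gain[:, None, None] * np.cos(
            2 * np.pi * f_line * t[None, :, None] + phi_line[None, None, :]
        )

    if config.common_reference_amp > 0:
        ref = _one_over_f_noise(rng, 1.0, 1, n_samp, n_trials, fs)[0]  # (tr, samp)
        signal += config.common_reference_amp * ref.T[None, :, :]

    # -- artifact trials: scale whole trial so variance >= 5x typical --------
    signal[:, :, artifact] *= 3.0

    rec = SessionRecording(
        signal=signal, sample_rate=fs, rt=rt, condition=condition,
        cue_time=cue, change_time=change, target_first=target_first,
        correct=correct, channel_meta=meta, subject_id=config.subject_id,
        derivation="unipolar",
    )
    gt = GroundTruth(
        shared_deviation={OCCIPITAL: s_occ, FRONTOCENTRAL: s_fc},
        coupling_gain=gain, power_lag=config.power_lag, condition=condition,
        channel_jitter=jitter, deviation_weight=w, artifact=artifact,
        rt_params={
            "baseline": config.rt_baseline, "effect": config.rt_effect,
            "noise_sd": config.rt_noise_sd,
            "gain_slope": config.coupling_gain_rt_slope,
            "deviation_for_rt": s_for_rt, "gain_for_rt": g_for_rt,
        },
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleStats:
    """Monte-Carlo expectations computed from the generative equations only."""

    gpr_rt_correlation: float       # expected site-pair-level r (IN trials)
    gpr_rt_correlation_se: float    # MC standard error of that expectation
    power_lag: float                # ms, by construction
    gc_asymmetry_sign: int          # +1: frontocentral -> occipital dominates
    n_mc: int

    def session_se(self, n_trials: int) -> float:
        """Sampling SD of a session's estimated r (Fisher-z approximation)."""
        if not np.isfinite(self.gpr_rt_correlation):
            return np.nan
        return (1.0 - self.gpr_rt_correlation**2) / np.sqrt(max(n_trials - 3, 1))


def oracle_statistics(config: SimConfig, n_mc: int = 10_000,
                      seed: int | None = None) -> OracleStats:
    """Expected statistics from the generative equations (no signal processing).

    Draws the latents exactly as ``simulate_session`` does and evaluates the
    site-pair GPR as the cosine of the pair-weighted shared deviation plus the
    pair's phase noise.  A bipolar site's phase perturbation is the half-sum
    of its two electrodes' von Mises jitters, so the pair noise is
    (e1+e2-e3-e4)/2.  The expectation is averaged over the occipital cluster's
    inter-areal pair-weight distribution (sites per area are equal within the
    default grid), matching a measurement that averages over all selected
    inter-areal site pairs of that cluster.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10^4 for stable oracle expectations")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    kappa = config.phase_jitter_kappa["IN"]
    s = _von_mises(rng, config.shared_deviation_kappa, n_mc)
    g = np.exp(rng.normal(-0.5 * config.gain_log_sd**2, config.gain_log_sd, n_mc))
    eps = _von_mises(rng, kappa, (4, n_mc))
    pair_noise = 0.5 * (eps[0] + eps[1] - eps[2] - eps[3])
    h = _area_deviation_weights(config.areas)
    occ = [a.name for a in config.areas if a.cluster == OCCIPITAL]
    weights = [abs(h[a] - h[b]) for i, a in enumerate(occ)
               for b in occ[i + 1:]]
    rt = (config.rt_baseline
          + config.rt_effect * (1.0 - np.cos(s))
          - config.coupling_gain_rt_slope * (g - 1.0)
          + rng.normal(0.0, config.rt_noise_sd, n_mc))

    def _corr(x, y):
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    # mean over the pair-weight distribution of the per-pair correlation
    # (matches a measurement averaging correlation spectra over site pairs)
    per_weight = [_corr(np.cos(w * s + pair_noise), rt) for w in weights]
    r = float(np.nanmean(per_weight)) if not np.all(np.isnan(per_weight)) \
        else np.nan
    if np.isnan(r):
        se = np.nan
    else:
        # block MC standard error of the weight-averaged correlation
        n_blocks = 20
        blocks = []
        for b in range(n_blocks):
            sl = slice(b * n_mc // n_blocks, (b + 1) * n_mc // n_blocks)
            vals = [_corr(np.cos(w * s[sl] + pair_noise[sl]), rt[sl])
                    for w in weights]
            blocks.append(np.nanmean(vals))
        se = float(np.std(blocks, ddof=1) / np.sqrt(len(blocks)))
    return OracleStats(
        gpr_rt_correlation=r, gpr_rt_correlation_se=se,
        power_lag=config.power_lag, gc_asymmetry_sign=+1, n_mc=n_mc,
    )
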