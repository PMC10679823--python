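"""End-to-end orchestration: simulate -> preprocess -> spectra -> PPC/selection
-> GPR/GC/lag analyses -> randomization inference, from one configuration.

Every stage writes round-trippable TSV/JSON outputs; identical configuration
and seed give identical bundles.  The HDF5 session container stores the raw
arrays (/signal, /rt, /condition, /cue_time, /change_time, /target_first,
/correct, /channel_meta/*) with sample_rate, derivation and subject_id as
attributes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthgen import SimConfig, SessionRecording, simulate_session
from .preprocess import (bipolar_derive, clean_and_select_trials,
                         condition_signal, extract_epochs)
from .spectral import (fft_epochs, power_spectra, sliding_band_power,
                       SpectralFrame, PowerTimecourse)
from .connectivity import (inter_areal_pairs, ppc_spectrum, select_site_pairs,
                           define_clusters, peak_align, BAND_HALFWIDTHS)
from .phase_behavior import (rotated_deviations, pearson_rows,
                             cross_cluster_gpr_correlation,
                             rt_quintile_ppc_contrast, power_rt_correlation)
from .granger import estimate_csd, wilson_factorize, granger_spectrum, \
    gc_rt_correlation
from .power_dynamics import lagged_power_correlation
from .inference import max_corrected_from_null

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "SchemaError",
    "run_pipeline",
    "write_session",
    "read_session",
    "ALL_STAGES",
]

ALL_STAGES = ("simulate", "preprocess", "ppc", "gpr", "gc", "lag")

REQUIRED_DATASETS = ("signal", "rt", "condition", "cue_time", "change_time",
                     "target_first", "correct")


class SchemaError(RuntimeError):
    """The HDF5 container does not match the documented layout."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict:
        return {"stage": self.stage, "error": type(self.cause).__name__,
                "message": str(self.cause)}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple = ALL_STAGES
    n_rand: int = 1000             # randomizations for max-corrected tests
    lag_band: tuple = (14.0, 16.0)
    lag_surrogates: int = 200
    max_gc_pairs: int = 3          # site pairs entering the jackknife GC stage
    gc_tol: float = 1e-8
    gc_max_iter: int = 100     # empirical CSDs stall around 1e-5; see methods
    seed: int | None = None        # overrides sim.seed when set

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "lag_band" in d:
            d["lag_band"] = tuple(d["lag_band"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# HDF5 session container
# ---------------------------------------------------------------------------

def write_session(rec: SessionRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("rt", data=rec.rt)
        f.create_dataset("condition",
                         data=np.char.encode(rec.condition.astype(str)))
        f.create_dataset("cue_time", data=rec.cue_time)
        f.create_dataset("change_time", data=rec.change_time)
        f.create_dataset("target_first", data=rec.target_first)
        f.create_dataset("correct", data=rec.correct)
        g = f.create_group("channel_meta")
        g.create_dataset("area", data=np.char.encode(
            rec.channel_meta["area"].to_numpy(str)))
        g.create_dataset("cluster", data=np.char.encode(
            rec.channel_meta["cluster"].to_numpy(str)))
        g.create_dataset("lane", data=rec.channel_meta["lane"].to_numpy(int))
        g.create_dataset("electrode",
                         data=rec.channel_meta["electrode"].to_numpy(int))
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["derivation"] = rec.derivation
        f.attrs["subject_id"] = rec.subject_id


def read_session(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        for name in REQUIRED_DATASETS:
            if name not in f:
                raise SchemaError(f"missing required dataset /{name}")
        if "channel_meta" not in f:
            raise SchemaError("missing required group /channel_meta")
        meta = pd.DataFrame({
            "area": np.char.decode(f["channel_meta/area"][...]),
            "cluster": np.char.decode(f["channel_meta/cluster"][...]),
            "lane": f["channel_meta/lane"][...],
            "electrode": f["channel_meta/electrode"][...],
        })
        return SessionRecording(
            signal=f["signal"][...], sample_rate=float(f.attrs["sample_rate"]),
            rt=f["rt"][...], condition=np.char.decode(f["condition"][...]),
            cue_time=f["cue_time"][...], change_time=f["change_time"][...],
            target_first=f["target_first"][...].astype(bool),
            correct=f["correct"][...].astype(bool), channel_meta=meta,
            subject_id=str(f.attrs["subject_id"]),
            derivation=str(f.attrs["derivation"]),
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    c = x - x.mean(axis=axis, keepdims=True)
    s = np.sqrt((c ** 2).sum(axis=axis, keepdims=True))
    s[s == 0] = np.inf
    return c / s


def rt_shuffle_null(gpr: np.ndarray, rt: np.ndarray, n_rand: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Null correlation spectra under RT shuffling.

    gpr: (n_units, n_freq, n_trials); the statistic is the unit-averaged
    Pearson correlation spectrum.  Returns (n_rand, n_freq).
    """
    n_trials = gpr.shape[-1]
    X = _standardize(gpr)                              # unit length per row
    perms = np.stack([rng.permutation(n_trials) for _ in range(n_rand)], axis=1)
    Y = _standardize(np.asarray(rt, float)[perms], axis=0)   # trials x n_rand
    null = np.einsum("uft,tr->ufr", X, Y).mean(axis=0)       # freq x n_rand
    return null.T


def _pairs_by_cluster(meta: pd.DataFrame, pairs: list, selected: np.ndarray,
                      cluster: tuple) -> list:
    areas = set(cluster)
    area = meta["area"].to_numpy()
    return [k for k, (i, j) in enumerate(pairs)
            if selected[k] and area[i] in areas and area[j] in areas]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir=None,
                 session: SessionRecording | None = None) -> dict:
    """Run the enabled stages in dependency order and return a results bundle.

    ``session`` replaces the simulate stage when a recording is supplied
    (e.g. loaded with ``read_session``).  With ``out_dir``, TSV tables, JSON
    summaries, the config echo, and a timing log are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    results: dict = {"config": config.to_dict()}
    seed = config.sim.seed if config.seed is None else config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**16 + 1]))
    stages = config.stages
    t_start = time.time()

    def _log(msg):
        log.append(f"[{time.time() - t_start:8.2f}s] {msg}")

    def _run(stage, fn):
        try:
            t0 = time.time()
            r = fn()
            _log(f"stage {stage}: done in {time.time() - t0:.2f}s")
            return r
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            err = PipelineStageError(stage, e)
            if out is not None:
                with open(out / "error.json", "w") as fh:
                    json.dump(err.record(), fh)
            raise err from e

    # -- simulate ------------------------------------------------------------
    if session is None:
        sim_cfg = config.sim if config.seed is None \
            else config.sim.replace(seed=config.seed)
        rec, gt = _run("simulate", lambda: simulate_session(sim_cfg))
        results["ground_truth_power_lag"] = gt.power_lag
    else:
        rec, gt = session, None
    if "preprocess" not in stages:
        results["log"] = log
        return results

    # -- preprocess ----------------------------------------------------------
    def _preprocess():
        bp = bipolar_derive(rec)
        lined = condition_signal(bp, steps=("line",))
        mask = clean_and_select_trials(lined)
        clean = condition_signal(lined, keep=mask.keep,
                                 steps=("detrend", "normalize"))
        return clean, mask

    clean, mask = _run("preprocess", _preprocess)
    keep = mask.keep
    rt = clean.rt[keep]
    condition = clean.condition[keep]
    meta = clean.channel_meta
    results["n_trials_used"] = int(keep.sum())
    if out is not None:
        mask.to_frame().to_csv(out / "trial_mask.tsv", sep="\t", index=False)

    if "ppc" not in stages:
        results["log"] = log
        return results

    # -- spectra, PPC, selection, clusters, alignment ------------------------
    def _ppc():
        epochs = extract_epochs(clean, "power-ppc-gpr", keep)
        frame = fft_epochs(epochs)
        frame_high = fft_epochs(epochs, fmin=101.0, fmax=200.0)
        pairs = inter_areal_pairs(meta)
        ppc = ppc_spectrum(frame, pairs, meta)
        ppc_high = ppc_spectrum(frame_high, pairs, meta)
        sel = select_site_pairs(ppc, ppc_high)
        # area-pair averages: over the selected site pairs of each area pair,
        # falling back to all its (non-artifact) site pairs so that every
        # area pair enters the pooled threshold statistics
        key = list(zip(ppc.pair_meta["area_a"], ppc.pair_meta["area_b"]))
        area_pairs, avg = [], []
        for ap in sorted(set(key)):
            member = np.array([k == ap for k in key])
            rows = member & sel.selected
            if not rows.any():
                rows = member & ~sel.artifact_excluded
            if not rows.any():
                rows = member
            area_pairs.append(ap)
            avg.append(ppc.ppc[rows].mean(axis=0))
        clusters = define_clusters(np.array(avg), area_pairs, frame.freqs)
        return frame, pairs, ppc, sel, clusters

    frame, pairs, ppc, sel, clusters = _run("ppc", _ppc)
    by_band = {c.band: c for c in clusters}
    if set(by_band) != {"gamma", "beta"} or len(clusters) != 2:
        raise PipelineStageError(
            "ppc", RuntimeError(f"expected one gamma and one beta cluster, "
                                f"got {clusters}"))
    align = {}
    cluster_pair_idx = {}
    for band, c in by_band.items():
        idx = _pairs_by_cluster(meta, pairs, sel.selected, c.areas)
        cluster_pair_idx[band] = idx
        spec = ppc.ppc[idx].mean(axis=0)
        align[band] = peak_align(spec, ppc.freqs, band, rec.subject_id)
    results["clusters"] = [
        {"areas": list(c.areas), "band": c.band,
         "peak_freq": align[c.band].peak_freq} for c in clusters]
    results["selection"] = {
        "n_pairs": len(pairs),
        "n_selected": int(sel.selected.sum()),
        "n_artifact_excluded": int(sel.artifact_excluded.sum()),
        "threshold": sel.threshold_value,
    }
    if out is not None:
        pd.DataFrame({
            "site_a": [p[0] for p in pairs], "site_b": [p[1] for p in pairs],
            "artifact_excluded": sel.artifact_excluded,
            "selected": sel.selected,
        }).to_csv(out / "selection.tsv", sep="\t", index=False)

    if "gpr" not in stages:
        results["log"] = log
        return results

    # -- GPR at all pooling levels, with RT-shuffle inference ----------------
    def _gpr():
        gpr_results = {}
        cluster_gpr_peak = {}   # band -> per-trial GPR at offset 0, full length
        for band, c in by_band.items():
            pk = align[band]
            freqs_al = pk.aligned_freqs()
            offsets = freqs_al - pk.peak_freq
            idx = cluster_pair_idx[band]
            pair_list = [pairs[k] for k in idx]
            area_of = meta["area"].to_numpy()
            per_cond = {}
            for cond in ("IN", "OUT"):
                tr = np.flatnonzero(condition == cond)
                sub = frame.coeff[:, :, tr]
                subframe = SpectralFrame(sub, frame.freqs, frame.taper,
                                         frame.epoch_window)
                dev, _ = rotated_deviations(subframe, pair_list, freqs_al)
                rt_c = rt[tr]
                # site-pair level
                gpr_site = np.cos(dev)
                r_site = np.stack([pearson_rows(g, rt_c) for g in gpr_site])
                # area-pair level
                ap_key = [(area_of[a], area_of[b]) for a, b in pair_list]
                r_area = []
                for ap in sorted(set(ap_key)):
                    m = np.array([k == ap for k in ap_key])
                    gpr_ap = np.cos(dev[m].mean(axis=0))
                    r_area.append(pearson_rows(gpr_ap, rt_c))
                # cluster level
                gpr_cl = np.cos(dev.mean(axis=0))
                r_cluster = pearson_rows(gpr_cl, rt_c)
                null = rt_shuffle_null(gpr_site, rt_c, config.n_rand, rng)
                rand = max_corrected_from_null(r_site.mean(axis=0), null)
                per_cond[cond] = {
                    "offsets": offsets,
                    "site": r_site.mean(axis=0),
                    "area": np.mean(r_area, axis=0),
                    "cluster": r_cluster,
                    "lo": rand.lo_threshold, "hi": rand.hi_threshold,
                    "significant": rand.significant,
                    "dev": dev, "trials": tr,
                }
                peak_col = int(np.argmin(np.abs(offsets)))
                g_full = np.full(len(rt), np.nan)
                g_full[tr] = gpr_cl[peak_col]
                cluster_gpr_peak.setdefault(band, np.full(len(rt), np.nan))
                cluster_gpr_peak[band][tr] = g_full[tr]
            gpr_results[band] = per_cond

        # controls on the gamma system, attend-IN: RT-quintile PPC contrast
        # and the power-RT correlation spectrum
        gband = by_band["gamma"]
        g_idx = cluster_pair_idx["gamma"]
        tr_in = np.flatnonzero(condition == "IN")
        sub_in = SpectralFrame(frame.coeff[:, :, tr_in], frame.freqs,
                               frame.taper, frame.epoch_window)
        _, _, quintile_diff = rt_quintile_ppc_contrast(
            sub_in, rt[tr_in], [pairs[k] for k in g_idx])
        occ_sites = sorted({s for k in g_idx for s in pairs[k]})
        pw = power_spectra(SpectralFrame(sub_in.coeff[occ_sites], frame.freqs,
                                         frame.taper, frame.epoch_window),
                           average=False)
        power_rt = power_rt_correlation(pw, rt[tr_in])
        controls = {"quintile_ppc_diff": quintile_diff,
                    "power_rt_r": power_rt, "freqs": frame.freqs}

        # population level: average deviations over both clusters on the
        # common peak-relative axis (+/- the smaller halfwidth)
        half = min(BAND_HALFWIDTHS.values())
        common = np.arange(-half, half + 1.0)
        pop = {}
        for cond in ("IN", "OUT"):
            devs = []
            for band in by_band:
                d = gpr_results[band][cond]
                cols = [int(np.flatnonzero(d["offsets"] == o)[0])
                        for o in common]
                devs.append(d["dev"][:, cols, :].mean(axis=0))
            gpr_pop = np.cos(np.mean(devs, axis=0))
            tr = gpr_results[list(by_band)[0]][cond]["trials"]
            pop[cond] = {"offsets": common,
                         "r": pearson_rows(gpr_pop, rt[tr])}
        cross = cross_cluster_gpr_correlation(
            cluster_gpr_peak["gamma"], cluster_gpr_peak["beta"], condition,
            n_rand=config.n_rand, rng=rng)
        return gpr_results, pop, cross, controls

    gpr_results, pop, cross, controls = _run("gpr", _gpr)
    results["gpr_rt"] = {
        band: {cond: {"offsets": d["offsets"].tolist(),
                      "site": d["site"].tolist(),
                      "area": np.asarray(d["area"]).tolist(),
                      "cluster": d["cluster"].tolist(),
                      "lo": d["lo"], "hi": d["hi"],
                      "significant": d["significant"].tolist()}
               for cond, d in per_cond.items()}
        for band, per_cond in gpr_results.items()}
    results["gpr_rt_population"] = {
        cond: {"offsets": d["offsets"].tolist(), "r": d["r"].tolist()}
        for cond, d in pop.items()}
    results["cross_cluster_gpr"] = cross
    results["controls"] = {
        "freqs": controls["freqs"].tolist(),
        "quintile_ppc_diff": np.asarray(
            controls["quintile_ppc_diff"]).tolist(),
        "power_rt_r": np.asarray(controls["power_rt_r"]).tolist(),
    }
    if out is not None:
        rows = []
        for band, per_cond in gpr_results.items():
            for cond, d in per_cond.items():
                for i, o in enumerate(d["offsets"]):
                    rows.append({"band": band, "condition": cond,
                                 "freq_offset": o, "r_site": d["site"][i],
                                 "r_area": d["area"][i],
                                 "r_cluster": d["cluster"][i],
                                 "lo": d["lo"], "hi": d["hi"],
                                 "significant": bool(d["significant"][i])})
        pd.DataFrame(rows).to_csv(out / "gpr_rt.tsv", sep="\t", index=False)

    # -- GC (cross-cluster, top-down vs bottom-up) ---------------------------
    if "gc" in stages:
        def _gc():
            epochs_gc = extract_epochs(clean, "gc", keep)
            frame_gc = fft_epochs(epochs_gc, fmin=None)
            occ_areas = set(by_band["gamma"].areas)
            fc_areas = set(by_band["beta"].areas)
            area_of = meta["area"].to_numpy()
            # inter-cluster pairs get their own mean+3SD selection, pooled
            # over the respective (inter-cluster) PPC values only
            inter = np.array([
                (area_of[i] in occ_areas and area_of[j] in fc_areas) or
                (area_of[i] in fc_areas and area_of[j] in occ_areas)
                for i, j in pairs])
            usable = inter & ~sel.artifact_excluded
            pooled = ppc.ppc[usable].ravel()
            thr = pooled.mean() + 3.0 * pooled.std()
            cand = []
            for k in np.flatnonzero(usable):
                if not (ppc.ppc[k] > thr).any():
                    continue
                i, j = pairs[k]
                p = (j, i) if area_of[i] in occ_areas else (i, j)
                cand.append((k, p))      # ordered (fc, occ): dir 0 = top-down
            if not cand:
                raise RuntimeError("no selected inter-cluster site pair")
            beta_pk = align["beta"]
            bcol = ppc.freqs == beta_pk.peak_freq
            cand.sort(key=lambda kp: -float(ppc.ppc[kp[0], bcol][0]))
            gc_pairs = [p for _, p in cand[: config.max_gc_pairs]]
            out_gc = {"pairs": gc_pairs}
            for cond in ("IN", "OUT"):
                tr = np.flatnonzero(condition == cond)
                subframe = SpectralFrame(frame_gc.coeff[:, :, tr],
                                         frame_gc.freqs, frame_gc.taper,
                                         frame_gc.epoch_window)
                spectra = []
                for p in gc_pairs:
                    csd = estimate_csd(subframe, p)
                    fact = wilson_factorize(csd, tol=config.gc_tol,
                                            max_iter=config.gc_max_iter,
                                            strict=False)
                    spectra.append(granger_spectrum(fact, csd).gc)
                jack = gc_rt_correlation(subframe, gc_pairs, rt[tr],
                                         tol=config.gc_tol,
                                         max_iter=config.gc_max_iter)
                out_gc[cond] = {"freqs": frame_gc.freqs,
                                "gc_mean": np.mean(spectra, axis=0),
                                "gc_rt": jack["mean"]}
            return out_gc

        gc_out = _run("gc", _gc)
        fsel = (gc_out["IN"]["freqs"] >= 1) & (gc_out["IN"]["freqs"] <= 95)
        results["gc"] = {
            "pairs": [list(map(int, p)) for p in gc_out["pairs"]],
            "freqs": gc_out["IN"]["freqs"][fsel].tolist(),
        }
        for cond in ("IN", "OUT"):
            results["gc"][cond] = {
                "topdown": gc_out[cond]["gc_mean"][fsel, 0].tolist(),
                "bottomup": gc_out[cond]["gc_mean"][fsel, 1].tolist(),
                "gc_rt_topdown": gc_out[cond]["gc_rt"][fsel, 0].tolist(),
                "gc_rt_bottomup": gc_out[cond]["gc_rt"][fsel, 1].tolist(),
            }
        if out is not None:
            rows = []
            for cond in ("IN", "OUT"):
                d = results["gc"][cond]
                for i, f in enumerate(results["gc"]["freqs"]):
                    rows.append({"condition": cond, "freq": f,
                                 "gc_topdown": d["topdown"][i],
                                 "gc_bottomup": d["bottomup"][i],
                                 "gc_rt_topdown": d["gc_rt_topdown"][i],
                                 "gc_rt_bottomup": d["gc_rt_bottomup"][i]})
            pd.DataFrame(rows).to_csv(out / "gc.tsv", sep="\t", index=False)

    # -- lagged power-power correlation --------------------------------------
    if "lag" in stages:
        def _lag():
            pc = sliding_band_power(clean, band=config.lag_band, keep=keep)
            occ_sites = meta["cluster"].to_numpy() == "occipital"
            fc_sites = meta["cluster"].to_numpy() == "frontocentral"
            out_lag = {}
            for cond in ("IN", "OUT"):
                tr = np.flatnonzero(condition == cond)
                pa = PowerTimecourse(pc.power[fc_sites][:, :, tr],
                                     pc.window_centers, pc.band)
                pb = PowerTimecourse(pc.power[occ_sites][:, :, tr],
                                     pc.window_centers, pc.band)
                out_lag[cond] = lagged_power_correlation(
                    pa, pb, n_surrogates=config.lag_surrogates, rng=rng)
            return out_lag

        lag_out = _run("lag", _lag)
        results["lag"] = {
            cond: {"lags_ms": lc.lags_ms.tolist(), "r": lc.r.tolist(),
                   "peak_lag_ms": lc.peak_lag_ms,
                   "lo": None if lc.lo_threshold is None
                   else float(lc.lo_threshold[0]),
                   "hi": None if lc.hi_threshold is None
                   else float(lc.hi_threshold[0])}
            for cond, lc in lag_out.items()}
        if out is not None:
            rows = []
            for cond, lc in lag_out.items():
                for i, lag in enumerate(lc.lags_ms):
                    rows.append({"condition": cond, "lag_ms": lag,
                                 "r": lc.r[i]})
            pd.DataFrame(rows).to_csv(out / "lag.tsv", sep="\t", index=False)

    if out is not None:
        config.to_json(out / "config_echo.json")
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonable(results), fh, indent=1)   # timings stay out
        with open(out / "log.txt", "w") as fh:
            fh.write("\n".join(log) + "\n")
    results["log"] = log
    return results


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer, np.bool_)):
        return x.item()
    return x
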