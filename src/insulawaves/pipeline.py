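"""End-to-end orchestration: synth -> preprocess -> spectral -> gradients ->
clusters -> waves -> coupling, with deterministic outputs and a run
manifest.

A single seed in the study config fans out (via ``numpy.random.SeedSequence``)
to per-stage child seeds, so each stage is reproducible in isolation.  All
tabular outputs are TSV, summaries JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import coupling as cp
from . import gradients as gr
from . import preprocess as pp
from . import spectral as sp
from . import synth
from . import waves as wv
from .io import write_json, write_tsv

logger = logging.getLogger("insulawaves")

STAGES = ("synth", "preprocess", "spectral", "gradients", "clusters",
          "waves", "coupling")

GRADIENT_BAND_FALLBACK = {"theta": (6.0, 9.0), "beta": (15.0, 32.0)}


@dataclasses.dataclass
class PipelineParams:
    """Tunables of the analysis stages (the study config describes the data;
    these describe the analysis)."""

    notch_hz: float = 60.0
    epoch_s: float = 1.0
    psd_linear: tuple = (1.0, 50.0, 0.1)     # fmin, fmax, step
    psd_log: tuple = (3.0, 40.0, 200)        # fmin, fmax, n points
    cluster_distance_mm: float = 20.0
    cluster_min_size: int = 4
    fit_stride_s: float = 0.02               # spacing of wave-fit timepoints
    n_perm: int = 100
    surrogate_subsample: int = 10            # surrogate fits every k-th timepoint
    sig_level: float = 0.05
    n_shuffles: int = 200                    # coupling circular shuffles
    max_lag_ms: float = 100.0


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict
    outputs: dict

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RunResult:
    study: synth.Study
    preprocessed: dict
    spectra: dict
    gradient_table: pd.DataFrame | None
    clusters: list
    wave_results: dict
    coupling_results: list
    manifest: RunManifest


def _stage_preprocess(study: synth.Study, params: PipelineParams) -> dict:
    out = {}
    for subject, rec in study.recordings.items():
        cleaned_kw = dict(line_hz=params.notch_hz, epoch_s=params.epoch_s)
        bipolar = pp.clean(pp.rereference(rec, "bipolar"), **cleaned_kw)
        car = pp.clean(pp.rereference(rec, "common_average"), **cleaned_kw)
        out[subject] = {"bipolar": bipolar, "car": car}
    return out


def _stage_spectral(preprocessed: dict, params: PipelineParams) -> dict:
    """Per subject: 491-point linear-grid spectra on the bipolar recording
    (gradient path) and 200-point log-grid spectra on the common-average
    recording (cluster path, so cluster members map directly onto the wave
    analysis channels)."""

    fmin, fmax, step = params.psd_linear
    lmin, lmax, npts = params.psd_log
    out = {}
    for subject, recs in preprocessed.items():
        lin = sp.fit_spectra(sp.compute_psd(recs["bipolar"], "linear",
                                            fmin, fmax, step))
        log = sp.fit_spectra(sp.compute_psd(recs["car"], "log",
                                            lmin, lmax, npts))
        out[subject] = {"linear": lin, "log": log}
    return out


def _gradient_band_edges(spectra: dict) -> dict:
    """Study-level theta/beta band edges: MODAL bands of the pooled average
    spectrum, falling back to the canonical ~6-9 / ~15-32 Hz ranges when a
    band is not detected."""

    fits = [s["linear"] for s in spectra.values()]
    pooled = sp.SpectrumFit(
        freqs=fits[0].freqs,
        psd=np.vstack([f.psd for f in fits]),
        channel_ids=[c for f in fits for c in f.channel_ids])
    edges = dict(GRADIENT_BAND_FALLBACK)
    for band in sp.reference_bands(pooled):
        name = sp.label_band(band.edge_low, band.edge_high)
        if name in edges:
            edges[name] = (band.edge_low, band.edge_high)
    return edges


def _stage_gradients(spectra: dict, preprocessed: dict,
                     band_edges: dict) -> pd.DataFrame:
    """Gradient models for frequency and power per band and hemisphere, on
    the bipolar (midpoint-coordinate) electrode tables; FDR applied across
    all reported p-values."""

    elec = pd.concat([preprocessed[s]["bipolar"].electrodes
                      for s in sorted(preprocessed)], ignore_index=True)
    peak_rows = []
    for subject in sorted(spectra):
        fit = spectra[subject]["linear"]
        for band, (lo, hi) in band_edges.items():
            bands = [sp.OscillationBand(electrode_id=c, band=band,
                                        edge_low=lo, edge_high=hi)
                     for c in fit.channel_ids]
            for p in sp.find_peaks(fit, bands):
                peak_rows.append({"subject": subject, "electrode_id": p.electrode_id,
                                  "band": band, "peak_freq": p.peak_freq,
                                  "peak_power": p.peak_power})
    peaks = pd.DataFrame(peak_rows)

    fits = []
    for band in sorted(band_edges):
        sub = peaks[peaks["band"] == band].set_index(["subject", "electrode_id"])
        keys = list(zip(elec["subject"], elec["name"]))
        freq = np.array([sub["peak_freq"].get(k, np.nan) for k in keys])
        power = np.array([sub["peak_power"].get(k, np.nan) for k in keys])
        for measure, vals in (("frequency", freq), ("power", power)):
            for hemi in ("left", "right"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fits.append(gr.fit_gradient_model(
                            vals, elec, hemisphere=hemi,
                            dependent=f"{band}_{measure}"))
                except ValueError as err:
                    logger.warning("gradient fit skipped (%s %s %s): %s",
                                   band, measure, hemi, err)
    if not fits:
        return pd.DataFrame()
    table = gr.gradient_table(fits)
    table["q"] = gr.fdr_correct(table["p"].to_numpy())
    return table


def _stage_clusters(spectra: dict, study: synth.Study,
                    params: PipelineParams) -> list:
    peak_frames = []
    for subject in sorted(spectra):
        df = sp.peaks_table(sp.find_peaks(spectra[subject]["log"]))
        peak_frames.append(df)
    peaks = pd.concat(peak_frames, ignore_index=True) if peak_frames \
        else pd.DataFrame(columns=["electrode_id", "peak_freq", "peak_power"])
    return cl.find_oscillation_clusters(
        peaks, study.electrodes, distance_mm=params.cluster_distance_mm,
        min_size=params.cluster_min_size)


def _fit_time_idx(rec_mask: np.ndarray, fs: float, stride_s: float,
                  guard_s: float) -> np.ndarray:
    """Retained sample indices at the fit stride, excluding a guard band at
    the recording edges (filter/Hilbert transients)."""

    stride = max(int(round(stride_s * fs)), 1)
    guard = int(round(guard_s * fs))
    idx = np.arange(guard, rec_mask.size - guard, stride)
    return idx[rec_mask[idx]]


def _stage_waves(preprocessed: dict, cluster_list: list, study: synth.Study,
                 params: PipelineParams, seed_seq: np.random.SeedSequence
                 ) -> dict:
    results = {}
    child_seeds = seed_seq.spawn(max(len(cluster_list), 1))
    for cluster, child in zip(cluster_list, child_seeds):
        rec = preprocessed[cluster.subject_id]["car"]
        field = wv.phase_timeseries(rec, cluster)
        subclusters = wv.make_subclusters(
            cluster, study.electrodes,
            radius_mm=params.cluster_distance_mm,
            min_size=params.cluster_min_size)
        if not subclusters:
            logger.warning("cluster %s: no subclusters of size >= %d",
                           cluster.cluster_id, params.cluster_min_size)
            continue
        guard_s = 2.0 / cluster.f_p
        time_idx = _fit_time_idx(rec.sample_mask, rec.fs,
                                 params.fit_stride_s, guard_s)
        surr_idx = time_idx[::params.surrogate_subsample]
        test = wv.spatial_shuffle_test(
            field, subclusters, time_idx, n_perm=params.n_perm,
            seed=np.random.default_rng(child),
            surrogate_time_idx=surr_idx, sig_level=params.sig_level)
        summary = wv.summarize_waves(
            cluster.cluster_id, cluster.f_p, field.times[time_idx],
            test["observed"], test["sig_mask"], p_cluster=test["p_cluster"])
        results[cluster.cluster_id] = {
            "cluster": cluster, "field": field, "subclusters": subclusters,
            "time_idx": time_idx, "test": test, "summary": summary,
        }
    return results


def _mean_amplitude(res: dict) -> np.ndarray:
    """Cluster mean Hilbert amplitude at the fitted timepoints."""
    return res["field"].amplitude[:, res["time_idx"]].mean(axis=0)


def _mean_phase(res: dict) -> np.ndarray:
    """Circular-mean phase (deg) across cluster electrodes at fit times."""
    ph = np.deg2rad(res["field"].phases[:, res["time_idx"]])
    return np.rad2deg(np.angle(np.exp(1j * ph).mean(axis=0))) % 360.0


def _stage_coupling(wave_results: dict, params: PipelineParams,
                    seed_seq: np.random.SeedSequence) -> list:
    results = []
    items = sorted(wave_results.items())
    child = iter(seed_seq.spawn(3 * max(len(items), 1) + 64))
    fs_fit = 1.0 / params.fit_stride_s
    for cid, res in items:
        amp = _mean_amplitude(res)
        strength = res["summary"].strength
        r = cp.amplitude_strength_correlation(
            amp, strength, n_shuffles=params.n_shuffles,
            seed=np.random.default_rng(next(child)), label=cid)
        try:
            r.lag_ms = cp.lag_by_crosscorr(amp, strength, fs_fit,
                                           max_lag_ms=params.max_lag_ms)
        except ValueError:
            r.lag_ms = None
        results.append(r)

    # theta-beta independence on cluster pairs sharing electrodes
    for cid_t, res_t in items:
        if res_t["cluster"].band != "theta":
            continue
        for cid_b, res_b in items:
            if res_b["cluster"].band != "beta":
                continue
            if res_b["cluster"].subject_id != res_t["cluster"].subject_id:
                continue
            shared = set(res_t["cluster"].members) & set(res_b["cluster"].members)
            if len(shared) < params.cluster_min_size:
                continue
            n = min(res_t["summary"].strength.size,
                    res_b["summary"].strength.size)
            results.extend(cp.cross_frequency_independence(
                res_t["summary"].strength[:n],
                _mean_amplitude(res_t)[:n] ** 2,
                _mean_phase(res_t)[:n],
                res_b["summary"].strength[:n],
                n_shuffles=params.n_shuffles,
                seed=np.random.default_rng(next(child)),
                label=f"{cid_t}|{cid_b}"))
    return results


def _write_outputs(out_dir: Path, result: "RunResult",
                   params: PipelineParams) -> dict:
    outputs = {}
    synth.write_study(result.study, out_dir)
    outputs["study"] = ["config.json", "electrodes.tsv", "waves_truth.tsv"]
    if result.gradient_table is not None and not result.gradient_table.empty:
        write_tsv(result.gradient_table, out_dir / "gradients.tsv")
        outputs["gradients"] = ["gradients.tsv"]
    write_tsv(cl.clusters_table(result.clusters), out_dir / "clusters.tsv")
    outputs["clusters"] = ["clusters.tsv"]
    wave_files = []
    summary = {"clusters": []}
    for cid, res in sorted(result.wave_results.items()):
        s = res["summary"]
        fit = res["test"]["observed"]
        alpha_stack = np.vstack([np.deg2rad(np.where(np.isfinite(r["alpha"]),
                                                     r["alpha"], np.nan))
                                 for r in fit["per_sub"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha_mode = np.rad2deg(np.angle(
                np.nanmean(np.exp(1j * alpha_stack), axis=0))) % 360.0
            xi_med = np.nanmedian(np.vstack(
                [np.where(r["xi"] > 0, r["xi"], np.nan)
                 for r in fit["per_sub"]]), axis=0)
        speed = np.where(xi_med > 0,
                         res["cluster"].f_p * (360.0 / xi_med) / 1000.0, np.nan)
        df = pd.DataFrame({
            "time": s.times, "mean_rho2_adj": s.strength,
            "alpha_mode_deg": alpha_mode, "xi_deg_mm": xi_med,
            "speed_m_s": speed, "significant": s.sig_mask.astype(int)})
        fname = f"waves_{cid}.tsv"
        write_tsv(df, out_dir / fname)
        wave_files.append(fname)
        summary["clusters"].append({
            "cluster_id": cid, "band": res["cluster"].band,
            "f_p": res["cluster"].f_p, "n_members": len(res["cluster"].members),
            "prevalence": s.prevalence, "p_cluster": s.p_cluster,
            "median_speed_m_s": s.median_speed})
    outputs["waves"] = wave_files
    if result.wave_results:
        prevs = [c["prevalence"] for c in summary["clusters"]]
        speeds = np.concatenate([res["summary"].speeds
                                 for res in result.wave_results.values()]) \
            if any(r["summary"].speeds.size for r in result.wave_results.values()) \
            else np.array([np.nan])
        summary["mean_prevalence"] = float(np.mean(prevs))
        summary["median_speed_m_s"] = float(np.nanmedian(speeds))
    coup_rows = [dataclasses.asdict(r) for r in result.coupling_results]
    if coup_rows:
        write_tsv(pd.DataFrame(coup_rows), out_dir / "coupling.tsv")
        outputs["coupling"] = ["coupling.tsv"]
    write_json(summary, out_dir / "summary.json")
    write_json(result.manifest.to_dict(), out_dir / "manifest.json")
    outputs["summary"] = ["summary.json", "manifest.json"]
    return outputs


def run_study(config: synth.StudyConfig, out_dir=None,
              params: PipelineParams | None = None,
              auto_waves: bool = True) -> RunResult:
    """Run the full pipeline on a synthetic study defined by ``config``.

    All stage outputs are written under ``out_dir`` when given; the returned
    :class:`RunResult` keeps everything in memory.  Identical configs yield
    identical scientific outputs.
    """

    params = params or PipelineParams()
    stage_seconds = {}
    seed_seq = np.random.SeedSequence(config.seed ^ 0x5EED)
    waves_seed, coupling_seed = seed_seq.spawn(2)

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        out = fn(*args, **kw)
        stage_seconds[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-10s %.1f s", name, stage_seconds[name])
        return out

    study = timed("synth", synth.make_study, config, auto_waves=auto_waves)
    preprocessed = timed("preprocess", _stage_preprocess, study, params)
    spectra = timed("spectral", _stage_spectral, preprocessed, params)
    band_edges = _gradient_band_edges(spectra)
    gradient_table = timed("gradients", _stage_gradients, spectra,
                           preprocessed, band_edges)
    cluster_list = timed("clusters", _stage_clusters, spectra, study, params)
    wave_results = timed("waves", _stage_waves, preprocessed, cluster_list,
                         study, params, waves_seed)
    coupling_results = timed("coupling", _stage_coupling, wave_results,
                             params, coupling_seed)

    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True,
                   default=str).encode()).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=config.seed,
                           stage_seconds=stage_seconds, outputs={})
    result = RunResult(study=study, preprocessed=preprocessed, spectra=spectra,
                       gradient_table=gradient_table, clusters=cluster_list,
                       wave_results=wave_results,
                       coupling_results=coupling_results, manifest=manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.outputs = _write_outputs(out_dir, result, params)
        write_json(manifest.to_dict(), out_dir / "manifest.json")
    return result
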