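"""Morlet-wavelet spectra, robust 1/f fitting and narrowband peak detection.

The aperiodic background of an iEEG power spectrum follows a power law
(1/f^beta); genuine oscillations appear as narrowband deviations above it.
The detection scheme here fits a robust (bisquare) line to log-power versus
log-frequency, subtracts it, and flags contiguous frequency runs where the
normalized spectrum exceeds one standard deviation of the fit residuals
(the MODAL rule).  Narrowband peaks — local maxima of the normalized
spectrum more than one SD above its mean — feed the spatial clustering
stage.

Two frequency grids are used downstream: a 491-point linear grid from 1 to
50 Hz (0.1 Hz steps) for the gradient analyses, and a 200-point
log-spaced grid from 3 to 40 Hz for cluster building.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Recording

N_CYCLES_DEFAULT = 6.0


def frequency_grid(kind: str = "linear", fmin: float = 1.0, fmax: float = 50.0,
                   n_or_step: float = 0.1) -> np.ndarray:
    """Frequency grid: linear with step ``n_or_step`` (inclusive of fmax when
    it falls on the grid) or log-spaced with ``n_or_step`` points."""

    if kind == "linear":
        n = int(round((fmax - fmin) / n_or_step)) + 1
        return fmin + n_or_step * np.arange(n)
    if kind == "log":
        return np.logspace(np.log10(fmin), np.log10(fmax), int(n_or_step))
    raise ValueError(f"unknown grid kind: {kind}")


@dataclasses.dataclass
class SpectrumFit:
    """Per-electrode mean power spectra plus (after fitting) the robust 1/f
    line and the normalized spectrum (log10 power minus fitted line)."""

    freqs: np.ndarray              # (n_freqs,)
    psd: np.ndarray                # (n_channels, n_freqs), linear power
    channel_ids: list
    slope: np.ndarray | None = None        # (n_channels,)
    intercept: np.ndarray | None = None
    normalized: np.ndarray | None = None   # (n_channels, n_freqs), log10 units
    resid_sd: np.ndarray | None = None


@dataclasses.dataclass
class OscillationBand:
    electrode_id: str
    band: str                 # 'theta', 'beta' or 'other'
    edge_low: float
    edge_high: float
    peak_freq: float | None = None
    peak_power: float | None = None  # normalized (above-fit) log10 units
    peak_power_raw: float | None = None


def compute_psd(rec: Recording, grid: str = "linear", fmin: float = 1.0,
                fmax: float = 50.0, n_or_step: float = 0.1,
                n_cycles: float = N_CYCLES_DEFAULT,
                chunk: int = 20) -> SpectrumFit:
    """Mean-over-time Morlet wavelet power per electrode and grid frequency.

    Wavelets have ``n_cycles`` cycles at every frequency (duration
    sigma_t = n_cycles / (2 pi f)).  Samples excluded by ``rec.sample_mask``
    do not enter the time average.  Frequencies are processed in chunks to
    bound memory.
    """

    from mne.time_frequency import tfr_array_morlet

    if fmax >= rec.fs / 2.0:
        raise ValueError("fmax must be below Nyquist")
    mask = rec.sample_mask
    if not mask.any():
        raise ValueError("sample mask excludes all samples")
    freqs = frequency_grid(grid, fmin, fmax, n_or_step)
    x = rec.data[np.newaxis]  # (1, n_ch, n_times)
    psd = np.empty((rec.n_channels, freqs.size))
    for start in range(0, freqs.size, chunk):
        fband = freqs[start:start + chunk]
        power = tfr_array_morlet(x, sfreq=rec.fs, freqs=fband,
                                 n_cycles=n_cycles, output="power",
                                 verbose="error")[0]  # (n_ch, n_f, n_t)
        psd[:, start:start + chunk] = power[:, :, mask].mean(axis=2)
    return SpectrumFit(freqs=freqs, psd=psd, channel_ids=list(rec.channel_ids))


def fit_one_over_f(spectrum: np.ndarray, freqs: np.ndarray
                   ) -> tuple[float, float, float, np.ndarray]:
    """Robust (bisquare) line fit of log10 power on log10 frequency.

    Returns (slope, intercept, residual SD, normalized spectrum), the
    normalized spectrum being observed log-power minus the fitted line.
    The residual SD is computed with the bisquare weights, so a narrow
    oscillatory bump inflates neither the line nor the SD.
    """

    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size < 10:
        raise ValueError("need at least 10 grid points")
    if np.any(spectrum <= 0):
        raise ValueError("powers must be positive")
    logf = np.log10(freqs)
    logp = np.log10(spectrum)
    X = sm.add_constant(logf)
    ols = sm.OLS(logp, X).fit()
    if np.sqrt(ols.ssr / logp.size) < 1e-12:
        # numerically perfect line (exact power law / flat spectrum): the
        # IRLS scale estimate degenerates, so keep the OLS solution
        intercept, slope = ols.params
        return float(slope), float(intercept), 0.0, \
            logp - (intercept + slope * logf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(logp, X, M=sm.robust.norms.TukeyBiweight()).fit()
    intercept, slope = fit.params
    normalized = logp - (intercept + slope * logf)
    w = fit.weights
    wsum = w.sum()
    if wsum > 0:
        resid_sd = float(np.sqrt((w * normalized ** 2).sum() / wsum))
    else:  # pragma: no cover - bisquare degenerate fallback
        resid_sd = float(normalized.std())
    return float(slope), float(intercept), resid_sd, normalized


def fit_spectra(fit: SpectrumFit) -> SpectrumFit:
    """Apply :func:`fit_one_over_f` to every electrode in place."""

    n_ch = fit.psd.shape[0]
    fit.slope = np.empty(n_ch)
    fit.intercept = np.empty(n_ch)
    fit.resid_sd = np.empty(n_ch)
    fit.normalized = np.empty_like(fit.psd)
    for i in range(n_ch):
        s, b, sd, norm = fit_one_over_f(fit.psd[i], fit.freqs)
        fit.slope[i], fit.intercept[i], fit.resid_sd[i] = s, b, sd
        fit.normalized[i] = norm
    return fit


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) index pairs (stop inclusive)."""
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, above.size - 1))
    return runs


def detect_bands_modal(fit: SpectrumFit, min_width: int = 3,
                       channel: int | None = None) -> list[OscillationBand]:
    """MODAL band detection: contiguous grid runs where the normalized
    spectrum exceeds one residual SD, at least ``min_width`` points wide.

    With ``channel=None`` all electrodes are scanned; band labels are left
    ``other`` here and assigned later against reference ranges.
    """

    if fit.normalized is None:
        fit = fit_spectra(fit)
    channels = range(fit.psd.shape[0]) if channel is None else [channel]
    bands = []
    for i in channels:
        # floor guards the exact-power-law case, where the residual SD is
        # numerically zero and rounding noise would otherwise become "bands"
        above = fit.normalized[i] > max(fit.resid_sd[i], 1e-9)
        for start, stop in _runs(above):
            if stop - start + 1 < min_width:
                continue
            bands.append(OscillationBand(
                electrode_id=fit.channel_ids[i], band="other",
                edge_low=float(fit.freqs[start]),
                edge_high=float(fit.freqs[stop])))
    return bands


def reference_bands(fit: SpectrumFit, min_width: int = 3) -> list[OscillationBand]:
    """MODAL bands of the electrode-average spectrum, used as the study-level
    reference ranges for labeling theta/beta."""

    mean_fit = SpectrumFit(freqs=fit.freqs,
                           psd=fit.psd.mean(axis=0, keepdims=True),
                           channel_ids=["average"])
    return detect_bands_modal(fit_spectra(mean_fit), min_width=min_width)


def label_band(f_low: float, f_high: float,
               band_ranges: dict | None = None) -> str:
    """Label a band by overlap with reference ranges (largest overlap wins)."""

    if band_ranges is None:
        band_ranges = {"theta": (6.0, 9.0), "beta": (15.0, 32.0)}
    best, best_ov = "other", 0.0
    for name, (lo, hi) in band_ranges.items():
        ov = min(f_high, hi) - max(f_low, lo)
        if ov > best_ov:
            best, best_ov = name, ov
    return best


def find_peaks(fit: SpectrumFit, bands: list[OscillationBand] | None = None,
               band_ranges: dict | None = None) -> list[OscillationBand]:
    """Attach peak frequency/power to detected bands, or search globally.

    With ``bands`` given: per band, the peak is the argmax of the normalized
    spectrum inside the band (a monotone band peaks at its edge).  Without
    ``bands``: per electrode, all local maxima of the normalized spectrum
    greater than one SD above its mean are reported (the rule used for
    cluster building).  Peak power is in normalized (above-fit) log10 units;
    the raw log10 power is exported alongside.
    """

    if fit.normalized is None:
        fit = fit_spectra(fit)
    idx = {c: i for i, c in enumerate(fit.channel_ids)}
    out = []
    if bands is not None:
        for band in bands:
            i = idx[band.electrode_id]
            sel = (fit.freqs >= band.edge_low) & (fit.freqs <= band.edge_high)
            if not sel.any():
                warnings.warn(f"empty band {band.edge_low}-{band.edge_high} Hz; skipped")
                continue
            seg = fit.normalized[i][sel]
            fseg = fit.freqs[sel]
            j = int(np.argmax(seg))
            out.append(OscillationBand(
                electrode_id=band.electrode_id,
                band=label_band(band.edge_low, band.edge_high, band_ranges),
                edge_low=band.edge_low, edge_high=band.edge_high,
                peak_freq=float(fseg[j]), peak_power=float(seg[j]),
                peak_power_raw=float(np.log10(fit.psd[i][sel][j]))))
        return out
    # global local-maxima rule
    for i, ch in enumerate(fit.channel_ids):
        norm = fit.normalized[i]
        thresh = norm.mean() + norm.std()
        interior = np.flatnonzero(
            (norm[1:-1] > norm[:-2]) & (norm[1:-1] >= norm[2:])) + 1
        for j in interior:
            if norm[j] <= thresh:
                continue
            f = float(fit.freqs[j])
            out.append(OscillationBand(
                electrode_id=ch, band=label_band(f, f, band_ranges),
                edge_low=f, edge_high=f,
                peak_freq=f, peak_power=float(norm[j]),
                peak_power_raw=float(np.log10(fit.psd[i, j]))))
    return out


def peaks_table(peaks: list[OscillationBand]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in peaks],
                        columns=["electrode_id", "band", "edge_low", "edge_high",
                                 "peak_freq", "peak_power", "peak_power_raw"])
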