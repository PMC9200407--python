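"""Referencing, line-noise removal and spectrum-based artifact rejection.

Two reference schemes are supported, matching standard stereo-EEG practice:
bipolar (each contact minus its nearest same-subject neighbor, used for
spectral gradient analyses) and common average (used for traveling-wave
analyses).  Line noise is removed with a zero-phase IIR notch at the mains
frequency and its harmonics.  Artifact rejection is epoch-wise: the mean
log-spectrum (1-50 Hz) of each fixed-length epoch is compared across epochs
and epochs deviating by more than 3 standard deviations are masked out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import cdist

from .io import Recording


def rereference(rec: Recording, mode: str) -> Recording:
    """Re-reference a recording.

    ``common_average``: subtract the across-channel mean at each sample.
    ``bipolar``: subtract each channel's nearest neighbor (3-D Euclidean
    distance within subject; requires ``rec.electrodes``); the derived
    channel is assigned the midpoint coordinate of the pair.
    """

    if rec.n_channels < 2:
        raise ValueError("re-referencing requires at least 2 channels")
    out = rec.copy()
    if mode == "common_average":
        out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
        out.reference = "common_average"
        return out
    if mode != "bipolar":
        raise ValueError(f"unknown reference mode: {mode}")
    if rec.electrodes is None:
        raise ValueError("bipolar referencing requires electrode coordinates")
    coords = rec.electrodes[["x", "y", "z"]].to_numpy(dtype=float)
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.argmin(axis=1)
    out.data = rec.data - rec.data[nearest]
    elec = rec.electrodes.copy().reset_index(drop=True)
    mid = (coords + coords[nearest]) / 2.0
    elec[["x", "y", "z"]] = mid
    out.electrodes = elec
    out.reference = "bipolar"
    return out


def notch_filter(rec: Recording, line_hz: float = 60.0,
                 width_hz: float = 2.0) -> Recording:
    """Zero-phase IIR notch at ``line_hz`` and all harmonics below Nyquist."""

    out = rec.copy()
    nyq = rec.fs / 2.0
    f = line_hz
    while f < nyq - width_hz:
        b, a = signal.iirnotch(f, f / width_hz, fs=rec.fs)
        out.data = signal.filtfilt(b, a, out.data, axis=1)
        f += line_hz
    out.reference = rec.reference
    return out


def reject_epochs(rec: Recording, epoch_s: float = 1.0,
                  threshold_sd: float = 3.0,
                  fmin: float = 1.0, fmax: float = 50.0) -> Recording:
    """Mask epochs whose 1-50 Hz log-spectrum deviates from the across-epoch
    mean by more than ``threshold_sd`` standard deviations.

    The per-epoch statistic is the channel- and frequency-averaged log power
    (Welch periodogram over the epoch), which is scale-invariant: multiplying
    all channels by a constant shifts every epoch's statistic equally and
    changes no masking decision.
    """

    n_per = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    out = rec.copy()
    stats = np.empty(n_epochs)
    for e in range(n_epochs):
        seg = rec.data[:, e * n_per:(e + 1) * n_per]
        freqs, psd = signal.periodogram(seg, fs=rec.fs, axis=1)
        sel = (freqs >= fmin) & (freqs <= fmax)
        stats[e] = np.log10(psd[:, sel] + 1e-30).mean()
    dev = stats - stats.mean()
    sd = dev.std()
    bad = np.abs(dev) > threshold_sd * sd if sd > 0 else np.zeros(n_epochs, bool)
    mask = out.sample_mask
    for e in np.flatnonzero(bad):
        mask[e * n_per:(e + 1) * n_per] = False
    # samples beyond the last whole epoch keep their existing mask value
    out.sample_mask = mask
    return out


def clean(rec: Recording, line_hz: float = 60.0, epoch_s: float = 1.0,
          threshold_sd: float = 3.0) -> Recording:
    """Notch-filter line noise and harmonics, then mask artifact epochs."""

    nyq = rec.fs / 2.0
    if nyq <= line_hz:
        raise ValueError("sampling rate too low for the requested notch")
    out = notch_filter(rec, line_hz=line_hz)
    out = reject_epochs(out, epoch_s=epoch_s, threshold_sd=threshold_sd)
    return out


def epoch_retention(rec: Recording) -> float:
    """Fraction of samples retained by the artifact mask."""
    return float(rec.sample_mask.mean())
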