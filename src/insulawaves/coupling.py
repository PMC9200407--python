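"""Coupling between oscillation amplitude, wave-strength and frequency bands.

All tests use circular-shuffle surrogates: one series is rotated by a
random offset relative to the other, which preserves each series'
autocorrelation exactly while destroying their temporal alignment, so the
null distribution is valid for autocorrelated signals.  P-values carry the
+1 correction and are two-sided on |r| for Pearson statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal
from scipy.stats import pearsonr


@dataclasses.dataclass
class CouplingResult:
    label: str
    statistic: str        # e.g. 'amp-strength pearson', 'phase-strength circlin'
    value: float
    p: float
    lag_ms: float | None = None
    flagged: bool = False  # True when the statistic was undefined


def _circular_shuffle_null(x: np.ndarray, y: np.ndarray, stat,
                           n_shuffles: int, rng: np.random.Generator,
                           two_sided: bool = True) -> tuple[float, float]:
    obs = stat(x, y)
    offsets = rng.integers(1, x.size, size=n_shuffles)
    null = np.array([stat(x, np.roll(y, k)) for k in offsets])
    if two_sided:
        exceed = np.sum(np.abs(null) >= abs(obs))
    else:
        exceed = np.sum(null >= obs)
    return float(obs), float((1 + exceed) / (n_shuffles + 1))


def _pearson(x, y):
    return pearsonr(x, y)[0]


def amplitude_strength_correlation(amplitude: np.ndarray,
                                   strength: np.ndarray,
                                   n_shuffles: int = 200,
                                   seed: int | np.random.Generator = 0,
                                   label: str = "") -> CouplingResult:
    """Pearson correlation over time between a cluster's mean oscillation
    amplitude and its traveling-wave strength, with a circular-shuffle
    null."""

    amplitude = np.asarray(amplitude, dtype=float)
    strength = np.asarray(strength, dtype=float)
    if amplitude.shape != strength.shape:
        raise ValueError("series must have equal length")
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if amplitude.std() == 0 or strength.std() == 0:
        return CouplingResult(label=label, statistic="amp-strength pearson",
                              value=float("nan"), p=1.0, flagged=True)
    r, p = _circular_shuffle_null(amplitude, strength, _pearson,
                                  n_shuffles, rng)
    return CouplingResult(label=label, statistic="amp-strength pearson",
                          value=r, p=p)


def lag_by_crosscorr(amplitude: np.ndarray, strength: np.ndarray,
                     fs: float, max_lag_ms: float = 100.0) -> float:
    """Lag (ms) at the maximum of the normalized cross-correlation.

    Sign convention: positive lag means the amplitude series leads the
    strength series (strength is a delayed copy).  A flat cross-correlation
    (constant input) yields NaN.
    """

    amplitude = np.asarray(amplitude, dtype=float)
    strength = np.asarray(strength, dtype=float)
    max_lag = int(round(max_lag_ms * fs / 1000.0))
    if amplitude.size <= 2 * max_lag:
        raise ValueError("series shorter than twice the maximum lag")
    if amplitude.std() == 0 or strength.std() == 0:
        return float("nan")
    a = (amplitude - amplitude.mean()) / amplitude.std()
    s = (strength - strength.mean()) / strength.std()
    cc = signal.correlate(s, a, mode="full") / a.size
    lags = signal.correlation_lags(s.size, a.size, mode="full")
    sel = np.abs(lags) <= max_lag
    cc, lags = cc[sel], lags[sel]
    if np.allclose(cc, cc[0]):
        return float("nan")
    # correlate(s, a)[lag] ~ sum a(t) s(t + lag): the peak lag is the delay
    # of strength behind amplitude, i.e. positive when amplitude leads
    return float(lags[np.argmax(cc)] * 1000.0 / fs)


def circular_linear_correlation(phase_deg: np.ndarray,
                                x: np.ndarray) -> float:
    """Circular-linear correlation coefficient (Zar / Mardia), on [0, 1]:

        r = sqrt((r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2))

    with r_cx = corr(cos(phase), x), r_sx = corr(sin(phase), x),
    r_cs = corr(cos(phase), sin(phase)).
    """

    phase = np.deg2rad(np.asarray(phase_deg, dtype=float))
    x = np.asarray(x, dtype=float)
    c, s = np.cos(phase), np.sin(phase)
    if x.std() == 0 or c.std() == 0 or s.std() == 0:
        return float("nan")
    rcx = np.corrcoef(c, x)[0, 1]
    rsx = np.corrcoef(s, x)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    num = rcx ** 2 + rsx ** 2 - 2 * rcx * rsx * rcs
    den = 1.0 - rcs ** 2
    if den <= 0:
        return float("nan")
    return float(np.sqrt(max(num / den, 0.0)))


def cross_frequency_independence(theta_strength: np.ndarray,
                                 theta_power: np.ndarray,
                                 theta_phase_deg: np.ndarray,
                                 beta_strength: np.ndarray,
                                 n_shuffles: int = 200,
                                 seed: int | np.random.Generator = 0,
                                 label: str = "") -> list[CouplingResult]:
    """Independence tests between simultaneous theta and beta traveling
    waves on a shared time base: Pearson(theta-strength, beta-strength),
    Pearson(theta-power, beta-strength), and the circular-linear
    correlation of theta phase with beta strength, each against its
    circular-shuffle null (one-sided for the non-negative circular-linear
    coefficient)."""

    series = [np.asarray(v, dtype=float) for v in
              (theta_strength, theta_power, theta_phase_deg, beta_strength)]
    lengths = {s.shape for s in series}
    if len(lengths) != 1:
        raise ValueError("series must share one time base")
    if series[0].size == 0:
        raise ValueError("non-overlapping time support")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    th_s, th_p, th_ph, be_s = series
    out = []
    for name, x in (("strength-strength pearson", th_s),
                    ("power-strength pearson", th_p)):
        if x.std() == 0 or be_s.std() == 0:
            out.append(CouplingResult(label=label, statistic=name,
                                      value=float("nan"), p=1.0, flagged=True))
            continue
        r, p = _circular_shuffle_null(x, be_s, _pearson, n_shuffles, rng)
        out.append(CouplingResult(label=label, statistic=name, value=r, p=p))
    r, p = _circular_shuffle_null(
        th_ph, be_s, lambda ph, y: circular_linear_correlation(ph, y),
        n_shuffles, rng, two_sided=False)
    out.append(CouplingResult(label=label,
                              statistic="phase-strength circlin",
                              value=r, p=p, flagged=not np.isfinite(r)))
    return out
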