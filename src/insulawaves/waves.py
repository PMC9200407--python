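"""Traveling-wave detection by localized 2-D circular-linear regression.

A traveling phase wave is a set of simultaneous narrowband oscillations
whose instantaneous phases vary systematically with electrode location.
For each electrode of an oscillation cluster, the neighboring electrodes
within 20 mm form a subcluster; its 3-D coordinates are projected onto
their best-fit plane (PCA), and at each time point the phases are fitted
with the plane-wave model

    theta_hat_i = (a*x_i + b*y_i + theta) mod 360,

where a = xi*cos(alpha), b = xi*sin(alpha); alpha = atan2(b, a) is the
fitted phase-gradient angle and xi = sqrt(a^2 + b^2) the spatial frequency
(deg/mm).  The fit maximizes the mean resultant length r of the circular
residuals over a grid of alpha (5 deg steps) and xi (0.5 deg/mm steps, up
to the spatial Nyquist limit 180/max-neighbor-spacing); the phase offset
theta is profiled out analytically as the circular mean of the residuals,
which yields the same maximizer with one fewer grid dimension.

Fit quality is the circular correlation rho_cc between predicted and
observed phases, adjusted for the k = 3 fitted regressors:

    rho2_adj = 1 - (1 - rho_cc^2) * (n - 1) / (n - k - 1),

the "wave-strength".  Statistical reliability comes from a spatial-shuffle
surrogate test: electrode coordinates are permuted against the phase
traces, destroying contiguous spatial phase variation while preserving
everything else.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import squareform, pdist

from .io import Recording
from .clusters import OscillationCluster
from .synth import plane_coordinates

K_REGRESSORS = 3
ALPHA_STEP_DEG = 5.0
XI_STEP_DEG_MM = 0.5


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PhaseField:
    """Instantaneous phase (deg, in [0, 360)) and amplitude envelope (uV)
    of the band-filtered analytic signal, for each cluster electrode."""

    cluster_id: str
    f_p: float
    times: np.ndarray         # (n_times,)
    electrodes: list          # member names, order matches rows
    phases: np.ndarray        # (n_members, n_times), degrees
    amplitude: np.ndarray     # (n_members, n_times), uV
    sample_mask: np.ndarray   # (n_times,) bool


def phase_timeseries(rec: Recording, cluster: OscillationCluster) -> PhaseField:
    """Band-pass each member electrode at the cluster peak frequency
    (3rd-order zero-phase Butterworth, pass band [0.85*f_p, f_p/0.85]) and
    take the Hilbert analytic signal's phase and amplitude."""

    f_lo = 0.85 * cluster.f_p
    f_hi = cluster.f_p / 0.85
    if f_hi >= rec.fs / 2.0:
        raise ValueError("pass band extends above Nyquist")
    idx = [rec.channel_ids.index(m) for m in cluster.members]
    sos = signal.butter(3, [f_lo, f_hi], btype="bandpass", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data[idx], axis=1)
    analytic = signal.hilbert(filtered, axis=1)
    phases = np.rad2deg(np.angle(analytic)) % 360.0
    return PhaseField(cluster_id=cluster.cluster_id, f_p=cluster.f_p,
                      times=rec.times(), electrodes=list(cluster.members),
                      phases=phases, amplitude=np.abs(analytic),
                      sample_mask=rec.sample_mask.copy())


# ---------------------------------------------------------------------------
# subclusters
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Subcluster:
    center: str
    members: list             # electrode names (includes center)
    member_idx: np.ndarray    # indices into the cluster's member list
    xy: np.ndarray            # (n, 2) best-fit-plane coordinates, mm


def make_subclusters(cluster: OscillationCluster, electrodes: pd.DataFrame,
                     radius_mm: float = 20.0, min_size: int = 4
                     ) -> list[Subcluster]:
    """One candidate subcluster per cluster electrode: the neighbors within
    ``radius_mm`` (inclusive).  Candidates with fewer than ``min_size``
    members are dropped.  Member 3-D coordinates are projected onto their
    top-2 principal axes; for coplanar members this preserves pairwise
    distances exactly."""

    sub = electrodes[electrodes["subject"] == cluster.subject_id] \
        if "subject" in electrodes.columns else electrodes
    sub = sub.set_index("name")
    coords = sub.loc[cluster.members, ["x", "y", "z"]].to_numpy(dtype=float)
    dist = squareform(pdist(coords))
    out = []
    for i, center in enumerate(cluster.members):
        member_idx = np.flatnonzero(dist[i] <= radius_mm)
        if member_idx.size < min_size:
            continue
        xy, _ = plane_coordinates(coords[member_idx])
        out.append(Subcluster(center=center,
                              members=[cluster.members[j] for j in member_idx],
                              member_idx=member_idx, xy=xy))
    return out


# ---------------------------------------------------------------------------
# circular-linear grid fit
# ---------------------------------------------------------------------------


def spatial_nyquist(xy: np.ndarray) -> float:
    """Spatial Nyquist limit in deg/mm: 180 divided by the largest
    nearest-neighbor spacing among the given 2-D positions."""

    d = squareform(pdist(np.asarray(xy, dtype=float)))
    np.fill_diagonal(d, np.inf)
    max_neighbor = d.min(axis=1).max()
    return 180.0 / max_neighbor


def _grid(xy: np.ndarray, alpha_step: float, xi_step: float,
          xi_max: float | None):
    """Grid of (a, b) slopes ordered xi-ascending then alpha-ascending, so a
    first-maximum argmax breaks ties toward the smallest xi, then the
    smallest alpha (prefer the simplest wave).  Row 0 is the degenerate
    xi = 0 entry (alpha undefined)."""

    if xi_max is None:
        xi_max = spatial_nyquist(xy)
    alphas = np.arange(0.0, 360.0, alpha_step)
    xis = np.arange(xi_step, xi_max + 1e-9, xi_step)
    grid_xi = np.concatenate([[0.0], np.repeat(xis, alphas.size)])
    grid_alpha = np.concatenate([[np.nan], np.tile(alphas, xis.size)])
    a = grid_xi * np.cos(np.deg2rad(np.where(np.isnan(grid_alpha), 0.0,
                                             grid_alpha)))
    b = grid_xi * np.sin(np.deg2rad(np.where(np.isnan(grid_alpha), 0.0,
                                             grid_alpha)))
    return grid_alpha, grid_xi, a, b


def _circ_mean(angles_rad: np.ndarray, axis=-1) -> np.ndarray:
    return np.angle(np.exp(1j * angles_rad).mean(axis=axis))


def adjusted_wave_strength(rho_cc, n: int, k: int = K_REGRESSORS):
    """Adjust a circular correlation for the k fitted regressors:

        rho2_adj = 1 - (1 - rho_cc^2) * (n - 1) / (n - k - 1).

    Defined for n > k + 1; equals 1 whenever |rho_cc| = 1 and can be
    negative for weak correlations at small n.
    """

    if n <= k + 1:
        raise ValueError(f"need n > k+1 = {k + 1}")
    rho_cc = np.asarray(rho_cc, dtype=float)
    out = 1.0 - (1.0 - rho_cc ** 2) * (n - 1) / (n - k - 1)
    return float(out) if out.ndim == 0 else out


def fit_phase_matrix(phases_deg: np.ndarray, xy: np.ndarray,
                     alpha_step: float = ALPHA_STEP_DEG,
                     xi_step: float = XI_STEP_DEG_MM,
                     xi_max: float | None = None,
                     k: int = K_REGRESSORS,
                     chunk_rows: int = 2000) -> dict:
    """Vectorized grid fit of M phase snapshots (rows) on one geometry.

    Returns arrays of length M: ``alpha`` (deg; NaN for the degenerate
    xi = 0 maximizer), ``xi`` (deg/mm), ``rbar`` (mean resultant length of
    residuals), ``theta`` (fitted phase offset, deg), ``rho_cc`` (circular
    correlation; NaN when undefined) and ``wave_strength`` (rho2_adj; 0
    when rho_cc is undefined, NaN when n <= k + 1).
    """

    phases_deg = np.atleast_2d(np.asarray(phases_deg, dtype=float))
    M, n = phases_deg.shape
    if n < 4:
        raise ValueError("need at least 4 electrodes")
    grid_alpha, grid_xi, a, b = _grid(xy, alpha_step, xi_step, xi_max)
    pred_rad = np.deg2rad(a[:, None] * xy[None, :, 0]
                          + b[:, None] * xy[None, :, 1])  # (G, n)
    e_pred_conj = np.exp(-1j * pred_rad).T                # (n, G)
    theta_rad = np.deg2rad(phases_deg)
    e_obs = np.exp(1j * theta_rad)                        # (M, n)

    best = np.empty(M, dtype=int)
    rbar = np.empty(M)
    for start in range(0, M, chunk_rows):
        z = e_obs[start:start + chunk_rows] @ e_pred_conj / n
        r = np.abs(z)
        idx = np.argmax(r, axis=1)
        best[start:start + chunk_rows] = idx
        rbar[start:start + chunk_rows] = r[np.arange(r.shape[0]), idx]

    alpha = grid_alpha[best]
    xi = grid_xi[best]
    a_best, b_best = a[best], b[best]

    lin = a_best[:, None] * xy[None, :, 0] + b_best[:, None] * xy[None, :, 1]
    resid = theta_rad - np.deg2rad(lin)
    theta_off = _circ_mean(resid, axis=1)                 # (M,)
    pred = np.deg2rad(lin) + theta_off[:, None]           # predicted, rad

    obs_mean = _circ_mean(theta_rad, axis=1)
    pred_mean = _circ_mean(pred, axis=1)
    s_obs = np.sin(theta_rad - obs_mean[:, None])
    s_pred = np.sin(pred - pred_mean[:, None])
    num = (s_obs * s_pred).sum(axis=1)
    den = np.sqrt((s_obs ** 2).sum(axis=1) * (s_pred ** 2).sum(axis=1))
    ok = den > 1e-12  # constant observed or predicted phases: undefined
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_cc = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    if n > k + 1:
        strength = adjusted_wave_strength(rho_cc, n, k)
        strength = np.where(np.isnan(rho_cc), 0.0, strength)
    else:
        strength = np.full(M, np.nan)
    return {
        "alpha": alpha, "xi": xi, "a": a_best, "b": b_best,
        "rbar": rbar, "theta": (np.rad2deg(theta_off) % 360.0),
        "rho_cc": rho_cc, "wave_strength": strength, "n": n, "k": k,
    }


@dataclasses.dataclass
class WaveFit:
    """One circular-linear plane-wave fit."""

    a: float
    b: float
    alpha: float            # deg; NaN when xi = 0
    xi: float               # deg/mm
    theta: float            # phase offset, deg
    rbar: float
    rho_cc: float
    wave_strength: float    # rho2_adj
    n: int
    k: int = K_REGRESSORS


def circular_linear_fit(phases_deg: np.ndarray, xy: np.ndarray,
                        alpha_step: float = ALPHA_STEP_DEG,
                        xi_step: float = XI_STEP_DEG_MM,
                        xi_max: float | None = None) -> WaveFit:
    """Fit one phase snapshot; see :func:`fit_phase_matrix` for the model."""

    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.ndim != 1 or phases_deg.size < 4:
        raise ValueError("need a 1-D phase vector with at least 4 entries")
    res = fit_phase_matrix(phases_deg[None, :], xy, alpha_step=alpha_step,
                           xi_step=xi_step, xi_max=xi_max)
    return WaveFit(a=float(res["a"][0]), b=float(res["b"][0]),
                   alpha=float(res["alpha"][0]), xi=float(res["xi"][0]),
                   theta=float(res["theta"][0]), rbar=float(res["rbar"][0]),
                   rho_cc=float(res["rho_cc"][0]),
                   wave_strength=float(res["wave_strength"][0]),
                   n=phases_deg.size)


def fit_quality(theta_deg: np.ndarray, theta_hat_deg: np.ndarray,
                k: int = K_REGRESSORS) -> tuple[float, float]:
    """Circular correlation between observed and predicted phases, and the
    regressor-count-adjusted wave-strength rho2_adj.

    When either phase set is constant the circular correlation is undefined
    (zero denominator); rho_cc is returned as NaN and the wave-strength as
    0 by convention.
    """

    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    theta_hat = np.deg2rad(np.asarray(theta_hat_deg, dtype=float))
    n = theta.size
    if n <= k + 1:
        raise ValueError(f"need more than k+1 = {k + 1} phases")
    s_obs = np.sin(theta - _circ_mean(theta))
    s_pred = np.sin(theta_hat - _circ_mean(theta_hat))
    den = np.sqrt((s_obs ** 2).sum() * (s_pred ** 2).sum())
    if den <= 1e-12:
        return float("nan"), 0.0
    rho_cc = float((s_obs * s_pred).sum() / den)
    return rho_cc, adjusted_wave_strength(rho_cc, n, k)


def wave_speed(xi_deg_mm: float, f_p: float) -> float:
    """Propagation speed in m/s: temporal frequency times wavelength
    (360/xi mm).  Undefined (NaN) for xi = 0."""

    if xi_deg_mm < 0:
        raise ValueError("xi must be non-negative")
    if xi_deg_mm == 0:
        return float("nan")
    return f_p * (360.0 / xi_deg_mm) / 1000.0


# ---------------------------------------------------------------------------
# cluster-level fits and surrogate test
# ---------------------------------------------------------------------------


def fit_cluster(field: PhaseField, subclusters: list[Subcluster],
                time_idx: np.ndarray,
                alpha_step: float = ALPHA_STEP_DEG,
                xi_step: float = XI_STEP_DEG_MM) -> dict:
    """Fit every subcluster at the given time indices.

    Returns ``{"per_sub": [fit dict per subcluster], "strength": (T,)}``
    where ``strength`` is the across-subcluster mean wave-strength
    (NaN-aware: size-4 subclusters have undefined rho2_adj)."""

    per_sub = []
    for sc in subclusters:
        phases = field.phases[sc.member_idx][:, time_idx].T  # (T, n)
        per_sub.append(fit_phase_matrix(phases, sc.xy, alpha_step=alpha_step,
                                        xi_step=xi_step))
    stack = np.vstack([r["wave_strength"] for r in per_sub])
    with np.errstate(invalid="ignore"):
        strength = np.nanmean(stack, axis=0)
    return {"per_sub": per_sub, "strength": strength}


def spatial_shuffle_test(field: PhaseField, subclusters: list[Subcluster],
                         time_idx: np.ndarray, n_perm: int = 100,
                         seed: int | np.random.Generator = 0,
                         surrogate_time_idx: np.ndarray | None = None,
                         sig_level: float = 0.05,
                         alpha_step: float = ALPHA_STEP_DEG,
                         xi_step: float = XI_STEP_DEG_MM) -> dict:
    """Permutation test of the cluster's traveling waves.

    Electrode coordinates are randomly permuted against the phase traces
    (equivalently, the phase rows are permuted among the cluster
    electrodes) and the full subcluster fit pipeline re-run.  The
    cluster-level p-value compares the observed time-averaged wave-strength
    with the surrogate distribution, with the +1 correction
    p = (1 + #{surrogate >= observed}) / (n_perm + 1).  The per-time
    significance mask thresholds the observed strength at the
    (1 - sig_level) quantile of the pooled surrogate values.

    ``surrogate_time_idx`` lets surrogates run on a subsample of the fitted
    time points to bound compute; it defaults to ``time_idx``.
    """

    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if surrogate_time_idx is None:
        surrogate_time_idx = time_idx
    observed = fit_cluster(field, subclusters, time_idx,
                           alpha_step=alpha_step, xi_step=xi_step)
    obs_strength = observed["strength"]
    obs_mean = float(np.nanmean(obs_strength))

    n_members = len(field.electrodes)
    perms = np.vstack([rng.permutation(n_members) for _ in range(n_perm)])

    t_surr = np.asarray(surrogate_time_idx)
    per_perm = np.zeros((n_perm, t_surr.size))
    counts = np.zeros((n_perm, t_surr.size))
    for sc in subclusters:
        base = field.phases[:, t_surr]  # (n_members, T_surr)
        # stack all permutations' phase snapshots into one matrix
        rows = np.concatenate([base[perms[p][sc.member_idx]].T
                               for p in range(n_perm)], axis=0)
        res = fit_phase_matrix(rows, sc.xy, alpha_step=alpha_step,
                               xi_step=xi_step)
        strength = res["wave_strength"].reshape(n_perm, t_surr.size)
        valid = np.isfinite(strength)
        per_perm += np.where(valid, strength, 0.0)
        counts += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        surr_strength = per_perm / counts
    surr_means = np.nanmean(surr_strength, axis=1)
    p_cluster = float((1 + np.sum(surr_means >= obs_mean)) / (n_perm + 1))
    pooled = surr_strength[np.isfinite(surr_strength)]
    threshold = float(np.quantile(pooled, 1.0 - sig_level)) if pooled.size \
        else np.inf
    sig_mask = obs_strength >= threshold
    return {
        "observed": observed, "strength": obs_strength,
        "mean_strength": obs_mean, "p_cluster": p_cluster,
        "threshold": threshold, "sig_mask": sig_mask,
        "surrogate_means": surr_means,
    }


@dataclasses.dataclass
class WaveSummary:
    cluster_id: str
    times: np.ndarray
    strength: np.ndarray        # per-time mean wave-strength
    sig_mask: np.ndarray
    prevalence: float
    p_cluster: float | None
    speeds: np.ndarray          # m/s over significant timepoints
    median_speed: float
    direction_bins: np.ndarray  # bin left edges, deg
    direction_hist: np.ndarray


def summarize_waves(cluster_id: str, f_p: float, times: np.ndarray,
                    fit: dict, sig_mask: np.ndarray,
                    p_cluster: float | None = None,
                    direction_bin_deg: float = 10.0) -> WaveSummary:
    """Prevalence, speed distribution and direction histogram of a
    cluster's traveling waves.

    Prevalence is the fraction of fitted timepoints flagged significant.
    Speeds (f_p * 360/xi, in m/s) and directions are pooled over
    subclusters at significant timepoints only.
    """

    sig_mask = np.asarray(sig_mask, dtype=bool)
    prevalence = float(sig_mask.mean()) if sig_mask.size else 0.0
    speeds = []
    angles = []
    for res in fit["per_sub"]:
        xi = res["xi"][sig_mask]
        al = res["alpha"][sig_mask]
        ok = xi > 0
        speeds.append(f_p * (360.0 / xi[ok]) / 1000.0)
        angles.append(al[ok & np.isfinite(al)])
    speeds = np.concatenate(speeds) if speeds else np.array([])
    angles = np.concatenate(angles) if angles else np.array([])
    bins = np.arange(0.0, 360.0, direction_bin_deg)
    hist, _ = np.histogram(angles, bins=np.append(bins, 360.0))
    return WaveSummary(
        cluster_id=cluster_id, times=times, strength=fit["strength"],
        sig_mask=sig_mask, prevalence=prevalence, p_cluster=p_cluster,
        speeds=speeds,
        median_speed=float(np.median(speeds)) if speeds.size else float("nan"),
        direction_bins=bins, direction_hist=hist)
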