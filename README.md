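# insulawaves

Analysis pipeline for spontaneous oscillations and traveling waves in
stereo-EEG depth recordings, with a synthetic-data generator that provides
ground truth for every stage.

Resting-state intracranial EEG of deep structures such as the human insula
shows narrowband theta (~6–9 Hz) and beta (~15–32 Hz) oscillations riding
on a 1/f aperiodic background. Two questions drive this package: how the
frequency and power of those oscillations are organized along the
anterior–posterior (AP) and superior–inferior (SI) anatomical axes, and
whether the oscillations are *traveling waves* — rhythms whose
instantaneous phase varies systematically with electrode position, implying
propagation. It is aimed at electrophysiologists who want a tested,
reusable implementation of this analysis chain, and at methodologists who
want to probe its operating characteristics on data with known ground
truth.

## The method

1. **Preprocessing** — bipolar referencing (nearest neighbor) for spectral
   gradients, common-average referencing for wave analysis; zero-phase
   notch at 60 Hz and harmonics; epoch-wise artifact rejection masking
   epochs whose 1–50 Hz log-spectrum deviates by >3 SD across epochs.
2. **Spectra** — Morlet-wavelet power (6 cycles) on a 491-point linear
   1–50 Hz grid (gradients) and a 200-point log 3–40 Hz grid (clusters); a
   robust bisquare line fit of log-power on log-frequency removes the 1/f
   background; frequency bands where the normalized spectrum exceeds one
   residual SD are detected oscillations (the MODAL rule), and narrowband
   peaks are local maxima >1 SD above the mean of the normalized spectrum.
3. **Gradients** — per hemisphere, peak frequency and power are regressed
   on the AP (y) and SI (z) coordinates with subject as a categorical
   covariate and pairwise interactions:
   `EPHYS = β0 + βAP·y + βSI·z + βSUBJ + y:z + y:SUBJ + z:SUBJ`,
   with Benjamini–Hochberg FDR across terms.
4. **Oscillation clusters** — per subject and band, connected components of
   the graph joining electrode pairs closer than 20 mm, among electrodes
   with an in-band narrowband peak; components with ≥4 members become
   clusters with peak frequency `f_p` (median of members).
5. **Traveling waves** — each cluster electrode's signal is band-passed at
   `[0.85·f_p, f_p/0.85]` (3rd-order zero-phase Butterworth) and
   Hilbert-transformed. For each electrode, its ≤20 mm neighbors form a
   subcluster whose 3-D positions are projected onto their best-fit plane
   (PCA). At each time point the phases are fitted with the plane-wave
   model `θ̂ᵢ = (a·xᵢ + b·yᵢ + θ) mod 360°`, maximizing the mean resultant
   length r̄ of circular residuals over a grid of propagation angle
   `α = atan2(b, a)` (5° steps) and spatial frequency `ξ = √(a²+b²)`
   (0.5 °/mm steps up to the spatial Nyquist limit, 180°/max spacing =
   32.5 °/mm at 5.53 mm). Fit quality is the circular correlation ρcc
   between predicted and observed phases, adjusted for the k = 3
   regressors: `ρ²adj = 1 − (1 − ρcc²)(n−1)/(n−k−1)` — the
   **wave-strength**. Propagation speed is `f_p · (360/ξ)` (temporal
   frequency × wavelength).
6. **Statistics** — cluster-level significance by spatial shuffling
   (electrode coordinates permuted against phase traces, full refit,
   `p = (1+#{surrogate ≥ observed})/(n_perm+1)`); coupling between
   oscillation amplitude, wave-strength and across frequency bands by
   Pearson or circular-linear correlation against circular-shift
   surrogates that preserve autocorrelation.

## Worked example

```python
import insulawaves as iw

config = iw.default_config(n_subjects=2, electrodes_per_subject=16,
                           sampling_rate=500.0, duration=48.0,
                           artifact_rate_per_min=1.0, seed=2026)
result = iw.run_study(config, out_dir="run")   # waves injected 40% of the time
for cid, r in sorted(result.wave_results.items()):
    s = r["summary"]
    print(f"{cid}: prevalence={s.prevalence:.2f} p={s.p_cluster:.3f} "
          f"median speed={s.median_speed:.2f} m/s")
```

prints (seed 2026):

```
sub01_beta_2: prevalence=0.34 p=0.010 median speed=0.59 m/s
sub01_beta_3: prevalence=0.01 p=0.426 median speed=0.44 m/s
sub01_theta_0: prevalence=0.31 p=0.010 median speed=0.34 m/s
sub01_theta_1: prevalence=0.06 p=0.069 median speed=0.07 m/s
sub02_beta_6: prevalence=0.34 p=0.020 median speed=0.61 m/s
sub02_beta_7: prevalence=0.03 p=0.248 median speed=0.24 m/s
sub02_theta_4: prevalence=0.32 p=0.030 median speed=0.41 m/s
sub02_theta_5: prevalence=0.07 p=0.208 median speed=0.12 m/s
```

Clusters carrying the injected theta (7.5 Hz) and beta (22 Hz) waves
(`*_theta_0/4`, `*_beta_2/6`) are detected as significant traveling waves
with prevalence near the injected 40% duty cycle; the remaining clusters
hold incoherent oscillations and stay at chance. Speeds on wave clusters
sit below the injected 0.7 m/s because common-average referencing steepens
apparent phase gradients (see `docs/methods.md`). The same run writes
`clusters.tsv`, `gradients.tsv`, `waves_<cluster>.tsv`, `coupling.tsv`,
`summary.json` and a reproducibility manifest. The same pipeline runs from
the shell: `insulawaves run --config config.json --out run/`.

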