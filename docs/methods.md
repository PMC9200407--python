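# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and synthetic studies

The generator (`insulawaves.synth`) emulates resting-state stereo-EEG:

* **Background**: power-law noise with spectrum ∝ f^(−β), synthesized by
  spectral shaping of white noise (FFT amplitude ∝ f^(−β/2)), exact and
  fully seeded. Default β = 2, RMS 10 µV, typical of depth-contact LFP.
* **Electrode geometry**: quasi-linear depth probes. Contacts are placed
  sequentially with center-to-center steps drawn uniformly from
  3.5–5.53 mm along a slowly drifting direction, so within-probe spacing
  honors the stated range exactly while trajectories are realistically
  bent. Each hemisphere receives ⌈count/6⌉ roughly parallel probes offset
  ~10 mm along z. The multi-probe fan matters: with a single straight
  probe the electrode sampling is one-dimensional, and both the
  2-D phase-gradient fit and the AP×SI regression (whose y, z and y·z
  regressors become collinear) are ill-conditioned.
* **Oscillations with gradients**: per electrode, a narrowband sinusoid
  whose center frequency and amplitude vary linearly with the AP (y)
  coordinate (defaults: theta f₀ = 7.5 Hz, slope −0.05 Hz/mm, beta
  f₀ = 22 Hz, amplitude slope +2 %/mm, amplitudes 4–5 µV). Each
  electrode's phase performs a random walk (0.5 rad/√s): real oscillators
  decohere over seconds. Without this drift, same-frequency oscillators
  hold a frozen random phase pattern that a circular-linear fit can
  mistake for a static wave.
* **Traveling waves**: on a chosen electrode group, phase at electrode i
  is 2πft − ξ·(uᵢ·d̂)·(π/180) + θ₀, with uᵢ the position projected on the
  group's best-fit (PCA) plane and d̂ the unit vector at the propagation
  angle α. The amplitude envelope is a train of raised-cosine bursts with
  configurable duty cycle, so wave prevalence has controllable ground
  truth. Defaults give theta and beta waves at 0.7 m/s
  (ξ = 360f/(1000·v)) with 40% duty cycle. Because the model fits phase
  *gradients*, the fitted angle equals the propagation angle + 180°
  (phase decreases along the travel direction); ground-truth tables store
  both (`alpha`, `alpha_fit`).
* **Nuisance**: a common 60 Hz sinusoid and Poisson-scheduled 0.3–0.8 s
  broadband high-variance segments exercise the notch and the 3×SD
  spectral rejection rule.

What the generator does **not** emulate: volume conduction and spatially
correlated background noise, epileptiform spike morphology, non-planar
(spiral/radial) waves, electrode localization error, and non-stationary
background spectra. Passing tests therefore show that the pipeline
recovers planted planar waves and linear gradients under realistic SNR,
line noise and artifacts — not that it is robust to every property of
clinical recordings.

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| wavelet cycles | 6 | – | fixed-Q spectral estimate; bandwidth ≈ f/6 |
| linear PSD grid | 1–50 Hz, 0.1 Hz (491 pts) | Hz | gradient path |
| log PSD grid | 3–40 Hz, 200 pts | Hz | cluster path |
| MODAL threshold | 1 residual SD | log₁₀ power | band detection |
| min band width | 3 grid points | – | suppress single-point noise runs |
| adjacency radius | 20 mm (strict `<` for clusters, `≤` for subclusters) | mm | spatial contiguity |
| min cluster/subcluster size | 4 | electrodes | fit needs n ≥ 4 |
| band ranges (clusters) | theta 4–8, beta 12–30 | Hz | cluster stage |
| band ranges (gradients) | MODAL bands of the pooled mean spectrum, fallback theta 6–9 / beta 15–32 | Hz | gradient stage |
| α grid | 0–360 in 5° | deg | plane-wave search |
| ξ grid | 0.5 °/mm steps, 0 to 180/max-neighbor-spacing | °/mm | spatial Nyquist ceiling (32.5 °/mm at 5.53 mm) |
| Butterworth | order 3, [0.85·f_p, f_p/0.85], zero-phase | – | narrowband phase extraction |
| notch | 60 Hz + harmonics, 2 Hz stop-band, zero-phase IIR | Hz | line removal |
| rejection | 1 s epochs, 3×SD of mean 1–50 Hz log-spectrum | – | artifact masking |
| permutations | ≥100 (`p = (1+k)/(n+1)`) | – | surrogate tests |

The two theta/beta range conventions (4–8/12–30 for clustering,
~6–9/~15–32 from MODAL for gradients) are deliberate: the clustering
ranges are generous so that electrodes with slightly shifted peaks still
join a cluster, while the gradient ranges follow the detected bands.
Both are configurable per stage.

## Numerical choices

* **Offset profiling.** The phase offset θ of the plane-wave model is not
  grid-searched: for any (α, ξ), r̄ of the residuals δᵢ = θᵢ − (a·xᵢ+b·yᵢ)
  is independent of a common rotation, and the maximizing offset is the
  circular mean of δᵢ. This is exactly equivalent to a 3-D grid search
  and removes one dimension.
* **Tie-breaking.** The grid is ordered ξ-ascending then α-ascending and
  the first maximum wins, so exact ties resolve to the simplest wave
  (smallest ξ, then smallest α). The degenerate ξ = 0 entry (uniform
  phases) reports α as missing, ρcc undefined and wave-strength 0.
* **Undefined ρ²adj at n = 4.** The adjustment divides by n−k−1 = 0 for
  four-electrode subclusters; their wave-strength is undefined (NaN) and
  they are excluded from cluster averages (NaN-aware mean). Subclusters
  of five or more electrodes carry the statistic.
* **Robust 1/f fit.** Bisquare (Tukey) iteratively reweighted regression
  of log₁₀ power on log₁₀ frequency; the residual SD uses the bisquare
  weights, so narrow oscillatory bumps inflate neither the line nor the
  detection threshold. A 10⁻⁹ floor on the threshold guards the exact
  power-law case where the residual SD is numerically zero.
* **Surrogate economics.** Spatial-shuffle surrogates refit the full
  pipeline on permuted coordinate↔phase assignments. All permutations and
  timepoints are stacked into one matrix multiplication against the
  precomputed grid-phase matrix, which keeps 100 permutations of a
  multi-subcluster fit in seconds. Surrogates may run on a subsample of
  fitted timepoints (`surrogate_subsample`, default every 10th); the
  cluster statistic is a time average, so subsampling trades variance of
  the null estimate for compute without bias. Per-time significance uses
  the pooled surrogate distribution across time (the cluster-level test
  is primary).
* **Filter guards.** Wave fits exclude 2/f_p s at the recording edges
  (filter and Hilbert transients) and masked samples.
* **Referencing.** Gradients use bipolar derivations (nearest same-subject
  contact, midpoint coordinate); wave analysis uses the common average,
  the convention for phase analyses. Common-average referencing subtracts
  the wave's common component across electrodes, which steepens apparent
  phase gradients: fitted ξ is biased upward and speeds downward, the
  more so the longer the wavelength relative to the array (visible for
  theta in the worked example, where raw-reference fits recover the
  injected speed nearly exactly). This is a property of the referencing
  scheme, not of the fit.
* **Cluster spectra on the common average.** The cluster-building spectra
  are computed on the common-average recording so that cluster members
  map one-to-one onto the channels entering the wave analysis (bipolar
  derivations live at midpoint coordinates and would not).

## Design decisions where the design was open

* The gradient model is the printed fixed-effects formula (OLS with
  subject dummies and pairwise interactions). A random-intercept mixed
  model is available behind `mixed=True` for sensitivity; the fixed-effects
  fit is the default because it is the form the formula states.
* Artifact rejection is epoch-wise across channels (1 s epochs, channel-
  and frequency-averaged log power, 3×SD): the most self-contained reading
  of a "3× SD of spectra from 1 to 50 Hz" rule. It is scale-invariant by
  construction. Per-channel masking is a possible alternative; the
  per-epoch choice keeps a single time base for all channels.
* Cluster peak frequency f_p is the median of members' in-band peaks —
  robust to a single outlier electrode.
* The amplitude–wave-strength lag is reported with a signed convention
  (positive = amplitude leads strength) and the package takes no stance on
  which series "drives" the other.
* Theta "power" in the cross-band tests is the squared mean envelope.
* Theta phase for the phase–strength test is the circular mean phase
  across cluster electrodes.

## Problem sizes

Desk-scale runs use 1–2 subjects, 10–16 electrodes, 24–60 s at 250–500 Hz,
wave fits every 20 ms, 100 permutations with surrogates on every 10th
fitted timepoint, and 100–200 circular shuffles. These sizes are the
package's defaults for simulation studies; the full clinical-scale
configuration (10 subjects, ~24 contacts, 5 min at 2 kHz) is expressible
through the same `StudyConfig` and scales linearly in duration, channels
and permutations.

## Known limitations

* Wave speeds under common-average referencing are systematically
  underestimated (see above); comparisons across clusters of similar
  geometry remain meaningful.
* On clusters whose electrodes carry a coherent wave, per-electrode
  "peak frequency" is the wave frequency, so frequency-gradient analysis
  is uninformative there (the generator deliberately does not stack an
  incoherent same-band oscillation on top of an injected wave).
* The wavelet's fixed-Q smearing widens detected band edges by roughly
  f/6 Hz; MODAL band edges are therefore not sharp oscillation
  boundaries.
* Circular-linear fits on fewer than five electrodes have no defined
  wave-strength; arrays dominated by four-electrode subclusters will
  yield sparse cluster statistics.
* The lag estimator resolves delays only down to the wave-fit stride
  (default 20 ms); millisecond-scale lags require fitting at the raw
  sampling rate.
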