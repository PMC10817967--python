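# Methods

## Signal model and estimator

All quantities derive from the Hamming-tapered periodogram of a uniformly
sampled signal x(n), n = 0..N−1:

    S(f_k) = Σ_n w(n) (x(n) − x̄) e^{−i2πkn/NFFT},
    P(f_k) = |S(f_k)|² / K,  K = Σ_n w(n)²,  f_k = k·fs/NFFT,  k = 0..NFFT/2.

Choices that are fixed in the implementation:

* **Normalization direction.** The squared transform is *divided* by the
  taper energy K. Multiplying by K (which one reading of the defining
  formula would suggest) would scale power by the window energy squared;
  division is the standard convention and keeps P independent of taper
  scale. Band powers are only ever compared with like-computed band powers,
  so the absolute convention is internally consistent.
* **Mean subtraction before tapering.** Without it, the DC component leaks
  through the taper's sidelobes into the 0.01–0.1 Hz vasomotor band, which
  sits only a few bins above DC at Δf = 0.005 Hz.
* **One-sided spectrum without the 2× interior-bin energy compensation.**
  Same rationale: only like-with-like comparisons are made.
* **NFFT** is 2048 for the 10 Hz BOLD series (next power of two above the
  1780 retained volumes of a 3-minute epoch; Δf = 0.0049 Hz) and 3000 for
  30 fps video (aligning bins to exactly 0.01 Hz, so the 10 Hz artifact
  line falls on bin 1000). The estimator refuses traces longer than NFFT;
  longer recordings should be trimmed or segmented by the caller.

## Bands, band power, and maps

* VLF is fixed at [0.01, 0.1] Hz for every subject. RESP and CARD are
  adaptive: the highest-power bin inside the search range (0.12–0.35 Hz
  and 0.8–1.3 Hz respectively) defines the individual peak, and the band is
  peak ± 0.05 Hz (0.1 Hz wide by construction). Ties break toward the lower
  frequency, making the selection deterministic.
* Band power is the plain sum of P(f_k) over bins with lo ≤ f_k ≤ hi
  (closed interval). The DC bin never participates, even if a band edge
  touches 0.
* ROI mean spectra average *power* across elements, not complex spectra, so
  co-frequent components with independent phases (different tissue
  compartments, different ROIs) reinforce rather than cancel. This matches
  the voxelwise-periodogram-then-ROI-mean route and is what makes the
  whole-image mean spectrum usable for peak detection.
* Per-voxel maps resolve the band once on the ROI/global mean spectrum and
  integrate every voxel over that shared interval. Re-peaking per voxel
  would let noisy voxels wander to unrelated frequencies and would decouple
  the map's elements; subject-level peaks are the intended granularity.
* Narrowband artifacts are excised in the frequency domain: `remove_bins`
  zeroes all bins within half a bin spacing (configurable) of each target
  frequency. This mirrors the periodogram-then-excise treatment of the
  retinal hot-spot reflection and of the 10 Hz scanner interference, and it
  keeps the operation exactly accountable: band power drops by precisely
  the removed bins' sum.

## Preprocessing

* **Trimming**: the first 20 volumes/frames (pre-steady-state) are dropped.
* **High-pass**: zero-phase (forward-backward) 2nd-order Butterworth at
  0.008 Hz (125 s period). The filter is well-posed only for records
  meaningfully longer than the cutoff period; on short clips (e.g. 30 s
  camera videos) it passes through with edge transients and the spectral
  band selection downstream is the robust step.
* **Despiking**: a sample is a spike when it deviates from the centered
  running median (window 5, reflect-padded edges) by more than
  3.5 · 1.4826 · running MAD; spikes are replaced by that median. This is a
  deliberate simplification of curve-fit despiking tools: equivalent for
  the isolated transients it targets, and exactly testable. Replacement
  with the local median makes the operation idempotent for such spikes.
* **Blink handling**: a frame is a blink when its global mean intensity
  falls below median − 3.5 · 1.4826 · MAD of the frame means. Flagged
  frames are invalidated and repaired per pixel by linear interpolation
  between the nearest valid neighbors (nearest-copy at the edges). Because
  at least half the frames always sit at or above the median, this detector
  cannot flag everything; the all-flagged guard exists for pathological
  thresholds.
* **Registration**: translation-only, by phase correlation on the
  border-cropped interior (default 10 px border excluded) against the first
  frame. Shifts are integer pixels; the estimated displacement is undone
  with median-fill at the exposed edges. Sub-pixel motion and non-rigid
  vessel tracking are out of scope.

Volume series pass through registration-free: rigid-body correction of
1–2-slice data is unreliable for saccadic motion and whether any was
ultimately applied upstream of band power in the reference workflow is
unstated, so none is applied here.

## Cross-modal comparison

Traces from different modalities are linearly resampled to the lower of the
two rates, band-passed (zero-phase 2nd-order Butterworth over the resolved
band), and correlated at every integer-sample lag within ±4 s (one
respiratory period). The maximum Pearson r and its lag are reported, ties
broken toward zero lag; a positive lag means the second trace is delayed.
Optimal-lag rather than zero-lag correlation is the contract because the
modalities share no millisecond-accurate trigger. Peak-frequency agreement
across subjects uses Spearman rank correlation with average ranks for ties.

## Group statistics

Paired two-tailed t across subjects (df = n−1) with Bonferroni correction
over the three bands (p_adj = min(1, 3p)) for the 1- vs 2-slice design;
one-way ANOVA (F with df = (k−1, N−k)) with Tukey HSD post-hocs
(Tukey-Kramer for unequal n) *and* Kruskal–Wallis for the slice-thickness
design — the reference analysis names both the parametric and the
rank-based test for that comparison, so both are computed and reported,
with the ANOVA as headline. Shapiro–Wilk is exposed for normality checks.
Zero-variance difference vectors are rejected rather than reported as
infinite t.

## Synthetic scenes: what they emulate, and what they do not

The generator renders one physiological model into all four modalities:

    x(t) = baseline + Σ_bands Σ_k a·d^(k−1) sin(2πkft + φ_k) + N(0, σ²)

* Defaults are the study conditions: VLF 0.05 Hz (a slow sinusoid inside
  0.01–0.1 Hz; the vasomotor waveform is not otherwise constrained), RESP
  0.25 Hz and CARD 1.10 Hz — the representative subject rates — each with
  2 harmonics at geometric decay 0.5 (cardiorespiratory harmonics are
  visible in real spectra; the waveform itself is unspecified, so sinusoids
  with decaying harmonics are the minimal model). σ = 0.05, baseline 100
  (arbitrary BOLD units), 180 s epochs, TR 0.1 s, 128×128 in-plane grid,
  two slices with the second slice's baseline 1.2× the first (two-slice
  acquisitions show a consistently higher baseline), 640×480 @ 30 fps
  video, 30 s eye-surface clips, monitor traces at 50 Hz (rate
  configurable; the acquisition hardware's rate is not documented).
* BOLD ROIs are disjoint rectangles (eye, optic nerve, brain, background)
  with per-ROI band gains: eye/ON respiratory-dominant with weak cardiac,
  brain carrying all three bands, background noise-only. Each ROI has its
  own phases; every voxel has independent noise.
* Video artifacts: whole-frame blink darkening (rate 0.25 /s, ~3 frames,
  60% darkening), persistent integer-pixel saccade offsets applied as
  circular shifts (so the integer-shift registration oracle is exact), a
  fixed central hot-spot disk oscillating at 3 Hz in retinal video, and —
  in single-slice scan mode only — a global 10 Hz flicker, reproducing the
  scanner-interference line that motivates two-slice acquisition.
* Determinism: one seeded generator per dataset and a fixed draw order
  (VLF, RESP, CARD phases; flicker; hot-spot; saccades; blinks; noise), so
  identical configs give identical datasets and enabling a later component
  never perturbs earlier draws.

Passing tests on these scenes demonstrates that the pipeline recovers known
spectral structure through the full I/O → preprocessing → periodogram →
band-selection chain. The scenes do **not** emulate BOLD biophysics,
photorealistic retinal texture, non-stationary breathing/heart rates,
partial-volume effects, head motion of the volume series, or correlated
(1/f) noise — conclusions about detection thresholds on real data do not
follow.

## Problem sizes and numerical notes

* Tests and the acceptance script run the video generator on a 64×48 grid
  and the BOLD generator on 32×32 to 128×128 grids; frequency content is
  grid-independent (the flicker and physiological components are global or
  ROI-wide), so the reduced grids measure the same quantities as the
  full-scale scene. Full-scale 3-minute retinal video (640×480 @ 30 fps,
  float32) needs ~6.6 GB and is only materialized when explicitly requested.
* Volume and frame data are float32; all spectral accumulation is float64,
  chunked over 2048 elements per FFT block to bound memory.
* NIfTI headers store pixdim as float32; the reader rounds the time step to
  7 significant digits so a TR written as 0.1 s reads back exactly.
* AVI I/O uses a minimal uncompressed 24-bit RIFF writer/reader
  (`ocupulse._avi`); 8-bit gray content round-trips bit-exactly. Grayscale
  conversion uses Rec. 601 luma weights and collapses equal-channel RGB
  exactly.
* Degenerate inputs fail loudly rather than silently: constant spectra
  cannot be min-max normalized, constant traces have no defined
  correlation, a constant reference frame cannot anchor registration, and
  zero-variance paired differences are rejected.
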