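# Methods

## Overview

`eegnets` implements a pipeline for decomposing multi-subject, sham-controlled
64-channel EEG into spatiotemporal networks and quantifying how an 8-minute
stimulation block modulates each network's oscillatory power:

1. **Cleaning** — downsample to the cohort's common rate, average re-reference,
   1–70 Hz bandpass, 60 Hz notch, robust PCA.
2. **Standardize + concatenate** — z-score each channel of each session, stack
   every subject's active and sham sessions into one tall samples × 64 matrix B.
3. **Group SVD** — economy decomposition `B = U S Vᵀ`; columns of V are shared
   scalp topographies (relative electrical potential, rEP), columns of U their
   time courses, S their root-mean-square weights.
4. **Selection** — keep components decaying less than 90% from the top weight
   (`S_k > 0.1 · S_1`, strict).
5. **Source localization** — eLORETA on each selected topography over a
   three-shell spherical head model; binarize at >75% of the map maximum.
6. **Spectra** — per subject/condition, segment each component time course into
   baseline (2 min), stim 0–4 min, stim 4–8 min, recovery (3 min); Welch PSD.
7. **Band-power indices + inference** — band power `P` = mean PSD × bandwidth;
   `nP = P / P(baseline)` (self-baseline normalization removes inter-subject
   amplitude variation); `ΔnP = nP(active) − nP(sham)`; one-sample sign-flip
   permutation test of ΔnP against zero per (band, component, period), marked
   at p < 0.05 and p < 0.01.

## Model assumptions

The group SVD treats the multi-subject recording as a shared set of fixed
scalp topographies driven by temporally uncorrelated sources. Z-scoring each
channel of each session before concatenation prevents high-amplitude subjects
from dominating the common basis, at the cost of making the topographies
unitless. The decomposition is done on the full 1–70 Hz signal, never
band-split first: slow and fast rhythms of one network are kept in a single
component, and band structure is analyzed afterwards on the component time
courses.

Orthogonality of U columns holds over the whole concatenated matrix, not
within any single session, so per-session component correlations are a
genuine (and useful) independence diagnostic rather than a tautology.

## Synthetic data generator

No public recording of this design exists, so the generator is a first-class
module that defines the study conditions: 44 subjects × {active, sham} ×
13-minute sessions at 256 Hz (2-min baseline, 4+4-min stimulation, 3-min
recovery), 64-channel 10-10 montage (Biosemi layout, unit-sphere normalized).

* **Networks.** Eleven planted networks by default. Topographies start as
  random smooth scalp patterns (sums of spherical Gaussians), are
  orthonormalized, and then balanced so the power-weighted planted variance is
  uniform across channels. The balancing matters: per-channel z-scoring
  rescales channels by their inverse SD, and an unbalanced planted set would
  be systematically rotated away from the recovered SVD basis, making the
  generator's ground truth unidentifiable regardless of sample size.
* **Sources.** Per band, unit-variance Gaussian noise shaped by a 4th-order
  Butterworth bandpass; each network mixes the five bands with a dominant-band
  fraction of 0.6 over a 1/f-flavored floor, dominant bands cycling
  alpha → theta → beta → delta → gamma. Network powers decay geometrically
  (ratio 0.8), giving distinct singular values so components are identifiable.
* **Effects.** In the active condition only, a band's source variance is
  multiplied by the network's effect scaling inside the chosen segments.
  Defaults plant alpha ×1.5 on the first alpha-dominant network and gamma
  ×0.7 on the first gamma-dominant network during both stimulation halves.
  These sizes are package choices made once — large enough to be physiological
  headline effects, small enough not to trivialize detection.
* **Subject variability.** Log-normal (σ = 0.2) channel-by-network gains per
  subject, shared between that subject's two sessions.
* **Sensor noise.** Spatially white noise with a 1/f power spectrum (flat
  below 1 Hz). `noise_level` is the noise SD relative to the mixed-signal
  RMS; the default 0.3 corresponds to sensor SNR ≈ 11, and SNR 5 is
  `noise_level = 1/√5`.
* **Artifacts.** Optional sparse transients (Poisson event count, half-sine
  bumps of 0.1–0.3 s on random channel subsets, amplitude in channel-SD
  units) emulate motion/jaw-clench artifacts for exercising robust PCA.

What the generator does **not** emulate: biophysically realistic cortical
dynamics, volume-conduction-consistent source-to-scalp projection (planted
topographies are abstract patterns, not leadfield columns), eyes-open/closed
state changes, electrode drift, or non-stationary background. Passing tests
therefore demonstrate the pipeline's correctness and sensitivity under its
own model class, not performance on real recordings.

## Numerical choices

* **Filters.** Butterworth bandpass (4th order standalone; the cleaning
  chain uses 8th order, because a gentler rolloff keeps re-attenuating
  1-Hz-edge energy on every re-application and breaks the chain's
  approximate idempotence on delta-heavy data) and an IIR notch (Q = 30),
  both applied forward-backward (zero phase). Downsampling uses an
  8th-order Butterworth anti-alias lowpass at 0.8 × target Nyquist before
  decimation.
* **Robust PCA.** Principal component pursuit via the inexact augmented
  Lagrangian method; λ = 1/√max(m, n), tol 1e-7, 500 iterations max. The
  low-rank part is kept downstream (configurable); non-convergence returns
  the partial result flagged.
* **SVD.** LAPACK economy SVD for matrices up to 2×10⁸ entries; above that, a
  blockwise float64 Gram accumulation with `eigh`, leaving U implicit
  (`U = B V / S` per block on demand). Both routes apply the same sign
  convention — each V column's largest-magnitude entry is positive — so runs
  are reproducible; ties in S keep original column order. The group matrix
  can be held in float32 at full cohort scale; the Gram is always accumulated
  in float64. Standardization uses the population (divide-by-n) SD.
* **Component selection.** Strict inequality against the decay cutoff, with a
  1e-12 relative tolerance so weights exactly at the cutoff are excluded
  regardless of rounding.
* **Welch.** 4-s Hann windows, 50% overlap → 0.25 Hz resolution. Band edges
  are half-open low-inclusive (delta [1,4), …) with gamma closed at 70 Hz, so
  the five bands partition [1, 70] without double-counting shared edges. All
  arithmetic is in linear power units.
* **Permutation tests.** Statistic = group mean of ΔnP; null by independent
  sign flips. Exact enumeration of all 2ⁿ patterns for n ≤ 20; otherwise
  Monte-Carlo with the +1-smoothed estimator `p = (1+k)/(1+N)` so p is never
  0. Two-sided by default; per-cell seeds derive deterministically from one
  global seed. No multiplicity correction by default (raw 0.05/0.01 marks,
  matching the reporting convention); Benjamini–Hochberg available as a flag.
* **eLORETA.** Three concentric shells, radii 0.87/0.92/1.0, conductivities
  1/0.0125/1 (≈80:1 skull contrast). Forward potentials come from the
  Legendre-series expansion; each degree's radial transfer solves a small
  interface system whose variables are rescaled per shell so all matrix
  entries stay ≤ 1 in magnitude (well-conditioned to degree several hundred);
  the series is truncated adaptively near machine precision. The inverse uses
  the standard fixed-point iteration on symmetric 3×3 voxel weights,
  `W_v ← (K_vᵀ (K W⁻¹ Kᵀ + α H)⁺ K_v)^{1/2}`, with H the average-reference
  centering operator. The regularization parameter is scale-free: α multiplies
  the mean diagonal of the gain gram, so α = 1 is a ridge the size of the
  average sensor variance. Source grid: cubic lattice offset by half a
  spacing (no voxel at the head center), default spacing 0.15 normalized
  radii (~13 mm on a 9-cm head, < 1000 voxels).
* **Thresholding.** Fraction-of-max (strict >) is the primary rule;
  rank-percentile thresholding is offered as an option since the two differ
  whenever the magnitude distribution is not uniform.

## Design decisions that were genuinely open

* **Which rPCA part continues downstream.** The low-rank part is kept (sparse
  treated as artifact); `rpca_keep="residual"` preserves broadband detail
  while still removing transients.
* **Time courses by slicing U** rather than re-projecting each session
  (`B_m V S⁻¹`); the two are identical for concatenated data and slicing is
  cheaper and exact.
* **Independence window.** Pearson correlations between component time
  courses are computed over each full session and averaged across sessions;
  the window is configurable (slice the time courses) if a shorter
  measurement window is wanted.
* **ICA confirmation** is not implemented: with eyes-closed data cleaned by
  rPCA it has been reported to flag nothing; the cleaning chain leaves a hook
  between notch and rPCA for inserting one.
* **rPCA operates per session on the channels × time matrix** (not on an
  epoch-stacked tensor), matching the rest of the per-session chain.

## Test and verification scale

The pytest suite runs the full pipeline repeatedly, so it uses shortened
sessions with the same four-segment structure (protocol scaled to 1/5–1/10)
and groups of 4–12 subjects; the independence bound is exercised on a
44-subject group with 5.2-min sessions, and `scripts/acceptance.py`
recomputes it at the full 44 × 2 × 13-min × 256 Hz scale. Effect-recovery
and type-I calibration checks use 20 seeded replicates; the calibration band
is the binomial 95% interval around the exact test's attainable level
(50/1024 at n = 10), widened 1.5× for within-replicate correlation — fixed
before the experiments were run.

## Known limitations

* The spherical head model and abstract planted topographies mean source
  localizations are only meaningful in the model's own geometry; no
  anatomical labelling is attempted.
* The generator's stationarity means baseline normalization faces no drift;
  real EEG vigilance drifts are harsher on `nP` than anything tested here.
* Exact permutation inference is limited to n ≤ 20 by enumeration cost;
  larger groups use Monte-Carlo p-values with seed-reproducible streams.
* EDF output quantizes to 16 bits over each channel's range and pads to
  whole-second records; use the delimited format for lossless round trips.
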