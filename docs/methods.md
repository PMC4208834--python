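# Methods

## Generative model

A cohort is a pure function of a configuration and one master seed
(per-stage, per-subject sub-seeds are spawned from it, so stages can be
rerun in isolation).

**Geometry.** Each hemisphere is a cap of `n_per_hemi` vertices cut from a
subdivided icosphere (radius 7 cm) around the ±x pole, slightly rotated by
the seed to break icosahedral symmetry.  Normals are radial; per-vertex
area is one third of the incident triangle area (mm²); adjacency derives
from the induced triangles.  Parcels are defined by polar angle from the
hemisphere pole: cACC seeds near the medial cap edge, DLPFC seeds
dorso-anteriorly, a 9-vertex lateral-frontal target near the pole, and a
broader 18-vertex inferior-frontal (IFC) patch used for the gamma-power
effect.  The cACC→lateral-frontal arc is ~47 mm, so their sensor
footprints are distinct.

**Forward model.** Magnetometers and planar gradiometers sit on a 12-cm
sphere (Fibonacci layout), EEG electrodes on a 10.2-cm sphere.
Magnetometers measure the radial free-space current-dipole field
B = μ₀/4π·q×R/|R|³; gradiometers a finite-difference tangential derivative
(1.7-cm baseline, T/m); EEG an average-referenced homogeneous-medium dipole
potential (σ = 0.33 S/m); EOG channels have zero gain to cortical sources.
Dipole moments lie along vertex normals.  Default sensor counts are
102/204/74 (mag/grad/EEG); the desk preset scales the array to 61/122/48 so
a cohort simulates in minutes on one CPU.

**Trial structure.** 50/50 congruent/incongruent, hands balanced within
condition, inter-onset gaps uniform in [2.95, 3.05] s, target onset 300 ms
after the flankers.  Three windows per trial, placed on the trial's
absolute timeline: noise-covariance baseline [−0.80, −0.62) s, pre-stimulus
[−0.5, 0) s, pre-response [0.3+RT−0.5, 0.3+RT) s.  RT is clipped at 0.55 s
so the windows are pairwise disjoint, which lets them be generated directly
(for stationary noise this is distributionally identical to slicing one
continuous segment) and keeps the baseline free of the planted oscillation
— in real recordings the pre-stimulus baseline is quiet empirically; in a
generator that plants pre-stimulus coupling it must be quiet by
construction, so the baseline precedes the analysis window.

**Signals.** All vertices carry unit-RMS 1/f (power) background, mixed from
64 independent pink series through a random spatial basis (spatially
correlated brain noise; the reduced rank keeps generation O(modes) rather
than O(vertices)).  Sensor noise is white with per-kind SD (50 fT mag,
2.5 fT/cm grad, 1.25 µV EEG, 10 µV EOG), chosen so clean epochs sit well
below the peak-to-peak rejection thresholds.  On each trial the seed parcel
oscillates at `freq_hz` (default 8 Hz) with uniform random phase; the
target parcel at the same frequency with lag ~ von Mises(π/2, κ), where κ
is `kappa_base` (default 0) on congruent and the subject's `kappa_conflict`
on incongruent trials.  The oscillation amplitude is set by a band-limited
SNR: the whitened sensor RMS of the parcel signal equals `snr` (default 9)
times the whitened sensor-noise RMS **within the 2-Hz analysis bin** of the
500-ms window.  (A broadband-RMS definition would make a pure tone ~16×
stronger per bin and saturate the connectivity maps everywhere through
point spread; the band-limited definition makes "SNR 9" a strong but
spatially resolvable oscillation.)

**Behavior link.** Subject coupling strengths are drawn stratified over
`kappa_range` (default (0, 4): subject *i* samples the *i*-th stratum, so
even an 8-subject cohort spans the full range; i.i.d. draws occasionally
collapse onto a narrow band with no between-subject signal).  With
g(κ) = I₁(κ)/I₀(κ) the von Mises mean resultant length, the subject's
conflict effect is ΔRT = 0.30 − 0.35·g(κ) + N(0, 0.01) on the log-RT
scale; per-trial log RT is Gaussian with SD 0.10 around ln(0.569 s)
(+ΔRT on incongruent trials), clipped to [0.55, 1.8] s.  These constants
reproduce the emulated condition means (569 vs 637 ms, mean ΔRT ≈ 0.113)
with a between-subject ΔRT SD of ≈ 0.09; only between-subject RT dispersion
is constrained by the emulated paradigm, so the trial-level SD is a modeling
choice.
Hit rates are Bernoulli (0.98 congruent / 0.95 incongruent).  The
log-normal RT model itself is a convenience — per-trial RT distributions
are not otherwise constrained.

**Gamma-power effect.** Optionally the IFC patch carries a 70-Hz tone whose
amplitude is 3.5·g(κ) times the coupling-oscillation amplitude (the 3.5
compensates the ~40× dilution of a single-bin tone in the 32–110 Hz band
mean), riding on the same subject effect strength, hence negatively linked
to ΔRT.

**Artifacts.** `inject_artifacts` adds a half-sine bump at twice the kind's
rejection threshold to the first channel of that kind in exactly the
requested trials (disjoint across kinds), so rejection exactness is testable
by construction.

## Analysis chain

**Preprocessing.** Zero-phase low-pass (forward+backward FIR, 101 taps at
1 kHz, cutoff 110 Hz, transition ≈ 33 Hz, applied as one symmetric-kernel
FFT convolution with reflected edges) then Fourier resampling to
333 samples/s (output length round(n·333/1000)).  The 0.5-Hz high-pass edge
uses a true zero-phase FIR (transition 0.25–0.75 Hz) when the series is
long enough to hold it; on 0.5–1.5 s epochs it falls back to mean+linear
detrending, which gives equivalent drift suppression at epoch length.

**Rejection.** An epoch is dropped iff any channel of a kind exceeds that
kind's peak-to-peak threshold (150 µV EOG, 100 µV EEG, 2 pT/cm grad,
4 pT mag); order-preserving and idempotent.

**Noise covariance.** Empirical covariance of the concatenated baseline
windows, regularized per channel kind by diagonal loading λ·mean-diagonal
of that kind (λ = 0.1): the per-kind loading keeps the joint MEG+EEG solve
well conditioned despite the T / T/m / V scale disparity.

**Inverse.** R_ii ∝ (a_iᵀa_i)^(−γ) with depth exponent γ = 0.8 (a
conventional default, configurable), scaled so
trace(A_w R A_wᵀ)/trace(C_w) = SNR² (= 9, i.e. λ² = 1/9).  Both the depth
weights and the scaling are evaluated on the noise-whitened gain
A_w = C^(−1/2)A: with heterogeneous channel units the raw-column versions
are dominated by whichever kind has the largest numerical scale, and the
unwhitened solve is condition ~10¹⁷ (the whitener itself rescales C to
unit diagonal before eigendecomposition for the same reason).  The
operator is exactly W = R Aᵀ(A R Aᵀ + C)⁻¹, computed in whitened
coordinates (algebraically identical).  Noise normalization is dSPM-style
division by √diag(W C Wᵀ), configurable off.

**Seed extraction.** Parcel waveform signs are aligned by the first
principal direction d of the parcel normals (d's sign fixed so the
majority of sign(nᵢ·d) is +1; near-orthogonal normals get +1); the seed
series is the sign-weighted parcel mean.  By default seeds are extracted
from raw MNE amplitudes (noise normalization undone), configurable; the
dwPLI is invariant to per-vertex positive rescaling either way.

**Connectivity and power.** Hanning-tapered DFT on the 500-ms window at
the exact 2-Hz bins (no zero padding); dwPLI per vertex per frequency over
the filtered trials (pre-stimulus design: correct incongruent trials;
pre-response design: per hand × congruence cell; cell floor 10 trials,
configurable).  Degenerate dwPLI denominators (all-zero imaginary
cross-spectra — the zero-lag case) map to 0, with a relative threshold
because exact zero-lag inputs leave ~ε float residue.  Power: 4–30 Hz
Hanning on a centered 3-cycle subwindow clamped at the 0.5-s window (at
4–6 Hz three cycles exceed the window; the window is a hard boundary);
30–110 Hz mean over three Slepian tapers at time-halfbandwidth 2 (the
taper count is the binding choice: nominal 3-Hz smoothing at T = 0.5 s
would admit only two tapers, so NW is rounded up to keep three).  All power estimates are
taper-energy normalized so different window lengths share one per-bin
variance scale; band values average the in-band grid frequencies
(lower-inclusive/upper-exclusive, top band inclusive).

**Group statistics.** Behavioral covariate: ΔRT = ln(RT_incong/RT_cong)
over correct trials (the log-ratio reading of "RT normalized by"; the raw
ratio is available via config; correct-trials-only is a choice the source
leaves open).  Vertex-wise OLS of per-subject maps on ΔRT (t for the
slope, df = n−2); pre-response design: per subject the hand-mean
incongruent−congruent difference map, slope t = brain–behavior link,
intercept t = behavior-adjusted conflict effect.  Power maps enter the GLM
as per-subject-demeaned log power (demeaned by the per-subject log-median:
the subject-level multiplicative scale is otherwise a common additive
offset whose chance alignment with permuted covariates produces
hemisphere-wide null clusters; the median resists the focal effect itself,
which a mean would smear into an anti-correlated complement).

**Cluster correction.** Suprathreshold vertices (p < 0.05) form
sign-consistent connected components per hemisphere; cluster mass is the
summed vertex area (mm², no t-weighting).  The null permutes the covariate
(correlation designs) or sign-flips subject difference maps (the
behavior-adjusted main contrast) and records the maximum cluster mass per
permutation per hemisphere; cluster-wise p = (1+exceedances)/(1+n_perm),
tested at 0.05/2 hemispheres = 0.025.  Default 10,000 permutations;
desk-scale runs use 200.  Cross-subject vertex correspondence is the
identity (one shared synthetic source space; surface morphing is out of
scope).  Peak coordinates in the cluster tables are toy-space mm, labeled
as such.

## Problem sizes

Desk preset: 8 subjects × 100 trials, 162 vertices/hemisphere, 61/122/48
sensors, 200 permutations, 2 seed parcels — one end-to-end run ≈ 1 minute
on one CPU.  The full preset (12 × 300, 1000 vertices/hemisphere,
102/204/74, 10,000 permutations, 4 seeds) mirrors the study scale.  The
acceptance suite uses 20 recovery cohorts at desk scale and 1000
scaled-down null-calibration runs (estimator-level null maps — independent
circular-Gaussian spectral coefficients through the real dwPLI, GLM,
clustering and permutation machinery — a design that preserves the
exchangeability on which family-wise validity rests while staying three
orders of magnitude cheaper than full sensor simulation).

## What the synthetic cohorts do and do not show

Passing tests demonstrate that the chain recovers a planted, behavior-linked
coupling at the right location, frequency, band and sign, controls its
family-wise false-positive rate on null cohorts, and is deterministic and
exact where closed forms exist.  They do not validate the physics
simplifications against real anatomy (spherical geometry, free-space
fields, no BEM, no head movement or SSS, shared source space across
subjects, radial-only source orientations), nor the realism of pure-tone
oscillations, the log-normal RT model, or the stratified κ design.  Real
data add inter-subject anatomical variability, non-stationary artifacts and
correlated sensor noise that this generator deliberately omits.

## Known limitations

* The EEG forward model is an average-referenced infinite-medium potential;
  relative MEG/EEG weighting is only qualitatively realistic.
* dwPLI values at vertices adjacent to a true source are inflated by
  point spread of the *coupled partner* (zero-lag leakage of the seed
  itself is suppressed by construction); detected clusters therefore
  extend beyond the planted parcel, as in real minimum-norm maps.
* With 8 subjects the covariate-permutation null is granular (8! orderings);
  cluster-wise p-values below ~1/201 are not resolvable at 200 permutations.
* Incorrect-response trials are excluded from both the behavioral means and
  the pre-response spectral cells; including them is a config switch away
  and the convention differs between labs.
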