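# cortsync

Cortically constrained MEG/EEG oscillatory connectivity analysis, exercised
end to end on synthetic auditory-flanker cohorts with planted,
behavior-linked cross-regional phase coupling.

## The scientific problem

During conflict tasks (e.g. identifying a spoken target among phonetically
conflicting flankers), phase synchronization between the caudal anterior
cingulate cortex (cACC) and lateral prefrontal regions is thought to support
fast conflict resolution: subjects whose cingulo-frontal coupling is stronger
show a smaller reaction-time cost on incongruent trials.  Testing this from
MEG/EEG requires a long chain of machinery — source localization with a
cortically constrained minimum-norm inverse, seed-based phase-synchrony
mapping with an estimator robust to field spread, and cluster-based
permutation inference across the cortical surface — and every link of that
chain can silently fail.

This package implements the full chain **and** a synthetic-cohort generator
that plants the hypothesized structure, so each stage is verifiable against
ground truth without any recorded data:

* **Generator** — toy two-hemisphere cortical source space (icosphere caps
  with per-vertex areas/normals/adjacency), a spherical MEG+EEG forward
  model (magnetometers, planar gradiometers, average-referenced EEG, EOG),
  and multi-trial sensor epochs: flanker trial structure (50/50
  congruent/incongruent, 2.95–3.05 s inter-onset gaps, target 300 ms after
  the flankers), 1/f cortical background, per-kind sensor noise, and
  seed→target 8-Hz coupling with von Mises phase lags whose per-subject
  concentration κ drives the subject's conflict effect
  ΔRT = ln(RT_incong/RT_cong) through a negative linear link.
* **Inverse** — band-pass + downsampling (333 samples/s, 0.5–110 Hz),
  peak-to-peak artifact rejection (150 µV EOG / 100 µV EEG / 2 pT/cm grad /
  4 pT mag), baseline noise covariance C with per-kind regularization,
  depth-weighted source covariance R, the minimum-norm operator
  **W = R Aᵀ (A R Aᵀ + C)⁻¹**, dSPM-style noise normalization, and
  sign-aligned seed time-course extraction.
* **Spectral** — Hanning-tapered DFT at 2-Hz steps (6–20 Hz, 500-ms
  windows); debiased weighted phase lag index (dwPLI) seed-to-vertex maps,
  with Z_k = Im(S_k V_k*) over trials k:

      dwPLI = ((ΣZ)² − ΣZ²) / ((Σ|Z|)² − ΣZ²)

  plus band power maps (3-cycle Hanning at 4–30 Hz, three Slepian tapers at
  30–110 Hz; theta/alpha/beta/low-gamma/high-gamma octave bands).
* **Statistics** — per-subject behavioral summaries (log-RT transform,
  cubic hit-rate transform, Jarque–Bera, paired t); vertex-wise GLM of
  connectivity/power on ΔRT; pre-response 2×2 (hand × congruence)
  factorial; cluster-based max-mass Monte Carlo correction (vertex p<0.05,
  cluster-wise p Bonferroni-corrected over hemispheres, −log₁₀(p)·sign(t)
  peak summaries, cluster sizes in mm²).

## Worked example

```sh
python analysis/01_simulate_cohort.py 1
python analysis/02_connectivity_stats.py 1
```

The first command simulates the desk-scale cohort (8 subjects × 100 trials)
and prints its behavioral conflict effect:

```
cohort: 8 subjects x 100 trials -> results/run/cohort.h5
conflict effect: mean dRT = 0.0878 (log RT ratio), t(7) = 2.59, p = 0.036
planted coupling strengths g(kappa): [0.06 0.27 0.54 0.63 0.74 0.78 0.81 0.85]
```

i.e. incongruent responses are ~9% slower on the log scale for this draw
(the planted condition means are 569 ms vs 637 ms), and each subject
carries a planted coupling strength g(κ) ∈ [0, 1] — subjects with strong
coupling pay almost no conflict cost, which is exactly the between-subject
spread the brain–behavior analysis feeds on.  The second command runs
source estimation, dwPLI mapping and cluster permutation for both analysis
windows; its pre-stimulus table reads

```
target_hemisphere    seed contrast  f_hz  max_value  size_mm2  cluster_p                      coverage
               rh cACC-rh behavior   6.0    -2.4433    1351.1   0.009950        DLPFC-rh,latfrontal-rh
               rh cACC-rh behavior   8.0    -4.8566    2204.1   0.004975 DLPFC-rh,IFC-rh,latfrontal-rh
               rh cACC-rh behavior  10.0    -3.8637    1169.6   0.009950        DLPFC-rh,latfrontal-rh
```

the strongest cluster sits over the right lateral-frontal target parcel at
the planted 8 Hz (the 6/10-Hz neighbors reflect the Hanning taper's 2-Hz
spread); its negative peak value (−log₁₀(p)·sign(t)) encodes that
*stronger* coupling predicts a *smaller* RT lag.
`analysis/03_planted_effect_recovery.py` repeats the experiment over fresh
cohorts and reports detection rates and the null false-positive rate of the
cluster test.

## Layout

```
src/cortsync/        library: data_model, io, synth, inverse, spectral,
                     behavior, group_stats, pipeline, studies, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (tests/test_acceptance.py holds the
                     end-to-end scientific checks)
scripts/acceptance.py
docs/methods.md      model, parameters, numerical choices, limitations
```

A `cortsync` console command exposes the stages
(`simulate`, `behavior`, `stats`, `report`, `run-all`); see
`cortsync --help`.  The HDF5 cohort layout is documented in
`src/cortsync/io.py`.
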