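"""Reusable study drivers: planted-effect recovery and null calibration.

These functions run the package's own machinery on freshly generated inputs
and reduce each run to a small summary, so the same code backs the analysis
scripts, the acceptance tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import group_stats as gs
from .pipeline import PipelineConfig, behavior_table
from .spectral import SpectralConfig, debiased_wpli
from .synth import build_toy_source_space, simulate_cohort


def _sub_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % 2**31)


def recovery_config(
    n_subjects: int = 8,
    n_trials: int = 100,
    snr: float = 9.0,
    with_power_effect: bool = True,
    coupling_on: bool = True,
) -> PipelineConfig:
    """Desk-scale study conditions for the planted-coupling recovery runs.

    8-Hz seed-to-target phase coupling (right cACC -> right lateral frontal)
    in the pre-stimulus window of incongruent trials, subject strength
    negatively linked to dRT; optionally a 70-Hz amplitude effect in the
    left lateral-frontal parcel riding on the same subject effect.
    """
    cfg = PipelineConfig.preset("desk")
    cfg.cohort.n_subjects = n_subjects
    cfg.cohort.n_trials = n_trials
    cfg.cohort.snr = snr
    cfg.cohort.coupling_on = coupling_on
    cfg.cohort.power_effect_on = with_power_effect
    cfg.seeds = ("cACC-rh",)
    cfg.spectral = SpectralConfig(conn_freqs=np.array([8.0, 16.0]))
    cfg.n_permutations = 200
    return cfg


@dataclass
class RecoveryResult:
    detected_8hz: bool
    detected_16hz: bool
    sign_8hz: float  # sign of the peak value of the best 8-Hz target cluster
    band_detected: dict  # band name -> planted-power cluster found over parcel


def _target_clusters(clusters, spec, parcel, negative_only=True):
    hits = []
    for c in gs.significant(clusters, spec):
        if negative_only and c.max_value >= 0:
            continue
        if np.intersect1d(parcel.vertex_ids, c.vertex_ids).size > 0:
            hits.append(c)
    return hits


def coupling_recovery_run(seed: int, config: PipelineConfig | None = None) -> RecoveryResult:
    """One synthetic cohort through the pre-stimulus correlation design.

    Detection = a significant negative-sign cluster overlapping the planted
    target parcel at the given frequency; optionally also band-power
    detection over the power-effect parcel per band.
    """
    from .pipeline import _masked_trials, prepare_subject
    from .spectral import seed_wpli_map, spectral_power

    cfg = config or recovery_config()
    cohort, _truth = simulate_cohort(cfg.cohort, seed=_sub_seed(seed, 11))
    btab = behavior_table(cohort)
    covariate = btab["delta_rt"].to_numpy()
    spec = gs.DesignSpec(vertex_alpha=cfg.vertex_alpha,
                         cluster_alpha=cfg.cluster_alpha,
                         n_permutations=cfg.n_permutations)
    seed_name = cfg.seeds[0]
    # one preprocessing/inverse pass per subject serves both analyses
    conn_maps, pow_maps = {}, {}
    for sid in cohort.subjects:
        spectra, stc = prepare_subject(cohort, sid, "pre_stimulus", cfg)
        mask = _masked_trials(cohort, sid, spectra.trial_mask_source,
                              condition="incongruent", correct_only=True)
        conn_maps[sid] = seed_wpli_map(
            spectra.seed_series[seed_name], stc, seed_name, cfg.spectral,
            mask, condition_cell="incongruent")
        if cfg.cohort.power_effect_on:
            pow_maps[sid] = spectral_power(stc, cfg.spectral, mask,
                                           condition_cell="incongruent")

    target = cohort.parcel(cfg.cohort.target_parcel)
    sids = sorted(conn_maps)
    freqs = np.asarray(cfg.spectral.conn_freqs)
    found = {}
    sign8 = 0.0
    for fi, f in enumerate(freqs):
        maps = np.stack([conn_maps[s].values[:, fi] for s in sids])
        design = gs.PermutationDesign(subject_maps=maps, covariate=covariate,
                                      stat="slope", spec=spec)
        clusters = gs.cluster_permutation(
            design, cohort.source_space, seed=_sub_seed(seed, 13, fi), freq=f)
        hits = _target_clusters(clusters, spec, target)
        found[float(f)] = len(hits) > 0
        if f == 8.0 and hits:
            sign8 = float(np.sign(hits[0].max_value))

    band_detected = {}
    if cfg.cohort.power_effect_on:
        pparcel = cohort.parcel(cfg.cohort.power_parcel)
        bands = pow_maps[sids[0]].bands
        for bi, band in enumerate(bands):
            maps = gs.relative_log_power(
                np.stack([pow_maps[s].values[:, bi] for s in sids]))
            design = gs.PermutationDesign(subject_maps=maps, covariate=covariate,
                                          stat="slope", spec=spec)
            clusters = gs.cluster_permutation(
                design, cohort.source_space, seed=_sub_seed(seed, 17, bi),
                freq=np.nan)
            band_detected[band] = len(
                _target_clusters(clusters, spec, pparcel)) > 0
    return RecoveryResult(
        detected_8hz=found.get(8.0, False),
        detected_16hz=found.get(16.0, False),
        sign_8hz=sign8,
        band_detected=band_detected,
    )


def null_maps(rng, n_subjects: int, n_trials: int, n_vertices: int) -> np.ndarray:
    """Per-subject debiased-wPLI maps under the no-coupling null.

    Spectral coefficients of seed and vertices are independent circular
    complex Gaussians (uniform phases) — exactly the spectral-domain picture
    of a cohort without planted coupling — run through the real estimator.
    """
    out = np.empty((n_subjects, n_vertices))
    for s in range(n_subjects):
        sc = rng.standard_normal((n_trials, 1)) + 1j * rng.standard_normal((n_trials, 1))
        vc = rng.standard_normal((n_trials, n_vertices)) \
            + 1j * rng.standard_normal((n_trials, n_vertices))
        out[s] = debiased_wpli(sc, vc)
    return out


def null_fwer_study(
    n_runs: int = 1000,
    seed: int = 0,
    n_subjects: int = 8,
    n_trials: int = 30,
    n_per_hemi: int = 100,
    n_permutations: int = 200,
) -> dict:
    """Family-wise false-positive rate of the cluster machinery on null cohorts.

    Each run draws null connectivity maps (no coupling) and a behavior
    covariate with zero slope, then runs the real GLM + clustering +
    max-statistic permutation test.  A family is one hemisphere of one run;
    returns the fraction of families with any cluster_p < 0.025.
    """
    src = build_toy_source_space(n_per_hemi, seed=_sub_seed(seed, 23))
    spec = gs.DesignSpec(n_permutations=n_permutations)
    rng = np.random.default_rng(_sub_seed(seed, 29))
    fp = {"lh": 0, "rh": 0}
    for run in range(n_runs):
        maps = null_maps(rng, n_subjects, n_trials, src.n_vertices)
        covariate = rng.standard_normal(n_subjects)
        design = gs.PermutationDesign(subject_maps=maps, covariate=covariate,
                                      stat="slope", spec=spec)
        clusters = gs.cluster_permutation(
            design, src, seed=_sub_seed(seed, 31, run), freq=np.nan)
        for h in ("lh", "rh"):
            if any(c.cluster_p < spec.per_hemi_alpha and c.hemisphere == h
                   for c in clusters):
                fp[h] += 1
    n_families = 2 * n_runs
    return {
        "n_runs": n_runs,
        "n_families": n_families,
        "false_positives": fp["lh"] + fp["rh"],
        "fwer": (fp["lh"] + fp["rh"]) / n_families,
        "nominal": spec.per_hemi_alpha,
    }
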