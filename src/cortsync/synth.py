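"""Synthetic cohort generator.

Builds a toy two-hemisphere cortical source space, a spherical-sensor forward
model, and multi-trial MEG/EEG epochs with planted cross-regional phase
coupling whose subject-level strength covaries (negatively) with the
behavioral conflict effect.  The generator is the ground truth every later
stage is tested against: the planted structure mirrors a flanker-type
conflict task — 50/50 congruent/incongruent trials, inter-onset gaps of
2.95-3.05 s, a target sound 300 ms after the flankers, and 500-ms
pre-stimulus / pre-response analysis windows.

Coupling model: on each trial the seed parcel oscillates at ``freq_hz`` with a
uniformly random phase; the target parcel oscillates at the same frequency
with phase = seed phase + lag, lag ~ von Mises(mean_lag_rad, kappa).  The
concentration kappa is ``kappa_base`` on congruent trials and a per-subject
``kappa_conflict`` on incongruent trials.  The subject's conflict RT effect is
linked to g(kappa_conflict) = I1(k)/I0(k) (the von Mises mean resultant
length) through a linear model with negative slope, so stronger coupling
means a smaller RT cost of conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special
from scipy.sparse.csgraph import connected_components

from .data_model import (
    ChannelInfo,
    Cohort,
    EpochSet,
    Parcel,
    SourceSpace,
    SubjectData,
    TrialTable,
)

MU0_4PI = 1e-7  # magnetic constant / 4 pi
HEAD_RADIUS = 0.07  # m, cortical shell
SENSOR_RADIUS = 0.12  # m, MEG helmet shell
EEG_RADIUS = 0.102  # m, scalp shell
GRAD_BASELINE = 0.017  # m, planar gradiometer baseline

# Per-kind sensor noise standard deviations (white, per sample).  Chosen so
# that clean epochs -- noise plus a planted parcel signal at the default
# whitened SNR -- stay comfortably below the peak-to-peak rejection
# thresholds (150 uV EOG / 100 uV EEG / 2 pT/cm grad / 4 pT mag).
NOISE_SD = {"mag": 5.0e-14, "grad": 2.5e-15, "eeg": 1.25e-6, "eog": 1.0e-5}

REJECTION_PTP = {"eog": 150e-6, "eeg": 100e-6, "grad": 2e-12, "mag": 4e-12}


def resultant_length(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution, g(kappa)=I1/I0.

    Monotone from 0 (uniform phases) to 1 (a deterministic lag); used as the
    bounded coupling-strength scale in the behavior link.
    """
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


@dataclass
class CouplingSpec:
    """Planted seed-to-target narrow-band phase coupling for one subject."""

    seed_parcel: str = "cACC-rh"
    target_parcel: str = "latfrontal-rh"
    freq_hz: float = 8.0
    mean_lag_rad: float = np.pi / 2
    kappa_base: float = 0.0
    kappa_conflict: float = 5.0
    window: str = "pre_stimulus"  # which analysis window carries the coupling

    def validate(self) -> None:
        lag = np.mod(self.mean_lag_rad, np.pi)
        if min(lag, np.pi - lag) < 1e-6:
            raise ValueError(
                "mean_lag_rad must be away from 0 and pi: the wPLI is blind "
                "to zero-lag coupling")
        if self.kappa_base < 0 or self.kappa_conflict < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class PowerEffectSpec:
    """Planted band-limited amplitude increase (no phase coupling) for one subject."""

    parcel: str = "IFC-lh"
    freq_hz: float = 70.0
    amplitude: float = 1.0  # relative to the phase-coupling oscillation amplitude
    window: str = "pre_stimulus"


@dataclass
class BehaviorSpec:
    """Behavioral generative model (log-normal RTs, Bernoulli correctness)."""

    # Congruent mean and the dRT the intercept/slope produce at the mean
    # planted coupling strength reproduce the reported condition means
    # (0.569 s vs 0.637 s, i.e. dRT ~ 0.113); the slope spreads dRT across
    # subjects by ~0.06 (between-subject SD ~0.05, consistent with a
    # conflict effect of t ~ 7.5 over ~10 subjects).
    rt_congruent_mean_s: float = 0.569
    rt_sd_s: float = 0.10  # SD of log RT across trials (within subject)
    conflict_slope: float = -0.35  # dRT per unit g(kappa_conflict); negative
    conflict_intercept: float = 0.30
    conflict_noise_sd: float = 0.01  # subject-level noise on dRT
    hr_congruent: float = 0.98
    hr_incongruent: float = 0.95

    def validate(self) -> None:
        for p in (self.hr_congruent, self.hr_incongruent):
            if not (0 < p <= 1):
                raise ValueError("hit probabilities must be in (0, 1]")
        if self.rt_congruent_mean_s <= 0:
            raise ValueError("rt mean must be positive")


# ---------------------------------------------------------------------------
# Geometry


def _icosphere(subdivisions: int):
    """Unit icosphere vertices/faces by repeated edge-midpoint subdivision."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        verts_list = list(verts)
        cache: dict = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return verts, faces


def _triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def build_toy_source_space(n_per_hemi: int, seed: int = 0) -> SourceSpace:
    """Two disjoint icosphere caps, one per hemisphere.

    Each hemisphere is the ``n_per_hemi`` vertices of a (seeded, slightly
    rotated) icosphere nearest to its pole (-x for left, +x for right), with
    the triangles they induce.  Normals are radial; per-vertex area is one
    third of the incident triangle area, in mm**2.
    """
    if n_per_hemi < 40:
        raise ValueError("n_per_hemi must be >= 40")
    # pick a subdivision level with comfortably more vertices than two caps
    level = 2
    while 10 * 4**level + 2 < 2.6 * n_per_hemi:
        level += 1
    verts, faces = _icosphere(level)
    rng = np.random.default_rng(seed)
    # a small random rotation decorrelates the caps from icosahedral symmetry
    q = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(q)
    rot *= np.sign(np.linalg.det(rot))
    verts = verts @ rot.T

    all_pos, all_norm, all_area, all_hemi, all_tris = [], [], [], [], []
    offset = 0
    for hemi, pole in (("lh", np.array([-1.0, 0, 0])), ("rh", np.array([1.0, 0, 0]))):
        order = np.argsort(-verts @ pole)
        chosen = order[:n_per_hemi]
        # extend the cap until every chosen vertex sits in an induced triangle
        k = n_per_hemi
        while True:
            sel = set(order[:k].tolist())
            tri_mask = np.all(np.isin(faces, list(sel)), axis=1)
            used = np.unique(faces[tri_mask])
            if np.all(np.isin(chosen, used)):
                break
            k += max(4, n_per_hemi // 20)
            if k > len(order):  # pragma: no cover - cannot happen at >=40
                raise RuntimeError("cap construction failed")
        keep = chosen
        local = {v: i for i, v in enumerate(keep)}
        tri_keep = faces[np.all(np.isin(faces, keep), axis=1)]
        tris = np.array([[local[v] for v in tri] for tri in tri_keep], dtype=int)
        pos = verts[keep] * HEAD_RADIUS
        areas_m2 = np.zeros(len(keep))
        tri_area = _triangle_areas(pos, tris) if len(tris) else np.zeros(0)
        for ti, tri in enumerate(tris):
            areas_m2[tri] += tri_area[ti] / 3.0
        # cap-boundary vertices with no induced triangle get the mean area
        zero = areas_m2 <= 0
        if np.any(zero):
            areas_m2[zero] = areas_m2[~zero].mean()
        normals = verts[keep]  # radial, unit by construction
        shift = np.array([-0.005 if hemi == "lh" else 0.005, 0.0, 0.0])
        all_pos.append(pos + shift)
        all_norm.append(normals)
        all_area.append(areas_m2 * 1e6)  # -> mm**2
        all_hemi.append(np.full(len(keep), hemi, dtype="U2"))
        all_tris.append(tris + offset)
        offset += len(keep)

    src = SourceSpace(
        vertex_positions=np.vstack(all_pos),
        vertex_normals=np.vstack(all_norm),
        vertex_area=np.concatenate(all_area),
        hemisphere=np.concatenate(all_hemi),
        triangles=np.vstack(all_tris),
    )
    src.validate()
    for hemi in ("lh", "rh"):
        idx = src.hemi_vertices(hemi)
        sub = src.adjacency_sparse()[np.ix_(idx, idx)]
        n_comp, _ = connected_components(sub, directed=False)
        if n_comp != 1:
            raise RuntimeError(f"{hemi} cap is not connected")
    return src


def default_parcels(src: SourceSpace, n_vertices: int = 9,
                    n_vertices_target: int = 18) -> list[Parcel]:
    """Seed/target parcels at fixed anatomical-analogue positions.

    Each hemisphere cap is centred on its +-x pole, so landmarks are defined
    by the polar angle from that pole and a tangent direction in (y, z):
    cACC seeds sit near the medial cap boundary (large polar angle), DLPFC
    dorso-anteriorly at mid angle, and the lateral-frontal targets close to
    the pole — a coarse analogue of the caudal-ACC / rostral-middle-frontal
    / lateral-prefrontal parcels of a cortical atlas.  The cACC-to-
    lateral-frontal arc is ~60 mm, so their sensor footprints are distinct.
    """
    landmarks = {  # polar angle (deg), tangent (y, z), vertex count
        "cACC": (58.0, (0.5, 1.0), n_vertices),
        "DLPFC": (35.0, (1.0, 0.2), n_vertices),
        "latfrontal": (12.0, (1.0, 0.6), n_vertices),
        "IFC": (34.0, (0.8, -0.6), n_vertices_target),  # broader patch
    }
    roles = {"cACC": "seed", "DLPFC": "seed", "latfrontal": "target",
             "IFC": "target"}
    parcels = []
    for base, (theta_deg, (ty, tz), n_take) in landmarks.items():
        for hemi, sign in (("lh", -1.0), ("rh", 1.0)):
            pole = np.array([sign, 0.0, 0.0])
            tangent = np.array([0.0, ty, tz])
            tangent /= np.linalg.norm(tangent)
            th = np.deg2rad(theta_deg)
            direction = np.cos(th) * pole + np.sin(th) * tangent
            idx = src.hemi_vertices(hemi)
            dirs = src.vertex_normals[idx]  # radial: position direction
            ang = np.arccos(np.clip(dirs @ direction, -1, 1))
            vids = idx[np.argsort(ang)[:n_take]]
            parcels.append(
                Parcel(name=f"{base}-{hemi}", vertex_ids=vids, role=roles[base]))
    return parcels


# ---------------------------------------------------------------------------
# Forward model


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])


def _dipole_field(r_sens: np.ndarray, r_src: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Free-space magnetic field of current dipoles q at r_src, at points r_sens.

    Returns (n_sens, n_src, 3).  B = mu0/(4 pi) q x R / |R|^3.
    """
    R = r_sens[:, None, :] - r_src[None, :, :]
    dist = np.linalg.norm(R, axis=2)
    if np.any(dist < 1e-3):
        raise ValueError("sensor coincident with source")
    cross = np.cross(np.broadcast_to(q[None, :, :], R.shape), R, axis=2)
    return MU0_4PI * cross / dist[:, :, None] ** 3


def build_forward(
    src: SourceSpace,
    n_mag: int = 102,
    n_grad: int = 204,
    n_eeg: int = 74,
    n_eog: int = 1,
    seed: int = 0,
):
    """Gain matrix + channel list for sensors on an enclosing sphere.

    Magnetometers measure the radial free-space dipole field (T); planar
    gradiometers a tangential spatial derivative of it (T/m); EEG channels an
    average-referenced homogeneous-medium dipole potential (V).  EOG channels
    have zero gain to brain sources.  Dipole moments lie along the vertex
    normals (unit gain column = 1 A.m source).
    """
    for n in (n_mag, n_grad, n_eeg):
        if n < 1:
            raise ValueError("sensor counts must be >= 1")
    rng = np.random.default_rng(seed)
    pos_src = src.vertex_positions
    q = src.vertex_normals

    channels: list[ChannelInfo] = []
    rows = []

    meg_pos = _fibonacci_sphere(n_mag + n_grad, SENSOR_RADIUS)
    meg_pos += rng.normal(scale=1e-4, size=meg_pos.shape)
    mag_pos, grad_pos = meg_pos[:n_mag], meg_pos[n_mag:]

    # magnetometers: radial projection of B
    B = _dipole_field(mag_pos, pos_src, q)
    er = mag_pos / np.linalg.norm(mag_pos, axis=1, keepdims=True)
    rows.append(np.einsum("ijk,ik->ij", B, er))
    channels += [
        ChannelInfo(f"MAG{i:03d}", "mag", "T", mag_pos[i]) for i in range(n_mag)
    ]

    # planar gradiometers: finite-difference tangential derivative of radial B
    er_g = grad_pos / np.linalg.norm(grad_pos, axis=1, keepdims=True)
    ref = np.where(np.abs(er_g[:, 2:3]) < 0.9, np.array([[0.0, 0, 1]]), np.array([[1.0, 0, 0]]))
    tang = np.cross(er_g, ref)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    d = GRAD_BASELINE / 2
    Bp = _dipole_field(grad_pos + d * tang, pos_src, q)
    Bm = _dipole_field(grad_pos - d * tang, pos_src, q)
    g_rows = (
        np.einsum("ijk,ik->ij", Bp, er_g) - np.einsum("ijk,ik->ij", Bm, er_g)
    ) / GRAD_BASELINE
    rows.append(g_rows)
    channels += [
        ChannelInfo(f"GRAD{i:03d}", "grad", "T/m", grad_pos[i]) for i in range(n_grad)
    ]

    # EEG: infinite-homogeneous-medium dipole potential, average reference
    eeg_pos = _fibonacci_sphere(n_eeg, EEG_RADIUS)
    eeg_pos += rng.normal(scale=1e-4, size=eeg_pos.shape)
    Re = eeg_pos[:, None, :] - pos_src[None, :, :]
    dist = np.linalg.norm(Re, axis=2)
    if np.any(dist < 1e-3):
        raise ValueError("electrode coincident with source")
    sigma = 0.33  # S/m
    V = np.einsum("ijk,jk->ij", Re, q) / (4 * np.pi * sigma * dist**3)
    V -= V.mean(axis=0, keepdims=True)
    rows.append(V)
    channels += [
        ChannelInfo(f"EEG{i:03d}", "eeg", "V", eeg_pos[i]) for i in range(n_eeg)
    ]

    # EOG: periocular channels, blind to cortical sources
    for i in range(n_eog):
        channels.append(
            ChannelInfo(f"EOG{i:03d}", "eog", "V", np.array([0.0, 0.095, -0.02])))
    rows.append(np.zeros((n_eog, src.n_vertices)))

    gain = np.vstack(rows)
    nonzero = np.linalg.norm(gain[: n_mag + n_grad + n_eeg], axis=0)
    if np.any(nonzero == 0):
        raise ValueError("gain has a zero column")
    return gain, channels


# ---------------------------------------------------------------------------
# Subject simulation


def _pink_noise(rng, n_series: int, n_samples: int, sfreq: float) -> np.ndarray:
    """1/f (power) background: white noise shaped to PSD ~ 1/f, unit RMS.

    float32 throughout and FFT at the next fast length: the generator is
    bandwidth-bound at cohort scale.
    """
    from scipy import fft as sfft

    nf = sfft.next_fast_len(n_samples, real=True)
    white = rng.standard_normal((n_series, nf), dtype=np.float32)
    spec = sfft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(nf, 1 / sfreq)
    spec *= (1.0 / np.sqrt(np.maximum(freqs, 1.0))).astype(np.float32)
    out = sfft.irfft(spec, n=nf, axis=1)[:, :n_samples]
    rms = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    return out / rms


def _vonmises(rng, mu: float, kappa: float, size) -> np.ndarray:
    if np.isinf(kappa):
        return np.full(() if size is None else size, mu)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=size) + mu
    return rng.vonmises(mu, kappa, size=size)


@dataclass
class SimTruth:
    """Ground truth planted for one subject (for recovery diagnostics)."""

    kappa_conflict: float
    coupling_strength: float  # g(kappa_conflict)
    delta_rt_true: float
    power_amplitude: float = 0.0
    lags: Optional[np.ndarray] = None  # drawn seed->target phase lags, rad


def simulate_subject(
    gain: np.ndarray,
    channels: Sequence[ChannelInfo],
    src: SourceSpace,
    parcels: Sequence[Parcel],
    coupling: CouplingSpec,
    behavior: BehaviorSpec,
    n_trials: int = 100,
    sfreq: float = 1000.0,
    seed: int = 0,
    snr: float = 9.0,
    background_rms: float = 1.0,
    power_effect: Optional[PowerEffectSpec] = None,
    window_s: float = 0.5,
    effect_strength: Optional[float] = None,
):
    """Simulate one subject's trials at the acquisition rate.

    Returns ``(pre_stimulus EpochSet, pre_response EpochSet, baseline
    EpochSet, TrialTable, SimTruth)``.  Windows are placed on each trial's
    absolute timeline (target onset 300 ms after the flankers, response at
    the trial's RT), so pre-response placement genuinely depends on the
    simulated RT.

    ``snr`` scales the parcel oscillation so that the noise-whitened sensor
    RMS of the planted parcel signal equals ``snr`` (whitening by each
    channel kind's noise SD).  ``background_rms`` sets the whitened sensor
    RMS of the 1/f cortical background the same way.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even (half congruent, half incongruent)")
    if sfreq < 333:
        raise ValueError("sfreq must be >= 333")
    coupling.validate()
    behavior.validate()
    names = {p.name for p in parcels}
    for pn in (coupling.seed_parcel, coupling.target_parcel):
        if pn not in names:
            raise ValueError(f"parcel {pn!r} not in source space parcels")
    parcel_of = {p.name: p for p in parcels}
    rng = np.random.default_rng(seed)

    # --- behavior -----------------------------------------------------------
    cond = np.array(["congruent", "incongruent"] * (n_trials // 2), dtype="U11")
    rng.shuffle(cond)
    hand = np.empty(n_trials, dtype="U5")
    for c in ("congruent", "incongruent"):
        idx = np.nonzero(cond == c)[0]
        h = np.array(["left", "right"] * (len(idx) // 2 + 1))[: len(idx)]
        rng.shuffle(h)
        hand[idx] = h
    g_k = (resultant_length(coupling.kappa_conflict)
           if effect_strength is None else float(effect_strength))
    delta_rt = (
        behavior.conflict_intercept
        + behavior.conflict_slope * g_k
        + rng.normal(scale=behavior.conflict_noise_sd)
    )
    log_rt = np.log(behavior.rt_congruent_mean_s) + rng.normal(
        scale=behavior.rt_sd_s, size=n_trials)
    log_rt[cond == "incongruent"] += delta_rt
    rt = np.exp(log_rt)
    rt = np.clip(rt, 0.55, 1.8)  # keep the pre-response window clear of onset
    hr = np.where(cond == "congruent", behavior.hr_congruent, behavior.hr_incongruent)
    correct = rng.uniform(size=n_trials) < hr
    gaps = rng.uniform(2.95, 3.05, size=n_trials)
    onset = 5.0 + np.cumsum(gaps)
    trials = TrialTable(condition=cond, hand=hand, rt=rt, correct=correct, onset=onset)

    # --- source signals -----------------------------------------------------
    n_src = src.n_vertices
    seed_vids = parcel_of[coupling.seed_parcel].vertex_ids
    target_vids = parcel_of[coupling.target_parcel].vertex_ids
    pre_len = int(round(window_s * sfreq))
    t_target = 0.3  # target sound onset after the flankers, s

    # whitened-gain energy for SNR calibration
    sd_ch = np.array([NOISE_SD[c.kind] for c in channels])
    parcel_cols = np.unique(np.concatenate([seed_vids, target_vids]))
    gw = gain / sd_ch[:, None]

    def whitened_rms_of_unit_parcel(vids):
        # RMS over channels of a unit-amplitude coherent parcel sinusoid
        col = gw[:, vids].sum(axis=1)
        return np.sqrt(np.mean(col**2)) / np.sqrt(2.0)  # sinusoid RMS factor

    amp_unit = whitened_rms_of_unit_parcel(parcel_cols)
    # snr is band-limited: parcel-signal RMS over sensor-noise RMS within the
    # 2-Hz analysis bin of the 500-ms window.  White sensor noise of unit
    # whitened RMS carries sqrt(2 * bin_hz / sfreq) of its RMS in one bin; a
    # tone concentrates all of its RMS there.  (A broadband-RMS definition
    # would make a pure tone's per-bin strength ~sqrt(n_bins) larger and
    # spatial specificity unattainable at any plausible inverse resolution.)
    bin_hz = 1.0 / window_s
    noise_band_rms = np.sqrt(2.0 * bin_hz / sfreq)
    osc_amp = snr * noise_band_rms / amp_unit if amp_unit > 0 else 0.0

    kappas = np.where(cond == "incongruent", coupling.kappa_conflict, coupling.kappa_base)
    seed_phase = rng.uniform(-np.pi, np.pi, size=n_trials)
    lags = np.array([_vonmises(rng, coupling.mean_lag_rad, k, None) for k in kappas])

    pe_amp = 0.0
    if power_effect is not None:
        if power_effect.parcel not in names:
            raise ValueError(f"parcel {power_effect.parcel!r} not in source space parcels")
        pe_amp = power_effect.amplitude * osc_amp

    # The three per-trial windows — noise-covariance baseline [-0.80, -0.62),
    # pre-stimulus [-0.5, 0) and pre-response [0.3 + rt - 0.5, 0.3 + rt),
    # all relative to stimulus onset — are pairwise disjoint (RT is clipped
    # at 0.55 s), so they are generated directly with absolute-trial-time
    # oscillation phases; for stationary noise this is distributionally
    # identical to slicing one continuous segment, without simulating the
    # dead time between windows.  The baseline precedes the pre-stimulus
    # analysis window so it never contains the planted oscillation; it does
    # contain the 1/f background, which a noise covariance should capture.
    #
    # The 1/f cortical background lives in a reduced spatial basis: every
    # vertex carries unit-RMS pink activity mixed from `n_modes` independent
    # pink series (spatially correlated brain noise), projected through a
    # precomputed gain @ B.
    n_modes = min(64, n_src)
    B = rng.standard_normal((n_src, n_modes)) / np.sqrt(n_modes)
    gain_bg = ((gain @ B) * (background_rms / amp_unit)).astype(np.float32) \
        if background_rms > 0 else None
    pe_vids = (parcel_of[power_effect.parcel].vertex_ids
               if power_effect is not None else None)
    g_seed = gain[:, seed_vids].sum(axis=1).astype(np.float32)
    g_target = gain[:, target_vids].sum(axis=1).astype(np.float32)
    g_pe = gain[:, pe_vids].sum(axis=1).astype(np.float32) \
        if pe_vids is not None else None

    n_ch = len(channels)
    base_len = int(round(0.18 * sfreq))
    win_starts = {  # window start time relative to stimulus onset, per trial
        "baseline": np.full(n_trials, -0.80),
        "pre_stimulus": np.full(n_trials, -window_s),
        "pre_response": t_target + rt - window_s,
    }
    win_lens = {"baseline": base_len, "pre_stimulus": pre_len,
                "pre_response": pre_len}
    sd32 = sd_ch[None, :, None].astype(np.float32)

    def gen_window(name):
        n = win_lens[name]
        X = rng.standard_normal((n_trials, n_ch, n), dtype=np.float32)
        X *= sd32
        if gain_bg is not None:
            modes = _pink_noise(rng, n_trials * n_modes, n, sfreq)
            X += np.einsum(
                "cm,tmn->tcn", gain_bg,
                modes.reshape(n_trials, n_modes, n), optimize=True)
        return X

    windows = {name: gen_window(name) for name in
               ("baseline", "pre_stimulus", "pre_response")}

    # planted oscillations, at absolute trial time within the carrier window
    w = coupling.window
    t_abs = (win_starts[w][:, None]
             + np.arange(win_lens[w])[None, :] / sfreq)  # trials x samples
    phase = 2 * np.pi * coupling.freq_hz * t_abs + seed_phase[:, None]
    osc = (np.sin(phase)[:, None, :] * g_seed[None, :, None]
           + np.sin(phase + lags[:, None])[:, None, :] * g_target[None, :, None])
    windows[w] += np.float32(osc_amp) * osc.astype(np.float32)
    if g_pe is not None and pe_amp > 0:
        wp = power_effect.window
        t_abs = (win_starts[wp][:, None]
                 + np.arange(win_lens[wp])[None, :] / sfreq)
        gp = (2 * np.pi * power_effect.freq_hz * t_abs
              + rng.uniform(-np.pi, np.pi, size=(n_trials, 1)))
        windows[wp] += np.float32(pe_amp) * (
            np.sin(gp)[:, None, :] * g_pe[None, :, None]).astype(np.float32)

    ids = np.arange(n_trials)
    # float32 storage: sensor dynamic range is tiny compared to the 7-digit
    # mantissa, and cohorts at the acquisition rate are memory-bound
    mk = lambda data, window, t0: EpochSet(
        data=data, channels=list(channels), sfreq=sfreq, window=window,
        t0=t0, trial_ids=ids.copy())
    pre_stim = windows["pre_stimulus"]
    pre_resp = windows["pre_response"]
    baselines = windows["baseline"]
    truth = SimTruth(
        kappa_conflict=float(coupling.kappa_conflict),
        coupling_strength=g_k,
        delta_rt_true=float(delta_rt),
        power_amplitude=float(pe_amp),
        lags=lags,
    )
    return (
        mk(pre_stim, "pre_stimulus", -window_s),
        mk(pre_resp, "pre_response", -window_s),
        mk(baselines, "baseline", -0.800),
        trials,
        truth,
    )


def inject_artifacts(epochs: EpochSet, counts: dict, seed: int = 0):
    """Plant peak-to-peak threshold exceedances in exactly `counts[kind]` epochs.

    A slow half-sine bump at twice the kind's rejection threshold is added to
    the first channel of that kind; injected trial sets are disjoint across
    kinds.  Returns ``(new EpochSet, {kind: trial indices})``.
    """
    total = sum(counts.values())
    if total > epochs.n_trials:
        raise ValueError("requested more artifact epochs than available trials")
    rng = np.random.default_rng(seed)
    order = rng.permutation(epochs.n_trials)
    data = epochs.data.copy()
    n_samp = data.shape[2]
    bump = np.sin(np.linspace(0, np.pi, n_samp))
    injected = {}
    pos = 0
    for kind, k in counts.items():
        chans = np.nonzero(epochs.kind_mask(kind))[0]
        if len(chans) == 0 and k > 0:
            raise ValueError(f"no channels of kind {kind}")
        ids = order[pos:pos + k]
        pos += k
        for tid in ids:
            data[tid, chans[0]] += 2.0 * REJECTION_PTP[kind] * bump
        injected[kind] = np.sort(ids)
    out = EpochSet(
        data=data, channels=epochs.channels, sfreq=epochs.sfreq,
        window=epochs.window, t0=epochs.t0, trial_ids=epochs.trial_ids.copy())
    return out, injected


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class CohortConfig:
    """Study conditions for a full synthetic cohort."""

    n_subjects: int = 8
    n_trials: int = 100
    n_per_hemi: int = 162
    n_mag: int = 61
    n_grad: int = 122
    n_eeg: int = 48
    sfreq: float = 1000.0
    snr: float = 9.0
    background_rms: float = 1.0
    coupling_freq_hz: float = 8.0
    mean_lag_rad: float = np.pi / 2
    kappa_base: float = 0.0
    # subject kappa_conflict ~ U(range); capped at ~2.5 because the wPLI of
    # a von Mises lag saturates above (g(2.5) ~ 0.76 already maps to
    # dwPLI ~ 0.9 at this SNR), and between-subject variation is the signal
    kappa_range: tuple = (0.0, 4.0)
    coupling_window: str = "pre_stimulus"
    seed_parcel: str = "cACC-rh"
    target_parcel: str = "latfrontal-rh"
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    coupling_on: bool = True
    power_effect_on: bool = False
    power_parcel: str = "IFC-lh"
    power_freq_hz: float = 70.0
    # gamma-amplitude scale relative to the phase-coupling oscillation: the
    # band mean over 32-110 Hz dilutes a single-bin tone ~40x, so the
    # planted gamma rides 2.5x higher to represent a robust band effect
    power_amp_scale: float = 3.5
    artifact_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["kappa_range"] = list(d["kappa_range"])
        return d


def simulate_cohort(config: CohortConfig, seed: int) -> tuple[Cohort, dict]:
    """Full deterministic cohort: geometry, forward, subjects, behavior.

    Per-subject generators are spawned from the master seed, so the cohort is
    a pure function of ``(config, seed)``.  Returns ``(cohort, truth)`` where
    truth maps subject id -> :class:`SimTruth`.
    """
    ss = np.random.SeedSequence(seed)
    geo_seed, fwd_seed, *subj_seeds = ss.spawn(2 + config.n_subjects)
    src = build_toy_source_space(
        config.n_per_hemi, seed=int(geo_seed.generate_state(1)[0] % 2**31))
    parcels = default_parcels(src)
    gain, channels = build_forward(
        src, config.n_mag, config.n_grad, config.n_eeg,
        seed=int(fwd_seed.generate_state(1)[0] % 2**31))

    subjects = {}
    truth = {}
    lo, hi = config.kappa_range
    width = (hi - lo) / config.n_subjects
    for si, sseq in enumerate(subj_seeds):
        sub_rng = np.random.default_rng(sseq)
        # stratified draw: subject i samples the i-th stratum of the kappa
        # range, so every cohort spans the full coupling-strength range
        # (small cohorts drawn fully at random can collapse onto a narrow
        # band and carry no between-subject signal at all)
        kappa = float(sub_rng.uniform(lo + si * width, lo + (si + 1) * width))
        coupling = CouplingSpec(
            seed_parcel=config.seed_parcel,
            target_parcel=config.target_parcel,
            freq_hz=config.coupling_freq_hz,
            mean_lag_rad=config.mean_lag_rad,
            kappa_base=config.kappa_base,
            kappa_conflict=kappa if config.coupling_on else config.kappa_base,
            window=config.coupling_window,
        )
        pe = None
        if config.power_effect_on:
            pe = PowerEffectSpec(
                parcel=config.power_parcel, freq_hz=config.power_freq_hz,
                amplitude=config.power_amp_scale * resultant_length(kappa),
                window=config.coupling_window)
        behavior = config.behavior
        if not config.coupling_on and not config.power_effect_on:
            # null cohort: zero behavior link
            behavior = BehaviorSpec(
                rt_congruent_mean_s=behavior.rt_congruent_mean_s,
                rt_sd_s=behavior.rt_sd_s, conflict_slope=0.0,
                conflict_intercept=behavior.conflict_intercept,
                conflict_noise_sd=behavior.conflict_noise_sd,
                hr_congruent=behavior.hr_congruent,
                hr_incongruent=behavior.hr_incongruent)
        # the behavior link always rides on the planted subject effect
        # strength g(kappa): phase concentration for coupling cohorts, the
        # relative oscillation amplitude for power cohorts, 0 for null ones
        effect = (resultant_length(kappa)
                  if (config.coupling_on or config.power_effect_on) else 0.0)
        pre_s, pre_r, base, trials, tr = simulate_subject(
            gain, channels, src, parcels, coupling, behavior,
            n_trials=config.n_trials, sfreq=config.sfreq,
            seed=int(sub_rng.integers(2**31)), snr=config.snr,
            background_rms=config.background_rms, power_effect=pe,
            effect_strength=effect)
        if config.artifact_counts:
            pre_s, _ = inject_artifacts(
                pre_s, config.artifact_counts, seed=int(sub_rng.integers(2**31)))
        sid = f"sub{si:02d}"
        subjects[sid] = SubjectData(
            epochs_pre_stimulus=pre_s, epochs_pre_response=pre_r,
            epochs_baseline=base, trials=trials)
        truth[sid] = tr
    cohort = Cohort(
        source_space=src, gain=gain, channels=channels, parcels=parcels,
        subjects=subjects, config=config.to_dict())
    return cohort, truth
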