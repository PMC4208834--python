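"""Preprocessing, artifact rejection, noise covariance, and the
depth-weighted minimum-norm inverse.

The inverse operator is computed exactly as W = R A^T (A R A^T + C)^-1 with a
diagonal, depth-weighted source covariance R and a baseline-estimated,
per-channel-kind regularized noise covariance C.  Noise normalization divides
each source estimate by sqrt(diag(W C W^T)), giving dSPM-style
signal-to-noise units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .data_model import EpochSet, InverseOperator, Parcel, SourceEpochs, SourceSpace


@dataclass
class RejectionThresholds:
    """Peak-to-peak epoch rejection thresholds per channel kind."""

    eog_v: float = 150e-6
    eeg_v: float = 100e-6
    grad_tpm: float = 2e-12
    mag_t: float = 4e-12

    def by_kind(self) -> dict:
        return {"eog": self.eog_v, "eeg": self.eeg_v,
                "grad": self.grad_tpm, "mag": self.mag_t}

    def validate(self) -> None:
        if min(self.eog_v, self.eeg_v, self.grad_tpm, self.mag_t) <= 0:
            raise ValueError("thresholds must be positive")


def _lowpass_taps(sfreq: float, cutoff: float, n_samples: int) -> np.ndarray:
    # anti-alias ahead of resampling: transition ~cutoff/3 wide is ample
    numtaps = min(101, 2 * (n_samples // 7) + 1)
    numtaps = max(numtaps, 11)
    return signal.firwin(numtaps, cutoff, fs=sfreq)


def filter_resample(
    x: np.ndarray,
    sfreq: float,
    target_sfreq: float = 333.0,
    passband: tuple = (0.5, 110.0),
) -> np.ndarray:
    """Zero-phase band-limit then resample the last axis.

    The low-pass edge is a zero-phase FIR (filtfilt).  The high-pass edge
    uses a zero-phase FIR when the series is long enough to hold the
    required taps (transition width = passband[0], i.e. stopband reaches
    passband[0]/2); on short epochs it falls back to removing the mean and
    linear trend, which suppresses sub-hertz drift at epoch length.
    Output length is round(n * target_sfreq / sfreq).
    """
    lo, hi = passband
    if hi >= sfreq / 2:
        raise ValueError(f"upper passband edge {hi} infeasible at sfreq {sfreq}")
    n = x.shape[-1]
    taps = _lowpass_taps(sfreq, hi, n)
    # forward+backward FIR == one convolution with the symmetric kernel
    # taps*taps[::-1]; applied via overlap-add FFT with reflected edges
    kernel = np.convolve(taps, taps[::-1]).astype(x.dtype, copy=False)
    half = len(taps) - 1
    pad = min(half, n - 1)
    xp = np.concatenate(
        [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]], axis=-1)
    y = signal.fftconvolve(xp, kernel.reshape((1,) * (x.ndim - 1) + (-1,)),
                           mode="same", axes=-1)[..., pad:pad + n]
    hp_taps = int(3.3 / (lo / sfreq))
    hp_taps += (hp_taps + 1) % 2
    if n > 3 * hp_taps:
        h = signal.firwin(hp_taps, lo, fs=sfreq, pass_zero=False, width=lo)
        y = signal.filtfilt(h, [1.0], y, axis=-1, padlen=min(3 * hp_taps, n - 1))
    else:
        # mean + linear trend removal (closed form; epoch-length drift path)
        t = np.arange(n, dtype=y.dtype)
        t -= t.mean()
        y = y - y.mean(axis=-1, keepdims=True)
        slope = (y @ t) / (t @ t)
        y -= slope[..., None] * t
    n_out = int(round(n * target_sfreq / sfreq))
    # FFT resampling; the series is already band-limited below target Nyquist
    return signal.resample(y, n_out, axis=-1)


def preprocess(
    epochs: EpochSet,
    target_sfreq: float = 333.0,
    passband: tuple = (0.5, 110.0),
) -> EpochSet:
    """Band-limit and downsample an epoch set (zero-phase)."""
    data = filter_resample(epochs.data, epochs.sfreq, target_sfreq, passband)
    return EpochSet(
        data=data, channels=epochs.channels, sfreq=target_sfreq,
        window=epochs.window, t0=epochs.t0, trial_ids=epochs.trial_ids.copy())


def reject_artifacts(
    epochs: EpochSet, thresholds: Optional[RejectionThresholds] = None
):
    """Drop epochs whose peak-to-peak exceeds any channel kind's threshold.

    Returns ``(accepted EpochSet, rejected trial ids)``; trial order is
    preserved and the operation is idempotent.
    """
    thresholds = thresholds or RejectionThresholds()
    thresholds.validate()
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    bad = np.zeros(epochs.n_trials, dtype=bool)
    for kind, thr in thresholds.by_kind().items():
        mask = epochs.kind_mask(kind)
        if mask.any():
            bad |= (ptp[:, mask] > thr).any(axis=1)
    keep = ~bad
    accepted = EpochSet(
        data=epochs.data[keep], channels=epochs.channels, sfreq=epochs.sfreq,
        window=epochs.window, t0=epochs.t0, trial_ids=epochs.trial_ids[keep])
    return accepted, epochs.trial_ids[bad]


def estimate_noise_covariance(
    baseline: EpochSet, lam: float = 0.1
) -> np.ndarray:
    """Empirical sensor covariance over concatenated baseline samples.

    Regularized by per-channel-kind diagonal loading: for each kind, lam
    times the mean diagonal of that kind is added to its diagonal entries.
    The per-kind loading keeps the joint MEG+EEG problem well-conditioned
    despite the T / T/m / V scale disparity.
    """
    if baseline.n_trials < 2:
        raise ValueError("need at least 2 baseline epochs")
    X = np.concatenate(list(baseline.data), axis=1)  # channels x samples
    n_ch, n_samp = X.shape
    if n_samp < n_ch and lam <= 0:
        raise ValueError(
            f"{n_samp} samples < {n_ch} channels: covariance is rank deficient; "
            "set lam > 0 to regularize")
    X = X - X.mean(axis=1, keepdims=True)
    C = X @ X.T / (n_samp - 1)
    C = 0.5 * (C + C.T)
    if lam > 0:
        for kind in ("mag", "grad", "eeg", "eog"):
            mask = baseline.kind_mask(kind)
            if mask.any():
                load = lam * float(np.mean(np.diag(C)[mask]))
                C[mask, mask] += load
    return C


def _whitener(C: np.ndarray) -> np.ndarray:
    """Symmetric-per-scaling C^{-1/2} (C must be positive definite).

    The diagonal spans many orders of magnitude across channel kinds, so C
    is first rescaled to unit diagonal; eigh on the raw matrix would lose
    the small-unit blocks to float error.
    """
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        raise ValueError("noise covariance has non-positive diagonal")
    Cs = C / d[:, None] / d[None, :]
    vals, vecs = np.linalg.eigh(0.5 * (Cs + Cs.T))
    if vals.min() <= 0:
        raise ValueError("noise covariance is not positive definite")
    return ((vecs / np.sqrt(vals)) @ vecs.T) / d[None, :]


def compute_source_covariance(
    A: np.ndarray,
    depth_exponent: float = 0.8,
    C: Optional[np.ndarray] = None,
    snr2: float = 9.0,
) -> np.ndarray:
    """Diagonal depth-weighted source covariance R_ii ~ (a_i' a_i)^-gamma.

    When C is given, both the depth weights and the overall scale are
    evaluated in the noise-whitened metric (columns of C^{-1/2} A): with
    heterogeneous channel units (T, T/m, V) raw column norms are dominated
    by whichever kind has the largest numerical scale, so the depth prior
    and the regularization balance are only meaningful after whitening.
    The scale then satisfies trace(A_w R A_w^T) / trace(C_w) = snr2, the
    conventional lambda^2 = 1/snr2 balance (C_w = I, trace n_channels).
    Without C the raw column norms are used and no scaling is applied.
    """
    Aw = A if C is None else _whitener(C) @ A
    norms2 = np.einsum("ij,ij->j", Aw, Aw)
    if np.any(norms2 == 0):
        bad = int(np.nonzero(norms2 == 0)[0][0])
        raise ValueError(f"gain column {bad} is zero")
    R = norms2 ** (-depth_exponent)
    if C is not None:
        scale = snr2 * A.shape[0] / np.sum(norms2 * R)
        R = R * scale
    return R


def compute_inverse_operator(
    A: np.ndarray, C: np.ndarray, R: np.ndarray
) -> InverseOperator:
    """W = R A^T (A R A^T + C)^-1, with dSPM norm factors sqrt(diag(W C W^T)).

    Evaluated in whitened coordinates, W = R A_w^T (A_w R A_w^T + I)^-1 Wh
    with Wh = C^{-1/2} and A_w = Wh A — algebraically identical to the
    plain formula but numerically stable across channel kinds whose units
    differ by many orders of magnitude.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim == 2:
        R = np.diag(R)
    Wh = _whitener(C)
    Aw = Wh @ A
    M = (Aw * R[None, :]) @ Aw.T + np.eye(A.shape[0])
    W = (R[:, None] * Aw.T) @ np.linalg.solve(M, Wh)
    # dSPM normalization: in whitened coords W C W^T = (W Wh^-1)(W Wh^-1)^T
    Ww = (R[:, None] * Aw.T) @ np.linalg.inv(M)
    norm = np.sqrt(np.einsum("ij,ij->i", Ww, Ww))
    norm = np.maximum(norm, np.finfo(float).tiny)
    return InverseOperator(W=W, A=A, C=C, R=R, norm_factors=norm)


def apply_inverse(
    inv: InverseOperator,
    epochs: EpochSet,
    noise_normalize: bool = True,
) -> SourceEpochs:
    """Project sensor epochs to source space (optionally dSPM-normalized)."""
    if epochs.data.shape[1] != inv.W.shape[1]:
        raise ValueError(
            f"channel count {epochs.data.shape[1]} does not match inverse "
            f"operator ({inv.W.shape[1]})")
    out = np.einsum("sc,tcn->tsn", inv.W, epochs.data)
    if noise_normalize:
        out = out / inv.norm_factors[None, :, None]
    return SourceEpochs(
        data=out, sfreq=epochs.sfreq, window=epochs.window,
        trial_ids=epochs.trial_ids.copy())


def parcel_sign_flips(parcel: Parcel, src: SourceSpace) -> np.ndarray:
    """Surface-normal sign alignment for a parcel.

    The reference direction d is the first principal direction of the
    parcel's normals; its own sign is fixed so that the majority of
    s_i = sign(n_i . d) is +1.  Near-orthogonal normals (|n_i . d| < 1e-6)
    get s_i = +1.
    """
    N = src.vertex_normals[parcel.vertex_ids]
    _, _, vt = np.linalg.svd(N - 0 * N.mean(axis=0), full_matrices=False)
    d = vt[0]
    proj = N @ d
    s = np.sign(proj)
    s[np.abs(proj) < 1e-6] = 1.0
    if np.sum(s > 0) < np.sum(s < 0):
        s = -s
    elif np.sum(s > 0) == np.sum(s < 0) and s[0] < 0:
        s = -s  # deterministic tie-break
    return s


def extract_seed_timecourse(
    stc: SourceEpochs, parcel: Parcel, src: SourceSpace
) -> np.ndarray:
    """Sign-aligned mean source series over a parcel: (trials, samples).

    Waveform signs are aligned using the surface-normal principal direction
    before averaging, so anti-parallel walls of a sulcus do not cancel.
    """
    if len(parcel.vertex_ids) == 0:
        raise ValueError("empty parcel")
    s = parcel_sign_flips(parcel, src)
    series = stc.data[:, parcel.vertex_ids, :]  # trials x p x samples
    return np.einsum("p,tpn->tn", s, series) / len(s)
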