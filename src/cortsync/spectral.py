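"""Tapered spectral estimation, debiased wPLI maps, and band power maps.

Connectivity uses a Hanning-tapered DFT on the 500-ms analysis window at a
2-Hz grid (6-20 Hz).  The debiased weighted phase lag index over trials k,
with Z_k = Im(S_k V_k*) the imaginary cross-spectrum, is

    dwPLI = ((sum Z)^2 - sum Z^2) / ((sum |Z|)^2 - sum Z^2),

an estimator of squared wPLI that removes the positive sample-size bias and
is insensitive to zero-lag (volume-conduction) coupling.  Power uses a
3-cycle adaptive Hanning window at 4-30 Hz and three Slepian tapers on the
full window at 30-110 Hz, averaged into one-octave bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import windows

from .data_model import ConnectivityMap, PowerMap, SourceEpochs, TrialTable

BANDS = {
    "theta": (4.0, 7.5),
    "alpha": (7.5, 15.0),
    "beta": (15.0, 30.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (60.0, 110.0),
}


@dataclass
class SpectralConfig:
    conn_freqs: np.ndarray = field(
        default_factory=lambda: np.arange(6.0, 20.0 + 1e-9, 2.0))
    conn_window_s: float = 0.5
    low_freqs: np.ndarray = field(
        default_factory=lambda: np.arange(4.0, 30.0 + 1e-9, 2.0))
    high_freqs: np.ndarray = field(
        default_factory=lambda: np.arange(32.0, 110.0 + 1e-9, 2.0))
    n_slepian: int = 3
    slepian_nw: float = 2.0
    bands: dict = field(default_factory=lambda: dict(BANDS))
    min_trials: int = 10


def taper_fft(
    series: np.ndarray,
    sfreq: float,
    freqs: np.ndarray,
    window_s: float = 0.5,
    taper: str = "hanning",
) -> np.ndarray:
    """Hanning-windowed DFT coefficients at the nearest bins to `freqs`.

    `series` is (..., samples); a centered subwindow of ``window_s`` seconds
    is used.  Returns complex (..., len(freqs)).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs > sfreq / 2):
        raise ValueError("requested frequency beyond Nyquist")
    n = series.shape[-1]
    n_win = int(round(window_s * sfreq))
    if n < n_win:
        raise ValueError(f"series length {n} < window {n_win} samples")
    start = (n - n_win) // 2
    seg = series[..., start:start + n_win]
    if taper == "hanning":
        w = windows.hann(n_win, sym=False)
    elif taper == "boxcar":
        w = np.ones(n_win)
    else:
        raise ValueError(f"unknown taper {taper}")
    spec = np.fft.rfft(seg * w, axis=-1)
    bin_freqs = np.fft.rfftfreq(n_win, 1 / sfreq)
    idx = np.array([int(np.argmin(np.abs(bin_freqs - f))) for f in freqs])
    return spec[..., idx]


def debiased_wpli(seed_coeffs: np.ndarray, vertex_coeffs: np.ndarray) -> np.ndarray:
    """Debiased wPLI over the first (trial) axis.

    ``seed_coeffs``: (trials, ...) complex; ``vertex_coeffs`` broadcastable to
    it.  Degenerate denominators (all zero imaginary cross-spectra, the
    zero-lag case) map to 0.
    """
    if seed_coeffs.shape[0] < 2:
        raise ValueError("debiased wPLI is undefined for a single trial")
    Z = np.imag(seed_coeffs * np.conj(vertex_coeffs))
    sZ = Z.sum(axis=0)
    sZ2 = (Z**2).sum(axis=0)
    sAbs = np.abs(Z).sum(axis=0)
    num = sZ**2 - sZ2
    den = sAbs**2 - sZ2
    # degenerate (all Z ~ 0, the zero-lag case) -> 0; the threshold is
    # relative to the coefficient magnitudes because exact zero-lag inputs
    # leave float residue ~eps in the imaginary cross-spectrum
    scale = (np.abs(seed_coeffs) * np.abs(vertex_coeffs)).sum(axis=0) ** 2
    good = den > 1e-24 * scale
    return np.where(good, num / np.where(good, den, 1.0), 0.0)


def trial_filter(
    trials: TrialTable,
    condition: Optional[str] = None,
    hand: Optional[str] = None,
    correct_only: bool = True,
) -> np.ndarray:
    """Boolean trial mask for one condition cell."""
    mask = np.ones(len(trials), dtype=bool)
    if condition is not None:
        mask &= trials.condition == condition
    if hand is not None:
        mask &= trials.hand == hand
    if correct_only:
        mask &= trials.correct
    return mask


def seed_wpli_map(
    seed_series: np.ndarray,
    stc: SourceEpochs,
    seed_name: str,
    config: SpectralConfig,
    trial_mask: Optional[np.ndarray] = None,
    condition_cell: str = "pooled",
) -> ConnectivityMap:
    """Debiased wPLI between a seed series and every vertex, per frequency.

    ``seed_series`` is (trials, samples) aligned with ``stc.data``.  The
    trial mask selects the condition cell; fewer than ``config.min_trials``
    surviving trials is an error naming the cell.
    """
    if trial_mask is None:
        trial_mask = np.ones(stc.n_trials, dtype=bool)
    n_kept = int(trial_mask.sum())
    if n_kept < config.min_trials:
        raise ValueError(
            f"cell {condition_cell!r} has {n_kept} trials "
            f"(< {config.min_trials})")
    sc = taper_fft(seed_series[trial_mask], stc.sfreq, config.conn_freqs,
                   config.conn_window_s)  # trials x freqs
    vc = taper_fft(stc.data[trial_mask], stc.sfreq, config.conn_freqs,
                   config.conn_window_s)  # trials x vertices x freqs
    values = debiased_wpli(sc[:, None, :], vc)  # vertices x freqs
    return ConnectivityMap(
        values=values, seed=seed_name, freqs=np.asarray(config.conn_freqs),
        window=stc.window, condition_cell=condition_cell, n_trials=n_kept)


def _power_at(series: np.ndarray, sfreq: float, f: float, window_s: float,
              full_len_s: float) -> np.ndarray:
    """Trial-mean Hanning power at one frequency on a centered subwindow.

    Normalized by the taper energy so that estimates from different window
    lengths (the 3-cycle adaptive scheme) are on one per-bin variance scale:
    white noise of variance s^2 gives s^2 at every frequency.
    """
    sub = min(window_s, full_len_s)
    n_win = int(round(sub * sfreq))
    w2 = float(np.sum(windows.hann(n_win, sym=False) ** 2))
    coef = taper_fft(series, sfreq, np.array([f]), window_s=sub)
    return np.mean(np.abs(coef[..., 0]) ** 2, axis=0) / w2


def spectral_power(
    stc: SourceEpochs,
    config: Optional[SpectralConfig] = None,
    trial_mask: Optional[np.ndarray] = None,
    condition_cell: str = "pooled",
) -> PowerMap:
    """Band-averaged source power map.

    4-30 Hz: Hanning taper on a centered 3-cycle subwindow (clamped at the
    analysis window length).  30-110 Hz: mean over three Slepian tapers
    (NW=2) on the full window.  Band values average the in-band grid
    frequencies; band edges are lower-inclusive/upper-exclusive, top band
    upper-inclusive.
    """
    config = config or SpectralConfig()
    data = stc.data if trial_mask is None else stc.data[trial_mask]
    n = data.shape[-1]
    full_len_s = n / stc.sfreq
    freq_power = {}
    for f in config.low_freqs:
        freq_power[float(f)] = _power_at(data, stc.sfreq, f, 3.0 / f, full_len_s)
    if len(config.high_freqs):
        n_win = n
        tapers = windows.dpss(n_win, config.slepian_nw, Kmax=config.n_slepian)
        bin_freqs = np.fft.rfftfreq(n_win, 1 / stc.sfreq)
        idx = [int(np.argmin(np.abs(bin_freqs - f))) for f in config.high_freqs]
        acc = 0.0
        for tap in tapers:
            spec = np.fft.rfft(data * tap, axis=-1)[..., idx]
            acc = acc + np.abs(spec) ** 2 / float(np.sum(tap**2))
        p = np.mean(acc / config.n_slepian, axis=0)  # vertices x n_high
        for j, f in enumerate(config.high_freqs):
            freq_power[float(f)] = p[..., j]
    grid = np.array(sorted(freq_power))
    names = list(config.bands)
    top = names[-1]
    band_vals = []
    for name in names:
        lo, hi = config.bands[name]
        in_band = (grid >= lo) & ((grid <= hi) if name == top else (grid < hi))
        if not in_band.any():
            raise ValueError(f"band {name} has no grid frequencies")
        band_vals.append(np.mean([freq_power[float(f)] for f in grid[in_band]], axis=0))
    values = np.stack(band_vals, axis=-1)  # vertices x bands
    return PowerMap(values=values, bands=names, window=stc.window,
                    condition_cell=condition_cell)
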