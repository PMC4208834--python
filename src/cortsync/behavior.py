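"""Behavioral statistics: RT/HR summaries, Gaussianizing transforms,
Jarque-Bera normality check, paired t-tests, and the normalized conflict
effect dRT = ln(RT_incongruent / RT_congruent) used as the brain-behavior
covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import TrialTable


@dataclass
class SubjectBehavior:
    rt_mean: dict  # condition -> mean RT over correct trials, s
    hr: dict  # condition -> hit rate
    delta_rt: float  # ln(RT_incong / RT_cong)
    n_trials: dict  # condition -> total trial count

    def validate(self) -> None:
        if not np.isfinite(self.delta_rt):
            raise ValueError("delta_rt not finite")
        for c, v in self.hr.items():
            if not (0 <= v <= 1):
                raise ValueError(f"hit rate outside [0,1] for {c}")


def summarize_behavior(trials: TrialTable, correct_only: bool = True) -> SubjectBehavior:
    """Condition-wise RT means (correct trials), hit rates, and log-ratio dRT."""
    rt_mean, hr, n = {}, {}, {}
    for cond in ("congruent", "incongruent"):
        sel = trials.condition == cond
        if not sel.any():
            raise ValueError(f"no {cond} trials")
        use = sel & trials.correct if correct_only else sel
        if not use.any():
            raise ValueError(f"no usable (correct) {cond} trials")
        rt_mean[cond] = float(np.mean(trials.rt[use]))
        hr[cond] = float(np.mean(trials.correct[sel]))
        n[cond] = int(sel.sum())
    delta = float(np.log(rt_mean["incongruent"]) - np.log(rt_mean["congruent"]))
    sb = SubjectBehavior(rt_mean=rt_mean, hr=hr, delta_rt=delta, n_trials=n)
    sb.validate()
    return sb


def transform_for_tests(values, kind: str) -> np.ndarray:
    """Gaussianizing transforms: RT -> ln(RT); HR -> HR**3."""
    v = np.asarray(values, dtype=float)
    if kind == "rt":
        if np.any(v <= 0):
            raise ValueError("RT values must be positive for the log transform")
        return np.log(v)
    if kind == "hr":
        return v**3
    raise ValueError(f"unknown transform kind {kind!r}")


def jarque_bera(values) -> tuple[float, float]:
    """Jarque-Bera normality statistic JB = n/6 (S^2 + K^2/4), p from chi2(2)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 8:
        raise ValueError("need at least 8 observations")
    m = v.mean()
    d = v - m
    s2 = np.mean(d**2)
    S = np.mean(d**3) / s2**1.5
    K = np.mean(d**4) / s2**2 - 3.0
    jb = n / 6.0 * (S**2 + K**2 / 4.0)
    p = float(stats.chi2.sf(jb, df=2))
    return float(jb), p


def paired_ttest(values_a, values_b) -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, p).  Zero-variance differences error."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two paired 1-d samples of equal length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t is undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), df, p
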