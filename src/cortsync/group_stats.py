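"""Vertex-wise brain-behavior GLM and cluster-based max-statistic
permutation correction.

Two designs mirror the two analysis windows:

* pre-stimulus correlation — per-subject maps from incongruent-trial
  baselines regressed on the conflict effect dRT; the null permutes the
  covariate across subjects;
* pre-response 2x2 factorial — per subject the hand-mean
  (incongruent - congruent) difference map; the covariate slope tests the
  brain-behavior link (null: covariate permutation) and the intercept tests
  the behavior-adjusted conflict main effect (null: subject sign flips).

Suprathreshold (vertex p < 0.05) sign-consistent connected components are
formed per hemisphere; cluster mass is the summed vertex area (mm^2); the
family-wise null records the maximum cluster mass per permutation per
hemisphere; cluster-wise p uses the (1 + exceedances)/(1 + n_perm)
correction and is Bonferroni-tested at 0.05/2 hemispheres = 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .data_model import ClusterResult, Parcel, SourceSpace


@dataclass
class DesignSpec:
    design: str = "pre_stimulus_correlation"  # or pre_response_factorial
    vertex_alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_hemispheres: int = 2
    n_permutations: int = 10000

    @property
    def per_hemi_alpha(self) -> float:
        return self.cluster_alpha / self.n_hemispheres

    def validate(self) -> None:
        if not (0 < self.vertex_alpha < 1 and 0 < self.cluster_alpha < 1):
            raise ValueError("alphas must be in (0,1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


def relative_log_power(maps: np.ndarray) -> np.ndarray:
    """Per-subject relative log power for between-subject designs.

    Band power carries a multiplicative subject-level scale (noise level,
    normalization) that is common to all vertices; on the log scale it is an
    additive offset, removed by demeaning each subject's map across
    vertices.  Without this, covariate permutations that happen to align
    with the scale ordering produce hemisphere-wide null clusters and the
    max-cluster null swamps any focal effect.  The offset is the per-subject
    log-median, not the mean: a focal effect covering ~10-20% of the map
    would drag the mean and imprint an anti-correlated complement on every
    other vertex.
    """
    lp = np.log(np.maximum(maps, np.finfo(float).tiny))
    return lp - np.median(lp, axis=1, keepdims=True)


def vertexwise_glm(maps: np.ndarray, covariate: np.ndarray):
    """Simple linear model value ~ 1 + covariate at every vertex.

    ``maps``: (n_subjects, n_vertices).  Returns (t_slope, p, excluded)
    where excluded flags vertices with constant values across subjects.
    Closed-form OLS, df = n - 2.
    """
    y = np.asarray(maps, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    t, _, excluded = _glm_t(y, x, which="slope")
    df = n - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    p[excluded] = 1.0
    return t, p, excluded


def _glm_t(y: np.ndarray, x: np.ndarray, which: str = "slope"):
    """Vectorized t-statistics for y ~ 1 + x at every column of y."""
    n = len(x)
    df = n - 2
    xm = x - x.mean()
    sxx = np.dot(xm, xm)
    ym = y - y.mean(axis=0)
    sxy = xm @ y
    beta = sxy / sxx
    sse = np.einsum("ij,ij->j", ym, ym) - beta**2 * sxx
    sse = np.maximum(sse, 0.0)
    excluded = np.einsum("ij,ij->j", ym, ym) == 0
    mse = sse / df
    with np.errstate(divide="ignore", invalid="ignore"):
        if which == "slope":
            se = np.sqrt(mse / sxx)
            t = beta / se
        elif which == "intercept":
            b0 = y.mean(axis=0) - beta * x.mean()
            se = np.sqrt(mse * (1.0 / n + x.mean() ** 2 / sxx))
            t = b0 / se
        else:
            raise ValueError(which)
    t = np.where(np.isfinite(t), t, 0.0)
    return t, df, excluded


def pre_response_contrast(
    cell_maps: dict,
    covariate: np.ndarray,
):
    """Behavior-covaried conflict contrast of the 2x2 (hand x congruence) design.

    ``cell_maps[(condition, hand)]`` is (n_subjects, n_vertices).  Per subject
    the difference map averaged over hands,
    dmap = mean_h (incongruent,h - congruent,h), is regressed on dRT:
    the slope t tests the brain-behavior link, the intercept t the conflict
    effect with behavioral variability regressed out.  Returns
    (t_behavior, t_main, dmaps).
    """
    cells = [("incongruent", "left"), ("incongruent", "right"),
             ("congruent", "left"), ("congruent", "right")]
    for cell in cells:
        if cell not in cell_maps:
            raise ValueError(f"missing cell {cell}")
    dmap = 0.5 * (
        (cell_maps[("incongruent", "left")] - cell_maps[("congruent", "left")])
        + (cell_maps[("incongruent", "right")] - cell_maps[("congruent", "right")])
    )
    t_beh, _, _ = _glm_t(dmap, np.asarray(covariate, dtype=float), which="slope")
    t_main, _, _ = _glm_t(dmap, np.asarray(covariate, dtype=float), which="intercept")
    return t_beh, t_main, dmap


def _components_mass(
    mask: np.ndarray, adj: sparse.csr_matrix, areas: np.ndarray
):
    """Connected components of the masked subgraph with their area mass."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    sub = adj[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for c in range(n_comp):
        members = idx[labels == c]
        out.append((members, float(areas[members].sum())))
    return out


def _suprathreshold_clusters(t, p, alpha, adj, areas):
    """Sign-split suprathreshold components: list of (members, mass, sign)."""
    res = []
    for sgn in (1.0, -1.0):
        mask = (p < alpha) & (np.sign(t) == sgn)
        for members, mass in _components_mass(mask, adj, areas):
            res.append((members, mass, sgn))
    return res


@dataclass
class PermutationDesign:
    """Inputs the permutation null needs to re-run the GLM."""

    subject_maps: np.ndarray  # n_subjects x n_vertices
    covariate: np.ndarray
    stat: str = "slope"  # slope -> permute covariate; intercept -> sign flip
    spec: DesignSpec = field(default_factory=DesignSpec)


def cluster_permutation(
    design: PermutationDesign,
    src: SourceSpace,
    seed: int = 0,
    freq: float = np.nan,
) -> list[ClusterResult]:
    """Max-cluster-mass Monte Carlo correction, per hemisphere.

    Builds the observed sign-consistent suprathreshold clusters and an
    empirical null of the maximum cluster mass per hemisphere, using
    covariate permutation (correlation designs) or subject-level sign
    flipping (the behavior-adjusted main contrast).
    """
    spec = design.spec
    spec.validate()
    y = design.subject_maps
    x = np.asarray(design.covariate, dtype=float)
    n_subj, n_vert = y.shape
    if n_vert != src.n_vertices:
        raise ValueError("map length does not match source space adjacency")
    adj = src.adjacency_sparse()
    areas = src.vertex_area
    rng = np.random.default_rng(seed)

    def stat_maps(yy, xx):
        t, df, excl = _glm_t(yy, xx, which=design.stat)
        p = 2 * stats.t.sf(np.abs(t), df)
        p[excl] = 1.0
        return t, p

    t_obs, p_obs = stat_maps(y, x)

    hemi_idx = {h: src.hemi_vertices(h) for h in ("lh", "rh")}
    hemi_adj = {h: adj[np.ix_(idx, idx)].tocsr() for h, idx in hemi_idx.items()}
    null_max = {h: np.zeros(spec.n_permutations) for h in ("lh", "rh")}
    for it in range(spec.n_permutations):
        if design.stat == "intercept":
            flips = rng.choice([-1.0, 1.0], size=n_subj)
            t_p, p_p = stat_maps(flips[:, None] * y, x)
        else:
            t_p, p_p = stat_maps(y, rng.permutation(x))
        for h, idx in hemi_idx.items():
            clusters = _suprathreshold_clusters(
                t_p[idx], p_p[idx], spec.vertex_alpha, hemi_adj[h], areas[idx])
            null_max[h][it] = max((m for _, m, _ in clusters), default=0.0)

    results = []
    for h, idx in hemi_idx.items():
        clusters = _suprathreshold_clusters(
            t_obs[idx], p_obs[idx], spec.vertex_alpha, hemi_adj[h], areas[idx])
        for members_local, mass, sgn in clusters:
            members = idx[members_local]
            peak_local = members[np.argmax(np.abs(t_obs[members]))]
            p_peak = max(p_obs[peak_local], 1e-300)
            cp = (1.0 + np.sum(null_max[h] >= mass)) / (1.0 + spec.n_permutations)
            results.append(
                ClusterResult(
                    vertex_ids=members, hemisphere=h, size_mm2=mass,
                    max_value=float(-np.log10(p_peak) * sgn),
                    peak_vertex=int(peak_local), cluster_p=float(cp), freq=freq))
    results.sort(key=lambda c: c.cluster_p)
    return results


def significant(clusters: Sequence[ClusterResult], spec: DesignSpec) -> list:
    return [c for c in clusters if c.cluster_p < spec.per_hemi_alpha]


def cluster_table(
    clusters: Sequence[ClusterResult],
    seed_name: str,
    window: str,
    src: Optional[SourceSpace] = None,
    parcels: Optional[Sequence[Parcel]] = None,
) -> pd.DataFrame:
    """Cluster summary table (toy-space peak coordinates, mm).

    Columns mirror the conventional cluster report: target hemisphere, seed,
    frequency, peak -log10(p) x sign(t), size in mm^2, peak coordinate,
    cluster-wise P, and covered parcel names.
    """
    rows = []
    for c in clusters:
        coord = (np.full(3, np.nan) if src is None
                 else src.vertex_positions[c.peak_vertex] * 1000.0)
        coverage = ""
        if parcels is not None:
            hit = [p.name for p in parcels
                   if np.intersect1d(p.vertex_ids, c.vertex_ids).size > 0]
            coverage = ",".join(sorted(hit))
        rows.append(
            {
                "target_hemisphere": c.hemisphere,
                "seed": seed_name,
                "window": window,
                "f_hz": c.freq,
                "max_value": round(c.max_value, 4),
                "size_mm2": round(c.size_mm2, 1),
                "peak_x_mm": round(float(coord[0]), 1),
                "peak_y_mm": round(float(coord[1]), 1),
                "peak_z_mm": round(float(coord[2]), 1),
                "cluster_p": round(c.cluster_p, 6),
                "coverage": coverage,
            }
        )
    cols = ["target_hemisphere", "seed", "window", "f_hz", "max_value",
            "size_mm2", "peak_x_mm", "peak_y_mm", "peak_z_mm", "cluster_p",
            "coverage"]
    return pd.DataFrame(rows, columns=cols)
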