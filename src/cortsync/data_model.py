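"""Shared domain types for the synthetic MEG/EEG connectivity pipeline.

Every type carries an explicit :func:`validate` so that invariant breaches are
caught at the boundaries between pipeline stages rather than deep inside the
numerics.  Coordinates are metres internally; vertex areas are stored in mm**2
because cluster extents are conventionally reported in mm**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CHANNEL_KINDS = ("mag", "grad", "eeg", "eog")
KIND_UNITS = {"mag": "T", "grad": "T/m", "eeg": "V", "eog": "V"}
BAND_NAMES = ("theta", "alpha", "beta", "low_gamma", "high_gamma")
WINDOWS = ("pre_stimulus", "pre_response", "baseline")

# Inter-trial onset gaps of the flanker paradigm, seconds.
ONSET_GAP_RANGE = (2.95, 3.05)


class ValidationError(ValueError):
    """Invariant breach; names the offending type and field."""

    def __init__(self, type_name: str, fieldname: str, message: str):
        self.type_name = type_name
        self.fieldname = fieldname
        super().__init__(f"{type_name}.{fieldname}: {message}")


@dataclass
class SourceSpace:
    """Toy two-hemisphere cortical geometry.

    Attributes
    ----------
    vertex_positions : (n, 3) float array, metres.
    vertex_normals : (n, 3) float array, outward unit normals.
    vertex_area : (n,) float array, mm**2 (one third of incident triangle area).
    hemisphere : (n,) array of "lh"/"rh".
    triangles : (m, 3) int array indexing vertices.
    """

    vertex_positions: np.ndarray
    vertex_normals: np.ndarray
    vertex_area: np.ndarray
    hemisphere: np.ndarray
    triangles: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Undirected unique edge list (e, 2) derived from triangles."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def hemi_vertices(self, hemi: str) -> np.ndarray:
        return np.nonzero(self.hemisphere == hemi)[0]

    def adjacency_sparse(self):
        """Symmetric sparse adjacency over vertices (scipy CSR)."""
        from scipy import sparse

        e = self.edges
        n = self.n_vertices
        data = np.ones(2 * len(e), dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def validate(self) -> None:
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValidationError(
                "SourceSpace", "vertex_normals",
                f"normal at vertex {bad} has length {norms[bad]:.6f}, expected 1")
        if np.any(self.vertex_area <= 0):
            raise ValidationError("SourceSpace", "vertex_area", "non-positive vertex area")
        if not np.all(np.isin(self.hemisphere, ("lh", "rh"))):
            raise ValidationError("SourceSpace", "hemisphere", "labels must be lh/rh")
        e = self.edges
        if np.any(self.hemisphere[e[:, 0]] != self.hemisphere[e[:, 1]]):
            raise ValidationError("SourceSpace", "adjacency", "cross-hemisphere edge")
        if self.triangles.max(initial=-1) >= self.n_vertices:
            raise ValidationError("SourceSpace", "triangles", "vertex index out of range")


@dataclass
class Parcel:
    """Named set of vertices within one hemisphere (seed, target or background)."""

    name: str
    vertex_ids: np.ndarray
    role: str = "background"  # seed | target | background

    def validate(self, src: Optional[SourceSpace] = None) -> None:
        if len(self.vertex_ids) == 0:
            raise ValidationError("Parcel", "vertex_ids", f"parcel {self.name} is empty")
        if self.role not in ("seed", "target", "background"):
            raise ValidationError("Parcel", "role", f"unknown role {self.role}")
        if src is not None:
            hemis = np.unique(src.hemisphere[self.vertex_ids])
            if len(hemis) != 1:
                raise ValidationError(
                    "Parcel", "vertex_ids", f"parcel {self.name} spans hemispheres")


@dataclass
class ChannelInfo:
    name: str
    kind: str  # mag | grad | eeg | eog
    unit: str  # T | T/m | V
    position: np.ndarray  # (3,), metres

    def validate(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValidationError("ChannelInfo", "kind", f"unknown kind {self.kind}")
        if self.unit != KIND_UNITS[self.kind]:
            raise ValidationError(
                "ChannelInfo", "unit",
                f"{self.name}: kind {self.kind} requires unit {KIND_UNITS[self.kind]}")


@dataclass
class TrialTable:
    """Per-trial behavior: condition, responding hand, RT, correctness, onset."""

    condition: np.ndarray  # "congruent" | "incongruent"
    hand: np.ndarray  # "left" | "right"
    rt: np.ndarray  # seconds, from target onset
    correct: np.ndarray  # bool
    onset: np.ndarray  # seconds, strictly increasing

    def __len__(self) -> int:
        return len(self.rt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": np.arange(len(self)),
                "condition": self.condition,
                "hand": self.hand,
                "rt_s": self.rt,
                "correct": self.correct.astype(int),
                "onset_s": self.onset,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        return cls(
            condition=df["condition"].to_numpy(dtype="U11"),
            hand=df["hand"].to_numpy(dtype="U5"),
            rt=df["rt_s"].to_numpy(dtype=float),
            correct=df["correct"].to_numpy().astype(bool),
            onset=df["onset_s"].to_numpy(dtype=float),
        )

    def validate(self) -> None:
        answered = np.isfinite(self.rt)
        if np.any(self.rt[answered] <= 0):
            raise ValidationError("TrialTable", "rt", "non-positive RT on answered trial")
        gaps = np.diff(self.onset)
        if np.any(gaps <= 0):
            raise ValidationError("TrialTable", "onset", "onsets not strictly increasing")
        lo, hi = ONSET_GAP_RANGE
        if np.any(gaps < lo - 1e-9) or np.any(gaps > hi + 1e-9):
            raise ValidationError(
                "TrialTable", "onset", f"inter-onset gap outside [{lo}, {hi}] s")
        if not np.all(np.isin(self.condition, ("congruent", "incongruent"))):
            raise ValidationError("TrialTable", "condition", "unknown condition label")
        if not np.all(np.isin(self.hand, ("left", "right"))):
            raise ValidationError("TrialTable", "hand", "unknown hand label")


@dataclass
class EpochSet:
    """Trial-segmented multichannel data: trials x channels x samples."""

    data: np.ndarray
    channels: Sequence[ChannelInfo]
    sfreq: float
    window: str  # pre_stimulus | pre_response | baseline
    t0: float  # window start, seconds relative to the anchor event
    trial_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[2] / self.sfreq

    def kind_mask(self, kind: str) -> np.ndarray:
        return np.array([c.kind == kind for c in self.channels])

    def validate(self, window_length_s: Optional[float] = None) -> None:
        if self.data.ndim != 3:
            raise ValidationError("EpochSet", "data", "expected trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise ValidationError("EpochSet", "channels", "channel count mismatch")
        if self.window not in WINDOWS:
            raise ValidationError("EpochSet", "window", f"unknown window {self.window}")
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise ValidationError("EpochSet", "trial_ids", "duplicate trial ids")
        if window_length_s is not None:
            expect = window_length_s * self.sfreq
            if abs(self.data.shape[2] - expect) > 1.0:
                raise ValidationError(
                    "EpochSet", "data",
                    f"{self.data.shape[2]} samples != {expect:.1f} +- 1")
        for c in self.channels:
            c.validate()


@dataclass
class SourceEpochs:
    """Source-space trial data: trials x sources x samples."""

    data: np.ndarray
    sfreq: float
    window: str
    trial_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class InverseOperator:
    """Depth-weighted minimum-norm inverse W = R A^T (A R A^T + C)^-1."""

    W: np.ndarray  # sources x channels
    A: np.ndarray  # channels x sources
    C: np.ndarray  # channels x channels
    R: np.ndarray  # (sources,) diagonal of the source covariance
    norm_factors: np.ndarray  # (sources,) sqrt(diag(W C W^T))

    def validate(self) -> None:
        ns, nc = self.W.shape
        if self.A.shape != (nc, ns):
            raise ValidationError("InverseOperator", "A", "gain shape mismatch")
        if not np.allclose(self.C, self.C.T):
            raise ValidationError("InverseOperator", "C", "noise covariance not symmetric")
        if np.any(np.linalg.eigvalsh(self.C) < -1e-10 * np.abs(self.C).max()):
            raise ValidationError("InverseOperator", "C", "noise covariance not PSD")
        if np.any(self.R < 0):
            raise ValidationError("InverseOperator", "R", "negative source variance")
        if np.any(self.norm_factors <= 0):
            raise ValidationError("InverseOperator", "norm_factors", "must be positive")


@dataclass
class ConnectivityMap:
    """Seed-to-vertex debiased wPLI: vertices x frequencies, one subject/window/cell."""

    values: np.ndarray
    seed: str
    freqs: np.ndarray
    window: str
    condition_cell: str  # e.g. "incongruent", "incongruent/left", "pooled"
    n_trials: int

    def validate(self) -> None:
        if np.any(self.values > 1 + 1e-9) or np.any(self.values < -1 - 1e-9):
            raise ValidationError("ConnectivityMap", "values", "outside [-1, 1]")


@dataclass
class PowerMap:
    """Band-averaged spectral power: vertices x bands, one subject/window."""

    values: np.ndarray
    bands: Sequence[str]
    window: str
    condition_cell: str = "pooled"

    def validate(self) -> None:
        if np.any(self.values < 0):
            raise ValidationError("PowerMap", "values", "negative power")
        for b in self.bands:
            if b not in BAND_NAMES:
                raise ValidationError("PowerMap", "bands", f"unknown band {b}")


@dataclass
class ClusterResult:
    """One suprathreshold connected component with its Monte Carlo p-value."""

    vertex_ids: np.ndarray
    hemisphere: str
    size_mm2: float
    max_value: float  # -log10(p) x sign(t) at the peak vertex
    peak_vertex: int
    cluster_p: float
    freq: float

    def validate(self, src: Optional[SourceSpace] = None) -> None:
        if self.size_mm2 <= 0:
            raise ValidationError("ClusterResult", "size_mm2", "must be positive")
        if src is not None:
            from scipy.sparse.csgraph import connected_components

            sub = src.adjacency_sparse()[np.ix_(self.vertex_ids, self.vertex_ids)]
            n_comp, _ = connected_components(sub, directed=False)
            if len(self.vertex_ids) > 1 and n_comp != 1:
                raise ValidationError("ClusterResult", "vertex_ids", "not connected")


@dataclass
class SubjectData:
    """One subject's epochs and behavior."""

    epochs_pre_stimulus: EpochSet
    epochs_pre_response: EpochSet
    epochs_baseline: EpochSet
    trials: TrialTable


@dataclass
class Cohort:
    """A full synthetic cohort sharing one source space and forward model."""

    source_space: SourceSpace
    gain: np.ndarray  # channels x sources
    channels: Sequence[ChannelInfo]
    parcels: Sequence[Parcel]
    subjects: dict  # subject id -> SubjectData
    config: dict = field(default_factory=dict)

    def parcel(self, name: str) -> Parcel:
        for p in self.parcels:
            if p.name == name:
                return p
        raise KeyError(f"no parcel named {name!r}")

    def validate(self) -> None:
        self.source_space.validate()
        for p in self.parcels:
            p.validate(self.source_space)
        if self.gain.shape != (len(self.channels), self.source_space.n_vertices):
            raise ValidationError("Cohort", "gain", "shape mismatch")
        for sd in self.subjects.values():
            sd.trials.validate()
            for ep in (sd.epochs_pre_stimulus, sd.epochs_pre_response, sd.epochs_baseline):
                ep.validate()
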