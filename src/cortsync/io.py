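"""HDF5 cohort container and TSV trial-table export.

Layout (version 1), one file per cohort::

    /                       attrs: layout_version, package
    /geometry               vertex_positions, vertex_normals, vertex_area,
                            hemisphere, triangles
    /forward                gain; channel name/kind/unit/position
    /parcels/<name>         vertex_ids; attrs: role
    /subjects/<id>/epochs_pre_stimulus   data; attrs: sfreq, window, t0; trial_ids
    /subjects/<id>/epochs_pre_response   (same)
    /subjects/<id>/epochs_baseline       (same)
    /subjects/<id>/trials   condition, hand, rt_s, correct, onset_s
    /config                 JSON string of the generating configuration

HDF5 is canonical; trial tables are additionally mirrored to TSV for eyeball
inspection (derived, never read back).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .data_model import (
    ChannelInfo,
    Cohort,
    EpochSet,
    Parcel,
    SourceSpace,
    SubjectData,
    TrialTable,
)

LAYOUT_VERSION = 1


class DatasetError(IOError):
    """Structured container error (missing group, bad version, truncation)."""


def _write_epochs(grp: h5py.Group, name: str, ep: EpochSet) -> None:
    g = grp.create_group(name)
    g.create_dataset("data", data=ep.data)
    g.create_dataset("trial_ids", data=np.asarray(ep.trial_ids, dtype=np.int64))
    g.attrs["sfreq"] = float(ep.sfreq)
    g.attrs["window"] = ep.window
    g.attrs["t0"] = float(ep.t0)


def _read_epochs(grp: h5py.Group, name: str, channels) -> EpochSet:
    if name not in grp:
        raise DatasetError(f"missing group {grp.name}/{name}")
    g = grp[name]
    return EpochSet(
        data=g["data"][()],
        channels=channels,
        sfreq=float(g.attrs["sfreq"]),
        window=str(g.attrs["window"]),
        t0=float(g.attrs["t0"]),
        trial_ids=g["trial_ids"][()],
    )


def write_dataset(cohort: Cohort, path, tsv_dir=None) -> Path:
    """Validate and write a cohort to one HDF5 container.

    Parameters
    ----------
    tsv_dir : optional directory for the derived per-subject trial TSVs;
        defaults to ``<path stem>_trials/`` next to the container.
    """
    cohort.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["package"] = "cortsync"
        geo = f.create_group("geometry")
        src = cohort.source_space
        geo.create_dataset("vertex_positions", data=src.vertex_positions)
        geo.create_dataset("vertex_normals", data=src.vertex_normals)
        geo.create_dataset("vertex_area", data=src.vertex_area)
        geo.create_dataset("hemisphere", data=np.char.encode(src.hemisphere.astype("U2")))
        geo.create_dataset("triangles", data=src.triangles)

        fwd = f.create_group("forward")
        fwd.create_dataset("gain", data=cohort.gain)
        fwd.create_dataset(
            "channel_name", data=np.array([c.name for c in cohort.channels], dtype="S32"))
        fwd.create_dataset(
            "channel_kind", data=np.array([c.kind for c in cohort.channels], dtype="S8"))
        fwd.create_dataset(
            "channel_unit", data=np.array([c.unit for c in cohort.channels], dtype="S8"))
        fwd.create_dataset(
            "channel_position", data=np.array([c.position for c in cohort.channels]))

        pg = f.create_group("parcels")
        for p in cohort.parcels:
            g = pg.create_group(p.name)
            g.create_dataset("vertex_ids", data=np.asarray(p.vertex_ids, dtype=np.int64))
            g.attrs["role"] = p.role

        sg = f.create_group("subjects")
        for sid, sd in cohort.subjects.items():
            g = sg.create_group(str(sid))
            _write_epochs(g, "epochs_pre_stimulus", sd.epochs_pre_stimulus)
            _write_epochs(g, "epochs_pre_response", sd.epochs_pre_response)
            _write_epochs(g, "epochs_baseline", sd.epochs_baseline)
            tg = g.create_group("trials")
            t = sd.trials
            tg.create_dataset("condition", data=np.char.encode(t.condition.astype("U11")))
            tg.create_dataset("hand", data=np.char.encode(t.hand.astype("U5")))
            tg.create_dataset("rt_s", data=t.rt)
            tg.create_dataset("correct", data=t.correct.astype(np.int8))
            tg.create_dataset("onset_s", data=t.onset)

        f.create_dataset("config", data=json.dumps(cohort.config, sort_keys=True))

    if tsv_dir is None:
        tsv_dir = path.with_name(path.stem + "_trials")
    tsv_dir = Path(tsv_dir)
    tsv_dir.mkdir(parents=True, exist_ok=True)
    for sid, sd in cohort.subjects.items():
        sd.trials.to_frame().to_csv(tsv_dir / f"{sid}.tsv", sep="\t", index=False)
    return path


def read_dataset(path) -> Cohort:
    """Read a cohort container written by :func:`write_dataset`."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DatasetError(f"cannot open {path}: {exc}") from exc
    with f:
        version = int(f.attrs.get("layout_version", -1))
        if version != LAYOUT_VERSION:
            raise DatasetError(
                f"unsupported layout version {version} (expected {LAYOUT_VERSION})")
        for group in ("geometry", "forward", "subjects"):
            if group not in f:
                raise DatasetError(f"missing group /{group} in {path}")
        geo = f["geometry"]
        src = SourceSpace(
            vertex_positions=geo["vertex_positions"][()],
            vertex_normals=geo["vertex_normals"][()],
            vertex_area=geo["vertex_area"][()],
            hemisphere=np.char.decode(geo["hemisphere"][()]).astype("U2"),
            triangles=geo["triangles"][()],
        )
        fwd = f["forward"]
        gain = fwd["gain"][()]
        names = np.char.decode(fwd["channel_name"][()])
        kinds = np.char.decode(fwd["channel_kind"][()])
        units = np.char.decode(fwd["channel_unit"][()])
        pos = fwd["channel_position"][()]
        channels = [
            ChannelInfo(name=str(n), kind=str(k), unit=str(u), position=p)
            for n, k, u, p in zip(names, kinds, units, pos)
        ]
        parcels = []
        if "parcels" in f:
            for name, g in f["parcels"].items():
                parcels.append(
                    Parcel(name=name, vertex_ids=g["vertex_ids"][()],
                           role=str(g.attrs["role"])))
        subjects = {}
        for sid, g in f["subjects"].items():
            tg = g["trials"]
            trials = TrialTable(
                condition=np.char.decode(tg["condition"][()]).astype("U11"),
                hand=np.char.decode(tg["hand"][()]).astype("U5"),
                rt=tg["rt_s"][()],
                correct=tg["correct"][()].astype(bool),
                onset=tg["onset_s"][()],
            )
            subjects[sid] = SubjectData(
                epochs_pre_stimulus=_read_epochs(g, "epochs_pre_stimulus", channels),
                epochs_pre_response=_read_epochs(g, "epochs_pre_response", channels),
                epochs_baseline=_read_epochs(g, "epochs_baseline", channels),
                trials=trials,
            )
        config = json.loads(f["config"][()]) if "config" in f else {}
    return Cohort(
        source_space=src, gain=gain, channels=channels, parcels=parcels,
        subjects=subjects, config=config)
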