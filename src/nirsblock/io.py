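"""Reading and writing recordings, event schedules, game logs and tables.

Primary on-disk container is SNIRF (HDF5, the community standard for fNIRS),
written and read through h5py following the v1.0 group layout. A plain-text
CSV dialect (wide table, one column per channel x component, with a JSON
sidecar for metadata) is provided as a fallback for text-only workflows.
Event schedules are BIDS-style tab-separated files with onset / duration /
trial_type columns.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    BlockLog,
    EventSchedule,
    GameLog,
    Montage,
    RecordingBundle,
    ValidationError,
    default_montage,
)

logger = logging.getLogger("nirsblock")

__all__ = [
    "save_recording", "load_recording",
    "save_snirf", "load_snirf",
    "save_recording_csv", "load_recording_csv",
    "save_events", "load_events",
    "save_game_log", "load_game_log",
]

SNIRF_SUFFIXES = {".snirf", ".h5", ".hdf5"}


def _is_snirf(path) -> bool:
    return Path(path).suffix.lower() in SNIRF_SUFFIXES


def save_recording(rec: RecordingBundle, path) -> None:
    """Dispatch on suffix: .snirf/.h5/.hdf5 -> SNIRF, anything else -> CSV."""
    if _is_snirf(path):
        save_snirf(rec, path)
    else:
        save_recording_csv(rec, path)


def load_recording(path, montage: Montage | None = None) -> RecordingBundle:
    if not os.path.exists(path):
        raise ValidationError(f"no such recording file: {path}")
    if _is_snirf(path):
        return load_snirf(path, montage=montage)
    return load_recording_csv(path, montage=montage)


# ---------------------------------------------------------------------------
# SNIRF (HDF5)
# ---------------------------------------------------------------------------

def _write_str(group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def save_snirf(rec: RecordingBundle, path) -> None:
    """Write a SNIRF v1.0 file: /formatVersion, /nirs/data1 with a
    measurementList entry per channel x component, probe geometry and the
    required metaDataTags. Processing state and pruning are stored in
    metaDataTags so a round trip is lossless."""
    n_cols = rec.n_channels * 2
    dts = np.empty((rec.n_times, n_cols))
    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _write_str(meta, "SubjectID", str(rec.meta.get("subject", "sim")))
        _write_str(meta, "MeasurementDate", "unknown")
        _write_str(meta, "MeasurementTime", "unknown")
        _write_str(meta, "LengthUnit", "mm")
        _write_str(meta, "TimeUnit", "s")
        _write_str(meta, "FrequencyUnit", "Hz")
        _write_str(meta, "nirsblockState", rec.state)
        _write_str(meta, "nirsblockComponents",
                   json.dumps(list(map(str, rec.component_labels))))
        _write_str(meta, "nirsblockPruned", json.dumps(rec.pruned_channels))
        _write_str(meta, "nirsblockSampleRate", repr(rec.sample_rate))

        probe = nirs.create_group("probe")
        if rec.state == "concentration":
            wavelengths = [760.0, 850.0]  # acquisition wavelengths, informational
        else:
            wavelengths = [float(w) for w in rec.component_labels]
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths))
        src_labels = list(rec.montage.sources)
        det_labels = list(rec.montage.detectors)
        probe.create_dataset("sourceLabels",
                             data=np.array(src_labels, dtype=h5py.string_dtype()))
        probe.create_dataset("detectorLabels",
                             data=np.array(det_labels, dtype=h5py.string_dtype()))
        probe.create_dataset(
            "sourcePos3D",
            data=np.array([rec.montage.sources[s] for s in src_labels], float))
        probe.create_dataset(
            "detectorPos3D",
            data=np.array([rec.montage.detectors[d] for d in det_labels], float))

        data1 = nirs.create_group("data1")
        data1.create_dataset("time", data=rec.timestamps)
        col = 0
        for ci, (src, det) in enumerate(rec.montage.channels):
            for comp in range(2):
                dts[:, col] = rec.data[:, ci, comp]
                ml = data1.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=src_labels.index(src) + 1)
                ml.create_dataset("detectorIndex", data=det_labels.index(det) + 1)
                if rec.state == "concentration":
                    ml.create_dataset("wavelengthIndex", data=-1)
                    ml.create_dataset("dataType", data=99999)
                    _write_str(ml, "dataTypeLabel", str(rec.component_labels[comp]))
                else:
                    ml.create_dataset("wavelengthIndex", data=comp + 1)
                    ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1
        data1.create_dataset("dataTimeSeries", data=dts)


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def load_snirf(path, montage: Montage | None = None) -> RecordingBundle:
    montage = montage or default_montage()
    ids = montage.channel_ids
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data1 = nirs["data1"]
        time = np.asarray(data1["time"])
        dts = np.asarray(data1["dataTimeSeries"])
        meta = nirs["metaDataTags"]
        state = _read_str(meta["nirsblockState"]) if "nirsblockState" in meta \
            else "intensity"
        if "nirsblockComponents" in meta:
            comps = json.loads(_read_str(meta["nirsblockComponents"]))
        else:
            comps = [str(w) for w in np.asarray(nirs["probe"]["wavelengths"])]
        pruned = json.loads(_read_str(meta["nirsblockPruned"])) \
            if "nirsblockPruned" in meta else {}
        if "nirsblockSampleRate" in meta:
            fs = float(_read_str(meta["nirsblockSampleRate"]))
        else:
            fs = 1.0 / float(np.mean(np.diff(time)))
        src_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in np.asarray(nirs["probe"]["sourceLabels"])]
        det_labels = [d.decode() if isinstance(d, bytes) else str(d)
                      for d in np.asarray(nirs["probe"]["detectorLabels"])]

        ml_names = sorted((k for k in data1 if k.startswith("measurementList")),
                          key=lambda k: int(k[len("measurementList"):]))
        if len(ml_names) != dts.shape[1]:
            raise ValidationError("measurementList count != data columns")
        # column -> (channel index, component index)
        per_channel: dict[str, dict[int, int]] = {}
        for col, name in enumerate(ml_names):
            ml = data1[name]
            src = src_labels[int(ml["sourceIndex"][()]) - 1]
            det = det_labels[int(ml["detectorIndex"][()]) - 1]
            cid = f"{src}-{det}"
            wl_idx = int(ml["wavelengthIndex"][()])
            comp = (wl_idx - 1) if wl_idx > 0 else \
                (0 if _read_str(ml["dataTypeLabel"]) == str(comps[0]) else 1)
            per_channel.setdefault(cid, {})[comp] = col
        missing = [c for c in ids if c not in per_channel]
        if missing:
            raise ValidationError(
                f"file is missing montage channels: {missing}")
        extra = [c for c in per_channel if c not in ids]
        if extra:
            raise ValidationError(f"file has channels not in montage: {extra}")
        data = np.empty((time.size, len(ids), 2))
        for ci, cid in enumerate(ids):
            comps_here = per_channel[cid]
            for comp in range(2):
                if comp not in comps_here:
                    raise ValidationError(
                        f"channel {cid} is missing component/wavelength "
                        f"{comps[comp]!r}")
                data[:, ci, comp] = dts[:, comps_here[comp]]

    labels = tuple(float(c) if state != "concentration" else c for c in comps)
    return RecordingBundle(timestamps=time, data=data, state=state,
                           component_labels=labels, montage=montage,
                           sample_rate=fs, pruned_channels=dict(pruned))


# ---------------------------------------------------------------------------
# CSV fallback
# ---------------------------------------------------------------------------

def save_recording_csv(rec: RecordingBundle, path) -> None:
    """Wide CSV (time + one column per channel|component) with a JSON sidecar
    ``<path>.json`` holding state, labels, sample rate and pruning."""
    cols = {"time": rec.timestamps}
    for ci, cid in enumerate(rec.montage.channel_ids):
        for comp, lab in enumerate(rec.component_labels):
            cols[f"{cid}|{lab}"] = rec.data[:, ci, comp]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "state": rec.state,
        "component_labels": list(map(str, rec.component_labels)),
        "sample_rate": rec.sample_rate,
        "pruned_channels": rec.pruned_channels,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_recording_csv(path, montage: Montage | None = None) -> RecordingBundle:
    montage = montage or default_montage()
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    state = sidecar["state"]
    raw_labels = sidecar["component_labels"]
    labels = tuple(raw_labels if state == "concentration"
                   else [float(x) for x in raw_labels])
    data = np.empty((len(df), montage.n_channels, 2))
    for ci, cid in enumerate(montage.channel_ids):
        for comp, lab in enumerate(raw_labels):
            col = f"{cid}|{lab}"
            if col not in df.columns:
                # labels may have been formatted as floats (760.0 vs 760)
                alt = f"{cid}|{float(lab):g}" if state != "concentration" else col
                if alt not in df.columns:
                    raise ValidationError(f"CSV is missing column {col!r}")
                col = alt
            data[:, ci, comp] = df[col].to_numpy()
    return RecordingBundle(
        timestamps=df["time"].to_numpy(), data=data, state=state,
        component_labels=labels, montage=montage,
        sample_rate=float(sidecar["sample_rate"]),
        pruned_channels=dict(sidecar.get("pruned_channels", {})))


# ---------------------------------------------------------------------------
# Events (BIDS-style TSV)
# ---------------------------------------------------------------------------

def save_events(schedule: EventSchedule, path) -> None:
    pd.DataFrame(
        {"onset": [e.onset for e in schedule.events],
         "duration": [e.duration for e in schedule.events],
         "trial_type": [e.condition for e in schedule.events]},
    ).to_csv(path, sep="\t", index=False)


def load_events(path) -> EventSchedule:
    """Read an onset/duration/trial_type TSV into a validated, sorted
    schedule. An empty file yields an empty schedule with a warning."""
    if not os.path.exists(path):
        raise ValidationError(f"no such events file: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["onset", "duration", "trial_type"])
    if df.empty:
        logger.warning("events file %s is empty", path)
        return EventSchedule(())
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"events file must have columns {sorted(required)}")
    return EventSchedule.from_rows(
        zip(df["onset"], df["duration"], df["trial_type"]))


# ---------------------------------------------------------------------------
# Game logs (tidy CSV)
# ---------------------------------------------------------------------------

def save_game_log(log: GameLog, path) -> None:
    """Tidy long CSV: one row per force sample / grasp / feed record."""
    rows = []
    rows.append({"block": -1, "condition": "meta", "t_start": np.nan,
                 "t_end": np.nan, "record": "mvc", "time": np.nan,
                 "value": log.mvc, "expected": np.nan})
    for bid, bl in sorted(log.blocks.items()):
        base = {"block": bid, "condition": bl.condition,
                "t_start": bl.t_start, "t_end": bl.t_end}
        for t, fnewton in zip(bl.force_t, bl.force_n):
            rows.append({**base, "record": "force", "time": t,
                         "value": fnewton, "expected": np.nan})
        for t in bl.grasp_times:
            rows.append({**base, "record": "grasp", "time": t,
                         "value": np.nan, "expected": np.nan})
        for delivered, expected in bl.feeds:
            rows.append({**base, "record": "feed", "time": np.nan,
                         "value": delivered, "expected": expected})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_game_log(path) -> GameLog:
    df = pd.read_csv(path)
    mvc_rows = df[df["record"] == "mvc"]
    if mvc_rows.empty:
        raise ValidationError("game log has no mvc record")
    mvc = float(mvc_rows["value"].iloc[0])
    blocks: dict[int, BlockLog] = {}
    for bid, g in df[df["record"] != "mvc"].groupby("block"):
        force = g[g["record"] == "force"].sort_values("time")
        grasps = g[g["record"] == "grasp"]
        feeds = g[g["record"] == "feed"]
        blocks[int(bid)] = BlockLog(
            block_id=int(bid),
            condition=str(g["condition"].iloc[0]),
            t_start=float(g["t_start"].iloc[0]),
            t_end=float(g["t_end"].iloc[0]),
            force_t=force["time"].to_numpy(float),
            force_n=force["value"].to_numpy(float),
            grasp_times=np.sort(grasps["time"].to_numpy(float)),
            feeds=[(int(v), int(e))
                   for v, e in zip(feeds["value"], feeds["expected"])],
        )
    return GameLog(mvc=mvc, blocks=blocks)
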