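"""Readers and writers: SNIRF (HDF5), TSV recordings, event files, manifests.

TSV dialect: recordings are written as one column per trace with a header
row of names like ``S1_D1 hbo`` / ``S1_D1 hbr`` and a first comment line
holding a JSON object with the sampling rate and hemisphere labels. Event
files are 4-column TSVs (session, condition, onset_s, duration_s). Ground
truth goes to a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import BlockAverage, HbTimeSeries
from .schedule import TaskBlock, TaskSchedule
from .simulate import Coupling, GroundTruth

__all__ = [
    "write_hb_tsv",
    "read_hb_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "write_snirf",
    "read_snirf",
    "write_ground_truth",
    "read_ground_truth",
    "write_block_average_tsv",
    "read_block_average_tsv",
]


def write_hb_tsv(ts: HbTimeSeries, path: str | Path) -> None:
    path = Path(path)
    meta = {"fs": ts.fs, "hemispheres": dict(zip(ts.channels, ts.hemispheres))}
    cols: dict[str, np.ndarray] = {}
    for i, ch in enumerate(ts.channels):
        cols[f"{ch} hbo"] = ts.hbo[i]
        cols[f"{ch} hbr"] = ts.hbr[i]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_hb_tsv(path: str | Path) -> HbTimeSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON metadata header line")
        meta = json.loads(first[2:])
        df = pd.read_csv(fh, sep="\t")
    channels = tuple(dict.fromkeys(c.rsplit(" ", 1)[0] for c in df.columns))
    hbo = np.stack([df[f"{ch} hbo"].to_numpy() for ch in channels])
    hbr = np.stack([df[f"{ch} hbr"].to_numpy() for ch in channels])
    hemis = tuple(meta["hemispheres"][ch] for ch in channels)
    return HbTimeSeries(
        hbo=hbo, hbr=hbr, fs=float(meta["fs"]), channels=channels, hemispheres=hemis
    )


def write_events_tsv(schedule: TaskSchedule, path: str | Path) -> None:
    rows = [
        (b.session, b.condition, b.onset, b.duration) for b in schedule.blocks
    ]
    df = pd.DataFrame(rows, columns=["session", "condition", "onset_s", "duration_s"])
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> TaskSchedule:
    df = pd.read_csv(path, sep="\t")
    blocks = tuple(
        TaskBlock(
            session=int(r.session),
            condition=str(r.condition),
            onset=float(r.onset_s),
            duration=float(r.duration_s),
        )
        for r in df.itertuples(index=False)
    )
    return TaskSchedule(blocks=blocks)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "channels": list(gt.channels),
        "conditions": list(gt.conditions),
        "amplitudes": gt.amplitudes.tolist(),
        "couplings": [
            {
                "driver": c.driver,
                "receiver": c.receiver,
                "lag": c.lag,
                "gain": c.gain,
                "condition": c.condition,
            }
            for c in gt.couplings
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        amplitudes=np.asarray(payload["amplitudes"], dtype=float),
        conditions=tuple(payload["conditions"]),
        channels=tuple(payload["channels"]),
        couplings=tuple(Coupling(**c) for c in payload["couplings"]),
    )


def write_block_average_tsv(avg: BlockAverage, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "fs": avg.fs,
        "tmin": avg.tmin,
        "condition": avg.condition,
        "n_blocks": avg.n_blocks,
        "hemispheres": dict(zip(avg.channels, avg.hemispheres)),
    }
    cols: dict[str, np.ndarray] = {}
    for i, ch in enumerate(avg.channels):
        cols[f"{ch} mean"] = avg.data[i]
        cols[f"{ch} sd"] = avg.sd[i]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_block_average_tsv(path: str | Path) -> BlockAverage:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON metadata header line")
        meta = json.loads(first[2:])
        df = pd.read_csv(fh, sep="\t")
    channels = tuple(dict.fromkeys(c.rsplit(" ", 1)[0] for c in df.columns))
    data = np.stack([df[f"{ch} mean"].to_numpy() for ch in channels])
    sd = np.stack([df[f"{ch} sd"].to_numpy() for ch in channels])
    return BlockAverage(
        data=data,
        sd=sd,
        n_blocks=int(meta["n_blocks"]),
        condition=str(meta["condition"]),
        tmin=float(meta["tmin"]),
        fs=float(meta["fs"]),
        channels=channels,
        hemispheres=tuple(meta["hemispheres"][ch] for ch in channels),
    )


def _str_dataset(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(ts: HbTimeSeries, path: str | Path, subject_id: str = "sim") -> None:
    """Write a processed-hemoglobin SNIRF file (dataType 99999, HbO/HbR)."""
    path = Path(path)
    n = ts.n_samples
    traces = []
    labels = []
    for i, ch in enumerate(ts.channels):
        traces.append(ts.hbo[i])
        labels.append((ch, "HbO"))
        traces.append(ts.hbr[i])
        labels.append((ch, "HbR"))
    data = np.column_stack(traces)

    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", subject_id)
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "cm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        _str_dataset(meta, "Hemispheres", json.dumps(dict(zip(ts.channels, ts.hemispheres))))

        sources = sorted({ch.split("_")[0] for ch in ts.channels}, key=lambda s: int(s[1:]))
        detectors = sorted({ch.split("_")[1] for ch in ts.channels}, key=lambda s: int(s[1:]))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))
        probe.create_dataset(
            "sourceLabels", data=np.array([np.bytes_(s) for s in sources])
        )
        probe.create_dataset(
            "detectorLabels", data=np.array([np.bytes_(d) for d in detectors])
        )
        # Schematic 2D layout: right-hemisphere optodes at x > 0, left at x < 0.
        spos = np.array([[(3.0 if int(s[1:]) <= 5 else -3.0), float(int(s[1:]) % 5)] for s in sources])
        dpos = np.array([[(3.0 if int(d[1:]) <= 4 else -3.0), float(int(d[1:]) % 4)] for d in detectors])
        probe.create_dataset("sourcePos2D", data=spos)
        probe.create_dataset("detectorPos2D", data=dpos)

        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(n) / ts.fs)
        for j, (ch, label) in enumerate(labels, start=1):
            src, det = ch.split("_")
            ml = d1.create_group(f"measurementList{j}")
            ml.create_dataset("sourceIndex", data=sources.index(src) + 1)
            ml.create_dataset("detectorIndex", data=detectors.index(det) + 1)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeIndex", data=1)
            _str_dataset(ml, "dataTypeLabel", label)


def read_snirf(path: str | Path) -> HbTimeSeries:
    """Read a processed-hemoglobin SNIRF file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        if time.size == 2:  # [start, dt] convention
            fs = 1.0 / float(time[1])
        else:
            fs = 1.0 / float(np.median(np.diff(time)))
        sources = [s.decode() for s in nirs["probe"]["sourceLabels"][()]]
        detectors = [d.decode() for d in nirs["probe"]["detectorLabels"][()]]
        ml_names = sorted(
            (k for k in d1.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList") :]),
        )
        traces: dict[str, dict[str, np.ndarray]] = {}
        order: list[str] = []
        for j, name in enumerate(ml_names):
            ml = d1[name]
            src = sources[int(ml["sourceIndex"][()]) - 1]
            det = detectors[int(ml["detectorIndex"][()]) - 1]
            label = ml["dataTypeLabel"][()]
            label = label.decode() if isinstance(label, bytes) else str(label)
            ch = f"{src}_{det}"
            if ch not in traces:
                traces[ch] = {}
                order.append(ch)
            traces[ch][label.lower()] = data[:, j]
        meta = nirs["metaDataTags"]
        if "Hemispheres" in meta:
            hemi_map = json.loads(meta["Hemispheres"][()].decode())
            hemis = tuple(hemi_map[ch] for ch in order)
        else:
            hemis = tuple(
                "right" if int(ch.split("_")[0][1:]) <= 5 else "left" for ch in order
            )
    hbo = np.stack([traces[ch]["hbo"] for ch in order])
    hbr = np.stack([traces[ch]["hbr"] for ch in order])
    return HbTimeSeries(
        hbo=hbo, hbr=hbr, fs=fs, channels=tuple(order), hemispheres=hemis
    )
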