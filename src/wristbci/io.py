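"""Containers and file I/O for continuous multichannel EEG with event markers.

Two on-disk dialects are supported:

* ``brainvision`` — a BrainVision-style triplet (``.vhdr`` INI header,
  ``.vmrk`` marker file, ``.eeg`` multiplexed IEEE float32 binary, µV).
* ``hdf5`` — a single HDF5 container with datasets ``signal``, ``labels``
  and ``events`` plus a montage table.

Signals are stored as float32, so round-trips are exact at float32
precision; event times are stored on the sample grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage, load_default_montage

__all__ = [
    "CLASS_LABELS",
    "MARKER_NAMES",
    "EventStream",
    "ContinuousRecording",
    "read_recording",
    "write_recording",
]

#: Cue markers delimiting the four stages of every trial.
MARKER_NAMES = ("GetReady", "StartMoving", "HoldMovement", "Stop")

#: The four movement classes: right/left hand × wrist extension/flexion.
CLASS_LABELS = ("RH-WE", "RH-WF", "LH-WE", "LH-WF")


@dataclass(frozen=True)
class EventStream:
    """Cue markers: (time in ms from recording start, marker name, class).

    Times must be strictly increasing.  Well-formedness of the
    GetReady → StartMoving → HoldMovement → Stop quadruples is checked by
    :meth:`check_sequences`; segmentation tolerates and reports violations.
    """

    frame: pd.DataFrame  # columns: time_ms, marker, label

    def __post_init__(self):
        df = self.frame
        required = {"time_ms", "marker", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"event frame needs columns {sorted(required)}")
        t = df["time_ms"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        bad = set(df["marker"]) - set(MARKER_NAMES)
        if bad:
            raise ValueError(f"unknown marker names: {sorted(bad)}")
        bad = set(df["label"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records) -> "EventStream":
        return cls(pd.DataFrame(records, columns=["time_ms", "marker", "label"]))

    def __len__(self) -> int:
        return len(self.frame)

    def of_marker(self, marker: str) -> pd.DataFrame:
        return self.frame[self.frame["marker"] == marker]

    def check_sequences(self) -> bool:
        """True if markers form complete, ordered per-trial quadruples."""
        seq = list(self.frame["marker"])
        if len(seq) % 4:
            return False
        for i in range(0, len(seq), 4):
            if tuple(seq[i:i + 4]) != MARKER_NAMES:
                return False
            if len(set(self.frame["label"].iloc[i:i + 4])) != 1:
                return False
        return True


@dataclass
class ContinuousRecording:
    """channels × samples signal (µV) with montage and event markers."""

    signal: np.ndarray
    fs: float
    montage: Montage
    events: EventStream

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != len(self.montage):
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but montage "
                f"has {len(self.montage)}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0


# ---------------------------------------------------------------------------
# dialect detection and montage resolution

def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        return "brainvision"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer dialect from {path.name!r}; "
                     "pass dialect='brainvision' or 'hdf5'")


def _resolve_montage(labels, montage: Montage | None, strict: bool) -> Montage:
    if montage is None:
        montage = load_default_montage()
        if strict and len(labels) != len(montage):
            raise ValueError(
                f"file has {len(labels)} labelled channels; expected "
                f"{len(montage)} (the configured 10-5 montage)"
            )
    # subset() raises a KeyError naming any unknown label
    return montage.subset(labels)


def read_recording(path, dialect: str | None = None, *,
                   montage: Montage | None = None,
                   strict: bool = True) -> ContinuousRecording:
    """Read a recording; montage resolved from the file's channel labels.

    With ``montage=None`` and ``strict=True`` the file must carry exactly
    the packaged 128-electrode montage.  Pass ``strict=False`` (or an
    explicit reduced montage) for reduced-channel files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "brainvision":
        return _read_brainvision(path, montage, strict)
    if dialect == "hdf5":
        return _read_hdf5(path, montage, strict)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_recording(rec: ContinuousRecording, path) -> Path:
    """Write a recording; dialect chosen from the file extension."""
    path = Path(path)
    dialect = _detect_dialect(path)
    if dialect == "brainvision":
        return _write_brainvision(rec, path)
    return _write_hdf5(rec, path)


# ---------------------------------------------------------------------------
# BrainVision-style triplet

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by wristbci

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={nchan}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
{markers}
"""


def _write_brainvision(rec: ContinuousRecording, path: Path) -> Path:
    stem = path.stem
    channels = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(rec.montage.labels)
    )
    sampling_interval = int(round(1e6 / rec.fs))  # microseconds
    path.write_text(
        _VHDR_TEMPLATE.format(stem=stem, nchan=rec.n_channels,
                              sampling_interval=sampling_interval,
                              channels=channels),
        encoding="utf-8",
    )
    markers = ["Mk1=New Segment,,1,1,0,0"]
    for k, row in enumerate(rec.events.frame.itertuples(index=False)):
        sample = int(round(row.time_ms * rec.fs / 1000.0)) + 1  # 1-based
        markers.append(
            f"Mk{k + 2}=Stimulus,{row.marker}/{row.label},{sample},1,0"
        )
    path.with_suffix(".vmrk").write_text(
        _VMRK_TEMPLATE.format(stem=stem, markers="\n".join(markers)),
        encoding="utf-8",
    )
    data = np.asarray(rec.signal, dtype="<f4").T  # multiplexed: sample-major
    data.tofile(path.with_suffix(".eeg"))
    return path


def _parse_ini(text: str) -> dict:
    sections: dict[str, dict] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, _, value = line.partition("=")
            sections[current][key.strip()] = value.strip()
    return sections


def _read_brainvision(path: Path, montage, strict) -> ContinuousRecording:
    sections = _parse_ini(path.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    nchan = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    if sections.get("Binary Infos", {}).get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError("only IEEE_FLOAT_32 binary data is supported")
    labels = []
    chinfo = sections.get("Channel Infos", {})
    for i in range(nchan):
        labels.append(chinfo[f"Ch{i + 1}"].split(",")[0])
    marker_path = path.with_name(common["MarkerFile"])
    if not marker_path.exists():
        raise FileNotFoundError(
            f"marker file {marker_path.name!r} missing for {path.name!r}"
        )
    data = np.fromfile(path.with_name(common["DataFile"]), dtype="<f4")
    if data.size % nchan:
        raise ValueError("binary data size is not a multiple of channel count")
    signal = data.reshape(-1, nchan).T.astype(float)

    records = []
    msections = _parse_ini(marker_path.read_text(encoding="utf-8"))
    for key, value in msections.get("Marker Infos", {}).items():
        parts = value.split(",")
        if parts[0] != "Stimulus":
            continue
        marker, _, label = parts[1].partition("/")
        time_ms = (int(parts[2]) - 1) / fs * 1000.0
        records.append((time_ms, marker, label))
    events = EventStream.from_records(records)
    return ContinuousRecording(signal, fs, _resolve_montage(labels, montage, strict), events)


# ---------------------------------------------------------------------------
# HDF5 container

def _write_hdf5(rec: ContinuousRecording, path: Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal.astype("<f4"))
        f.create_dataset(
            "labels",
            data=np.array(rec.montage.labels, dtype=h5py.string_dtype()),
        )
        ev = rec.events.frame
        grp = f.create_group("events")
        grp.create_dataset("time_ms", data=ev["time_ms"].to_numpy(float))
        grp.create_dataset(
            "marker", data=ev["marker"].to_numpy(dtype=h5py.string_dtype())
        )
        grp.create_dataset(
            "label", data=ev["label"].to_numpy(dtype=h5py.string_dtype())
        )
        f.create_dataset("montage_positions", data=rec.montage.positions)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["head_radius_mm"] = float(rec.montage.head_radius_mm)
    return path


def _read_hdf5(path: Path, montage, strict) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        if "events" not in f:
            raise ValueError(f"{path.name!r} has no event stream")
        signal = f["signal"][()].astype(float)
        labels = [l.decode() for l in f["labels"][()]]
        grp = f["events"]
        records = list(zip(
            grp["time_ms"][()].tolist(),
            (m.decode() for m in grp["marker"][()]),
            (l.decode() for l in grp["label"][()]),
        ))
        fs = float(f.attrs["fs"])
    events = EventStream.from_records(records)
    return ContinuousRecording(signal, fs, _resolve_montage(labels, montage, strict), events)
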