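"""Raw-recording container and file formats.

The in-memory container is :class:`RawRecording` (channels x samples, µV).
On disk the canonical format is a small, versioned HDF5 layout::

    /               attrs: format="streambci-raw", version="1.0"
    /data           float64, (n_channels, n_samples), microvolts
    /channel_labels UTF-8 strings
    /channel_types  UTF-8 strings, "EEG" | "EOG"
    /events/<col>   one dataset per event-table column
    /               attrs: rate (Hz), metadata (JSON)

Event tables are pandas DataFrames with columns
``onset_sample, stream, role, attended_stream, run_index`` (0-based sample
indexing; all windows downstream are half-open ``[start, stop)``).

BrainVision triplets (.vhdr/.vmrk/.eeg) are read through MNE-Python; a
minimal IEEE-float32 multiplexed writer is provided for export and
round-trip testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

FORMAT_NAME = "streambci-raw"
FORMAT_VERSION = "1.0"

EVENT_COLUMNS = ["onset_sample", "stream", "role", "attended_stream", "run_index"]


@dataclass
class RawRecording:
    """A continuous multichannel recording in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), µV
    rate: float  # Hz
    channel_labels: list[str]
    channel_types: list[str]  # "EEG" | "EOG"
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_types) != n_ch:
            raise ValueError("channel labels/types must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def picks(self, ch_type: str) -> np.ndarray:
        """Row indices of channels of the given type."""
        return np.array([i for i, t in enumerate(self.channel_types) if t == ch_type],
                        dtype=int)

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        return RawRecording(
            data=data,
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            channel_types=list(self.channel_types),
            events=self.events.copy(),
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# canonical HDF5 container
# ---------------------------------------------------------------------------


def write_canonical(recording: RawRecording, path: str | Path) -> None:
    """Write a recording to the canonical HDF5 container (lossless)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_NAME
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["rate"] = float(recording.rate)
        f.attrs["metadata"] = json.dumps(recording.metadata, default=str)
        f.create_dataset("data", data=recording.data)
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("channel_labels",
                         data=np.array(recording.channel_labels, dtype=object),
                         dtype=str_dt)
        f.create_dataset("channel_types",
                         data=np.array(recording.channel_types, dtype=object),
                         dtype=str_dt)
        grp = f.create_group("events")
        for col in recording.events.columns:
            values = recording.events[col].to_numpy()
            if values.dtype == object:
                grp.create_dataset(col, data=values.astype(object), dtype=str_dt)
            else:
                grp.create_dataset(col, data=values)
        grp.attrs["columns"] = json.dumps(list(recording.events.columns))


def read_canonical(path: str | Path) -> RawRecording:
    """Read a canonical container; refuses unknown major versions."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open canonical container {path}: {exc}") from exc
    with f:
        fmt = f.attrs.get("format")
        if fmt != FORMAT_NAME:
            raise ValueError(f"not a {FORMAT_NAME} container (format={fmt!r})")
        version = str(f.attrs["version"])
        if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
            raise ValueError(
                f"unsupported container version: found {version}, "
                f"expected major {FORMAT_VERSION.split('.')[0]} "
                f"(writer version {FORMAT_VERSION})"
            )
        data = f["data"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][()]]
        types = [s.decode() if isinstance(s, bytes) else str(s)
                 for s in f["channel_types"][()]]
        cols = json.loads(f["events"].attrs.get("columns", "[]"))
        events = {}
        for col in cols:
            values = f["events"][col][()]
            if values.dtype.kind in ("O", "S"):
                values = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                   for v in values])
            events[col] = values
        return RawRecording(
            data=data,
            rate=float(f.attrs["rate"]),
            channel_labels=labels,
            channel_types=types,
            events=pd.DataFrame(events),
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


# ---------------------------------------------------------------------------
# events CSV
# ---------------------------------------------------------------------------


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in ("onset_sample", "stream", "role") if c not in events]
    if missing:
        raise ValueError(f"events CSV missing required columns: {missing}")
    return events


def assemble_recording(
    data: np.ndarray,
    rate: float,
    events_csv: str | Path,
    channel_labels: list[str] | None = None,
    eog_channels: tuple[str, ...] = ("vEOG", "hEOG"),
) -> RawRecording:
    """Build a RawRecording from a bare array plus an events CSV."""
    from .montage import ALL_CHANNELS, channel_types as infer_types

    if channel_labels is None:
        channel_labels = list(ALL_CHANNELS[: data.shape[0]])
    types = ["EOG" if lab in eog_channels else t
             for lab, t in zip(channel_labels, infer_types(channel_labels))]
    return RawRecording(
        data=data, rate=rate, channel_labels=channel_labels,
        channel_types=types, events=read_events_csv(events_csv),
    )


# ---------------------------------------------------------------------------
# BrainVision triplet
# ---------------------------------------------------------------------------


def default_marker_map() -> dict[str, tuple[int, str]]:
    """Marker description -> (stream, role) for triplets written here.

    Codes are ``S <stream><d>`` with d=1 for deviant, 0 for standard.
    """
    out = {}
    for stream in (1, 2, 3):
        for d, role in ((0, "standard"), (1, "deviant")):
            out[f"Stimulus/S {stream * 10 + d}"] = (stream, role)
    return out


def read_brainvision(
    header_path: str | Path,
    marker_map: dict[str, tuple[int, str]] | None = None,
    eog_channels: tuple[str, ...] = ("vEOG", "hEOG"),
) -> RawRecording:
    """Read a .vhdr/.vmrk/.eeg triplet into a RawRecording (µV).

    ``marker_map`` translates annotation descriptions into (stream, role)
    pairs; unmapped markers are dropped with a warning.  Channel types are
    inferred from ``eog_channels``.
    """
    import mne

    header_path = Path(header_path)
    raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> µV
    labels = list(raw.ch_names)
    types = ["EOG" if lab in eog_channels else "EEG" for lab in labels]
    rate = float(raw.info["sfreq"])

    marker_map = marker_map or default_marker_map()
    rows = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        if desc not in marker_map:
            warnings.warn(f"unknown marker code {desc!r}: event dropped")
            continue
        stream, role = marker_map[desc]
        rows.append(
            {"onset_sample": int(round(ann["onset"] * rate)),
             "stream": stream, "role": role}
        )
    events = pd.DataFrame(rows, columns=["onset_sample", "stream", "role"])
    return RawRecording(
        data=data, rate=rate, channel_labels=labels, channel_types=types,
        events=events, metadata={"source": str(header_path)},
    )


def write_brainvision(recording: RawRecording, basename: str | Path) -> Path:
    """Export to a BrainVision triplet (IEEE float32, multiplexed, µV).

    Returns the header path.  Markers encode (stream, role) with the codes
    of :func:`default_marker_map`.
    """
    basename = Path(basename)
    vhdr, vmrk, eeg = (basename.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    n_ch = recording.n_channels
    interval_us = 1e6 / recording.rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    k = 2
    for _, row in recording.events.iterrows():
        code = int(row["stream"]) * 10 + (1 if row["role"] == "deviant" else 0)
        pos = int(row["onset_sample"]) + 1  # BrainVision markers are 1-based
        mlines.append(f"Mk{k}=Stimulus,S {code},{pos},1,0")
        k += 1
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr
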