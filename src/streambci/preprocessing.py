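"""Filtering, epoching, baseline correction and amplitude-based rejection.

Two filter bands are used from the same raw recording: 0.1–40 Hz for ERP
averaging and 1–40 Hz for the classification path, both zero-phase
2nd-order Butterworth applied forward and backward (24 dB/octave effective
slope).  Epochs span −100 to +500 ms around tone onset (half-open sample
windows, 600 samples at 1000 Hz), baseline-corrected by the −50–0 ms mean,
and rejected when any EEG sample exceeds ±100 µV or any EOG sample exceeds
±500 µV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import RawRecording

#: (low, high) Hz of the two analysis paths.
ERP_BAND = (0.1, 40.0)
CLF_BAND = (1.0, 40.0)


def design_bandpass(low: float, high: float, rate: float, order: int = 2) -> np.ndarray:
    """Second-order sections of the one-pass Butterworth design."""
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    if low < 0 or low >= high:
        raise ValueError("need 0 <= low < high")
    if low == 0:
        return signal.butter(order, high, btype="lowpass", fs=rate, output="sos")
    return signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass_filter(
    recording: RawRecording, low: float, high: float, order: int = 2
) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth bandpass of a recording.

    The one-pass design has the given ``order`` (2 by default, 12 dB/octave);
    the two-pass application doubles the effective slope to 24 dB/octave and
    cancels the phase response.  Edges are handled by reflection padding of
    at least three time constants of the low cut.
    """
    sos = design_bandpass(low, high, recording.rate, order=order)
    n = recording.n_samples
    if low > 0:
        padlen = int(min(n - 1, round(3.0 * recording.rate / low)))
    else:
        padlen = int(min(n - 1, round(3.0 * recording.rate / high)))
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1, padlen=padlen)
    out = recording.copy_with(filtered)
    out.metadata["bandpass_hz"] = (low, high)
    return out


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------


@dataclass
class Epoch:
    """A single event-locked window (channels x time, µV)."""

    data: np.ndarray
    onset_sample: int
    stream: int
    role: str
    attended_stream: int
    rejected: bool = False
    reject_reason: str = ""

    @property
    def attended(self) -> bool:
        return self.stream == self.attended_stream


@dataclass
class EpochSet:
    """Event-locked windows with labels and rejection status.

    ``data`` is (n_epochs, n_channels, n_times) in µV, already
    baseline-corrected when a baseline was requested at extraction;
    ``baseline_means`` keeps the subtracted per-channel means so the raw
    window can be reconstructed exactly.  ``metadata`` rows carry
    onset_sample (global, 0-based), stream, role, attended_stream,
    run_index, rejected, reject_reason.
    """

    data: np.ndarray
    metadata: pd.DataFrame
    rate: float
    tmin: float
    channel_labels: list[str]
    channel_types: list[str]
    baseline_means: np.ndarray | None = None
    n_dropped_edge: int = 0

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.rate

    def epoch(self, i: int) -> Epoch:
        row = self.metadata.iloc[i]
        return Epoch(
            data=self.data[i],
            onset_sample=int(row["onset_sample"]),
            stream=int(row["stream"]),
            role=str(row["role"]),
            attended_stream=int(row["attended_stream"]),
            rejected=bool(row.get("rejected", False)),
            reject_reason=str(row.get("reject_reason", "")),
        )

    def _subset(self, mask: np.ndarray) -> "EpochSet":
        idx = np.flatnonzero(mask)
        return replace(
            self,
            data=self.data[idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            baseline_means=None if self.baseline_means is None
            else self.baseline_means[idx],
        )

    def select(
        self,
        stream: int | None = None,
        role: str | None = None,
        attended: bool | None = None,
        include_rejected: bool = False,
    ) -> "EpochSet":
        """Subset by event stream, role, and attention status.

        ``attended`` refers to whether the event's stream was the attended
        stream of its run.  Rejected epochs are excluded unless requested.
        """
        md = self.metadata
        mask = np.ones(len(self), dtype=bool)
        if stream is not None:
            mask &= (md["stream"] == stream).to_numpy()
        if role is not None:
            mask &= (md["role"] == role).to_numpy()
        if attended is not None:
            is_att = (md["stream"] == md["attended_stream"]).to_numpy()
            mask &= is_att if attended else ~is_att
        if not include_rejected and "rejected" in md:
            mask &= ~md["rejected"].to_numpy()
        return self._subset(mask)

    def survivors(self) -> "EpochSet":
        if "rejected" not in self.metadata:
            return self
        return self._subset(~self.metadata["rejected"].to_numpy())

    @property
    def n_rejected(self) -> int:
        if "rejected" not in self.metadata:
            return 0
        return int(self.metadata["rejected"].sum())

    def rejection_report(self) -> pd.DataFrame:
        """Per-epoch rejection log (epoch index, reason)."""
        md = self.metadata
        if "rejected" not in md:
            return pd.DataFrame(columns=["epoch", "reason"])
        rej = md.index[md["rejected"]]
        return pd.DataFrame(
            {"epoch": rej, "reason": md.loc[rej, "reject_reason"].to_numpy()}
        )

    @staticmethod
    def concatenate(sets: "list[EpochSet]") -> "EpochSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        baselines = None
        if all(s.baseline_means is not None for s in sets):
            baselines = np.concatenate([s.baseline_means for s in sets], axis=0)
        return replace(
            first,
            data=np.concatenate([s.data for s in sets], axis=0),
            metadata=pd.concat([s.metadata for s in sets], ignore_index=True),
            baseline_means=baselines,
            n_dropped_edge=sum(s.n_dropped_edge for s in sets),
        )


def extract_epochs(
    recording: RawRecording,
    events: pd.DataFrame | None = None,
    tmin: float = -0.1,
    tmax: float = 0.5,
    baseline: tuple[float, float] | None = (-0.05, 0.0),
    sample_offset: int = 0,
    dtype=np.float64,
) -> EpochSet:
    """Cut event-locked windows out of a recording.

    Windows are half-open ``[onset + tmin*rate, onset + tmax*rate)``
    (600 samples at 1000 Hz for the −100–500 ms default).  The per-channel
    mean over the baseline interval is subtracted when ``baseline`` is
    given.  Events whose window leaves the recording are dropped with a
    warning and counted in ``n_dropped_edge``.  ``sample_offset`` shifts the
    stored (global) onset samples, for multi-run concatenation.
    """
    if events is None:
        events = recording.events
    rate = recording.rate
    start_off = int(round(tmin * rate))
    n_times = int(round((tmax - tmin) * rate))

    keep_rows, windows = [], []
    n_dropped = 0
    onset_samples = events["onset_sample"].to_numpy(dtype=int)
    for i, onset in enumerate(onset_samples):
        s0 = onset + start_off
        if s0 < 0 or s0 + n_times > recording.n_samples:
            n_dropped += 1
            continue
        keep_rows.append(i)
        windows.append(recording.data[:, s0 : s0 + n_times])
    if n_dropped:
        warnings.warn(f"{n_dropped} event(s) too close to the recording edge; dropped")

    data = (np.stack(windows) if windows
            else np.empty((0, recording.n_channels, n_times))).astype(dtype)
    md = events.iloc[keep_rows].reset_index(drop=True).copy()
    md["onset_sample"] = md["onset_sample"].astype(int) + sample_offset
    if "attended_stream" not in md:
        md["attended_stream"] = recording.metadata.get("attended_stream", 0)
    if "run_index" not in md:
        md["run_index"] = recording.metadata.get("run_index", 0)
    md["rejected"] = False
    md["reject_reason"] = ""

    baseline_means = None
    if baseline is not None:
        b0 = int(round((baseline[0] - tmin) * rate))
        b1 = int(round((baseline[1] - tmin) * rate))
        if not 0 <= b0 < b1 <= n_times:
            raise ValueError(f"baseline {baseline} outside the epoch window")
        baseline_means = data[:, :, b0:b1].mean(axis=2)
        data -= baseline_means[:, :, None]

    return EpochSet(
        data=data,
        metadata=md,
        rate=rate,
        tmin=tmin,
        channel_labels=list(recording.channel_labels),
        channel_types=list(recording.channel_types),
        baseline_means=baseline_means,
        n_dropped_edge=n_dropped,
    )


def reject_artifacts(
    epochs: EpochSet,
    eeg_threshold: float = 100.0,
    eog_threshold: float = 500.0,
) -> EpochSet:
    """Flag epochs whose instantaneous amplitude exceeds the thresholds.

    An epoch is rejected iff any EEG sample's absolute value exceeds
    ``eeg_threshold`` (µV) or any EOG sample's absolute value exceeds
    ``eog_threshold``, evaluated on the data as given (i.e. after filtering
    and baseline correction in the default pipeline order).  All epochs are
    returned with flags set; use :meth:`EpochSet.survivors` for the kept
    set.
    """
    if eeg_threshold <= 0 or eog_threshold <= 0:
        raise ValueError("thresholds must be positive")
    ctypes = np.asarray(epochs.channel_types)
    eeg_rows = ctypes == "EEG"
    eog_rows = ctypes == "EOG"

    n = len(epochs)
    peak = np.abs(epochs.data)
    eeg_bad = (peak[:, eeg_rows, :].max(axis=(1, 2)) > eeg_threshold
               if eeg_rows.any() else np.zeros(n, bool))
    eog_bad = (peak[:, eog_rows, :].max(axis=(1, 2)) > eog_threshold
               if eog_rows.any() else np.zeros(n, bool))

    md = epochs.metadata.copy()
    md["rejected"] = eeg_bad | eog_bad
    reasons = np.where(
        eeg_bad & eog_bad, "eeg+eog",
        np.where(eeg_bad, "eeg", np.where(eog_bad, "eog", "")),
    )
    md["reject_reason"] = reasons
    out = replace(epochs, metadata=md)
    if out.n_rejected == n and n > 0:
        warnings.warn("all epochs rejected")
    return out
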