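"""Synthetic auditory-oddball EEG sessions.

Three interleaved tone streams are presented at a fixed stimulus onset
asynchrony (SOA); each stream is an oddball sequence with rare deviants.
This module generates the timed stimulus sequences and raw multichannel
EEG/EOG recordings carrying the event-related components the analysis
assumes (N1 on every tone, MMN and a parietal P3b on attended deviants,
an optional frontal P3a on nonattended deviants) on top of spatially
correlated 1/f background noise, plus occasional blink artifacts that
exceed the amplitude-rejection thresholds.

Defaults reproduce the study conditions: SOA 180 ms (per-stream cycle
540 ms), deviant probability 0.1, 5-minute runs, two blocks of three runs
attending streams 1, 2, 3 in order, 64 EEG + 2 EOG channels at 1000 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import ALL_CHANNELS, EEG_CHANNELS, channel_types, gaussian_scalp_map
from .io_formats import RawRecording

__all__ = [
    "TONE_TABLE",
    "ToneSpec",
    "StimulusEvent",
    "StimulusSequence",
    "generate_stimulus_sequence",
    "classification_intervals",
    "ERPComponent",
    "ERPTemplateSet",
    "make_erp_templates",
    "NoiseConfig",
    "SessionPlan",
    "simulate_run",
    "simulate_session",
]


@dataclass(frozen=True)
class ToneSpec:
    """A tone assigned to one (stream, role) slot of the paradigm."""

    stream_index: int
    role: str  # "standard" | "deviant"
    note_name: str
    frequency_hz: float

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("tone frequency must be positive")
        if self.role not in ("standard", "deviant"):
            raise ValueError(f"unknown role {self.role!r}")


#: Stimulus tones: each stream pairs a frequent standard with a rare deviant,
#: streams separated widely in frequency so they segregate perceptually.
TONE_TABLE: dict[tuple[int, str], ToneSpec] = {
    (1, "standard"): ToneSpec(1, "standard", "C3", 131.0),
    (1, "deviant"): ToneSpec(1, "deviant", "G3", 196.0),
    (2, "standard"): ToneSpec(2, "standard", "D5", 587.0),
    (2, "deviant"): ToneSpec(2, "deviant", "A5", 880.0),
    (3, "standard"): ToneSpec(3, "standard", "E7", 2637.0),
    (3, "deviant"): ToneSpec(3, "deviant", "B7", 3951.0),
}


@dataclass(frozen=True)
class StimulusEvent:
    """One presented tone."""

    onset: float  # seconds from run start
    stream_index: int
    role: str  # "standard" | "deviant"
    duration: float = 0.150

    def onset_sample(self, rate: float) -> int:
        return int(round(self.onset * rate))


@dataclass
class StimulusSequence:
    """A run's ordered tone events with the generating parameters."""

    events: list[StimulusEvent]
    soa: float
    deviant_prob: float
    run_duration: float
    seed: int
    n_streams: int = 3

    def __len__(self) -> int:
        return len(self.events)

    def to_dataframe(self, rate: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "stream": [e.stream_index for e in self.events],
                "role": [e.role for e in self.events],
                "duration": [e.duration for e in self.events],
            }
        )
        if rate is not None:
            df.insert(0, "onset_sample", [e.onset_sample(rate) for e in self.events])
        return df

    def onsets(self, stream: int | None = None, role: str | None = None) -> np.ndarray:
        """Onset times (s) filtered by stream and/or role."""
        return np.array(
            [
                e.onset
                for e in self.events
                if (stream is None or e.stream_index == stream)
                and (role is None or e.role == role)
            ]
        )


def generate_stimulus_sequence(
    soa: float = 0.18,
    deviant_prob: float = 0.1,
    run_duration: float = 300.0,
    n_streams: int = 3,
    seed: int = 0,
    min_separation: int = 0,
) -> StimulusSequence:
    """Generate one run's interleaved oddball sequence.

    Streams are presented cyclically (1, 2, 3, 1, 2, ...), one tone per SOA,
    so consecutive tones of the same stream are ``n_streams * soa`` apart.
    Each stream's tone in each cycle is a deviant independently with
    probability ``deviant_prob``; ``min_separation`` optionally enforces that
    many standards between consecutive deviants within a stream (0 = the
    plain Bernoulli model).

    Parameters
    ----------
    soa : float
        Stimulus onset asynchrony in seconds (default 0.18).
    deviant_prob : float
        Per-stream, per-cycle deviant probability, in (0, 0.5).
    run_duration : float
        Run length in seconds; events cover [0, run_duration).
    n_streams : int
        Number of interleaved streams (>= 2).
    seed : int
        Seed for the deviant draws; the sequence is reproducible given it.
    min_separation : int
        Minimum number of standards between consecutive deviants of one
        stream (default 0 = unconstrained).
    """
    if soa <= 0:
        raise ValueError("soa must be positive")
    if run_duration <= 0:
        raise ValueError("run_duration must be positive")
    if not 0 < deviant_prob < 0.5:
        raise ValueError("deviant_prob must lie in (0, 0.5)")
    if n_streams < 2:
        raise ValueError("need at least 2 streams")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")

    rng = np.random.default_rng(seed)
    n_events = int(np.ceil(run_duration / soa))
    since_deviant = {s: min_separation for s in range(1, n_streams + 1)}
    events: list[StimulusEvent] = []
    for k in range(n_events):
        onset = k * soa
        if onset >= run_duration:
            break
        stream = (k % n_streams) + 1
        draw = rng.random() < deviant_prob
        if draw and since_deviant[stream] >= min_separation:
            role = "deviant"
            since_deviant[stream] = 0
        else:
            role = "standard"
            since_deviant[stream] += 1
        events.append(StimulusEvent(onset=onset, stream_index=stream, role=role))
    return StimulusSequence(
        events=events,
        soa=soa,
        deviant_prob=deviant_prob,
        run_duration=run_duration,
        seed=seed,
        n_streams=n_streams,
    )


def classification_intervals(sequence: StimulusSequence) -> np.ndarray:
    """Empirical waiting times until every stream has shown >= 1 deviant.

    Scanning the run from the start, record the elapsed time at which all
    streams have presented at least one deviant since the previous reset,
    then reset and continue.  This is the interval at which one 3-way
    selection becomes decidable; its distribution depends on the deviant
    placement model, so it is reported empirically rather than assumed.
    """
    intervals: list[float] = []
    t0 = 0.0
    seen: set[int] = set()
    for e in sequence.events:
        if e.role == "deviant":
            seen.add(e.stream_index)
            if len(seen) == sequence.n_streams:
                intervals.append(e.onset + sequence.soa - t0)
                t0 = e.onset + sequence.soa
                seen = set()
    return np.array(intervals)


# ---------------------------------------------------------------------------
# ERP templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ERPComponent:
    """A single evoked component: a Gaussian pulse with a fixed scalp map."""

    name: str
    peak_latency: float  # seconds from tone onset
    peak_amplitude: float  # microvolts, sign-carrying
    half_width: float  # FWHM of the temporal pulse, seconds
    scalp_map: np.ndarray  # per-channel weights, unit maximum |weight|

    @property
    def sigma(self) -> float:
        return self.half_width / 2.3548200450309493  # FWHM -> Gaussian sigma

    def pulse(self, t: np.ndarray, latency: float | None = None) -> np.ndarray:
        """Amplitude (µV) at times ``t`` (s, relative to tone onset).

        The Gaussian is truncated at |t - latency| > 4 sigma so components
        have compact support and a noiseless epoch reproduces the template
        sum exactly.
        """
        lat = self.peak_latency if latency is None else latency
        w = self.peak_amplitude * np.exp(-((t - lat) ** 2) / (2.0 * self.sigma**2))
        w[np.abs(t - lat) > 4.0 * self.sigma] = 0.0
        return w


@dataclass
class ERPTemplateSet:
    """The component set injected by the simulator.

    P3b: parietal, attended deviants only.  P3a: frontal, nonattended
    deviants.  MMN: frontocentral negativity, attended deviants.  N1: vertex
    response to every tone.
    """

    components: dict[str, ERPComponent]
    channel_labels: tuple[str, ...] = ALL_CHANNELS

    def __getitem__(self, name: str) -> ERPComponent:
        return self.components[name]

    def with_amplitudes(self, **amps: float) -> "ERPTemplateSet":
        """Copy with some components' peak amplitudes replaced."""
        comps = dict(self.components)
        for name, amp in amps.items():
            comps[name] = dataclasses.replace(comps[name], peak_amplitude=float(amp))
        return ERPTemplateSet(comps, self.channel_labels)

    def components_for(self, role: str, attended: bool) -> list[ERPComponent]:
        """Components evoked by a tone of the given role/attention status."""
        active = [self.components["N1"]]
        if role == "deviant":
            if attended:
                active += [self.components["MMN"], self.components["P3b"]]
            else:
                active += [self.components["P3a"]]
        return [c for c in active if c.peak_amplitude != 0.0]

    def expected_epoch(
        self,
        role: str,
        attended: bool,
        tmin: float = -0.1,
        tmax: float = 0.5,
        rate: float = 1000.0,
    ) -> np.ndarray:
        """Noise-free single-event signal over the epoch window, channels x time."""
        samples = np.arange(int(round(tmin * rate)), int(round(tmax * rate)))
        t = samples / rate
        out = np.zeros((len(self.channel_labels), t.size))
        for comp in self.components_for(role, attended):
            out += np.outer(comp.scalp_map, comp.pulse(t))
        return out


_DEFAULTS = {
    # name: (latency s, amplitude µV, FWHM s, scalp centre)
    "P3b": (0.30, +5.0, 0.15, "Pz"),
    "P3a": (0.25, +2.0, 0.12, "Fz"),
    "MMN": (0.15, -2.0, 0.08, "FCz"),
    "N1": (0.10, -1.0, 0.05, "Cz"),
}


def make_erp_templates(
    config: dict | None = None,
    channel_labels: tuple[str, ...] = ALL_CHANNELS,
    epoch_tmax: float = 0.5,
) -> ERPTemplateSet:
    """Build the component templates, overriding defaults from ``config``.

    ``config`` maps component name to a dict with any of ``latency``,
    ``amplitude``, ``half_width``, ``center`` keys.  Latencies must fall
    inside the epoch window (<= ``epoch_tmax``).
    """
    config = config or {}
    comps: dict[str, ERPComponent] = {}
    for name, (lat, amp, hw, center) in _DEFAULTS.items():
        over = config.get(name, {})
        lat = float(over.get("latency", lat))
        amp = float(over.get("amplitude", amp))
        hw = float(over.get("half_width", hw))
        center = over.get("center", center)
        if not 0.0 < lat <= epoch_tmax:
            raise ValueError(
                f"{name} latency {lat} s outside the epoch window (0, {epoch_tmax}] s"
            )
        comps[name] = ERPComponent(
            name=name,
            peak_latency=lat,
            peak_amplitude=amp,
            half_width=hw,
            scalp_map=gaussian_scalp_map(center, labels=channel_labels),
        )
    return ERPTemplateSet(comps, channel_labels)


# ---------------------------------------------------------------------------
# Raw-recording simulation
# ---------------------------------------------------------------------------


@dataclass
class NoiseConfig:
    """Background-noise and artifact parameters of the simulator.

    rms_uV
        Per-channel RMS of the 1/f background, microvolts.  ERP
        signal-to-noise is controlled via template amplitudes only.
    blink_rate_hz
        Poisson rate of blink artifacts (per second).  0 disables blinks.
    latency_jitter_s
        Per-trial Gaussian jitter (SD, seconds) on component latencies;
        0 makes every trial time-locked exactly.
    mixing_seed
        Seed of the spatial mixing matrix that correlates the noise across
        channels.  Within a session the background spatial covariance is a
        stable property of the head and montage, so
        :func:`simulate_session` draws one mixing seed and shares it across
        runs; leaving it None draws the mixing from the run's own seed.
    """

    rms_uV: float = 10.0
    blink_rate_hz: float = 0.1
    latency_jitter_s: float = 0.02
    mixing_seed: int | None = None


@dataclass
class SessionPlan:
    """Ordered (run_index, attended_stream) pairs grouped in blocks."""

    runs: list[tuple[int, int]] = field(default_factory=list)
    blocks: int = 2

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty session plan")
        for _, att in self.runs:
            if att not in (1, 2, 3):
                raise ValueError(f"attended stream must be 1-3, got {att}")

    @classmethod
    def default(cls, blocks: int = 2) -> "SessionPlan":
        """Each block attends streams 1, 2, 3 in order."""
        runs = [(b * 3 + i, i + 1) for b in range(blocks) for i in range(3)]
        return cls(runs=runs, blocks=blocks)


def _pink_noise(rng: np.random.Generator, mixing_rng: np.random.Generator,
                n_channels: int, n_samples: int, rms: float) -> np.ndarray:
    """Spatially correlated 1/f noise, per-channel RMS = ``rms``.

    The temporal realization comes from ``rng``; the spatial mixing matrix
    from ``mixing_rng`` so it can stay fixed across a session's runs.
    """
    n_freq = n_samples // 2 + 1
    spectrum = (
        rng.normal(size=(n_channels, n_freq))
        + 1j * rng.normal(size=(n_channels, n_freq))
    )
    freqs = np.arange(n_freq, dtype=float)
    freqs[0] = np.inf  # no DC power
    spectrum /= np.sqrt(freqs)
    sources = np.fft.irfft(spectrum, n=n_samples, axis=1)
    mixing = mixing_rng.normal(size=(n_channels, n_channels)) / np.sqrt(n_channels)
    data = mixing @ sources
    scale = rms / np.maximum(data.std(axis=1, keepdims=True), 1e-30)
    return data * scale


def _blink_map(channel_labels: tuple[str, ...]) -> np.ndarray:
    """Frontal EEG projection of the ocular artifact (unit peak)."""
    m = gaussian_scalp_map("Fp1", sigma_m=0.06, labels=channel_labels)
    m = m + gaussian_scalp_map("Fp2", sigma_m=0.06, labels=channel_labels)
    return m / np.max(np.abs(m))


def simulate_run(
    sequence: StimulusSequence,
    attended_stream: int,
    templates: ERPTemplateSet,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    rate: float = 1000.0,
    channel_labels: tuple[str, ...] = ALL_CHANNELS,
    run_index: int = 0,
) -> RawRecording:
    """Simulate one run's raw EEG/EOG at ``rate`` Hz.

    signal = 1/f spatially correlated noise + evoked components per event
    (see :class:`ERPTemplateSet`) + Poisson-scheduled blink artifacts whose
    EOG excursion lands in [600, 1200] µV and whose frontal-EEG projection
    is ~20% of that, guaranteeing both rejection rules fire.
    """
    if attended_stream not in (1, 2, 3):
        raise ValueError(f"attended_stream must be 1-3, got {attended_stream}")
    unknown = [
        lab for lab in channel_labels
        if lab not in EEG_CHANNELS and "EOG" not in lab.upper()
    ]
    if unknown:
        raise ValueError(f"unknown montage channels: {unknown}")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    n_ch = len(channel_labels)
    n_samples = int(round(sequence.run_duration * rate)) + int(rate)  # 1 s tail pad

    if noise.rms_uV > 0:
        mixing_rng = (np.random.default_rng(noise.mixing_seed)
                      if noise.mixing_seed is not None else rng)
        data = _pink_noise(rng, mixing_rng, n_ch, n_samples, noise.rms_uV)
    else:
        data = np.zeros((n_ch, n_samples))

    # evoked components, per event
    for ev in sequence.events:
        o = ev.onset_sample(rate)
        attended = ev.stream_index == attended_stream
        for comp in templates.components_for(ev.role, attended):
            lat = comp.peak_latency
            if noise.latency_jitter_s > 0:
                lat += rng.normal(scale=noise.latency_jitter_s)
            k0 = max(0, o + int(np.ceil((lat - 4 * comp.sigma) * rate)))
            k1 = min(n_samples, o + int(np.floor((lat + 4 * comp.sigma) * rate)) + 1)
            if k1 <= k0:
                continue
            t = (np.arange(k0, k1) - o) / rate
            data[:, k0:k1] += np.outer(comp.scalp_map, comp.pulse(t, latency=lat))

    # blink artifacts
    if noise.blink_rate_hz > 0:
        ctypes = np.array(channel_types(channel_labels))
        eog_rows = ctypes == "EOG"
        bmap = _blink_map(channel_labels)
        n_blinks = rng.poisson(noise.blink_rate_hz * sequence.run_duration)
        for _ in range(n_blinks):
            start = int(rng.uniform(0, n_samples - int(rate)))
            dur = rng.uniform(0.5, 1.0)
            amp = rng.uniform(600.0, 1200.0)
            n = int(dur * rate)
            pulse = amp * np.sin(2 * np.pi * np.arange(n) / n)  # biphasic
            stop = min(n_samples, start + n)
            seg = pulse[: stop - start]
            data[eog_rows, start:stop] += seg
            data[~eog_rows, start:stop] += 0.2 * np.outer(bmap[~eog_rows], seg)

    events = sequence.to_dataframe(rate=rate)
    events["attended_stream"] = attended_stream
    events["run_index"] = run_index
    return RawRecording(
        data=data,
        rate=rate,
        channel_labels=list(channel_labels),
        channel_types=channel_types(channel_labels),
        events=events,
        metadata={
            "run_index": run_index,
            "attended_stream": attended_stream,
            "seed": seed,
            "soa": sequence.soa,
            "deviant_prob": sequence.deviant_prob,
        },
    )


def simulate_session(
    plan: SessionPlan | None = None,
    templates: ERPTemplateSet | None = None,
    noise: NoiseConfig | None = None,
    *,
    soa: float = 0.18,
    deviant_prob: float = 0.1,
    run_duration: float = 300.0,
    rate: float = 1000.0,
    seed: int = 0,
    min_separation: int = 0,
):
    """Yield one :class:`RawRecording` per planned run (lazily, runs are big).

    Default plan: 2 blocks x 3 runs, attending streams 1, 2, 3 in each block.
    Per-run sequence and noise seeds are derived deterministically from
    ``seed``.
    """
    plan = plan or SessionPlan.default()
    templates = templates or make_erp_templates()
    noise = noise or NoiseConfig()
    seed_rng = np.random.default_rng(seed)
    if noise.mixing_seed is None:
        # one spatial noise-mixing matrix per session, shared by all runs
        noise = dataclasses.replace(
            noise, mixing_seed=int(seed_rng.integers(0, 2**31 - 1))
        )
    sub_seeds = seed_rng.integers(0, 2**31 - 1, size=(len(plan.runs), 2))
    for (run_index, attended), (seq_seed, run_seed) in zip(plan.runs, sub_seeds):
        seq = generate_stimulus_sequence(
            soa=soa,
            deviant_prob=deviant_prob,
            run_duration=run_duration,
            seed=int(seq_seed),
            min_separation=min_separation,
        )
        yield simulate_run(
            seq,
            attended,
            templates,
            noise,
            seed=int(run_seed),
            rate=rate,
            run_index=run_index,
        )
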