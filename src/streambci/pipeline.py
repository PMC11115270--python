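"""End-to-end session pipelines tying the modules together.

``preprocess_session`` turns raw run recordings into the classification-
ready :class:`~streambci.evaluation.PreprocessedSession` (filter, epoch
the deviants, baseline-correct, reject artifacts, accumulate the
continuous signal covariance).  ``decode_session`` runs the three
per-stream cross-validated decoders.  ``simulate_and_decode`` is the
synthetic parameter-recovery experiment used throughout the tests and the
acceptance run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import CVResult, PreprocessedSession, run_stream_cv
from .preprocessing import CLF_BAND, EpochSet, bandpass_filter, extract_epochs, \
    reject_artifacts
from .synthetic_data import ERPTemplateSet, NoiseConfig, SessionPlan, \
    make_erp_templates, simulate_session


def preprocess_session(
    recordings,
    band: tuple[float, float] = CLF_BAND,
    tmin: float = -0.1,
    tmax: float = 0.5,
    baseline: tuple[float, float] | None = (-0.05, 0.0),
    reject: bool = True,
    eeg_threshold: float = 100.0,
    eog_threshold: float = 500.0,
    deviants_only: bool = True,
) -> PreprocessedSession:
    """Filter and epoch a session's runs into one classification-ready set.

    Runs are processed one at a time (recordings may be a generator) and
    concatenated with global sample offsets, so memory stays bounded by a
    single continuous run plus the retained epochs.
    """
    epoch_sets: list[EpochSet] = []
    sigma_sum = None
    n_t = 0
    offset = 0
    for rec in recordings:
        filtered = bandpass_filter(rec, *band)
        eeg = filtered.data[filtered.picks("EEG")]
        sigma = eeg @ eeg.T
        sigma_sum = sigma if sigma_sum is None else sigma_sum + sigma
        n_t += filtered.n_samples

        events = filtered.events
        if deviants_only:
            events = events[events["role"] == "deviant"].reset_index(drop=True)
        es = extract_epochs(
            filtered, events, tmin=tmin, tmax=tmax, baseline=baseline,
            sample_offset=offset, dtype=np.float32,
        )
        if reject:
            es = reject_artifacts(es, eeg_threshold, eog_threshold)
        epoch_sets.append(es)
        offset += filtered.n_samples

    if sigma_sum is None:
        raise ValueError("no recordings given")
    return PreprocessedSession(
        epochs=EpochSet.concatenate(epoch_sets),
        sigma_x=sigma_sum / n_t,
        n_t=n_t,
    )


def decode_session(
    session: PreprocessedSession,
    streams=(1, 2, 3),
    n_folds: int = 10,
    seed: int = 0,
    classifier: str = "logreg",
    n_components: int = 3,
) -> dict[int, CVResult]:
    """Cross-validated attention decoding for each requested stream."""
    return {
        s: run_stream_cv(
            session, s, n_folds=n_folds, seed=seed, classifier=classifier,
            n_components=n_components,
        )
        for s in streams
    }


@dataclass
class SyntheticStudyConfig:
    """Conditions of the synthetic parameter-recovery experiment.

    Defaults mirror the study paradigm: 2 blocks x 3 runs of 300 s at
    SOA 0.18 s, deviant probability 0.1, 1000 Hz, P3b +5 µV / MMN −2 µV /
    P3a +2 µV templates over 10 µV RMS pink noise.
    """

    blocks: int = 2
    run_duration: float = 300.0
    soa: float = 0.18
    deviant_prob: float = 0.1
    rate: float = 1000.0
    p3b_uv: float | None = None  # None = template default (+5)
    p3a_uv: float | None = None
    mmn_uv: float | None = None
    n1_uv: float | None = None
    noise: NoiseConfig | None = None

    def templates(self) -> ERPTemplateSet:
        t = make_erp_templates()
        amps = {}
        for name, val in (("P3b", self.p3b_uv), ("P3a", self.p3a_uv),
                          ("MMN", self.mmn_uv), ("N1", self.n1_uv)):
            if val is not None:
                amps[name] = val
        return t.with_amplitudes(**amps) if amps else t


def simulate_and_decode(
    seed: int,
    config: SyntheticStudyConfig | None = None,
    streams=(1, 2, 3),
    n_folds: int = 10,
    classifier: str = "logreg",
) -> dict[int, CVResult]:
    """Simulate one synthetic session and decode it; one call per 'subject'."""
    config = config or SyntheticStudyConfig()
    recs = simulate_session(
        SessionPlan.default(blocks=config.blocks),
        config.templates(),
        config.noise or NoiseConfig(),
        soa=config.soa,
        deviant_prob=config.deviant_prob,
        run_duration=config.run_duration,
        rate=config.rate,
        seed=seed,
    )
    session = preprocess_session(recs)
    return decode_session(
        session, streams=streams, n_folds=n_folds, seed=seed,
        classifier=classifier,
    )
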