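"""Stimulus sequences, ERP templates and the raw-EEG simulator."""

import numpy as np
import pytest
from scipy import stats

from streambci.montage import ALL_CHANNELS, EEG_CHANNELS
from streambci.preprocessing import extract_epochs, reject_artifacts
from streambci.synthetic_data import (
    TONE_TABLE,
    NoiseConfig,
    SessionPlan,
    classification_intervals,
    generate_stimulus_sequence,
    make_erp_templates,
    simulate_run,
    simulate_session,
)


class TestStimulusSequence:
    def test_tone_table_frequencies(self):
        assert TONE_TABLE[(1, "standard")].frequency_hz == 131.0
        assert TONE_TABLE[(1, "deviant")].frequency_hz == 196.0
        assert TONE_TABLE[(3, "deviant")].frequency_hz == 3951.0
        # each (stream, role) slot maps to exactly one tone
        assert len(TONE_TABLE) == 6

    def test_five_minute_run_counts(self):
        seq = generate_stimulus_sequence(soa=0.18, run_duration=300.0, seed=0)
        assert len(seq) == 1667  # ceil(300 / 0.18) events cover [0, 300)
        for stream in (1, 2, 3):
            n_stream = sum(e.stream_index == stream for e in seq.events)
            assert 550 <= n_stream <= 560
            frac = seq.onsets(stream=stream, role="deviant").size / n_stream
            # binomial error band around the deviant probability
            se = np.sqrt(0.1 * 0.9 / n_stream)
            assert abs(frac - 0.1) < 4 * se

    def test_within_stream_cycle_is_three_soas(self):
        seq = generate_stimulus_sequence(soa=0.18, run_duration=30.0, seed=1)
        for stream in (1, 2, 3):
            onsets = seq.onsets(stream=stream)
            assert np.allclose(np.diff(onsets), 0.54)

    def test_events_sorted_and_cyclic(self):
        seq = generate_stimulus_sequence(run_duration=10.0, seed=2)
        onsets = [e.onset for e in seq.events]
        assert onsets == sorted(onsets)
        streams = [e.stream_index for e in seq.events]
        assert streams[:6] == [1, 2, 3, 1, 2, 3]

    @pytest.mark.parametrize("bad", [0.0, 0.5, -0.1, 0.9])
    def test_degenerate_deviant_prob_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_stimulus_sequence(deviant_prob=bad)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_stimulus_sequence(run_duration=0.0)

    def test_reproducible_given_seed(self):
        a = generate_stimulus_sequence(run_duration=60.0, seed=5)
        b = generate_stimulus_sequence(run_duration=60.0, seed=5)
        assert [e.role for e in a.events] == [e.role for e in b.events]

    def test_min_separation_enforced(self):
        seq = generate_stimulus_sequence(
            run_duration=300.0, seed=3, min_separation=2
        )
        for stream in (1, 2, 3):
            dev = seq.onsets(stream=stream, role="deviant")
            # >= 2 standards between deviants -> gaps of >= 3 cycles
            assert np.diff(dev).min() >= 3 * 0.54 - 1e-9

    def test_deviant_counts_follow_binomial(self):
        """Chi-square goodness of fit of per-stream deviant counts.

        With the minimum-separation rule disabled, each stream's deviant
        count over a run is Binomial(n_cycles, p); pooled over 200 seeded
        sequences the histogram must be consistent with that law.
        """
        p = 0.1
        counts = []
        n_cycles = None
        for seed in range(200):
            seq = generate_stimulus_sequence(
                soa=0.18, deviant_prob=p, run_duration=54.0, seed=seed
            )
            for stream in (1, 2, 3):
                n_cycles = sum(e.stream_index == stream for e in seq.events)
                counts.append(seq.onsets(stream=stream, role="deviant").size)
        counts = np.array(counts)
        dist = stats.binom(n_cycles, p)
        # bin the support so every expected count is >= 5
        lo, hi = dist.ppf(0.001), dist.ppf(0.999)
        edges = np.arange(lo, hi + 1)
        expected = dist.pmf(edges) * counts.size
        observed = np.array([(counts == k).sum() for k in edges])
        # collapse tails
        observed = np.r_[counts[counts < lo].size + observed[0],
                         observed[1:-1],
                         counts[counts > hi].size + observed[-1]]
        expected = np.r_[dist.cdf(lo) * counts.size,
                         expected[1:-1],
                         dist.sf(hi - 1) * counts.size]
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.001

    def test_classification_intervals_reported_not_assumed(self):
        seq = generate_stimulus_sequence(run_duration=300.0, seed=9)
        iv = classification_intervals(seq)
        assert iv.size > 10
        assert (iv > 0).all()
        # minimum possible interval: one deviant per stream in one cycle
        assert iv.min() >= 3 * 0.18 - 1e-9


class TestErpTemplates:
    def test_default_p3b_peaks_parietal_midline(self, templates):
        peak = ALL_CHANNELS[int(np.argmax(templates["P3b"].scalp_map))]
        assert peak in ("Pz", "POz", "CPz", "P1", "P2")

    def test_component_polarities_and_maps(self, templates):
        assert templates["MMN"].peak_amplitude < 0
        frontal_peak = ALL_CHANNELS[int(np.argmax(np.abs(templates["P3a"].scalp_map)))]
        assert frontal_peak.startswith(("F", "AF"))
        for comp in templates.components.values():
            assert np.isclose(np.max(np.abs(comp.scalp_map)), 1.0)

    def test_zero_p3b_leaves_only_mmn_p3a_difference(self, templates):
        t = templates.with_amplitudes(P3b=0.0)
        att = t.expected_epoch("deviant", attended=True)
        non = t.expected_epoch("deviant", attended=False)
        mmn = np.outer(t["MMN"].scalp_map,
                       t["MMN"].pulse(np.arange(-100, 500) / 1000.0))
        p3a = np.outer(t["P3a"].scalp_map,
                       t["P3a"].pulse(np.arange(-100, 500) / 1000.0))
        assert np.allclose(att - non, mmn - p3a, atol=1e-12)

    def test_latency_beyond_epoch_rejected(self):
        with pytest.raises(ValueError):
            make_erp_templates({"P3b": {"latency": 0.9}})


class TestSimulateRun:
    def test_noiseless_attended_average_equals_template_sum(self):
        """With noise, jitter, N1 and P3a off, the attended-deviant epoch
        average reproduces the injected P3b + MMN template exactly."""
        templates = make_erp_templates().with_amplitudes(N1=0.0, P3a=0.0)
        seq = generate_stimulus_sequence(
            run_duration=60.0, seed=4, min_separation=2
        )
        rec = simulate_run(
            seq, attended_stream=1, templates=templates,
            noise=NoiseConfig(rms_uV=0.0, blink_rate_hz=0.0, latency_jitter_s=0.0),
            seed=0,
        )
        epochs = extract_epochs(rec)
        att = epochs.select(stream=1, role="deviant", attended=True)
        assert len(att) > 0
        expected = templates.expected_epoch("deviant", attended=True)
        assert np.allclose(att.data.mean(axis=0), expected, atol=1e-9)

    def test_blink_rate_zero_rejects_nothing(self, templates):
        seq = generate_stimulus_sequence(run_duration=20.0, seed=5)
        rec = simulate_run(
            seq, 1, templates,
            NoiseConfig(rms_uV=5.0, blink_rate_hz=0.0), seed=1,
        )
        epochs = reject_artifacts(extract_epochs(rec))
        assert epochs.n_rejected == 0

    def test_blinks_trip_both_rejection_rules(self, templates):
        seq = generate_stimulus_sequence(run_duration=60.0, seed=6)
        rec = simulate_run(
            seq, 1, templates,
            NoiseConfig(rms_uV=0.0, blink_rate_hz=0.5, latency_jitter_s=0.0),
            seed=2,
        )
        eog = rec.data[rec.picks("EOG")]
        frontal = rec.data[rec.channel_labels.index("Fp1")]
        assert np.abs(eog).max() > 500.0
        assert np.abs(frontal).max() > 100.0

    def test_seeding_contract(self, templates):
        seq = generate_stimulus_sequence(run_duration=10.0, seed=7)
        a = simulate_run(seq, 2, templates, NoiseConfig(), seed=10)
        b = simulate_run(seq, 2, templates, NoiseConfig(), seed=11)
        c = simulate_run(seq, 2, templates, NoiseConfig(), seed=10)
        assert not np.allclose(a.data, b.data)
        assert np.array_equal(a.data, c.data)
        assert a.events.equals(b.events)

    def test_unknown_montage_rejected(self, templates):
        seq = generate_stimulus_sequence(run_duration=5.0, seed=8)
        with pytest.raises(ValueError, match="unknown montage"):
            simulate_run(seq, 1, templates,
                         channel_labels=("NotAChannel", "Cz"))

    def test_invalid_attended_stream_rejected(self, templates):
        seq = generate_stimulus_sequence(run_duration=5.0, seed=8)
        with pytest.raises(ValueError):
            simulate_run(seq, 4, templates)


class TestSessionPlan:
    def test_default_plan_cycles_streams_over_two_blocks(self):
        plan = SessionPlan.default()
        assert [att for _, att in plan.runs] == [1, 2, 3, 1, 2, 3]

    def test_one_block_three_runs(self):
        assert len(SessionPlan.default(blocks=1).runs) == 3

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            SessionPlan(runs=[])
        with pytest.raises(ValueError):
            SessionPlan(runs=[(0, 4)])

    def test_session_generates_one_recording_per_run(self, templates):
        recs = list(simulate_session(
            SessionPlan.default(blocks=1), templates, NoiseConfig(),
            run_duration=5.0, seed=0,
        ))
        assert len(recs) == 3
        assert [r.metadata["attended_stream"] for r in recs] == [1, 2, 3]
        assert all(len(r.channel_labels) == 66 for r in recs)
        assert all(r.channel_types.count("EOG") == 2 for r in recs)


def test_default_montage_has_64_eeg_channels():
    assert len(EEG_CHANNELS) == 64
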