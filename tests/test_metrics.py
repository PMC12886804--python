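"""EMG preprocessing chain and per-phase scalar metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal

from hapticlab.cohort import FS_EMG
from hapticlab.metrics import (
    EnvelopeRecording,
    compute_cci,
    compute_rom,
    compute_sparc,
    descriptives,
    preprocess_emg,
    pronation_angle,
    segment_phases,
    time_to_bounded_error,
)


class TestPreprocess:
    def test_zero_in_zero_out(self):
        env = preprocess_emg(np.zeros((5000, 3)), 1.0)
        assert np.allclose(env.envelopes, 0.0)

    def test_rectified_sine_envelope_level(self):
        """A full-scale in-band tone yields an envelope near 2/pi."""
        t = np.arange(0, 4, 1 / FS_EMG)
        env = preprocess_emg(np.sin(2 * np.pi * 100 * t), 1.0).envelopes[:, 0]
        assert np.mean(env[2000:-2000]) == pytest.approx(2 / np.pi, rel=0.02)

    def test_out_of_band_attenuation(self):
        """10 Hz (below band) is attenuated > 20 dB relative to 100 Hz."""
        t = np.arange(0, 4, 1 / FS_EMG)
        e100 = preprocess_emg(np.sin(2 * np.pi * 100 * t), 1.0).envelopes[:, 0]
        e10 = preprocess_emg(np.sin(2 * np.pi * 10 * t), 1.0).envelopes[:, 0]
        ratio = np.mean(e10[2000:-2000]) / np.mean(e100[2000:-2000])
        assert ratio < 0.1

    def test_zero_phase_no_lag(self):
        """The envelope of a tone burst is not delayed (zero-phase filters)."""
        t = np.arange(0, 4, 1 / FS_EMG)
        gauss = np.exp(-0.5 * ((t - 2) / 0.15) ** 2)
        burst = gauss * np.sin(2 * np.pi * 100 * t)
        env = preprocess_emg(burst, 1.0).envelopes[:, 0]
        xc = signal.correlate(env - env.mean(), gauss - gauss.mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(t) - 1)
        assert abs(lag) <= 1

    def test_median_removes_artifact_spike(self):
        t = np.arange(0, 4, 1 / FS_EMG)
        tone = 0.02 * np.sin(2 * np.pi * 100 * t)
        spiked = tone.copy()
        i0 = len(t) // 2
        spiked[i0 : i0 + 11] += 5.0  # 5 ms artifact, 250x the signal
        clean = preprocess_emg(tone, 1.0).envelopes[:, 0]
        dirty = preprocess_emg(spiked, 1.0).envelopes[:, 0]
        assert np.max(np.abs(dirty - clean)) < 0.25 * np.mean(clean[2000:-2000])

    def test_mvc_validation(self):
        with pytest.raises(ValueError):
            preprocess_emg(np.zeros((1000, 2)), [1.0, -1.0])


class TestSegmentation:
    def test_direct_event_mapping(self):
        table = segment_phases(
            [dict(grab=0.0, over_cauldron=2.0, pour_start=4.0,
                  pour_stop=6.0, release=8.0)]
        )
        assert table.repetitions[0] == (
            (0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 13.0)
        )

    def test_rate_conversion_arithmetic(self):
        table = segment_phases(
            [dict(grab=0.0, over_cauldron=2.0, pour_start=4.0,
                  pour_stop=6.0, release=8.0)]
        )
        intervals = table.sample_intervals(2148.1)[0]
        assert intervals[1][0] == 4296  # round(2.0 * 2148.1)

    def test_out_of_order_events_excluded(self):
        table = segment_phases(
            [
                dict(grab=0.0, over_cauldron=2.0, pour_start=6.0,
                     pour_stop=4.0, release=8.0),
                dict(grab=10.0, over_cauldron=12.0, pour_start=14.0,
                     pour_stop=16.0, release=18.0),
            ]
        )
        assert table.excluded == [0] and len(table.repetitions) == 1

    def test_missing_event_excluded(self):
        table = segment_phases([dict(grab=0.0, release=8.0)])
        assert table.excluded == [0] and not table.repetitions


class TestRom:
    def test_examples(self):
        assert compute_rom([10.0, 30.0, 25.0]) == pytest.approx(20.0)
        assert compute_rom(np.full(50, 7.0)) == 0.0

    def test_sine_peak_to_peak(self):
        t = np.linspace(0, 2, 2000)
        assert compute_rom(5 * np.sin(2 * np.pi * t)) == pytest.approx(10.0, abs=1e-3)

    @given(offset=st.floats(-100, 100))
    def test_translation_invariance(self, offset):
        trace = np.array([1.0, 4.0, 2.0, 6.0])
        assert compute_rom(trace + offset) == pytest.approx(compute_rom(trace))

    def test_empty_interval(self):
        with pytest.raises(ValueError):
            compute_rom(np.arange(10.0), (5, 5))


class TestSparc:
    fs = 100.0

    def _gauss(self, center, width=0.2):
        t = np.arange(0, 3, 1 / self.fs)
        return np.exp(-0.5 * ((t - center) / width) ** 2)

    def test_amplitude_invariance(self):
        v = self._gauss(1.0)
        assert compute_sparc(2 * v, self.fs) == compute_sparc(v, self.fs)

    def test_time_reversal_invariance(self):
        v = self._gauss(1.0)
        assert compute_sparc(v[::-1], self.fs) == pytest.approx(
            compute_sparc(v, self.fs), abs=1e-9
        )

    def test_single_peak_smoother_than_double(self):
        single = self._gauss(1.0)
        double = single + 0.8 * self._gauss(2.0)
        assert compute_sparc(single, self.fs) > compute_sparc(double, self.fs)

    def test_monotone_degradation(self):
        single = self._gauss(1.0)
        values = [
            compute_sparc(single + a * self._gauss(2.0), self.fs)
            for a in (0.1, 0.2, 0.3, 0.5, 0.7)
        ]
        assert all(np.diff(values) < 0)

    def test_all_zero_signalled(self):
        with pytest.raises(ValueError):
            compute_sparc(np.zeros(100), self.fs)


class TestCci:
    def test_identical_envelopes(self):
        assert compute_cci(np.ones(100), np.ones(100)) == pytest.approx(100.0)

    def test_disjoint_activation(self):
        a = np.r_[np.ones(50), np.zeros(50)]
        assert compute_cci(a, a[::-1]) == 0.0

    def test_direct_evaluation(self):
        assert compute_cci(np.ones(10), np.full(10, 0.5)) == pytest.approx(200 / 3)

    def test_symmetry(self, rng):
        a, b = rng.random(200), rng.random(200)
        assert compute_cci(a, b) == pytest.approx(compute_cci(b, a))

    def test_bounds_random(self, rng):
        for _ in range(50):
            a, b = rng.random(100), rng.random(100)
            assert 0.0 <= compute_cci(a, b) <= 100.0

    def test_both_zero_signalled(self):
        with pytest.raises(ValueError):
            compute_cci(np.zeros(10), np.zeros(10))

    def test_rudolph_variant_bounded(self, rng):
        a, b = rng.random(100), rng.random(100)
        assert 0.0 <= compute_cci(a, b, variant="rudolph") <= 100.0


class TestPronationAngle:
    def test_reference_cases(self):
        assert pronation_angle((0, 0, 2.0)) == pytest.approx(0.0)
        assert pronation_angle((1.0, 0, 0)) == pytest.approx(90.0)
        assert pronation_angle((0, 2**-0.5, 2**-0.5)) == pytest.approx(45.0)

    def test_zero_vector(self):
        with pytest.raises(ValueError):
            pronation_angle((0.0, 0.0, 0.0))


class TestAggregation:
    def test_ci_halfwidth_t_interval(self):
        import pandas as pd

        metrics = pd.DataFrame(
            {
                "subject": [1, 2, 3],
                "condition": "GV",
                "phase": 3,
                "metric": "pose_mean",
                "channel": "grasp_ratio",
                "value": [1.0, 2.0, 3.0],
            }
        )
        desc = descriptives(metrics)
        half = (desc["ci_high"] - desc["ci_low"]).iloc[0] / 2
        assert half == pytest.approx(4.303 * 1.0 / np.sqrt(3), abs=1e-3)

    def test_single_and_mean_aggregation(self):
        import pandas as pd
        from hapticlab.metrics import aggregate_metrics

        row = dict(subject=1, condition="GC", phase=1, metric="emg_rms",
                   channel="BIC")
        f1 = pd.DataFrame([{**row, "trial": 1, "value": 1.0}])
        f2 = pd.DataFrame([{**row, "trial": 2, "value": 3.0}])
        assert aggregate_metrics([f1])["value"].iloc[0] == 1.0
        assert aggregate_metrics([f1, f2])["value"].iloc[0] == 2.0


class TestSettleTime:
    def test_settles_at_last_excursion(self):
        t = np.arange(0, 10, 0.01)
        err = np.exp(-t)
        tau = time_to_bounded_error(t, err, 0.1)
        assert tau == pytest.approx(-np.log(0.1), abs=0.02)

    def test_never_settles(self):
        t = np.arange(0, 5, 0.01)
        assert np.isnan(time_to_bounded_error(t, np.ones_like(t), 0.1))


def test_envelope_recording_validation():
    with pytest.raises(ValueError):
        EnvelopeRecording(-np.ones((10, 2)), 100.0)
    with pytest.raises(ValueError):
        EnvelopeRecording(np.ones((10, 2)), -1.0)
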