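"""Filtering, resampling, epoching, rejection and condition arithmetic."""

import numpy as np
import pandas as pd
import pytest

from roving_aep.io import Recording
from roving_aep.paradigm import ParadigmConfig, build_paradigm
from roving_aep.preprocess import (
    average_epochs,
    bandpass,
    epoch,
    notch_power_line,
    reject_epochs,
    resample,
    rs_pseudo_onsets,
    select_condition,
)


def sine_recording(freq_hz: float, fs: float = 5000.0, dur: float = 10.0) -> Recording:
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq_hz * t)
    return Recording(data=np.vstack([x, x]), sample_rate_hz=fs)


def steady_amplitude(x: np.ndarray) -> float:
    core = x[len(x) // 4 : -len(x) // 4]  # ignore filter edge transients
    return np.abs(core).max()


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = bandpass(sine_recording(40.0), (25.0, 55.0), order=2)
        assert steady_amplitude(out.data[0]) == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated_20db(self):
        out = bandpass(sine_recording(220.0), (25.0, 55.0), order=2)
        assert steady_amplitude(out.data[0]) < 0.1  # ≥ 20 dB down

    def test_zero_in_zero_out(self):
        rec = Recording(data=np.zeros((2, 1000)), sample_rate_hz=1000.0)
        out = bandpass(rec, (2.0, 20.0))
        assert not out.data.any()

    def test_band_reaching_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sine_recording(40.0, fs=1000.0), (2.0, 500.0))


class TestNotch:
    def test_line_frequency_attenuated(self):
        out = notch_power_line(sine_recording(60.0), 60.0, up_to_hz=300.0)
        assert steady_amplitude(out.data[0]) < 0.1

    def test_neighbouring_tone_preserved(self):
        out = notch_power_line(sine_recording(40.0), 60.0, up_to_hz=300.0)
        assert steady_amplitude(out.data[0]) == pytest.approx(1.0, rel=0.05)

    def test_no_harmonics_in_range_is_identity(self):
        rec = sine_recording(10.0, fs=1000.0, dur=2.0)
        out = notch_power_line(rec, 60.0, up_to_hz=50.0)
        np.testing.assert_array_equal(out.data, rec.data)


class TestResample:
    def test_slow_tone_amplitude_preserved(self):
        rec = sine_recording(10.0, fs=5000.0, dur=10.0)
        out = resample(rec, 250.0)
        assert out.sample_rate_hz == 250.0
        assert steady_amplitude(out.data[0]) == pytest.approx(1.0, rel=0.01)

    def test_identity_at_same_rate(self):
        rec = sine_recording(10.0, fs=1000.0, dur=1.0)
        out = resample(rec, 1000.0)
        np.testing.assert_allclose(out.data, rec.data)

    def test_event_remapping(self):
        rec = sine_recording(10.0, fs=5000.0, dur=4.0)
        rec.events = np.array([[10000, 1]])  # t = 2.000 s
        out = resample(rec, 250.0)
        assert out.events[0, 0] == 500

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            resample(sine_recording(10.0, fs=250.0, dur=1.0), 500.0)


class TestEpoching:
    def test_baseline_removes_constant(self):
        rec = Recording(data=np.full((2, 1000), 5.0), sample_rate_hz=100.0)
        es = epoch(rec, [2.0, 5.0], (-0.1, 0.45), baseline_s=(-0.1, 0.0))
        assert np.allclose(es.data, 0.0)

    def test_one_epoch_per_trial(self):
        sched = build_paradigm(rng_seed=0, config=ParadigmConfig(n_blocks=1))
        rec = Recording(
            data=np.zeros((2, int(186 * 100))), sample_rate_hz=100.0
        )
        es = epoch(rec, sched.trials["onset_s"], (-0.1, 0.45), (-0.1, 0.0))
        assert es.n_epochs == 150
        assert len({e.shape for e in es.data}) == 1

    def test_150s_block_gives_10_slow_segments(self):
        from roving_aep.pipeline import slow_epoch_onsets

        sched = build_paradigm(rng_seed=0, config=ParadigmConfig(n_blocks=1))
        onsets = slow_epoch_onsets(sched, 15.0)
        assert len(onsets) == 10

    def test_edge_epochs_dropped(self):
        rec = Recording(data=np.zeros((2, 500)), sample_rate_hz=100.0)
        es = epoch(rec, [0.0, 2.0, 10.0], (-0.1, 0.45))
        assert es.n_epochs == 1  # only the t=2 s epoch fits

    def test_all_outside_is_error(self):
        rec = Recording(data=np.zeros((2, 100)), sample_rate_hz=100.0)
        with pytest.raises(ValueError, match="no epoch"):
            epoch(rec, [50.0], (-0.1, 0.45))


class TestRejection:
    def make_set(self):
        sched = build_paradigm(rng_seed=1, config=ParadigmConfig(n_blocks=1, trials_per_block=30))
        rec = Recording(data=np.zeros((2, 66 * 100)), sample_rate_hz=100.0)
        return epoch(
            rec, sched.trials["onset_s"], (-0.1, 0.45),
            info=sched.trials.assign(is_rs=False),
        )

    def test_clean_epochs_kept(self):
        es = reject_epochs(self.make_set(), 150.0)
        assert es.rejected.sum() == 0

    def test_spiking_epoch_rejected(self):
        es = self.make_set()
        es.data[7, 0, 3] = 200.0
        out = reject_epochs(es, 150.0)
        assert out.rejected[7]
        assert out.rejected.sum() == 1

    def test_mask_only_grows(self):
        es = self.make_set()
        es.rejected[3] = True
        out = reject_epochs(es, 150.0)
        assert out.rejected[3]

    def test_rejection_commutes_with_selection(self):
        es = self.make_set()
        es.data[5, 1, 0] = 300.0
        a = select_condition(reject_epochs(es, 150.0), "NONDEVIANT_LOW")
        b = reject_epochs(es, 150.0)
        b = select_condition(b, "NONDEVIANT_LOW")
        np.testing.assert_array_equal(a.data, b.data)


@pytest.fixture(scope="module")
def block_set():
    sched = build_paradigm(rng_seed=3, config=ParadigmConfig(n_blocks=1))
    rec = Recording(data=np.zeros((2, 188 * 100)), sample_rate_hz=100.0)
    return epoch(
        rec, sched.trials["onset_s"], (-0.1, 0.45),
        info=sched.trials.assign(is_rs=False),
    )


class TestConditionSelection:

    def test_nondeviant_low_count_59(self, block_set):
        # low-start block: 75 low trials − 15 descending deviants − 1 unlabeled
        assert select_condition(block_set, "NONDEVIANT_LOW").n_epochs == 59

    def test_deviant_counts_15_per_direction(self, block_set):
        assert select_condition(block_set, "DEVIANT_ASC").n_epochs == 15
        assert select_condition(block_set, "DEVIANT_DESC").n_epochs == 15

    def test_standard_pairing_direction(self, block_set):
        asc = select_condition(block_set, "STANDARD_ASC")
        assert (asc.info["tone"] == "low").all()
        assert asc.n_epochs == 15

    def test_rs_empty_with_warning(self, block_set, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = select_condition(block_set, "RS")
        assert out.n_epochs == 0
        assert "resting-state" in caplog.text

    def test_unknown_condition_rejected(self, block_set):
        with pytest.raises(ValueError, match="unknown condition"):
            select_condition(block_set, "SOMETHING")


class TestAveraging:
    def test_single_epoch_is_itself(self):
        es_data = np.random.default_rng(0).normal(size=(1, 2, 10))
        from roving_aep.preprocess import EpochSet

        es = EpochSet(
            data=es_data, sample_rate_hz=100.0, window_s=(0, 0.1),
            baseline_s=None, info=pd.DataFrame(index=[0]),
        )
        np.testing.assert_array_equal(average_epochs(es), es_data[0])

    def test_opposite_epochs_cancel(self):
        from roving_aep.preprocess import EpochSet

        x = np.random.default_rng(1).normal(size=(2, 10))
        es = EpochSet(
            data=np.stack([x, -x]), sample_rate_hz=100.0, window_s=(0, 0.1),
            baseline_s=None, info=pd.DataFrame(index=[0, 1]),
        )
        assert np.allclose(average_epochs(es), 0.0)

    def test_zero_accepted_is_error(self):
        from roving_aep.preprocess import EpochSet

        es = EpochSet(
            data=np.zeros((2, 2, 5)), sample_rate_hz=100.0, window_s=(0, 0.05),
            baseline_s=None, info=pd.DataFrame(index=[0, 1]),
            rejected=np.array([True, True]),
        )
        with pytest.raises(ValueError, match="no accepted"):
            average_epochs(es)


class TestRsPseudoOnsets:
    def test_windows_fit_in_rest(self):
        sched = build_paradigm(rng_seed=0, config=ParadigmConfig(n_blocks=3))
        tbl = rs_pseudo_onsets(sched, 59, (-0.1, 0.9))
        assert len(tbl) == 3 * 59
        for _, row in tbl.iterrows():
            _, stim_end, rest_end = sched.blocks[row["block"]]
            assert row["onset_s"] - 0.1 >= stim_end - 1e-9
            assert row["onset_s"] + 0.9 <= rest_end + 1e-9
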