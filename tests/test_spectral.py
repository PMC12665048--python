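"""Zero-padded PSD, normalized increments, TFCE cluster and band detection."""

import numpy as np
import pytest

from conftest import brute_force_psd, exhaustive_sign_flip_pvals
from roving_aep.spectral import (
    BandSpec,
    COMPONENT_BANDS,
    Spectrum,
    compute_psd,
    group_cluster_test,
    individual_band_detection,
    normalize_psd,
    psd_increment,
)


class TestComputePsd:
    def test_single_tone_peaks_at_its_bin(self):
        fs = 5000.0
        t = np.arange(int(0.45 * fs)) / fs
        spec = compute_psd(np.sin(2 * np.pi * 40.0 * t), fs, 0.25)
        assert spec.freqs_hz[np.argmax(spec.power[0])] == pytest.approx(40.0)
        assert spec.resolution_hz == pytest.approx(0.25)

    def test_zero_series_zero_power(self):
        spec = compute_psd(np.zeros(100), 1000.0, 0.25)
        assert not spec.power.any()
        assert spec.freqs_hz[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_dft(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        x = rng.normal(size=n)
        fs = 1000.0
        spec = compute_psd(x, fs, fs / 2048)
        oracle = brute_force_psd(x, 2048)
        np.testing.assert_allclose(spec.power[0], oracle, rtol=1e-8, atol=1e-10)

    def test_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="coarser"):
            compute_psd(np.zeros(1000), 1000.0, 2.0)

    def test_window_cropping(self):
        fs = 1000.0
        times = -0.1 + np.arange(550) / fs
        x = np.ones(550)
        spec = compute_psd(x, fs, 0.25, times=times, window_s=(0.0, 0.45))
        # power at DC equals (window length in samples)^2
        assert spec.power[0, 0] == pytest.approx(450.0**2)


class TestNormalize:
    def grid(self, n=101, res=0.25, start=25.0):
        return start + np.arange(n) * res

    def test_single_nonzero_bin(self):
        f = self.grid()
        p = np.zeros_like(f)
        p[40] = 7.0
        out = normalize_psd(Spectrum(f, p, 0.25), (25.0, 50.0))
        assert out.power[0, 40] == 1.0

    def test_uniform_power(self):
        f = self.grid()
        out = normalize_psd(Spectrum(f, np.ones_like(f), 0.25), (25.0, 50.0))
        np.testing.assert_allclose(out.power, 1.0 / out.freqs_hz.size)

    def test_unit_sum_identity(self):
        rng = np.random.default_rng(0)
        f = self.grid()
        out = normalize_psd(Spectrum(f, rng.random(f.size), 0.25), (30.0, 45.0))
        assert out.power.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.freqs_hz.min() >= 30.0 and out.freqs_hz.max() <= 45.0

    def test_zero_in_band_rejected(self):
        f = self.grid()
        with pytest.raises(ValueError, match="degenerate"):
            normalize_psd(Spectrum(f, np.zeros_like(f), 0.25), (25.0, 50.0))


class TestIncrement:
    def make(self, p):
        f = 25.0 + np.arange(len(p)) * 0.25
        return Spectrum(f, np.asarray(p, float), 0.25)

    def test_equal_spectra_degenerate(self):
        s = self.make(np.ones(50))
        with pytest.raises(ValueError, match="degenerate"):
            psd_increment(s, self.make(np.ones(50)))

    def test_single_elevated_bin(self):
        base = np.ones(50)
        stim = base.copy()
        stim[10] += 3.0
        out = psd_increment(self.make(stim), self.make(base))
        assert out.power[0, 10] == pytest.approx(1.0)

    def test_nonnegative_unit_sum(self):
        rng = np.random.default_rng(1)
        out = psd_increment(self.make(rng.random(60) + 1), self.make(rng.random(60) + 1))
        assert (out.power >= 0).all()
        assert out.power.sum() == pytest.approx(1.0, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self.make(np.ones(50))
        b = Spectrum(np.arange(50) * 0.5, np.ones(50) * 2, 0.5)
        with pytest.raises(ValueError, match="grid"):
            psd_increment(a, b)


def _increment_spectrum(values, start=25.0, res=0.25):
    f = start + np.arange(len(values)) * res
    v = np.clip(np.asarray(values, float), 0, None)
    v = v / v.sum()
    return Spectrum(f, np.vstack([v, v]), res, normalization="total-power-in-band")


class TestIndividualDetection:
    band40 = COMPONENT_BANDS["assr_40hz"]

    def test_flat_spectrum_not_detected(self):
        # strictly exchangeable bins: every permutation statistic ties
        spec = _increment_spectrum(np.ones(121))
        det = individual_band_detection(spec, self.band40, rng_seed=0)
        assert not det.detected

    def test_plateau_at_center_detected(self):
        vals = np.ones(121)
        center = np.argmin(np.abs(25.0 + np.arange(121) * 0.25 - 40.0))
        vals[center - 2 : center + 3] = 10.0
        det = individual_band_detection(_increment_spectrum(vals), self.band40, rng_seed=0)
        assert det.detected
        assert det.run_length >= 3

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.random(121)
        a = individual_band_detection(_increment_spectrum(vals), self.band40, rng_seed=5)
        b = individual_band_detection(_increment_spectrum(vals * 40), self.band40, rng_seed=5)
        assert a.detected == b.detected
        np.testing.assert_allclose(
            a.bin_pvalues[40.0], b.bin_pvalues[40.0]
        )

    def test_sideband_alone_counts_for_component(self):
        """A 260-Hz-only response still detects the low-tone FFR component."""
        band = COMPONENT_BANDS["ffr_220hz"]
        n = 321  # 200–280 Hz at 0.25 Hz
        vals = np.ones(n)
        f = 200.0 + np.arange(n) * 0.25
        vals[np.abs(f - 260.0) <= 0.5] = 20.0
        det = individual_band_detection(
            _increment_spectrum(vals, start=200.0), band, rng_seed=0
        )
        assert det.detected
        assert (det.bin_pvalues[220.0] >= 0.05).all()  # carrier window silent

    def test_window_shorter_than_min_run_rejected(self):
        spec = _increment_spectrum(np.ones(121))
        bad = BandSpec("x", (40.0,), 0.2, (25.0, 55.0))  # 2-bin window
        with pytest.raises(ValueError, match="min_run"):
            individual_band_detection(spec, bad, rng_seed=0)

    def test_false_positive_rate_on_white_noise(self):
        """Exchangeable white-noise increments rarely trigger the run rule."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            spec = _increment_spectrum(rng.random(121))
            det = individual_band_detection(spec, self.band40, rng_seed=seed)
            hits += int(det.detected)
        assert hits / 50 <= 0.10


class TestGroupClusterTest:
    def test_null_differences_no_clusters(self):
        X = np.zeros((8, 2, 20))
        res = group_cluster_test(X, np.arange(20), tail=1, n_permutations=200, seed=0)
        assert res.clusters == []

    def test_known_support_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2, 40))
        X[:, :, 10:21] += 2.0
        res = group_cluster_test(X, np.arange(40), tail=1, n_permutations=500, seed=0)
        assert res.significant
        onset = min(c["onset"] for c in res.clusters)
        offset = max(c["offset"] for c in res.clusters)
        assert 9 <= onset <= 11
        assert 19 <= offset <= 21
        table = res.to_frame()
        assert list(table.columns) == ["onset", "offset", "peak_stat", "p_cluster"]
        assert (table["p_cluster"] < 0.05).all()

    def test_matches_exhaustive_sign_flip_enumeration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2, 6))
        X[:, :, 2:4] += 1.5
        res = group_cluster_test(
            X, np.arange(6), tail=1, n_permutations=64, seed=0
        )
        oracle = exhaustive_sign_flip_pvals(X, step=0.1)
        # both tests are exact over the same 64 sign patterns; allow two
        # enumeration steps for TFCE threshold-discretization edge effects
        assert np.max(np.abs(res.p_map - oracle)) <= 2 / 64 + 1e-12

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            group_cluster_test(np.zeros((1, 2, 5)), np.arange(5))

    def test_type_i_error_controlled(self):
        """Family-wise false-cluster rate stays near the nominal level."""
        false_hits = 0
        for run in range(20):
            rng = np.random.default_rng(500 + run)
            X = rng.normal(size=(8, 2, 30))
            res = group_cluster_test(X, np.arange(30), tail=1, n_permutations=250, seed=run)
            false_hits += int(res.significant)
        assert false_hits / 20 <= 0.15
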