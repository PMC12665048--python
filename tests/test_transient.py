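"""Block-wise ERP decoding: sample construction, SVM calibration, comparisons."""

import numpy as np
import pytest

from conftest import exhaustive_sign_flip_pvals, make_epoch_set
from roving_aep.paradigm import ParadigmConfig, build_paradigm
from roving_aep.transient import (
    ClassificationResult,
    blockwise_averages,
    blockwise_difference_waves,
    erp_group_cluster_test,
    run_transient_comparisons,
    svm_permutation_test,
)


@pytest.fixture(scope="module")
def full_schedule():
    return build_paradigm(rng_seed=1)


class TestBlockwiseAverages:
    def test_forty_samples_per_condition(self, full_schedule):
        es = make_epoch_set(full_schedule, rs_per_block=10)
        X, info = blockwise_averages(es, "NONDEVIANT_LOW")
        assert X.shape[0] == 40  # 20 blocks × 2 electrodes
        assert set(info["electrode"]) == {"Fz", "Cz"}

    def test_five_block_subset_gives_ten(self, full_schedule):
        es = make_epoch_set(full_schedule)
        sub = es.subset(es.info["block"] <= 5)
        X, _ = blockwise_averages(sub, "NONDEVIANT_LOW")
        assert X.shape[0] == 10

    def test_block_average_recovers_clean_signal(self, full_schedule):
        """With identical noise-free epochs, every sample equals the template."""
        rng = np.random.default_rng(0)
        template = rng.normal(size=8)

        def fill(row):
            if not row.get("is_rs", False) and row.get("nondeviant", False):
                return np.vstack([template, template])
            return np.zeros((2, 8))

        es = make_epoch_set(full_schedule, n_times=8, window_s=(0.0, 8 / 250), fill=fill)
        X, _ = blockwise_averages(es, "NONDEVIANT_LOW")
        assert X.shape == (40, 8)
        np.testing.assert_allclose(X - template[None, :], 0.0, atol=1e-12)

    def test_difference_waves_pair_blocks(self, full_schedule):
        es = make_epoch_set(full_schedule)
        X, info = blockwise_difference_waves(es, "DEVIANT_ASC", "STANDARD_ASC")
        assert X.shape[0] == 40
        assert (info["condition"] == "DEVIANT_ASC-STANDARD_ASC").all()


class TestSvmPermutation:
    def test_separable_conditions_significant(self):
        rng = np.random.default_rng(0)
        Xa = rng.normal(scale=1.0, size=(40, 50))
        Xb = rng.normal(scale=1.0, size=(40, 50))
        Xb[:, 10:20] += 5.0  # a 5-μV deflection against 1-μV noise
        res = svm_permutation_test(Xa, Xb, n_folds=20, n_permutations=300, rng_seed=0)
        assert res.mean_accuracy == 1.0
        assert res.significant

    def test_null_rarely_significant(self):
        """Same-generator conditions stay at chance in ≥ 90 % of seeded runs."""
        sig = 0
        means = []
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            Xa = rng.normal(size=(20, 30))
            Xb = rng.normal(size=(20, 30))
            res = svm_permutation_test(Xa, Xb, n_folds=10, n_permutations=300, rng_seed=seed)
            sig += int(res.significant)
            means.append(res.mean_accuracy)
        assert sig <= 2
        assert np.mean(means) == pytest.approx(0.5, abs=0.08)

    def test_null_distribution_centered_at_chance(self):
        rng = np.random.default_rng(4)
        Xa = rng.normal(size=(30, 40))
        Xb = rng.normal(size=(30, 40))
        res = svm_permutation_test(Xa, Xb, n_folds=10, n_permutations=500, rng_seed=1)
        assert np.mean(res.null_accuracies) == pytest.approx(0.5, abs=0.05)

    def test_affine_feature_invariance(self):
        """Standardization makes decoding invariant to common affine maps."""
        rng = np.random.default_rng(7)
        Xa = rng.normal(size=(20, 25))
        Xb = rng.normal(size=(20, 25)) + 0.8
        r1 = svm_permutation_test(Xa, Xb, n_folds=10, n_permutations=100, rng_seed=3)
        r2 = svm_permutation_test(
            Xa * 40.0 - 7.0, Xb * 40.0 - 7.0, n_folds=10, n_permutations=100, rng_seed=3
        )
        assert r1.mean_accuracy == pytest.approx(r2.mean_accuracy, abs=1e-12)
        np.testing.assert_allclose(r1.null_accuracies, r2.null_accuracies)

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for effect in (0.0, 0.8, 5.0):
            rng = np.random.default_rng(11)
            Xa = rng.normal(size=(20, 30))
            Xb = rng.normal(size=(20, 30)) + effect
            res = svm_permutation_test(Xa, Xb, n_folds=10, n_permutations=50, rng_seed=0)
            accs.append(res.mean_accuracy)
        assert accs[0] - 0.1 <= accs[1] <= accs[2] + 1e-9
        assert accs[2] > accs[0]

    def test_too_few_samples_for_folds_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            svm_permutation_test(np.zeros((5, 4)), np.zeros((5, 4)), n_folds=20)


@pytest.fixture(scope="module")
def labelled_epochs():
    """Synthetic ERP epochs: MMN on descending deviants only, noise elsewhere."""
    sched = build_paradigm(rng_seed=2)
    n_times = 32
    t = np.arange(n_times) / 250.0
    mmn = -3.0 * np.exp(-0.5 * ((t * 1000 - 60) / 15) ** 2)
    rng = np.random.default_rng(0)

    def fill(row):
        base = rng.normal(scale=1.0, size=(2, n_times))
        if row.get("is_rs", False):
            return base
        base += 2.0 * np.sin(2 * np.pi * 5 * t)  # obligatory response
        if row.get("deviant", False) and row["transition"] == "descending":
            base += mmn
        return base

    return make_epoch_set(
        sched, n_times=n_times, window_s=(0.0, n_times / 250), fill=fill,
        rs_per_block=10,
    )


class TestComparisons:

    def test_descending_mmn_detected_ascending_at_chance(self, labelled_epochs):
        res = run_transient_comparisons(
            labelled_epochs,
            n_folds=20,
            n_permutations=200,
            rng_seed=0,
            comparisons=["deviant_vs_standard_desc", "deviant_vs_standard_asc"],
        )
        desc = res["deviant_vs_standard_desc"]
        asc = res["deviant_vs_standard_asc"]
        assert desc.significant
        assert not asc.significant
        assert abs(asc.mean_accuracy - 0.5) < 0.15

    def test_stimulus_vs_rest_detected(self, labelled_epochs):
        res = run_transient_comparisons(
            labelled_epochs, n_folds=20, n_permutations=200, rng_seed=1,
            comparisons=["nondeviant_low_vs_rs"],
        )["nondeviant_low_vs_rs"]
        assert res.significant

    def test_identical_tone_kernels_at_chance(self, labelled_epochs):
        """Low and high nondeviants share the same generator → chance decoding."""
        res = run_transient_comparisons(
            labelled_epochs, n_folds=20, n_permutations=200, rng_seed=2,
            comparisons=["low_vs_high"],
        )["low_vs_high"]
        assert not res.significant

    def test_all_comparisons_emit_records(self, labelled_epochs):
        res = run_transient_comparisons(
            labelled_epochs, n_folds=5, n_permutations=20, rng_seed=3
        )
        assert len(res) == 6
        for name, r in res.items():
            assert isinstance(r, ClassificationResult), name
            d = r.to_dict()
            assert {"mean_accuracy", "threshold_95", "p_value", "significant",
                    "rng_seed"} <= d.keys()

    def test_missing_condition_reported(self):
        sched = build_paradigm(rng_seed=0, config=ParadigmConfig(n_blocks=2))
        es = make_epoch_set(sched)  # no RS epochs at all
        res = run_transient_comparisons(
            es, n_folds=2, n_permutations=10, rng_seed=0,
            comparisons=["nondeviant_low_vs_rs"],
        )["nondeviant_low_vs_rs"]
        assert isinstance(res, str) and res.startswith("not_evaluable")


class TestErpGroupCluster:
    def test_null_no_clusters(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 2, 25)) * 0.1
        res = erp_group_cluster_test(X, np.arange(25) / 250.0, n_permutations=200, seed=0)
        assert not res.significant

    def test_n1_window_recovered(self):
        """A shared negative deflection at 96–128 ms yields a cluster there."""
        times = np.arange(0, 0.3, 1 / 250.0)
        rng = np.random.default_rng(1)
        X = rng.normal(scale=0.3, size=(12, 2, times.size))
        n1 = -2.0 * np.exp(-0.5 * ((times - 0.112) / 0.008) ** 2)
        X += n1[None, None, :]
        res = erp_group_cluster_test(X, times, n_permutations=300, seed=0)
        assert res.significant
        spans = [(c["onset"], c["offset"]) for c in res.clusters]
        assert any(on <= 112 <= off for on, off in spans)
        # the underlying deflection is negative
        peak_t = res.t_map[:, np.argmin(np.abs(times - 0.112))]
        assert (peak_t < 0).all()

    def test_exhaustive_sign_flip_agreement(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2, 20))
        X[:, :, 8:12] += 1.8
        res = erp_group_cluster_test(
            X, np.arange(20) / 250.0, tail=1, n_permutations=64, seed=0
        )
        oracle = exhaustive_sign_flip_pvals(X, step=0.1)
        assert np.max(np.abs(res.p_map - oracle)) <= 2 / 64 + 1e-12
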