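import numpy as np
import pytest

from svcsim.info import (ResponseDataset, confusion_from_dataset,
                         dot_product_decode, info_from_confusion,
                         info_vs_ensemble, single_cell_info)
from svcsim.synth import gen_view_population


@pytest.fixture(scope="module")
def fixture_ds():
    _, R, labels = gen_view_population(S=16, n_cells=20, trials_per_stimulus=50,
                                       seed=0)
    return ResponseDataset(R, labels)


class TestDecoder:
    def test_orthogonal_means_decode_perfectly(self):
        R = np.repeat(np.eye(4), 3, axis=0) * 10.0
        labels = np.repeat(np.arange(4), 3)
        for t in range(12):
            mask = np.arange(12) != t
            assert dot_product_decode(R[mask], labels[mask], R[t]) == labels[t]

    def test_equidistant_tie_goes_to_lower_index(self):
        R = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        test = np.array([1.0, 1.0])
        assert dot_product_decode(R, labels, test) == 0

    def test_zero_snr_accuracy_near_chance(self, rng):
        S, trials = 8, 125
        labels = np.repeat(np.arange(S), trials)
        R = rng.normal(10.0, 1.0, size=(S * trials, 10)).clip(min=0)
        cm = confusion_from_dataset(ResponseDataset(R, labels))
        acc = np.trace(cm) / cm.sum()
        assert abs(acc - 1.0 / S) < 0.05

    def test_dot_product_close_to_gaussian_ml(self, fixture_ds):
        # biologically plausible decoding loses little: accuracy within 10
        # percentage points of a Gaussian maximum-likelihood decoder
        R, labels = fixture_ds.responses, fixture_ds.labels
        cm = confusion_from_dataset(fixture_ds)
        acc_dp = np.trace(cm) / cm.sum()
        S = fixture_ds.n_stimuli
        sums = np.zeros((S, R.shape[1]))
        np.add.at(sums, labels, R)
        n_per = np.bincount(labels)
        correct = 0
        for t in range(R.shape[0]):
            mu = sums / n_per[:, None]
            mu[labels[t]] = (sums[labels[t]] - R[t]) / (n_per[labels[t]] - 1)
            ll = -np.sum((R[t] - mu) ** 2, axis=1)
            correct += int(np.argmax(ll)) == labels[t]
        acc_ml = correct / R.shape[0]
        assert abs(acc_dp - acc_ml) <= 0.10


class TestConfusion:
    def test_noiseless_dataset_gives_diagonal(self):
        R = np.repeat(np.eye(5), 4, axis=0) * 7.0
        labels = np.repeat(np.arange(5), 4)
        cm = confusion_from_dataset(ResponseDataset(R, labels))
        assert np.array_equal(cm, np.eye(5, dtype=int) * 4)

    def test_row_sums_are_trial_counts(self, fixture_ds):
        cm = confusion_from_dataset(fixture_ds)
        assert np.array_equal(cm.sum(axis=1),
                              np.bincount(fixture_ds.labels))

    def test_permuted_labels_mostly_offdiagonal(self, fixture_ds, rng):
        perm = rng.permutation(fixture_ds.labels)
        cm = confusion_from_dataset(ResponseDataset(fixture_ds.responses, perm))
        off = 1.0 - np.trace(cm) / cm.sum()
        assert off > 0.85  # ~ (S-1)/S of trials land off the diagonal

    def test_single_trial_per_stimulus_rejected(self):
        with pytest.raises(ValueError):
            ResponseDataset(np.ones((2, 3)), np.array([0, 1]))


class TestMutualInformation:
    def test_identity_confusion_is_log2_s(self):
        assert info_from_confusion(np.eye(16) * 50) == pytest.approx(4.0)

    def test_uniform_confusion_is_zero(self):
        assert info_from_confusion(np.ones((16, 16))) == pytest.approx(0.0)

    def test_two_by_two_joint(self):
        cm = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert info_from_confusion(cm) == pytest.approx(0.2781, abs=2e-4)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            info_from_confusion(np.zeros((4, 4)))

    def test_jackknife_reduces_positive_bias(self, rng):
        # pure-noise dataset: plug-in MI is biased upward; the jackknife
        # correction should shrink it
        labels = np.repeat(np.arange(8), 10)
        R = rng.normal(10, 2, size=(80, 4)).clip(min=0)
        cm = confusion_from_dataset(ResponseDataset(R, labels))
        assert info_from_confusion(cm, jackknife=True) < info_from_confusion(cm)


class TestSingleCell:
    def test_one_of_sixteen_selective_cell(self):
        # fires only for stimulus 5 of 16; noiseless
        labels = np.repeat(np.arange(16), 4)
        R = (labels == 5).astype(float)[:, None] * 10.0
        bits = single_cell_info(ResponseDataset(R, labels), 0)
        expected = (1 / 16) * np.log2(16) + (15 / 16) * np.log2(16 / 15)
        assert bits == pytest.approx(expected, abs=1e-6)  # ~0.337

    def test_constant_cell_carries_nothing(self):
        labels = np.repeat(np.arange(4), 3)
        R = np.full((12, 1), 5.0)
        assert single_cell_info(ResponseDataset(R, labels), 0) == \
            pytest.approx(0.0)

    def test_perfect_discriminator_reaches_ceiling(self):
        labels = np.repeat(np.arange(16), 3)
        R = labels[:, None].astype(float) * 3.0
        assert single_cell_info(ResponseDataset(R, labels), 0) == \
            pytest.approx(4.0)


class TestEnsembleCurve:
    def test_never_exceeds_stimulus_entropy(self, fixture_ds):
        _, bits = info_vs_ensemble(fixture_ds, [1, 5, 10, 20],
                                   n_resamples=3, seed=2)
        assert np.all(bits <= np.log2(16) + 1e-9)

    def test_single_cell_below_containing_ensemble(self, fixture_ds):
        _, bits = info_vs_ensemble(fixture_ds, [1, 10], n_resamples=5, seed=3)
        assert bits[0] < bits[1]

    def test_duplicated_cell_curve_is_flat(self, fixture_ds):
        R1 = np.tile(fixture_ds.responses[:, [0]], (1, 20))
        ds = ResponseDataset(R1, fixture_ds.labels)
        sizes, bits = info_vs_ensemble(ds, [1, 5, 20], n_resamples=3, seed=4)
        assert np.ptp(bits) < 1e-9

    def test_noiseless_population_saturates_quickly(self):
        _, R, labels = gen_view_population(noise_sd=0.0, seed=1)
        _, bits = info_vs_ensemble(ResponseDataset(R, labels), [3, 5],
                                   n_resamples=3, seed=5)
        assert bits[-1] == pytest.approx(4.0, abs=0.05)

    def test_information_degrades_with_noise(self):
        # monotone on average over a five-point noise sweep
        vals = []
        for sd in (1.0, 3.0, 6.0, 10.0, 15.0):
            _, R, labels = gen_view_population(noise_sd=sd, seed=6)
            cm = confusion_from_dataset(ResponseDataset(R, labels))
            vals.append(info_from_confusion(cm))
        diffs = np.diff(vals)
        assert vals[0] > vals[-1]
        assert (diffs <= 1e-9).sum() >= 3

    def test_zero_size_rejected(self, fixture_ds):
        with pytest.raises(ValueError):
            info_vs_ensemble(fixture_ds, [0, 5])
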