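"""Spectrogram pipeline, balancing, cross-validation, and odds-ratio math."""

import numpy as np
import pytest

from seismocrab import (
    balance_by_duplication,
    chance_accuracy,
    crossval_classify,
    group_of,
    odds_ratio,
    preprocess_image,
    spectrogram,
)
from seismocrab.spectrogram_classify import (
    GROUPS,
    SpectrogramImage,
    hop_for,
    pooled_features,
)

FS = 1612.0


class TestSpectrogram:
    @pytest.mark.parametrize("wl,hop,frames", [(128, 3, 173), (256, 5, 78)])
    def test_frame_counts_at_645_samples(self, wl, hop, frames, rng):
        assert hop_for(wl) == hop
        freqs, mags = spectrogram(rng.normal(size=645), FS, wl)
        assert mags.shape == (wl // 2 + 1, frames)
        # arithmetic oracle: floor((N − wl)/hop) + 1
        assert mags.shape[1] == (645 - wl) // hop + 1

    def test_tone_ridge(self):
        t = np.arange(645) / FS
        freqs, mags = spectrogram(np.sin(2 * np.pi * 200.0 * t), FS, 256)
        ridge_bins = np.argmax(mags, axis=0)
        assert np.all(np.abs(freqs[ridge_bins] - 200.0) <= FS / 256)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), FS, 128)


class TestPreprocess:
    def test_output_shape_and_range(self, rng):
        freqs, mags = spectrogram(rng.normal(size=645), FS, 256)
        img = preprocess_image(mags, freqs, "high", 256)
        assert img.matrix.shape == (224, 224)
        assert img.matrix.min() >= 0.0 and img.matrix.max() <= 1.0
        assert not img.degenerate

    def test_band_crop(self, rng):
        # energy confined to 300 Hz must survive the high-band crop and
        # vanish under the low-band crop
        t = np.arange(645) / FS
        tone = np.sin(2 * np.pi * 300.0 * t)
        freqs, mags = spectrogram(tone, FS, 256)
        hi = preprocess_image(mags, freqs, "high", 256)
        lo = preprocess_image(mags, freqs, "low", 256)
        assert hi.matrix.max() >= 0.99  # bilinear resize smooths the peak
        assert lo.matrix.shape == hi.matrix.shape == (224, 224)

    def test_all_zero_matrix_flagged(self):
        freqs = np.linspace(0, 400, 129)
        img = preprocess_image(np.zeros((129, 50)), freqs, "low", 128)
        assert img.degenerate
        assert np.all(img.matrix == 0.0)

    def test_identity_resize(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.1, 1.0, size=(224, 224))
        from skimage.transform import resize

        out = resize(m, (224, 224), order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
        np.testing.assert_allclose(out, m, atol=1e-6)


class TestBalancing:
    def test_minority_duplicated_to_majority(self):
        items = list("aaaaaaaaaabbbbb")
        labels = ["A"] * 10 + ["B"] * 5
        bal_items, bal_labels = balance_by_duplication(items, labels)
        assert bal_labels.count("A") == bal_labels.count("B") == 10
        # originals all retained
        assert bal_items[: len(items)] == items

    def test_already_balanced_unchanged(self):
        items, labels = [1, 2, 3, 4], ["A", "A", "B", "B"]
        out_items, out_labels = balance_by_duplication(items, labels)
        assert out_items == items and out_labels == labels

    def test_three_class_rule(self):
        labels = ["A"] * 7 + ["B"] * 3 + ["C"] * 2
        _, bal = balance_by_duplication(list(range(12)), labels)
        assert all(bal.count(c) == 7 for c in "ABC")

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_by_duplication([], [])


class TestOddsRatio:
    def test_chance_values(self):
        assert chance_accuracy(9) * 100 == pytest.approx(11.11, abs=0.005)
        assert chance_accuracy(3) * 100 == pytest.approx(33.33, abs=0.005)
        assert chance_accuracy(1) == 1.0
        with pytest.raises(ValueError):
            chance_accuracy(0)

    def test_accuracy_at_chance_gives_unit_odds(self):
        assert odds_ratio(0.5, 2) == pytest.approx(1.0)
        assert odds_ratio(1 / 9, 9) == pytest.approx(1.0)

    def test_strictly_increasing_in_accuracy(self):
        accs = np.linspace(0.05, 0.95, 19)
        ors = [odds_ratio(a, 9) for a in accs]
        assert np.all(np.diff(ors) > 0)

    def test_degenerate_accuracy_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                odds_ratio(bad, 3)

    # every printed cell of the published classification table, reproduced
    # from its printed mean accuracies at 1 dp
    @pytest.mark.parametrize(
        "acc,k,expected",
        [
            (0.3176, 9, 3.7), (0.3422, 9, 4.2), (0.3318, 9, 4.0),
            (0.6654, 3, 4.0), (0.7003, 3, 4.7), (0.6868, 3, 4.4),
            (0.2687, 9, 2.9), (0.3108, 9, 3.6), (0.5197, 9, 8.7),
            (0.5296, 3, 2.3), (0.6330, 3, 3.4), (0.6381, 3, 3.5),
        ],
    )
    def test_published_table_cells(self, acc, k, expected):
        assert round(odds_ratio(acc, k), 1) == expected


class TestGrouping:
    @pytest.mark.parametrize(
        "label,group",
        [
            ("conflict", "non_percussive"), ("locomotion", "non_percussive"),
            ("MB", "non_percussive"), ("waving", "non_percussive"),
            ("seqW", "non_percussive"),
            ("simWBD", "body_dropping"), ("seqBD", "body_dropping"),
            ("AD", "drumming"), ("UGD", "drumming"),
        ],
    )
    def test_nine_to_three_mapping(self, label, group):
        assert group_of(label) == group
        assert group in GROUPS

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            group_of("dance")


def _toy_images(n_per_class, seed, separated=True):
    """Tiny image corpus: classes occupy disjoint intensity ranges when
    separated, identical distributions otherwise."""
    rng = np.random.default_rng(seed)
    samples, labels = [], []
    levels = {"A": 0.2, "B": 0.5, "C": 0.8}
    for lab, level in levels.items():
        for _ in range(n_per_class):
            base = level if separated else 0.5
            m = np.clip(rng.normal(base, 0.03, size=(224, 224)), 0, 1)
            samples.append(
                {"high": SpectrogramImage(matrix=m, band="high", wl=128, hop=3)}
            )
            labels.append(lab)
    return samples, labels


class TestCrossValidation:
    def test_separable_classes_near_perfect(self):
        samples, labels = _toy_images(20, seed=0)
        res = crossval_classify(samples, labels, k=10, repeats=1, seed=0)
        assert res.mean_accuracy >= 0.99
        assert res.n_classes == 3

    def test_permuted_labels_score_at_chance(self):
        samples, labels = _toy_images(20, seed=1)
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(labels))
        res = crossval_classify(samples, shuffled, k=10, repeats=1, seed=1)
        # permutation null: within 3 binomial SDs of 1/3
        n = len(labels)
        sd = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(res.mean_accuracy - 1 / 3) <= 3 * sd

    def test_every_sample_tested_once_per_repeat(self):
        samples, labels = _toy_images(10, seed=2)
        res = crossval_classify(samples, labels, k=10, repeats=2, seed=2)
        # confusion rows sum to per-class test counts over all repeats
        counts = {lab: labels.count(lab) for lab in set(labels)}
        for i, cls in enumerate(res.classes):
            assert res.confusion[i].sum() == counts[cls] * 2

    def test_deterministic_under_seed(self):
        samples, labels = _toy_images(12, seed=3)
        r1 = crossval_classify(samples, labels, k=4, repeats=2, seed=7)
        r2 = crossval_classify(samples, labels, k=4, repeats=2, seed=7)
        np.testing.assert_array_equal(r1.fold_accuracies, r2.fold_accuracies)
        assert r1.mean_accuracy == r2.mean_accuracy

    def test_k_larger_than_smallest_class_rejected(self):
        samples, labels = _toy_images(5, seed=4)
        with pytest.raises(ValueError):
            crossval_classify(samples, labels, k=10, repeats=1, seed=0)

    def test_combined_mode_concatenates_bands(self):
        samples, labels = _toy_images(8, seed=5)
        for s in samples:
            s["low"] = s["high"]
        res = crossval_classify(samples, labels, k=4, repeats=1, seed=0)
        assert res.mean_accuracy >= 0.99
        # feature width doubles with two bands
        one = pooled_features(samples[0]["high"])
        assert len(one) * 2 == len(
            np.concatenate([pooled_features(samples[0][b]) for b in ("high", "low")])
        )
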