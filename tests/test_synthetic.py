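"""Cohort generators: determinism, exact counts, class structure, domain shift."""

import numpy as np
import pytest
from sklearn.neighbors import NearestCentroid

from milpath.config import CohortSpec, LABELS
from milpath.synthetic import (generate_feature_bags, generate_slide,
                               stratified_counts)


def bag_means(samples, split=None):
    X, y = [], []
    for bag, label, _, s in samples:
        if split is None or s == split:
            X.append(bag.features.mean(axis=0))
            y.append(label)
    return np.array(X), np.array(y)


class TestGenerateSlide:
    def test_mask_coverage_within_sane_band(self):
        slide = generate_slide("Good", "wsi", 1024, np.random.default_rng(0))
        cover = slide.lesion_mask.mean()
        assert 0.05 < cover < 0.80

    def test_same_seed_bit_identical(self):
        a = generate_slide("Medium", "wsi", 512, np.random.default_rng(7))
        b = generate_slide("Medium", "wsi", 512, np.random.default_rng(7))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)

    def test_blob_density_orders_bad_above_good(self):
        rng = np.random.default_rng(0)
        bad = [generate_slide("Bad", "wsi", 512, rng).n_blobs
               for _ in range(50)]
        good = [generate_slide("Good", "wsi", 512, rng).n_blobs
                for _ in range(50)]
        assert np.mean(bad) > np.mean(good)

    def test_microscope_domain_differs_from_wsi(self):
        a = generate_slide("Good", "wsi", 512, np.random.default_rng(3))
        b = generate_slide("Good", "microscope", 512,
                           np.random.default_rng(3))
        assert not np.array_equal(a.image, b.image)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_slide("Excellent", "wsi", 512, rng)
        with pytest.raises(ValueError):
            generate_slide("Good", "phone", 512, rng)
        with pytest.raises(ValueError):
            generate_slide("Good", "wsi", 256, rng)


class TestGenerateFeatureBags:
    def test_cohort_counts_and_splits_exact(self):
        spec = CohortSpec(separation=0.0, domain_shift=0.0, seed=1)
        samples = generate_feature_bags(spec)
        assert len(samples) == 150
        splits = [s for _, _, _, s in samples]
        assert splits.count("train") == 86
        assert splits.count("val") == 42
        assert splits.count("external") == 22
        labels = [l for _, l, _, s in samples if s != "external"]
        assert labels.count("Good") == 60
        assert labels.count("Medium") == 51
        assert labels.count("Bad") == 17
        domains = {d for _, _, d, s in samples if s == "external"}
        assert domains == {"microscope"}

    def test_determinism_bytewise(self):
        spec = CohortSpec(seed=5)
        a = generate_feature_bags(spec)
        b = generate_feature_bags(spec)
        for (ba, *_), (bb, *_) in zip(a, b):
            assert np.array_equal(ba.features, bb.features)
            assert np.array_equal(ba.coords, bb.coords)

    def test_zero_separation_class_means_indistinct(self):
        spec = CohortSpec(separation=0.0, domain_shift=0.0, seed=2)
        X, y = bag_means(generate_feature_bags(spec))
        means = {c: X[y == c].mean(axis=0) for c in LABELS}
        for a in LABELS:
            for b in LABELS:
                if a >= b:
                    continue
                diff = means[a] - means[b]
                # per-dimension standard error of the difference
                se = np.sqrt(X[y == a].var(axis=0) / (y == a).sum()
                             + X[y == b].var(axis=0) / (y == b).sum())
                z = np.abs(diff) / se
                assert np.mean(z) < 3.0

    def test_separation_six_nearest_centroid_recovers_classes(self):
        spec = CohortSpec(separation=6.0, domain_shift=0.0, seed=3)
        samples = generate_feature_bags(spec)
        X, y = bag_means(samples, split="train")
        clf = NearestCentroid().fit(X, y)
        assert clf.score(X, y) >= 0.95

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for sep in (0.0, 2.0, 6.0):
            spec = CohortSpec(separation=sep, domain_shift=0.0, seed=4)
            samples = generate_feature_bags(spec)
            Xtr, ytr = bag_means(samples, split="train")
            Xva, yva = bag_means(samples, split="val")
            accs.append(NearestCentroid().fit(Xtr, ytr).score(Xva, yva))
        assert accs[0] <= accs[1] <= accs[2]

    def test_domain_shift_moves_external_bags(self):
        base = dict(n_good=10, n_medium=8, n_bad=6, n_train=16, n_val=8,
                    n_external=10, separation=0.0, seed=6)
        no_shift = generate_feature_bags(CohortSpec(**base, domain_shift=0.0))
        shifted = generate_feature_bags(CohortSpec(**base, domain_shift=2.0))
        ext_a, _ = bag_means(no_shift, split="external")
        ext_b, _ = bag_means(shifted, split="external")
        assert np.linalg.norm(ext_a - ext_b) > 1.0

    def test_invalid_dim_and_bag_size_rejected(self):
        spec = CohortSpec(seed=0)
        with pytest.raises(ValueError):
            generate_feature_bags(spec, dim=0)
        with pytest.raises(ValueError):
            generate_feature_bags(spec, bag_size_range=(2, 8))


def test_stratified_counts_largest_remainder():
    assert stratified_counts([60, 51, 17], 86) == [40, 34, 12]
    assert stratified_counts([60, 51, 17], 22) == [10, 9, 3]
    assert sum(stratified_counts([3, 3, 3], 7)) == 7


def test_cohort_spec_invariant_enforced():
    with pytest.raises(ValueError):
        CohortSpec(n_good=10, n_medium=10, n_bad=10, n_train=20, n_val=5)
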