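"""Habitat generation: entropy maps, supervoxels, CH selection, Otsu."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from habitatrad import habitats as hab
from habitatrad.io_preprocess import CtVolume, PetVolume, VoiMask, VoiPair


def make_voi(pet, ct, mask):
    return VoiPair(
        ct=CtVolume(np.asarray(ct, float), (1.0, 1.0, 1.0)),
        pet=PetVolume(np.asarray(pet, float), (1.0, 1.0, 1.0), units="suv"),
        mask=VoiMask(np.asarray(mask, np.uint8), (1.0, 1.0, 1.0)),
    )


class TestLocalEntropy:
    def test_constant_volume_has_zero_entropy(self):
        out = hab.local_entropy_map(np.full((11, 11, 11), 3.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_checkerboard_interior_is_one_bit(self):
        z, y, x = np.indices((11, 11, 11))
        vol = np.where((z + y + x) % 2 == 0, 0.0, 10.0)
        out = hab.local_entropy_map(vol, neighborhood=9, n_bins=2)
        # direct histogram oracle for the centre voxel's 9^3 cube
        cube = vol[1:10, 1:10, 1:10]
        p = np.array([(cube == 0).mean(), (cube == 10).mean()])
        expected = -(p * np.log2(p)).sum()
        assert out[5, 5, 5] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.0, abs=1e-5)

    def test_entropy_bounds(self, rng):
        vol = rng.normal(size=(9, 9, 9))
        for n_bins in (2, 8, 32):
            out = hab.local_entropy_map(vol, n_bins=n_bins)
            assert out.min() >= 0.0
            assert out.max() <= np.log2(n_bins) + 1e-9

    def test_masked_histogram_ignores_background(self):
        # lesion constant inside the mask, extreme values outside: entropy
        # within the mask must be 0 when the histogram is mask-restricted
        vol = np.full((9, 9, 9), 5.0)
        mask = np.zeros_like(vol, dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        vol[~mask] = 1000.0
        out = hab.local_entropy_map(vol, mask, n_bins=8)
        np.testing.assert_allclose(out[mask], 0.0, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hab.local_entropy_map(np.zeros((5, 5, 5)), n_bins=1)
        with pytest.raises(ValueError):
            hab.local_entropy_map(np.zeros((5, 5, 5)), neighborhood=4)


class TestHypervolume:
    def test_shape_and_passthrough_channels(self, rng):
        pet = np.abs(rng.normal(2, 0.5, (12, 13, 14)))
        ct = rng.normal(-300, 50, (12, 13, 14))
        mask = np.ones((12, 13, 14), np.uint8)
        voi = make_voi(pet, ct, mask)
        hv = hab.build_hypervolume(voi)
        assert hv.channels.shape == (4, 12, 13, 14)
        np.testing.assert_array_equal(hv.channels[0], pet)
        np.testing.assert_array_equal(hv.channels[1], ct)
        np.testing.assert_array_equal(
            hv.channels[2], hab.local_entropy_map(pet, mask)
        )

    def test_crops_to_mask_bounding_box(self, rng):
        mask = np.zeros((20, 20, 20), np.uint8)
        mask[5:11, 4:12, 3:13] = 1
        voi = make_voi(np.ones((20, 20, 20)), np.zeros((20, 20, 20)), mask)
        hv = hab.build_hypervolume(voi)
        assert hv.channels.shape == (4, 6, 8, 10)


class TestSupervoxels:
    def test_adaptive_count_examples(self):
        mask = np.ones((7290, 1, 1), bool)
        assert hab.adaptive_supervoxel_count(mask) == 10
        assert hab.adaptive_supervoxel_count(np.ones((729, 1, 1), bool)) == 1
        assert hab.adaptive_supervoxel_count(np.ones((100, 1, 1), bool)) == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            hab.adaptive_supervoxel_count(np.zeros((3, 3, 3), bool))

    def test_count_scales_linearly_with_volume(self):
        counts = [
            hab.adaptive_supervoxel_count(np.ones((n * 729, 1, 1), bool)) for n in (1, 2, 5, 9)
        ]
        assert counts == [1, 2, 5, 9]

    def test_two_blob_recovery_and_centroid_consistency(self, rng):
        mask = np.ones((4, 4, 8), bool)
        feats = np.zeros((4, 4, 4, 8))
        feats[0, :, :, 4:] = 10.0  # PET channel splits the two halves
        hv = hab.FeatureHypervolume(feats, mask)
        sv = hab.cluster_supervoxels(hv, 2, seed=0)
        truth = np.zeros((4, 4, 8), int)
        truth[:, :, 4:] = 1
        assert adjusted_rand_score(truth[mask], sv.labels) == 1.0
        vectors = hv.masked_vectors()
        for j in range(sv.k_sv):
            np.testing.assert_allclose(sv.centroids[j], vectors[sv.labels == j].mean(axis=0))

    def test_single_supervoxel_is_masked_mean(self, rng):
        feats = rng.random((4, 3, 3, 3))
        hv = hab.FeatureHypervolume(feats, np.ones((3, 3, 3), bool))
        sv = hab.cluster_supervoxels(hv, 1, seed=0)
        np.testing.assert_allclose(sv.centroids[0], hv.masked_vectors().mean(axis=0))

    def test_too_many_supervoxels_rejected(self, rng):
        hv = hab.FeatureHypervolume(rng.random((4, 2, 2, 2)), np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            hab.cluster_supervoxels(hv, 9, seed=0)


class TestNormalization:
    def _hv(self, channels):
        return hab.FeatureHypervolume(
            np.asarray(channels, float), np.ones(np.asarray(channels).shape[1:], bool)
        )

    def test_global_midpoint_maps_to_half(self):
        c = np.zeros((4, 1, 1, 3))
        c[0, 0, 0] = [0.0, 5.0, 10.0]
        c[1, 0, 0] = [0.0, 1.0, 2.0]
        c[2, 0, 0] = [0.0, 1.0, 2.0]
        c[3, 0, 0] = [0.0, 1.0, 2.0]
        normed, stats = hab.normalize_global([self._hv(c)])
        assert normed[0].channels[0, 0, 0, 1] == pytest.approx(0.5)

    def test_global_contract_and_order_preservation(self, rng):
        a = self._hv(rng.random((4, 3, 3, 3)))
        b = self._hv(rng.random((4, 3, 3, 3)) + 2.0)  # disjoint range
        normed, stats = hab.normalize_global([a, b])
        stacked = np.concatenate([h.masked_vectors() for h in normed])
        np.testing.assert_allclose(stacked.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(stacked.max(axis=0), 1.0, atol=1e-12)
        # affine map preserves the order of lesion means
        for c in range(4):
            assert normed[0].masked_vectors()[:, c].mean() < normed[1].masked_vectors()[:, c].mean()

    def test_constant_channel_rejected_with_name(self, rng):
        c = rng.random((4, 2, 2, 2))
        c[1] = 3.0
        with pytest.raises(ValueError, match="ct_intensity"):
            hab.normalize_global([self._hv(c)])

    def test_local_constant_maps_to_zero(self):
        out = hab.normalize_local(self._hv(np.full((4, 5, 5, 5), 2.0)))
        np.testing.assert_array_equal(out.channels, 0.0)

    def test_local_against_brute_force_window_scan(self, rng):
        vol = rng.random((4, 6, 6, 6))
        out = hab.normalize_local(self._hv(vol), neighborhood=3)
        for c, z, y, x in [(0, 2, 3, 1), (3, 5, 0, 4), (1, 0, 0, 0)]:
            zz = slice(max(z - 1, 0), z + 2)
            yy = slice(max(y - 1, 0), y + 2)
            xx = slice(max(x - 1, 0), x + 2)
            win = vol[c, zz, yy, xx]
            expect = (vol[c, z, y, x] - win.min()) / (win.max() - win.min())
            assert out.channels[c, z, y, x] == pytest.approx(expect, abs=1e-12)

    def test_local_window_maximum_maps_to_one(self, rng):
        vol = rng.random((4, 5, 5, 5))
        vol[0, 2, 2, 2] = 10.0  # strictly the max of its own neighbourhood
        out = hab.normalize_local(self._hv(vol))
        assert out.channels[0, 2, 2, 2] == pytest.approx(1.0)


class TestHabitatModel:
    def test_ch_worked_example_equals_200(self):
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        from sklearn.metrics import calinski_harabasz_score

        assert calinski_harabasz_score(x, labels) == pytest.approx(200.0)

    def test_three_gaussian_signatures_select_k3(self, rng):
        sets = []
        centers = np.array(
            [[0.1, 0.1, 0.5, 0.5], [0.5, 0.9, 0.5, 0.5], [0.9, 0.2, 0.5, 0.5]]
        )
        for i in range(12):
            pts = centers[rng.integers(3, size=8)] + rng.normal(0, 0.01, (8, 4))
            sets.append(
                hab.SupervoxelSet(
                    lesion_id=f"L{i}", labels=np.zeros(8, int), centroids=pts, k_sv=8,
                    mask=np.ones((2, 2, 2), bool),
                )
            )
        model = hab.fit_habitat_model(sets, k_range=range(2, 8), seed=0)
        assert model.n_habitats == 3
        assert set(model.ch_scores) == set(range(2, 8))
        assert all(v > 0 and np.isfinite(v) for v in model.ch_scores.values())

    def test_centers_sorted_by_pet_uptake(self, rng):
        sets = []
        for i in range(10):
            pts = rng.random((6, 4))
            sets.append(
                hab.SupervoxelSet(f"L{i}", np.zeros(6, int), pts, 6, np.ones((2, 2, 2), bool))
            )
        model = hab.fit_habitat_model(sets, k_range=range(2, 5), seed=0)
        assert np.all(np.diff(model.centers[:, 0]) >= 0)

    def test_assignment_and_partition_properties(self, rng):
        centers = np.array([[0.2, 0.2, 0.2, 0.2], [0.8, 0.8, 0.8, 0.8]])
        model = hab.HabitatModel(method="adapted", n_habitats=2, centers=centers)
        mask = np.ones((2, 2, 2), bool)
        centroids = np.array([[0.2, 0.2, 0.2, 0.2], [0.75, 0.8, 0.85, 0.8]])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        sv = hab.SupervoxelSet("L", labels, centroids, 2, mask)
        hmap = hab.assign_habitats(model, sv)
        assert hmap.counts == {1: 4, 2: 4}
        assert sum(hmap.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        # exact-center centroid goes to that habitat
        assert hmap.labels.ravel()[0] == 1


class TestOtsu:
    def test_balanced_toy_split(self):
        t = hab.otsu_threshold(np.array([0, 0, 0, 10, 10, 10.0]))
        assert 0.0 < t < 10.0
        assert t == pytest.approx(5.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            hab.otsu_threshold(np.full(10, 3.0))

    def test_agrees_with_exhaustive_oracle(self, rng):
        def brute_force(values):
            uniq = np.unique(values)
            best, best_score = None, -1.0
            for i in range(len(uniq) - 1):
                cut = (uniq[i] + uniq[i + 1]) / 2
                lo, hi = values[values <= cut], values[values > cut]
                score = (
                    len(lo) / len(values) * len(hi) / len(values) * (lo.mean() - hi.mean()) ** 2
                )
                if score > best_score:
                    best, best_score = cut, score
            return best

        for _ in range(30):
            n_distinct = rng.integers(2, 65)
            values = rng.choice(rng.normal(size=n_distinct), size=200, replace=True)
            assert hab.otsu_threshold(values) == pytest.approx(brute_force(values))

    def test_bimodal_threshold_between_modes(self, rng):
        values = np.concatenate([rng.normal(0, 1, 300), rng.normal(10, 1, 300)])
        t = hab.otsu_threshold(values)
        assert 2.0 < t < 8.0

        # independent oracle: the exact search must reach at least the
        # between-class variance of scikit-image's 256-bin Otsu threshold
        def between_var(cut):
            lo, hi = values[values <= cut], values[values > cut]
            return len(lo) * len(hi) / len(values) ** 2 * (lo.mean() - hi.mean()) ** 2

        from skimage.filters import threshold_otsu

        assert between_var(t) >= between_var(threshold_otsu(values)) - 1e-12

    def test_habitat_map_partition(self, rng):
        shape = (8, 8, 8)
        pet = np.where(np.indices(shape)[0] < 4, 1.0, 8.0) + rng.normal(0, 0.05, shape)
        ct = np.where(np.indices(shape)[2] < 4, -400.0, 0.0) + rng.normal(0, 2.0, shape)
        mask = np.ones(shape, np.uint8)
        hmap = hab.otsu_habitat_map(make_voi(pet, ct, mask))
        assert set(hmap.counts) <= {1, 2, 3, 4}
        assert sum(hmap.counts.values()) == mask.sum()
        assert sum(hmap.proportions.values()) == pytest.approx(1.0)

    def test_aligned_two_valued_channels_give_two_habitats(self):
        shape = (4, 4, 4)
        half = np.indices(shape)[0] < 2
        pet = np.where(half, 1.0, 8.0)
        ct = np.where(half, -400.0, 0.0)
        hmap = hab.otsu_habitat_map(make_voi(pet, ct, np.ones(shape, np.uint8)))
        assert set(hmap.counts) == {1, 4}  # low&low and high&high only

    def test_constant_channel_rejected(self):
        shape = (4, 4, 4)
        pet = np.ones(shape)
        ct = np.where(np.indices(shape)[0] < 2, -400.0, 0.0)
        with pytest.raises(ValueError, match="PET"):
            hab.otsu_habitat_map(make_voi(pet, ct, np.ones(shape, np.uint8)))


class TestDeterminism:
    def test_identical_inputs_and_seed_reproduce_model(self, small_cohort):
        _, vois, _, _ = small_cohort
        m1, maps1 = hab.fit_clustering_habitats(vois[:6], "adapted", seed=7)
        m2, maps2 = hab.fit_clustering_habitats(vois[:6], "adapted", seed=7)
        assert m1.n_habitats == m2.n_habitats
        np.testing.assert_array_equal(m1.centers, m2.centers)
        for a, b in zip(maps1, maps2):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_conventional_constant_supervoxel_count(self, small_cohort):
        _, vois, _, _ = small_cohort
        hvs = [hab.normalize_local(hab.build_hypervolume(v)) for v in vois[:3]]
        svs = [hab.cluster_supervoxels(h, 50, seed=0) for h in hvs]
        assert {s.k_sv for s in svs} == {50}
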