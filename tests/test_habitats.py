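"""Cohort habitat clustering, semantic labels, and spatial connectivity."""

import numpy as np
import pytest

from tumorhab import habitats
from tumorhab.habitats import (assign_semantic_labels, build_feature_matrix,
                               cluster_habitats, n_label_combinations,
                               pct_unneighbored, shuffled_connectivity_test,
                               spatial_interaction_matrix)


def synthetic_features(n_patients=2, shape=(8, 8, 4), seed=0):
    """Patients whose ROI voxels carry two well-separated feature blobs."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_patients):
        roi = np.zeros(shape, bool)
        roi[1:-1, 1:-1, 1:-1] = True
        half = np.zeros(shape, bool)
        half[: shape[0] // 2] = True
        maps = {"adc": {}, "msi": {}, "roi": roi}
        for visit in ("V1", "V2"):
            adc = np.where(half, 1.0e-3, 2.0e-3) \
                + 1e-5 * rng.standard_normal(shape)
            msi = np.where(half, 0.10, 0.01) \
                + 1e-4 * rng.standard_normal(shape)
            maps["adc"][visit] = adc
            maps["msi"][visit] = msi
        out.append(maps)
    return out


class TestFeatureMatrix:
    def test_shape_and_standardization(self):
        pf = synthetic_features()
        fm = build_feature_matrix(pf, "msi")
        n_vox = int(pf[0]["roi"].sum())
        assert fm.values.shape == (2 * n_vox, 4)
        assert np.allclose(fm.values.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(fm.values.std(axis=0), 1, atol=1e-8)

    def test_constant_column_flagged(self):
        pf = synthetic_features()
        for p in pf:
            p["adc"]["V1"] = np.full(p["roi"].shape, 1.5e-3)
        fm = build_feature_matrix(pf, "msi")
        assert fm.zero_variance[0]
        assert np.all(fm.values[:, 0] == 0)

    def test_missing_map_errors(self):
        pf = synthetic_features()
        del pf[1]["msi"]["V2"]
        with pytest.raises(ValueError, match="patient 1"):
            build_feature_matrix(pf, "msi")


class TestClustering:
    def test_two_blobs_exact_partition(self):
        pf = synthetic_features()
        fm = build_feature_matrix(pf, "msi")
        ha = cluster_habitats(fm, H=2, seed=0)
        # brute-force check: every row is nearest its own center
        d = ((fm.values[:, None, :] - ha.centers[None]) ** 2).sum(axis=2)
        assert np.array_equal(d.argmin(axis=1) + 1, ha.labels)
        # partition must match the generating blob membership
        low_adc = fm.raw[:, 0] < 1.5e-3
        assert (np.unique(ha.labels[low_adc]).size == 1
                and np.unique(ha.labels[~low_adc]).size == 1)

    def test_ordering_by_mean_v1_adc(self):
        pf = synthetic_features()
        fm = build_feature_matrix(pf, "msi")
        ha = cluster_habitats(fm, H=2, seed=3)
        m1 = fm.raw[ha.labels == 1, 0].mean()
        m2 = fm.raw[ha.labels == 2, 0].mean()
        assert m1 < m2

    def test_wss_nonincreasing_in_h(self):
        pf = synthetic_features(n_patients=3, seed=5)
        fm = build_feature_matrix(pf, "msi")
        wss = []
        for H in range(2, 9):
            ha = cluster_habitats(fm, H=H, seed=0)
            wss.append(((fm.values - ha.centers[ha.labels - 1]) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))

    def test_h_bounds(self):
        fm = build_feature_matrix(synthetic_features(), "msi")
        for bad in (1, 17):
            with pytest.raises(ValueError):
                cluster_habitats(fm, H=bad, seed=0)

    def test_per_patient_maps_slice_global_assignment(self):
        pf = synthetic_features(n_patients=3, seed=9)
        fm = build_feature_matrix(pf, "msi")
        ha = cluster_habitats(fm, H=2, seed=1)
        maps = ha.per_patient_maps(fm, pf[0]["roi"].shape)
        rebuilt = np.concatenate([m[p["roi"]] for m, p in zip(maps, pf)])
        assert np.array_equal(rebuilt, ha.labels)


class TestSemanticLabels:
    def test_high_low_assignment_and_tie_rule(self):
        pf = synthetic_features()
        fm = build_feature_matrix(pf, "msi")
        ha = cluster_habitats(fm, H=2, seed=0)
        labels = assign_semantic_labels(ha, fm)
        assert len(labels) == 2 and all(len(l) == 4 for l in labels)
        # habitat 1 has low ADC (below pooled mean) and high MSI
        assert labels[0][0] == "low" and labels[0][2] == "high"
        assert labels[1][0] == "high" and labels[1][2] == "low"

    def test_sixteen_combinations(self):
        assert n_label_combinations() == 16

    def test_exact_tie_is_low(self):
        # habitat mean equal to the pooled mean maps to 'low'
        import tumorhab.habitats as H
        fm = H.FeatureMatrix(values=np.zeros((4, 4)), raw=np.ones((4, 4)),
                             col_mean=np.ones(4), col_sd=np.zeros(4),
                             zero_variance=np.ones(4, bool),
                             patient_ids=np.zeros(4, int),
                             voxel_index=[np.zeros((4, 3), int)])
        ha = H.HabitatAssignment(H=1, labels=np.ones(4, int),
                                 centers=np.zeros((1, 4)))
        assert assign_semantic_labels(ha, fm) == [("low",) * 4]


class TestConnectivity:
    def brute_force_pct(self, labels, roi):
        """Exhaustive 26-neighbor enumeration, independent of the vectorized path."""
        shape = labels.shape
        counts, lonely = {}, {}
        for idx in np.argwhere(roi):
            h = labels[tuple(idx)]
            counts[h] = counts.get(h, 0) + 1
            mate = False
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        nb = idx + (dx, dy, dz)
                        if np.any(nb < 0) or np.any(nb >= shape):
                            continue
                        if roi[tuple(nb)] and labels[tuple(nb)] == h:
                            mate = True
            if not mate:
                lonely[h] = lonely.get(h, 0) + 1
        return {h: 100.0 * lonely.get(h, 0) / c for h, c in counts.items()}

    def test_single_connected_habitat_zero(self):
        labels = np.ones((4, 4, 4), np.int32)
        roi = np.ones((4, 4, 4), bool)
        assert pct_unneighbored(labels, roi) == {1: 0.0}

    def test_checkerboard_matches_brute_force(self):
        x, y, z = np.meshgrid(*[np.arange(4)] * 3, indexing="ij")
        labels = ((x + y + z) % 2 + 1).astype(np.int32)
        roi = np.ones((4, 4, 4), bool)
        assert pct_unneighbored(labels, roi) == self.brute_force_pct(labels, roi)

    def test_isolated_voxel_count(self):
        labels = np.ones((6, 6, 3), np.int32)
        roi = np.ones((6, 6, 3), bool)
        labels[0, 0, 0:2] = 2            # contiguous pair far away
        # ... 10 contiguous habitat-2 voxels plus one isolated one
        labels[5, 0:5, 0] = 2
        labels[5, 0:5, 1] = 2   # 2+10 = 12 voxels in habitat 2 so far
        labels[2, 3, 1] = 2     # isolated inside habitat-1 sea
        pct = pct_unneighbored(labels, roi)
        n2 = (labels == 2).sum()
        assert pct[2] == pytest.approx(100.0 / n2)

    def test_random_labels_match_brute_force(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(1, 4, size=(5, 4, 3)).astype(np.int32)
        roi = rng.random((5, 4, 3)) < 0.8
        labels[~roi] = 0
        assert pct_unneighbored(labels, roi) == pytest.approx(
            self.brute_force_pct(labels, roi))


class TestInteractionMatrix:
    def brute_force_matrix(self, labels, roi, H):
        shape = labels.shape
        mat = np.zeros((H, H))
        for idx in np.argwhere(roi):
            a = labels[tuple(idx)]
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        nb = idx + (dx, dy, dz)
                        if np.any(nb < 0) or np.any(nb >= shape):
                            continue
                        if roi[tuple(nb)]:
                            mat[a - 1, labels[tuple(nb)] - 1] += 1
        sums = mat.sum(axis=1, keepdims=True)
        out = mat / np.where(sums == 0, 1, sums)
        out[sums[:, 0] == 0] = np.nan
        return out

    def test_single_habitat_trivial(self):
        labels = np.ones((3, 3, 3), np.int32)
        roi = np.ones((3, 3, 3), bool)
        assert spatial_interaction_matrix(labels, roi, 1) == pytest.approx(
            np.array([[1.0]]))

    def test_two_halves_match_brute_force(self):
        labels = np.ones((4, 4, 4), np.int32)
        labels[2:] = 2
        roi = np.ones((4, 4, 4), bool)
        got = spatial_interaction_matrix(labels, roi, 2)
        want = self.brute_force_matrix(labels, roi, 2)
        assert got == pytest.approx(want)
        assert got[0, 0] > 0.5 and got[1, 1] > 0.5
        assert np.allclose(got.sum(axis=1), 1.0)

    def test_absent_habitat_nan_row(self):
        labels = np.ones((3, 3, 3), np.int32)
        roi = np.ones((3, 3, 3), bool)
        mat = spatial_interaction_matrix(labels, roi, 2)
        assert np.isnan(mat[1]).all()


class TestShuffledConnectivity:
    def _contiguous_maps(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        maps, rois = [], []
        for _ in range(n):
            labels = np.ones((8, 8, 4), np.int32)
            labels[4:] = 2
            labels[:, 6:] = 3
            roi = np.ones((8, 8, 4), bool)
            maps.append(labels)
            rois.append(roi)
        return maps, rois

    def test_contiguous_beats_shuffled(self):
        maps, rois = self._contiguous_maps()
        p, true_d, null_d = shuffled_connectivity_test(maps, rois, 3,
                                                       n_shuffles=3, seed=1)
        assert np.median(true_d) > np.median(null_d)
        assert p < 0.05

    def test_random_labels_not_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for s in range(10):
            maps, rois = [], []
            for _ in range(6):
                roi = np.ones((6, 6, 4), bool)
                labels = rng.integers(1, 4, size=(6, 6, 4)).astype(np.int32)
                maps.append(labels)
                rois.append(roi)
            p, _, _ = shuffled_connectivity_test(maps, rois, 3,
                                                 n_shuffles=3, seed=s)
            hits += p < 0.05
        assert hits <= 1   # null labels should rarely reach significance

    def test_invalid_shuffle_count(self):
        maps, rois = self._contiguous_maps(n=2)
        with pytest.raises(ValueError):
            shuffled_connectivity_test(maps, rois, 3, n_shuffles=0, seed=0)
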