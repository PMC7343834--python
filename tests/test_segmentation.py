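"""VOI construction, bimodal thresholding, component extraction."""

import numpy as np
import pytest

from cereplaq._exceptions import DomainError
from cereplaq import segmentation as seg
from cereplaq.volume_io import SeedROI, Volume

from conftest import flood_fill_26

VS = 1.625


def flat_volume(shape=(32, 32, 32), value=0.0):
    return Volume(np.full(shape, value, np.float32), VS)


class TestVoiMask:
    def test_no_seeds_empty_mask(self):
        voi = seg.build_voi_mask([], flat_volume())
        assert voi.n_voxels == 0

    def test_cylinder_voxel_count_matches_analytic(self):
        # radius 10 um over 10 slices at 1.625 um: pi*(10/1.625)^2*10 ~ 1190
        vol = flat_volume((40, 40, 12))
        seed = SeedROI((20.0, 20.0), 10.0, (0, 9))
        voi = seg.build_voi_mask([seed], vol)
        expected = np.pi * (10.0 / VS) ** 2 * 10
        assert abs(voi.n_voxels - expected) / expected < 0.10

    def test_duplicate_seeds_union_idempotent(self):
        vol = flat_volume((40, 40, 12))
        seed = SeedROI((20.0, 20.0), 10.0, (0, 9))
        one = seg.build_voi_mask([seed], vol)
        two = seg.build_voi_mask([seed, seed], vol)
        np.testing.assert_array_equal(one.mask, two.mask)

    def test_fully_outside_seed_warned_and_skipped(self):
        vol = flat_volume((20, 20, 20))
        inside = SeedROI((10.0, 10.0), 5.0, (0, 5))
        outside = SeedROI((10.0, 10.0), 5.0, (30, 40))
        with pytest.warns(UserWarning, match="outside"):
            voi = seg.build_voi_mask([inside, outside], vol)
        assert voi.n_voxels == seg.build_voi_mask([inside], vol).n_voxels

    def test_slice_range_inclusive(self):
        vol = flat_volume((20, 20, 20))
        voi = seg.build_voi_mask([SeedROI((10.0, 10.0), 3.0, (4, 6))], vol)
        zs = np.unique(np.nonzero(voi.mask)[2])
        assert zs.tolist() == [4, 5, 6]


class TestBimodalThreshold:
    def _voi_of(self, values):
        n = values.size
        side = int(np.ceil(n ** (1 / 3))) + 1
        vox = np.zeros(side**3, np.float32)
        vox[:n] = values
        vol = Volume(vox.reshape(side, side, side), VS)
        mask = np.zeros(vol.shape, bool)
        mask.reshape(-1)[:n] = True
        return vol, seg.VOIMask(mask=mask)

    def test_two_gaussian_mixture_valley(self):
        rng = np.random.default_rng(1234)
        values = np.concatenate([
            rng.normal(100, 10, 50_000), rng.normal(200, 10, 50_000)
        ]).astype(np.float32)
        vol, voi = self._voi_of(values)
        res = seg.find_bimodal_threshold(vol, voi)
        assert res.bimodal_found
        # analytic minimum of the equal mixture density is at 150
        assert 140.0 <= res.threshold <= 160.0
        assert res.background_peak < res.threshold < res.plaque_peak

    def test_unimodal_falls_back_to_otsu_with_flag(self):
        rng = np.random.default_rng(5)
        vol, voi = self._voi_of(rng.normal(120, 8, 20_000).astype(np.float32))
        res = seg.find_bimodal_threshold(vol, voi)
        assert not res.bimodal_found
        assert res.method == "otsu-fallback"

    def test_delta_peaks_threshold_is_valley_midpoint(self):
        values = np.array([50.0] * 5000 + [150.0] * 5000, np.float32)
        vol, voi = self._voi_of(values)
        res = seg.find_bimodal_threshold(vol, voi)
        assert res.bimodal_found
        # empty valley between 50 and 150: midpoint 100 (bin-center accuracy)
        assert res.threshold == pytest.approx(100.0, abs=2.0)

    def test_empty_and_constant_voi_error(self):
        vol = flat_volume()
        with pytest.raises(DomainError):
            seg.find_bimodal_threshold(vol, seg.VOIMask(np.zeros(vol.shape, bool)))
        with pytest.raises(DomainError):
            seg.find_bimodal_threshold(vol, seg.VOIMask(np.ones(vol.shape, bool)))


class TestExtractPlaques:
    def _volume_with_components(self, sizes, gray=200.0):
        """Disjoint straight-line components of given voxel counts."""
        vox = np.zeros((len(sizes) * 4, max(sizes) + 2, 8), np.float32)
        for i, s in enumerate(sizes):
            vox[i * 4, 1 : 1 + s, 1] = gray
        vol = Volume(vox, VS)
        voi = seg.VOIMask(mask=np.ones(vox.shape, bool))
        return vol, voi

    def test_min_volume_filter_arithmetic(self):
        # 30 voxels * 1.625^3 = 128.7 um^3 <= 150 -> removed;
        # 100 voxels = 429.2 um^3 > 150 -> retained
        vol, voi = self._volume_with_components([30, 100])
        labels = seg.extract_plaques(vol, voi, threshold=100.0, min_volume_um3=150.0)
        assert len(labels.ids()) == 1
        assert (labels.labels > 0).sum() == 100

    def test_exact_boundary_is_strict(self):
        # 150 um^3 / 1.625^3 = 34.95 -> a 35-voxel object (150.2 um^3) survives
        # and a 34-voxel object (145.9 um^3) does not
        vol, voi = self._volume_with_components([34, 35])
        labels = seg.extract_plaques(vol, voi, threshold=100.0, min_volume_um3=150.0)
        assert len(labels.ids()) == 1
        assert (labels.labels > 0).sum() == 35

    def test_labels_ordered_by_descending_volume(self):
        vol, voi = self._volume_with_components([40, 90, 60])
        labels = seg.extract_plaques(vol, voi, threshold=100.0, min_volume_um3=0.0)
        counts = [int((labels.labels == i).sum()) for i in (1, 2, 3)]
        assert counts == [90, 60, 40]

    def test_monotone_in_threshold_and_min_volume(self, phantom144, phantom144_seeds):
        _, vol, _ = phantom144
        voi = seg.build_voi_mask(phantom144_seeds, vol)
        res = seg.find_bimodal_threshold(vol, voi)
        base = seg.extract_plaques(vol, voi, res.threshold, 150.0)
        higher_thr = seg.extract_plaques(vol, voi, res.threshold + 20, 150.0)
        higher_vol = seg.extract_plaques(vol, voi, res.threshold, 600.0)
        assert len(higher_thr.ids()) <= len(base.ids())
        assert len(higher_vol.ids()) <= len(base.ids())
        assert (higher_thr.labels > 0).sum() <= (base.labels > 0).sum()
        assert (higher_vol.labels > 0).sum() <= (base.labels > 0).sum()

    def test_voi_confinement(self, phantom144, phantom144_seeds):
        _, vol, _ = phantom144
        voi = seg.build_voi_mask(phantom144_seeds, vol)
        res = seg.find_bimodal_threshold(vol, voi)
        labels = seg.extract_plaques(vol, voi, res.threshold)
        assert not (labels.labels[~voi.mask] > 0).any()

    def test_connectivity_26_vs_flood_fill_oracle(self):
        """Label sets match an exhaustive BFS flood fill on small volumes."""
        rng = np.random.default_rng(99)
        for trial in range(5):
            vox = (rng.random((18, 18, 18)) < 0.25).astype(np.float32) * 200
            vol = Volume(vox, VS)
            voi = seg.VOIMask(mask=np.ones(vox.shape, bool))
            labels = seg.extract_plaques(vol, voi, 100.0, min_volume_um3=0.0)
            oracle = flood_fill_26(vox > 100.0)
            assert labels.labels.max() == oracle.max()
            # identical partition: each oracle component maps to one label
            for oid in range(1, oracle.max() + 1):
                got = np.unique(labels.labels[oracle == oid])
                assert len(got) == 1 and got[0] > 0

    def test_phantom_recovery_dice(self, phantom144, phantom144_seeds):
        """>= 95% of true plaques above the filter recovered at Dice >= 0.8."""
        spec, vol, gt = phantom144
        voi = seg.build_voi_mask(phantom144_seeds, vol)
        res = seg.find_bimodal_threshold(vol, voi)
        labels = seg.extract_plaques(vol, voi, res.threshold)
        vs3 = spec.voxel_size_um**3
        tl = gt.plaque_labels.labels
        above, good = 0, 0
        for obj in gt.objects_of("plaque"):
            true_mask = tl == obj.object_id
            if true_mask.sum() * vs3 <= 150.0:
                continue
            above += 1
            overlap = labels.labels[true_mask]
            ids, counts = np.unique(overlap[overlap > 0], return_counts=True)
            if not len(ids):
                continue
            best = labels.labels == ids[np.argmax(counts)]
            dice = 2 * (true_mask & best).sum() / (true_mask.sum() + best.sum())
            good += dice >= 0.8
        assert above > 0
        assert good / above >= 0.95
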