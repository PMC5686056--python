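"""Otsu and beta-purity segmentation, component cleanup, zone assignment."""

import numpy as np
import pytest

from dcehabitat.decomposition import NmfResult
from dcehabitat.io_core import MaskVolume, TimeGrid
from dcehabitat.segmentation import (
    SegmentationConfig,
    cleanup_components,
    gate_and_assign,
    otsu_threshold,
    purity_segment,
    segment_wp,
)

SPACING = (1.25, 1.25, 2.5)


def _brute_force_otsu(values, nbins=256):
    """Exhaustive between-class-variance search over histogram cut points."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, edges[0]
    total = counts.sum()
    for cut in range(1, nbins):
        w0 = counts[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[cut - 1]
    return best_thr


class TestOtsu:
    def test_bimodal_separation(self):
        values = np.array([0.0] * 50 + [10.0] * 50)
        thr = otsu_threshold(values)
        assert 0.0 < thr < 10.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        values = np.concatenate(
            [rng.normal(2, 0.5, 500), rng.normal(8, 1.0, 500)]
        )
        thr = otsu_threshold(values)
        oracle = _brute_force_otsu(values)
        # same histogram bin
        bin_width = (values.max() - values.min()) / 256
        assert abs(thr - oracle) <= bin_width

    def test_two_distinct_values_split(self):
        thr = otsu_threshold(np.array([1.0, 5.0]))
        assert 1.0 <= thr < 5.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(10, 3.0))


def _synthetic_nmf(weights, shape=(4, 4, 1), wp_index=0):
    """NmfResult with prescribed per-voxel weight rows (P x k)."""
    weights = np.asarray(weights, dtype=float)
    coords = np.argwhere(np.ones(shape, bool))[: len(weights)]
    k = weights.shape[1]
    return NmfResult(
        W=weights,
        S=np.ones((k, 12)),
        coords=coords,
        shape=shape,
        grid=TimeGrid.default(),
        residual=0.0,
        wp_index=wp_index,
    )


class TestPuritySegment:
    def test_included_above_beta(self):
        nmf = _synthetic_nmf([[0.7, 0.2, 0.1]])
        assert purity_segment(nmf, 60).n_voxels == 1  # 70% > 60%

    def test_boundary_is_strict(self):
        nmf = _synthetic_nmf([[0.6, 0.4, 0.0]])
        assert purity_segment(nmf, 60).n_voxels == 0  # 60% not > 60%

    def test_zero_total_weight_excluded(self):
        nmf = _synthetic_nmf([[0.0, 0.0, 0.0]])
        assert purity_segment(nmf, 40).n_voxels == 0

    def test_pure_pattern_voxels_exactly_recovered(self, exact_factorization):
        from dcehabitat.decomposition import run_nmf, select_wp

        cm, W0, S0 = exact_factorization
        res = run_nmf(cm, k=3)
        res.wp_index = select_wp(res.S, cm.grid)
        roi = purity_segment(res, 70)
        # each voxel loads exactly one pattern: ROI = one 100-voxel block
        assert roi.n_voxels == 100

    def test_beta_monotonicity(self, nmf_snr20):
        rois = {b: purity_segment(nmf_snr20, b).data for b in (40, 50, 60, 70)}
        assert not np.any(rois[70] & ~rois[60])
        assert not np.any(rois[60] & ~rois[50])
        assert not np.any(rois[50] & ~rois[40])


class TestCleanup:
    def _mask_with_component(self, n_voxels):
        m = np.zeros((20, 20, 4), dtype=bool)
        m.ravel()[:0] = True
        # a compact 26-connected blob of exactly n voxels in one slice block
        filled = 0
        for z in range(4):
            for y in range(20):
                for x in range(20):
                    if filled < n_voxels:
                        m[x, y, 0] = True
                        filled += 1
        return m

    def test_component_below_005cc_removed(self):
        # 12 voxels at paper spacing = 0.0469 cc < 0.05 cc
        m = np.zeros((20, 20, 2), dtype=bool)
        m[2:6, 2:5, 0] = True  # 12 voxels
        out = cleanup_components(MaskVolume(m), 0.05, SPACING)
        assert out.n_voxels == 0

    def test_component_at_00508cc_kept(self):
        # 13 voxels = 0.0508 cc >= 0.05 cc
        m = np.zeros((20, 20, 2), dtype=bool)
        m[2:6, 2:5, 0] = True
        m[6, 4, 0] = True
        out = cleanup_components(MaskVolume(m), 0.05, SPACING)
        assert out.n_voxels == 13

    def test_empty_mask(self):
        m = np.zeros((5, 5, 2), dtype=bool)
        out = cleanup_components(MaskVolume(m), 0.05, SPACING)
        assert out.n_voxels == 0

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(5)
        m = rng.random((20, 20, 6)) < 0.1
        once = cleanup_components(MaskVolume(m), 0.05, SPACING)
        twice = cleanup_components(once, 0.05, SPACING)
        assert not np.any(once.data & ~m)
        np.testing.assert_array_equal(once.data, twice.data)


class TestGateAndAssign:
    def _zones(self, shape=(10, 10, 8)):
        pz = np.zeros(shape, dtype=bool)
        pz[:, 5:, :] = True
        tz = ~pz
        return MaskVolume(pz, "PZ"), MaskVolume(tz, "TZ")

    def _roi_with_pz_count(self, n_total, n_pz, shape=(10, 10, 8)):
        roi = np.zeros(shape, dtype=bool)
        pz_part = np.argwhere(np.zeros(shape) == 0)
        # fill n_pz voxels in y >= 5, rest in y < 5
        count_pz = count_tz = 0
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if y >= 5 and count_pz < n_pz:
                        roi[x, y, z] = True
                        count_pz += 1
                    elif y < 5 and count_tz < n_total - n_pz:
                        roi[x, y, z] = True
                        count_tz += 1
        return MaskVolume(roi, "ROI")

    def test_pz_assignment_above_fraction(self):
        pz, tz = self._zones()
        roi = self._roi_with_pz_count(100, 15)
        seg = gate_and_assign(roi, pz, tz, SegmentationConfig(), SPACING)
        assert seg.zone == "PZ"  # 15% > 10%

    def test_boundary_fraction_goes_tz(self):
        pz, tz = self._zones()
        roi = self._roi_with_pz_count(100, 10)
        seg = gate_and_assign(roi, pz, tz, SegmentationConfig(), SPACING)
        assert seg.zone == "TZ"  # 10% not > 10%

    def test_04cc_roi_rejected_at_05cc_gate(self):
        pz, tz = self._zones()
        roi = self._roi_with_pz_count(102, 50)  # 102 voxels = 0.3984 cc
        seg = gate_and_assign(roi, pz, tz, SegmentationConfig(), SPACING)
        assert seg.volume_cc_after < 0.5
        assert seg.rejected

    def test_empty_roi_rejected_with_no_zone(self):
        pz, tz = self._zones()
        roi = MaskVolume(np.zeros((10, 10, 8), bool), "ROI")
        seg = gate_and_assign(roi, pz, tz, SegmentationConfig(), SPACING)
        assert seg.rejected and seg.zone is None

    def test_nat_masks_partition_zones(self):
        pz, tz = self._zones()
        roi = self._roi_with_pz_count(200, 150)
        seg = gate_and_assign(roi, pz, tz, SegmentationConfig(), SPACING)
        assert not np.any(seg.nat_pz.data & seg.roi_wp.data)
        assert not np.any(seg.nat_tz.data & seg.roi_wp.data)
        np.testing.assert_array_equal(
            seg.nat_pz.data | (pz.data & roi.data), pz.data
        )


class TestFullStage:
    def test_dice_against_true_lesion_at_beta60(
        self, nmf_snr20, snr20_phantom
    ):
        series, truth = snr20_phantom
        seg = segment_wp(
            nmf_snr20,
            truth.masks["PZ"],
            truth.masks["TZ"],
            SegmentationConfig(),
            series.spacing,
        )
        lesion = truth.masks["lesion_0"].data
        dice = (
            2.0 * np.sum(seg.roi_wp.data & lesion)
            / (seg.roi_wp.data.sum() + lesion.sum())
        )
        assert dice >= 0.6
        assert seg.zone == "PZ"
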