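import numpy as np
import pytest

from conftest import (
    BASE_SEED,
    analyze_phantom,
    flood_fill_label,
    label_partition,
    match_truth,
)
from fociquant3d import foci
from fociquant3d.imaging import voxel_volume
from fociquant3d.synthetic import FociPhantomParams, gen_foci_stack


def _box_mask(shape=(20, 30, 30), box=(slice(2, 18), slice(4, 26), slice(4, 26))):
    labels = np.zeros(shape, np.int32)
    labels[box] = 1
    count = int((labels == 1).sum())
    idx = np.argwhere(labels == 1)
    return foci.NucleusMask(
        labels, {1: count}, {1: box}, {1: idx.mean(axis=0)}
    )


class TestLabeling:
    def test_matches_flood_fill_on_random_grids(self):
        rng = np.random.default_rng(BASE_SEED)
        for _ in range(50):
            grid = rng.random((6, 12, 12)) < 0.3
            ours = label_partition(foci.label_components(grid))
            oracle = set(flood_fill_label(grid))
            assert ours == oracle

    def test_corner_touch_is_26_connected(self):
        grid = np.zeros((2, 2, 2), bool)
        grid[0, 0, 0] = grid[1, 1, 1] = True
        assert foci.label_components(grid).max() == 1
        assert foci.label_components(grid, connectivity=1).max() == 2


class TestSegmentNuclei:
    def test_recovers_ellipsoids_with_analytic_volume(self, noiseless_phantom):
        params, stack, truth = noiseless_phantom
        mask = foci.segment_nuclei(stack.data[0])
        assert mask.n_nuclei == params.n_nuclei
        rz, ry, rx = params.nucleus_radii_um
        analytic = 4.0 / 3.0 * np.pi * rz * ry * rx  # µm³
        vv = voxel_volume(params.voxel_size_nm)
        for lab, count in mask.voxel_counts.items():
            assert count * vv == pytest.approx(analytic, rel=0.05)

    def test_blank_image_gives_zero_labels(self):
        with pytest.warns(UserWarning):
            mask = foci.segment_nuclei(np.zeros((10, 20, 20)))
        assert mask.n_nuclei == 0

    def test_border_touching_nucleus_excluded(self):
        img = np.zeros((12, 40, 40))
        zz, yy, xx = np.ogrid[:12, :40, :40]
        # interior nucleus
        img[((zz - 6) / 4) ** 2 + ((yy - 20) / 8) ** 2 + ((xx - 12) / 8) ** 2 <= 1] = 100
        # nucleus clipped by the x border (center just outside the field)
        img[((zz - 6) / 4) ** 2 + ((yy - 20) / 8) ** 2 + ((xx - 41) / 8) ** 2 <= 1] = 100
        mask = foci.segment_nuclei(img, min_nucleus_voxels=100)
        assert mask.n_nuclei == 1
        assert mask.labels[:, :, -1].max() == 0


class TestDetectFoci:
    def test_inclusive_size_threshold_at_exactly_min_voxels(self):
        mask = _box_mask()
        ch = np.zeros(mask.labels.shape)
        ch[10, 8:15, 8:15] = 100.0  # 49-voxel plate
        det = foci.detect_foci(ch, mask, min_voxels=50)
        assert len(det.foci) == 0
        ch[11, 8, 8] = 100.0  # 50th voxel, 26-connected to the plate
        det = foci.detect_foci(ch, mask, min_voxels=50)
        assert len(det.foci) == 1
        assert det.foci[0].volume_voxels == 50

    def test_volume_um3_consistent_with_voxel_volume(self, noisy_phantom):
        params, stack, _ = noisy_phantom
        mask, gh, smc, _ = analyze_phantom(stack)
        vv = voxel_volume(params.voxel_size_nm)
        for fset in (gh, smc):
            for f in fset.foci:
                assert f.volume_um3 == pytest.approx(f.volume_voxels * vv)
                assert f.volume_voxels >= fset.min_voxels

    def test_empty_nucleus_no_foci_no_error(self):
        mask = _box_mask()
        ch = np.full(mask.labels.shape, 7.0)
        det = foci.detect_foci(ch, mask, min_voxels=10)
        assert det.foci == []

    def test_unknown_threshold_method_is_config_error(self):
        mask = _box_mask()
        with pytest.raises(ValueError, match="threshold_method"):
            foci.detect_foci(np.zeros(mask.labels.shape), mask, 10,
                             threshold_method="magic")

    def test_min_voxels_monotonicity(self, noisy_phantom):
        _, stack, _ = noisy_phantom
        mask = foci.segment_nuclei(stack.data[0])
        n_small = len(foci.detect_foci(stack.data[2], mask, 10).foci)
        n_large = len(foci.detect_foci(stack.data[2], mask, 50).foci)
        assert n_large <= n_small

    def test_intensity_threshold_monotonicity(self, noisy_phantom):
        _, stack, _ = noisy_phantom
        mask = foci.segment_nuclei(stack.data[0])
        vol_lo = sum(f.volume_voxels for f in
                     foci.detect_foci(stack.data[1], mask, 1, k_sd=3.0).foci)
        vol_hi = sum(f.volume_voxels for f in
                     foci.detect_foci(stack.data[1], mask, 1, k_sd=4.5).foci)
        assert vol_hi <= vol_lo

    def test_foci_voxel_sets_disjoint_within_channel(self, noisy_phantom):
        _, stack, _ = noisy_phantom
        _, gh, _, _ = analyze_phantom(stack)
        all_vox = np.concatenate([f.voxels_flat for f in gh.foci])
        assert all_vox.size == np.unique(all_vox).size


class TestOverlaps:
    def test_disjoint_channels_no_overlap(self):
        mask = _box_mask()
        a = np.zeros(mask.labels.shape)
        b = np.zeros(mask.labels.shape)
        a[8:10, 6:10, 6:10] = 50.0
        b[12:14, 16:20, 16:20] = 50.0
        gh = foci.detect_foci(a, mask, 10)
        smc = foci.detect_foci(b, mask, 10)
        assert foci.count_overlaps(gh, smc) == {1: 0}

    def test_one_smc6_spanning_two_gh2ax_counts_both(self):
        mask = _box_mask()
        gh_img = np.zeros(mask.labels.shape)
        smc_img = np.zeros(mask.labels.shape)
        gh_img[8:11, 6:10, 6:10] = 50.0  # focus 1
        gh_img[8:11, 14:18, 6:10] = 50.0  # focus 2
        smc_img[8:11, 6:18, 6:10] = 50.0  # one bar across both
        gh = foci.detect_foci(gh_img, mask, 10)
        smc = foci.detect_foci(smc_img, mask, 10)
        assert len(gh.foci) == 2 and len(smc.foci) == 1
        assert foci.count_overlaps(gh, smc) == {1: 2}

    def test_cocentered_phantom_full_overlap(self):
        params = FociPhantomParams(
            n_nuclei=4, coloc_prob=1.0, extra_smc6=0, noise=False,
            stack_shape=(42, 224, 224), seed=BASE_SEED + 3,
        )
        stack, truth = gen_foci_stack(params)
        mask, gh, smc, records = analyze_phantom(stack)
        for r in records:
            assert r.n_overlap == r.n_gh2ax


class TestRecordsAndSummaries:
    def test_selection_rule_and_undefined_fraction(self):
        recs = [
            foci.CellFociRecord(1, 5, 1, 1, 0.2, selected=False),
            foci.CellFociRecord(2, 0, 3, 0, None, selected=True),
            foci.CellFociRecord(3, 4, 2, 2, 0.5, selected=True),
        ]
        # nucleus with a single SMC6 focus is not selected
        assert recs[0].selected is False
        summary = foci.summarize_condition(recs)
        # cell with zero γH2AX foci excluded from the fraction average
        assert summary.mean_frac_smc6_positive == pytest.approx(0.5)
        assert summary.n_cells == 2

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            foci.CellFociRecord(1, 2, 1, 3, 1.5, selected=True)
        with pytest.raises(ValueError):
            foci.CellFociRecord(1, 0, 1, 0, 0.0, selected=False)

    def test_hand_arithmetic_mean_sem(self):
        recs = [
            foci.CellFociRecord(1, 4, 2, 2, 0.5, selected=True),
            foci.CellFociRecord(2, 6, 2, 3, 0.5, selected=True),
        ]
        s = foci.summarize_condition(recs)
        assert s.mean_gh2ax == pytest.approx(5.0)
        assert s.sem_gh2ax == pytest.approx(1.0)

    def test_single_cell_sem_missing(self):
        recs = [foci.CellFociRecord(1, 4, 2, 2, 0.5, selected=True)]
        s = foci.summarize_condition(recs)
        assert s.sem_gh2ax is None and s.sem_frac_smc6_positive is None

    def test_noiseless_phantom_totals_match_ground_truth(self, noiseless_phantom):
        params, stack, truth = noiseless_phantom
        mask, gh, smc, records = analyze_phantom(stack)
        mapping = match_truth(mask, truth, params.voxel_size_nm)
        for r in records:
            nt = mapping[r.nucleus_label]
            assert (r.n_gh2ax, r.n_smc6, r.n_overlap) == (
                nt.n_gh2ax, nt.n_smc6, nt.n_overlap,
            )

    def test_pooled_mode(self):
        recs = [
            foci.CellFociRecord(1, 8, 2, 2, 0.25, selected=True),
            foci.CellFociRecord(2, 2, 2, 2, 1.0, selected=True),
        ]
        s = foci.summarize_condition(recs, pooled=True)
        assert s.mean_frac_smc6_positive == pytest.approx(4 / 10)
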