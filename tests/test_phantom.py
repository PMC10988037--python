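"""Vessel-tree growth, capsule rasterization (vs brute-force oracle), CT rendering."""

import numpy as np
import pytest

from vesseg.phantom import (
    PhantomConfig,
    VesselSegment,
    VesselTree,
    grow_vessel_tree,
    make_dataset,
    make_phantom,
    rasterize_tree,
    render_ct,
)
from vesseg.volumes import read_nifti_image, read_nifti_mask, write_nifti


def brute_force_rasterize(tree, shape, spacing):
    """Independent oracle: per-voxel min distance to every segment axis."""
    out = np.zeros(shape, dtype=np.uint8)
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * np.asarray(spacing, dtype=float)
    for seg in tree.segments:
        a, b = np.asarray(seg.start), np.asarray(seg.end)
        ab = b - a
        denom = ab @ ab
        if denom < 1e-12:
            d2 = np.sum((centers - a) ** 2, axis=1)
        else:
            t = np.clip((centers - a) @ ab / denom, 0, 1)
            d2 = np.sum((centers - (a + t[:, None] * ab)) ** 2, axis=1)
        out.reshape(-1)[d2 <= seg.radius**2] = 1
    return out


class TestGrowTree:
    def test_seeded_reproducibility(self):
        cfg = PhantomConfig(rng_seed=3)
        t1 = grow_vessel_tree(cfg)
        t2 = grow_vessel_tree(cfg)
        assert t1.segments == t2.segments

    def test_single_level_is_root_only(self):
        cfg = PhantomConfig(n_branch_levels=1)
        tree = grow_vessel_tree(cfg)
        assert len(tree) == 1
        assert tree.segments[0].radius == cfg.root_radius

    def test_geometric_radius_taper(self):
        cfg = PhantomConfig(root_radius=4.0, radius_taper=0.7, n_branch_levels=3,
                            target_foreground_fraction=0.02)
        tree = grow_vessel_tree(cfg)
        level3 = [s for s in tree.segments if s.level == 3]
        assert level3
        for seg in level3:
            assert seg.radius == pytest.approx(4 * 0.7**2)

    def test_child_radius_never_exceeds_parent(self):
        tree = grow_vessel_tree(PhantomConfig(rng_seed=9))
        by_level = {}
        for s in tree.segments:
            by_level.setdefault(s.level, []).append(s.radius)
        for lvl in sorted(by_level)[:-1]:
            assert max(by_level[lvl + 1]) <= min(by_level[lvl])

    def test_endpoints_inside_bounds(self):
        tree = grow_vessel_tree(PhantomConfig(rng_seed=17))
        for seg in tree.segments:
            for p in (seg.start, seg.end):
                assert all(0 <= c <= b for c, b in zip(p, tree.bounds_mm))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="root_radius"):
            PhantomConfig(root_radius=0)
        with pytest.raises(ValueError, match="16 voxels"):
            PhantomConfig(shape=(8, 64, 64))
        with pytest.raises(ValueError, match="radius_taper"):
            PhantomConfig(radius_taper=1.0)
        with pytest.raises(ValueError, match="foreground_fraction"):
            PhantomConfig(target_foreground_fraction=0.2)


class TestRasterize:
    def test_empty_tree_warns_and_zeroes(self):
        tree = VesselTree([], (32.0, 32.0, 32.0))
        with pytest.warns(UserWarning, match="empty"):
            mask = rasterize_tree(tree, (32, 32, 32), (1, 1, 1))
        assert mask.voxels.sum() == 0

    def test_axis_aligned_tube_volume(self):
        """Radius 3 mm, length 40 mm at 1 mm spacing: voxel count within
        10% of the capsule volume pi*r^2*L + 4/3 pi r^3."""
        tree = VesselTree(
            [VesselSegment((24.0, 24.0, 4.0), (24.0, 24.0, 44.0), 3.0)],
            (48.0, 48.0, 48.0),
        )
        mask = rasterize_tree(tree, (48, 48, 48), (1, 1, 1))
        expected = np.pi * 9 * 40 + 4 / 3 * np.pi * 27
        assert abs(int(mask.voxels.sum()) - expected) < 0.10 * expected

    def test_spacing_halves_count_along_axis(self):
        tree = VesselTree(
            [VesselSegment((16.0, 16.0, 4.0), (16.0, 16.0, 60.0), 3.0)],
            (32.0, 32.0, 64.0),
        )
        fine = rasterize_tree(tree, (32, 32, 64), (1, 1, 1))
        coarse = rasterize_tree(tree, (32, 32, 32), (1, 1, 2))
        ratio = fine.voxels.sum() / coarse.voxels.sum()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_agrees_with_brute_force_oracle(self):
        for seed in (0, 1, 2):
            cfg = PhantomConfig(shape=(24, 24, 24), spacing=(1, 1, 1.5),
                                root_radius=2.0, rng_seed=seed)
            tree = grow_vessel_tree(cfg)
            fast = rasterize_tree(tree, cfg.shape, cfg.spacing)
            oracle = brute_force_rasterize(tree, cfg.shape, cfg.spacing)
            assert np.array_equal(fast.voxels, oracle)

    def test_foreground_monotone_in_root_radius(self):
        counts = []
        for r in (1.0, 1.5, 2.0, 3.0):
            cfg = PhantomConfig(shape=(32, 32, 32), spacing=(1, 1, 1),
                                root_radius=r, rng_seed=4,
                                target_foreground_fraction=0.05)
            tree = grow_vessel_tree(cfg)
            counts.append(rasterize_tree(tree, cfg.shape, cfg.spacing).voxels.sum())
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestRenderCT:
    def test_zero_noise_two_values(self, small_phantom_pair):
        _, mask = small_phantom_pair
        cfg = PhantomConfig(shape=mask.shape, spacing=mask.spacing, noise_sigma=0.0)
        img = render_ct(mask, cfg)
        assert len(np.unique(img.voxels)) == 2

    def test_empty_mask_stays_background(self):
        from vesseg.volumes import MaskVolume

        cfg = PhantomConfig(shape=(16, 16, 16), spacing=(1, 1, 1), noise_sigma=10.0)
        mask = MaskVolume(np.zeros(cfg.shape, dtype=np.uint8), cfg.spacing)
        img = render_ct(mask, cfg)
        # nothing near the vessel intensity beyond noise expectation
        assert img.voxels.max() < cfg.background_mean + cfg.vessel_contrast - 3 * cfg.noise_sigma

    def test_contrast_recovered_within_noise(self, small_phantom_pair):
        _, mask = small_phantom_pair
        cfg = PhantomConfig(shape=mask.shape, spacing=mask.spacing, rng_seed=2)
        img = render_ct(mask, cfg)
        fg = mask.voxels.astype(bool)
        n = min(fg.sum(), (~fg).sum())
        observed = img.voxels[fg].mean() - img.voxels[~fg].mean()
        assert abs(observed - cfg.vessel_contrast) < 3 * cfg.noise_sigma / np.sqrt(n)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(noise_sigma=-1.0)


class TestMakeDataset:
    def test_reproducible_and_distinct(self):
        cfg = PhantomConfig(shape=(32, 32, 16), spacing=(1, 1, 2), rng_seed=21,
                            root_radius=1.8)
        d1 = make_dataset(cfg, 3)
        d2 = make_dataset(cfg, 3)
        for (i1, m1), (i2, m2) in zip(d1, d2):
            assert np.array_equal(i1.voxels, i2.voxels)
            assert np.array_equal(m1.voxels, m2.voxels)
        assert not np.array_equal(d1[0][1].voxels, d1[1][1].voxels)

    def test_foreground_fraction_band(self):
        cfg = PhantomConfig(shape=(32, 32, 32), spacing=(1, 1, 1), rng_seed=2,
                            root_radius=1.8, target_foreground_fraction=0.01)
        for _, mask in make_dataset(cfg, 4):
            assert 0.0025 <= mask.foreground_fraction <= 0.04

    def test_zero_volumes_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(PhantomConfig(), 0)


class TestNiftiRoundTrip:
    def test_bit_exact_roundtrip(self, tmp_path, small_phantom_pair):
        image, mask = small_phantom_pair
        ip = str(tmp_path / "img.nii.gz")
        mp = str(tmp_path / "msk.nii.gz")
        write_nifti(image, ip)
        write_nifti(mask, mp)
        image2 = read_nifti_image(ip)
        mask2 = read_nifti_mask(mp)
        assert np.array_equal(image.voxels, image2.voxels)
        assert np.array_equal(mask.voxels, mask2.voxels)
        assert image2.spacing == pytest.approx(image.spacing)
        assert mask2.spacing == pytest.approx(mask.spacing)
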