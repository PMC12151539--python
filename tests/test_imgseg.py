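"""Segmentation primitives: background subtraction, thresholding,
labeling, object filtering, spot detection."""

import numpy as np
import pytest
from scipy import ndimage

import helpers
from synquant import imgseg
from synquant.imgseg import VoxelGrid


def _grid3(data, vsz=(0.4, 0.2, 0.2)):
    return VoxelGrid(np.asarray(data, dtype=float), vsz)


def _ball_image(shape, center_vox, radius_um, vsz, amplitude=100.0):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center_vox, vsz))
    return np.where(d2 <= radius_um**2, amplitude, 0.0)


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        grid = _grid3(np.full((8, 16, 16), 37.0))
        out = imgseg.subtract_background(grid, 1.0)
        assert np.allclose(out.data, 0.0)

    def test_small_punctum_preserved(self):
        vsz = (0.2, 0.1, 0.1)
        img = _ball_image((20, 40, 40), (10, 20, 20), 0.3, vsz)
        grid = VoxelGrid(img, vsz)
        out = imgseg.subtract_background(grid, 1.0)
        assert out.data.sum() >= 0.99 * img.sum()

    def test_offset_invariance(self):
        vsz = (0.2, 0.1, 0.1)
        img = _ball_image((20, 40, 40), (10, 20, 20), 0.3, vsz)
        out0 = imgseg.subtract_background(VoxelGrid(img, vsz), 1.0)
        outb = imgseg.subtract_background(VoxelGrid(img + 25.0, vsz), 1.0)
        assert np.allclose(out0.data, outb.data, atol=1e-6)

    def test_radius_below_voxel_names_axis(self):
        grid = _grid3(np.zeros((4, 8, 8)), vsz=(0.5, 0.1, 0.1))
        with pytest.raises(ValueError, match="'z'"):
            imgseg.subtract_background(grid, 0.3)


class TestThreshold:
    def test_otsu_separates_bimodal(self):
        rng = np.random.default_rng(0)
        data = np.concatenate([
            rng.normal(10, 1, 500), rng.normal(100, 1, 500)
        ]).reshape(10, 10, 10)
        mask = imgseg.threshold(_grid3(data), "otsu")
        # The implied cutoff separates the modes: all of the bright mode
        # is selected and essentially none of the dim mode.
        assert mask[data > 90].all()
        assert mask[data < 15].mean() < 0.01

    def test_manual_value_selects_upper(self):
        data = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 40.0, 60.0)
        mask = imgseg.threshold(VoxelGrid(data, (1.0, 1.0)), "manual", 50.0)
        assert np.array_equal(mask, data == 60.0)

    def test_otsu_constant_image_warns_empty(self):
        grid = _grid3(np.full((4, 8, 8), 5.0))
        with pytest.warns(UserWarning, match="constant"):
            mask = imgseg.threshold(grid, "otsu")
        assert not mask.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_otsu_matches_bruteforce_sweep(self, seed):
        rng = np.random.default_rng(seed)
        modes = rng.uniform(10, 240, size=2)
        data = np.concatenate([
            rng.normal(modes[0], rng.uniform(2, 12), 600),
            rng.normal(modes[1], rng.uniform(2, 12), 400),
        ]).clip(0, 255).reshape(10, 10, 10)
        from skimage.filters import threshold_otsu

        t_impl = threshold_otsu(data)
        t_oracle = helpers.brute_otsu_threshold(data)
        v_impl = helpers.binned_between_class_variance(data, t_impl)
        v_oracle = helpers.binned_between_class_variance(data, t_oracle)
        # Same maximal between-class variance (plateau ties are equivalent).
        assert v_impl == pytest.approx(v_oracle, rel=1e-9)
        mask = imgseg.threshold(_grid3(data), "otsu")
        assert np.array_equal(mask, data > t_impl)

    def test_inflection_lies_on_descending_limb(self):
        rng = np.random.default_rng(3)
        # Bulk background + sparse bright tail.
        data = np.concatenate([
            rng.normal(20, 4, 5000), rng.uniform(60, 200, 250)
        ]).reshape(50, 105)
        t_mask = imgseg.threshold(VoxelGrid(data, (1.0, 1.0)), "inflection")
        # Cutoff above the background mode, below the tail maximum.
        selected = data[t_mask]
        assert selected.min() > 20
        assert t_mask.sum() > 0


class TestLabeling:
    def test_two_separated_spheres(self):
        vsz = (0.2, 0.2, 0.2)
        img = (_ball_image((20, 40, 40), (10, 10, 10), 1.0, vsz)
               + _ball_image((20, 40, 40), (10, 30, 30), 1.0, vsz))
        labels = imgseg.label_components(img > 0)
        assert labels.max() == 2

    def test_empty_mask(self):
        assert imgseg.label_components(np.zeros((4, 4, 4), bool)).max() == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_masks_match_flood_fill(self, connectivity):
        rng = np.random.default_rng(11)
        for _ in range(5):
            mask = rng.random((16, 16, 16)) < 0.2
            labels = imgseg.label_components(mask, connectivity)
            assert labels.max() == helpers.flood_fill_count(mask, connectivity)

    def test_idempotent_and_label_order_free(self):
        rng = np.random.default_rng(5)
        mask = rng.random((12, 12, 12)) < 0.25
        l1 = imgseg.label_components(mask, 26)
        l2 = imgseg.label_components(l1 > 0, 26)
        # Same partition, regardless of label numbering.
        assert l1.max() == l2.max()
        for cid in range(1, l1.max() + 1):
            vals = np.unique(l2[l1 == cid])
            assert len(vals) == 1


class TestFilterObjects:
    def test_strict_inequality_bounds(self):
        # Objects of exactly 10, 11, 1999 and 2000 voxels; bounds (10, 2000)
        # keep only the strictly-inside sizes 11 and 1999.  One object per
        # z-slice pair so they cannot touch.
        sizes = [10, 11, 1999, 2000]
        labels = np.zeros((8, 50, 50), dtype=np.int32)
        for i, size in enumerate(sizes, start=1):
            z = (i - 1) * 2
            flat_idx = np.unravel_index(np.arange(size), (50, 50))
            labels[z][flat_idx] = i
        filtered = imgseg.filter_objects(labels, 10, 2000)
        surviving = sorted(np.bincount(filtered.ravel())[1:].tolist())
        assert surviving == [11, 1999]

    def test_all_within_bounds_is_identity_up_to_relabel(self):
        rng = np.random.default_rng(2)
        mask = ndimage.binary_dilation(rng.random((16, 16, 16)) < 0.02)
        labels = imgseg.label_components(mask, 26)
        filtered = imgseg.filter_objects(labels, 1, 10**6)
        assert (filtered > 0).sum() == (labels > 0).sum()
        assert filtered.max() == labels.max()

    def test_survivors_match_per_object_size_oracle(self):
        rng = np.random.default_rng(9)
        mask = rng.random((24, 24, 24)) < 0.15
        labels = imgseg.label_components(mask, 26)
        lo, hi = 3, 30
        filtered = imgseg.filter_objects(labels, lo, hi)
        sizes = imgseg.object_sizes(labels)
        expected = {cid for cid, s in sizes.items() if lo < s < hi}
        kept = set()
        for cid in expected:
            vals = np.unique(filtered[labels == cid])
            assert len(vals) == 1 and vals[0] > 0
            kept.add(int(vals[0]))
        assert len(kept) == len(expected)
        assert filtered.max() == len(expected)
        removed = set(sizes) - expected
        for cid in removed:
            assert (filtered[labels == cid] == 0).all()


class TestDetectSpots:
    VSZ = (0.25, 0.1, 0.1)

    def _render_gaussians(self, centers_um, shape=(16, 128, 128), sigma_um=(0.25, 0.12, 0.12)):
        img = np.zeros(shape)
        vsz = np.array(self.VSZ)
        sig_vox = np.array(sigma_um) / vsz
        half = np.ceil(5 * sig_vox).astype(int)
        for c in centers_um:
            cv = np.array(c) / vsz - 0.5
            lo = np.maximum(0, np.floor(cv - half).astype(int))
            hi = np.minimum(shape, np.ceil(cv + half + 1).astype(int))
            grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
            d2 = sum(((g - cv[ax]) / sig_vox[ax]) ** 2 for ax, g in enumerate(grids))
            img[tuple(slice(a, b) for a, b in zip(lo, hi))] += 100.0 * np.exp(-0.5 * d2)
        return VoxelGrid(img, self.VSZ)

    def test_single_punctum_recovered(self):
        center_zyx = (2.05, 6.44, 7.01)
        grid = self._render_gaussians([center_zyx])
        spots = imgseg.detect_spots(grid, (0.25, 0.425))
        assert len(spots) == 1
        x, y, z = spots.spots[0].center_um
        assert abs(z - center_zyx[0]) <= 0.5 * self.VSZ[0]
        assert abs(y - center_zyx[1]) <= 0.5 * self.VSZ[1]
        assert abs(x - center_zyx[2]) <= 0.5 * self.VSZ[2]

    def test_empty_image_no_spots(self):
        grid = VoxelGrid(np.zeros((8, 32, 32)), self.VSZ)
        assert len(imgseg.detect_spots(grid, (0.25, 0.425))) == 0

    def test_dense_field_full_recall_precision(self):
        rng = np.random.default_rng(21)
        # 100 puncta separated by > 4x the spot radius, SNR 10.
        centers = []
        lo = np.array([1.0, 1.5, 1.5])
        hi = np.array([5.0, 24.1, 24.1])
        while len(centers) < 100:
            p = rng.uniform(lo, hi)
            if all(np.linalg.norm(p - q) > 1.8 for q in centers):
                centers.append(p)
        grid = self._render_gaussians(centers, shape=(24, 256, 256))
        noisy = VoxelGrid(
            grid.data + rng.normal(50.0, 10.0, grid.data.shape), self.VSZ
        )
        spots = imgseg.detect_spots(noisy, (0.25, 0.425))
        assert len(spots) == 100
        det_zyx = spots.centers_um[:, ::-1]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(np.array(centers)).query(det_zyx)
        assert (d < 0.25).all()  # every center within one voxel-scale radius

    def test_radii_below_voxel_size_error(self):
        grid = VoxelGrid(np.zeros((8, 32, 32)), self.VSZ)
        with pytest.raises(ValueError, match="voxel"):
            imgseg.detect_spots(grid, (0.05, 0.425))


def test_labeled_volume_matches_analytic_sphere():
    # Voxel-count volume of a rasterized sphere is within 5% of 4/3 pi r^3
    # once the radius spans >= 4 voxels per axis.
    vsz = (0.2, 0.2, 0.2)
    r = 1.0  # 5 voxels
    img = _ball_image((24, 24, 24), (12.3, 11.8, 12.1), r, vsz)
    labels = imgseg.label_components(img > 0)
    count = (labels == 1).sum()
    analytic = 4.0 / 3.0 * np.pi * r**3
    assert abs(count * np.prod(vsz) - analytic) / analytic <= 0.05
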