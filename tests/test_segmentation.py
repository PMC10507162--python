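"""Segmentation and measurement checks against geometric oracles."""

import numpy as np
import pytest

from mitoglia import (
    DomainError,
    SegmentationParams,
    VoxelImage,
    measure_components,
    segment_cell_channels,
    wadell_sphericity,
)
from conftest import flood_fill_components, label_grid_components

ISO = (0.05, 0.05, 0.05)
ANISO = (0.15, 0.05, 0.05)


def _ball_image(radius_um, spacing, pad_um=0.3):
    extent = radius_um + pad_um
    shape = tuple(int(np.ceil(2 * extent / s)) for s in spacing)
    center = np.array([(n * s) / 2 for n, s in zip(shape, spacing)])
    zz, yy, xx = np.meshgrid(*[
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
    ], indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return VoxelImage((d2 <= radius_um**2).astype(np.uint8), spacing)


def _full_mask_like(img):
    return VoxelImage(np.ones_like(img.data, dtype=np.uint8), img.spacing)


class TestSegmentCellChannels:
    def test_two_disjoint_blobs_give_two_labels(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[1:3, 1:3, 1:3] = 1
        data[6:9, 6:9, 6:9] = 1
        channel = VoxelImage(data, ISO)
        labels = segment_cell_channels(
            _full_mask_like(channel), channel, SegmentationParams(threshold=0.5)
        )
        assert labels.max() == 2

    def test_blob_outside_mask_gives_zero_labels(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[6:9, 6:9, 6:9] = 1
        mask = np.zeros_like(data)
        mask[0:4, 0:4, 0:4] = 1
        labels = segment_cell_channels(
            VoxelImage(mask, ISO), VoxelImage(data, ISO),
            SegmentationParams(threshold=0.5),
        )
        assert labels.max() == 0

    def test_shape_mismatch_is_dimension_error(self):
        a = VoxelImage(np.zeros((4, 4, 4)), ISO)
        b = VoxelImage(np.zeros((4, 4, 5)), ISO)
        with pytest.raises(DomainError, match="shape"):
            segment_cell_channels(a, b, SegmentationParams(threshold=0.5))

    def test_all_zero_mask_warns_and_returns_empty(self):
        img = VoxelImage(np.ones((4, 4, 4)), ISO)
        mask = VoxelImage(np.zeros((4, 4, 4)), ISO)
        labels = segment_cell_channels(mask, img, SegmentationParams(threshold=0.5))
        assert labels.max() == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labels_match_flood_fill_oracle(self, connectivity, rng):
        for _ in range(5):
            fg = rng.random((16, 16, 16)) < 0.18
            channel = VoxelImage(fg.astype(np.uint8), ISO)
            labels = segment_cell_channels(
                _full_mask_like(channel), channel,
                SegmentationParams(threshold=0.5, connectivity=connectivity),
            )
            got = set(label_grid_components(labels))
            expected = set(flood_fill_components(fg, connectivity))
            assert got == expected

    def test_min_volume_drops_small_components(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[1, 1, 1] = 1                    # 1 voxel
        data[5:8, 5:8, 5:8] = 1              # 27 voxels
        channel = VoxelImage(data, ISO)
        voxvol = channel.voxel_volume
        labels = segment_cell_channels(
            _full_mask_like(channel), channel,
            SegmentationParams(threshold=0.5, min_volume=5 * voxvol),
        )
        assert labels.max() == 1
        assert (labels > 0).sum() == 27


class TestMeasureComponents:
    def test_single_voxel_volume_anisotropic(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[1, 1, 1] = 1
        (rec,) = measure_components(labels, ANISO)
        assert rec.volume == pytest.approx(3.75e-4)
        np.testing.assert_allclose(rec.centroid, [1.5 * 0.15, 1.5 * 0.05, 1.5 * 0.05])

    def test_rasterized_sphere_volume_and_sphericity(self):
        ball = _ball_image(1.0, ISO)
        labels = ball.data.astype(np.int32)
        (rec,) = measure_components(labels, ISO)
        assert rec.volume == pytest.approx(4.18879, rel=0.05)
        assert rec.sphericity >= 0.95

    def test_prolate_ellipsoid_less_spherical_than_ball(self):
        spacing = (0.05, 0.05, 0.05)
        shape = (60, 240, 60)
        zz, yy, xx = np.meshgrid(*[
            (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
        ], indexing="ij")
        c = np.array([shape[k] * spacing[k] / 2 for k in range(3)])
        # 10:1 prolate: semi-axes (0.4, 4.0, 0.4) μm
        ell = (((zz - c[0]) / 0.4) ** 2 + ((yy - c[1]) / 4.0) ** 2
               + ((xx - c[2]) / 0.4) ** 2) <= 1
        (rec_e,) = measure_components(ell.astype(np.int32), spacing)
        ball = _ball_image((0.4 * 0.4 * 4.0) ** (1 / 3), ISO)
        (rec_b,) = measure_components(ball.data.astype(np.int32), ISO)
        assert rec_e.volume == pytest.approx(rec_b.volume, rel=0.06)
        assert rec_e.sphericity < rec_b.sphericity
        # analytic Wadell sphericity of a 10:1 prolate spheroid is ~0.58
        assert rec_e.sphericity == pytest.approx(0.58, abs=0.05)

    def test_empty_labeling_gives_empty_list(self):
        assert measure_components(np.zeros((4, 4, 4), np.int32), ISO) == []

    def test_volume_conservation_against_foreground(self, rng):
        fg = rng.random((20, 20, 20)) < 0.1
        channel = VoxelImage(fg.astype(np.uint8), ANISO)
        labels = segment_cell_channels(
            _full_mask_like(channel), channel, SegmentationParams(threshold=0.5)
        )
        records = measure_components(labels, ANISO)
        total = sum(r.volume for r in records)
        assert total == pytest.approx(fg.sum() * channel.voxel_volume)

    def test_measurements_invariant_to_axis_permutation(self):
        data = np.zeros((8, 10, 12), np.int32)
        data[2:5, 3:8, 4:10] = 1
        spacing = (0.15, 0.05, 0.08)
        (rec,) = measure_components(data, spacing)
        perm = (2, 0, 1)
        data_p = np.transpose(data, perm)
        spacing_p = tuple(spacing[k] for k in perm)
        (rec_p,) = measure_components(data_p, spacing_p)
        assert rec_p.volume == pytest.approx(rec.volume)
        # marching-cubes triangulation is not exactly symmetric under axis
        # permutation; agreement to 1e-4 relative is the discretization floor
        assert rec_p.surface_area == pytest.approx(rec.surface_area, rel=1e-4)
        assert rec_p.sphericity == pytest.approx(rec.sphericity, rel=1e-4)

    def test_sphericity_approaches_one_under_refinement(self):
        errs = []
        for factor in (1, 2, 4):
            s = 0.2 / factor
            ball = _ball_image(1.0, (s, s, s))
            (rec,) = measure_components(ball.data.astype(np.int32), (s, s, s))
            errs.append(abs(rec.sphericity - 1.0))
        assert errs[1] <= errs[0] + 0.02
        assert errs[2] <= errs[1] + 0.02
        assert errs[2] < 0.05


def test_wadell_sphericity_of_ball_is_one():
    v = 4.18879
    a = np.pi ** (1 / 3) * (6 * v) ** (2 / 3)
    assert wadell_sphericity(v, a) == pytest.approx(1.0)
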