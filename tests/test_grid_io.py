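"""Grid/mask containers, portable-format round trips, and rasterisation."""

import numpy as np
import pytest

from vmatqa import (
    DoseGrid,
    GridFormatError,
    GridValidationError,
    StructureMask,
    coregistered,
    rasterize_contours,
    rasterize_ellipsoid,
    read_grid,
    read_mask,
    write_grid,
    write_mask,
)


class TestDoseGrid:
    def test_invariants_enforced(self):
        with pytest.raises(GridValidationError):
            DoseGrid((0, 0, 0), (1, -1, 1), np.zeros((2, 2, 2)))
        with pytest.raises(GridValidationError):
            DoseGrid((0, 0, 0), (1, 1, 1), np.full((2, 2, 2), -0.5))
        with pytest.raises(GridValidationError):
            DoseGrid((0, 0, 0), (1, 1, 1), np.full((2, 2, 2), np.nan))

    def test_voxel_positions(self):
        grid = DoseGrid((-3, 0, 5), (3, 2, 1), np.zeros((4, 3, 2)))
        assert np.allclose(grid.axis_coords(0), [-3, 0, 3, 6])
        assert np.allclose(grid.axis_coords(2), [5, 6])
        assert np.allclose(grid.extent(), [9, 4, 1])

    def test_coregistration_symmetric_and_transitive(self):
        grids = [
            DoseGrid((0, 0, 0), (1, 1, 1), np.random.default_rng(i).random((2, 2, 2)))
            for i in range(3)
        ]
        other = DoseGrid((1, 0, 0), (1, 1, 1), np.zeros((2, 2, 2)))
        for a in grids:
            for b in grids:
                assert coregistered(a, b) == coregistered(b, a) is True
        assert not coregistered(grids[0], other)
        # transitivity across the chain
        assert coregistered(grids[0], grids[1]) and coregistered(grids[1], grids[2])
        assert coregistered(grids[0], grids[2])


class TestPortableFormat:
    def test_declared_layout(self, tmp_path):
        # dims (2,2,1), values in (x, y, z) C-order: value at index (1,1,0) is 3
        path = tmp_path / "g.grid"
        path.write_text(
            "# vmatqa grid v1\n"
            "kind: dose\nframe_id: f1\n"
            "spacing: 1 1 1\norigin: 0 0 0\n"
            "dims: 2 2 1\ndata:\n0\n1\n2\n3\n"
        )
        grid = read_grid(path)
        assert grid.values[1, 1, 0] == 3.0
        assert grid.frame_id == "f1"

    def test_round_trip_identity(self, tmp_path, rng):
        grid = DoseGrid((-10, 2.5, 7), (3, 3, 2.5), rng.random((5, 4, 3)) * 60, "fr")
        write_grid(grid, tmp_path / "g.grid")
        back = read_grid(tmp_path / "g.grid")
        assert np.array_equal(back.values, grid.values)  # bit-exact
        assert np.array_equal(back.origin, grid.origin)
        assert coregistered(grid, back)

    def test_single_voxel(self, tmp_path):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.full((1, 1, 1), 50.09))
        write_grid(grid, tmp_path / "one.grid")
        assert read_grid(tmp_path / "one.grid").values[0, 0, 0] == 50.09

    def test_round_trip_randomized(self, tmp_path):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dims = tuple(rng.integers(1, 5, 3))
            grid = DoseGrid(
                rng.normal(0, 100, 3),
                rng.uniform(0.1, 5, 3),
                rng.random(dims) * rng.uniform(1, 100),
            )
            path = tmp_path / f"rt-{seed}.grid"
            write_grid(grid, path)
            back = read_grid(path)
            assert np.max(np.abs(back.values - grid.values)) == 0.0

    def test_mask_round_trip(self, tmp_path, rng):
        mask = StructureMask("rectum", (0, 0, 0), (3, 3, 3), rng.random((4, 4, 4)) > 0.5)
        write_mask(mask, tmp_path / "m.grid")
        back = read_mask(tmp_path / "m.grid")
        assert back.name == "rectum"
        assert np.array_equal(back.voxels, mask.voxels)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("wrong magic\n", "magic"),
            ("# vmatqa grid v1\nspacing: 1 1 1\norigin: 0 0 0\ndims: 2 2 1\ndata:\n0 1 2\n", "expected 4 values"),
            ("# vmatqa grid v1\norigin: 0 0 0\ndims: 1 1 1\ndata:\n0\n", "spacing"),
            ("# vmatqa grid v1\nspacing: 1 1\norigin: 0 0 0\ndims: 1 1 1\ndata:\n0\n", "spacing"),
        ],
    )
    def test_malformed_header_names_field(self, tmp_path, content, match):
        path = tmp_path / "bad.grid"
        path.write_text(content)
        with pytest.raises(GridFormatError, match=match):
            read_grid(path)

    def test_negative_spacing_is_validation_error(self, tmp_path):
        path = tmp_path / "neg.grid"
        path.write_text(
            "# vmatqa grid v1\nkind: dose\nspacing: 1 -1 1\norigin: 0 0 0\n"
            "dims: 1 1 1\ndata:\n0\n"
        )
        with pytest.raises(GridValidationError):
            read_grid(path)


class TestRasterizeEllipsoid:
    def test_sphere_volume_matches_analytic(self):
        grid = DoseGrid((-15, -15, -15), (0.5, 0.5, 0.5), np.zeros((61, 61, 61)))
        mask = rasterize_ellipsoid(grid, (0, 0, 0), (10, 10, 10))
        assert mask.volume_mm3() == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.02)

    def test_subvoxel_ellipsoid_is_single_voxel(self):
        grid = DoseGrid((0, 0, 0), (2, 2, 2), np.zeros((5, 5, 5)))
        mask = rasterize_ellipsoid(grid, (4, 4, 4), (0.9, 0.9, 0.9))
        assert mask.n_true == 1
        assert mask.voxels[2, 2, 2]

    def test_matches_per_voxel_brute_force(self, rng):
        grid = DoseGrid((-9, -9, -9), (1.5, 2.0, 3.0), np.zeros((13, 10, 7)))
        center, radii = (1.0, -2.0, 0.5), (7.0, 5.0, 6.0)
        mask = rasterize_ellipsoid(grid, center, radii)
        brute = np.zeros(grid.dims, dtype=bool)
        for i in range(grid.dims[0]):
            for j in range(grid.dims[1]):
                for k in range(grid.dims[2]):
                    p = grid.origin + np.array([i, j, k]) * grid.spacing
                    brute[i, j, k] = np.sum(((p - center) / radii) ** 2) <= 1
        assert np.array_equal(mask.voxels, brute)

    def test_outside_grid_is_error(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((4, 4, 4)))
        with pytest.raises(GridValidationError, match="no voxel"):
            rasterize_ellipsoid(grid, (100, 100, 100), (1, 1, 1))


class TestDicom:
    def test_rtdose_scaling_and_geometry(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        nx, ny, nz = 3, 2, 2
        stored = np.zeros((nz, ny, nx), dtype=np.uint32)
        stored[0, 1, 2] = 50090  # x=2, y=1, z=0
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
        ds.PixelSpacing = [2.0, 3.0]  # row (y), column (x)
        ds.ImagePositionPatient = [-10.0, -20.0, 5.0]
        ds.GridFrameOffsetVector = [0.0, 2.5]
        ds.DoseGridScaling = 0.001
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.PixelData = stored.tobytes()
        path = tmp_path / "dose.dcm"
        ds.save_as(path, enforce_file_format=True)

        grid = read_grid(path, format="rtdose")
        assert grid.dims == (nx, ny, nz)
        assert grid.values[2, 1, 0] == pytest.approx(50.09)
        assert np.allclose(grid.spacing, [3.0, 2.0, 2.5])
        assert np.allclose(grid.origin, [-10.0, -20.0, 5.0])


class TestRasterizeContours:
    def test_square_contour_area(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((20, 20, 3)))
        square = np.array(
            [[4.0, 4.0, 1.0], [14.0, 4.0, 1.0], [14.0, 14.0, 1.0], [4.0, 14.0, 1.0]]
        )
        mask = rasterize_contours(grid, [square], name="sq")
        assert mask.voxels[:, :, 0].sum() == 0 and mask.voxels[:, :, 2].sum() == 0
        # 10 mm x 10 mm square on a 1 mm grid: between the open interior
        # (9x9 centres) and the closed hull (11x11 centres)
        assert 81 <= mask.voxels[:, :, 1].sum() <= 121
        assert mask.voxels[9, 9, 1]

    def test_off_slice_contour_rejected(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((5, 5, 2)))
        tilted = np.array([[0, 0, 0.0], [2, 0, 0.4], [2, 2, 0.0]])
        with pytest.raises(ValueError, match="planar"):
            rasterize_contours(grid, [tilted])
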