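"""Proportional grid construction, ROI enumeration, AC/PC alignment."""

import numpy as np
import pytest
from scipy import ndimage

from csfspace import talairach as tal
from csfspace.grid import VolumeGrid


def make_grid(bbox_lo=(0, 0, 0), bbox_hi=(80, 110, 50), ac=(40, 70, 25), pc=(40, 46, 25)):
    return tal.build_grid(tal.BoundingBox(bbox_lo, bbox_hi), ac, pc)


class TestBuildGrid:
    def test_total_cell_count_is_1056(self):
        grid = make_grid()
        assert grid.n_cells == 1056
        assert (len(grid.ap_bounds), len(grid.is_bounds), len(grid.sag_bounds)) == (12, 13, 9)

    def test_division_widths_follow_proportional_rules(self):
        # AP extent 110 with AC 40 from the anterior edge and PC 24 behind AC:
        # anterior widths 40/4, AC-PC widths 24/3, posterior widths 46/4
        grid = make_grid()
        widths = np.diff(grid.ap_bounds)
        assert np.allclose(widths[7:], 10.0)   # anterior-of-AC divisions
        assert np.allclose(widths[4:7], 8.0)   # AC-to-PC divisions
        assert np.allclose(widths[:4], 11.5)   # posterior-of-PC divisions

    def test_reference_planes_pass_through_landmarks(self):
        grid = make_grid()
        assert grid.vac(0) == 70 and grid.vpc(0) == 46
        assert grid.acpc(0) == 25
        assert grid.m(0) == 40

    def test_sagittal_bounds_mirror_symmetric_for_symmetric_bbox(self):
        grid = make_grid()
        mid = grid.m(0)
        left = mid - np.array([grid.m(-k) for k in range(1, 5)])
        right = np.array([grid.m(k) for k in range(1, 5)]) - mid
        assert np.allclose(left, right)

    def test_scale_equivariance(self):
        g1 = make_grid()
        g2 = tal.build_grid(
            tal.BoundingBox((0, 0, 0), (160, 220, 100)), (80, 140, 50), (80, 92, 50)
        )
        for attr in ("ap_bounds", "is_bounds", "sag_bounds"):
            assert np.allclose(getattr(g2, attr), 2 * np.asarray(getattr(g1, attr)))

    def test_named_plane_outside_grid_raises(self):
        grid = make_grid()
        with pytest.raises(tal.GridError):
            grid.vac(5)
        with pytest.raises(tal.GridError):
            grid.acpc(-5)

    @pytest.mark.parametrize(
        "ac,pc,msg",
        [
            ((40, 46, 25), (40, 46, 25), "coincide"),
            ((40, 46, 25), (40, 70, 25), "anterior"),
            ((40, 110, 25), (40, 46, 25), "zero-width"),
            ((40, 70, 30), (40, 46, 25), "axial"),
        ],
    )
    def test_degenerate_landmarks_rejected(self, ac, pc, msg):
        with pytest.raises(tal.GridError, match=msg):
            make_grid(ac=ac, pc=pc)


class TestPartition:
    def test_cells_tile_the_bounding_box_exactly(self):
        grid = make_grid(bbox_lo=(3, 5, 2), bbox_hi=(77, 103, 49))
        shape = (84, 112, 56)
        sag_c, ap_c, is_c = grid.cell_indices(shape)
        inside = (sag_c >= 0)[:, None, None] & (ap_c >= 0)[None, :, None] & (is_c >= 0)[None, None, :]
        bbox_voxels = np.prod([
            int(h) - int(np.ceil(l)) + 1 for l, h in zip(grid.bbox.lo, grid.bbox.hi)
        ])
        assert inside.sum() == bbox_voxels
        # disjointness: each inside voxel maps to exactly one (sag, ap, is) cell
        cell_id = (sag_c[:, None, None] * 1000 + ap_c[None, :, None] * 20
                   + is_c[None, None, :])[inside]
        counts = np.bincount(cell_id.ravel())
        assert counts.sum() == bbox_voxels


def enumerate_roi_cells(roi):
    """Independent enumeration of the grid cells satisfying the printed
    coordinate ranges; cells are named by (ap, is, sag) division indices
    counted from the posterior/inferior/left edge of the bounding box."""
    # AP cells 0..10: 0-3 posterior of PC, 4-6 between PC and AC, 7-10 anterior
    # IS cells 0..11: 0-3 below AC-PC, 4-11 above
    # SAG cells 0..7: 0-3 left hemisphere, 4-7 right
    cells = []
    for ap in range(11):
        for is_ in range(12):
            for sag in range(8):
                if roi == "high_convexity":
                    ok = (
                        4 <= ap <= 7  # vPC(0) .. vAC(+1)
                        and 7 <= is_ <= 11  # AC-PC(+3) .. AC-PC(+8)
                        and 3 <= sag <= 4  # M(-1) .. M(+1)
                    )
                elif roi == "sylvian":
                    ok = (
                        3 <= ap <= 8  # vPC(-1) .. vAC(+2)
                        and 2 <= is_ <= 6  # AC-PC(-2) .. AC-PC(+3)
                        and (sag <= 1 or sag >= 6)  # M(+-2) .. M(+-4), both sides
                    )
                if ok:
                    cells.append((ap, is_, sag))
    return cells


class TestRoiMasks:
    def test_high_convexity_covers_40_cells(self):
        assert len(enumerate_roi_cells("high_convexity")) == 40
        assert tal.roi_cell_count("high_convexity") == 40

    def test_sylvian_covers_120_cells(self):
        assert len(enumerate_roi_cells("sylvian")) == 120
        assert tal.roi_cell_count("sylvian_both") == 120
        assert tal.roi_cell_count("sylvian_left") == 60

    def test_mask_cells_match_independent_enumeration(self):
        grid = make_grid()
        shape = (84, 112, 56)
        sag_c, ap_c, is_c = grid.cell_indices(shape)
        hc = tal.roi_mask(grid, "high_convexity", shape).data
        syl = tal.roi_mask(grid, "sylvian_both", shape).data
        for mask, roi in ((hc, "high_convexity"), (syl, "sylvian")):
            expected = set(enumerate_roi_cells(roi))
            got = set()
            for idx in np.argwhere(mask):
                got.add((int(ap_c[idx[1]]), int(is_c[idx[2]]), int(sag_c[idx[0]])))
            assert got <= expected
            # every expected cell contributes at least one voxel at this shape
            assert len(got) == len(expected)

    def test_high_convexity_and_sylvian_disjoint(self):
        grid = make_grid()
        shape = (84, 112, 56)
        hc = tal.roi_mask(grid, "high_convexity", shape).data
        syl = tal.roi_mask(grid, "sylvian_both", shape).data
        assert not np.any(hc & syl)

    def test_sylvian_sides_mirror_for_symmetric_grid(self):
        # fractional boundary planes (no voxel center on a sagittal plane):
        # midline 40.5 on an 82-voxel axis, mirror map i -> 81 - i
        grid = make_grid(bbox_lo=(0, 0, 0), bbox_hi=(81, 110, 50),
                         ac=(40.5, 70, 25), pc=(40.5, 46, 25))
        shape = (82, 112, 56)
        left = tal.roi_mask(grid, "sylvian_left", shape).data
        right = tal.roi_mask(grid, "sylvian_right", shape).data
        assert left.sum() > 0
        assert np.array_equal(left, right[::-1, :, :])

    def test_unknown_roi_rejected(self):
        with pytest.raises(tal.GridError, match="unknown ROI"):
            tal.roi_mask(make_grid(), "cerebellum", (10, 10, 10))


class TestBoundingBox:
    def test_full_mask_spans_all_indices_without_erosion(self):
        mask = VolumeGrid(np.ones((10, 10, 10), dtype=bool))
        bbox = tal.bounding_box(mask, erode_r=0)
        assert bbox.lo == (0.0, 0.0, 0.0) and bbox.hi == (9.0, 9.0, 9.0)

    def test_erosion_shrinks_ball_bbox_by_about_one_voxel_per_face(self):
        zz, yy, xx = np.ogrid[:21, :21, :21]
        ball = (xx - 10) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 <= 64
        b0 = tal.bounding_box(VolumeGrid(ball), erode_r=0)
        b1 = tal.bounding_box(VolumeGrid(ball), erode_r=1)
        assert all(l1 - l0 == 1 for l0, l1 in zip(b0.lo, b1.lo))
        assert all(h0 - h1 == 1 for h0, h1 in zip(b0.hi, b1.hi))

    def test_bbox_contains_phantom_landmarks(self, noiseless_phantom):
        from csfspace import preprocess as pp

        intensity, truth = noiseless_phantom
        bbox = tal.bounding_box(pp.extract_brain(intensity), erode_r=1)
        assert bbox.contains(truth.ac) and bbox.contains(truth.pc)

    def test_erosion_emptying_mask_raises(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[4, 4, 4] = True
        with pytest.raises(tal.GridError, match="emptied"):
            tal.bounding_box(VolumeGrid(m), erode_r=1)


class TestAcpcAlign:
    def test_already_aligned_input_is_identity(self):
        R = tal._acpc_rotation(np.array([40.0, 70.0, 25.0]), np.array([40.0, 46.0, 25.0]))
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_known_pitch_recovered(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        angle = np.deg2rad(10.0)
        c, s = np.cos(angle), np.sin(angle)
        Rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
        pivot = np.array(truth.pc, dtype=float)
        rotated = ndimage.affine_transform(
            intensity.data, Rx.T, offset=pivot - Rx.T @ pivot, order=1
        )
        ac_rot = Rx @ (np.array(truth.ac) - pivot) + pivot
        aligned, ac_new, pc_new = tal.acpc_align(
            intensity.like(rotated), ac_rot, truth.pc
        )
        # recovered rotation: landmarks back on a horizontal line
        assert abs(ac_new[2] - pc_new[2]) < 1e-6
        recovered = tal._acpc_rotation(np.asarray(ac_rot), pivot)
        residual = recovered @ Rx - np.eye(3)
        assert np.abs(residual).max() < np.deg2rad(0.1)

    def test_output_landmarks_share_axial_coordinate(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        ac = np.array(truth.ac, dtype=float) + np.array([0.0, 0.0, 3.0])
        _, ac_new, pc_new = tal.acpc_align(intensity, ac, truth.pc)
        assert abs(ac_new[2] - pc_new[2]) < 0.5

    def test_coincident_landmarks_rejected(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        with pytest.raises(tal.GridError, match="coincide"):
            tal.acpc_align(intensity, truth.ac, truth.ac)
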