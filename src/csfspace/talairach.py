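"""Talairach proportional grid: AC/PC alignment, bounding box, the 11x12x8
tessellation, and the two study ROIs.

The proportional grid divides the brain bounding box by rule rather than by
fixed millimetre coordinates: along the anterior-posterior axis, 4 equal
divisions anterior to the AC, 3 between AC and PC, 4 posterior to the PC
(11 total); along the inferior-superior axis, 8 equal divisions above the
AC-PC plane and 4 below (12); each hemisphere is split into 4 equal sagittal
divisions (8), for 11 x 12 x 8 = 1056 cells.  Boundary planes are kept at
fractional voxel coordinates and voxels are assigned to cells by their center
(half-open intervals, lower edge inclusive; the last cell also includes its
upper edge), which makes the cells an exact partition of the bounding box.

Grid coordinates are named relative to the reference planes: ``vAC(+1)`` is
one vertical grid plane anterior to the AC, ``vPC(-2)`` two planes posterior
to the PC, ``AC-PC(+3)`` the third horizontal plane above the AC-PC plane,
and ``M(+-k)`` the k-th sagittal plane from the midline.

ROIs (cell ranges in those named coordinates):

* high convexity: AC-PC(+3)..AC-PC(+8) vertically, M(-1)..M(+1) sagittally,
  vAC(+1)..vPC(0) anterior-posterior - 4 x 5 x 2 = 40 cells;
* Sylvian fissure region (per side): AC-PC(-2)..AC-PC(+3) vertically,
  M(+-2)..M(+-4) sagittally, vAC(+2)..vPC(-1) anterior-posterior -
  6 x 5 x 2 = 60 cells per side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = [
    "BoundingBox",
    "TalairachGrid",
    "GridError",
    "acpc_align",
    "bounding_box",
    "build_grid",
    "roi_mask",
    "ROI_NAMES",
]

ROI_NAMES = ("high_convexity", "sylvian_left", "sylvian_right", "sylvian_both")

# plane indices of the reference planes within the boundary arrays
_AP_PC, _AP_AC = 4, 7  # ap_bounds has 12 planes: 4 post + 3 mid + 4 ant
_IS_ACPC = 4  # is_bounds has 13 planes: 4 below + 8 above
_SAG_M = 4  # sag_bounds has 9 planes: 4 per hemisphere


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive per-axis voxel-index extents of the (eroded) brain mask."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, point) -> bool:
        return all(l <= p <= h for l, p, h in zip(self.lo, point, self.hi))


def bounding_box(brain_mask: VolumeGrid, erode_r: int = 1) -> BoundingBox:
    """Per-axis extents of the brain mask after erosion by ``erode_r``
    (3-D cross / 6-neighborhood structuring element)."""
    m = brain_mask.data.astype(bool)
    if erode_r > 0:
        m = ndimage.binary_erosion(
            m, structure=ndimage.generate_binary_structure(3, 1), iterations=erode_r
        )
    if not np.any(m):
        raise GridError(f"erosion by {erode_r} emptied the brain mask")
    lo, hi = [], []
    for ax in range(3):
        proj = np.any(m, axis=tuple(i for i in range(3) if i != ax))
        nz = np.nonzero(proj)[0]
        lo.append(float(nz[0]))
        hi.append(float(nz[-1]))
    return BoundingBox(tuple(lo), tuple(hi))


@dataclass(frozen=True)
class TalairachGrid:
    """The proportional grid: landmarks, bounding box, and boundary planes.

    ``ap_bounds`` (12), ``is_bounds`` (13) and ``sag_bounds`` (9) are
    ascending fractional voxel coordinates along axes 1, 2 and 0.
    """

    ac: tuple[float, float, float]
    pc: tuple[float, float, float]
    bbox: BoundingBox
    ap_bounds: np.ndarray
    is_bounds: np.ndarray
    sag_bounds: np.ndarray

    # -- named planes -------------------------------------------------------

    def vac(self, k: int) -> float:
        """Vertical plane k grid steps anterior (+) / posterior (-) of AC."""
        return float(self.ap_bounds[self._index(_AP_AC + k, 12, f"vAC({k:+d})")])

    def vpc(self, k: int) -> float:
        """Vertical plane k grid steps anterior (+) / posterior (-) of PC."""
        return float(self.ap_bounds[self._index(_AP_PC + k, 12, f"vPC({k:+d})")])

    def acpc(self, k: int) -> float:
        """Horizontal plane k grid steps above (+) / below (-) the AC-PC plane."""
        return float(self.is_bounds[self._index(_IS_ACPC + k, 13, f"AC-PC({k:+d})")])

    def m(self, k: int) -> float:
        """Sagittal plane k grid steps right (+) / left (-) of the midline."""
        return float(self.sag_bounds[self._index(_SAG_M + k, 9, f"M({k:+d})")])

    @staticmethod
    def _index(idx: int, n: int, name: str) -> int:
        if not 0 <= idx < n:
            raise GridError(f"named plane {name} lies outside the grid")
        return idx

    # -- cell assignment ----------------------------------------------------

    def cell_indices(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis cell index of every voxel center; -1 outside the bbox.

        Half-open membership (lower boundary inclusive, upper exclusive); the
        last cell on each axis includes its upper boundary, so cells tile the
        bounding box exactly.
        """
        out = []
        for ax, bounds in ((0, self.sag_bounds), (1, self.ap_bounds), (2, self.is_bounds)):
            coords = np.arange(shape[ax], dtype=float)
            cells = np.searchsorted(bounds, coords, side="right") - 1
            cells = np.where(cells == len(bounds) - 1, len(bounds) - 2, cells)  # top edge
            outside = (coords < bounds[0]) | (coords > bounds[-1])
            cells[outside] = -1
            out.append(cells)
        return tuple(out)

    @property
    def n_cells(self) -> int:
        return (len(self.ap_bounds) - 1) * (len(self.is_bounds) - 1) * (len(self.sag_bounds) - 1)


def build_grid(bbox: BoundingBox, ac, pc) -> TalairachGrid:
    """Construct the proportional grid from the bounding box and landmarks.

    ``ac`` must be anterior to ``pc`` (larger axis-1 coordinate), both on the
    same axial plane and the same sagittal (midline) plane, strictly inside
    the bounding box on every axis the grid divides.
    """
    ac = tuple(float(v) for v in ac)
    pc = tuple(float(v) for v in pc)
    if ac == pc:
        raise GridError("AC and PC coincide")
    if abs(ac[2] - pc[2]) > 1e-9 or abs(ac[0] - pc[0]) > 1e-9:
        raise GridError(
            f"AC {ac} and PC {pc} must share the axial and midsagittal planes; "
            "run acpc_align first"
        )
    if not (bbox.contains(ac) and bbox.contains(pc)):
        raise GridError(f"landmarks {ac}, {pc} outside bounding box {bbox}")
    y0, y1 = bbox.lo[1], bbox.hi[1]
    z0, z1 = bbox.lo[2], bbox.hi[2]
    x0, x1 = bbox.lo[0], bbox.hi[0]
    ya, yp = ac[1], pc[1]
    if not ya > yp:
        raise GridError(f"AC (y={ya}) must be anterior to PC (y={yp})")
    zac = ac[2]
    xm = ac[0]
    for name, lo, hi in (
        ("posterior-of-PC", y0, yp),
        ("AC-to-PC", yp, ya),
        ("anterior-of-AC", ya, y1),
        ("below-AC-PC", z0, zac),
        ("above-AC-PC", zac, z1),
        ("left-hemisphere", x0, xm),
        ("right-hemisphere", xm, x1),
    ):
        if not hi > lo:
            raise GridError(f"zero-width {name} span (landmark on the bbox edge)")

    ap = np.concatenate([
        np.linspace(y0, yp, 5),
        np.linspace(yp, ya, 4)[1:],
        np.linspace(ya, y1, 5)[1:],
    ])
    is_ = np.concatenate([np.linspace(z0, zac, 5), np.linspace(zac, z1, 9)[1:]])
    sag = np.concatenate([np.linspace(x0, xm, 5), np.linspace(xm, x1, 5)[1:]])
    return TalairachGrid(ac=ac, pc=pc, bbox=bbox, ap_bounds=ap, is_bounds=is_, sag_bounds=sag)


# cell ranges (inclusive cell index intervals per axis) of the named ROIs;
# cell i spans planes i..i+1, so the range between plane a and plane b > a
# covers cells a..b-1
_ROI_CELLS = {
    "high_convexity": {
        "sag": (_SAG_M - 1, _SAG_M),  # M(-1)..M(+1)
        "ap": (_AP_PC, _AP_AC),  # vPC(0)..vAC(+1)
        "is": (_IS_ACPC + 3, _IS_ACPC + 7),  # AC-PC(+3)..AC-PC(+8)
    },
    "sylvian_left": {
        "sag": (_SAG_M - 4, _SAG_M - 3),  # M(-4)..M(-2)
        "ap": (_AP_PC - 1, _AP_AC + 1),  # vPC(-1)..vAC(+2)
        "is": (_IS_ACPC - 2, _IS_ACPC + 2),  # AC-PC(-2)..AC-PC(+3)
    },
    "sylvian_right": {
        "sag": (_SAG_M + 2, _SAG_M + 3),  # M(+2)..M(+4)
        "ap": (_AP_PC - 1, _AP_AC + 1),
        "is": (_IS_ACPC - 2, _IS_ACPC + 2),
    },
}


def roi_cell_count(roi: str) -> int:
    """Number of grid cells in the named ROI."""
    if roi == "sylvian_both":
        return roi_cell_count("sylvian_left") + roi_cell_count("sylvian_right")
    r = _ROI_CELLS[roi]
    return int(np.prod([hi - lo + 1 for lo, hi in (r["sag"], r["ap"], r["is"])]))


def roi_mask(grid: TalairachGrid, roi: str, shape: tuple[int, int, int]) -> VolumeGrid:
    """Binary mask of the named ROI (union of its grid cells) on ``shape``."""
    if roi not in ROI_NAMES:
        raise GridError(f"unknown ROI {roi!r}; expected one of {ROI_NAMES}")
    if roi == "sylvian_both":
        left = roi_mask(grid, "sylvian_left", shape)
        right = roi_mask(grid, "sylvian_right", shape)
        return left.like(left.data | right.data)
    r = _ROI_CELLS[roi]
    sag_c, ap_c, is_c = grid.cell_indices(shape)
    sel = lambda cells, rng: (cells >= rng[0]) & (cells <= rng[1])  # noqa: E731
    mask = (
        sel(sag_c, r["sag"])[:, None, None]
        & sel(ap_c, r["ap"])[None, :, None]
        & sel(is_c, r["is"])[None, None, :]
    )
    if not np.any(mask):
        raise GridError(f"ROI {roi!r} lies outside the volume")
    return VolumeGrid(mask, (1.0, 1.0, 1.0))


def _acpc_rotation(ac: np.ndarray, pc: np.ndarray) -> np.ndarray:
    """Rotation taking the AC-PC direction to the +y axis (yaw then pitch;
    the roll about the AC-PC axis is left at zero)."""
    v = np.asarray(ac, dtype=float) - np.asarray(pc, dtype=float)
    if np.linalg.norm(v) < 1e-12:
        raise GridError("AC and PC coincide")
    # yaw about z removes the x-component
    yaw = np.arctan2(v[0], v[1])
    cz, sz = np.cos(yaw), np.sin(yaw)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    v2 = Rz.T @ v
    # pitch about x removes the z-component
    pitch = np.arctan2(v2[2], v2[1])
    cx, sx = np.cos(pitch), np.sin(pitch)
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, sx], [0.0, -sx, cx]])
    return Rx @ Rz.T


def acpc_align(
    volume: VolumeGrid, ac, pc, order: int = 1
) -> tuple[VolumeGrid, tuple[float, float, float], tuple[float, float, float]]:
    """Rigidly rotate the volume so AC and PC lie on one horizontal axial
    line (and the midsagittal plane stays vertical), pivoting about the PC.

    ``order=1`` resamples intensities trilinearly; use ``order=0`` for label
    volumes.  Returns the resampled volume and the transformed landmarks.
    """
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    R = _acpc_rotation(ac, pc)
    # output(idx) = input(R.T (idx - pc) + pc)
    offset = pc - R.T @ pc
    data = ndimage.affine_transform(volume.data, R.T, offset=offset, order=order)
    ac_new = R @ (ac - pc) + pc
    return volume.like(data), tuple(float(v) for v in ac_new), tuple(float(v) for v in pc)
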