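"""Lateral-ventricle segmentation by graph cuts with an atlas prior.

The binary labeling minimizes the contrast-sensitive energy

    E(L) = sum_v D_v(L_v) + lambda * sum_{(u,v) in N6} [L_u != L_v] * w_uv

with data terms ``D_v(fg) = -ln(eps + p_v)``, ``D_v(bg) = -ln(eps + 1 - p_v)``
where ``p_v`` is the normalized product of the CSF probability and the atlas
prior, and boundary weights ``w_uv = exp(-(I_u - I_v)^2 / (2 sigma^2))`` on
6-connected neighbor pairs.  The energy is submodular, so the max-flow/min-cut
solution is the global minimum.  Atlas-derived hard seeds are enforced through
effectively infinite terminal capacities.

Max flow is solved with :func:`scipy.sparse.csgraph.maximum_flow` on integer
capacities (scaled so the flow value fits 32-bit arithmetic, with quantization
far below any energy difference of interest); the source side of the minimum
cut is recovered by breadth-first search on the residual graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_array
from scipy.sparse.csgraph import maximum_flow
from skimage.morphology import ball

from .grid import VolumeGrid
from .preprocess import TissueMaps

__all__ = [
    "SeedMap",
    "CutEnergy",
    "SegmentationError",
    "atlas_from_masks",
    "make_seeds",
    "graph_cut",
    "cut_energy",
    "postprocess_mask",
]

FREE, FG_HARD, BG_HARD = 0, 1, 2
_CAP_SCALE = 1e8


class SegmentationError(RuntimeError):
    pass


@dataclass
class SeedMap:
    """Per-voxel seed states: 0 free, 1 foreground-hard, 2 background-hard."""

    states: np.ndarray

    def __post_init__(self) -> None:
        fg = self.states == FG_HARD
        bg = self.states == BG_HARD
        if not np.any(fg):
            raise SegmentationError("empty foreground seed set (atlas misaligned?)")
        if not np.any(bg):
            raise SegmentationError("empty background seed set")

    @property
    def foreground(self) -> np.ndarray:
        return self.states == FG_HARD

    @property
    def background(self) -> np.ndarray:
        return self.states == BG_HARD


@dataclass
class CutEnergy:
    """Graph-cut energy parameters.

    ``sigma=None`` sets the contrast scale to the median absolute neighbor
    intensity difference of the contrast image (a standard robust choice).
    """

    lam: float = 0.5
    sigma: float | None = None
    epsilon: float = 1e-6
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.connectivity != 6:
            raise ValueError("only 6-connectivity is supported")


def atlas_from_masks(masks: list[VolumeGrid], sigma: float = 2.0) -> VolumeGrid:
    """Probabilistic atlas prior: the Gaussian-blurred voxelwise mean of
    aligned training ventricle masks (values in [0, 1])."""
    if not masks:
        raise ValueError("need at least one training mask")
    mean = np.mean([m.data.astype(float) for m in masks], axis=0)
    prior = ndimage.gaussian_filter(mean, sigma)
    return masks[0].like(np.clip(prior, 0.0, 1.0))


def make_seeds(
    atlas_prior: VolumeGrid,
    fractions: TissueMaps,
    erode_r: int = 1,
    dilate_r: int = 2,
    support_threshold: float = 0.01,
) -> SeedMap:
    """Derive hard seeds from the atlas prior and the CSF fraction map.

    Foreground-hard: high-confidence atlas core (prior >= 0.9, eroded by
    ``erode_r``) that is also majority CSF by partial-volume fraction.
    Background-hard: outside the atlas support dilated by ``dilate_r``.
    """
    prior = atlas_prior.data.astype(float)
    core = prior >= 0.9
    structure = ndimage.generate_binary_structure(3, 1)
    if erode_r > 0:
        core = ndimage.binary_erosion(core, structure=structure, iterations=erode_r)
    fg = core & (fractions.csf_fraction() >= 0.5)
    support = prior > support_threshold
    if dilate_r > 0:
        support = ndimage.binary_dilation(support, structure=structure, iterations=dilate_r)
    bg = ~support
    states = np.zeros(prior.shape, dtype=np.uint8)
    states[bg] = BG_HARD
    states[fg] = FG_HARD  # fg wins where sets would overlap; disjoint by construction
    if not np.any(states == FG_HARD):
        raise SegmentationError(
            "empty foreground seed set: atlas prior core contains no CSF-majority voxel"
        )
    if not np.any(states == BG_HARD):
        raise SegmentationError("dilated atlas support covers the whole volume")
    return SeedMap(states)


def _fused_probability(prob_csf: np.ndarray, atlas_prior: np.ndarray) -> np.ndarray:
    """Normalized product p = c*a / (c*a + (1-c)(1-a)), 0.5 where undefined."""
    num = prob_csf * atlas_prior
    den = num + (1.0 - prob_csf) * (1.0 - atlas_prior)
    p = np.full(prob_csf.shape, 0.5)
    ok = den > 0
    p[ok] = num[ok] / den[ok]
    return p


def _neighbor_pairs(shape: tuple[int, int, int]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flat index pairs of 6-connected neighbors along each axis."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    pairs = []
    for ax in range(3):
        a = np.swapaxes(idx, 0, ax)
        pairs.append((a[:-1].ravel(), a[1:].ravel()))
    return pairs


def _boundary_weights(
    contrast: np.ndarray, energy: CutEnergy
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[np.ndarray]]:
    pairs = _neighbor_pairs(contrast.shape)
    flat = contrast.ravel()
    diffs = [flat[u] - flat[v] for u, v in pairs]
    sigma = energy.sigma
    if sigma is None:
        all_abs = np.abs(np.concatenate(diffs))
        sigma = float(np.median(all_abs))
        if sigma <= 0:
            sigma = 1.0  # uniform contrast: weights become 1 everywhere
    weights = [np.exp(-(d**2) / (2.0 * sigma**2)) for d in diffs]
    return pairs, weights


def cut_energy(
    labels: np.ndarray,
    prob_csf: VolumeGrid,
    atlas_prior: VolumeGrid,
    energy: CutEnergy,
    contrast: np.ndarray | None = None,
) -> float:
    """Evaluate E(L) for a binary labeling; independent of the solver path."""
    p = _fused_probability(prob_csf.data.astype(float), atlas_prior.data.astype(float))
    eps = energy.epsilon
    lab = labels.astype(bool)
    data = np.where(lab, -np.log(eps + p), -np.log(eps + 1.0 - p))
    total = float(data.sum())
    if energy.lam > 0:
        img = p if contrast is None else contrast
        pairs, weights = _boundary_weights(img, energy)
        flat = lab.ravel()
        for (u, v), w in zip(pairs, weights):
            total += energy.lam * float(w[flat[u] != flat[v]].sum())
    return total


def graph_cut(
    prob_csf: VolumeGrid,
    atlas_prior: VolumeGrid,
    seeds: SeedMap,
    energy: CutEnergy,
    intensity: VolumeGrid | None = None,
) -> VolumeGrid:
    """Globally minimize the segmentation energy; returns the binary mask.

    ``intensity`` supplies the contrast image for the boundary weights; when
    omitted, the fused probability map is used.  The problem is restricted to
    the bounding box of the non-background-seed region (plus a one-voxel ring
    of background-hard voxels), which leaves the minimizer unchanged.
    """
    shape = prob_csf.shape
    if atlas_prior.shape != shape or seeds.states.shape != shape:
        raise ValueError("prob_csf, atlas_prior, and seeds must share a shape")
    if intensity is not None and intensity.shape != shape:
        raise ValueError("intensity must share the volume shape")

    active = seeds.states != BG_HARD
    if not np.any(active):
        raise SegmentationError("no free or foreground voxels to segment")
    lo = []
    hi = []
    for ax in range(3):
        proj = np.any(active, axis=tuple(i for i in range(3) if i != ax))
        nz = np.nonzero(proj)[0]
        lo.append(max(int(nz[0]) - 1, 0))
        hi.append(min(int(nz[-1]) + 2, shape[ax]))
    box = tuple(slice(l, h) for l, h in zip(lo, hi))

    p = _fused_probability(
        prob_csf.data.astype(float)[box], atlas_prior.data.astype(float)[box]
    )
    states = seeds.states[box]
    eps = energy.epsilon
    d_fg = -np.log(eps + p).ravel()
    d_bg = -np.log(eps + 1.0 - p).ravel()
    # shift both terminal capacities per voxel to be non-negative (adds a
    # labeling-independent constant to the energy; the minimizer is unchanged)
    shift = np.minimum(d_fg, d_bg)
    d_fg = d_fg - shift
    d_bg = d_bg - shift

    contrast = (intensity.data.astype(float)[box] if intensity is not None else p)
    n = p.size
    flat_states = states.ravel()

    pairs_weights: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    if energy.lam > 0:
        pairs, weights = _boundary_weights(contrast, energy)
        pairs_weights = [(u, v, energy.lam * w) for (u, v), w in zip(pairs, weights)]

    # scipy's max-flow works in int32: pick the integer capacity scale so that
    # the cut value of the all-background-but-seeds labeling (an upper bound on
    # the max flow) stays below 2^30, capping at 1e8 for quantization accuracy
    fg_seed = flat_states == FG_HARD
    bound = float(d_fg[fg_seed].sum() + d_bg[~fg_seed].sum())
    for u, v, w in pairs_weights:
        crossing = fg_seed[u] != fg_seed[v]
        bound += float(w[crossing].sum())
    scale = min(_CAP_SCALE, 2.0**30 / max(bound, 1e-12))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    caps: list[np.ndarray] = []
    for u, v, w in pairs_weights:
        c = np.rint(w * scale).astype(np.int64)
        rows += [u, v]
        cols += [v, u]
        caps += [c, c]

    src_cap = np.rint(d_bg * scale).astype(np.int64)  # cut when v is background
    sink_cap = np.rint(d_fg * scale).astype(np.int64)  # cut when v is foreground
    inf_cap = int(min(np.rint(bound * scale) + 2, 2**31 - 1))
    src_cap = np.where(fg_seed, inf_cap, src_cap)
    sink_cap = np.where(flat_states == BG_HARD, inf_cap, sink_cap)

    source, sink = n, n + 1
    all_nodes = np.arange(n)
    rows += [np.full(n, source), all_nodes]
    cols += [all_nodes, np.full(n, sink)]
    caps += [src_cap, sink_cap]

    graph = coo_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
        dtype=np.int64,
    ).tocsr().astype(np.int32)
    result = maximum_flow(csr_array(graph), source, sink)

    residual = graph - result.flow
    residual.data = (residual.data > 0).astype(np.int8)
    residual.eliminate_zeros()
    reach = np.zeros(n + 2, dtype=bool)
    frontier = np.zeros(n + 2, dtype=bool)
    frontier[source] = reach[source] = True
    while frontier.any():
        nxt = (residual.T @ frontier.astype(np.int8)) > 0
        frontier = nxt & ~reach
        reach |= frontier

    sub_mask = reach[:n].reshape(p.shape)
    out = np.zeros(shape, dtype=bool)
    out[box] = sub_mask
    return prob_csf.like(out)


def postprocess_mask(
    mask: VolumeGrid,
    open_r: int,
    seeds: SeedMap | None = None,
) -> VolumeGrid:
    """Morphological opening (ball of radius ``open_r``) followed by component
    filtering: keep components overlapping a foreground seed when seeds are
    given, else the largest component.  ``open_r=0`` applies only the
    component filter when seeds are given, otherwise is the identity."""
    if open_r < 0:
        raise ValueError("open_r must be >= 0")
    m = mask.data.astype(bool)
    if open_r > 0:
        m = ndimage.binary_opening(m, structure=ball(open_r))
        if not np.any(m):
            raise SegmentationError(
                f"opening with radius {open_r} removed the whole mask "
                f"(input had {int(mask.data.astype(bool).sum())} voxels)"
            )
    if seeds is not None or open_r > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        lab, n = ndimage.label(m, structure=structure)
        if n > 1 or seeds is not None:
            if seeds is not None:
                keep = np.unique(lab[seeds.foreground & (lab > 0)])
                if keep.size == 0:
                    raise SegmentationError("no component overlaps a foreground seed")
                m = np.isin(lab, keep)
            else:
                sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
                m = lab == (1 + int(np.argmax(sizes)))
    return mask.like(m)
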