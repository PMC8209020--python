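"""Skeletonization, branching-point detection and the four morphometric
parameters: positive area fraction, branching-point density, total network
length, and mean fiber thickness.

Conventions
-----------
* foreground connectivity is 8-connected throughout;
* a skeleton pixel is a junction pixel iff it has >= 3 skeleton neighbors in
  its 8-neighborhood, and 8-adjacent junction pixels are merged into a single
  branching point (a single anatomical bifurcation otherwise contributes 2-3
  pixel-level junctions);
* network length is the sum over unique adjacent skeleton-pixel pairs of 1
  (orthogonal) or sqrt(2) (diagonal) pixel spacings, which is exact on
  axis-aligned and 45-degree lines; a raw pixel-count estimator is available
  for sensitivity analysis;
* mean thickness is foreground area divided by skeleton length, so
  ``thickness x length == area`` holds identically; a zero-length skeleton
  leaves the thickness undefined (NaN, flagged), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .errors import ValidationError
from .segmentation import BinaryMask

__all__ = [
    "SkeletonImage",
    "MorphometrySummary",
    "skeletonize",
    "find_branch_points",
    "measure_length",
    "summarize",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=int)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)


@dataclass
class SkeletonImage:
    """Unit-width 8-connected centerline mask plus its branching points."""

    skeleton: np.ndarray
    branch_points: list[tuple[int, int]]
    um_per_px: float

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=bool)
        if self.skeleton.ndim != 2:
            raise ValidationError(
                f"skeleton: expected 2-D, got ndim={self.skeleton.ndim}"
            )
        if not self.um_per_px > 0:
            raise ValidationError(f"um_per_px: must be > 0, got {self.um_per_px}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.skeleton.shape

    @property
    def n_skeleton_px(self) -> int:
        return int(self.skeleton.sum())


@dataclass
class MorphometrySummary:
    """The four morphometric parameters of one image, plus raw tallies.

    ``mean_thickness_um`` is NaN (and ``thickness_defined`` False) when the
    skeleton has zero length; it is excluded from group statistics rather
    than reported as zero.
    """

    positive_area_pct: float
    bp_density_per_mm2: float
    total_length_mm: float
    mean_thickness_um: float
    n_foreground_px: int
    n_skeleton_px: int
    n_branch_points: int
    image_area_mm2: float
    thickness_defined: bool = True
    extras: dict = field(default_factory=dict)


_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)
]


def _crossing_number(s: np.ndarray, r: int, c: int) -> int:
    """0->1 transitions around the 8-neighborhood (cyclic); 1 for simple points."""
    ring = []
    for dr, dc in [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]:
        rr, cc = r + dr, c + dc
        ring.append(
            bool(s[rr, cc]) if 0 <= rr < s.shape[0] and 0 <= cc < s.shape[1] else False
        )
    return sum(
        1 for k in range(8) if not ring[k] and ring[(k + 1) % 8]
    )


def _remove_staircase_blocks(skel: np.ndarray) -> np.ndarray:
    """Delete deletable pixels of residual 2x2 blocks after thinning.

    Zhang–Suen thinning can leave isolated 2x2 "staircase" squares on ragged
    masks; each would masquerade as a junction cluster.  Pixels belonging to
    such a block are removed in raster order whenever they are simple
    (crossing number 1) and not endpoints, which preserves connectivity.
    """
    s = skel.copy()
    for _ in range(4):
        blocks = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        if not blocks.any():
            break
        changed = False
        for br, bc in np.argwhere(blocks):
            for r, c in ((br, bc), (br, bc + 1), (br + 1, bc), (br + 1, bc + 1)):
                if not s[r, c]:
                    continue
                n_nbrs = sum(
                    bool(s[r + dr, c + dc])
                    for dr, dc in _NEIGHBOR_OFFSETS
                    if 0 <= r + dr < s.shape[0] and 0 <= c + dc < s.shape[1]
                )
                if n_nbrs > 1 and _crossing_number(s, r, c) == 1:
                    s[r, c] = False
                    changed = True
                    break
        if not changed:
            break
    return s


def _live_neighbors(s: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
    return [
        (p[0] + dr, p[1] + dc)
        for dr, dc in _NEIGHBOR_OFFSETS
        if 0 <= p[0] + dr < s.shape[0]
        and 0 <= p[1] + dc < s.shape[1]
        and s[p[0] + dr, p[1] + dc]
    ]


def _single_cluster(points: list[tuple[int, int]]) -> bool:
    """True iff the points form one 8-connected cluster (or are empty)."""
    if len(points) <= 1:
        return True
    remaining = set(points)
    stack = [points[0]]
    remaining.discard(points[0])
    while stack:
        r, c = stack.pop()
        for q in list(remaining):
            if max(abs(q[0] - r), abs(q[1] - c)) == 1:
                remaining.discard(q)
                stack.append(q)
    return not remaining


def _prune_spurs(skel: np.ndarray, max_spur_px: int) -> np.ndarray:
    """Delete terminal branches of at most ``max_spur_px`` pixels that end in
    a junction.  Open tips of genuine fibers (no junction within reach) are
    left alone, so pruning never shortens a simple path.  The junction pixel
    itself is deleted as well when its remaining neighbors stay connected
    without it (a diagonal nub base, not a true bifurcation)."""
    s = skel.copy()
    counts = _neighbor_counts(s)
    endpoints = [tuple(p) for p in np.argwhere(s & (counts == 1))]
    for start in endpoints:
        if not s[start]:
            continue
        trail = [start]
        prev: tuple[int, int] | None = None
        cur = start
        reached_junction = False
        while len(trail) <= max_spur_px:
            nbrs = [q for q in _live_neighbors(s, cur) if q != prev]
            if len(nbrs) == 0:
                break  # isolated path: not a spur
            if len(nbrs) >= 2:
                reached_junction = True
                break
            nxt = nbrs[0]
            if len(_live_neighbors(s, nxt)) >= 3:
                reached_junction = True
                others = [
                    q for q in _live_neighbors(s, nxt) if q != cur and q not in trail
                ]
                if _single_cluster(others):
                    trail.append(nxt)
                break
            prev, cur = cur, nxt
            trail.append(cur)
        if reached_junction:
            for r, c in trail:
                s[r, c] = False
    return s


def skeletonize(
    mask: BinaryMask, prune_spurs_px: int = 0, bp_merge_radius_px: float = 0.0
) -> SkeletonImage:
    """Thin the mask to a unit-width, topology-preserving skeleton.

    Uses the Zhang–Suen two-subiteration thinning as implemented in
    scikit-image: deterministic, 8-connected, and preserving the number of
    foreground components.  With ``prune_spurs_px > 0``, terminal skeleton
    branches up to that many pixels long that terminate in a junction —
    typically artifacts of boundary roughness, one spur per bump — are
    removed; genuine open fiber ends are untouched.  Branching points are
    identified immediately so the result is self-contained.
    """
    skel = skmorph.skeletonize(mask.mask, method="zhang")
    skel = _remove_staircase_blocks(skel)
    if prune_spurs_px > 0:
        # iterate: pruning a spur can expose a shorter one behind it
        for _ in range(5):
            pruned = _prune_spurs(skel, prune_spurs_px)
            if pruned.sum() == skel.sum():
                break
            skel = pruned
        skel = pruned
    image = SkeletonImage(skeleton=skel, branch_points=[], um_per_px=mask.um_per_px)
    image.branch_points = find_branch_points(
        image, warn_if_thick=False, merge_radius_px=bp_merge_radius_px
    )
    return image


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(
        skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )


def _is_thin(skel: np.ndarray) -> bool:
    # a 2x2 solid block means the input was not reduced to unit width
    if skel.shape[0] < 2 or skel.shape[1] < 2:
        return True
    blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    return not bool(blocks.any())


def find_branch_points(
    skel: SkeletonImage,
    warn_if_thick: bool = True,
    merge_radius_px: float = 0.0,
) -> list[tuple[int, int]]:
    """Locate branching points of a unit-width skeleton.

    Junction pixels (>= 3 skeleton neighbors in the 8-neighborhood) are
    clustered by 8-adjacency; each cluster yields one branching point whose
    representative coordinate is the cluster pixel closest to the cluster
    centroid (ties broken lexicographically).

    With ``merge_radius_px > 0`` branching points closer than that distance
    are additionally fused (single linkage) into one, keeping the first
    representative in raster order.  A single anatomical bifurcation in a
    ragged mask often thins to two or three junction pixels a few pixels
    apart; merging within about one fiber width undoes that split.
    """
    s = skel.skeleton
    if warn_if_thick and not _is_thin(s):
        warnings.warn(
            "skeleton is not unit-width; branching-point counts may inflate",
            stacklevel=2,
        )
    junctions = s & (_neighbor_counts(s) >= 3)
    labels, n = ndi.label(junctions, structure=_STRUCTURE_8)
    points: list[tuple[int, int]] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        centroid = coords.mean(axis=0)
        dist2 = ((coords - centroid) ** 2).sum(axis=1)
        order = np.lexsort((coords[:, 1], coords[:, 0], dist2))
        r, c = coords[order[0]]
        points.append((int(r), int(c)))
    if merge_radius_px > 0 and len(points) > 1:
        pts = np.asarray(points, dtype=float)
        parent = list(range(len(points)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        r2 = merge_radius_px**2
        for i in range(len(points)):
            d2 = ((pts[i + 1 :] - pts[i]) ** 2).sum(axis=1)
            for j in np.nonzero(d2 <= r2)[0] + i + 1:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
        points = [points[i] for i in sorted({find(i) for i in range(len(points))})]
    return points


def measure_length(skel: SkeletonImage, estimator: str = "adjacency") -> float:
    """Total skeleton length in millimetres.

    ``adjacency`` (default) sums unique adjacent skeleton-pixel pairs with
    weight 1 for orthogonal and sqrt(2) for diagonal neighbors, times the
    pixel size.  ``pixel-count`` multiplies the skeleton pixel count by the
    pixel size instead.  Isolated pixels contribute zero length under the
    adjacency estimator.
    """
    s = skel.skeleton
    if estimator == "pixel-count":
        length_px = float(s.sum())
    elif estimator == "adjacency":
        horiz = int(np.count_nonzero(s[:, :-1] & s[:, 1:]))
        vert = int(np.count_nonzero(s[:-1, :] & s[1:, :]))
        diag_main = int(np.count_nonzero(s[:-1, :-1] & s[1:, 1:]))
        diag_anti = int(np.count_nonzero(s[:-1, 1:] & s[1:, :-1]))
        length_px = horiz + vert + np.sqrt(2.0) * (diag_main + diag_anti)
    else:
        raise ValidationError(
            f"estimator: expected 'adjacency' or 'pixel-count', got {estimator!r}"
        )
    return length_px * skel.um_per_px / 1000.0


def summarize(
    mask: BinaryMask, skel: SkeletonImage, estimator: str = "adjacency"
) -> MorphometrySummary:
    """Compute the four morphometric parameters from mask and skeleton."""
    if mask.shape != skel.shape:
        raise ValidationError(
            f"shape mismatch: mask {mask.shape} vs skeleton {skel.shape}"
        )
    if not np.isclose(mask.um_per_px, skel.um_per_px):
        raise ValidationError(
            f"calibration mismatch: mask {mask.um_per_px} vs skeleton "
            f"{skel.um_per_px} um/px"
        )
    n_px = mask.mask.size
    n_fg = mask.n_foreground_px
    image_area_mm2 = n_px * (mask.um_per_px / 1000.0) ** 2
    total_length_mm = measure_length(skel, estimator=estimator)
    n_bp = len(skel.branch_points)
    foreground_area_um2 = n_fg * mask.um_per_px**2
    total_length_um = total_length_mm * 1000.0
    if total_length_um > 0:
        mean_thickness_um = foreground_area_um2 / total_length_um
        defined = True
    else:
        mean_thickness_um = float("nan")
        defined = False
    return MorphometrySummary(
        positive_area_pct=100.0 * n_fg / n_px,
        bp_density_per_mm2=n_bp / image_area_mm2,
        total_length_mm=total_length_mm,
        mean_thickness_um=mean_thickness_um,
        n_foreground_px=n_fg,
        n_skeleton_px=skel.n_skeleton_px,
        n_branch_points=n_bp,
        image_area_mm2=image_area_mm2,
        thickness_defined=defined,
    )
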