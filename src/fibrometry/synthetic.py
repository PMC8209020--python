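"""Seeded synthetic micrographs of branching fiber networks with ground truth.

The generator emulates the statistical structure of DAB-immunostained deep
fascia: a "rhomboid", loosely meshed network of dark fibers a few µm thick on
a bright, unevenly illuminated background, contaminated by blob-shaped
non-nervous structures and sensor noise.  Fibers are piecewise-linear random
walks with curvature-limited turning; child branches attach at random points
of their parent and inherit a reduced width.

Ground truth (centerline length, branch count, width, rendered area) is
computed from the noiseless geometry, with foreground area measured on a 4x
supersampled rasterization, so that segmentation and morphometry can be
scored against exact references.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``NetworkSpec.seed``: the same spec reproduces the same image and ground
truth bit for bit.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage import draw as skdraw

from .errors import ValidationError
from .preprocessing import CalibratedImage

__all__ = [
    "NetworkSpec",
    "GroundTruth",
    "CohortMember",
    "generate_network",
    "generate_cohort",
    "preset_spec",
    "PRESETS",
]

SUPERSAMPLE = 4
#: child branches are drawn at this fraction of the parent width
BRANCH_WIDTH_FACTOR = 0.9
#: grandchildren beyond this depth are not spawned
MAX_BRANCH_DEPTH = 2
#: nominal background (bright-field) intensity before shading
BACKGROUND_LEVEL = 0.8
#: safety cap on the number of primary fibers in target-coverage mode
_MAX_PRIMARIES = 10_000


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one synthetic stained-fascia micrograph.

    ``branch_prob`` is the probability per micrometre of drawn centerline of
    spawning a child branch.  When ``target_area_fraction_pct`` is set, the
    generator keeps adding primary fibers (``n_seeds`` is then ignored) until
    the drawn stroke area reaches the Boolean-model budget
    ``-A ln(1 - p)`` that yields the requested coverage ``p`` under random
    overlap, truncating the last fiber mid-walk, which keeps the realized
    coverage within a few per cent of the target.
    """

    image_size_px: tuple[int, int] = (512, 512)
    um_per_px: float = 1.0
    n_seeds: int = 10
    branch_prob: float = 0.03
    fiber_width_um: float = 5.0
    width_jitter: float = 0.15
    target_area_fraction_pct: float | None = None
    stain_contrast: float = 0.5
    shading_amplitude: float = 0.2
    noise_sd: float = 0.05
    n_blob_artifacts: int = 3
    seed: int = 0
    fiber_length_um: float = 150.0
    length_jitter: float = 0.3
    step_um: float = 4.0
    curvature_sd: float = 0.15

    def __post_init__(self) -> None:
        rows, cols = self.image_size_px
        if rows < 64 or cols < 64:
            raise ValidationError(
                f"image_size_px: must be at least (64, 64), got {self.image_size_px}"
            )
        if not self.um_per_px > 0:
            raise ValidationError(f"um_per_px: must be > 0, got {self.um_per_px}")
        if self.n_seeds < 0:
            raise ValidationError(f"n_seeds: must be >= 0, got {self.n_seeds}")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValidationError(
                f"branch_prob: must lie in [0, 1], got {self.branch_prob}"
            )
        if not self.fiber_width_um > 0:
            raise ValidationError(
                f"fiber_width_um: must be > 0, got {self.fiber_width_um}"
            )
        if not 0.0 <= self.width_jitter < 0.5:
            raise ValidationError(
                f"width_jitter: must lie in [0, 0.5), got {self.width_jitter}"
            )
        if self.target_area_fraction_pct is not None and not (
            0.0 < self.target_area_fraction_pct < 100.0
        ):
            raise ValidationError(
                "target_area_fraction_pct: must lie in (0, 100), got "
                f"{self.target_area_fraction_pct}"
            )
        if not 0.0 <= self.stain_contrast <= 1.0:
            raise ValidationError(
                f"stain_contrast: must lie in [0, 1], got {self.stain_contrast}"
            )
        if not 0.0 <= self.shading_amplitude <= 0.5:
            raise ValidationError(
                f"shading_amplitude: must lie in [0, 0.5], got {self.shading_amplitude}"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.n_blob_artifacts < 0:
            raise ValidationError(
                f"n_blob_artifacts: must be >= 0, got {self.n_blob_artifacts}"
            )
        if not self.fiber_length_um > 0:
            raise ValidationError(
                f"fiber_length_um: must be > 0, got {self.fiber_length_um}"
            )
        if not 0.0 <= self.length_jitter < 1.0:
            raise ValidationError(
                f"length_jitter: must lie in [0, 1), got {self.length_jitter}"
            )
        if not self.step_um > 0:
            raise ValidationError(f"step_um: must be > 0, got {self.step_um}")
        if self.curvature_sd < 0:
            raise ValidationError(
                f"curvature_sd: must be >= 0, got {self.curvature_sd}"
            )


@dataclass
class GroundTruth:
    """Analytic description of a rendered network, for recovery testing.

    ``n_branch_points`` counts attachment events (one per drawn child
    polyline).  In a 2-D projection, crossings of otherwise unrelated fibers
    are geometrically indistinguishable from bifurcations, so the junction
    count a perfect detector recovers is larger: ``n_junctions`` clusters
    the attachment points together with all pairwise centerline crossings at
    a one-stroke-width merge radius and counts the clusters, exactly
    mirroring how nearby junctions fuse in the rendered image.
    """

    centerline_polylines: list[np.ndarray]
    widths_um: list[float]
    total_length_um: float
    n_branch_points: int
    mean_width_um: float
    foreground_area_um2: float
    true_area_fraction_pct: float
    n_crossings: int = 0
    n_junctions: int = 0
    foreground_mask: np.ndarray | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        """JSON-serializable summary (polylines included, pixel mask omitted)."""
        return {
            "total_length_um": self.total_length_um,
            "n_branch_points": self.n_branch_points,
            "n_crossings": self.n_crossings,
            "n_junctions": self.n_junctions,
            "mean_width_um": self.mean_width_um,
            "foreground_area_um2": self.foreground_area_um2,
            "true_area_fraction_pct": self.true_area_fraction_pct,
            "centerline_polylines": [p.tolist() for p in self.centerline_polylines],
            "widths_um": list(self.widths_um),
        }


class _AreaBudget:
    """Stroke-area budget used to hit a target coverage under random overlap."""

    def __init__(self, target_pct: float | None, image_area_um2: float) -> None:
        if target_pct is None:
            self.limit = None
        else:
            self.limit = -image_area_um2 * np.log1p(-target_pct / 100.0)
        self.spent = 0.0

    def exhausted(self) -> bool:
        return self.limit is not None and self.spent >= self.limit

    def charge(self, segment_area_um2: float) -> None:
        self.spent += segment_area_um2


def _clip_to_image(p: np.ndarray, q: np.ndarray, rows: int, cols: int):
    """Truncate segment p->q at the image border; return (endpoint, fraction kept)."""
    lo = np.array([0.0, 0.0])
    hi = np.array([rows - 1.0, cols - 1.0])
    if np.all(q >= lo) and np.all(q <= hi):
        return q, 1.0
    t = 1.0
    d = q - p
    for k in range(2):
        if d[k] > 0:
            t = min(t, (hi[k] - p[k]) / d[k])
        elif d[k] < 0:
            t = min(t, (lo[k] - p[k]) / d[k])
    t = max(t, 0.0)
    return p + t * d, t


def _walk_fiber(
    rng: np.random.Generator,
    spec: NetworkSpec,
    start: np.ndarray,
    heading: float,
    length_um: float,
    width_um: float,
    depth: int,
    budget: _AreaBudget,
):
    """Trace one fiber; return (polyline, drawn_length_um, branch sites)."""
    rows, cols = spec.image_size_px
    points = [start.copy()]
    branch_sites: list[tuple[np.ndarray, float, int]] = []
    traveled = 0.0
    drawn = 0.0
    pos = start.copy()
    while traveled < length_um and not budget.exhausted():
        step = min(spec.step_um, length_um - traveled)
        heading += rng.normal(0.0, spec.curvature_sd)
        direction = np.array([np.sin(heading), np.cos(heading)])
        target = pos + direction * (step / spec.um_per_px)
        endpoint, kept = _clip_to_image(pos, target, rows, cols)
        seg_um = step * kept
        if seg_um > 0:
            points.append(endpoint)
            drawn += seg_um
            budget.charge(seg_um * width_um)
        # spawn at most one child per step, anywhere along the drawn part
        if (
            depth < MAX_BRANCH_DEPTH
            and seg_um > 0
            and rng.random() < spec.branch_prob * seg_um
        ):
            u = rng.random()
            # steep take-off keeps the child from retracing its parent
            turn = rng.uniform(0.7, 1.5) * (1 if rng.random() < 0.5 else -1)
            site = pos + direction * (seg_um / spec.um_per_px) * u
            branch_sites.append((site, heading + turn, depth + 1))
        if kept < 1.0:  # left the field of view
            break
        pos = endpoint
        traveled += step
    return np.asarray(points), drawn, branch_sites


class _GeometryGrower:
    """Incremental network growth against a (possibly extensible) area budget.

    Keeps its pending-branch queue across calls to :meth:`grow`, so that the
    caller can rasterize the network, compare the realized coverage with the
    target, raise the budget, and resume — all on one deterministic random
    stream.
    """

    def __init__(self, rng: np.random.Generator, spec: NetworkSpec) -> None:
        self.rng = rng
        self.spec = spec
        rows, cols = spec.image_size_px
        self.image_area_um2 = rows * cols * spec.um_per_px**2
        self.budget = _AreaBudget(spec.target_area_fraction_pct, self.image_area_um2)
        self.target_mode = spec.target_area_fraction_pct is not None
        self.pending: deque[tuple[np.ndarray, float, float, int, int]] = deque()
        self.n_primaries = 0
        self.polylines: list[np.ndarray] = []
        self.widths: list[float] = []
        self.lengths: list[float] = []
        self.parents: list[int | None] = []
        self.n_branch_points = 0
        self.exhausted_supply = False

    def extend_budget(self, extra_um2: float) -> None:
        if self.budget.limit is not None:
            self.budget.limit += max(extra_um2, 0.0)

    def grow(self) -> None:
        rng, spec = self.rng, self.spec
        rows, cols = spec.image_size_px
        while not self.budget.exhausted():
            if self.pending:
                start, heading, width, depth, parent = self.pending.popleft()
            else:
                if self.target_mode:
                    if self.n_primaries >= _MAX_PRIMARIES:
                        self.exhausted_supply = True
                        return
                elif self.n_primaries >= spec.n_seeds:
                    self.exhausted_supply = True
                    return
                # relative-coordinate placement keeps the physical geometry
                # invariant under resampling (same seed, finer um_per_px)
                rel = rng.uniform(size=2)
                start = rel * np.array([rows - 1.0, cols - 1.0])
                heading = rng.uniform(0, 2 * np.pi)
                width = spec.fiber_width_um * (
                    1.0 + rng.normal(0.0, spec.width_jitter)
                )
                width = max(width, 0.5 * spec.fiber_width_um)
                depth = 0
                parent = -1
                self.n_primaries += 1
            if depth == 0:
                length_um = spec.fiber_length_um * rng.uniform(
                    1.0 - spec.length_jitter, 1.0 + spec.length_jitter
                )
            else:
                length_um = spec.fiber_length_um * rng.uniform(0.5, 1.0)
            poly, drawn, sites = _walk_fiber(
                rng, spec, start, heading, length_um, width, depth, self.budget
            )
            if drawn > 0:
                self.polylines.append(poly)
                self.widths.append(width)
                self.lengths.append(drawn)
                self.parents.append(parent if parent >= 0 else None)
                index = len(self.polylines) - 1
                if depth > 0:
                    self.n_branch_points += 1
                for site, child_heading, child_depth in sites:
                    self.pending.append(
                        (
                            site,
                            child_heading,
                            width * BRANCH_WIDTH_FACTOR,
                            child_depth,
                            index,
                        )
                    )


def _segment_intersections(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Intersection points between all segment pairs of two polylines."""
    a0 = P[:-1][:, None, :]
    d1 = (P[1:] - P[:-1])[:, None, :]
    b0 = Q[:-1][None, :, :]
    d2 = (Q[1:] - Q[:-1])[None, :, :]
    denom = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
    diff = b0 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (diff[..., 0] * d2[..., 1] - diff[..., 1] * d2[..., 0]) / denom
        u = (diff[..., 0] * d1[..., 1] - diff[..., 1] * d1[..., 0]) / denom
    valid = (
        np.isfinite(t) & np.isfinite(u) & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)
    )
    return (a0 + t[..., None] * d1)[valid]


def _cluster_count(points: np.ndarray, radius_px: float) -> int:
    """Number of clusters under single-linkage at the given radius."""
    n = len(points)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    r2 = radius_px**2
    for i in range(n):
        d2 = ((points[i + 1 :] - points[i]) ** 2).sum(axis=1)
        for j in np.nonzero(d2 <= r2)[0] + i + 1:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[rj] = ri
    return len({find(i) for i in range(n)})


def _expected_junctions(
    polylines: Sequence[np.ndarray],
    widths_um: Sequence[float],
    parents: Sequence[int | None],
    um_per_px: float,
) -> tuple[int, int]:
    """Junction clusters a perfect detector would see in the rendered union.

    Candidate junction points are the attachment points (one per child) plus
    all pairwise geometric intersections of distinct centerlines, excluding
    a child's intersections with its own parent near the attachment (those
    *are* the attachment).  Crossing points of the same fiber pair closer
    than the combined stroke half-widths fuse into one junction in the
    rendered image and are counted once (single-linkage clusters per pair).
    Returns ``(n_junctions, n_crossing_clusters)`` with ``n_junctions`` the
    attachment count plus the crossing-cluster count.
    """
    n = len(polylines)
    n_attach = sum(1 for p in parents if p is not None)
    if n < 2:
        return n_attach, 0
    boxes = np.array(
        [[p[:, 0].min(), p[:, 1].min(), p[:, 0].max(), p[:, 1].max()] for p in polylines]
    )
    n_cross = 0
    for i in range(n):
        for j in range(i + 1, n):
            pad = 0.5 * (widths_um[i] + widths_um[j]) / um_per_px
            if (
                boxes[i, 2] + pad < boxes[j, 0]
                or boxes[j, 2] + pad < boxes[i, 0]
                or boxes[i, 3] + pad < boxes[j, 1]
                or boxes[j, 3] + pad < boxes[i, 1]
            ):
                continue
            pts = _segment_intersections(polylines[i], polylines[j])
            if len(pts) == 0:
                continue
            if parents[j] == i or parents[i] == j:
                child = polylines[j] if parents[j] == i else polylines[i]
                anchor = child[0]
                keep = ((pts - anchor) ** 2).sum(axis=1) > (2.0 * pad) ** 2
                pts = pts[keep]
                if len(pts) == 0:
                    continue
            n_cross += _cluster_count(pts, pad)
    return n_attach + n_cross, n_cross


def _rasterize_supersampled(
    polylines: Sequence[np.ndarray],
    widths_um: Sequence[float],
    spec: NetworkSpec,
    canvas: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean foreground at SUPERSAMPLE x resolution (round-capped strokes).

    Passing an existing canvas draws additional polylines onto it in place.
    """
    s = SUPERSAMPLE
    rows, cols = spec.image_size_px
    if canvas is None:
        canvas = np.zeros((rows * s, cols * s), dtype=bool)
    for poly, width in zip(polylines, widths_um):
        half = 0.5 * width / spec.um_per_px * s
        pts = (poly + 0.5) * s - 0.5
        for p, q in zip(pts[:-1], pts[1:]):
            d = q - p
            norm = np.hypot(*d)
            if norm == 0:
                continue
            n = np.array([-d[1], d[0]]) / norm * half
            corners = np.array([p + n, q + n, q - n, p - n])
            rr, cc = skdraw.polygon(
                corners[:, 0], corners[:, 1], shape=canvas.shape
            )
            canvas[rr, cc] = True
        for v in pts:
            rr, cc = skdraw.disk((v[0], v[1]), half, shape=canvas.shape)
            canvas[rr, cc] = True
    return canvas


def _block_mean(canvas: np.ndarray, s: int) -> np.ndarray:
    rows, cols = canvas.shape[0] // s, canvas.shape[1] // s
    return canvas.reshape(rows, s, cols, s).mean(axis=(1, 3))


def _shading_field(rng: np.random.Generator, shape, amplitude: float) -> np.ndarray:
    """Smooth multiplicative illumination surface (low-order polynomial)."""
    coeffs = rng.uniform(-1.0, 1.0, size=5)
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, shape[0]), np.linspace(-1, 1, shape[1]), indexing="ij"
    )
    surface = (
        coeffs[0] * xx
        + coeffs[1] * yy
        + coeffs[2] * xx * yy
        + coeffs[3] * xx**2
        + coeffs[4] * yy**2
    )
    peak = np.abs(surface).max()
    if peak > 0:
        surface = surface / peak
    return 1.0 + amplitude * surface


def generate_network(spec: NetworkSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic micrograph and its exact ground truth.

    The returned image has *dark* fibers on a bright background (DAB-like
    polarity, recorded on the image); ground truth is computed from the
    geometry before shading and noise are applied.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size_px
    image_area_um2 = rows * cols * spec.um_per_px**2
    px_area_um2 = (spec.um_per_px / SUPERSAMPLE) ** 2

    shade = _shading_field(rng, (rows, cols), spec.shading_amplitude)

    grower = _GeometryGrower(rng, spec)
    grower.grow()
    canvas = _rasterize_supersampled(grower.polylines, grower.widths, spec)
    n_drawn = len(grower.polylines)
    if spec.target_area_fraction_pct is not None:
        # close the loop on the rendered coverage: the Boolean-model budget
        # slightly undershoots because branches overlap their parents, so
        # extend it by the measured deficit and resume growth
        target = spec.target_area_fraction_pct / 100.0
        for _ in range(8):
            realized = float(canvas.sum()) * px_area_um2 / image_area_um2
            if grower.exhausted_supply or realized >= 0.98 * target:
                break
            extra = -image_area_um2 * (np.log1p(-target) - np.log1p(-realized))
            grower.extend_budget(extra)
            grower.grow()
            canvas = _rasterize_supersampled(
                grower.polylines[n_drawn:], grower.widths[n_drawn:], spec, canvas
            )
            n_drawn = len(grower.polylines)

    polylines, widths, lengths = grower.polylines, grower.widths, grower.lengths
    foreground_area_um2 = float(canvas.sum()) * px_area_um2
    coverage = _block_mean(canvas, SUPERSAMPLE)

    total_length_um = float(np.sum(lengths)) if lengths else 0.0
    if total_length_um > 0:
        wl = np.asarray(widths) * np.asarray(lengths)
        mean_width_um = float(np.sum(np.asarray(widths) * wl) / np.sum(wl))
    else:
        mean_width_um = 0.0
    if polylines:
        n_junctions, n_crossings = _expected_junctions(
            polylines, widths, grower.parents, spec.um_per_px
        )
    else:
        n_junctions = n_crossings = 0
    truth = GroundTruth(
        centerline_polylines=polylines,
        widths_um=widths,
        total_length_um=total_length_um,
        n_branch_points=grower.n_branch_points,
        mean_width_um=mean_width_um,
        foreground_area_um2=foreground_area_um2,
        true_area_fraction_pct=100.0 * foreground_area_um2 / image_area_um2,
        n_crossings=n_crossings,
        n_junctions=n_junctions,
        foreground_mask=coverage >= 0.5,
    )

    image = BACKGROUND_LEVEL * shade * (1.0 - spec.stain_contrast * coverage)
    for _ in range(spec.n_blob_artifacts):
        rel = rng.uniform(size=2)
        center = (rel[0] * (rows - 1), rel[1] * (cols - 1))
        radius_px = rng.uniform(5.0, 12.0) / spec.um_per_px
        strength = spec.stain_contrast * rng.uniform(0.7, 1.0)
        rr, cc = skdraw.disk(center, radius_px, shape=(rows, cols))
        image[rr, cc] *= 1.0 - strength
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(rows, cols))
    image = np.clip(image, 0.0, 1.0)

    calibrated = CalibratedImage(
        pixels=image,
        um_per_px=spec.um_per_px,
        polarity="dark",
        provenance=("synthetic",),
    )
    return calibrated, truth


@dataclass
class CohortMember:
    """One image of a two-group synthetic cohort."""

    group: str
    index: int
    seed: int
    image: CalibratedImage
    ground_truth: GroundTruth


def generate_cohort(
    spec_a: NetworkSpec,
    spec_b: NetworkSpec,
    n_images_per_group: int,
    seed: int,
    labels: tuple[str, str] = ("a", "b"),
) -> list[CohortMember]:
    """Generate two groups of images differing only by their spec parameters.

    Per-image seeds are drawn deterministically from the cohort seed, so a
    repeated call reproduces the cohort exactly.
    """
    if n_images_per_group < 2:
        raise ValidationError(
            f"n_images_per_group: must be >= 2, got {n_images_per_group}"
        )
    rng = np.random.default_rng(seed)
    image_seeds = rng.integers(0, 2**31, size=2 * n_images_per_group)
    members: list[CohortMember] = []
    for g, (label, spec) in enumerate(zip(labels, (spec_a, spec_b))):
        for i in range(n_images_per_group):
            member_seed = int(image_seeds[g * n_images_per_group + i])
            img, truth = generate_network(replace(spec, seed=member_seed))
            members.append(CohortMember(label, i, member_seed, img, truth))
    return members


#: study-condition presets: a densely innervated aponeurotic-fascia regime
#: (~9% stained area, ~500 branch points/mm², ~5.8 µm fibers) and a sparse
#: epimysial regime (~2.8%, ~140/mm², ~4.9 µm).  Branch probabilities follow
#: from branch density / (area fraction / width).
PRESETS: dict[str, dict] = {
    "tlf": {
        "target_area_fraction_pct": 9.0,
        "fiber_width_um": 5.8,
        "branch_prob": 0.012,
    },
    "gluteal": {
        "target_area_fraction_pct": 2.8,
        "fiber_width_um": 4.9,
        "branch_prob": 0.015,
    },
}


def preset_spec(
    name: str,
    image_size_px: tuple[int, int] = (512, 512),
    um_per_px: float = 1.0,
    seed: int = 0,
    **overrides,
) -> NetworkSpec:
    """A :class:`NetworkSpec` for one of the named tissue presets."""
    if name not in PRESETS:
        raise ValidationError(
            f"preset: unknown name {name!r}; available: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[name])
    params.update(overrides)
    return NetworkSpec(
        image_size_px=image_size_px, um_per_px=um_per_px, seed=seed, **params
    )
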