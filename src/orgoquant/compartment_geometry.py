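"""Two-ellipse decomposition of the merged organoid cluster.

A confronted tumor sphere and brain organoid merge into a "snowman" outline.
The outline is split at its two concave neck points and one ellipse is fitted
per arc — one for the brain organoid, one for the tumor — so that the brain
ellipse can serve as the reference region for the invasion ratios. All
compartment areas downstream are pixel counts over rasterized pixel-center
masks, never analytic πab, so every ratio is a ratio of pixel counts.

Neck detection works on a canonicalized contour: oriented counter-clockwise,
arc-length origin at the topmost-then-leftmost original vertex, resampled to
a fixed number of equally spaced vertices. Canonicalization makes the
decomposition invariant to the starting vertex and traversal direction of the
input polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.measure import EllipseModel

__all__ = [
    "ClusterContour",
    "Ellipse",
    "EllipsePair",
    "NeckPoints",
    "NoNeckError",
    "EllipseFitError",
    "find_neck_points",
    "fit_ellipse",
    "decompose_ellipses",
    "ellipse_region",
]


class NoNeckError(ValueError):
    """The contour has no usable pair of concave neck points."""


class EllipseFitError(ValueError):
    """An arc could not be fitted with an ellipse (degenerate/collinear)."""


@dataclass
class ClusterContour:
    """Closed boundary polygon of the merged cluster, pixel-center (x, y).

    ``vertices`` is an (N, 2) array. Contours with fewer than 3 vertices or
    zero enclosed area are flagged :attr:`degenerate` and excluded from
    geometric decomposition.
    """

    vertices: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (N, 2)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def signed_area_px2(self) -> float:
        """Shoelace area; positive for counter-clockwise vertex order."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area_px2(self) -> float:
        return abs(self.signed_area_px2)

    @property
    def area_um2(self) -> float:
        return self.area_px2 * self.pixel_size_um**2

    @property
    def degenerate(self) -> bool:
        return self.n_vertices < 3 or self.area_px2 == 0.0

    @property
    def perimeter_px(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def contains_point(self, xy: tuple[float, float]) -> bool:
        if self.degenerate:
            return False
        return Polygon(self.vertices).covers(Point(*xy))

    def is_simple(self) -> bool:
        return not self.degenerate and Polygon(self.vertices).is_valid

    def canonical(self, n: int = 360) -> "ClusterContour":
        """CCW orientation, landmark start, uniform arc-length resampling.

        The arc-length origin is placed at the original vertex with minimal y
        (then minimal x), which depends only on the vertex *set*, so any
        rotation or reversal of the input vertex list canonicalizes to the
        same resampled contour.
        """
        if self.degenerate:
            raise ValueError("cannot canonicalize a degenerate contour")
        verts = self.vertices
        if self.signed_area_px2 < 0:
            verts = verts[::-1]
        k = int(np.lexsort((verts[:, 0], verts[:, 1]))[0])
        verts = np.roll(verts, -k, axis=0)
        closed = np.vstack([verts, verts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        si = np.linspace(0.0, total, n, endpoint=False)
        x = np.interp(si, s, closed[:, 0])
        y = np.interp(si, s, closed[:, 1])
        return ClusterContour(np.column_stack([x, y]), self.pixel_size_um)


@dataclass
class Ellipse:
    """Axis-aligned-then-rotated ellipse, parameters in pixel units."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    rotation: float  # radians, in [0, pi); angle of the major axis vs +x

    def __post_init__(self) -> None:
        a, b = float(self.semi_major), float(self.semi_minor)
        rot = float(self.rotation)
        if b > a:  # normalize so semi_major >= semi_minor
            a, b = b, a
            rot += np.pi / 2
        rot = rot % np.pi
        self.semi_major, self.semi_minor, self.rotation = a, b, rot
        self.center = (float(self.center[0]), float(self.center[1]))
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")

    def normalized_radius(self, xy: np.ndarray) -> np.ndarray:
        """rho(x, y): < 1 inside, 1 on the boundary, > 1 outside."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        dx = xy[:, 0] - self.center[0]
        dy = xy[:, 1] - self.center[1]
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return np.sqrt((u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2)

    def contains(self, xy: tuple[float, float]) -> bool:
        return bool(self.normalized_radius(np.asarray(xy)[None])[0] <= 1.0)

    def boundary_distance(self, xy: np.ndarray) -> np.ndarray:
        """Radial distance (along the ray through the center) to the boundary.

        Exact along that ray; used as the margin measure for boundary events.
        Zero at the center direction singularity is returned as the minor
        radius.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        rho = self.normalized_radius(xy)
        d = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.abs(1.0 - rho) * d / rho
        return np.where(rho > 1e-12, dist, self.semi_minor)

    def point_at(self, theta: float | np.ndarray) -> np.ndarray:
        """Boundary point(s) at parametric angle(s) theta."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        u = self.semi_major * np.cos(theta)
        v = self.semi_minor * np.sin(theta)
        return np.column_stack([self.center[0] + u * c - v * s,
                                self.center[1] + u * s + v * c])

    @property
    def area_px2_analytic(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def to_dict(self) -> dict:
        return {
            "center_x": self.center[0],
            "center_y": self.center[1],
            "semi_major": self.semi_major,
            "semi_minor": self.semi_minor,
            "rotation_rad": self.rotation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipse":
        return cls((d["center_x"], d["center_y"]), d["semi_major"],
                   d["semi_minor"], d["rotation_rad"])


@dataclass
class EllipsePair:
    """Brain and tumor ellipses decomposing a merged cluster."""

    brain: Ellipse
    tumor: Ellipse
    overlap_area_px2: float = 0.0
    fit_residual_px: dict = field(default_factory=dict)
    manual: bool = False

    def __post_init__(self) -> None:
        if self.overlap_area_px2 < 0:
            raise ValueError("overlap_area_px2 must be >= 0")

    def to_dict(self) -> dict:
        return {
            "brain": self.brain.to_dict(),
            "tumor": self.tumor.to_dict(),
            "overlap_area_px2": self.overlap_area_px2,
            "fit_residual_px": dict(self.fit_residual_px),
            "manual": self.manual,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipsePair":
        return cls(
            Ellipse.from_dict(d["brain"]),
            Ellipse.from_dict(d["tumor"]),
            float(d.get("overlap_area_px2", 0.0)),
            dict(d.get("fit_residual_px", {})),
            bool(d.get("manual", False)),
        )


@dataclass
class NeckPoints:
    """Two neck indices into a canonicalized contour (i < j)."""

    i: int
    j: int
    contour: ClusterContour
    turn: np.ndarray  # smoothed signed turn angle per canonical vertex


def _signed_turn(verts: np.ndarray, window: int) -> np.ndarray:
    """Signed turning angle at each vertex of a closed CCW polygon.

    Discrete curvature proxy: the angle between the chords to the vertices
    ``window`` steps back and ahead; positive where the boundary is locally
    convex (CCW), negative at concavities. Smoothed by a circular moving
    average of the same window.
    """
    a = verts - np.roll(verts, window, axis=0)
    b = np.roll(verts, -window, axis=0) - verts
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    turn = np.arctan2(cross, dot)
    kernel = np.ones(window) / window
    n = len(turn)
    padded = np.concatenate([turn[-window:], turn, turn[:window]])
    sm = np.convolve(padded, kernel, mode="same")[window:window + n]
    return sm


def find_neck_points(
    contour: ClusterContour,
    n_resample: int = 360,
    window: int = 5,
    concave_min_turn_rad: float = 0.05,
) -> NeckPoints:
    """Locate the two concave neck vertices splitting a two-lobe outline.

    The contour is canonicalized and resampled, the signed turning angle is
    computed over a smoothing window, and local concavity minima below
    ``-concave_min_turn_rad`` become candidates. Among candidates the pair
    farthest apart along the contour (circular index distance) is returned;
    concavity strength breaks ties. Fewer than two candidates — a convex
    blob, or organoids fully engulfed — raises :class:`NoNeckError`.
    """
    canon = contour.canonical(n_resample)
    turn = _signed_turn(canon.vertices, window)
    n = len(turn)
    concave = turn < -abs(concave_min_turn_rad)
    is_min = np.ones(n, dtype=bool)
    for off in range(1, window + 1):
        is_min &= turn <= np.roll(turn, off)
        is_min &= turn <= np.roll(turn, -off)
    cand = np.flatnonzero(concave & is_min)
    # plateaus produce runs of equal minima; keep one index per run
    if cand.size:
        keep = [cand[0]]
        for c in cand[1:]:
            if c - keep[-1] > window:
                keep.append(int(c))
        if len(keep) > 1 and (n - keep[-1] + keep[0]) <= window:
            keep.pop()
        cand = np.asarray(keep)
    if cand.size < 2:
        raise NoNeckError(
            f"found {cand.size} concave candidate(s); need 2 to split the contour"
        )
    # A neck is two deep concavities facing each other across a narrow
    # waist that splits the outline into two substantial arcs. Score
    # candidate pairs by (combined depth) x (shorter arc between them) per
    # unit chord length: this rejects both isolated dents carved into one
    # lobe by boundary noise (no facing partner, long chord) and local
    # double-wiggles (tiny arc separation).
    min_sep = max(2 * window, n // 12)
    best: tuple[float, tuple[int, int]] | None = None
    for ii in range(len(cand)):
        for jj in range(ii + 1, len(cand)):
            i, j = int(cand[ii]), int(cand[jj])
            arc = min(j - i, n - (j - i))
            if arc < min_sep:
                continue
            chord = float(np.hypot(*(canon.vertices[i] - canon.vertices[j])))
            depth = -(turn[i] + turn[j])
            score = depth * arc / max(chord, 1e-9)
            if best is None or score > best[0]:
                best = (score, (i, j))
    if best is None:
        raise NoNeckError(
            "concave candidates cluster on one side of the contour; no neck pair"
        )
    i, j = best[1]
    return NeckPoints(i, j, canon, turn)


def fit_ellipse(points: np.ndarray) -> tuple[Ellipse, float]:
    """Direct least-squares ellipse fit of a point set.

    Returns the fitted ellipse (axes normalized so major >= minor, rotation
    in [0, pi)) and the RMS radial point-to-ellipse distance (measured along
    the ray through the ellipse center, which is exact for points on the
    ellipse and a tight proxy for the orthogonal distance near it).
    Degenerate inputs (collinear arcs, < 5 points) raise
    :class:`EllipseFitError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EllipseFitError(f"need >= 5 planar points, got shape {pts.shape}")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise EllipseFitError("direct ellipse fit failed (degenerate arc)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts) or model.params is None:
            raise EllipseFitError("direct ellipse fit failed (degenerate arc)")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("direct ellipse fit failed (non-finite parameters)")
    if a <= 0 or b <= 0:
        raise EllipseFitError("fit returned non-positive axes")
    ell = Ellipse((xc, yc), a, b, theta)
    res = ell.boundary_distance(pts)
    rms = float(np.sqrt(np.mean(res**2)))
    return ell, rms


def _split_arcs(
    verts: np.ndarray, i: int, j: int, trim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex runs between neck indices, trimming vertices nearest the neck."""
    n = len(verts)
    idx1 = np.arange(i, j + 1) % n
    idx2 = np.arange(j, i + n + 1) % n
    if trim > 0:
        if len(idx1) > 2 * trim + 5:
            idx1 = idx1[trim:-trim]
        if len(idx2) > 2 * trim + 5:
            idx2 = idx2[trim:-trim]
    return verts[idx1], verts[idx2]


def _seeded_split(
    verts: np.ndarray, hint_a: tuple[float, float], hint_b: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Fallback split: assign vertices to the nearer hint.

    Valid only when the nearest-hint labeling changes exactly twice along the
    closed contour, i.e. it cuts the outline into two contiguous arcs.
    """
    da = np.hypot(verts[:, 0] - hint_a[0], verts[:, 1] - hint_a[1])
    db = np.hypot(verts[:, 0] - hint_b[0], verts[:, 1] - hint_b[1])
    lab = da <= db
    changes = np.flatnonzero(lab != np.roll(lab, 1))
    if len(changes) != 2 or lab.all() or (~lab).all():
        return None
    c0, c1 = int(changes[0]), int(changes[1])
    n = len(verts)
    idx1 = np.arange(c0, c1) % n
    idx2 = np.arange(c1, c0 + n) % n
    return verts[idx1], verts[idx2]


def decompose_ellipses(
    contour: ClusterContour,
    brain_hint: tuple[float, float],
    tumor_hint: tuple[float, float],
    gfp_mask: np.ndarray | None = None,
    n_resample: int = 360,
    neck_trim: int = 3,
    frame_shape: tuple[int, int] | None = None,
) -> EllipsePair:
    """Split the cluster outline at its neck and fit one ellipse per lobe.

    Tumor identity goes to the ellipse whose interior holds the larger
    GFP-positive pixel fraction when ``gfp_mask`` is given, else to the
    ellipse containing ``tumor_hint`` (nearest center on ties). When no neck
    is found the contour is split by nearest hint instead; if that also fails
    to yield two arcs the :class:`NoNeckError` propagates.
    """
    if not contour.contains_point(brain_hint) or not contour.contains_point(tumor_hint):
        raise ValueError("hints must lie inside the contour")
    try:
        neck = find_neck_points(contour, n_resample=n_resample)
        arc1, arc2 = _split_arcs(neck.contour.vertices, neck.i, neck.j, neck_trim)
    except NoNeckError:
        canon = contour.canonical(n_resample)
        split = _seeded_split(canon.vertices, brain_hint, tumor_hint)
        if split is None:
            raise
        arc1, arc2 = split

    fits = []
    for name, arc in (("arc1", arc1), ("arc2", arc2)):
        try:
            fits.append(fit_ellipse(arc))
        except EllipseFitError as exc:
            raise EllipseFitError(f"{name}: {exc}") from exc
    (e1, r1), (e2, r2) = fits

    if frame_shape is None and gfp_mask is not None:
        frame_shape = gfp_mask.shape
    if frame_shape is None:
        hi = contour.vertices.max(axis=0)
        frame_shape = (int(np.ceil(hi[1])) + 3, int(np.ceil(hi[0])) + 3)

    if gfp_mask is not None:
        fracs = []
        for e in (e1, e2):
            reg = ellipse_region(e, frame_shape)
            npx = reg.sum()
            fracs.append((gfp_mask & reg).sum() / npx if npx else 0.0)
        tumor_first = fracs[0] > fracs[1]
    else:
        in1, in2 = e1.contains(tumor_hint), e2.contains(tumor_hint)
        if in1 != in2:
            tumor_first = in1
        else:
            d1 = np.hypot(e1.center[0] - tumor_hint[0], e1.center[1] - tumor_hint[1])
            d2 = np.hypot(e2.center[0] - tumor_hint[0], e2.center[1] - tumor_hint[1])
            tumor_first = d1 < d2
    if tumor_first:
        tumor, rt, brain, rb = e1, r1, e2, r2
    else:
        tumor, rt, brain, rb = e2, r2, e1, r1

    overlap = int(
        (ellipse_region(brain, frame_shape) & ellipse_region(tumor, frame_shape)).sum()
    )
    return EllipsePair(
        brain=brain,
        tumor=tumor,
        overlap_area_px2=float(overlap),
        fit_residual_px={"brain": rb, "tumor": rt},
    )


def ellipse_region(e: Ellipse, frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ellipse: pixel (r, c) is True iff its center is inside.

    Exact per-pixel-center evaluation of the interior inequality; this is the
    area accounting used for every compartment ratio.
    """
    rows, cols = frame_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("frame must be nonempty")
    cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    dx = cc - e.center[0]
    dy = rr - e.center[1]
    c, s = np.cos(e.rotation), np.sin(e.rotation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    # small epsilon keeps pixels lying exactly on the boundary inside
    # regardless of rotation round-off
    return (u / e.semi_major) ** 2 + (v / e.semi_minor) ** 2 <= 1.0 + 1e-12
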