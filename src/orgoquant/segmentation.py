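"""Cluster and tumor-channel segmentation.

The merged organoid cluster is delineated by seeded region growing on the
brightfield/reference channel: a breadth-first flood from the seed that
accepts a 4-connected neighbor when its intensity lies within ``tolerance``
of the running region mean, the mean being updated after every accepted
pixel. The criterion uses intensity differences only, so the result is
invariant to adding a constant to the whole image.

The tumor (GFP) channel is thresholded inside the cluster and labeled with
8-connectivity — thin diagonal links such as tumor microtubes should keep a
protrusion attached to the mass — and split into the core component (the one
holding the tumor anchor) versus detached single cells, after discarding
objects below a physical size filter.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imaging_io import PlanarImage

__all__ = [
    "ClusterMask",
    "TumorSegmentation",
    "region_grow",
    "extract_contour",
    "tumor_mask",
    "classify_components",
]

#: neighbor offsets in row-major scan order (up, left, right, down)
_N4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ClusterMask:
    """Segmented merged-organoid region; 4-connected and containing the seed."""

    member: np.ndarray
    seed: tuple[int, int]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if not self.member.any():
            raise ValueError("empty cluster mask")
        if not self.member[self.seed]:
            raise ValueError(f"seed {self.seed} not inside mask")

    @property
    def area_px(self) -> int:
        return int(self.member.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


@dataclass
class TumorSegmentation:
    """GFP mask partitioned into core mass vs detached single cells.

    ``component_labels`` is 0 for background; every nonzero label is either
    ``core_label`` or listed in ``single_cell_labels``. ``core_label`` of 0
    means no core survived the size filter (flagged via :attr:`empty`).
    """

    gfp_mask: np.ndarray
    component_labels: np.ndarray
    core_label: int
    single_cell_labels: list[int]
    min_object_um2: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.gfp_mask = np.asarray(self.gfp_mask, dtype=bool)
        self.component_labels = np.asarray(self.component_labels)
        if np.any(self.component_labels.astype(bool) & ~self.gfp_mask):
            raise ValueError("labeled pixels outside gfp_mask")
        if self.core_label in self.single_cell_labels:
            raise ValueError("core_label also listed as a single cell")

    @property
    def empty(self) -> bool:
        return self.core_label == 0 and not self.single_cell_labels

    @property
    def core_mask(self) -> np.ndarray:
        return self.component_labels == self.core_label if self.core_label else np.zeros_like(self.gfp_mask)

    @property
    def single_cell_mask(self) -> np.ndarray:
        return np.isin(self.component_labels, self.single_cell_labels)

    def component_areas_um2(self) -> dict[int, float]:
        labels, counts = np.unique(self.component_labels, return_counts=True)
        px2 = self.pixel_size_um**2
        return {int(l): float(c) * px2 for l, c in zip(labels, counts) if l != 0}


def region_grow(
    image: PlanarImage, seed: tuple[int, int], tolerance: float
) -> ClusterMask:
    """Seeded region growing with a running-mean homogeneity criterion.

    Breadth-first growth from ``seed``: a candidate 4-neighbor is accepted
    when ``|intensity - region_mean| <= tolerance`` with the mean taken over
    pixels accepted so far; the mean is updated immediately on acceptance.
    Neighbors are offered in row-major order (up, left, right, down), which
    makes the result deterministic. The seed itself is always accepted, so a
    seed failing its own criterion yields a singleton region. Rejected pixels
    may be re-offered later by a different frontier neighbor (the mean will
    have moved), which is intentional.
    """
    arr = np.asarray(image.intensities, dtype=np.float64)
    rows, cols = arr.shape
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise IndexError(f"seed {seed} outside image of shape {arr.shape}")

    member = np.zeros(arr.shape, dtype=bool)
    member[r0, c0] = True
    total = arr[r0, c0]
    count = 1
    frontier: deque[tuple[int, int]] = deque([(r0, c0)])
    while frontier:
        r, c = frontier.popleft()
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not member[rr, cc]:
                if abs(arr[rr, cc] - total / count) <= tolerance:
                    member[rr, cc] = True
                    total += arr[rr, cc]
                    count += 1
                    frontier.append((rr, cc))
    return ClusterMask(member, (r0, c0), image.pixel_size_um)


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary tracing of a single filled region.

    Returns ordered boundary pixel coordinates as (row, col) pairs, starting
    from the topmost-then-leftmost foreground pixel and traversing the outer
    boundary once. Termination is by repeated (pixel, exit-direction) state,
    which is robust for 1-px-wide protrusions (those pixels legitimately
    appear twice in the traversal).
    """
    rows, cols = mask.shape
    rs, cs = np.nonzero(mask)
    i = int(np.lexsort((cs, rs))[0])
    start = (int(rs[i]), int(cs[i]))
    # Moore neighborhood scanned in fixed rotational order starting east
    nbrs = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))

    boundary = [start]
    cur = start
    back = 4  # pretend we entered the start pixel from the west
    seen: set[tuple[tuple[int, int], int]] = set()
    while True:
        for k in range(1, 9):
            d = (back + k) % 8
            nr, nc = cur[0] + nbrs[d][0], cur[1] + nbrs[d][1]
            if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc]:
                break
        else:  # isolated single pixel
            return np.array([start], dtype=float)
        state = (cur, d)
        if state in seen:
            break
        seen.add(state)
        cur = (nr, nc)
        boundary.append(cur)
        back = (d + 4) % 8
    while len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    return np.array(boundary, dtype=float)


def extract_contour(mask: ClusterMask):
    """Outer boundary polygon of the largest hole-filled region of a mask.

    Vertices are pixel-center ``(x, y)`` coordinates ordered counter-clockwise
    (positive shoelace area in the image frame). Interior holes are filled
    before tracing, so the polygon is the filled outline only. Masks that are
    too thin to bound area (a single pixel, a 1-px line) are returned flagged
    degenerate.
    """
    from .compartment_geometry import ClusterContour

    labeled, n = ndimage.label(mask.member, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        region = labeled == keep
    else:
        region = mask.member.copy()
    region = ndimage.binary_fill_holes(region)

    rc = _trace_boundary(region)
    xy = rc[:, ::-1].copy()  # (row, col) -> (x, y)
    contour = ClusterContour(xy, pixel_size_um=mask.pixel_size_um)
    return contour


def tumor_mask(
    gfp: PlanarImage, cluster: ClusterMask, method: str = "otsu"
) -> np.ndarray:
    """Threshold the GFP channel restricted to the cluster region.

    ``method`` is ``"otsu"`` (threshold computed from intensities inside the
    cluster only) or ``"fixed:<value>"``. Pixels outside the cluster are
    always False.
    """
    if gfp.intensities.shape != cluster.member.shape:
        raise ValueError("gfp image and cluster mask are not aligned")
    inside = cluster.member
    if not inside.any():
        raise ValueError("empty cluster")
    vals = np.asarray(gfp.intensities, dtype=np.float64)
    if method == "otsu":
        pool = vals[inside]
        if np.ptp(pool) == 0:
            return np.zeros_like(inside)
        thr = threshold_otsu(pool)
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (vals > thr) & inside


def classify_components(
    gfp_mask: np.ndarray,
    tumor_anchor: tuple[int, int],
    min_object_um2: float,
    pixel_size_um: float,
) -> TumorSegmentation:
    """Label the GFP mask (8-connected) into core mass vs detached cells.

    Components smaller than ``min_object_um2`` are discarded. The component
    containing ``tumor_anchor`` — or, if the anchor pixel is background, the
    nearest surviving component in pixel distance — becomes the core; all
    other components are detached single cells. If nothing survives the
    filter the segmentation is returned empty (``core_label == 0``).
    """
    gfp_mask = np.asarray(gfp_mask, dtype=bool)
    ar, ac = int(tumor_anchor[0]), int(tumor_anchor[1])
    if not (0 <= ar < gfp_mask.shape[0] and 0 <= ac < gfp_mask.shape[1]):
        raise IndexError(f"tumor_anchor {tumor_anchor} outside image")

    labels, n = ndimage.label(gfp_mask, structure=_STRUCT8)
    if n:
        counts = np.bincount(labels.ravel())
        min_px = min_object_um2 / pixel_size_um**2
        small = np.flatnonzero(counts < min_px)
        small = small[small != 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    survivors = np.unique(labels)
    survivors = survivors[survivors != 0]
    if survivors.size == 0:
        return TumorSegmentation(
            gfp_mask, np.zeros_like(labels), 0, [], min_object_um2, pixel_size_um
        )

    if labels[ar, ac] != 0:
        core = int(labels[ar, ac])
    else:
        # nearest surviving labeled pixel to the anchor
        rr, cc = np.nonzero(np.isin(labels, survivors))
        d2 = (rr - ar) ** 2 + (cc - ac) ** 2
        k = int(np.argmin(d2))
        core = int(labels[rr[k], cc[k]])
    singles = [int(l) for l in survivors if l != core]
    return TumorSegmentation(
        gfp_mask, labels, core, singles, min_object_um2, pixel_size_um
    )
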