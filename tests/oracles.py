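"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately written in the most naive way possible —
explicit Python loops, list-based queues — so that agreement with the
vectorized/optimized library code is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_oracle(arr, seed, tolerance):
    """Running-mean region growing, list-based FIFO, row-major neighbors."""
    arr = np.asarray(arr, dtype=float)
    rows, cols = arr.shape
    member = [[False] * cols for _ in range(rows)]
    r0, c0 = seed
    member[r0][c0] = True
    total = float(arr[r0, c0])
    count = 1
    queue = [(r0, c0)]
    while queue:
        r, c = queue.pop(0)
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not member[rr][cc]:
                if abs(float(arr[rr, cc]) - total / count) <= tolerance:
                    member[rr][cc] = True
                    total += float(arr[rr, cc])
                    count += 1
                    queue.append((rr, cc))
    return np.array(member, dtype=bool)


def shoelace_area(vertices) -> float:
    """Plain shoelace formula over an (N, 2) closed polygon."""
    verts = np.asarray(vertices, dtype=float)
    total = 0.0
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        total += x1 * y2 - x2 * y1
    return abs(total) / 2.0


def mip_oracle(planes) -> np.ndarray:
    """Pointwise supremum over z via explicit triple loop."""
    planes = np.asarray(planes)
    nz, rows, cols = planes.shape
    out = np.zeros((rows, cols), dtype=planes.dtype)
    for r in range(rows):
        for c in range(cols):
            best = planes[0, r, c]
            for z in range(1, nz):
                if planes[z, r, c] > best:
                    best = planes[z, r, c]
            out[r, c] = best
    return out


def ellipse_pixel_count(cx, cy, a, b, rot, frame_shape) -> int:
    """Exhaustive pixel-center membership count of an ellipse interior."""
    count = 0
    for r in range(frame_shape[0]):
        for c in range(frame_shape[1]):
            dx, dy = c - cx, r - cy
            u = dx * math.cos(rot) + dy * math.sin(rot)
            v = -dx * math.sin(rot) + dy * math.cos(rot)
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                count += 1
    return count
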