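"""Synthetic confrontation scenes and migration tracks with known truth.

The scene generator emulates the structure the quantification assumes: a
brightfield-like channel showing two merged elliptical lobes (brain organoid
and tumor sphere) with a jittered outline and darker rim, and a GFP channel
in which the tumor core plus an advancing replacement front and a set of
detached single cells are painted before noise. The replacement front is
grown as a geodesic flood from the lobe junction into the brain lobe, so
the replaced region stays connected to the core — contiguous mass
replacement, which is what lets component labeling call it "core".

Ground truth is recomputed from the rendered pre-noise masks (realized pixel
fractions), never echoed from the requested parameters. All outputs are pure
functions of (spec, seed).

The walk generator produces persistent random walks inside a reflecting
brain ellipse. Per-step turning angles are wrapped-normal with spread chosen
so that the expected step-direction correlation equals the requested
persistence; step lengths are gamma-jittered around ``speed × Δt``.
Divisions are Poisson events: the parent halts, and after a stationary
mitotic pause (default 160 min) two daughters leave the division point with
antiparallel headings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .compartment_geometry import Ellipse
from .imaging_io import ImageStack
from .track_analysis import CellTrack

__all__ = [
    "SceneSpec",
    "WalkSpec",
    "SceneTruth",
    "WalkTruth",
    "InfeasibleSpecError",
    "render_scene",
    "simulate_walks",
]


class InfeasibleSpecError(ValueError):
    """Requested fractions or counts do not fit in the available area."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic confrontation scene (pixel units).

    Ellipse tuples are ``(cx, cy, semi_major, semi_minor, rotation_rad)`` in
    the (x, y) = (col, row) frame. ``competition_true`` is the target
    fraction of the brain-lobe pixel area replaced by the advancing core
    front; ``single_cell_true`` the target area fraction covered by detached
    cells. ``n_debris_cells`` adds GFP specks below the usual object-size
    filter, for testing the filter itself.
    """

    frame_shape: tuple[int, int] = (256, 256)
    brain_ellipse: tuple[float, float, float, float, float] = (158.0, 128.0, 78.0, 66.0, 0.0)
    tumor_ellipse: tuple[float, float, float, float, float] = (62.0, 128.0, 48.0, 42.0, 0.0)
    competition_true: float = 0.3
    single_cell_true: float = 0.05
    n_cells_true: int = 12
    cell_radius_um: tuple[float, float] = (1.5, 12.0)
    n_debris_cells: int = 0
    debris_area_px: int = 6
    pixel_size_um: float = 1.0
    gfp_signal: float = 3000.0
    gfp_background: float = 100.0
    bf_interior: float = 170.0
    bf_rim: float = 140.0
    bf_background: float = 90.0
    gauss_sd: float = 8.0
    boundary_jitter: float = 0.02
    jitter_sigma_px: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.competition_true <= 1.0:
            raise InfeasibleSpecError("competition_true outside [0, 1]")
        if self.single_cell_true < 0:
            raise InfeasibleSpecError("single_cell_true must be >= 0")
        if self.competition_true + self.single_cell_true > 1.0:
            raise InfeasibleSpecError(
                "competition_true + single_cell_true exceeds 1"
            )
        if self.single_cell_true > 0 and self.n_cells_true == 0:
            raise InfeasibleSpecError(
                "single_cell_true > 0 requires n_cells_true > 0"
            )

    def brain(self) -> Ellipse:
        cx, cy, a, b, rot = self.brain_ellipse
        return Ellipse((cx, cy), a, b, rot)

    def tumor(self) -> Ellipse:
        cx, cy, a, b, rot = self.tumor_ellipse
        return Ellipse((cx, cy), a, b, rot)


@dataclass
class SceneTruth:
    """Pixel-exact ground truth recomputed from the rendered masks."""

    competition_realized: float
    single_fraction_realized: float
    n_single_cells: int
    brain_area_px: int
    core_in_brain_px: int
    single_area_px: int
    cell_centers_xy: list[tuple[float, float]]
    brain_center_xy: tuple[float, float]
    tumor_center_xy: tuple[float, float]
    seed: int
    brain_mask: np.ndarray | None = None
    core_mask: np.ndarray | None = None
    single_mask: np.ndarray | None = None
    debris_mask: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "competition_realized": self.competition_realized,
            "single_fraction_realized": self.single_fraction_realized,
            "n_single_cells": self.n_single_cells,
            "brain_area_px": self.brain_area_px,
            "core_in_brain_px": self.core_in_brain_px,
            "single_area_px": self.single_area_px,
            "cell_centers_xy": [list(c) for c in self.cell_centers_xy],
            "brain_center_xy": list(self.brain_center_xy),
            "tumor_center_xy": list(self.tumor_center_xy),
            "seed": self.seed,
        }


def _jittered_region(
    e: Ellipse, frame_shape: tuple[int, int], jfield: np.ndarray, amp: float
) -> np.ndarray:
    """Ellipse raster with a smooth radial wobble of relative amplitude amp."""
    rows, cols = frame_shape
    cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    rho = e.normalized_radius(pts).reshape(frame_shape)
    return rho <= 1.0 + amp * jfield


def _geodesic_flood(
    region: np.ndarray, seeds: np.ndarray, n_pixels: int
) -> np.ndarray:
    """First ``n_pixels`` of ``region`` by 4-connected BFS distance from seeds.

    Within one distance level pixels are taken in row-major order, making the
    front deterministic and reproducible.
    """
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    chosen = np.zeros_like(region)
    frontier = seeds & region
    visited = frontier.copy()
    remaining = n_pixels
    while remaining > 0 and frontier.any():
        idx = np.argwhere(frontier)  # row-major sorted
        take = idx[:remaining]
        chosen[take[:, 0], take[:, 1]] = True
        remaining -= len(take)
        frontier = ndimage.binary_dilation(visited, structure=struct) & region & ~visited
        visited |= frontier
    if remaining > 0:
        raise InfeasibleSpecError(
            f"replacement front short by {remaining} px: requested fraction "
            "exceeds the reachable brain-lobe area"
        )
    return chosen


def _place_blob(
    rng: np.random.Generator,
    available: np.ndarray,
    n_px: int,
    radius_px: float,
    max_attempts: int = 200,
) -> tuple[np.ndarray, tuple[float, float]]:
    """One detached blob of exactly ``n_px`` pixels inside ``available``."""
    r_int = max(1, int(np.ceil(radius_px)))
    centers = ndimage.binary_erosion(available, structure=disk(r_int + 1))
    cand = np.argwhere(centers)
    for _ in range(max_attempts):
        pool = cand if cand.size else np.argwhere(available)
        if not pool.size:
            break
        cr, cc = pool[rng.integers(len(pool))]
        # nearest n_px available pixels to the chosen center
        r0, r1 = max(0, cr - 3 * r_int), min(available.shape[0], cr + 3 * r_int + 1)
        c0, c1 = max(0, cc - 3 * r_int), min(available.shape[1], cc + 3 * r_int + 1)
        sub = available[r0:r1, c0:c1]
        rr, ccx = np.nonzero(sub)
        if len(rr) < n_px:
            continue
        d2 = (rr + r0 - cr) ** 2 + (ccx + c0 - cc) ** 2
        order = np.lexsort((ccx, rr, d2))[:n_px]
        blob = np.zeros_like(available)
        blob[rr[order] + r0, ccx[order] + c0] = True
        # reject blobs that came out disconnected (pathological pockets)
        _, ncomp = ndimage.label(blob, structure=np.ones((3, 3), bool))
        if ncomp != 1:
            continue
        return blob, (float(cc), float(cr))
    raise InfeasibleSpecError(
        f"could not place a detached cell of {n_px} px; area too crowded"
    )


def _shot_noise(rng: np.random.Generator, base: np.ndarray, gauss_sd: float) -> np.ndarray:
    noisy = rng.poisson(base).astype(np.float64) + rng.normal(0.0, gauss_sd, base.shape)
    return np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)


def render_scene(spec: SceneSpec) -> tuple[ImageStack, SceneTruth]:
    """Render one two-channel confrontation scene and its pixel-exact truth.

    Channel 0 is GFP, channel 1 the brightfield-like reference. The realized
    competition fraction matches ``competition_true`` to within one pixel of
    the brain-lobe area; detached-cell pixel quotas are filled exactly, so
    the realized single-cell fraction is within rounding of the target.
    """
    rng = np.random.default_rng(spec.seed)
    frame = spec.frame_shape
    brain_e, tumor_e = spec.brain(), spec.tumor()

    jfield = ndimage.gaussian_filter(rng.standard_normal(frame), spec.jitter_sigma_px)
    sd = jfield.std()
    if sd > 0:
        jfield = jfield / sd
    B = _jittered_region(brain_e, frame, jfield, spec.boundary_jitter)
    T = _jittered_region(tumor_e, frame, jfield, spec.boundary_jitter)
    if not (B & T).any():
        raise InfeasibleSpecError("brain and tumor ellipses do not overlap")
    union = B | T
    n_B = int(B.sum())

    # advancing replacement front, grown from the lobe junction into the brain
    T_excl = T & ~B
    seeds = ndimage.binary_dilation(T_excl, structure=np.ones((3, 3), bool)) & B
    if not seeds.any():
        seeds = B & T
    target_front = int(round(spec.competition_true * n_B))
    front = _geodesic_flood(B, seeds, target_front) if target_front else np.zeros(frame, bool)
    core = T_excl | front

    # detached single cells: exact per-cell pixel quotas summing to the target
    target_single = int(round(spec.single_cell_true * n_B))
    single_mask = np.zeros(frame, bool)
    centers: list[tuple[float, float]] = []
    struct8 = np.ones((3, 3), bool)
    available = B & ~ndimage.binary_dilation(core, structure=struct8, iterations=2)
    if spec.n_cells_true > 0 and target_single > 0:
        base_q, extra = divmod(target_single, spec.n_cells_true)
        quotas = [base_q + (1 if i < extra else 0) for i in range(spec.n_cells_true)]
        r_lo, r_hi = spec.cell_radius_um
        for q in quotas:
            r_eff = np.sqrt(q / np.pi) * spec.pixel_size_um
            if not (0.5 * r_lo <= r_eff <= 1.5 * r_hi):
                raise InfeasibleSpecError(
                    f"cell_radius_um: per-cell radius {r_eff:.2f} µm falls outside "
                    f"the plausible range around {spec.cell_radius_um}"
                )
            blob, c = _place_blob(rng, available, q, np.sqrt(q / np.pi))
            single_mask |= blob
            centers.append(c)
            available &= ~ndimage.binary_dilation(blob, structure=struct8, iterations=2)

    debris_mask = np.zeros(frame, bool)
    for _ in range(spec.n_debris_cells):
        blob, _c = _place_blob(rng, available, spec.debris_area_px,
                               np.sqrt(spec.debris_area_px / np.pi))
        debris_mask |= blob
        available &= ~ndimage.binary_dilation(blob, structure=struct8, iterations=2)

    # paint channels, then noise
    rim = union & ~ndimage.binary_erosion(union, structure=struct8, iterations=2)
    bf_base = np.full(frame, spec.bf_background, dtype=np.float64)
    bf_base[union] = spec.bf_interior
    bf_base[rim] = spec.bf_rim
    gfp_all = core | single_mask | debris_mask
    gfp_base = np.full(frame, spec.gfp_background, dtype=np.float64)
    gfp_base[gfp_all] = spec.gfp_signal

    gfp_img = _shot_noise(rng, gfp_base, spec.gauss_sd)
    bf_img = _shot_noise(rng, bf_base, spec.gauss_sd)
    stack = ImageStack(
        np.stack([gfp_img, bf_img])[:, np.newaxis],
        ["GFP", "BF"],
        spec.pixel_size_um,
    )

    core_in_B = int((core & B).sum())
    single_px = int((single_mask & B).sum())
    truth = SceneTruth(
        competition_realized=core_in_B / n_B,
        single_fraction_realized=single_px / n_B,
        n_single_cells=len(centers),
        brain_area_px=n_B,
        core_in_brain_px=core_in_B,
        single_area_px=single_px,
        cell_centers_xy=centers,
        brain_center_xy=(brain_e.center[0], brain_e.center[1]),
        tumor_center_xy=(tumor_e.center[0], tumor_e.center[1]),
        seed=spec.seed,
        brain_mask=B,
        core_mask=core,
        single_mask=single_mask,
        debris_mask=debris_mask,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# persistent random walks


@dataclass
class WalkSpec:
    """Parameters of the migration simulator (µm, minutes).

    ``persistence`` is the expected correlation of step directions,
    E[cos Δθ]; turning angles are wrapped-normal with σ = sqrt(-2 ln p).
    The default speed matches the fastest invading line observed in the
    confrontation assay (≈24 µm/h); tracks default to one 40-min recording
    sampled every 2 min.
    """

    speed_um_per_h: float = 23.8
    persistence: float = 0.7
    step_min: float = 2.0
    duration_min: float = 40.0
    brain_ellipse: tuple[float, float, float, float, float] = (0.0, 0.0, 150.0, 130.0, 0.0)
    division_rate: float = 0.0
    mitotic_pause_min: float = 160.0
    speed_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_um_per_h < 0:
            raise ValueError("speed_um_per_h must be >= 0")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must be in [0, 1)")
        if self.step_min <= 0:
            raise ValueError("step_min must be > 0")

    def brain(self) -> Ellipse:
        cx, cy, a, b, rot = self.brain_ellipse
        return Ellipse((cx, cy), a, b, rot)


@dataclass
class ReflectionLog:
    track_id: str
    sample_index: int  # index of the sample ending the reflected step
    t_min: float
    x_um: float
    y_um: float


@dataclass
class DivisionLog:
    parent_id: str
    daughter_ids: tuple[str, str]
    t_min: float
    x_um: float
    y_um: float


@dataclass
class WalkTruth:
    """Generator-side truth: realized speeds and event logs."""

    mean_step_speed_um_per_h: float
    n_steps: int
    reflections: list[ReflectionLog] = field(default_factory=list)
    divisions: list[DivisionLog] = field(default_factory=list)
    seed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "mean_step_speed_um_per_h": self.mean_step_speed_um_per_h,
            "n_steps": self.n_steps,
            "reflections": [asdict(r) for r in self.reflections],
            "divisions": [asdict(d) for d in self.divisions],
            "seed": self.seed,
        }


def _reflect_step(
    e: Ellipse, p: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Advance p by d inside e with specular reflection; preserves |d|."""
    reflected = False
    for _ in range(10):
        q = p + d
        if e.normalized_radius(q[None])[0] <= 1.0:
            return q, reflected
        # intersection of the segment with the boundary, in the ellipse frame
        c, s = np.cos(e.rotation), np.sin(e.rotation)
        R = np.array([[c, s], [-s, c]])
        scale = np.array([e.semi_major, e.semi_minor])
        up = R @ (p - np.asarray(e.center)) / scale
        ud = R @ d / scale
        A = ud @ ud
        Bq = 2.0 * (up @ ud)
        C = up @ up - 1.0
        disc = Bq * Bq - 4.0 * A * C
        if A == 0 or disc < 0:
            return p, reflected  # numerically stuck; stay put
        t = (-Bq + np.sqrt(disc)) / (2.0 * A)
        t = float(np.clip(t, 0.0, 1.0))
        hit = p + t * d
        # outward normal from the gradient of the implicit form
        uh = R @ (hit - np.asarray(e.center)) / scale
        n_world = R.T @ (uh / scale)
        norm = np.linalg.norm(n_world)
        if norm == 0:
            return hit, True
        n_hat = n_world / norm
        rest = (1.0 - t) * d
        d = rest - 2.0 * (rest @ n_hat) * n_hat
        # nudge inward to avoid re-hitting the boundary at t=0
        p = hit + 1e-9 * (-n_hat)
        reflected = True
    return p, reflected


def _walk(
    rng: np.random.Generator,
    spec: WalkSpec,
    start: np.ndarray,
    heading: float,
    t0: float,
    n_steps: int,
    track_id: str,
    parent_id: str | None,
    step_speeds: list[float],
    hazard: float,
) -> tuple[CellTrack, list[int], tuple[float, np.ndarray] | None]:
    """Simulate one track.

    Returns the track, the sample indices that ended a bounced step (raw
    boundary contacts), and a pending division (t, position) or None.
    """
    e = spec.brain()
    sigma = np.sqrt(-2.0 * np.log(spec.persistence)) if spec.persistence > 0 else None
    mean_len = spec.speed_um_per_h * spec.step_min / 60.0
    shape = 1.0 / spec.speed_cv**2 if spec.speed_cv > 0 else None

    ts = [t0]
    xs = [start[0]]
    ys = [start[1]]
    p = start.astype(float).copy()
    contacts: list[int] = []
    division: tuple[float, np.ndarray] | None = None
    for k in range(n_steps):
        if hazard > 0 and rng.random() < hazard and k >= 1:
            division = (ts[-1], p.copy())
            break
        if sigma is None:
            heading = rng.uniform(0.0, 2.0 * np.pi)
        else:
            heading = heading + sigma * rng.standard_normal()
        if shape is not None and mean_len > 0:
            L = rng.gamma(shape, mean_len / shape)
        else:
            L = mean_len
        step_speeds.append(L * 60.0 / spec.step_min)
        d = L * np.array([np.cos(heading), np.sin(heading)])
        p, bounced = _reflect_step(e, p, d)
        ts.append(t0 + (k + 1) * spec.step_min)
        xs.append(p[0])
        ys.append(p[1])
        if bounced:
            contacts.append(len(ts) - 1)
            last = p - np.array([xs[-2], ys[-2]])
            if np.linalg.norm(last) > 0:
                heading = float(np.arctan2(last[1], last[0]))
    track = CellTrack(track_id, np.array(ts), np.array(xs), np.array(ys), parent_id)
    return track, contacts, division


def _log_reflections(
    track: CellTrack, e: Ellipse, contacts: list[int], truth: "WalkTruth"
) -> None:
    """Convert raw boundary contacts into sampled reversal events.

    A grazing cell can touch the boundary on several consecutive steps and
    keep drifting outward between touches, so the behavioral turnaround —
    the sample where the normalized radius peaks — may trail the first
    numerical contact. Truth is defined at sampling resolution: one event
    per contact episode, placed at the first radial peak at or after the
    contact. Contacts whose turn is never resolved in the recorded samples
    (track ends first, or sampling hides the outward leg entirely) are not
    reversal events and are not logged.
    """
    if not contacts:
        return
    rho = e.normalized_radius(track.positions)
    drho = np.diff(rho)
    n = track.n_samples
    logged_until = -10
    for c in contacts:
        if c <= logged_until + 1:  # same episode as the previous event
            continue
        k = max(c - 1, 1)
        while k <= n - 2 and drho[k] >= 0:
            k += 1
        if k > n - 2:
            continue  # turnaround beyond the end of the recording
        if drho[k - 1] <= 0:
            continue  # outward leg not captured by the sampling
        truth.reflections.append(
            ReflectionLog(
                track.track_id, k, float(track.t_min[k]),
                float(track.x_um[k]), float(track.y_um[k]),
            )
        )
        logged_until = k


def simulate_walks(
    spec: WalkSpec, n_tracks: int
) -> tuple[list[CellTrack], WalkTruth]:
    """Simulate persistent random walks in the organoid, with event logs.

    Start positions are uniform over the brain ellipse (area-uniform).
    When ``division_rate`` > 0 each track carries a per-step division hazard
    of ``division_rate / n_steps``; on division the parent ends, stays put
    through the mitotic pause, and two daughters depart antiparallel.
    Daughter tracks run at least 5 steps so their departure direction is
    measurable.
    """
    rng = np.random.default_rng(spec.seed)
    e = spec.brain()
    n_steps = int(round(spec.duration_min / spec.step_min))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")
    hazard = spec.division_rate / n_steps if spec.division_rate > 0 else 0.0

    truth = WalkTruth(0.0, 0, seed=spec.seed)
    step_speeds: list[float] = []
    tracks: list[CellTrack] = []
    for i in range(n_tracks):
        # area-uniform start inside the ellipse, away from the very edge
        u = rng.uniform(0.0, 2.0 * np.pi)
        r = 0.9 * np.sqrt(rng.uniform())
        start = np.asarray(e.center) + r * np.array(
            [e.semi_major * np.cos(u), e.semi_minor * np.sin(u)]
        )
        heading = rng.uniform(0.0, 2.0 * np.pi)
        tid = f"t{i:04d}"
        track, contacts, division = _walk(
            rng, spec, start, heading, 0.0, n_steps, tid, None,
            step_speeds, hazard,
        )
        tracks.append(track)
        _log_reflections(track, e, contacts, truth)
        if division is not None:
            t_div, pos = division
            t_start = t_div + spec.mitotic_pause_min
            phi = rng.uniform(0.0, 2.0 * np.pi)
            remaining = max(n_steps - int(round(t_div / spec.step_min)), 5)
            dids = []
            for suffix, h in (("a", phi), ("b", phi + np.pi)):
                did = f"{tid}{suffix}"
                dids.append(did)
                dtrack, dcontacts, _ = _walk(
                    rng, spec, pos.copy(), h, t_start, remaining, did, tid,
                    step_speeds, 0.0,
                )
                # force the first step exactly along the assigned heading so
                # the antiparallel departure rule holds even at low persistence
                dx = dtrack.x_um.copy()
                dy = dtrack.y_um.copy()
                L0 = np.hypot(dx[1] - dx[0], dy[1] - dy[0])
                dx[1] = dx[0] + L0 * np.cos(h)
                dy[1] = dy[0] + L0 * np.sin(h)
                dtrack = CellTrack(did, dtrack.t_min, dx, dy, tid)
                tracks.append(dtrack)
                _log_reflections(dtrack, e, dcontacts, truth)
            truth.divisions.append(
                DivisionLog(tid, (dids[0], dids[1]), t_div, pos[0], pos[1])
            )
    truth.mean_step_speed_um_per_h = float(np.mean(step_speeds)) if step_speeds else 0.0
    truth.n_steps = len(step_speeds)
    return tracks, truth
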