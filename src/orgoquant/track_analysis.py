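"""Single-cell migration analysis from time-lapse trajectory tables.

Speed follows the video-recording convention of the confrontation assay:
each track is cut into consecutive non-overlapping 40-minute windows from
its first sample, the path length (sum of Euclidean step distances, not net
displacement) inside each window is converted to µm/h, and each window
contributes one data point. Straightness (net displacement over path length)
is reported alongside. Trajectories are analyzed in 2D; a z column, if
present, is ignored with a warning — the speeds derive from projected
movies. No smoothing is applied.

Boundary reversals — an invading cell reaching the organoid margin and
turning back toward the tumor — are detected as an outward-to-inward sign
change of the radial motion component within a configurable margin of the
brain-ellipse boundary. Division events are screened for the "go and grow"
signature: two daughters leaving the division site in opposite directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compartment_geometry import Ellipse

__all__ = [
    "CellTrack",
    "SpeedMeasurement",
    "ReversalEvent",
    "DivisionReport",
    "TrackSchemaError",
    "read_tracks",
    "write_tracks",
    "window_speeds",
    "detect_reversals",
    "division_check",
    "speeds_frame",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("track_id", "t_min", "x_um", "y_um")


class TrackSchemaError(ValueError):
    """The trajectory table violates the required schema."""


@dataclass
class CellTrack:
    """One cell trajectory: strictly increasing times, planar positions."""

    track_id: str
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    parent_id: str | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_min) == len(self.x_um) == len(self.y_um)):
            raise ValueError("t/x/y length mismatch")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError(f"track {self.track_id!r}: times not strictly increasing")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValueError(f"track {self.track_id!r}: non-finite coordinates")

    @property
    def n_samples(self) -> int:
        return len(self.t_min)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    @property
    def step_lengths_um(self) -> np.ndarray:
        return np.hypot(np.diff(self.x_um), np.diff(self.y_um))


@dataclass
class SpeedMeasurement:
    """One windowed speed data point."""

    track_id: str
    window_start_min: float
    window_duration_min: float
    path_length_um: float
    net_displacement_um: float
    speed_um_per_h: float
    straightness: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.path_length_um < 0 or self.speed_um_per_h < 0:
            raise ValueError("negative path length or speed")


@dataclass
class ReversalEvent:
    """Outward-to-inward turning at the organoid margin."""

    track_id: str
    t_min: float
    sample_index: int
    x_um: float
    y_um: float
    boundary_distance_um: float

    def __post_init__(self) -> None:
        if self.boundary_distance_um < 0:
            raise ValueError("boundary_distance_um must be >= 0")


@dataclass
class DivisionReport:
    """Angle between daughter departure directions for one division."""

    parent_id: str
    daughter_ids: tuple[str, ...]
    angle_deg: float | None
    opposite: bool | None
    flagged: str = ""


def read_tracks(path: str | Path) -> list[CellTrack]:
    """Load a delimited trajectory table into per-track objects.

    Requires a header with columns ``track_id, t_min, x_um, y_um``
    (``parent_id`` optional). Rows are grouped per track and time-sorted;
    duplicate (track, time) rows are an error. A ``z_um`` column is ignored
    with a warning — analysis is planar.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise TrackSchemaError(f"{path.name}: empty file, no header") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackSchemaError(f"{path.name}: missing column(s) {missing}")
    if "z_um" in df.columns:
        logger.warning("%s: z_um column present; ignored (2D analysis)", path.name)
    return tracks_from_frame(df)


def tracks_from_frame(df: pd.DataFrame) -> list[CellTrack]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackSchemaError(f"missing column(s) {missing}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        if grp["t_min"].duplicated().any():
            dup = grp.loc[grp["t_min"].duplicated(), "t_min"].iloc[0]
            raise TrackSchemaError(f"track {tid!r}: duplicate timestamp t={dup}")
        parent = None
        if "parent_id" in grp.columns:
            p = grp["parent_id"].iloc[0]
            parent = None if pd.isna(p) or p == "" else str(p)
        tracks.append(
            CellTrack(
                str(tid),
                grp["t_min"].to_numpy(float),
                grp["x_um"].to_numpy(float),
                grp["y_um"].to_numpy(float),
                parent,
            )
        )
    return tracks


def write_tracks(path: str | Path, tracks: list[CellTrack]) -> None:
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t_min, tr.x_um, tr.y_um):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "t_min": t,
                    "x_um": x,
                    "y_um": y,
                    "parent_id": tr.parent_id or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def window_speeds(track: CellTrack, window_min: float = 40.0) -> list[SpeedMeasurement]:
    """Per-window path length and speed of one track.

    Windows of ``window_min`` minutes tile the track from its first sample;
    the step from t_a to t_b is assigned to the window containing t_a, so a
    sample landing exactly on a window boundary closes one window and opens
    the next. Windows with fewer than 2 samples (no steps) are skipped and
    logged, as is an incomplete trailing window. A track shorter than one
    window yields an empty list.
    """
    if window_min <= 0:
        raise ValueError("window_min must be > 0")
    if track.n_samples < 2:
        logger.info("track %s: fewer than 2 samples, no windows", track.track_id)
        return []
    t0 = track.t_min[0]
    span = track.t_min[-1] - t0
    n_windows = int(np.floor(span / window_min + 1e-9))
    if n_windows == 0:
        logger.info(
            "track %s: span %.1f min shorter than one %g-min window",
            track.track_id, span, window_min,
        )
        return []
    steps = track.step_lengths_um
    widx = np.floor((track.t_min[:-1] - t0) / window_min + 1e-9).astype(int)
    out = []
    for w in range(n_windows):
        in_w = widx == w
        if not in_w.any():
            logger.info("track %s: window %d has <2 samples, skipped",
                        track.track_id, w)
            continue
        path = float(steps[in_w].sum())
        k = np.flatnonzero(in_w)
        first, last = k[0], k[-1] + 1
        net = float(np.hypot(track.x_um[last] - track.x_um[first],
                             track.y_um[last] - track.y_um[first]))
        out.append(
            SpeedMeasurement(
                track_id=track.track_id,
                window_start_min=float(t0 + w * window_min),
                window_duration_min=float(window_min),
                path_length_um=path,
                net_displacement_um=net,
                speed_um_per_h=path * 60.0 / window_min,
                straightness=net / path if path > 0 else 0.0,
                n_samples=int(in_w.sum()) + 1,
            )
        )
    return out


def speeds_frame(measurements: list[SpeedMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": m.track_id,
                "window_start_min": m.window_start_min,
                "window_duration_min": m.window_duration_min,
                "path_length_um": m.path_length_um,
                "net_displacement_um": m.net_displacement_um,
                "speed_um_per_h": m.speed_um_per_h,
                "straightness": m.straightness,
                "n_samples": m.n_samples,
            }
            for m in measurements
        ]
    )


def detect_reversals(
    track: CellTrack, brain: Ellipse, margin_um: float = 15.0
) -> list[ReversalEvent]:
    """Boundary-reversal events of one track at the organoid margin.

    An event fires at sample j when (a) the position is within ``margin_um``
    of the brain-ellipse boundary, (b) the cell arrived moving outward
    (normalized ellipse radius increased over the previous step), and (c)
    the radial motion turns inward within the next 2 samples. Consecutive
    samples of one approach are collapsed into a single event at the first
    qualifying sample.
    """
    if track.n_samples < 3:
        return []
    pos = track.positions
    rho = brain.normalized_radius(pos)
    dist = brain.boundary_distance(pos)
    drho = np.diff(rho)
    events = []
    for j in range(1, track.n_samples - 1):
        if dist[j] > margin_um:
            continue
        if drho[j - 1] <= 0:  # did not arrive moving outward
            continue
        # inward turn within the next 2 samples, anchored at the radial peak
        if drho[j] < 0 or (drho[j] == 0 and j + 1 < len(drho) and drho[j + 1] < 0):
            events.append(
                ReversalEvent(
                    track_id=track.track_id,
                    t_min=float(track.t_min[j]),
                    sample_index=j,
                    x_um=float(pos[j, 0]),
                    y_um=float(pos[j, 1]),
                    boundary_distance_um=float(dist[j]),
                )
            )
    return events


def division_check(tracks: list[CellTrack]) -> list[DivisionReport]:
    """Screen divisions for opposite-direction daughter departure.

    For every parent with exactly two daughters (lineage via ``parent_id``),
    reports the angle between the daughters' initial displacement vectors
    (first two samples of each) and whether it exceeds 90°. Parents with a
    different daughter count are flagged; a daughter naming an unknown
    parent raises.
    """
    by_id = {t.track_id: t for t in tracks}
    children: dict[str, list[CellTrack]] = {}
    for t in tracks:
        if t.parent_id is not None:
            if t.parent_id not in by_id:
                raise ValueError(
                    f"track {t.track_id!r} references unknown parent {t.parent_id!r}"
                )
            children.setdefault(t.parent_id, []).append(t)

    reports = []
    for pid in sorted(children):
        kids = sorted(children[pid], key=lambda t: t.track_id)
        if len(kids) != 2:
            reports.append(
                DivisionReport(pid, tuple(k.track_id for k in kids), None, None,
                               flagged=f"{len(kids)} daughters"))
            continue
        vecs = []
        short = False
        for k in kids:
            if k.n_samples < 2:
                short = True
                break
            vecs.append(np.array([k.x_um[1] - k.x_um[0], k.y_um[1] - k.y_um[0]]))
        if short or any(np.linalg.norm(v) == 0 for v in vecs):
            reports.append(
                DivisionReport(pid, tuple(k.track_id for k in kids), None, None,
                               flagged="daughter too short or stationary"))
            continue
        u, v = vecs
        cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        reports.append(
            DivisionReport(pid, tuple(k.track_id for k in kids), ang, ang > 90.0)
        )
    return reports
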