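"""Invasion metrics for the confrontation assay.

Three quantities summarize tumor invasion into the brain organoid at one
time point, all normalized to the brain-ellipse pixel area R (the "rBO
area"):

* competition ratio — fraction of R covered by the contiguous tumor core
  (tumor mass replacing brain tissue),
* single-cell ratio — fraction of R covered by GFP components detached from
  the core,
* total invasion — their sum, by construction exact.

The denominator is always the brain ellipse; overlap pixels claimed by the
core are precisely what "replacement" means, so they are not excluded. The
single-cell metric is area-based; the detached-component count is reported
alongside for the count interpretation. Ratios are never clipped — a value
outside its admissible range signals an upstream geometry or segmentation
failure and raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartment_geometry import EllipsePair, ellipse_region
from .segmentation import TumorSegmentation

__all__ = [
    "InvasionMetrics",
    "TreatmentSummary",
    "compute_metrics",
    "timecourse",
    "summarize",
    "percent_inhibition",
    "metrics_frame",
]


@dataclass
class InvasionMetrics:
    """Per-image invasion readout."""

    competition_ratio: float
    single_cell_ratio: float
    total_invasion: float
    brain_area_um2: float
    core_in_brain_area_um2: float
    single_cell_area_um2: float
    n_single_cells: int
    timepoint_h: float = 0.0
    sample_id: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.competition_ratio <= 1.0:
            raise ValueError(
                f"competition_ratio {self.competition_ratio} outside [0, 1]; "
                "upstream segmentation/geometry failure"
            )
        if self.single_cell_ratio < 0:
            raise ValueError("single_cell_ratio must be >= 0")
        if self.total_invasion != self.competition_ratio + self.single_cell_ratio:
            raise ValueError("total_invasion must equal the exact sum of the ratios")
        for name in ("brain_area_um2", "core_in_brain_area_um2", "single_cell_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_single_cells < 0:
            raise ValueError("n_single_cells must be >= 0")


@dataclass
class TreatmentSummary:
    """Mean ± SEM of each metric over replicates of one (arm, timepoint)."""

    arm: str
    timepoint_h: float
    n_replicates: int
    mean: dict
    sem: dict

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(v < 0 for v in self.sem.values()):
            raise ValueError("SEM must be >= 0")


_METRIC_COLS = ("competition_ratio", "single_cell_ratio", "total_invasion")


def compute_metrics(
    seg: TumorSegmentation,
    pair: EllipsePair,
    pixel_size_um: float,
    timepoint_h: float = 0.0,
    sample_id: str = "",
    arm: str = "",
) -> InvasionMetrics:
    """Pixel-count invasion metrics for one image.

    With R the rasterized brain-ellipse pixel set:
    ``competition = |core ∩ R| / |R|``, ``single = |singles ∩ R| / |R|``,
    ``total = competition + single`` (exact). ``n_single_cells`` counts
    detached components with at least one pixel in R. Areas are pixel counts
    scaled by ``pixel_size_um**2``.
    """
    frame_shape = seg.gfp_mask.shape
    R = ellipse_region(pair.brain, frame_shape)
    n_R = int(R.sum())
    if n_R == 0:
        raise ValueError("degenerate brain ellipse: empty pixel region")

    core_in_R = int((seg.core_mask & R).sum())
    labels_in_R = np.unique(seg.component_labels[R])
    singles_in_R = [l for l in seg.single_cell_labels if l in labels_in_R]
    single_px = int(
        (np.isin(seg.component_labels, seg.single_cell_labels) & R).sum()
    )

    px2 = pixel_size_um**2
    comp = core_in_R / n_R
    single = single_px / n_R
    return InvasionMetrics(
        competition_ratio=comp,
        single_cell_ratio=single,
        total_invasion=comp + single,
        brain_area_um2=n_R * px2,
        core_in_brain_area_um2=core_in_R * px2,
        single_cell_area_um2=single_px * px2,
        n_single_cells=len(singles_in_R),
        timepoint_h=timepoint_h,
        sample_id=sample_id,
        arm=arm,
    )


def metrics_frame(records: list[InvasionMetrics]) -> pd.DataFrame:
    """Tabulate metric records, one row per image."""
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "arm": m.arm,
                "timepoint_h": m.timepoint_h,
                "competition_ratio": m.competition_ratio,
                "single_cell_ratio": m.single_cell_ratio,
                "total_invasion": m.total_invasion,
                "brain_area_um2": m.brain_area_um2,
                "core_in_brain_area_um2": m.core_in_brain_area_um2,
                "single_cell_area_um2": m.single_cell_area_um2,
                "n_single_cells": m.n_single_cells,
            }
            for m in records
        ]
    )


@dataclass
class SampleSeries:
    """Time-ordered metrics of one sample, with monotonicity diagnostics."""

    sample_id: str
    records: list[InvasionMetrics]
    nonmonotone_total: list[float] = field(default_factory=list)
    missing_timepoints: list[float] = field(default_factory=list)


def timecourse(
    records: list[InvasionMetrics],
    expected_timepoints: list[float] | None = None,
) -> list[SampleSeries]:
    """Group records per sample and order them in time.

    Duplicate (sample, timepoint) pairs are an error. Decreases of total
    invasion between consecutive time points are allowed but flagged, as are
    time points from ``expected_timepoints`` absent in a series.
    """
    by_sample: dict[str, list[InvasionMetrics]] = {}
    for m in records:
        by_sample.setdefault(m.sample_id, []).append(m)
    out = []
    for sid, recs in by_sample.items():
        times = [m.timepoint_h for m in recs]
        if len(set(times)) != len(times):
            dup = sorted({t for t in times if times.count(t) > 1})
            raise ValueError(f"sample {sid!r}: duplicate timepoint(s) {dup}")
        recs = sorted(recs, key=lambda m: m.timepoint_h)
        flags = [
            recs[k + 1].timepoint_h
            for k in range(len(recs) - 1)
            if recs[k + 1].total_invasion < recs[k].total_invasion
        ]
        missing = []
        if expected_timepoints is not None:
            have = {m.timepoint_h for m in recs}
            missing = [t for t in expected_timepoints if t not in have]
        out.append(SampleSeries(sid, recs, flags, missing))
    return sorted(out, key=lambda s: s.sample_id)


def summarize(records: list[InvasionMetrics]) -> list[TreatmentSummary]:
    """Mean ± SEM per (arm, timepoint); SEM uses the n-1 SD denominator."""
    df = metrics_frame(records)
    out = []
    for (arm, t), grp in df.groupby(["arm", "timepoint_h"], sort=True):
        n = len(grp)
        mean = {c: float(grp[c].mean()) for c in _METRIC_COLS}
        sem = {
            c: float(grp[c].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            for c in _METRIC_COLS
        }
        out.append(TreatmentSummary(str(arm), float(t), n, mean, sem))
    return out


def percent_inhibition(treated: float, control: float) -> float:
    """Percent reduction of a treated-arm mean relative to control.

    ``100 * (1 - treated / control)``; e.g. control 0.100 vs treated 0.037
    reads as 63% inhibition. Undefined for non-positive control means.
    """
    if control <= 0:
        raise ValueError(f"control mean must be > 0, got {control}")
    return 100.0 * (1.0 - treated / control)
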