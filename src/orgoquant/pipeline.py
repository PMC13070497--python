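"""End-to-end quantification of one confrontation image.

Chains the stages: channel projection → seeded region growing → contour
extraction → two-ellipse decomposition → tumor segmentation → invasion
metrics. The semi-automated entry point is ``manual_pair``: when the user
supplies ellipses (e.g. drawn in a viewer and exported as JSON), fitting is
skipped and the supplied pair is used verbatim, which is recorded on the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compartment_geometry import ClusterContour, EllipsePair, decompose_ellipses
from .imaging_io import ImageStack, PlanarImage, max_intensity_projection
from .invasion_metrics import InvasionMetrics, compute_metrics
from .segmentation import ClusterMask, TumorSegmentation, classify_components, region_grow, tumor_mask

__all__ = ["ImageHints", "QuantifyResult", "quantify_image"]


@dataclass
class ImageHints:
    """Per-image operator input: seed and compartment hints, (x, y) µ-free px."""

    seed_rc: tuple[int, int]
    brain_xy: tuple[float, float]
    tumor_xy: tuple[float, float]
    manual_pair: EllipsePair | None = None
    contour_override: ClusterContour | None = None


@dataclass
class QuantifyResult:
    metrics: InvasionMetrics
    cluster: ClusterMask
    contour: ClusterContour
    pair: EllipsePair
    segmentation: TumorSegmentation
    gfp: PlanarImage
    reference: PlanarImage
    used_manual_pair: bool = False


def quantify_image(
    stack: ImageStack,
    hints: ImageHints,
    gfp_channel: str = "GFP",
    reference_channel: str = "BF",
    tolerance: float = 35.0,
    threshold_method: str = "otsu",
    min_object_um2: float = 20.0,
    timepoint_h: float = 0.0,
    sample_id: str = "",
    arm: str = "",
) -> QuantifyResult:
    """Run the full invasion quantification on one image stack."""
    ref = max_intensity_projection(stack, reference_channel)
    gfp = max_intensity_projection(stack, gfp_channel)

    cluster = region_grow(ref, hints.seed_rc, tolerance)
    if hints.contour_override is not None:
        contour = hints.contour_override
    else:
        from .segmentation import extract_contour

        contour = extract_contour(cluster)
    if contour.degenerate:
        raise ValueError("degenerate cluster contour; check seed and tolerance")

    gmask = tumor_mask(gfp, cluster, method=threshold_method)

    if hints.manual_pair is not None:
        pair = hints.manual_pair
        used_manual = True
    else:
        pair = decompose_ellipses(
            contour, hints.brain_xy, hints.tumor_xy, gfp_mask=gmask,
            frame_shape=gfp.shape,
        )
        used_manual = False

    anchor_rc = (int(round(hints.tumor_xy[1])), int(round(hints.tumor_xy[0])))
    seg = classify_components(gmask, anchor_rc, min_object_um2, gfp.pixel_size_um)
    metrics = compute_metrics(
        seg, pair, gfp.pixel_size_um, timepoint_h=timepoint_h,
        sample_id=sample_id, arm=arm,
    )
    return QuantifyResult(metrics, cluster, contour, pair, seg, gfp, ref, used_manual)
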