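"""Reading, writing and projecting multi-channel microscopy stacks.

Internal axis order is fixed as ``(channel, z, row, col)``; readers permute
whatever the file supplies into that order. Coordinates are 0-based and refer
to pixel centers; when a point is exported as ``(x, y)`` it means
``(col, row)``. All in-plane metrics assume square pixels, so anisotropic
calibration is rejected outright rather than averaged away.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "PlanarImage",
    "MissingCalibrationError",
    "AnisotropicPixelError",
    "load_image",
    "write_stack",
    "max_intensity_projection",
]


class MissingCalibrationError(ValueError):
    """The file carries no physical pixel size and no override was given."""


class AnisotropicPixelError(ValueError):
    """X and Y pixel sizes differ; area accounting assumes square pixels."""


@dataclass
class ImageStack:
    """A multi-channel, possibly z-resolved acquisition.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(channel, z, row, col)``.
    channel_labels
        One label per channel, e.g. ``["GFP", "BF"]``.
    pixel_size_um
        In-plane pixel edge length in micrometres (isotropic).
    z_step_um
        Optional spacing between optical sections.
    """

    intensities: np.ndarray
    channel_labels: list[str]
    pixel_size_um: float
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"expected (channel, z, row, col), got ndim={self.intensities.ndim}"
            )
        if self.intensities.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.intensities.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if self.intensities.shape[0] < 1 or self.intensities.shape[1] < 1:
            raise ValueError("stack needs at least one channel and one z-plane")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if np.issubdtype(self.intensities.dtype, np.floating):
            if not np.all(np.isfinite(self.intensities)):
                raise ValueError("non-finite intensities")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[2], self.intensities.shape[3]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None


@dataclass
class PlanarImage:
    """A single 2D channel with physical calibration."""

    intensities: np.ndarray
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ValueError("PlanarImage is strictly 2D")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if np.issubdtype(self.intensities.dtype, np.floating):
            if not np.all(np.isfinite(self.intensities)):
                raise ValueError("non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


_UNIT_TO_UM = {"µm": 1.0, "um": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3}


def _pixel_size_from_ome(ome_xml: str) -> tuple[float | None, float | None]:
    """Return (xy size in µm or None, z step in µm or None) from OME-XML."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None, None

    def _get(axis: str) -> float | None:
        val = pixels.get(f"PhysicalSize{axis}")
        if val is None:
            return None
        unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
        scale = _UNIT_TO_UM.get(unit)
        if scale is None:
            return None
        return float(val) * scale

    sx, sy, sz = _get("X"), _get("Y"), _get("Z")
    if sx is not None and sy is not None:
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise AnisotropicPixelError(f"PhysicalSizeX={sx} != PhysicalSizeY={sy} µm")
    return sx if sx is not None else sy, sz


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    """Derive µm/px from classic TIFF resolution tags, if resolvable."""
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)  # enum -> int
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if unit_um is None:  # RESUNIT.NONE: tag present but meaningless
        return None

    def _ratio(tag_name: str) -> float | None:
        if tag_name not in tags:
            return None
        num, denom = tags[tag_name].value
        if num == 0:
            return None
        return unit_um * denom / num  # value is pixels per unit

    sx = _ratio("XResolution")
    sy = _ratio("YResolution")
    if sx is None:
        return None
    if sy is not None and abs(sx - sy) > 1e-6 * max(sx, sy):
        raise AnisotropicPixelError(f"x={sx:.6g} µm/px but y={sy:.6g} µm/px")
    return sx


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand a tifffile series into (C, Z, Y, X)."""
    axes = axes.replace("S", "C") if "C" not in axes else axes.replace("S", "")
    if axes.count("C") > 1:
        raise ValueError(f"cannot interpret axes {axes!r}")
    keep: list[str] = []
    for ax, size in zip(axes, data.shape):
        if ax in "CZYX":
            keep.append(ax)
        elif ax in ("T", "I", "Q"):
            if size != 1:
                raise ValueError(
                    f"unsupported non-singleton axis {ax!r} of size {size}"
                )
            data = data.reshape([s for a, s in zip(axes, data.shape) if a != ax])
        else:
            raise ValueError(f"unknown axis {ax!r}")
    axes = "".join(keep)
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"no planar axes in {axes!r}")
    for missing in ("C", "Z"):
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def load_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_labels: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into the canonical (channel, z, row, col) layout.

    Pixel size is taken from OME metadata or TIFF resolution tags when present,
    else from ``pixel_size_override``. A file with neither raises
    :class:`MissingCalibrationError` — 1 µm is never silently assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        pixel_size = None
        z_step = None
        if tif.ome_metadata:
            pixel_size, z_step = _pixel_size_from_ome(tif.ome_metadata)
        if pixel_size is None:
            pixel_size = _pixel_size_from_tags(tif.pages[0])
        labels = channel_labels
        if labels is None and tif.ome_metadata:
            labels = _channel_labels_from_ome(tif.ome_metadata)

    data = _normalize_axes(np.asarray(data), axes)
    if pixel_size is None:
        pixel_size = pixel_size_override
    if pixel_size is None:
        raise MissingCalibrationError(
            f"{path.name}: no pixel size in metadata and no override given"
        )
    if labels is None or len(labels) != data.shape[0]:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data, list(labels), float(pixel_size), z_step)


def _channel_labels_from_ome(ome_xml: str) -> list[str] | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    names = [ch.get("Name") for ch in root.findall(f".//{ns}Channel")]
    if names and all(n for n in names):
        return [str(n) for n in names]
    return None


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as 16-bit OME-TIFF with calibration.

    The OME UUID is derived from the pixel data and calibration, so writing
    the same stack twice produces bit-identical files.
    """
    data = stack.intensities
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    import hashlib

    digest = hashlib.sha256(
        data.tobytes() + repr((stack.channel_labels, stack.pixel_size_um)).encode()
    ).hexdigest()
    uuid = (
        f"urn:uuid:{digest[:8]}-{digest[8:12]}-{digest[12:16]}-"
        f"{digest[16:20]}-{digest[20:32]}"
    )
    metadata = {
        "axes": "CZYX",
        "UUID": uuid,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": stack.channel_labels},
    }
    if stack.z_step_um is not None:
        metadata["PhysicalSizeZ"] = stack.z_step_um
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def max_intensity_projection(stack: ImageStack, channel: str) -> PlanarImage:
    """Maximum-intensity projection of one channel over z.

    ``out[r, c] = max_z stack[channel, z, r, c]``; physical pixel size is
    propagated unchanged. Depth-1 stacks project to the identical plane.
    """
    idx = stack.channel_index(channel)
    mip = stack.intensities[idx].max(axis=0)
    return PlanarImage(mip, stack.pixel_size_um, channel_label=channel)
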