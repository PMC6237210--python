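"""Multi-channel time-lapse container and OME-TIFF round-trip.

The central in-memory object is :class:`ImageStack`, a T×C×Y×X float array of
nonnegative intensities with named channels and physical metadata (pixel size
in µm, frame interval in minutes). Stacks are written as OME-TIFF via
``tifffile`` so that channel names and axis order survive a round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A T×C×Y×X intensity stack with channel names and acquisition metadata.

    Parameters
    ----------
    data:
        Array of shape ``(T, C, Y, X)`` with nonnegative intensities.
    channels:
        Ordered channel names, one per C plane (e.g. ``["reporter",
        "ph_probe", "bone"]``).
    pixel_size:
        Lateral pixel size in µm/pixel.
    frame_interval:
        Time between frames in minutes.
    """

    data: np.ndarray
    channels: list[str]
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4-D (T, C, Y, X), got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} channel planes but "
                f"{len(self.channels)} channel names {self.channels}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the T×Y×X planes of one named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channels}"
            ) from None
        return self.data[:, idx]


def save_ome_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with TCYX axes and channel names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata = {
        "axes": "TCYX",
        "Channel": {"Name": list(stack.channels)},
        "PhysicalSizeX": stack.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": stack.frame_interval,
        "TimeIncrementUnit": "min",
    }
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        ome=True,
        metadata=metadata,
    )


def load_ome_tiff(path: str | Path) -> ImageStack:
    """Read an OME-TIFF written by :func:`save_ome_tiff` back into a stack."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tif.ome_metadata
    # squeeze/expand to TCYX
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 3:  # single channel or single frame collapsed
        if "C" not in axes:
            data = data[:, None]
        elif "T" not in axes:
            data = data[None]
    if data.ndim != 4:
        raise ValueError(f"cannot coerce axes {axes!r} shape {data.shape} to TCYX")

    channels = [f"ch{i}" for i in range(data.shape[1])]
    pixel_size = 1.0
    frame_interval = 1.0
    if ome:
        names = _parse_ome_channel_names(ome)
        if len(names) == data.shape[1]:
            channels = names
        pixel_size, frame_interval = _parse_ome_physical(ome, pixel_size, frame_interval)
    return ImageStack(data, channels, pixel_size, frame_interval)


def _parse_ome_channel_names(ome_xml: str) -> list[str]:
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome_xml)
    names = []
    for elem in root.iter():
        if elem.tag.endswith("Channel"):
            names.append(elem.get("Name") or f"ch{len(names)}")
    return names


def _parse_ome_physical(ome_xml: str, pixel_size: float, frame_interval: float):
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome_xml)
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            ps = elem.get("PhysicalSizeX")
            ti = elem.get("TimeIncrement")
            if ps is not None:
                pixel_size = float(ps)
            if ti is not None:
                frame_interval = float(ti)
    return pixel_size, frame_interval


def save_masks(masks: np.ndarray, path: str | Path, sidecar: dict | None = None) -> None:
    """Save per-frame per-cell boolean masks (N_cells×T×Y×X) as a compressed
    archive, with an optional JSON sidecar describing their provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, masks=np.asarray(masks, dtype=bool))
    if sidecar is not None:
        sidecar_path = path.with_suffix(".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_masks(path: str | Path) -> np.ndarray:
    with np.load(Path(path)) as npz:
        return npz["masks"]
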