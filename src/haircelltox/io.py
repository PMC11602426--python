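"""OME-TIFF stack I/O and the in-memory voxel container.

Stacks are stored internally with a fixed ``(t, c, z, y, x)`` axis order.
Channel names, voxel size and (for time-lapse data) the frame interval are
carried in the OME-XML metadata and must round-trip through write/read.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelStack", "StackIOError", "read_stack", "write_stack"]

AXES = "TCZYX"


class StackIOError(ValueError):
    """Raised when a stack file is missing required metadata."""


@dataclass
class VoxelStack:
    """n-D fluorescence image with named channels.

    Parameters
    ----------
    data:
        Intensity array.  Accepted shapes are ``(z, y, x)`` (one channel,
        one frame), ``(c, z, y, x)`` (one frame) and ``(t, c, z, y, x)``;
        the array is normalized to 5-D on construction.
    channel_names:
        One label per channel, e.g. ``("reporter", "ag")``.
    voxel_size_um:
        Physical voxel size ``(z, y, x)`` in micrometres.
    time_interval_s:
        Frame interval in seconds for time-lapse stacks, else ``None``.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_interval_s: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:
            arr = arr[None, None]
        elif arr.ndim == 4:
            arr = arr[None]
        if arr.ndim != 5:
            raise ValueError(f"expected 3-5 dimensional data, got shape {arr.shape}")
        self.data = arr
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive lengths (z, y, x)")

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as ``(z, y, x)`` (single frame) or ``(t, z, y, x)``."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        out = self.data[:, i]
        return out[0] if self.n_frames == 1 else out

    def with_data(self, data: np.ndarray) -> "VoxelStack":
        return VoxelStack(data, self.channel_names, self.voxel_size_um, self.time_interval_s)


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a :class:`VoxelStack` as OME-TIFF with axes/channel/voxel metadata."""
    path = Path(path)
    vz, vy, vx = stack.voxel_size_um
    metadata = {
        "axes": AXES,
        "Channel": {"Name": list(stack.channel_names)},
        "PhysicalSizeZ": vz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": vy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": vx,
        "PhysicalSizeXUnit": "µm",
    }
    if stack.time_interval_s is not None:
        metadata["TimeIncrement"] = float(stack.time_interval_s)
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, stack.data, ome=True, metadata=metadata)
    return path


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_stack(path: str | Path) -> VoxelStack:
    """Read an OME-TIFF written by :func:`write_stack` (or compatible).

    Raises
    ------
    StackIOError
        If axes, channel names or voxel size are absent from the metadata;
        nothing is silently defaulted.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        ome_xml = tf.ome_metadata
    if ome_xml is None:
        raise StackIOError(f"{path}: no OME metadata found")

    root = ET.fromstring(ome_xml)
    pixels = None
    for el in root.iter():
        if _strip_ns(el.tag) == "Pixels":
            pixels = el
            break
    if pixels is None:
        raise StackIOError(f"{path}: OME metadata lacks a Pixels element")

    channel_names: list[str] = []
    for el in pixels:
        if _strip_ns(el.tag) == "Channel":
            name = el.get("Name")
            if name is None:
                raise StackIOError(f"{path}: a Channel element has no Name attribute")
            channel_names.append(name)
    if not channel_names:
        raise StackIOError(f"{path}: OME metadata lists no channel names")

    sizes = []
    for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
        val = pixels.get(key)
        if val is None:
            raise StackIOError(f"{path}: OME metadata lacks {key}")
        sizes.append(float(val))

    time_increment = pixels.get("TimeIncrement")
    time_interval_s = float(time_increment) if time_increment is not None else None

    # normalize to (t, c, z, y, x); tifffile may squeeze singleton axes
    for ax in AXES:
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    data = np.transpose(data, order)

    return VoxelStack(data, tuple(channel_names), tuple(sizes), time_interval_s)
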