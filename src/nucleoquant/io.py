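"""Image-stack plumbing shared by every pipeline.

All rasters are canonicalized to a five-dimensional ``(t, z, c, y, x)`` array,
inserting singleton axes where an acquisition lacks time or depth.  This keeps
a single code path for 2D fields, 3D confocal stacks and time-lapses.
Intensities are processed as floating point; the dtype of the source file is
recorded so that write/read round trips are lossless.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ContractError, FormatError

CANONICAL_AXES = "TZCYX"


@dataclass
class ImageStack:
    """Multi-channel raster with named channels and optional pixel size.

    Parameters
    ----------
    data:
        Array of shape ``(t, z, c, y, x)``; singleton ``t``/``z`` axes are kept
        even when the corresponding dimension is absent (see ``has_t``/``has_z``).
    channel_names:
        One name per channel, e.g. ``["hoechst", "gamma_h2ax"]``.
    pixel_size:
        Lateral pixel size in micrometres per pixel, if known.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float | None = None
    has_t: bool = False
    has_z: bool = False
    orig_dtype: np.dtype | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ContractError(
                f"ImageStack data must be 5D (t, z, c, y, x); got {self.data.ndim}D"
            )
        if len(self.channel_names) != self.data.shape[2]:
            raise ContractError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[2]} channels"
            )
        if self.orig_dtype is None:
            self.orig_dtype = self.data.dtype

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        axes: str,
        channel_names: list[str] | None = None,
        pixel_size: float | None = None,
    ) -> "ImageStack":
        """Build a stack from an array with an explicit axis string.

        ``axes`` uses single letters from ``TZCYX`` (e.g. ``"CYX"``, ``"ZCYX"``,
        ``"TCYX"``).  Missing axes become singletons.
        """
        arr = np.asarray(arr)
        axes = axes.upper()
        if arr.ndim != len(axes):
            raise ContractError(f"array is {arr.ndim}D but axes={axes!r}")
        if set(axes) - set(CANONICAL_AXES):
            raise FormatError(f"unsupported axes in {axes!r}")
        if len(set(axes)) != len(axes):
            raise FormatError(f"repeated axis in {axes!r}")
        if "Y" not in axes or "X" not in axes:
            raise FormatError("axes must include Y and X")
        # expand missing axes, then transpose to canonical order
        for ax in CANONICAL_AXES:
            if ax not in axes:
                arr = np.expand_dims(arr, 0)
                axes = ax + axes
        order = [axes.index(ax) for ax in CANONICAL_AXES]
        arr = np.transpose(arr, order)
        n_c = arr.shape[2]
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(n_c)]
        return cls(
            data=arr,
            channel_names=list(channel_names),
            pixel_size=pixel_size,
            has_t=arr.shape[0] > 1,
            has_z=arr.shape[1] > 1,
        )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ContractError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a ``(t, z, y, x)`` array (no copy)."""
        return self.data[:, :, self.channel_index(name)]

    def plane(self, name: str, t: int = 0) -> np.ndarray:
        """Return a single 2D ``(y, x)`` plane of a channel (first z)."""
        return self.data[t, 0, self.channel_index(name)]

    def volume(self, name: str, t: int = 0) -> np.ndarray:
        """Return a single 3D ``(z, y, x)`` volume of a channel."""
        return self.data[t, :, self.channel_index(name)]


@dataclass
class FlatField:
    """Multiplicative gain image, normalized so its mean is exactly 1.

    Dividing an image by the gain removes slowly varying illumination
    (vignetting) while preserving the mean intensity of the field.
    """

    gain: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ContractError("flat-field gain must be a 2D (y, x) image")
        if not np.all(self.gain > 0):
            raise ContractError("flat-field gain must be strictly positive")
        self.gain = self.gain / self.gain.mean()


def read_stack(
    path,
    channel_map: dict[str, int] | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into a canonical :class:`ImageStack`.

    Channel names are taken from OME metadata when present; otherwise from
    ``channel_map`` (name -> channel index); otherwise ``ch0..chN``.  The axis
    order is inferred from file metadata and can be overridden with ``axes``.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            file_axes = series.axes
            ome = tf.ome_metadata
    except (OSError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc

    use_axes = (axes or file_axes).upper().replace("S", "C").replace("I", "T")
    use_axes = use_axes.replace("Q", "T")
    if len(use_axes) != arr.ndim:
        raise FormatError(
            f"axis string {use_axes!r} does not match {arr.ndim}D data in {path}"
        )

    names = _ome_channel_names(ome)
    stack = ImageStack.from_array(arr, use_axes, channel_names=names)
    stack.orig_dtype = arr.dtype

    if channel_map is not None:
        n_c = stack.data.shape[2]
        missing = [n for n, i in channel_map.items() if not 0 <= i < n_c]
        if missing:
            raise FormatError(
                f"channels {missing} map outside the {n_c} channels of {path}"
            )
        names = [f"ch{i}" for i in range(n_c)]
        for name, idx in channel_map.items():
            names[idx] = name
        stack.channel_names = names
    return stack


def _ome_channel_names(ome_xml: str | None) -> list[str] | None:
    if not ome_xml:
        return None
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    names = [
        ch.get("Name")
        for ch in root.iter()
        if ch.tag.endswith("Channel") and ch.get("Name")
    ]
    return names or None


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with channel names in metadata."""
    meta: dict = {
        "axes": CANONICAL_AXES,
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.pixel_size is not None:
        meta["PhysicalSizeX"] = stack.pixel_size
        meta["PhysicalSizeY"] = stack.pixel_size
    tifffile.imwrite(str(path), stack.data, ome=True, metadata=meta)


def max_project(stack: ImageStack) -> ImageStack:
    """Collapse the z axis by a per-pixel maximum.

    Idempotent: projecting an already projected (single-z) stack returns the
    identical image.
    """
    if not stack.has_z and stack.data.shape[1] == 0:
        raise ContractError("stack has no z axis to project")
    if stack.data.shape[1] < 1:
        raise ContractError("stack has no z planes")
    proj = stack.data.max(axis=1, keepdims=True)
    return ImageStack(
        data=proj,
        channel_names=list(stack.channel_names),
        pixel_size=stack.pixel_size,
        has_t=stack.has_t,
        has_z=False,
        orig_dtype=stack.orig_dtype,
    )


def flatfield_correct(stack: ImageStack, ff: FlatField) -> ImageStack:
    """Divide every plane of every channel by the normalized gain image.

    Because the gain is normalized to mean 1 the correction is mean-preserving
    for a spatially uniform specimen.
    """
    if ff.gain.shape != stack.data.shape[-2:]:
        raise ContractError(
            f"gain shape {ff.gain.shape} does not match image {stack.data.shape[-2:]}"
        )
    if np.any(stack.data < 0):
        warnings.warn("input stack has negative intensities", stacklevel=2)
    out = stack.data.astype(float) / ff.gain
    return ImageStack(
        data=out,
        channel_names=list(stack.channel_names),
        pixel_size=stack.pixel_size,
        has_t=stack.has_t,
        has_z=stack.has_z,
        orig_dtype=stack.orig_dtype,
    )
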