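"""Calibrated multi-channel z-stack I/O and extended-focus projection.

A z-stack is a short series of images of one field acquired at successive
focal depths (typically 7 planes, 0.4 µm apart) in up to three fluorescence
channels: DAPI (nuclear counterstain), FITC (green probe) and TRITC (red
probe).  Scanners store one multi-page grayscale TIFF per channel.  The
*extended-focus image* collapses a channel's stack into a single 2-D
composite by keeping, at every pixel, the highest intensity attained in any
plane — the standard way to count objects in sections thicker than the depth
of field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

DEFAULT_CHANNELS = ("DAPI", "FITC", "TRITC")
DEFAULT_Z_STEP_UM = 0.4
DEFAULT_PIXEL_SIZE_UM = 0.25

# RGB colour plane conventionally carrying each fluorescence channel.
CHANNEL_COLOR_PLANE = {"DAPI": 2, "FITC": 1, "TRITC": 0}


class StackShapeError(ValueError):
    """Channels disagree on plane count or plane shape."""


class StackFormatError(ValueError):
    """A TIFF page is not interpretable as a grayscale plane."""


@dataclass
class ZStack:
    """Multi-channel, multi-plane image volume with physical calibration.

    Parameters
    ----------
    channel_names
        Ordered channel names; defaults to ``("DAPI", "FITC", "TRITC")``.
    data
        Non-negative intensity volume indexed ``(channel, plane, row, col)``.
    z_step_um
        Axial distance between consecutive planes, in µm (> 0).
    pixel_size_um
        Lateral pixel pitch, in µm (> 0).
    focal_plane_index
        Index of the best-focus ("zero") plane.  Scanners focus first and
        then step symmetrically up and down, so this defaults to the centre
        plane of the stack.
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    z_step_um: float = DEFAULT_Z_STEP_UM
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    focal_plane_index: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise StackShapeError(
                f"data must be (channel, plane, row, col); got ndim={self.data.ndim}"
            )
        if self.data.shape[0] != len(self.channel_names):
            raise StackShapeError(
                f"{self.data.shape[0]} data channels vs {len(self.channel_names)} names"
            )
        if self.n_planes < 1:
            raise StackShapeError("stack must contain at least one plane")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("z_step_um and pixel_size_um must be > 0")
        if self.focal_plane_index is None:
            self.focal_plane_index = self.n_planes // 2
        if not 0 <= self.focal_plane_index < self.n_planes:
            raise ValueError(
                f"focal_plane_index {self.focal_plane_index} outside [0, {self.n_planes})"
            )
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(plane, row, col)`` volume of one channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None
        return self.data[idx]

    def plane_order(self) -> list[int]:
        """Plane indices sorted focal-plane-first, then outward.

        Ordering is by increasing distance from the focal plane; ties
        (symmetric ±k pairs) resolve to the lower index first.
        """
        f = self.focal_plane_index
        return sorted(range(self.n_planes), key=lambda p: (abs(p - f), p))


@dataclass
class ExtendedFocusImage:
    """2-D composite of one channel built from per-pixel plane maxima."""

    channel_name: str
    data: np.ndarray
    provenance: np.ndarray | None = field(default=None, repr=False)  # source plane per pixel


def _coerce_gray(page: np.ndarray, channel_name: str) -> np.ndarray:
    """Reduce a TIFF page to a single grayscale plane.

    RGB pages are split and the colour plane conventionally carrying the
    channel is kept (blue for DAPI, green for FITC, red for TRITC).
    """
    if page.ndim == 2:
        return page
    if page.ndim == 3 and page.shape[-1] in (3, 4):  # interleaved RGB(A)
        return page[..., CHANNEL_COLOR_PLANE.get(channel_name, 0)]
    if page.ndim == 3 and page.shape[0] in (3, 4):  # planar RGB(A)
        return page[CHANNEL_COLOR_PLANE.get(channel_name, 0)]
    raise StackFormatError(f"page shape {page.shape} is not grayscale or RGB")


def read_stack(
    paths: Mapping[str, str | Path] | Sequence[str | Path],
    *,
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
    z_step_um: float | None = None,
    pixel_size_um: float | None = None,
    focal_plane_index: int | None = None,
) -> ZStack:
    """Read one multi-page grayscale TIFF per channel into a :class:`ZStack`.

    ``paths`` is either a mapping ``{channel_name: path}`` or a sequence of
    paths in ``channel_names`` order.  Calibration (z-step, pixel size,
    focal plane) is taken from explicit arguments first, then from metadata
    embedded by :func:`write_stack`, then from package defaults (0.4 µm
    step, centre focal plane, 0.25 µm pixels).
    """
    if isinstance(paths, Mapping):
        ordered = [(name, Path(paths[name])) for name in paths]
        channel_names = tuple(name for name, _ in ordered)
        path_list = [p for _, p in ordered]
    else:
        path_list = [Path(p) for p in paths]
        channel_names = tuple(channel_names)[: len(path_list)]
        if len(path_list) != len(channel_names):
            raise ValueError("one path per channel required")

    volumes = []
    meta: dict = {}
    for name, path in zip(channel_names, path_list):
        with tifffile.TiffFile(path) as tif:
            pages = [_coerce_gray(page.asarray(), name) for page in tif.pages]
            desc = tif.pages[0].description
        if desc:
            try:
                meta.update(json.loads(desc))
            except (json.JSONDecodeError, TypeError):
                pass
        if not pages:
            raise StackFormatError(f"{path} contains no pages")
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise StackShapeError(f"{path}: pages differ in shape: {shapes}")
        volumes.append(np.stack(pages))

    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise StackShapeError(f"channels disagree on (plane, row, col) shape: {shapes}")

    return ZStack(
        data=np.stack(volumes),
        channel_names=channel_names,
        z_step_um=z_step_um if z_step_um is not None else meta.get("z_step_um", DEFAULT_Z_STEP_UM),
        pixel_size_um=(
            pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
        ),
        focal_plane_index=(
            focal_plane_index if focal_plane_index is not None else meta.get("focal_plane_index")
        ),
    )


def write_stack(stack: ZStack, paths: Mapping[str, str | Path] | Sequence[str | Path]) -> None:
    """Write one multi-page TIFF per channel, calibration in the description.

    Plane order and dtype are preserved; calibration is serialised as a JSON
    image description so that :func:`read_stack` round-trips it.
    """
    if isinstance(paths, Mapping):
        path_list = [Path(paths[name]) for name in stack.channel_names]
    else:
        path_list = [Path(p) for p in paths]
    if len(path_list) != len(stack.channel_names):
        raise ValueError("one output path per channel required")

    description = json.dumps(
        {
            "z_step_um": stack.z_step_um,
            "pixel_size_um": stack.pixel_size_um,
            "focal_plane_index": stack.focal_plane_index,
        }
    )
    for idx, path in enumerate(path_list):
        tifffile.imwrite(
            path, stack.data[idx], description=description, photometric="minisblack"
        )


def extended_focus(stack: ZStack, channel: str, *, keep_provenance: bool = False) -> ExtendedFocusImage:
    """Per-pixel maximum-intensity projection of one channel over planes.

    Every output pixel equals the highest intensity attained at that pixel
    in any focal plane, so the composite dominates each individual plane
    pixelwise and each value is attained in at least one source plane.
    With ``keep_provenance`` the (lowest) plane index attaining the maximum
    is recorded per pixel.
    """
    volume = stack.channel(channel)
    data = volume.max(axis=0)
    provenance = volume.argmax(axis=0).astype(np.int32) if keep_provenance else None
    return ExtendedFocusImage(channel_name=channel, data=data, provenance=provenance)
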