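"""Multi-dimensional image container and TIFF round-tripping.

``ImageStack`` is a thin carrier for microscope data: a pixel array, an axes
string (ordered subset of ``TZCYX`` always ending in ``YX``), optional
channel names and the physical calibration (pixel size, z-step, frame
interval).  Files are written as TIFF with the stack metadata embedded as
JSON in the image description, so a write/read cycle is lossless without any
sidecar file; plain third-party TIFFs are read too, with the axes taken from
the file series or from an explicit override.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

_AXES_ORDER = "TZCYX"
_META_KEY = "hydraplate"


@dataclass
class ImageStack:
    pixels: np.ndarray
    axes: str
    channel_names: tuple[str, ...] | None = None
    pixel_size_um: float | None = None
    z_step_um: float | None = None
    time_step_min: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.axes = self.axes.upper()
        if len(self.axes) != self.pixels.ndim:
            raise ValueError(
                f"axes {self.axes!r} do not match array ndim {self.pixels.ndim}")
        if not self.axes.endswith("YX"):
            raise ValueError("axes must end in 'YX'")
        if any(a not in _AXES_ORDER for a in self.axes) or \
                len(set(self.axes)) != len(self.axes):
            raise ValueError(f"axes must be a subset of {_AXES_ORDER!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if "C" not in self.axes:
                raise ValueError("channel_names given but no C axis")
            if len(self.channel_names) != self.pixels.shape[self.axes.index("C")]:
                raise ValueError("channel_names length does not match C axis")

    # -- axis helpers -------------------------------------------------------
    def axis(self, name: str) -> int:
        if name not in self.axes:
            raise KeyError(f"stack has no {name!r} axis")
        return self.axes.index(name)

    def canonical(self) -> "ImageStack":
        """Reorder axes into TZCYX order (dropping absent axes)."""
        order = [a for a in _AXES_ORDER if a in self.axes]
        perm = [self.axes.index(a) for a in order]
        return replace(self, pixels=np.transpose(self.pixels, perm),
                       axes="".join(order))

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Extract one channel (C axis removed)."""
        c = self.axis("C")
        if isinstance(name_or_index, str):
            if self.channel_names is None:
                raise KeyError("stack has no channel names")
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return np.take(self.pixels, idx, axis=c)

    def max_projection(self, axis: str = "Z") -> np.ndarray:
        return self.pixels.max(axis=self.axis(axis))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as TIFF with its metadata embedded as JSON."""
    meta = {
        _META_KEY: {
            "axes": stack.axes,
            "channel_names": list(stack.channel_names) if stack.channel_names else None,
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "time_step_min": stack.time_step_min,
        }
    }
    tifffile.imwrite(Path(path), stack.pixels, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path: str | Path, axes: str | None = None,
               channel_names: tuple[str, ...] | None = None,
               pixel_size_um: float | None = None,
               z_step_um: float | None = None,
               time_step_min: float | None = None) -> ImageStack:
    """Read a TIFF as an ImageStack.

    Embedded JSON metadata wins; otherwise the axes come from the file
    series, and any axis letters tifffile cannot identify must be resolved
    with the ``axes`` override.  Explicit keyword overrides always replace
    the stored calibration.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        pixels = series.asarray()
        file_axes = series.axes
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if _META_KEY in desc:
        try:
            meta = json.loads(desc).get(_META_KEY, {})
        except json.JSONDecodeError:
            meta = {}
    resolved_axes = axes or meta.get("axes") or file_axes
    resolved_axes = resolved_axes.upper()
    if any(a not in _AXES_ORDER for a in resolved_axes):
        raise ValueError(
            f"ambiguous axes {resolved_axes!r} for {path.name}; pass axes=...")
    names = channel_names or meta.get("channel_names")
    stack = ImageStack(
        pixels=pixels,
        axes=resolved_axes,
        channel_names=tuple(names) if names else None,
        pixel_size_um=pixel_size_um if pixel_size_um is not None
        else meta.get("pixel_size_um"),
        z_step_um=z_step_um if z_step_um is not None else meta.get("z_step_um"),
        time_step_min=time_step_min if time_step_min is not None
        else meta.get("time_step_min"),
    )
    return stack
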