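"""Gel thickness and flatness extraction.

Three acquisition styles are covered:

* confocal z-stacks of bead-laden gels -- per-pixel height maps from the
  axial extent of the thresholded signal (Otsu + per-slice closing, height
  = (last - first detected slice) x z-step);
* two-plane focus measurements -- thickness per field of view from the
  z-level difference between the gel top and the plastic substrate, with
  flatness reported as the SD across fields of view;
* dry profilometry -- quadratic background removal fitted on the bare
  substrate around the gel, center cross-cuts, and swelling ratios
  (hydrated / dry thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .stack import ImageStack

__all__ = [
    "HeightMap",
    "ThicknessSummary",
    "extract_height_map",
    "radial_profile",
    "moving_average",
    "two_plane_thickness",
    "detrend_dry_map",
    "cross_cuts",
    "swelling_ratio",
]


@dataclass
class HeightMap:
    """Per-pixel gel height in micrometres (0 where no signal)."""

    heights: np.ndarray
    pixel_size_um: float
    source: str = "zstack"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    @property
    def footprint(self) -> np.ndarray:
        return self.heights > 0

    def centroid(self) -> tuple[float, float]:
        if not self.footprint.any():
            raise ValueError("empty height map")
        cy, cx = ndi.center_of_mass(self.footprint)
        return float(cy), float(cx)


@dataclass
class ThicknessSummary:
    """Per-sample thickness (mean over FOVs) and flatness (SD over FOVs)."""

    mean_um: float
    flatness_sd_um: float
    n_fov: int
    thicknesses_um: tuple[float, ...] = field(default_factory=tuple)


def extract_height_map(zstack: ImageStack | np.ndarray, z_step_um: float | None = None,
                       inclusive: bool = False, per_slice_threshold: bool = False
                       ) -> HeightMap:
    """Height map from a single-channel z-stack.

    Otsu threshold (global over the stack by default, avoiding slice-wise
    threshold drift) and per-slice morphological closing separate gel signal
    from background; per column the height is ``(last - first detected
    slice) * z_step_um``.  ``inclusive`` adds one slice so an isolated
    single-slice signal counts as one z-step instead of zero.
    """
    if isinstance(zstack, ImageStack):
        canon = zstack.canonical()
        data = np.asarray(canon.pixels, dtype=float)
        if "C" in canon.axes:
            if data.shape[canon.axes.index("C")] != 1:
                raise ValueError("expected a single-channel stack")
            data = np.squeeze(data, axis=canon.axes.index("C"))
        z_step_um = z_step_um if z_step_um is not None else canon.z_step_um
        pixel_size = canon.pixel_size_um or 1.0
    else:
        data = np.asarray(zstack, dtype=float)
        pixel_size = 1.0
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need a (z, y, x) stack with >= 2 slices")
    if z_step_um is None or z_step_um <= 0:
        raise ValueError("z_step_um must be positive")

    se = disk(2)
    if per_slice_threshold:
        masks = []
        for plane in data:
            try:
                masks.append(plane > threshold_otsu(plane))
            except ValueError:
                masks.append(np.zeros_like(plane, dtype=bool))
        mask = np.stack(masks)
    else:
        mask = data > threshold_otsu(data)
    mask = np.stack([ndi.binary_closing(m, structure=se) for m in mask])
    if not mask.any():
        raise ValueError("no voxels above threshold: empty height map")

    any_sig = mask.any(axis=0)
    zidx = np.arange(data.shape[0])[:, None, None]
    first = np.where(any_sig, np.where(mask, zidx, data.shape[0]).min(axis=0), 0)
    last = np.where(any_sig, np.where(mask, zidx, -1).max(axis=0), 0)
    span = (last - first + (1 if inclusive else 0)).astype(float)
    heights = np.where(any_sig, span * z_step_um, 0.0)
    return HeightMap(heights=heights, pixel_size_um=pixel_size, source="zstack")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrink-to-valid window at the edges."""
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = x.size
    half_lo, half_hi = (window - 1) // 2, window // 2
    out = np.empty(n)
    for i in range(n):
        out[i] = x[max(0, i - half_lo): min(n, i + half_hi + 1)].mean()
    return out


def radial_profile(height_map: HeightMap, smoothing_window_px: int = 15,
                   axis: str = "x") -> tuple[np.ndarray, np.ndarray]:
    """Diameter profile through the footprint centroid, smoothed.

    Returns (positions_um, heights_um) along the requested axis, smoothed
    with a centered moving average of ``smoothing_window_px`` (the classic
    15-pixel filter at ~0.67 um pixels is ~10 um wide).
    """
    cy, cx = height_map.centroid()
    h = height_map.heights
    line = h[int(round(cy)), :] if axis == "x" else h[:, int(round(cx))]
    if np.count_nonzero(line) < smoothing_window_px:
        raise ValueError("footprint smaller than the smoothing window")
    smoothed = moving_average(line, smoothing_window_px)
    pos = (np.arange(line.size) - (cx if axis == "x" else cy)) * height_map.pixel_size_um
    return pos, smoothed


def two_plane_thickness(z_top_um, z_bottom_um: float) -> ThicknessSummary:
    """Thickness per FOV from gel-top and substrate z-levels.

    ``z_top_um`` is one z-level per field of view (the paper's design uses
    five); ``z_bottom_um`` the common substrate level.  Flatness is the SD
    of the per-FOV thicknesses.
    """
    tops = np.atleast_1d(np.asarray(z_top_um, dtype=float))
    if tops.size < 1:
        raise ValueError("need at least one field of view")
    if np.any(tops < z_bottom_um):
        raise ValueError("gel top below substrate level")
    t = tops - z_bottom_um
    sd = float(np.std(t, ddof=1)) if t.size > 1 else 0.0
    return ThicknessSummary(mean_um=float(t.mean()), flatness_sd_um=sd,
                            n_fov=int(t.size), thicknesses_um=tuple(t))


def detrend_dry_map(height_map: HeightMap, substrate_mask: np.ndarray) -> HeightMap:
    """Remove a second-order polynomial background fitted on the substrate.

    Fits z = a + b x + c y + d x^2 + e x y + f y^2 to the substrate pixels
    by least squares (coordinates relative to the map center) and subtracts
    it everywhere, zeroing the substrate level around the gel.
    """
    substrate = np.asarray(substrate_mask, dtype=bool)
    if substrate.shape != height_map.heights.shape:
        raise ValueError("substrate mask shape mismatch")
    if substrate.sum() < 6:
        raise ValueError("need >= 6 substrate pixels for a quadratic fit")
    h, w = height_map.heights.shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy - (h - 1) / 2.0).astype(float)
    x = (xx - (w - 1) / 2.0).astype(float)
    design = np.column_stack([np.ones(substrate.sum()), x[substrate], y[substrate],
                              x[substrate] ** 2, (x * y)[substrate],
                              y[substrate] ** 2])
    coef, *_ = np.linalg.lstsq(design, height_map.heights[substrate], rcond=None)
    background = (coef[0] + coef[1] * x + coef[2] * y + coef[3] * x**2
                  + coef[4] * x * y + coef[5] * y**2)
    return HeightMap(heights=height_map.heights - background,
                     pixel_size_um=height_map.pixel_size_um,
                     source="profilometer")


def cross_cuts(height_map: HeightMap, smoothing_window_px: int = 15,
               planarity_deg: float = 3.0) -> dict:
    """Center x- and y-cuts with thickness and flatness estimates.

    Thickness is the mean of the central plateau (inner half of the
    footprint along each cut); flatness is the percentage of the footprint
    extent along the cut where the local slope stays within
    ``planarity_deg`` of horizontal.
    """
    results: dict = {}
    slope_tol = np.tan(np.radians(planarity_deg))
    for ax in ("x", "y"):
        pos, cut = radial_profile(height_map, smoothing_window_px, axis=ax)
        inside = cut > 0
        if not inside.any():
            raise ValueError("empty cut")
        extent = pos[inside]
        half_span = 0.5 * (extent.max() - extent.min())
        center = 0.5 * (extent.max() + extent.min())
        plateau = inside & (np.abs(pos - center) <= 0.5 * half_span)
        slopes = np.gradient(cut, pos)
        planar = inside & (np.abs(slopes) <= slope_tol)
        dx = np.median(np.diff(pos))
        flatness = 100.0 * planar.sum() * dx / max(extent.max() - extent.min(), dx)
        results[f"{ax}_cut"] = (pos, cut)
        results[f"{ax}_thickness_um"] = float(cut[plateau].mean())
        results[f"{ax}_flatness_pct"] = float(min(flatness, 100.0))
    results["thickness_um"] = 0.5 * (results["x_thickness_um"]
                                     + results["y_thickness_um"])
    results["flatness_pct"] = 0.5 * (results["x_flatness_pct"]
                                     + results["y_flatness_pct"])
    return results


def swelling_ratio(hydrated_um: float, dry_um: float) -> float:
    """Hydrated over dry thickness."""
    if dry_um <= 0:
        raise ValueError("dry thickness must be positive")
    return float(hydrated_um) / float(dry_um)
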