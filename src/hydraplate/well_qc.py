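"""Automated plate-scale quality control of cast hydrogel wells.

Per well the input is a 2-channel z-stack: a "wall" channel showing the
bright well-wall ring and a "gel" channel showing fluorescent beads embedded
in the gel.  Maximum-intensity projections are centered on the wall ring,
cleaned up morphologically, and the well is classified:

* ``bad``     -- the gel footprint overlaps the wall ring (meniscus / wall
                 contact),
* ``planar``  -- the gel projection is filled nearly everywhere
                 (post-threshold mean gray >= 250 of 255),
* ``concave`` -- the projection has a dim, patchy interior (central sag),
* ``empty``   -- no detectable wall ring or no gel signal.

The chain mirrors a classic FIJI macro: gamma correction, triangle /
isodata auto-thresholding, opening, closing, hole filling, outlier removal
(median, radius 10 px) and mask-boundary edge extraction.  All steps are
histogram-relative, so classifications are invariant to global intensity
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .morphology import binary_closing, binary_opening
from .stack import ImageStack
from .thresholds import DegenerateHistogramError, threshold_image

__all__ = [
    "WellRecord",
    "PlateReport",
    "EmptyWellSignal",
    "preprocess_well",
    "wall_mask",
    "gel_mask",
    "detect_wall_contact",
    "shape_class",
    "classify_well",
    "qc_plate",
]

QC_CLASSES = ("planar", "concave", "bad", "empty")
_FRAME_COLORS = {"planar": (0, 200, 0), "bad": (220, 0, 0),
                 "concave": (230, 200, 0), "empty": (90, 90, 90),
                 "error": (150, 0, 150)}


class EmptyWellSignal(ValueError):
    """Raised when a processing stage finds no usable signal in the well."""


@dataclass
class WellRecord:
    well_id: str
    qc_class: str
    wall_overlap_px: int = 0
    gel_fill_mean: float = 0.0
    footprint_area_px: int = 0

    def __post_init__(self) -> None:
        if self.qc_class not in QC_CLASSES + ("error",):
            raise ValueError(f"unknown qc class {self.qc_class!r}")
        if self.qc_class == "bad" and self.wall_overlap_px <= 0:
            raise ValueError("'bad' requires positive wall overlap")
        if self.qc_class in ("planar", "concave") and self.wall_overlap_px != 0:
            raise ValueError("planar/concave require zero wall overlap")
        if not (0.0 <= self.gel_fill_mean <= 255.0):
            raise ValueError("gel_fill_mean must lie in [0, 255]")


@dataclass
class PlateReport:
    records: list[WellRecord]
    class_fractions: dict[str, float]
    tile_image: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _normalize(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise EmptyWellSignal("constant projection")
    return (img - lo) / (hi - lo)


def _gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    return _normalize(image) ** gamma


def preprocess_well(stack: ImageStack, wall_channel="wall", gel_channel="gel",
                    crop_factor: float = 2.2) -> tuple[np.ndarray, np.ndarray]:
    """Max-project both channels and center the field on the wall ring.

    The wall-ring centroid is moved to the image center by an integer
    translation (rotation is a no-op for circular wells and omitted), and
    the field cropped to a square of side ``crop_factor`` x wall radius
    (clipped to the image).  Raises ``EmptyWellSignal`` when no wall ring is
    detectable.
    """
    canon = stack.canonical()
    wall = np.asarray(canon.channel(wall_channel), dtype=float)
    gel = np.asarray(canon.channel(gel_channel), dtype=float)
    if wall.ndim == 3:
        wall = wall.max(axis=0)
        gel = gel.max(axis=0)
    try:
        ring = threshold_image(wall, "triangle")
    except DegenerateHistogramError as exc:
        raise EmptyWellSignal("no wall signal") from exc
    if not ring.any():
        raise EmptyWellSignal("no pixels above the wall threshold")
    cy, cx = ndi.center_of_mass(ring)
    yy, xx = np.nonzero(ring)
    radius = float(np.hypot(yy - cy, xx - cx).mean())
    h, w = wall.shape
    dy, dx = int(round(h / 2 - cy)), int(round(w / 2 - cx))
    wall = np.roll(np.roll(wall, dy, axis=0), dx, axis=1)
    gel = np.roll(np.roll(gel, dy, axis=0), dx, axis=1)
    half = int(min(crop_factor * radius / 2, h / 2, w / 2))
    y0, x0 = h // 2 - half, w // 2 - half
    sl = np.s_[y0:y0 + 2 * half, x0:x0 + 2 * half]
    return wall[sl], gel[sl]


def _cleanup(mask: np.ndarray, fill_all_holes: bool) -> np.ndarray:
    """Opening, closing (disk 2), hole filling and radius-10 outlier removal."""
    se = disk(2)
    mask = binary_closing(binary_opening(mask, se), se)
    if fill_all_holes:
        mask = ndi.binary_fill_holes(mask)
    else:
        mask = _fill_small_holes(mask, max_area=64)
    mask = remove_outliers(mask, radius=10)
    return mask


def remove_outliers(mask: np.ndarray, radius: int = 10) -> np.ndarray:
    """Bright-outlier removal on a binary mask.

    A set pixel whose local median (disk ``radius``) is background is
    replaced by that median, i.e. cleared; structures wider than the radius
    survive, isolated specks and thin debris do not.
    """
    med = ndi.median_filter(mask.astype(np.uint8), footprint=disk(radius))
    return mask & (med > 0)


def _fill_small_holes(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Fill enclosed background regions up to ``max_area`` pixels.

    The well lumen enclosed by the wall ring must stay open, so only
    pinhole-scale holes are filled.
    """
    holes = ndi.binary_fill_holes(mask) & ~mask
    lab, n = ndi.label(holes)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(holes, lab, index=np.arange(1, n + 1))
    small = np.isin(lab, np.nonzero(sizes <= max_area)[0] + 1)
    return mask | small


def wall_mask(wall_mip: np.ndarray) -> np.ndarray:
    """Binary wall-ring band from the wall-channel projection."""
    try:
        raw = threshold_image(_gamma(wall_mip, 0.5), "triangle")
    except (DegenerateHistogramError, EmptyWellSignal) as exc:
        raise EmptyWellSignal("wall projection has no contrast") from exc
    band = _cleanup(raw, fill_all_holes=False)
    if not band.any():
        raise EmptyWellSignal("wall mask empty after cleanup")
    return band


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Edge detection on a binary mask: the mask minus its erosion."""
    return mask & ~ndi.binary_erosion(mask)


def gel_mask(gel_mip: np.ndarray) -> np.ndarray:
    """Filled gel-footprint mask from the gel-channel projection."""
    try:
        raw = threshold_image(_gamma(gel_mip, 0.5), "isodata")
    except (DegenerateHistogramError, EmptyWellSignal) as exc:
        raise EmptyWellSignal("gel projection has no contrast") from exc
    footprint = _cleanup(raw, fill_all_holes=True)
    if not footprint.any():
        raise EmptyWellSignal("gel mask empty after cleanup")
    return footprint


def detect_wall_contact(gel: np.ndarray, wall: np.ndarray,
                        min_overlap: int = 5) -> tuple[bool, int]:
    """Logical AND of the gel and wall masks; contact above ``min_overlap`` px."""
    if gel.shape != wall.shape:
        raise ValueError("gel and wall masks must share a shape")
    overlap = int(np.count_nonzero(gel & wall))
    return overlap > min_overlap, overlap


def shape_class(gel_mip: np.ndarray, footprint: np.ndarray) -> tuple[str, float]:
    """Secondary shape analysis: planar versus concave.

    Gamma 2, isodata threshold and closing on the gel projection; the mean
    of the resulting 0/255 image over the gel footprint is the fill score.
    A nearly saturated projection (>= 250) is planar, anything patchier is
    concave.
    """
    if not footprint.any():
        raise EmptyWellSignal("empty gel footprint")
    try:
        binary = threshold_image(_gamma(gel_mip, 2.0), "isodata")
    except (DegenerateHistogramError, EmptyWellSignal):
        return "concave", 0.0
    binary = binary_closing(binary, disk(2))
    # score the footprint interior: the PSF-blur rim of the footprint mask
    # systematically fails the gamma-2 threshold and would mask the
    # planar/concave contrast the fill rule is after
    interior = ndi.binary_erosion(footprint, structure=disk(3))
    region = interior if interior.any() else footprint
    fill_mean = float(binary[region].mean() * 255.0)
    return ("planar" if fill_mean >= 250.0 else "concave"), fill_mean


def classify_well(stack: ImageStack, well_id: str = "", wall_channel="wall",
                  gel_channel="gel", min_overlap: int = 5) -> WellRecord:
    """Full per-well chain: empty -> bad (wall contact) -> planar/concave."""
    try:
        wall_mip, gel_mip = preprocess_well(stack, wall_channel, gel_channel)
        wall = wall_mask(wall_mip)
    except EmptyWellSignal:
        return WellRecord(well_id, "empty")
    try:
        gel = gel_mask(gel_mip)
    except EmptyWellSignal:
        return WellRecord(well_id, "empty")
    contact, overlap = detect_wall_contact(gel, wall, min_overlap)
    area = int(np.count_nonzero(gel))
    if contact:
        return WellRecord(well_id, "bad", wall_overlap_px=overlap,
                          footprint_area_px=area)
    cls, fill = shape_class(gel_mip, gel)
    return WellRecord(well_id, cls, wall_overlap_px=0, gel_fill_mean=fill,
                      footprint_area_px=area)


def _tile_montage(wells: list[tuple[str, np.ndarray]], classes: list[str],
                  n_cols: int = 12, frame_px: int = 3) -> np.ndarray:
    """RGB montage of gel projections with class-colored frames."""
    if not wells:
        return np.zeros((1, 1, 3), dtype=np.uint8)
    size = max(max(img.shape) for _, img in wells)
    tiles = []
    for (_, img), cls in zip(wells, classes):
        norm = img - img.min()
        if norm.max() > 0:
            norm = norm / norm.max()
        tile = np.zeros((size, size, 3), dtype=np.uint8)
        gray = (norm * 255).astype(np.uint8)
        tile[: img.shape[0], : img.shape[1]] = gray[..., None]
        if cls != "empty":
            color = np.array(_FRAME_COLORS.get(cls, (255, 255, 255)), np.uint8)
            tile[:frame_px, :] = color
            tile[-frame_px:, :] = color
            tile[:, :frame_px] = color
            tile[:, -frame_px:] = color
        tiles.append(tile)
    n = len(tiles)
    n_rows = -(-n // n_cols)
    montage = np.zeros((n_rows * size, n_cols * size, 3), dtype=np.uint8)
    for i, tile in enumerate(tiles):
        r, c = divmod(i, n_cols)
        montage[r * size:(r + 1) * size, c * size:(c + 1) * size] = tile
    return montage


def qc_plate(stacks, wall_channel="wall", gel_channel="gel",
             min_overlap: int = 5) -> PlateReport:
    """Classify every well and assemble the plate report.

    ``stacks`` is an iterable of (well_id, ImageStack).  A well whose
    processing raises is recorded as class ``error`` without aborting the
    plate.
    """
    records: list[WellRecord] = []
    previews: list[tuple[str, np.ndarray]] = []
    for well_id, stack in stacks:
        try:
            rec = classify_well(stack, well_id, wall_channel, gel_channel,
                                min_overlap)
        except Exception:
            rec = WellRecord(well_id, "error")
        records.append(rec)
        try:
            _, gel_mip = preprocess_well(stack, wall_channel, gel_channel)
        except EmptyWellSignal:
            canon = stack.canonical()
            gel_mip = np.asarray(canon.channel(gel_channel), dtype=float)
            if gel_mip.ndim == 3:
                gel_mip = gel_mip.max(axis=0)
        previews.append((well_id, gel_mip))
    n = len(records)
    fractions = {cls: 100.0 * sum(r.qc_class == cls for r in records) / n
                 for cls in QC_CLASSES + ("error",)} if n else {}
    montage = _tile_montage(previews, [r.qc_class for r in records])
    return PlateReport(records=records, class_fractions=fractions,
                       tile_image=montage)
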