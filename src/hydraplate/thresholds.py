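"""Histogram auto-thresholding: triangle and isodata (intermeans).

Both operate on 256-bin histograms taken over the image's own intensity
range, which makes every downstream mask invariant to a global intensity
rescaling.  The triangle method suits strongly skewed histograms (sparse
bright foreground); isodata is the classic iterative intermeans rule used
as the "default" method of common image-analysis macros.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateHistogramError",
    "triangle_threshold",
    "isodata_threshold",
    "histogram_256",
    "threshold_image",
]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two populated intensity levels."""


def _check_histogram(histogram: np.ndarray) -> np.ndarray:
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1-D array")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has < 2 populated bins")
    return hist


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle-method threshold bin.

    Draws a line from the histogram peak to the farthest populated bin on
    the longer-tail side and returns the bin index maximizing the
    perpendicular distance between histogram and line.
    """
    hist = _check_histogram(histogram)
    peak = int(np.argmax(hist))
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    # pick the longer tail measured from the peak
    if (hi - peak) >= (peak - lo):
        tail = hi
        idx = np.arange(peak, tail + 1)
    else:
        tail = lo
        idx = np.arange(tail, peak + 1)
    # perpendicular distance of (x, h(x)) from the peak->tail chord
    x1, y1 = peak, hist[peak]
    x2, y2 = tail, hist[tail]
    norm = np.hypot(x2 - x1, y2 - y1)
    d = np.abs((y2 - y1) * idx - (x2 - x1) * hist[idx] + x2 * y1 - y2 * x1) / norm
    return int(idx[np.argmax(d)])


def isodata_threshold(histogram: np.ndarray) -> int:
    """Iterative intermeans threshold bin.

    Starting from the mid-intensity of the populated range, iterates
    t <- floor((mean below t) + (mean above t)) / 2) until a fixed point;
    "below" includes bin t itself. Ties break downward through the floor.
    """
    hist = _check_histogram(histogram)
    bins = np.arange(hist.size)
    nz = np.nonzero(hist)[0]
    t = int((nz[0] + nz[-1]) // 2)
    for _ in range(hist.size + 1):
        below = hist[: t + 1]
        above = hist[t + 1:]
        if below.sum() == 0:
            t += 1
            continue
        if above.sum() == 0:
            t -= 1
            continue
        mu_b = (below * bins[: t + 1]).sum() / below.sum()
        mu_a = (above * bins[t + 1:]).sum() / above.sum()
        t_new = int(np.floor(0.5 * (mu_b + mu_a)))
        if t_new == t:
            return t
        t = t_new
    return t


def histogram_256(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over the image's own min-max range.

    Returns (counts, bin_edges); edges span [min, max] of the image.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image")
    counts, edges = np.histogram(img, bins=256, range=(lo, hi))
    return counts, edges


def threshold_image(image: np.ndarray, method: str = "triangle") -> np.ndarray:
    """Binary mask: pixels strictly above the auto-threshold level."""
    counts, edges = histogram_256(image)
    fn = {"triangle": triangle_threshold, "isodata": isodata_threshold}[method]
    level_bin = fn(counts)
    level = edges[level_bin + 1]  # upper edge of the threshold bin
    return np.asarray(image, dtype=float) > level
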