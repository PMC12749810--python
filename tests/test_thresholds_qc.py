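"""Auto-threshold oracles and the plate-QC classification chain."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from hydraplate import well_qc
from hydraplate.synth import PhantomSpec, generate_well_phantom
from hydraplate.thresholds import (DegenerateHistogramError, histogram_256,
                                   isodata_threshold, threshold_image,
                                   triangle_threshold)

# ---------------------------------------------------------------------------
# brute-force reference searches
# ---------------------------------------------------------------------------


def brute_triangle(hist):
    """Exhaustive perpendicular-distance search on the longer-tail side."""
    hist = np.asarray(hist, dtype=float)
    peak = int(np.argmax(hist))
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    tail = hi if (hi - peak) >= (peak - lo) else lo
    a, b = min(peak, tail), max(peak, tail)
    x1, y1, x2, y2 = peak, hist[peak], tail, hist[tail]
    norm = np.hypot(x2 - x1, y2 - y1)
    best, best_d = a, -1.0
    for i in range(a, b + 1):
        d = abs((y2 - y1) * i - (x2 - x1) * hist[i] + x2 * y1 - y2 * x1) / norm
        if d > best_d:
            best, best_d = i, d
    return best


def isodata_fixed_points(hist):
    """All levels t with t == floor((mean below + mean above) / 2)."""
    hist = np.asarray(hist, dtype=float)
    bins = np.arange(hist.size)
    points = []
    for t in range(hist.size - 1):
        below, above = hist[: t + 1], hist[t + 1:]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mu_b = (below * bins[: t + 1]).sum() / below.sum()
        mu_a = (above * bins[t + 1:]).sum() / above.sum()
        if int(np.floor(0.5 * (mu_b + mu_a))) == t:
            points.append(t)
    return points


def _random_histogram(rng):
    """Bimodal-ish random 256-bin histogram."""
    h = np.zeros(256)
    for _ in range(rng.integers(1, 4)):
        mu = rng.integers(5, 250)
        sd = rng.uniform(2, 40)
        amp = rng.uniform(10, 1e4)
        x = np.arange(256)
        h += amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return np.round(h)


def test_thresholds_match_brute_force_on_200_histograms(rng):
    for _ in range(200):
        hist = _random_histogram(rng)
        if np.count_nonzero(hist) < 2:
            continue
        assert triangle_threshold(hist) == brute_triangle(hist)
        fixed = isodata_fixed_points(hist)
        if fixed:
            assert isodata_threshold(hist) in fixed


def test_triangle_spike_with_linear_decay():
    hist = np.zeros(256)
    hist[10] = 1e4
    hist[11:111] = np.linspace(100, 1, 100)
    level = triangle_threshold(hist)
    assert level == brute_triangle(hist)
    assert 10 < level < 111


def test_triangle_mirror_symmetry():
    """Flipping an asymmetric histogram mirrors the threshold level."""
    x = np.arange(256)
    hump = np.round(5000 * np.exp(-0.5 * ((x - 60) / 8.0) ** 2)
                    + 300 * np.exp(-0.5 * ((x - 150) / 35.0) ** 2))
    level = triangle_threshold(hump)
    mirrored = triangle_threshold(hump[::-1])
    assert level + mirrored == 255


def test_isodata_two_deltas():
    hist = np.zeros(256)
    hist[50] = 500
    hist[150] = 500
    assert isodata_threshold(hist) == 100


def test_isodata_uniform_histogram():
    assert isodata_threshold(np.ones(256)) == 127


def test_degenerate_histogram_errors():
    with pytest.raises(DegenerateHistogramError):
        triangle_threshold(np.eye(1, 256, 42).ravel() * 100)
    with pytest.raises(DegenerateHistogramError):
        isodata_threshold(np.zeros(256))
    with pytest.raises(DegenerateHistogramError):
        histogram_256(np.full((8, 8), 7.0))


# ---------------------------------------------------------------------------
# per-well chain
# ---------------------------------------------------------------------------


def _phantom(cls, seed=0, **kw):
    spec = PhantomSpec(shape_class=cls, seed=seed, **kw)
    return generate_well_phantom(spec)


def test_preprocess_centers_offset_well():
    stack, _ = _phantom("planar", noise=(0.0, 0.0),
                        center_offset_px=(15, -10), seed=1)
    wall_mip, _ = well_qc.preprocess_well(stack)
    ring = threshold_image(wall_mip, "triangle")
    cy, cx = ndi.center_of_mass(ring)
    assert abs(cy - (wall_mip.shape[0] - 1) / 2) <= 1.0
    assert abs(cx - (wall_mip.shape[1] - 1) / 2) <= 1.0


def test_preprocess_centered_identity():
    stack, _ = _phantom("planar", noise=(0.0, 0.0), seed=2)
    wall_mip, _ = well_qc.preprocess_well(stack)
    ring = threshold_image(wall_mip, "triangle")
    cy, cx = ndi.center_of_mass(ring)
    assert abs(cy - (wall_mip.shape[0] - 1) / 2) <= 1.0


def test_blank_stack_is_empty():
    stack, _ = _phantom("empty", noise=(0.0, 0.0), seed=3)
    # zero the wall channel too: nothing in the well at all
    stack.pixels[:, 0] = 0.0
    rec = well_qc.classify_well(stack, "A01")
    assert rec.qc_class == "empty"


def test_wall_mask_recovers_ring():
    stack, _ = _phantom("planar", noise=(0.0, 0.0), seed=4)
    wall_mip, _ = well_qc.preprocess_well(stack)
    band = well_qc.wall_mask(wall_mip)
    h, w = wall_mip.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
    true_band = (r >= 40) & (r < 70)
    iou = (band & true_band).sum() / (band | true_band).sum()
    assert iou >= 0.9


def test_wall_mask_removes_hot_pixels(rng):
    stack, _ = _phantom("planar", noise=(0.0, 0.0), seed=5)
    wall_mip, _ = well_qc.preprocess_well(stack)
    clean = well_qc.wall_mask(wall_mip)
    noisy = wall_mip.copy()
    ys = rng.integers(0, noisy.shape[0], 50)
    xs = rng.integers(0, noisy.shape[1], 50)
    noisy[ys, xs] = noisy.max() * 2
    dirty = well_qc.wall_mask(noisy)
    assert (clean ^ dirty).sum() <= 0.01 * clean.sum() + 5


def test_gel_mask_footprint_area():
    stack, truth = _phantom("planar", noise=(0.0, 0.0), seed=6)
    _, gel_mip = well_qc.preprocess_well(stack)
    footprint = well_qc.gel_mask(gel_mip)
    true_area = (truth.height_map_um > 0).sum()
    assert footprint.sum() == pytest.approx(true_area, rel=0.05)


def test_wall_contact_trivial_cases():
    zeros = np.zeros((32, 32), dtype=bool)
    ring = np.zeros((32, 32), dtype=bool)
    ring[10, 10] = True
    assert well_qc.detect_wall_contact(zeros, ring) == (False, 0)
    with pytest.raises(ValueError):
        well_qc.detect_wall_contact(zeros, np.zeros((16, 16), dtype=bool))


@pytest.mark.parametrize("cls,expected", [("planar", "planar"),
                                          ("concave", "concave"),
                                          ("meniscus", "bad"),
                                          ("empty", "empty")])
def test_noise_free_classification(cls, expected):
    for seed in range(8):
        stack, _ = _phantom(cls, noise=(0.0, 0.0), seed=seed)
        assert well_qc.classify_well(stack).qc_class == expected


def test_classification_scale_invariant():
    """Thresholds are histogram-relative: a global gain must not matter."""
    for cls in ("planar", "concave", "meniscus"):
        stack, _ = _phantom(cls, seed=11)
        rec1 = well_qc.classify_well(stack)
        scaled = well_qc.classify_well(
            type(stack)(pixels=stack.pixels * 2.7, axes=stack.axes,
                        channel_names=stack.channel_names,
                        pixel_size_um=stack.pixel_size_um,
                        z_step_um=stack.z_step_um))
        assert rec1.qc_class == scaled.qc_class


def test_qc_plate_report():
    wells = []
    for i, cls in enumerate(["planar", "planar", "meniscus", "concave"]):
        stack, _ = _phantom(cls, seed=20 + i)
        wells.append((f"A{i + 1:02d}", stack))
    report = well_qc.qc_plate(wells)
    assert sum(report.class_fractions.values()) == pytest.approx(100.0, abs=0.1)
    assert report.class_fractions["planar"] == pytest.approx(50.0)
    assert report.tile_image.ndim == 3 and report.tile_image.shape[2] == 3
    df = report.to_frame()
    assert list(df.well_id) == ["A01", "A02", "A03", "A04"]


def test_well_record_invariants():
    with pytest.raises(ValueError):
        well_qc.WellRecord("A01", "bad", wall_overlap_px=0)
    with pytest.raises(ValueError):
        well_qc.WellRecord("A01", "planar", wall_overlap_px=3)
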