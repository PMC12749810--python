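"""FUCCI classification rules, mitosis thresholds, exclusion and tracking."""

import numpy as np
import pandas as pd
import pytest

from hydraplate import cellcycle as cc
from hydraplate.synth import generate_fucci_timelapse

PHASE_TO_CLASS = {"EG1": "EG1", "G1": "G1", "SG2": "SG2M", "M": "SG2M", "T": "T"}


def _tiny_frame(cyan_level, magenta_level, tubulin_nucleus=40.0,
                tubulin_base=40.0):
    """One 24x24 frame with a single radius-4 nucleus at the center."""
    size = 24
    yy, xx = np.mgrid[0:size, 0:size]
    nucleus = (yy - 12) ** 2 + (xx - 12) ** 2 <= 16
    frame = np.zeros((4, size, size))
    frame[1] = tubulin_base
    frame[1][nucleus] = tubulin_nucleus
    frame[2][nucleus] = cyan_level
    frame[3][nucleus] = magenta_level
    labels = nucleus.astype(np.int32)
    return frame, labels


@pytest.mark.parametrize("cyan,magenta,expected", [
    (0.0, 0.0, "EG1"),
    (100.0, 0.0, "G1"),
    (0.0, 100.0, "SG2M"),
    (100.0, 100.0, "T"),
])
def test_four_way_classification_rule(cyan, magenta, expected):
    frame, labels = _tiny_frame(cyan, magenta)
    [rec] = cc.classify_nuclei(frame, labels, cyan_thr=10.0, magenta_thr=10.0)
    assert rec.cycle_class == expected


def test_classification_offset_invariant():
    """Adding a constant to every channel must not change any class."""
    frame, labels = _tiny_frame(100.0, 0.0)
    [rec] = cc.classify_nuclei(frame, labels, 10.0, 10.0)
    [rec_off] = cc.classify_nuclei(frame + 37.0, labels, 10.0, 10.0)
    assert rec.cycle_class == rec_off.cycle_class == "G1"


def test_empty_labels_empty_result():
    frame, _ = _tiny_frame(0.0, 0.0)
    assert cc.classify_nuclei(frame, np.zeros((24, 24), np.int32), 1, 1) == []


def test_mitotic_substrate_thresholds():
    """Relative excess 0.3 is mitotic on plastic (>=0.2), not on gel (>=0.4)."""
    frame, labels = _tiny_frame(0.0, 100.0, tubulin_nucleus=52.0)
    plastic = cc.detect_mitotic(frame, labels, substrate="plastic")
    gel = cc.detect_mitotic(frame, labels, substrate="hydrogel")
    assert plastic[1]["excess"] == pytest.approx(0.3, abs=0.02)
    assert plastic[1]["mitotic"] and not gel[1]["mitotic"]


def test_mitotic_zero_excess_and_undefined_background():
    frame, labels = _tiny_frame(0.0, 100.0, tubulin_nucleus=40.0)
    assert not cc.detect_mitotic(frame, labels, substrate="plastic")[1]["mitotic"]
    dark, labels = _tiny_frame(0.0, 100.0, tubulin_nucleus=0.0, tubulin_base=0.0)
    flags = cc.detect_mitotic(dark, labels, substrate="plastic")
    assert not flags[1]["defined"]


def test_bleedthrough_correction():
    """Cyan bleed into tubulin must not fake mitosis once corrected."""
    frame, labels = _tiny_frame(150.0, 0.0)
    frame[1] = frame[1] + 0.3 * frame[2]  # bleed-through
    uncorrected = cc.detect_mitotic(frame, labels, substrate="hydrogel",
                                    bleed_coeff=0.0)
    corrected = cc.detect_mitotic(frame, labels, substrate="hydrogel",
                                  bleed_coeff=0.3)
    assert uncorrected[1]["mitotic"]
    assert not corrected[1]["mitotic"]


def test_zero_noise_timelapse_perfect_scores():
    """Generator truth: 100% class accuracy, >= 99% mitotic recall/precision."""
    movie, truth = generate_fucci_timelapse(n_cells=40, n_frames=4,
                                            mitotic_fraction=0.2, seed=21)
    n_ok = n_tot = 0
    tp = fp = fn = 0
    for t in range(4):
        frame = movie.pixels[t]
        recs = cc.classify_nuclei(frame, truth.labels[t], frame_index=t)
        flags = cc.detect_mitotic(frame, truth.labels[t], substrate="hydrogel")
        td = truth.cells[truth.cells.frame == t].set_index("label_id")
        for r in recs:
            n_tot += 1
            n_ok += r.cycle_class == PHASE_TO_CLASS[td.loc[r.label_id, "phase"]]
            pred = flags[r.label_id]["mitotic"]
            true = bool(td.loc[r.label_id, "mitotic"])
            tp += pred and true
            fp += pred and not true
            fn += true and not pred
    assert n_ok == n_tot
    assert tp / (tp + fn) >= 0.99
    assert tp / (tp + fp) >= 0.99


def test_bleedthrough_timelapse_detection():
    movie, truth = generate_fucci_timelapse(n_cells=40, n_frames=2,
                                            mitotic_fraction=0.2,
                                            bleedthrough=0.3, seed=22)
    correct = total = 0
    for t in range(2):
        flags = cc.detect_mitotic(movie.pixels[t], truth.labels[t],
                                  substrate="hydrogel", bleed_coeff=0.3)
        td = truth.cells[truth.cells.frame == t].set_index("label_id")
        for lab, f in flags.items():
            total += 1
            correct += f["mitotic"] == bool(td.loc[lab, "mitotic"])
    assert correct / total >= 0.99


def test_fragmentation_filter_rules():
    def rec(area, mitotic=False):
        return cc.NucleusRecord(label_id=1, frame=0, centroid=(0, 0),
                                area_px=area, area_um2=area, mean_cyan=0,
                                mean_magenta=0, cycle_class="EG1",
                                mitotic=mitotic)

    # boundary: area equal to the control mean is kept (strict <)
    [kept] = cc.fragmentation_filter([rec(50.0)], control_mean_area=50.0)
    assert not kept.excluded_fragmented
    [cut] = cc.fragmentation_filter([rec(49.0, mitotic=True)], 50.0)
    assert cut.excluded_fragmented and not cut.mitotic
    [free] = cc.fragmentation_filter([rec(1.0)], 50.0, exclusion_fraction=0.0)
    assert not free.excluded_fragmented


def test_fragmentation_on_generated_population():
    _, truth = generate_fucci_timelapse(n_cells=150, n_frames=1,
                                        fragment_fraction=0.1, seed=23)
    frame0 = truth.cells[truth.cells.frame == 0]
    control_mean = frame0[~frame0.fragmented].area_px.mean()
    recs = [cc.NucleusRecord(label_id=int(r.label_id), frame=0, centroid=(r.y, r.x),
                             area_px=r.area_px, area_um2=r.area_px,
                             mean_cyan=0, mean_magenta=0, cycle_class="EG1")
            for r in frame0.itertuples()]
    out = cc.fragmentation_filter(recs, control_mean, exclusion_fraction=0.5)
    frac = np.mean([r.excluded_fragmented for r in out])
    assert frac == pytest.approx(frame0.fragmented.mean(), abs=0.02)


def test_mphase_fold_change_arithmetic():
    def population(n, m):
        out = []
        for i in range(n):
            out.append(cc.NucleusRecord(label_id=i, frame=0, centroid=(0, 0),
                                        area_px=10, area_um2=10, mean_cyan=0,
                                        mean_magenta=0, cycle_class="SG2M",
                                        mitotic=i < m))
        return out

    folds = cc.mphase_fold_change(
        {"vehicle": population(100, 2), "treated": population(100, 8)},
        "vehicle")
    assert folds["vehicle"] == 1.0
    assert folds["treated"] == pytest.approx(4.0)
    with pytest.raises(ValueError):
        cc.mphase_fold_change({"vehicle": population(10, 0)}, "vehicle")


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _detections(rows):
    return pd.DataFrame(rows, columns=["frame", "label_id", "y", "x"])


def test_single_drifting_cell_single_track():
    det = _detections([(t, 1, 10.0 + 5 * t, 10.0) for t in range(6)])
    ts = cc.link_tracks(det, pixel_size_um=1.0)
    assert len(ts.tracks) == 1
    assert ts.tracks[0] == [(t, 1) for t in range(6)]


def test_gap_closing_within_budget():
    det = _detections([(0, 1, 10, 10), (1, 1, 12, 10), (4, 1, 16, 10),
                       (5, 1, 18, 10)])
    ts = cc.link_tracks(det, pixel_size_um=1.0, max_gap_frames=3)
    assert len(ts.tracks) == 1
    strict = cc.link_tracks(det, pixel_size_um=1.0, max_gap_frames=2)
    assert len(strict.tracks) == 2


def test_distant_cells_never_merge():
    det = _detections([(t, lab, 10.0 + 200 * (lab - 1), 10.0)
                       for t in range(4) for lab in (1, 2)])
    ts = cc.link_tracks(det, pixel_size_um=1.0, max_distance_um=50.0)
    assert len(ts.tracks) == 2
    for chain in ts.tracks:
        labs = {lab for _, lab in chain}
        assert len(labs) == 1


def test_each_detection_in_exactly_one_track():
    movie, truth = generate_fucci_timelapse(n_cells=30, n_frames=5, seed=24)
    det = truth.cells[["frame", "label_id", "y", "x"]]
    ts = cc.link_tracks(det, pixel_size_um=1.0)
    seen = [pair for chain in ts.tracks for pair in chain]
    assert len(seen) == len(set(seen)) == len(det)
    # drift is ~1 px/frame and cells sit on a wide grid: pure tracks
    assert len(ts.tracks) == 30


def test_link_requires_pixel_size():
    with pytest.raises(ValueError):
        cc.link_tracks(_detections([(0, 1, 0, 0)]), pixel_size_um=None)
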