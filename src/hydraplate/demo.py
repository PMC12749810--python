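"""End-to-end demonstration run on synthetic data.

``run_demo`` exercises every pipeline once at a small scale -- meniscus
simulation, plate QC, height-map extraction, confluency/IC50 and FUCCI
scoring -- and writes their headline metrics plus CSV artifacts to an
output directory.  All randomness flows from the single seed, so two runs
with the same seed produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellcycle as cc
from . import confluency as cf
from . import meniscus as mn
from . import synth
from .gel_profile import extract_height_map
from .well_qc import qc_plate

__all__ = ["run_demo"]


def run_demo(seed: int = 0, out_dir: str | Path = "demo_out") -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
    summary: dict = {"seed": seed}

    # 1. meniscus model: conventional casting versus thin-layer protocol
    fluid, well, wetting = mn.FluidParams(), mn.WellGeometry(), mn.WettingParams()
    meniscus = mn.solve_wall_meniscus(20 * mn.UL, well, fluid, wetting.theta_wall)
    thin = mn.simulate_protocol(mn.hydra_protocol(12 * mn.UL), well, fluid, wetting)
    summary["meniscus"] = {
        "meniscus_flatness_pct": mn.flatness_metric(meniscus, well),
        "meniscus_coverage_pct": mn.coverage_metric(meniscus, well),
        "thin_layer_flatness_pct": thin.flatness,
        "thin_layer_coverage_pct": thin.coverage,
    }
    thin.trajectory.to_csv(out / "meniscus_trajectory.csv", index=False)

    # 2. plate QC on a 24-well synthetic plate
    plate = synth.generate_plate(
        24, {"planar": 0.75, "bad": 0.125, "concave": 0.125}, seed=rng_seed)
    report = qc_plate((wid, stack) for wid, stack, _ in plate)
    report.to_frame().to_csv(out / "plate_qc.csv", index=False)
    truth_ok = sum(rec.qc_class == tr.qc_class
                   for rec, (_, _, tr) in zip(report.records, plate))
    summary["qc"] = {"class_fractions_pct": report.class_fractions,
                     "accuracy_vs_truth": truth_ok / len(plate)}

    # 3. height-map extraction from a fine z-stack phantom
    spec = synth.PhantomSpec(shape_class="planar", gel_height_um=30.0,
                             z_step_um=2.0, n_z=20, pixel_size_um=2.0,
                             well_radius_px=40, bead_density=2e-2,
                             noise=(0.0, 0.0), seed=rng_seed + 1)
    stack, truth = synth.generate_well_phantom(spec)
    hm = extract_height_map(
        stack.__class__(pixels=stack.channel("gel"), axes="ZYX",
                        pixel_size_um=stack.pixel_size_um,
                        z_step_um=stack.z_step_um))
    inside = truth.height_map_um > 0
    summary["profile"] = {
        "true_height_um": 30.0,
        "median_height_um": float(np.median(hm.heights[inside])),
    }

    # 4. confluency + IC50 on a small dose series
    doses = [0.0, 4.0, 9.0, 18.0, 36.0, 80.0]
    rows = []
    for di, dose in enumerate(doses):
        for rep in range(3):
            movie, _ = synth.generate_confluency_movie(
                dose=dose, c0=0.3, r0=0.2, seed=rng_seed + 10 * di + rep,
                frames_subset=[0, 1, 2, 6, 7, 8])
            trace = cf.confluency_trace(movie)
            rows.append({"dose": dose, "replicate": rep,
                         "endpoint": trace.normalized[-1]})
    responses = pd.DataFrame(rows)
    responses.to_csv(out / "dose_endpoints.csv", index=False)
    fit = cf.fit_dose_response(responses["dose"], responses["endpoint"],
                               n_boot=50, seed=rng_seed)
    summary["confluency"] = {"ic50": fit.ic50, "hill": fit.hill,
                             "generator_ic50": 18.0}

    # 5. FUCCI cell-cycle scoring
    movie, truth = synth.generate_fucci_timelapse(
        n_cells=25, n_frames=4, mitotic_fraction=0.2, seed=rng_seed + 2)
    frames = movie.pixels
    all_records = []
    for t in range(frames.shape[0]):
        recs = cc.classify_nuclei(frames[t], truth.labels[t], 10.0, 10.0,
                                  frame_index=t)
        flags = cc.detect_mitotic(frames[t], truth.labels[t],
                                  substrate="hydrogel")
        for r in recs:
            r.mitotic = flags[r.label_id]["mitotic"]
        all_records.extend(recs)
    nuc = pd.DataFrame([vars(r) for r in all_records])
    nuc.to_csv(out / "nuclei.csv", index=False)
    merged = nuc.merge(truth.cells, left_on=["frame", "label_id"],
                       right_on=["frame", "label_id"])
    cls_acc = float(
        ((merged.cycle_class == merged.phase.map(
            {"EG1": "EG1", "G1": "G1", "SG2": "SG2M", "M": "SG2M", "T": "T"}))
         ).mean())
    tracks = cc.link_tracks(nuc.assign(y=[c[0] for c in nuc.centroid],
                                       x=[c[1] for c in nuc.centroid]),
                            pixel_size_um=1.0)
    summary["cellcycle"] = {
        "class_accuracy": cls_acc,
        "mitotic_rate": float(nuc.mitotic.mean()),
        "n_tracks": len(tracks.tracks),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
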