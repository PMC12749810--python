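"""Seeded synthetic-data generators with ground truth.

Every imaging pipeline in the package can be exercised without any external
data: these generators emulate the relevant acquisitions -- bead-speckled
gel z-stacks inside a bright well-wall ring (plate QC), label-free growth
movies whose logistic rate is suppressed by drug dose through a Hill
function (confluency / IC50), four-channel nuclei time-lapses driven by a
cell-cycle state machine (FUCCI scoring) and profilometer height maps with
a quadratic instrument background (dry-gel detrending).  Identical seeds
give bit-identical output.

The generators aim at *analytical* realism: intensities, shapes and noise
are rich enough to stress thresholds and morphology, not to fool a human or
train a segmentation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack import ImageStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_well_phantom",
    "generate_plate",
    "largest_remainder_allocation",
    "generate_confluency_movie",
    "generate_fucci_timelapse",
    "generate_dry_height_map",
    "PHASES",
]

_PSF_SIGMA_PX = 1.2  # per-slice Gaussian PSF


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic well z-stack.

    ``shape_class`` selects the gel geometry: ``planar`` (flat slab),
    ``concave`` (slab with a central parabolic sag of ``sag_depth_um``),
    ``meniscus`` (full-footprint gel climbing the wall to the top of the
    stack) or ``empty``.  Defaults emulate a low-magnification QC scan:
    5 um pixels, 30 um z-step, a bright wall ring and Poisson-placed beads.
    """

    shape_class: str = "planar"
    well_radius_px: int = 40
    gel_footprint_fraction: float = 0.8
    gel_height_um: float = 25.0
    sag_depth_um: float = 20.0
    bead_density: float = 5e-3  # beads per um^3
    pixel_size_um: float = 5.0
    z_step_um: float = 30.0
    n_z: int = 6
    noise: tuple[float, float] = (5.0, 1.0)  # (gaussian_sd, poisson_scale)
    wall_width_px: int = 30
    center_offset_px: tuple[int, int] = (0, 0)
    pad_px: int = 38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_class not in ("planar", "concave", "meniscus", "empty"):
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if not (0.0 < self.gel_footprint_fraction <= 1.0):
            raise ValueError("gel_footprint_fraction must lie in (0, 1]")
        if min(self.well_radius_px, self.pixel_size_um, self.z_step_um,
               self.n_z, self.gel_height_um) <= 0:
            raise ValueError("all sizes must be positive")
        if self.gel_height_um > self.n_z * self.z_step_um:
            raise ValueError("gel taller than the stack extent")

    @property
    def footprint_fraction_effective(self) -> float:
        # a meniscus by definition spans the whole well
        return 1.0 if self.shape_class == "meniscus" else self.gel_footprint_fraction


@dataclass
class GroundTruth:
    """Generator-side truth; only the fields relevant to a generator are set."""

    qc_class: str | None = None
    height_map_um: np.ndarray | None = None
    substrate_mask: np.ndarray | None = None
    covered_fraction: np.ndarray | None = None
    cells: pd.DataFrame | None = None
    labels: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _apply_noise(image: np.ndarray, rng: np.random.Generator,
                 gaussian_sd: float, poisson_scale: float) -> np.ndarray:
    out = np.asarray(image, dtype=float)
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) / poisson_scale) * poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# well phantoms (plate QC and profile extraction)
# ---------------------------------------------------------------------------


def _gel_height_profile(spec: PhantomSpec, r_um: np.ndarray) -> np.ndarray:
    """True gel height (um) versus radius (um) for the spec's shape class."""
    rw_um = spec.well_radius_px * spec.pixel_size_um
    rf_um = spec.footprint_fraction_effective * rw_um
    h = np.zeros_like(r_um)
    inside = r_um <= rf_um
    if spec.shape_class == "empty":
        return h
    if spec.shape_class == "planar":
        h[inside] = spec.gel_height_um
    elif spec.shape_class == "concave":
        sag = np.clip(spec.sag_depth_um, 0.0, spec.gel_height_um)
        h[inside] = spec.gel_height_um - sag * (1.0 - (r_um[inside] / rf_um) ** 2)
    else:  # meniscus: flat interior, climbing to the stack top at the wall
        top = spec.n_z * spec.z_step_um
        rim = 0.7 * rf_um
        h[inside] = spec.gel_height_um
        climb = inside & (r_um > rim)
        frac = (r_um[climb] - rim) / (rf_um - rim)
        h[climb] = spec.gel_height_um + frac * (top - spec.gel_height_um)
    return h


def generate_well_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Two-channel z-stack (wall ring + gel beads) with per-well truth.

    Beads are a Poisson point process inside the gel volume, rendered as
    puncta blurred with a per-slice Gaussian PSF, then Poisson + Gaussian
    noise.  The meniscus class extends the gel slightly past the well
    radius so that wall contact is guaranteed by construction.
    """
    rng = np.random.default_rng(spec.seed)
    size = 2 * (spec.well_radius_px + spec.pad_px)
    oy, ox = spec.center_offset_px
    cy, cx = size / 2 - 0.5 + oy, size / 2 - 0.5 + ox
    yy, xx = np.mgrid[0:size, 0:size]
    r_px = np.hypot(yy - cy, xx - cx)
    r_um = r_px * spec.pixel_size_um

    # wall channel: bright annulus across all slices.  Plastic walls are
    # hundreds of micrometres thick at this magnification and their signal
    # saturates, so the band is wide and sharp-edged (no visible PSF skirt).
    band = (r_px >= spec.well_radius_px) & (r_px < spec.well_radius_px
                                            + spec.wall_width_px)
    wall_plane = np.where(band, 3000.0, 0.0)

    height = _gel_height_profile(spec, r_um)
    if spec.shape_class == "meniscus":
        # guarantee overlap with the wall band
        contact = (r_px >= spec.well_radius_px) & (r_px < spec.well_radius_px + 3)
        height = np.where(contact, spec.n_z * spec.z_step_um, height)

    # Poisson bead placement in the gel volume
    gel = np.zeros((spec.n_z, size, size), dtype=float)
    area_um2 = spec.pixel_size_um ** 2
    lam = spec.bead_density * area_um2 * height  # beads per pixel column
    n_beads = rng.poisson(lam)
    for (y, x) in zip(*np.nonzero(n_beads)):
        for _ in range(n_beads[y, x]):
            z_um = rng.uniform(0.0, height[y, x])
            k = min(int(z_um / spec.z_step_um), spec.n_z - 1)
            gel[k, y, x] += 3500.0
    for k in range(spec.n_z):
        gel[k] = ndi.gaussian_filter(gel[k], _PSF_SIGMA_PX)

    wall = np.broadcast_to(wall_plane, gel.shape).copy()
    g_sd, p_sc = spec.noise
    wall = _apply_noise(wall, rng, g_sd, p_sc)
    gel = _apply_noise(gel, rng, g_sd, p_sc)

    pixels = np.stack([wall, gel], axis=1)  # (Z, C, Y, X)
    stack = ImageStack(pixels=pixels, axes="ZCYX",
                       channel_names=("wall", "gel"),
                       pixel_size_um=spec.pixel_size_um,
                       z_step_um=spec.z_step_um)
    truth = GroundTruth(
        qc_class={"meniscus": "bad"}.get(spec.shape_class, spec.shape_class),
        height_map_um=height,
        params={"spec": spec},
    )
    return stack, truth


def largest_remainder_allocation(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Integer class counts summing to ``n`` by the largest-remainder rule."""
    if n <= 0:
        raise ValueError("n must be positive")
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("composition fractions must sum to 1")
    quotas = {k: n * f for k, f in fractions.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(fractions, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def _well_ids(n: int, n_cols: int = 12):
    for i in range(n):
        yield f"{chr(ord('A') + i // n_cols)}{i % n_cols + 1:02d}"


def generate_plate(n_wells: int, composition: Mapping[str, float], seed: int,
                   base_spec: PhantomSpec | None = None):
    """Synthetic plate: a list of (well_id, ImageStack, GroundTruth).

    Class counts follow the largest-remainder allocation of ``composition``;
    the class-to-well assignment is a seeded shuffle and per-well seeds are
    spawned from the master seed.
    """
    if n_wells <= 0:
        raise ValueError("n_wells must be positive")
    base = base_spec or PhantomSpec()
    counts = largest_remainder_allocation(n_wells, composition)
    # compositions may be phrased in QC labels; "bad" wells are meniscus-shaped
    alias = {"bad": "meniscus"}
    classes = [alias.get(cls, cls) for cls, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(classes)
    children = np.random.SeedSequence(seed).spawn(n_wells)
    plate = []
    for well_id, cls, child in zip(_well_ids(n_wells), classes, children):
        spec = PhantomSpec(**{**vars(base), "shape_class": cls,
                              "seed": int(child.generate_state(1)[0] % 2**31)})
        stack, truth = generate_well_phantom(spec)
        plate.append((well_id, stack, truth))
    return plate


# ---------------------------------------------------------------------------
# confluency growth movies
# ---------------------------------------------------------------------------


def hill_rate(dose: float, r0: float, ic50: float, hill: float) -> float:
    """Per-frame logistic growth rate suppressed by dose through a Hill term."""
    return r0 / (1.0 + (dose / ic50) ** hill) if dose > 0 else r0


def logistic_series(c0: float, rate: float, n_frames: int) -> np.ndarray:
    c = np.empty(n_frames)
    c[0] = c0
    for t in range(1, n_frames):
        c[t] = c[t - 1] + rate * c[t - 1] * (1.0 - c[t - 1])
    return c


def _render_coverage(target: float, shape: tuple[int, int], cell_radius_px: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place textured cell disks until covered area matches ``target`` within 1%."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    n_px = mask.size
    r = cell_radius_px
    for _ in range(20000):
        if mask.sum() / n_px >= target - 0.005:
            break
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        disk_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        grown = mask | disk_mask
        if grown.sum() / n_px <= target + 0.01:
            mask = grown
    # flat bright cell bodies with tight speckle: phase-like frames are
    # near-bimodal, which is what keeps threshold segmentation accurate
    body = np.where(mask, 170.0, 20.0)
    body += np.where(mask, rng.normal(0.0, 4.0, shape), 0.0)
    return np.clip(body, 0, None), mask


def generate_confluency_movie(dose: float, ic50_true: float = 18.0,
                              hill: float = 1.5, r0: float = 0.3,
                              n_frames: int = 9, cell_radius_px: float = 6.0,
                              seed: int = 0, frame_shape: tuple[int, int] = (96, 96),
                              c0: float = 0.05, noise_sd: float = 4.0,
                              time_step_min: float = 360.0,
                              frames_subset: Sequence[int] | None = None
                              ) -> tuple[ImageStack, GroundTruth]:
    """Label-free growth movie at one drug dose.

    Covered-area fraction follows the logistic map
    ``C[t+1] = C[t] + r * C[t] * (1 - C[t])`` with
    ``r = r0 / (1 + (dose / ic50_true)^hill)``; each frame renders bright
    textured disks on a dark background until the rendered coverage matches
    C[t] within one area-percent.  ``frames_subset`` renders only the listed
    frame indices (same truth), for endpoint-only workflows.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if min(ic50_true, r0, hill) <= 0 or dose < 0:
        raise ValueError("rates, ic50 and hill must be positive; dose >= 0")
    rng = np.random.default_rng(seed)
    rate = hill_rate(dose, r0, ic50_true, hill)
    c_true = logistic_series(c0, rate, n_frames)
    idx = list(range(n_frames)) if frames_subset is None else sorted(frames_subset)
    frames = []
    for t in idx:
        img, _ = _render_coverage(c_true[t], frame_shape, cell_radius_px, rng)
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0, None)
        frames.append(img)
    stack = ImageStack(pixels=np.stack(frames), axes="TYX",
                       pixel_size_um=1.0, time_step_min=time_step_min)
    truth = GroundTruth(covered_fraction=c_true,
                        params={"dose": dose, "rate": rate, "ic50": ic50_true,
                                "hill": hill, "r0": r0, "frame_indices": idx})
    return stack, truth


# ---------------------------------------------------------------------------
# FUCCI cell-cycle time-lapse
# ---------------------------------------------------------------------------

PHASES = ("EG1", "G1", "SG2", "T", "M")

# per-phase reporter levels: (cyan, magenta)
_PHASE_LEVELS = {
    "EG1": (0.0, 0.0),
    "G1": (150.0, 0.0),
    "SG2": (0.0, 150.0),
    "T": (150.0, 150.0),
    "M": (0.0, 150.0),
}
_TUBULIN_BASE = 40.0
_MITOTIC_EXCESS = 0.8  # relative tubulin elevation of mitotic nuclei
_NUCLEUS_R = 5
_FRAGMENT_R = 3


def _phase_schedule(durations: Mapping[str, int]) -> list[str]:
    seq = []
    for phase in PHASES:
        seq.extend([phase] * int(durations[phase]))
    return seq


def generate_fucci_timelapse(n_cells: int = 30, n_frames: int = 6,
                             phase_durations: Mapping[str, int] | None = None,
                             mitotic_fraction: float = 0.15,
                             fragment_fraction: float = 0.0,
                             bleedthrough: float = 0.0, seed: int = 0,
                             noise_sd: float = 0.0,
                             pixel_size_um: float = 1.0,
                             drift_px: float = 1.0
                             ) -> tuple[ImageStack, GroundTruth]:
    """Four-channel (actin, tubulin, cyan, magenta) nuclei time-lapse.

    Each cell advances through the cycle EG1 -> G1 -> S/G2 -> T -> M and
    wraps around; reporter intensities follow the phase, mitotic nuclei get
    tubulin elevated by a relative excess of 0.8 over the cytoplasmic base,
    and fragmented cells get a nuclear area below half the population mean.
    The tubulin channel additionally receives ``bleedthrough`` x cyan.
    Truth carries the per-frame label images and a per-detection table.
    """
    if phase_durations is None:
        phase_durations = {"EG1": 2, "G1": 4, "SG2": 6, "T": 2, "M": 2}
    if any(phase_durations[p] <= 0 for p in PHASES):
        raise ValueError("phase durations must be positive")
    if not (0.0 <= mitotic_fraction <= 1.0 and 0.0 <= fragment_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    schedule = _phase_schedule(phase_durations)
    cycle = len(schedule)

    # non-overlapping placement on a jittered grid
    pitch = 4 * _NUCLEUS_R + 4
    n_side = math.ceil(math.sqrt(n_cells))
    size = n_side * pitch + 2 * pitch
    slots = [(i, j) for i in range(n_side) for j in range(n_side)]
    rng.shuffle(slots)
    cells = []
    for cid, (gi, gj) in enumerate(slots[:n_cells]):
        y = pitch + gi * pitch + pitch // 2 + rng.integers(-3, 4)
        x = pitch + gj * pitch + pitch // 2 + rng.integers(-3, 4)
        if rng.random() < mitotic_fraction:
            start = schedule.index("M")
        else:
            non_m = [k for k, p in enumerate(schedule) if p != "M"]
            start = non_m[rng.integers(len(non_m))]
        fragmented = bool(rng.random() < fragment_fraction)
        cells.append({"id": cid + 1, "y": float(y), "x": float(x),
                      "start": start, "fragmented": fragmented})

    yy, xx = np.mgrid[0:size, 0:size]
    frames = np.zeros((n_frames, 4, size, size), dtype=float)
    labels = np.zeros((n_frames, size, size), dtype=np.int32)
    rows = []
    for t in range(n_frames):
        actin = np.zeros((size, size))
        tubulin = np.full((size, size), _TUBULIN_BASE)
        cyan = np.zeros((size, size))
        magenta = np.zeros((size, size))
        for cell in cells:
            cell["y"] += rng.uniform(-drift_px, drift_px)
            cell["x"] += rng.uniform(-drift_px, drift_px)
            phase = schedule[(cell["start"] + t) % cycle]
            r_nuc = _FRAGMENT_R if cell["fragmented"] else _NUCLEUS_R
            d2 = (yy - cell["y"]) ** 2 + (xx - cell["x"]) ** 2
            nucleus = d2 <= r_nuc**2
            body = d2 <= (2 * _NUCLEUS_R) ** 2
            actin[body] += 60.0
            c_lvl, m_lvl = _PHASE_LEVELS[phase]
            cyan[nucleus] += c_lvl
            magenta[nucleus] += m_lvl
            mitotic = phase == "M"
            if mitotic:
                tubulin[nucleus] = _TUBULIN_BASE * (1.0 + _MITOTIC_EXCESS)
            labels[t][nucleus] = cell["id"]
            rows.append({"frame": t, "label_id": cell["id"], "track_id": cell["id"],
                         "y": cell["y"], "x": cell["x"],
                         "area_px": int(nucleus.sum()), "phase": phase,
                         "mitotic": mitotic, "fragmented": cell["fragmented"]})
        tubulin = tubulin + bleedthrough * cyan
        chans = np.stack([actin, tubulin, cyan, magenta])
        if noise_sd > 0:
            chans = np.clip(chans + rng.normal(0, noise_sd, chans.shape), 0, None)
        frames[t] = chans
    stack = ImageStack(pixels=frames, axes="TCYX",
                       channel_names=("actin", "tubulin", "cyan", "magenta"),
                       pixel_size_um=pixel_size_um)
    truth = GroundTruth(cells=pd.DataFrame(rows), labels=labels,
                        params={"bleedthrough": bleedthrough,
                                "mitotic_excess": _MITOTIC_EXCESS,
                                "tubulin_base": _TUBULIN_BASE,
                                "phase_durations": dict(phase_durations)})
    return stack, truth


# ---------------------------------------------------------------------------
# dry-profilometry height maps
# ---------------------------------------------------------------------------


def generate_dry_height_map(profile: Callable[[np.ndarray], np.ndarray] | None,
                            background_poly2: Sequence[float] = (0, 0, 0, 0, 0, 0),
                            noise_sd: float = 0.0, seed: int = 0,
                            shape: tuple[int, int] = (96, 96),
                            pixel_size_um: float = 10.0,
                            footprint_radius_um: float = 300.0
                            ) -> tuple[np.ndarray, GroundTruth]:
    """Profilometer-style height map: revolved gel profile + quadratic background.

    ``profile`` maps radius (um) to gel height (um); ``None`` means no gel.
    ``background_poly2`` are the coefficients (a, b, c, d, e, f) of
    a + b*x + c*y + d*x^2 + e*x*y + f*y^2 in pixel coordinates relative to
    the map center.  The substrate mask in the truth marks gel-free pixels.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - (h - 1) / 2.0
    x = xx - (w - 1) / 2.0
    r_um = np.hypot(y, x) * pixel_size_um
    gel = profile(r_um) if profile is not None else np.zeros(shape)
    gel = np.clip(np.asarray(gel, dtype=float), 0.0, None)
    a, b, c, d, e, f = background_poly2
    bg = a + b * x + c * y + d * x**2 + e * x * y + f * y**2
    heights = gel + bg
    if noise_sd > 0:
        heights = heights + rng.normal(0.0, noise_sd, shape)
    substrate = r_um > footprint_radius_um
    truth = GroundTruth(height_map_um=gel, substrate_mask=substrate,
                        params={"background_poly2": tuple(background_poly2),
                                "noise_sd": noise_sd})
    return heights, truth
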