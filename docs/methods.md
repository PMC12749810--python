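# Methods

## Quasi-static meniscus model

The dispensing/re-aspiration of hydrogel precursor in a cylindrical well is
modelled as a sequence of capillary equilibria: at every volume the
air–liquid interface satisfies the axisymmetric Young–Laplace equation

    σ · 2H(r) = Δp₀ − ρ g z(r)

with σ the surface tension, ρ the density, g gravity and 2H the mean
curvature. This replaces transient two-phase flow with its quasi-static
limit; the approximation is appropriate because the reported metrics
(coverage, flatness) are evaluated on near-final configurations, and its
cost is discussed under *Limitations*. Flow-rate and viscosity effects are
outside the model (viscosity is carried as metadata only).

Two interface families are solved by shooting:

* **Pinned sessile cap.** The profile is integrated from the apex in arc
  length, `dφ/ds = b + (ρg/σ)·u − sinφ/r`, with `b` the apex curvature;
  `b` is bisected until the enclosed volume matches the target within 0.1%.
  Only graph-representable caps (apparent angle ≤ 90°) are supported — the
  protocol state machine never needs more, because advancing contact angles
  are below 90°. With gravity off the solution reduces to a spherical cap
  and is verified against the closed form V = (πh/6)(3rc² + h²),
  h = rc·tan(θ/2) to 0.5% over θ ∈ (5°, 90°).
* **Wall-wetted meniscus.** The surface spans the whole well, meets the
  sidewall at the prescribed contact angle θ_wall and is flat at the axis.
  A shift symmetry (z → z + Δ, λ → λ − cΔ) makes the slope profile unique
  and volume-independent; the volume only sets the vertical offset, so the
  meniscus flatness is a property of (σ, ρ, θ_wall, R_w) alone.

**Hysteresis state machine.** Dispensing inflates a pinned cap until the
apparent angle reaches θ_advancing, then the contact line advances at that
angle; if it reaches the well radius the state switches (irreversibly for
the protocol) to the wall meniscus. Aspiration deflates the pinned cap until
θ_receding, then the line recedes at θ_receding. Aspiration from the wall
regime lowers the surface until the wall configuration becomes infeasible
(the center would touch the bottom), then re-pins the contact line at the
rim — a simplification of the physical dewetting transition, adequate
because the protocols of interest never aspirate from a wall-wetted state.

**Metrics.** Coverage = 100·r_contact/R_w. Flatness = the percentage of the
well radius over which |dz/dr| ≤ tan 3° (the 90° ± 3° planarity rule),
measured as radial projection; for near-flat regions this differs from arc
length by < tan²3° ≈ 0.3%. The planar extent of a cap can never exceed its
footprint, so flatness ≤ coverage for cap-type profiles.

**Default parameters** (all configurable):

| parameter | default | rationale |
|---|---|---|
| R_w, H_w | 3.2 mm, 11 mm | typical 96-well geometry |
| ρ | 1000 kg m⁻³ | aqueous precursor |
| σ | 0.05 N m⁻¹ | gelatin lowers water's 0.072 N m⁻¹ |
| θ_wall | 60° | partial wetting of polystyrene |
| θ_advancing | 50° | calibrated so the model reproduces the documented dispensing ladder: 24 µL reaches the wall, 18 µL only under plate-tolerance perturbations (−100/−200 µm radius, ±20% volume), 12 µL never |
| θ_receding | 2° | gelatin adsorbs at the contact line and pins strongly; a receding angle below the final film's apparent angle (~3°) is the only regime in which re-aspiration leaves the footprint intact, which is the method's defining observation |
| residual film thickness | 30 µm | matches the hydrated thickness ceiling of robot-cast gels; sets the default residual volume as π·r_footprint²·30 µm |

With these defaults the wall meniscus covers 100% of the well at 13.3%
flatness, and the 12 µL protocol yields 79.6% coverage (20.4% reduction)
with the residual film planar over essentially its whole footprint.

**Numerics.** RK45 integration at rtol 1e-10; Δp₀/apex-curvature bisection
to 1e-12 relative; profiles returned on ≥ 400 radial samples (s-uniform, so
points concentrate near steep rims and the solid-of-revolution volume closes
within 0.1%). Protocol trajectories are sampled every 1% of the largest
step by default; the trajectory interpolates two cached one-parameter
families per configuration (volume↔footprint at fixed angle, volume↔angle at
fixed footprint), each a sweep of ~90 apex curvatures with monotone (PCHIP)
interpolation.

## Synthetic data

The generators produce every input the imaging pipelines consume, with
ground truth, from a single seed (bit-identical reruns). They aim at
*analytical* realism — intensities, shapes and noise rich enough to stress
thresholds and morphology — not photorealism; passing tests demonstrate
correct pipeline logic on controlled inputs, not performance on real
microscopy.

* **Well phantoms.** A bright, sharp-edged wall annulus (plastic walls are
  hundreds of µm thick at low magnification and their signal saturates)
  plus Poisson-placed beads inside the gel volume (flat slab, central
  parabolic sag, or a wall-climbing meniscus), blurred with a per-slice
  Gaussian PSF (σ = 1.2 px; QC uses max projections, so no 3D PSF), then
  Poisson + Gaussian noise (read noise SD 5 on the 16-bit-like scale). The
  default bead density (5×10⁻³ µm⁻³) makes a planar gel's projection
  spatially continuous — a planar gel with a patchy projection would be
  concave by the fill-fraction definition — while a sagging center thins
  the bead column enough to read patchy.
* **Growth movies.** Covered-area fraction follows the logistic map
  C[t+1] = C[t] + r·C[t]·(1−C[t]) with r = r0 / (1 + (dose/IC50)^hill).
  Defaults: C₀ = 0.05, r0 = 0.3 per frame, 9 frames at 6 h spacing (a 48 h
  assay sampled six-hourly for runtime), IC50 = 18, hill = 1.5 — the
  vehicle ends near 32% coverage, the working range of threshold-based
  confluency (frames above 30% are flagged for review, mirroring practice).
  Frames render flat bright disks (radius 6 px) with tight speckle on a
  dark background; the near-bimodal histogram is what keeps triangle
  thresholding accurate to ≤ 2 area-percent per frame.
* **Dose–response experiments** use a denser seeding (C₀ = 0.30,
  r0 = 0.2/frame). For compounded logistic growth the midpoint of the
  endpoint-response curve lies below the rate-level IC50 (the r→endpoint
  map is convex), while saturation bends it the other way; at these
  conditions the two nearly cancel (noiseless response-level IC50 17.3 vs
  rate-level 18), so a 4-parameter-logistic fit of normalized endpoints
  recovers the generator's IC50. This is a property of the assay design,
  verified on the noiseless generating equations.
* **FUCCI time-lapses.** Each cell advances through
  EG1 → G1 → S/G2 → T → M and wraps; reporter levels per phase are
  (cyan, magenta) = (0,0), (150,0), (0,150), (150,150), (0,150); mitotic
  nuclei get tubulin elevated by a relative excess of 0.8 over the uniform
  cytoplasmic base (40), comfortably above both substrate thresholds;
  fragmented cells get radius 3 px versus 5 px (area < 0.5× the mean);
  bleed-through adds a fixed linear fraction of cyan to the tubulin
  channel, matching the linear correction in the analysis. Cells sit on a
  jittered grid with ±1 px drift, so nuclei never overlap and truth labels
  are exact.
* **Dry height maps.** A revolved radial gel profile plus a full quadratic
  surface (a + bx + cy + dx² + exy + fy²) and Gaussian noise, with the
  substrate region flagged.

## Image pipelines: choices that were genuinely open

* **Auto-thresholds** are computed on 256-bin histograms over each image's
  own min–max range, making every downstream mask invariant to global
  intensity scaling. Isodata iterates t ← ⌊(μ_below + μ_above)/2⌋ from the
  mid-intensity start (ties break downward); triangle maximizes the
  perpendicular distance to the peak→far-tail chord on the longer-tail
  side. Both are verified against exhaustive searches.
* **Binary morphology is edge-safe**: erosion steps treat the region
  outside the image as foreground, because plain zero-padded closing
  shaves a one-pixel frame off any border-touching structure (a confluent
  field loses its entire rim, ~6% of a 64² frame).
* **Confluency open/close uses the 3×3 neighbourhood** (the classic ImageJ
  default); radius-2 disks amplify noise holes and erode merged-cell
  boundaries, biasing dense fields by several area-percent. The QC chain
  keeps radius-2 disks, with the outlier-removal step implemented as
  bright-outlier removal (a set pixel is cleared when the local median in a
  radius-10 disk is background): structures wider than the radius survive,
  specks do not.
* **The planar/concave fill score** (gamma 2, isodata, closing, mean of the
  0/255 binary ≥ 250) is measured over the footprint *interior* (footprint
  eroded by a 3 px disk). Scored over the full footprint, the PSF-blur rim
  of the footprint mask always fails the gamma-2 threshold and caps planar
  wells near 240, making the 250 cutoff unreachable for any input.
* **Heights** use the exclusive convention (last − first detected slice) ×
  z-step, so a single-slice signal reads zero; `inclusive=True` adds one
  slice. Otsu is computed on the global stack histogram to avoid slice-wise
  threshold drift (per-slice mode available). On planar phantoms the median
  height lands exactly one z-step below truth — the convention's intrinsic
  bias, within the one-z-step resolution limit.
* **Trace smoothing** is a centered moving average with a shrink-to-valid
  window at the edges (window 4 by default); normalization divides by the
  initial smoothed value. Frames above 30% confluency are flagged
  `review`, never auto-corrected.
* **Dose 0** is placed half a decade below the smallest nonzero dose on
  the log axis for fitting; IC50 confidence intervals come from a seeded
  residual bootstrap (200 refits).
* **Nucleus segmentation is pluggable**: every classification function
  takes a label image, and the built-in segmenter (denoise + isodata +
  watershed) is a simple default, not a learned model. Mitosis uses
  relative tubulin excess ((nucleus − background)/background) against the
  cytoplasmic median in a 5 px annulus; an absolute-excess mode exists.
  The fragmentation rule (area < control mean) is implemented literally
  with the fraction exposed, because the literal rule would discard half
  of any symmetric population and is only meaningful for treated groups.
* **Track linking** is greedy nearest-neighbour with gap closing (50 µm,
  3 frames), deterministic with ties broken by smaller label id. Division
  linking is out of scope; tracks terminate at division.

## Limitations

* The quasi-static model has no dynamics: film deposition during fast
  aspiration, inertial and viscous effects, and the rim left by a moving
  contact line are all absent. The clearest consequence is the flatness
  fold change of the thin-layer protocol: a 30 µm equilibrium film over a
  2.55 mm footprint is planar over essentially its whole footprint
  (apparent angle ≈ 3°), so the fold over the meniscus comes out ≈ 6,
  whereas a transient simulation that retains a non-equilibrium rim reports
  ≈ 4.5. Coverage-type quantities are insensitive to this and agree.
* Wetting parameters are material properties that were not available;
  the defaults are calibrated to the documented qualitative dispensing
  ladder, not measured. All are exposed.
* Caps beyond 90° apparent angle (bulging drops) are not representable.
* The generators do not emulate holographic speckle, optical sectioning or
  realistic nuclear texture; accuracy numbers on phantoms bound pipeline
  logic, not real-data performance.
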