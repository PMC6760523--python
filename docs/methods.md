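# Methods

## Acquisition-chain model

The camera model treats a pixel's expected photoelectron count as
S = γ·δ²·QE·t (flux γ in photons·µm⁻²·s⁻¹, pixel size δ, quantum
efficiency QE, exposure t) and the total noise as the quadrature sum
√(σ_camera² + S) of a signal-independent camera term and Poisson shot
noise √S. The dark-noise temperature dependence and read-noise exposure
dependence are collapsed into one configured σ_camera (default
3.30 e⁻); temperature and exposure dependence of the noise floor are
not modelled. Defaults describe the reference instrument: QE 0.79,
δ = 2.4 µm, 4×4 binning, 16-bit output at unit conversion gain, a field
of view of 818 × 547 µm imaged on 1368 × 912 px (object-space pixel
area ≈ 0.3586 µm²).

The noise-equivalent photon floor solves S = √(σ_camera² + S) in
closed form, S = (1 + √(1 + 4σ_camera²))/2, then divides by QE. With
the defaults this gives 4.858 photons; agreement with the instrument's
stated 4.83 is expected only to ~1% because the published QE is a
rounded figure (QE ≈ 0.794 reproduces 4.83 exactly). The implementation
does not force closer agreement.

Size gates convert a minimum diameter d to a strict pixel-area
threshold round(π(d/2)²/A), A being the product of the x and y
object-space pixel pitches, rounding half away from zero; this
convention reproduces both instrument gates (107 px at 7 µm, 14 px at
2.5 µm). Quantization divides electrons by the conversion gain
(default 1 e⁻/DN), rounds, and clips to [0, 2^bits − 1].

## Synthetic membranes and the virtual microscope

`make_scene` places three phenotype populations uniformly at random on
a rectangular membrane region (default one field of view), insetting
centres by one radius + 2 µm from the border and optionally enforcing a
minimum pairwise separation by rejection sampling (bounded retries;
infeasible packings raise). Phenotype emission is consistent by
construction — CTCs emit blue/green/orange and are dark in red, WBCs
blue/red, other nucleated cells blue only — and checked again at cell
construction.

Default study conditions:

* **Diameters** (uniform): CTC 8–14 µm, WBC 6–12 µm, other nucleated
  cells 4–9 µm. CTCs sit above the 7 µm classification gate by design
  of the assay; the 4 µm lower bound for the smallest population keeps
  thresholded areas clear of the 14 px gate (see *Area fidelity*
  below) and corresponds to the smallest nucleated objects retained by
  the membrane.
* **Exposures**: blue 50 ms, green 100 ms, orange 1500 ms, red 100 ms
  (the four-color assay settings).
* **Brightness**: per-channel nominal peak fluxes chosen to deposit
  ≈1.5×10³ photoelectrons per pixel at those exposures, with a uniform
  ×0.7–1.5 cell-to-cell factor; background flux deposits ≈15 e⁻ per
  pixel. These are artifact choices — the assay publishes no intensity
  distributions — selected to give bright-but-unsaturated cells at
  realistic SNR.
* **Noise**: photoelectrons are drawn Poisson with mean S (shot
  variance exactly S, equivalent to thinning the photon Poisson process
  by QE), plus Gaussian camera noise of σ_camera electrons, then
  quantized. `noise=False` renders the deterministic mean image.

Each cell is a uniform disc of its physical diameter convolved with an
isotropic Gaussian PSF whose σ grows linearly with defocus:
σ(z) = σ₀ + s·|z_stage − z_cell|, default σ₀ = 0.3 µm (the diffraction
scale of a 20×/NA 0.4 objective) and s = 0.25 µm of blur per µm of
defocus. The convolution is evaluated exactly through the
noncentral-χ²(2) CDF — the value at radius r is the probability that a
2-D Gaussian displacement lands inside the disc — tabulated radially
and interpolated. Consequences used by the tests: total flux is
conserved under defocus (blur redistributes light), the peak amplitude
strictly decreases with defocus (the property the brightness autofocus
relies on), and each pixel's noise-free value is a pure function of its
global sample-plane coordinate, so pixel-aligned tilings reproduce the
whole-scene render bit for bit.

**Area fidelity.** The pipeline measures a cell as the pixels of its
thresholded mask, so the measured area is the iso-contour of the
blurred disc at the Otsu threshold. For a dim cell the threshold can
sit at ~0.7 of its plateau, shrinking the measured radius by ~15%, and
a 3×3 median erodes another 1–2 edge pixels. The generator therefore
keeps its smallest population at 4 µm nominal (≈35 px), so measured
areas stay comfortably above the 14 px gate; a population straddling a
gate would make exact recovery impossible by construction, which is a
property of strict size gating, not of the implementation.

Coordinates: sample-frame positions are µm, origin top-left, y
downward; pixel indices are 0-based; a tile's pixel (0,0) centre sits
half a pixel inside the tile's top-left corner. Stage coordinates
address the centre of the field of view, so a cell at the stage
position images at the frame centre. Stage jitter is modelled as a
Gaussian displacement of the realized position (σ defaulting to the
stated 2.2 µm bi-directional repeatability when enabled); within one
mapped tile all channels share a single realized displacement, since
the stage settles once per tile. All randomness derives from explicit
seeds; repeated acquisitions at the same position with the same
configuration are identical.

What the simulator does *not* emulate: channel crosstalk/bleed-through,
optical aberrations and field-dependent PSFs, photobleaching, membrane
pore texture, autofluorescent debris, and cell-shape irregularity.
Passing recovery tests therefore demonstrate the pipeline's correctness
under its own model assumptions, not its performance on real membrane
images.

## Classification pipeline

Stages per field of view: median filter (default 3×3) → window/level →
per-phenotype mask (Σ required − Σ excluded channels, widened int64
arithmetic saturated to the dtype range) → from-scratch Otsu threshold
(between-class-variance maximization over the histogram; ties to the
smallest threshold; constant images flagged non-separable) →
8-connected components (area = pixel count, centroid = pixel-centre
mean, border components kept) → strict area gate → channel-coincidence
check → priority assignment.

**Window/level.** The stretch maps the low-percentile anchor to 0 and
the high-percentile anchor to the dtype maximum, linearly in between.
Defaults are (1, 100): the low anchor subtracts the background
pedestal; the high anchor is the image maximum, so the stretch is a
harmless monotone rescaling. An interior high anchor (e.g. 99.5) is
deliberately avoided as a default: in a channel whose foreground covers
less than the clipped tail — five CTCs occupy ~0.05% of a full field —
both anchors fall inside the background noise band and the stretch
maps noise across the full dynamic range, destroying Otsu
separability. Both percentiles remain configurable.

**Stretch guard.** Even with a (1, 100) window, a channel with *no*
emitters at all would have its noise band stretched to full scale
(maximum ≈ background + 5σ), and subtracting such a channel in the mask
arithmetic wipes out genuine signal. The preprocessing therefore
stretches a channel only when its upper window half exceeds
`stretch_guard_ratio` (default 10) times its lower half — a scale-free
signal-presence test; otherwise only the pedestal is subtracted. The
same flag feeds classification: a rule whose required channel carries
no signal in the snap can match nothing, and an excluded channel
without signal excludes nothing. The guard assumes foreground occupies
well under half the field; a membrane tiled majority with bright cells
would defeat it (known limitation).

**Coincidence check.** Mask arithmetic admits a pixel that is merely
very bright in one required channel, so each surviving component must
additionally show mean intensity above the per-channel Otsu threshold
in every required channel and at or below it in every excluded one —
classification by appearance channel, brightness and size. Components
claimed by a higher-priority rule (CTC first) are excluded from later
rules by centroid containment.

Known, asserted-not-fixed behaviours: two cells closer than about one
radius merge into a single contour and count once (the documented
undercount mode of contour-based counting); cells straddling a tile
seam may count in both tiles (detections are per-snap; no cross-seam
merging).

## Autofocus

Brightness metric: maximum pixel value after a 3×3 median (hot-pixel
rejection); invariant to surrounding dark area; a saturated frame
raises a warning since a clipped peak cannot discriminate focus.
Contrast metric: normalized variance, var/mean. The search takes
`n_coarse` (default 15) equidistant frames across the configured Z
range, then `n_fine` (default 7) frames over ± one coarse step (or a
configured half-width) around the optimum, returning the argmax over
all acquisitions with ties to the lowest z; exactly n_coarse + n_fine
acquisitions are issued.

Because the cell model is a flat-core disc, sub-pixel blur barely moves
the peak: brightness discriminates defocus at the step scale only for
cells whose radius is within a few blur widths (≲6 µm at the default
optics). The brightness-vs-contrast comparison concerns *almost-empty,
dim* fields — one faint cell whose variance contribution is below the
sampling error of the background variance estimate; there the contrast
metric degenerates to noise-chasing while the brightness metric still
locks onto the cell. With bright cells or dense fields both metrics
perform comparably (and contrast can be sharper near focus). The tests
probe exactly these regimes.

## Mapping and stitching

The grid planner covers the requested extent with the smallest number
of abutting full fields of view (ceil per axis), serpentine traversal
by default (minimizes stage travel; order does not affect results).
Stitching is pure placement at (row·H, col·W) — no overlap, no
registration, no blending — relying on stage repeatability, with a
configurable missing-tile policy (error or zero-fill). The panorama's
pixel dimensions equal (cols·tile_w, rows·tile_h) exactly.

## Problem sizes and numerical choices

The test suite exercises full-FOV scenes (1368 × 912 px) for count
recovery — 20 seeded scenes of 5 CTC / 100 WBC / 200 other cells with
15 µm minimum separation (above the largest possible radius sum),
noise-free and with the full noise model — and quarter-FOV geometry
(256 × 170 px at the same pixel pitch) for pipeline, autofocus, and
stitching unit tests; the sparse-autofocus comparison uses a half-FOV
field so a single dim cell's variance contribution sits below the
background-variance sampling error. Otsu runs over the full integer
histogram (65536 bins at 16 bit). Radial PSF profiles are tabulated at
512 points out to R + 6σ (truncated mass < 10⁻⁶) and linearly
interpolated. Rounding of electron values to digital numbers follows
numpy's round-half-to-even.
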