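# Methods

This note records the models, conventions and numerical choices behind
`densestrain`, in the order the pipeline applies them, together with what
the synthetic validation does and does not establish.

## Observable and coordinate conventions

A DENSE acquisition of one aortic cross-section yields N_t cine frames
(default 18, one every 32 ms after the ECG trigger) of three images:
magnitude, x-phase and y-phase. The phase of a wall voxel observed at
position p in frame t stores the in-plane displacement of the tissue
currently at p, measured from the reference configuration at the time of
encoding (frame 1):

    φ_i = wrap(2π k_e d_i),   i = x, y,

with k_e the encoding frequency in cyc/mm (defaults honour the acquisition
range 0.17–0.25 cyc/mm; 0.25 is the package default) and wrap(·) the
restriction to (−π, π], boundary mapped to +π so that encode/decode tests
are bit-exact.

All positions are in mm. Arrays are indexed [frame, row, col]; the voxel
centre of (row, col) is ((col+0.5)·Δ, (row+0.5)·Δ). The x axis is
left-lateral and y anterior in the standard transverse display, so the
displacement angle convention (0° left-lateral, +90° anterior, range
(−180°, 180°]) falls out of atan2(u_y, u_x). Counterclockwise means
increasing angle in this frame; oblique distal-arch sections are treated
in their own in-plane frame with the AVI angle supplied by the caller.
Frames are 1-based in all user-facing indices.

## Phase unwrapping and its 2π anchor

Unwrapping is restricted to the wall mask (voxel centres strictly inside
the adventitial polygon and not strictly inside the luminal one, so
contour points count as wall — this matches the ≥ 2-voxel wall-thickness
requirement of the strain calculation). A quality-guided flood fill grows
from the highest-magnitude masked pixel, always expanding the
highest-quality frontier pixel, adding the 2π multiple that removes any
neighbour jump above π. Disconnected mask components are unwrapped
independently with a logged warning.

Spatial unwrapping fixes phase only up to a per-component multiple of 2π.
The pipeline resolves it temporally: frame 1 is anchored at zero mean
phase (it *is* the encoding reference, so its true phase is zero) and
frame t at frame t−1's mean unwrapped phase. This is valid whenever the
bulk phase change between consecutive frames stays below π — comfortably
true at 32 ms spacing for aortic motion, where even the largest observed
bulk displacements (~4.4 mm over the whole systole at k_e = 0.25 cyc/mm)
accrue phase over many frames. Displacements beyond ±2 cycles of phase
(|d| > 2/(2k_e)) are double-wrapped and unrecoverable; the synthetic
generator flags such configurations instead of pretending to invert them.

## Tracking

Each frame-t observation (p, d_t) is back-projected to its implied
reference origin p − d_t. The forward displacement of each frame-1 wall
voxel X₁ is the inverse-distance-weighted mean of the d_t of the 3 closest
origins (ties in distance broken by voxel scan order; an origin within
1e-9 mm of X₁ supplies its value alone). u₁ ≡ 0 by construction.

IDW over 3 neighbours reproduces constants exactly but not general affine
fields; its first-order error is the displacement gradient applied to the
weighted centroid offset of the neighbours. Two practical consequences,
both measured in the test suite: (i) recovered trajectories are accurate
to well under 0.1 voxel at physiological stretches; (ii) at the wall's
outer edge the origin cloud contracts by 1/λ, so edge voxels extrapolate
one-sidedly, with sector-strain error growing from < 0.005 at ≤ 10% mean
stretch to ~0.02 at 15% on 1.0 mm voxels. Whether the 3-neighbour search
is joint over both phase channels or per channel is not observable from
the method description; it is implemented jointly (one neighbour set for
both components).

## Noise reduction

Three linear operators, in pipeline order:

* **Spatial smoothing** of the back-displacement vectors: unweighted mean
  over wall voxels within Chebyshev radius 1 voxel-space (2 for the IAA,
  where signal is poorest); non-wall neighbours never enter the average.
* **Temporal smoothing** of tracked positions: centred moving average,
  window 3 frames (configurable and recorded in output metadata, since
  the exact operator used in practice — moving average, spline or
  polynomial — is not recoverable from the method description). Edges are
  truncated rather than padded: fabricating pre-trigger data would bias
  u near frame 1. Frame 1 itself is pinned back to the measured reference
  positions so u₁ = 0 exactly; subtracting the frame-1 smoothed offset
  from *all* frames instead would shift every displacement down by half
  the frame-2 displacement and systematically underestimate strain by
  ~2.5% of peak.
* **Polynomial smoothing** of each sector's circumferential strain
  time-course: ordinary least-squares degree-5 fit over the frame index
  (refused below 7 frames, where it would interpolate rather than
  smooth). Together with the moving average this attenuates the strain
  peak of a raised-cosine pulse by ~4% — a deliberate bias-for-variance
  trade that the validation numbers account for explicitly.

## Sector elements and Green strain

Sixteen equal angular sectors are defined about the frame-1 mid-wall
centroid, boundaries anchored at the aorto-vertebral interface angle:
sector 1 spans the first 22.5° counterclockwise from the AVI and a point
exactly on a boundary belongs to the clockwise sector. Sector identity
follows material (reference) points — strain is referential, so no
deformed-frame re-binning is done.

Within each sector, tracked voxels are pooled into quadrants by median
reference radius (inner/outer) and by side of the sector bisector
(clockwise/counterclockwise). Quadrant means of the reference positions
form the four element nodes (reference point averaging); each node moves
with the mean trajectory of its voxels (spatial averaging with weights
implicit in voxel counts). With bilinear shape functions N_a(ξ, η) on
[−1, 1]², the referential displacement gradient at the element centre is
H = (Σ_a u_a ∇N_aᵀ) J⁻¹ — centre evaluation being the standard symmetric
single-point rule — and

    E = ½ (H + Hᵀ + Hᵀ H),

the Green–Lagrange tensor, which is exactly zero under rigid motion and
exactly reproduced for affine displacement fields regardless of element
shape. The gradient is taken with respect to reference coordinates
(recorded in the output conventions block). E is rotated into
radial–circumferential axes using the local wall tangent, estimated as
the central difference of adjacent element centres along the wall (falling
back to the geometric tangent where a neighbour is invalid); trace and
determinant are preserved to 1e-12.

Sectors with fewer than 4 usable voxels, an empty quadrant, or a
near-degenerate Jacobian (condition number > 1e6) are flagged invalid and
carried as NaN; a map needs at least 12 of 16 valid sectors, below which
the scan is rejected outright — but unlike a discard-the-scan policy,
partial maps remain usable and every summary records n_valid. The full
rotated tensor (E_rr, E_rθ, E_θθ) is retained per sector and frame for
future radial/shear analyses, though only the circumferential component
is a deliverable metric: the thin wall makes radial and shear components
markedly less reliable.

## Summary metrics

* **Local systole**: frame of maximal mean circumferential strain (ties →
  earliest). For the distal aortic arch, where some sectors peak in local
  diastole, systole is instead the half-up-rounded mean peaking frame of
  the six sectors that peak earliest after the onset of local systole;
  onset is operationalized as the mean strain first exceeding 10% of its
  eventual maximum (the threshold is configurable and logged, since
  "beginning of local systole" admits no unique definition).
* **NCS**: sector strain at systole over the cross-sectional mean at
  systole; mean NCS ≡ 1 to machine precision, which is also why the
  reproducibility CoV uses 1 as its denominator. The maximum NCS searches
  all sectors *and all frames* (the overall peak may fall in local
  diastole, clinically meaningful in hypertension).
* **Heterogeneity index**: sample SD (n−1; n = 16 is small and the
  convention is recorded) of the sector strains at systole over their
  mean; zero for homogeneous deformation and invariant under strain
  scaling.
* **Mean displacement angle** at systole, with magnitude; vanishing mean
  displacement yields a flagged undefined angle rather than an exception.
* **Distal-arch alignment**: oblique arch sections are non-parallel
  between subjects, so a map may be rotated by ±1 sector to maximize
  Pearson correlation with a caller-supplied reference map (a library
  cannot presume a cohort); ties prefer no rotation.
* **Diastolic geometry**: the mid-wall contour's x- and y-extents at
  frame 1, averaged, in cm; relative size divides by body surface area.
  The mid-wall radius is found by angular interpolation about the
  centroid, valid for star-shaped (non-pathological) cross-sections.

## Reproducibility metrics

Differences between two NCS maps of one scan are summarized by the mean
|ΔNCS|, the CoV (sample SD of the signed ΔNCS divided by the mean NCS,
fixed at 1 by construction), and the same two metrics restricted to the
two largest local maxima and two smallest local minima of the circular
16-vector (strict inequality against both neighbours; an equal-valued
plateau bounded by strictly lower/higher values counts once at its lowest
sector index — no plateau rule is canonical, so one is fixed and
documented). Extrema of map A are paired with the nearest same-type
extremum of map B by circular sector distance (pairing by proximity
rather than rank; the test suite avoids cases where the two differ), and
the mean circular distance of the pairs is reported. CoV bands: good
≤ 0.20, fair 0.21–0.30, poor > 0.30, boundaries read as printed.
Three-way comparisons (one reader against two analyses by another) are a
convenience wrapper averaging two pairwise reports.

## Synthetic data: what it emulates, what it does not

The generator renders the observable of an aortic DENSE scan — bright
annular wall over dark lumen/background, wrapped displacement-encoded
phases, deformed contours — from the invertible motion model

    x(X, t) = c + b_max p(t) + λ(Θ, t) (X − c),
    λ(Θ, t) = 1 + A_max p(t) (1 + h cos(Θ − Θ_peak)) / (1 + h),

with p(t) a raised-cosine pulse rising to 1 at the peak frame (default 8
of 18) and decaying to 0 at the last frame. This family was chosen
because its Green strain has a closed form in the homogeneous case
(E_θθ = (λ²−1)/2) and a cheap finite-difference oracle otherwise (central
differences of the map at 5 µm steps at each sector's mid-wall point, the
arbiter for all strain-recovery tests; for the heterogeneous case note
E_θθ = (λ² + λ′² − 1)/2, the oracle capturing the λ′ term automatically).
Noise is injected in phase (radians), where acquisition noise lives, not
in displacement; magnitude noise shares the same seeded generator.
Defaults are chosen to mirror the imaging conditions: 18 frames at 32 ms,
k_e = 0.25 cyc/mm, 1.0 mm voxels, annulus radii 7.5/11.5 mm (≈1.9 cm
diameter, 4-voxel wall), A_max = 0.1 (≈0.10 mean systolic strain),
b_max = (2, 1) mm (≈2.2 mm bulk motion), contours sampled at 256
points/frame so the polygon–annulus discrepancy (sagitta < 1 µm) cannot
flip boundary voxels. No phase-noise magnitude is reported for in-vivo
scans; the default 0.05 rad is a free parameter stated with every
validation run.

Passing tests on this phantom establish that the chain inverts its own
encoding exactly, recovers analytically known strain to the documented
tolerances, localizes circumferential heterogeneity to the correct
sector, and is frame-invariant. They do not establish robustness to what
the phantom omits: stimulated-echo signal decay and T1 recovery, spiral
k-space artifacts, through-plane motion and partial-volume contamination
from neighbouring structures, segmentation error (contours are exact
here; in practice they are manual and are the dominant reproducibility
limit), or non-star-shaped pathological geometries.

## Numerical choices and degenerate inputs

* wrap to (−π, π] with the boundary at +π, everywhere.
* Polynomial fits use numpy's scaled-domain `Polynomial.fit` for
  conditioning; degree-≤5 inputs are reproduced to < 1e-10.
* Ties: equal-quality unwrap seeds and equal tracking distances resolve
  by scan order; equal systolic maxima by the earlier frame; equal
  alignment correlations by no rotation, then the smaller |rotation|;
  plateau extrema by the lowest sector index. All deterministic.
* Identical seeds give bit-identical synthetic renders.
* Empty masks, < 3 tracking entries, degenerate elements, < 12 valid
  sectors, zero-strain normalization and un-normalized comparison inputs
  all raise typed errors naming the frame/sector/field; vanishing mean
  displacement and constant alignment maps return flags instead, since
  both are legitimate (if uninformative) measurements.

## Validation problem sizes

The shipped validation (test suite and `scripts/acceptance.py`) runs on
64×64-voxel, 18-frame scans (~250–300 wall voxels per frame), 20 noise
seeds for the stochastic recovery checks and 100 seeds for the
Monte-Carlo smoothing/unwrapping properties — sizes at which every
analytic comparison above is already sharp and the whole battery
completes in seconds on one CPU.
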