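# densestrain

Regional circumferential strain mapping of the aortic wall from cine DENSE
(Displacement ENcoding with Stimulated Echoes) cardiovascular MR.

Aortic disease — aneurysm, dissection, rupture — is focal: it strikes
specific sectors of specific cross-sections, yet most in-vivo stiffness
metrics (pulse wave velocity, distensibility) collapse the whole vessel or
cross-section into one number. DENSE CMR encodes the in-plane tissue
displacement of every voxel into its phase, making it possible to resolve
strain *around* the wall of a single 2D aortic cross-section. This package
implements the post-processing chain that turns wrapped DENSE phase images
plus manual wall contours into a 16-sector circumferential Green strain
map and the normalized summary metrics used to compare strain
distributions between subjects. It is aimed at cardiovascular imaging
researchers working with (or simulating) aortic DENSE acquisitions.

## Method

Given magnitude and x/y-phase cine stacks (N_t frames) and per-frame
luminal/adventitial contours:

1. **Unwrap + decode.** Phase is unwrapped within the wall mask
   (quality-guided flood fill, magnitude as quality, temporal anchoring of
   the 2π ambiguity), then converted to displacement per voxel and axis:
   d_i = φ_i / (2π k_e), with k_e the encoding frequency in cyc/mm.
2. **Track.** Each frame's displacements are back-projected to their
   implied reference origins; the forward displacement u_t(X₁) of every
   frame-1 wall voxel is interpolated from the 3 closest origins
   (inverse-distance weights), giving trajectories X_t = X₁ + u_t.
3. **Smooth.** Displacement vectors are averaged over the wall within 1
   voxel-space (2 for the infrarenal aorta); tracked positions get a
   centred 3-frame moving average.
4. **Strain.** The wall is split into 16 equal sectors about the mid-wall
   centroid. Per sector, voxels pooled into inner/outer ×
   clockwise/counterclockwise quadrants define a bilinear quadrilateral
   element; the referential displacement gradient H = ∂u/∂X at the element
   centre gives the Green–Lagrange tensor E = ½(H + Hᵀ + HᵀH), rotated
   into radial–circumferential axes by the local wall tangent and
   time-smoothed with a 5th-order polynomial.
5. **Summarize.** Local systole is the frame of largest mean
   circumferential strain (distal-arch rule: mean peaking frame of the six
   earliest-peaking sectors); NCS divides each sector's strain by the
   cross-sectional mean (mean NCS ≡ 1); the heterogeneity index is the
   sample SD of the 16 sector strains over their mean; plus the mean
   displacement angle (0° = left-lateral, +90° = anterior) and diastolic
   diameter. Sector 1 is the first sector counterclockwise from the
   aorto-vertebral interface (AVI).
6. **Reproducibility.** Two NCS maps of one scan are compared by mean
   |ΔNCS|, the CoV (sample SD of ΔNCS over the mean NCS ≡ 1, rated good
   ≤ 0.20 / fair 0.21–0.30 / poor > 0.30), and the same metrics restricted
   to the two local NCS maxima and two minima.

Because no public aortic DENSE data exist, the package ships a synthetic
generator (`densestrain.synthetic`): a bright annulus over dark lumen,
deformed by x(X, t) = c + b(t) + λ(Θ, t)(X − c) with a raised-cosine
systolic pulse, configurable bulk translation, homogeneous or
circumferentially heterogeneous stretch and Gaussian phase noise — with
the exact displacement field and a finite-difference strain oracle as
ground truth.

## Worked example

```python
import numpy as np
import densestrain as ds

enc = ds.EncodingParams(ke=0.25, voxel_size=1.0, frame_interval_ms=32.0, n_frames=18)
kin = ds.make_kinematics(
    stretch_amplitude=0.1,            # 10% mean circumferential stretch at peak
    heterogeneity=0.3,                # stretch modulated +-30% around the wall
    peak_angle=4.5 * 2 * np.pi / 16,  # hottest wall region: sector 5 from the AVI
    translation_amplitude=np.array([2.0, 1.0]),  # bulk systolic motion, mm
)
series, seg, truth = ds.render_dense_series(kin, enc, noise_sd=0.05, seed=1)

ctx = ds.AnatomicalContext(location="DTA", avi_angle=0.0, bsa=1.8)
result = ds.analyze(series, seg, ctx)
s = result.summary

print(f"local systole:        frame {s.systole_frame} (truth: {truth.systole_frame_true})")
print(f"mean strain there:    {s.mean_strain_systole:.3f}")
print(f"peak NCS:             {np.nanmax(s.ncs):.2f} in sector {s.peak_sector}")
print(f"heterogeneity index:  {s.het_index:.2f}")
print(f"mean displacement:    {s.mean_disp_magnitude_mm:.1f} mm at {s.mean_disp_angle_deg:.0f} deg")
print(f"diastolic diameter:   {s.diameter_cm:.1f} cm ({s.relative_size_cm_per_m2:.2f} cm/m2)")
```

prints

```
local systole:        frame 8 (truth: 8)
mean strain there:    0.077
peak NCS:             1.39 in sector 5
heterogeneity index:  0.23
mean displacement:    2.2 mm at 29 deg
diastolic diameter:   1.9 cm (1.06 cm/m2)
```

The analysis finds systole at the true peak frame; the mean strain is the
10% peak stretch scaled by the heterogeneity normalization (λ̄ − 1 =
A/(1+h) ≈ 0.077 → E ≈ 0.080) minus the deliberate ~4% attenuation of the
temporal filters; and the hottest sector lands exactly where the stretch
peak was placed, 4–5 sectors counterclockwise of the AVI, with peak NCS
within a few percent of the analytic oracle's 1.31.

The same workflow is available from the shell:

```bash
densestrain simulate --ke 0.25 --noise-sd 0.05 --heterogeneity 0.3 --seed 1 --out scan/
densestrain run --mag scan/mag.nii --phx scan/phx.nii --phy scan/phy.nii \
    --contours scan/contours.json --ke 0.25 --location DTA --bsa 1.8 --out out/
densestrain compare --map-a out/sectors.csv --map-b other/sectors.csv
```

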