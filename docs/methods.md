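# Methods

## Path-length-matching refractive-index estimation

OCT depth axes are calibrated in air-equivalent optical distance: a
reflection at physical depth z beneath a sample surface appears at
z1 + n_s·(z − z1) when the intervening medium has group index n_s. The
estimator exploits the geometry of a spheroid tangent to a flat dish: the
exposed dish flanks give the true dish line; extrapolated beneath the
spheroid it provides the geometrical reference z0 (the top-to-dish distance
is a path through air), while the spheroid's bottom reflection z0' is
reached through tissue. The index is the ratio of optical to geometrical
thickness, n_s = (z0' − z1)/(z0 − z1), computed with magnitudes so either
depth-axis orientation gives n_s ≥ 1.

The working identity treats the group index as equal to the phase index:
the group index differs from the phase index by a term proportional to the
source centre wavelength times the dispersion dn/dλ, which is small for
soft tissue over a narrow bandwidth and is neglected here, as is standard
for this kind of measurement.

Assumptions: the spheroid is elliptical in cross-section (silhouette
circularity of real spheroids exceeds 0.9), rests tangent on the dish, and
is measured near its apex, where the spheroid–dish air gap and surface
obliquity vanish. Off-apex the dish-to-top distance includes the air gap,
so the ratio *underestimates* n_s; this is intrinsic to the method, not to
the implementation, and is why measurement columns are confined to ± one
lateral-resolution width around the apex.

### Pipeline stages and numerical choices

1. **Background correction** — per-column mean of caller-designated blank
   rows (default: top 10% of rows) subtracted; negatives clipped to zero.
2. **Peak detection** — each column is smoothed with a Gaussian matched to
   the axial point-spread function (matched filtering), then local maxima
   above `k_sigma` (default 3) times the column's robust blank-region noise
   scale are kept. The blank region of a corrected image is zero-clipped
   noise, so its standard deviation is rescaled by 1/√(1/2 − 1/π) to the
   raw scale. Matched filtering is what makes k = 3 usable: over a few
   hundred rows of white noise the chance that some raw local maximum
   exceeds 3σ is tens of percent, but smoothing narrows the noise bandwidth
   so the effective threshold is ≈ 4.6σ of the smoothed process and the
   per-column false-positive rate drops below 1%. The shallowest qualifying
   peak wins (first-reflection semantics); bottom surfaces are found with
   the deepest-peak mode plus a relative-height gate (25% of the window
   maximum) that ignores diffuse interior backscatter. Columns with no
   qualifying peak are reported missing, never fabricated.
3. **Sub-pixel refinement** — 3-point parabolic interpolation around the
   discrete maximum, applied to log-intensity when all three samples are
   positive. A Gaussian peak is exactly parabolic in log space, so
   noise-free localisation is exact even at ~1.5 samples per FWHM; without
   sub-pixel refinement the 2 µm axial pitch alone would bound RI precision
   well above 0.01.
4. **Surface fitting** — least-squares degree-2 polynomials. The dish is
   fitted on columns outside the footprint plus a 10-column margin and
   extrapolated beneath the spheroid. The top and bottom polynomials are
   fitted only over the central 50% of the footprint half-width
   (`fit_fraction`): a quadratic is a local model of an elliptical arc, and
   fitting the full arc biases the apex by ≈ 3% of the axial semi-axis
   (≈ 0.015 in n_s), whereas over the central half the bias is below
   0.3 µm. Duplicate columns are averaged; fewer than 3 points is an error.
5. **Footprint** — largest contiguous run of columns whose first reflection
   sits ≥ 10 µm above the extrapolated dish line; a footprint touching the
   image edge is an error (the dish cannot be fitted on both flanks), and
   no such column yields a distinct "empty footprint" result.
6. **Measurement and aggregation** — z1, z0, z0' evaluated at the apex
   column ± `n_measurement_columns//2` spaced by half a lateral-resolution
   width; measurements with t ≤ 0 or d < t are excluded with a logged
   reason, never clamped. Spheroid estimates average single-column values;
   fewer than 15 is flagged under-replicated. Group comparisons use the
   classical one-way fixed-effects ANOVA (F from sums of squares, p from
   the F distribution), reported at α = 0.05, two-sided, with no
   multiple-testing correction — a deliberate mirror of common practice in
   this field and a documented limitation.

### Necrotic-dip detection

An A-scan through a necrotic core shows an interior intensity dip. After
moving-average smoothing (default 15 µm) the interior — strictly between z1
and z0', minus a one-axial-resolution guard band at each end — is compared
against `dip_ratio` (default 0.5) times the median smoothed intensity of
the interior rim zones (first and last 20% of the interior span). The
longest sub-threshold run bracketed by supra-threshold signal on **both**
sides is reported. Runs touching a guard band are rejected: attenuation
with depth is deliberately not compensated, and a profile that merely
decays exponentially never recovers, so it cannot fire the detector — deep
signal loss from attenuation must not be read as necrosis.

## Brightfield morphometry

Intermodes autothreshold: the 256-bin histogram is repeatedly smoothed with
a 3-bin mean filter until exactly two local maxima remain; the threshold is
the floor of the peaks' midpoint (iteration count returned for audit;
non-bimodal input errors out after 10,000 passes). Binarisation uses the
dark-object convention (switchable); cleaning is binary erosion with a 3×3
cross element, default 1 iteration. The spheroid is the largest
8-connected component not touching the border, which excludes debris and
clipped objects.

**Perimeter convention.** Circularity 4πA/P² is dominated by the perimeter
estimator. Chain-code boundary lengths (unit steps plus √2 diagonals)
overestimate a digital circle's perimeter by ≈ 5.5% on average, forcing
disk circularity to ≈ 0.90 no matter how large the disk. The package
instead defines the perimeter as the length of the convex-hull boundary
polygon of the region's pixel squares. Consequences: an axis-aligned
square of side a px measures exactly 4a (circularity exactly π/4); a
digitized disk of radius r measures ≈ 2π(r + ½), giving circularity
(r/(r+½))² → 1 from below (0.990 at r = 100, 0.995 at r = 200); and since
the hull both contains the pixel area and minimises perimeter, the
isoperimetric inequality keeps circularity ≤ 1 for every region. The
convention is exact for convex silhouettes — the spheroid use case — and
convexifies concave boundaries, which is the documented trade-off.

Area is the raw pixel count (× calibration² for µm²); equivalent diameter
is 2√(A/π). Default calibration 0.891 µm/px. Growth summaries aggregate
per-day diameters; a doubling time can be estimated by log₂-linear
regression of diameter on day.

## Confocal imaging depth

Raw integrated density is the exact sum of pixel values inside the ROI.
The ROI in auto mode is the convex hull of the largest bright component of
the maximum-intensity projection after Intermodes thresholding (the
plugin-based ROI of common practice is not published; this is a declared
stand-in, and an explicit mask can always be supplied). Background is the
mean of out-of-ROI pixels on the *first* slice — the most signal-free
context available in every stack; this location is a package decision and
can be overridden. The maximum imaging depth is z_step × k for the first
slice k whose in-ROI maximum is ≤ the background mean — a literal "no pixel
above background" stopping rule, choosing the first signal-free slice over
the last signal-bearing one (the two readings differ by one z-step). An
optional `consecutive=q` guard requires q successive stopping slices. On
Poisson-noisy stacks the literal rule is conservative (a single hot pixel
keeps a slice "signal-bearing"); noise-free or averaged data match the
closed-form stopping index exactly. Depth is 0-indexed from the first
slice; default z-step 7 µm.

## Synthetic-data generator

The generator encodes exactly the physics the pipeline inverts, with known
ground truth returned alongside every image.

**B-scan.** Elliptical phantom (lateral semi-axis a, axial semi-axis b)
tangent to a flat dish. Per column x with footprint coordinate u: top
reflection at the ellipse boundary z_t(x); interior backscatter attenuated
as exp(−2·µ_t·path-in-tissue); bottom reflection at z_t + n_s·chord(x);
optional extra dish reflection deeper by the air gap b(1−√(1−u²)) when
`air_gap` is enabled (off by default — the pipeline measures at the apex
where the gap vanishes). All reflections carry a Gaussian axial PSF whose
FWHM is the instrument's axial resolution; an optional necrotic core
(radius fraction, contrast) scales interior backscatter. Speckle is
multiplicative unit-mean gamma noise with σ/mean = `speckle_contrast`
(exponential intensity statistics — fully developed speckle — at contrast
1); the additive floor is Gaussian about `noise_floor`. Identical seeds
give bit-identical rasters.

Instrument metadata records a centre wavelength of 840 nm and bandwidth
≈ 10 nm; the axial PSF width is an explicit parameter defaulting to the
quoted 3.1 µm rather than being derived from the bandwidth, because quoted
source bandwidths and measured axial resolutions of real systems need not
satisfy the Gaussian coherence-length formula (which is exposed separately
as `coherence_axial_resolution`). Default study conditions, chosen once as
realistic for day-4–7 spheroids on this class of instrument: apex chord
300 µm (b = 150 µm), a = 250 µm, dish at 500 µm depth, axial pitch 2 µm/px,
lateral pitch 5 µm/px, surface reflectivity 800 counts, dish reflectivity
1000, interior backscatter 60; noisy runs add speckle contrast 0.3 and an
additive floor of 20 counts. A 95 dB-class system resolves these surfaces
comfortably; the contrast-0.3 speckle regime is deliberately harsher than
fully averaged clinical data.

**Brightfield.** Dark disk of radius a on a bright background (levels
50/200), optional small debris blobs placed with clearance from the main
object, Gaussian pixel noise. Ground truth records the analytic area πa²
and diameter 2a plus the noiseless mask.

**Confocal stack.** In-ROI expected signal background + S₀·exp(−k·Δz/L)
with per-pixel Poisson noise (or rounded expectations noise-free). The
ground-truth maximum depth is the first slice whose expected excess falls
below half an intensity count — the first slice whose rounded noise-free
value is indistinguishable from background — or the full stack extent.

**What the generator does not emulate** — and hence what passing tests do
and do not show: no refraction-induced ray bending beneath curved surfaces,
no dispersion or chromatic effects, no spectral-domain reconstruction
artefacts (simulation starts at reconstructed intensity), no spatially
correlated speckle, no real spheroid surface roughness or internal
heterogeneity beyond the single necrotic core, and no dye-penetration or
photobleaching kinetics in the confocal model. Recovery of the generator's
index to 0.005 therefore validates the *estimator* under the stated forward
model; accuracy on instrument data additionally depends on effects outside
that model. Real-specimen quantities (measured spheroid RIs, Table-style
imaging-depth values, day-7 necrosis onset, the ~30% fixation-shrinkage gap
between OCT and live brightfield diameters) are properties of biological
material and are not reproduced by simulation; the package provides the
measurement tools, and its diameter-comparison utility reports the
ratio/percent difference for such data.

## Problem sizes used in verification

Simulated B-scans are 384 × 256 px (768 µm × 1275 µm), three images per
speckled replicate set; the ANOVA null calibration uses 10⁴ simulated
three-group datasets of 10 values each; the circularity checks use disks up
to radius 200 px. These sizes make every verification quantity stable to
well within its stated tolerance while keeping the whole suite fast.

## Known limitations

- The quadratic dish/top/bottom model assumes smooth, near-elliptical
  geometry; strongly aspherical or tilted samples violate the
  central-fit-window assumptions.
- The estimator is single-scattering: very turbid samples whose bottom
  reflection is extinguished yield missing detections, not estimates.
- Circularity of concave regions is overestimated by the convex-perimeter
  convention (by design; spheroid silhouettes are convex).
- α = 0.05 without multiple-testing correction mirrors field convention;
  users running many group comparisons should correct externally.
- The literal confocal stopping rule is noise-sensitive on raw Poisson
  data; use the `consecutive` guard or pre-averaging for noisy stacks.
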