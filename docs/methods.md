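# Methods

## Scope and model overview

`alphadosim` models the irradiation of an adherent cell monolayer at the
bottom of a culture well by an uncollimated ²⁴¹Am disk source, and links the
simulated per-nucleus alpha-hit distribution to detected γ-H2AX focus
distributions. The chain is:

1. **Transport.** Alphas are emitted from a disk source (window radius
   5.9 mm) centred 19 mm above the well bottom, isotropically into the
   downward hemisphere, and tracked as straight lines. A history reaches the
   bottom iff it passes inside the rim circle (radius 8.1 mm, 17 mm above the
   bottom) and lands inside the bottom disk; radial distance along a straight
   segment is convex, so checking the two planes is exact. Particles striking
   plastic are terminated (alpha absorption in plastic is total at MeV
   energies). Arrival energy is the source energy degraded through air along
   the slant path to the top of the 20 µm water layer.
2. **Phantoms.** Cell nuclei are represented either as elliptical cylinders
   (minor axis = 2/3 major, height 8 µm) or as closed triangle meshes, placed
   without footprint overlap in the central 4 × 4 mm² scoring square with
   tops 2.5 µm below the water surface.
3. **Scoring.** A *hit* is a track entering a nucleus volume with positive
   chord and positive residual energy at entry — no energy threshold. Energy
   imparted per hit is ε_s = E_entry − degrade(E_entry, chord, water), with
   full absorption when the residual range is shorter than the chord.
   Specific energy is z = ε × 1.602·10⁻¹³ J/MeV / (V_µm³ × 10⁻¹⁵ kg), i.e.
   z[Gy] = 160.2 ε[MeV]/V[µm³] for unit-density water.
4. **Focus statistics.** Detected focus counts are modelled as
   radiation-induced foci (RIF) superimposed on a pre-existing background.
   The RIF PMF is deconvolved from the detected PMF using the background PMF
   measured in sham-irradiated nuclei; mean RIF is regressed through the
   origin on mean simulated hits; the slope p̂ (≈0.2, i.e. ~5 hits per
   detectable focus) converts simulated hit counts into simulated RIF by
   binomial thinning; a missed-foci correction redistributes the ~25% of
   foci invisible to single-plane imaging.

## Energy-loss physics

The paper's transport is delegated to a general-purpose Monte Carlo code;
here it is replaced by a continuous-slowing-down (CSDA) model on packaged
stopping-power tables for dry air (ρ = 1.205·10⁻³ g/cm³) and liquid water
(ρ = 1 g/cm³), sampled on a 120-point log grid over 0.05–6 MeV. The tables
were derived from the Bethe mass stopping power with a Barkas-type
effective-charge reduction z_eff = 2(1 − exp(−125 β / 2^{2/3})), with
velocity-proportional scaling (S ∝ √E) below the stopping maximum where
Bethe theory breaks down, and a single per-medium normalization factor
(≈1.11–1.17) chosen so the CSDA range of the principal 5.486 MeV line
matches classic range–energy anchors (Geiger rule R_air = 0.318 E^1.5 cm;
Bragg–Kleeman scaling ×1.07·10⁻³ to water). Resulting anchors: LET in water
93 keV/µm at 5.486 MeV and 198 keV/µm at 1 MeV; water range 43.7 µm at
5.486 MeV; air range 34.5 mm at 4.9 MeV.

Interpolation is piecewise-linear in log E–log S, which keeps LET continuous
and range quadrature stable. Range and its inverse are precomputed on a
2000-point grid; `degrade` solves range(E) − s = range(E′) on that grid.
Particles below the 0.05 MeV table floor are considered stopped and deposit
their residual energy locally — irrelevant at the 8 µm scoring scale, since
arrival energies are ≳2 MeV. No angular or energy-loss straggling, nuclear
reactions, or delta-ray transport: over 19 mm of air the RMS multiple-
scattering deflection of a ~5 MeV alpha is ≪1°, and the study's variance is
geometry-dominated.

The measured source spectrum is not published; the default emission spectrum
is Gaussian, peak 4.9 MeV (the measured peak), SD 0.3 MeV, truncated to
(0, 5.486] MeV, replaceable by a two-column CSV. Hit counts — the quantity
that drives the focus statistics — are independent of the spectrum; energy
summaries are not, and the simulated arrival median (~2.2–2.4 MeV) should be
read with that caveat.

## Central-region importance sampling

Only ~0.65% of emitted alphas land in the central 4 × 4 mm² square where
nuclei are scored. `sample_central_arrivals` therefore draws the landing
point uniformly on the square and the emission point uniformly on the
source window, and accepts each pair by rejection against the exact
per-area arrival density cos θ/(2π d²) (maximum 1/(2π h²) at the vertical);
tracks blocked by the rim are rejected (never the case for the printed
geometry). Acceptance is ≈80%, a ~150× speed-up over brute force, and the
sampled positions and angles agree with brute-force filtering of the full
simulation (tested within 2 SE / by a KS test). The per-history arrival
probability estimated from the same weights normalizes scored counts to
real seconds via the printed surface emission rate (2.4·10⁵ α/s).

## Phantom construction

**Elliptical cylinders.** Major axes follow a logistic distribution
(scale from the fitted SD 4.1 µm → s = 4.1·√3/π) truncated to [4, 40] µm.
The printed mean major axis (15.3 µm) and mean phantom volume (930 µm³) are
mutually inconsistent: V = (π·8/6)·maj² gives E[V] ≥ 981 µm³ whenever
E[maj] = 15.3 µm. The sampler therefore calibrates the logistic *location*
so that the expected phantom volume equals the 930 µm³ target (location
≈ 14.25 µm); the sampled mean volume at n = 10,000 is within 1% of target.
Azimuths are uniform (overlap is azimuth-dependent, so it must be fixed);
placement is rejection sampling on a uniform grid hash with an exact
footprint-overlap test (centre containment + dense boundary membership,
256 points/boundary). At the study's ~0.7% packing fraction placement is
essentially always successful.

**Meshes.** The study's segmented nuclei are not deposited; the synthetic
generator produces star-shaped deformed ellipsoids: an icosphere
(subdivision 3, 1280 facets) scaled to semi-axes (a, 2a/3, 4 µm) with the
major axis logistic-distributed, radially modulated by a smooth random
directional-harmonic field of amplitude ≤15%. Star-shaped radial
perturbation preserves watertightness and orientation by construction;
every mesh is validated (watertight, consistent winding, positive
divergence-theorem volume). The whole set is isotropically rescaled so the
mean enclosed volume equals the 1070 µm³ target, then placed without
footprint overlap in a 0.4 mm unit cell; `tile_mesh_set` replicates the
cell across the region (105 nuclei × 95 tiles = 9975 by default).

Because footprint × mean vertical chord = volume for any shape, the mean
specific energy under a given fluence is shape-independent
(z̄ ≈ Φ·LET/ρ); the mesh set therefore shows more hits and more energy
imparted than the ellipse set (larger volumes and footprints) but
near-identical mean specific energy — the behaviour the comparison tests
assert.

## Scoring details

Arrivals are binned against nuclei via a KD-tree on (x, y) with a search
radius of footprint radius plus the maximal lateral drift over the slab
depth. Ray–elliptical-cylinder chords are solved analytically (quadratic in
the ellipse frame intersected with the slab interval; axis-parallel rays
handled as a degenerate case); ray–mesh chords by vectorized
Möller–Trumbore intersection with entry/exit pairing of sorted hit
distances. Nuclei are transparent to tracks (no mutual shadowing; packing
<1%). Energy bookkeeping (Σε_s ≤ arrival energy, ε_s ≤ E_entry) is asserted
in tests. Summaries report population variance by default (configurable);
for count data the mode is the smallest most-frequent integer.

## Statistical chain

* **Convolution/deconvolution.** Counts PMFs are convolved with
  `numpy.convolve`. Deconvolution recovers the RIF PMF on support 0–15.
  The textbook triangular solve (available as `method="sequential"`,
  negatives clipped, renormalized) divides by p_bg(0) at each order and
  amplifies sampling noise geometrically; its clipped solution is biased
  upward. The default therefore solves the identical non-negative linear
  system by NNLS; both methods are exact (≤10⁻⁹) on noise-free input, and
  the L1 re-convolution residual is always reported as an audit of the
  information removed by the non-negativity constraint.
* **KS test.** D is the sup-distance of the two empirical CDFs; the p-value
  uses the asymptotic Kolmogorov distribution at the effective sample size
  n_a n_b/(n_a+n_b) with the standard small-sample continuity correction;
  below n = 30 a label-permutation p-value is used instead. On continuous
  data the empirical type-I error at α = 0.05 is ≈0.047; on heavily tied
  count data any KS test is conservative.
* **Calibration.** Through-origin weighted least squares of mean RIF on
  mean hits (weights 1/SE²; thinned-hit means are proportional to hit
  means by construction); an intercept mode exists. The CI uses the t
  distribution on the residual degrees of freedom. The reciprocal slope is
  reported as "hits per RIF".
* **Thinning and correction.** Simulated RIF are Binomial(hits, p̂) draws.
  The missed-foci correction adds round(N_detected·(1/f − 1)) foci
  (nearest integer, ties to even) for detection fraction f = 0.75,
  distributed uniformly over all nuclei including zero-count ones; it
  raises the mean by 1/f in expectation and shrinks the zero-count excess
  relative to simulation.

## Synthetic data

Backgrounds are zero-inflated Poisson (the simplest family matching the
reported means and the zero-inflated detected shape): control presets with
means 2.2 (all foci) and 1.2 (large foci), zero-inflation 0.10; sham
presets 2.6/1.5 with inflation 0.08, sized so a two-sample KS test at
n = 5000 separates sham from control at p < 0.01 in ≥95% of seeds (the
study found medium removal itself induces foci). The detected-count
generator composes hits → Binomial(hits, p) RIF → + background →
Binomial(total, detection fraction), retaining every latent variable; a
Poisson-surrogate hits mode allows statistical tests without transport.

The image generator renders 16-bit two-channel frames at the fixed
0.1318 µm pixel size (which makes the 2000–12,000 px inclusion bounds equal
35–209 µm²): smooth-edged elliptical DAPI blobs and hard-disk foci softened
by a 0.6 px Gaussian, plus offset and Gaussian read noise. It emulates
neither PSF structure, bleed-through, intensity vignetting, pan-nuclear
signal, nor focus clustering along tracks — so passing segmentation tests
demonstrate correctness of the workflow on compact, well-separated foci,
not performance on real confocal data.

## Segmentation parameters

The study names its operations but no parameters; defaults here are:
nucleus channel — Gaussian σ 2 px, adaptive local-mean threshold with
window ≈465 px (~4 nucleus diameters, clamped to the image) and offset
5% of dynamic range, global floor at half-Otsu, hole filling, minimum
object 500 px, distance-transform watershed with 25 px peak separation;
focus channel — separable median background (21 px window, rows then
columns, chosen over the full 2-D median for speed), Gaussian σ 1 px,
threshold at 6 robust noise SDs (MAD-based), restriction to nucleus
labels, minimum area 9 px (30 px for the large-focus class). Component
areas are measured at half-maximum so the low detection threshold's
smoothing skirt does not inflate the size classes (a rendered radius-2
disk measures ~13 px ≈ π·2²). Inclusion bounds are treated as inclusive;
the focus-count exclusion is 20 (the stricter of the two values the study
mentions). On the default synthetic benchmark (50 nuclei, 2048² px) the
workflow recovers ≥95% of ground-truth foci with no spurious detections.

## Problem sizes and reproducibility

Default pipeline runs use the study-scale configuration (10,000 ellipse
nuclei, 9975 mesh nuclei, real-time arrival counts for 4/8/12 min — about
0.38/0.75/1.13 million central-region arrivals). The test suite uses
3000 nuclei and the full real-time arrival counts for the end-to-end
checks, 10⁷ histories for the transmission and detector-efficiency checks,
and n = 5000 nuclei per condition (the study's own order of magnitude) for
the calibration-coverage simulation; these sizes keep the whole suite
around half a minute while leaving Monte Carlo error well inside every
asserted tolerance. All generators take explicit integer seeds; the
pipeline derives per-stage seeds from one master seed via
`numpy.random.SeedSequence` and records them, with the config hash, in
`provenance.json` — identical config + seed reproduces byte-identical
artifacts.

## Known limitations

* Straight-line monoenergetic CSDA underestimates the low-energy tail of
  the arrival spectrum that a measured (source-degraded) spectrum would
  produce; simulated hit means run ~10% below the reported simulated RIF
  means (well inside the acceptance band, but systematic).
* The ~18% difference between emission-spectrum models (e.g. Lambertian
  vs isotropic emission) is resolved by the spec's choice of isotropic
  hemisphere emission, which reproduces the reported 7.6% transmission.
* Mesh nuclei are deformed ellipsoids, not segmented morphologies; their
  chord-length distribution is smoother than real nuclei.
* The deconvolution support cap (0–15) truncates any true RIF mass beyond
  15 foci; negligible at the studied exposure times.
* Detected-foci "data" are generated by the package's own forward model,
  so detected-vs-simulated comparisons validate internal consistency of
  the statistical chain, not the biology.
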