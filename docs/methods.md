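# Methods

## Image model

The activity distribution is represented as a sum of overlapping,
spherically symmetric, compactly supported basis functions (blobs) centred
on a polar grid, f(r) ≈ Σᵢ cᵢ ψ(|r − rᵢ|).  The blob is the generalized
Kaiser–Bessel window of order m, radius a and taper α,

    ψ(r) = [√(1 − (r/a)²)]^m · I_m(α √(1 − (r/a)²)) / I_m(α),  0 ≤ r ≤ a,

and zero beyond.  Defaults are m = 2, a = 1.994 Δ and α = 10.4, the
frequency-domain optimum for this family; m = 2 gives a continuous first
derivative at the support boundary, which the tests verify numerically.
Blobs are *not* normalized to unit integral — the coefficients carry the
activity scale, matching the expansion as written.

Blob centres sit body-centred on the polar voxels: radii (k + ½)Δ, azimuths
(j + ½)·2π/n_angular and axial planes spaced Δ symmetrically about the
scanner mid-plane.  The half offsets matter: they place each centre at its
polar-voxel centre and make the scanner's reflection symmetries act on the
grid without fixed points, so a commensurate grid (n_angular divisible by
2·n_modules, n_axial even) folds onto exactly n_blobs/(4·n_modules)
canonical wedge blobs.  An odd n_axial leaves the central plane fixed under
the axial mirror; canonical-representative selection (minimum flat index in
each orbit) still folds such grids correctly, just with a slightly larger
wedge.

The line integral of ψ along a chord at perpendicular distance s (the
projector "footprint") has the closed form

    F(s) = (a / I_m(α)) √(2π/α) · w^{m+½} · I_{m+½}(α w),
    w = √(1 − (s/a)²),

validated in the test suite against adaptive quadrature to 1e-8 relative —
the accuracy bound chosen because every system-matrix element inherits it.

## Scanner geometry and symmetry group

The scanner is a ring of n_modules flat modules, each with n_layers radial
crystal layers of crystals_tangential × crystals_axial crystals.  The
default reproduces a small-animal scanner: 18 modules, two layers (front
2×2×6 mm³, rear 2×2×8 mm³), 71 mm bore, 18.1 mm axial FOV, 1,152 crystals,
662,976 LORs.  Inter-crystal gaps and exact module face geometry are not
published for this scanner; the defaults assume gap-free 2 mm tangential
pitch, axial pitch 18.1/8 mm, and a rear face at the front radius plus the
front crystal depth — all configurable.

The symmetry group combines module-step rotations with one transaxial
reflection (about the plane through module 0's centre) and one axial
reflection: order 4·n_modules (72 by default).  A transform acts by first
mirroring, then rotating; the composition law is closed-form and verified
exhaustively (72 × 72) against the induced crystal permutations.  LOR and
blob orbits are folded by canonical-representative selection — never by
weighting — so probabilities are stored once per canonical element and
unfolding visits each real element exactly once, including for orbits
smaller than the group.

## System response matrix

Weights p_{d,b} are computed only for canonical wedge blobs and stored
LOR-ordered in CSR (rows = all LORs, columns = wedge blobs); any element is
recovered as p_{d,T(b₀)} = p_{T⁻¹(d),b₀}.  Entries below a configurable
floor (default 1e-9) are dropped to bound file size.

Two projectors are provided:

* **Analytic footprint projector** (default): p_{d,b} is the mean of the
  blob footprint over a deterministic bundle of chords sampled between the
  two crystal inner faces — a stratified g × g grid per face (n_rays = g²,
  default 16), faces paired point-to-point.  The sample grids are symmetric
  about the face centres, so the chord *set* is invariant under the
  symmetry group and the folded matrix is exactly equivariant (the fold
  versus brute-force test holds to 1e-12 relative).  The per-ray
  normalization is 1: the pair's geometric acceptance is deliberately
  absorbed into the ML-EM sensitivity, since EM is invariant to the global
  SRM scale and the same SRM generates the simulated data.
* **Geometric Monte Carlo projector**: emission points drawn within each
  canonical blob with density ∝ ψ, isotropic back-to-back ray pairs,
  coincidence scored for the crystal pair whose volumes both rays first
  intersect; p = counts/n_events.  This estimates an *absolute*
  per-emission coincidence probability including the solid-angle acceptance
  of each pair, which the analytic projector folds into sensitivity — so
  the two builders differ by a per-LOR factor and agree elementwise only up
  to a per-LOR-orbit scale.  The tests therefore check the MC builder by
  statistical self-consistency across seeds and by per-orbit correlation
  with the analytic build, not by elementwise identity.

Physics deliberately excluded from both projectors, matching the simulated
study conditions: attenuation, scatter, accidentals, positron range,
noncollinearity, energy and timing windows, dead time.

## ML-EM

Standard multiplicative EM with sensitivity s_b = Σ_d p_{d,b}; uniform
initialization c = 1 on supported blobs.  All accumulation is double
precision, removing the floating-point-precision confound that different
hardware accumulation orders would otherwise introduce.  LORs with y_d > 0
but q_d below 1e-300 are excluded from the update and counted, never
clamped (clamping would silently bias the ratio).  Blobs with zero
sensitivity remain exactly zero.  Guarantees verified per iteration in the
tests: non-negativity, support preservation, weighted count conservation
Σ s_b c_b = Σ y_d over modelled LORs (1e-10 relative), and monotone
Poisson log-likelihood.

The backprojection 'transpose' and 'scatter' strategies are algebraically
identical sums in different orders; the suite requires agreement to 1e-9
relative, including under seeded random chunk ordering.  Ordered-subsets
acceleration is intentionally not implemented.

## Synthetic data

The image-quality phantom is a 20 mm long, 30 mm radius warm cylinder
(concentration 1) with 10 mm radius rod inserts at ±15 mm: hot at 3
(3:1) and cold at 0.  The rod offsets are a configuration default — the
published description does not give transaxial positions — chosen to keep
both rods inside the warm cylinder with a 5 mm margin.  The resolution
phantom is a 35 × 20 mm transaxial, 2 mm long warm ellipsoid offset
12.5 mm, with six 200:1 point sources spaced 5 mm radially and six cold
1.5 mm spheres; point sources are modelled as 0.5 mm spheres (one reference
voxel) to keep the field integrable.  Conversion to blob coefficients is by
centre sampling (default) or non-negative least squares on a raster.

Counts are Poisson per LOR with the expected sinogram λ = P c_true scaled
to a total-count budget.  Because the data are generated by the same
forward model used in reconstruction, end-to-end studies probe the
algorithmic chain (folding, projections, EM), not model mismatch: passing
them does not demonstrate robustness to the physics absent from the
projector, detector blurring, or real-data normalization effects.

## Figures of merit

CV = σ/μ and CNR = (μ_s − μ_b)/√((σ_s² + σ_b²)/2) over 8 × 9 × 0.5 mm³ box
ROIs (voxel membership by centre; the sample n−1 standard deviation is
used — the estimator is not specified in the published definitions).  CC is
the Pearson correlation over whole volumes, computed with mean-centred sums
in double precision; mathematically CC = −1 is perfect *anti*-correlation
(the published prose calls it "completely uncorrelated"; the formula is
followed as written).  FWHM is measured on a trilinearly interpolated line
profile; because the resolution phantom's point sources sit on a warm
background, the half maximum is taken above the profile minimum (baseline
subtraction, configurable to raw half-max), with crossings located by
linear interpolation on both flanks.  Verified accuracy: FWHM error at most
one sample spacing for analytic peaks across a grid of widths and spacings.

## Desk-scale study conditions

The published-scale system (dual-layer 1,152-crystal scanner, a
Monte-Carlo SRM of 7 × 10⁸ nonzeros from 3.7 × 10¹⁰ simulated events,
4.5 × 10⁷ coincidences) is far beyond a single-workstation build, so the
package's quantitative end-to-end study runs on a scaled-down system chosen
once and fixed:

* scanner: 18 modules × 1 layer × 4 × 4 crystals (288 crystals, 41,328
  LORs), same 71 mm bore and 18.1 mm axial FOV — the full 72-element
  symmetry group is preserved;
* grid: Δ = 2 mm, 16 × 72 × 8 = 9,216 blobs, 128 wedge blobs;
* analytic SRM, 16 rays per LOR, floor 1e-9 (≈2 × 10⁵ stored nonzeros);
* 5 × 10⁶ coincidences (≈1/9 of the published image-quality acquisition);
* 300 ML-EM iterations, matching the published iteration count;
* ROIs 8 × 9 × 0.5 mm³ at the hot-rod centre (15, 0, 0) and a warm
  background point (0, 15, 0), on a 140 × 140 × 40 raster of 0.5 mm voxels.

Under these conditions the recovered hot:warm contrast is ≈2.93 (within
2.5% of the true 3.0).  Absolute noise trajectories (CV/CNR/CC versus
iteration) and millimetre-scale FWHM values from the published full-scale
study depend on the full-statistics Monte-Carlo SRM and scanner granularity
and are not reproduced at this scale; the resolution phantom study here
shows the qualitative parallax trend (FWHM grows with radial distance)
rather than the published absolute numbers.

## Numerical and design notes

* LOR flat index d = c₂(c₂−1)/2 + c₁ with c₁ < c₂: dense, deterministic,
  equals the LOR-histogram bin.
* Analytic SRM builds are bit-reproducible; MC builds require an explicit
  seed, as does count simulation and the random chunk ordering.  No global
  default seed exists.
* The wedge-folded projections loop over the 72 transforms with permuted
  sparse matrix-vector products; peak memory is dominated by the per-
  transform LOR permutation table (n_transforms × n_LOR int32).
* SRM values are stored with the dtype recorded in the sidecar; the
  default preserves the in-memory float64 (lossless round trip), float32
  is available for compact files.
* Degenerate inputs are rejected, not repaired: zero-activity phantoms,
  all-zero sinograms scale factors, incommensurate angular counts,
  out-of-range indices, equal-crystal "pairs".
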