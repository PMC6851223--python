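# Methods

## Fiber objects

Every model is a tree of named groups whose leaves are *fiber objects*:
ordered chains of ≥ 2 data points, each point carrying a 3D coordinate and
a radius.  All lengths are µm.  A thin axon and a thick bundle envelope
are the same data structure; only the radius differs.  Storage (HDF5 and
plain text) is single precision, which fixes the numeric identity of a
phantom across round trips; in memory everything is float64.

### Construction

*Parametric*: four textual expressions x(t), y(t), z(t), r(t) are compiled
through a whitelist AST walker (variable `t`, arithmetic, `sin cos tan exp
log abs sqrt`, constants `pi`, `e`; nothing else, no attribute access or
calls outside the whitelist) and sampled at `n_steps + 1` uniform t.  This
supports both continuous sampling and the integer-step convention
(t ∈ {0, 1, …, N}) by choosing `n_steps = t_max − t_min`.

*Spline*: coordinates **and** radii are interpolated by one cubic spline
through the control points.  Default boundary condition is **natural** and
the spline parameter is the control-point **index** (uniform
parameterization); both are exposed (`bc_type`, `parameterization="chord"`)
because neither choice is canonical.  Note that a natural spline cannot
reproduce a strict cubic polynomial (its second derivative vanishes at the
ends); `bc_type="not-a-knot"` does, and the test suite uses it for the
cubic-reproduction oracle.  Two control points degenerate to the straight
segment.  Interpolated radii are clamped at 0 against overshoot.

### Transforms

Translation, rotation and uniform scaling act on whole fibers or
recursively on groups; rotation is axis–angle via the Rodrigues formula
v cosθ + (a×v) sinθ + a(a·v)(1−cosθ) about a pivot defaulting to the
target centroid.  Scaling multiplies radii as well, so scaled phantoms
stay geometrically similar.  Duplication is a deep copy.

## Bundle filling

A bundle envelope is filled with child fibers of constant radius
`r_fiber`:

1. **Reference cross-section** — the data point with the minimum
   *positive* radius `R_ref`.  Zero radii (closed tips) are excluded,
   otherwise every fill would collapse onto the axis.
2. **Seed grid** — a triangular lattice with center-to-center pitch
   `spacing` in the reference cross-section plane.  The lattice is placed
   with a **cell centroid on the bundle axis** (the three innermost seeds
   are equidistant from the axis, at pitch/√3), and a seed is kept when
   its **center** lies inside the envelope (|seed| ≤ R_ref).  If nothing
   fits, a single child is seeded on the axis.  This is the package's
   packing convention; with it, a unit-radius envelope filled at
   r_fiber = 0.1 and surface gap 0.2 (pitch 0.4) packs exactly 21 fibers,
   and the Fiber Cup bundles (R = 60 µm, pitch 3 µm) pack 1443 each.
   `spacing` is always a center distance; when a surface-to-surface gap g
   is given (as in the Fiber Cup description), pitch = 2·r_fiber + g.
3. **Frame transport** — tangents are normalized central differences
   (one-sided at the ends).  The in-plane frame at point i+1 is the frame
   at i rotated about t_i × t_{i+1} (normalized) by arccos(t_i·t_{i+1}),
   i.e. the minimal rotation mapping one tangent to the next; this avoids
   torsion accumulation beyond what the trajectory itself imposes.
   Near-parallel tangents (|cross| < 1e−12) use the identity; antiparallel
   ones have no unique axis — an arbitrary perpendicular is used with a
   warning.  The initial normal is the global axis least aligned with the
   first tangent, projected and normalized (deterministic); it can be
   overridden, which is also how rotation-equivariance of the fill is
   achieved (the default initial frame is tied to the global axes and is
   deliberately reproducible rather than rotation-covariant).
4. **Scaling** — at data point j the in-plane offset is multiplied by
   R_j / R_ref, so inter-fiber distances grow with the envelope and, for
   spacing ≥ 2·r_fiber, child tubes never intersect (for spacing exactly
   2·r_fiber on curved parents the guarantee holds up to the polyline
   discretization of the arcs, which shrinks chord distances by
   O(Δθ²/8)).

Collision detection reports every fiber pair whose minimum axis distance
falls below r_a + r_b − tolerance, using the exact clamped closed-form
segment–segment distance and linearly interpolated radii, with an AABB
prefilter; output ordering is lexicographic in the fiber paths.

## The Fiber Cup phantom

Seven bundle envelopes of diameter 120 µm on a 2 mm plate at z = 0:
a long bending bundle (1), a diagonal bundle (2) crossing the straight
transverse bundle (3), three bundles (4–6) sharing their tail controls so
they merge into one corridor that crosses bundle 3, and a bending bundle
in the lower half (7).  The control-point tables are this repository's
fixture: they reproduce the layout's topology (crossing, fanning into a
merge, bending), not any particular hardware phantom's exact coordinates.
Envelopes are sampled at 42 points per fiber, so the default filled
phantom has 10,101 fibers × 42 = 424,242 data points.  Envelopes may
overlap; filling is per-envelope, so the merge corridor carries three
bundles' densities (≈ 3× the transverse bundle).  Collision *solving* is
out of scope — the builder only detects overlaps.

Defaults: fiber diameter 1.5 µm, surface gap 1.5 µm (center pitch
3.0 µm), plate diameter 2000 µm; all scalable via `FiberCupConfig.scaled`.

## Polarimetric simulation

### Voxelization

A voxel (default 1 µm) becomes tissue when its center lies inside some
fiber tube (distance to the nearest axis segment < local radius); it then
stores that fiber's unit tangent.  Overlaps resolve to the nearest axis.
The orientation field is therefore piecewise constant per segment, which
is adequate at fiber radii ≳ the voxel size.

### Forward model

Light enters the specimen linearly polarized at the polarizer angle ρ with
intensity I₀ (I₀ is defined *after* the polarizer).  Each tissue voxel of
thickness d applies

- a linear retarder with fast axis the in-plane fiber direction
  φ = atan2(u_y, u_x) and retardance δ = 2π·(d/λ)·Δn·cos²α, where α is
  the fiber inclination out of the section plane (cos²α = u_x² + u_y²) —
  the standard 3D-PLI retardance model for a uniaxial medium with the
  optic axis along the fiber;
- Beer–Lambert attenuation exp(−µ·d) (tissue only; background is
  lossless).

After the specimen: a quarter-wave retarder with fast axis ρ − π/4, then
the crossed analyzer at ρ + π/2.  With this element order a homogeneous
column yields exactly

I(ρ) = I_T/2 · (1 + sin(2ρ − 2φ)·sin δ_total),

which the test suite verifies against the Müller chain to 1e−9 relative
(the ρ − π/4 fast-axis convention fixes the sign of the modulation; the
mirrored convention flips it).  Stokes vectors remain physical
(S₀ ≥ |S₁₂₃|) at every step, which is audited by a propagation hook.

Defaults: λ = 525 nm, Δn = 0.001, µ = 5 mm⁻¹, I₀ = 26,000 counts, section
thickness 60 µm, nine polarizer angles 0°–160° in 20° steps, camera pixel
Δx = 20 µm, blur σ = 0.714·Δx.

### Blur, downsampling, noise

Gaussian blur with σ = 0.714·Δx precedes block-average downsampling by the
integer factor Δx/voxel_size.  The blur uses periodic boundary handling,
the one choice that conserves the image mean exactly (asserted to 1e−6).
Camera noise is Gaussian with variance gain·I (a shot-noise
approximation), applied after downsampling (sensor-level reading of the
noise model); gain defaults to 1.3, i.e. SNR ≈ 100 at I₀/2.  Noise
requires an explicit seed and is unbiased; negative outcomes clip at 0
with a warning.

### Orientation recovery ("rofl-lite")

A deliberately simple harmonic estimator (a full ROFL-style fit would need
tilting-stage measurements this single-view simulation does not produce):
per pixel, the discrete Fourier coefficients of I(ρ) at frequency 2 give
the phase, hence φ ∈ [0, π), and the relative modulation m/mean gives
|sin δ_total|.  The inclination follows from inverting
δ = 2π·(t/λ)·Δn·cos²α, with δ = arcsin(m/mean) (valid while
δ_total < π/2; at the defaults δ_total ≤ 0.72 rad).  The effective tissue
thickness t is estimated from the attenuated mean via Beer–Lambert,
t̂ = ln((I₀/2)/mean)/µ — this cancels the packing fill-fraction and keeps
α̂ unbiased on columns that are only partly tissue; when µ = 0 the full
section thickness is used instead.  Pixels with relative modulation below
1e−3 (background, vertical fibers) are masked invalid, as are unphysical
pixels with modulation exceeding the mean (with a warning).

### Color coding

Antipodally symmetric orientation colors: RGB mode maps a unit vector to
(|x|, |y|, |z|); HSV mode uses hue = φ/π, saturation = cos α, value = 1.
Hue is 2π-periodic in 2φ, so the map is continuous across the φ = 0/π
boundary.

## Problem sizes and numerical choices

- Test-suite simulations use volumes of ≲ 120×120×60 voxels and camera
  pixels of 5–10 µm, large enough for fully-tissue central pixels and
  small enough to run the whole suite in well under a minute.
- The symmetric-crossing check stacks the two bundles inside one 60 µm
  section and evaluates pixels centered on the crossing bisector, where
  the two densities match by reflection symmetry; off-bisector pixels are
  legitimately pulled toward the locally denser bundle (the same
  density-weighted averaging seen in real measurements).  Residual
  bisector error from retarder non-commutativity scales with the square
  of the per-bundle retardance and stays well below 1°at the defaults.
- Ties and degenerate cases: duplicate consecutive control points are
  rejected; zero-radius envelope tips are excluded from the reference
  radius; near-parallel tangent rotations collapse to the identity;
  seed ordering is by (radius², angle) so fills are deterministic.

## What the synthetic data does and does not show

The generated phantoms are idealized: circular cross-sections, constant
child radii, no myelin sub-structure, no collision *solving* (overlapping
envelopes yield physically impossible interpenetrating fibers at
crossings, which is precisely what makes them useful for studying
crossing artifacts, but density changes from overlap removal are not
modeled).  The optical model is a pure retarder/absorber — no scattering,
diffraction or interference, so effects that require full-wave treatment
are outside its reach.  Passing tests demonstrate internal consistency of
the geometry and optics at these idealizations, not fidelity to any
particular tissue sample.
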