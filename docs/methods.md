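# Methods

## Problem and model

In laparoscopy the trocar leaves an endoscope only three useful degrees
of freedom, so there is essentially one physical orientation from which a
region of interest can be observed. `pseudoview` synthesizes the image a
*virtual* camera would record after rotating the viewpoint about a pivot
in the scene, using only one real frame and a sparse set of pixel ↔ 3D
correspondences — no camera motion and no dense depth.

The pipeline is a chain of exact coordinate transforms followed by one
approximation step:

1. **Undistortion.** The frame is resampled so the ideal pinhole model
   `u = fx·x/z + u0`, `v = fy·y/z + v0` holds (Brown–Conrady model,
   coefficients (k1, k2, p1, p2, k3); inverse mapping by fixed-point
   iteration, converging to ≪1e−6 px for endoscope-scale coefficients).
2. **Pivot rotation.** Each 3D point `P` with known pixel `p` is moved to
   `P′ = H⁻¹·Rz(θz)Ry(θy)Rx(θx)·H·P`, where `H` relates the camera frame
   to the rotation-center frame. For a pivot point `c` this is
   `T(c)·R·T(−c)`: `c` is a fixed point, so the region of interest stays
   in view. Right-handed rotations, camera frame +z forward / +y down,
   degrees at all interfaces.
3. **Reprojection.** `P′` is projected to the virtual pixel `p′` with the
   same intrinsics. Points with transformed `z ≤ 1e−6 mm` are dropped.
4. **Meshing + barycentric rendering** (the approximation). The `p′`
   positions are Delaunay-triangulated (near-equilateral triangles —
   well-conditioned interpolation). For every output pixel inside a
   triangle the three vertices' *source* positions are combined with the
   pixel's barycentric weights and the source image is sampled there
   (bilinear by default, nearest available). Positions are interpolated,
   never colors across unrelated pixels, so sparse or irregular depth
   degrades the geometry smoothly rather than producing color bleeding.

## Control law

A 2-axis joystick sample `q` is referenced to a neutral position
`q₀` (mean of the first 10 frames after start-up), clamped to [−1, 1],
and mapped to an increment `Δθ = Ω(γ)·(q − q₀)` with
`Ω = [[cos γ, sin γ], [sin γ, cos γ], [0, 0]]` — the zero third row means
a 2-axis device never commands roll. Integration uses the
sign-preserving power law `θᵢ ← θᵢ + αᵢ·sign(Δθᵢ)·|Δθᵢ|^r`, clamped to
±`theta_limit` (default ±90°). `r = 1` is exactly linear; larger `r`
gives fine motion near neutral and fast sweeps at full deflection. The
power is applied to the magnitude only, because `r` shapes sensitivity —
it must not rectify direction at even powers. A switch press resets θ
to zero.

Defaults reproduce the single-axis clinical configuration: `γ = 0`,
`αy = αz = 0`, `r = 2`, and `αx = 28.2 / 16.0 = 1.7625°` per update so
full deflection sweeps 28.2°/s at a 16 Hz loop rate. Since `|Δθ| = 1`
at full deflection regardless of `r`, the gain is rate/update-rate
independent of `r`.

One printed-form ambiguity is resolved deliberately: the update is
written elsewhere as `Ω·(q + q₀)`, but `q₀` is defined as the neutral
position and neutral input must be stationary, so the implementation
subtracts the calibrated neutral (equivalently, the printed `q₀` is the
negated mean). `Ω` is used exactly as printed (it is symmetric, not a
rotation matrix); a custom 3×2 matrix can be supplied.

## Synthetic bench and what it does (not) represent

All test inputs are generated, with ground truth known by construction:

* **Phantom**: an 80 × 60 mm flat sheet, white background, a 30 mm black
  cut line through the center (half-width 0.5 mm) flanked by six dot
  pairs (radius 1.5 mm) at 5 mm pitch, ±5 mm from the line. The exact
  printed layout of the physical training sheet is not published; these
  dimensions are a realistic stand-in and are configurable.
* **Pose**: optical axis meeting the sheet at 20° elevation, sheet center
  117 mm away, pivot at (0, 0, 120) mm — the near-horizontal suturing
  view in which depth perception is worst.
* **Camera**: 640×480, fx = fy = 800 px, principal point at the center,
  zero distortion. The original device's calibration is unpublished;
  every acceptance quantity is defined relative to whatever intrinsics
  are configured.
* **Depth grid**: uniform 5 mm pitch on the sheet (0.2 points/mm),
  endpoints inclusive, FOV-filtered; pixels are exact projections. This
  stands in for 3D shape acquisition with a *perfect* sparse depth
  source.
* **Ground-truth renderer**: per-pixel ray–plane intersection against the
  pivot-rotated sheet, 2×2 (4×) supersampling, no meshing anywhere.
  Deterministic and bit-reproducible.
* **Input traces**: `neutral`, `hold` (deflect then release → plateau),
  `pulse` (deflect, reverse, rest → returns to zero), `continuous`
  (seeded low-pass noise); all deterministic for a fixed seed.

The bench is deliberately idealized: planar scene, exact depth, no
sensor noise, no specular tissue texture, no instruments above the
surface. Passing tests therefore demonstrate the correctness of the
geometry/interpolation chain and the control law — not robustness to
depth-acquisition error, non-planar anatomy, or off-plane objects
(instruments warped under a planar assumption are known to distort).

## Evaluation

For a planar scene the exact source→virtual pixel map is a homography
`H₂·H₁⁻¹` with `Hᵢ = K·[b1 b2 M]` built from the plane frame before and
after the pivot rotation. This closed form is the independent oracle for
the mesh warp.

Two error measures are reported:

* **Image-based (the figure of merit).** Each dot is localized in the
  warped raster by an intensity-weighted centroid inside an adaptive
  window (1.3× the projected dot extent + 2 px, computed from the exact
  projection of the dot rim — wide enough to hold the foreshortened dot,
  tight enough to exclude the cut line). The reference position is the
  same centroid measured in the analytic ground-truth render from the
  virtual viewpoint. Comparing centroid to centroid cancels the
  perspective offset between a foreshortened disk's centroid and its
  projected center (~0.02 mm at this geometry), which both images share
  and which is not a warp error. The displacement is converted to mm on
  the surface by back-projecting both pixel positions onto the rotated
  sheet plane. Passing `reference_image=None` to `rendering_error`
  instead compares against the homography-mapped dot center directly.
* **Geometric.** The mesh induces a piecewise-affine source→virtual map
  (each triangle's vertices carry exact correspondences); evaluating it
  densely via the warp's per-pixel source map and comparing with the
  homography gives a rasterization-free error field. This is the
  quantity used for convergence checks: landmark-only sampling can
  alias (a landmark sitting on a grid line of one pitch measures ~0
  there regardless of the mesh's true error), and centroid localization
  has a ~0.1 px noise floor that would mask the O(pitch²) interpolation
  error at fine pitches.

Measured on the default bench (5 mm pitch, θx swept to 34°), the maximum
on-surface landmark error is ≈ 0.03 mm, comfortably inside the 1.00 mm
system bound used as the acceptance target; the dense geometric error
shrinks monotonically from ≈ 1.8 px at 10 mm pitch to < 0.01 px at 1 mm.

## Numerical choices

* Triangulation input is sorted lexicographically by (u, v), so the mesh
  is independent of point ordering; cocircular ties fall to the
  triangulator's deterministic default; boundary pixels are assigned by
  the point locator deterministically, and the brute-force piecewise
  map resolves edge ties to the lowest triangle index.
* Coincident projected pixels (within 1e−9 px) are collapsed, keeping
  the point nearer the camera when z-buffering is enabled (default) and
  the first occurrence otherwise. The planar bench never exercises
  occlusion; per-triangle depth ordering is the extension point for
  non-planar scenes.
* Interpolated source positions are clamped to the source raster before
  sampling (they can drift one ULP outside the hull).
* Identity configuration (θ = 0, zero distortion) reproduces the input
  bit-exactly on the mesh interior: barycentric interpolation of an
  identity vertex map is the identity, and bilinear sampling at integer
  coordinates is exact.
* The undistortion inverse iterates the forward model to a 1e−12 fixed
  point (≤ 25 iterations), adequate for radial coefficients ≲ 0.3.
* Degenerate inputs raise: z ≤ 0 projections, < 3 or collinear mesh
  points, empty transformed point sets, planes through the camera
  center, sheets viewed edge-on or from behind.

## Reproducibility

Every operation is deterministic given its inputs; the only randomness
in the package is the seeded `continuous` input-trace profile. CLI runs
write a manifest with SHA-256 checksums of all inputs. Problem sizes
used by the bundled checks (640×480 frames, depth pitches 1–10 mm,
10,000-step control traces) were chosen so the full suite and the
acceptance sweep each complete in well under a minute of CPU.
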