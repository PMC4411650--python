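# pseudoview

Pseudo-viewpoint alternation for endoscopic images: synthesize the view a
virtual camera would see after rotating the viewpoint about a pivot in the
scene, from a single real frame plus sparse depth — no extra degrees of
freedom at the endoscope tip required.

A trocar-constrained endoscope has effectively three useful degrees of
freedom, so a surgeon usually gets exactly one orientation onto a region
of interest; with the near-horizontal views typical of suturing deep in
the abdomen, depth perception suffers. This package implements the
image-processing alternative to mechanical articulation: given a frame,
the camera intrinsics, and a sparse set of pixel ↔ 3D correspondences
(uniform grid, structured light, sparse stereo — any source), it rotates
the 3D points about a pivot in the scene, reprojects them, and
re-renders the frame from the virtual pose by Delaunay meshing and
barycentric interpolation. An interactive control law maps raw 2-axis
joystick values to incremental viewpoint rotations.

Intended users: researchers in computer-assisted intervention and
surgical-simulation groups who need a reference implementation of
sparse-depth novel-view warping with a quantitative error harness.

## Method

With pinhole intrinsics (after undistortion) a scene point projects as
`u = fx·x/z + u0`, `v = fy·y/z + v0`. For a commanded rotation
θ = (θx, θy, θz) about a pivot pose `H`, each depth point `P` moves to

    P′ = H⁻¹ · Rz(θz) Ry(θy) Rx(θx) · H · P

(for a pivot point `c`: `T(c)·R·T(−c)`, so `c` stays fixed and the
region of interest stays in view). The reprojected pixels `p′` are
Delaunay-triangulated; each output pixel inside a triangle takes the
color of the source image sampled at the barycentric combination of the
vertices' source pixels. Joystick input `q` drives θ through
`Δθ = Ω(γ)·(q − q₀)` and the sign-preserving power law
`θᵢ ← θᵢ + αᵢ·sign(Δθᵢ)|Δθᵢ|^r` (default r = 2, 28.2°/s at full
deflection, 16 Hz loop).

Because the bundled synthetic bench is a planar phantom, the exact warp
is a closed-form homography, which serves as an independent oracle for
every rendered result. See `docs/methods.md` for assumptions,
parameters, and numerical choices.

## Worked example

```python
import pseudoview as pv

setup = pv.make_default_setup()                   # 20° elevation, 117 mm standoff
base  = pv.render_phantom_view(setup)             # 640x480 ground-truth view
grid  = pv.sample_depth_grid(setup, pitch=5.0)    # sparse depth, 0.2 points/mm
print(f"depth points: {len(grid)}")

warp = pv.warp_frame(base, grid, (25, 0, 0), setup.pose.pivot_pose, setup.cam)
print(f"valid output pixels: {warp.validity_mask.mean():.1%}")
print(f"mesh triangles: {len(warp.mesh.simplices)}")

reports = pv.sweep_angles(setup, 5.0, [5, 15, 25, 34])
for rep in reports:
    print(f"theta_x={rep.theta[0]:>4.0f}  max={rep.max_mm:.3f} mm  "
          f"mean={rep.mean_mm:.3f} mm  (max {rep.max_px:.2f} px)")
print(f"worst-case rendering error: {max(r.max_mm for r in reports):.3f} mm")
```

prints

```
depth points: 215
valid output pixels: 54.3%
mesh triangles: 386
theta_x=   5  max=0.026 mm  mean=0.013 mm  (max 0.13 px)
theta_x=  15  max=0.014 mm  mean=0.008 mm  (max 0.09 px)
theta_x=  25  max=0.018 mm  mean=0.011 mm  (max 0.11 px)
theta_x=  34  max=0.021 mm  mean=0.015 mm  (max 0.12 px)
worst-case rendering error: 0.026 mm
```

Reading the numbers: 215 grid points at 5 mm pitch cover the visible
sheet; the warp fills the 54% of the output frame inside the mesh hull.
For each virtual elevation, every aiming dot is localized in the warped
image and compared with its position in the analytic ground-truth render
from the same virtual pose; errors are reported in image pixels and in
mm of displacement on the phantom surface. Even at the steepest sweep
(+34°, i.e. a 54° overlooking view) the warp stays within ~0.03 mm on
the surface — two orders of magnitude inside the 1 mm scale that matters
for aiming a suture.

The same operations are available from a shell:

```sh
pseudoview simulate --out fixture              # view.png, depth_points.csv, calib.json
pseudoview warp --image fixture/view.png --points fixture/depth_points.csv \
                --calib fixture/calib.json --theta 25,0,0 --out run
pseudoview evaluate --out eval --pitch 5 --thetas 5,15,25,34
pseudoview make-trace --profile hold --out trace.csv
pseudoview replay --trace trace.csv --out traj
```

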