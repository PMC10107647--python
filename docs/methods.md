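# Methods notes

## Model and assumptions

The registration model is a proper rigid rotation plus translation between
two 3D point sets expressed in physical micrometres. Translation is never a
free parameter: the rotation centers are pinned to the landmark centroids
of the two images, which makes the cost

    C(φ, θ, ψ) = Σᵢ ‖ R(φ, θ, ψ) (qᵢ − c₂) + c₁ − pᵢ ‖

a function of the three Euler angles only. The cost is the **sum of
Euclidean distances**, not squared distances; it is therefore robust-ish to
a single badly placed landmark but non-smooth wherever a pair distance
reaches zero, which motivates a derivative-free optimizer. A sum-of-squared
variant (`squared=True`) exists because its optimum has a closed form
(orthogonal Procrustes) and serves as an independent cross-check in the
test suite; it is not the method's cost.

Assumptions inherited by everything downstream:

* landmark tables are row-paired (row *i* of both tables is the same
  physical point) and expressed in μm;
* the true motion between images is rigid — deformation (shrinkage,
  depth-dependent distortion) is a model violation whose effect the
  benchmark quantifies rather than corrects, unless the user applies the
  per-axis scale correction first;
* reflections are out of scope: only det +1 rotations are representable.

## Rotation parameterization

`R = Rz(φ)·Ry(θ)·Rx(ψ)` (intrinsic Z–Y–X), centralized in
`geometry.rotation_matrix`. Any proper-rotation parameterization covers
SO(3), so this choice affects only which angle triple labels a given
matrix — equivalent Euler triples near the gimbal singularity are accepted,
and correctness is always asserted on the matrix, not the triple. Reported
angles are wrapped to [−π, π).

## Multi-start minimization

* Local optimizer: Nelder–Mead simplex (`scipy.optimize.minimize`),
  `xatol = fatol = 1e-10`, at most 10 000 cost evaluations per start.
* Start grid: three initial values per angle, {−2π/3, 0, +2π/3} — even
  coverage of the circle — giving 27 independent local minimizations at the
  defaults. `starts_per_angle` scales the grid; extra uniformly random
  starts can be appended (`n_random_starts`, the only consumer of `seed`).
* A start is counted as having reached the global minimum when its final
  cost is within `tol_cost` of the best; default
  `max(1e-6, 1e-4 × bounding-box diagonal of the first landmark set)` μm,
  i.e. a scale-aware tolerance that treats sub-tenth-of-a-nanometre spreads
  on a 100 μm field as ties. The reported probability (n reaching / n
  starts) is a convergence diagnostic: values near 1 mean the surface was
  benign for this specimen.
* Ties for best fit break toward the lowest start index, so results are
  deterministic.
* Degenerate inputs: fewer than 3 pairs raises
  `InsufficientLandmarksError`. Collinearity is detected on the *second*
  singular value of the centered landmark matrix (rank < 2 ⇔ the points
  lie on a line, threshold 1e-9 relative to the largest singular value); a
  planar triangle has a zero third singular value but still determines the
  rotation uniquely, so the third value is deliberately not consulted.

## Pairing

Independent nearest-neighbour per image-1 object over an explicit distance
matrix (the sets are tens to hundreds of points; an exact matrix is cheaper
than a tree and makes the deterministic tie-break — smaller image-2 id —
trivial). The top k = 3 candidates and their distances are reported per
object. One-to-one (Hungarian) matching is deliberately not performed:
an image-2 object nearest to several image-1 objects is evidence of a
labeling gap or count mismatch, and is surfaced in the multiply-assigned
list for the user to judge. No distance cutoff is imposed for declaring
"no counterpart"; the distances are in the output for exactly that
judgement.

Accuracy, where ground truth exists (benchmark, or manually curated pairs),
is the percentage of rank-1 assignments equal to the true counterpart.

## Image resampling

* Convention: arrays are (z, y, x); voxel index i sits at physical
  coordinate i × voxel_size (μm) at the voxel center; physical points are
  (x, y, z).
* `rotate_stack` pulls: each output voxel position q samples the source at
  `Rᵀ(q − c_to) + c_from`, linear interpolation, zeros outside the field.
  Anisotropic stacks are first resampled to isotropic sampling at the
  smallest voxel dimension — rotating in anisotropic index space shears the
  image. Label (id-valued) images should be rotated with `order=0`.
* Default output canvas is the (isotropized) source geometry; passing the
  first image's shape and voxel size reconstructs on its grid, which is the
  normal workflow.
* Intensity is conserved to within interpolation error for content fully
  inside the field; no per-slice contrast normalization is applied (an
  acquisition-side practice that deliberately does not conserve intensity).
* `render_particles` draws spheres whose voxel value is the object id
  (later ids overwrite on overlap), so a modulo-style lookup table colors
  corresponding particles of two images identically; 8-bit output caps ids
  at 255, 16-bit lifts the cap.

## Synthetic benchmark

The generator emulates the failure modes of real two-image experiments on
top of an exactly known ground truth:

* object clouds: n = 50 points i.i.d. uniform in a 200 × 150 × 100 μm box —
  roughly a blastocyst-scale field with several tens of nuclei;
* z-scaling: z × (scale/100) about z = 0, mimicking voxel-spacing
  miscalibration and fixation shrinkage (80–120% brackets realistic
  severity);
* trapezoid deformation: xy offsets from the box center scaled by
  1 + (ε/100)(2z/z_max − 1) — expanded by ε% at the top plane, contracted
  at the bottom, fixed at mid-height — a depth-dependent optical
  distortion;
* positional noise: i.i.d. uniform(−ξ, +ξ) per coordinate on **both**
  point sets independently, ξ expressed in percent of the z extent
  (landmark-placement and segmentation error);
* second image: deform, then rotate uniformly over SO(3) about the box
  center; landmarks are a shared random subset of the objects (re-drawn in
  the measure-zero event of collinearity); replicates default to N = 4 per
  condition, configurable upward for trend tests.

What passing benchmarks do *not* show about real data: real landmark error
is neither uniform nor independent of depth, real deformation is not
exactly trapezoid, and real specimens add occlusion, unequal object counts
and stain-dependent localization differences. The benchmark bounds the
geometric behaviour of the algorithm, not microscope physics.

Problem sizes in the shipped tests and the reproduction script (4
replicates per condition, 20 for trend assertions, 100 instances for the
recovery and Procrustes cross-checks) were chosen as the smallest that make
the respective claims statistically meaningful.

## Known limitations

* Only rigid rotation + translation; per-axis scale must be corrected
  beforehand (`apply_scale` / `rescale_stack`), and non-rigid deformation
  is quantified but not modeled.
* Euler-angle reporting is convention-bound; compare matrices, not angle
  triples, across tools.
* Nearest-neighbour pairing has no global consistency constraint by
  design; heavily deformed or very dense fields can produce chains of
  off-by-one assignments that a one-to-one matcher would partly avoid.
* `fit_rotation` cost is O(starts × iterations × landmarks); with tens of
  landmarks it is interactive (< 1 s), but the 27-start protocol is not
  tuned for thousands of landmarks.
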