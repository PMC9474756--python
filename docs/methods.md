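# Methods

This note documents the models, algorithms and numerical choices behind
`tbmoco`, and what the synthetic phantom does and does not establish about
behaviour on real data.

## Problem setting

A dynamic total-body FDG acquisition bins 60 minutes of list-mode data into
contiguous frames (clinically 66 frames: 5 s x 24, 10 s x 6, 30 s x 6,
60 s x 6, 120 s x 24). Patients rarely stay still for an hour; body shifts
and soft-tissue deformation after the first ~10 minutes misalign the late
frames, corrupting both static SUV images and voxelwise kinetic parameters.
`tbmoco` implements an image-based inter-frame correction: the 10-60-min
data are rebinned into fifty 1-min frames (90 frames total) for better
temporal sampling, each frame from 41 onwards is registered to its previous
neighbour, and the per-frame total motion field is the concatenation of all
pairwise fields back to the reference (frame 40, the last frame of the
motion-free early window). Each frame is resampled exactly once with its
concatenated field, then the series is regrouped back to the 66-frame
schedule for analysis. Frames at or before the reference are never touched.

Neighbour-to-neighbour pairing keeps the contrast difference between the two
images of every registration small, which is why a cross-correlation metric
suffices; the mid-frame comparison strategy (every frame registered directly
to frame 70) must instead cope with large early/late contrast differences
and therefore seeds its registrations with a normalized-mutual-information
search.

## Registration

### Symmetric diffeomorphic engine

Pairwise nonrigid registration follows the symmetric-normalization idea:
two half-warps evolve the fixed and moving images toward a common midpoint,
and the final forward map is the moving half composed with the inverted
fixed half, so a consistent forward/inverse pair is returned by
construction. The continuous formulation — minimize image dissimilarity
plus a smoothness penalty on a time-varying velocity field, with the warp
obtained by integrating that field — is discretized greedily: per iteration,

1. warp both images to the current midpoint;
2. compute the analytic gradient of the mean squared windowed (local)
   cross-correlation with respect to each warped image, and turn it into a
   displacement update via the intensity gradient;
3. smooth the update with a Gaussian of `sigma_update` voxels (the
   practical realization of the velocity-smoothness penalty);
4. cap the update magnitude at `step` voxels and compose it into the
   corresponding half-field and its running inverse;
5. reject the update and halve the step if the metric worsens or any
   interior Jacobian determinant of a half-field becomes non-positive; the
   step relaxes back toward its cap after accepted iterations.

The local-CC gradient is exact: the derivative of the mean of CC^2 over all
valid windows with respect to every voxel, accumulated by box filters over
the windows containing the voxel (a finite-difference check at 1e-4 is part
of the test suite). Windows touching the image border or with (near-)zero
variance are excluded from the mean rather than zero-filled, which avoids
background bias.

Registration is multi-resolution (3 levels, shrink 4/2/1, pre-smoothing
2/1/0 voxels, iterations 40/40/60) and entirely deterministic — there is no
random initialization anywhere, so identical inputs give identical fields.
Before the diffeomorphic refinement, a bulk translation is estimated at the
coarsest level (Powell search maximizing NCC, or a sub-voxel NMI grid
search in the mid-frame pairing mode) and split evenly between the two
half-fields. This rigid-first initialization matters: greedy local-CC
updates recover bulk body shifts extremely slowly on their own, while a
body shift is precisely the dominant motion mode in practice.

Default parameters (all overridable via `SynConfig` / YAML):

| parameter | default | units | why |
| --- | --- | --- | --- |
| `step_vox` | 0.4 | voxels/iteration | stability cap on each update; must be <= 0.5 |
| `sigma_update_vox` | 1.5 | voxels | fluid regularization; larger values oversmooth at PET voxel sizes (6-9 mm) and suppress deformation scales of interest |
| `sigma_total_vox` | 0.0 | voxels | per-iteration smoothing of the accumulated field decays the recovered warp geometrically; off by default |
| `cc_radius` | 2 | voxels | 5^3 local-CC window |
| `iterations` | (40, 40, 60) | per level | deformation detail lives at the finest level |
| convergence | < 1e-6 improvement over 10 iterations | cc^2 | per-level early stop |

### Affine engine

The affine comparison strategy models motion as translation + rotation +
anisotropic scale (9 parameters, no shear), optimized per pyramid level by
Powell's direction-set method (fractional tolerance 1e-4, at most 500
iterations) on the global NCC, with the coarse-level result initializing
the next finer level. Parameters are scaled (mm; radians x 100;
log-scale x 100) so one Powell step is commensurate across parameter
types. Sequential affine totals are exact matrix products; they are
converted to a dense field only for uniform downstream handling.

### Fields and resampling

All transforms act on world coordinates (mm) in the pull (backward-warp)
convention; fields are stored in mm so composition is grid-independent.
Concatenation is `w(x) = inner(x) + outer(x + inner(x))` with linear
interpolation of the outer field, chosen so that the per-frame total field
maps reference-space points to frame-k space and each corrected frame is
produced by a single resampling (never k successive ones — repeated linear
interpolation compounds blur). Field inversion uses the standard fixed
point `v <- -u(x + v(x))`; inverses are tightened at the end of every
pyramid level. Diffeomorphism is monitored via the central-difference
Jacobian determinant of `x + u(x)`, which must stay positive on interior
voxels for every emitted field.

## Kinetics

Tissue activity follows the irreversible two-tissue-compartment model
(k4 = 0) with closed form

    CT(t) = Ki * int_0^t Cp + (K1 k2 / (k2+k3)) * [exp(-(k2+k3)t) (*) Cp](t),
    Ki    = K1 k3 / (k2 + k3).

The fractional blood-volume term is omitted and plasma is taken equal to
whole blood. The convolution is evaluated on a uniform 1-s grid as a causal
recursive filter equivalent to the trapezoid rule (O(n) per model
evaluation; verified against a stiff ODE integration of the compartment
system to < 0.1%). Model TACs are averaged over each frame interval before
comparison with measured frame values.

Fitting is bounded nonlinear least squares (K1, k2 in [0, 3] /min, k3 in
[0, 1] /min) with uniform frame weights, from a fixed 3-point initial grid
with the best start kept — deterministic by construction. The fitting
residual FR is the sum of squared frame-domain differences over all fitted
voxels; because its raw units ((Bq/ml)^2) are awkward, the per-sample RMS
form (Bq/ml) is reported alongside. Patlak graphical analysis (OLS slope of
CT/Cp against intCp/Cp over frames with mid-time >= t*) provides an
independent estimate of Ki used as a cross-method check; on noise-free
irreversible data the two agree to ~1-3%, limited by the finite t*.

The image-derived input function is the per-frame mean in a cylindrical
blood-pool ROI (10-mm diameter, 6 consecutive slices) placed on the
ascending aorta in the 0-60 s combined image, sampled at frame mid-times.

## Synthetic phantom

The generator emulates a 60-min dynamic total-body acquisition at desk
scale: a 64 x 64 x 192 grid at 6 mm isotropic spacing (a stand-in for the
clinical 192 x 192 x 673 at ~3 mm), the 90-frame fine schedule, ellipsoidal
organs (cerebral cortex, liver, kidney cortex, thigh muscle, blood-pool
aorta, optional tumor) with representative FDG rate constants, a Feng-type
analytic arterial input (bolus peak + multi-exponential washout), and body
motion beginning after frame 40. Motion events are either rigid shifts or
smooth random deformations built by exponentiating (scaling-and-squaring) a
Gaussian-smoothed stationary velocity field — diffeomorphic by
construction, with exact inverses, both exported as ground truth.

Two realism choices deserve emphasis because naive phantoms actively
mislead registration benchmarks:

* **Reconstruction PSF.** Organ uptake is blurred with a 6-mm Gaussian.
  Piecewise-constant organs have edges far sharper than any reconstruction
  delivers, and with such edges the similarity optimum sits ~1.5 mm away
  from the true motion purely through interpolation-blur effects.
* **Intra-organ texture.** Uptake within each structure is modulated by a
  smooth multiplicative field (15% amplitude, 50-mm correlation length),
  normalized to zero mean per structure so organ-mean TACs stay exactly on
  the compartment model. Without texture, motion of a homogeneous interior
  is unobservable to any intensity-driven method (the aperture problem) and
  no registration could recover it even in principle.

Noise is additive Gaussian with variance proportional to mean frame
activity divided by frame duration — a post-reconstruction surrogate for
count statistics, scaled so a 1-min frame at the scan-mean activity has 5%
relative noise by default. The phantom does **not** simulate
attenuation-map mismatch, scatter, randoms, projection-domain Poisson
statistics, intra-frame motion, or respiratory/cardiac cycles; passing
tests therefore demonstrate correctness of the correction and
quantification machinery under controlled motion, not clinical performance.
Partial-volume bias exists only through the PSF blur; tests stated on a
partial-volume-free phantom disable it.

## Test-scale choices

End-to-end pipeline tests and the repeated runs in `scripts/acceptance.py`
use a reduced phantom (28 x 28 x 72 at 9 mm, sixteen 1-min frames,
reference frame 10, motion from frame 12) so that a full
generate-correct-fit-evaluate cycle completes in about a minute; the
single-pair warp-recovery benchmark runs at the full 64 x 64 x 192 default
grid. The reduced scale is a deliberate package choice for routine
verification; the library itself has no size assumptions. At the reduced
9-mm resolution, partial amplitude recovery of fine-scale warps is expected
(the similarity surface is nearly flat between partial and full recovery on
smooth images), which is why desk-scale assertions demand clear error
reduction rather than exact recovery.

## Known limitations

* The greedy two-half-field scheme is a surrogate for the full
  time-discretized geodesic formulation; it returns a diffeomorphic pair
  but not a geodesic path.
* An NMI gradient for dense fields is not implemented; the mid-frame mode
  uses NMI only for its translation seeding, with local CC driving the
  diffeomorphic refinement.
* Sequential correction propagates any pairwise failure to later frames;
  failures are therefore substituted with the identity, flagged, and
  surfaced in the result rather than silently absorbed.
* Decay correction is assumed already applied by the scanner; the package
  performs none.
* B-spline transform models and GPU execution are out of scope.
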