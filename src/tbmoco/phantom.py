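"""Synthetic 4-D dynamic total-body FDG phantom with ground truth.

The phantom emulates a 60-min dynamic acquisition on a long-axial-FOV
scanner: multi-organ ellipsoids whose time-activity curves follow the
irreversible two-tissue-compartment model driven by a Feng-type arterial
input function, inter-frame body shifts and smooth deformations starting
after the motion-free early window, and additive Gaussian noise whose
variance scales with mean activity and inversely with frame duration (a
post-reconstruction surrogate for count statistics). Smooth deformations
are built by integrating a Gaussian-smoothed stationary velocity field with
scaling-and-squaring, which guarantees diffeomorphic (positive-Jacobian)
truth fields together with their exact inverses.

Everything is reproducible from the spec's seed, and the generator exports
the full ground truth: per-frame displacement fields to the reference
position, organ masks, true K1/Ki maps, the true plasma input and the
noise-free reference-position dynamic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DynamicImage, FrameSchedule, VoxelGrid, build_schedule
from .errors import InvalidArgumentError
from .kinetics import InputFunction, KineticParams, _ModelContext, feng_input
from .transforms import DiffeoTransform, DisplacementField, compose, jacobian_determinant, resample

__all__ = [
    "OrganSpec",
    "MotionEvent",
    "PhantomSpec",
    "PhantomTruth",
    "generate",
    "static_phantom",
    "default_paper_like_spec",
    "small_test_spec",
]


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ: world-mm center/radii and its kinetic behaviour.

    ``blood=True`` marks a blood-pool structure (the aorta) whose TAC is the
    plasma input itself rather than a 2TC tissue response.
    """

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    params: KineticParams | None = None
    blood: bool = False

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise InvalidArgumentError(f"organ {self.name}: radii must be positive")
        if not self.blood and self.params is None:
            raise InvalidArgumentError(f"organ {self.name}: kinetic parameters required")


@dataclass(frozen=True)
class MotionEvent:
    """A body-motion event switching on at ``onset_frame`` (1-based) and
    persisting for the rest of the scan.

    ``kind`` is ``"shift"`` (rigid translation along ``direction``) or
    ``"smooth-warp"`` (random smooth diffeomorphic deformation with spatial
    scale ``wavelength_mm``); ``magnitude_mm`` is the peak displacement.
    """

    onset_frame: int
    kind: str
    magnitude_mm: float
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    wavelength_mm: float = 80.0

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "smooth-warp"):
            raise InvalidArgumentError(f"unknown motion kind {self.kind!r}")
        if self.magnitude_mm < 0:
            raise InvalidArgumentError("motion magnitude must be >= 0")
        if self.onset_frame < 1:
            raise InvalidArgumentError("onset frame must be >= 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic dynamic acquisition."""

    grid: VoxelGrid
    schedule: FrameSchedule
    body: OrganSpec
    organs: tuple[OrganSpec, ...]
    cp_scale_Bq_ml: float = 4000.0
    cp_delay_s: float = 30.0
    motion: tuple[MotionEvent, ...] = ()
    noise_level: float = 0.05
    # emulates the reconstruction point-spread function / post-smoothing;
    # without it the piecewise-constant organs would have unphysically sharp
    # edges at desk-scale voxel sizes
    psf_sigma_mm: float = 6.0
    # smooth multiplicative uptake heterogeneity inside each structure,
    # zero-mean per structure so organ-mean TACs stay exactly on-model; real
    # tracer distributions are never uniform, and without internal texture a
    # deformation of a homogeneous interior would be unobservable to any
    # intensity-based registration
    texture_amp: float = 0.15
    texture_wavelength_mm: float = 50.0
    seed: int = 0
    reference_cut_s: float = 600.0


@dataclass
class PhantomTruth:
    """Ground truth exported alongside the observed dynamic."""

    fields_to_reference: dict  # 1-based frame -> DiffeoTransform (absent = identity)
    organ_masks: dict  # name -> bool array (reference position)
    body_mask: np.ndarray
    k1_map: np.ndarray
    ki_map: np.ndarray
    cp: InputFunction
    noise_free: DynamicImage  # reference-position, noise-free series
    organ_tacs: dict  # name -> frame-averaged true TAC (Bq/ml)

    def field_to_reference(self, k: int) -> DisplacementField:
        d = self.fields_to_reference.get(k)
        if d is None:
            return DisplacementField.zero(self.noise_free.grid)
        return d.forward


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_mask(grid: VoxelGrid, center_mm, radii_mm) -> np.ndarray:
    xyz = grid.world_coordinates()
    c = np.asarray(center_mm, dtype=float)
    r = np.asarray(radii_mm, dtype=float)
    return (((xyz - c) / r) ** 2).sum(axis=-1) <= 1.0


def _exp_velocity(v: np.ndarray, grid: VoxelGrid, n_squarings: int = 6) -> DisplacementField:
    """Integrate a stationary velocity field by scaling and squaring."""
    u = DisplacementField(v / (2.0**n_squarings), grid)
    for _ in range(n_squarings):
        u = compose(u, u)
    return u


def _event_diffeo(event: MotionEvent, grid: VoxelGrid, rng: np.random.Generator) -> DiffeoTransform:
    """Build (generating pull field g, inverse) for one motion event.

    The observed frame is ``resample(reference, g)``; the truth field that
    re-aligns the frame to the reference is the inverse of g.
    """
    if event.kind == "shift":
        d = np.asarray(event.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise InvalidArgumentError("shift direction must be non-zero")
        t = event.magnitude_mm * d / nrm
        return DiffeoTransform(
            forward=DisplacementField.constant(grid, -t),
            inverse=DisplacementField.constant(grid, t),
        )
    # smooth-warp: smoothed white-noise stationary velocity, exponentiated
    sigma_vox = event.wavelength_mm / (2.0 * float(np.mean(grid.spacing)))
    v = rng.standard_normal(size=grid.shape + (3,))
    for c in range(3):
        v[..., c] = ndimage.gaussian_filter(v[..., c], sigma_vox, mode="constant")
    mx = float(np.linalg.norm(v, axis=-1).max())
    if mx > 0:
        v *= event.magnitude_mm / mx
    fwd = _exp_velocity(v, grid)
    inv = _exp_velocity(-v, grid)
    return DiffeoTransform(forward=fwd, inverse=inv)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _organ_frame_values(spec: PhantomSpec) -> tuple[dict, InputFunction]:
    """Frame-averaged true TAC per structure (body background + organs)."""
    cp = feng_input(spec.schedule, scale_Bq_ml=spec.cp_scale_Bq_ml, delay_s=spec.cp_delay_s)
    ctx = _ModelContext(cp, spec.schedule)
    tacs = {spec.body.name: ctx.frame_tac(spec.body.params.K1, spec.body.params.k2, spec.body.params.k3)}
    for organ in spec.organs:
        if organ.blood:
            tacs[organ.name] = ctx.frame_average(ctx.cp)
        else:
            tacs[organ.name] = ctx.frame_tac(organ.params.K1, organ.params.k2, organ.params.k3)
    return tacs, cp


def _masks(spec: PhantomSpec) -> tuple[dict, np.ndarray]:
    """Organ masks with exclusive ownership: where ellipsoids overlap, the
    later organ in the spec wins (matching the frame-assignment order)."""
    body = _ellipsoid_mask(spec.grid, spec.body.center_mm, spec.body.radii_mm)
    raw = {}
    for organ in spec.organs:
        m = _ellipsoid_mask(spec.grid, organ.center_mm, organ.radii_mm)
        if not (m & body).sum() == m.sum():
            raise InvalidArgumentError(f"organ {organ.name} extends outside the body")
        raw[organ.name] = m
    claimed = np.zeros(spec.grid.shape, dtype=bool)
    masks = {}
    for organ in reversed(spec.organs):
        m = raw[organ.name] & ~claimed
        if not m.any():
            raise InvalidArgumentError(f"organ {organ.name} has an empty mask on this grid")
        masks[organ.name] = m
        claimed |= m
    return {o.name: masks[o.name] for o in spec.organs}, body


def _texture_field(
    spec: PhantomSpec, masks: dict, body: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative heterogeneity map (1 + t), zero-mean unit-free texture
    per structure; returns all-ones when texture is disabled."""
    if spec.texture_amp <= 0:
        return np.ones(spec.grid.shape)
    sigma_vox = [
        spec.texture_wavelength_mm / (2.0 * s) for s in spec.grid.spacing
    ]
    raw = ndimage.gaussian_filter(rng.standard_normal(spec.grid.shape), sigma_vox)
    t = np.zeros(spec.grid.shape)
    organ_union = np.zeros(spec.grid.shape, dtype=bool)
    regions = list(masks.values())
    for m in regions:
        organ_union |= m
    regions.append(body & ~organ_union)  # background tissue
    for m in regions:
        if m.sum() < 2:
            continue
        r = raw[m]
        sd = r.std()
        if sd > 0:
            t[m] = spec.texture_amp * (r - r.mean()) / sd
    return 1.0 + t


def _apply_psf(im: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.psf_sigma_mm <= 0:
        return im
    sigma_vox = [spec.psf_sigma_mm / s for s in spec.grid.spacing]
    return ndimage.gaussian_filter(im, sigma_vox)


def static_phantom(spec: PhantomSpec, frame_index: int | None = None) -> np.ndarray:
    """One noise-free reference-position frame (default: the last frame)."""
    tacs, _ = _organ_frame_values(spec)
    masks, body = _masks(spec)
    tex = _texture_field(spec, masks, body, np.random.default_rng(spec.seed))
    k = (frame_index or len(spec.schedule)) - 1
    im = np.zeros(spec.grid.shape)
    im[body] = tacs[spec.body.name][k]
    for organ in spec.organs:
        im[masks[organ.name]] = tacs[organ.name][k]
    return _apply_psf(im * tex, spec)


def generate(spec: PhantomSpec) -> tuple[DynamicImage, PhantomTruth]:
    """Generate the observed noisy dynamic series plus full ground truth."""
    rng = np.random.default_rng(spec.seed)
    tacs, cp = _organ_frame_values(spec)
    masks, body = _masks(spec)
    n = len(spec.schedule)

    from .core import reference_frame_index

    try:
        ref = reference_frame_index(spec.schedule, spec.reference_cut_s)
    except Exception:
        ref = 0
    for ev in spec.motion:
        if ev.onset_frame <= ref:
            import warnings

            warnings.warn(
                f"motion event at frame {ev.onset_frame} precedes the reference "
                f"frame {ref}; sequential correction will not remove it",
                RuntimeWarning,
                stacklevel=2,
            )

    # noise-free reference-position frames
    tex = _texture_field(spec, masks, body, rng)
    ref_frames = np.zeros((n,) + spec.grid.shape, dtype=np.float32)
    for k in range(n):
        im = np.zeros(spec.grid.shape)
        im[body] = tacs[spec.body.name][k]
        for organ in spec.organs:
            im[masks[organ.name]] = tacs[organ.name][k]
        ref_frames[k] = _apply_psf(im * tex, spec)

    # motion events -> per-frame generating/inverse diffeos (events are drawn
    # once, in onset order, then concatenated as they switch on)
    events = sorted(spec.motion, key=lambda e: e.onset_frame)
    event_diffeos = [_event_diffeo(ev, spec.grid, rng) for ev in events]
    for ev, d in zip(events, event_diffeos):
        jd = jacobian_determinant(d.forward)
        if float(jd[1:-1, 1:-1, 1:-1].min()) <= 0:
            raise InvalidArgumentError(
                f"motion event at frame {ev.onset_frame} (magnitude "
                f"{ev.magnitude_mm} mm) is not diffeomorphic on this grid"
            )

    combo_cache: dict[tuple, DiffeoTransform] = {}

    def combined(active: tuple[int, ...]) -> DiffeoTransform | None:
        if not active:
            return None
        if active not in combo_cache:
            g = event_diffeos[active[0]].forward
            gi = event_diffeos[active[0]].inverse
            for i in active[1:]:
                g = compose(g, event_diffeos[i].forward)
                gi = compose(event_diffeos[i].inverse, gi)
            combo_cache[active] = DiffeoTransform(forward=g, inverse=gi)
        return combo_cache[active]

    observed = ref_frames.copy()
    fields_to_ref: dict[int, DiffeoTransform] = {}
    for k in range(1, n + 1):
        active = tuple(i for i, ev in enumerate(events) if ev.onset_frame <= k)
        d = combined(active)
        if d is None:
            continue
        observed[k - 1] = resample(
            ref_frames[k - 1].astype(float), spec.grid, d.forward, interp="linear"
        )
        # the aligning (truth) field is the inverse of the generating field
        fields_to_ref[k] = DiffeoTransform(forward=d.inverse, inverse=d.forward)

    # activity/duration-scaled Gaussian noise (post-reconstruction surrogate):
    # var_k ~ mean_k / duration_k, normalized so a 60-s frame at the scan-mean
    # activity has relative noise `noise_level`
    if spec.noise_level > 0:
        durs = spec.schedule.durations
        frame_means = np.array([observed[k][body].mean() for k in range(n)])
        a_ref = max(float(frame_means.mean()), 1e-9)
        var = spec.noise_level**2 * np.clip(frame_means, 0, None) * a_ref * (60.0 / durs)
        for k in range(n):
            observed[k] = observed[k] + rng.normal(
                0.0, np.sqrt(var[k]), size=spec.grid.shape
            ).astype(np.float32)

    # the multiplicative texture scales every voxel TAC, which for the 2TC
    # model is exactly a local scaling of K1 (and hence Ki); the truth maps
    # carry that factor so voxelwise fits are comparable per voxel
    k1_map = np.zeros(spec.grid.shape)
    ki_map = np.zeros(spec.grid.shape)
    k1_map[body] = spec.body.params.K1
    ki_map[body] = spec.body.params.Ki
    for organ in spec.organs:
        m = masks[organ.name]
        if organ.blood:
            k1_map[m] = 0.0
            ki_map[m] = 0.0
        else:
            k1_map[m] = organ.params.K1
            ki_map[m] = organ.params.Ki
    k1_map *= tex
    ki_map *= tex

    truth = PhantomTruth(
        fields_to_reference=fields_to_ref,
        organ_masks=masks,
        body_mask=body,
        k1_map=k1_map,
        ki_map=ki_map,
        cp=cp,
        noise_free=DynamicImage(ref_frames, spec.grid, spec.schedule),
        organ_tacs=tacs,
    )
    return DynamicImage(observed, spec.grid, spec.schedule), truth


# ---------------------------------------------------------------------------
# stock specifications
# ---------------------------------------------------------------------------

# typical whole-body FDG rate constants (per-minute); implementer-chosen
# representative values for a synthetic subject, not patient-derived
_ORGAN_PARAMS = {
    "cerebral_cortex": KineticParams(0.10, 0.13, 0.06),
    "liver": KineticParams(0.60, 0.80, 0.01),
    "kidney_cortex": KineticParams(0.35, 0.30, 0.02),
    "thigh_muscle": KineticParams(0.03, 0.25, 0.02),
    "tumor": KineticParams(0.30, 0.45, 0.10),
}
_BODY_PARAMS = KineticParams(0.05, 0.40, 0.01)


def default_paper_like_spec(seed: int = 0, with_tumor: bool = True) -> PhantomSpec:
    """Desk-scale stand-in for a 60-min total-body acquisition.

    90-frame schedule (5 s x 24, 10 s x 6, 30 s x 6, 60 s x 54) on a
    64 x 64 x 192 grid at 6 mm isotropic spacing; body motion (a shift and a
    smooth deformation) begins after the reference frame 40.
    """
    grid = VoxelGrid.centered((64, 64, 192), (6.0, 6.0, 6.0))
    schedule = build_schedule([(5, 24), (10, 6), (30, 6), (60, 54)])
    body = OrganSpec("body", (0.0, 0.0, 0.0), (160.0, 130.0, 560.0), _BODY_PARAMS)
    organs = [
        OrganSpec("cerebral_cortex", (0.0, 0.0, 440.0), (50.0, 50.0, 45.0),
                  _ORGAN_PARAMS["cerebral_cortex"]),
        OrganSpec("liver", (45.0, 25.0, 130.0), (80.0, 60.0, 55.0), _ORGAN_PARAMS["liver"]),
        OrganSpec("kidney_cortex", (-55.0, -35.0, 60.0), (28.0, 20.0, 40.0),
                  _ORGAN_PARAMS["kidney_cortex"]),
        OrganSpec("thigh_muscle", (40.0, 0.0, -380.0), (40.0, 40.0, 140.0),
                  _ORGAN_PARAMS["thigh_muscle"]),
        OrganSpec("aorta", (0.0, -40.0, 280.0), (14.0, 14.0, 110.0), blood=True),
    ]
    if with_tumor:
        organs.append(
            OrganSpec("tumor", (-60.0, 30.0, 170.0), (20.0, 20.0, 20.0), _ORGAN_PARAMS["tumor"])
        )
    motion = (
        MotionEvent(48, "shift", 6.0, direction=(0.3, 0.2, 0.95)),
        MotionEvent(66, "smooth-warp", 6.0, wavelength_mm=90.0),
    )
    return PhantomSpec(
        grid=grid,
        schedule=schedule,
        body=body,
        organs=tuple(organs),
        motion=motion,
        noise_level=0.05,
        seed=seed,
    )


def small_test_spec(
    seed: int = 0,
    motion: tuple[MotionEvent, ...] | None = None,
    noise_level: float = 0.05,
    with_tumor: bool = True,
) -> PhantomSpec:
    """Reduced phantom for fast end-to-end runs.

    28 x 28 x 72 grid at 9 mm, 16 one-minute frames (reference = frame 10,
    motion beginning at frame 12 by default). Same organ set and kinetics as
    the default phantom, scaled to the smaller field of view.
    """
    grid = VoxelGrid.centered((28, 28, 72), (9.0, 9.0, 9.0))
    schedule = build_schedule([(60, 16)])
    body = OrganSpec("body", (0.0, 0.0, 0.0), (105.0, 95.0, 300.0), _BODY_PARAMS)
    organs = [
        OrganSpec("cerebral_cortex", (0.0, 0.0, 230.0), (40.0, 40.0, 36.0),
                  _ORGAN_PARAMS["cerebral_cortex"]),
        OrganSpec("liver", (28.0, 18.0, 65.0), (55.0, 45.0, 42.0), _ORGAN_PARAMS["liver"]),
        OrganSpec("kidney_cortex", (-35.0, -25.0, 10.0), (25.0, 20.0, 32.0),
                  _ORGAN_PARAMS["kidney_cortex"]),
        OrganSpec("thigh_muscle", (18.0, 0.0, -190.0), (30.0, 30.0, 80.0),
                  _ORGAN_PARAMS["thigh_muscle"]),
        OrganSpec("aorta", (0.0, -30.0, 140.0), (16.0, 16.0, 85.0), blood=True),
    ]
    if with_tumor:
        organs.append(
            OrganSpec("tumor", (-42.0, 22.0, 95.0), (20.0, 20.0, 20.0), _ORGAN_PARAMS["tumor"])
        )
    if motion is None:
        motion = (
            MotionEvent(12, "shift", 8.0, direction=(0.4, 0.2, 0.9)),
            MotionEvent(14, "smooth-warp", 6.0, wavelength_mm=70.0),
        )
    return PhantomSpec(
        grid=grid,
        schedule=schedule,
        body=body,
        organs=tuple(organs),
        motion=tuple(motion),
        noise_level=noise_level,
        seed=seed,
        reference_cut_s=600.0,
    )
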