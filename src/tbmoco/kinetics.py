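"""Irreversible two-tissue-compartment FDG kinetics.

The tracer model is the standard irreversible 2TC (k4 = 0):

    dC1/dt = K1 Cp(t) - (k2 + k3) C1,    dC2/dt = k3 C1,    CT = C1 + C2

whose closed form is

    CT(t) = Ki * int_0^t Cp + (K1 k2 / (k2 + k3)) * [exp(-(k2+k3) t) (*) Cp](t)

with the net influx rate Ki = K1 k3 / (k2 + k3). The fractional blood-volume
term is omitted and plasma is taken equal to whole blood. Convolutions are
evaluated by trapezoid rule on a uniform 1-second grid (as a causal recursive
filter, so each model evaluation is O(n)); model TACs are averaged over each
frame interval before comparison with data.

Fitting is bounded nonlinear least squares with uniform frame weights and a
small fixed multi-start grid; the fitting residual FR is the plain sum of
squared differences between measured and model frame values over all voxels
and frames, reported both raw ((Bq/ml)^2) and as a root-mean-square in Bq/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .core import DynamicImage, FrameSchedule
from .errors import InvalidArgumentError

__all__ = [
    "InputFunction",
    "KineticParams",
    "KineticFit",
    "feng_input",
    "extract_idif",
    "cylinder_mask",
    "model_tac",
    "fit_tac",
    "fit_map",
    "patlak_ki",
]

_DT = 1.0  # model integration grid (seconds)

# fixed multi-start initial points (K1 ml/min/ml, k2 1/min, k3 1/min)
_DEFAULT_STARTS = ((0.05, 0.10, 0.01), (0.30, 0.50, 0.05), (1.00, 1.00, 0.20))
_DEFAULT_BOUNDS = ((0.0, 3.0), (0.0, 3.0), (0.0, 1.0))


@dataclass(frozen=True)
class InputFunction:
    """Arterial plasma activity Cp(t): sample times (s) and values (Bq/ml).

    Dense evaluation is by linear interpolation, zero before the first
    sample and constant after the last.
    """

    times_s: tuple
    cp_Bq_ml: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.cp_Bq_ml, dtype=float)
        if t.ndim != 1 or t.size != c.size or t.size < 2:
            raise InvalidArgumentError("input function needs matching 1-D time/value arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("input-function times must be strictly increasing")
        if np.any(c < 0):
            raise InvalidArgumentError("plasma activity must be non-negative")
        object.__setattr__(self, "times_s", tuple(float(x) for x in t))
        object.__setattr__(self, "cp_Bq_ml", tuple(float(x) for x in c))

    def dense(self, t_end_s: float, dt_s: float = _DT) -> tuple[np.ndarray, np.ndarray]:
        """Cp on a uniform grid [0, t_end] with step dt."""
        t = np.arange(0.0, t_end_s + dt_s / 2, dt_s)
        tt = np.asarray(self.times_s)
        cc = np.asarray(self.cp_Bq_ml)
        c = np.interp(t, tt, cc, left=0.0, right=cc[-1])
        c[t < tt[0]] = 0.0
        return t, c

    def to_tsv(self, path) -> None:
        lines = ["time_s\tcp_Bq_ml"] + [
            f"{t:g}\t{c:g}" for t, c in zip(self.times_s, self.cp_Bq_ml)
        ]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "InputFunction":
        from pathlib import Path

        rows = Path(path).read_text().strip().splitlines()
        if rows and not rows[0].split("\t")[0].replace(".", "").lstrip("-").isdigit():
            rows = rows[1:]
        t, c = zip(*(tuple(float(x) for x in r.split("\t")[:2]) for r in rows))
        return cls(t, c)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the irreversible 2TC model (per-minute units)."""

    K1: float  # ml/min/ml, plasma -> tissue delivery
    k2: float  # 1/min, tissue -> plasma efflux
    k3: float  # 1/min, trapping (phosphorylation)

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise InvalidArgumentError("rate constants must be non-negative")

    @property
    def Ki(self) -> float:
        """Net influx rate K1 k3 / (k2 + k3), ml/min/ml; equals K1 when k2=0."""
        denom = self.k2 + self.k3
        if denom == 0.0:
            return self.K1  # pure-trapping limit: everything delivered is kept
        return self.K1 * self.k3 / denom


@dataclass
class KineticFit:
    """Result of a TAC or map fit: parameters, residuals and the global FR."""

    params: KineticParams | None
    residual_ss: float  # sum of squared residuals, (Bq/ml)^2
    n_points: int
    fitted_tac: np.ndarray | None = None
    flagged: bool = False

    @property
    def fr(self) -> float:
        """Fitting residual: raw sum of squared differences, (Bq/ml)^2."""
        return self.residual_ss

    @property
    def fr_rms(self) -> float:
        """Root-mean-square residual in Bq/ml (unit-unambiguous form)."""
        return float(np.sqrt(self.residual_ss / max(self.n_points, 1)))


# ---------------------------------------------------------------------------
# input functions
# ---------------------------------------------------------------------------

def feng_input(
    schedule_or_tend,
    scale_Bq_ml: float = 4000.0,
    delay_s: float = 30.0,
    dt_s: float = _DT,
) -> InputFunction:
    """Feng-type analytic arterial input function.

    Cp(t') = (A1 t' - A2 - A3) e^{l1 t'} + A2 e^{l2 t'} + A3 e^{l3 t'} for
    t' = t - delay (minutes), with the classic FDG parameter set
    A = (851.1, 21.9, 20.8), l = (-4.134, -0.1191, -0.01043) min^-1, rescaled
    so the late-time (60-min) plasma level is about ``scale_Bq_ml``.
    """
    t_end = (
        schedule_or_tend.total_duration
        if isinstance(schedule_or_tend, FrameSchedule)
        else float(schedule_or_tend)
    )
    t = np.arange(0.0, t_end + dt_s / 2, dt_s)
    tm = np.clip((t - delay_s) / 60.0, 0.0, None)  # minutes post-arrival
    A1, A2, A3 = 851.1225, 21.8798, 20.8113
    l1, l2, l3 = -4.1339, -0.1191, -0.01043
    cp = (A1 * tm - A2 - A3) * np.exp(l1 * tm) + A2 * np.exp(l2 * tm) + A3 * np.exp(l3 * tm)
    cp[t < delay_s] = 0.0
    cp = np.clip(cp, 0.0, None)
    late = cp[-1] if cp[-1] > 0 else cp.max()
    return InputFunction(tuple(t), tuple(cp * (scale_Bq_ml / late)))


def cylinder_mask(
    grid, center_world, diameter_mm: float = 10.0, n_slices: int = 6
) -> np.ndarray:
    """Cylindrical blood-pool ROI: ``diameter_mm`` circle on ``n_slices``
    consecutive axial slices centered at ``center_world`` (mm).

    This mirrors the image-derived input-function ROI drawn on the ascending
    aorta in an early (0-60 s) combined image.
    """
    xyz = grid.world_coordinates()
    c = np.asarray(center_world, dtype=float)
    r2 = (diameter_mm / 2.0) ** 2
    in_circle = ((xyz[..., 0] - c[0]) ** 2 + (xyz[..., 1] - c[1]) ** 2) <= r2
    k_c = int(round(grid.world_to_voxel(c[None, :])[0][2]))
    k0 = max(0, k_c - (n_slices - 1) // 2)
    k1 = min(grid.shape[2], k0 + n_slices)
    in_slices = np.zeros(grid.shape, dtype=bool)
    in_slices[:, :, k0:k1] = True
    mask = in_circle & in_slices
    if not mask.any():
        raise InvalidArgumentError("cylindrical ROI does not intersect the grid")
    return mask


def extract_idif(dynamic: DynamicImage, aorta_mask: np.ndarray) -> InputFunction:
    """Image-derived input function: per-frame mean concentration in the
    blood-pool mask, sampled at frame mid-times."""
    import warnings

    mask = np.asarray(aorta_mask, dtype=bool)
    if not mask.any():
        raise InvalidArgumentError("empty aorta mask")
    vals = dynamic.data[:, mask].mean(axis=1).astype(float)
    if np.allclose(vals, 0.0):
        warnings.warn("IDIF mask contains no activity", RuntimeWarning, stacklevel=2)
    times = dynamic.schedule.mid_times
    return InputFunction(tuple(times), tuple(np.clip(vals, 0.0, None)))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

class _ModelContext:
    """Precomputed quantities shared by many model evaluations on one
    (input function, schedule) pair."""

    def __init__(self, cp: InputFunction, schedule: FrameSchedule, dt_s: float = _DT):
        self.schedule = schedule
        self.dt = dt_s
        self.t, self.cp = cp.dense(schedule.total_duration, dt_s)
        # cumulative trapezoid integral of Cp in minutes (rates are 1/min)
        dt_min = dt_s / 60.0
        self.int_cp = np.concatenate(
            [[0.0], np.cumsum((self.cp[1:] + self.cp[:-1]) / 2.0) * dt_min]
        )
        self.frame_idx = [
            (int(round(a / dt_s)), int(round(b / dt_s))) for a, b in schedule.frames
        ]

    def conv_exp(self, lam_per_min: float) -> np.ndarray:
        """[exp(-lam t) (*) Cp](t) in (Bq/ml) * min, trapezoid rule, O(n)."""
        dt_min = self.dt / 60.0
        a = np.exp(-lam_per_min * dt_min)
        # y[i] = a y[i-1] + dt/2 (cp[i] + a cp[i-1])  <=> trapezoid convolution
        b = [dt_min / 2.0, a * dt_min / 2.0]
        return signal.lfilter(b, [1.0, -a], self.cp)

    def frame_average(self, ct: np.ndarray) -> np.ndarray:
        """Average a dense curve over each frame interval (trapezoid rule)."""
        cum = np.concatenate([[0.0], np.cumsum((ct[1:] + ct[:-1]) / 2.0) * self.dt])
        out = np.empty(len(self.frame_idx))
        for k, (i0, i1) in enumerate(self.frame_idx):
            out[k] = (cum[i1] - cum[i0]) / ((i1 - i0) * self.dt)
        return out

    def tissue_curve(self, K1: float, k2: float, k3: float) -> np.ndarray:
        lam = k2 + k3
        if lam <= 0.0:
            return K1 * self.int_cp  # pure-integral (full trapping) limit
        ki = K1 * k3 / lam
        return ki * self.int_cp + (K1 * k2 / lam) * self.conv_exp(lam)

    def frame_tac(self, K1: float, k2: float, k3: float) -> np.ndarray:
        return self.frame_average(self.tissue_curve(K1, k2, k3))


def model_tac(
    params: KineticParams, cp: InputFunction, schedule: FrameSchedule
) -> np.ndarray:
    """Frame-averaged tissue TAC (Bq/ml) predicted by the irreversible 2TC
    model for the given parameters and plasma input."""
    ctx = _ModelContext(cp, schedule)
    return ctx.frame_tac(params.K1, params.k2, params.k3)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_one(
    tac: np.ndarray,
    ctx: _ModelContext,
    starts=_DEFAULT_STARTS,
    bounds=_DEFAULT_BOUNDS,
    weights: np.ndarray | None = None,
) -> KineticFit:
    w = np.ones_like(tac) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def residuals(p):
        return sw * (ctx.frame_tac(*p) - tac)

    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return KineticFit(None, float(np.sum(w * tac**2)), tac.size, flagged=True)
    p = KineticParams(*best.x)
    fitted = ctx.frame_tac(*best.x)
    ss = float(np.sum(w * (fitted - tac) ** 2))
    return KineticFit(p, ss, tac.size, fitted_tac=fitted)


def fit_tac(
    tac: np.ndarray,
    cp: InputFunction,
    schedule: FrameSchedule,
    starts=_DEFAULT_STARTS,
    bounds=_DEFAULT_BOUNDS,
    weights: np.ndarray | None = None,
) -> KineticFit:
    """Fit the irreversible 2TC model to one frame-averaged TAC.

    Bounded least squares (default K1, k2 in [0, 3], k3 in [0, 1] per-minute)
    from a fixed 3-point initial grid; the best of the starts is kept. An
    all-zero TAC short-circuits to zero parameters with FR 0, flagged.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.size != len(schedule):
        raise InvalidArgumentError(
            f"TAC length {tac.size} does not match schedule {len(schedule)}"
        )
    if np.allclose(tac, 0.0):
        return KineticFit(KineticParams(0.0, 0.0, 0.0), 0.0, tac.size, flagged=True,
                          fitted_tac=np.zeros_like(tac))
    ctx = _ModelContext(cp, schedule)
    return _fit_one(tac, ctx, starts=starts, bounds=bounds, weights=weights)


@dataclass
class MapFit:
    """Voxelwise fit over a mask: parametric maps plus the global FR."""

    k1_map: np.ndarray
    ki_map: np.ndarray
    fr: float  # Eq.-style global sum of squared residuals, (Bq/ml)^2
    fr_rms: float  # per-sample RMS form, Bq/ml
    qc_flags: np.ndarray  # True where the voxel fit failed / was degenerate
    n_flagged: int


def fit_map(
    dynamic: DynamicImage,
    cp: InputFunction,
    mask: np.ndarray,
    starts=_DEFAULT_STARTS,
    bounds=_DEFAULT_BOUNDS,
) -> MapFit:
    """Voxelwise irreversible-2TC fit over ``mask`` producing K1 and Ki maps.

    The global fitting residual sums squared frame-domain residuals over all
    non-flagged voxels; flagged voxels (failed fits) are excluded and counted.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dynamic.grid.shape:
        raise InvalidArgumentError("mask shape does not match the dynamic grid")
    ctx = _ModelContext(cp, dynamic.schedule)
    k1 = np.zeros(dynamic.grid.shape)
    ki = np.zeros(dynamic.grid.shape)
    qc = np.zeros(dynamic.grid.shape, dtype=bool)
    fr = 0.0
    n_pts = 0
    coords = np.argwhere(mask)
    for x, y, z in coords:
        tac = dynamic.data[:, x, y, z].astype(float)
        if np.allclose(tac, 0.0):
            qc[x, y, z] = True
            continue
        fit = _fit_one(tac, ctx, starts=starts, bounds=bounds)
        if fit.flagged or fit.params is None:
            qc[x, y, z] = True
            continue
        k1[x, y, z] = fit.params.K1
        ki[x, y, z] = fit.params.Ki
        fr += fit.residual_ss
        n_pts += fit.n_points
    return MapFit(
        k1_map=k1,
        ki_map=ki,
        fr=fr,
        fr_rms=float(np.sqrt(fr / max(n_pts, 1))),
        qc_flags=qc,
        n_flagged=int(qc.sum()),
    )


# ---------------------------------------------------------------------------
# Patlak graphical analysis
# ---------------------------------------------------------------------------

def patlak_ki(
    dynamic_or_tac,
    cp: InputFunction,
    schedule: FrameSchedule | None = None,
    t_star_s: float = 1200.0,
):
    """Patlak net-influx slope Ki from the late-time linear phase.

    Ordinary least squares of CT(t)/Cp(t) against int_0^t Cp / Cp(t) over
    frames with mid-time >= ``t_star_s``; for an irreversible tracer the
    slope converges to K1 k3/(k2+k3). Accepts a 1-D TAC or a
    :class:`DynamicImage` (then a Ki map is returned). Frames where Cp <= 0
    are excluded; fewer than 3 usable frames is an error.
    """
    if isinstance(dynamic_or_tac, DynamicImage):
        dyn = dynamic_or_tac
        schedule = dyn.schedule
        tacs = dyn.data.reshape(dyn.n_frames, -1).astype(float)
        out_shape = dyn.grid.shape
    else:
        if schedule is None:
            raise InvalidArgumentError("schedule required when passing a bare TAC")
        tacs = np.asarray(dynamic_or_tac, dtype=float).reshape(len(schedule), -1)
        out_shape = None

    ctx = _ModelContext(cp, schedule)
    mids = schedule.mid_times
    mid_idx = np.clip(np.round(mids / ctx.dt).astype(int), 0, ctx.t.size - 1)
    cp_mid = ctx.cp[mid_idx]
    int_mid = ctx.int_cp[mid_idx]
    usable = (mids >= t_star_s) & (cp_mid > 0)
    if int(usable.sum()) < 3:
        raise InvalidArgumentError("fewer than 3 usable late frames for Patlak")
    x = int_mid[usable] / cp_mid[usable]
    y = tacs[usable] / cp_mid[usable, None]
    xm = x.mean()
    slope = ((x - xm) @ (y - y.mean(axis=0))) / np.sum((x - xm) ** 2)
    if out_shape is None:
        return float(slope[0]) if slope.size == 1 else slope
    return slope.reshape(out_shape)
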