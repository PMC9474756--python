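"""Core domain types for dynamic PET series.

Voxel/world geometry, frame-schedule arithmetic, 4D NIfTI I/O with a
frame-timing sidecar, frame combination/regrouping, and SUV normalization.

Conventions
-----------
* Frame indices are **1-based** in every user-facing API, matching common
  clinical reporting ("frame 40", "frame 70"); array storage is 0-based.
* Dynamic data are stored as ``data[frame, x, y, z]`` activity concentration
  in Bq/ml, assumed decay-corrected to injection time by the scanner.
* Voxel indices are 0-based; world coordinates are millimetres; a voxel's
  world position refers to its center (NIfTI convention).
* Combining frames always uses the duration-weighted *mean* concentration,
  never the sum, so combined images remain in Bq/ml and SUV semantics are
  preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InvalidArgumentError, NoReferenceFrameError

__all__ = [
    "VoxelGrid",
    "FrameSchedule",
    "DynamicImage",
    "SubjectMeta",
    "build_schedule",
    "reference_frame_index",
    "rebin_fine",
    "regroup",
    "combine_frames",
    "suv",
    "read_dynamic",
    "write_dynamic",
    "read_volume",
    "write_volume",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D sampling grid: voxel counts, spacing (mm), world origin (mm)
    and direction cosines mapping voxel axes to world axes."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise InvalidArgumentError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError(f"spacing must be positive, got {self.spacing}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3) or not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise InvalidArgumentError("direction cosines must be orthonormal")
        if np.linalg.det(d) < 0:
            raise InvalidArgumentError("direction cosines must have determinant +1")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", tuple(tuple(float(x) for x in row) for row in d))

    # -- geometry -----------------------------------------------------------
    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine, voxel-center convention."""
        A = np.eye(4)
        A[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the geometric center of the grid."""
        c_idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.voxel_to_world(c_idx[None, :])[0]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        M = self.direction_matrix @ np.diag(self.spacing)
        return idx @ M.T + np.asarray(self.origin)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm points to (fractional) voxel indices."""
        pts = np.asarray(pts, dtype=float)
        M = self.direction_matrix @ np.diag(self.spacing)
        return (pts - np.asarray(self.origin)) @ np.linalg.inv(M).T

    def world_coordinates(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel-center world coordinates."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        return self.voxel_to_world(idx)

    @classmethod
    def centered(cls, shape, spacing) -> "VoxelGrid":
        """Axis-aligned grid whose world origin places the center at (0,0,0)."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(shape=shape, spacing=spacing, origin=origin)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous, non-overlapping frame intervals (seconds).

    Frames are addressed 1-based in every public method.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        fr = tuple((float(a), float(b)) for a, b in self.frames)
        if not fr:
            raise InvalidArgumentError("schedule must contain at least one frame")
        for k, (a, b) in enumerate(fr):
            if not b > a:
                raise InvalidArgumentError(f"frame {k + 1} has end <= start: {(a, b)}")
            if k and not np.isclose(a, fr[k - 1][1]):
                raise InvalidArgumentError(
                    f"frames must be contiguous: frame {k} ends {fr[k - 1][1]}, "
                    f"frame {k + 1} starts {a}"
                )
        object.__setattr__(self, "frames", fr)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([b for _, b in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def mid_times(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.frames[-1][1])

    def bounds(self, k: int) -> tuple[float, float]:
        """(start_s, end_s) of 1-based frame k."""
        if not 1 <= k <= len(self.frames):
            raise InvalidArgumentError(f"frame index {k} out of range 1..{len(self.frames)}")
        return self.frames[k - 1]

    # -- sidecar I/O --------------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps([[a, b] for a, b in self.frames]))

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        try:
            pairs = json.loads(Path(path).read_text())
            return cls(tuple((float(a), float(b)) for a, b in pairs))
        except (json.JSONDecodeError, TypeError, ValueError) as exc:
            if isinstance(exc, InvalidArgumentError):
                raise
            raise FormatError(f"cannot parse frame sidecar {path}: {exc}") from exc

    def to_tsv(self, path) -> None:
        lines = ["start_s\tend_s"] + [f"{a:g}\t{b:g}" for a, b in self.frames]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "FrameSchedule":
        rows = Path(path).read_text().strip().splitlines()
        if rows and rows[0].lower().startswith("start"):
            rows = rows[1:]
        try:
            pairs = [tuple(float(x) for x in r.split("\t")[:2]) for r in rows]
            return cls(tuple(pairs))
        except (ValueError, IndexError) as exc:
            if isinstance(exc, InvalidArgumentError):
                raise
            raise FormatError(f"cannot parse frame TSV {path}: {exc}") from exc


@dataclass
class DynamicImage:
    """4-D dynamic series: ``data[frame, x, y, z]`` Bq/ml + grid + schedule."""

    data: np.ndarray
    grid: VoxelGrid
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InvalidArgumentError(f"dynamic data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[0] != len(self.schedule):
            raise InvalidArgumentError(
                f"{self.data.shape[0]} frames in data vs "
                f"{len(self.schedule)} in schedule"
            )
        if self.data.shape[1:] != self.grid.shape:
            raise InvalidArgumentError(
                f"frame shape {self.data.shape[1:]} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("dynamic data contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, k: int) -> np.ndarray:
        """3-D volume of 1-based frame k (a view)."""
        self.schedule.bounds(k)  # range check
        return self.data[k - 1]

    def copy(self) -> "DynamicImage":
        return DynamicImage(self.data.copy(), self.grid, self.schedule)


@dataclass(frozen=True)
class SubjectMeta:
    """Injected dose (Bq), body weight (g) and identifier, for SUV scaling."""

    injected_dose_Bq: float
    body_weight_g: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.injected_dose_Bq <= 0:
            raise InvalidArgumentError("injected dose must be positive")
        if self.body_weight_g <= 0:
            raise InvalidArgumentError("body weight must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "dose_Bq": self.injected_dose_Bq,
                    "weight_g": self.body_weight_g,
                    "subject_id": self.subject_id,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "SubjectMeta":
        d = json.loads(Path(path).read_text())
        return cls(d["dose_Bq"], d["weight_g"], d.get("subject_id", ""))


# ---------------------------------------------------------------------------
# schedule arithmetic
# ---------------------------------------------------------------------------

def build_schedule(segments) -> FrameSchedule:
    """Build a contiguous schedule starting at 0 s from (duration_s, count) runs.

    E.g. ``[(5, 24), (10, 6), (30, 6), (60, 6), (120, 24)]`` gives the 66-frame
    60-min clinical binning.
    """
    frames = []
    t = 0.0
    for dur, count in segments:
        if dur <= 0:
            raise InvalidArgumentError(f"non-positive frame duration {dur}")
        if int(count) < 1 or int(count) != count:
            raise InvalidArgumentError(f"invalid frame count {count}")
        for _ in range(int(count)):
            frames.append((t, t + dur))
            t += dur
    return FrameSchedule(tuple(frames))


def reference_frame_index(schedule: FrameSchedule, cut_s: float) -> int:
    """Largest 1-based frame index whose end time is <= ``cut_s``.

    The last frame ending within the motion-free early window (typically the
    first 10 min) serves as the registration reference.
    """
    ends = schedule.ends
    ok = np.nonzero(ends <= cut_s + 1e-9)[0]
    if ok.size == 0:
        raise NoReferenceFrameError(f"no frame ends by t = {cut_s} s")
    return int(ok[-1]) + 1


def rebin_fine(
    schedule: FrameSchedule, fine_duration_s: float = 60.0, rebin_after_s: float = 600.0
) -> FrameSchedule:
    """Replace all frames after ``rebin_after_s`` with uniform fine frames.

    Mirrors re-reconstructing the 10-60-min list-mode data into 1-min frames:
    the 66-frame schedule becomes 90 frames (40 early + fifty 1-min frames).
    """
    ends = schedule.ends
    if not np.any(np.isclose(ends, rebin_after_s)) and not np.isclose(
        schedule.starts[0], rebin_after_s
    ):
        raise InvalidArgumentError(
            f"rebin boundary {rebin_after_s} s is not a frame boundary"
        )
    kept = [fr for fr in schedule.frames if fr[1] <= rebin_after_s + 1e-9]
    total = schedule.total_duration
    n_fine = (total - rebin_after_s) / fine_duration_s
    if abs(n_fine - round(n_fine)) > 1e-9:
        raise InvalidArgumentError(
            f"fine duration {fine_duration_s} s does not tile the remaining "
            f"{total - rebin_after_s} s"
        )
    t = rebin_after_s
    for _ in range(int(round(n_fine))):
        kept.append((t, t + fine_duration_s))
        t += fine_duration_s
    return FrameSchedule(tuple(kept))


def _nesting_map(fine: FrameSchedule, target: FrameSchedule) -> list[list[int]]:
    """For each target frame, the 0-based indices of constituent fine frames."""
    groups: list[list[int]] = []
    j = 0
    for a, b in target.frames:
        if j >= len(fine) or not np.isclose(fine.frames[j][0], a):
            raise InvalidArgumentError(
                f"target frame ({a}, {b}) does not start on a fine-frame boundary"
            )
        members = []
        while j < len(fine) and fine.frames[j][1] <= b + 1e-9:
            members.append(j)
            j += 1
        if not members or not np.isclose(fine.frames[members[-1]][1], b):
            raise InvalidArgumentError(
                f"target frame ({a}, {b}) is not an exact union of fine frames"
            )
        groups.append(members)
    if j != len(fine):
        raise InvalidArgumentError("fine schedule extends beyond target schedule")
    return groups


def regroup(dynamic: DynamicImage, target: FrameSchedule) -> DynamicImage:
    """Regroup a fine-schedule series onto a coarser nesting schedule.

    Each target frame is the duration-weighted mean concentration of its
    constituent fine frames, so total activity x time is conserved and units
    stay Bq/ml. Typically used to sum the 90-frame corrected series back to
    the 66-frame clinical schedule.
    """
    groups = _nesting_map(dynamic.schedule, target)
    durs = dynamic.schedule.durations
    out = np.empty((len(target),) + dynamic.grid.shape, dtype=np.result_type(dynamic.data, float))
    for t, members in enumerate(groups):
        w = durs[members]
        out[t] = np.tensordot(w, dynamic.data[members], axes=(0, 0)) / w.sum()
    return DynamicImage(out, dynamic.grid, target)


def combine_frames(dynamic: DynamicImage, t0_s: float, t1_s: float) -> np.ndarray:
    """Duration-weighted mean concentration image over the window [t0, t1].

    The window must be aligned to frame boundaries (e.g. a 10-min SUV window).
    """
    starts, ends = dynamic.schedule.starts, dynamic.schedule.ends
    if not (np.any(np.isclose(starts, t0_s)) and np.any(np.isclose(ends, t1_s))):
        raise InvalidArgumentError(f"window ({t0_s}, {t1_s}) not aligned to frame boundaries")
    sel = np.nonzero((starts >= t0_s - 1e-9) & (ends <= t1_s + 1e-9))[0]
    if sel.size == 0 or not np.isclose(
        (ends[sel] - starts[sel]).sum(), t1_s - t0_s
    ):
        raise InvalidArgumentError(f"window ({t0_s}, {t1_s}) not covered by the schedule")
    w = (ends[sel] - starts[sel]).astype(float)
    return np.tensordot(w, dynamic.data[sel].astype(float), axes=(0, 0)) / w.sum()


def suv(image: np.ndarray, meta: SubjectMeta) -> np.ndarray:
    """Standardized uptake value: concentration (Bq/ml) x weight (g) / dose (Bq)."""
    return np.asarray(image, dtype=float) * (meta.body_weight_g / meta.injected_dose_Bq)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_nifti(img) -> VoxelGrid:
    img = nib.as_closest_canonical(img)
    A = img.affine
    spacing = np.sqrt((A[:3, :3] ** 2).sum(axis=0))
    direction = A[:3, :3] / spacing
    return VoxelGrid(
        shape=tuple(int(n) for n in img.shape[:3]),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in A[:3, 3]),
        direction=tuple(tuple(float(x) for x in row) for row in direction),
    )


def sidecar_path(image_path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".frames.json")
    return p.with_suffix(".frames.json")


def write_dynamic(dynamic: DynamicImage, path) -> None:
    """Write a 4-D NIfTI plus ``<name>.frames.json`` timing sidecar."""
    arr = np.moveaxis(np.asarray(dynamic.data, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(arr, dynamic.grid.affine), str(path))
    dynamic.schedule.to_json(sidecar_path(path))


def read_dynamic(path, schedule: FrameSchedule | None = None) -> DynamicImage:
    """Read a 4-D NIfTI dynamic series; schedule from the sidecar unless given."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"expected a 4-D dynamic NIfTI, got {img.ndim}-D: {path}")
    if schedule is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise FormatError(f"missing frame-timing sidecar {sc}")
        schedule = FrameSchedule.from_json(sc)
    canon = nib.as_closest_canonical(img)
    data = np.moveaxis(np.asarray(canon.dataobj, dtype=np.float32), -1, 0)
    if data.shape[0] != len(schedule):
        raise FormatError(
            f"{data.shape[0]} frames in image vs {len(schedule)} in sidecar"
        )
    return DynamicImage(data, _grid_from_nifti(img), schedule)


def write_volume(data: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a 3-D volume (static/SUV/parametric image or mask) as NIfTI."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, grid.affine), str(path))


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"expected a 3-D NIfTI, got {img.ndim}-D: {path}")
    canon = nib.as_closest_canonical(img)
    return np.asarray(canon.dataobj, dtype=np.float64), _grid_from_nifti(img)
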