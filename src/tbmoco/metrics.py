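"""Image similarity and overlap measures.

Registration objectives (global NCC, windowed local cross-correlation with an
analytic gradient, NMI) and frame-alignment evaluation measures (MI in bits,
dice). Histogram-based measures use equal-width bins spanning the joint
1st-99th percentile intensity range so that PET hot spots do not collapse the
histogram into a few bins.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, SegmentationError, UndefinedMetricError

__all__ = [
    "ncc",
    "local_cc",
    "mutual_information",
    "nmi",
    "dice",
    "body_mask",
]

_EPS = 1e-12


def ncc(I: np.ndarray, J: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Global normalized cross-correlation (Pearson r) of two images.

    Invariant under affine intensity rescaling of either image; value in
    [-1, 1]. Raises :class:`UndefinedMetricError` when either image has zero
    variance over the evaluation mask.
    """
    I = np.asarray(I, dtype=float)
    J = np.asarray(J, dtype=float)
    if I.shape != J.shape:
        raise InvalidArgumentError(f"shape mismatch {I.shape} vs {J.shape}")
    if mask is not None:
        I, J = I[mask], J[mask]
    else:
        I, J = I.ravel(), J.ravel()
    if I.size < 2:
        raise UndefinedMetricError("need at least 2 voxels")
    a = I - I.mean()
    b = J - J.mean()
    va, vb = float(a @ a), float(b @ b)
    if va <= _EPS * I.size or vb <= _EPS * J.size:
        raise UndefinedMetricError("zero intensity variance under the mask")
    return float(np.clip((a @ b) / np.sqrt(va * vb), -1.0, 1.0))


def _box_sum(x: np.ndarray, radius: int) -> np.ndarray:
    """Sum of ``x`` over the cubic window of half-width ``radius`` (zero-padded)."""
    size = 2 * radius + 1
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * size ** x.ndim


def local_cc(
    I: np.ndarray,
    J: np.ndarray,
    radius_vox: int = 2,
    grad: bool = False,
):
    """Mean squared local correlation over cubic windows, with exact gradient.

    For each interior voxel x, CC(x)^2 = A^2/(B C) where A, B, C are the
    windowed covariance and variances of I and J in the (2r+1)^3 cube centered
    at x. Windows touching the border or with (near-)zero variance are flagged
    undefined and excluded from the mean.

    Returns ``(mean, cc2_map)`` or ``(mean, cc2_map, dmean_dJ)`` when
    ``grad=True``; the gradient is the exact derivative of the mean w.r.t.
    every voxel of J (accumulated over all windows containing it), suitable
    for driving diffeomorphic updates.
    """
    I = np.asarray(I, dtype=float)
    J = np.asarray(J, dtype=float)
    if I.shape != J.shape:
        raise InvalidArgumentError(f"shape mismatch {I.shape} vs {J.shape}")
    r = int(radius_vox)
    if r < 1:
        raise InvalidArgumentError("window radius must be >= 1")
    if any(n < 2 * r + 1 for n in I.shape):
        raise InvalidArgumentError(
            f"window {2 * r + 1} exceeds image extent {I.shape}"
        )
    n = (2 * r + 1) ** I.ndim
    sI, sJ = _box_sum(I, r), _box_sum(J, r)
    A = _box_sum(I * J, r) - sI * sJ / n
    B = _box_sum(I * I, r) - sI * sI / n
    C = _box_sum(J * J, r) - sJ * sJ / n

    interior = np.zeros(I.shape, dtype=bool)
    interior[tuple(slice(r, s - r) for s in I.shape)] = True
    scale = max(float(np.abs(I).max()) * float(np.abs(J).max()), 1.0)
    valid = interior & (B > 1e-9 * scale) & (C > 1e-9 * scale)

    cc2 = np.full(I.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc2[valid] = (A[valid] ** 2) / (B[valid] * C[valid])
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UndefinedMetricError("no valid local-CC window")
    mean = float(np.nanmean(cc2[valid]))
    if not grad:
        return mean, cc2

    # d(cc2_x)/dJ_y = 2A/(BC) (I_y - Ibar_x) - 2A^2/(BC^2) (J_y - Jbar_x);
    # accumulate over all windows x containing y via box sums of the
    # per-window coefficients.
    q1 = np.zeros(I.shape)
    q3 = np.zeros(I.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        q1[valid] = 2.0 * A[valid] / (B[valid] * C[valid])
        q3[valid] = 2.0 * A[valid] ** 2 / (B[valid] * C[valid] ** 2)
    q2 = q1 * (sI / n)
    q4 = q3 * (sJ / n)
    g = (I * _box_sum(q1, r) - _box_sum(q2, r) - J * _box_sum(q3, r) + _box_sum(q4, r)) / n_valid
    return mean, cc2, g


def _joint_histogram(
    I: np.ndarray, J: np.ndarray, bins: int, mask: np.ndarray | None
) -> np.ndarray:
    if I.shape != J.shape:
        raise InvalidArgumentError(f"shape mismatch {I.shape} vs {J.shape}")
    if bins < 2:
        raise InvalidArgumentError("need at least 2 histogram bins")
    if mask is not None:
        I, J = I[mask], J[mask]
    else:
        I, J = I.ravel(), J.ravel()
    if I.size == 0:
        raise UndefinedMetricError("empty overlap")

    def _range(x):
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi <= lo:
            lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        return lo, hi

    H, _, _ = np.histogram2d(
        np.clip(I, *_range(I)), np.clip(J, *_range(J)), bins=bins
    )
    return H / H.sum()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    I: np.ndarray, J: np.ndarray, bins: int = 64, mask: np.ndarray | None = None
) -> float:
    """Mutual information in bits from the joint intensity histogram."""
    P = _joint_histogram(np.asarray(I, float), np.asarray(J, float), bins, mask)
    return max(0.0, _entropy(P.sum(axis=1)) + _entropy(P.sum(axis=0)) - _entropy(P))


def nmi(
    I: np.ndarray, J: np.ndarray, bins: int = 64, mask: np.ndarray | None = None
) -> float:
    """Normalized mutual information, Studholme form (H(I)+H(J))/H(I,J) in [1, 2]."""
    P = _joint_histogram(np.asarray(I, float), np.asarray(J, float), bins, mask)
    hj = _entropy(P)
    if hj <= 0:
        # both marginals degenerate to a single bin: images carry no
        # information, but are trivially perfectly predictable from each other
        return 2.0
    return (_entropy(P.sum(axis=1)) + _entropy(P.sum(axis=0))) / hj


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap 2|A^B|/(|A|+|B|); defined as 1.0 for two empty masks."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise InvalidArgumentError(f"shape mismatch {A.shape} vs {B.shape}")
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (sa + sb)


def body_mask(
    image: np.ndarray, threshold_fraction: float = 0.10, fill_holes: bool = True
) -> np.ndarray:
    """Segment the body from a PET frame.

    Threshold at ``threshold_fraction`` of the 99th intensity percentile,
    keep the largest 6-connected component and fill internal holes. The 99th
    percentile (rather than the max) makes the threshold robust to hot spots
    such as the bladder.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidArgumentError("empty image")
    thr = threshold_fraction * float(np.percentile(image, 99.0))
    raw = image > thr
    if not raw.any():
        raise SegmentationError("body-mask threshold removed every voxel")
    labels, n = ndimage.label(raw)  # default structure = 6-connectivity in 3-D
    if n == 0:
        raise SegmentationError("no connected component above threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask
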