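"""Stack pre-processing and inter-round alignment.

The fixed pre-processing order is retrospective flat-field correction followed
by a 3x3x3 3D median filter. The flat-field estimator is a robust
median-baseline surrogate for low-rank/sparse decomposition: the per-pixel
median across z (and across FOVs when several are supplied) is heavily
smoothed and normalized to mean 1, which captures the smooth multiplicative
illumination component while ignoring the sparse diffraction-limited dots.

Hybridization rounds drift by whole-voxel stage offsets between rounds; they
are aligned by exhaustive normalized cross-correlation of the nuclear
reference channel over a bounded integer search window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter

from .utils import translate_integer

__all__ = [
    "FlatField", "RoundShift",
    "estimate_flatfield", "apply_flatfield", "median3d",
    "register_rounds", "apply_shift",
]


@dataclass
class RoundShift:
    round_id: object
    shift: tuple  # (dz, dy, dx), integer
    score: float  # normalized correlation at the optimum


def _as_volume(stack: np.ndarray, channel) -> np.ndarray:
    if stack.ndim == 4:
        if channel is None:
            raise ValueError("a channel index is required for a 4D stack")
        return stack[channel]
    if stack.ndim == 3:
        return stack
    raise ValueError("expected a (z,y,x) volume or (c,z,y,x) stack")


def estimate_flatfield(stack, channel=None, smooth_sigma=None) -> np.ndarray:
    """Estimate the multiplicative illumination field of one channel.

    ``stack`` may be a single (z,y,x) volume, a (c,z,y,x) stack with
    ``channel``, or a list of either (multiple FOVs sharing the field). The
    estimate is the median projection across z (then across FOVs), Gaussian
    smoothed, and normalized to mean exactly 1. Strictly positive everywhere.
    """
    if isinstance(stack, (list, tuple)):
        baselines = [np.median(_as_volume(s, channel), axis=0) for s in stack]
        baseline = np.median(np.stack(baselines), axis=0)
    else:
        baseline = np.median(_as_volume(stack, channel), axis=0)
    if not np.any(baseline > 0):
        raise ValueError("channel is all zero: nothing to estimate")
    # half the footprint: keeps only the lowest-frequency illumination
    # component and suppresses specimen (tissue) structure in the baseline
    if smooth_sigma is None:
        smooth_sigma = max(min(baseline.shape) / 2.0, 1.0)
    field = gaussian_filter(baseline.astype(np.float64), smooth_sigma,
                            mode="nearest")
    field = np.maximum(field, 1e-9)
    return field / field.mean()


def apply_flatfield(stack: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Voxelwise division by the field, broadcast over z (and channels)."""
    field = np.asarray(field)
    if field.min() <= 0:
        raise ValueError("flat field must be strictly positive")
    if field.shape != stack.shape[-2:]:
        raise ValueError("field footprint does not match the stack")
    return stack.astype(np.float64) / field


def median3d(volume: np.ndarray, kernel=(3, 3, 3)) -> np.ndarray:
    """3D median filter with edge replication at the borders."""
    if any(k % 2 == 0 or k < 1 for k in kernel):
        raise ValueError("median kernel dimensions must be odd")
    return median_filter(volume, size=tuple(kernel), mode="nearest")


def register_rounds(reference, moving, channel=None, max_shift=(2, 8, 8),
                    round_id=None) -> RoundShift:
    """Integer shift aligning ``moving`` onto ``reference``.

    Exhaustive search (via FFT cross-correlation of mean-subtracted volumes)
    over all integer shifts within ``±max_shift``; ties broken toward the
    smaller absolute shift, lexicographically in (z, y, x). The returned shift
    is such that translating ``reference`` by it reproduces ``moving``; apply
    the negated shift to ``moving`` to align it to the reference frame.
    """
    ref = np.asarray(_as_volume(reference, channel), np.float64)
    mov = np.asarray(_as_volume(moving, channel), np.float64)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving stacks must share a shape")
    if ref.std() == 0:
        raise ValueError("flat (zero-variance) reference channel")
    a = ref - ref.mean()
    b = mov - mov.mean()
    # circular cross-correlation c(s) = sum_x a(x) b(x+s)
    corr = np.fft.ifftn(np.conj(np.fft.fftn(a)) * np.fft.fftn(b)).real
    candidates = sorted(
        (
            (dz, dy, dx)
            for dz in range(-int(max_shift[0]), int(max_shift[0]) + 1)
            for dy in range(-int(max_shift[1]), int(max_shift[1]) + 1)
            for dx in range(-int(max_shift[2]), int(max_shift[2]) + 1)
        ),
        key=lambda s: (abs(s[0]), abs(s[1]), abs(s[2]), s[0], s[1], s[2]),
    )
    best, best_val = None, -np.inf
    for s in candidates:
        v = corr[s[0] % ref.shape[0], s[1] % ref.shape[1], s[2] % ref.shape[2]]
        if v > best_val:  # strict: the first (smallest-|shift|) optimum wins ties
            best, best_val = s, v
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    score = float(best_val / denom) if denom > 0 else 0.0
    return RoundShift(round_id=round_id, shift=best, score=score)


def apply_shift(stack: np.ndarray, shift) -> np.ndarray:
    """Integer translation of the last three axes with zero fill."""
    if any(abs(int(s)) >= n for s, n in zip(shift, stack.shape[-3:])):
        raise ValueError("shift exceeds the volume extent")
    return translate_integer(stack, shift)


def preprocess_stack(stack: np.ndarray, smooth_sigma=None,
                     median_kernel=(3, 3, 3)) -> np.ndarray:
    """Fixed two-step pre-processing of a (c,z,y,x) stack.

    Per channel: flat-field correction (field estimated from that channel),
    then the 3D median filter. Channels with no signal are passed through
    median filtering only.
    """
    out = np.empty(stack.shape, np.float64)
    for c in range(stack.shape[0]):
        vol = stack[c]
        try:
            field = estimate_flatfield(vol, smooth_sigma=smooth_sigma)
            vol = apply_flatfield(vol, field)
        except ValueError:
            vol = vol.astype(np.float64)
        out[c] = median3d(vol, median_kernel)
    return out
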