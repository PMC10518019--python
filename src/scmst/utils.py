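"""Small shared numeric helpers used across pipeline stages."""

from __future__ import annotations

import numpy as np


def translate_integer(volume: np.ndarray, shift, fill=0) -> np.ndarray:
    """Translate the last three axes of ``volume`` by an integer ``shift``.

    Content at voxel ``p`` moves to ``p + shift``; voxels shifted out of the
    array are dropped and vacated voxels are filled with ``fill``.
    """
    shift = tuple(int(s) for s in shift)
    if len(shift) != 3:
        raise ValueError("shift must be a (z, y, x) triple")
    out = np.full_like(volume, fill)
    src = [slice(None)] * (volume.ndim - 3)
    dst = [slice(None)] * (volume.ndim - 3)
    for ax, s in zip(range(volume.ndim - 3, volume.ndim), shift):
        n = volume.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def ellipsoid_footprint(radii) -> np.ndarray:
    """Boolean ellipsoid with per-axis radii (voxels), for anisotropic ops."""
    radii = [max(float(r), 1e-9) for r in radii]
    ranges = [np.arange(-int(np.ceil(r)), int(np.ceil(r)) + 1) for r in radii]
    zz, yy, xx = np.meshgrid(*ranges, indexing="ij")
    return (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2 <= 1.0


def ellipsoid_offsets(radii) -> np.ndarray:
    """Integer (dz, dy, dx) offsets inside the ellipsoid, as an (n, 3) array."""
    fp = ellipsoid_footprint(radii)
    offs = np.argwhere(fp)
    center = (np.array(fp.shape) - 1) // 2
    return offs - center


def gaussian_kernel_3d(sigma) -> np.ndarray:
    """Separable 3D Gaussian with unit peak, truncated at 3 sigma."""
    axes = []
    for s in sigma:
        if s <= 0:
            raise ValueError("PSF sigma must be positive")
        r = int(np.ceil(3 * s))
        x = np.arange(-r, r + 1)
        axes.append(np.exp(-0.5 * (x / s) ** 2))
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def add_blob(volume: np.ndarray, center, kernel: np.ndarray, amplitude: float) -> None:
    """Accumulate ``amplitude * kernel`` into ``volume`` centred at ``center``,
    clipping the kernel at the array borders (in place)."""
    center = [int(round(c)) for c in center]
    half = [(k - 1) // 2 for k in kernel.shape]
    vsl, ksl = [], []
    for c, h, n, klen in zip(center, half, volume.shape, kernel.shape):
        lo, hi = c - h, c - h + klen
        klo = max(0, -lo)
        khi = klen - max(0, hi - n)
        if klo >= khi:
            return
        vsl.append(slice(lo + klo, lo + khi))
        ksl.append(slice(klo, khi))
    volume[tuple(vsl)] += amplitude * kernel[tuple(ksl)]
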