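"""Pseudo-color back-mapping of analyzed cells and display-only FOV stitching.

Back-mapping paints every cell of a label volume with the color of its
assigned subpopulation (or co-expression selection) so clusters can be
inspected in their original tissue context. Stitching pastes fields of view
onto one canvas at acquisition offsets for display only: all quantification
happens per FOV beforehand, so the mosaic never feeds back into the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Mosaic", "build_colormap", "backmap", "stitch"]

GRAY = (128, 128, 128)  # unanalyzed cells
BLACK = (0, 0, 0)  # background


@dataclass
class Mosaic:
    image: np.ndarray
    offsets: list  # per-FOV (y, x) placement on the canvas
    policy: str


def build_colormap(group_ids) -> dict:
    """Distinct RGB color per group id, stable in sorted-id order."""
    from matplotlib import colormaps

    ids = sorted(set(group_ids))
    n = max(len(ids), 1)
    cmap = colormaps["hsv"] if n > 20 else colormaps["tab20"]
    colors = {}
    for i, gid in enumerate(ids):
        r, g, b, _ = cmap(i / n if n > 20 else i % 20)
        colors[gid] = (int(255 * r), int(255 * g), int(255 * b))
    return colors


def _majority_projection(labels: np.ndarray) -> np.ndarray:
    """Per (y, x), the nonzero label occupying the most z-planes (smallest
    label wins ties); 0 where the column is pure background."""
    nz, ny, nx = labels.shape
    best = np.zeros((ny, nx), labels.dtype)
    best_count = np.zeros((ny, nx), np.int32)
    for lab in range(1, int(labels.max()) + 1):
        count = (labels == lab).sum(axis=0)
        upd = count > best_count
        best[upd] = lab
        best_count[upd] = count[upd]
    return best


def backmap(labels: np.ndarray, cell_to_group: dict, colormap: dict,
            projection: str = "majority", z: int | None = None) -> np.ndarray:
    """RGB view of a label volume with cells painted by their group color.

    Cells absent from ``cell_to_group`` are gray; background is black. This is
    a pure view: it never alters counts or cluster assignments. Projection is
    z label-majority by default, or a single plane via ``z``.
    """
    present = set(np.unique(labels)) - {0}
    unknown = set(cell_to_group) - present
    if unknown:
        raise ValueError(f"mapped cell ids missing from the label volume: "
                         f"{sorted(unknown)[:5]}")
    if z is not None:
        plane = labels[z]
    elif projection == "majority":
        plane = _majority_projection(labels)
    else:
        raise ValueError(f"unknown projection {projection!r}")
    rgb = np.zeros(plane.shape + (3,), np.uint8)
    for lab in present:
        where = plane == lab
        if lab in cell_to_group:
            rgb[where] = colormap[cell_to_group[lab]]
        else:
            rgb[where] = GRAY
    return rgb


def stitch(fov_images: list, offsets: list, policy: str = "last") -> Mosaic:
    """Paste FOV images onto one canvas at integer (y, x) offsets.

    ``policy``: ``"last"`` (later FOVs overwrite overlaps) or ``"error"``
    (raise with the overlap extent). Non-overlapping pixels are conserved
    exactly.
    """
    if policy not in ("last", "error"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    if len(fov_images) != len(offsets):
        raise ValueError("one offset per FOV is required")
    offs = np.array([(int(y), int(x)) for y, x in offsets])
    origin = offs.min(axis=0)
    offs = offs - origin
    shapes = np.array([im.shape[:2] for im in fov_images])
    canvas_shape = tuple((offs + shapes).max(axis=0))
    extra = fov_images[0].shape[2:]
    canvas = np.zeros(canvas_shape + extra, fov_images[0].dtype)
    occupied = np.zeros(canvas_shape, bool)
    for im, (oy, ox) in zip(fov_images, offs):
        sl = (slice(oy, oy + im.shape[0]), slice(ox, ox + im.shape[1]))
        overlap = int(occupied[sl].sum())
        if overlap and policy == "error":
            raise ValueError(f"FOVs overlap on {overlap} pixels")
        canvas[sl] = im
        occupied[sl] = True
    return Mosaic(image=canvas, offsets=[tuple(o) for o in offs], policy=policy)
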