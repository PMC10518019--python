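"""3D cell segmentation, dot-to-cell assignment and the count matrix.

Cells are segmented by a classical seeded 3D watershed: seeds are local maxima
of the smoothed nuclear channel, the elevation map is the smoothed membrane
composite (the summed membrane immunostains), and flooding is restricted to a
tissue mask thresholded from the combined signal. Kept dots are mapped into
the reference frame through their round's registered shift and assigned to
the cell label at their centroid voxel; the result is a cells x genes integer
count matrix carried as an AnnData with per-cell and per-gene metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import closing
from skimage.segmentation import relabel_sequential, watershed

from .utils import ellipsoid_footprint

__all__ = [
    "SegmentationParams", "segment_cells", "drop_edge_cells",
    "assign_dots", "build_count_matrix", "cell_metadata",
]


@dataclass
class SegmentationParams:
    """Knobs of the seeded-watershed segmenter (lengths in um)."""

    voxel_size: tuple = (0.5, 0.25, 0.25)
    cell_radius_um: float = 2.5  # expected cell radius, sets seed spacing
    nuclei_smooth_sigma: tuple = (1.0, 2.0, 2.0)  # voxels
    membrane_smooth_sigma: tuple = (0.5, 1.0, 1.0)
    tissue_threshold: float | None = None  # None -> Otsu on the combined signal
    min_volume_voxels: int = 40


def _seed_footprint(params: SegmentationParams) -> np.ndarray:
    radii = [max(params.cell_radius_um / v * 0.8, 1.0) for v in params.voxel_size]
    return ellipsoid_footprint(radii)


def segment_cells(membrane_composite: np.ndarray, nuclei: np.ndarray,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Seeded 3D watershed segmentation; labels contiguous 1..N, 0 background."""
    params = params or SegmentationParams()
    if not np.any(nuclei > 0):
        raise ValueError("nuclei channel is empty")
    nuc = ndi.gaussian_filter(np.asarray(nuclei, np.float64),
                              params.nuclei_smooth_sigma)
    mem = ndi.gaussian_filter(np.asarray(membrane_composite, np.float64),
                              params.membrane_smooth_sigma)

    combined = nuc + mem
    thr = params.tissue_threshold
    if thr is None:
        thr = threshold_otsu(combined)
    mask = combined > thr
    # seal pinholes only; cell-scale closing would bridge distinct regions
    mask = closing(mask, ellipsoid_footprint((1.0, 2.0, 2.0)))
    mask = ndi.binary_fill_holes(mask)

    seed_thr = threshold_otsu(nuc) if nuc.max() > 0 else 0.0
    peaks = peak_local_max(nuc, footprint=_seed_footprint(params),
                           threshold_abs=seed_thr, exclude_border=False)
    markers = np.zeros(nuc.shape, np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)

    labels = watershed(mem, markers=markers, mask=mask).astype(np.int32)

    # prune specks, then make labels contiguous
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < params.min_volume_voxels)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def drop_edge_cells(labels: np.ndarray):
    """Zero out labels touching a lateral (y or x) border; relabel contiguous.

    Returns ``(labels, edge_cell_old_ids)``. Idempotent; partial cells at FOV
    borders would otherwise bias per-cell counts downward.
    """
    border = np.zeros(labels.shape, bool)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    edge_ids = sorted(int(v) for v in np.unique(labels[border]) if v != 0)
    out = labels.copy()
    out[np.isin(out, edge_ids)] = 0
    out, _, _ = relabel_sequential(out)
    return out.astype(np.int32), edge_ids


def assign_dots(dots: pd.DataFrame, labels: np.ndarray, round_shifts: dict):
    """Map each kept dot into the reference frame and pick up its cell label.

    ``round_shifts`` maps round id -> (dz, dy, dx) as estimated by
    registration (the planted/estimated translation of that round relative to
    the reference); a dot detected at ``p`` in its round therefore sits at
    ``p - shift`` in the reference frame. Dots landing on background or
    outside the volume get cell_id 0.
    """
    out = dots.copy()
    cell_ids = np.zeros(len(out), np.int32)
    outside = 0
    pts = out[["z", "y", "x"]].to_numpy(np.float64)
    rounds = out["round"].to_numpy(object) if "round" in out.columns else np.zeros(len(out), int)
    shape = np.array(labels.shape)
    for i, (p, r) in enumerate(zip(pts, rounds)):
        shift = round_shifts.get(r, (0, 0, 0))
        q = np.rint(p - np.asarray(shift)).astype(int)
        if np.any(q < 0) or np.any(q >= shape):
            outside += 1
            continue
        cell_ids[i] = labels[tuple(q)]
    out["cell_id"] = cell_ids
    out.attrs["n_outside_volume"] = outside
    return out


def cell_metadata(labels: np.ndarray, voxel_size=(0.5, 0.25, 0.25),
                  embryo=0, fov=0, stage="", edge_ids=()) -> pd.DataFrame:
    """Per-cell table: centroid, voxel volume and acquisition provenance."""
    rows = []
    for rp in regionprops(labels):
        rows.append({
            "cell_id": int(rp.label), "embryo": embryo, "fov": fov,
            "stage": stage,
            "centroid_z": rp.centroid[0], "centroid_y": rp.centroid[1],
            "centroid_x": rp.centroid[2],
            "volume_voxels": int(rp.area),
            "volume_um3": float(rp.area * np.prod(voxel_size)),
            "edge_flag": int(rp.label) in set(edge_ids),
        })
    return pd.DataFrame(rows)


def build_count_matrix(assigned_dots: pd.DataFrame, panel, cell_meta: pd.DataFrame,
                       gene_meta: pd.DataFrame | None = None) -> ad.AnnData:
    """Tally kept, cell-assigned dots into a cells x genes AnnData.

    Cells with zero total counts are retained (flagged in ``obs['zero_count']``);
    the matrix total equals the number of kept dots assigned to nonzero labels.
    """
    panel = list(panel)
    kept = assigned_dots
    if "kept" in kept.columns:
        kept = kept[kept["kept"]]
    kept = kept[kept["cell_id"] > 0]
    unknown = set(kept["gene"]) - set(panel)
    if unknown:
        raise ValueError(f"dots carry genes outside the panel: {sorted(unknown)}")

    cells = cell_meta["cell_id"].to_numpy(int)
    cell_pos = {c: i for i, c in enumerate(cells)}
    gene_pos = {g: j for j, g in enumerate(panel)}
    x = np.zeros((len(cells), len(panel)), np.int64)
    for (cell, gene), n in kept.groupby(["cell_id", "gene"]).size().items():
        if cell in cell_pos:
            x[cell_pos[cell], gene_pos[gene]] = n
    obs = cell_meta.copy()
    if {"embryo", "fov"} <= set(obs.columns):
        names = [f"e{e}_f{f}_c{c}" for e, f, c in
                 zip(obs["embryo"], obs["fov"], cells)]
    else:
        names = [str(c) for c in cells]
    obs.index = pd.Index(names, name="cell")
    obs["zero_count"] = x.sum(axis=1) == 0
    var = (gene_meta.copy() if gene_meta is not None
           else pd.DataFrame(index=panel))
    var.index = pd.Index(panel, name="gene")
    return ad.AnnData(X=x, obs=obs, var=var)


def concat_count_matrices(adatas: list) -> ad.AnnData:
    """Concatenate per-FOV matrices (cell names are already FOV-scoped)."""
    out = ad.concat(adatas, join="outer", index_unique=None, merge="same")
    out.X = np.nan_to_num(np.asarray(out.X)).astype(np.int64)
    return out
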