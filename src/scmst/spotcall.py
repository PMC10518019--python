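"""Dot detection and K-means intensity triage.

Candidate transcripts are local maxima of a band-pass (difference-of-Gaussians)
response, detected permissively — the floor is a quantile of the response, so
recall is high and quality control happens downstream. Each dot is summarized
by two features, its mean intensity and its intensity variability (standard
deviation of the voxel intensities within a one-sigma ellipsoidal support),
and the dots of each gene are clustered by K-means in that feature plane.
Non-specific probe binding shows up as a dim cluster and imaging artifacts as
extreme clusters; the default retain rule rejects the dimmest cluster and any
extreme-intensity or extreme-variability cluster and keeps the middle band as
true signal.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .utils import ellipsoid_footprint, ellipsoid_offsets

__all__ = [
    "TriageResult", "detect_dots", "dot_features", "select_k",
    "kmeans_triage", "triage_per_gene", "recovery_rate",
]

FEATURES = ["mean_intensity", "intensity_variability"]


@dataclass
class TriageResult:
    """Outcome of K-means triage for one dot population."""

    k: int
    centroids: np.ndarray  # (k, 2) in original feature units
    sizes: np.ndarray
    retained: list  # retained cluster ids
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Detection and features
# ---------------------------------------------------------------------------


def detect_dots(volume: np.ndarray, psf_sigma=(1.0, 1.3, 1.3),
                min_distance=None, floor_quantile: float = 0.95) -> pd.DataFrame:
    """High-recall 3D dot detection on a preprocessed single-channel volume.

    Local maxima of a difference-of-Gaussians response, separated by at least
    ``min_distance`` (default 1.5x the PSF sigma, per axis, so the exclusion
    region is anisotropy-aware), above the ``floor_quantile`` quantile of the
    response. Returns a table with integer voxel positions (z, y, x).
    """
    psf_sigma = tuple(float(s) for s in psf_sigma)
    if any(s <= 0 for s in psf_sigma):
        raise ValueError("PSF sigma must be positive")
    if min_distance is None:
        min_distance = tuple(1.5 * s for s in psf_sigma)
    vol = np.asarray(volume, np.float64)
    response = gaussian_filter(vol, psf_sigma) - gaussian_filter(
        vol, tuple(2 * s for s in psf_sigma)
    )
    floor = np.quantile(response, floor_quantile)
    peaks = peak_local_max(
        response,
        footprint=ellipsoid_footprint(min_distance),
        threshold_abs=floor,
        exclude_border=False,
    )
    return pd.DataFrame(peaks, columns=["z", "y", "x"])


def dot_features(volume: np.ndarray, dots: pd.DataFrame,
                 psf_sigma=(1.0, 1.3, 1.3),
                 variability: str = "sd") -> pd.DataFrame:
    """Mean intensity and intensity variability over each dot's support.

    The support is the one-sigma ellipsoid around the centroid, clipped at the
    volume borders. Variability is the population standard deviation of the
    support voxels (``"range"`` switches to max - min).
    """
    vol = np.asarray(volume, np.float64)
    offs = ellipsoid_offsets(psf_sigma)
    if len(offs) == 0:
        raise ValueError("empty dot support: PSF sigma too small")
    means, var = [], []
    shape = np.array(vol.shape)
    pts = dots[["z", "y", "x"]].to_numpy(int)
    for p in pts:
        vox = p[None, :] + offs
        ok = np.all((vox >= 0) & (vox < shape[None, :]), axis=1)
        vals = vol[tuple(vox[ok].T)]
        if vals.size == 0:
            raise ValueError(f"dot at {tuple(p)} has empty support")
        means.append(vals.mean())
        if variability == "sd":
            var.append(vals.std())
        elif variability == "range":
            var.append(vals.max() - vals.min())
        else:
            raise ValueError("variability must be 'sd' or 'range'")
    out = dots.copy()
    out["mean_intensity"] = means
    out["intensity_variability"] = var
    return out


# ---------------------------------------------------------------------------
# K-means triage
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fit_kmeans(xs: np.ndarray, k: int, seed) -> KMeans:
    # fit on a canonically sorted copy so the result is independent of the
    # input ordering of the dots; labels come from predict() afterwards
    order = np.lexsort(xs.T[::-1])
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    km.fit(xs[order])
    return km


def select_k(features: pd.DataFrame, k_range=range(2, 7), seed: int = 0):
    """Choose the cluster count for triage.

    Default: the k maximizing the mean silhouette on standardized features.
    The elbow of the within-cluster SSE curve (largest second difference) is
    reported as a diagnostic. A config override always wins over both; with
    too few dots, k=1 is returned with a warning.
    """
    x = features[FEATURES].to_numpy(np.float64)
    ks = [k for k in k_range if k + 1 <= len(x)]
    warnings = []
    if not ks or np.all(x == x[0]):
        return 1, {"sse": {}, "silhouette": {}, "elbow_k": None,
                   "warnings": ["too few or degenerate dots; k=1"]}
    xs = _standardize(x)
    sse, sil = {}, {}
    for k in ks:
        km = _fit_kmeans(xs, k, seed)
        labels = km.predict(xs)
        sse[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(xs, labels)) if len(set(labels)) > 1 else -1.0
    elbow_k = None
    if len(ks) >= 3:
        vals = np.array([sse[k] for k in ks])
        second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
        elbow_k = ks[1 + int(np.argmax(second))]
    best = max(sil, key=lambda k: (sil[k], -k))
    return best, {"sse": sse, "silhouette": sil, "elbow_k": elbow_k,
                  "warnings": warnings}


def kmeans_triage(features: pd.DataFrame, k: int, retain_rule: str = "middle_band",
                  seed: int = 0, artifact_quantile: float = 0.995,
                  variability_factor: float = 2.0):
    """Cluster dots by (mean intensity, variability) and keep the true band.

    The default ``middle_band`` rule rejects the cluster with the lowest
    mean-intensity centroid (non-specific binding) plus any cluster whose
    mean-intensity centroid exceeds the ``artifact_quantile`` of the dot
    intensities, or whose variability centroid is both the maximum and more
    than ``variability_factor`` times the median centroid variability
    (artifacts). Returns ``(TriageResult, kept boolean array)``.
    """
    x = features[FEATURES].to_numpy(np.float64)
    n = len(x)
    if k <= 1 or n < 2:
        res = TriageResult(k=1, centroids=x.mean(axis=0, keepdims=True) if n else
                           np.zeros((1, 2)), sizes=np.array([n]), retained=[0],
                           warnings=["k=1: no triage possible, all dots kept"])
        return res, np.ones(n, bool)
    if retain_rule != "middle_band":
        raise ValueError(f"unknown retain rule {retain_rule!r}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    km = _fit_kmeans(xs, k, seed)
    labels = km.predict(xs)
    centroids = km.cluster_centers_ * sd + mu
    sizes = np.bincount(labels, minlength=k)

    rejected = set()
    rejected.add(int(np.argmin(centroids[:, 0])))  # dimmest: non-specific
    thr = np.quantile(x[:, 0], artifact_quantile)
    for c in range(k):
        if centroids[c, 0] > thr:
            rejected.add(c)
    var_c = centroids[:, 1]
    vmax = int(np.argmax(var_c))
    if var_c[vmax] > variability_factor * np.median(var_c):
        rejected.add(vmax)
    retained = [c for c in range(k) if c not in rejected]
    warnings = []
    if not retained:
        # pathological geometry: fall back to the largest non-dim cluster
        dim = int(np.argmin(centroids[:, 0]))
        pool = [c for c in range(k) if c != dim] or [dim]
        keep = max(pool, key=lambda c: sizes[c])
        retained = [keep]
        warnings.append("retain rule rejected every cluster; "
                        "kept the largest non-dim cluster instead")
    kept = np.isin(labels, retained)
    res = TriageResult(
        k=k, centroids=centroids, sizes=sizes, retained=sorted(retained),
        diagnostics={"labels": labels, "artifact_threshold": float(thr)},
        warnings=warnings,
    )
    return res, kept


def triage_per_gene(dots: pd.DataFrame, k=None, seed: int = 0,
                    artifact_quantile: float = 0.995):
    """Run (optional k selection and) K-means triage gene by gene.

    ``dots`` must carry the feature columns and a ``gene`` column; returns the
    table with ``cluster`` and ``kept`` columns added, plus a per-gene dict of
    TriageResults. ``k`` may be an int (forced for all genes), a per-gene
    mapping, or None (silhouette selection per gene).
    """
    out = dots.copy()
    out["cluster"] = -1
    out["kept"] = False
    results = {}
    for gene, idx in out.groupby("gene").groups.items():
        sub = out.loc[idx]
        if k is None:
            kg, _ = select_k(sub, seed=seed)
        elif isinstance(k, dict):
            kg = k.get(gene)
            if kg is None:
                kg, _ = select_k(sub, seed=seed)
        else:
            kg = int(k)
        res, kept = kmeans_triage(sub, kg, seed=seed,
                                  artifact_quantile=artifact_quantile)
        out.loc[idx, "kept"] = kept
        if "labels" in res.diagnostics:
            out.loc[idx, "cluster"] = res.diagnostics["labels"]
        results[gene] = res
    return out, results


# ---------------------------------------------------------------------------
# Round-repeat quality control
# ---------------------------------------------------------------------------


def recovery_rate(dots_initial: pd.DataFrame, dots_repeat: pd.DataFrame,
                  qc_threshold: float = 0.70):
    """Signal recovery of a repeated first-round hybridization.

    Per gene: kept-dot count in the repeat round over kept-dot count in the
    initial round (may exceed 1). Overall: total kept repeat / total kept
    initial; the run FAILs QC when the overall rate falls below the threshold.
    """
    def kept_counts(d):
        dd = d[d["kept"]] if "kept" in d.columns else d
        return dd.groupby("gene").size()

    init = kept_counts(dots_initial)
    rep = kept_counts(dots_repeat)
    genes = sorted(set(init.index) | set(rep.index))
    rows = []
    for g in genes:
        n0 = int(init.get(g, 0))
        n1 = int(rep.get(g, 0))
        rows.append({"gene": g, "n_initial": n0, "n_repeat": n1,
                     "recovery": n1 / n0 if n0 > 0 else np.nan})
    table = pd.DataFrame(rows)
    total0 = int(table["n_initial"].sum())
    total1 = int(table["n_repeat"].sum())
    if total0 == 0:
        _warnings.warn("no kept dots in the initial round; recovery undefined")
        overall = np.nan
        passed = False
    else:
        overall = total1 / total0
        passed = overall >= qc_threshold
    return {"per_gene": table, "overall": overall, "passed": passed,
            "threshold": qc_threshold}


def plot_triage(dots: pd.DataFrame, out_dir, max_genes=None) -> list:
    """Per-gene QC scatter (mean intensity vs variability, colored by
    cluster; rejected dots hollow). Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    genes = sorted(dots["gene"].unique())[:max_genes]
    for gene in genes:
        sub = dots[dots["gene"] == gene]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        for cluster, grp in sub.groupby("cluster"):
            kept = bool(grp["kept"].iloc[0]) if len(grp) else False
            ax.scatter(grp["mean_intensity"], grp["intensity_variability"],
                       s=6, label=f"cluster {cluster}" + (" (kept)" if kept else ""),
                       alpha=0.6, edgecolors="none" if kept else "k",
                       linewidths=0 if kept else 0.3)
        ax.set_xlabel("mean intensity")
        ax.set_ylabel("intensity variability")
        ax.set_title(gene)
        ax.legend(fontsize=6, markerscale=2)
        fig.tight_layout()
        path = out_dir / f"triage_{gene}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
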