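"""Two-stage z-score normalization, cosine hierarchical clustering and
co-expression cell selection.

Counts are standardized gene-wise in two passes: first within each embryo
(pooling its fields of view), then again across all embryos of a group — a
developmental stage, or every stage at once for cross-stage comparisons.
Cells are then clustered agglomeratively with cosine distance, and cells
co-expressing a gene set are selected as those with a z-score strictly above
zero (expression above the mean) for every gene of interest simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterResult", "Selection",
    "zscore_within_embryo", "zscore_pooled", "zscore_cross_stage",
    "hcluster", "select_coexpressing", "overlap_stats", "stage_composition",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell cluster id, contiguous from 1
    linkage: np.ndarray  # scipy linkage matrix over cells
    leaf_order: np.ndarray
    gene_linkage: np.ndarray | None
    gene_leaf_order: np.ndarray | None
    k: int
    metric: str = "cosine"
    method: str = "average"


@dataclass
class Selection:
    gene_set: list
    cell_ids: list  # obs names of the selected cells
    mask: np.ndarray
    per_stage: pd.DataFrame | None = None
    mode: str = "all_above_mean"
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    """Gene-wise z-score with sample sd (n-1); degenerate columns map to 0."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = np.zeros_like(x, np.float64)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return z


def _values(counts, log1p: bool) -> np.ndarray:
    x = np.asarray(counts.X, np.float64)
    return np.log1p(x) if log1p else x


def zscore_within_embryo(counts: ad.AnnData, log1p: bool = False) -> ad.AnnData:
    """First pass: per embryo, per gene, across all of its FOVs' cells."""
    if "embryo" not in counts.obs:
        raise ValueError("cell metadata lacks embryo ids")
    x = _values(counts, log1p)
    z = np.empty_like(x)
    for embryo, idx in counts.obs.groupby("embryo", observed=True).indices.items():
        if len(idx) < 2:
            raise ValueError(
                f"embryo {embryo!r} has a single cell: sd undefined"
            )
        z[idx] = _zscore_columns(x[idx])
    out = ad.AnnData(X=z, obs=counts.obs.copy(), var=counts.var.copy())
    out.uns["mode"] = "within_embryo"
    out.uns["provenance"] = {"embryos": sorted(map(str, set(counts.obs["embryo"])))}
    return out


def zscore_pooled(zwithin: ad.AnnData, groupby: str = "stage") -> ad.AnnData:
    """Second pass: re-standardize gene-wise across each pooled group."""
    if groupby not in zwithin.obs:
        raise ValueError(f"cell metadata lacks {groupby!r}")
    x = np.asarray(zwithin.X, np.float64)
    z = np.empty_like(x)
    groups = zwithin.obs.groupby(groupby, observed=True).indices
    if not groups:
        raise ValueError("no groups to pool")
    for _, idx in groups.items():
        z[idx] = _zscore_columns(x[idx])
    out = ad.AnnData(X=z, obs=zwithin.obs.copy(), var=zwithin.var.copy())
    out.uns["mode"] = "pooled_stage"
    out.uns["provenance"] = {
        "first_pass": zwithin.uns.get("mode", "unknown"),
        "pooled_groups": sorted(map(str, groups)),
    }
    return out


def zscore_cross_stage(counts: ad.AnnData, log1p: bool = False) -> ad.AnnData:
    """Gene-wise z-score over the cells of ALL stages pooled together.

    Unlike the per-stage scheme, no within-embryo pass precedes the pooling:
    standardizing within embryos first would remove exactly the between-stage
    expression-level differences this mode exists to compare.
    """
    stages = set(counts.obs.get("stage", []))
    if len(stages) < 2:
        raise ValueError("cross-stage normalization needs at least two stages")
    if counts.n_obs < 2:
        raise ValueError("need at least two cells")
    z = _zscore_columns(_values(counts, log1p))
    out = ad.AnnData(X=z, obs=counts.obs.copy(), var=counts.var.copy())
    out.uns["mode"] = "cross_stage"
    out.uns["provenance"] = {"stages": sorted(map(str, stages))}
    return out


# ---------------------------------------------------------------------------
# Cosine hierarchical clustering
# ---------------------------------------------------------------------------


def cosine_distances(x: np.ndarray) -> np.ndarray:
    """Condensed pairwise cosine distances, with the zero-vector convention.

    d(u, v) = 1 - u.v / (|u||v|); any pair involving an all-zero vector is
    assigned distance 1. Distances are clipped into [0, 2].
    """
    d = pdist(np.asarray(x, np.float64), metric="cosine")
    d = np.nan_to_num(d, nan=1.0)
    return np.clip(d, 0.0, 2.0)


def hcluster(z, k: int, method: str = "average",
             cluster_genes: bool = True) -> ClusterResult:
    """Agglomerative clustering of cells on cosine distance, cut at k.

    Genes are clustered the same way (for two-dimensional heatmap ordering).
    Cluster ids are contiguous from 1 in order of first appearance.
    """
    x = np.asarray(z.X if isinstance(z, ad.AnnData) else z, np.float64)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    lk = linkage(cosine_distances(x), method=method)
    raw = fcluster(lk, t=k, criterion="maxclust")
    # relabel by first appearance for determinism
    remap, labels = {}, np.empty(n, np.int32)
    for i, lab in enumerate(raw):
        labels[i] = remap.setdefault(lab, len(remap) + 1)
    gene_lk = gene_order = None
    if cluster_genes and x.shape[1] > 2:
        gene_lk = linkage(cosine_distances(x.T), method=method)
        gene_order = leaves_list(gene_lk)
    return ClusterResult(labels=labels, linkage=lk, leaf_order=leaves_list(lk),
                         gene_linkage=gene_lk, gene_leaf_order=gene_order,
                         k=int(labels.max()), method=method)


def dendrogram_newick(lk: np.ndarray, leaf_names=None) -> str:
    """Render a scipy linkage matrix as a Newick string with merge heights."""
    tree = to_tree(lk)

    def name(i):
        return str(leaf_names[i]) if leaf_names is not None else f"L{i}"

    def rec(node, parent_dist):
        bl = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{name(node.id)}:{bl:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Co-expression selection
# ---------------------------------------------------------------------------


def select_coexpressing(z: ad.AnnData, gene_set) -> Selection:
    """Cells with z > 0 (strictly above the mean) for every gene in the set."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = [g for g in gene_set if g not in z.var_names]
    if missing:
        raise ValueError(f"genes not in the panel: {missing}")
    cols = [z.var_names.get_loc(g) for g in gene_set]
    x = np.asarray(z.X, np.float64)
    mask = np.all(x[:, cols] > 0, axis=1)
    sel = Selection(
        gene_set=gene_set,
        cell_ids=list(np.asarray(z.obs_names)[mask]),
        mask=mask,
        provenance={"mode": z.uns.get("mode", "unknown")},
    )
    if "stage" in z.obs:
        sel.per_stage = stage_composition(sel, z.obs["stage"])
    return sel


def overlap_stats(sel_a: Selection, sel_b: Selection,
                  stages: pd.Series | None = None) -> dict:
    """Exact set-overlap fractions between two selections.

    Returns |A∩B|/|A| and |A∩B|/|B| (NaN for an empty side) plus a per-stage
    breakdown when stage labels are supplied.
    """
    a, b = set(sel_a.cell_ids), set(sel_b.cell_ids)
    inter = a & b
    out = {
        "n_a": len(a), "n_b": len(b), "n_intersection": len(inter),
        "frac_of_a": len(inter) / len(a) if a else np.nan,
        "frac_of_b": len(inter) / len(b) if b else np.nan,
    }
    if stages is not None:
        rows = []
        for stage in sorted(set(stages)):
            ids = set(stages.index[stages == stage])
            ai, bi = a & ids, b & ids
            ii = ai & bi
            rows.append({"stage": stage, "n_a": len(ai), "n_b": len(bi),
                         "n_intersection": len(ii),
                         "frac_of_a": len(ii) / len(ai) if ai else np.nan,
                         "frac_of_b": len(ii) / len(bi) if bi else np.nan})
        out["per_stage"] = pd.DataFrame(rows)
    return out


def stage_composition(sel: Selection, stages: pd.Series) -> pd.DataFrame:
    """Per-stage tabulation of a selection (percentages at one decimal)."""
    selected = set(sel.cell_ids)
    n_sel = len(selected)
    rows = []
    for stage in sorted(set(stages)):
        ids = set(stages.index[stages == stage])
        n_in = len(ids & selected)
        rows.append({
            "stage": stage,
            "n_selected": n_in,
            "n_stage_total": len(ids),
            "pct_of_stage": round(100.0 * n_in / len(ids), 1) if ids else np.nan,
            "pct_of_selection": round(100.0 * n_in / n_sel, 1) if n_sel else np.nan,
        })
    return pd.DataFrame(rows)


def plot_heatmap(z, result: ClusterResult, path, cell_names=None) -> None:
    """Cells x genes heatmap in dendrogram leaf order with a cluster color
    bar, the standard visualization for spatial single-cell subpopulations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(z.X if isinstance(z, ad.AnnData) else z, np.float64)
    order = result.leaf_order
    gene_order = (result.gene_leaf_order if result.gene_leaf_order is not None
                  else np.arange(x.shape[1]))
    fig, (ax_bar, ax_hm) = plt.subplots(
        1, 2, figsize=(8, 6), gridspec_kw={"width_ratios": [0.3, 10]})
    ax_bar.imshow(result.labels[order][:, None], aspect="auto", cmap="tab10",
                  interpolation="nearest")
    ax_bar.set_xticks([])
    ax_bar.set_yticks([])
    im = ax_hm.imshow(x[np.ix_(order, gene_order)], aspect="auto",
                      cmap="RdBu_r", vmin=-2.5, vmax=2.5,
                      interpolation="nearest")
    if isinstance(z, ad.AnnData):
        ax_hm.set_xticks(range(len(gene_order)))
        ax_hm.set_xticklabels(np.asarray(z.var_names)[gene_order],
                              rotation=90, fontsize=5)
    ax_hm.set_yticks([])
    fig.colorbar(im, ax=ax_hm, label="z-score", shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
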