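"""Shared fixtures: phantom acquisitions processed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from scmst import cells as cellmod
from scmst import imageproc, spotcall
from scmst.phantom import PhantomConfig, simulate_fov


def corrected(volume):
    """Flat-field corrected copy of a single-channel volume."""
    return imageproc.apply_flatfield(volume, imageproc.estimate_flatfield(volume))


@pytest.fixture(scope="session")
def imaging_phantom():
    """One embryo section: 3 FOVs at the default desk-scale geometry, with the
    repeated first-round hybridization used for signal-recovery QC."""
    cfg = PhantomConfig(n_embryos=1, rng_seed=11, simulate_repeat_round=True)
    fovs = [simulate_fov(cfg, 0, f) for f in range(3)]
    return cfg, fovs


@pytest.fixture(scope="session")
def imaging_products(imaging_phantom):
    """Full imaging-side processing of the phantom section.

    Preprocess + register + detect + feature + triage + segment + count each
    FOV once; downstream tests assert against the bundled ground truth.
    """
    cfg, fovs = imaging_phantom
    plan = fovs[0].round_plan
    per_fov = []
    dot_frames = []
    for fp in fovs:
        ref = corrected(fp.stacks[0][plan.ref_channel])
        shifts = {}
        for r, st in fp.stacks.items():
            rs = imageproc.register_rounds(ref, corrected(st[plan.ref_channel]),
                                           max_shift=(2, 8, 8), round_id=r)
            shifts[r] = rs.shift
            for gene in plan.genes_in_round(0 if r == "repeat" else r):
                _, ch = plan.channel_of(gene)
                corr = corrected(st[ch])
                dots = spotcall.detect_dots(imageproc.median3d(corr))
                dots = spotcall.dot_features(corr, dots)
                dots["gene"] = gene
                dots["round"] = r
                dots["channel"] = ch
                dots["fov"] = fp.fov
                dot_frames.append(dots)
        mem_rs = imageproc.register_rounds(ref, corrected(fp.membrane_stack[0]),
                                           max_shift=(2, 8, 8), round_id="membrane")
        shifts["membrane"] = mem_rs.shift
        aligned = imageproc.apply_shift(fp.membrane_stack,
                                        tuple(-s for s in mem_rs.shift))
        labels = cellmod.segment_cells(aligned[1], aligned[0])
        labels, edge_ids = cellmod.drop_edge_cells(labels)
        meta = cellmod.cell_metadata(labels, embryo=fp.embryo, fov=fp.fov,
                                     stage=fp.stage, edge_ids=edge_ids)
        per_fov.append({"fp": fp, "shifts": shifts, "labels": labels,
                        "cell_meta": meta})

    dots = pd.concat(dot_frames, ignore_index=True)
    dots, triage_results = spotcall.triage_per_gene(
        dots[dots["round"] != "repeat"].copy(), k=3, seed=1)
    repeat_dots = pd.concat(dot_frames, ignore_index=True)
    repeat_dots = repeat_dots[repeat_dots["round"].isin([0, "repeat"])].copy()
    repeat_dots, _ = spotcall.triage_per_gene(repeat_dots, k=3, seed=1)

    matrices = []
    for item in per_fov:
        sub = dots[(dots["fov"] == item["fp"].fov) & dots["kept"]]
        assigned = cellmod.assign_dots(sub, item["labels"], item["shifts"])
        item["assigned"] = assigned
        matrices.append(cellmod.build_count_matrix(
            assigned, cfg.gene_panel, item["cell_meta"]))
    counts = cellmod.concat_count_matrices(matrices)

    return {"cfg": cfg, "plan": plan, "per_fov": per_fov, "dots": dots,
            "repeat_dots": repeat_dots, "counts": counts,
            "triage_results": triage_results}


def match_rates(dots, per_fov, plan, gene_panel, radius=3.0):
    """Aggregate kept-dot recall and precision against the dot truth tables."""
    rec = prec = n_true = n_kept = 0
    for item in per_fov:
        fp = item["fp"]
        dt = fp.dot_truth
        for gene in gene_panel:
            r, ch = plan.channel_of(gene)
            truth = dt[(dt["round"] == r) & (dt["channel"] == ch)]
            tr = truth[truth["class"] == "true"]
            n_true += len(tr)
            sub = dots[(dots["gene"] == gene) & dots["kept"]
                       & (dots["fov"] == fp.fov)]
            det = sub[["z", "y", "x"]].to_numpy() - np.asarray(fp.true_shifts[r])
            n_kept += len(det)
            if len(det) == 0 or len(tr) == 0:
                continue
            d, _ = cKDTree(tr[["z", "y", "x"]].to_numpy()).query(det)
            prec += int((d <= radius).sum())
            d2, _ = cKDTree(det).query(tr[["z", "y", "x"]].to_numpy())
            rec += int((d2 <= radius).sum())
    return rec / n_true, prec / n_kept, n_true, n_kept
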