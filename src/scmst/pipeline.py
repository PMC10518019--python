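"""End-to-end pipeline orchestration with validated config and provenance.

Stages run in a fixed order — preprocess, register, detect, triage, segment,
count, normalize, cluster, select, backmap/stitch — on a phantom acquisition
generated from the validated config. Every artifact is derivable from config
plus seeds: re-running with the same config reproduces all deterministic
artifacts byte for byte. The manifest records the package version, the full
config and an SHA-256 per artifact; structured logs go to ``run.log`` as JSON
lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cells as cellmod
from . import expression as expr
from . import imageproc, spatialviz, spotcall
from .phantom import PhantomConfig, simulate_fov

LOGGER_NAME = "scmst.pipeline"


class PhantomSettings(BaseModel):
    """Phantom acquisition geometry exposed to the pipeline config."""

    model_config = ConfigDict(extra="forbid")

    n_embryos: int = 1
    n_fovs_per_embryo: int = 3
    volume_shape: tuple[int, int, int] = (12, 192, 192)
    n_cells_per_fov: int = 50
    stage: str = "HH5"
    simulate_repeat_round: bool = True
    rng_seed: int = 0

    def to_config(self) -> PhantomConfig:
        return PhantomConfig(
            n_embryos=self.n_embryos,
            n_fovs_per_embryo=self.n_fovs_per_embryo,
            volume_shape=tuple(self.volume_shape),
            n_cells_per_fov=self.n_cells_per_fov,
            stage=self.stage,
            simulate_repeat_round=self.simulate_repeat_round,
            rng_seed=self.rng_seed,
        )


class StageFlags(BaseModel):
    model_config = ConfigDict(extra="forbid")

    triage: bool = True
    triage_plots: bool = True
    drop_edge_cells: bool = True
    recovery_qc: bool = True
    backmap: bool = True
    stitch: bool = True


class PipelineConfig(BaseModel):
    """Schema-validated pipeline parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    phantom: PhantomSettings = Field(default_factory=PhantomSettings)
    seed: int = 0
    max_shift: tuple[int, int, int] = (2, 8, 8)
    floor_quantile: float = 0.95
    psf_sigma: tuple[float, float, float] = (1.0, 1.3, 1.3)
    triage_k: int | None = 3
    artifact_quantile: float = 0.995
    recovery_threshold: float = 0.70
    cluster_k: int = 4
    selection_genes: list[str] = Field(
        default_factory=lambda: ["Nanog", "PouV", "Klf4"]
    )
    stages: StageFlags = Field(default_factory=StageFlags)
    fov_gap_px: int = 8  # display-only spacing between stitched FOVs


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _setup_logging(run_dir: Path) -> logging.Logger:
    logger = logging.getLogger(LOGGER_NAME)
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(run_dir / "run.log")

    class JsonFormatter(logging.Formatter):
        def format(self, record):
            return json.dumps({"t": self.formatTime(record),
                               "level": record.levelname,
                               "msg": record.getMessage()})

    handler.setFormatter(JsonFormatter())
    logger.addHandler(handler)
    return logger


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Per-FOV imaging stages
# ---------------------------------------------------------------------------


def _process_fov(fp, config: PipelineConfig, logger):
    """Preprocess, register, detect and segment one field of view.

    Returns ``(dots, labels, cell_meta, shifts)`` where dot features come from
    the flat-field-corrected volumes and detection from their median-filtered
    version, and shifts are the registered per-round offsets.
    """
    plan = fp.round_plan
    ref_channel = plan.ref_channel

    def corrected(volume):
        field = imageproc.estimate_flatfield(volume)
        return imageproc.apply_flatfield(volume, field)

    ref_nuclei = corrected(fp.stacks[0][ref_channel])

    shifts, dot_frames = {}, []
    for r, stack in fp.stacks.items():
        mov = corrected(stack[ref_channel])
        rs = imageproc.register_rounds(ref_nuclei, mov,
                                       max_shift=config.max_shift, round_id=r)
        shifts[r] = rs.shift
        for gene in plan.genes_in_round(0 if r == "repeat" else r):
            _, ch = plan.channel_of(gene)
            corr = corrected(stack[ch])
            filt = imageproc.median3d(corr)
            dots = spotcall.detect_dots(filt, psf_sigma=config.psf_sigma,
                                        floor_quantile=config.floor_quantile)
            dots = spotcall.dot_features(corr, dots, psf_sigma=config.psf_sigma)
            dots["gene"] = gene
            dots["round"] = r
            dots["channel"] = ch
            dot_frames.append(dots)
    dots = pd.concat(dot_frames, ignore_index=True)
    dots["embryo"] = fp.embryo
    dots["fov"] = fp.fov

    mem_rs = imageproc.register_rounds(ref_nuclei,
                                       corrected(fp.membrane_stack[0]),
                                       max_shift=config.max_shift,
                                       round_id="membrane")
    shifts["membrane"] = mem_rs.shift
    aligned = imageproc.apply_shift(fp.membrane_stack,
                                    tuple(-s for s in mem_rs.shift))
    params = cellmod.SegmentationParams()
    labels = cellmod.segment_cells(aligned[1], aligned[0], params)
    edge_ids = []
    if config.stages.drop_edge_cells:
        labels, edge_ids = cellmod.drop_edge_cells(labels)
    cell_meta = cellmod.cell_metadata(labels, params.voxel_size,
                                      embryo=fp.embryo, fov=fp.fov,
                                      stage=fp.stage, edge_ids=edge_ids)
    logger.info(f"embryo {fp.embryo} fov {fp.fov}: {len(dots)} candidate dots, "
                f"{labels.max()} cells, shifts {shifts}")
    return dots, labels, cell_meta, shifts


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages on the configured phantom; returns the manifest."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logging(run_dir)
    manifest = {"config": json.loads(config.model_dump_json()),
                "stages": [], "artifacts": {}, "warnings": []}

    def save(name, writer):
        path = run_dir / name
        writer(path)
        manifest["artifacts"][name] = _sha256(path)
        return path

    try:
        phantom_cfg = config.phantom.to_config()
        fov_results = []
        truth = []
        for embryo in range(phantom_cfg.n_embryos):
            for fov in range(phantom_cfg.n_fovs_per_embryo):
                fp = simulate_fov(phantom_cfg, embryo, fov)
                truth.append(fp)
                fov_results.append(_process_fov(fp, config, logger))
        manifest["stages"] += ["simulate", "preprocess", "register", "detect",
                               "segment"]

        save("shifts.json", lambda p: p.write_text(json.dumps(
            [{"embryo": fp.embryo, "fov": fp.fov,
              "shifts": {str(k): list(v) for k, v in res[3].items()}}
             for fp, res in zip(truth, fov_results)], indent=1)))

        all_dots = pd.concat([r[0] for r in fov_results], ignore_index=True)
        if config.stages.triage:
            all_dots, triage_results = spotcall.triage_per_gene(
                all_dots, k=config.triage_k, seed=config.seed,
                artifact_quantile=config.artifact_quantile)
            diag = {g: {"k": t.k, "retained": t.retained,
                        "sizes": t.sizes.tolist(),
                        "centroids": np.round(t.centroids, 3).tolist(),
                        "warnings": t.warnings}
                    for g, t in triage_results.items()}
            save("triage.json", lambda p: p.write_text(json.dumps(diag, indent=1)))
            if config.stages.triage_plots:
                for path in spotcall.plot_triage(all_dots, run_dir / "triage_qc"):
                    manifest["artifacts"][f"triage_qc/{path.name}"] = _sha256(path)
        else:
            all_dots["cluster"] = 0
            all_dots["kept"] = True
            manifest["warnings"].append(
                "triage disabled: counts include non-specific dots and artifacts"
            )
        manifest["stages"].append("triage")

        recovery = None
        if config.stages.recovery_qc and (all_dots["round"] == "repeat").any():
            recovery = spotcall.recovery_rate(
                all_dots[all_dots["round"] == 0],
                all_dots[all_dots["round"] == "repeat"],
                qc_threshold=config.recovery_threshold)
            save("recovery.json", lambda p: p.write_text(json.dumps({
                "overall": None if np.isnan(recovery["overall"])
                else recovery["overall"],
                "passed": bool(recovery["passed"]),
                "threshold": recovery["threshold"],
                "per_gene": recovery["per_gene"].to_dict("records"),
            }, indent=1)))
        manifest["stages"].append("recovery_qc")

        # counting: per FOV, with that FOV's registered shifts
        matrices = []
        for fp, (dots, labels, cell_meta, shifts) in zip(truth, fov_results):
            sub = all_dots[(all_dots["embryo"] == fp.embryo)
                           & (all_dots["fov"] == fp.fov)
                           & (all_dots["round"] != "repeat")]
            assigned = cellmod.assign_dots(sub[sub["kept"]], labels, shifts)
            gene_meta = pd.DataFrame(
                {"round": [fp.round_plan.channel_of(g)[0] for g in phantom_cfg.gene_panel],
                 "channel": [fp.round_plan.channel_of(g)[1] for g in phantom_cfg.gene_panel]},
                index=phantom_cfg.gene_panel)
            matrices.append(cellmod.build_count_matrix(
                assigned, phantom_cfg.gene_panel, cell_meta, gene_meta))
        counts = cellmod.concat_count_matrices(matrices)
        save("counts.csv", lambda p: counts.to_df().to_csv(p))
        save("cells.tsv", lambda p: counts.obs.to_csv(p, sep="\t"))
        save("genes.tsv", lambda p: counts.var.to_csv(p, sep="\t"))

        def write_mtx(p):
            from scipy.io import mmwrite
            from scipy.sparse import csr_matrix
            mmwrite(str(p), csr_matrix(counts.X))

        save("counts.mtx", write_mtx)
        manifest["stages"].append("count")

        zw = expr.zscore_within_embryo(counts)
        z = expr.zscore_pooled(zw, groupby="stage")
        save("zscores.csv", lambda p: pd.DataFrame(
            z.X, index=z.obs_names, columns=z.var_names).to_csv(p))
        manifest["stages"].append("normalize")

        clus = expr.hcluster(z, k=config.cluster_k)
        save("clusters.csv", lambda p: pd.DataFrame(
            {"cell": z.obs_names, "cluster": clus.labels}).to_csv(p, index=False))
        save("dendrogram.nwk", lambda p: p.write_text(
            expr.dendrogram_newick(clus.linkage, list(z.obs_names))))
        save("heatmap.png", lambda p: expr.plot_heatmap(z, clus, p))
        manifest["stages"].append("cluster")

        sel = expr.select_coexpressing(z, config.selection_genes)
        save("selection.csv", lambda p: pd.DataFrame(
            {"cell": sel.cell_ids}).to_csv(p, index=False))
        manifest["stages"].append("select")

        if config.stages.backmap:
            colormap = spatialviz.build_colormap(sorted(set(clus.labels)))
            panels = []
            for fp, (dots, labels, cell_meta, shifts) in zip(truth, fov_results):
                prefix = f"e{fp.embryo}_f{fp.fov}_"
                group = {
                    int(name.split("_c")[1]): int(lab)
                    for name, lab in zip(z.obs_names, clus.labels)
                    if name.startswith(prefix)
                }
                rgb = spatialviz.backmap(labels, group, colormap)
                panels.append(rgb)
                import matplotlib
                matplotlib.use("Agg")
                from matplotlib.image import imsave
                save(f"backmap_e{fp.embryo}_f{fp.fov}.png",
                     lambda p, rgb=rgb: imsave(p, rgb))
            if config.stages.stitch:
                gap = config.fov_gap_px
                offsets = [(0, i * (panels[0].shape[1] + gap))
                           for i in range(len(panels))]
                mosaic = spatialviz.stitch(panels, offsets)
                from matplotlib.image import imsave
                save("mosaic.png", lambda p: imsave(p, mosaic.image))
        manifest["stages"] += ["backmap", "stitch"]

        try:
            from importlib.metadata import version
            manifest["version"] = version("scmst")
        except Exception:
            manifest["version"] = "unknown"
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("pipeline complete")
        return manifest
    except Exception as exc:
        manifest["error"] = {"stage": manifest["stages"][-1] if manifest["stages"]
                             else "simulate", "message": str(exc)}
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.error(f"pipeline failed: {exc}")
        raise


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------


def qc_report(run_dir) -> Path:
    """Assemble a markdown QC report from a (possibly partial) run directory."""
    run_dir = Path(run_dir)
    lines = ["# scMST run QC report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"Stages completed: {', '.join(manifest.get('stages', []))}")
        for w in manifest.get("warnings", []):
            lines.append(f"**Warning:** {w}")
        if "error" in manifest:
            lines.append(f"**Run failed at stage {manifest['error']['stage']}:** "
                         f"{manifest['error']['message']}")
        lines.append("")

    lines.append("## Signal recovery (repeated first round)")
    rec = run_dir / "recovery.json"
    if rec.exists():
        data = json.loads(rec.read_text())
        status = "PASS" if data["passed"] else "FAIL"
        overall = data["overall"]
        lines.append(f"Overall recovery: "
                     f"{overall:.1%} — **{status}** "
                     f"(threshold {data['threshold']:.0%})"
                     if overall is not None else "Overall recovery undefined")
        lines.append("")
        lines.append("| gene | initial | repeat | recovery |")
        lines.append("|---|---|---|---|")
        for row in data["per_gene"]:
            r = row["recovery"]
            lines.append(f"| {row['gene']} | {row['n_initial']} | "
                         f"{row['n_repeat']} | "
                         f"{'%.1f%%' % (100 * r) if r == r else 'missing'} |")
    else:
        lines.append("Not performed (no repeat round in this run).")
    lines.append("")

    lines.append("## Dot triage")
    if (run_dir / "triage_qc").is_dir():
        pngs = sorted(p.name for p in (run_dir / "triage_qc").glob("*.png"))
        lines.append(f"Per-gene scatter plots: {len(pngs)} files in `triage_qc/`.")
        lines.append("")
    triage = run_dir / "triage.json"
    if triage.exists():
        diag = json.loads(triage.read_text())
        lines.append("| gene | k | cluster sizes | retained |")
        lines.append("|---|---|---|---|")
        for g, t in sorted(diag.items()):
            lines.append(f"| {g} | {t['k']} | {t['sizes']} | {t['retained']} |")
    else:
        lines.append("Missing (triage disabled or not reached).")
    lines.append("")

    counts = run_dir / "counts.csv"
    if counts.exists():
        df = pd.read_csv(counts, index_col=0)
        lines.append("## Counting")
        lines.append(f"{df.shape[0]} cells x {df.shape[1]} genes; "
                     f"total transcripts {int(df.to_numpy().sum())}.")
        lines.append("")

    clusters = run_dir / "clusters.csv"
    if clusters.exists():
        df = pd.read_csv(clusters)
        sizes = df["cluster"].value_counts().sort_index()
        lines.append("## Clusters")
        lines.append(", ".join(f"cluster {c}: {n} cells"
                               for c, n in sizes.items()))
        lines.append("")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
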