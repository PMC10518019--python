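"""Synthetic multi-round smFISH acquisitions with complete ground truth.

The phantom emulates one serial-hybridization experiment on an embryo cross
section: five genes imaged per six-channel round (channel 0 carries the
nuclear reference stain in every round), three fields of view per section,
diffraction-limited dots drawn from distinct true / non-specific / artifact
intensity populations, a smooth multiplicative illumination field, integer
inter-round stage shifts, a final immunostaining round carrying the membrane
channel, and subpopulation-structured per-cell expression (committed
ectodermal domains plus a stem group co-expressing pluripotency genes).

Every downstream stage of the pipeline is testable against the ground truth
bundled with each rendered field of view: the cell label volume, the true
per-cell count matrix, a per-dot truth table and the planted round shifts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries, watershed

from .utils import add_blob, gaussian_kernel_3d, translate_integer

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: 30-gene ectoderm panel: pluripotency factors plus markers of the central
#: nervous system (CNS), neural plate border (NPB), neural crest (NC) and
#: non-neural ectoderm (NNE) domains.
DEFAULT_GENE_PANEL = [
    # pluripotency
    "Nanog", "PouV", "Klf4",
    # CNS / neural progenitor
    "Sox2", "Sox3", "Sox21", "Otx2", "Six3", "Pax6", "Zic2",
    # neural plate border
    "Pax7", "Msx1", "Zic1", "Tfap2B", "Gbx2", "Wnt8A",
    # neural crest specifiers
    "FoxD3", "Snai2", "Sox9", "Sox10", "Ets1", "Tfap2C",
    # non-neural ectoderm
    "Tfap2A", "Dlx5", "Dlx6", "Gata2", "Gata3", "Krt19", "Bmp4", "Epcam",
]

_CNS = ["Sox2", "Sox3", "Sox21", "Otx2", "Six3", "Pax6", "Zic2"]
_NPB = ["Pax7", "Msx1", "Zic1", "Tfap2B", "Gbx2", "Wnt8A"]
_NNE = ["Tfap2A", "Dlx5", "Dlx6", "Gata2", "Gata3", "Krt19", "Bmp4", "Epcam"]
_PLURI = ["Nanog", "PouV", "Klf4"]

#: Default subpopulation structure: three committed ectodermal domains plus a
#: stem group co-expressing the pluripotency genes with moderate broad
#: expression of domain markers (a transitioning/undecided profile).
DEFAULT_SUBPOP_SPEC = [
    ("committed_cns", 0.30, {g: 8.0 for g in _CNS}),
    ("committed_npb", 0.25, {g: 8.0 for g in _NPB}),
    ("committed_nne", 0.25, {g: 8.0 for g in _NNE}),
    (
        "stem",
        0.20,
        {**{g: 8.0 for g in _PLURI}, **{g: 2.0 for g in ("Sox2", "Tfap2A", "Pax7")}},
    ),
]

#: Mean expression for genes a subpopulation does not actively express.
BASELINE_MEAN = 0.2


@dataclass
class DotClassModel:
    """Amplitude distribution and volumetric rate of one dot class."""

    mean: float
    sd: float
    rate: float = 0.0  # dots per voxel; 0 for the expression-driven true class

    def validate(self) -> None:
        if self.sd < 0 or self.rate < 0:
            raise ValueError("dot class sd and rate must be non-negative")


@dataclass
class PhantomConfig:
    """Acquisition geometry, optics and biology of the synthetic experiment.

    Defaults are desk scale: 2 embryos x 3 FOVs of (12, 192, 192) voxels at
    (0.5, 0.25, 0.25) um, ~50 cells per FOV, 30 genes at 5 per round on a
    6-channel microscope (channel 0 = nuclear reference in every round, with
    a final immunostaining round carrying the membrane composite).
    """

    n_embryos: int = 2
    n_fovs_per_embryo: int = 3
    volume_shape: tuple = (12, 192, 192)
    voxel_size: tuple = (0.5, 0.25, 0.25)  # um (z, y, x)
    n_cells_per_fov: int = 50
    gene_panel: list = field(default_factory=lambda: list(DEFAULT_GENE_PANEL))
    genes_per_round: int = 5
    channels_per_round: int = 6
    subpop_spec: list = field(default_factory=lambda: list(DEFAULT_SUBPOP_SPEC))
    count_model: str = "poisson"  # or "negbin"
    nb_dispersion: float = 2.0  # gamma shape for the negbin option
    dot_intensity_model: dict = field(
        default_factory=lambda: {
            "true": DotClassModel(mean=1000.0, sd=80.0, rate=0.0),
            "nonspecific": DotClassModel(mean=300.0, sd=60.0, rate=1e-4),
            "artifact": DotClassModel(mean=3500.0, sd=400.0, rate=8e-6),
        }
    )
    psf_sigma: tuple = (1.0, 1.3, 1.3)  # voxels (z, y, x)
    min_dot_separation: float = 3.0  # voxels, xy scale, within one channel/cell
    illumination_strength: float = 0.25  # peak-to-mean amplitude of the field
    max_shift: tuple = (1, 8, 8)  # per-round |integer shift| bound (z, y, x)
    background: float = 100.0  # camera offset + slide autofluorescence
    tissue_autofluorescence: float = 60.0  # extra background inside tissue
    read_noise_sd: float = 5.0
    nuclei_amplitude: float = 600.0
    nuclei_sigma: tuple = (1.5, 3.0, 3.0)
    membrane_amplitude: float = 800.0
    tissue_margin: tuple = (2, 14, 14)  # keeps tissue visible at max shift
    simulate_repeat_round: bool = False
    repeat_recovery: float = 0.8  # transcript survival in the repeated round 0
    stage: str = "HH5"
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("volume_shape", "voxel_size", "psf_sigma", "max_shift",
                     "tissue_margin", "nuclei_sigma"):
            value = tuple(getattr(self, name))
            if len(value) != 3:
                raise ValueError(f"{name} must have three (z, y, x) entries")
            setattr(self, name, value)
        fr = [f for _, f, _ in self.subpop_spec]
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("subpopulation mixing fractions must sum to 1")
        if self.genes_per_round > self.channels_per_round - 1:
            raise ValueError(
                "genes_per_round must leave one channel free for the reference stain"
            )
        for m in self.dot_intensity_model.values():
            m.validate()
        if any(s <= 0 for s in self.psf_sigma):
            raise ValueError("PSF sigma must be positive")
        if any(v <= 0 for v in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if not (0.0 <= self.repeat_recovery <= 1.0):
            raise ValueError("repeat_recovery must lie in [0, 1]")


@dataclass
class RoundPlan:
    """Assignment of every gene to one (hybridization round, channel)."""

    assignments: dict  # gene -> (round, channel)
    n_rounds: int
    channels_per_round: int
    ref_channel: int = 0

    def genes_in_round(self, r: int) -> list:
        return [g for g, (rr, _) in self.assignments.items() if rr == r]

    def channel_of(self, gene: str):
        return self.assignments[gene]


@dataclass
class FovPhantom:
    """One rendered field of view plus its complete ground truth."""

    embryo: int
    fov: int
    stage: str
    labels: np.ndarray  # (z, y, x) int32, 0 = background
    cell_table: pd.DataFrame
    true_counts: pd.DataFrame  # index cell_id, columns gene panel
    dot_truth: pd.DataFrame
    stacks: dict  # round id -> (channels, z, y, x) float32
    membrane_stack: np.ndarray  # (2, z, y, x): [nuclei, membrane composite]
    true_shifts: dict  # round id (incl. "membrane", "repeat") -> (dz, dy, dx)
    illumination: np.ndarray  # (y, x) multiplicative field, mean 1
    round_plan: RoundPlan


# ---------------------------------------------------------------------------
# Round plan
# ---------------------------------------------------------------------------


def make_round_plan(gene_panel, genes_per_round: int, channels: int) -> RoundPlan:
    """Fill hybridization rounds in panel order, ``genes_per_round`` at a time.

    Channel 0 is reserved for the nuclear reference stain whenever the channel
    count allows; genes occupy channels 1..genes_per_round.
    """
    if not gene_panel:
        raise ValueError("gene panel is empty")
    if len(set(gene_panel)) != len(gene_panel):
        raise ValueError("gene panel contains duplicate names")
    if genes_per_round < 1:
        raise ValueError("genes_per_round must be >= 1")
    if channels < genes_per_round:
        raise ValueError("not enough channels for the requested genes per round")
    first = 1 if channels > genes_per_round else 0
    assignments = {}
    for i, gene in enumerate(gene_panel):
        assignments[gene] = (i // genes_per_round, first + i % genes_per_round)
    n_rounds = -(-len(gene_panel) // genes_per_round)
    return RoundPlan(assignments=assignments, n_rounds=n_rounds,
                     channels_per_round=channels, ref_channel=0)


# ---------------------------------------------------------------------------
# Tissue & expression ground truth
# ---------------------------------------------------------------------------


def _tissue_mask(shape, margin, rng) -> np.ndarray:
    """Smooth ectoderm-like band through the FOV, away from the borders."""
    nz, ny, nx = shape
    mz, my, mx = margin
    x = np.arange(nx)
    center = ny / 2 + 0.08 * ny * np.sin(2 * np.pi * x / nx * rng.uniform(0.5, 1.5)
                                         + rng.uniform(0, 2 * np.pi))
    half = 0.30 * ny * (1 + 0.15 * np.sin(2 * np.pi * x / nx * rng.uniform(0.5, 1.5)
                                          + rng.uniform(0, 2 * np.pi)))
    yy = np.arange(ny)[:, None]
    band = np.abs(yy - center[None, :]) <= half[None, :]
    band[: my, :] = False
    band[ny - my:, :] = False
    band[:, : mx] = False
    band[:, nx - mx:] = False
    mask = np.zeros(shape, bool)
    mask[mz: nz - mz] = band[None, :, :]
    return mask


def simulate_tissue(config: PhantomConfig, seed) -> tuple[np.ndarray, pd.DataFrame]:
    """Tessellate a tissue band into ``n_cells_per_fov`` connected cells.

    Seed points are scattered with approximate blue-noise spacing and grown by
    a nearest-seed flood (watershed on the anisotropy-scaled distance to the
    closest seed) restricted to the tissue mask, which guarantees connected,
    Voronoi-like cell territories. Labels are contiguous 1..N; 0 = background.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_cells_per_fov
    if n < 1:
        raise ValueError("need at least one cell")
    mask = _tissue_mask(config.volume_shape, config.tissue_margin, rng)
    voxels = np.argwhere(mask)
    if len(voxels) < n:
        raise ValueError(
            f"cannot place {n} cells in a tissue mask of {len(voxels)} voxels"
        )
    scale = np.asarray(config.voxel_size)
    # blue-noise-ish dart throwing for realistic spacing
    target = 0.7 * (len(voxels) * np.prod(scale) / n) ** (1 / 3)
    order = rng.permutation(len(voxels))
    seeds: list[np.ndarray] = []
    for idx in order:
        p = voxels[idx]
        if all(np.linalg.norm((p - q) * scale) >= target for q in seeds):
            seeds.append(p)
            if len(seeds) == n:
                break
    if len(seeds) < n:  # fall back to unconstrained placement for the remainder
        taken = {tuple(s) for s in seeds}
        for idx in order:
            p = voxels[idx]
            if tuple(p) not in taken:
                seeds.append(p)
                taken.add(tuple(p))
                if len(seeds) == n:
                    break
    seeds = np.asarray(seeds)

    tree = cKDTree(seeds * scale)
    dist, _ = tree.query(voxels * scale)
    elevation = np.zeros(config.volume_shape, np.float64)
    elevation[tuple(voxels.T)] = dist
    markers = np.zeros(config.volume_shape, np.int32)
    markers[tuple(seeds.T)] = np.arange(1, n + 1)
    labels = watershed(elevation, markers=markers, mask=mask).astype(np.int32)

    # relabel contiguous in case any seed territory vanished (should not happen)
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(labels.max() + 1, np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    labels = remap[labels]

    names = [s[0] for s in config.subpop_spec]
    fracs = [s[1] for s in config.subpop_spec]
    rows = []
    for lab in range(1, labels.max() + 1):
        vox = np.argwhere(labels == lab)
        centroid = vox.mean(axis=0)
        rows.append({
            "cell_id": lab,
            "subpop": rng.choice(names, p=fracs),
            "centroid_z": centroid[0],
            "centroid_y": centroid[1],
            "centroid_x": centroid[2],
            "volume_voxels": len(vox),
        })
    return labels, pd.DataFrame(rows)


def simulate_counts(cell_table: pd.DataFrame, subpop_spec, seed,
                    gene_panel=None, model: str = "poisson",
                    nb_dispersion: float = 2.0) -> pd.DataFrame:
    """Draw the true per-cell transcript counts from the subpopulation means.

    Counts are independent Poisson (optionally gamma-Poisson, i.e. negative
    binomial) per cell x gene with the cell's subpopulation mean; genes the
    subpopulation does not express get the small baseline mean.
    """
    gene_panel = list(gene_panel) if gene_panel is not None else list(DEFAULT_GENE_PANEL)
    rng = np.random.default_rng(seed)
    means_by_subpop = {}
    for name, _, gene_means in subpop_spec:
        for g, m in gene_means.items():
            if m < 0:
                raise ValueError(f"negative mean expression for {g} in {name}")
        means_by_subpop[name] = np.array(
            [gene_means.get(g, BASELINE_MEAN) for g in gene_panel]
        )
    mu = np.vstack([means_by_subpop[s] for s in cell_table["subpop"]])
    if model == "poisson":
        counts = rng.poisson(mu)
    elif model == "negbin":
        lam = rng.gamma(nb_dispersion, mu / nb_dispersion)
        counts = rng.poisson(lam)
    else:
        raise ValueError(f"unknown count model {model!r}")
    return pd.DataFrame(counts, index=cell_table["cell_id"].to_numpy(),
                        columns=gene_panel)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _illumination_field(shape_yx, strength, rng) -> np.ndarray:
    """Smooth multiplicative field, strictly positive, normalized to mean 1."""
    ny, nx = shape_yx
    y = (np.arange(ny) - rng.uniform(0.2, 0.8) * ny) / ny
    x = (np.arange(nx) - rng.uniform(0.2, 0.8) * nx) / nx
    bump = np.exp(-(y[:, None] ** 2 + x[None, :] ** 2) / (2 * 0.45 ** 2))
    tilt = 0.3 * (y[:, None] * rng.uniform(-1, 1) + x[None, :] * rng.uniform(-1, 1))
    f = 1.0 + strength * (bump - bump.mean()) + strength * tilt
    f = np.clip(f, 0.1, None)
    return f / f.mean()


def _place_dots(candidates, k, placed, sep_radii, rng):
    """Uniform positions among ``candidates``, kept at least one separation
    ellipsoid away from every dot already placed in the same channel so each
    rendered transcript is individually resolvable. Relaxes to unconstrained
    placement if the region is too crowded, keeping the count invariant."""
    if k == 0:
        return np.empty((0, 3), int)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < k and attempts < 60 * k:
        p = candidates[rng.integers(len(candidates))]
        if all((((p - q) / sep_radii) ** 2).sum() >= 1.0 for q in placed):
            chosen.append(p)
            placed.append(p)
        attempts += 1
    while len(chosen) < k:
        p = candidates[rng.integers(len(candidates))]
        chosen.append(p)
        placed.append(p)
    return np.asarray(chosen)


def render_stacks(labels: np.ndarray, cell_table: pd.DataFrame,
                  true_counts: pd.DataFrame, plan: RoundPlan,
                  config: PhantomConfig, seed):
    """Render the multi-round acquisition for one FOV.

    Returns ``(stacks, membrane_stack, dot_truth, true_shifts, illumination)``.
    Each true transcript becomes one PSF blob inside its cell; non-specific and
    artifact dots are scattered at their class rates; each round's stack is
    multiplied by the illumination field and translated by its planted shift.
    Dot positions in ``dot_truth`` are in the reference (round 0) frame.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    shape = config.volume_shape
    kernel = gaussian_kernel_3d(config.psf_sigma)
    # separation ellipsoid: comfortably larger than a 2-sigma suppression
    # footprint so dots of one channel stay individually resolvable maxima
    sep_radii = 2.0 * np.maximum(
        2.0 * np.asarray(config.psf_sigma),
        config.min_dot_separation / 3.0,
    )
    field_yx = _illumination_field(shape[1:], config.illumination_strength, rng)
    tissue = labels > 0

    label_voxels = {
        lab: np.argwhere(labels == lab) for lab in range(1, labels.max() + 1)
    }

    nuclei = np.zeros(shape, np.float32)
    nk = gaussian_kernel_3d(config.nuclei_sigma)
    for _, row in cell_table.iterrows():
        c = (row["centroid_z"], row["centroid_y"], row["centroid_x"])
        add_blob(nuclei, c, nk, config.nuclei_amplitude * rng.uniform(0.8, 1.2))

    membrane = find_boundaries(labels, mode="thick").astype(np.float32)
    membrane = gaussian_filter(membrane, sigma=(0.5, 1.0, 1.0))
    membrane *= config.membrane_amplitude / max(membrane.max(), 1e-9)

    model = config.dot_intensity_model
    n_vox = int(np.prod(shape))

    all_voxels = np.indices(shape).reshape(3, -1).T

    def scatter_noise(cls, round_id, channel, scene, records, placed):
        m = model[cls]
        n_dots = rng.poisson(m.rate * n_vox)
        pts = _place_dots(all_voxels, n_dots, placed, sep_radii, rng)
        for p in pts:
            amp = max(rng.normal(m.mean, m.sd), m.mean / 4)
            add_blob(scene, p, kernel, amp)
            records.append((round_id, channel, "", cls, -1, *p, amp))

    def render_gene(gene, counts_for_gene, round_id, channel, scene, records,
                    placed):
        m = model["true"]
        for cell_id, k in counts_for_gene.items():
            if k == 0:
                continue
            pts = _place_dots(label_voxels[cell_id], int(k), placed,
                              sep_radii, rng)
            for p in pts:
                amp = max(rng.normal(m.mean, m.sd), m.mean / 4)
                add_blob(scene, p, kernel, amp)
                records.append((round_id, channel, gene, "true", cell_id, *p, amp))

    records: list[tuple] = []
    base = config.background + config.tissue_autofluorescence * tissue

    def finish(scene_stack, shift):
        raw = field_yx[None, None, :, :] * (base[None] + scene_stack)
        raw = raw + rng.normal(0, config.read_noise_sd, raw.shape)
        raw = np.clip(raw, 0, None).astype(np.float32)
        return translate_integer(raw, shift)

    def draw_shift():
        return tuple(int(rng.integers(-m, m + 1)) for m in config.max_shift)

    stacks = {}
    true_shifts = {}
    for r in range(plan.n_rounds):
        scene = np.zeros((plan.channels_per_round,) + shape, np.float32)
        scene[plan.ref_channel] = nuclei
        for gene in plan.genes_in_round(r):
            _, ch = plan.channel_of(gene)
            placed: list = []
            render_gene(gene, true_counts[gene], r, ch, scene[ch], records, placed)
            scatter_noise("nonspecific", r, ch, scene[ch], records, placed)
            scatter_noise("artifact", r, ch, scene[ch], records, placed)
        shift = (0, 0, 0) if r == 0 else draw_shift()
        true_shifts[r] = shift
        stacks[r] = finish(scene, shift)

    # final immunostaining round: nuclei reference + membrane composite
    mem_scene = np.stack([nuclei, membrane])
    mem_shift = draw_shift()
    true_shifts["membrane"] = mem_shift
    membrane_stack = finish(mem_scene, mem_shift)

    if config.simulate_repeat_round:
        # round 0 probes re-hybridized after the routine: thinned transcripts
        scene = np.zeros((plan.channels_per_round,) + shape, np.float32)
        scene[plan.ref_channel] = nuclei
        for gene in plan.genes_in_round(0):
            _, ch = plan.channel_of(gene)
            thinned = pd.Series(
                rng.binomial(true_counts[gene].to_numpy(), config.repeat_recovery),
                index=true_counts.index,
            )
            placed = []
            render_gene(gene, thinned, "repeat", ch, scene[ch], records, placed)
            scatter_noise("nonspecific", "repeat", ch, scene[ch], records, placed)
            scatter_noise("artifact", "repeat", ch, scene[ch], records, placed)
        shift = draw_shift()
        true_shifts["repeat"] = shift
        stacks["repeat"] = finish(scene, shift)

    dot_truth = pd.DataFrame(
        records,
        columns=["round", "channel", "gene", "class", "cell_id", "z", "y", "x",
                 "amplitude"],
    )
    return stacks, membrane_stack, dot_truth, true_shifts, field_yx


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------


def simulate_fov(config: PhantomConfig, embryo: int, fov: int) -> FovPhantom:
    """Simulate one field of view end to end, deterministically.

    The RNG stream is derived from ``(rng_seed, embryo, fov)`` so FOVs are
    independent and the whole acquisition is reproducible byte for byte.
    """
    config.validate()
    plan = make_round_plan(config.gene_panel, config.genes_per_round,
                           config.channels_per_round)
    key = [int(config.rng_seed), int(embryo), int(fov)]
    labels, cell_table = simulate_tissue(config, seed=key + [1])
    cell_table = cell_table.assign(embryo=embryo, fov=fov, stage=config.stage)
    true_counts = simulate_counts(cell_table, config.subpop_spec, seed=key + [2],
                                  gene_panel=config.gene_panel,
                                  model=config.count_model,
                                  nb_dispersion=config.nb_dispersion)
    stacks, membrane_stack, dot_truth, shifts, illum = render_stacks(
        labels, cell_table, true_counts, plan, config, seed=key + [3]
    )
    return FovPhantom(embryo=embryo, fov=fov, stage=config.stage, labels=labels,
                      cell_table=cell_table, true_counts=true_counts,
                      dot_truth=dot_truth, stacks=stacks,
                      membrane_stack=membrane_stack, true_shifts=shifts,
                      illumination=illum, round_plan=plan)


def simulate_acquisition(config: PhantomConfig) -> list[FovPhantom]:
    """All embryos x FOVs of the configured experiment."""
    return [
        simulate_fov(config, embryo, fov)
        for embryo in range(config.n_embryos)
        for fov in range(config.n_fovs_per_embryo)
    ]


# ---------------------------------------------------------------------------
# On-disk round trip (TIFF stacks + CSV/JSON ground truth)
# ---------------------------------------------------------------------------


def write_acquisition(fovs: list[FovPhantom], out_dir, with_truth: bool = True) -> None:
    """Write stacks as channel-major multi-page TIFFs plus a JSON sidecar.

    Ground truth (cell table, true counts, dot truth, labels, shifts) is
    withheld unless ``with_truth`` is set, mirroring a blinded acquisition.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fp in fovs:
        tag = f"e{fp.embryo}_f{fp.fov}"
        for r, stack in fp.stacks.items():
            tifffile.imwrite(out / f"{tag}_round{r}.tif",
                             stack.reshape((-1,) + stack.shape[2:]))
        tifffile.imwrite(out / f"{tag}_membrane.tif",
                         fp.membrane_stack.reshape((-1,) + fp.membrane_stack.shape[2:]))
        sidecar = {
            "embryo": fp.embryo, "fov": fp.fov, "stage": fp.stage,
            "rounds": [str(r) for r in fp.stacks],
            "channels_per_round": fp.round_plan.channels_per_round,
            "ref_channel": fp.round_plan.ref_channel,
            "round_plan": {g: list(rc) for g, rc in fp.round_plan.assignments.items()},
            "volume_shape": list(fp.labels.shape),
        }
        if with_truth:
            sidecar["true_shifts"] = {str(k): list(v) for k, v in fp.true_shifts.items()}
            tifffile.imwrite(out / f"{tag}_labels.tif", fp.labels)
            fp.cell_table.to_csv(out / f"{tag}_cells.csv", index=False)
            fp.true_counts.to_csv(out / f"{tag}_true_counts.csv")
            fp.dot_truth.to_csv(out / f"{tag}_dot_truth.csv", index=False)
        (out / f"{tag}_meta.json").write_text(json.dumps(sidecar, indent=1))
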