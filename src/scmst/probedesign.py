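"""HCR-style probe construction and tiling for the multiplex panel.

Each probe targets the coding sequence of one mRNA: the reverse complement of
a binding site, joined via a short linker to an HCR initiator (B1..B5), for a
fixed 60-nt total. Up to 24 probes are tiled per gene, left to right along the
CDS; genes that admit fewer than 13 sites are flagged as under-covered.
Initiators multiplex genes within a hybridization round, so genes sharing a
round must carry distinct initiators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "ProbeConfig", "Probe", "ProbeSet",
    "construct_probe", "tile_gene", "assign_initiators",
    "DEFAULT_INITIATORS",
]


def _synthetic_initiator(name: str, length: int = 36) -> str:
    """Deterministic synthetic 36-nt initiator stand-in.

    The real B1..B5 amplifier sequences are proprietary to the HCR kits; these
    placeholders have the right length and composition so the geometry of the
    probe (binding site / linker / initiator split) is exercised faithfully.
    Supply validated sequences through ``ProbeConfig.initiators`` for real use.
    """
    rng = np.random.default_rng(sum(ord(c) * 257**i for i, c in enumerate(name)))
    return "".join(rng.choice(list("ACGT"), size=length))


#: Synthetic stand-ins for the five HCR initiators (see _synthetic_initiator).
DEFAULT_INITIATORS = {name: _synthetic_initiator(name)
                      for name in ("B1", "B2", "B3", "B4", "B5")}

_VALID = set("ACGT")


@dataclass
class ProbeConfig:
    """Probe geometry and tiling rules."""

    total_len: int = 60
    linker_len: int = 4
    linker_seq: str = "AAAA"
    initiators: dict = field(default_factory=lambda: dict(DEFAULT_INITIATORS))
    min_probes: int = 13
    max_probes: int = 24
    min_gap: int = 2  # nt between adjacent binding sites
    gc_bounds: tuple = (0.35, 0.70)
    strict: bool = False

    def binding_len(self, initiator: str) -> int:
        n = self.total_len - self.linker_len - len(self.initiators[initiator])
        if n <= 0:
            raise ValueError(
                "total_len must exceed linker + initiator length"
            )
        return n

    def validate(self) -> None:
        if self.min_probes > self.max_probes:
            raise ValueError("min_probes must not exceed max_probes")
        if len(self.linker_seq) != self.linker_len:
            raise ValueError("linker sequence length must equal linker_len")


@dataclass
class Probe:
    start: int  # 0-based site start on the CDS
    end: int  # exclusive
    binding_seq: str
    linker_seq: str
    initiator: str
    sequence: str  # full probe, 5'->3'


@dataclass
class ProbeSet:
    gene: str
    probes: list
    warnings: list


def _check_sequence(seq: str, what: str) -> str:
    if not seq:
        raise ValueError(f"{what} is empty")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def construct_probe(target_site: str, initiator: str,
                    config: ProbeConfig | None = None) -> str:
    """Build one probe: revcomp(binding site) + linker + initiator sequence.

    The binding site length is whatever the fixed total length leaves after
    the linker and the named initiator; the result is exactly ``total_len`` nt.
    """
    config = config or ProbeConfig()
    config.validate()
    site = _check_sequence(target_site, "target site")
    init_seq = _check_sequence(config.initiators[initiator], "initiator")
    expected = config.binding_len(initiator)
    if len(site) != expected:
        raise ValueError(
            f"target site must be {expected} nt for initiator {initiator}, "
            f"got {len(site)}"
        )
    return str(Seq(site).reverse_complement()) + config.linker_seq + init_seq


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def tile_gene(cds: str, initiator: str, config: ProbeConfig | None = None,
              gene: str = "") -> ProbeSet:
    """Greedy left-to-right tiling of non-overlapping binding sites.

    Sites must pass the GC bounds and sit at least ``min_gap`` nt apart;
    tiling stops at ``max_probes``. Fewer than ``min_probes`` accepted sites
    yields an under-coverage warning (or an error in strict mode).
    """
    config = config or ProbeConfig()
    config.validate()
    cds = _check_sequence(cds, "coding sequence")
    blen = config.binding_len(initiator)
    if len(cds) < blen:
        raise ValueError(
            f"coding sequence ({len(cds)} nt) shorter than one binding site ({blen} nt)"
        )
    lo, hi = config.gc_bounds
    probes: list[Probe] = []
    pos = 0
    while pos + blen <= len(cds) and len(probes) < config.max_probes:
        site = cds[pos: pos + blen]
        if lo <= _gc(site) <= hi:
            probes.append(Probe(
                start=pos, end=pos + blen, binding_seq=site,
                linker_seq=config.linker_seq, initiator=initiator,
                sequence=construct_probe(site, initiator, config),
            ))
            pos += blen + config.min_gap
        else:
            pos += 1
    warnings = []
    if len(probes) < config.min_probes:
        msg = (f"{gene or 'gene'}: only {len(probes)} probes found "
               f"(minimum {config.min_probes})")
        if config.strict:
            raise ValueError(msg)
        warnings.append(msg)
    return ProbeSet(gene=gene, probes=probes, warnings=warnings)


def assign_initiators(round_plan, initiators=None) -> dict:
    """Give every gene an initiator, distinct within each hybridization round.

    The same initiator recurs across rounds (signal is stripped between
    rounds), so five initiators suffice for any panel at five genes per round.
    """
    names = list(initiators) if initiators is not None else list(DEFAULT_INITIATORS)
    assignment = {}
    for r in range(round_plan.n_rounds):
        genes = sorted(round_plan.genes_in_round(r),
                       key=lambda g: round_plan.channel_of(g)[1])
        if len(genes) > len(names):
            raise ValueError(
                f"round {r} carries {len(genes)} genes but only "
                f"{len(names)} initiators are available"
            )
        for gene, init in zip(genes, names):
            assignment[gene] = init
    return assignment


def probe_table(probe_sets: list) -> "pandas.DataFrame":  # noqa: F821
    """Flat order-sheet style table of all probes."""
    import pandas as pd

    rows = []
    for ps in probe_sets:
        for i, p in enumerate(ps.probes, start=1):
            rows.append({
                "gene": ps.gene, "probe": f"{ps.gene}_{i:02d}",
                "start": p.start, "end": p.end, "initiator": p.initiator,
                "binding_seq": p.binding_seq, "sequence": p.sequence,
            })
    return pd.DataFrame(rows)
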