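"""The gene-dropping simulator.

Founders receive labelled whole-chromosome haplotype pairs; every
non-founder, visited in topological order, receives one recombinant
meiotic product from each parent. No alleles are carried — only crossover
breakpoints and founder-chromosome labels — which is what makes the method
fast in genealogies with hundreds of thousands of individuals.

Replicates are generated and flushed one at a time: nothing scales with
the number of replicates in memory. A fixed seed plus fixed inputs yields
byte-identical output files; the generator stream is consumed in a fixed
order (replicate, then topological order, then father-meiosis before
mother-meiosis, crossovers before the strand coin).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .genealogy import Genealogy, GenealogyError, Sex, prune_to_relevant
from .genetic_map import GeneticMap
from .haplotypes import Haplotype, UNTRACKED, founder_label
from .meiosis import MeiosisModel, recombine

__all__ = [
    "SimulationConfig",
    "Replicate",
    "initialize_founder",
    "drop_once",
    "simulate",
    "run_simulation",
    "PROBAND_FILE",
    "ALL_NODES_FILE",
]

PROBAND_FILE = "Proband_Haplotypes.txt"
ALL_NODES_FILE = "All_nodes_haplotypes.txt"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one simulation run needs besides the genealogy."""

    probands: tuple[int, ...]
    tracked_founders: tuple[int, ...] | None  # None = track every founder
    n_sim: int
    model: MeiosisModel
    bp_len: int
    map_male: GeneticMap = field(default_factory=GeneticMap.linear)
    map_female: GeneticMap = field(default_factory=GeneticMap.linear)
    seed: int = 0
    emit_all_nodes: bool = False

    def __post_init__(self):
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.bp_len < 2:
            raise ValueError("bp_len must be >= 2")
        if not self.probands:
            raise ValueError("proband list must be non-empty")


@dataclass(frozen=True)
class Replicate:
    """One replicate: 1-based index and per-individual (paternal, maternal)
    haplotype pairs (probands only, or every pruned individual)."""

    index: int
    haplotypes: dict[int, tuple[Haplotype, Haplotype]]

    def pair(self, i: int) -> tuple[Haplotype, Haplotype]:
        return self.haplotypes[i]


def initialize_founder(f: int, tracked: set[int] | frozenset[int], bp_len: int,
                       founders: frozenset[int] | None = None) -> tuple[Haplotype, Haplotype]:
    """Whole-chromosome haplotype pair for a founder: labels ``f.1``/``f.2``
    if tracked, else both ``"0"``."""
    if founders is not None and f not in founders:
        raise GenealogyError(f"id {f} is not a founder")
    if f in tracked:
        return (
            Haplotype.uniform(founder_label(f, 1), bp_len),
            Haplotype.uniform(founder_label(f, 2), bp_len),
        )
    return (Haplotype.uniform(UNTRACKED, bp_len), Haplotype.uniform(UNTRACKED, bp_len))


def _gamete(parent_pair: tuple[Haplotype, Haplotype], parent_sex: Sex,
            cfg: SimulationConfig, rng: np.random.Generator) -> Haplotype:
    L = cfg.model.length_for(parent_sex)
    gmap = cfg.map_male if parent_sex is Sex.MALE else cfg.map_female
    x_gen = cfg.model.crossovers(parent_sex, rng)
    x_bp = gmap.to_physical(x_gen, L, cfg.bp_len) if len(x_gen) else []
    start_with_a = bool(rng.random() < 0.5)
    return recombine(parent_pair[0], parent_pair[1], x_bp, start_with_a)


def drop_once(g: Genealogy, cfg: SimulationConfig, rng: np.random.Generator,
              tracked: set[int], index: int = 1) -> Replicate:
    """Run one gene-dropping replicate down an already-pruned genealogy."""
    haps: dict[int, tuple[Haplotype, Haplotype]] = {}
    for i in g.topo_order:
        ind = g.individuals[i]
        if ind.is_founder:
            haps[i] = initialize_founder(i, tracked, cfg.bp_len)
        else:
            pat = _gamete(haps[ind.father_id], Sex.MALE, cfg, rng)
            mat = _gamete(haps[ind.mother_id], Sex.FEMALE, cfg, rng)
            haps[i] = (pat, mat)
    if cfg.emit_all_nodes:
        kept = haps
    else:
        kept = {p: haps[p] for p in cfg.probands}
    return Replicate(index, kept)


def _prepare(g: Genealogy, cfg: SimulationConfig) -> tuple[Genealogy, set[int], SimulationConfig]:
    pruned, tracked = prune_to_relevant(g, cfg.probands, cfg.tracked_founders)
    total_cm_m = cfg.model.l_male * 100.0
    total_cm_f = cfg.model.l_female * 100.0
    cfg = replace(
        cfg,
        map_male=cfg.map_male.with_endpoints(total_cm_m, cfg.bp_len),
        map_female=cfg.map_female.with_endpoints(total_cm_f, cfg.bp_len),
    )
    return pruned, tracked, cfg


def simulate(g: Genealogy, cfg: SimulationConfig) -> Iterator[Replicate]:
    """Yield ``cfg.n_sim`` independent replicates, streamed one at a time."""
    pruned, tracked, cfg = _prepare(g, cfg)
    rng = np.random.default_rng(cfg.seed)
    for r in range(1, cfg.n_sim + 1):
        yield drop_once(pruned, cfg, rng, tracked, index=r)


def run_simulation(g: Genealogy, cfg: SimulationConfig, out_dir) -> dict[str, str]:
    """Run the full simulation and stream results to the two output files.

    Writes ``Proband_Haplotypes.txt`` always and ``All_nodes_haplotypes.txt``
    when ``cfg.emit_all_nodes``; returns the paths written.
    """
    from .simio import HaplotypeWriter  # local import to avoid a cycle

    os.makedirs(out_dir, exist_ok=True)
    proband_path = os.path.join(out_dir, PROBAND_FILE)
    all_path = os.path.join(out_dir, ALL_NODES_FILE)
    probands_sorted = sorted(set(cfg.probands))
    with HaplotypeWriter(proband_path, cfg.bp_len, cfg.model.kind) as pw:
        all_writer = (
            HaplotypeWriter(all_path, cfg.bp_len, cfg.model.kind)
            if cfg.emit_all_nodes else None
        )
        try:
            for rep in simulate(g, cfg):
                for i in probands_sorted:
                    pair = rep.haplotypes[i]
                    pw.write(rep.index, i, 1, pair[0])
                    pw.write(rep.index, i, 2, pair[1])
                if all_writer is not None:
                    for i in sorted(rep.haplotypes):
                        pair = rep.haplotypes[i]
                        all_writer.write(rep.index, i, 1, pair[0])
                        all_writer.write(rep.index, i, 2, pair[1])
        finally:
            if all_writer is not None:
                all_writer.close()
    out = {"proband": proband_path}
    if cfg.emit_all_nodes:
        out["all_nodes"] = all_path
    return out
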