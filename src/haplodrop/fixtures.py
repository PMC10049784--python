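"""Synthetic genealogies and founder genotypes for testing and demos.

``canonical_pedigrees`` returns small hand-built pedigrees covering the
structures the simulator must handle: an outbred trio, full and half
siblings, a three-meiosis chain, a first-cousin-mating loop with an inbred
child, and the loop extended by one generation so that autozygous founder
material in the inbred ancestor can descend further — the configuration in
which concatenated (multi-path) segments arise.

``generate_pedigree`` grows random multi-generation pedigrees with a
tunable consanguinity rate: each new couple's mother is, with that
probability, recruited from inside the existing pedigree (never a parent,
child, or sib of the father) instead of entering as a new founder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genealogy import Genealogy, GenealogyError, Sex, build_genealogy
from .haplotypes import founder_label

__all__ = [
    "PedigreeSpec",
    "canonical_pedigrees",
    "generate_pedigree",
    "generate_founder_genotypes",
]


def canonical_pedigrees() -> dict[str, Genealogy]:
    """Named fixture pedigrees (see module docstring)."""
    peds: dict[str, list[tuple[int, int, int, int]]] = {
        # founders 1 (m), 2 (f); child 3
        "trio": [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1)],
        # two full sibs 3, 4
        "sib_quartet": [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 1, 2, 2)],
        # shared father 1, mothers 2 and 3; half sibs 4, 5
        "half_sibs": [(1, 0, 0, 1), (2, 0, 0, 2), (3, 0, 0, 2),
                      (4, 1, 2, 1), (5, 1, 3, 2)],
        # three meioses from founder 1 down to 7; grandparent 4 contributes 1/4
        "chain": [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 0, 0, 2),
                  (5, 3, 4, 1), (6, 0, 0, 2), (7, 5, 6, 1)],
        # sibs 3, 4 marry out; their children 7, 8 (first cousins) marry;
        # 9 is inbred with two descent paths from founder 1 (via 3 and via 4)
        "cousin_loop": [
            (1, 0, 0, 1), (2, 0, 0, 2),
            (3, 1, 2, 1), (4, 1, 2, 2),
            (5, 0, 0, 2), (6, 0, 0, 1),
            (7, 3, 5, 1), (8, 6, 4, 2),
            (9, 7, 8, 1),
        ],
        # cousin loop extended one generation: autozygous material in 9 can
        # pass to 11 as a single concatenated segment
        "loop_concat": [
            (1, 0, 0, 1), (2, 0, 0, 2),
            (3, 1, 2, 1), (4, 1, 2, 2),
            (5, 0, 0, 2), (6, 0, 0, 1),
            (7, 3, 5, 1), (8, 6, 4, 2),
            (9, 7, 8, 1), (10, 0, 0, 2),
            (11, 9, 10, 1),
        ],
    }
    return {name: build_genealogy(rows) for name, rows in peds.items()}


@dataclass(frozen=True)
class PedigreeSpec:
    """Parameters for random pedigree growth.

    consanguinity_rate is the probability that a couple's mother is drawn
    from within the pedigree rather than entering as a new founder.
    """

    generations: int
    couples_per_generation: int
    offspring_mean: float = 2.5
    consanguinity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1 or self.couples_per_generation < 1:
            raise ValueError("generations and couples_per_generation must be >= 1")
        if self.offspring_mean <= 0:
            raise ValueError("offspring_mean must be > 0")
        if not 0.0 <= self.consanguinity_rate <= 1.0:
            raise ValueError("consanguinity_rate must be in [0, 1]")


def generate_pedigree(spec: PedigreeSpec) -> Genealogy:
    """Grow a random pedigree generation by generation (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[int, int, int, int]] = []
    parents_of: dict[int, tuple[int, int]] = {}
    next_id = 1

    def new_individual(father: int, mother: int, sex: int) -> int:
        nonlocal next_id
        i = next_id
        next_id += 1
        rows.append((i, father, mother, sex))
        if father:
            parents_of[i] = (father, mother)
        return i

    def are_close_kin(male: int, female: int) -> bool:
        pm = parents_of.get(male)
        pf = parents_of.get(female)
        if pm and female in pm:  # she is his mother
            return True
        if pf and male in pf:  # he is her father
            return True
        if pm and pf and set(pm) & set(pf):  # full or half sibs
            return True
        return False

    born_females: list[int] = []  # pedigree-born (non-founder) females
    current_males: list[int] = []

    for gen in range(spec.generations):
        couples: list[tuple[int, int]] = []
        for _ in range(spec.couples_per_generation):
            if current_males:
                father = current_males.pop(0)
            else:
                father = new_individual(0, 0, 1)
            mother = None
            if spec.consanguinity_rate > 0 and rng.random() < spec.consanguinity_rate:
                eligible = [f for f in born_females if not are_close_kin(father, f)]
                if eligible:
                    mother = int(rng.choice(eligible))
                elif spec.consanguinity_rate >= 1.0 and gen > 0:
                    raise GenealogyError("infeasible spec: no eligible in-pedigree mates")
            if mother is None:
                mother = new_individual(0, 0, 2)
            couples.append((father, mother))
        next_males: list[int] = []
        for father, mother in couples:
            n_children = int(rng.poisson(spec.offspring_mean))
            for _ in range(n_children):
                sex = 1 if rng.random() < 0.5 else 2
                child = new_individual(father, mother, sex)
                if sex == 1:
                    next_males.append(child)
                else:
                    born_females.append(child)
        current_males = next_males

    return build_genealogy(rows)


def generate_founder_genotypes(g: Genealogy, markers: int, bp_len: int,
                               seed: int = 0) -> pd.DataFrame:
    """Haploid founder genotypes with a unique allele per chromosome at
    every marker (so identity-by-state implies identity-by-descent).

    Marker positions are uniform on [0, bp_len), distinct and sorted.
    Alleles are the strings "1".."2F" (the missing code "0" is reserved).
    """
    if markers < 1:
        raise ValueError("need at least one marker")
    if markers > bp_len:
        raise ValueError("more markers than bp positions")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(bp_len, size=markers, replace=False))
    labels = [founder_label(f, s) for f in sorted(g.founders) for s in (1, 2)]
    table = {"bp": positions}
    for j, lab in enumerate(labels):
        table[lab] = np.full(markers, str(j + 1), dtype=object)
    return pd.DataFrame(table)
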