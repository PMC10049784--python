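"""Pedigree graphs: parsing, validation, kinship and descent-path queries.

A genealogy is a two-parents-or-none pedigree: every individual either has
both parents recorded in the table or is a founder (both parent fields 0).
Founders are assumed mutually unrelated and non-inbred, so the recursive
kinship coefficient and the path-counting (Wright) formula agree exactly;
both are provided so either can serve as an independent check of the other.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenealogyError",
    "Sex",
    "Individual",
    "Genealogy",
    "build_genealogy",
    "read_pedigree",
    "write_pedigree",
    "prune_to_relevant",
    "kinship",
    "kinship_path_formula",
    "inbreeding",
    "genetic_contribution",
    "enumerate_paths",
]


class GenealogyError(ValueError):
    """Raised when a pedigree violates the two-parents-or-none model."""


class Sex(Enum):
    MALE = 1
    FEMALE = 2

    @classmethod
    def parse(cls, value) -> "Sex":
        if isinstance(value, Sex):
            return value
        s = str(value).strip().lower()
        if s in {"1", "m", "male"}:
            return cls.MALE
        if s in {"2", "f", "female"}:
            return cls.FEMALE
        raise GenealogyError(f"unrecognized sex code: {value!r} (use 1/M/male or 2/F/female)")


@dataclass(frozen=True)
class Individual:
    """One pedigree row: id, father id, mother id (0 = unknown), sex."""

    id: int
    father_id: int
    mother_id: int
    sex: Sex

    @property
    def is_founder(self) -> bool:
        return self.father_id == 0


class Genealogy:
    """Validated pedigree with topological order and parent/child indexes.

    Construct with :func:`build_genealogy`; the constructor assumes already
    validated inputs.
    """

    def __init__(
        self,
        individuals: dict[int, Individual],
        topo_order: list[int],
        probands: frozenset[int],
    ):
        self.individuals = individuals
        self.topo_order = topo_order
        self.founders = frozenset(i for i, ind in individuals.items() if ind.is_founder)
        self.probands = probands
        self.children: dict[int, list[int]] = {i: [] for i in individuals}
        for ind in individuals.values():
            if not ind.is_founder:
                self.children[ind.father_id].append(ind.id)
                self.children[ind.mother_id].append(ind.id)
        for kids in self.children.values():
            kids.sort()
        self._topo_index = {i: k for k, i in enumerate(topo_order)}
        self._kinship_memo: dict[tuple[int, int], float] = {}

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, i: int) -> bool:
        return i in self.individuals

    def _require(self, *ids: int) -> None:
        for i in ids:
            if i not in self.individuals:
                raise GenealogyError(f"unknown individual id: {i}")

    # ------------------------------------------------------------------
    # kinship / contribution / paths
    # ------------------------------------------------------------------

    def kinship(self, a: int, b: int) -> float:
        """Recursive kinship coefficient phi(a, b).

        phi(f, f) = 1/2 for a founder f; phi(f, g) = 0 for distinct
        founders; otherwise the standard recursion on the later individual's
        parents.
        """
        self._require(a, b)
        return self._phi(a, b)

    def _phi(self, a: int, b: int) -> float:
        key = (a, b) if a <= b else (b, a)
        memo = self._kinship_memo
        if key in memo:
            return memo[key]
        if a == b:
            ind = self.individuals[a]
            val = 0.5 if ind.is_founder else 0.5 * (1.0 + self._phi(ind.father_id, ind.mother_id))
        else:
            # recurse on the individual later in topological order: the
            # other cannot be its descendant
            if self._topo_index[a] < self._topo_index[b]:
                a, b = b, a
            ind = self.individuals[a]
            if ind.is_founder:
                val = 0.0
            else:
                val = 0.5 * (self._phi(ind.father_id, b) + self._phi(ind.mother_id, b))
        memo[key] = val
        return val

    def inbreeding(self, i: int) -> float:
        """Inbreeding coefficient F = kinship of the parents (0 for founders)."""
        self._require(i)
        ind = self.individuals[i]
        if ind.is_founder:
            return 0.0
        return self._phi(ind.father_id, ind.mother_id)

    def genetic_contribution(self, proband: int, founder: int) -> float:
        """Expected fraction of `proband`'s diploid genome from `founder`.

        Equals sum over all distinct descent paths founder -> proband of
        (1/2)^(meioses on the path).
        """
        self._require(proband, founder)
        if founder not in self.founders:
            raise GenealogyError(f"id {founder} is not a founder")
        contrib: dict[int, float] = {founder: 1.0}
        for i in self.topo_order:
            ind = self.individuals[i]
            if ind.is_founder:
                continue
            c = 0.5 * contrib.get(ind.father_id, 0.0) + 0.5 * contrib.get(ind.mother_id, 0.0)
            if c:
                contrib[i] = c
        if proband == founder:
            return 1.0
        return contrib.get(proband, 0.0)

    def enumerate_paths(self, ancestor: int, descendant: int) -> list[tuple[int, ...]]:
        """All distinct directed parent->child paths from ancestor to descendant."""
        self._require(ancestor, descendant)
        if ancestor == descendant:
            return [(ancestor,)]
        paths: list[tuple[int, ...]] = []
        stack: list[int] = [ancestor]

        def dfs(node: int) -> None:
            if node == descendant:
                paths.append(tuple(stack))
                return
            for child in self.children[node]:
                stack.append(child)
                dfs(child)
                stack.pop()

        dfs(ancestor)
        return paths

    def ancestors_of(self, ids: Iterable[int]) -> set[int]:
        """Closure of `ids` under the parent relation (includes `ids`)."""
        out: set[int] = set()
        todo = list(ids)
        while todo:
            i = todo.pop()
            if i in out:
                continue
            out.add(i)
            ind = self.individuals[i]
            if not ind.is_founder:
                todo.append(ind.father_id)
                todo.append(ind.mother_id)
        return out

    def prune_to_relevant(self, probands: Iterable[int]) -> "Genealogy":
        """Sub-genealogy of the probands and all of their ancestors.

        Individuals with no proband descendant are dropped. The result's
        proband set is the given one.
        """
        probands = set(probands)
        if not probands:
            raise GenealogyError("empty proband set")
        self._require(*probands)
        keep = self.ancestors_of(probands)
        individuals = {i: self.individuals[i] for i in keep}
        topo = [i for i in self.topo_order if i in keep]
        return Genealogy(individuals, topo, frozenset(probands))


def build_genealogy(
    rows: Sequence[tuple],
    probands: Iterable[int] | None = None,
) -> Genealogy:
    """Validate pedigree rows (id, father_id, mother_id, sex) into a Genealogy.

    Raises :class:`GenealogyError` on duplicate ids, dangling parent
    references, parent-sex mismatches, cycles, or rows with exactly one
    known parent. Probands default to the childless individuals.
    """
    if len(rows) == 0:
        raise GenealogyError("empty pedigree")
    individuals: dict[int, Individual] = {}
    for row in rows:
        i, fa, mo, sex = int(row[0]), int(row[1]), int(row[2]), Sex.parse(row[3])
        if i <= 0:
            raise GenealogyError(f"individual id must be positive, got {i}")
        if i in individuals:
            raise GenealogyError(f"duplicate individual id: {i}")
        if fa < 0 or mo < 0:
            raise GenealogyError(f"negative parent id for individual {i}")
        if (fa == 0) != (mo == 0):
            raise GenealogyError(
                f"individual {i} has exactly one known parent; "
                "the model requires both parents or neither"
            )
        individuals[i] = Individual(i, fa, mo, sex)

    has_child: set[int] = set()
    for ind in individuals.values():
        if ind.is_founder:
            continue
        for pid, want in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
            parent = individuals.get(pid)
            if parent is None:
                raise GenealogyError(
                    f"individual {ind.id} references parent {pid} absent from the pedigree"
                )
            if parent.sex is not want:
                role = "father" if want is Sex.MALE else "mother"
                raise GenealogyError(f"{role} {pid} of individual {ind.id} has wrong sex")
            has_child.add(pid)
        if ind.father_id == ind.id or ind.mother_id == ind.id:
            raise GenealogyError(f"individual {ind.id} is its own parent")

    # Kahn topological sort, ties broken by ascending id for reproducibility
    indeg = {i: (0 if ind.is_founder else 2) for i, ind in individuals.items()}
    ready = [i for i, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    topo: list[int] = []
    children: dict[int, list[int]] = {i: [] for i in individuals}
    for ind in individuals.values():
        if not ind.is_founder:
            children[ind.father_id].append(ind.id)
            children[ind.mother_id].append(ind.id)
    while ready:
        i = heapq.heappop(ready)
        topo.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(topo) != len(individuals):
        cyclic = sorted(set(individuals) - set(topo))
        raise GenealogyError(f"pedigree contains a cycle involving ids {cyclic}")

    if probands is None:
        proband_set = frozenset(i for i in individuals if i not in has_child)
    else:
        proband_set = frozenset(int(p) for p in probands)
        for p in proband_set:
            if p not in individuals:
                raise GenealogyError(f"proband {p} not in pedigree")
    return Genealogy(individuals, topo, proband_set)


def read_pedigree(path, probands: Iterable[int] | None = None) -> Genealogy:
    """Read a delimited pedigree file (ind, father, mother, sex; 0 = unknown).

    Comma, tab or whitespace delimited; a header line is detected and
    skipped. Sex codes 1/2 or M/F.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise GenealogyError(f"pedigree file needs 4 columns (ind father mother sex), got {df.shape[1]}")
    first = str(df.iloc[0, 0]).strip()
    if not first.lstrip("-").isdigit():
        df = df.iloc[1:]
    if len(df) == 0:
        raise GenealogyError("empty pedigree")
    rows = [
        (int(r.iloc[0]), int(r.iloc[1]), int(r.iloc[2]), r.iloc[3])
        for _, r in df.iterrows()
    ]
    return build_genealogy(rows, probands=probands)


def write_pedigree(g: Genealogy, path) -> None:
    """Write a genealogy as a 4-column TSV with a header line."""
    with open(path, "w", newline="\n") as fh:
        fh.write("ind\tfather\tmother\tsex\n")
        for i in sorted(g.individuals):
            ind = g.individuals[i]
            fh.write(f"{ind.id}\t{ind.father_id}\t{ind.mother_id}\t{ind.sex.value}\n")


# ----------------------------------------------------------------------
# module-level functional aliases
# ----------------------------------------------------------------------

def prune_to_relevant(g: Genealogy, probands: Iterable[int], founders: Iterable[int] | None = None):
    """Prune to ancestors of `probands`; return (genealogy, retained tracked founders)."""
    pruned = g.prune_to_relevant(probands)
    if founders is None:
        tracked = set(pruned.founders)
    else:
        founders = set(founders)
        for f in founders:
            if f not in g:
                raise GenealogyError(f"unknown founder id: {f}")
            if f not in g.founders:
                raise GenealogyError(f"id {f} is not a founder")
        tracked = founders & pruned.founders
    return pruned, tracked


def kinship(g: Genealogy, a: int, b: int) -> float:
    return g.kinship(a, b)


def inbreeding(g: Genealogy, i: int) -> float:
    return g.inbreeding(i)


def genetic_contribution(g: Genealogy, proband: int, founder: int) -> float:
    return g.genetic_contribution(proband, founder)


def enumerate_paths(g: Genealogy, ancestor: int, descendant: int) -> list[tuple[int, ...]]:
    return g.enumerate_paths(ancestor, descendant)


def kinship_path_formula(g: Genealogy, a: int, b: int) -> float:
    """Wright's path-counting kinship: sum over common ancestors A and pairs
    of node-disjoint paths A->a, A->b of (1/2)^(n1+n2+1) * (1 + F_A).

    Independent of the recursion in :meth:`Genealogy.kinship`; used as a
    cross-check. Only defined for a != b.
    """
    if a == b:
        raise GenealogyError("path formula defined for distinct individuals")
    g._require(a, b)
    anc_a = g.ancestors_of([a])
    anc_b = g.ancestors_of([b])
    total = 0.0
    for anc in anc_a & anc_b:
        f_anc = g.inbreeding(anc)
        for p1 in g.enumerate_paths(anc, a):
            s1 = set(p1)
            for p2 in g.enumerate_paths(anc, b):
                if s1.intersection(p2) == {anc}:
                    n = (len(p1) - 1) + (len(p2) - 1)
                    total += 0.5 ** (n + 1) * (1.0 + f_anc)
    return total
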