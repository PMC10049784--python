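"""Post-simulation analyses: traceback, pairwise IBD, genotype conversion.

``traceback`` walks each founder-labelled proband segment back up the
genealogy using the all-node haplotype records. In a region where an
internal ancestor is autozygous for the founder chromosome, the descent
route is resolved minimally: a single route is reported whenever one of
the ancestor's chromosomes alone covers the traced material (ties resolved
to the paternal chromosome), and the segment is split across both routes —
a "concatenation" — only when neither chromosome alone explains it.

``compare_ibd`` reports, per replicate, the mean over the four ordered
haplotype pairs of the fraction of the chromosome with matching non-zero
labels (expectation = the kinship coefficient), plus the union fraction
(bp where at least one pair is IBD).

``convert_genotypes`` projects proband haplotypes onto user-supplied
haploid founder genotypes, yielding phased marker data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import Replicate
from .genealogy import Genealogy, GenealogyError
from .haplotypes import Haplotype, UNTRACKED, founder_label

__all__ = [
    "TransmissionPath",
    "TracedSegment",
    "IBDComparison",
    "traceback",
    "compare_ibd",
    "convert_genotypes",
    "read_founder_genotypes",
    "write_founder_genotypes",
]

Interval = tuple[int, int]


# ----------------------------------------------------------------------
# interval set arithmetic (half-open, sorted, disjoint)
# ----------------------------------------------------------------------

def _intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    j = 0
    for lo, hi in a:
        cur = lo
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < hi:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < hi:
            out.append((cur, hi))
    return out


def _total(a: list[Interval]) -> int:
    return sum(hi - lo for lo, hi in a)


# ----------------------------------------------------------------------
# traceback
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TransmissionPath:
    """Founder-to-proband descent chain (consecutive ids are parent/child)."""

    ids: tuple[int, ...]

    @property
    def meioses(self) -> int:
        return len(self.ids) - 1


@dataclass(frozen=True)
class TracedSegment:
    """A proband segment with the descent path(s) that delivered it."""

    sim: int
    start: int
    end: int
    label: str
    paths: tuple[TransmissionPath, ...]
    concatenated: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def _trace_up(g: Genealogy, rep: Replicate, ind_id: int, intervals: list[Interval],
              label: str) -> list[tuple[int, ...]]:
    ind = g.individuals[ind_id]
    if ind.is_founder:
        if not label.startswith(f"{ind_id}."):
            raise GenealogyError(
                f"label {label} traced into unrelated founder {ind_id}"
            )
        return [(ind_id,)]
    hap_pat, hap_mat = rep.haplotypes[ind_id]
    cov1 = _intersect(intervals, hap_pat.intervals_with_label(label))
    cov2 = _intersect(intervals, hap_mat.intervals_with_label(label))
    if _total(cov1) == _total(intervals):
        return [p + (ind_id,) for p in _trace_up(g, rep, ind.father_id, intervals, label)]
    if _total(cov2) == _total(intervals):
        return [p + (ind_id,) for p in _trace_up(g, rep, ind.mother_id, intervals, label)]
    rest = _subtract(intervals, cov1)
    if _total(cov1) + _total(rest) != _total(intervals) or _total(_intersect(rest, cov2)) != _total(rest):
        raise GenealogyError(
            f"replicate {rep.index}: material with label {label} not present in "
            f"individual {ind_id}'s haplotypes — all-node records inconsistent"
        )
    paths = [p + (ind_id,) for p in _trace_up(g, rep, ind.father_id, cov1, label)]
    paths += [p + (ind_id,) for p in _trace_up(g, rep, ind.mother_id, rest, label)]
    return paths


def traceback(replicates: Iterable[Replicate], g: Genealogy, proband: int,
              founder: int) -> list[list[TracedSegment]]:
    """Trace every founder-labelled proband segment up to the founder.

    Requires all-node replicates (every individual on the descent paths
    present). Returns one list of :class:`TracedSegment` per replicate.
    """
    g._require(proband, founder)
    if founder not in g.founders:
        raise GenealogyError(f"id {founder} is not a founder")
    wanted = (founder_label(founder, 1), founder_label(founder, 2))
    out: list[list[TracedSegment]] = []
    for rep in replicates:
        if proband not in rep.haplotypes:
            raise GenealogyError(f"proband {proband} absent from replicate {rep.index}")
        traced: list[TracedSegment] = []
        pair = rep.haplotypes[proband]
        pro = g.individuals[proband]
        for slot, hap in ((1, pair[0]), (2, pair[1])):
            if pro.is_founder:
                continue  # a founder proband's own chromosomes have no descent path
            parent = pro.father_id if slot == 1 else pro.mother_id
            if parent not in rep.haplotypes:
                raise GenealogyError(
                    "traceback requires all-node records (run with emit_all_nodes)"
                )
            for seg in hap.segments:
                if seg.label not in wanted:
                    continue
                raw = _trace_up(g, rep, parent, [(seg.start, seg.end)], seg.label)
                uniq = sorted(set(p + (proband,) for p in raw))
                traced.append(TracedSegment(
                    sim=rep.index,
                    start=seg.start,
                    end=seg.end,
                    label=seg.label,
                    paths=tuple(TransmissionPath(p) for p in uniq),
                    concatenated=len(uniq) > 1,
                ))
        out.append(traced)
    return out


# ----------------------------------------------------------------------
# pairwise IBD
# ----------------------------------------------------------------------

@dataclass
class IBDComparison:
    """Per-replicate IBD sharing between two probands.

    ``mean_pairwise`` averages the IBD bp-fraction over the four ordered
    haplotype pairs; its expectation equals the kinship coefficient.
    ``union`` is the fraction of bp where at least one pair is IBD.
    ``lower_bound`` flags runs with untracked material, where both
    fractions understate true sharing.
    """

    pair: tuple[int, int]
    mean_pairwise: np.ndarray
    union: np.ndarray
    lower_bound: bool

    @property
    def mean(self) -> float:
        return float(self.mean_pairwise.mean())

    @property
    def sd(self) -> float:
        return float(self.mean_pairwise.std(ddof=1)) if len(self.mean_pairwise) > 1 else 0.0


def compare_ibd(replicates: Iterable[Replicate], a: int, b: int) -> IBDComparison:
    """Diploid IBD sharing between probands ``a`` and ``b`` per replicate."""
    mp: list[float] = []
    un: list[float] = []
    saw_untracked = False
    for rep in replicates:
        for p in (a, b):
            if p not in rep.haplotypes:
                raise GenealogyError(f"individual {p} is not recorded in replicate {rep.index}")
        a1, a2 = rep.haplotypes[a]
        b1, b2 = rep.haplotypes[b]
        bp_len = a1.bp_len
        cuts = sorted({0, *a1.starts, *a2.starts, *b1.starts, *b2.starts, bp_len})
        match_bp = 0
        union_bp = 0
        for lo, hi in zip(cuts, cuts[1:]):
            la = (a1.label_at(lo), a2.label_at(lo))
            lb = (b1.label_at(lo), b2.label_at(lo))
            if UNTRACKED in la or UNTRACKED in lb:
                saw_untracked = True
            w = hi - lo
            n = sum(1 for x in la for y in lb if x == y and x != UNTRACKED)
            match_bp += n * w
            if n:
                union_bp += w
        mp.append(match_bp / (4.0 * bp_len))
        un.append(union_bp / bp_len)
    return IBDComparison((a, b), np.asarray(mp), np.asarray(un), saw_untracked)


# ----------------------------------------------------------------------
# genotype conversion
# ----------------------------------------------------------------------

def read_founder_genotypes(path) -> pd.DataFrame:
    """Founder haploid genotype table: TSV with column ``bp`` then one
    column per founder-chromosome label (``<id>.1``, ``<id>.2``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "bp" not in df.columns:
        raise ValueError("founder genotype table must have a 'bp' column")
    df["bp"] = df["bp"].astype(np.int64)
    return df.sort_values("bp").reset_index(drop=True)


def write_founder_genotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def convert_genotypes(
    replicates: Iterable[Replicate],
    founder_table: pd.DataFrame,
    probands: Sequence[int] | None = None,
    markers: Sequence[int] | None = None,
    missing: str = "0",
) -> pd.DataFrame:
    """Project simulated proband haplotypes onto haploid founder genotypes.

    ``founder_table`` holds marker bp positions (column ``bp``) and one
    allele column per founder-chromosome label; ``markers`` optionally
    restricts to a subset of those positions. Untracked (label "0")
    material emits the missing code. Returns a long DataFrame with columns
    ``sim, proband, bp, allele_pat, allele_mat`` (phase preserved).
    """
    positions = founder_table["bp"].to_numpy(np.int64)
    if markers is not None:
        sel = np.isin(positions, np.asarray(markers, dtype=np.int64))
        if sel.sum() != len(set(markers)):
            raise ValueError("requested markers absent from the founder table")
        founder_table = founder_table.loc[sel].reset_index(drop=True)
        positions = founder_table["bp"].to_numpy(np.int64)
    columns = {str(c): founder_table[c].to_numpy(dtype=object) for c in founder_table.columns
               if c != "bp"}

    def alleles_for(hap: Haplotype) -> np.ndarray:
        if positions.size and (positions[0] < 0 or positions[-1] >= hap.bp_len):
            raise ValueError("marker position outside the simulated chromosome")
        idx = np.searchsorted(np.asarray(hap.starts), positions, side="right") - 1
        labels = np.asarray(hap.labels, dtype=object)[idx]
        out = np.empty(positions.size, dtype=object)
        for lab in np.unique(labels):
            mask = labels == lab
            if lab == UNTRACKED:
                out[mask] = missing
            else:
                if lab not in columns:
                    raise ValueError(f"founder chromosome {lab} missing from the genotype table")
                out[mask] = columns[lab][mask]
        return out

    frames: list[pd.DataFrame] = []
    for rep in replicates:
        ids = probands if probands is not None else sorted(rep.haplotypes)
        for p in ids:
            pat, mat = rep.haplotypes[p]
            frames.append(pd.DataFrame({
                "sim": rep.index,
                "proband": p,
                "bp": positions,
                "allele_pat": alleles_for(pat),
                "allele_mat": alleles_for(mat),
            }))
    if not frames:
        return pd.DataFrame(columns=["sim", "proband", "bp", "allele_pat", "allele_mat"])
    return pd.concat(frames, ignore_index=True)
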