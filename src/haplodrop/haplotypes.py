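"""Labelled haplotype mosaics.

A haplotype is an ordered tiling of the simulated chromosome [0, bp_len)
by segments, each carrying a founder-chromosome label: ``"<founder_id>.1"``
or ``"<founder_id>.2"``, or ``"0"`` for material of untracked origin.
Adjacent segments with equal labels are always merged, so the breakpoint
list is canonical.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, NamedTuple

__all__ = ["Segment", "Haplotype", "UNTRACKED", "founder_label"]

UNTRACKED = "0"


def founder_label(founder_id: int, slot: int) -> str:
    """Label of a founder chromosome: slot 1 = paternal, slot 2 = maternal."""
    if slot not in (1, 2):
        raise ValueError("slot must be 1 or 2")
    return f"{founder_id}.{slot}"


class Segment(NamedTuple):
    start: int  # bp, 0-based inclusive
    end: int    # bp, exclusive
    label: str


@dataclass(frozen=True)
class Haplotype:
    """Segment i spans [starts[i], starts[i+1]) (last end = bp_len)."""

    starts: tuple[int, ...]
    labels: tuple[str, ...]
    bp_len: int

    def __post_init__(self):
        if self.bp_len < 1:
            raise ValueError("bp_len must be positive")
        if len(self.starts) != len(self.labels) or not self.starts:
            raise ValueError("starts and labels must be equal-length and non-empty")
        if self.starts[0] != 0:
            raise ValueError("first segment must start at 0")
        for i in range(1, len(self.starts)):
            if self.starts[i] <= self.starts[i - 1]:
                raise ValueError("segment starts must be strictly increasing")
            if self.labels[i] == self.labels[i - 1]:
                raise ValueError("adjacent segments with equal labels must be merged")
        if self.starts[-1] >= self.bp_len:
            raise ValueError("segment start beyond chromosome end")

    @classmethod
    def uniform(cls, label: str, bp_len: int) -> "Haplotype":
        return cls((0,), (label,), bp_len)

    @classmethod
    def from_segments(cls, segments: Iterable[Segment | tuple], bp_len: int) -> "Haplotype":
        """Build from (start, end, label) triples tiling [0, bp_len); merges
        adjacent equal labels."""
        starts: list[int] = []
        labels: list[str] = []
        expected = 0
        for start, end, label in segments:
            if start != expected:
                raise ValueError(f"segments do not tile: gap/overlap at {start} (expected {expected})")
            if end <= start:
                raise ValueError("empty segment")
            if labels and labels[-1] == label:
                pass  # merge
            else:
                starts.append(start)
                labels.append(label)
            expected = end
        if expected != bp_len:
            raise ValueError(f"segments end at {expected}, expected bp_len={bp_len}")
        return cls(tuple(starts), tuple(labels), bp_len)

    @property
    def segments(self) -> list[Segment]:
        ends = list(self.starts[1:]) + [self.bp_len]
        return [Segment(s, e, l) for s, e, l in zip(self.starts, ends, self.labels)]

    def label_at(self, pos: int) -> str:
        if not 0 <= pos < self.bp_len:
            raise ValueError(f"position {pos} outside [0, {self.bp_len})")
        return self.labels[bisect_right(self.starts, pos) - 1]

    def intervals_with_label(self, label: str) -> list[tuple[int, int]]:
        return [(s.start, s.end) for s in self.segments if s.label == label]

    def intervals_with_founder(self, founder_id: int) -> list[tuple[int, int]]:
        """Intervals carrying either chromosome of the founder (merged)."""
        prefix = f"{founder_id}."
        out: list[tuple[int, int]] = []
        for s in self.segments:
            if s.label.startswith(prefix):
                if out and out[-1][1] == s.start:
                    out[-1] = (out[-1][0], s.end)
                else:
                    out.append((s.start, s.end))
        return out

    def labelled_fraction(self) -> float:
        """Fraction of the chromosome with tracked (non-"0") origin."""
        return sum(s.end - s.start for s in self.segments if s.label != UNTRACKED) / self.bp_len

    def founder_fraction(self, founder_id: int) -> float:
        return sum(e - s for s, e in self.intervals_with_founder(founder_id)) / self.bp_len
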