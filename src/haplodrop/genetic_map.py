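"""Genetic (Morgan) to physical (bp) conversion of crossover locations.

Without a user map the relation is linear over the chromosome. With a map,
conversion is piecewise-linear interpolation between (cM, bp) anchors that
must span [0, total cM] <-> [0, bp_len]. Converted positions are rounded
half-away-from-zero to integer bp, clamped to [1, bp_len - 1], and pairs of
crossovers that collide on the same bp annihilate (an even count at one bp
leaves no breakpoint, an odd count leaves one) — the parity semantics of
recombination at coarse physical resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "MapError", "load_map", "to_physical"]

logger = logging.getLogger(__name__)


class MapError(ValueError):
    """Raised for non-monotone or non-spanning genetic maps."""


@dataclass(frozen=True)
class GeneticMap:
    """Anchor table cM <-> bp, or the implicit linear map (no anchors)."""

    cm: tuple[float, ...] = ()
    bp: tuple[int, ...] = ()
    implicit_linear: bool = True

    def __post_init__(self):
        if self.implicit_linear:
            if self.cm or self.bp:
                raise MapError("implicit linear map takes no anchors")
            return
        if len(self.cm) != len(self.bp) or len(self.cm) < 2:
            raise MapError("anchored map needs >= 2 (cM, bp) pairs of equal length")
        if any(b - a <= 0 for a, b in zip(self.cm, self.cm[1:])):
            raise MapError("cM anchors must be strictly increasing")
        if any(b - a <= 0 for a, b in zip(self.bp, self.bp[1:])):
            raise MapError("bp anchors must be strictly increasing")

    @classmethod
    def linear(cls) -> "GeneticMap":
        return cls()

    @classmethod
    def from_anchors(cls, cm: Sequence[float], bp: Sequence[int]) -> "GeneticMap":
        return cls(tuple(float(c) for c in cm), tuple(int(b) for b in bp), implicit_linear=False)

    def with_endpoints(self, total_cm: float, bp_len: int) -> "GeneticMap":
        """Return a copy whose anchors span exactly (0,0)..(total_cm, bp_len),
        synthesizing missing endpoint anchors with a logged warning."""
        if self.implicit_linear:
            return self
        cm, bp = list(self.cm), list(self.bp)
        if cm[0] != 0.0 or bp[0] != 0:
            if cm[0] < 0 or bp[0] < 0:
                raise MapError("anchors must be non-negative")
            logger.warning("map missing origin anchor; synthesizing (0 cM, 0 bp)")
            cm.insert(0, 0.0)
            bp.insert(0, 0)
        if not np.isclose(cm[-1], total_cm) or bp[-1] != bp_len:
            if cm[-1] > total_cm + 1e-9 or bp[-1] > bp_len:
                raise MapError(
                    f"map anchors extend beyond the simulated lengths "
                    f"({cm[-1]} cM/{bp[-1]} bp vs {total_cm} cM/{bp_len} bp)"
                )
            logger.warning(
                "map missing terminal anchor; synthesizing (%s cM, %s bp)", total_cm, bp_len
            )
            cm.append(float(total_cm))
            bp.append(int(bp_len))
        return GeneticMap.from_anchors(cm, bp)

    def _check_span(self, total_cm: float, bp_len: int) -> None:
        if self.implicit_linear:
            return
        if self.cm[0] != 0.0 or self.bp[0] != 0:
            raise MapError("map must start at (0 cM, 0 bp); use with_endpoints() to complete it")
        if not np.isclose(self.cm[-1], total_cm) or self.bp[-1] != bp_len:
            raise MapError(
                f"map spans ({self.cm[-1]} cM, {self.bp[-1]} bp) but the simulation "
                f"requires ({total_cm} cM, {bp_len} bp)"
            )

    def to_physical(self, positions_morgans: Sequence[float], L: float, bp_len: int) -> list[int]:
        """Convert genetic positions (Morgans, inside (0, L)) to breakpoint bp."""
        pos = np.asarray(positions_morgans, dtype=float)
        if pos.size == 0:
            return []
        if L <= 0:
            raise MapError("genetic length must be > 0 when crossovers exist")
        if np.any(pos <= 0) or np.any(pos >= L):
            raise MapError(f"crossover positions must lie strictly inside (0, {L})")
        self._check_span(L * 100.0, bp_len)
        if self.implicit_linear:
            raw = pos / L * bp_len
        else:
            raw = np.interp(pos * 100.0, self.cm, self.bp)
        ibp = np.floor(raw + 0.5).astype(np.int64)  # round half away from zero (all positive)
        ibp = np.clip(ibp, 1, bp_len - 1)
        vals, counts = np.unique(ibp, return_counts=True)
        return [int(v) for v, c in zip(vals, counts) if c % 2 == 1]


def to_physical(gmap: GeneticMap, positions_morgans, L: float, bp_len: int) -> list[int]:
    return gmap.to_physical(positions_morgans, L, bp_len)


def load_map(path):
    """Load a map file: TSV/CSV with header ``cM,bp`` or ``sex,cM,bp``.

    Returns a single shared :class:`GeneticMap`, or a dict
    ``{"male": ..., "female": ...}`` when a sex column is present.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [str(c).strip().lower() for c in df.columns]
    df.columns = cols
    if "cm" not in cols or "bp" not in cols:
        raise MapError(f"map file must have columns cM and bp (and optional sex); got {cols}")
    if "sex" in cols:
        out: dict[str, GeneticMap] = {}
        for sex_val, sub in df.groupby("sex"):
            key = str(sex_val).strip().lower()
            key = {"1": "male", "m": "male", "male": "male",
                   "2": "female", "f": "female", "female": "female"}.get(key)
            if key is None:
                raise MapError(f"unrecognized sex value {sex_val!r} in map file")
            sub = sub.sort_values("cm")
            out[key] = GeneticMap.from_anchors(sub["cm"].tolist(), sub["bp"].tolist())
        if set(out) != {"male", "female"}:
            raise MapError("sexed map file must provide both male and female rows")
        return out
    df = df.sort_values("cm")
    return GeneticMap.from_anchors(df["cm"].tolist(), df["bp"].tolist())
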