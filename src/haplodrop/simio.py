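"""Text dialect for simulated haplotypes, and round-trip readers.

One record per line::

    sim;individual;slot;{label_1,b_1,label_2,b_2,...,label_k}

where ``slot`` is 1 (paternal) or 2 (maternal), labels are
founder-chromosome ids (``4.1``) or ``0`` for untracked material, and
``b_i`` is the bp start of segment ``i+1``. A single header line records
the chromosome length and meiosis model::

    # haplodrop bp_len=250000000 model=poisson

Writers stream (constant memory in the number of replicates) and enforce
ordering by (sim, individual, slot); the reader is a lossless inverse and
re-validates the tiling invariants of every haplotype it parses.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, NamedTuple

from .haplotypes import Haplotype

__all__ = [
    "HaplotypeRecord",
    "HaplotypeWriter",
    "FileFormatError",
    "format_haplotype",
    "parse_haplotype",
    "write_proband_file",
    "write_all_nodes_file",
    "read_haplotype_file",
    "read_header",
    "replicates_from_records",
]

_LABEL_RE = re.compile(r"^(0|[1-9]\d*\.[12])$")


class FileFormatError(ValueError):
    """Malformed haplotype file (message includes the line number)."""


class HaplotypeRecord(NamedTuple):
    sim: int
    individual: int
    slot: int
    haplotype: Haplotype


def format_haplotype(h: Haplotype) -> str:
    parts: list[str] = []
    for i, lab in enumerate(h.labels):
        parts.append(lab)
        if i + 1 < len(h.starts):
            parts.append(str(h.starts[i + 1]))
    return "{" + ",".join(parts) + "}"


def parse_haplotype(text: str, bp_len: int) -> Haplotype:
    text = text.strip()
    if not (text.startswith("{") and text.endswith("}")):
        raise ValueError(f"haplotype field must be brace-delimited, got {text!r}")
    tokens = text[1:-1].split(",")
    if len(tokens) % 2 == 0:
        raise ValueError("haplotype field must alternate label,boundary,...,label")
    labels = tokens[0::2]
    for lab in labels:
        if not _LABEL_RE.match(lab):
            raise ValueError(f"bad founder-chromosome label {lab!r}")
    starts = [0] + [int(b) for b in tokens[1::2]]
    return Haplotype(tuple(starts), tuple(labels), bp_len)


class HaplotypeWriter:
    """Streaming writer enforcing (sim, individual, slot) ordering."""

    def __init__(self, path, bp_len: int, model_kind: str):
        self.bp_len = int(bp_len)
        self._fh = open(path, "w", newline="\n")
        self._fh.write(f"# haplodrop bp_len={self.bp_len} model={model_kind}\n")
        self._last: tuple[int, int, int] | None = None

    def write(self, sim: int, individual: int, slot: int, hap: Haplotype) -> None:
        key = (sim, individual, slot)
        if self._last is not None and key <= self._last:
            raise ValueError(f"records out of order: {key} after {self._last}")
        if hap.bp_len != self.bp_len:
            raise ValueError("haplotype bp_len does not match file header")
        self._last = key
        self._fh.write(f"{sim};{individual};{slot};{format_haplotype(hap)}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


def _write_records(records: Iterable[HaplotypeRecord], path, bp_len: int, model_kind: str) -> None:
    with HaplotypeWriter(path, bp_len, model_kind) as w:
        for r in records:
            w.write(r.sim, r.individual, r.slot, r.haplotype)


def write_proband_file(records: Iterable[HaplotypeRecord], path, bp_len: int,
                       model_kind: str = "poisson") -> None:
    _write_records(records, path, bp_len, model_kind)


def write_all_nodes_file(records: Iterable[HaplotypeRecord], path, bp_len: int,
                         model_kind: str = "poisson") -> None:
    _write_records(records, path, bp_len, model_kind)


_HEADER_RE = re.compile(r"^#\s*haplodrop\s+bp_len=(\d+)\s+model=(\w+)\s*$")


def read_header(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    m = _HEADER_RE.match(first)
    if not m:
        raise FileFormatError(f"{path}: line 1: missing or malformed haplodrop header")
    return {"bp_len": int(m.group(1)), "model": m.group(2)}


def read_haplotype_file(path, expect_bp_len: int | None = None) -> Iterator[HaplotypeRecord]:
    """Yield records from a haplotype file; lossless inverse of the writers.

    ``expect_bp_len`` guards an analysis against being run on a file
    simulated with a different chromosome length.
    """
    meta = read_header(path)
    bp_len = meta["bp_len"]
    if expect_bp_len is not None and expect_bp_len != bp_len:
        raise FileFormatError(
            f"{path}: header bp_len={bp_len} does not match required {expect_bp_len}"
        )
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(";")
            if len(fields) != 4:
                raise FileFormatError(f"{path}: line {lineno}: expected 4 ';'-fields")
            try:
                sim, ind, slot = int(fields[0]), int(fields[1]), int(fields[2])
                if slot not in (1, 2):
                    raise ValueError(f"slot must be 1 or 2, got {slot}")
                hap = parse_haplotype(fields[3], bp_len)
            except ValueError as e:
                raise FileFormatError(f"{path}: line {lineno}: {e}") from e
            yield HaplotypeRecord(sim, ind, slot, hap)


def replicates_from_records(records: Iterable[HaplotypeRecord]):
    """Group an ordered record stream into engine Replicate objects."""
    from .engine import Replicate

    current_sim: int | None = None
    haps: dict[int, dict[int, Haplotype]] = {}

    def finish() -> "Replicate":
        pairs = {}
        for i, slots in haps.items():
            if set(slots) != {1, 2}:
                raise FileFormatError(f"individual {i} in replicate {current_sim} lacks both slots")
            pairs[i] = (slots[1], slots[2])
        return Replicate(current_sim, pairs)

    for r in records:
        if current_sim is None:
            current_sim = r.sim
        elif r.sim != current_sim:
            yield finish()
            current_sim, haps = r.sim, {}
        haps.setdefault(r.individual, {})[r.slot] = r.haplotype
    if current_sim is not None:
        yield finish()
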