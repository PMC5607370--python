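"""Per-position, per-strand counts of read 5' ends, with bedGraph I/O.

A FivePrimeCoverage holds one sequencing library's 5'-end pileup as two
integer arrays (forward and reverse strand), each the full genome length.
bedGraph files are 4-column, 0-based half-open, one file per strand, with
intervals as maximal runs of equal count (zero runs included, so a written
track round-trips to the exact array).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import NcostminError


@dataclass
class FivePrimeCoverage:
    fwd: np.ndarray
    rev: np.ndarray
    library_label: str = ""
    condition: str | None = None
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=np.int64)
        self.rev = np.asarray(self.rev, dtype=np.int64)
        if self.fwd.shape != self.rev.shape or self.fwd.ndim != 1:
            raise NcostminError("strand arrays must be 1-D and equal length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise NcostminError("counts must be non-negative")

    @property
    def length(self) -> int:
        return int(self.fwd.shape[0])

    def counts(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.fwd
        if strand == "-":
            return self.rev
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def total(self) -> int:
        return int(self.fwd.sum() + self.rev.sum())


def run_length_intervals(counts: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal value as (start, end, value) triples."""
    counts = np.asarray(counts)
    if counts.size == 0:
        return []
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [counts.size]))
    return [(int(s), int(e), int(counts[s])) for s, e in zip(starts, ends)]


def write_bedgraph(counts: np.ndarray, path: str | os.PathLike, chrom: str = "genome") -> None:
    try:
        with open(path, "w") as fh:
            for start, end, value in run_length_intervals(counts):
                fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")
    except OSError as exc:
        raise NcostminError(f"failed writing bedGraph {path}: {exc}") from exc


def read_bedgraph(path: str | os.PathLike, genome_length: int) -> np.ndarray:
    """Read a 4-column bedGraph into a dense count array (absent runs are 0)."""
    counts = np.zeros(genome_length, dtype=np.int64)
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise NcostminError(f"{path}:{lineno}: expected 4 columns")
                start, end, value = int(fields[1]), int(fields[2]), int(float(fields[3]))
                if not (0 <= start <= end <= genome_length):
                    raise NcostminError(
                        f"{path}:{lineno}: interval [{start},{end}) outside genome"
                    )
                counts[start:end] = value
    except OSError as exc:
        raise NcostminError(f"failed reading bedGraph {path}: {exc}") from exc
    return counts


def load_coverage(fwd_path, rev_path, genome_length: int, library_label: str = "",
                  condition: str | None = None, timepoint_h: float | None = None) -> FivePrimeCoverage:
    return FivePrimeCoverage(
        fwd=read_bedgraph(fwd_path, genome_length),
        rev=read_bedgraph(rev_path, genome_length),
        library_label=library_label,
        condition=condition,
        timepoint_h=timepoint_h,
    )
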