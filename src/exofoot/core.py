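"""Shared containers for the footprint-profiling pipeline.

Conventions used throughout the package:

* genomic coordinates are 0-based, intervals half-open ``[start, end)``
  (BED-compatible);
* TSS-relative offsets are signed base pairs in the direction of
  transcription, with offset 0 being the TSS base itself (negative =
  upstream, positive = downstream);
* for a ``+`` promoter, genomic position = ``tss + offset``;
  for a ``-`` promoter, genomic position = ``tss - offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

STRANDS = ("+", "-")


@dataclass
class GenomeModel:
    """A (possibly synthetic) genome: a name, a length, and optionally sequence.

    The sequence, when present, is an upper-case string over ``{A, C, G, T}``
    of exactly ``length`` characters.
    """

    name: str
    length: int
    circular: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DataError(f"genome length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise DataError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )


@dataclass
class Promoter:
    """A transcription start site with strand, class label, and gene content."""

    id: str
    tss: int
    strand: str
    label: str = "sigma70"
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise DataError(f"promoter {self.id!r}: strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise DataError(f"promoter {self.id!r}: negative TSS {self.tss}")

    def to_genomic(self, offset: int) -> int:
        """Map a TSS-relative offset to a genomic coordinate."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


@dataclass
class TagTrack:
    """Per-strand counts of ChIP-exo 5' tag ends along a genome.

    ``forward[i]`` / ``reverse[i]`` count 5' tag ends on the respective
    genomic strand at position ``i``.
    """

    name: str
    forward: np.ndarray
    reverse: np.ndarray
    circular: bool = False

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward)
        self.reverse = np.asarray(self.reverse)
        if self.forward.shape != self.reverse.shape or self.forward.ndim != 1:
            raise DataError("forward/reverse tag vectors must be 1-D and equal length")
        if (self.forward < 0).any() or (self.reverse < 0).any():
            raise DataError("tag counts must be non-negative")

    @classmethod
    def zeros(cls, genome: GenomeModel) -> "TagTrack":
        return cls(
            name=genome.name,
            forward=np.zeros(genome.length, dtype=np.int64),
            reverse=np.zeros(genome.length, dtype=np.int64),
            circular=genome.circular,
        )

    @property
    def length(self) -> int:
        return int(self.forward.shape[0])

    def total(self) -> int:
        return int(self.forward.sum() + self.reverse.sum())

    def combined(self) -> np.ndarray:
        return self.forward + self.reverse

    def mirrored(self) -> "TagTrack":
        """The track of the reverse-complemented genome: positions reversed,
        strands swapped."""
        return TagTrack(
            name=self.name,
            forward=self.reverse[::-1].copy(),
            reverse=self.forward[::-1].copy(),
            circular=self.circular,
        )


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]
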