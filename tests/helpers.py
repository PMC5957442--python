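"""Independent oracles and small constructors shared across the test suite."""

from __future__ import annotations

import dataclasses

import numpy as np

from exofoot.core import GenomeModel, Promoter, TagTrack
from exofoot.simulate import FootprintModel, MixtureComponent


def digest_fragment(tss: int, strand: str, u: int, d: int, genome_length: int):
    """Brute-force lambda-exonuclease oracle.

    A duplex protected over the TSS-relative interval [u, d] is digested
    literally base by base: the top (forward) strand from its 5' end on the
    left, the bottom (reverse) strand from its 5' end on the right, each
    until the first protected base.  Returns the genomic positions of the
    two surviving 5' ends: (forward_tag, reverse_tag).
    """
    if strand == "+":
        g_lo, g_hi = tss + u, tss + d
    else:
        g_lo, g_hi = tss - d, tss - u
    pos = 0
    while pos < genome_length and not (g_lo <= pos <= g_hi):
        pos += 1
    fwd_tag = pos
    pos = genome_length - 1
    while pos >= 0 and not (g_lo <= pos <= g_hi):
        pos -= 1
    rev_tag = pos
    return fwd_tag, rev_tag


def fixed_model(u: int, d: int, *, n_fragments: float = 1, jitter: float = 0.0,
                background: float = 0.0, name: str = "fixed") -> FootprintModel:
    """Degenerate model emitting exactly (u, d) boundaries."""
    return FootprintModel(
        name=name,
        u_mixture=[MixtureComponent(1.0, u, 0.0)],
        d_mixture=[MixtureComponent(1.0, d, 0.0)],
        tags_per_promoter=(n_fragments, 0.0),  # dispersion 0 -> deterministic
        jitter_sd=jitter,
        background_fraction=background,
    )


def bare_genome(length: int, name: str = "chrT", circular: bool = False) -> GenomeModel:
    return GenomeModel(name=name, length=length, circular=circular)


def track_from_tags(length: int, fwd: dict[int, int] | None = None,
                    rev: dict[int, int] | None = None, name: str = "chrT") -> TagTrack:
    track = TagTrack(name=name, forward=np.zeros(length, dtype=np.int64),
                     reverse=np.zeros(length, dtype=np.int64))
    for pos, c in (fwd or {}).items():
        track.forward[pos] += c
    for pos, c in (rev or {}).items():
        track.reverse[pos] += c
    return track


def mirror_promoters(promoters: list[Promoter], length: int) -> list[Promoter]:
    """Reverse-complement the coordinate system: flip positions and strands."""
    return [
        dataclasses.replace(p, tss=length - 1 - p.tss,
                            strand="-" if p.strand == "+" else "+")
        for p in promoters
    ]
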