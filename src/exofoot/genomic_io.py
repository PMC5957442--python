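"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: BED6 (single-base tag records, strand column routes the
record), per-strand bedGraph, FASTA (via Biopython), and tab-separated tables
for promoters, profiles, peaks, and simulation truth.  All readers validate
loudly and fail with a line number; there are no partial silent loads.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomeModel, Promoter, TagTrack
from .errors import DataError

# ---------------------------------------------------------------------------
# tag tracks
# ---------------------------------------------------------------------------


def read_tags_bed(path: str | Path, genome: GenomeModel) -> TagTrack:
    """Accumulate single-base BED6 tag records into a per-strand track.

    Each record must span exactly one base (``end == start + 1``); the score
    column is the tag count at that base and the strand column routes the
    record to the forward or reverse vector.
    """
    track = TagTrack.zeros(genome)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                count = int(float(fields[4]))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric coordinate or score") from exc
            if end != start + 1:
                raise DataError(
                    f"{path}:{lineno}: tag records must be single-base, got [{start}, {end})"
                )
            if not 0 <= start < genome.length:
                raise DataError(
                    f"{path}:{lineno}: position {start} outside genome of length {genome.length}"
                )
            strand = fields[5]
            if strand == "+":
                track.forward[start] += count
            elif strand == "-":
                track.reverse[start] += count
            else:
                raise DataError(f"{path}:{lineno}: bad strand {strand!r}")
    return track


def write_tags_bed(track: TagTrack, path: str | Path) -> None:
    """One record per occupied (position, strand), score = tag count."""
    with open(path, "w") as fh:
        for strand, vec in (("+", track.forward), ("-", track.reverse)):
            for pos in np.flatnonzero(vec):
                fh.write(f"{track.name}\t{pos}\t{pos + 1}\ttag\t{int(vec[pos])}\t{strand}\n")


def read_tags_bedgraph(
    forward_path: str | Path, reverse_path: str | Path, genome: GenomeModel
) -> TagTrack:
    """Read one bedGraph file per strand; interval values are added per base."""
    track = TagTrack.zeros(genome)
    for path, vec in ((forward_path, track.forward), (reverse_path, track.reverse)):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise DataError(
                        f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                    value = float(fields[3])
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: non-numeric field") from exc
                if not (0 <= start < end <= genome.length):
                    raise DataError(
                        f"{path}:{lineno}: interval [{start}, {end}) outside genome "
                        f"of length {genome.length}"
                    )
                if value != int(value) or value < 0:
                    raise DataError(f"{path}:{lineno}: counts must be non-negative integers")
                vec[start:end] += int(value)
    return track


def write_tags_bedgraph(
    track: TagTrack, forward_path: str | Path, reverse_path: str | Path
) -> None:
    for path, vec in ((forward_path, track.forward), (reverse_path, track.reverse)):
        with open(path, "w") as fh:
            for pos in np.flatnonzero(vec):
                fh.write(f"{track.name}\t{pos}\t{pos + 1}\t{int(vec[pos])}\n")


# ---------------------------------------------------------------------------
# promoter annotation
# ---------------------------------------------------------------------------

_PROMOTER_COLUMNS = ["id", "tss", "strand", "label", "genes"]


def read_promoters(path: str | Path) -> list[Promoter]:
    """Read a promoter annotation TSV (columns id, tss, strand, label, genes)."""
    promoters: list[Promoter] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.reader(
            (l for l in fh if l.strip() and not l.startswith("#")), delimiter="\t"
        )
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty promoter table") from None
        if [h.strip() for h in header[: len(_PROMOTER_COLUMNS)]] != _PROMOTER_COLUMNS:
            raise DataError(
                f"{path}: header must start with {_PROMOTER_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) < 4:
                raise DataError(f"{path}:{lineno}: expected >= 4 columns")
            pid = row[0].strip()
            if pid in seen:
                raise DataError(f"{path}:{lineno}: duplicate promoter id {pid!r}")
            seen.add(pid)
            try:
                tss = int(row[1])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer TSS {row[1]!r}") from exc
            genes = [g for g in row[4].split(",") if g] if len(row) > 4 else []
            promoters.append(Promoter(id=pid, tss=tss, strand=row[2].strip(),
                                      label=row[3].strip(), genes=genes))
    return promoters


def write_promoters(promoters: Iterable[Promoter], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PROMOTER_COLUMNS) + "\n")
        for p in promoters:
            fh.write(f"{p.id}\t{p.tss}\t{p.strand}\t{p.label}\t{','.join(p.genes)}\n")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_profile(profile, path: str | Path) -> None:
    """Write an aggregate (or single oriented) profile as a TSV.

    Columns: offset, template_density, nontemplate_density.  Densities are
    written with 8 significant digits so fractions recompute stably.
    """
    with open(path, "w") as fh:
        fh.write("offset\ttemplate_density\tnontemplate_density\n")
        for off, t, nt in zip(profile.offsets, profile.template, profile.nontemplate):
            fh.write(f"{off}\t{t:.8g}\t{nt:.8g}\n")


def read_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["offset", "template_density", "nontemplate_density"]
    if list(df.columns) != expected:
        raise DataError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "start", "end", "center", "max_fwd", "max_rev", "pair_distance",
    "total_tags", "mode_index", "group_label", "assigned_promoter", "offset",
]


def write_peaks(regions, path: str | Path) -> None:
    rows = []
    for r in regions:
        wc = r.width_class
        rows.append({
            "start": r.start, "end": r.end, "center": r.center,
            "max_fwd": r.max_fwd, "max_rev": r.max_rev,
            "pair_distance": r.pair_distance, "total_tags": r.total_tags,
            "mode_index": None if wc is None or wc.mode_index is None else wc.mode_index,
            "group_label": None if wc is None else wc.group_label,
            "assigned_promoter": r.assigned_promoter, "offset": r.offset,
        })
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing peak columns {missing}")
    return df


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, *, simulation: bool = False) -> GenomeModel:
    """Read the first record of a FASTA file as a genome.

    Sequence is upper-cased.  In ``simulation`` mode non-ACGT characters are
    rejected; otherwise they are tolerated (the motif scanner skips them).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    rec = records[0]
    seq = str(rec.seq).upper()
    if simulation and set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise DataError(f"{path}: non-ACGT characters {bad} in simulation genome")
    return GenomeModel(name=rec.id, length=len(seq), sequence=seq)


def write_fasta(genome: GenomeModel, path: str | Path) -> None:
    if genome.sequence is None:
        raise DataError("genome has no sequence to write")
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")
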