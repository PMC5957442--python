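"""Position weight matrices for promoter elements and activator sites.

PWMs are column-stochastic frequency models scored as log-odds (base 2)
against a uniform 0.25 background.  The packaged Crp site model is a 22-bp
palindromic matrix built around the TGTGA-N6-TCACA core; because the site
length is even, site centers fall on half-integer coordinates, which makes
the canonical Crp promoter-class offsets (-41.5, -61.5, -93.5) exactly
representable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .core import GenomeModel, Promoter
from .errors import DataError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# complement permutation of the ACGT row order
_COMPLEMENT = np.array([3, 2, 1, 0])


@dataclass
class PWM:
    """A position count matrix with a per-cell pseudocount.

    ``counts`` has shape (4, length) in ACGT row order.  Frequencies and
    log-odds are derived lazily with the pseudocount applied.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise DataError("PWM counts must have shape (4, length)")
        if (self.counts < 0).any():
            raise DataError("PWM counts must be non-negative")
        if self.pseudocount < 0:
            raise DataError("pseudocount must be non-negative")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    @property
    def frequencies(self) -> np.ndarray:
        adj = self.counts + self.pseudocount
        return adj / adj.sum(axis=0, keepdims=True)

    @property
    def info_content(self) -> np.ndarray:
        """Information content per column in bits (uniform background)."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(f > 0, -f * np.log2(f), 0.0).sum(axis=0)
        return 2.0 - ent

    @property
    def log_odds(self) -> np.ndarray:
        """log2(frequency / 0.25) per cell; requires pseudocount > 0 for
        finiteness when a count is zero."""
        return np.log2(self.frequencies / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=0))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one site sequence column-wise from the frequency model."""
        f = self.frequencies
        return "".join(BASES[rng.choice(4, p=f[:, j])] for j in range(self.length))


@dataclass
class MotifSite:
    """A scored motif occurrence; ``center`` is half-integer for even length."""

    center: float
    strand: str
    score: float
    start: int


def build_pwm(sequences: list[str], pseudocount: float = 0.5, name: str = "pwm") -> PWM:
    """Build a PWM from equal-length ACGT strings by column base counting."""
    if not sequences:
        raise DataError("build_pwm needs at least one sequence")
    length = len(sequences[0])
    counts = np.zeros((4, length), dtype=float)
    for seq in sequences:
        if len(seq) != length:
            raise DataError(f"ragged sequence lengths: {len(seq)} vs {length}")
        for j, base in enumerate(seq.upper()):
            if base not in _BASE_INDEX:
                raise DataError(f"non-ACGT base {base!r} in PWM training sequence")
            counts[_BASE_INDEX[base], j] += 1
    return PWM(name=name, counts=counts, pseudocount=pseudocount)


def encode(sequence: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> 4 (scored -inf by the scanner)."""
    table = np.full(256, 4, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def scan(sequence: str, pwm: PWM, threshold: float) -> list[MotifSite]:
    """Scan both strands; report every window scoring >= threshold.

    The reverse-strand score of a window is the forward score of its reverse
    complement; site centers are reported on the forward coordinate system.
    Windows containing non-ACGT characters never match.
    """
    if pwm.pseudocount <= 0:
        raise DataError("scan requires pseudocount > 0 for finite log-odds")
    L = pwm.length
    if len(sequence) < L:
        return []
    codes = encode(sequence)
    lom = np.vstack([pwm.log_odds, np.full(L, -np.inf)])  # row 4: invalid base
    lom_rc = lom[[3, 2, 1, 0, 4]][:, ::-1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    cols = np.arange(L)
    fwd_scores = lom[windows, cols].sum(axis=1)
    rev_scores = lom_rc[windows, cols].sum(axis=1)
    half = (L - 1) / 2.0
    sites = [
        MotifSite(center=start + half, strand="+", score=float(s), start=int(start))
        for start, s in zip(np.flatnonzero(fwd_scores >= threshold),
                            fwd_scores[fwd_scores >= threshold])
    ]
    sites += [
        MotifSite(center=start + half, strand="-", score=float(s), start=int(start))
        for start, s in zip(np.flatnonzero(rev_scores >= threshold),
                            rev_scores[rev_scores >= threshold])
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def site_offset_histogram(
    sites: list[MotifSite],
    promoters: list[Promoter],
    max_dist: float = 150,
    bin_width: int = 1,
    smoothing_sd: float = 2.0,
    min_fraction: float = 0.02,
    valley_ratio: float = 0.5,
):
    """Histogram strand-oriented site-center offsets around the nearest TSS.

    Each site is assigned to the nearest TSS within ``max_dist``; the offset
    is signed in the promoter's direction of transcription.  Returns
    ``(bin_centers, counts, modes)`` where modes are detected with the same
    valley-separation machinery used for density profiles.
    """
    from .profiles import find_modes_array  # shared mode machinery

    order = np.argsort([p.tss for p in promoters])
    tss = np.array([promoters[i].tss for i in order], dtype=float)
    strands = [promoters[i].strand for i in order]
    offsets: list[float] = []
    for site in sites:
        j = int(np.searchsorted(tss, site.center))
        best, best_dist = None, None
        for k in (j - 1, j):
            if 0 <= k < len(tss):
                dist = abs(site.center - tss[k])
                if best_dist is None or dist < best_dist:
                    best, best_dist = k, dist
        if best is None or best_dist > max_dist:
            continue
        off = site.center - tss[best] if strands[best] == "+" else tss[best] - site.center
        offsets.append(off)
    lo = -int(max_dist)
    edges = np.arange(lo, int(max_dist) + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(offsets, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    modes = find_modes_array(
        counts.astype(float), centers, denominator=float(max(counts.sum(), 1)),
        strand="sites", smoothing_sd=smoothing_sd, min_fraction=min_fraction,
        valley_ratio=valley_ratio,
    )
    return centers, counts, modes


def oriented_window(genome: GenomeModel, promoter: Promoter, lo: int, hi: int) -> str:
    """Extract the promoter-sense sequence spanning offsets [lo, hi] inclusive."""
    if genome.sequence is None:
        raise DataError("genome has no sequence")
    if promoter.strand == "+":
        start, end = promoter.tss + lo, promoter.tss + hi + 1
        if start < 0 or end > genome.length:
            raise DataError(f"window out of range for promoter {promoter.id}")
        return genome.sequence[start:end]
    start, end = promoter.tss - hi, promoter.tss - lo + 1
    if start < 0 or end > genome.length:
        raise DataError(f"window out of range for promoter {promoter.id}")
    from .core import revcomp

    return revcomp(genome.sequence[start:end])


# ---------------------------------------------------------------------------
# PWM text format: header line "name length pseudocount", then 4 labelled rows
# ---------------------------------------------------------------------------


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{pwm.name}\t{pwm.length}\t{pwm.pseudocount}\n")
        for i, base in enumerate(BASES):
            fh.write(base + "\t" + "\t".join(f"{c:g}" for c in pwm.counts[i]) + "\n")


def read_pwm(path: str | Path) -> PWM:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if len(lines) != 5:
        raise DataError(f"{path}: expected header + 4 base rows")
    name, length_s, pc_s = lines[0].split("\t")
    rows = {}
    for line in lines[1:]:
        fields = line.split("\t")
        rows[fields[0]] = [float(x) for x in fields[1:]]
    try:
        counts = np.array([rows[b] for b in BASES])
    except KeyError as exc:
        raise DataError(f"{path}: missing base row {exc}") from exc
    if counts.shape[1] != int(length_s):
        raise DataError(f"{path}: row length != declared length {length_s}")
    return PWM(name=name, counts=counts, pseudocount=float(pc_s))


def load_crp_pwm() -> PWM:
    """The packaged 22-bp Crp site model (TGTGA-N6-TCACA core)."""
    ref = resources.files("exofoot.data").joinpath("crp_site_pwm.txt")
    with resources.as_file(ref) as path:
        return read_pwm(path)


#: default log-odds threshold for scanning with the packaged Crp model;
#: retains >= 95% of PWM-sampled sites while uniform background exceeds it
#: about 3e-5 of the time per strand position (see docs/methods.md).
DEFAULT_CRP_THRESHOLD = 8.0
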