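"""TSS-aligned, strand-oriented 5' tag density profiles and their summaries.

The central construction: for each promoter, tag counts in a 400-bp window
are re-expressed in TSS-relative offsets oriented along transcription.  The
strand read by RNA polymerase (template) carries the DOWNSTREAM protected
boundary of the footprint, its complement (nontemplate) the UPSTREAM
boundary — a direct consequence of 5'->3' exonuclease digestion.  Aggregate
profiles average per-promoter windows after unit-sum normalization so that
high-coverage promoters do not dominate; all reported maxima and density
fractions are computed on unsmoothed densities, smoothing being used only to
detect modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import Promoter, TagTrack
from .errors import DataError

HALFWIDTH = 200  # window is [-200, +200): 400 offsets


@dataclass
class OrientedProfile:
    promoter_id: str
    offsets: np.ndarray
    template: np.ndarray
    nontemplate: np.ndarray

    def total(self) -> float:
        return float(self.template.sum() + self.nontemplate.sum())


@dataclass
class AggregateProfile:
    n_regions: int
    offsets: np.ndarray
    template: np.ndarray
    nontemplate: np.ndarray
    normalization: str = "per_region_unit_sum"

    def strand(self, name: str) -> np.ndarray:
        if name not in ("template", "nontemplate"):
            raise DataError(f"strand must be template or nontemplate, got {name!r}")
        return getattr(self, name)


@dataclass
class Mode:
    """One detected density mode: a valley-to-valley span on one strand."""

    strand: str
    lo: float
    hi: float
    peak_offset: float
    fraction: float


def orient_profile(
    track: TagTrack, promoter: Promoter, halfwidth: int = HALFWIDTH
) -> OrientedProfile:
    """Extract the oriented per-strand tag counts around one TSS.

    For a ``+`` promoter the template density at offset x is the
    reverse-strand count at ``tss + x`` and the nontemplate density the
    forward-strand count there; a ``-`` promoter mirrors both.
    """
    offsets = np.arange(-halfwidth, halfwidth)
    if promoter.strand == "+":
        lo, hi = promoter.tss - halfwidth, promoter.tss + halfwidth
        if lo < 0 or hi > track.length:
            if not track.circular:
                raise DataError(
                    f"window [{lo}, {hi}) out of range for promoter {promoter.id}"
                )
            idx = np.arange(lo, hi) % track.length
            return OrientedProfile(promoter.id, offsets,
                                   track.reverse[idx].astype(float),
                                   track.forward[idx].astype(float))
        return OrientedProfile(promoter.id, offsets,
                               track.reverse[lo:hi].astype(float),
                               track.forward[lo:hi].astype(float))
    # '-' promoter: genomic position of offset x is tss - x
    positions = promoter.tss - offsets
    if positions.min() < 0 or positions.max() >= track.length:
        if not track.circular:
            raise DataError(
                f"window [{positions.min()}, {positions.max()}] out of range "
                f"for promoter {promoter.id}"
            )
        positions = positions % track.length
    return OrientedProfile(promoter.id, offsets,
                           track.forward[positions].astype(float),
                           track.reverse[positions].astype(float))


def aggregate(
    profiles: list[OrientedProfile], normalization: str = "per_region_unit_sum"
) -> AggregateProfile:
    """Offset-wise mean over oriented windows.

    ``per_region_unit_sum`` (default) scales each nonempty window to combined
    sum 1 first, so the aggregate's combined sum is exactly 1; ``raw_mean``
    averages raw counts.
    """
    if normalization not in ("per_region_unit_sum", "raw_mean"):
        raise DataError(f"unknown normalization {normalization!r}")
    nonempty = [p for p in profiles if p.total() > 0]
    if not nonempty:
        raise DataError("aggregate needs at least one nonempty profile")
    offsets = nonempty[0].offsets
    t = np.zeros(len(offsets))
    nt = np.zeros(len(offsets))
    for p in nonempty:
        scale = 1.0 / p.total() if normalization == "per_region_unit_sum" else 1.0
        t += p.template * scale
        nt += p.nontemplate * scale
    n = len(nonempty)
    return AggregateProfile(n_regions=n, offsets=offsets, template=t / n,
                            nontemplate=nt / n, normalization=normalization)


def density_fraction(
    profile: AggregateProfile, strand: str, interval: tuple[int, int]
) -> float:
    """Share of the COMBINED window density carried by one strand over an
    inclusive offset interval."""
    lo, hi = interval
    if lo > hi:
        raise DataError(f"inverted interval [{lo}, {hi}]")
    offsets = profile.offsets
    if lo < offsets[0] or hi > offsets[-1]:
        raise DataError(f"interval [{lo}, {hi}] outside window "
                        f"[{offsets[0]}, {offsets[-1]}]")
    mask = (offsets >= lo) & (offsets <= hi)
    denom = profile.template.sum() + profile.nontemplate.sum()
    if denom == 0:
        raise DataError("empty profile has no density fractions")
    return float(profile.strand(strand)[mask].sum() / denom)


def median_center_offset(offsets: list[int]) -> int:
    """Integer-preserving median: for even counts, the lower central value."""
    if len(offsets) == 0:
        raise DataError("median of no offsets")
    ordered = sorted(offsets)
    return ordered[(len(ordered) - 1) // 2]


# ---------------------------------------------------------------------------
# mode detection
# ---------------------------------------------------------------------------


def find_modes_array(
    raw: np.ndarray,
    offsets: np.ndarray,
    denominator: float,
    strand: str,
    smoothing_sd: float = 2.0,
    min_fraction: float = 0.02,
    valley_ratio: float = 0.5,
) -> list[Mode]:
    """Valley-separated modes of a 1-D density.

    Local maxima of the Gaussian-smoothed density are merged while the
    deepest valley between two neighbours exceeds ``valley_ratio`` times the
    lower maximum; mode spans run valley-to-valley (outermost spans to the
    window edges), fractions and peak offsets are computed on the unsmoothed
    density, and modes below ``min_fraction`` of the denominator are dropped.
    Peak-offset ties prefer the smallest |offset|, then the negative one.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.sum() <= 0:
        return []
    y = gaussian_filter1d(raw, smoothing_sd, mode="nearest")
    peak_idx, _ = find_peaks(y, plateau_size=1)
    peak_idx = list(peak_idx)
    # allow edge maxima
    if len(y) > 1 and y[0] > y[1]:
        peak_idx.insert(0, 0)
    if len(y) > 1 and y[-1] > y[-2]:
        peak_idx.append(len(y) - 1)
    if not peak_idx:
        peak_idx = [int(np.argmax(y))]

    def valley(a: int, b: int) -> float:
        return float(y[a : b + 1].min())

    while len(peak_idx) > 1:
        ratios = []
        for k in range(len(peak_idx) - 1):
            a, b = peak_idx[k], peak_idx[k + 1]
            lower = min(y[a], y[b])
            ratios.append(valley(a, b) / lower if lower > 0 else 1.0)
        worst = int(np.argmax(ratios))
        if ratios[worst] <= valley_ratio:
            break
        a, b = peak_idx[worst], peak_idx[worst + 1]
        peak_idx.remove(a if y[a] <= y[b] else b)

    boundaries = [0]
    for k in range(len(peak_idx) - 1):
        a, b = peak_idx[k], peak_idx[k + 1]
        boundaries.append(a + int(np.argmin(y[a : b + 1])))
    boundaries.append(len(y) - 1)

    modes: list[Mode] = []
    for k in range(len(peak_idx)):
        lo_i = boundaries[k] if k == 0 else boundaries[k] + 1
        hi_i = boundaries[k + 1]
        if lo_i > hi_i:
            continue
        span = raw[lo_i : hi_i + 1]
        fraction = float(span.sum() / denominator)
        if fraction < min_fraction:
            continue
        peak_val = span.max()
        candidates = np.flatnonzero(span == peak_val) + lo_i
        best = min(candidates, key=lambda i: (abs(offsets[i]), offsets[i]))
        modes.append(Mode(strand=strand, lo=float(offsets[lo_i]),
                          hi=float(offsets[hi_i]),
                          peak_offset=float(offsets[best]), fraction=fraction))
    return modes


def find_modes(
    profile: AggregateProfile,
    strand: str,
    smoothing_sd: float = 2.0,
    min_fraction: float = 0.02,
    valley_ratio: float = 0.5,
) -> list[Mode]:
    """Detect modes of one strand of an aggregate profile.

    Fractions are shares of the combined two-strand window density.
    """
    denom = float(profile.template.sum() + profile.nontemplate.sum())
    if denom <= 0:
        return []
    return find_modes_array(
        profile.strand(strand), profile.offsets, denominator=denom, strand=strand,
        smoothing_sd=smoothing_sd, min_fraction=min_fraction,
        valley_ratio=valley_ratio,
    )


def profiles_for_called_promoters(
    track: TagTrack,
    regions,
    promoters: list[Promoter],
    max_dist: int = 300,
    halfwidth: int = HALFWIDTH,
) -> list[OrientedProfile]:
    """Oriented windows for every promoter that owns at least one called peak."""
    from .peaks import center_offsets

    center_offsets(regions, promoters, max_dist=max_dist)
    called = {r.assigned_promoter for r in regions if r.assigned_promoter}
    return [
        orient_profile(track, p, halfwidth=halfwidth)
        for p in promoters
        if p.id in called
    ]
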