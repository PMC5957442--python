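"""Peak-region calling, peak-pair geometry, and footprint-width classes.

The caller is deliberately simple: smooth the combined-strand tag density
with a Gaussian kernel, keep contiguous runs above a height threshold, merge
nearby runs, and drop short regions.  Per-strand maxima — the peak pair whose
separation estimates the footprint width — are always taken on UNsmoothed
counts, because smoothing shifts boundary estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import Promoter, TagTrack
from .errors import ConfigError, DataError


@dataclass(frozen=True)
class WidthClass:
    """Footprint width bin.

    The width-mode numbering and the promoter-group numbering run in opposite
    directions (mode 1 = narrowest = Group III), so both labels are always
    carried together.
    """

    mode_index: int | None
    group_label: str | None

    @property
    def classified(self) -> bool:
        return self.mode_index is not None


UNCLASSIFIED = WidthClass(None, None)
_WIDTH_BINS = (  # inclusive bounds -> (mode, group)
    (5, 20, 1, "III"),
    (21, 40, 2, "II"),
    (41, 60, 3, "I"),
)


def classify_width(distance: int) -> WidthClass:
    """Map a peak-pair distance (bp) to its width mode / promoter group."""
    for lo, hi, mode, group in _WIDTH_BINS:
        if lo <= distance <= hi:
            return WidthClass(mode, group)
    return UNCLASSIFIED


@dataclass
class PeakRegion:
    """A called binding region with per-strand maxima.

    ``pair_distance`` is ``max_rev - max_fwd`` (an estimate of footprint
    width); it is None, and the region flagged, if either strand has no tags
    in the region.  ``center`` is the midpoint of the strand maxima, rounded
    half toward ``max_rev``.
    """

    start: int
    end: int
    center: int
    max_fwd: int | None
    max_rev: int | None
    pair_distance: int | None
    total_tags: int
    strand_missing: bool = False
    width_class: WidthClass | None = None
    assigned_promoter: str | None = None
    offset: int | None = None


def _strand_max(counts: np.ndarray, start: int, end: int) -> int | None:
    """Position of the maximum count in [start, end); ties broken toward the
    position closest to the region midpoint, then leftmost."""
    window = counts[start:end]
    if window.sum() == 0:
        return None
    peak = window.max()
    candidates = np.flatnonzero(window == peak) + start
    mid = (start + end - 1) / 2.0
    return int(min(candidates, key=lambda p: (abs(p - mid), p)))


def _make_region(track: TagTrack, start: int, end: int) -> PeakRegion:
    max_fwd = _strand_max(track.forward, start, end)
    max_rev = _strand_max(track.reverse, start, end)
    total = int(track.forward[start:end].sum() + track.reverse[start:end].sum())
    if max_fwd is None or max_rev is None:
        center = (start + end) // 2
        return PeakRegion(start, end, center, max_fwd, max_rev, None, total,
                          strand_missing=True, width_class=UNCLASSIFIED)
    dist = max_rev - max_fwd
    s = max_fwd + max_rev
    if s % 2 == 0:
        center = s // 2
    else:  # round the half toward max_rev
        center = (s + 1) // 2 if max_rev > max_fwd else s // 2
    return PeakRegion(start, end, center, max_fwd, max_rev, dist, total,
                      width_class=classify_width(dist))


def call_peaks(
    track: TagTrack,
    smoothing_bw: float = 3.0,
    min_height: float = 0.7,
    merge_dist: int = 50,
    min_region: int = 10,
) -> list[PeakRegion]:
    """Call peak regions from the combined-strand tag density.

    Parameters: Gaussian smoothing sd in bp; minimum smoothed height (tags);
    maximum gap between runs that still merges them; minimum region length.
    """
    if smoothing_bw <= 0 or min_height <= 0 or merge_dist < 0 or min_region < 1:
        raise ConfigError("peak-calling parameters must be positive")
    combined = track.combined().astype(float)
    if combined.sum() == 0:
        return []
    smooth = gaussian_filter1d(
        combined, smoothing_bw, mode="wrap" if track.circular else "constant"
    )
    above = smooth >= min_height
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if len(edges) else []
    ends = list(edges[above[edges]] + 1) if len(edges) else []
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    runs = list(zip(starts, ends))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_dist:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        _make_region(track, s, e) for s, e in merged if e - s >= min_region
    ]


def peak_pair_distance(region: PeakRegion) -> int:
    """``max_rev - max_fwd`` for a region with tags on both strands."""
    if region.pair_distance is None:
        raise DataError(
            f"region [{region.start}, {region.end}) lacks tags on one strand; "
            "pair distance undefined"
        )
    return region.pair_distance


def center_offsets(
    regions: list[PeakRegion],
    promoters: list[Promoter],
    max_dist: int = 300,
) -> tuple[list[int], list[PeakRegion]]:
    """Assign each region to the nearest TSS within ``max_dist`` and return
    strand-oriented signed center offsets plus the unassigned regions.

    Regions are annotated in place (``assigned_promoter``, ``offset``).
    """
    if not promoters:
        return [], list(regions)
    order = sorted(range(len(promoters)), key=lambda i: promoters[i].tss)
    tss = np.array([promoters[i].tss for i in order])
    offsets: list[int] = []
    unassigned: list[PeakRegion] = []
    for region in regions:
        j = int(np.searchsorted(tss, region.center))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(tss):
                dist = abs(region.center - int(tss[k]))
                if best is None or dist < best[0]:
                    best = (dist, k)
        if best is None or best[0] > max_dist:
            region.assigned_promoter = None
            region.offset = None
            unassigned.append(region)
            continue
        prom = promoters[order[best[1]]]
        off = region.center - prom.tss if prom.strand == "+" else prom.tss - region.center
        region.assigned_promoter = prom.id
        region.offset = int(off)
        offsets.append(int(off))
    return offsets, unassigned
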