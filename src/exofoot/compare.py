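"""Factor/condition/replicate comparisons.

Three comparison modes: region-wise profile overlays (one factor's tag
density profiled over another factor's peak regions), genome-wide binned
track correlation (the conventional replicate-quality statistic), and
peak-set overlap by greedy nearest-center matching (retention of binding
regions across genetic perturbations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Promoter, TagTrack
from .errors import DataError
from .peaks import PeakRegion, center_offsets
from .profiles import HALFWIDTH, AggregateProfile, OrientedProfile, aggregate, orient_profile


@dataclass
class OverlayResult:
    profiles_a: list[OrientedProfile]
    profiles_b: list[OrientedProfile]
    mean_a: AggregateProfile | None
    mean_b: AggregateProfile | None  # None when every window on that side is empty
    correlations: list[float | None]  # per region; None where a track is flat

    @property
    def median_r(self) -> float:
        vals = [r for r in self.correlations if r is not None]
        if not vals:
            raise DataError("no region had variance on both tracks")
        return float(np.median(vals))


def overlay_profiles(
    regions: list[PeakRegion],
    track_a: TagTrack,
    track_b: TagTrack,
    promoters: list[Promoter],
    max_dist: int = 300,
    halfwidth: int = HALFWIDTH,
) -> OverlayResult:
    """Profile both tracks over the SAME (track A's) peak regions.

    Each region is anchored at its assigned promoter's TSS; the per-region
    Pearson r is computed on the concatenated template+nontemplate raw window
    counts.  Regions where either window is constant are flagged (r = None).
    """
    if track_a.length != track_b.length:
        raise DataError("overlay requires tracks on the same genome")
    center_offsets(regions, promoters, max_dist=max_dist)
    by_id = {p.id: p for p in promoters}
    profiles_a, profiles_b, correlations = [], [], []
    for region in regions:
        if region.assigned_promoter is None:
            continue
        prom = by_id[region.assigned_promoter]
        pa = orient_profile(track_a, prom, halfwidth=halfwidth)
        pb = orient_profile(track_b, prom, halfwidth=halfwidth)
        profiles_a.append(pa)
        profiles_b.append(pb)
        xa = np.concatenate([pa.template, pa.nontemplate])
        xb = np.concatenate([pb.template, pb.nontemplate])
        if xa.std() == 0 or xb.std() == 0:
            correlations.append(None)
        else:
            correlations.append(float(stats.pearsonr(xa, xb)[0]))
    if not profiles_a:
        raise DataError("no region could be assigned to a promoter")

    def _mean(profiles):
        return aggregate(profiles) if any(p.total() > 0 for p in profiles) else None

    return OverlayResult(
        profiles_a=profiles_a, profiles_b=profiles_b,
        mean_a=_mean(profiles_a), mean_b=_mean(profiles_b),
        correlations=correlations,
    )


def track_correlation(track_a: TagTrack, track_b: TagTrack, bin_size: int = 100) -> float:
    """Genome-wide Pearson r of binned per-strand counts (strands concatenated).

    Returns NaN (reported, not raised) when either binned track has zero
    variance.
    """
    if track_a.length != track_b.length:
        raise DataError("track correlation requires equal genome lengths")
    if bin_size < 1:
        raise DataError("bin size must be >= 1")
    n_bins = track_a.length // bin_size
    if n_bins < 2:
        raise DataError("genome shorter than two bins")

    def binned(track: TagTrack) -> np.ndarray:
        cut = n_bins * bin_size
        f = track.forward[:cut].reshape(n_bins, bin_size).sum(axis=1)
        r = track.reverse[:cut].reshape(n_bins, bin_size).sum(axis=1)
        return np.concatenate([f, r]).astype(float)

    xa, xb = binned(track_a), binned(track_b)
    if xa.std() == 0 or xb.std() == 0:
        return float("nan")
    return float(stats.pearsonr(xa, xb)[0])


@dataclass
class PeakSetComparison:
    n_a: int
    n_b: int
    n_shared: int
    retained_fraction: float


def peak_set_overlap(
    peaks_a: list[PeakRegion], peaks_b: list[PeakRegion], tolerance: int = 50
) -> PeakSetComparison:
    """Greedy one-to-one nearest-center matching within ``tolerance`` bp.

    ``retained_fraction`` is relative to set A; the shared count is symmetric
    in the two sets.
    """
    ca = [p.center for p in peaks_a]
    cb = [p.center for p in peaks_b]
    pairs = [
        (abs(a - b), i, j)
        for i, a in enumerate(ca)
        for j, b in enumerate(cb)
        if abs(a - b) <= tolerance
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    fraction = shared / len(ca) if ca else 0.0
    return PeakSetComparison(n_a=len(ca), n_b=len(cb), n_shared=shared,
                             retained_fraction=fraction)
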