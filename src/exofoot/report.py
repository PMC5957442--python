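"""End-to-end synthetic reproductions of the headline footprint statistics.

Each function runs simulate -> call peaks -> assign to TSSs -> profile /
scan -> summarize for one packaged preset, and returns plain numbers.  These
are the quantities the pipeline is calibrated to recover: the +20 template
boundary, the trimodal nontemplate structure (28/9/8% density fractions with
maxima at -28 and +6), the +5 median peak center, the Crp 33%/13% density
split and -41.5/-61.5/-93.5 site placements, the ~30-bp repressor footprint,
and the ~40% peak retention of the double activating-region mutant.
"""

from __future__ import annotations

import numpy as np

from . import motifs, peaks, profiles
from .compare import peak_set_overlap
from .simulate import SimConfig, SimResult, simulate


def _aggregate_for(result: SimResult):
    regions = peaks.call_peaks(result.track)
    offsets, _ = peaks.center_offsets(regions, result.promoters)
    prof = profiles.profiles_for_called_promoters(result.track, regions,
                                                 result.promoters)
    agg = profiles.aggregate(prof)
    return regions, offsets, agg


def sigma70_recovery(seed: int, n: int = 500) -> dict:
    """Template/nontemplate aggregate structure of the sigma70 preset."""
    result = simulate(SimConfig(preset="sigma70", n_promoters=n, seed=seed,
                                with_sequence=False))
    regions, offsets, agg = _aggregate_for(result)
    template_argmax = int(agg.offsets[np.argmax(agg.template)])
    modes = profiles.find_modes(agg, "nontemplate")
    modes = sorted(modes, key=lambda m: m.peak_offset)
    return {
        "n_regions": len(regions),
        "template_argmax": template_argmax,
        "median_center_offset": profiles.median_center_offset(offsets),
        "core_fraction_pct": 100 * profiles.density_fraction(agg, "nontemplate", (-18, -1)),
        "nontemplate_modes": [
            {"peak_offset": m.peak_offset, "fraction_pct": 100 * m.fraction,
             "lo": m.lo, "hi": m.hi}
            for m in modes
        ],
        "upstream_mode_offset": modes[0].peak_offset if modes else None,
        "downstream_mode_offset": modes[-1].peak_offset if modes else None,
    }


def crp_recovery(seed: int, n: int = 500) -> dict:
    """Density split and motif-site geometry of the activating Crp preset."""
    result = simulate(SimConfig(preset="crp_activating", n_promoters=n, seed=seed))
    _, offsets, agg = _aggregate_for(result)
    pwm = motifs.load_crp_pwm()
    sites = motifs.scan(result.genome.sequence, pwm,
                        threshold=motifs.DEFAULT_CRP_THRESHOLD)
    _, _, site_modes = motifs.site_offset_histogram(sites, result.promoters)
    mode_offsets = sorted(m.peak_offset for m in site_modes)
    return {
        "median_center_offset": profiles.median_center_offset(offsets),
        "template_downstream_pct": 100 * profiles.density_fraction(agg, "template", (13, 27)),
        "nontemplate_upstream_pct": 100 * profiles.density_fraction(agg, "nontemplate", (-94, -61)),
        "site_mode_offsets": mode_offsets,
        "upstream_site_mode": mode_offsets[0] if mode_offsets else None,
        "n_sites": len(sites),
    }


def repressor_recovery(seed: int, n: int = 300) -> dict:
    """Footprint width of the motif-centered repressor preset."""
    result = simulate(SimConfig(preset="repressor", n_promoters=n, seed=seed,
                                with_sequence=False))
    regions = peaks.call_peaks(result.track)
    distances = [r.pair_distance for r in regions if r.pair_distance is not None]
    return {
        "n_regions": len(regions),
        "median_pair_distance": float(np.median(distances)) if distances else None,
    }


def mutant_retention(seed: int, n: int = 500, mutant: str = "ar1ar2") -> dict:
    """Peak retention of an activating-region mutant vs wild-type Crp.

    Both runs share the seed, hence the genome, promoter layout, and
    fragment draws; the mutant differs only in the silenced promoter classes.
    """
    wt = simulate(SimConfig(preset="crp_activating", n_promoters=n, seed=seed,
                            with_sequence=False))
    mut = simulate(SimConfig(preset=mutant, n_promoters=n, seed=seed,
                             with_sequence=False))
    peaks_wt = peaks.call_peaks(wt.track)
    peaks_mut = peaks.call_peaks(mut.track)
    cmp = peak_set_overlap(peaks_wt, peaks_mut)
    return {
        "n_wt": cmp.n_a,
        "n_mutant": cmp.n_b,
        "n_shared": cmp.n_shared,
        "retained_fraction": cmp.retained_fraction,
    }


def full_report(seed: int, n_sigma: int = 500, n_crp: int = 500,
                n_repressor: int = 300) -> dict:
    """The eight headline summary numbers across the four preset analyses."""
    sig = sigma70_recovery(seed, n=n_sigma)
    crp = crp_recovery(seed, n=n_crp)
    rep = repressor_recovery(seed, n=n_repressor)
    mut = mutant_retention(seed, n=n_crp)
    return {
        "template_argmax": sig["template_argmax"],
        "median_center_offset": sig["median_center_offset"],
        "nontemplate_core_fraction_pct": sig["core_fraction_pct"],
        "nontemplate_upstream_mode_offset": sig["upstream_mode_offset"],
        "nontemplate_downstream_mode_offset": sig["downstream_mode_offset"],
        "crp_template_downstream_pct": crp["template_downstream_pct"],
        "crp_upstream_site_mode": crp["upstream_site_mode"],
        "repressor_median_pair_distance": rep["median_pair_distance"],
        "ar1ar2_retained_fraction": mut["retained_fraction"],
    }
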