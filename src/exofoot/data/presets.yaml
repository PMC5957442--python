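# Footprint geometries and run-level presets for the synthetic ChIP-exo
# generator.  All calibrated numeric defaults live here, versioned as data.
#
# Mixture components are [weight, mean_bp, sd_bp, [span_lo, span_hi]] in
# TSS-relative offsets; draws are rounded to integer bp and truncated to the
# component span.  tags_per_promoter is [mean, dispersion] of a negative
# binomial fragment count (variance = mean + dispersion * mean^2);
# dispersion <= 0 means a deterministic count.  motif_protection, when set,
# overrides the mixtures: the protected interval is exactly
# [offset - half_width, offset + half_width].

models:
  # Housekeeping sigma-factor geometry: upstream (nontemplate) boundary is a
  # three-state mixture over the -35-proximal, core-promoter, and
  # post-TSS modes; downstream (template) boundary sits at +20 (open
  # complex / initial transcribing complex / early elongation).
  sigma70:
    u_mixture:
      - [0.20, -28, 2.5, [-36, -20]]
      - [0.62, -10, 4.0, [-22, -2]]
      - [0.18, 6, 2.0, [3, 12]]
    d_mixture:
      - [1.0, 20, 7.0, [6, 34]]
    tags_per_promoter: [60, 0.3]
    jitter_sd: 2.0
    background_fraction: 0.10

  # RNAP-co-complex geometry used for activator-bound (Class I/II) promoters;
  # identical upstream structure to sigma70 with a tighter +20 downstream
  # boundary (see docs/methods.md on calibration).
  crp_rnap:
    u_mixture:
      - [0.20, -28, 2.5, [-36, -20]]
      - [0.62, -10, 4.0, [-22, -2]]
      - [0.18, 6, 2.0, [3, 12]]
    d_mixture:
      - [1.0, 20, 3.0, [11, 29]]
    tags_per_promoter: [60, 0.3]
    jitter_sd: 2.0
    background_fraction: 0.10

  # Motif-bound protection at the downstream (-61.5) Crp site of Class III
  # promoters: interval [-76.5, -46.5], i.e. u = -76, width 30.
  crp_motif:
    motif_protection: [-61.5, 15]
    tags_per_promoter: [60, 0.3]
    jitter_sd: 2.0
    background_fraction: 0.10

  # Rifampicin arrests initiation at the ITC: downstream boundary cannot
  # advance past +25.
  rifampicin:
    u_mixture:
      - [0.20, -28, 2.5, [-36, -20]]
      - [0.62, -10, 4.0, [-22, -2]]
      - [0.18, 6, 2.0, [3, 12]]
    d_mixture:
      - [1.0, 20, 4.0, [8, 25]]
    tags_per_promoter: [60, 0.3]
    jitter_sd: 2.0
    background_fraction: 0.10

  # TSS-occluding repressor: exact 30-bp motif-centered protection, sharp
  # boundaries.
  repressor:
    motif_protection: [0.0, 15]
    tags_per_promoter: [60, 0.3]
    jitter_sd: 1.0
    background_fraction: 0.10

  # Promoters whose signal a perturbation removed: background only.
  silenced:
    tags_per_promoter: [0, 0.3]
    jitter_sd: 2.0
    background_fraction: 1.0

# Footprint-geometry aliases so that every named condition resolves to a
# model in the registry.
aliases:
  crp_activating: crp_rnap
  crp_repressing: crp_motif
  fnr: crp_rnap
  ar1: crp_rnap
  ar2: crp_rnap
  ar1ar2: crp_rnap

# Run-level presets: promoter class composition, which geometry each class
# uses, which 22-bp sites are embedded in the genome (TSS-relative centers;
# half-integer because the site length is even), and which fraction of each
# class a perturbation silences.
presets:
  sigma70:
    composition: {sigma70: 1.0}
    models: {sigma70: sigma70}
    sites: {}

  crp_activating:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: crp_rnap
      crp_classII: crp_rnap
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]

  fnr:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: crp_rnap
      crp_classII: crp_rnap
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]

  # Repressing carbon source: the RNAP-co-complex signal is gone and only the
  # motif-bound subset remains.
  crp_repressing:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: crp_rnap
      crp_classII: crp_rnap
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]
    drop: {crp_classI: 1.0, crp_classII: 1.0}

  rifampicin:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: rifampicin
      crp_classII: rifampicin
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]

  repressor:
    composition: {repressor: 1.0}
    models: {repressor: repressor}
    sites: {}

  # Activating-region mutants: silence the configured fraction of Class I/II
  # RNAP-co-complex promoters; Class III motif-bound signal is untouched.
  # The double mutant silences 82.2% of Class I+II, i.e. 60% of all
  # promoters, leaving 40% of wild-type peaks.
  ar1:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: crp_rnap
      crp_classII: crp_rnap
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]
    drop: {crp_classI: 0.822, crp_classII: 0.25}

  ar2:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: crp_rnap
      crp_classII: crp_rnap
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]
    drop: {crp_classI: 0.25, crp_classII: 0.822}

  ar1ar2:
    composition: {crp_classI: 0.40, crp_classII: 0.33, crp_classIII: 0.27}
    models:
      crp_classI: crp_rnap
      crp_classII: crp_rnap
      crp_classIII: crp_motif
    sites:
      crp_classI: [-61.5]
      crp_classII: [-41.5]
      crp_classIII: [-93.5, -61.5]
    drop: {crp_classI: 0.822, crp_classII: 0.822}

# Consensus sigma70 promoter elements embedded (with per-base substitution
# noise) in simulated promoter sequence: element -> [sequence, start_offset].
sigma_elements:
  minus35: [TTGACA, -36]
  extended_minus10: [TGCTATAAT, -14]
element_noise: 0.15
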