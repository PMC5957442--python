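# Methods

## Coordinate conventions

Genomic coordinates are 0-based with half-open intervals (BED-compatible).
TSS-relative offsets are signed base pairs along the direction of
transcription; offset 0 **is** the TSS base (some promoter-biology
conventions omit a zero position — landmarks such as −28, +6, +20 are used
here unchanged, with the convention that −1 and +1 are adjacent to 0). For
a `+` promoter, genomic position = `tss + offset`; for a `-` promoter,
`tss − offset`.

## The generative model

Each immunoprecipitated fragment is a duplex interval protected from
lambda-exonuclease digestion. Because the enzyme degrades each strand
5'→3', the surviving 5' ends are: one **forward-strand** tag at the *left*
genomic edge of the protection and one **reverse-strand** tag at the
*right* edge. Mapped through the promoter orientation, the oriented
nontemplate-strand tag sits at the upstream boundary `u` and the oriented
template-strand tag at the downstream boundary `d`. The test suite checks
this mapping exhaustively against a literal per-base digestion simulator.

Per promoter, the generator:

1. draws a fragment count from a negative binomial with mean 60 and
   dispersion 0.3 (variance = μ + 0.3 μ²), emulating the broad per-site
   occupancy spread of ChIP enrichment;
2. draws `(u, d)` per fragment from the factor's **footprint model** —
   either truncated-normal mixtures over initiation-intermediate
   geometries, or an exact motif-centered interval
   `[offset − half_width, offset + half_width]` for motif-bound factors
   (resampled within a bounded retry budget until `u < d`, with component
   truncation by resampling then clipping);
3. adds integer-rounded Gaussian jitter (default sd 2 bp) independently to
   each tag, representing crosslink/digestion heterogeneity without heavy
   tails. Jitter is drawn in offset space and then mapped through the
   strand transform, which makes the generator exactly equivariant under
   genome mirroring (reverse-complementing the coordinate system with
   flipped promoter strands mirrors the track draw-for-draw);
4. reroutes each fragment to background with probability
   `background_fraction` (default 0.10): its two tags land at uniform
   positions on uniform strands. Rerouting at fragment level keeps total
   tag count equal to twice the fragment count, keeps forward and reverse
   *signal* totals exactly equal, and makes `background_fraction = 1` the
   pure-noise limit used for knocked-out-factor controls.

Randomness is hierarchical: one run seed spawns per-promoter substreams
keyed by promoter index, so extending a simulation never reshuffles
existing promoters; a separate `replicate` index re-randomizes only tag
noise (jitter, background routing) while keeping fragments fixed — the
construction used for replicate-correlation analyses.

Promoters are placed in equal slots with random within-slot positions
(pairwise distance ≥ `min_spacing`, default 1000 bp), strands split half
and half. Genome sequence is uniform ACGT; promoter positions receive
consensus −35 (`TTGACA`) and extended −10 (`TGnTATAAT`) elements with 15%
per-base substitution noise, and Crp-class promoters receive 22-bp sites
sampled column-wise from the packaged Crp PWM, centered at the class
offsets −61.5 (Class I), −41.5 (Class II), and −93.5 plus −61.5
(Class III, two-site architecture). Half-integer centers are exact because
the site length is even.

## Calibration of the presets

All numeric defaults live in `src/exofoot/data/presets.yaml`. They were
calibrated by Monte Carlo (n = 500 promoters, many seeds) so that the
pipeline's own estimators recover the published summary statistics, and
then frozen:

* **sigma70** — upstream mixture 0.20/0.62/0.18 at means −28/−10/+6
  (sd 2.5/4/2, spans [−36,−20]/[−22,−2]/[3,12]); downstream single
  component at +20 (sd 7, span [6,34]). This yields a template maximum at
  +20, ~29% of combined window density on the nontemplate strand in
  [−18,−1], upstream/downstream modes at −28/+6 with ~10%/~9% shares, and
  a median peak-center offset of +5. The gap between the core span end
  (−2) and the downstream span start (+3) is what keeps the −10 and +6
  modes valley-separated at the default detection settings; with
  overlapping spans the +6 mode merges into the core mode on a minority of
  seeds.
* **crp_rnap** (Class I/II activator co-complex) — same upstream structure;
  downstream component sd tightened to 3 (span [11,29]) so that, with 27%
  of promoters motif-bound (below), the template fraction over [13,27]
  lands at 33% and the upstream nontemplate fraction over [−94,−61] at
  13%. The sd-7 sigma70 geometry under the same mixture would give ~24%
  downstream — the tighter boundary is a deliberate calibration to the
  published Crp fractions, not a measured physical difference.
* **crp_motif** (Class III) — exact protection of the downstream (−61.5)
  Crp site with half-width 15, i.e. boundaries (−76, −46); its upstream
  tags are what populate the −94…−61 nontemplate band.
* **repressor** — motif-centered protection at the TSS (offset 0,
  half-width 15), jitter sd 1: every fragment has width 30, so the median
  peak-pair distance is 30 bp.
* **rifampicin** — crp_rnap with the downstream span capped at +25 (the
  arrested initially-transcribing complex cannot advance further).
* **ar1/ar2/ar1ar2** — activating-region mutants silence a configured
  fraction of Class I/II promoters (the silenced model emits no
  fragments); Class III motif-bound promoters are untouched. The double
  mutant silences 82.2% of Class I+II — 60% of all promoters under the
  0.40/0.33/0.27 composition — so the expected wild-type peak retention is
  0.40.

`background_fraction = 0.10` is a calibration knob, not a measured
quantity: the noise composition of real ChIP-exo libraries is not pinned
down by the published summaries.

## Analysis choices

* **Peak calling** is intentionally simple (this package's contribution is
  the downstream profiling, not event detection): Gaussian smoothing of
  the combined strands (sd 3 bp), runs above a height threshold, gap
  merging (< 50 bp), short-region filtering (< 10 bp). The default
  threshold of 0.7 smoothed tags balances two measured failure modes: at
  1.0, ~10% of promoters (the low tail of the negative binomial) are
  missed; at 0.5, uniform background at the default density produces
  spurious regions on a third of seeds. At 0.7, ≥ 95% of promoters yield
  exactly one region within ±40 bp of the TSS and background-only runs
  yield none. Per-strand maxima are always computed on **unsmoothed**
  counts (smoothing shifts boundary estimates); ties break toward the
  region midpoint, then leftmost. The region center is the strand-maxima
  midpoint, halves rounded toward the reverse maximum.
* **Aggregation** normalizes each 400-bp window (`[−200, +200)`) to unit
  combined sum before averaging, so high-coverage promoters do not
  dominate; `raw_mean` is available. Density fractions use the **combined**
  two-strand window total as denominator — the published per-strand
  percentages (30% template; 28+9+8% nontemplate) only coexist under a
  common denominator.
* **Mode detection** smooths the chosen strand (sd 2 bp), finds local
  maxima, and merges a pair whenever the deepest valley between them
  exceeds half the lower maximum; spans run valley-to-valley (outermost
  spans to the window edge, or to the boundary with a sub-threshold
  stray maximum), fractions and peak offsets come from the unsmoothed
  density, and modes under 2% of the denominator are dropped. Peak-offset
  ties prefer the smallest |offset|, then the negative one.
* **Median center offset** uses the lower central value for even counts,
  preserving integers.
* **PWM scoring** is log₂-odds against a uniform 0.25 background with
  pseudocount 0.5. The packaged Crp model is a palindromic 22-mer
  (TGTGA-N6-TCACA core at 0.91 consensus frequency, AAA/TTT flanks at
  0.55, near-uniform spacer). The default scan threshold of 8 bits retains
  ~93% of PWM-sampled sites while uniform background crosses it ~1.5×10⁻⁴
  of the time per window and strand (~45 in-histogram false hits per
  0.5-Mb genome, spread over 300 bins). The provenance of the published
  predicted-site track is unstated; the packaged model is this package's
  own site definition and users can substitute their own PWM file.
* **Comparisons**: overlay correlations are Pearson on concatenated raw
  template+nontemplate window counts (flat windows flagged, not
  correlated); track correlation bins 100 bp per strand and concatenates
  strands, zero-count bins included; peak-set retention uses greedy
  one-to-one nearest-center matching within 50 bp, relative to the first
  set. With the default ±2 bp tag jitter, per-base overlay correlations
  between replicates center near 0.66 even though the underlying
  fragments are identical; the binned genome-wide statistic is the robust
  replicate-quality measure.

## What the synthetic recoveries show — and what they do not

Passing recoveries demonstrate that the estimators are unbiased and
well-calibrated *under the generative model*: boundary mixtures plus
integer jitter, uniform background, independent promoters, no sequence
bias. Real libraries add PCR duplicates, mappability structure, copy-number
and Shine-Dalgarno-like sequence composition effects, overlapping
promoters, and condition-dependent occupancy — none of which are modeled.
The generator works at the 5'-tag level; read simulation, alignment, and
peak-caller idiosyncrasies are out of scope, as are eukaryotic features.
Group-specific promoter-element conservation differences are not modeled
(elements are embedded with uniform noise), so element PWMs built from
simulated groups differ only by sampling noise. Published statistics that
depend on the actual sequencing libraries (e.g. the identity of the 699
classified promoters, absolute genome-wide peak counts) are not
reproducible at this scale and are not targeted.

## Problem sizes and runtime

Default analyses use 500 promoters (sigma-70, Crp, mutants) and 300
(repressor) on ~0.3–0.5-Mb genomes — roughly one tag-dense promoter per
kilobase, ~120 tags per promoter. The full report runs in a few seconds on
one CPU; the exhaustive boundary-digestion check (~10,000 boundary pairs on
both strands) takes a few seconds more.
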