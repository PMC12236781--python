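# Methods

## Scope and model

`supersil` identifies super-silencers (SSs) from repressive-mark
(H3K27me3) data and characterizes them against typical silencers (TSs) and
against the enhancer-side analogues (SE/TE from H3K27ac). The pipeline has
two modeling assumptions at its core:

1. **Silencer evidence is local and thresholdable.** Candidate silencers
   live inside repressive-mark peaks, carry open-chromatin or TF-binding
   evidence, and can be ranked by a scalar score per 1 kb window. The scorer
   is a pluggable contract — any deterministic callable from a window
   interval to a finite score. The packaged `SignalMeanScorer` (mean mark
   signal under the window) is the default used on synthetic data; a
   sequence-based classifier's precomputed scores can be supplied through
   `TableScorer` instead. The cutoff *t*<sub>s</sub> is calibrated as the
   (1 − FPR) empirical quantile of background-window scores — the smallest
   background score with at least that fraction of the background at or
   below it. The 9:1 background:candidate ratio describes the composition of
   the calibration set, not the quantile itself, and is carried as metadata.

2. **"Super" is a property of the rank–signal curve, not a fixed quantile.**
   After stitching (gap ≤ stitch distance) and summing member signal areas,
   regions are sorted ascending; ranks and signals are min–max scaled to
   [0, 1] and the cutoff index is the last minimizer of
   (scaled signal − scaled rank). This is the point where a unit-slope line
   touches the curve from below: equivalently, the smallest index whose
   unit-slope line leaves every later point strictly above it. Ties are
   resolved with a 1e-12 tolerance so an exactly linear curve returns the
   last rank (no supers) instead of an arbitrary rounding-dependent index.
   Degenerate all-equal signal vectors place the cutoff at that value, and
   because the super rule is *strictly above*, they yield zero super
   regions. Equality between the vectorized implementation and an
   exhaustive per-index tangent check is asserted on 1,000 random vectors
   in the acceptance suite.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| screening window / step | 1,000 / 100 | bp | evidence is scored on fixed 1 kb sequences |
| FPR for *t*<sub>s</sub> | 0.1 | — | calibration target on background windows |
| stitch distance | 12,500 | bp | rank-ordering convention for clustering elements |
| promoter flank | 2,000 | bp | TSS ± flank defines a promoter (configurable; no canonical value exists) |
| variant flank | 50,000 | bp | the "by" zone of the in/by/outside partition, boundary inclusive |
| LD threshold | r² > 0.8 | — | strict inequality; linked SNPs inherit the trait |
| CGI overlap | > 200 | bp | strict; split overlaps accumulate after merging CGIs |
| TAD flank / shore | ≤ 20k / 20–50k | bp | distances to the nearest boundary midpoint; both upper edges inclusive |
| contact bins / min span | 10,000 / 80,000 | bp | contacts are binned anchor pairs; shorter spans rejected at read time |
| conversion recurrence | > n/2 samples | — | strict majority of cancer samples |
| expression pseudocount | 1.0 | expr. units | fold changes on linear scale, zeros well-defined |

Other conventions: coordinates are 0-based half-open everywhere internally
(1-based table/interval inputs convert at the reader); chromosome names are
normalized to the `chr` prefix; strand is ignored for regulatory elements;
book-ended intervals merge; element score after merging is the maximum
member-window score (strongest local evidence); peaks shorter than the
window are skipped unless `score_short_peaks` treats the whole peak as one
window; elements are assigned to TAD segments by their midpoints.

Choices made where the design was genuinely open:

- **Activity encoding of the neither-mark case is 0.** Only three of the
  four cases have a defined value (+1 active-only, −1 repressive-only,
  0 both); "neither" carries no evidence either way.
- **All-zero activity rows yield a missing cooperativity**, not 0 — the
  cosine is undefined and a fake "uncorrelated" value would bias background
  means toward zero. Missing pairs are excluded from aggregates.
- **Distance matching** uses two-octave log₂ bins from 1 kb to 1 Mb
  (open-ended below/above). A bin the typical-element pool cannot fill is
  dropped from both the background and the foreground, so the compared sets
  always have identical per-bin distance histograms; the drop is surfaced
  as a warning.
- **Multi-binding TF fraction** uses all profiled TFs as denominator
  (exposed, so the bound-in-region denominator is one argument away).
- **Nearest gene** = minimal |element midpoint − TSS|, ties to the smaller
  gene id for determinism. "Locus" = gene body ± 50 kb.
- **Breakpoint class labels** resolve in > by, then
  SS > SE > TS > TE > none.
- **Conversion detection is region-level** (any ≥ 1 bp overlap between a
  source element and an opposite-sign cancer super region), with the
  overlap threshold exposed.
- **Repression models are continuous signatures, not hard labels**: flank
  contact density (condensation, model I) and promoter enhancer-contact
  counts (shielding, model II) are reported per subclass; no per-element
  model assignment is made.
- **Binomial tests are two-sided by default**; directional variants are an
  argument. Rank-sum and t-tests come from scipy.

## The synthetic epigenome

The generator (`supersil.simulate`) plants a complete input set on a
2 × 20 Mb genome and records every planted object exactly, so downstream
stages can be scored against ground truth. What it emulates:

- **Elements.** 20 SS and 20 SE clusters of 5 components (~1.5 kb each;
  regular clusters place one component per 10 kb bin so each component owns
  its contact anchor bin; shore-resident clusters are compact, 6 kb pitch,
  so all components fit a 30 kb shore), plus 150 TS and 150 TE placed in
  loose groups of three with 15–28 kb gaps (typical elements do cluster at
  this scale, and the groups give the background pool pairs at the same
  distances as super-cluster component pairs), plus 300 low-signal decoy
  peaks that calibrate the screening threshold and contribute realistic
  false positives at the configured FPR.
- **Signal.** Log-normal mark signal (heavy right tail), class means
  16 vs 2 track units (super vs typical; ratio 8, log-sd 0.25) and 0.5 for
  decoys — super and typical score distributions are separated by several
  standard deviations, the regime the screening recovery guarantee assumes.
- **Activity across 12 cell types.** Cluster-level latent states copied by
  members with probability 0.8, independent draws otherwise — planting the
  within-region activity correlation the cooperativity stage measures.
- **CGIs, methylation.** 27% of SS components overlap an 800 bp CGI; SS
  components are hypomethylated (mean 0.10 vs 0.45).
- **TADs.** Boundaries every ~2 Mb (jittered); each SS cluster is placed on
  a shore with probability 0.10; per-component shore flags are recomputed
  from the realized geometry.
- **Variants.** Per-kb B-cell-cancer SNV rates proportional to the
  class profile 0.50 : 0.38 : 0.33 : 0.81 (SS : TS : TE : SE) with a
  background of 0.29, all scaled ×20 — on a 40 Mb genome the unscaled
  genome-wide densities would leave class ratios inside Poisson noise, so
  rates are scaled to reach the counting regime while preserving every
  ratio, which is what the analyses measure. Recurrence (≥ 2 donors) is
  planted per class (3.5% in SS); translocation breakpoints concentrate in
  shore-resident SS components (48%) with super-enhancer partners in 26% of
  cases; GWAS SNPs are SS-enriched with planted replication fractions and
  LD blocks.
- **Conversions.** 13% of SS components (and 5% of SE components, the
  reverse direction) become opposite-sign cancer super regions, detected
  independently per sample with probability 0.6 across 6 samples — so the
  recurrent fraction among detected conversions has the closed-form
  expectation P(X > S/2 | X ≥ 1), X ~ Binomial(S, q), which the acceptance
  suite checks.
- **Contacts.** Poisson per-element contact counts (CGI SS components get
  2× the mean), flank contacts depleted ×0.15 around non-CGI SS components
  (condensation signature), promoters of SS-target genes shielded from
  enhancer-anchored contacts (shielding signature), and a cancer contact
  set that drops 91% of conversion-anchored contacts vs 20% elsewhere.
  Distal partner anchors avoid element neighborhoods and flank anchors
  avoid element-occupied bins, so per-element counts equal the planted
  draws rather than being blurred by incidental hits.

What it does **not** emulate — and hence what green tests do not show about
real data: no sequence content (the deep-learning scorer is out of scope by
design; screening is validated with the signal-mean scorer), no read-level
noise or peak-calling artifacts, no copy-number structure or mutation
signatures, no distance-decay in Hi-C contact probability, no LD structure
beyond pairwise blocks, and element classes that are cleanly separated by
construction. Passing recovery tests certify the pipeline's logic under the
planted statistical structure, not discovery power on noisy genomes.

Determinism: one seed; each output family draws from its own substream
(`default_rng([seed, crc32(role)])`), so regenerating one file family never
shifts another, and full regeneration is byte-identical (tested).

## Problem sizes

The default synthetic epigenome (2 × 20 Mb, 500 planted elements, ~5,000
windows screened, ~30,000 contacts, ~11,000 SNVs) runs the full pipeline in
a few seconds; the whole test suite takes well under a minute, and
`scripts/acceptance.py` regenerates and re-measures everything in under a
minute on one CPU. These sizes were chosen so the class-level statistics
(density ratios, rank-sum comparisons, binomial recovery checks) sit
comfortably inside their error bands while iteration stays interactive.

## Known limitations

- The screening guarantee (precision/recall ≥ 0.9) holds when class score
  distributions are separated by ≥ 3 SD; with overlapping distributions the
  FPR calibration still holds marginally but per-element calls degrade.
- Contact-based measures treat contacts as unweighted pairs at 10 kb bin
  resolution; confidence values are carried but not used in densities.
- The flank contact density of clustered components includes the sibling
  components' own anchors (they sit inside the ±50 kb window); comparisons
  across subclasses remain valid because the geometry is shared, but
  absolute flank densities are not comparable between clustered and
  isolated element classes.
- `tau` shifts negative (log-scale) inputs by the minimum before scoring;
  mixing linear and log expression across analyses is the caller's
  responsibility.
- The LD expansion is single-hop (SNPs linked to a catalog SNP), not the
  transitive closure of LD blocks.
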