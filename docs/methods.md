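# Methods

## Scope and data model

`ampcnv` screens dual-gene targeted-amplicon panels for copy-number
variants from three independent dosage readouts and integrates them:

1. **Fragment analysis (FA)** — capillary-electrophoresis peak heights
   of the multiplexed library, compared against a confirmed
   copy-number-normal (TN-CNV) reference profile.
2. **Read counts (RC)** — per-amplicon sequencing counts, screened
   against run-level statistics.
3. **Dosage assays (MAQ/MLPA)** — orthogonal probe-based quantification
   against dedicated reference probes and control samples.

A panel (`PanelDesign`) is a set of plexes, each containing amplicons of
both gene labels. The bundled default describes a 93-amplicon, 5-plex
BRCA1/BRCA2 layout (plex sizes 17/20/19/18/19; BRCA1 41 amplicons,
BRCA2 52). Its expected fragment sizes and genomic intervals are
synthetic placeholders laid out to be physically plausible (sizes
150–530 bp inside the 600-bp ladder range, within-plex spacing 20 bp);
real kits are described by the same YAML schema.

**Coordinate convention.** Intervals are 1-based and
`genomic_span = end − start` (not `end − start + 1`), matching the
arithmetic of clinical LGR reports of the form "a deletion of N bp from
chrN:start to chrN:end". BED export converts to 0-based half-open.

## Fragment-analysis calibration

Traces are intensity-vs-scan arrays with a sample channel and a
size-standard channel (default: the 36-fragment LIZ-600 ladder).

- **Peak detection**: local maxima of a centered moving average
  (default window 5 scans, plateau ties to the leftmost scan) above a
  minimum height (default 50 fluorescence units). Heights are read from
  the *raw* signal at the detected scan so smoothing cannot bias
  downstream ratios. Height, not area, is the carried statistic.
- **Ladder identification**: the *n* tallest peaks (n = ladder size)
  ordered by position, paired 1:1 with the ascending known sizes. This
  is deterministic and adequate for clean standards; quality is gated
  downstream.
- **Calibration**: ordinary least squares `bp = slope·scan + intercept`
  (degree 1 only). The fit is rejected when r² < 0.99 — a mis-identified
  ladder produces a visibly non-linear relation. Calibration is
  affine-equivariant: rescaling scan positions rescales the slope
  reciprocally and leaves predicted bp unchanged.
- **Assignment**: each plex amplicon is greedily matched to the nearest
  unassigned peak within 2.0 bp (candidates sorted by distance; exact
  ties to the smaller expected size). 2.0 bp is half the minimum design
  spacing of typical multiplex layouts (≥ 4 bp); designs violating that
  spacing trigger a warning. Unmatched amplicons are MISSING, unmatched
  peaks reported as unexpected.

## Cross-gene normalization and the identifiability limit

For a sample peak set and the TN-CNV reference, anchoring on gene *g*:

    scale   = median over amplicons a of gene g of (ref_height_a / sample_height_a)
    ratio_a = scale · sample_height_a / ref_height_a        (all amplicons)

The **median** (not mean) anchor is robust to a minority of CNV-affected
amplicons inside the anchor gene, which is what keeps partial events
(< half of the gene's amplicons per plex) unambiguous. Both anchors are
always computed. Ratios are gated against the closed interval
[0.7, 1.3] — the dosage-assay normal range reused for FA ratios, since
heterozygous events sit near 0.5/1.5 and well clear of realistic
multiplicative noise (≈5%).

The construction is scale-invariant (any per-sample multiplicative
factor cancels) and therefore carries a built-in degeneracy: a uniform
ratio *r* on all of gene 2 under the gene-1 anchor is algebraically
identical to a uniform 1/*r* on gene 1 under the gene-2 anchor. Whole
deletions of one gene and whole duplications of the other are
*indistinguishable* inside the panel. This limit is surfaced explicitly
by the caller rather than papered over.

The TN-CNV reference is a single confirmed-normal profile by default;
pooling several negatives by per-amplicon median is supported
(`ReferenceProfile.from_pool`).

Plot output is a static sample-vs-reference overlay on a common bp axis
(sample red, reference blue, out-of-range amplicons starred) plus the
resampled aligned curve table; no interactive controls.

## Read-count screening

Counts are summarized as **within-plex frequencies**
(count / plex total per sample), which removes per-plex loading and
library-size effects. Per amplicon, the run's samples give a mean and
empirical sd; the CI99% band is `mean ± 2.576·sd`. The band is
run-empirical by construction — it plays the role of the historical
validation intervals a production lab would maintain. Screening a
sample that belongs to the run uses a leave-one-out baseline (≥ 3
baseline samples required) so an aberrant sample cannot widen its own
band.

Within-plex frequencies are compositional: a CNV shifts *every other*
amplicon's frequency in its plex. `flag_rc_outliers` therefore offers
per-plex **median recentering** of the sample's frequency-to-baseline
ratios (the same anchor logic as the FA stage) before comparison; the
pipeline uses it. When the affected amplicons are the plex majority the
anchor lands on them and the *unaffected* gene flags instead — either
way exactly one gene's pattern surfaces, which is all the caller needs.
The raw absolute comparison remains available (no `panel` argument).

The **global gene ratio** is, per plex, Σ(gene-1 counts)/Σ(gene-2
counts), averaged unweighted over plexes (a pooled-counts variant is
available). Each sample is gated against the mean ± 2 sd of the other
samples' global ratios. Under the bundled calibration the diploid
cohort centers on 0.7; halving gene-2 counts doubles every per-plex
ratio, hence a case value near 1.4.

## Evidence integration and calling

Per amplicon the caller sees a triple: the FA flag under the *other*
gene's anchor (`fa_cross`, sensitive to whole-gene events), the FA flag
under its *own* gene's anchor (`fa_same`, sensitive only to partial
events), and the RC flag. The integration table is explicit versioned
data (v1), exportable/loadable as JSON so laboratories can tune it. The
default is conservative:

| fa_cross | fa_same  | rc             | call    |
|----------|----------|----------------|---------|
| LOW      | LOW      | not HIGH       | LOSS    |
| LOW      | IN_RANGE | LOW or MISSING | LOSS    |
| HIGH     | HIGH     | not LOW        | GAIN    |
| HIGH     | IN_RANGE | HIGH or MISSING| GAIN    |
| IN_RANGE | IN_RANGE | IN_CI or MISSING| NEUTRAL|
| any FA MISSING, mixed LOW/HIGH, or other conflicts | | | NO_CALL |

Rationale: two agreeing FA normalizations are sufficient on their own
(RC corroborates but is not required — FA alone carries partial events),
while the whole-gene-shaped pattern (cross flagged, same quiet) demands
RC support or its absence, because it is exactly the pattern the
degeneracy produces. RC MISSING means "no sequencing evidence", never
contradiction.

Gene-level lifting (`detect_ambiguity`): a full-gene LOSS pattern on one
gene and/or a full-gene GAIN pattern on the other emits
`WHOLE_GENE_AMBIGUITY` carrying both rival hypotheses and a
recommendation mandating MLPA/MAQ. A one-sided full-gene pattern is
*also* treated as ambiguous — the mirror hypothesis is implied by the
normalization algebra even when the partner gene's calls were blocked
(e.g. by RC anchoring) — which preserves the invariant that **no code
path yields a whole-gene final call without dosage evidence**. The
full-gene patterns tolerate up to 10% NO_CALL amplicons (dropout
robustness). Proper subsets yield unambiguous PARTIAL events.

`resolve_with_dosage` is the only constructor of whole-gene final
calls: it selects the hypothesis consistent with the classified dosage
per-gene summary, stays UNRESOLVED (both hypotheses retained) when
dosage contradicts both, and never re-weights intra-panel evidence.

## Dosage quotients

MAQ and MLPA share one computation; only probe panels differ. With
reference probes REF and control samples c:

    v(s, p) = height(s, p) / median over r∈REF of height(s, r)
    DQ(p)   = v(test, p) / median over c of v(c, p)

Median at both stages (a `center=np.mean` switch mimics mean-based
software). DQ is invariant to per-sample scaling and equals CN/2 under
the proportional model; an absent target peak in the test sample is a
homozygous deletion (DQ 0), not an error. Reference probes must be
present and positive in every sample. Classification against the closed
normal range [0.7, 1.3]: DELETED / NORMAL / DUPLICATED, with per-gene
summaries (WHOLE_LOSS when *all* of a gene's probes are DELETED, etc.).
The bundled MAQ-style (36 targets + 6 reference probes) and MLPA-style
(51 per-exon targets + 10 reference probes) panels are synthetic
layouts mirroring typical kit sizes.

## Synthetic data generator

All generators share the copy-number model
`signal ∝ efficiency · CN/2` with multiplicative lognormal noise:

- **efficiency spread** (default 0.25 in the CLI presets): per-amplicon
  lognormal sd of amplification efficiency, drawn *once per cohort* —
  efficiency is a property of the amplicon chemistry, so it is shared
  across the samples of a run (making CI99 statistics meaningful) and,
  critically, between a sample and its TN-CNV reference trace
  (`gen_fa_case`); without that sharing, reference normalization would
  be meaningless, as it is in reality.
- **sample noise sd** (default 0.05): per-observation lognormal noise —
  the ≈5% multiplicative scatter typical of amplification/injection.
- All generators require an explicit integer seed and record it in
  their outputs; fixed seeds reproduce outputs exactly.

Counts: per-amplicon diploid expectations are `depth·efficiency`
quantized to even integers, so noiseless CN=1 counts are exactly half
their diploid values; an optional calibration rescales gene-1
efficiencies per plex so the diploid global gene ratio equals a target
(0.7 in the presets). Default depth 1000 reads/amplicon and cohorts of
8–12 samples keep simulations representative of a small bench-top run
while fast. Traces: one Gaussian peak per amplicon (σ = 3 scans)
through a known affine scan model chosen so integer-bp sizes land on
integer scans — the noiseless chain is exactly invertible, which the
oracle tests exploit. Dosage runs: diploid controls plus one test
sample under the same model.

Not emulated: read-level errors, PCR stutter, heteroduplexes, dye
pull-up, GC trends, FFPE degradation, tumor fraction. Passing tests
therefore demonstrate the *algorithmic* correctness and the
identifiability behavior of the workflow, not robustness to every
artifact of real instruments.

## Numerical choices and degenerate inputs

- Gate and CI comparisons use closed intervals (boundary values pass).
- All-zero/flat traces detect no peaks (empty result, not an error);
  fewer ladder peaks than standard fragments, r² below threshold, < 2
  distinct scan positions, missing normalization anchors, zero plex
  totals and zero gene sums raise typed errors naming the offender.
- Greedy assignment ties break to the smaller expected size;
  peak-detection plateau ties to the leftmost scan.
- CI99 uses the normal z = 2.576 on the sample sd (ddof = 1).

## Known limitations

- The whole-gene rule's 10% NO_CALL tolerance and the 0.7–1.3 FA gate
  are policy defaults, exposed in configuration, not estimated from
  data.
- Mosaic/partial-tumor fractions (non-half-integer dosages) are out of
  scope; classification assumes germline integer copy numbers.
- The RC stage assumes counts produced upstream; no FASTQ/BAM handling.
- Breakpoint estimation is not attempted; calls are per-amplicon/exon.
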