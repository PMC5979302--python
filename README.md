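# ampcnv

CNV screening toolkit for **dual-gene targeted-amplicon panels** —
fragment-analysis calibration and cross-gene normalization, read-count
CI99% statistics, an ambiguity-aware integrated CNV caller, and MAQ/MLPA
dosage-quotient computation.

## The problem

Clinical BRCA1/BRCA2 screening panels amplify both genes in a handful of
multiplex PCR reactions ("plexes"). Small variants are called from the
reads, but **large genomic rearrangements (LGRs)** — whole-exon or
whole-gene deletions/duplications — only show up as *dosage* changes in
peak heights (capillary-electrophoresis fragment analysis, FA) and
read counts (RC). Because an amplicon panel carries no absolute
copy-number anchor, dosage must be inferred by **intra-sample cross-gene
normalization**: each gene serves as the reference for the other,
against a "true-negative" (TN-CNV) profile previously confirmed
copy-number-normal.

That construction has a hard identifiability limit. For a sample with
peak-height ratios $h_a$ against the reference, anchoring on gene 1 with
the median scale

$$s = \operatorname{median}_{a \in G_1}\left(\frac{h^{\text{ref}}_a}{h^{\text{sample}}_a}\right),
\qquad r_a = s \cdot \frac{h^{\text{sample}}_a}{h^{\text{ref}}_a},$$

a **whole deletion of gene 2** (all $r_{G_2} \approx 0.5$) produces
*exactly* the same evidence as a **whole duplication of gene 1**
($r_{G_1} \approx 2$ under the gene-2 anchor). Partial events — a
minority of one gene's amplicons — are unambiguous, because the median
anchor of the affected gene still holds. `ampcnv` makes this degeneracy a
first-class verdict (`WHOLE_GENE_AMBIGUITY`) and refuses to resolve it
from intra-panel evidence; resolution requires an orthogonal dosage
assay (MAQ or MLPA), via the doubly normalized **dosage quotient**

$$\mathrm{DQ}(p) = \frac{v(\text{test}, p)}{\operatorname{median}_c\, v(c, p)},
\qquad v(s,p) = \frac{h(s,p)}{\operatorname{median}_{r \in \text{REF}} h(s,r)},$$

which equals CN/2 for diploid controls: ≈1.0 normal, ≈0.5 heterozygous
deletion, ≈1.5 heterozygous duplication (normal range 0.7–1.3).

## Worked example

The bundled synthetic generators reproduce the hardest case — a
germline whole-gene-2 deletion — end to end:

```bash
ampcnv simulate --preset whole-gene2-del --seed 7 --out run/sim
ampcnv fa-qc  --traces run/sim/traces     --out run/fa
ampcnv rc-qc  --counts run/sim/counts.tsv --sample CASE --out run/rc
ampcnv call   --fa run/fa/fa_report.json --rc run/rc/rc_flags.json --out run/call
ampcnv dosage --probes maq --peaks run/sim/maq_peaks.tsv --out run/dos
ampcnv report --verdict run/call/verdict.json --dosage run/dos/dosage.json \
              --out run/final.json
```

`run/call/verdict.txt` reads:

```
ampcnv 0.1.0 CNV verdict
gene level: BRCA2=WHOLE_LOSS, BRCA1=WHOLE_GAIN
ambiguity: WHOLE_GENE_AMBIGUITY
Whole-gene copy-number ambiguity: intra-panel evidence cannot distinguish the rival hypotheses. Orthogonal dosage testing (MLPA/MAQ) is REQUIRED before reporting.
```

i.e. from FA+RC evidence alone the sample looks *simultaneously* like a
whole BRCA2 deletion and a whole BRCA1 duplication — the rc-qc report
shows the case's global BRCA1/BRCA2 count ratio at **1.399** against a
cohort at 0.7, twice normal, which is consistent with *either*
hypothesis. The MAQ dosage step then measures DQ 0.48–0.57 on every
BRCA2 probe (all < 0.7 ⇒ DELETED) with BRCA1 normal, and the final
report prints:

```
final call: RESOLVED BRCA2=WHOLE_LOSS, BRCA1=NEUTRAL
```

The same flow with `--preset exon-5-7-del` yields an unambiguous
`PARTIAL_LOSS` on BRCA1 (amplicons D_9, D_10, C_6) without needing the
dosage route, and `--preset normal` flags nothing.

The library is usable without the CLI; every stage is a plain function
(`ampcnv.fragtrace.calibrate_trace`, `ampcnv.fa_cnv.analyze_fa`,
`ampcnv.rc_cnv.run_ci99`, `ampcnv.caller.detect_ambiguity`,
`ampcnv.dosage.compute_dq`, …) over documented dataclasses.

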