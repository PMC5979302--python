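# Synthetic MAQ-style probe panel (targets for both genes + reference
# amplicons); layout is a placeholder, not a commercial kit table.
name: maq-default
gene_labels:
- BRCA1
- BRCA2
probes:
- id: MAQ_B1_1
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex1
  expected_length_bp: 130
- id: MAQ_B1_2
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex2
  expected_length_bp: 140
- id: MAQ_B1_3
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex3
  expected_length_bp: 150
- id: MAQ_B1_4
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex4
  expected_length_bp: 160
- id: MAQ_B1_5
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex5
  expected_length_bp: 170
- id: MAQ_B1_6
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex6
  expected_length_bp: 180
- id: MAQ_B1_7
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex7
  expected_length_bp: 190
- id: MAQ_B1_8
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex8
  expected_length_bp: 200
- id: MAQ_B1_9
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex9
  expected_length_bp: 210
- id: MAQ_B1_10
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex10
  expected_length_bp: 220
- id: MAQ_B1_11
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex11
  expected_length_bp: 230
- id: MAQ_B1_12
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex12
  expected_length_bp: 240
- id: MAQ_B1_13
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex13
  expected_length_bp: 250
- id: MAQ_B1_14
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex14
  expected_length_bp: 260
- id: MAQ_B1_15
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex15
  expected_length_bp: 270
- id: MAQ_B1_16
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex16
  expected_length_bp: 280
- id: MAQ_B2_1
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex1
  expected_length_bp: 310
- id: MAQ_B2_2
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex2
  expected_length_bp: 320
- id: MAQ_B2_3
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex3
  expected_length_bp: 330
- id: MAQ_B2_4
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex4
  expected_length_bp: 340
- id: MAQ_B2_5
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex5
  expected_length_bp: 350
- id: MAQ_B2_6
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex6
  expected_length_bp: 360
- id: MAQ_B2_7
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex7
  expected_length_bp: 370
- id: MAQ_B2_8
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex8
  expected_length_bp: 380
- id: MAQ_B2_9
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex9
  expected_length_bp: 390
- id: MAQ_B2_10
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex10
  expected_length_bp: 400
- id: MAQ_B2_11
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex11
  expected_length_bp: 410
- id: MAQ_B2_12
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex12
  expected_length_bp: 420
- id: MAQ_B2_13
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex13
  expected_length_bp: 430
- id: MAQ_B2_14
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex14
  expected_length_bp: 440
- id: MAQ_B2_15
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex15
  expected_length_bp: 450
- id: MAQ_B2_16
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex16
  expected_length_bp: 460
- id: MAQ_B2_17
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex17
  expected_length_bp: 470
- id: MAQ_B2_18
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex18
  expected_length_bp: 480
- id: MAQ_B2_19
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex19
  expected_length_bp: 490
- id: MAQ_B2_20
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex20
  expected_length_bp: 500
- id: MAQ_REF_1
  role: REFERENCE
  expected_length_bp: 522
- id: MAQ_REF_2
  role: REFERENCE
  expected_length_bp: 534
- id: MAQ_REF_3
  role: REFERENCE
  expected_length_bp: 546
- id: MAQ_REF_4
  role: REFERENCE
  expected_length_bp: 558
- id: MAQ_REF_5
  role: REFERENCE
  expected_length_bp: 570
- id: MAQ_REF_6
  role: REFERENCE
  expected_length_bp: 582
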