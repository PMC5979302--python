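# Synthetic MLPA-style probe panel (per-exon probes for both genes +
# reference probes); layout is a placeholder, not a commercial kit table.
name: mlpa-default
gene_labels:
- BRCA1
- BRCA2
probes:
- id: MLPA_B1_ex1
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex1
  expected_length_bp: 137
- id: MLPA_B1_ex2
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex2
  expected_length_bp: 146
- id: MLPA_B1_ex3
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex3
  expected_length_bp: 155
- id: MLPA_B1_ex4
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex4
  expected_length_bp: 164
- id: MLPA_B1_ex5
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex5
  expected_length_bp: 173
- id: MLPA_B1_ex6
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex6
  expected_length_bp: 182
- id: MLPA_B1_ex7
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex7
  expected_length_bp: 191
- id: MLPA_B1_ex8
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex8
  expected_length_bp: 200
- id: MLPA_B1_ex9
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex9
  expected_length_bp: 209
- id: MLPA_B1_ex10
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex10
  expected_length_bp: 218
- id: MLPA_B1_ex11
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex11
  expected_length_bp: 227
- id: MLPA_B1_ex12
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex12
  expected_length_bp: 236
- id: MLPA_B1_ex13
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex13
  expected_length_bp: 245
- id: MLPA_B1_ex14
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex14
  expected_length_bp: 254
- id: MLPA_B1_ex15
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex15
  expected_length_bp: 263
- id: MLPA_B1_ex16
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex16
  expected_length_bp: 272
- id: MLPA_B1_ex17
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex17
  expected_length_bp: 281
- id: MLPA_B1_ex18
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex18
  expected_length_bp: 290
- id: MLPA_B1_ex19
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex19
  expected_length_bp: 299
- id: MLPA_B1_ex20
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex20
  expected_length_bp: 308
- id: MLPA_B1_ex21
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex21
  expected_length_bp: 317
- id: MLPA_B1_ex22
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex22
  expected_length_bp: 326
- id: MLPA_B1_ex23
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex23
  expected_length_bp: 335
- id: MLPA_B1_ex24
  role: TARGET
  gene: BRCA1
  exon_label: BRCA1 ex24
  expected_length_bp: 344
- id: MLPA_B2_ex1
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex1
  expected_length_bp: 362
- id: MLPA_B2_ex2
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex2
  expected_length_bp: 369
- id: MLPA_B2_ex3
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex3
  expected_length_bp: 376
- id: MLPA_B2_ex4
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex4
  expected_length_bp: 383
- id: MLPA_B2_ex5
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex5
  expected_length_bp: 390
- id: MLPA_B2_ex6
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex6
  expected_length_bp: 397
- id: MLPA_B2_ex7
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex7
  expected_length_bp: 404
- id: MLPA_B2_ex8
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex8
  expected_length_bp: 411
- id: MLPA_B2_ex9
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex9
  expected_length_bp: 418
- id: MLPA_B2_ex10
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex10
  expected_length_bp: 425
- id: MLPA_B2_ex11
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex11
  expected_length_bp: 432
- id: MLPA_B2_ex12
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex12
  expected_length_bp: 439
- id: MLPA_B2_ex13
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex13
  expected_length_bp: 446
- id: MLPA_B2_ex14
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex14
  expected_length_bp: 453
- id: MLPA_B2_ex15
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex15
  expected_length_bp: 460
- id: MLPA_B2_ex16
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex16
  expected_length_bp: 467
- id: MLPA_B2_ex17
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex17
  expected_length_bp: 474
- id: MLPA_B2_ex18
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex18
  expected_length_bp: 481
- id: MLPA_B2_ex19
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex19
  expected_length_bp: 488
- id: MLPA_B2_ex20
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex20
  expected_length_bp: 495
- id: MLPA_B2_ex21
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex21
  expected_length_bp: 502
- id: MLPA_B2_ex22
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex22
  expected_length_bp: 509
- id: MLPA_B2_ex23
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex23
  expected_length_bp: 516
- id: MLPA_B2_ex24
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex24
  expected_length_bp: 523
- id: MLPA_B2_ex25
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex25
  expected_length_bp: 530
- id: MLPA_B2_ex26
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex26
  expected_length_bp: 537
- id: MLPA_B2_ex27
  role: TARGET
  gene: BRCA2
  exon_label: BRCA2 ex27
  expected_length_bp: 544
- id: MLPA_REF_1
  role: REFERENCE
  expected_length_bp: 551
- id: MLPA_REF_2
  role: REFERENCE
  expected_length_bp: 556
- id: MLPA_REF_3
  role: REFERENCE
  expected_length_bp: 561
- id: MLPA_REF_4
  role: REFERENCE
  expected_length_bp: 566
- id: MLPA_REF_5
  role: REFERENCE
  expected_length_bp: 571
- id: MLPA_REF_6
  role: REFERENCE
  expected_length_bp: 576
- id: MLPA_REF_7
  role: REFERENCE
  expected_length_bp: 581
- id: MLPA_REF_8
  role: REFERENCE
  expected_length_bp: 586
- id: MLPA_REF_9
  role: REFERENCE
  expected_length_bp: 591
- id: MLPA_REF_10
  role: REFERENCE
  expected_length_bp: 596
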