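# eep-mpra

Analysis pipeline for **three-way combinatorial reporter assays** that place a
promoter together with *two* candidate enhancers on one episomal reporter
(enhancer–enhancer–promoter, "EEP", combinations). Libraries of this design
ask two questions that single-enhancer MPRAs cannot: *how do two enhancers
combine their signals* (additively? multiplicatively? synergistically?), and
*how does the promoter transform the combined signal*?

The package takes the three tables such an experiment produces after barcode
clustering — a fragment catalog, a barcode→insert assignment table, and
per-replicate cDNA/pDNA barcode counts — and carries them through to the
assay's standard readouts. It also ships a fully parameterised simulator that
generates the same tables from known ground truth, so every stage can be
validated end to end.

## The quantities computed

With `A` the activity of a combination (normalised cDNA:pDNA ratio, averaged
over ≥5 barcodes per replicate and geometric-mean combined across replicates):

* **Baseline** `A_CCP = median{A_C1C2P, …}` over a promoter's
  control–control combinations.
* **Boost index** `log2(A / A_CCP)` — the enhancer effect in doublings.
* **Single-enhancer estimates** `A_E1CP`, `A_CE2P` — median activity across
  all combinations of an enhancer with scrambled controls at position 1 or 2.
* **Expectation models** for an enhancer pair, in linear activity space:

  ```
  expected_additive        = A_E1CP + A_CE2P − A_CCP
  expected_multiplicative  = A_E1CP · A_CE2P / A_CCP
  sd_additive              = sqrt(sd_E1² + sd_E2² + sd_CC²)
  ```

  A pair is **supra-additive** when observed > expected_additive + 1 SD,
  **sub-additive** below −1 SD, near-additive otherwise.
* **Promoter selectivity** — Welch's heteroscedastic one-way F-test across a
  single enhancer's per-promoter boost populations (Shapiro–Wilk screened,
  BH-FDR corrected).
* **Promoter scaling** — per-promoter OLS slope of observed boost indices
  against the cross-promoter average boost, over enhancer pairs shared by all
  libraries. Slopes ≠ 1 reveal non-linear (power-law-like) signal
  integration; the slope–baseline correlation tests whether weak promoters
  respond more steeply.

## Worked example

Simulate a full-scale assay (8 promoter libraries × 79 fragments × 79
fragments, 10 barcodes per combination, 3 replicates) and run every stage:

```bash
eep all --outdir demo_run --seed 1
```

```
pipeline complete -> demo_run ({'activities': 49928, 'baselines': 8,
'boosts': 49928, 'singles': 944, 'activation': 472, 'expectations': 27848,
'fractions': 9, 'preference': 9, 'enhancer_summary': 472, 'selectivity': 59,
'scaling_fits': 8}); slopes 0.52-1.43
```

The run covers all 8 × 79 × 79 = 49,928 combinations and classifies the
27,848 enhancer-pair records. Two of the output tables
(`demo_run/additivity_fractions.tsv`, `demo_run/scaling_fits.tsv`):

```
promoter     n  pct_supra  pct_sub  pct_within_1sd  pct_within_2sd
     P01  3481        9.1      9.6            81.3            98.9
     ...
  pooled 27848       13.7     13.1            73.2            96.3

promoter  slope  intercept  pearson_r  n_combinations  baseline
     P01  0.517     -0.258      0.980            1770     0.751
     P08  1.432      0.665      0.995            1770     0.155
```

Read: the simulated ground truth here is *exactly additive*, and indeed 73%
of enhancer-pair activities fall within one propagated SD of the additive
expectation (96% within two) — deviations are measurement noise. The scaling
fits show the structural flip side of linear-space additivity: on a weak
promoter the same enhancer pair produces a larger *fold*-change, so in
log–log space the weakest promoter (P08, baseline 0.155) responds ~2.8× more
steeply than the strongest (P01), even though every promoter integrates
signals linearly.

Each stage is also available separately (`eep simulate`, `eep quantify`,
`eep boost`, `eep additivity`, `eep selectivity`, `eep scaling`) over flat
TSV files, so real count tables in the same format drop straight in — see
`eep <stage> --help`.

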