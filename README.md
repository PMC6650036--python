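# refstab

Reference-gene stability validation for longitudinal RT-qPCR studies.

Relative quantification (2^-ΔΔCt) stands or falls with the reference genes
used for normalization, and in longitudinal designs — developmental time
courses, disease progression, treatment kinetics — classical "housekeeping"
genes often drift with time. Worse, the popular validation statistics
disagree with each other in predictable ways: methods built on *pairwise*
expression agreement (GeNorm, pairwise ΔCt) reward co-regulated genes even
when both drift strongly, and model-based ranking (NormFinder) is perturbed
by the presence of highly variable genes in the panel. `refstab` implements
the four standard estimators plus an integrated workflow that plays them to
their strengths, for researchers validating reference genes from Cq data.

## What it computes

For a complete gene × sample matrix of mean Cq values with a group label per
sample (lower score = more stable throughout):

- **CV analysis** — `CV% = 100·SD(2^-Cq)/mean(2^-Cq)` pooled across all
  samples; absolute overall variation, independent of the other genes.
- **GeNorm** — stability `M`: the mean SD of a gene's log2 expression ratios
  to every partner gene, with stepwise elimination of the worst gene down to
  a final pair that shares one `M`.
- **NormFinder** — model-based stability `S`: per-group intergroup deviation
  `d_ig` and bias-corrected intragroup variance `σ̂²_ig` after removing
  per-sample loadings, with empirical-Bayes shrinkage of `d`;
  `S_i = mean_g(|d̃_ig| + SE)`. Also returns the best two-gene combination
  and its grouped stability.
- **Pairwise ΔCt** — mean over partner genes of `SD(Cq_i − Cq_k)`.
- **Integrated workflow** — linearize → CV screen (exclude CV > 50 %) →
  fold-change profiles with per-gene one-way ANOVA → NormFinder on the
  survivors → best pair → per-sample normalization factor
  `NF = 2^(−mean Cq of pair)` → 2^-ΔΔCt normalization of target genes.

Supporting QC: technical-replicate collapse with an SD ≤ 0.25-cycle
consistency rule (single-outlier removal, logged), amplification-efficiency
fits from dilution series (`E = 10^(−1/slope)`, gates 1.93–2.05 and
R² ≥ 0.98), Pearson correlation of linearized quantities, and a BestKeeper
style SD-of-Cq screen for comparison reports. A synthetic-data generator
simulates longitudinal panels with known ground truth (group drifts,
co-regulated blocks, technical replicates) for closed-loop testing.

See `docs/methods.md` for formulas, assumptions and design choices.

## Worked example

Simulate a developmental panel (4 timepoints, 23 samples, 10 candidate
genes + 1 induced target, 3 technical replicates) and run the workflow:

```bash
$ refstab simulate --preset developmental --seed 42 --out demo.csv
wrote demo.csv (759 replicate rows)

$ refstab run --input demo.csv --calibrator P5 --ignore-genes MyelinT \
      --audit --out demo_report
excluded: ['GlycoG', 'GlycoH', 'TbpI']
best pair: ActB + RibC (grouped stability = 0.11)
report written to demo_report

$ cat demo_report/normfinder.tsv
gene	score	rank
RefA	0.11	1
RefB	0.18	2
RibC	0.21	3
ActB	0.22	4
ChapD	0.3	5
MitoF	0.32	6
RibE	0.35	7
```

Reading this: the three genes sharing a strongly drifting co-regulation
block (`GlycoG`, `GlycoH`, `TbpI`) exceed the 50 % CV screen and are
excluded before model-based ranking. NormFinder ranks the designed-stable
`RefA` first (S = 0.11). The best *pair* is `ActB + RibC` rather than
`RefA + RefB`: the pair criterion rewards two genes whose small intergroup
deviations point in opposite directions, so their average is flatter than
either stable gene alone — the intended behaviour of the combination rule
(see `docs/methods.md`). The grouped stability 0.11 is the pair's value of
the same criterion.

Normalizing the target against the selected pair:

```bash
$ refstab normalize --input demo.csv --calibrator P5 --target MyelinT \
      --pair ActB,RibC | head -8
sample group  fold_change
 P5_s1    P5     0.609611
 P5_s2    P5     0.964330
 P5_s3    P5     0.756240
 P5_s4    P5     1.003753
 P5_s5    P5     1.666065
P10_s1   P10     9.377888
P10_s2   P10    23.168003
```

The calibrator group's folds average to 1 by construction; the target's
strong induction after P5 is visible immediately.

The same operations are available as a library (`refstab.cv_analysis`,
`refstab.genorm`, `refstab.normfinder`, `refstab.pairwise_dct`,
`refstab.integrated_workflow`, ...) on a `CqMatrix`, and accept long CSV/TSV
(sample, group, gene, cq), wide CSV, or XLSX input with a configurable
column mapping.

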