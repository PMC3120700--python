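# hmboost

Predicting tissue/cell-type-specific vs housekeeping genes from histone
modification/variant (HMV) profiles.

Tissue/cell-type-specific regulation (TCSR) — the restriction of a gene's
expression to particular tissues or cell types — leaves a chromatin
signature: the levels of histone marks such as H3K4me3, H3K27ac and
H3K79me3 around the promoter and across the gene body differ between
specifically expressed genes and broadly expressed housekeeping genes.
`hmboost` implements the full analysis pipeline that exploits this
signature, for computational epigenomics researchers who want to train,
dissect and transfer such classifiers:

1. **Gene-set calling by expression entropy.** For relative expression
   *p<sub>t</sub>* of a gene across *T* tissues, the overall entropy is
   *H* = −Σ<sub>t</sub> *p<sub>t</sub>* log₂ *p<sub>t</sub>* and the
   categorical entropy for tissue *t* is
   *Q<sub>t</sub>* = *H* − log₂ *p<sub>t</sub>*. Specific genes satisfy
   *H* < 5 and *Q<sub>target</sub>* < 9 bits (a *z*-score mode is also
   provided); housekeeping genes must exceed overall-entropy floors in two
   independent expression datasets (6.2 and 8.9 bits).
2. **Nucleosome-anchored feature tables.** The promoter is a fixed grid of
   26 TSS-relative nucleosome intervals (−6…+20; the −2…+5 intervals use
   published nucleosome positions, e.g. +1 = [−45, 134]; outer intervals
   extend in 150-bp steps). A mark's level on a nucleosome is its tag
   count in that interval. Gene-body tables hold sums and per-bp averages
   over the first exon, first intron and whole body, plus a summed count
   over twenty 150-bp windows after the first exon. Control tables repeat
   the promoter featurization 50 kb upstream of each TSS.
3. **PCA mark grouping.** Marks are partitioned into Set I (highest
   contributions to the first four principal components of the ±2 kb TSS
   tag matrix) and Set II (the rest).
4. **Boosting with stumps.** A discrete AdaBoost classifier over one-split
   decision trees, with per-round bookkeeping so that the "top predictive
   feature" (the first-round stump) can be counted across replicates.
5. **Evaluation.** Sensitivity, PPV and F-score under stratified 5-fold
   cross-validation, repeated over balanced resampling replicates (each
   drawing as many housekeeping genes as there are specific genes), and
   compared against control-region classifiers by two-sided Wilcoxon
   rank-sum. Cross-cell-type transfer, TSS-jitter (low-resolution promoter)
   and mark-redundancy experiments reuse the same machinery.

Because the real CD4⁺ T-cell / ENCODE inputs are large external downloads,
the package ships a synthetic-data generator that emulates their
statistical structure (entropy-separable expression classes, negative-
binomial tag tracks with planted class-differential (mark, region) pairs),
so every stage runs end-to-end out of the box.

## Worked example

```sh
hmboost simulate --out bundle --seed 1 --n-specific 60 --n-housekeeping 90
hmboost specificity --bundle bundle --out sets.tsv
hmboost featurize --bundle bundle --region promoter --out promoter.tsv
hmboost group --bundle bundle --out partition.json
hmboost evaluate --bundle bundle --region promoter --labels sets.tsv \
    --replicates 10 --rounds 40 --seed 1 --out report.json
hmboost report --evaluation report.json
```

prints

```
bundle written to bundle
60 specific, 90 housekeeping
150 genes x 312 features
Set I: H2A.Z,H3K27ac,H3K27me3,H3K36me3,H3K4me1,H3K4me3,H3K79me2,H3K79me3,H3K9ac,H3K9me1,H4K20me1
mean F = 0.994 (control p = 0.000157)
region: promoter
 sensitivity: 0.988 +/- 0.008
         ppv: 1.000 +/- 0.000
      fscore: 0.994 +/- 0.004
vs control: p = 0.000157 [*]
  top feature H3K27ac:+1: 10/10 replicates
```

Reading the output: the entropy thresholds recover exactly the 60 planted
specific and 90 planted housekeeping genes; the promoter table has
12 marks × 26 nucleosomes = 312 features; the boosting classifier separates
the classes almost perfectly (mean F = 0.994 ± 0.004 across 10 balanced
replicates) while the same classifier trained on control regions 50 kb
upstream stays at chance, a difference significant by rank-sum; and the
planted informative mark/nucleosome H3K27ac:+1 is the top selected feature
in every replicate. The same stages are available as library functions
(`hmboost.specificity`, `hmboost.features`, `hmboost.boost`,
`hmboost.evaluation`, `hmboost.transfer`, `hmboost.simulate`).

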