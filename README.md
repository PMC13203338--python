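# rfi-coexnet

Residual-feed-intake phenotyping and weighted gene co-expression network
analysis for feed-efficiency transcriptomics.

Feed accounts for roughly half of the production cost in shrimp
aquaculture, and replacing fishmeal with plant protein makes the
*efficiency* with which an animal converts feed into growth a direct
breeding target. This package implements, as a tested and reusable
pipeline, the analysis chain used to connect that phenotype to candidate
genes in species such as *Penaeus vannamei*:

1. **Phenotypes.** From individually-housed feeding records (initial and
   harvest body weight `W1`, `W2`; feed bookkeeping `F1`, `Fr`, `F0`;
   trial duration) it computes average daily gain
   `ADG = (W2 − W1)/t`, daily feed intake `DFI = (F1 − Fr − F0)/t`,
   fits the nonlinear expected-intake model

   ```
   DFI = b1 · MW^b2 + b3 · ADG,     MW = (W1 + W2)/2
   ```

   by least squares (`MW^b2` is the metabolic mid-weight), and derives
   each animal's **residual feed intake** `RFI = DFI − expected DFI`.
   Negative RFI = eats less than predicted for its size and growth =
   more feed-efficient.
2. **Co-expression network, from scratch.** Gene filtering
   (mean TPM > 3, detection rate > 60 %, CV > 0.2), Pearson gene–gene
   correlation, a soft-threshold scan against the scale-free topology
   fit index, adjacency `a_ij = |cor_ij|^β`, the topological overlap
   matrix `TOM_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij)`,
   average-linkage clustering on `1 − TOM`, a height-sweep tree cut with
   minimum module size 50, module eigengenes (first principal component
   of each module), and merging of modules whose eigengenes are closer
   than 0.15.
3. **Trait modules and hubs.** Eigengene–RFI Pearson correlation with
   Student-t p-values; modules with |r| > 0.4 and p < 0.05 are
   trait-specific; within them, genes are ranked by intramodular
   connectivity (summed adjacency to same-module genes) and the top five
   annotated genes become hub candidates.
4. **Validation.** On an independent extreme-group cohort (30 highest-
   vs 30 lowest-RFI animals), each hub gene is compared with a
   Shapiro–Wilk/Levene-gated test (t-test when both gates pass,
   Mann–Whitney U otherwise), fold changes are `log2(mean_low/mean_high)`,
   p-values are Benjamini–Hochberg adjusted within the panel, and
   validated genes (q < 0.1) are correlated with ADG to separate
   efficiency-specific genes from general growth genes.

Because studies of this design rarely deposit raw data, the package
ships a first-class synthetic-data module (`rfi_coexnet.synthetic`) that
generates feeding trials, planted-module expression matrices and
validation cohorts with known ground truth, so every stage is testable
end to end.

## Worked example

`examples/01_phenotypes.py` simulates a 468-animal, 42-day trial and
recovers the phenotypes:

```
fitted coefficients: b1=0.0526  b2=0.7261  b3=1.1909
  (generating values: b1=0.05, b2=0.75, b3=1.2)
ADG range: 0.019 to 0.210 g/day
RFI range: -0.068 to 0.058 g/day, sd 0.0209
cor(estimated RFI, true RFI) = 0.966
extreme groups (k=30): high-efficiency mean RFI -0.0425, low-efficiency mean RFI 0.0395
```

The fitted coefficients sit near the generating values (they are
estimated from noisy intake), the estimated RFI tracks the planted
individual deviations at r ≈ 0.97, and the extreme groups bracket zero.
The remaining examples walk the other capabilities: network and module
detection (`02`), trait-specific modules and hub screening (`03`), and
gated two-group validation (`04`). A thin CLI mirrors the stages
(`rfi-coexnet simulate|phenotype|network|module-trait|hubs|validate|run-all`).

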