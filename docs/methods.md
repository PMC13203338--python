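# Methods

This note documents the models, defaults and numerical choices behind
`rfi_coexnet`, and what the synthetic-data generators do and do not
emulate.

## Residual feed intake

Each animal is housed and fed individually, so its phenotypes come
straight from bookkeeping: `ADG = (W2 − W1)/t` (g/day),
`DFI = (F1 − Fr − F0)/t` (g/day), mid-weight `MW = (W1 + W2)/2` (g),
with trial duration `t` in days (default 42). Expected intake is the
allometric partition of energy into maintenance and growth,

```
E[DFI] = b1 · MW^b2 + b3 · ADG
```

and `RFI = DFI − E[DFI]`. The sign convention is the field's: negative
RFI means the animal eats less than predicted, i.e. is more efficient.
Only survivors enter the fit (dead or moulting animals are removed from
the trial and their records are flagged).

**Fitting.** The model is linear in `(b1, b3)` given `b2`, so the fit
uses variable projection: for each `b2` the inner pair is solved by
ordinary least squares and the one-dimensional profiled RSS is minimised
over `b2 ∈ [0.05, 3]` with a bounded Brent search started near the
standard metabolic exponent 0.75, followed by a localised polish pass
(tolerance 1e-10 on the parameter). This is deterministic, requires no
starting guess for `b1, b3`, and its accepted-iteration RSS trace is
monotone non-increasing by construction. A fit whose `b2` lands outside
(0.3, 1.2) is reported with a warning — such exponents usually indicate
a degenerate design rather than biology. Non-convergence raises; RFI is
never computed from a non-converged fit. On zero-noise simulated trials
(n = 200) the coefficients are recovered to ~1e-11 relative error; the
package's tests assert 1e-4.

**Extreme groups.** The k lowest-RFI animals form the high-efficiency
group and the k highest the low-efficiency group; boundary ties are
broken lexicographically by individual id so selection is deterministic.

## Expression handling

TPM conversion follows the two-step definition (per-sample
length-normalised rates rescaled to 1e6), so columns sum to 1e6 exactly.
The gene filter keeps genes with mean TPM > 3 AND detection rate > 0.6
AND coefficient of variation > 0.2, all strict inequalities, so boundary
genes are removed. CV uses the sample (n−1) standard deviation — a
convention choice, documented because either is defensible. Zero-mean
genes fail the mean criterion before CV is evaluated. Filtering is
idempotent and each gene's fate depends only on its own row.

## Network construction

* **Correlation**: Pearson on raw TPM by default. A `log_transform`
  flag (log2(TPM+1)) is provided; which scale is "right" depends on the
  data's dynamic range and is recorded in the run report.
* **Network type**: unsigned by default, `a_ij = |cor_ij|^β`; signed
  (`((1+cor)/2)^β`) available via `NetworkParams`.
* **Soft-threshold scan**: per power, connectivity `k_i = Σ_j a_ij`
  (self-edges excluded) is binned into 10 equal-width bins and
  log10(mean frequency) is regressed on log10(mean k); the scale-free
  fit index is R² signed by −sign(slope). The recommended power is the
  smallest with index ≥ 0.8. When no power reaches 0.8 the curve is
  taken to have reached its stable level at the first power where the
  gain over the next power drops below 0.02 while the index is already
  ≥ 0.5; chasing the global argmax instead would push the power so high
  that the topological overlap collapses toward zero and module
  detection starves. Mean connectivity is strictly decreasing in β, a
  tested invariant.
* **TOM**: unsigned topological overlap,
  `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
  `l_ij = Σ_{u≠i,j} a_iu a_uj`, diagonal 1. The vectorised computation
  is tested against a brute-force triple loop to < 1e-12 on matrices up
  to 20 genes.
* **Clustering and tree cut**: average linkage on `1 − TOM`. The cut is
  a height sweep — candidate heights at the 99th down to the 50th
  percentile of the merge heights, plus an absolute ceiling of 0.99
  which is always a candidate and always an upper bound. The cut
  producing the most clusters of at least `min_module_size` (default
  50) genes wins; ties go to the highest cut, which keeps modules
  maximal. The ceiling is what rejects unstructured data: at the powers
  the scan recommends, a pure-noise TOM is numerically ~0, its entire
  dendrogram sits above 0.99, and no admissible cut yields any cluster —
  everything stays grey. Genes in undersized clusters are labelled grey,
  then one reassignment round attaches a grey gene to its nearest module
  when its mean TOM to that module exceeds the module's median
  intra-module TOM. This simplified cut is deliberately not the
  published dynamic-hybrid algorithm; it is validated by
  planted-structure recovery (adjusted Rand index ≥ 0.99 against planted
  labels over 10 seeds at the default settings) rather than
  label-for-label agreement with any reference implementation. Detected
  modules err on the side of recall: a module may absorb a minority of
  background genes that happen to co-cluster, which leaves eigengenes
  and trait correlations essentially unaffected.
* **Naming**: modules are renamed after every detection/merge step by
  descending size over a fixed 40-colour list (turquoise, blue, brown,
  …), so "turquoise" is always the largest module and runs are
  reproducible. Grey is reserved for unassigned genes.
* **Eigengenes**: member genes are standardised across samples; the
  eigengene is the first left singular vector of the samples × genes
  block, rescaled to unit sample variance and oriented to correlate
  non-negatively with the module's mean standardised profile (fallbacks:
  the first member gene, then a fixed sign rule, so orientation is
  always deterministic, even for pathological antagonistic modules).
  Variance explained is the first squared singular value over the total.
* **Merging**: iteratively, modules whose eigengene dissimilarity
  `1 − cor(ME_a, ME_b)` clusters below 0.15 (average linkage) are
  merged and eigengenes recomputed, until stable. Grey never merges.

Matrices are held in memory as dense gene × gene arrays; at the desk
scales this package targets (≤ ~12k genes) this needs at most a few GiB
and no blockwise processing.

## Module–trait association and hubs

Eigengene–trait association uses the sample Pearson correlation with the
two-sided Student-t p-value (`t = r·sqrt((n−2)/(1−r²))` on n−2 df;
|r| = 1 reports the smallest positive float). A module is trait-specific
when |r| > 0.4 AND p < 0.05 — the conjunction, with both thresholds
configurable. No multiple-testing correction is applied across modules
at this stage, matching common practice for module-level screening; the
validation stage carries the FDR control instead. Grey is excluded.

Intramodular connectivity is computed from the post-power adjacency (not
TOM): `k_within(g) = Σ_{j ∈ module(g), j≠g} a_gj`. It is invariant to
genes outside the module and scales linearly under adjacency scaling.
Because it is a sum, larger modules produce larger values; connectivity
is only compared within a module. Hub selection takes, per trait
module, the `top_n` (default 5) genes by `k_within` that carry a usable
functional annotation — a non-empty description not matching an
"uncharacterized"/"hypothetical" pattern list (configurable). Skipped
genes do not count against the five; ties break lexicographically.

## Validation statistics

Per gene, the test is gated: independent two-sample t-test (pooled
variance — legitimate because the variance gate has already passed) when
Shapiro–Wilk p > 0.05 in both groups and mean-centred Levene p > 0.05;
otherwise the two-sided Mann–Whitney U (exact for small untied samples,
normal approximation with tie and continuity correction otherwise, via
scipy). Under Gaussian equal-variance data the three gates pass jointly
about 0.95³ ≈ 86 % of the time — an inherent property of gate testing,
asserted in the tests. Fold change is `log2(mean_low/mean_high)` on
arithmetic group means; a non-positive mean yields NaN fold change but
the gene is still tested. BH adjustment is the step-up rule
`q_(i) = min_{j≥i} p_(j)·m/j` applied within the tested panel (the hub
panel, typically 20 genes), not transcriptome-wide, and significance is
q < 0.1. Validated genes are then correlated with ADG across all
individuals of both groups; p < 0.05 flags a gene as growth-correlated
rather than efficiency-specific.

## Synthetic data: what it emulates, and what it does not

`TrialSimConfig` defaults describe a 42-day trial of 468 individually
housed animals: initial weights uniform on 3–6 g, daily gains uniform on
0.019–0.210 g/day (the printed population range of the motivating
design), intake coefficients (b1, b2, b3) = (0.05, 0.75, 1.2), true RFI
~ N(0, 0.02 g/day) — which reproduces a population RFI range of about
±0.05 g/day — and 0.005 g/day intake measurement noise. Published work
of this design does not report variance components for RFI or intake, so
the two noise scales are chosen to reproduce the printed phenotype
ranges, not estimated from data. Feed bookkeeping fixes `F1` at 1.5×
expected total intake and draws `F0` as a uniform 0–5 % of intake; only
the combination `F1 − Fr − F0` matters downstream.

`ExpressionSimConfig` plants modules as latent factors: each module
eigengene mixes the standardised trait with orthogonalised noise at the
closed-form weight ρ, so the realised eigengene–trait correlation equals
the request exactly; member genes load on the eigengene with loadings
spanning 0.6–0.95, descending within the module so connectivity ranks
are non-degenerate; background genes are independent. Latent Gaussian
profiles become TPM-like values through a lognormal map (per-gene base
means lognormal around 50 TPM, log-sd 0.5 ⇒ CV ≈ 0.53), which keeps
values non-negative and right-skewed and passes the default filter for
all planted genes. The lognormal map attenuates Pearson correlations by
a known factor (≈ 0.94 at these settings for trait–gene pairs), so a
planted eigengene–trait correlation of 0.54 is observed at ≈ 0.50–0.52
after detection — by design, since real TPM would behave the same way.

`simulate_validation_cohort` draws per-sample values lognormal around
group means with a chosen coefficient of variation; `cv = 0` returns the
group means exactly, which is how the published fold-change worked
examples are reproduced.

What the generators do **not** emulate: count-level sampling noise and
library-size effects (expression is simulated at the TPM level),
sequencing batch effects, correlated background genes, family/pedigree
structure among animals, tank or temporal environmental effects, and
molting-related missingness beyond a Bernoulli survival flag. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
algorithms under the stated generative model, not robustness to every
artefact of real RNA-seq.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by choice:
networks of 200–600 genes × 50 samples (recovery over 10 seeds), trials
of 100–468 animals, validation panels of 20–2000 genes at n = 30/30.
These sizes keep the full suite around ten seconds while exercising
every code path; the algorithms themselves are vectorised and handle
the ~10k-gene scale of real tissues. All generators take a single
integer seed and derive per-stream substreams by fixed offsets;
identical config + seed gives byte-identical outputs.

## Known limitations

* The tree cut is a documented simplification; module boundaries will
  not match the published dynamic-hybrid algorithm label-for-label.
* Unsigned networks conflate positive and negative co-expression;
  signed networks are available but not the default.
* The scale-free fit index on small gene sets (a few hundred genes) is
  noisy; the plateau fallback makes power selection stable but the
  selected power can vary by ±2 across seeds.
* BH adjustment within a 20-gene panel controls FDR over that panel
  only; it says nothing transcriptome-wide.
* One printed worked example in the motivating literature
  (r = 0.54, n = 50 → p = 4.0e-5) is not reproducible from the rounded
  r: the exact formula gives 5.2e-5 for any r that rounds to 0.54. The
  package reports the exact value.
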