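# Methods

This note documents the statistical procedures implemented in `txconcord`,
the choices made where the design was genuinely open, and what validation on
synthetic data does and does not establish.

## Differential expression

**Model.** Per gene, counts follow a negative binomial with mean
`mu_ij = s_j * q_ij` and variance `mu + alpha * mu^2`; `log q_ij` is linear
in an intercept and a two-group indicator. Only two-group designs are
supported: multi-factor designs, continuous covariates and batch terms are
out of scope.

**Size factors.** The median-of-ratios estimator: for sample *j*, the median
over reference genes of `count_gj / geometric-mean_g`. Reference genes are
those with strictly positive counts in every sample; an optional
`pseudo_reference` mode takes geometric means over positive entries only,
for data where no gene is everywhere positive. The median is taken on the
ratio scale (linear interpolation of the middle pair for even counts), which
is what the brute-force definition produces; a log-scale median differs in
the fourth decimal for even reference sets and would fail exact-agreement
checks. Size factors enter the GLM as offsets, so only their ratios matter.

**Dispersions.** A deliberately simplified pipeline compared to full
Cox–Reid adjusted profile likelihood with outlier replacement:

1. *raw*: method-of-moments on size-factor-normalised counts with moments
   pooled within condition, `alpha_hat = max(0, (s2 - xi*mu) / mu^2)`, where
   `xi` is the mean reciprocal size factor (the Poisson part of a scaled
   count's variance);
2. *trend*: nonnegative least squares of `alpha_hat` against `a0 + a1/mu`
   on genes with positive raw estimates, with one trimming pass against
   gross outliers (ratio to trend outside `[1e-4, 15]`); falls back to a
   constant (median raw) when fewer than 10 genes are usable;
3. *final*: geometric interpolation between raw and trend in log space with
   weight 0.5 (configurable `shrink_weight`); raw values below the floor
   collapse to the trend. Everything is floored at `1e-8`.

The 50/50 log-space shrink balances the high variance of per-gene moment
estimates at n = 3–24 against trend bias; with it, the Wald test is
calibrated at the design sizes used here (global-null p < 0.05 fraction
0.050–0.055 at 12 vs 12, KS distance to uniform < 0.03 at 5000 genes).
Treating the shrunken dispersion as known makes the Wald test mildly
anticonservative, as with all plug-in NB tests; the measured mean
false-discovery proportion of DEG selection at `padj < 0.05` on
10%-non-null data is ~0.06.

**Fitting.** The per-gene GLM (log link, offsets, known dispersion) is fit
by IRLS with the 2×2 weighted normal equations solved in closed form,
vectorised across all genes simultaneously; linear predictors are clipped to
±30 to stabilise separated genes (a group of all zeros), which then yield
huge standard errors and p ≈ 1 rather than spurious significance. Genes not
converged after 60 iterations are flagged and their p set missing. Genes
with zero counts across all analysed samples are excluded before testing and
from the BH family. No independent filtering, no fold-change shrinkage, no
outlier replacement.

**DEG selection.** `padj < 0.05` and `|log2FC| >= 0.2` by default — the
deliberately permissive fold-change gate used when interrogating subtle
treatment effects, with significance still required. Both thresholds are
arguments everywhere they appear.

## Concordance classification

For each reference DEG and each model contrast: *absent* if the gene was not
tested in the model contrast; *unresolved* if it fails the model-side gates
(same two thresholds as DEG selection, overridable); otherwise *convergent*
or *divergent* by sign agreement of the log2FCs. The model-side significance
gate is a design decision — sign-only labelling would classify noise — and
can be loosened via the thresholds for sensitivity analysis.

Orientation safety: every contrast carries an orientation stamp
(`cond_b` over `cond_a`) plus an optional semantic `direction_label`
(e.g. `case_vs_control`). When reference and model labels are both set and
disagree, classification refuses to proceed without an explicit `flip`
argument; flipping negates model signs and provably swaps
convergent↔divergent while leaving unresolved/absent fixed.

Exclusion sets intersect labels across *all supplied* model contrasts (the
caller decides which contrasts constitute "all"); residual sets subtract
the union of both exclusion sets from each contrast's convergent and
divergent sets. `summarize` reports counts, fractions and a signed
concordance fraction `(conv - div) / (conv + div)`; no gene-level
concordance p-value or cross-contrast meta-analysis is attempted. Degenerate
empty reference sets yield `None` fractions, never NaN.

## Enrichment

**ORA.** Upper hypergeometric tail `P(X >= k)`, `X ~ Hypergeom(N, K, n)`.
The universe is the mapped, tested genes of the originating contrast — not
the genome — to avoid inflating enrichment with never-testable genes. BH
runs across sets with `K >= 1` and `k >= min_overlap` (default 1); sets
below the overlap floor are reported but kept out of the family. Retention
means `p_adjust < 0.05`.

**GSEA.** Running enrichment score: `+|metric|^w / sum_hits |metric|^w` at
set members, `-1/(N - |S|)` at non-members; ES is the running-sum value of
largest magnitude (first occurrence on exact ties; when the positive and
negative extrema tie in magnitude the sign is genuinely ambiguous and the
implementation keeps the first). Defaults: weight `w = 1`, `B = 1000`
permutations, gene-set permutation. Phenotype permutation (sample-label
reshuffling with signal-to-noise re-ranking of `log2(normalized + 1)`,
Broad-style sd floors) is available and requires at least 3 samples per
group, below which the call falls back to gene-set permutation with a
warning — the emulated study's n = 3–4 cohorts sit exactly at this boundary.
Whenever the number of distinct permutations (label splits, or same-size
subsets) is at most `B`, the null is enumerated exhaustively, making small
instances exact and reproducible. The permutation p is
`(1 + #extreme-same-side) / (#same-side + 1)`: the comparison restricted to
the same-sign side of the null, normalised by that side's size. Normalising
by `B + 1` instead would concentrate null p below 0.5 and double the false
positive rate; the implemented convention is uniform under the null
(measured 3–6% of null sets at p < 0.05) and respects the `1/(B+1)`
granularity floor. NES divides ES by the mean absolute same-sign null ES.

**Report tables.** Row z-scores use the sample standard deviation (ddof 1);
constant rows map to zeros with a warning. The lollipop table places
BH-retained pathways of the convergent query on the left and of the
divergent query on the right, sorted by `-log10 p_adjust` within side; a
pathway retained on both sides appears once per side. Plots are rendered
from the serialized TSVs only.

## Identifier handling

Mapping is a static two-column table lookup; no live annotation services,
alias resolution or orthology. One-to-many source ids are resolved by
policy: `drop_ambiguous` (default — silent first-match would bias
enrichment universes) or `first`. Many-to-one collisions are resolved by
`sum` (default; conserves total counts, the usual treatment of transcripts
collapsing to one symbol) or `drop`. Symbols are compared case-sensitively
after whitespace stripping. The mapping report partitions input rows
exactly into mapped and unmapped.

## Synthetic data

The generator emulates the target study's shapes: a 12 vs 12 reference
cohort and a model cohort with NM = 3, NUntr = 3, NTr = 4 replicates.
Defaults, chosen once: log-normal baseline means (median 100, sigma 1.0 in
log space — RNA-seq means are heavy-tailed), log-uniform library sizes on
[0.5, 2] to exercise size-factor estimation, shared NB dispersion 0.1, DE
fraction 0.1 with |log2FC| = 1 split evenly between signs, model effects
|log2FC| = 2. A single shared dispersion per dataset keeps the truth table
simple; the trend-fit code is additionally exercised by Poisson and
high-dispersion configurations in the tests. The concordance plan assigns
each reference DE gene a per-condition label (convergent: same sign as the
reference effect; divergent: opposite; null: no effect) at configured
fractions, realised within ±1 gene. Planted-enriched gene sets draw a
configured fraction of members from the planted pool; background sets are
uniform. Everything is reproducible from (config, seed); the three
generators draw from independent seed streams so each stage is individually
reproducible.

What the generator does *not* emulate: mean-dispersion trends, batch
effects, GC/length bias, outlier counts, correlated genes, read-level
artefacts. Passing tests therefore demonstrate correctness of the
statistics under the assumed NB model and power under clean planted
signal — not robustness to the full messiness of real cohorts, where
dispersion outliers and confounding would matter.

## Pipeline

The orchestrated run executes reference DE → model DE → concordance →
exclusion/residual subsetting → ORA/GSEA → report tables → plots, writing a
manifest with the config hash, seed, version and stage-by-stage counts;
bookkeeping violations (label counts not summing to the DEG count, residual
sets exceeding it) abort the run. Configs reject unknown keys. Stage
failures raise an error naming the stage and clean up partial output.
All numeric tables are written with a fixed `%.10g` float format, so
identical config + seed reproduces byte-identical tables across runs.

## Problem sizes used in validation

Validation runs use 300–2000 genes per dataset, the study-shaped group
sizes (12 vs 12 and 3/3/4) plus 20 vs 20 and 50 vs 50 for estimator
recovery checks, 100 seeded end-to-end repetitions for the planted-recovery
rates, 200 repetitions for permutation-null calibration, and exhaustive
enumeration sweeps (hypergeometric tails to N = 60, enrichment-score
subsets to N = 12). These sizes give Monte-Carlo standard errors well below
the asserted bands while keeping the whole suite fast on a single CPU.

## Known limitations

- Two-group contrasts only; serial contrasts are separate fits, not a
  shared multi-level model.
- Plug-in dispersions make Wald p-values mildly anticonservative at n ≤ 4
  per group; treat model-side gates at those sizes as screening, not
  inference.
- No parity with any specific external DE tool's gene lists is claimed; the
  dispersion machinery is intentionally simpler (no APL, no outlier
  handling, no independent filtering).
- GSEA phenotype permutation at the emulated design (3 vs 4) has only 35
  distinct label splits, bounding attainable significance at p = 1/36 per
  side; gene-set permutation is the default for that reason.
- The curated-collection merge records provenance in the set description,
  which is unwieldy for very large sources.
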