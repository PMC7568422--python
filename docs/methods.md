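# Methods

## Model

`ebscreen` screens a genes × samples count matrix from a small panel of
conditions (the motivating design: 5 tumor cell lines × 4 biological
replicates) for genes whose condition means follow an interpretable
equality/ordering structure.

Counts are negative binomial. For gene g in sample i,

    X_gi ~ NB(r_gi, q_g),   r_gi = r0_g · l_i,

where l_i is the sample's library size factor, r0_g the gene's NB size
(inverse dispersion), and q_g the NB probability parameter, shared by
all samples within an *equality block* of conditions and given a
conjugate Beta(α, β) prior. Under this prior the block marginal is
available in closed form:

    log f(x | r, α, β) = Σ_i log C(x_i + r_i − 1, x_i)
                       + log B(α + Σ_i r_i, β + Σ_i x_i) − log B(α, β).

An expression pattern P is a partition of the K conditions into
equality blocks; the likelihood of gene g under P is the product of
block marginals over P's blocks, with samples pooled within a block.
With mixture weights p_P over candidate patterns, Bayes' rule gives the
posterior pattern probability PP(P | x_g). The binomial-coefficient sum
is identical across patterns (it depends only on per-sample x_i, r_i),
so posteriors depend on the Beta-function terms alone; the full
log-likelihood including that term is used for the EM objective trace.

Assumptions worth stating: dispersion is gene-specific but shared
across conditions; the Beta prior on q is shared by all genes and all
blocks; samples are independent given the gene's block means; library
size enters only by scaling r.

### Candidate patterns

For K conditions there are Bell(K) partitions (52 at K = 5), all
enumerable. A named restriction `p1_p6` provides the classic
five-condition screen set: the fully split pattern, each single
adjacent-pair merge, and the 3+2 split ({1,2,3}{4,5}). When the
all-equal pattern is absent from a requested set the pipeline adds it,
both as the null component of the mixture and to define the
"differentially expressed universe" (genes with PP(all-equal) below a
configurable threshold, default 0.05).

## Estimation

* **Size factors** — median-of-ratios: l_i is the median over reference
  genes of x_gi divided by the gene's geometric mean across samples.
  Reference genes are rows with no zero count, because the geometric
  mean of a row containing a zero is degenerate; when no such row
  exists an explicit `allow_pseudo_reference` flag switches to
  positive-entry geometric means rather than silently changing
  conventions. Note these factors are invariant to a global rescaling
  of the matrix (ratios to the per-gene geometric mean cancel any
  common constant); what is identified is the *relative* scale between
  samples.
* **Gene size r0** — method of moments, r0 = m² / (v − m), with m the
  mean normalized count and v the *within-condition pooled* variance
  (per-condition sample variances, df-weighted). Pooling within
  conditions keeps genuine between-condition differences out of the
  dispersion estimate; a variance taken across all samples would count
  a differential gene's signal as overdispersion and suppress
  detection. Because the within-condition estimate rests on few
  degrees of freedom (15 in the 5 × 4 design), the genewise dispersion
  φ = 1/r0 is floored at the panel median of the genewise estimates:
  a gene whose variance is underestimated by chance otherwise looks
  spuriously precise, and such genes were the dominant source of
  false selections in calibration experiments (with known true
  dispersions the selection FDR sat at its nominal level; with raw
  15-df estimates it ran about 1.5 points high). The floor quantile is
  exposed (`dispersion_floor_quantile`, default 0.5); r0 is clamped to
  (1e−3, 1e4), the upper clamp meaning effectively Poisson.
* **Hyperparameters (α, β) and mixture p** — EM. The E-step computes
  posteriors by Bayes' rule; the M-step sets p to the posterior means
  and maximizes the expected log-marginal over (log α, log β) by
  Nelder-Mead. If the numerical search fails to improve the expected
  objective the previous point is kept, so the observed-data
  log-likelihood is non-decreasing (asserted in tests to 1e−6 slack).
  Initialization α = β = 1, p uniform; convergence when the largest
  change in (α, β, p) drops below `tol` (default 1e−4, default
  `max_iter` 100); non-convergence returns the last iterate flagged
  `converged=False`. Genes with all-zero counts are dropped before
  fitting and reported.

All likelihood arithmetic is in log space (`gammaln`, `betaln`,
log-sum-exp for posterior normalization); counts at the 10³–10⁴ scale
overflow raw Beta functions.

## FDR control

Selection for a target pattern is *soft*: rank genes by PP(target)
descending (ties broken by gene identifier for determinism) and return
the largest prefix whose mean (1 − PP) is at most the nominal level;
that mean is the selection's self-estimated FDR. This controls the
Bayesian FDR exactly when posteriors are calibrated; its empirical
behavior under the synthetic generator is the package's headline
acceptance computation (nominal 5%, twenty 2,000-gene panels with 10%
monotone genes at ≥ 2-fold steps — observed ≈ 5%).

## Ordering gate

Constraints are chains of {<=, >=, =} over condition labels with a
relative tolerance and an absolute floor: a ≤ b passes iff
a ≤ b(1 + rel_tol) + abs_floor; equality iff |a − b| ≤
rel_tol·max(a,b) + abs_floor; a `strict` flag makes the inequalities
exclude equality beyond tolerance. The gate operates on median-ratio
normalized condition means (the replicate-averaged quantity a bench
scientist reads off a normalized count table), not on EB-fitted
posterior means; genes pass a constraint set disjunctively
(`mode="any"`, the C1-or-C2 usage) or conjunctively.

Four presets cover the five-line screen: `c1_main`
(OV90≤OVCAR4≤OVCAR3≤OVCAR5≤OVCA432), `c2_main` (same with a final ≥),
and the strict tied-head variants `c1_supp` / `c2_supp`
(μ1=μ2=μ3<μ4<μ5 and μ1=μ2=μ3<μ4>μ5). Defaults are strict
(rel_tol = 0); a documented soft preset (rel_tol = 0.05) exists because
a screen's published candidate list can include genes that narrowly
violate a strict chain — the tolerance makes that reproducible
behavior rather than a hidden judgment call, and the reference-table
test shows strict C1 keeps exactly the four strictly monotone rows of
the nine-candidate table.

The target ordering itself can be derived from data:
`derive_condition_order` sorts conditions by donor-averaged phenotype
counts (e.g. CD68+ or CD163+ cells per field of view), ascending, with
lexicographic tie-breaking flagged by a warning. The pipeline derives
one chain per marker column and unions the gates, mirroring a
two-marker phenotype.

`univariate_r2` (squared Pearson correlation with the slope sign
reported) supports the companion single-factor correlation screen; a
constant feature yields NaN — explicitly not 0, which would mean "no
relationship" rather than "undefined".

## Annotation filter

Curation (pathway relevance, secreted/soluble status) enters as a
plain table keyed by gene symbol with boolean flags; the filter keeps
genes whose annotation has every required flag, matches symbols
case-insensitively, excludes-and-logs genes absent from the table, and
distinguishes "no annotations supplied" (an error) from "none pass"
(an empty result). No external databases are queried; encoding the
curation as data is what makes the 277 → 52 → 9-style funnel stages
reproducible.

## Synthetic data

`simulate_counts` emulates the motivating study design: defaults of 5
conditions × 4 replicates, gene base means log-uniform on (10, 5000)
normalized counts, per-gene dispersion φ ~ Gamma(shape 2, scale 0.05)
(mean 0.1, a typical bulk RNA-seq scale; chosen by the implementer —
no reference dispersion estimates exist for the motivating dataset),
library size factors uniform on (0.7, 1.3), and a pattern mixture with
a configurable differential fraction. Unequal blocks are separated by
at least `effect_size_min` fold (default 2; adjacent folds drawn
uniformly from [min, 1.5·min]), with direction set by the pattern's
`ordering` tag (increasing / decreasing / random). All randomness
flows from one integer seed through one generator, so identical
configurations reproduce bitwise.

`simulate_phenotype` produces donor × condition marker counts with
geometrically spaced condition means along a requested order
(per-marker orders overridable) plus Gaussian noise, so the
order-derivation step can be tested from noiseless recovery up to
realistic donor scatter.

What the generator does *not* emulate: mean-dependent dispersion
trends, correlated genes, batch effects, gene length or GC effects,
isoform structure, or outlier samples. Passing tests therefore show the
inference is correct *under its stated model*, and that selection is
calibrated when data really are NB with block-equal means — not that
the model is adequate for any particular real dataset.

## Problem sizes and numerical choices

The test suite and acceptance computation use panels of 2,000 genes
(20 panels) for calibration, 5,000 genes for mixture recovery, and
10,000 genes for law-of-large-numbers checks — sizes at which
Monte-Carlo error is small relative to the tolerances asserted while a
full run stays comfortably interactive. Degenerate inputs are handled
explicitly: empty blocks have log-marginal 0; all-zero genes are
dropped and reported; a single candidate pattern yields posterior 1;
conditions with zero samples, unmapped samples, duplicate chain labels
and empty annotation tables raise typed errors.

## Limitations

* The gate is a deterministic filter, not an order-restricted test; no
  uncertainty is attached to "passes C1".
* (α, β) are shared across genes; strongly bimodal expression panels
  may be poorly served by a single Beta prior.
* The soft FDR guarantee is Bayesian: it inherits whatever
  miscalibration the plug-in r0 and fitted prior carry. The dispersion
  floor trades a little power for calibration; panels with genuinely
  tight, well-estimated dispersions would lose some sensitivity.
* With one replicate per condition the within-condition dispersion
  estimate is unavailable and a global-variance fallback is used;
  pattern inference in that regime identifies only large effects.
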