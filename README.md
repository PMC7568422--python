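# ebscreen

Empirical-Bayes screening of multi-condition RNA-seq count data for
candidate factors whose expression tracks an observed phenotype.

The motivating setting is a tumor–macrophage soluble-factor screen: a
panel of five high-grade serous ovarian carcinoma (HGSOC) cell lines
(OV90, OVCAR4, OVCAR3, OVCAR5, OVCA432) differs in its ability to turn
naïve monocytes into CD68+ macrophages and CD163+ alternatively
activated macrophages. Genes whose expression across the panel is (a)
credibly different between lines, (b) ordered like the phenotype, and
(c) annotated as secreted are candidate drivers. `ebscreen` implements
that funnel as a reusable, fully tested pipeline, together with a
synthetic-data generator so every stage can be verified against known
ground truth.

## The model

Counts are modeled per gene g and sample i as negative binomial,

    X_gi ~ NB(r_gi, q_g),    r_gi = r0_g * l_i,

with l_i the sample's median-of-ratios library size factor and a
conjugate Beta(α, β) prior on the NB probability q_g. An *expression
pattern* is a partition of the K conditions into equality blocks (all
52 set partitions for K = 5, or the classic restricted set P1–P6, e.g.
P1: μ1 ≠ μ2 ≠ μ3 ≠ μ4 ≠ μ5). Integrating q out gives a closed-form
predictive for each block,

    log f(x) = Σ_i log C(x_i + r_i − 1, x_i)
             + log B(α + Σ r_i, β + Σ x_i) − log B(α, β),

and a gene's likelihood under a pattern is the product of block
predictives. EM estimates the pattern mixture proportions and (α, β);
r0_g comes from moderated method-of-moments. Bayes' rule then yields
per-gene posterior pattern probabilities, and selection controls the
FDR *softly*: take the largest posterior-ranked gene set whose mean
posterior misassignment probability stays at or below the nominal
level (default 5%).

Selected genes pass through a deterministic directionality gate —
chains like `OV90<=OVCAR4<=OVCAR3<=OVCAR5<=OVCA432` over the
normalized condition means, derivable from a phenotype table — and
finally through an annotation join that keeps genes flagged as, e.g.,
secreted.

## Worked example

```python
from ebscreen import (
    SimConfig, simulate_counts, all_equal_pattern, all_unequal_pattern,
    NBBetaPatternModel, constraint_preset, apply_gate, condition_means,
    median_ratio_size_factors,
)

lines = ("OV90", "OVCAR4", "OVCAR3", "OVCAR5", "OVCA432")
config = SimConfig(
    n_genes=2000,
    pattern_mixture={
        all_equal_pattern(lines): 0.9,
        all_unequal_pattern(lines, name="DE", ordering="increasing"): 0.1,
    },
    effect_size_min=2.0,
    seed=1,
)
counts, truth = simulate_counts(config)

patterns = [all_equal_pattern(lines), all_unequal_pattern(lines, name="DE")]
results = NBBetaPatternModel(counts, config.condition_map, patterns).fit()
print(results.summary())

selection = results.fdr_select("DE", fdr_level=0.05)
factors = median_ratio_size_factors(counts)
means = condition_means(counts, factors, config.condition_map)
gated, _ = apply_gate(
    selection.genes, means,
    [constraint_preset("c1_main"), constraint_preset("c2_main")],
)
```

Output:

```
NB-beta pattern-posterior model
==============================================
genes: 2000
samples: 20  conditions: 5
patterns: 2
alpha: 0.3939  beta: 4.0201
EM iterations: 5  converged: True
log-likelihood: -240446.59

mixture proportions / MAP share:
  EE                   p=0.8957  map=0.8960
  DE                   p=0.1043  map=0.1040

selected 219 genes at estimated FDR 0.0493
205 genes follow the macrophage/AAM ordering
of which 205 are truly in the monotone pattern
```

The EM recovers the simulated 90/10 pattern mixture (p̂(DE) = 0.104);
at a nominal 5% level the soft FDR rule selects 219 genes with a
self-estimated FDR of 0.049; and the ordering gate (ascending CD68-like
chain, or ascending-then-descending CD163-like chain) keeps 205 genes,
all of which are truly in the monotone pattern here.

The same funnel runs from the shell:

```sh
ebscreen simulate --n-genes 2000 --seed 1 --out data/
ebscreen run --counts data/counts.tsv --condition-map data/condition_map.tsv \
    --annotations annotations.tsv --constraint c1_main --constraint c2_main \
    --out results/
```

which writes per-stage tables plus `manifest.json` recording the gene
count at every funnel stage and all parameters.

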