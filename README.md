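# crushmdr

Multiobjective evolutionary search for non-additive gene-gene interactions
(statistical epistasis) affecting quantitative traits.

Genome-wide association studies mostly catalogue independent single-SNP
effects, yet part of the unexplained heritability of common disease is
expected to hide in context-dependent, non-additive interactions between
variants. Exhaustively testing all K-way SNP combinations is combinatorially
impossible beyond pairs, and parametric interaction models are underpowered
in the resulting dimensionality. `crushmdr` is for statistical geneticists
and ML-in-genomics researchers who want to search for such interactions in
panels of hundreds to thousands of SNPs (typically a pathway's tag SNPs
after biological or LD filtering) with a stochastic, model-free method.

## Method

The kernel is **QMDR** (quantitative multifactor dimensionality reduction):
for a candidate SNP set, each multilocus genotype cell is labeled
high-level iff its mean trait exceeds the overall mean; pooling cells gives
one binary attribute, and the pooled-variance two-sample *t*-statistic
between the groups scores the model. A **Crush** evolutionary search
evolves candidate SNP sets under three jointly optimized objectives,

* maximize the QMDR *t*-statistic,
* maximize the mean pairwise interaction information
  IG(A;B;C) = I(A,B;C) − I(A;C) − I(B;C) of the SNPs in the model,
* minimize the model order K,

ranked by NSGA-II nondominated sorting with crowding-distance diversity. A
steady-state client population breeds seeds for generational evolutionary
tasks (an in-process island loop); initial models are *sensibly
initialized* from a lookup table of pairwise interaction gains, each SNP
half the time joined by its best entropy partner. The result is the Pareto
front of models, not a single winner. A matched-budget random search over
the same model distribution is the built-in baseline, and a hierarchical
simulator (pure-epistasis two-SNP penetrance tables per gene, summed
additively into a quantitative trait) measures detection power.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 50-SNP panel in which two hidden "genes" (two SNP pairs with
purely epistatic effects, h² = 0.2 each, MAF 0.4, trait noise σ = 0.05)
generate the phenotype of 1000 samples, then search with a 5000-evaluation
budget:

```
$ crushmdr simulate --genes 2 --maf 0.4 --h2 0.2 --sd 0.05 \
    --samples 1000 --snps 50 --seed 42 --out pathway.tsv
wrote pathway.tsv (1000 samples x 50 SNPs)

$ crushmdr search --dataset pathway.tsv --seed 7 --budget 5000 --out crush.json
round 1: evaluations=805 best_t=42.064 front_size=114
round 2: evaluations=991 best_t=42.917 front_size=200
...
round 17: evaluations=5000 best_t=43.260 front_size=200
crush: 5000 evaluations, front of 52 models -> crush.json
```

The per-round lines report the budget consumed (only unique SNP sets count;
re-evaluations are cached), the best training *t* in the steady-state
population, and its rank-0 front size. The final Pareto front (rank 0 of the
final population plus the archive of everything evaluated) lands in
`crush.json`/`crush.tsv`. Its best two-SNP model,

```
snps                t_statistic  mean_interaction_info  size  pareto_rank
snp18,snp05         22.59        0.3056                 2     0
```

is exactly one of the planted gene pairs (`pathway.tsv.truth.json` records
the truth: genes `snp29,snp32` and `snp18,snp05`), and the front's SNP
union covers all four functional SNPs — the "front-union" success
criterion of the power study. The highest-t front models are large
(K = 10, t ≈ 43): training-*t* overfitting grows with model order, which is
precisely why parsimony and interaction information are co-equal
objectives and why small models with high interaction gain sit on the
front alongside them.

The same machinery is available as scikit-learn selectors:

```python
from crushmdr import CrushMDR
sel = CrushMDR(evaluation_budget=5000, random_state=7).fit(X, y)
X_selected = sel.transform(X)      # columns of the Pareto-front SNPs
sel.best_model_, sel.pareto_front_
```

Other subcommands: `crushmdr rank-pairs` (the expert-knowledge table),
`crushmdr baseline` (matched-budget random search), and
`crushmdr experiment` (power grids with checkpointing; presets
`paper-100`/`paper-1000`).

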