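# Methods

`crushmdr` detects non-additive gene-gene interactions (statistical
epistasis) affecting a quantitative trait. It combines three pieces: the
QMDR constructive-induction kernel as the association measure, a
multiobjective evolutionary search (NSGA-II) over SNP subsets, and an
entropy-based expert-knowledge table that seeds the search. A hierarchical
quantitative-trait simulator and a grid harness measure detection power
against a matched-budget random search.

## The QMDR kernel

For a candidate set of K SNPs (additive 0/1/2 coding), the 3^K multilocus
genotype cells are labeled *high-level* when the cell's mean trait strictly
exceeds the overall mean, otherwise *low-level*; pooling the cells yields a
single binary attribute. The high and low groups are compared with a
pooled-variance two-sample t-test; the t-statistic is the model's
association score (a Welch variant is available behind `welch=True`).

Conventions and degenerate cases:

* a cell whose mean equals the grand mean is low ("exceeds" is strict);
* unobserved cells are recorded as `empty`, contribute no samples, and are
  treated as low if ever queried;
* if either pooled group has fewer than two members, or the pooled variance
  is zero, the score is 0 with `valid=False` rather than an exception, so
  the evolutionary loop never aborts on a degenerate model;
* for a binary endpoint, the classic MDR rule applies: a cell is high-risk
  iff cases/controls strictly exceeds a threshold T (default: the overall
  case/control ratio); a cell with cases and no controls is high-risk.

Cross-validation is deliberately absent from the search — Pareto
optimization over (association, interaction information, parsimony) takes
its place. A standalone k-fold QMDR scorer (`kfold_qmdr_score`) is provided
for post-hoc inspection of a chosen model only.

Model order is capped (`max_model_size`, default 10): crossover can grow
models past five SNPs by design, but 3^K cells empty out quickly, so scores
lose meaning long before K = 10; the cap guards against blow-up.

## Expert knowledge: pairwise interaction gain

For SNPs A, B and a binary class C the interaction gain is
IG = I(A,B;C) − I(A;C) − I(B;C) (bits), with (A,B) the 9-category joint
variable. Positive gain is synergy; negative is redundancy. All entropies
use the plug-in (maximum-likelihood) estimator with no bias correction —
exactly checkable against a nested-loop oracle, at the price of a positive
O(1/n) bias of roughly 4/(2n ln 2) bits per pair under the null, which is
why null gains center *near*, not at, zero.

A continuous trait is binarized at its overall mean before computing gains
(median split by flag), mirroring the kernel's high/low semantics. The full
symmetric gain matrix is the lookup table; each SNP's best partner (row
argmax) drives *sensible initialization*: initial model sizes are uniform
on [1, 5] (3 ± 2, configurable), the first SNP is uniform, and each further
SNP is, with probability 0.5, the best partner of the previously chosen SNP,
otherwise uniform. The same quantity serves as a search objective: a model's
mean pairwise gain over its SNP pairs (0 for single-SNP models, where no
pair exists).

## The Crush search

Candidate models are ranked by NSGA-II nondominated sorting on three
objectives — maximize t, maximize mean interaction gain, minimize model
order — with standard crowding distances (boundary solutions infinite).

Two breeding regimes cooperate, mirroring the original client/worker
deployment:

* **steady-state (client)** — seed models for each task are bred by two
  rank/crowding tournaments of size 3; the second winner is mutated (each
  position replaced with a per-SNP probability of 5% for ~100-SNP panels
  and 0.5% for panels of 1000+ SNPs), then any-point crossover produces two
  children;
* **generational (tasks)** — each of 25 generations breeds 50 children:
  90% of the time by any-point crossover of a parsimony-tournament (size 6)
  winner with a rank/crowding-tournament (size 3) winner, 10% of the time
  by mutating a uniformly drawn model; parents and children are merged and
  truncated elitist-style (rank, then crowding).

Any-point crossover cuts each parent at an independent uniform point and
swaps tails; duplicate SNPs within a child are removed keeping the first
occurrence, an empty child is repaired to one random parental SNP, and
children are truncated at `max_model_size`. The parsimony tournament is the
parsimony-pressure mechanism: no weights or hard caps, just selection.

Returned subpopulations merge into the steady-state population (200 models)
with NSGA-II truncation. The search stops when the evaluation budget is
consumed: every *unique* SNP set is scored once, cache hits are free, and
`archive_size` counts cache misses. The reported Pareto front is the rank-0
set of the union of the final population and a running nondominated archive
of everything ever evaluated (both front sizes are recorded, since either
convention appears in practice).

Determinism: one root seed; the client stream and each task's stream are
derived via `SeedSequence([seed, round, task])`, so serial and parallel
executions of the island loop would give identical results. The original
opportunistic cloud scheduler is replaced by this in-process island loop
with the same algorithmic contract — the contribution is the search logic,
not spot-instance management.

The random baseline draws models from the same initial-sampling
distribution with expert knowledge disabled (pure uniform), scores them
under the identical budget accounting, and reports the Pareto front of
everything it evaluated.

Unstated sizes were chosen for desk scale and are all configurable:
steady-state population 200, task population 50, task generations 25,
4 tasks per round, default budget 50,000 evaluations.

## The simulator

Each simulated *gene* is a pure-epistasis two-SNP penetrance table: a 3×3
matrix f whose Hardy-Weinberg-weighted row and column marginals all equal
the population mean K, so neither SNP has a main effect. Effect size is the
GAMETES table heritability h² = Σ p_ij (f_ij − K)² / (K(1−K)). Tables are
generated by projecting a random Gaussian deviation table onto the
zero-marginal subspace (iterated weighted row/column centering), scaling
around a baseline K₀ = 0.5 to hit the target h² exactly (rejecting draws
that would clip outside [0, 1]). K₀ = 0.5 maximizes the feasible deviation
range; only dispersion matters for a quantitative trait. This deterministic
construction replaces a stochastic table search and is exactly verifiable:
marginals within 1e-9 of K, h² within a relative 1e-6 of target, or the
draw is rejected.

h² here is a *table-level* quantity, not the phenotypic variance ratio —
trait dispersion σ is an independent knob, so the realized fraction of
phenotypic variance explained by one gene is
h²·K(1−K) / (n_genes·(h²·K(1−K) + σ²)).

A sample's phenotype is hierarchical: per gene, a product is drawn
Normal(f(g₁, g₂), σ) — non-additivity within genes — and the products are
summed across genes — additivity between genes. Noise is per-gene by
default (the trait is derived per gene, then summed); a single post-sum
Normal(0, σ) is available by flag. Both functional SNPs within a gene share
the configured MAF; the remaining columns are independent noise SNPs with
MAFs uniform on [0.05, 0.5] (the usual GWAS common-variant filter), and all
columns are shuffled so detection cannot exploit ordering.

What the simulator does *not* emulate: linkage disequilibrium between SNPs,
covariates, genotyping error, or case/control ascertainment. Passing tests
therefore demonstrate detection of clean, independent-marker epistasis at
the stated effect sizes — not robustness to the correlation structure of
real GWAS panels, where upstream LD pruning is assumed.

## The experiment harness

For each grid cell, `replicates` datasets are simulated with derived seeds
and analyzed by Crush and by the random baseline at the *identical* number
of fitness evaluations (asserted per replicate). Three success criteria are
recorded per replicate; the default, `front_union_contains_all` (every
functional SNP appears in at least one Pareto-front model), matches
gene/pathway-level identification; `best_model_contains_all` and
`best_model_exact` are stricter and always recorded so any can be reported.
Success rates are exact integer ratios. Grids are checkpointed per cell
(JSON lines) and resume to an identical table after interruption.

Benchmark cells (`reference_cells()`) use the 100-SNP panel: the full
1000-SNP grid is provided as a preset (`--preset paper-1000`) but is a
multi-hour offline run; the 100-SNP variants of the two hardest reliably
detected settings — four functional SNPs at h² = 0.001 and eight at
h² = 0.01, both with n = 8000, MAF 0.4, σ = 0.05, a 50,000-evaluation
budget and 10 replicates — are the standing benchmark, sized to run in
minutes each.

## Numerical and design notes

* Genotype orientation is taken at face value; MDR is invariant to allele
  relabeling within a SNP (tested).
* Rows with missing genotypes are dropped at load (cell statistics are
  count-based); the count is logged and stored.
* The hot scoring path is a single-pass compiled kernel (numba) over
  samples with persistent scratch buffers; a pure-numpy bincount path is
  the fallback. Both are checked against an explicit-loop oracle.
* Tie-breaks everywhere are deterministic given the seed: tournaments break
  full ties uniformly via the stream; environmental selection breaks
  rank/crowding ties by insertion order.
* The t objective is (mean high − mean low)/se, non-negative by
  construction except in pathological tie layouts; degenerate models score
  0 and are flagged invalid rather than removed.
* Single-sample cells make large-K models overfit the training t; the
  parsimony objective and the interaction-information objective are the
  designed counterweights, and the front-union success criterion does not
  depend on the overfit models.
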