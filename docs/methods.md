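# Methods

## Sampling model

We model the observed count for gene *g* in library *k* as having
expectation

    E[Y_gk] = (μ_gk / S_k) · N_k ,      S_k = Σ_g μ_gk ,

where μ_gk is the true expression level (transcript abundance; gene length
is absorbed into μ and never used by the estimator), N_k is the library's
total read count, and S_k the sample's total RNA output. N_k is observed;
S_k is not, and differences in S_k between samples are precisely what
library-size scaling cannot correct. Counts are treated as Poisson around
this mean, appropriate for technical replicates; biological replicates are
over-dispersed and outside this package's testing scope (the factors
themselves remain usable as offsets in any count model).

## The TMM estimator

For a library pair (k, r), every gene with positive counts in both
libraries contributes a log-fold-change M_g and average log-abundance A_g
of the library-size-scaled counts (see README for formulas). The estimator
is the precision-weighted mean of M over the doubly trimmed set G*:

* **Zero removal.** Genes with Y = 0 in either library are removed first
  (M undefined). A gene whose count equals the library size in *both*
  libraries has zero delta-method variance and is also removed, with a
  warning; this arises only in degenerate one-gene matrices.
* **Double trim.** With n candidate genes, the genes whose M-rank falls
  outside [⌊n·m_trim⌋+1, n−⌊n·m_trim⌋] are removed, and likewise for A;
  G* is the intersection of the two keep-sets over the same candidate
  pool (not sequential re-ranking). Defaults: m_trim = 0.30,
  a_trim = 0.05 per tail. An optional floor `a_min` drops low-abundance
  genes before trimming.
* **Weights.** w_g = 1/var(M_g) with the binomial delta-method variance;
  genes with large counts have far less log-ratio noise and dominate the
  mean. `weighted=False` gives the plain trimmed mean.

The result is reported three ways: `log2_factor`; `factor = 2^log2_factor`,
which multiplies library k's size to give its effective size; and
`production_ratio = 2^(−log2_factor)`, the estimate of S_k/S_r. The
orientation is chosen so that a sample with *larger* RNA output gets a
factor *below* 1 — its effective library size shrinks, raising its
normalized expression back to comparability.

Multi-sample factors are computed pairwise against one reference library
(first library by default; `"auto"` picks the library whose median A
against the first is closest to zero, a deterministic proxy for "most
representative"). The reference keeps factor 1 and factors are not
recentred to multiply to one. For a two-library exact test the single
pairwise factor is split symmetrically: N_k·√f and N_r/√f, preserving the
product of the sizes while setting their ratio to (N_k/N_r)·f.

## Numerical choices

* **Exact cross-product form.** M is computed as log2 of the integer
  cross-product ratio (Y_gk·N_r)/(Y_gr·N_k), with the larger product
  placed in the numerator and the sign applied afterwards. Because the
  products are exact in double precision for realistic sizes, swapping k
  and r negates every M bitwise and scaling a library's counts (with its
  size recomputed) cancels bitwise — so the trim's rank order, and hence
  G*, is identical across those transformations, and the factor is exactly
  antisymmetric.
* **Tie handling in the trim.** Ranks are midranks: tied values share the
  average of the ranks they occupy, so a tie group is kept or removed
  wholesale. Midranks satisfy rank(−x) = n+1−rank(x) exactly, which makes
  the k↔r trim sets mirror images even in the presence of ties (exact
  ties are common in count data: any two genes with proportional count
  pairs share an M value). A per-gene stable tie-break would instead keep
  different tie-group members in the two orientations and break
  antisymmetry whenever a tie straddles a trim boundary.
* **Scale behaviour of the weighted mean.** Scaling *all* counts by c
  scales every weight by 1/c uniformly: the weighted factor is invariant
  to floating-point accuracy. Scaling *one* library's counts leaves M, A
  and G* bitwise unchanged and the unweighted factor exactly unchanged,
  but shifts the weighted factor slightly (typically ~10⁻³): only that
  library's variance term shrinks, so precision weights re-balance across
  genes. This is statistically correct — deeper sequencing genuinely
  changes each gene's precision — and is pinned by a test rather than
  hidden.
* **Exact test convention.** The two-sided conditional binomial p-value
  uses the minimum-likelihood rule: sum of P(X = x) over all outcomes with
  P(X = x) ≤ P(observed)·(1+10⁻⁷), the slack absorbing floating-point ties
  between symmetric outcomes. When the observed outcome is the conditional
  mode the p-value is exactly 1. Both counts zero ⇒ p = 1.
* **Poisson LR test.** Closed-form rate MLEs (group totals over group
  total effective sizes), 0·ln 0 ≡ 0, statistic clipped at 0 against
  roundoff, chi-squared(1) reference. Display log2-fold-changes add a
  half-count only when a zero is involved; p-values never use continuity
  corrections.
* **FDR.** Benjamini–Hochberg step-up (statsmodels), the field default.
* **Smoothed M overlays.** Gaussian KDE with Scott's bandwidth rule,
  deterministic; the bandwidth is recorded in the output.

## The simulator

`simulate_experiment` draws per-gene base expression values i.i.d. from
either a user-supplied empirical count column (resampled with replacement;
≥ 100 positive values required) or the parametric fallback
max(round(exp(Normal(log_mean, log_sd))), 1) with log_mean = 4 and
log_sd = 2 on the natural-log scale. The fallback's heavy right skew
matches the defining feature of real count distributions — a small number
of genes consuming a large share of reads — which is what makes
composition bias material; its default depth-per-gene (≈ 14 reads at the
median gene for 10⁴ genes and 10⁶ reads) is deliberately modest.

Composition structure is then imposed: `n_unique_1`/`n_unique_2` genes get
expression 0 in the other condition; ⌊prop_de·n_common⌋ shared genes are
DE at `fold_change`, with ⌊prop_de_up_1·n_DE⌋ favouring condition 1
(floors, so realized fractions are recorded in the truth table). Counts
are drawn Poisson(μ_gz/S_z·N_k) per library; all randomness flows from one
seed through spawned substreams, so results are reproducible per library.
Default scenario: 10,000 shared genes, 1,000 unique to condition 1, 5% DE
at 2-fold, 80% up in condition 1, 10⁶ reads — a typical
composition-biased two-condition design.

What the simulator does **not** emulate: biological over-dispersion
(negative-binomial variation between biological replicates), gene-length
or GC sampling bias, and positional effects. Tests passing under this
generator therefore demonstrate correctness of the estimator and tests
under the Poisson sampling model, not robustness to those real-data
features.

## Problem sizes and measured behaviour

The test suite exercises the estimator at desk scale: random matrices up
to 500 genes for the structural invariants and oracle equivalence,
10,000-gene simulations for recovery, robustness and error-control
checks, and 20 replicated 5,500-gene simulations (two libraries per
condition) for the normalization-versus-library-size false-discovery
comparison. The doubled-RNA-output scenario uses 5,000 + 5,000 genes at
equal expression and 10⁶ reads, averaged over 10 seeds.

One measured limitation worth stating: the robustness of the factor to
heavy one-directional DE depends on sequencing depth. With 25% of genes
2-fold up in one condition, the DE genes fill one trim tail, so the
surviving null genes are an asymmetric slice of their distribution; the
bias of the trimmed mean then scales with the null genes' log-ratio noise.
At 10⁷ reads per library (the depth scale of the bulk datasets the method
targets) the estimated production ratio stays within ~3% of truth; at 10⁶
reads over the same heavy-tailed 10,000-gene transcriptome the median gene
receives ~14 reads and the systematic error grows to ~7%. The robustness
test runs at the deeper setting; users with very shallow libraries and
suspected strong one-sided DE should treat the factor with proportional
caution (or raise `m_trim`).

## Known limitations

* Poisson-only inference: no dispersion estimation for biological
  replicates.
* The factor is pairwise; multi-sample factors inherit the reference
  choice (documented, deterministic, but still a choice).
* The exact test's discreteness makes it conservative at small totals;
  measured type-I error at p < 0.01 is ≈ 0.008 under the null simulation.
* Housekeeping-style subset diagnostics require the user to supply the
  gene list; no annotation retrieval is performed.
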