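# Methods

## Model

`ranklearn` implements a rank-concordance classifier for binary phenotypes
on high-dimensional omics feature tables (proteomics or metabolomics
intensity matrices, samples × features). The model artifact is a *feature
rank profile* `A`, a permutation of `{1, …, p}` assigning each feature a
rank. A sample `x ∈ R^p` is scored by counting, over all unordered feature
pairs `(i, j)`, whether its observed ordering agrees with the profile:

    u(x, A)_ij = sign((A_i − A_j)(x_i − x_j)),  0 if tied or either missing
    U(x, A)    = Σ_{i<j} u(x, A)_ij

`U` is the per-sample similarity (risk) score; higher is more case-like.
The training objective is the total similarity score

    TSS(A) = mean_{cases} U(x, A) − mean_{controls} U(x, A)

and the learner seeks `Â = argmax_A TSS(A)`.

Because `U` depends only on within-sample orderings, it is *exactly*
invariant to any strictly increasing transform of a sample — in particular
to additive batch shifts, the property the batch scenario exercises — and
missing entries simply drop the pairs they touch, which handles MCAR
missingness without imputation.

### Pair-summation convention

The double sum over `i, j` is symmetric with zero diagonal, so summing
unordered pairs `i < j` halves the work and rescales every score by exactly
2 relative to an ordered-pair sum. Rescaling changes no ranking, AUC, or
argmax; the unordered convention is used throughout. Scores are accumulated
as integers so accept/reject comparisons in the search are exact and
reproducible; ties in `x` take the explicit 0 branch with no randomization.

## Search

The profile space is all `p!` permutations; the optimizer is a two-phase
stochastic search.

**Phase 1 (specialized initialization).** Starting from the identity
permutation, `n_init = 100` uniformly random permutations are screened;
a candidate replaces the incumbent only when its similarity-score AUCs on
all three development datasets (D1 training, D2 and D3 validation) exceed
0.5 **and** their mean improves on the incumbent's. The gate orients the
profile (case-elevated features toward high ranks) before hill climbing.
The choice of identity as the very first incumbent is arbitrary but
reproducible; any fixed start is equivalent up to the gate.

**Phase 2 (swap search).** Up to `max_iter = 5000` iterations: two profile
positions are chosen uniformly at random and exchanged; the move is
accepted iff the TSS increases **strictly and simultaneously** on D1, D2
and D3. Equal-score proposals are rejected, preventing random walks on
plateaus. The accepted TSS triples are therefore strictly increasing
coordinate-wise — a property the tests replay from the trajectory log.
An optional `temperature` parameter enables Metropolis–Hastings-style
acceptance of non-improving moves (probability `exp(Δ/T)` on the summed
TSS gain); it is off by default, keeping the literal strict-improvement
rule.

**Early stopping.** At every `checkpoint_interval = 500` iterations the
current D1 AUC is snapshotted; the search halts once `t ≥ (1 + g) ×
last_checkpoint` with no strict D1 AUC improvement over the snapshot. The
stop test runs every iteration (inside the checkpoint block it could never
fire, since `t ≥ t(1+g)` is false for `g > 0`). Default `g = 0.5`: with
checkpoints every 500 iterations the search gets 50% extra budget to show
an improvement, a conservative choice relative to `max_iter`; `g` is the
main tunable and is exposed everywhere.

**Incremental scoring.** A swap of positions `(i, j)` touches only the
`≤ 2(p−2)+1` pairs involving `i` or `j`, so each proposal is evaluated in
O(n·p) via exact integer delta updates rather than O(n·p²) rescoring; the
test suite certifies delta ≡ full recomputation. Full scoring itself runs
in O(p log p) per sample by merge-sort inversion counting
(`U = C(m,2) − ties − 2·inversions` over the `m` observed entries laid out
in profile order), certified against the literal double loop. D3 is drawn
from D1, so D3 scores are obtained by row indexing rather than rescoring.

**Determinism.** One seeded generator drives Phase 1 candidates and Phase 2
swap positions, in that order; a fit is bit-reproducible from
`(split, SearchConfig)`.

## Evaluation

AUC is the rank-based (Mann–Whitney) statistic with ties counted 0.5.
Two confidence intervals are provided:

- `bootstrap_ci`: percentile bootstrap (default 1000 resamples) over whole
  (score, label) pairs, unstratified; single-class resamples are redrawn.
  Used for a single dataset's AUC. Percentile rather than BCa is the
  minimal construction consistent with its use here.
- `t_ci`: mean ± `t_{α/2, df}` × SE with `df = n − 1` across simulation
  replicates. Used for every benchmark table. Reported bounds are clipped
  to [0, 1].

## Synthetic scenarios

The generator emulates a plasma-proteomics-like intensity table and is the
package's only data source; all benchmark claims rest on it.

- **Base table**: feature `f` is Normal(μ_f, σ²_f) with μ_f ~ U(50, 70)
  and σ²_f ~ U(1, 80), identically in both classes. The second parameters
  of the stated Normal distributions are read as **variances**, matching
  the "means and variances" convention of the feature generator.
- **Differential** (`true_differential`): `⌈fraction × p⌉` features chosen
  uniformly; each gets a per-feature constant ~ N(60, 60) added to case
  samples only, redrawn (≤100 times) until Welch's t-test rejects at
  α = 0.05. Defaults: p = 300, 30 cases / 30 controls.
- **Missing**: exactly `round(rate × n × p)` entries masked uniformly at
  random over the whole matrix (development and test; a
  `missing_in_test=False` toggle restricts masking to development).
- **Batch**: 60 cases / 60 controls; development keeps 60 unshifted
  samples; the 60 test samples split into three stratified groups of 20
  (10/10), each receiving one additive constant from U(100, 300),
  U(300, 500), U(500, 700) applied to every feature (a per-sample-draw
  toggle exists; both preserve within-sample ranks provably).
- **Correlation**: one shared value ~ N(10, 10) per case sample added to
  all true differential features, inducing positive correlation among them
  within cases.
- **Splits**: stratified 70/30 development/test; development subdivided
  ~69/31 into D1/D2 (the ratio of the real-data protocol the grid
  mirrors); D3 (|D3| = |D2|) resampled from D1 without replacement,
  stratified.

What the generator does **not** emulate: MNAR missingness, heteroscedastic
platform noise, feature–feature correlation outside scenario d, and any
real biological covariance structure. A green simulation test therefore
establishes robustness to the *named* perturbations only, not clinical
performance.

## Comparator models

Logistic regression and random forest come from scikit-learn; the
package implements only the selection logic around them: greedy forward
selection maximizing out-of-fold LR AUC (continue while the gain exceeds
10⁻⁴), and a rank-product statistic (geometric mean of per-comparison
fold-change ranks across case–control pairings, both directions, with
label-permutation p-values). Selection sees development data only; missing
values are imputed with per-feature development medians (mean imputation
is a toggle) since neither estimator consumes masked entries.

## Known limitations

- The score ignores intensity magnitudes by construction; weighted or
  magnitude-aware pair scores are out of scope.
- The strict triple-improvement acceptance hill-climbs the empirical TSS
  and measurably overfits small development sets: held-out AUC typically
  *decreases* if the search is run far past the early stop. The default
  early stop mitigates but does not remove this.
- The TSS objective is blind to the ordering of non-differential features
  (their pairs contribute equally to both classes in expectation), so the
  search cannot learn the variance-reducing background ordering that a
  population-mean sort would provide; at very sparse signal (1% of
  features) held-out AUC is bounded near 0.72 for this generator no matter
  the optimizer. The benchmark harness reports what the method actually
  attains there.
- Single-process only; replicates are embarrassingly parallel but the
  benchmark runner executes them serially for reproducibility.
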