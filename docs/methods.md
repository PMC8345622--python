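# Methods

This note records the models implemented in `nacsig`, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and the
numerical choices made where the procedure left room.

## Study design and data model

The analysis targets a two-class expression cohort: 19 chemotherapy
responders vs 11 non-responders, each profiled on thousands of genes as
log-intensity values.  Expression is modelled directly as normal on the
log scale — `N(base_mean, base_sd²)` per gene, defaults 8.0 and 1.0, the
magnitude range typical of log2 microarray intensities — which matches the
homoscedastic-normal assumption underlying the moderated-t model.  A small
planted set of informative genes has its non-responder mean shifted by
`±effect_size × base_sd` (default 3 SD), with the sign alternating across
planted genes so that both responder-up and non-responder-up markers occur.
Ground truth (planted identities and shifts) travels in sidecar metadata,
never in the analysis inputs.

What the generator does **not** emulate: probe-level artefacts, batch
effects, correlated co-expression modules, FFPE RNA degradation, or any
array-normalisation pipeline.  Tests passing on these cohorts therefore
demonstrate the correctness and calibration of the algorithms under their
own assumptions, not robustness to real microarray pathology.

## DB-SCV folds

Per class, the builder starts at a seeded random sample and walks a
nearest-unassigned-neighbour chain (Euclidean distance on per-gene
z-scored expression — the distance metric convention of the
distribution-balanced CV method), dealing consecutive chain members to
folds 1..k round-robin.  The round-robin pointer continues from the larger
class into the smaller, so for 19+11 samples and k = 10 every fold totals
exactly 3 (responders 2/2/…/1, non-responders complementary).  Ties in
distance break by sample index; this makes the assignment a deterministic
function of cohort, k and seed.

## RGIFE

One run keeps a current feature set, its pooled 10-fold DB-SCV accuracy as
the *reference*, and a random-forest importance ranking (ties broken by
gene ID).  The trial block is `ceil(0.25 × current feature count)` genes
from the bottom of the ranking; a trial is accepted when the accuracy
without the block is **not lower** than the reference (non-strict — a
strict rule would forbid the neutral removals the procedure is built
around).  On acceptance the reference, ranking and block size are
recomputed from the surviving set and the failure counter resets; on
failure the same-sized block one position up the ranking is tried
(wrapping past the top back to the bottom — the traversal beyond
"following the ranking" is a free choice here), and after 5 consecutive
failures the block size is divided by 4 (floor, minimum 1) with the scan
restarting from the bottom.  Five consecutive failures at block size 1
terminate the run.  Block size is always capped at one less than the
current feature count so a trial can never empty the panel.

Numerical bookkeeping guarantees: the reference accuracy is non-decreasing
over accepted trials, the feature count strictly decreases exactly at
accepted trials, and termination is certain (failure caps are finite and
the block size reaches 1).  Folds are fixed per run by default
(`redraw_folds_per_trial` re-draws them per trial); forests are seeded per
(run seed, trial index) so a run is fully reproducible.

Accuracy is **pooled** over held-out samples (count of correct held-out
predictions over cohort size), which supports the `n_correct/n_total`
reporting form, rather than the mean of per-fold accuracies.

The default forest size is 500 trees; the bundled analyses and the
acceptance script use 50-tree forests, a problem size at which the
ranking and accuracy estimates are already stable for 30-sample cohorts
while keeping a 20-run repeat experiment at desk scale.

A property worth knowing: with very strong planted markers (3 SD), a
*single* surviving marker frequently classifies all 30 samples perfectly,
and since neutral removals are accepted by design, panels legitimately
shrink to one or two genes.  Larger panels survive only when no individual
gene sustains the reference accuracy alone — as is typical of real
cohorts, where signal is weaker and distributed.

## Permutation null

Each permutation uniformly shuffles the label vector (class counts are
preserved automatically), re-stratifies the folds on the permuted labels,
and records pooled CV accuracy for the fixed panel.  Plain stratified
folds are used under permutation (the scramble destroys the geometry that
DB-SCV exploits; a flag restores DB-SCV).  Significance defaults to the
upper tail of a normal fitted to the null accuracies; the add-one
empirical estimate `(1 + #{null ≥ obs})/(n + 1)` is always available, and
is the only one reported when the null is degenerate (n = 1 or sd = 0).
With a null of roughly 0.58 ± 0.08 and an observed accuracy of 1.0 the
normal tail is ≈ 7.7 × 10⁻⁸; published analyses of this kind sometimes
quote smaller values from other normality-based procedures, which cannot
be reconstructed from the summary statistics alone.

## Shapley explanation

The explained score is the forest's predicted probability of the
good-response class.  The value of a coalition S at point x is the
interventional expectation `v(S) = mean_b f(x_S, b_∖S)` over the training
samples b as background.  Panels of ≤ 12 genes are attributed exactly by
enumerating all 2^p coalitions and applying the Shapley weights (2¹²
coalition evaluations per sample is desk-scale, and the signatures of
interest have ≤ 9 genes); larger panels use a seeded Monte-Carlo estimator
over 200 random feature orderings, whose telescoping sums keep additivity
exact while individual attributions carry sampling error.  Exact mode
satisfies local accuracy (contributions plus base value equal the
prediction) to machine precision; the per-gene summary pairs mean
|contribution| with the Spearman correlation between expression and
contribution, which yields the "high expression of this marker argues
against good response" reading.

## Moderated t

Per gene: `log_fc` = non-responder mean − responder mean (so the study's
resistance markers come out positive), pooled variance `s²_g` on
`n₁+n₂−2` df.  The prior `(d₀, s0²)` is estimated by moment matching on
`log s²_g`: with `e_g = log s²_g − ψ(df/2) + log(df/2)`, solve
`ψ′(d₀/2) = var(e) − ψ′(df/2)` by Newton inversion of the trigamma
function, and `s0² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`; when the
empirical variance of `log s²_g` is at or below `ψ′(df/2)` — no detectable
variance heterogeneity — `d₀ = ∞` and `s0²` is the common variance.  The
moderated statistic uses `s²_post = (d₀s0² + df·s²_g)/(d₀+df)` on
`d₀+df` df (normal reference when `d₀ = ∞`); `d₀ = 0` reduces exactly to
the ordinary pooled t.  Genes with `s²_g = 0` are retained (moderation
gives a finite statistic through s0²) and flagged.  BH step-up correction
is applied to the two-sided p-values.  Fold-change-ranked lists report the
linear ratio `2^|log_fc|` (log2 is the working base) above a ratio
threshold, default 3-fold, ordered by descending ratio with adjusted p
retained — ordering by fold change, not p, with both exported.

## Survival evaluation

The Cox partial likelihood is maximised by Newton–Raphson with
step-halving (the log-likelihood never decreases across iterations);
convergence at score norm < 1e-8, cap 50 iterations, with monotone-
likelihood divergence surfaced via the `converged` flag rather than
clipped.  Tied event times use Breslow's approximation by default —
the simplest standard choice — with Efron available via `ties="efron"`.
The risk score is the linear predictor; the cohort splits at the median
score with ties assigned low-risk (explicit, because expression data can
tie), giving equal halves for even n with distinct scores.  Kaplan–Meier
curves are product-limit estimates (censored-only times do not drop the
curve) and strata are compared by the two-group log-rank test with
hypergeometric variance; for a single binary covariate without ties this
statistic coincides with the Cox score test, which is tested as an
internal consistency oracle.  Panel expression is z-scored per gene before
the Cox fit by default (`standardize=False` disables) — a package choice,
as the upstream procedure does not state one.  A degenerate median split
(constant panel) is flagged and the log-rank test skipped with an explicit
status.

Survival simulation: panel expression standard normal, event times
exponential with rate `baseline_rate × exp(β·x)` (defaults 0.1 and β = 1,
giving ≈ 80% events at the default independent exponential censoring rate
0.025 — censoring mechanism is a modelling choice, as none is stated for
any cohort).

## Clinical and TMA statistics

Welch's unequal-variance t-test is the default for group comparisons: on
the packaged clinical table it reproduces the published age comparison
(p = 0.672) where the pooled-variance test does not (≈ 0.667).  The grade
contingency dichotomises "any G3 component (G3 or G2/3) vs pure G2", the
only reading consistent with the published p = 1.000; it is configurable.
The immunostaining comparison is an **unpaired** t-test even though the
source describes a paired one — the groups have 19 and 11 members and no
pairing exists; both modes are implemented.  TMA scores live on the 0–3
half-point grid; the high rule (any core ≥ 2.5 or mean ≥ 1.5) takes
precedence over the low rule (any core ≤ 1) where both fire (possible,
e.g. cores 0.5 and 3), with such conflicts flagged, and combinations
matching neither rule are called `indeterminate`.  Classification is
verified by exhaustive enumeration of the grid for up to 3 cores.

IHC simulation defaults mirror the reported group scores (responders
2.1, non-responders 2.6, SD 0.3, duplicate cores), rounded to the nearest
half point and clipped to [0, 3].

## Problem sizes

The bundled analyses and tests run at desk scale: 2000-gene cohorts for
permutation and differential-expression calibration, 500-gene cohorts for
elimination runs, 200 label permutations, 20-run repeat experiments,
50-tree forests in the heavy loops, n = 400 for Cox parameter recovery.
These sizes were chosen so that every reported behaviour is estimated
with comfortable Monte-Carlo margins while a full run of the test suite
and acceptance script remains a coffee-break affair.

## Known limitations

- Synthetic cohorts have independent genes; commonality and Shapley
  behaviour under strong co-expression is untested.
- The permutation analysis fixes the panel; it does not re-run feature
  selection per permutation, so it tests the panel's association, not
  selection bias.
- The Monte-Carlo Shapley mode (panels > 12 genes) reports no standard
  errors.
- No multivariable clinical adjustment, proportional-hazards diagnostics
  or competing risks in the survival stack.
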