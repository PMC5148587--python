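# Methods

## Scope and data model

The package operates on a genes × samples matrix of continuous expression
values with one class label per sample (1-based integer codes, a name per
class). Files store genes as rows (microarray convention; a `--transpose`
flag accepts the other dialect), labels either as a companion two-column
file or an embedded `__class__` row. Rows with missing values are rejected
by default; per-gene mean imputation is available behind a flag. All
stochastic components draw from a single seeded generator, so every
result is a pure function of (data, config, seed).

## Fuzzification and the F-information filter

Each column (gene or the numeric class-code column) is mean-split into a
low and a high group. Centers are the group means; spreads are *sample*
standard deviations (ddof = 1). The estimator choice is deliberate: with
the population SD, a two-point group's spread equals exactly half the gap
between the points, the π-function support then ends exactly on the data,
and both points receive zero membership — for discrete class codes this
erases the class signal entirely. Degenerate spreads (constant or
single-member groups) are replaced by 10% of the column range, floored at
1e-6, so no normalization can divide by zero; a sample outside the support
of all three curves gets the uninformative column (⅓, ⅓, ⅓).

The π-membership uses the standard two-branch quadratic (1 − 2d² inside
half a spread, 2(1 − d)² out to one spread) — continuous, with both
branches equal to ½ at the junction. The three-term information
functional uses the pointwise minimum as fuzzy intersection, making
severance symmetric and bounded by 3 (three terms, each at most 1).

The ranking is a greedy forward pass seeded at the most significant gene;
a candidate's score is the minimum over already-admitted genes of
|F_sig − F_sev|, ties broken by larger F_sig then input order. Because the
class column is fuzzified as a *numeric code*, the filter detects ordinal
gene–label association: a gene graded along the class order registers
strongly, while a gene whose per-class centers are assigned in arbitrary
order is nearly invisible to it (measured significance at noise level).
This shapes both the synthetic generator defaults (below) and a known
limitation: genes that are individually relevant but mutually redundant
have severance against each other of the same magnitude as their
significance, so the absolute-difference score can demote all but the
first of a correlated marker group. On synthetic 4-class data (5 planted
markers among 200 genes, adjacent-class separation 4 SD, 10 samples per
class) the top-ranked gene is planted on 10/10 seeds but typically only
3 of 5 planted markers reach the top 10; this is a property of the score,
not of the implementation (the literal-transcription oracle agrees to
1e-12).

## Membership encoding, rules and inference

Nine breakpoints per gene, P1/P9 pinned to the observed range, P2…P8 free
within the chained admissible intervals; shoulder trapezoids for Low and
High and a triangle for Medium are the only three-point realizations
consistent with a three-term partition of a bounded range. Out-of-range
values are clamped to [P1, P9] before membership evaluation.

Rules are initialized with consequents covering every class exactly
`rules_per_class` times (default 3). Antecedent codes are
don't-care-weighted: each gene enters a rule with probability
`mean_premises / F` (default mean 3 premises per rule). A uniform draw
over {0,1,2,3} would give ~0.75·F premises, and a minimum-t-norm
conjunction of that many random terms essentially never fires, leaving
the optimizer with no classification signal at all; a handful of premises
per rule also matches the rule lengths such systems actually report.

Inference is single-winner Mamdani: the highest-firing selected rule
names the class; ties go to the lower rule index; a sample on which no
rule fires is left unclassified and counts as an error. The evaluation
triple is Cs (correct samples), Rs (selected rules with at least one
premise and a real consequent) and Gs (distinct genes used by those
rules).

## The swirl optimizer

Positions are the concatenation of 7F membership floats and
R_m (2 + F) rule slots relaxed to continuous values; repair clamps the
floats sequentially against the already-repaired earlier points and
round-and-clamps the rule slots (selection to {0,1}, codes to {0..3},
consequent to {1..C}). Repair is idempotent, so stored positions are
always feasible encodings.

The update equations are implemented exactly as written above. Two
surrounding choices are ours, made because the bare equations do not
specify a working system:

- strength vectors are clamped to the solution-variable range after each
  update (they are defined on that range at initialization; unclamped
  they drift without bound and every move saturates the repair clamps,
  reducing the search to noise);
- the reference position x_ref is, per particle per iteration, a random
  swarm member's position with probability 0.75 and a uniform random
  point of the solution box otherwise. Population references make the
  reference displacement shrink as the swarm clusters — moves become
  local and the incumbent is refined — while the occasional box draw
  keeps a fully collapsed swarm exploring.

Default weights k1 = k2 = 2 (the sensible range is roughly 2–5; larger k1
visibly shrinks the returned rule count, which the test suite checks).
Stopping is a fixed iteration budget (default 100; the examples and tests
use 20–50 on the small fixtures). Global- and per-particle bests are
tracked elitistically, so the best-objective trace is non-increasing by
construction.

On the bundled separable fixture, filtered to its top two genes, a
20-particle, 50-iteration run reaches training accuracy 1.0 on ~29 of 30
seeds; the residual stalls end at a one-rule local optimum (half the
samples covered), visible in cross-validation as occasional whole-split
errors rather than boundary effects.

## Interpretability indices

Coverage counts samples with positive firing degree (the notion of
"covered" is not otherwise quantified in this formulation). R_acc is
reported as 0 with a cleared flag when a rule covers nothing, likewise
R_gud when the covered firing mass is zero. A_fd is the total firing mass
divided by the number of active rules, so A_cfd = A_fd/#S is the mean
per-(rule, sample) firing confidence. Reports print coverage and accuracy
both as fractions and as percentages. CI compares against the threshold
T ∈ (0,1) on its raw scale by default; since CI can exceed 1 for heavily
cofired rulesets, a normalized mode (dividing by the largest per-rule CI)
is available and is what the bundled reports use — each report states the
mode. Rule simplification fuses same-consequent pairs whose per-rule CFCI
differs by less than 0.05 (keeping agreeing antecedent codes, zeroing
conflicts) and prunes never-firing rules plus those whose maximal firing
degree falls below the 10% quantile of active-rule maxima; every candidate
change is re-evaluated and kept only if training accuracy does not drop.

## Evaluation protocol

Monte-Carlo cross-validation uses stratified random splits (default 10
splits, 72% training — every class keeps at least one training sample and,
when it has more than one member, at least one test sample). Gene
filtering runs inside each training split by default; `paper_mode=True`
filters once on all samples before splitting, reproducing the common but
leakage-prone protocol of the microarray literature. ROC curves are
one-vs-rest with the per-class maximal rule firing degree as the score
(scikit-learn's `roc_curve`/`auc` compute the points and the trapezoidal
area). Confusion matrices carry an explicit extra column for unclassified
samples rather than silently assigning them.

## Synthetic data

The generator emulates mean-scale log-intensity microarray structure:
baseline 7.0 expression units, within-class SD 1.0, 2–11 classes with
arbitrary (imbalanced) per-class sizes, and a small planted informative
subset among hundreds of noise genes. Informative genes are graded along
the class code with adjacent-class separation `effect_size × noise_sd` —
the association structure the numeric-code class fuzzification detects;
`permute_centers=True` assigns the centers to classes in random order per
gene, a regime in which the filter (by design of its class fuzzification)
finds essentially nothing. A log-normal switch exponentiates the values
to mimic raw-intensity skew. The generator does not model probe-level
artifacts, batch effects or gene–gene correlation beyond the shared class
structure, so passing recovery tests here says nothing about robustness
to such effects on real data.

`separable_toy()` is a fixed 16-sample, 10-gene, two-class fixture (two
informative genes at opposite quartiles of the unit range, the second in
mirrored orientation so the pair is informative but not duplicated; eight
noise genes) used for exact end-to-end assertions.

## Numerical and degenerate-input conventions

FEPM columns renormalize to 1 within 1e-9 (exactly 0 deviation up to
float rounding in practice); constant genes are rejected by the optimizer
(their membership range is degenerate); repair of an already-feasible
encoding is the identity; all tie-breaks (ranking, winner rule) are
documented and deterministic. Test-suite oracles are independent literal
loop transcriptions of every formula, asserted to 1e-12 agreement.
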