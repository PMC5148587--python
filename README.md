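# frfiwsa

Fuzzy-rough F-information gene filtering combined with a water-swirl
metaheuristic that learns a compact Mamdani fuzzy-rule classifier, for
multiclass gene-expression data.

## The problem

Multiclass cancer diagnosis from expression profiles faces thousands of
genes, a few dozen patients, heavily imbalanced class sizes and expression
levels that overlap between tumor types. Hard thresholds discard exactly
the gradual, overlapping structure that matters, and black-box classifiers
give a clinician nothing to inspect. This package implements a two-level
pipeline that (1) filters candidate genes *without discretizing* the
continuous values and (2) learns a small set of human-readable if-then
rules over Low/Medium/High linguistic terms, tuned by a swarm optimizer.

## The method

**Filter (FRFI).** Every gene — and the class-label column, treated as one
more variable — is fuzzified: the sample mean μ splits its values into a
low and a high group; the three group centers (μ_L, μ_M, μ_H) and spreads
(σ_L, σ_M, σ_H) parameterize π-shaped membership curves

    π(x; μ, σ) = 1 − 2d²   for d ≤ ½,   2(1 − d)²  for ½ < d ≤ 1,   0 beyond,

with d = |x − μ|/σ. Normalizing the three memberships per sample gives the
3 × n fuzzy equivalence partition matrix (FEPM). Gene–class relevance
(significance) and gene–gene redundancy (severance) are the same
three-term functional of two FEPMs A, B:

    F(A, B) = Σ_{k∈{L,M,H}} | (1/n) Σ_j min(A_kj, B_kj) − (1/n²) Σ_j A_kj Σ_j B_kj |,

with fuzzy intersection as the pointwise minimum. Genes are ranked by a
greedy forward pass: the most significant gene seeds the selection, each
remaining gene scores FI = min over selected s of |F_sig − F_sev(·, s)|,
and the top-f genes by FI are kept.

**Classifier (FRBMS).** Each filtered gene carries nine breakpoints
P1…P9 on its expression range: P1,P2,P3 draw a left-shoulder trapezoid
(Low), P4,P5,P6 a triangle (Medium), P7,P8,P9 a right-shoulder trapezoid
(High); P1 and P9 are pinned to the data limits. Rules are integer-coded
(selection flag, one antecedent code per gene in {0 = unused, 1 = Low,
2 = Medium, 3 = High}, consequent class), 3 rules per class initially.
Inference is single-winner Mamdani with the minimum t-norm.

**Optimizer (WSA).** A particle's position concatenates the 7F free
membership floats with the R_m (2 + F) rule integers (relaxed to
continuous). Each position decodes — via an idempotent repair — to a
knowledge base scored by

    Obj = (Ts − Cs) + k1·Rs + k2·Gs        (minimized),

misclassified samples plus compactness penalties on active rules and used
genes. Strength and position updates are

    α_new = α_old + α_ref (x_prevBest − x_ref) + α_ref (x_gBest − x_old)
    x_new = α_new + α_ref (x_old − x_ref)

with α_ref ~ U(0,1) per particle per iteration.

**Reporting.** Per-rule coverage, accuracy and goodness
(R_cov = N_con/#S, R_acc = N_pro/N_con, R_gud = (PCS_fd − NCS_fd)/TCS_fd),
ruleset averages (A_rl, A_fr, A_cfd), the cofiring matrix
CF_ij = SF_ij/(IF_i·IF_j), the premise-weighted comprehensibility index
CI = Σ_ij (P_i + P_j) CF_ij with its thresholded complement CFCI,
rule simplification (fusion + pruning, accepted only if training accuracy
does not drop), Monte-Carlo cross-validation and one-vs-rest ROC.

## Worked example

```
python examples/02_train_classifier.py
```

prints (fixed seed):

```
training accuracy : 1.00 (16/16 samples)
active rules (Rs) : 2
genes used   (Gs) : 1
objective         : 6.0 = (16-16) + 2.0x2 + 2.0x1

learned rule base:
R1: If T01 is low, then it is class_1.
R2: If T01 is high, then it is class_2.
```

On the bundled 16-sample separable fixture the swirl finds two one-premise
rules over a single gene: zero misclassifications, so the objective is
pure compactness cost (two rules at k1 = 2 plus one gene at k2 = 2). The
other examples cover gene ranking (`01`), interpretability indices and
rule simplification (`03`) and cross-validation with ROC (`04`). A thin
CLI wraps the same calls: `frfiwsa synth | filter | train | classify |
interpret | mccv | run`.

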