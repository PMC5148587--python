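"""Rule readability and comprehensibility indices, and rule simplification.

Readability is quantified per rule by coverage R_cov = N_con / #S
(a sample is covered when the rule fires on it with positive degree),
accuracy R_acc = N_pro / N_con over covered samples, and goodness
R_gud = (PCS_fd - NCS_fd) / TCS_fd, the signed balance of firing-degree
mass on correctly versus incorrectly labeled covered samples. Ruleset
averages follow: A_rl = T_rl / #R (mean premises per active rule),
A_fr = T_fr / #R (mean firing events per rule) and A_cfd = A_fd / #S
with A_fd the total firing mass per rule.

Comprehensibility uses the cofiring matrix CF_ij = SF_ij / (IF_i IF_j)
(simultaneous-fire counts over the product of individual-fire counts,
zero on the diagonal), the premise-weighted index
CI = sum_ij (P_i + P_j) CF_ij and its thresholded complement
CFCI = 1 - CI/T when CI <= T (0 otherwise), T a heuristic threshold in
(0,1). Rule simplification fuses same-consequent rule pairs with nearly
equal per-rule CFCI and prunes the weakest-firing rules, accepting each
change only if training accuracy does not drop.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np

from .data import ExpressionDataset
from .frbms import KnowledgeBase, evaluate_kb


@dataclasses.dataclass
class RuleStats:
    """Readability indices for a single rule."""

    rule_index: int
    n_con: int
    n_pro: int
    r_cov: float
    r_acc: float
    r_gud: float
    if_count: int             # samples where the rule fires individually
    pcs_fd: float
    ncs_fd: float
    tcs_fd: float
    acc_defined: bool = True  # False when the rule covers no sample
    gud_defined: bool = True  # False when covered firing mass is zero


@dataclasses.dataclass
class RulesetStats:
    """Ruleset-level readability averages."""

    n_rules: int          # active rules (#R)
    n_samples: int        # #S
    t_rl: int             # total linguistic variables over active rules
    t_fr: int             # total (rule, sample) firing events
    a_fd: float           # total firing mass / #R
    a_rl: float
    a_fr: float
    a_cfd: float


@dataclasses.dataclass
class CofiringReport:
    """Cofiring structure of a ruleset on a dataset."""

    cf: np.ndarray        # R x R cofiring matrix, zero diagonal
    sf: np.ndarray        # R x R simultaneous-fire counts
    if_counts: np.ndarray  # per-rule individual-fire counts
    premises: np.ndarray   # per-rule premise counts


def rule_stats(kb: KnowledgeBase,
               dataset: ExpressionDataset) -> list[RuleStats]:
    """Per-rule coverage/accuracy/goodness on a dataset.

    Inactive (deselected or void) rules get all-zero statistics with
    their defined-flags cleared. A rule classifies a covered sample
    properly when its own consequent equals the sample label (this is a
    per-rule view, independent of which rule wins the inference).
    """
    fire = kb.firing_matrix(dataset.values)   # (n, R)
    n = dataset.n_samples
    stats = []
    for k, rule in enumerate(kb.rules):
        fired = fire[:, k] > 0
        n_con = int(fired.sum())
        correct = fired & (dataset.labels == rule.consequent)
        wrong = fired & (dataset.labels != rule.consequent)
        n_pro = int(correct.sum())
        pcs = float(fire[correct, k].sum())
        ncs = float(fire[wrong, k].sum())
        tcs = pcs + ncs
        acc_defined = n_con > 0
        gud_defined = tcs > 0
        stats.append(RuleStats(
            rule_index=k,
            n_con=n_con,
            n_pro=n_pro,
            r_cov=n_con / n,
            r_acc=n_pro / n_con if acc_defined else 0.0,
            r_gud=(pcs - ncs) / tcs if gud_defined else 0.0,
            if_count=n_con,
            pcs_fd=pcs,
            ncs_fd=ncs,
            tcs_fd=tcs,
            acc_defined=acc_defined,
            gud_defined=gud_defined,
        ))
    return stats


def ruleset_averages(kb: KnowledgeBase,
                     dataset: ExpressionDataset) -> RulesetStats:
    """Ruleset-level averages over the active rules."""
    active = [k for k, r in enumerate(kb.rules) if r.is_active]
    if not active:
        raise ValueError("ruleset has no active rules")
    fire = kb.firing_matrix(dataset.values)
    n_r = len(active)
    n_s = dataset.n_samples
    t_rl = int(sum(kb.rules[k].n_premises for k in active))
    t_fr = int((fire[:, active] > 0).sum())
    total_fd = float(fire[:, active].sum())
    a_fd = total_fd / n_r
    return RulesetStats(
        n_rules=n_r,
        n_samples=n_s,
        t_rl=t_rl,
        t_fr=t_fr,
        a_fd=a_fd,
        a_rl=t_rl / n_r,
        a_fr=t_fr / n_r,
        a_cfd=a_fd / n_s,
    )


def cofiring_matrix(kb: KnowledgeBase,
                    dataset: ExpressionDataset) -> CofiringReport:
    """SF/IF counts and the cofiring matrix CF over all rules.

    CF_ij = SF_ij / (IF_i * IF_j) off the diagonal and 0 on it; pairs
    where either rule never fires get CF_ij = 0.
    """
    fire = kb.firing_matrix(dataset.values) > 0   # (n, R) events
    sf = fire.T.astype(int) @ fire.astype(int)    # simultaneous counts
    if_counts = np.diag(sf).copy()
    np.fill_diagonal(sf, 0)
    denom = np.outer(if_counts, if_counts).astype(float)
    cf = np.zeros_like(denom)
    ok = denom > 0
    cf[ok] = sf[ok] / denom[ok]
    np.fill_diagonal(cf, 0.0)
    premises = np.array([r.n_premises if r.is_active else 0
                         for r in kb.rules])
    return CofiringReport(cf=cf, sf=sf, if_counts=if_counts,
                          premises=premises)


def comprehensibility(report: CofiringReport, threshold: float,
                      normalize: bool = False
                      ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Premise-weighted comprehensibility index and its complement.

    Returns (CI, CFCI, per-rule CI, per-rule CFCI). CI sums
    (P_i + P_j) CF_ij over all ordered rule pairs; the per-rule CI_i sums
    its row only. CFCI = 1 - CI/T when CI <= T and 0 otherwise. With
    ``normalize=True`` every CI is first divided by the largest per-rule
    CI (when positive) so that the thresholded comparison stays on a
    0..1 scale even for heavily cofired rulesets.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    p = report.premises.astype(float)
    weights = p[:, None] + p[None, :]
    ci_rows = (weights * report.cf).sum(axis=1)
    ci = float(ci_rows.sum())
    ci_rule = ci_rows.copy()
    if normalize:
        peak = ci_rule.max()
        if peak > 0:
            ci_rule = ci_rule / peak
            ci = ci / peak

    def _cfci(value: float) -> float:
        return 1.0 - value / threshold if value <= threshold else 0.0

    cfci = _cfci(ci)
    cfci_rule = np.array([_cfci(v) for v in ci_rule])
    return ci, cfci, ci_rows, cfci_rule


def _accuracy(kb: KnowledgeBase, dataset: ExpressionDataset) -> float:
    return evaluate_kb(kb, dataset).accuracy


def simplify_rules(kb: KnowledgeBase, dataset: ExpressionDataset,
                   *, fusion_tolerance: float = 0.05,
                   prune_quantile: float = 0.1,
                   threshold: float = 0.5) -> KnowledgeBase:
    """Fuse similar rules and prune weak ones without losing accuracy.

    Fusion: active rule pairs sharing a consequent whose per-rule CFCI
    values differ by less than ``fusion_tolerance`` are merged — shared
    antecedent codes are kept, conflicting ones zeroed — and the second
    rule is deselected. Pruning: rules that never fire are dropped, and
    rules whose maximal firing degree falls below the
    ``prune_quantile``-quantile of the active rules' maxima are tried for
    removal. Every candidate change is re-evaluated and kept only when
    training accuracy does not decrease.
    """
    kb = copy.deepcopy(kb)
    baseline = _accuracy(kb, dataset)

    # --- fusion of similar-CFCI rules (same consequent) ---
    report = cofiring_matrix(kb, dataset)
    _, _, _, cfci_rule = comprehensibility(report, threshold, normalize=True)
    active = [k for k, r in enumerate(kb.rules) if r.is_active]
    for a_i, i in enumerate(active):
        for j in active[a_i + 1:]:
            ri, rj = kb.rules[i], kb.rules[j]
            if not (ri.is_active and rj.is_active):
                continue
            if ri.consequent != rj.consequent:
                continue
            if abs(cfci_rule[i] - cfci_rule[j]) >= fusion_tolerance:
                continue
            fused = np.where(ri.antecedent == rj.antecedent,
                             ri.antecedent, 0)
            if not np.any(fused):
                continue
            trial = copy.deepcopy(kb)
            trial.rules[i].antecedent = fused
            trial.rules[j].selected = 0
            if _accuracy(trial, dataset) >= baseline:
                kb = trial
                baseline = _accuracy(kb, dataset)

    # --- pruning of weak-firing rules ---
    fire = kb.firing_matrix(dataset.values)
    max_fire = fire.max(axis=0)
    active = [k for k, r in enumerate(kb.rules) if r.is_active]
    if active:
        cut = float(np.quantile(max_fire[active], prune_quantile))
        # weakest first so strong rules are judged in a reduced context
        for k in sorted(active, key=lambda k: max_fire[k]):
            if max_fire[k] > 0 and max_fire[k] > cut:
                continue
            trial = copy.deepcopy(kb)
            trial.rules[k].selected = 0
            if _accuracy(trial, dataset) >= baseline:
                kb = trial
                baseline = _accuracy(kb, dataset)
    return kb
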