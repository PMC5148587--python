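"""Water Swirl Algorithm: swarm optimization of the fuzzy knowledge base.

A particle's position concatenates the 7F free membership breakpoints
(P2..P8 per gene, floats) with the R_m x (2 + F) rule integers relaxed to
continuous values. Each particle also carries a strength vector of the
same length. One iteration evaluates every decoded position on the
training data with the objective

    Obj = (Ts - Cs) + k1 * Rs + k2 * Gs        (minimized)

(misclassified samples plus compactness penalties on active rules and
used genes), tracks per-particle and global bests, and then moves via

    alpha_new = alpha_old + a_ref * (x_prevBest - x_ref)
                          + a_ref * (x_gBest - x_old)
    x_new     = alpha_new + a_ref * (x_old - x_ref)

with a_ref a fresh uniform(0,1) scalar and x_ref a fresh uniform random
position per particle per iteration. Moved positions are made feasible by
an idempotent repair (sequential interval clamping of breakpoints;
round-and-clamp of rule slots) before the next evaluation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import ExpressionDataset, RunConfig
from .frbms import (KnowledgeBase, MembershipPointSet, Rule, encode_rule_set,
                    evaluate_kb, init_membership_points)

N_FREE_MF_POINTS = 7   # P2..P8 per gene
#: chance that a move references a fresh random point instead of a
#: swarm member, keeping a clustered swarm from freezing
REFERENCE_BOX_PROBABILITY = 0.25


def objective(ts: int, cs: int, rs: int, gs: int,
              k1: float, k2: float) -> float:
    """(Ts - Cs) + k1*Rs + k2*Gs — error plus compactness penalties."""
    if cs > ts:
        raise ValueError("correct count cannot exceed total samples")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    return (ts - cs) + k1 * rs + k2 * gs


def update_strength(alpha_old: np.ndarray, alpha_qref: float,
                    x_prev_best: np.ndarray, x_qref: np.ndarray,
                    x_gbest: np.ndarray, x_p_old: np.ndarray) -> np.ndarray:
    """Strength update: pulls toward the particle and global bests."""
    arrays = [np.asarray(a, dtype=float)
              for a in (alpha_old, x_prev_best, x_qref, x_gbest, x_p_old)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("strength update requires equal-length vectors")
    alpha_old, x_prev_best, x_qref, x_gbest, x_p_old = arrays
    return (alpha_old
            + alpha_qref * (x_prev_best - x_qref)
            + alpha_qref * (x_gbest - x_p_old))


def update_position(alpha_new: np.ndarray, alpha_qref: float,
                    x_p_old: np.ndarray, x_qref: np.ndarray) -> np.ndarray:
    """Position update: the new strength plus a scaled displacement."""
    arrays = [np.asarray(a, dtype=float)
              for a in (alpha_new, x_p_old, x_qref)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("position update requires equal-length vectors")
    alpha_new, x_p_old, x_qref = arrays
    return alpha_new + alpha_qref * (x_p_old - x_qref)


def position_length(f: int, r_m: int) -> int:
    return N_FREE_MF_POINTS * f + r_m * (2 + f)


def encode_kb(kb: KnowledgeBase) -> np.ndarray:
    """Flatten a knowledge base into a continuous position vector."""
    mf_part = np.concatenate([np.asarray(m.points[1:8]) for m in kb.mfs])
    rule_part = np.concatenate([
        np.concatenate(([float(r.selected)],
                        r.antecedent.astype(float),
                        [float(r.consequent)]))
        for r in kb.rules
    ])
    return np.concatenate([mf_part, rule_part])


def repair_position(raw: np.ndarray, f: int, c: int, r_m: int,
                    gene_ranges: list[tuple[float, float]]) -> KnowledgeBase:
    """Decode a raw position into a feasible knowledge base.

    Membership slots are clamped sequentially — each point into the
    interval spanned by the already-repaired earlier points (P2 in
    [P1,P9], P3 in [P2,P9], P4 in [P2,P3], P5 in [P4,P9], P6 in [P5,P9],
    P7 in [P5,P6], P8 in [P7,P9]). Rule slots are rounded to the nearest
    integer and clamped: selection to {0,1}, antecedent codes to {0..3},
    consequents to {1..C}. Repair is idempotent.
    """
    raw = np.asarray(raw, dtype=float)
    expected = position_length(f, r_m)
    if raw.shape != (expected,):
        raise ValueError(f"position length {raw.shape} != ({expected},)")
    if len(gene_ranges) != f:
        raise ValueError("one (min,max) range required per gene")

    mfs = []
    for g in range(f):
        lo, hi = gene_ranges[g]
        s = raw[g * N_FREE_MF_POINTS:(g + 1) * N_FREE_MF_POINTS]
        p1, p9 = float(lo), float(hi)
        p2 = float(np.clip(s[0], p1, p9))
        p3 = float(np.clip(s[1], p2, p9))
        p4 = float(np.clip(s[2], p2, p3))
        p5 = float(np.clip(s[3], p4, p9))
        p6 = float(np.clip(s[4], p5, p9))
        p7 = float(np.clip(s[5], p5, p6))
        p8 = float(np.clip(s[6], p7, p9))
        mfs.append(MembershipPointSet((p1, p2, p3, p4, p5, p6, p7, p8, p9)))

    rules = []
    width = 2 + f
    base = N_FREE_MF_POINTS * f
    for k in range(r_m):
        s = np.rint(raw[base + k * width: base + (k + 1) * width])
        rules.append(Rule(
            selected=int(np.clip(s[0], 0, 1)),
            antecedent=np.clip(s[1:-1], 0, 3).astype(int),
            consequent=int(np.clip(s[-1], 1, c)),
        ))
    return KnowledgeBase(mfs=mfs, rules=rules, n_classes=c)


@dataclasses.dataclass
class SwirlResult:
    """Outcome of one optimization run."""

    kb: KnowledgeBase
    evaluation: "object"           # frbms.EvalResult of the best KB
    trace: np.ndarray              # best objective per iteration
    objective_value: float


def optimize(dataset: ExpressionDataset, config: RunConfig,
             rng: np.random.Generator | None = None) -> SwirlResult:
    """Run the swirl over a filtered dataset and return the best KB.

    Fully reproducible from ``config.seed`` (or an explicit generator).
    The returned trace holds the global-best objective after each
    iteration and is non-increasing by elitist bookkeeping.
    """
    if dataset.n_genes < 1 or dataset.n_samples < 1:
        raise ValueError("empty dataset")
    if dataset.n_classes < 2:
        raise ValueError("need at least two classes to classify")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    f = dataset.n_genes
    c = dataset.n_classes
    r_m = config.rules_per_class * c
    gene_ranges = [(float(row.min()), float(row.max()))
                   for row in dataset.values]
    for g, (lo, hi) in enumerate(gene_ranges):
        if not lo < hi:
            raise ValueError(f"gene {dataset.gene_ids[g]} is constant; "
                             "its membership range is degenerate")

    # per-component bounds of the solution space
    lower = np.concatenate([
        np.repeat([lo for lo, _ in gene_ranges], N_FREE_MF_POINTS),
        np.tile(np.concatenate(([0.0], np.zeros(f), [1.0])), r_m),
    ])
    upper = np.concatenate([
        np.repeat([hi for _, hi in gene_ranges], N_FREE_MF_POINTS),
        np.tile(np.concatenate(([1.0], np.full(f, 3.0), [float(c)])), r_m),
    ])

    def random_position() -> np.ndarray:
        return rng.uniform(lower, upper)

    n = config.swarm_size
    positions = []
    for _ in range(n):
        mfs = [init_membership_points(lo, hi, rng) for lo, hi in gene_ranges]
        rules = encode_rule_set(f, c, config.rules_per_class, rng)
        positions.append(encode_kb(KnowledgeBase(mfs, rules, c)))
    positions = np.array(positions)
    strengths = np.array([random_position() for _ in range(n)])

    prev_best_pos = positions.copy()
    prev_best_obj = np.full(n, np.inf)
    gbest_pos = positions[0].copy()
    gbest_obj = np.inf
    trace = np.empty(config.iterations)

    def score(pos: np.ndarray) -> float:
        kb = repair_position(pos, f, c, r_m, gene_ranges)
        res = evaluate_kb(kb, dataset)
        return objective(res.ts, res.cs, res.rs, res.gs,
                         config.k1, config.k2)

    for it in range(config.iterations):
        for p in range(n):
            obj = score(positions[p])
            if obj < prev_best_obj[p]:
                prev_best_obj[p] = obj
                prev_best_pos[p] = positions[p].copy()
            if obj < gbest_obj:
                gbest_obj = obj
                gbest_pos = positions[p].copy()
        trace[it] = gbest_obj

        for p in range(n):
            a_ref = float(rng.uniform(0.0, 1.0))
            # the reference position is usually a random swarm member
            # (reference displacements shrink as the swarm clusters, so
            # late moves become local) with an occasional random point of
            # the solution box to keep a collapsed swarm exploring
            if rng.uniform() < REFERENCE_BOX_PROBABILITY:
                x_ref = random_position()
            else:
                x_ref = positions[int(rng.integers(0, n))].copy()
            strengths[p] = np.clip(update_strength(
                strengths[p], a_ref, prev_best_pos[p], x_ref,
                gbest_pos, positions[p]), lower, upper)
            moved = update_position(strengths[p], a_ref, positions[p], x_ref)
            positions[p] = encode_kb(
                repair_position(moved, f, c, r_m, gene_ranges))

    best_kb = repair_position(gbest_pos, f, c, r_m, gene_ranges)
    best_eval = evaluate_kb(best_kb, dataset)
    return SwirlResult(kb=best_kb, evaluation=best_eval, trace=trace,
                       objective_value=float(gbest_obj))
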