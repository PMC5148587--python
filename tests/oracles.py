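"""Independent, literal loop-based transcriptions of every formula.

These oracles deliberately avoid the package's vectorized code paths:
plain Python loops, scalars and explicit branch-by-branch piecewise
definitions, so agreement with the implementation is a genuine
dual-route check.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------- filter

DEG_EPS = 1e-6
DEG_FRACTION = 0.1


def pi_oracle(x: float, center: float, sigma: float) -> float:
    d = abs(x - center) / sigma
    if d <= 0.5:
        return 1.0 - 2.0 * d * d
    if d <= 1.0:
        return 2.0 * (1.0 - d) ** 2
    return 0.0


def _sample_sd(vals: list[float]) -> float:
    if len(vals) < 2:
        return 0.0
    m = sum(vals) / len(vals)
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))


def group_stats_oracle(values) -> dict:
    vals = [float(v) for v in values]
    mu_m = sum(vals) / len(vals)
    low = [v for v in vals if v < mu_m]
    high = [v for v in vals if v >= mu_m]
    full_range = max(vals) - min(vals)

    def guard(sd):
        return sd if sd > 0 else max(DEG_EPS, DEG_FRACTION * full_range)

    return {
        "mu_l": sum(low) / len(low) if low else mu_m,
        "mu_m": mu_m,
        "mu_h": sum(high) / len(high) if high else mu_m,
        "sigma_l": guard(_sample_sd(low)),
        "sigma_m": guard(_sample_sd(vals)),
        "sigma_h": guard(_sample_sd(high)),
    }


def fepm_oracle(values, stats: dict) -> np.ndarray:
    n = len(values)
    out = np.empty((3, n))
    for j in range(n):
        raw = [
            pi_oracle(values[j], stats["mu_l"], stats["sigma_l"]),
            pi_oracle(values[j], stats["mu_m"], stats["sigma_m"]),
            pi_oracle(values[j], stats["mu_h"], stats["sigma_h"]),
        ]
        total = raw[0] + raw[1] + raw[2]
        if total == 0.0:
            out[:, j] = 1.0 / 3.0
        else:
            for k in range(3):
                out[k, j] = raw[k] / total
    return out


def fuzzify_oracle(values) -> np.ndarray:
    return fepm_oracle(list(values), group_stats_oracle(values))


def finfo_oracle(fa: np.ndarray, fb: np.ndarray) -> float:
    n = fa.shape[1]
    total = 0.0
    for k in range(3):
        joint = 0.0
        for j in range(n):
            joint += min(fa[k, j], fb[k, j])
        joint /= n
        ma = sum(fa[k, j] for j in range(n))
        mb = sum(fb[k, j] for j in range(n))
        total += abs(joint - ma * mb / n**2)
    return total


def ranking_oracle(dataset) -> list[str]:
    """Plain-loop greedy forward FI ranking; returns gene ids sorted."""
    m = dataset.n_genes
    fepms = [fuzzify_oracle(dataset.values[i]) for i in range(m)]
    cls = fuzzify_oracle([float(v) for v in dataset.labels])
    fsig = [finfo_oracle(fepms[i], cls) for i in range(m)]

    def better(i, j, score):  # larger score, then larger fsig, then lower idx
        return (score[i], fsig[i], -i) > (score[j], fsig[j], -j)

    selected = []
    fi = {}
    current = [math.inf] * m
    remaining = list(range(m))
    seed = remaining[0]
    for i in remaining[1:]:
        if better(i, seed, fsig):
            seed = i
    fi[seed] = fsig[seed]
    selected.append(seed)
    remaining.remove(seed)
    while remaining:
        last = selected[-1]
        for i in remaining:
            gap = abs(fsig[i] - finfo_oracle(fepms[i], fepms[last]))
            if gap < current[i]:
                current[i] = gap
        nxt = remaining[0]
        for i in remaining[1:]:
            if better(i, nxt, current):
                nxt = i
        fi[nxt] = current[nxt]
        selected.append(nxt)
        remaining.remove(nxt)
    order = sorted(range(m), key=lambda i: (-fi[i], -fsig[i], i))
    return [dataset.gene_ids[i] for i in order]


# ------------------------------------------------------------ classifier

def membership_oracle(x: float, points) -> tuple[float, float, float]:
    p1, p2, p3, p4, p5, p6, p7, p8, p9 = points
    x = min(max(x, p1), p9)
    if x <= p2:
        low = 1.0
    elif x < p3:
        low = (p3 - x) / (p3 - p2)
    else:
        low = 0.0
    if x < p4 or x > p6:
        med = 0.0
    elif x < p5:
        med = (x - p4) / (p5 - p4) if p5 > p4 else 0.0
    elif x > p5:
        med = (p6 - x) / (p6 - p5) if p6 > p5 else 0.0
    else:
        med = 1.0
    if x >= p8:
        high = 1.0
    elif x > p7:
        high = (x - p7) / (p8 - p7)
    else:
        high = 0.0
    return low, med, high


def fire_oracle(rule, degrees) -> float:
    """degrees: list of (low, med, high) per gene."""
    if rule.selected != 1 or rule.consequent < 1:
        return 0.0
    fired = None
    for g, code in enumerate(rule.antecedent):
        if code == 0:
            continue
        mu = degrees[g][code - 1]
        fired = mu if fired is None else min(fired, mu)
    return 0.0 if fired is None else fired


def evaluate_oracle(kb, dataset) -> dict:
    n = dataset.n_samples
    cs = 0
    preds = []
    for j in range(n):
        degrees = [membership_oracle(float(dataset.values[g, j]),
                                     kb.mfs[g].points)
                   for g in range(kb.n_genes)]
        best_fire, best_rule = 0.0, -1
        for k, rule in enumerate(kb.rules):
            f = fire_oracle(rule, degrees)
            if f > best_fire:
                best_fire, best_rule = f, k
        pred = kb.rules[best_rule].consequent if best_rule >= 0 else 0
        preds.append(pred)
        if pred == dataset.labels[j]:
            cs += 1
    rs = 0
    genes = set()
    for rule in kb.rules:
        if rule.selected == 1 and rule.consequent >= 1 \
                and any(c > 0 for c in rule.antecedent):
            rs += 1
            genes |= {g for g, c in enumerate(rule.antecedent) if c > 0}
    return {"cs": cs, "rs": rs, "gs": len(genes), "predictions": preds}


# -------------------------------------------------------------- swarm

def objective_oracle(ts, cs, rs, gs, k1, k2):
    return (ts - cs) + (k1 * rs) + (k2 * gs)


def strength_oracle(a_old, a_ref, prev_best, x_ref, g_best, x_old):
    return [a_old[i] + a_ref * (prev_best[i] - x_ref[i])
            + a_ref * (g_best[i] - x_old[i]) for i in range(len(a_old))]


def position_oracle(a_new, a_ref, x_old, x_ref):
    return [a_new[i] + a_ref * (x_old[i] - x_ref[i])
            for i in range(len(a_new))]


# ----------------------------------------------------- interpretability

def rule_stats_oracle(kb, dataset) -> list[dict]:
    n = dataset.n_samples
    out = []
    for rule in kb.rules:
        n_con = n_pro = 0
        pcs = ncs = 0.0
        for j in range(n):
            degrees = [membership_oracle(float(dataset.values[g, j]),
                                         kb.mfs[g].points)
                       for g in range(kb.n_genes)]
            f = fire_oracle(rule, degrees)
            if f > 0:
                n_con += 1
                if dataset.labels[j] == rule.consequent:
                    n_pro += 1
                    pcs += f
                else:
                    ncs += f
        tcs = pcs + ncs
        out.append({
            "n_con": n_con, "n_pro": n_pro,
            "r_cov": n_con / n,
            "r_acc": n_pro / n_con if n_con else 0.0,
            "r_gud": (pcs - ncs) / tcs if tcs > 0 else 0.0,
            "pcs": pcs, "ncs": ncs, "tcs": tcs,
        })
    return out


def _firing_table(kb, dataset):
    n = dataset.n_samples
    table = []
    for j in range(n):
        degrees = [membership_oracle(float(dataset.values[g, j]),
                                     kb.mfs[g].points)
                   for g in range(kb.n_genes)]
        table.append([fire_oracle(rule, degrees) for rule in kb.rules])
    return table


def averages_oracle(kb, dataset) -> dict:
    table = _firing_table(kb, dataset)
    active = [k for k, r in enumerate(kb.rules)
              if r.selected == 1 and r.consequent >= 1
              and any(c > 0 for c in r.antecedent)]
    n_r = len(active)
    n_s = dataset.n_samples
    t_rl = sum(sum(1 for c in kb.rules[k].antecedent if c > 0)
               for k in active)
    t_fr = sum(1 for row in table for k in active if row[k] > 0)
    total_fd = sum(row[k] for row in table for k in active)
    a_fd = total_fd / n_r
    return {"t_rl": t_rl, "t_fr": t_fr, "a_rl": t_rl / n_r,
            "a_fr": t_fr / n_r, "a_fd": a_fd, "a_cfd": a_fd / n_s}


def cofiring_oracle(kb, dataset):
    table = _firing_table(kb, dataset)
    r = len(kb.rules)
    sf = [[0] * r for _ in range(r)]
    iff = [0] * r
    for row in table:
        for i in range(r):
            if row[i] > 0:
                iff[i] += 1
            for j in range(r):
                if i != j and row[i] > 0 and row[j] > 0:
                    sf[i][j] += 1
    cf = [[0.0] * r for _ in range(r)]
    for i in range(r):
        for j in range(r):
            if i != j and iff[i] * iff[j] > 0:
                cf[i][j] = sf[i][j] / (iff[i] * iff[j])
    return np.array(cf), np.array(sf), np.array(iff)


def ci_oracle(cf: np.ndarray, premises) -> float:
    r = cf.shape[0]
    total = 0.0
    for i in range(r):
        for j in range(r):
            total += (premises[i] + premises[j]) * cf[i][j]
    return total


def cfci_oracle(ci: float, threshold: float) -> float:
    if ci <= threshold:
        return 1.0 - ci / threshold
    return 0.0
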