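"""Fuzzy-rough F-information gene filter.

Each gene (and the class-label column, treated as one more variable) is
fuzzified into Low / Medium / High equivalence partitions without
discretizing the continuous expression values: the sample mean splits the
values into a low and a high group, the three group means and spreads
parameterize pi-shaped membership curves, and per-sample memberships are
normalized into a 3 x n fuzzy equivalence partition matrix (FEPM).

Relevance of a gene to the class (significance, ``F_sig``) and redundancy
between two genes (severance, ``F_sev``) are the same three-term
F-information functional of two FEPMs, with fuzzy intersection realized
as the pointwise minimum. Genes are ranked by a greedy forward procedure:
the most significant gene seeds the selection, and each remaining gene is
scored FI = min over selected genes s of |F_sig(gene) - F_sev(gene, s)|,
which rewards relevance while punishing redundancy with anything already
admitted (mRMR-style).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import ExpressionDataset

#: floor used when a group of values has zero spread
DEGENERATE_SIGMA_EPS = 1e-6
#: degenerate spread is replaced by this fraction of the overall range
DEGENERATE_SIGMA_RANGE_FRACTION = 0.1


@dataclasses.dataclass(frozen=True)
class GroupStats:
    """Low/Medium/High centers and spreads for one column of values."""

    mu_l: float
    mu_m: float
    mu_h: float
    sigma_l: float
    sigma_m: float
    sigma_h: float

    def __post_init__(self) -> None:
        if not (self.mu_l <= self.mu_m <= self.mu_h):
            raise ValueError("group centers must satisfy mu_l <= mu_m <= mu_h")
        if min(self.sigma_l, self.sigma_m, self.sigma_h) <= 0:
            raise ValueError("group spreads must be positive")


@dataclasses.dataclass
class FiRanking:
    """Genes ordered by decreasing FI, with the greedy admission trace."""

    gene_ids: list[str]          # sorted by FI descending
    f_sig: np.ndarray            # aligned with gene_ids
    fi: np.ndarray               # aligned with gene_ids
    selection_order: list[str]   # gene ids in greedy admission order

    def as_rows(self) -> list[tuple[int, str, float, float]]:
        """(rank, gene_id, F_sig, FI) rows for a report table."""
        return [
            (r + 1, g, float(s), float(v))
            for r, (g, s, v) in enumerate(zip(self.gene_ids, self.f_sig, self.fi))
        ]


def _safe_sigma(group: np.ndarray, full_range: float) -> float:
    """Sample SD of a group, floored when degenerate.

    The sample estimator (ddof=1) matters for tiny groups: with the
    population SD a two-point group's spread is exactly half the gap, so
    the pi-function support ends exactly on the data points and both get
    zero membership — degenerate for discrete columns like class codes.
    """
    sigma = float(np.std(group, ddof=1)) if group.size >= 2 else 0.0
    if sigma <= 0.0:
        sigma = max(DEGENERATE_SIGMA_EPS,
                    DEGENERATE_SIGMA_RANGE_FRACTION * full_range)
    return sigma


def column_group_stats(values: np.ndarray) -> GroupStats:
    """Mean-split a value column into Low/Medium/High centers and spreads.

    The overall mean is the Medium center; values strictly below it form
    the Low group, the rest the High group. Spreads are population
    standard deviations of each group (the Medium spread is over all
    values). Constant columns or empty groups fall back to a spread of
    10% of the overall range (floored at 1e-6) so no later division can
    degenerate.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values per column")
    mu_m = float(np.mean(values))
    low = values[values < mu_m]
    high = values[values >= mu_m]
    full_range = float(np.ptp(values))
    mu_l = float(np.mean(low)) if low.size else mu_m
    mu_h = float(np.mean(high)) if high.size else mu_m
    return GroupStats(
        mu_l=mu_l,
        mu_m=mu_m,
        mu_h=mu_h,
        sigma_l=_safe_sigma(low, full_range),
        sigma_m=_safe_sigma(values, full_range),
        sigma_h=_safe_sigma(high, full_range),
    )


def pi_membership(x, center: float, sigma: float):
    """pi-shaped membership of ``x`` around ``center`` with spread ``sigma``.

    With d = |x - center| / sigma:
    1 - 2 d^2 on d <= 1/2; 2 (1 - d)^2 on 1/2 < d <= 1; 0 beyond. The two
    quadratic branches join continuously at 1/2 (both give 0.5) and the
    support ends at one spread from the center.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    d = np.abs(x - center) / sigma
    out = np.where(d <= 0.5, 1.0 - 2.0 * d * d, 2.0 * (1.0 - d) ** 2)
    out = np.where(d > 1.0, 0.0, out)
    return out if out.ndim else float(out)


def build_fepm(values: np.ndarray, stats: GroupStats) -> np.ndarray:
    """3 x n fuzzy equivalence partition matrix for one value column.

    Row k holds the positional value of partition k (Low, Medium, High):
    the raw pi-memberships normalized per sample so each column sums to
    one. A sample outside the support of all three curves gets the
    uninformative column (1/3, 1/3, 1/3).
    """
    values = np.asarray(values, dtype=float)
    raw = np.vstack([
        pi_membership(values, stats.mu_l, stats.sigma_l),
        pi_membership(values, stats.mu_m, stats.sigma_m),
        pi_membership(values, stats.mu_h, stats.sigma_h),
    ])
    totals = raw.sum(axis=0)
    dead = totals == 0.0
    totals[dead] = 1.0
    fepm = raw / totals
    fepm[:, dead] = 1.0 / 3.0
    return fepm


def fuzzify_column(values: np.ndarray) -> np.ndarray:
    """Convenience: group stats + FEPM for one column."""
    return build_fepm(values, column_group_stats(values))


def _f_information(fepm_a: np.ndarray, fepm_b: np.ndarray) -> float:
    # sum_k | E[min(Pk_a, Pk_b)] - E[Pk_a] E[Pk_b] |
    if fepm_a.shape != fepm_b.shape:
        raise ValueError(
            f"FEPM shapes differ: {fepm_a.shape} vs {fepm_b.shape}"
        )
    joint = np.minimum(fepm_a, fepm_b).mean(axis=1)
    marg = fepm_a.mean(axis=1) * fepm_b.mean(axis=1)
    return float(np.abs(joint - marg).sum())


def gene_group_significance(fepm_gene: np.ndarray,
                            fepm_class: np.ndarray) -> float:
    """Relevance of a gene to the class column (three-term F-information)."""
    return _f_information(fepm_gene, fepm_class)


def gene_gene_severance(fepm_a: np.ndarray, fepm_b: np.ndarray) -> float:
    """Redundancy between two genes; symmetric in its arguments."""
    return _f_information(fepm_a, fepm_b)


def _all_fepms(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-gene FEPMs (m,3,n) and the class-column FEPM (3,n).

    The class column is the 1-based label codes fuzzified exactly like a
    gene, and it is computed once and reused for every gene.
    """
    fepms = np.stack([fuzzify_column(row) for row in dataset.values])
    class_fepm = fuzzify_column(dataset.labels.astype(float))
    return fepms, class_fepm


def _significance_vector(fepms: np.ndarray, class_fepm: np.ndarray) -> np.ndarray:
    joint = np.minimum(fepms, class_fepm[None, :, :]).mean(axis=2)
    marg = fepms.mean(axis=2) * class_fepm.mean(axis=1)[None, :]
    return np.abs(joint - marg).sum(axis=1)


def _severance_against(fepms: np.ndarray, fepm_s: np.ndarray) -> np.ndarray:
    """Severance of every gene in ``fepms`` against one gene's FEPM."""
    joint = np.minimum(fepms, fepm_s[None, :, :]).mean(axis=2)
    marg = fepms.mean(axis=2) * fepm_s.mean(axis=1)[None, :]
    return np.abs(joint - marg).sum(axis=1)


def f_information_ranking(dataset: ExpressionDataset) -> FiRanking:
    """Rank all genes by FI via the greedy forward selection.

    The gene with the highest class significance seeds the selection (its
    FI is defined as its F_sig). Every remaining gene i carries the score
    FI_i = min over selected s of |F_sig(i) - F_sev(i, s)|; the candidate
    with the largest FI is admitted next, and admitting a gene can only
    lower the scores of the rest (a new min term). Ties are broken by the
    larger F_sig, then by input order. The result lists all genes sorted
    by FI descending.
    """
    m = dataset.n_genes
    if m < 1:
        raise ValueError("empty dataset")
    fepms, class_fepm = _all_fepms(dataset)
    f_sig = _significance_vector(fepms, class_fepm)

    fi = np.full(m, np.inf)
    admitted = np.zeros(m, dtype=bool)
    order: list[int] = []

    def _pick(scores: np.ndarray) -> int:
        # argmax with ties broken by larger F_sig then input order
        cand = np.flatnonzero(~admitted)
        best = cand[0]
        for i in cand[1:]:
            if (scores[i], f_sig[i], -i) > (scores[best], f_sig[best], -best):
                best = i
        return int(best)

    seed = _pick(f_sig)
    fi_final = np.empty(m)
    fi_final[seed] = f_sig[seed]
    admitted[seed] = True
    order.append(seed)

    while len(order) < m:
        last = order[-1]
        sev = _severance_against(fepms, fepms[last])
        fi = np.minimum(fi, np.abs(f_sig - sev))
        nxt = _pick(fi)
        fi_final[nxt] = fi[nxt]
        admitted[nxt] = True
        order.append(nxt)

    rank = sorted(range(m), key=lambda i: (-fi_final[i], -f_sig[i], i))
    return FiRanking(
        gene_ids=[dataset.gene_ids[i] for i in rank],
        f_sig=f_sig[rank],
        fi=fi_final[rank],
        selection_order=[dataset.gene_ids[i] for i in order],
    )


def filter_top_genes(dataset: ExpressionDataset, ranking: FiRanking,
                     f: int) -> ExpressionDataset:
    """Restrict the dataset to the ``f`` highest-FI genes (ranking order)."""
    if f < 1:
        raise ValueError("f must be >= 1")
    if f > dataset.n_genes:
        raise ValueError(
            f"cannot keep {f} genes from a {dataset.n_genes}-gene dataset"
        )
    keep = [dataset.gene_index(g) for g in ranking.gene_ids[:f]]
    return dataset.subset_genes(keep)
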