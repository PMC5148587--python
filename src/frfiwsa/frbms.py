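"""Mamdani fuzzy-rule multiclass classifier (knowledge base + inference).

Each filtered gene carries three linguistic terms -- Low, Medium, High --
drawn from nine ordered breakpoints P1..P9 on the gene's expression
range: P1,P2,P3 define a left-shoulder trapezoid (Low), P4,P5,P6 a
triangle (Medium) and P7,P8,P9 a right-shoulder trapezoid (High). P1 and
P9 are pinned to the gene's observed minimum and maximum; the seven free
points are what the optimizer tunes.

Rules are integer-coded: a selection flag, one antecedent code per gene
(0 = gene unused, 1 = Low, 2 = Medium, 3 = High) and a consequent class
in {1..C} (0 marks a void rule). Inference is single-winner Mamdani with
the minimum t-norm: a rule fires at the minimum membership over its used
genes, and the highest-firing selected rule's consequent is the
prediction (ties broken by the lower rule index; no rule firing means no
prediction, which counts as a misclassification).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import yaml

from .data import ExpressionDataset

#: antecedent code -> linguistic term (0 means the gene is unused)
LINGUISTIC_TERMS = {1: "low", 2: "medium", 3: "high"}


@dataclasses.dataclass(frozen=True)
class MembershipPointSet:
    """Nine ordered breakpoints defining Low/Medium/High curves for a gene."""

    points: tuple[float, ...]

    def __post_init__(self) -> None:
        p = self.points
        if len(p) != 9:
            raise ValueError("exactly nine membership points required")
        p1, p2, p3, p4, p5, p6, p7, p8, p9 = p
        ok = (
            p1 <= p2 <= p9 and p2 <= p3 <= p9 and p2 <= p4 <= p3
            and p4 <= p5 <= p9 and p5 <= p6 <= p9 and p5 <= p7 <= p6
            and p7 <= p8 <= p9
        )
        if not ok:
            raise ValueError(f"membership points violate ordering: {p}")

    def __getitem__(self, i: int) -> float:
        return self.points[i]


def init_membership_points(gene_min: float, gene_max: float,
                           rng: np.random.Generator) -> MembershipPointSet:
    """Draw a random admissible breakpoint set for one gene.

    P1 and P9 are pinned to the gene's data limits; P2..P8 are drawn
    sequentially, each uniform within the interval its predecessors allow
    (P2 in [P1,P9], P3 in [P2,P9], P4 in [P2,P3], P5 in [P4,P9],
    P6 in [P5,P9], P7 in [P5,P6], P8 in [P7,P9]).
    """
    if not gene_min < gene_max:
        raise ValueError("gene range is degenerate (min == max)")
    p1, p9 = float(gene_min), float(gene_max)
    p2 = rng.uniform(p1, p9)
    p3 = rng.uniform(p2, p9)
    p4 = rng.uniform(p2, p3)
    p5 = rng.uniform(p4, p9)
    p6 = rng.uniform(p5, p9)
    p7 = rng.uniform(p5, p6)
    p8 = rng.uniform(p7, p9)
    return MembershipPointSet((p1, p2, p3, p4, p5, p6, p7, p8, p9))


def membership_degrees(x, mps: MembershipPointSet) -> np.ndarray:
    """(…, 3) Low/Medium/High membership degrees of ``x``.

    Values outside [P1, P9] are clamped to the limits first. Degenerate
    segments (coincident breakpoints) resolve to step edges.
    """
    p1, p2, p3, p4, p5, p6, p7, p8, p9 = mps.points
    x = np.clip(np.asarray(x, dtype=float), p1, p9)

    # Low: 1 on [P1,P2], linear down to 0 at P3
    if p3 > p2:
        low = np.clip((p3 - x) / (p3 - p2), 0.0, 1.0)
    else:
        low = (x <= p2).astype(float)

    # Medium: triangle 0 at P4, 1 at P5, 0 at P6
    up = (x - p4) / (p5 - p4) if p5 > p4 else (x >= p5).astype(float)
    down = (p6 - x) / (p6 - p5) if p6 > p5 else (x <= p5).astype(float)
    med = np.clip(np.minimum(up, down), 0.0, 1.0)

    # High: 0 up to P7, linear up to 1 at P8, 1 on [P8,P9]
    if p8 > p7:
        high = np.clip((x - p7) / (p8 - p7), 0.0, 1.0)
    else:
        high = (x >= p8).astype(float)

    return np.stack([low, med, high], axis=-1)


@dataclasses.dataclass
class Rule:
    """One integer-coded if-then rule."""

    selected: int
    antecedent: np.ndarray   # codes in {0,1,2,3}, length F
    consequent: int          # class in {1..C}; 0 marks a void rule

    def __post_init__(self) -> None:
        self.antecedent = np.asarray(self.antecedent, dtype=int)
        if self.antecedent.ndim != 1:
            raise ValueError("antecedent must be a 1-D code vector")
        if not np.all((self.antecedent >= 0) & (self.antecedent <= 3)):
            raise ValueError("antecedent codes must lie in {0,1,2,3}")
        if self.selected not in (0, 1):
            raise ValueError("selection flag must be 0 or 1")

    @property
    def is_active(self) -> bool:
        """Selected, at least one used gene, and a real consequent."""
        return (self.selected == 1 and self.consequent >= 1
                and bool(np.any(self.antecedent > 0)))

    @property
    def n_premises(self) -> int:
        return int(np.count_nonzero(self.antecedent))


def encode_rule_set(f: int, c: int, rules_per_class: int,
                    rng: np.random.Generator,
                    mean_premises: float = 3.0) -> list[Rule]:
    """Random initial rule set with ``rules_per_class`` rules per class.

    Produces rules_per_class x C rules of width 2 + F integers each
    (selection flag, F antecedent codes, consequent). Consequents are a
    shuffled multiset holding each class exactly rules_per_class times so
    every category starts with rules of its own. Antecedent codes are
    don't-care-weighted: each gene is used with probability
    ``mean_premises / F`` (term uniform over Low/Medium/High when used),
    so initial rules carry a handful of premises — a rule conjoining many
    random terms under the minimum t-norm never fires, which would leave
    the optimizer without any classification signal to start from.
    """
    if f < 1:
        raise ValueError("need at least one filtered gene")
    if c < 2:
        raise ValueError("need at least two classes")
    if rules_per_class < 1:
        raise ValueError("rules_per_class must be >= 1")
    p_use = min(1.0, mean_premises / f)
    consequents = rng.permutation(np.repeat(np.arange(1, c + 1),
                                            rules_per_class))
    rules = []
    for cl in consequents:
        used = rng.random(f) < p_use
        codes = np.where(used, rng.integers(1, 4, size=f), 0)
        if not codes.any():   # guarantee a fireable rule
            codes[int(rng.integers(0, f))] = int(rng.integers(1, 4))
        rules.append(Rule(
            selected=int(rng.integers(0, 2)),
            antecedent=codes,
            consequent=int(cl),
        ))
    return rules


@dataclasses.dataclass
class KnowledgeBase:
    """Data base (per-gene membership points) + rule base."""

    mfs: list[MembershipPointSet]
    rules: list[Rule]
    n_classes: int

    def __post_init__(self) -> None:
        f = len(self.mfs)
        for r in self.rules:
            if r.antecedent.shape[0] != f:
                raise ValueError("rule antecedent width != number of genes")
            if r.consequent < 0 or r.consequent > self.n_classes:
                raise ValueError(
                    f"consequent {r.consequent} outside 0..{self.n_classes}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.mfs)

    # -- inference --------------------------------------------------------
    def sample_degrees(self, values: np.ndarray) -> np.ndarray:
        """(n_samples, F, 3) membership degrees for genes x samples values."""
        values = np.asarray(values, dtype=float)
        return np.stack(
            [membership_degrees(values[g], self.mfs[g])
             for g in range(self.n_genes)],
            axis=1,
        ) if values.ndim == 2 else np.stack(
            [membership_degrees(values[g], self.mfs[g])
             for g in range(self.n_genes)],
            axis=0,
        )

    def firing_matrix(self, values: np.ndarray) -> np.ndarray:
        """(n_samples, n_rules) firing degrees (min t-norm; 0 for inactive)."""
        degrees = np.stack(
            [membership_degrees(values[g], self.mfs[g])
             for g in range(self.n_genes)],
            axis=1,
        )  # (n, F, 3)
        n = degrees.shape[0]
        fire = np.zeros((n, len(self.rules)))
        for k, rule in enumerate(self.rules):
            if not rule.is_active:
                continue
            used = np.flatnonzero(rule.antecedent)
            terms = rule.antecedent[used] - 1
            fire[:, k] = degrees[:, used, terms].min(axis=1)
        return fire

    def classify(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray]:
        """Predict every sample of a genes x samples matrix.

        Returns (predicted class, winner rule index, winner firing
        degree); prediction 0 and winner -1 mean no rule fired.
        """
        fire = self.firing_matrix(values)
        winner = fire.argmax(axis=1)          # lowest index wins ties
        degree = fire[np.arange(fire.shape[0]), winner]
        consequents = np.array([r.consequent for r in self.rules]) \
            if self.rules else np.zeros(0, dtype=int)
        pred = np.where(degree > 0, consequents[winner], 0) \
            if self.rules else np.zeros(fire.shape[0], dtype=int)
        winner = np.where(degree > 0, winner, -1)
        return pred.astype(int), winner, degree

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "membership_points": [list(map(float, m.points)) for m in self.mfs],
            "rules": [
                {
                    "selected": int(r.selected),
                    "antecedent": [int(a) for a in r.antecedent],
                    "consequent": int(r.consequent),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeBase":
        return cls(
            mfs=[MembershipPointSet(tuple(p)) for p in d["membership_points"]],
            rules=[
                Rule(selected=r["selected"],
                     antecedent=np.array(r["antecedent"]),
                     consequent=r["consequent"])
                for r in d["rules"]
            ],
            n_classes=d["n_classes"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "KnowledgeBase":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class EvalResult:
    """Classification outcome of a knowledge base on one dataset."""

    ts: int                 # total samples
    cs: int                 # correctly classified samples
    rs: int                 # active (selected, non-void) rules
    gs: int                 # distinct genes used by active rules
    predictions: np.ndarray
    winner_rule: np.ndarray
    winner_degree: np.ndarray

    @property
    def accuracy(self) -> float:
        return self.cs / self.ts if self.ts else 0.0


def fire_rule(rule: Rule, sample_degrees: np.ndarray) -> float:
    """Firing degree of one rule given a sample's (F, 3) degree array."""
    if not rule.is_active:
        return 0.0
    used = np.flatnonzero(rule.antecedent)
    return float(sample_degrees[used, rule.antecedent[used] - 1].min())


def classify_sample(kb: KnowledgeBase,
                    sample: Sequence[float]) -> tuple[int | None, int, float]:
    """Single-sample convenience wrapper around :meth:`KnowledgeBase.classify`."""
    values = np.asarray(sample, dtype=float).reshape(-1, 1)
    pred, winner, degree = kb.classify(values)
    label = int(pred[0]) if pred[0] > 0 else None
    return label, int(winner[0]), float(degree[0])


def evaluate_kb(kb: KnowledgeBase, dataset: ExpressionDataset) -> EvalResult:
    """Score a knowledge base on a dataset (Cs, Rs, Gs and predictions).

    Cs counts samples whose single-winner prediction matches the label
    (unfired samples are wrong); Rs counts active rules; Gs counts the
    distinct genes with a nonzero antecedent code in any active rule.
    """
    if kb.n_genes != dataset.n_genes:
        raise ValueError(
            f"knowledge base covers {kb.n_genes} genes but dataset has "
            f"{dataset.n_genes}"
        )
    pred, winner, degree = kb.classify(dataset.values)
    cs = int(np.sum(pred == dataset.labels))
    active = [r for r in kb.rules if r.is_active]
    rs = len(active)
    used_genes: set[int] = set()
    for r in active:
        used_genes.update(np.flatnonzero(r.antecedent).tolist())
    return EvalResult(
        ts=dataset.n_samples,
        cs=cs,
        rs=rs,
        gs=len(used_genes),
        predictions=pred,
        winner_rule=winner,
        winner_degree=degree,
    )


def render_rules(kb: KnowledgeBase, gene_ids: Sequence[str],
                 class_names: Sequence[str]) -> str:
    """Readable if-then listing of the active rules."""
    lines = []
    idx = 0
    for rule in kb.rules:
        if not rule.is_active:
            continue
        idx += 1
        parts = [
            f"{gene_ids[g]} is {LINGUISTIC_TERMS[int(rule.antecedent[g])]}"
            for g in np.flatnonzero(rule.antecedent)
        ]
        lines.append(
            f"R{idx}: If {' and '.join(parts)}, "
            f"then it is {class_names[rule.consequent - 1]}."
        )
    return "\n".join(lines) if lines else "(no active rules)"
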