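"""Monte-Carlo cross-validation, confusion matrices and one-vs-rest ROC.

MCCV repeats a stratified random train/test split; on each split the
F-information filter is ranked on the training samples only (by default
— ``paper_mode=True`` filters on all samples before splitting, which
replicates the common-but-leaky microarray protocol), the swirl
optimizer is trained on the top-g training genes for every requested
gene count g, and the test error is recorded. ROC curves are one-vs-rest
with the per-class rule firing degree as the score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import auc, roc_curve

from .data import ExpressionDataset, RunConfig
from .frbms import KnowledgeBase, evaluate_kb
from .frfi import f_information_ranking, filter_top_genes
from .wsa import optimize


@dataclasses.dataclass
class MccvResult:
    """Error-versus-gene-count curve from repeated random splits."""

    gene_counts: list[int]
    errors: np.ndarray          # (n_splits, len(gene_counts))
    n_splits: int
    train_fraction: float

    @property
    def mean_error(self) -> np.ndarray:
        return self.errors.mean(axis=0)


@dataclasses.dataclass
class RocResult:
    """Per-class one-vs-rest ROC points and AUC."""

    class_names: list[str]
    fpr: list[np.ndarray]
    tpr: list[np.ndarray]
    auc: list[float]

    @property
    def macro_auc(self) -> float:
        return float(np.mean(self.auc))


def stratified_split(labels: np.ndarray, train_fraction: float,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random per-class split keeping at least one training sample per class."""
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        n_train = max(1, int(round(train_fraction * members.size)))
        if n_train == members.size and members.size > 1:
            n_train -= 1    # keep a test sample when the class allows it
        train_idx.extend(members[:n_train].tolist())
        test_idx.extend(members[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def mccv(dataset: ExpressionDataset, gene_counts: list[int],
         config: RunConfig, *, n_splits: int | None = None,
         train_fraction: float | None = None,
         rng: np.random.Generator | None = None,
         paper_mode: bool = False) -> MccvResult:
    """Mean test error per gene count over repeated stratified splits."""
    if not gene_counts or min(gene_counts) < 1:
        raise ValueError("gene_counts must be positive")
    if max(gene_counts) > dataset.n_genes:
        raise ValueError("gene count exceeds the number of genes")
    n_splits = n_splits if n_splits is not None else config.n_splits
    train_fraction = (train_fraction if train_fraction is not None
                      else config.train_fraction)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    full_ranking = f_information_ranking(dataset) if paper_mode else None
    errors = np.empty((n_splits, len(gene_counts)))
    for s in range(n_splits):
        tr, te = stratified_split(dataset.labels, train_fraction, rng)
        train = dataset.subset_samples(tr)
        test = dataset.subset_samples(te)
        ranking = full_ranking or f_information_ranking(train)
        for gi, g in enumerate(gene_counts):
            train_g = filter_top_genes(train, ranking, g)
            test_g = filter_top_genes(test, ranking, g)
            seed = int(rng.integers(0, 2**31 - 1))
            sub_cfg = dataclasses.replace(config, seed=seed)
            result = optimize(train_g, sub_cfg)
            res = evaluate_kb(result.kb, test_g)
            errors[s, gi] = 1.0 - res.accuracy
    return MccvResult(gene_counts=list(gene_counts), errors=errors,
                      n_splits=n_splits, train_fraction=train_fraction)


def class_scores(kb: KnowledgeBase, values: np.ndarray) -> np.ndarray:
    """(n_samples, C) score matrix: max firing degree per class's rules."""
    fire = kb.firing_matrix(values)
    scores = np.zeros((values.shape[1], kb.n_classes))
    for cls in range(1, kb.n_classes + 1):
        cols = [k for k, r in enumerate(kb.rules)
                if r.is_active and r.consequent == cls]
        if cols:
            scores[:, cls - 1] = fire[:, cols].max(axis=1)
    return scores


def roc_ovr(kb: KnowledgeBase, dataset: ExpressionDataset) -> RocResult:
    """One-vs-rest ROC per class, scored by class firing degree."""
    if dataset.n_classes < 2:
        raise ValueError("ROC analysis needs at least two classes")
    scores = class_scores(kb, dataset.values)
    fprs, tprs, aucs = [], [], []
    for cls in range(1, dataset.n_classes + 1):
        truth = (dataset.labels == cls).astype(int)
        fpr, tpr, _ = roc_curve(truth, scores[:, cls - 1])
        fprs.append(fpr)
        tprs.append(tpr)
        aucs.append(float(auc(fpr, tpr)))
    return RocResult(class_names=list(dataset.class_names),
                     fpr=fprs, tpr=tprs, auc=aucs)


def confusion(kb: KnowledgeBase,
              dataset: ExpressionDataset) -> tuple[np.ndarray, float]:
    """C x (C+1) confusion counts (last column = unclassified) + accuracy."""
    res = evaluate_kb(kb, dataset)
    c = dataset.n_classes
    matrix = np.zeros((c, c + 1), dtype=int)
    for label, pred in zip(dataset.labels, res.predictions):
        col = pred - 1 if pred > 0 else c
        matrix[label - 1, col] += 1
    accuracy = float(np.trace(matrix[:, :c])) / dataset.n_samples
    return matrix, accuracy
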