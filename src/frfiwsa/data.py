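"""Expression-matrix containers, delimited-text IO and run configuration.

A dataset is a genes x samples real matrix with one class label per
sample. Files store genes as rows and samples as columns (the microarray
convention); the first column holds gene identifiers and the header row
holds sample identifiers. Labels live either in a companion two-column
file (sample_id, label) or in a reserved final matrix row.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("frfiwsa")

#: reserved gene-id for an embedded label row
LABEL_ROW_ID = "__class__"


@dataclasses.dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with per-sample class labels.

    Labels are 1-based integer class codes in ``{1..C}``; ``class_names``
    maps code ``k`` to its display name at index ``k - 1``.
    """

    gene_ids: list[str]
    values: np.ndarray            # shape (n_genes, n_samples), float
    labels: np.ndarray            # shape (n_samples,), int in {1..C}
    class_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = list(self.gene_ids)
        self.class_names = list(self.class_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] != self.labels.shape[0]:
            raise ValueError(
                f"label count {self.labels.shape[0]} does not match "
                f"{self.values.shape[1]} sample columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        c = len(self.class_names)
        if c < 1:
            raise ValueError("at least one class required")
        present = set(np.unique(self.labels))
        if not present <= set(range(1, c + 1)):
            raise ValueError(f"labels outside 1..{c}: {sorted(present)}")

    # -- shape accessors ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    # -- subsetting -----------------------------------------------------
    def subset_genes(self, index: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given gene row indices (in order)."""
        index = list(index)
        return ExpressionDataset(
            gene_ids=[self.gene_ids[i] for i in index],
            values=self.values[index, :],
            labels=self.labels.copy(),
            class_names=self.class_names,
        )

    def subset_samples(self, index: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given sample column indices (in order).

        Class codes are preserved, so every class must survive the cut.
        """
        index = list(index)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            values=self.values[:, index],
            labels=self.labels[index],
            class_names=self.class_names,
        )

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def require_all_classes(self) -> "ExpressionDataset":
        """Raise unless every class in 1..C has at least one sample.

        Loaded and generated datasets must satisfy this; derived subsets
        (e.g. the test half of a split) may not.
        """
        present = set(np.unique(self.labels))
        missing = sorted(set(range(1, self.n_classes + 1)) - present)
        if missing:
            raise ValueError(f"classes with no samples: {missing}")
        return self


@dataclasses.dataclass
class RunConfig:
    """Tunable knobs shared across the pipeline.

    f_filtered      genes kept by the relevance/redundancy filter
    swarm_size      water particles in the optimizer (20-50 is sensible)
    iterations      optimizer iterations (10-100)
    k1, k2          compactness weights on rule count and gene count
    rules_per_class initial rules per class (rule budget = 3 x classes)
    cfci_threshold  heuristic threshold T in (0,1) for the cofiring
                    comprehensibility index
    fusion_tolerance, prune_quantile  rule-simplification knobs
    train_fraction, n_splits          Monte-Carlo cross-validation knobs
    seed            master seed for every stochastic component
    """

    f_filtered: int = 50
    swarm_size: int = 30
    iterations: int = 100
    k1: float = 2.0
    k2: float = 2.0
    rules_per_class: int = 3
    seed: int = 0
    cfci_threshold: float = 0.5
    fusion_tolerance: float = 0.05
    prune_quantile: float = 0.1
    train_fraction: float = 0.72
    n_splits: int = 10

    def __post_init__(self) -> None:
        for name in ("f_filtered", "swarm_size", "iterations",
                     "rules_per_class", "n_splits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if not 0 < self.cfci_threshold < 1:
            raise ValueError("cfci_threshold must lie in (0,1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_dataset(
    path: str | Path,
    labels: str | Path | None = None,
    *,
    transpose: bool = False,
    impute: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus class labels.

    ``labels`` is a two-column delimited file (sample_id, label); when it
    is ``None`` a reserved final row with gene id ``__class__`` must be
    present in the matrix. Labels may be integers or class-name strings;
    names are mapped to 1-based codes in sorted order. ``transpose``
    accepts samples-as-rows files. Rows with missing values are rejected
    unless ``impute`` enables per-gene mean imputation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = _read_table(path)
    if transpose:
        frame = frame.T

    label_series = None
    if labels is None:
        if LABEL_ROW_ID not in frame.index:
            raise ValueError(
                f"no labels file given and no '{LABEL_ROW_ID}' row in {path}"
            )
        label_series = frame.loc[LABEL_ROW_ID]
        frame = frame.drop(index=LABEL_ROW_ID)
    else:
        labels = Path(labels)
        if not labels.exists():
            raise FileNotFoundError(f"labels file not found: {labels}")
        lab = _read_table(labels)
        label_series = lab.iloc[:, 0]
        try:
            label_series = label_series.loc[list(frame.columns)]
        except KeyError as exc:
            raise ValueError(
                f"labels file {labels} is missing sample ids: {exc}"
            ) from None

    # strict numeric parse with a located error message
    values = np.empty(frame.shape, dtype=float)
    for i, (gene, row) in enumerate(frame.iterrows()):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at row {i + 1} (gene '{gene}'), "
                    f"column {j + 1} (sample '{frame.columns[j]}'): {cell!r}"
                ) from None

    if np.isnan(values).any():
        if impute:
            for i in range(values.shape[0]):
                row = values[i]
                if np.isnan(row).all():
                    raise ValueError(
                        f"gene '{frame.index[i]}' has no observed values"
                    )
                row[np.isnan(row)] = np.nanmean(row)
        else:
            bad = [str(frame.index[i])
                   for i in np.unique(np.where(np.isnan(values))[0])]
            raise ValueError(f"missing values in genes {bad}; "
                             "rerun with imputation to mean-fill them")

    if label_series.shape[0] != values.shape[1]:
        raise ValueError(
            f"label count {label_series.shape[0]} does not match "
            f"{values.shape[1]} samples"
        )

    raw_labels = list(label_series)
    try:
        codes = [int(x) for x in raw_labels]
        c = max(codes)
        class_names = [str(k) for k in range(1, c + 1)]
    except (TypeError, ValueError):
        class_names = sorted(set(str(x) for x in raw_labels))
        name_to_code = {n: k + 1 for k, n in enumerate(class_names)}
        codes = [name_to_code[str(x)] for x in raw_labels]

    ds = ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        values=values,
        labels=np.array(codes),
        class_names=class_names,
    ).require_all_classes()
    log.info("loaded %d genes x %d samples, %d classes from %s",
             ds.n_genes, ds.n_samples, ds.n_classes, path)
    return ds


def write_dataset(
    dataset: ExpressionDataset,
    path: str | Path,
    labels_path: str | Path | None = None,
    *,
    float_format: str = "%.10g",
) -> None:
    """Write the matrix (and labels) back to delimited text.

    With ``labels_path=None`` the labels are embedded as a final
    ``__class__`` row, so a single file round-trips through
    :func:`load_dataset`.
    """
    sample_ids = [f"S{j + 1}" for j in range(dataset.n_samples)]
    frame = pd.DataFrame(dataset.values, index=dataset.gene_ids,
                         columns=sample_ids)
    if labels_path is None:
        frame.loc[LABEL_ROW_ID] = dataset.labels
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame.to_csv(path, sep=sep, float_format=float_format,
                 index_label="gene_id")
    if labels_path is not None:
        lab = pd.DataFrame({"label": dataset.labels}, index=sample_ids)
        lsep = "\t" if str(labels_path).endswith((".tsv", ".tab", ".txt")) else ","
        lab.to_csv(labels_path, sep=lsep, index_label="sample_id")
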