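"""Synthetic two-class expression data with planted differential genes.

The generator emulates the premise that only a small set of genes
participates in the contrast between two sample classes: every entry is
i.i.d. Gaussian background noise, and a planted subset of genes receives a
mean shift (in units of the noise SD) in class-1 samples only.  Recovery
metrics score how well a ranking finds the planted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-gene expression simulation.

    Attributes
    ----------
    n_samples, m_genes : int
        Matrix shape (samples x genes).
    n_de : int
        Number of planted differentially expressed genes (<= m_genes).
    class_fraction : float
        Fraction of samples assigned to class 1 (0 < f < 1; both classes
        must be non-empty).
    effect_size : float
        Mean shift added to planted genes in class-1 samples, in units of
        the baseline noise SD.
    noise_sd : float
        Baseline Gaussian noise standard deviation.
    seed : int
        Generator seed; the dataset is a pure function of the spec.
    """

    n_samples: int = 40
    m_genes: int = 500
    n_de: int = 25
    class_fraction: float = 0.5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.m_genes < 2:
            raise ValueError("need at least 2 samples and 2 genes")
        if not 0 <= self.n_de <= self.m_genes:
            raise ValueError("n_de must be between 0 and m_genes")
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must be in (0, 1)")
        n1 = int(round(self.class_fraction * self.n_samples))
        if n1 == 0 or n1 == self.n_samples:
            raise ValueError("both classes must be non-empty")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``gene_ids`` carries the full gene universe so rankings can be
    validated against it.
    """

    de_gene_ids: set
    class_labels: np.ndarray
    gene_ids: list = field(default_factory=list)


def _gene_id(j: int, width: int) -> str:
    return f"G{j + 1:0{width}d}"


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic dataset from the spec.

    Background entries are Normal(0, noise_sd^2); planted genes get
    ``effect_size * noise_sd`` added in class-1 samples.  Class labels and
    the planted gene subset are drawn from the same seeded generator, so
    the whole dataset is reproducible from the spec alone.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.m_genes
    values = rng.normal(0.0, spec.noise_sd, size=(n, m))

    n1 = int(round(spec.class_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n1, replace=False)] = 1
    de_idx = np.sort(rng.choice(m, size=spec.n_de, replace=False))

    shift = spec.effect_size * spec.noise_sd
    values[np.ix_(labels == 1, de_idx)] += shift

    width = max(4, len(str(m)))
    gene_ids = [_gene_id(j, width) for j in range(m)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    matrix = ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)
    truth = GroundTruth(
        de_gene_ids={gene_ids[j] for j in de_idx},
        class_labels=labels,
        gene_ids=gene_ids,
    )
    return matrix, truth


def recovery_metrics(
    table: pd.DataFrame, truth: GroundTruth, h: int
) -> tuple[float, float]:
    """Precision and recall of the top-h ranked genes against the planted set.

    precision = |top-h ∩ planted| / h ; recall = |top-h ∩ planted| / n_de.
    """
    if h > len(table):
        raise ValueError(f"h={h} exceeds table size {len(table)}")
    ranked = list(table["gene_id"].astype(str).head(h))
    if truth.gene_ids:
        universe = set(truth.gene_ids)
        unknown = [g for g in ranked if g not in universe]
        if unknown:
            raise ValueError(f"unknown gene ids in ranking: {unknown[:5]}")
    hits = len(set(ranked) & truth.de_gene_ids)
    n_de = len(truth.de_gene_ids)
    precision = hits / h
    recall = hits / n_de if n_de else 0.0
    return precision, recall
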