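"""The SLDSF model: a greedy stack of sparse-filtering layers over samples.

The model is fitted layer by layer.  Layer 1 sees the standardized
expression matrix X (n samples x m genes).  Each subsequent layer sees the
previous layer's optimal sample distribution after L2 normalization by
rows then by columns, so every layer's input columns lie on the unit
L2-ball.  No joint fine-tuning pass is made across layers.

Gene selection reads the final layer's sample distribution: genes whose
columns carry large total activity across the learned samples are the most
differentially expressed, so the evaluating vector is the vector of column
sums and the top-h genes by that score are the characteristic genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .filtering import (
    DEFAULT_GTOL,
    DEFAULT_HISTORY,
    DEFAULT_MAX_ITER,
    LayerFit,
    fit_layer,
    l2_normalize_columns,
)
from .io import ExpressionMatrix, validate_ranking
from .preprocess import standardize

DEFAULT_N_LAYERS = 3
DEFAULT_LAYER_SIZE = 200
DEFAULT_TOP_GENES = 100


def interlayer_normalize(S: np.ndarray) -> np.ndarray:
    """Normalize a sample distribution by rows then by columns (L2).

    Row norms are accumulated over value-sorted squares so the result is
    bitwise invariant to the order of the gene columns (the column-norm
    step sums over the sample axis and is order-invariant already).
    """
    S = np.asarray(S, dtype=float)
    sq = np.ascontiguousarray(np.sort(S * S, axis=1))
    row_norms = np.sqrt(sq.sum(axis=1, keepdims=True))
    row_norms = np.where(row_norms < 1e-12, 1e-8, row_norms)
    return l2_normalize_columns(S / row_norms)


def evaluating_vector(S: np.ndarray) -> np.ndarray:
    """Column sums of absolute activity: one score per gene.

    The optimal sample distribution is positive by construction, so the
    absolute value is a no-op there; it is retained so the operation is
    safe on arbitrary matrices.
    """
    S = np.asarray(S, dtype=float)
    return np.abs(S).sum(axis=0)


def select_top_genes(scores: np.ndarray, gene_ids: list[str], h: int) -> pd.DataFrame:
    """Rank genes by score descending and keep the top h.

    Ties are broken by ascending input gene index (stable sort), so the
    ranking is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[0]
    if len(gene_ids) != m:
        raise ValueError("gene_ids length does not match score vector")
    if not 1 <= h <= m:
        raise ValueError(f"h must be in [1, {m}], got {h}")
    order = np.argsort(-scores, kind="stable")[:h]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, h + 1),
            "gene_id": [gene_ids[j] for j in order],
            "score": scores[order],
        }
    )
    return validate_ranking(table)


class SLDSF:
    """Sample-learning deep sparse filtering over a gene-expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix or DataFrame or ndarray
        Raw expression matrix, samples x genes.  A DataFrame's index is
        taken as sample ids and columns as gene ids.
    n_layers : int
        Number of sparse-filtering layers k (default 3).
    layer_sizes : int or sequence of int
        Learned samples t per layer; a scalar is used for every layer
        (default 200).
    standardize_input : bool
        Row-standardize the raw matrix before layer 1 (default True; turn
        off only if the input is already standardized).
    max_iter, gtol, history_size
        L-BFGS settings shared by all layers.

    Examples
    --------
    >>> model = SLDSF(expr, n_layers=2, layer_sizes=20)
    >>> results = model.fit(seed=1)
    >>> results.top_genes(h=25)
    """

    def __init__(
        self,
        data,
        n_layers: int = DEFAULT_N_LAYERS,
        layer_sizes=DEFAULT_LAYER_SIZE,
        standardize_input: bool = True,
        max_iter: int = DEFAULT_MAX_ITER,
        gtol: float = DEFAULT_GTOL,
        history_size: int = DEFAULT_HISTORY,
    ) -> None:
        if isinstance(data, ExpressionMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = ExpressionMatrix.from_frame(data, orientation="samples_in_rows")
        else:
            self.data = ExpressionMatrix(values=np.asarray(data, dtype=float))
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if np.isscalar(layer_sizes):
            layer_sizes = [int(layer_sizes)] * n_layers
        else:
            layer_sizes = [int(t) for t in layer_sizes]
        if len(layer_sizes) != n_layers:
            raise ValueError(
                f"layer_sizes has {len(layer_sizes)} entries but n_layers={n_layers}"
            )
        if any(t < 1 for t in layer_sizes):
            raise ValueError("every layer size must be >= 1")
        self.n_layers = int(n_layers)
        self.layer_sizes = layer_sizes
        self.standardize_input = bool(standardize_input)
        self.max_iter = int(max_iter)
        self.gtol = float(gtol)
        self.history_size = int(history_size)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, orientation: str = "genes_in_rows", **kwargs
    ) -> "SLDSF":
        """Build a model from a DataFrame in either file orientation."""
        return cls(ExpressionMatrix.from_frame(frame, orientation=orientation), **kwargs)

    def fit(self, seed: int = 0) -> "SLDSFResults":
        """Greedy layer-wise training; reproducible from the seed.

        Layer i draws its initialization from ``seed + i`` so adding a
        layer never perturbs the layers before it.
        """
        X = standardize(self.data).values if self.standardize_input else self.data.values
        layers: list[LayerFit] = []
        current = X
        for i, t in enumerate(self.layer_sizes, start=1):
            fit = fit_layer(
                current,
                t=t,
                seed=seed + i,
                max_iter=self.max_iter,
                gtol=self.gtol,
                history_size=self.history_size,
            )
            layers.append(fit)
            current = interlayer_normalize(fit.distribution)
        return SLDSFResults(model=self, layers=layers, seed=int(seed))


@dataclass
class SLDSFResults:
    """Fitted SLDSF stack: per-layer fits, final distribution, gene scores."""

    model: SLDSF
    layers: list[LayerFit]
    seed: int

    @property
    def final_distribution(self) -> np.ndarray:
        """Optimal sample distribution of the last layer (t_k x m)."""
        return self.layers[-1].distribution

    @property
    def evaluating_vector(self) -> pd.Series:
        """Per-gene scores (column sums of the final distribution)."""
        return pd.Series(
            evaluating_vector(self.final_distribution),
            index=self.model.data.gene_ids,
            name="score",
        )

    def top_genes(self, h: int = DEFAULT_TOP_GENES) -> pd.DataFrame:
        """Ranked table of the h highest-scoring (characteristic) genes."""
        return select_top_genes(
            self.evaluating_vector.to_numpy(), self.model.data.gene_ids, h
        )

    def summary(self) -> str:
        """Human-readable fit report: configuration and per-layer descent."""
        data = self.model.data
        lines = [
            "Sample-Learning Deep Sparse Filtering",
            "=" * 53,
            f"Input matrix:      {data.n_samples} samples x {data.n_genes} genes",
            f"Layers (k):        {self.model.n_layers}",
            f"Layer sizes (t):   {self.model.layer_sizes}",
            f"Seed:              {self.seed}",
            "",
            f"{'layer':>5} {'t':>5} {'iters':>6} {'J initial':>12} {'J final':>12} {'conv':>5}",
        ]
        for i, layer in enumerate(self.layers, start=1):
            lines.append(
                f"{i:>5} {layer.distribution.shape[0]:>5} {layer.n_iterations:>6} "
                f"{layer.initial_objective:>12.4f} {layer.final_objective:>12.4f} "
                f"{'yes' if layer.converged else 'no':>5}"
            )
        top = self.top_genes(h=min(5, data.n_genes))
        lines += ["", "Top genes by evaluating score:"]
        for row in top.itertuples(index=False):
            lines.append(f"  {row.rank:>3}  {row.gene_id:<16} {row.score:.4f}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Serialize the fitted stack: one filter matrix per layer + manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, layer in enumerate(self.layers, start=1):
            np.savetxt(directory / f"layer{i}_filter.tsv", layer.filter, delimiter="\t")
        np.savetxt(
            directory / "final_distribution.tsv",
            self.final_distribution,
            delimiter="\t",
        )
        manifest = {
            "version": _pkg_version,
            "n_layers": self.model.n_layers,
            "layer_sizes": ",".join(str(t) for t in self.model.layer_sizes),
            "seed": self.seed,
            "max_iter": self.model.max_iter,
            "gtol": self.model.gtol,
            "history_size": self.model.history_size,
            "standardize_input": self.model.standardize_input,
            "n_samples": self.model.data.n_samples,
            "n_genes": self.model.data.n_genes,
        }
        write_manifest(manifest, directory / "manifest.txt")


def write_manifest(entries: dict, path) -> None:
    """Write a key=value manifest, one entry per line, keys in given order."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")


def read_manifest(path) -> dict:
    entries = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, value = line.split("=", 1)
                entries[key] = value
    return entries


def fit_sldsf(
    X: np.ndarray,
    k: int,
    layer_sizes,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SLDSFResults:
    """Functional entry point: fit a k-layer stack on an already
    standardized matrix X (n x m)."""
    model = SLDSF(
        np.asarray(X, dtype=float),
        n_layers=k,
        layer_sizes=layer_sizes,
        standardize_input=False,
        max_iter=max_iter,
    )
    return model.fit(seed=seed)
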