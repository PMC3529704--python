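"""Discretization of continuous expression matrices.

Scoring operates on discrete levels; continuous data is binned per gene
into a fixed number of levels before any mutual-information computation.
Equal-frequency binning (boundaries at empirical quantiles) is the
default; equal-width splits each gene's observed range uniformly.  Both
are applied independently per gene, and a value equal to a boundary is
assigned to the lower level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GeneTable, TimeSeriesDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["DiscretizationSpec", "discretize", "discretize_dataset"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """How to map continuous expression to discrete levels.

    ``levels`` is the target alphabet size per gene (3 by default, the
    usual choice for MI-based network scoring); ``method`` is
    "equal-frequency" or "equal-width".
    """

    levels: int = 3
    method: str = "equal-frequency"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        if self.method not in ("equal-frequency", "equal-width"):
            raise ValidationError(f"unknown discretization method {self.method!r}")


def _gene_boundaries(values: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    if spec.method == "equal-frequency":
        qs = np.arange(1, spec.levels) / spec.levels
        return np.quantile(values, qs)
    lo, hi = float(values.min()), float(values.max())
    return np.linspace(lo, hi, spec.levels + 1)[1:-1]


def discretize(
    matrix: np.ndarray,
    spec: DiscretizationSpec = DiscretizationSpec(),
    gene_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a continuous genes x time matrix per gene.

    Returns ``(levels_matrix, boundaries)`` where ``levels_matrix`` has
    values in ``{0, ..., levels-1}`` and ``boundaries`` is a
    (n_genes, levels-1) array of bin edges.  A value ties with a
    boundary to the lower level.  A constant gene triggers a warning
    and maps entirely to level 0 (its declared arity stays ``levels``,
    so degrees of freedom then overcount).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("expected a 2-D genes x time matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValidationError("matrix contains non-finite values")
    n_genes = matrix.shape[0]
    out = np.empty_like(matrix, dtype=np.int64)
    bounds = np.empty((n_genes, spec.levels - 1), dtype=float)
    for g in range(n_genes):
        vals = matrix[g]
        name = gene_names[g] if gene_names else f"gene {g + 1}"
        if vals.min() == vals.max():
            logger.warning(
                "%s has constant expression; all values mapped to level 0 "
                "(declared arity %d will overcount degrees of freedom)",
                name, spec.levels,
            )
            bounds[g] = np.full(spec.levels - 1, vals[0])
            out[g] = 0
            continue
        b = _gene_boundaries(vals, spec)
        # strictly increasing boundaries; collapse duplicates from heavy ties
        b = np.maximum.accumulate(b)
        bounds[g] = b
        # side="left": value == boundary falls in the lower bin
        out[g] = np.searchsorted(b, vals, side="left")
    return out, bounds


def discretize_dataset(
    series: list[np.ndarray],
    gene_names: list[str],
    spec: DiscretizationSpec = DiscretizationSpec(),
    periodic: bool = False,
) -> tuple[TimeSeriesDataset, np.ndarray]:
    """Discretize one or more continuous series into a TimeSeriesDataset.

    Boundaries are estimated from the values pooled across series so
    that levels are comparable between replicates; each series is then
    binned with the shared per-gene boundaries.  Already-discrete
    integer input with ``max < levels`` is accepted verbatim.
    """
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in series], axis=1)
    if _looks_prediscretized(pooled, spec.levels):
        logger.info("input is pre-discretized (integer levels < %d); used verbatim", spec.levels)
        table = GeneTable.uniform(gene_names, spec.levels)
        ds = TimeSeriesDataset([np.asarray(s).astype(np.int64) for s in series],
                              table, periodic=periodic)
        return ds, np.empty((len(gene_names), 0))
    _, bounds = discretize(pooled, spec, gene_names)
    disc_series = []
    for s in series:
        s = np.asarray(s, dtype=float)
        levels = np.empty_like(s, dtype=np.int64)
        for g in range(s.shape[0]):
            levels[g] = np.searchsorted(bounds[g], s[g], side="left")
        disc_series.append(levels)
    table = GeneTable.uniform(gene_names, spec.levels)
    return TimeSeriesDataset(disc_series, table, periodic=periodic), bounds


def _looks_prediscretized(matrix: np.ndarray, levels: int) -> bool:
    return bool(
        np.all(matrix == np.floor(matrix))
        and matrix.min() >= 0
        and matrix.max() < levels
    )
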