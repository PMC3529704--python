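"""Lag alignment of time-series samples for a child and its parents.

When a child's parents act with different regulation orders, the sample
rows used for mutual information must align each parent column at its
own lag.  For aperiodic data only the child times t in [delta, N-1] are
usable (delta = the maximum lag in the parent set), leaving N - delta
effective samples per series; periodic data wraps circularly and keeps
all N samples.  Multiple series are aligned independently and their
rows pooled — a lag never crosses a series boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LaggedParentSet, TimeSeriesDataset

__all__ = ["AlignmentError", "AlignedTable", "effective_sample_count", "build_aligned_table"]


class AlignmentError(ValueError):
    """No usable aligned samples exist for the requested lags."""


@dataclass
class AlignedTable:
    """Column-aligned samples for one child and its lagged parents.

    ``parent_columns`` holds one level vector per (parent, lag) pair in
    the order given by ``parent_pairs``; all columns share length
    ``effective_n``.
    """

    child_column: np.ndarray
    parent_columns: list[np.ndarray]
    parent_pairs: list[tuple[int, int]]
    effective_n: int
    max_lag_used: int

    def __post_init__(self) -> None:
        if self.effective_n <= 0:
            raise AlignmentError("aligned table has no rows")
        assert len(self.child_column) == self.effective_n
        assert all(len(c) == self.effective_n for c in self.parent_columns)


def effective_sample_count(N: int, delta: int, periodic: bool) -> int:
    """Usable sample count for one series of N points at maximum lag delta.

    Periodic data keeps all N points (circular shift); aperiodic data
    loses the first ``delta`` child times, leaving N - delta.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if periodic:
        return N
    if delta >= N:
        raise AlignmentError(
            f"maximum lag {delta} leaves no samples in an aperiodic series of length {N}"
        )
    return N - delta


def build_aligned_table(
    dataset: TimeSeriesDataset, child: int, parents: LaggedParentSet
) -> AlignedTable:
    """Build the pooled aligned sample table for ``child`` and ``parents``.

    For each series: aperiodic rows are child times t in [delta, N_s-1]
    with each parent read at t - lag; periodic rows cover all t with
    the parent index taken modulo N_s.  An aperiodic series shorter
    than delta + 1 contributes no rows; if every series is empty an
    AlignmentError is raised.
    """
    pairs = parents.pairs()
    delta = parents.delta
    child_parts: list[np.ndarray] = []
    parent_parts: list[list[np.ndarray]] = [[] for _ in pairs]
    for arr in dataset.series:
        n_s = arr.shape[1]
        if dataset.periodic:
            child_parts.append(arr[child])
            for col, (p, lag) in enumerate(pairs):
                # np.roll(x, lag)[t] == x[t - lag] (mod N_s)
                parent_parts[col].append(np.roll(arr[p], lag))
        else:
            if n_s <= delta:
                continue
            child_parts.append(arr[child, delta:])
            for col, (p, lag) in enumerate(pairs):
                parent_parts[col].append(arr[p, delta - lag : n_s - lag])
    if not child_parts:
        raise AlignmentError(
            f"no series is long enough for maximum lag {delta} (aperiodic data)"
        )
    child_col = np.concatenate(child_parts)
    parent_cols = [np.concatenate(parts) for parts in parent_parts]
    return AlignedTable(
        child_column=child_col,
        parent_columns=parent_cols,
        parent_pairs=pairs,
        effective_n=len(child_col),
        max_lag_used=delta,
    )
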