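"""Domain types and text I/O for delay-annotated gene regulatory networks.

A regulatory network over ``n`` genes is a set of ``(regulator, target,
lag)`` arcs.  Lag-0 arcs are instantaneous (intra-slice) regulations and
must form a DAG.  Arcs with lag >= 1 point from an earlier time slice
into the present slice and can therefore never close a temporal cycle,
so cyclic regulatory motifs such as A <=> B remain representable, e.g.
as ``{(A, B, 0), (B, A, 1)}``.  Unrolling any network that satisfies the
lag-0 acyclicity condition over time yields a proper DAG.

Conventions: gene identity is positional (integer index) internally;
names are metadata resolved at I/O boundaries.  Matrices are genes x
time, with 0-based time indices internally and 1-based indices in
user-facing messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "FormatError",
    "GeneTable",
    "TimeSeriesDataset",
    "LaggedArc",
    "LaggedParentSet",
    "DelayAnnotatedNetwork",
    "read_expression_matrix",
    "read_network_edgelist",
    "write_network_edgelist",
    "export_dot",
]


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """An input file does not match its expected text format."""


@dataclass(frozen=True)
class GeneTable:
    """Ordered gene identifiers with their discrete alphabet sizes.

    ``arities[p]`` is the number of levels gene ``p`` can take after
    discretization (r_p), used for degrees-of-freedom computations.
    """

    names: tuple[str, ...]
    arities: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValidationError("gene table must contain at least one gene")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValidationError(f"duplicate gene names: {dupes}")
        if len(self.arities) != len(self.names):
            raise ValidationError("names and arities must have equal length")
        if any(r < 2 for r in self.arities):
            raise ValidationError("every gene arity must be >= 2")

    @property
    def n_genes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def uniform(cls, names: Sequence[str], arity: int) -> "GeneTable":
        return cls(tuple(names), (arity,) * len(names))


@dataclass
class TimeSeriesDataset:
    """One or more discrete expression time series over a common gene set.

    Each series is an integer matrix of shape (n_genes, N_s) with values
    in ``[0, arity)`` per gene.  ``periodic`` marks data that may be
    wrapped circularly during lag alignment (e.g. cell-cycle series).
    """

    series: list[np.ndarray]
    gene_table: GeneTable
    periodic: bool = False

    def __post_init__(self) -> None:
        if not self.series:
            raise ValidationError("dataset must contain at least one series")
        cleaned = []
        for s_idx, arr in enumerate(self.series):
            arr = np.asarray(arr)
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(arr == np.floor(arr)):
                    raise ValidationError(
                        f"series {s_idx + 1} contains non-integer levels"
                    )
                arr = arr.astype(np.int64)
            if arr.ndim != 2 or arr.shape[0] != self.gene_table.n_genes:
                raise ValidationError(
                    f"series {s_idx + 1} must be a genes x time matrix with "
                    f"{self.gene_table.n_genes} rows"
                )
            if arr.shape[1] < 2:
                raise ValidationError(f"series {s_idx + 1} has fewer than 2 time points")
            if arr.min() < 0:
                raise ValidationError(f"series {s_idx + 1} contains negative levels")
            for g, r in enumerate(self.gene_table.arities):
                if arr[g].max() >= r:
                    raise ValidationError(
                        f"gene {self.gene_table.names[g]!r} in series {s_idx + 1} "
                        f"exceeds its arity {r}"
                    )
            cleaned.append(arr)
        self.series = cleaned

    @property
    def n_genes(self) -> int:
        return self.gene_table.n_genes

    @property
    def n_timepoints(self) -> list[int]:
        return [arr.shape[1] for arr in self.series]


class LaggedArc(NamedTuple):
    """A regulation ``regulator -> target`` acting with a ``lag``-step delay."""

    regulator: int
    target: int
    lag: int


@dataclass(frozen=True)
class LaggedParentSet:
    """A child's parents partitioned by regulation order (lag).

    ``by_lag[k]`` lists the parent gene indices regulating ``child``
    with a k-step delay; the union over lags is the full parent set.
    """

    child: int
    by_lag: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for lag, parents in self.by_lag.items():
            if lag < 0:
                raise ValidationError("lags must be non-negative")
            for p in parents:
                if (p, lag) in seen:
                    raise ValidationError(f"duplicate parent (gene {p}, lag {lag})")
                seen.add((p, lag))

    @property
    def delta(self) -> int:
        """Maximum populated regulation order (0 for an empty set)."""
        lags = [k for k, ps in self.by_lag.items() if ps]
        return max(lags) if lags else 0

    @property
    def size(self) -> int:
        return sum(len(ps) for ps in self.by_lag.values())

    def pairs(self) -> list[tuple[int, int]]:
        """All (parent, lag) pairs, lags ascending, parents in listed order."""
        out = []
        for lag in sorted(self.by_lag):
            out.extend((p, lag) for p in self.by_lag[lag])
        return out

    def union(self) -> set[int]:
        return {p for ps in self.by_lag.values() for p in ps}

    @classmethod
    def empty(cls, child: int) -> "LaggedParentSet":
        return cls(child, {})


@dataclass
class DelayAnnotatedNetwork:
    """Network with instantaneous and multi-step delayed arcs.

    Equivalent to an adjacency representation with an instantaneous half
    (lag-0 arcs) and a delayed half annotated with the regulation order.
    At most one arc may exist per (regulator, target, lag) triple; a
    given ordered pair may carry both a lag-0 arc and lagged arcs.
    """

    gene_table: GeneTable
    arcs: set[LaggedArc] = field(default_factory=set)
    d_max: int = 3
    allow_self_lagged: bool = False

    def __post_init__(self) -> None:
        self.arcs = {LaggedArc(*a) for a in self.arcs}
        for arc in self.arcs:
            self._check_arc(arc)
        self._check_lag0_acyclic()

    def _check_arc(self, arc: LaggedArc) -> None:
        n = self.gene_table.n_genes
        if not (0 <= arc.regulator < n and 0 <= arc.target < n):
            raise ValidationError(f"arc {arc} references an unknown gene index")
        if not (0 <= arc.lag <= self.d_max):
            raise ValidationError(f"arc {arc} has lag outside [0, {self.d_max}]")
        if arc.regulator == arc.target:
            if arc.lag == 0:
                raise ValidationError(
                    f"lag-0 self-loop on gene {self.gene_table.names[arc.target]!r}"
                )
            if not self.allow_self_lagged:
                raise ValidationError(
                    f"lagged self-arc on gene {self.gene_table.names[arc.target]!r} "
                    "is disabled (allow_self_lagged=False)"
                )

    def _lag0_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.gene_table.n_genes))
        g.add_edges_from((a.regulator, a.target) for a in self.arcs if a.lag == 0)
        return g

    def _check_lag0_acyclic(self) -> None:
        g = self._lag0_graph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        names = self.gene_table.names
        path = " -> ".join(names[u] for u, _ in cycle) + f" -> {names[cycle[0][0]]}"
        raise ValidationError(f"instantaneous (lag-0) arcs form a cycle: {path}")

    def has_arc(self, regulator: int, target: int, lag: int) -> bool:
        return LaggedArc(regulator, target, lag) in self.arcs

    def add_arc(self, regulator: int, target: int, lag: int) -> None:
        arc = LaggedArc(regulator, target, lag)
        if arc in self.arcs:
            raise ValidationError(f"arc {arc} already present")
        self._check_arc(arc)
        if arc.lag == 0 and self.lag0_path_exists(target, regulator):
            raise ValidationError(
                f"adding lag-0 arc {self.gene_table.names[regulator]!r} -> "
                f"{self.gene_table.names[target]!r} would create a cycle"
            )
        self.arcs.add(arc)

    def remove_arc(self, regulator: int, target: int, lag: int) -> None:
        arc = LaggedArc(regulator, target, lag)
        if arc not in self.arcs:
            raise ValidationError(f"arc {arc} not present")
        self.arcs.remove(arc)

    def lag0_path_exists(self, src: int, dst: int) -> bool:
        """True if dst is reachable from src through lag-0 arcs."""
        if src == dst:
            return True
        adj: dict[int, list[int]] = {}
        for a in self.arcs:
            if a.lag == 0:
                adj.setdefault(a.regulator, []).append(a.target)
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v == dst:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def parent_set(self, child: int) -> LaggedParentSet:
        by_lag: dict[int, list[int]] = {}
        for a in sorted(self.arcs):
            if a.target == child:
                by_lag.setdefault(a.lag, []).append(a.regulator)
        return LaggedParentSet(child, {k: tuple(v) for k, v in by_lag.items()})

    def in_degree(self, child: int) -> int:
        return sum(1 for a in self.arcs if a.target == child)

    def lag0_topological_order(self) -> list[int]:
        return list(nx.topological_sort(self._lag0_graph()))

    def copy(self) -> "DelayAnnotatedNetwork":
        return DelayAnnotatedNetwork(
            self.gene_table, set(self.arcs), self.d_max, self.allow_self_lagged
        )

    def sorted_arcs(self) -> list[LaggedArc]:
        return sorted(self.arcs)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


def _sniff_delimiter(first_line: str) -> str:
    return "," if first_line.count(",") > first_line.count("\t") else "\t"


def read_expression_matrix(
    path, orientation: str = "genes-in-rows"
) -> tuple[np.ndarray, list[str]]:
    """Read a delimited expression table into a genes x time float matrix.

    The file has one header line of identifiers and one label per data
    row.  With ``orientation="genes-in-rows"`` the row labels are gene
    names; with ``"genes-in-columns"`` the header holds the gene names
    and the matrix is transposed on read so the result is always genes x
    time in the original gene order.
    """
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected a header line and at least one data row")
    sep = _sniff_delimiter(lines[0])
    header = lines[0].split(sep)
    rows = [ln.split(sep) for ln in lines[1:]]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"{path}: ragged input, data row {i + 1} has {len(r)} fields, "
                f"expected {width}"
            )
    # Header may or may not carry a corner label above the row-label column.
    if len(header) == width:
        header = header[1:]
    elif len(header) != width - 1:
        raise FormatError(
            f"{path}: header has {len(header)} identifiers for rows of "
            f"{width - 1} values"
        )
    row_labels = [r[0] for r in rows]
    values = np.empty((len(rows), width - 1), dtype=float)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at data row {i + 1}, "
                    f"column {j + 1}"
                ) from None
    if orientation == "genes-in-rows":
        names, matrix = row_labels, values
    else:
        names, matrix = header, values.T
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"{path}: duplicate gene names {dupes}")
    logger.info(
        "read expression matrix %s: %d genes x %d time points",
        path, matrix.shape[0], matrix.shape[1],
    )
    return matrix, list(names)


def read_network_edgelist(
    path,
    gene_names: Sequence[str] | None = None,
    d_max: int | None = None,
    default_arity: int = 3,
    allow_self_lagged: bool = False,
) -> DelayAnnotatedNetwork:
    """Read a 3-column (regulator, target, lag) edge list.

    Gene order is taken from ``gene_names`` when given, else from a
    ``# genes:`` comment line if present (this preserves isolated
    genes), else from first appearance in the arcs.  Lag-0 acyclicity
    is validated on read.  Arities are not stored in edge lists;
    ``default_arity`` is recorded for every gene.
    """
    triples: list[tuple[str, str, int]] = []
    declared: list[str] | None = None
    first_record = True
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if ln.startswith("# genes:"):
                declared = [nm for nm in ln[len("# genes:"):].strip().split("\t") if nm]
                continue
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("," if "," in ln and "\t" not in ln else "\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 fields (regulator, target, lag), "
                    f"got {len(parts)}"
                )
            reg, tgt, lag_s = (p.strip() for p in parts)
            if first_record and not _is_int(lag_s):
                first_record = False
                continue  # header line
            first_record = False
            if not _is_int(lag_s):
                raise FormatError(f"{path}:{lineno}: lag {lag_s!r} is not an integer")
            triples.append((reg, tgt, int(lag_s)))
    if gene_names is not None:
        names = list(gene_names)
    elif declared is not None:
        names = declared
    else:
        names = []
        for reg, tgt, _ in triples:
            for nm in (reg, tgt):
                if nm not in names:
                    names.append(nm)
    if not names:
        names = ["_placeholder"]
    table = GeneTable.uniform(names, default_arity)
    idx = {nm: i for i, nm in enumerate(names)}
    max_lag = max((lag for _, _, lag in triples), default=0)
    arcs = set()
    for reg, tgt, lag in triples:
        if reg not in idx or tgt not in idx:
            raise ValidationError(f"{path}: arc references unknown gene {reg!r} or {tgt!r}")
        arc = LaggedArc(idx[reg], idx[tgt], lag)
        if arc in arcs:
            raise ValidationError(f"{path}: duplicate arc ({reg}, {tgt}, {lag})")
        arcs.add(arc)
    net = DelayAnnotatedNetwork(
        table,
        arcs,
        d_max=d_max if d_max is not None else max(max_lag, 0) or 3,
        allow_self_lagged=allow_self_lagged,
    )
    logger.info("read network %s: %d genes, %d arcs", path, len(names), len(arcs))
    return net


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_network_edgelist(network: DelayAnnotatedNetwork, path) -> None:
    """Write the 3-column edge list, with the full gene universe recorded
    in a ``# genes:`` comment so isolated genes survive a round-trip."""
    names = network.gene_table.names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# genes:\t" + "\t".join(names) + "\n")
        fh.write("regulator\ttarget\tlag\n")
        for arc in network.sorted_arcs():
            fh.write(f"{names[arc.regulator]}\t{names[arc.target]}\t{arc.lag}\n")
    logger.info("wrote network %s: %d arcs", path, network.n_arcs)


def export_dot(network: DelayAnnotatedNetwork, path) -> None:
    """Write the network in DOT format.

    Lag-0 arcs are drawn solid; delayed arcs are dashed and labeled
    with their regulation order.  Arcs at different lags between the
    same gene pair appear as distinct edges.
    """
    names = network.gene_table.names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("digraph network {\n")
        for nm in names:
            fh.write(f'  "{nm}";\n')
        for arc in network.sorted_arcs():
            attrs = "" if arc.lag == 0 else f' [label="{arc.lag}", style=dashed]'
            fh.write(f'  "{names[arc.regulator]}" -> "{names[arc.target]}"{attrs};\n')
        fh.write("}\n")
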