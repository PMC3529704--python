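"""Ground-truth network generation and forward sampling of discrete series.

Every test input of the package can be produced here: random
lag-annotated DAGs, multinomial conditional probability tables (CPTs)
from three families, and discrete time series forward-sampled from
them.

CPD families
------------
binomial-noisy
    One binary parent, binary child.  Excitation: P(on|on) = 0.9,
    P(on|off) = 0.1; inhibition swaps the two.
noisy-xor
    Two binary parents, binary child, likely on iff exactly one parent
    is on: P(on|on,on) = P(on|off,off) = 0.1,
    P(on|on,off) = P(on|off,on) = 0.9.
dirichlet
    For a child with k levels, a basis vector is built by normalizing
    (1, 1/2, ..., 1/k); for the j-th parent instantiation the row is
    drawn from Dirichlet(s * alpha_j) with the basis cyclically
    right-shifted by (j mod k) positions and s the equivalent sample
    size.  The shifts keep d-connected variables visibly dependent.

Forward sampling fills the first d_max time slices with per-gene
uniform draws, then samples each later slice in lag-0 topological
order, each gene conditioned on its parents read at their respective
lags (lag-0 parents in the current, already-sampled slice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    DelayAnnotatedNetwork,
    GeneTable,
    LaggedArc,
    TimeSeriesDataset,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CPDSpec",
    "GroundTruth",
    "random_network",
    "make_cpd",
    "sample_timeseries",
    "make_benchmark",
]

CPD_FAMILIES = ("binomial-noisy", "noisy-xor", "dirichlet", "explicit-table")


@dataclass(frozen=True)
class CPDSpec:
    """Recipe for one gene's conditional probability table.

    ``params`` is family-specific: ``role`` ("excitation"/"inhibition"),
    ``p_on_on``/``p_on_off`` for binomial-noisy; ``flip`` for
    noisy-xor; ``ess`` for dirichlet; ``table`` for explicit-table.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in CPD_FAMILIES:
            raise ValidationError(f"unknown CPD family {self.family!r}")


@dataclass
class GroundTruth:
    """A generating network with realized CPTs for every gene.

    ``cpds[g]`` is an array of shape (n_parent_configs, arity_g) whose
    rows sum to 1; the parent configuration index follows the order of
    ``DelayAnnotatedNetwork.parent_set(g).pairs()``.  Genes listed in
    ``confounder_indices`` carry no arcs at all and act as pure-noise
    controls for false-positive behavior.
    """

    network: DelayAnnotatedNetwork
    cpds: dict[int, np.ndarray]
    confounder_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for g in range(self.network.gene_table.n_genes):
            pset = self.network.parent_set(g)
            n_cfg = int(
                np.prod(
                    [self.network.gene_table.arities[p] for p, _ in pset.pairs()]
                )
            ) if pset.size else 1
            cpt = np.asarray(self.cpds[g], dtype=float)
            if cpt.shape != (n_cfg, self.network.gene_table.arities[g]):
                raise ValidationError(
                    f"CPT of gene {g} has shape {cpt.shape}, expected "
                    f"({n_cfg}, {self.network.gene_table.arities[g]})"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12):
                raise ValidationError(f"CPT rows of gene {g} do not sum to 1")
            self.cpds[g] = cpt


def random_network(
    n_genes: int,
    n_arcs: int,
    d_max: int,
    seed: int | np.random.Generator | None = None,
    gene_table: GeneTable | None = None,
    lags: Sequence[int] | None = None,
    max_in_degree: int | None = None,
    allow_self_lagged: bool = False,
) -> DelayAnnotatedNetwork:
    """Draw a random delay-annotated network.

    Ordered gene pairs are drawn uniformly and each arc's regulation
    order uniformly from ``lags`` (default 0..d_max); draws violating
    lag-0 acyclicity, duplicate-arc or in-degree constraints are
    rejected and redrawn, with a bounded retry budget.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gene_table is None:
        gene_table = GeneTable.uniform([f"G{i + 1}" for i in range(n_genes)], 2)
    lags = tuple(lags) if lags is not None else tuple(range(d_max + 1))
    net = DelayAnnotatedNetwork(gene_table, set(), d_max, allow_self_lagged)
    budget = 1000 * max(n_arcs, 1)
    while net.n_arcs < n_arcs and budget > 0:
        budget -= 1
        reg = int(rng.integers(0, n_genes))
        tgt = int(rng.integers(0, n_genes))
        lag = int(lags[rng.integers(0, len(lags))])
        if reg == tgt and (lag == 0 or not allow_self_lagged):
            continue
        if net.has_arc(reg, tgt, lag):
            continue
        if max_in_degree is not None and net.in_degree(tgt) >= max_in_degree:
            continue
        if lag == 0 and net.lag0_path_exists(tgt, reg):
            continue
        net.add_arc(reg, tgt, lag)
    if net.n_arcs < n_arcs:
        raise ValidationError(
            f"could not place {n_arcs} arcs on {n_genes} genes under the given "
            "constraints (retry budget exhausted)"
        )
    return net


def _dirichlet_basis(k: int) -> np.ndarray:
    v = 1.0 / np.arange(1, k + 1)
    return v / v.sum()


def make_cpd(
    spec: CPDSpec,
    parent_arities: Sequence[int],
    child_arity: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Realize a CPD spec as an explicit (n_configs, child_arity) table.

    Parent configurations are indexed by ``np.ravel_multi_index`` over
    the parent columns in their listed order (first parent varies
    slowest).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cfg = int(np.prod(parent_arities)) if len(parent_arities) else 1
    if spec.family == "binomial-noisy":
        if child_arity != 2 or list(parent_arities) != [2]:
            raise ValidationError(
                "binomial-noisy requires a binary child with one binary parent"
            )
        p_on_on = float(spec.params.get("p_on_on", 0.9))
        p_on_off = float(spec.params.get("p_on_off", 0.1))
        if spec.params.get("role", "excitation") == "inhibition":
            p_on_on, p_on_off = p_on_off, p_on_on
        table = np.array([[1 - p_on_off, p_on_off], [1 - p_on_on, p_on_on]])
    elif spec.family == "noisy-xor":
        if child_arity != 2 or list(parent_arities) != [2, 2]:
            raise ValidationError(
                "noisy-xor requires a binary child with two binary parents"
            )
        flip = float(spec.params.get("flip", 0.1))
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                p_on = flip if a == b else 1 - flip
                rows.append([1 - p_on, p_on])
        table = np.array(rows)
    elif spec.family == "dirichlet":
        ess = float(spec.params.get("ess", 10.0))
        basis = _dirichlet_basis(child_arity)
        table = np.empty((n_cfg, child_arity))
        for j in range(n_cfg):
            alpha_j = np.roll(basis, j % child_arity)
            table[j] = rng.dirichlet(ess * alpha_j)
    elif spec.family == "explicit-table":
        table = np.asarray(spec.params["table"], dtype=float)
        if table.shape != (n_cfg, child_arity):
            raise ValidationError(
                f"explicit table has shape {table.shape}, expected ({n_cfg}, {child_arity})"
            )
    else:  # pragma: no cover - guarded in CPDSpec
        raise ValidationError(f"unknown CPD family {spec.family!r}")
    if table.min() < 0 or table.max() > 1:
        raise ValidationError("CPD probabilities must lie in [0, 1]")
    if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError("CPD rows must sum to 1")
    return table


def sample_timeseries(
    truth: GroundTruth,
    N: int,
    n_series: int = 1,
    seed: int | np.random.Generator | None = None,
    periodic_flag: bool = False,
    burn_in: int = 0,
) -> TimeSeriesDataset:
    """Forward-sample discrete series from a ground-truth network.

    The first ``d_max`` slices of each series are uniform per-gene
    draws; later slices are sampled gene by gene in lag-0 topological
    order, each gene conditioned on its parents' lag-aligned values.
    An optional ``burn_in`` prefix is sampled and discarded.
    Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = truth.network
    table = net.gene_table
    n = table.n_genes
    d_max = net.d_max
    if N <= d_max:
        raise ValidationError(f"N must exceed the network's d_max ({d_max})")
    order = net.lag0_topological_order()
    psets = {g: net.parent_set(g) for g in range(n)}
    series = []
    total_len = N + burn_in
    for _ in range(n_series):
        arr = np.zeros((n, total_len), dtype=np.int64)
        for g in range(n):
            arr[g, :d_max] = rng.integers(0, table.arities[g], size=d_max)
        for t in range(d_max, total_len):
            for g in order:
                pairs = psets[g].pairs()
                if not pairs:
                    row = truth.cpds[g][0]
                else:
                    vals = tuple(arr[p, t - lag] for p, lag in pairs)
                    dims = tuple(table.arities[p] for p, _ in pairs)
                    cfg = int(np.ravel_multi_index(vals, dims))
                    row = truth.cpds[g][cfg]
                arr[g, t] = rng.choice(table.arities[g], p=row)
        series.append(arr[:, burn_in:])
    return TimeSeriesDataset(series, table, periodic=periodic_flag)


def _uniform_cpt(arity: int) -> np.ndarray:
    return np.full((1, arity), 1.0 / arity)


def make_benchmark(
    preset: str,
    N: int,
    seed: int | np.random.Generator | None = None,
    n_series: int = 1,
) -> tuple[GroundTruth, TimeSeriesDataset]:
    """Generate a preset ground truth and matching sampled dataset.

    ``"yeast"``: 12 regulated binary genes with 11 interactions at
    random orders 0-3 (in-degree capped at 2 so each CPD family
    applies), plus 8 arc-free confounder genes for 20 nodes total;
    single-parent children get binomial-noisy CPDs with excitation or
    inhibition chosen at random, two-parent children get noisy-XOR
    co-regulation.

    ``"dirichlet"``: 35 three-level genes with 52 interactions at
    orders 1-2 and Dirichlet-sampled CPDs (equivalent sample size 10).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if preset == "yeast":
        n_core, n_conf, n_arcs, d_max, arity = 12, 8, 11, 3, 2
        n = n_core + n_conf
        names = [f"G{i + 1}" for i in range(n_core)] + [
            f"C{i + 1}" for i in range(n_conf)
        ]
        table = GeneTable.uniform(names, arity)
        core = random_network(
            n_core, n_arcs, d_max, rng, max_in_degree=2,
            gene_table=GeneTable.uniform(names[:n_core], arity),
        )
        net = DelayAnnotatedNetwork(
            table, {LaggedArc(*a) for a in core.arcs}, d_max
        )
        cpds: dict[int, np.ndarray] = {}
        for g in range(n):
            pset = net.parent_set(g)
            if pset.size == 0:
                cpds[g] = _uniform_cpt(arity)
            elif pset.size == 1:
                role = "excitation" if rng.random() < 0.5 else "inhibition"
                cpds[g] = make_cpd(
                    CPDSpec("binomial-noisy", {"role": role}), [2], 2, rng
                )
            else:
                cpds[g] = make_cpd(CPDSpec("noisy-xor"), [2, 2], 2, rng)
        truth = GroundTruth(net, cpds, tuple(range(n_core, n)))
    elif preset == "dirichlet":
        n, n_arcs, d_max, arity, ess = 35, 52, 2, 3, 10.0
        table = GeneTable.uniform([f"G{i + 1}" for i in range(n)], arity)
        net = random_network(
            n, n_arcs, d_max, rng, gene_table=table, lags=(1, 2),
        )
        cpds = {}
        for g in range(n):
            pset = net.parent_set(g)
            par_ar = [arity] * pset.size
            cpds[g] = make_cpd(CPDSpec("dirichlet", {"ess": ess}), par_ar, arity, rng)
        truth = GroundTruth(net, cpds, ())
    else:
        raise ValidationError(f"unknown preset {preset!r}; use 'yeast' or 'dirichlet'")
    data = sample_timeseries(truth, N, n_series=n_series, seed=rng)
    logger.info(
        "%s preset: %d genes, %d arcs, %d x %d dataset",
        preset, truth.network.gene_table.n_genes, truth.network.n_arcs,
        data.n_genes, N,
    )
    return truth, data
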