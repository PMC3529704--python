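"""Structure learning by greedy local search, plus an exhaustive oracle.

The search walks the space of delay-annotated networks with the
classical single-arc operators — addition, deletion and reversal —
starting from the empty graph and, at each step, applying the move
with the largest score improvement until none improves.  Because the
score decomposes into per-child terms, a move only requires rescoring
the one or two children it touches; local scores are cached by
(child, parent set).  Optional random restarts rerun the climb from
random seed graphs and keep the best result.

``exhaustive_search`` enumerates every valid network at very small
sizes and serves as the optimality oracle in tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DelayAnnotatedNetwork, GeneTable, LaggedArc, LaggedParentSet, TimeSeriesDataset
from .score import ScoreBreakdown, ScoreConfig, ccit_score, _node_score

logger = logging.getLogger(__name__)

__all__ = ["SearchConfig", "Move", "neighborhood", "hill_climb", "exhaustive_search"]

# Tie-break priority biases toward sparser, lower-order models.
_KIND_PRIORITY = {"delete": 0, "reverse": 1, "add": 2}


@dataclass(frozen=True)
class Move:
    kind: str  # "add" | "delete" | "reverse"
    arc: LaggedArc

    def sort_key(self) -> tuple:
        return (_KIND_PRIORITY[self.kind], self.arc.lag, self.arc.regulator, self.arc.target)


@dataclass
class SearchConfig:
    """Search parameters on top of a ScoreConfig."""

    score: ScoreConfig = field(default_factory=ScoreConfig)
    max_iterations: int = 10_000
    restarts: int = 0
    seed: int | None = None
    forbid_multi_lag_pairs: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def neighborhood(network: DelayAnnotatedNetwork, config: SearchConfig) -> list[Move]:
    """All valid single-arc moves from the current network.

    Additions cover every absent (regulator, target, lag) triple with
    lag <= d_max that respects the self-arc policy, the fan-in cap and
    lag-0 acyclicity; deletions cover every present arc; reversals
    re-point a present arc at the same lag, under the same constraints.
    """
    cfg = config.score
    n = network.gene_table.n_genes
    moves: list[Move] = []
    in_deg = {i: network.in_degree(i) for i in range(n)}
    pair_has_lag = set()
    if config.forbid_multi_lag_pairs:
        pair_has_lag = {(a.regulator, a.target) for a in network.arcs}

    for arc in network.sorted_arcs():
        moves.append(Move("delete", arc))
        rev = LaggedArc(arc.target, arc.regulator, arc.lag)
        if rev.regulator == rev.target:
            ok = False
        elif rev in network.arcs:
            ok = False
        elif in_deg[rev.target] + 1 > cfg.max_fan_in:
            ok = False
        elif config.forbid_multi_lag_pairs and any(
            (rev.regulator, rev.target) == (b.regulator, b.target) and b != arc
            for b in network.arcs
        ):
            ok = False
        elif arc.lag == 0:
            # reversal removes arc first, so a cycle only arises through other arcs
            trimmed = network.copy()
            trimmed.remove_arc(*arc)
            ok = not trimmed.lag0_path_exists(rev.target, rev.regulator)
        else:
            ok = True
        if ok:
            moves.append(Move("reverse", arc))

    for reg, tgt in itertools.product(range(n), repeat=2):
        if reg == tgt and not cfg.allow_self_lagged:
            continue
        if in_deg[tgt] + 1 > cfg.max_fan_in:
            continue
        if config.forbid_multi_lag_pairs and (reg, tgt) in pair_has_lag:
            continue
        for lag in range(cfg.d_max + 1):
            if lag == 0 and reg == tgt:
                continue
            if network.has_arc(reg, tgt, lag):
                continue
            if lag == 0 and network.lag0_path_exists(tgt, reg):
                continue
            moves.append(Move("add", LaggedArc(reg, tgt, lag)))
    return moves


class _LocalScoreCache:
    """Memoizes per-child local scores across hill-climb iterations."""

    def __init__(self, dataset: TimeSeriesDataset, config: ScoreConfig) -> None:
        self.dataset = dataset
        self.config = config
        self._cache: dict[tuple, float] = {}

    def local(self, child: int, parents: LaggedParentSet) -> float:
        key = (child, tuple(parents.pairs()))
        if key not in self._cache:
            if parents.size == 0:
                self._cache[key] = 0.0
            else:
                self._cache[key] = _node_score(
                    self.dataset, child, parents, self.config
                ).local_score
        return self._cache[key]


def _apply(network: DelayAnnotatedNetwork, move: Move) -> None:
    if move.kind == "add":
        network.add_arc(*move.arc)
    elif move.kind == "delete":
        network.remove_arc(*move.arc)
    else:
        network.remove_arc(*move.arc)
        network.add_arc(move.arc.target, move.arc.regulator, move.arc.lag)


def _affected_children(move: Move) -> set[int]:
    if move.kind == "reverse":
        return {move.arc.target, move.arc.regulator}
    return {move.arc.target}


def _modified_parents(
    current: LaggedParentSet, move: Move, child: int
) -> LaggedParentSet:
    """Parent set of ``child`` after ``move``, without touching the network."""
    by_lag = {k: list(ps) for k, ps in current.by_lag.items()}

    def drop(reg: int, lag: int) -> None:
        by_lag[lag].remove(reg)
        if not by_lag[lag]:
            del by_lag[lag]

    def put(reg: int, lag: int) -> None:
        by_lag.setdefault(lag, []).append(reg)
        by_lag[lag].sort()

    arc = move.arc
    if move.kind == "add" and arc.target == child:
        put(arc.regulator, arc.lag)
    elif move.kind == "delete" and arc.target == child:
        drop(arc.regulator, arc.lag)
    elif move.kind == "reverse":
        if arc.target == child:
            drop(arc.regulator, arc.lag)
        if arc.regulator == child:
            put(arc.target, arc.lag)
    return LaggedParentSet(child, {k: tuple(v) for k, v in by_lag.items()})


def _climb_from(
    start: DelayAnnotatedNetwork,
    dataset: TimeSeriesDataset,
    config: SearchConfig,
    cache: _LocalScoreCache,
) -> tuple[DelayAnnotatedNetwork, float, list[tuple[Move, float]]]:
    net = start.copy()
    parent_sets = {
        child: net.parent_set(child) for child in range(net.gene_table.n_genes)
    }
    local = {child: cache.local(child, ps) for child, ps in parent_sets.items()}
    total = sum(local.values())
    trace: list[tuple[Move, float]] = []
    for _ in range(config.max_iterations):
        best: tuple[float, tuple, Move] | None = None
        for move in neighborhood(net, config):
            gain = 0.0
            for child in _affected_children(move):
                new_ps = _modified_parents(parent_sets[child], move, child)
                gain += cache.local(child, new_ps) - local[child]
            if gain > 1e-12:
                cand = (-gain, move.sort_key(), move)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        move = best[2]
        _apply(net, move)
        for child in _affected_children(move):
            parent_sets[child] = net.parent_set(child)
            local[child] = cache.local(child, parent_sets[child])
        total = sum(local.values())
        trace.append((move, total))
    return net, total, trace


def _random_start(
    table: GeneTable, config: SearchConfig, rng: np.random.Generator
) -> DelayAnnotatedNetwork:
    cfg = config.score
    net = DelayAnnotatedNetwork(table, set(), cfg.d_max, cfg.allow_self_lagged)
    n = table.n_genes
    # start density spans the reachable space, up to the fan-in budget
    n_arcs = int(rng.integers(0, n * cfg.max_fan_in + 1))
    for _ in range(20 * n_arcs):
        if net.n_arcs >= n_arcs:
            break
        reg, tgt = (int(v) for v in rng.integers(0, n, size=2))
        lag = int(rng.integers(0, cfg.d_max + 1))
        try:
            candidate = net.copy()
            candidate.add_arc(reg, tgt, lag)
        except Exception:
            continue
        if candidate.in_degree(tgt) <= cfg.max_fan_in:
            net = candidate
    return net


def hill_climb(
    dataset: TimeSeriesDataset,
    config: SearchConfig = None,
) -> tuple[DelayAnnotatedNetwork, ScoreBreakdown, list[tuple[Move, float]]]:
    """Learn a network by best-improvement hill climbing.

    Starts from the empty graph; with ``restarts > 0`` additional climbs
    start from random seed graphs and the best-scoring result is kept.
    Fully deterministic given ``config.seed``.  Ties between equal-gain
    moves prefer deletion over reversal over addition, then lower lag,
    then lexicographic (regulator, target).
    """
    if config is None:
        config = SearchConfig()
    cache = _LocalScoreCache(dataset, config.score)
    empty = DelayAnnotatedNetwork(
        dataset.gene_table, set(), config.score.d_max, config.score.allow_self_lagged
    )
    best_net, best_total, best_trace = _climb_from(empty, dataset, config, cache)
    if config.restarts:
        rng = np.random.default_rng(config.seed)
        for r in range(config.restarts):
            start = _random_start(dataset.gene_table, config, rng)
            net, total, trace = _climb_from(start, dataset, config, cache)
            if total > best_total + 1e-12 or (
                abs(total - best_total) <= 1e-12
                and net.sorted_arcs() < best_net.sorted_arcs()
            ):
                best_net, best_total, best_trace = net, total, trace
            logger.info("restart %d/%d: score %.4f", r + 1, config.restarts, total)
    breakdown = ccit_score(best_net, dataset, config.score)
    return best_net, breakdown, best_trace


def exhaustive_search(
    dataset: TimeSeriesDataset, config: SearchConfig = None
) -> tuple[DelayAnnotatedNetwork, float]:
    """Globally optimal network by enumeration (test oracle).

    Guarded to n <= 4 genes and d_max <= 1.  Per child, every parent
    set within the fan-in cap is scored; the per-child choices are then
    combined subject to lag-0 acyclicity.  Ties resolve to the
    lexicographically smallest arc set.
    """
    if config is None:
        config = SearchConfig()
    cfg = config.score
    n = dataset.gene_table.n_genes
    if n > 4 or cfg.d_max > 1:
        raise ValueError("exhaustive search is limited to n <= 4 genes and d_max <= 1")
    cache = _LocalScoreCache(dataset, cfg)
    lag_sets: dict[int, list[tuple[float, tuple, frozenset, LaggedParentSet]]] = {}
    for child in range(n):
        candidates = []
        pool0 = [g for g in range(n) if g != child]
        pool_lag = [g for g in range(n) if g != child or cfg.allow_self_lagged]
        lag_pools = {0: pool0}
        for lag in range(1, cfg.d_max + 1):
            lag_pools[lag] = pool_lag
        per_lag_subsets = {
            lag: [
                combo
                for size in range(len(pool) + 1)
                for combo in itertools.combinations(pool, size)
            ]
            for lag, pool in lag_pools.items()
        }
        for combo in itertools.product(*(per_lag_subsets[k] for k in sorted(per_lag_subsets))):
            by_lag = {
                lag: parents
                for lag, parents in zip(sorted(per_lag_subsets), combo)
                if parents
            }
            pset = LaggedParentSet(child, by_lag)
            if pset.size > cfg.max_fan_in:
                continue
            if config.forbid_multi_lag_pairs:
                pairs = [p for p, _ in pset.pairs()]
                if len(pairs) != len(set(pairs)):
                    continue
            arcs = tuple(sorted(LaggedArc(p, child, lag) for p, lag in pset.pairs()))
            candidates.append(
                (cache.local(child, pset), arcs, frozenset(pset.by_lag.get(0, ())), pset)
            )
        lag_sets[child] = candidates

    best_score = -np.inf
    best_arcs: tuple | None = None
    for assignment in itertools.product(*(lag_sets[c] for c in range(n))):
        lag0_parents = {c: assignment[c][2] for c in range(n)}
        if _has_cycle(lag0_parents, n):
            continue
        total = sum(a[0] for a in assignment)
        arcs = tuple(sorted(a for cand in assignment for a in cand[1]))
        if total > best_score + 1e-12 or (
            abs(total - best_score) <= 1e-12 and (best_arcs is None or arcs < best_arcs)
        ):
            best_score, best_arcs = total, arcs
    net = DelayAnnotatedNetwork(
        dataset.gene_table, set(best_arcs), cfg.d_max, cfg.allow_self_lagged
    )
    return net, float(best_score)


def _has_cycle(lag0_parents: dict[int, frozenset], n: int) -> bool:
    color = [0] * n

    def visit(u: int) -> bool:
        color[u] = 1
        for p in lag0_parents[u]:
            if color[p] == 1 or (color[p] == 0 and visit(p)):
                return True
        color[u] = 2
        return False

    return any(color[u] == 0 and visit(u) for u in range(n))
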