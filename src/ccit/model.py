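"""Model/Results interface for network learning.

``CCITModel`` wraps a discrete time-series dataset together with the
scoring and search configuration; ``fit()`` runs the structure search
and returns a ``CCITResults`` holding the learned delay-annotated
network, the decomposed score and the search trace, with a
``summary()`` table in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import DelayAnnotatedNetwork, TimeSeriesDataset, write_network_edgelist
from .evaluate import confusion, metrics
from .preprocess import DiscretizationSpec, discretize_dataset
from .score import ScoreBreakdown, ScoreConfig, baseline_scores, ccit_score
from .search import Move, SearchConfig, exhaustive_search, hill_climb

__all__ = ["CCITModel", "CCITResults"]


class CCITModel:
    """Structure-learning model for gene regulatory networks.

    Parameters
    ----------
    dataset
        Discrete expression time series (genes x time, one or more
        series).
    alpha
        Confidence level of the embedded conditional independence
        tests.
    d_max
        Maximum regulation order (time delay, in sampling steps) an
        arc may carry.
    max_fan_in
        Cap on a child's total parent count across all lags.
    """

    def __init__(
        self,
        dataset: TimeSeriesDataset,
        alpha: float = 0.9,
        d_max: int = 3,
        max_fan_in: int = 4,
        allow_self_lagged: bool = False,
        penalty_mode: str = "per-order",
    ) -> None:
        self.dataset = dataset
        self.score_config = ScoreConfig(
            alpha=alpha,
            d_max=d_max,
            max_fan_in=max_fan_in,
            allow_self_lagged=allow_self_lagged,
            penalty_mode=penalty_mode,
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        levels: int = 3,
        method: str = "equal-frequency",
        periodic: bool = False,
        **kwargs,
    ) -> "CCITModel":
        """Build a model from a genes-in-rows DataFrame.

        Continuous values are discretized into ``levels`` per-gene
        bins; already-discrete integer input is used verbatim.
        """
        matrix = frame.to_numpy(dtype=float)
        names = [str(ix) for ix in frame.index]
        spec = DiscretizationSpec(levels=levels, method=method)
        dataset, _ = discretize_dataset([matrix], names, spec, periodic=periodic)
        return cls(dataset, **kwargs)

    def score(self, network: DelayAnnotatedNetwork) -> ScoreBreakdown:
        """Score an externally supplied network on this model's data."""
        return ccit_score(network, self.dataset, self.score_config)

    def baselines(self, network: DelayAnnotatedNetwork) -> dict[str, float]:
        return baseline_scores(network, self.dataset, self.score_config)

    def fit(
        self,
        method: str = "hillclimb",
        restarts: int = 0,
        seed: int | None = None,
        max_iterations: int = 10_000,
        forbid_multi_lag_pairs: bool = False,
    ) -> "CCITResults":
        """Learn the network structure; returns a results object."""
        config = SearchConfig(
            score=self.score_config,
            max_iterations=max_iterations,
            restarts=restarts,
            seed=seed,
            forbid_multi_lag_pairs=forbid_multi_lag_pairs,
        )
        if method == "hillclimb":
            network, breakdown, trace = hill_climb(self.dataset, config)
        elif method == "exhaustive":
            network, _ = exhaustive_search(self.dataset, config)
            breakdown = ccit_score(network, self.dataset, self.score_config)
            trace = []
        else:
            raise ValueError(f"unknown fit method {method!r}")
        return CCITResults(self, network, breakdown, trace)


@dataclass
class CCITResults:
    """Fitted structure with its decomposed score."""

    model: CCITModel
    network: DelayAnnotatedNetwork
    breakdown: ScoreBreakdown
    trace: list[tuple[Move, float]]

    @property
    def score(self) -> float:
        return self.breakdown.total

    def arcs_frame(self) -> pd.DataFrame:
        names = self.network.gene_table.names
        rows = [
            {
                "regulator": names[a.regulator],
                "target": names[a.target],
                "lag": a.lag,
                "kind": "instantaneous" if a.lag == 0 else "delayed",
            }
            for a in self.network.sorted_arcs()
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "lag", "kind"])

    def summary(self) -> str:
        names = self.network.gene_table.names
        lines = []
        lines.append("CCIT structure learning results")
        lines.append("=" * 46)
        lines.append(f"genes: {len(names)}   arcs: {self.network.n_arcs}   "
                     f"score: {self.score:.4f}")
        n_inst = sum(1 for a in self.network.arcs if a.lag == 0)
        lines.append(
            f"instantaneous arcs: {n_inst}   delayed arcs: {self.network.n_arcs - n_inst}"
        )
        cfg = self.model.score_config
        lines.append(
            f"alpha: {cfg.alpha}   d_max: {cfg.d_max}   fan-in cap: {cfg.max_fan_in}   "
            f"penalty: {cfg.penalty_mode}"
        )
        lines.append("-" * 46)
        lines.append(f"{'regulator':<12}{'target':<12}{'lag':>4}")
        for a in self.network.sorted_arcs():
            lines.append(f"{names[a.regulator]:<12}{names[a.target]:<12}{a.lag:>4}")
        lines.append("-" * 46)
        lines.append(f"{'child':<12}{'2N*MI':>12}{'penalty':>12}{'local':>12}")
        for child, ns in sorted(self.breakdown.per_node.items()):
            lines.append(
                f"{names[child]:<12}{ns.mi_term:>12.4f}{ns.penalty:>12.4f}"
                f"{ns.local_score:>12.4f}"
            )
        return "\n".join(lines)

    def evaluate(
        self, truth: DelayAnnotatedNetwork, mode: str = "order-agnostic"
    ) -> dict[str, float]:
        """Se/Sp/Pr/F of the fitted network against a ground truth."""
        return metrics(confusion(self.network, truth, mode))

    def save_edgelist(self, path) -> None:
        write_network_edgelist(self.network, path)
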