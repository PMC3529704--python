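"""Confusion counts against a ground-truth network and derived measures.

Two matching modes are supported.  Order-agnostic evaluation collapses
both networks onto ordered gene pairs — an arc counts as recovered if
the pair and direction match, whatever the regulation order — over the
universe of n(n-1) non-self ordered pairs.  Order-aware evaluation
requires the exact (pair, lag) slot to match, over the universe of
ordered pairs times the lags 0..d_max.

From the counts: sensitivity Se = TP/(TP+FN), specificity
Sp = TN/(TN+FP), precision Pr = TP/(TP+FP) and the F-score, the
harmonic mean of Se and Pr.  A power-law fit of the degree
distribution (R^2 of the log-log least-squares line) is provided as a
scale-freeness diagnostic of inferred networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import DelayAnnotatedNetwork, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientDataError",
    "ConfusionCounts",
    "confusion",
    "metrics",
    "powerlaw_r2",
]


class InsufficientDataError(ValueError):
    """Too few distinct values to fit the requested diagnostic."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: str

    @property
    def universe(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    inferred: DelayAnnotatedNetwork,
    truth: DelayAnnotatedNetwork,
    mode: str = "order-agnostic",
    include_self_pairs: bool = False,
) -> ConfusionCounts:
    """Count TP/FP/TN/FN of an inferred network against the truth.

    Self-pairs are excluded from the universe unless
    ``include_self_pairs`` (only meaningful when lagged self-arcs are
    in play).
    """
    if inferred.gene_table.names != truth.gene_table.names:
        raise ValidationError("inferred and truth networks have different gene sets")
    n = truth.gene_table.n_genes
    if mode == "order-agnostic":
        inf_set = {(a.regulator, a.target) for a in inferred.arcs}
        tru_set = {(a.regulator, a.target) for a in truth.arcs}
        if not include_self_pairs:
            inf_set = {p for p in inf_set if p[0] != p[1]}
            tru_set = {p for p in tru_set if p[0] != p[1]}
            universe = n * (n - 1)
        else:
            universe = n * n
    elif mode == "order-aware":
        d_max = max(inferred.d_max, truth.d_max)
        inf_set = {tuple(a) for a in inferred.arcs}
        tru_set = {tuple(a) for a in truth.arcs}
        if not include_self_pairs:
            universe = n * (n - 1) * (d_max + 1)
        else:
            universe = n * (n - 1) * (d_max + 1) + n * d_max
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    tp = len(inf_set & tru_set)
    fp = len(inf_set - tru_set)
    fn = len(tru_set - inf_set)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, mode=mode)


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision and F-score from counts.

    Ratios with a zero denominator (e.g. precision of an empty
    network) are reported as NaN with a warning.
    """

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s is undefined (0/0); reporting NaN", name)
            return math.nan
        return num / den

    se = ratio(c.tp, c.tp + c.fn, "sensitivity")
    sp = ratio(c.tn, c.tn + c.fp, "specificity")
    pr = ratio(c.tp, c.tp + c.fp, "precision")
    if math.isnan(se) or math.isnan(pr) or (se + pr) == 0:
        if not (math.isnan(se) or math.isnan(pr)):
            logger.warning("F-score is undefined (Se + Pr = 0); reporting NaN")
        f = math.nan
    else:
        f = 2 * pr * se / (pr + se)
    return {"Se": se, "Sp": sp, "Pr": pr, "F": f}


def degree_distribution(network: DelayAnnotatedNetwork) -> dict[int, int]:
    """Frequency of each positive total (in + out) degree."""
    n = network.gene_table.n_genes
    deg = np.zeros(n, dtype=int)
    for a in network.arcs:
        deg[a.regulator] += 1
        deg[a.target] += 1
    freq: dict[int, int] = {}
    for d in deg:
        if d > 0:
            freq[int(d)] = freq.get(int(d), 0) + 1
    return freq


def powerlaw_r2(network: DelayAnnotatedNetwork) -> float:
    """R^2 of the log10(frequency) vs log10(degree) least-squares line.

    A value near 1 on a broad degree range indicates a scale-free
    (power-law) degree distribution.  Requires at least 3 distinct
    positive degrees.
    """
    if network.n_arcs == 0:
        raise ValidationError("cannot fit a degree distribution of an empty network")
    freq = degree_distribution(network)
    if len(freq) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >= 3 distinct positive degrees, found {len(freq)}"
        )
    degrees = np.array(sorted(freq))
    counts = np.array([freq[d] for d in degrees], dtype=float)
    x = np.log10(degrees)
    y = np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot
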