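"""Incremental cost-effectiveness analysis: ICERs, dominance, frontier, NMB.

Two presentations are produced and labelled explicitly, because published
tables often mix them:

* *pairwise vs comparator* — every strategy's incremental cost and effect as
  a raw subtraction from a fixed comparator (the single-morning-sample DAY-1
  strategy by default), with the corresponding ICER;
* *frontier analysis* — strategies sorted by cost, strictly dominated ones
  removed (costlier and no more effective than another option), extendedly
  dominated ones removed (frontier ICER exceeding that of a more effective
  alternative), and ICERs recomputed between adjacent frontier members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CEAResult",
    "incremental_analysis",
    "frontier_analysis",
    "net_monetary_benefit",
]


@dataclass(frozen=True)
class CEAResult:
    """Per-strategy economics: totals, incrementals vs comparator, dominance."""

    strategy: str
    total_cost: float
    total_effect: float
    incr_cost: float
    incr_effect: float
    icer: Optional[float]  # None when undefined (zero or adverse denominator)
    dominance: str  # none | strictly_dominated | extendedly_dominated
    nmb: float
    frontier_icer: Optional[float]  # ICER vs next-cheaper frontier member


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """NMB = wtp * effect - cost (¥)."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp!r}")
    return wtp * effect - cost


def _pairwise_icer(d_cost: float, d_effect: float) -> Optional[float]:
    if d_effect == 0:
        return None
    return d_cost / d_effect


def frontier_analysis(
    costs: Mapping[str, float], effects: Mapping[str, float]
) -> Tuple[dict[str, str], dict[str, Optional[float]]]:
    """Classify dominance and compute frontier ICERs.

    Returns ``(dominance, frontier_icer)`` keyed by strategy. Strict
    dominance: some other strategy is no costlier and at least as effective,
    with at least one strict inequality. Extended dominance: after removing
    strictly dominated options, a strategy whose incremental ICER along the
    cost-sorted sequence exceeds that of the next more effective option is
    removed, and ICERs are recomputed until the frontier sequence of ICERs is
    increasing.
    """
    names = list(costs)
    dominance = {s: "none" for s in names}
    for s in names:
        for o in names:
            if o == s:
                continue
            if (
                costs[o] <= costs[s]
                and effects[o] >= effects[s]
                and (costs[o] < costs[s] or effects[o] > effects[s])
            ):
                dominance[s] = "strictly_dominated"
                break

    # Extended dominance on the survivors, sorted by cost (ties by effect).
    alive = [s for s in names if dominance[s] == "none"]
    alive.sort(key=lambda s: (costs[s], effects[s]))
    while True:
        removed = False
        icers = []
        for prev, cur in zip(alive, alive[1:]):
            d_e = effects[cur] - effects[prev]
            d_c = costs[cur] - costs[prev]
            icers.append(math.inf if d_e == 0 else d_c / d_e)
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                dominance[alive[i + 1]] = "extendedly_dominated"
                del alive[i + 1]
                removed = True
                break
        if not removed:
            break

    frontier_icer: dict[str, Optional[float]] = {s: None for s in names}
    for prev, cur in zip(alive, alive[1:]):
        d_e = effects[cur] - effects[prev]
        d_c = costs[cur] - costs[prev]
        frontier_icer[cur] = None if d_e == 0 else d_c / d_e
    return dominance, frontier_icer


def incremental_analysis(
    results: Mapping[str, Tuple[float, float]],
    comparator: str = "DAY1",
    wtp: float = 100_000.0,
) -> pd.DataFrame:
    """Build the incremental cost-effectiveness table.

    ``results`` maps strategy name to (total_cost, total_effect). Incremental
    columns are raw subtractions from the comparator; dominance and
    ``frontier_icer`` come from the cost-sorted frontier analysis. Rows are
    ordered by total cost.
    """
    names = list(results)
    if len(names) != len(set(names)):
        raise ValueError("duplicate strategy names")
    if len(names) < 1:
        raise ValueError("at least one strategy required")
    if comparator not in results:
        raise ValueError(f"comparator {comparator!r} not among strategies {names}")
    costs = {s: float(results[s][0]) for s in names}
    effects = {s: float(results[s][1]) for s in names}
    dominance, frontier_icer = frontier_analysis(costs, effects)

    c0, e0 = costs[comparator], effects[comparator]
    rows = []
    for s in sorted(names, key=lambda s: (costs[s], effects[s])):
        d_c, d_e = costs[s] - c0, effects[s] - e0
        rows.append(
            CEAResult(
                strategy=s,
                total_cost=costs[s],
                total_effect=effects[s],
                incr_cost=d_c,
                incr_effect=d_e,
                icer=_pairwise_icer(d_c, d_e),
                dominance=dominance[s],
                nmb=net_monetary_benefit(costs[s], effects[s], wtp),
                frontier_icer=frontier_icer[s],
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("strategy")
    df.attrs["comparator"] = comparator
    df.attrs["wtp"] = wtp
    return df
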