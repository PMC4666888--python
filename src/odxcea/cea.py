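"""Cost-effectiveness analysis: dominance, efficiency frontier, ICERs.

Given per-strategy mean costs and QALYs, strategies are sorted by cost;
any strategy that is at least as costly and no more effective than another
is (strictly) dominated, and strategies whose incremental
cost-effectiveness ratio exceeds that of a more effective alternative are
extendedly dominated.  What remains is the efficiency frontier, along which
ICERs (EUR per QALY gained, versus the previous frontier member) are
strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CEPoint",
    "CEATable",
    "build_frontier",
    "net_monetary_benefit",
    "export_plane",
]

FRONTIER = "frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly_dominated"


class CEPoint(NamedTuple):
    """A (strategy, cost, QALY) triple for frontier construction."""

    name: str
    cost: float
    qaly: float


def _as_points(results: Iterable) -> list[CEPoint]:
    pts = []
    for r in results:
        if isinstance(r, CEPoint):
            pts.append(r)
        elif hasattr(r, "mean_cost"):
            name = r.strategy.name if hasattr(r.strategy, "name") else str(r.strategy)
            pts.append(CEPoint(name, float(r.mean_cost), float(r.mean_qaly)))
        else:
            name, cost, qaly = r
            pts.append(CEPoint(str(name), float(cost), float(qaly)))
    names = [p.name for p in pts]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy codes in CEA input")
    if not pts:
        raise ValueError("at least one strategy is required")
    if not all(np.isfinite([p.cost for p in pts]) & np.isfinite([p.qaly for p in pts])):
        raise ValueError("costs and QALYs must be finite")
    return pts


@dataclass(frozen=True)
class CEATable:
    """Frontier membership, statuses and ICERs for a set of strategies."""

    table: pd.DataFrame  # columns: strategy, cost, qaly, status, delta_cost, delta_qaly, icer
    frontier: tuple[str, ...]

    def icer(self, name: str) -> float:
        row = self.table.loc[self.table["strategy"] == name, "icer"]
        if row.empty:
            raise KeyError(name)
        return float(row.iloc[0])

    def status(self, name: str) -> str:
        row = self.table.loc[self.table["strategy"] == name, "status"]
        if row.empty:
            raise KeyError(name)
        return str(row.iloc[0])


def build_frontier(results: Iterable) -> CEATable:
    """Classify strategies and compute frontier ICERs.

    Accepts :class:`~odxcea.simulate.StrategyResult` objects, ``CEPoint``
    triples or plain ``(name, cost, qaly)`` tuples.  Ties: of two strategies
    with equal cost and equal QALY, the lexicographically smaller code stays;
    a zero QALY gain at higher cost is treated as dominance of the cheaper.
    """
    pts = _as_points(results)
    order = sorted(pts, key=lambda p: (p.cost, -p.qaly, p.name))

    status: dict[str, str] = {}
    # strict dominance (including the zero-delta-QALY tie-break)
    candidates: list[CEPoint] = []
    for p in order:
        dominated = any(
            q.cost <= p.cost
            and q.qaly >= p.qaly
            and (q.cost < p.cost or q.qaly > p.qaly)
            for q in order
        )
        # among exact duplicates of (cost, qaly), keep only the lexicographically
        # smallest code (handled by the q != p clause plus name ordering)
        if not dominated:
            twins = [
                q for q in order if q.cost == p.cost and q.qaly == p.qaly and q.name < p.name
            ]
            dominated = bool(twins)
        if dominated:
            status[p.name] = DOMINATED
        else:
            candidates.append(p)

    # extended dominance: drop interior points until ICERs strictly increase
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_mid = (mid.cost - lo.cost) / (mid.qaly - lo.qaly)
            icer_hi = (hi.cost - mid.cost) / (hi.qaly - mid.qaly)
            if icer_hi <= icer_mid:
                status[mid.name] = EXT_DOMINATED
                candidates.pop(i)
                changed = True
                break

    frontier = tuple(p.name for p in candidates)
    for p in candidates:
        status[p.name] = FRONTIER

    rows = []
    prev: CEPoint | None = None
    frontier_set = set(frontier)
    for p in order:
        if p.name in frontier_set and prev is not None:
            d_cost = p.cost - prev.cost
            d_qaly = p.qaly - prev.qaly
            icer = d_cost / d_qaly
        elif p.name in frontier_set:
            d_cost = d_qaly = icer = float("nan")
        else:
            d_cost = d_qaly = icer = float("nan")
        rows.append(
            {
                "strategy": p.name,
                "cost": p.cost,
                "qaly": p.qaly,
                "status": status[p.name],
                "delta_cost": d_cost,
                "delta_qaly": d_qaly,
                "icer": icer,
            }
        )
        if p.name in frontier_set:
            prev = p
    return CEATable(table=pd.DataFrame(rows), frontier=frontier)


def net_monetary_benefit(result, threshold: float) -> float:
    """``threshold * QALY - cost`` for one strategy at a willingness-to-pay."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    pts = _as_points([result])
    p = pts[0]
    return threshold * p.qaly - p.cost


def export_plane(results: Iterable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cost-effectiveness-plane coordinates relative to the cheapest strategy.

    Returns ``(points, frontier_polyline)``: incremental (QALY, cost)
    coordinates per strategy, and the ordered frontier vertices whose
    segment slopes are the frontier ICERs.
    """
    pts = _as_points(results)
    if len(pts) < 2:
        raise ValueError("plane export needs at least 2 strategies")
    cea = build_frontier(pts)
    origin = min(pts, key=lambda p: (p.cost, -p.qaly, p.name))
    coords = pd.DataFrame(
        {
            "strategy": [p.name for p in pts],
            "delta_qaly": [p.qaly - origin.qaly for p in pts],
            "delta_cost": [p.cost - origin.cost for p in pts],
            "on_frontier": [p.name in set(cea.frontier) for p in pts],
        }
    )
    by_name = {p.name: p for p in pts}
    poly = pd.DataFrame(
        {
            "strategy": list(cea.frontier),
            "delta_qaly": [by_name[s].qaly - origin.qaly for s in cea.frontier],
            "delta_cost": [by_name[s].cost - origin.cost for s in cea.frontier],
        }
    )
    return coords, poly
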