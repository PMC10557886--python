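"""Incremental cost-effectiveness analysis: ICERs, strong and extended
dominance, and willingness-to-pay decisions.

A strategy is *strongly dominated* when another strategy has no higher cost
and no fewer QALYs (at least one strictly better); it is *extendedly
dominated* when it is removed to restore a strictly increasing ICER sequence
along the cost-sorted frontier.  ICERs are kept unrounded internally --
rounding only ever happens at display time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ON_FRONTIER = "on_frontier"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


class DominanceError(ValueError):
    """Raised when an ICER is requested for a dominance (equal-QALY) case."""


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> float:
    """Incremental cost per QALY gained of strategy a over strategy b."""
    if qaly_a == qaly_b:
        raise DominanceError(
            "equal QALYs: this is a dominance comparison, not a ratio"
        )
    return (cost_a - cost_b) / (qaly_a - qaly_b)


@dataclass
class FrontierEntry:
    strategy: str
    cost: float
    qaly: float
    status: str
    #: ICER against the previous (next-cheapest) frontier member; None for
    #: the cheapest frontier strategy and for dominated strategies.
    icer: float | None = None


@dataclass
class FrontierResult:
    entries: list[FrontierEntry]  # ascending cost

    def frontier(self) -> list[FrontierEntry]:
        return [e for e in self.entries if e.status == ON_FRONTIER]

    def by_strategy(self) -> dict[str, FrontierEntry]:
        return {e.strategy: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": e.strategy,
                    "cost_pp": e.cost,
                    "qaly_pp": e.qaly,
                    "status": e.status,
                    "icer": e.icer,
                }
                for e in self.entries
            ]
        )


def build_frontier(results: list[tuple[str, float, float]]) -> FrontierResult:
    """Label every strategy and compute frontier ICERs.

    ``results`` holds (strategy, mean cost, mean QALY) triples in any order.
    Sorting is by ascending cost with ties broken by higher QALY.
    """
    if not results:
        raise ValueError("at least one strategy is required")
    entries = [
        FrontierEntry(strategy=s, cost=float(c), qaly=float(q), status=ON_FRONTIER)
        for s, c, q in results
    ]
    entries.sort(key=lambda e: (e.cost, -e.qaly))

    # strong dominance: some other strategy is no worse on both axes and
    # strictly better on at least one
    for e in entries:
        for f in entries:
            if f is e:
                continue
            if (
                f.cost <= e.cost
                and f.qaly >= e.qaly
                and (f.cost < e.cost or f.qaly > e.qaly)
            ):
                e.status = STRONGLY_DOMINATED
                break

    # extended dominance: repair non-increasing ICER sequences by removal
    def candidates() -> list[FrontierEntry]:
        return [e for e in entries if e.status == ON_FRONTIER]

    changed = True
    while changed:
        changed = False
        cand = candidates()
        for i in range(1, len(cand) - 1):
            icer_lo = icer(cand[i].cost, cand[i].qaly, cand[i - 1].cost, cand[i - 1].qaly)
            icer_hi = icer(cand[i + 1].cost, cand[i + 1].qaly, cand[i].cost, cand[i].qaly)
            if icer_lo >= icer_hi:
                cand[i].status = EXTENDEDLY_DOMINATED
                changed = True
                break

    cand = candidates()
    for prev, e in zip(cand, cand[1:]):
        e.icer = icer(e.cost, e.qaly, prev.cost, prev.qaly)
    return FrontierResult(entries=entries)


def decide(frontier: FrontierResult, wtp: float) -> FrontierEntry:
    """The highest-QALY frontier strategy whose ICER does not exceed the
    willingness-to-pay threshold."""
    cand = frontier.frontier()
    if not cand:
        raise ValueError("frontier is empty")
    chosen = cand[0]
    for e in cand[1:]:
        if e.icer is not None and e.icer <= wtp:
            chosen = e
    return chosen
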