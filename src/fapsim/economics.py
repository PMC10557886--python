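"""Discounted cost and QALY accrual.

The vector functions are the canonical implementation used by the engine;
the scalar operations wrap them for single individuals so both paths cannot
drift apart.  Conventions: discounting is annual with t = 0 for the first
cycle; utility decrements are additive and the cycle utility is floored at
0; an individual dying within a cycle earns half that cycle's utility but
pays its costs in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Individual
from .interventions import CycleEvents
from .natural_history import CLINICAL, DiseaseState
from .parameters import CostSchedule, UtilitySchedule

STAGES = ("I", "II", "III", "IV")


@dataclass
class CycleLedger:
    """Undiscounted cost and utility earned in one cycle."""

    cost: float
    utility: float
    cycle_index: int
    died_this_cycle: bool = False
    half_cycle_death: bool = True


def discount_factor(t: int | np.ndarray, rate: float) -> float | np.ndarray:
    """1 / (1 + rate)^t with t = 0 for the first cycle."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("cycle index must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


def cost_vector(
    stage_idx: np.ndarray,
    ysd: np.ndarray,
    colonoscopy: np.ndarray,
    polypectomy: np.ndarray,
    ipaa_now: np.ndarray,
    aspirin_taken: np.ndarray,
    perforation: np.ndarray,
    bleeding: np.ndarray,
    costs: CostSchedule,
) -> np.ndarray:
    """Undiscounted cycle cost per individual.

    ``stage_idx`` is 0..3 for diagnosed CRC and -1 otherwise; ``ysd`` is
    years since diagnosis.  The IDP procedure fee replaces the screening
    colonoscopy fee in a polypectomy cycle (one combined procedure); CRC
    treatment bills the year-1 stage cost at diagnosis and the continuing
    cost in years 2-5.
    """
    c_y1 = np.array([costs.c_crc_year1[s] for s in STAGES])
    c_y25 = np.array([costs.c_crc_year2to5[s] for s in STAGES])
    cost = np.zeros(np.shape(stage_idx), dtype=float)
    cost += costs.c_colonoscopy * (colonoscopy & ~polypectomy)
    cost += costs.c_idp * polypectomy
    cost += costs.c_ipaa * ipaa_now
    cost += costs.c_aspirin_year * aspirin_taken
    cost += costs.c_perforation * perforation
    cost += costs.c_bleeding * bleeding
    clin = stage_idx >= 0
    safe_stage = np.where(clin, stage_idx, 0)
    cost += np.where(clin & (ysd == 1), c_y1[safe_stage], 0.0)
    cost += np.where(clin & (ysd >= 2) & (ysd <= 5), c_y25[safe_stage], 0.0)
    return cost


def utility_vector(
    stage_idx: np.ndarray,
    ysd: np.ndarray,
    colonoscopy: np.ndarray,
    perforation: np.ndarray,
    bleeding: np.ndarray,
    ipaa_now: np.ndarray,
    aspirin_gi: np.ndarray,
    utils: UtilitySchedule,
) -> np.ndarray:
    """Cycle utility weight: baseline minus additive decrements, floored at 0.

    CRC care decrements follow the cost phases: the initial-care decrement in
    the diagnosis year, the continuing-care decrement in years 2-5.
    """
    d_init = np.array([utils.d_crc_initial[s] for s in STAGES])
    d_cont = np.array([utils.d_crc_continuing[s] for s in STAGES])
    u = np.full(np.shape(stage_idx), float(utils.u_baseline))
    u -= utils.d_colonoscopy * colonoscopy
    u -= utils.d_colonoscopy_complication * (
        perforation.astype(float) + bleeding.astype(float)
    )
    u -= utils.d_ipaa * ipaa_now
    u -= utils.d_aspirin_gi * aspirin_gi
    clin = stage_idx >= 0
    safe_stage = np.where(clin, stage_idx, 0)
    u -= np.where(clin & (ysd == 1), d_init[safe_stage], 0.0)
    u -= np.where(clin & (ysd >= 2) & (ysd <= 5), d_cont[safe_stage], 0.0)
    return np.clip(u, 0.0, None)


def _stage_ysd(state: DiseaseState) -> tuple[int, int]:
    if state.compartment in CLINICAL:
        return state.stage_index, state.years_since_dx
    return -1, 0


def cycle_cost(state: DiseaseState, events: CycleEvents, costs: CostSchedule) -> float:
    """Undiscounted cost of one cycle for one individual."""
    stage, ysd = _stage_ysd(state)
    return float(
        cost_vector(
            np.array([stage]),
            np.array([ysd]),
            np.array([events.colonoscopy_done]),
            np.array([events.polypectomy_done]),
            np.array([events.ipaa_done]),
            np.array([events.aspirin_taken]),
            np.array([events.perforation]),
            np.array([events.bleeding]),
            costs,
        )[0]
    )


def cycle_utility(
    state: DiseaseState, events: CycleEvents, utils: UtilitySchedule
) -> float:
    """QALY weight of one cycle for one individual."""
    stage, ysd = _stage_ysd(state)
    return float(
        utility_vector(
            np.array([stage]),
            np.array([ysd]),
            np.array([events.colonoscopy_done]),
            np.array([events.perforation]),
            np.array([events.bleeding]),
            np.array([events.ipaa_done]),
            np.array([events.aspirin_gi_event]),
            utils,
        )[0]
    )


def accrue(ind: Individual, ledger: CycleLedger, rate: float) -> Individual:
    """Add one cycle's discounted cost and QALYs to an individual.

    Costs accrue in full in the death cycle; utility earns the half-cycle
    credit when ``ledger.half_cycle_death`` is set.
    """
    df = float(discount_factor(ledger.cycle_index, rate))
    ind.cum_cost += ledger.cost * df
    weight = 0.5 if (ledger.died_this_cycle and ledger.half_cycle_death) else 1.0
    ind.cum_qaly += ledger.utility * weight * df
    return ind
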