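"""Disease states and annual transition rules of the adenoma-carcinoma
sequence in FAP, plus a deterministic cohort "oracle" that propagates exact
expected state occupancies for the no-intervention arm.

The oracle is the expectation twin of the microsimulation: it applies the
same intra-cycle update order to occupancy masses instead of individuals,
and is used for calibration, for tuning the synthetic inputs, and as the
brute-force reference the stochastic engine is tested against.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .parameters import ParameterSet
from .synthetic_data import (
    MAX_AGE,
    CalibrationTargets,
    LifeTable,
    SurvivalTable,
)


class Compartment(enum.IntEnum):
    POLYP_FREE = 0
    POLYP = 1
    PRECLIN_I = 2
    PRECLIN_II = 3
    PRECLIN_III = 4
    PRECLIN_IV = 5
    CLIN_I = 6
    CLIN_II = 7
    CLIN_III = 8
    CLIN_IV = 9


PRECLIN = tuple(Compartment(c) for c in range(2, 6))
CLINICAL = tuple(Compartment(c) for c in range(6, 10))
STAGES = ("I", "II", "III", "IV")
PROGRESS_KEYS = ("I->II", "II->III", "III->IV")


class PolypClass(enum.Enum):
    LOW_5TO9MM = "low_5to9mm"
    HIGH_10PLUSMM = "high_10plusmm"


@dataclass
class DiseaseState:
    compartment: Compartment = Compartment.POLYP
    polyp_class: PolypClass | None = PolypClass.HIGH_10PLUSMM
    years_since_dx: int | None = None

    def __post_init__(self) -> None:
        if self.compartment is not Compartment.POLYP:
            self.polyp_class = None
        if self.compartment in CLINICAL:
            if self.years_since_dx is None:
                self.years_since_dx = 1
            if self.years_since_dx < 1:
                raise ValueError("years_since_dx must be >= 1 in clinical compartments")
        else:
            self.years_since_dx = None

    @property
    def stage_index(self) -> int:
        """0-based stage for preclinical or clinical cancer compartments."""
        c = self.compartment
        if c in PRECLIN:
            return int(c) - int(Compartment.PRECLIN_I)
        if c in CLINICAL:
            return int(c) - int(Compartment.CLIN_I)
        raise ValueError(f"{c.name} has no cancer stage")


def initial_state() -> DiseaseState:
    """Modal disease state at model entry: FAP patients carry a heavy polyp
    burden at diagnosis, represented as a high-risk (10+ mm) precursor."""
    return DiseaseState(Compartment.POLYP, PolypClass.HIGH_10PLUSMM)


def entry_state_probs(params: ParameterSet) -> np.ndarray:
    """Entry-state distribution over (POLYP, PRECLIN_I..IV).

    Most patients enter with the polyp burden only; a tuned minority already
    harbour an undetected preclinical cancer (the polyp burden predates
    specialist care by years).
    """
    prev = np.array(
        [params.natural_history.p_preclin_at_entry[s] for s in STAGES]
    )
    total = prev.sum()
    if total > 1.0:
        raise ValueError("total preclinical prevalence at entry exceeds 1")
    return np.concatenate([[1.0 - total], prev])


# ---------------------------------------------------------------------------
# Scalar transition operations
# ---------------------------------------------------------------------------

def polyp_to_preclinical_prob(age: float, params: ParameterSet) -> float:
    """Annual probability that the polyp burden yields a preclinical stage I
    cancer; age-banded at ``age_band_cut`` (default 30)."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    nh = params.natural_history
    if age < nh.age_band_cut:
        return nh.p_polyp_to_preclin_young
    return nh.p_polyp_to_preclin_old


def advance_disease(
    state: DiseaseState, age: float, params: ParameterSet, rng: np.random.Generator
) -> DiseaseState:
    """One annual natural-history update.

    Order within the cycle: a preclinical cancer first faces symptomatic
    (clinical) detection, then -- if still preclinical and below stage IV --
    stage progression; a polyp faces malignant transformation; a clinical
    cancer ages one year since diagnosis.  POLYP_FREE is managed by the
    intervention/recurrence logic, not here.
    """
    nh = params.natural_history
    c = state.compartment
    if c is Compartment.POLYP_FREE:
        return DiseaseState(Compartment.POLYP_FREE)
    if c is Compartment.POLYP:
        if rng.random() < polyp_to_preclinical_prob(age, params):
            return DiseaseState(Compartment.PRECLIN_I)
        return DiseaseState(Compartment.POLYP, state.polyp_class)
    if c in PRECLIN:
        s = state.stage_index
        if rng.random() < nh.p_clinical_detect[STAGES[s]]:
            return DiseaseState(Compartment(int(Compartment.CLIN_I) + s), years_since_dx=1)
        if s < 3 and rng.random() < nh.p_preclin_progress[PROGRESS_KEYS[s]]:
            return DiseaseState(Compartment(int(c) + 1))
        return DiseaseState(c)
    if c in CLINICAL:
        return DiseaseState(c, years_since_dx=state.years_since_dx + 1)
    raise ValueError(f"unknown compartment {c!r}")


def crc_death_prob(state: DiseaseState, sex: int, table: SurvivalTable) -> float:
    """Annual CRC death probability: the complement of the conditional net
    survival at (stage at diagnosis, sex, years since diagnosis); zero beyond
    year 10 (cure)."""
    if state.compartment not in CLINICAL:
        raise ValueError(f"CRC death applies to clinical states, got {state.compartment.name}")
    if state.years_since_dx > 10:
        return 0.0
    return 1.0 - table.lookup(state.stage_index, sex, state.years_since_dx)


# ---------------------------------------------------------------------------
# Deterministic cohort oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    """Exact expected trajectories of the no-intervention cohort."""

    #: per cycle (0..horizon): compartment name -> proportion, incl. DEAD_*
    occupancy: list[dict[str, float]]
    #: cumulative proportion ever clinically diagnosed, per cycle 0..horizon
    cum_clinical: np.ndarray
    crc_death_fraction: float
    other_death_fraction: float
    mean_discounted_qaly: float
    mean_discounted_cost: float

    def occupancy_sums(self) -> np.ndarray:
        return np.array([sum(v.values()) for v in self.occupancy])


_N_YSD = 11  # years-since-dx bins 1..10 plus an absorbing "cured" bin


def _occupancy_dict(polyp, preclin, clin, dead_crc, dead_other) -> dict[str, float]:
    out = {"POLYP_FREE": 0.0, "POLYP": float(polyp.sum())}
    for i, name in enumerate(("PRECLIN_I", "PRECLIN_II", "PRECLIN_III", "PRECLIN_IV")):
        out[name] = float(preclin[:, i].sum())
    for i, name in enumerate(("CLIN_I", "CLIN_II", "CLIN_III", "CLIN_IV")):
        out[name] = float(clin[:, i, :].sum())
    out["DEAD_CRC"] = float(dead_crc.sum())
    out["DEAD_OTHER"] = float(dead_other.sum())
    return out


def cohort_oracle(
    params: ParameterSet,
    life_table: LifeTable,
    survival_table: SurvivalTable,
    entry_age: int = 16,
    horizon: int = 40,
    multiplier: float = 1.0,
    female_fraction: float = 0.5,
) -> OracleResult:
    """Forward-propagate exact expected occupancies for the no-intervention
    arm, cycle by cycle, under the engine's intra-cycle order: clinical
    year-since-diagnosis increment, natural-history transitions (symptomatic
    detection before progression, then polyp transformation), CRC death,
    other-cause death, then discounted QALY/cost accrual with the half-cycle
    death credit.
    """
    nh = params.natural_history
    d = np.array([nh.p_clinical_detect[s] for s in STAGES])
    prog = np.array([nh.p_preclin_progress[k] for k in PROGRESS_KEYS] + [0.0])
    u = params.utilities
    costs = params.costs
    rate = params.economics.discount_rate
    d_init = np.array([u.d_crc_initial[s] for s in STAGES])
    d_cont = np.array([u.d_crc_continuing[s] for s in STAGES])
    c_y1 = np.array([costs.c_crc_year1[s] for s in STAGES])
    c_y25 = np.array([costs.c_crc_year2to5[s] for s in STAGES])
    half = 0.5 if u.half_cycle_death else 0.0

    # state masses, indexed [sex] (0 male, 1 female)
    sex_w = np.array([1.0 - female_fraction, female_fraction])
    entry = entry_state_probs(params)
    polyp = sex_w * entry[0]
    preclin = sex_w[:, None] * entry[1:][None, :]
    clin = np.zeros((2, 4, _N_YSD))
    dead_crc = np.zeros(2)
    dead_other = np.zeros(2)

    occupancy = [_occupancy_dict(polyp, preclin, clin, dead_crc, dead_other)]
    cum_clinical = np.zeros(horizon + 1)
    qaly = 0.0
    cost_acc = 0.0

    # utility weight and cost per (stage, ysd bin)
    util_by_bin = np.ones((4, _N_YSD))
    util_by_bin[:, 0] = 1.0 - d_init
    for y in range(1, 5):
        util_by_bin[:, y] = 1.0 - d_cont
    util_by_bin = np.clip(util_by_bin, 0.0, None)
    cost_by_bin = np.zeros((4, _N_YSD))
    cost_by_bin[:, 0] = c_y1
    for y in range(1, 5):
        cost_by_bin[:, y] = c_y25

    for t in range(horizon):
        age = entry_age + t
        df = (1.0 + rate) ** (-t)

        # 1) pre-existing clinical patients age one year since diagnosis
        aged = np.zeros_like(clin)
        aged[:, :, 1:10] = clin[:, :, 0:9]
        aged[:, :, 10] = clin[:, :, 9] + clin[:, :, 10]
        clin = aged

        # 2) natural-history transitions (from a snapshot, so new arrivals
        #    do not transition twice in one cycle)
        snap = preclin.copy()
        detected = snap * d          # symptomatic detection first
        progressed = (snap - detected) * prog
        preclin = snap - detected - progressed
        preclin[:, 1:] += progressed[:, :3]
        clin[:, :, 0] += detected
        p_onset = polyp_to_preclinical_prob(age, params) * multiplier
        onset = polyp * p_onset
        polyp = polyp - onset
        preclin[:, 0] += onset
        cum_clinical[t + 1] = cum_clinical[t] + detected.sum()

        # 3) no strategy actions, no recurrence in the no-intervention arm

        # 4) CRC death (clinical, years 1-10 since diagnosis)
        p_die = 1.0 - survival_table.s  # [stage, sex, year1..10]
        crc_deaths = np.einsum("xsy,sxy->xsy", clin[:, :, :10], p_die)
        clin[:, :, :10] -= crc_deaths
        dead_crc += crc_deaths.sum(axis=(1, 2))

        # 5) other-cause death
        q = np.array([life_table.lookup(age, 0), life_table.lookup(age, 1)])
        oc_polyp = polyp * q
        oc_preclin = preclin * q[:, None]
        oc_clin = clin * q[:, None, None]
        polyp = polyp - oc_polyp
        preclin = preclin - oc_preclin
        clin = clin - oc_clin
        dead_other += oc_polyp + oc_preclin.sum(axis=1) + oc_clin.sum(axis=(1, 2))

        # 6) accrual: survivors earn the full cycle, this cycle's dead earn
        #    half a cycle of utility; costs accrue in full either way
        u_healthy = u.u_baseline
        qaly += df * u_healthy * (polyp.sum() + preclin.sum())
        qaly += df * u_healthy * half * (oc_polyp.sum() + oc_preclin.sum())
        surv_q = np.einsum("xsy,sy->", clin, util_by_bin)
        dead_q = np.einsum("xsy,sy->", crc_deaths, util_by_bin[:, :10]) + np.einsum(
            "xsy,sy->", oc_clin, util_by_bin
        )
        qaly += df * (surv_q + half * dead_q)
        # cost: everyone alive at cycle start in a clinical bin pays the bin
        cost_mass = clin + oc_clin  # survivors + other-cause deaths
        cost_mass[:, :, :10] += crc_deaths
        cost_acc += df * np.einsum("xsy,sy->", cost_mass, cost_by_bin)

        occupancy.append(_occupancy_dict(polyp, preclin, clin, dead_crc, dead_other))

    return OracleResult(
        occupancy=occupancy,
        cum_clinical=cum_clinical,
        crc_death_fraction=float(dead_crc.sum()),
        other_death_fraction=float(dead_other.sum()),
        mean_discounted_qaly=float(qaly),
        mean_discounted_cost=float(cost_acc),
    )


# ---------------------------------------------------------------------------
# Calibration and validation
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    multiplier: float
    sse: float
    chi_square: float
    n_targets: int


def calibrate_multiplier(
    targets: CalibrationTargets,
    params: ParameterSet,
    life_table: LifeTable | None = None,
    survival_table: SurvivalTable | None = None,
    bounds: tuple[float, float] = (1e-3, 8.0),
) -> CalibrationResult:
    """Fit a scalar multiplier on both polyp-to-preclinical probabilities so
    the oracle's cumulative clinical incidence matches the targets (least
    squares; bounded scalar minimisation, xatol 1e-6).  Also reports a
    chi-square-style goodness-of-fit statistic sum((obs - exp)^2 / exp)."""
    from .synthetic_data import default_life_table, default_survival_table

    if not targets.age_upper:
        raise ValueError("calibration targets must be non-empty")
    if bounds[0] <= 0 or bounds[1] <= bounds[0]:
        raise ValueError("bounds must be positive and increasing")
    life_table = life_table if life_table is not None else default_life_table()
    survival_table = (
        survival_table if survival_table is not None else default_survival_table()
    )
    entry_age = params.economics.intervention_start_age
    horizon = max(targets.age_upper) - entry_age
    obs = np.asarray(targets.cum_incidence, dtype=float)
    idx = np.array(
        [max(0, min(a - entry_age, horizon)) for a in targets.age_upper]
    )
    max_mult = min(
        bounds[1],
        1.0 / max(params.natural_history.p_polyp_to_preclin_old, 1e-12),
    )

    def model_curve(mult: float) -> np.ndarray:
        res = cohort_oracle(
            params,
            life_table,
            survival_table,
            entry_age=entry_age,
            horizon=horizon,
            multiplier=mult,
        )
        return res.cum_clinical[idx]

    def sse(mult: float) -> float:
        return float(np.sum((model_curve(mult) - obs) ** 2))

    opt = optimize.minimize_scalar(
        sse, bounds=(bounds[0], max_mult), method="bounded", options={"xatol": 1e-6}
    )
    if not opt.success:
        raise RuntimeError(f"calibration optimizer failed: {opt.message}")
    best = float(opt.x)
    exp = model_curve(best)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    return CalibrationResult(
        multiplier=best,
        sse=float(opt.fun),
        chi_square=float(chi.sum()),
        n_targets=len(obs),
    )


def lifetime_crc_death_probability(
    params: ParameterSet,
    life_table: LifeTable | None = None,
    survival_table: SurvivalTable | None = None,
    entry_age: int = 16,
    mode: str = "oracle",
    n: int = 100_000,
    seed: int = 0,
) -> float:
    """Fraction of the no-intervention cohort dying of CRC over a lifetime
    horizon (to age 100).  ``mode='oracle'`` is exact; ``mode='microsim'``
    runs the stochastic engine."""
    from .synthetic_data import default_life_table, default_survival_table

    life_table = life_table if life_table is not None else default_life_table()
    survival_table = (
        survival_table if survival_table is not None else default_survival_table()
    )
    horizon = MAX_AGE - entry_age + 1
    if mode == "oracle":
        res = cohort_oracle(
            params, life_table, survival_table, entry_age=entry_age, horizon=horizon
        )
        return res.crc_death_fraction
    if mode == "microsim":
        from .engine import RunConfig, run_strategy
        from .interventions import Strategy, StrategyKind

        cfg = RunConfig(
            n=n,
            horizon=horizon,
            seed=seed,
            strategy=Strategy(kind=StrategyKind.NONE),
            entry_age=entry_age,
        )
        result = run_strategy(cfg, params, life_table, survival_table)
        return result.crc_deaths_per_1000 / 1000.0
    raise ValueError(f"unknown mode {mode!r}")
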