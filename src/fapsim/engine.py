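"""Annual-cycle simulation loop over the cohort for one strategy.

Intra-cycle order (applied identically to every strategy and mirrored by the
deterministic oracle for the no-intervention arm):

1. diagnosed patients age one year since diagnosis;
2. natural-history transitions -- symptomatic detection, stage progression,
   polyp-to-preclinical transformation;
3. strategy actions -- IPAA surgery at the start age, annual surveillance
   colonoscopy with same-session polypectomy (IDP), aspirin;
4. polyp recurrence in polyp-free individuals;
5. CRC death (clinical cases, by stage at diagnosis / sex / years since
   diagnosis);
6. other-cause death;
7. discounted cost and QALY accrual.

Natural-history transitions run before that cycle's colonoscopy: a polyp
that has already seeded a preclinical cancer by the time of the annual exam
cannot be sterilised retroactively by removing the polyp, though the exam
may then screen-detect the cancer.  All Bernoulli draws come from streams
keyed by (seed, purpose, cycle) with individual i at position i, so runs
with a common seed are paired across strategies (common random numbers).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

from . import _rng
from .cohort import build_cohort
from .economics import cost_vector, discount_factor, utility_vector
from .interventions import ALL_STRATEGY_KINDS, Strategy, StrategyKind
from .natural_history import Compartment
from .parameters import ParameterSet
from .synthetic_data import LifeTable, SurvivalTable

STAGES = ("I", "II", "III", "IV")
_STRATEGY_TAG = {k: i for i, k in enumerate(ALL_STRATEGY_KINDS)}

# compartment codes (match natural_history.Compartment)
_FREE = int(Compartment.POLYP_FREE)
_POLYP = int(Compartment.POLYP)
_PRE_I = int(Compartment.PRECLIN_I)
_CLIN_I = int(Compartment.CLIN_I)


@dataclass
class RunConfig:
    n: int = 100_000
    horizon: int = 40
    seed: int = 0
    strategy: Strategy = field(default_factory=lambda: Strategy(StrategyKind.NONE))
    entry_age: int = 16
    female_fraction: float = 0.5
    use_common_random_numbers: bool = True
    collect_occupancy: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class RunResult:
    strategy: str
    crc_deaths_per_1000: float
    mean_qaly: float
    mean_cost: float
    n_effective: int
    deaths_other: int
    alive_at_end: int
    rng_fingerprint: str
    per_cycle_occupancy: list[dict[str, float]] | None = None

    def to_row(self) -> dict[str, float | str | int]:
        return {
            "strategy": self.strategy,
            "crc_deaths_per_1000": self.crc_deaths_per_1000,
            "qaly_pp": self.mean_qaly,
            "cost_pp": self.mean_cost,
            "n": self.n_effective,
        }


def _occupancy(comp, alive, cause, n) -> dict[str, float]:
    out = {}
    for c in Compartment:
        out[c.name] = float(np.sum(alive & (comp == int(c))) / n)
    out["DEAD_CRC"] = float(np.sum(cause == 1) / n)
    out["DEAD_OTHER"] = float(np.sum(cause == 2) / n)
    return out


def run_strategy(
    cfg: RunConfig,
    params: ParameterSet,
    life_table: LifeTable,
    survival_table: SurvivalTable,
) -> RunResult:
    """Simulate one strategy over the whole cohort and aggregate outcomes."""
    strat = cfg.strategy
    nh = params.natural_history
    t_par = params.tests
    eff = params.effectiveness
    ae = params.adverse_events
    econ = params.economics
    n = cfg.n
    start_age = strat.start_age

    if cfg.use_common_random_numbers:
        key: int | tuple[int, ...] = cfg.seed
    else:
        key = (cfg.seed, 1000 + _STRATEGY_TAG[strat.kind])

    cohort = build_cohort(n, cfg.entry_age, cfg.female_fraction, cfg.seed)
    sex = cohort.sex.astype(np.intp)

    # entry states: polyp burden for most, an undetected preclinical cancer
    # for a tuned minority (same draws across strategies under CRN)
    from .natural_history import entry_state_probs

    entry_cum = np.cumsum(entry_state_probs(params))
    u_entry = _rng.uniforms(key, "entry_state", 0, n)
    entry_idx = np.searchsorted(entry_cum, u_entry, side="right")
    comp = np.where(
        entry_idx == 0, _POLYP, _PRE_I + np.clip(entry_idx - 1, 0, 3)
    ).astype(np.int8)
    polyp_high = np.ones(n, dtype=bool)
    ysd = np.zeros(n, dtype=np.int16)
    alive = np.ones(n, dtype=bool)
    cause = np.zeros(n, dtype=np.int8)  # 0 none, 1 crc, 2 other
    post_idp = np.zeros(n, dtype=bool)
    had_ipaa = np.zeros(n, dtype=bool)
    ipaa_recur_cycle = np.full(n, -1, dtype=np.int32)
    aspirin_started = np.zeros(n, dtype=bool)
    aspirin_halted = np.zeros(n, dtype=bool)
    cum_cost = np.zeros(n)
    cum_qaly = np.zeros(n)

    p_detect = np.array([nh.p_clinical_detect[s] for s in STAGES])
    p_prog = np.array([nh.p_preclin_progress[k] for k in ("I->II", "II->III", "III->IV")])
    p_die_tab = 1.0 - survival_table.s  # [stage, sex, year-1]
    if eff.rr_on_probability_scale:
        p_recur_asp = eff.p_polyp_recur_after_idp * eff.rr_polyp_with_aspirin
    else:
        p_recur_asp = 1.0 - (1.0 - eff.p_polyp_recur_after_idp) ** eff.rr_polyp_with_aspirin

    occupancy = [_occupancy(comp, alive, cause, n)] if cfg.collect_occupancy else None

    U = lambda purpose, t: _rng.uniforms(key, purpose, t, n)  # noqa: E731

    for t in range(cfg.horizon):
        age = cfg.entry_age + t
        if t % 10 == 0:
            log.info(
                "%s: cycle %d/%d, %d alive", strat.kind.value, t, cfg.horizon,
                int(alive.sum()),
            )

        # 1) diagnosed patients age one year since diagnosis
        clin_pre = alive & (comp >= _CLIN_I)
        ysd[clin_pre] += 1

        # 2) natural-history transitions, from a start-of-cycle snapshot
        comp0 = comp.copy()
        u_det = U("symptomatic_detect", t)
        u_prog = U("progress", t)
        u_onset = U("polyp_onset", t)
        for s in range(4):
            m = alive & (comp0 == _PRE_I + s)
            det = m & (u_det < p_detect[s])
            comp[det] = _CLIN_I + s
            ysd[det] = 1
            if s < 3:
                prog = m & ~det & (u_prog < p_prog[s])
                comp[prog] = _PRE_I + s + 1
        p_onset = (
            nh.p_polyp_to_preclin_young if age < nh.age_band_cut else nh.p_polyp_to_preclin_old
        )
        onset = alive & (comp0 == _POLYP) & (u_onset < p_onset)
        comp[onset] = _PRE_I

        # 3) strategy actions
        colonoscopy = np.zeros(n, dtype=bool)
        polypectomy = np.zeros(n, dtype=bool)
        perforation = np.zeros(n, dtype=bool)
        bleeding = np.zeros(n, dtype=bool)
        ipaa_now = np.zeros(n, dtype=bool)
        aspirin_taken = np.zeros(n, dtype=bool)
        aspirin_gi = np.zeros(n, dtype=bool)

        if strat.kind is StrategyKind.IPAA and age == start_age:
            ipaa_now = alive & ~had_ipaa & (comp < _CLIN_I)
            # pathology of the resected colorectum reveals any occult
            # preclinical cancer: diagnosed at surgery, treated at its stage
            path_dx = ipaa_now & (comp >= _PRE_I)
            no_cancer = ipaa_now & ~path_dx
            comp[path_dx] = comp[path_dx] + (_CLIN_I - _PRE_I)
            ysd[path_dx] = 1
            comp[no_cancer] = _FREE
            had_ipaa |= ipaa_now
            will = no_cancer & (U("ipaa_destiny", t) < eff.p_polyp_after_ipaa_lifetime)
            remaining = cfg.horizon - t - 1
            if remaining > 0:
                timing = np.floor(U("ipaa_timing", t) * remaining).astype(np.int32)
                ipaa_recur_cycle[will] = t + 1 + timing[will]

        scope_due = (
            strat.has_surveillance
            and age >= start_age
            and not (strat.kind is StrategyKind.IPAA and age == start_age)
        )
        if scope_due:
            scoped = alive & (comp < _CLIN_I)  # diagnosed patients exit surveillance
            colonoscopy = scoped
            sens = np.where(polyp_high, t_par.sens_high_risk_polyp, t_par.sens_low_risk_polyp)
            pol = scoped & (comp == _POLYP)
            detected = pol & (U("scope_polyp", t) < sens)
            if strat.kind in (StrategyKind.IDP, StrategyKind.IDP_ASPIRIN) and age == start_age:
                detected = pol  # first IDP clears the baseline burden outright
            u_pre = U("scope_preclin", t)
            for s in range(4):
                found = scoped & (comp == _PRE_I + s) & (u_pre < t_par.sens_preclinical_crc)
                comp[found] = _CLIN_I + s  # screen-detected cancer
                ysd[found] = 1
            polypectomy = detected
            comp[detected] = _FREE
            post_idp |= detected
            perforation |= polypectomy & (U("idp_perforation", t) < ae.p_idp_perforation)
            bleeding |= polypectomy & (U("idp_bleeding", t) < ae.p_idp_bleeding)
            perforation |= (
                colonoscopy
                & ~polypectomy
                & (U("perforation_no_polypectomy", t) < t_par.p_perforation_no_polypectomy)
            )

        if strat.uses_aspirin and age >= start_age:
            eligible = alive & ~aspirin_halted & (comp < _CLIN_I)
            aspirin_taken = eligible & (U("aspirin_adherence", t) < econ.adherence_aspirin)
            first_year = aspirin_taken & ~aspirin_started
            gi_pool = aspirin_taken if ae.aspirin_gi_every_year else first_year
            aspirin_gi = gi_pool & (U("aspirin_gi_minor", t) < ae.p_aspirin_gi_minor)
            if ae.p_aspirin_serious_bleed > 0:
                serious = aspirin_taken & (
                    U("aspirin_serious_bleed", t) < ae.p_aspirin_serious_bleed
                )
                aspirin_gi |= serious
                aspirin_halted |= serious
            aspirin_started |= aspirin_taken

        # 4) polyp recurrence in the polyp-free state
        free = alive & (comp == _FREE)
        recurred = np.zeros(n, dtype=bool)
        if strat.kind in (StrategyKind.IDP, StrategyKind.IDP_ASPIRIN):
            p_rec = np.where(aspirin_taken, p_recur_asp, eff.p_polyp_recur_after_idp)
            recurred = free & post_idp & (U("recurrence", t) < p_rec)
        elif strat.kind is StrategyKind.IPAA:
            recurred = free & (ipaa_recur_cycle == t)
            ipaa_recur_cycle[recurred] = -1  # once in a lifetime
        comp[recurred] = _POLYP
        polyp_high[recurred] = (
            U("recurrence_class", t)[recurred] < eff.recurrent_polyp_high_fraction
        )

        # 5) CRC death
        clin = alive & (comp >= _CLIN_I) & (ysd <= 10)
        stage_now = np.where(comp >= _CLIN_I, comp - _CLIN_I, 0)
        ysd_idx = np.clip(ysd, 1, 10) - 1
        p_die = np.where(clin, p_die_tab[stage_now, sex, ysd_idx], 0.0)
        die_crc = clin & (U("crc_death", t) < p_die)

        # 6) other-cause death (one cause per cycle; CRC checked first)
        q_other = life_table.lookup_vector(age, sex)
        die_other = alive & ~die_crc & (U("other_death", t) < q_other)

        # 7) economics: everyone alive at cycle start accrues
        stage_idx = np.where(comp >= _CLIN_I, comp - _CLIN_I, -1)
        cost = cost_vector(
            stage_idx, ysd, colonoscopy, polypectomy, ipaa_now, aspirin_taken,
            perforation, bleeding, params.costs,
        )
        util = utility_vector(
            stage_idx, ysd, colonoscopy, perforation, bleeding, ipaa_now,
            aspirin_gi, params.utilities,
        )
        df = float(discount_factor(t, econ.discount_rate))
        died_now = die_crc | die_other
        weight = (
            np.where(died_now, 0.5, 1.0) if params.utilities.half_cycle_death else 1.0
        )
        cum_cost[alive] += (cost * df)[alive]
        cum_qaly[alive] += (util * weight * df)[alive]

        cause[die_crc] = 1
        cause[die_other] = 2
        alive &= ~died_now

        if cfg.collect_occupancy:
            occupancy.append(_occupancy(comp, alive, cause, n))

    digest = hashlib.sha256()
    for arr in (comp, ysd, alive, cause, cum_cost, cum_qaly):
        digest.update(np.ascontiguousarray(arr).tobytes())
    return RunResult(
        strategy=strat.kind.value,
        crc_deaths_per_1000=1000.0 * float(np.mean(cause == 1)),
        mean_qaly=float(np.mean(cum_qaly)),
        mean_cost=float(np.mean(cum_cost)),
        n_effective=n,
        deaths_other=int(np.sum(cause == 2)),
        alive_at_end=int(np.sum(alive)),
        rng_fingerprint=digest.hexdigest(),
        per_cycle_occupancy=occupancy,
    )


def run_all_strategies(
    cfg: RunConfig,
    params: ParameterSet,
    life_table: LifeTable,
    survival_table: SurvivalTable,
    kinds: tuple[StrategyKind, ...] = ALL_STRATEGY_KINDS,
) -> list[RunResult]:
    """Run every strategy on the same hypothetical cohort.

    With common random numbers (the default) each strategy reuses identical
    draws keyed by (individual, cycle, purpose), so between-strategy
    differences are paired rather than confounded by sampling noise.
    """
    results = []
    for kind in kinds:
        strat = Strategy(
            kind=kind,
            start_age=params.economics.intervention_start_age,
            adherence_aspirin=params.economics.adherence_aspirin,
        )
        scfg = RunConfig(
            n=cfg.n,
            horizon=cfg.horizon,
            seed=cfg.seed,
            strategy=strat,
            entry_age=cfg.entry_age,
            female_fraction=cfg.female_fraction,
            use_common_random_numbers=cfg.use_common_random_numbers,
            collect_occupancy=cfg.collect_occupancy,
        )
        results.append(run_strategy(scfg, params, life_table, survival_table))
    return results
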