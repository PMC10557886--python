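"""The four prevention strategies: no intervention, intensive downstaging
polypectomy (IDP), IDP + low-dose aspirin, and prophylactic proctocolectomy
with ileal pouch-anal anastomosis (IPAA).

All intervention strategies include annual surveillance colonoscopy from the
start age, with perfect adherence to surveillance.  The scalar operations
here mutate an :class:`~fapsim.cohort.Individual` and return the cycle's
:class:`CycleEvents`; the engine applies identical rules in vectorized form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .cohort import Individual
from .natural_history import CLINICAL, Compartment, DiseaseState, PolypClass
from .parameters import ParameterSet

STAGES = ("I", "II", "III", "IV")


class StrategyKind(enum.Enum):
    NONE = "none"
    IDP = "idp"
    IDP_ASPIRIN = "idp_aspirin"
    IPAA = "ipaa"


@dataclass(frozen=True)
class Strategy:
    kind: StrategyKind
    start_age: int = 16
    surveillance_interval: int = 1
    adherence_aspirin: float = 1.0

    @property
    def has_surveillance(self) -> bool:
        return self.kind is not StrategyKind.NONE

    @property
    def uses_aspirin(self) -> bool:
        return self.kind is StrategyKind.IDP_ASPIRIN


ALL_STRATEGY_KINDS = (
    StrategyKind.NONE,
    StrategyKind.IDP,
    StrategyKind.IDP_ASPIRIN,
    StrategyKind.IPAA,
)


@dataclass
class CycleEvents:
    """Per-cycle event record feeding the economics module."""

    colonoscopy_done: bool = False
    polyp_detected: bool = False
    polypectomy_done: bool = False
    preclinical_detected_stage: str | None = None
    perforation: bool = False
    bleeding: bool = False
    aspirin_taken: bool = False
    aspirin_gi_event: bool = False
    ipaa_done: bool = False

    def __post_init__(self) -> None:
        if self.polypectomy_done and not self.colonoscopy_done:
            raise ValueError("polypectomy implies a colonoscopy")


def do_surveillance(
    ind: Individual,
    params: ParameterSet,
    rng: np.random.Generator,
    strategy: Strategy,
    force_polypectomy: bool = False,
) -> CycleEvents:
    """One annual surveillance colonoscopy.

    A polyp is detected with the size-class sensitivity; an undiagnosed
    preclinical cancer with ``sens_preclinical_crc`` (detection reassigns the
    individual to the clinical compartment of the same stage, i.e. screen
    detection).  Specificity is 1, so a polyp-free colon yields no findings
    beyond the small no-polypectomy perforation risk.
    """
    if not strategy.has_surveillance:
        raise ValueError("surveillance called under the no-intervention strategy")
    if not ind.alive or ind.age < strategy.start_age:
        raise ValueError("surveillance requires an alive individual at or above start age")
    t = params.tests
    ev = CycleEvents(colonoscopy_done=True)
    c = ind.disease.compartment
    if c is Compartment.POLYP:
        sens = (
            t.sens_high_risk_polyp
            if ind.disease.polyp_class is PolypClass.HIGH_10PLUSMM
            else t.sens_low_risk_polyp
        )
        if force_polypectomy or rng.random() < sens:
            ev.polyp_detected = True
    elif c in (
        Compartment.PRECLIN_I,
        Compartment.PRECLIN_II,
        Compartment.PRECLIN_III,
        Compartment.PRECLIN_IV,
    ):
        if rng.random() < t.sens_preclinical_crc:
            s = ind.disease.stage_index
            ind.disease = DiseaseState(
                Compartment(int(Compartment.CLIN_I) + s), years_since_dx=1
            )
            ev.preclinical_detected_stage = STAGES[s]
    if not ev.polyp_detected:
        if rng.random() < t.p_perforation_no_polypectomy:
            ev.perforation = True
    return ev


def do_idp(
    ind: Individual,
    events: CycleEvents,
    params: ParameterSet,
    rng: np.random.Generator,
) -> CycleEvents:
    """Endoscopic removal of all 5+ mm polyps in the same session as the
    detecting colonoscopy, with its perforation/bleeding risks."""
    if not events.polyp_detected:
        raise ValueError("IDP requires a detected polyp")
    ae = params.adverse_events
    ind.disease = DiseaseState(Compartment.POLYP_FREE)
    events.polypectomy_done = True
    if rng.random() < ae.p_idp_perforation:
        events.perforation = True
    if rng.random() < ae.p_idp_bleeding:
        events.bleeding = True
    return events


def polyp_recurrence_prob(
    ind: Individual,
    params: ParameterSet,
    aspirin_taken: bool = False,
    remaining_horizon_years: int | None = None,
) -> float:
    """Annual probability that new 5+ mm polyps appear in a polyp-free colon.

    Post-IDP: the trial's annual probability (0.554), multiplied by the
    aspirin relative risk on the probability scale in adherent cycles
    (rate-scale alternative behind ``rr_on_probability_scale``).  Post-IPAA:
    the lifetime probability is realized as a destiny draw at surgery plus a
    uniform recurrence time over the remaining horizon, so individuals
    destined to recur face a 1/remaining annual probability here.
    """
    if ind.disease.compartment is not Compartment.POLYP_FREE:
        raise ValueError("recurrence applies to the polyp-free state")
    e = params.effectiveness
    if ind.had_ipaa:
        if ind.ipaa_polyp_destiny != "will_recur":
            return 0.0
        if not remaining_horizon_years or remaining_horizon_years <= 0:
            return 0.0
        return 1.0 / remaining_horizon_years
    base = e.p_polyp_recur_after_idp
    if not aspirin_taken:
        return base
    if e.rr_on_probability_scale:
        return base * e.rr_polyp_with_aspirin
    return 1.0 - (1.0 - base) ** e.rr_polyp_with_aspirin


def apply_aspirin_cycle(
    ind: Individual,
    params: ParameterSet,
    rng: np.random.Generator,
    first_year: bool = True,
) -> CycleEvents:
    """One cycle of low-dose aspirin chemoprevention.

    Adherence is Bernoulli per cycle; the minor grade 1-2 GI event (3 days)
    occurs only in the first treatment year by default; a serious GI bleed
    halts aspirin permanently.
    """
    ae = params.adverse_events
    ev = CycleEvents()
    if not ind.alive or not ind.on_aspirin:
        return ev
    if rng.random() < params.economics.adherence_aspirin:
        ev.aspirin_taken = True
        if (first_year or ae.aspirin_gi_every_year) and rng.random() < ae.p_aspirin_gi_minor:
            ev.aspirin_gi_event = True
        if ae.p_aspirin_serious_bleed > 0 and rng.random() < ae.p_aspirin_serious_bleed:
            ev.aspirin_gi_event = True
            ind.on_aspirin = False  # permanent halt
    return ev


def do_ipaa(
    ind: Individual,
    params: ParameterSet,
    rng: np.random.Generator,
) -> CycleEvents:
    """Prophylactic total proctocolectomy with ileal pouch-anal anastomosis.

    Removes the colorectal polyp burden outright; whether 5+ mm polyps will
    ever recur in the residual tissue is decided once at surgery with the
    published lifetime probability.
    """
    if ind.had_ipaa:
        raise ValueError("IPAA is performed at most once per individual")
    if ind.disease.compartment in CLINICAL:
        raise ValueError("prophylactic IPAA applies before a cancer diagnosis")
    ind.had_ipaa = True
    c = ind.disease.compartment
    if c in (
        Compartment.PRECLIN_I,
        Compartment.PRECLIN_II,
        Compartment.PRECLIN_III,
        Compartment.PRECLIN_IV,
    ):
        # surgical pathology finds the occult cancer: diagnosed at its stage
        s = ind.disease.stage_index
        ind.disease = DiseaseState(Compartment(int(Compartment.CLIN_I) + s), years_since_dx=1)
        ind.ipaa_polyp_destiny = "never"
        return CycleEvents(ipaa_done=True)
    ind.disease = DiseaseState(Compartment.POLYP_FREE)
    if rng.random() < params.effectiveness.p_polyp_after_ipaa_lifetime:
        ind.ipaa_polyp_destiny = "will_recur"
    else:
        ind.ipaa_polyp_destiny = "never"
    return CycleEvents(ipaa_done=True)
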