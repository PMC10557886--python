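"""Simulated FAP cohort construction and other-cause mortality lookups.

The engine works on a struct-of-arrays :class:`Cohort`; the per-person
:class:`Individual` view exists for unit-level reasoning about single
trajectories and for inspecting simulated people after a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _rng
from .natural_history import Compartment, DiseaseState, initial_state
from .synthetic_data import LifeTable

MALE, FEMALE = 0, 1


@dataclass
class Individual:
    """One simulated person (scalar view, mainly for tests and inspection)."""

    id: int
    sex: int  # 0 male, 1 female
    age: float
    alive: bool = True
    cause_of_death: str = "none"  # none | crc | other
    disease: DiseaseState = field(default_factory=initial_state)
    on_aspirin: bool = False
    had_ipaa: bool = False
    ipaa_polyp_destiny: str = "unset"  # unset | will_recur | never
    cum_cost: float = 0.0
    cum_qaly: float = 0.0
    event_log: list[tuple[int, str]] | None = None


class Cohort:
    """A fixed-size closed cohort stored as parallel numpy arrays."""

    def __init__(self, ids: np.ndarray, sex: np.ndarray, entry_age: int, seed: int):
        if len(ids) != len(np.unique(ids)):
            raise ValueError("individual ids must be unique")
        self.ids = ids
        self.sex = sex
        self.entry_age = entry_age
        self.seed = seed

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_female(self) -> int:
        return int(self.sex.sum())

    def individuals(self) -> list[Individual]:
        """Materialize per-person views (entry state; O(n))."""
        return [
            Individual(id=int(i), sex=int(s), age=float(self.entry_age))
            for i, s in zip(self.ids, self.sex)
        ]


def build_cohort(
    n: int, entry_age: int = 16, female_fraction: float = 0.5, seed: int = 0
) -> Cohort:
    """Build the entry cohort: everyone alive, carrying the FAP polyp burden.

    Sex assignment is deterministic and stratified -- exactly
    ``round(n * female_fraction)`` females -- with the positions shuffled
    reproducibly from the seed.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if not 0.0 <= female_fraction <= 1.0:
        raise ValueError("female_fraction must be in [0, 1]")
    n_female = int(round(n * female_fraction))
    sex = np.zeros(n, dtype=np.int8)
    sex[:n_female] = FEMALE
    _rng.stream(seed, "cohort_sex").shuffle(sex)
    return Cohort(ids=np.arange(n), sex=sex, entry_age=entry_age, seed=seed)


def other_cause_death_prob(age: float, sex: int, table: LifeTable) -> float:
    """Annual probability of dying from causes other than CRC."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return table.lookup(int(age), sex)
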