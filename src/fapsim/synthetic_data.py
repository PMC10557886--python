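"""Synthetic stand-ins for the external inputs the model needs but which are
not published alongside it: an other-cause life table, a stage- and
year-specific conditional net-survival table for CRC, and calibration
targets.

The packaged defaults are tuned once (``scripts/tune_synthetic.py``) so that
the no-intervention arm of the model reproduces the headline outcomes the
model was built to match; they are documented stand-ins for national vital
statistics and registry net survival, not real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAX_AGE = 100
SEXES = ("male", "female")
STAGES = ("I", "II", "III", "IV")

#: Printed bounds of the conditional annual net-survival inputs.
SURVIVAL_FLOOR = 0.0729
SURVIVAL_CEIL = 1.000

# Tuned defaults (see scripts/tune_synthetic.py).  The Gompertz-Makeham
# constants produce the elevated mid-century background mortality the
# modelled cohort lives through (life expectancy at birth ~67 years,
# comparable to 1960s Japan, the decade the cohort enters the model).
DEFAULT_MAKEHAM_A = 0.00686
DEFAULT_GOMPERTZ_B = 3.22e-5
DEFAULT_GOMPERTZ_C = 0.0935
DEFAULT_SEX_RATIO_ADJUST = 0.75
#: 5-year net survival by stage at diagnosis (I, II, III, IV).  Deliberately
#: pessimistic for stages II-IV, reflecting mid-century treatment outcomes.
DEFAULT_FIVE_YEAR_SURVIVAL = (0.956, 0.541, 0.506, 0.471)
#: Excess-hazard decay per year since diagnosis, by stage: advanced disease
#: kills early (front-loaded excess), while localized disease loses ground
#: gradually across the whole 10-year net-survival window.
DEFAULT_CURE_SHAPE = (0.25, 2.0, 2.0, 2.0)


@dataclass
class LifeTable:
    """Annual probability of death from causes other than CRC.

    ``q[age, sex]`` with sex index 0 = male, 1 = female; closure at age 100
    (q = 1) so no simulated individual outlives the table.
    """

    q: np.ndarray  # shape (MAX_AGE + 1, 2)

    def lookup(self, age: int, sex: int) -> float:
        if age < 0:
            raise ValueError(f"age must be non-negative, got {age}")
        if age > MAX_AGE:
            return 1.0
        return float(self.q[age, sex])

    def lookup_vector(self, age: int, sex: np.ndarray) -> np.ndarray:
        if age > MAX_AGE:
            return np.ones(sex.shape)
        return self.q[age, sex]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"age": a, "sex": SEXES[s], "q_other": self.q[a, s]}
            for a in range(MAX_AGE + 1)
            for s in (0, 1)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        q = np.zeros((MAX_AGE + 1, 2))
        sex_idx = df["sex"].map({"male": 0, "female": 1})
        q[df["age"].to_numpy(), sex_idx.to_numpy()] = df["q_other"].to_numpy()
        return cls(q=q)

    def life_expectancy_at_birth(self, sex: int | None = None) -> float:
        """Trapezoid life expectancy; sex-averaged when sex is None."""
        if sex is None:
            return 0.5 * (self.life_expectancy_at_birth(0) + self.life_expectancy_at_birth(1))
        surv = np.concatenate([[1.0], np.cumprod(1.0 - self.q[:, sex])])
        return float(np.trapezoid(surv))


@dataclass
class SurvivalTable:
    """Conditional annual net survival for diagnosed CRC.

    ``s[stage, sex, year]`` with stage 0..3 = I..IV, year index 0..9 for
    years 1..10 since diagnosis.  Beyond year 10 patients are treated as
    cured of their cancer (conditional net survival 1).
    """

    s: np.ndarray  # shape (4, 2, 10)

    def lookup(self, stage: int, sex: int, year_since_dx: int) -> float:
        if year_since_dx < 1:
            raise ValueError("year_since_dx starts at 1")
        if year_since_dx > 10:
            return 1.0
        return float(self.s[stage, sex, year_since_dx - 1])

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "stage": STAGES[st],
                "sex": SEXES[sx],
                "year_since_dx": y + 1,
                "cond_net_survival": self.s[st, sx, y],
            }
            for st in range(4)
            for sx in (0, 1)
            for y in range(10)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurvivalTable":
        df = pd.read_csv(path)
        s = np.zeros((4, 2, 10))
        st = df["stage"].map({k: i for i, k in enumerate(STAGES)})
        sx = df["sex"].map({"male": 0, "female": 1})
        s[st.to_numpy(), sx.to_numpy(), df["year_since_dx"].to_numpy() - 1] = df[
            "cond_net_survival"
        ].to_numpy()
        return cls(s=s)


@dataclass
class CalibrationTargets:
    """Cumulative clinical CRC incidence by age-group upper bound."""

    age_upper: list[int]
    cum_incidence: list[float]
    source: str = "synthetic"

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age_upper": self.age_upper, "cum_incidence": self.cum_incidence}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "user") -> "CalibrationTargets":
        df = pd.read_csv(path)
        return cls(
            age_upper=[int(a) for a in df["age_upper"]],
            cum_incidence=[float(v) for v in df["cum_incidence"]],
            source=source,
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_life_table(
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    sex_ratio_adjust: float = DEFAULT_SEX_RATIO_ADJUST,
    seed: int | None = None,
) -> LifeTable:
    """Deterministic Gompertz-Makeham life table.

    Hazard mu(x) = a + b * exp(c * x) converted to annual probabilities
    q = 1 - exp(-mu); female mortality is multiplied by ``sex_ratio_adjust``
    (< 1).  The table closes with q = 1 at age 100.  ``seed`` is accepted for
    interface symmetry; the construction draws no random numbers.
    """
    ages = np.arange(MAX_AGE + 1, dtype=float)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    q_male = 1.0 - np.exp(-hazard)
    if np.any(q_male[:95] >= 1.0):
        raise ValueError(
            "parameter combination yields death probability >= 1 before age 95"
        )
    q = np.stack([q_male, np.clip(q_male * sex_ratio_adjust, 0.0, 1.0)], axis=1)
    q[MAX_AGE, :] = 1.0
    return LifeTable(q=q)


def make_survival_table(
    five_year_net_survival_by_stage: tuple[float, float, float, float] = DEFAULT_FIVE_YEAR_SURVIVAL,
    cure_fraction_shape: float | tuple[float, float, float, float] = DEFAULT_CURE_SHAPE,
    seed: int | None = None,
) -> SurvivalTable:
    """Conditional annual net survival with a mixture-cure shape.

    Excess mortality decays geometrically with years since diagnosis (rate
    ``cure_fraction_shape`` per year, scalar or per stage), flattening toward
    survival 1.0; conditional net survival is 1 (cure) beyond year 10.  A
    shape of 0 spreads the excess evenly across the 10-year window, which is
    how localized disease behaves; large shapes front-load it, as in
    metastatic disease.  The product of the year 1-5 conditional values
    equals the requested 5-year net survival to within 1e-6 (unless the
    printed floor 0.0729 forces clamping).  Deterministic; ``seed`` is
    accepted for interface symmetry.
    """
    s5 = np.asarray(five_year_net_survival_by_stage, dtype=float)
    if not np.all(np.diff(s5) <= 0):
        raise ValueError(
            "5-year net survival must be non-increasing from stage I to IV"
        )
    if np.any(s5 > 1.0) or np.any(s5 <= SURVIVAL_FLOOR):
        raise ValueError(
            f"5-year net survival values must lie in ({SURVIVAL_FLOOR}, 1]"
        )
    shapes = np.broadcast_to(
        np.asarray(cure_fraction_shape, dtype=float), (4,)
    )
    years = np.arange(10, dtype=float)  # year-since-dx 1..10
    table = np.zeros((4, 2, 10))
    for st in range(4):
        weights = np.exp(-shapes[st] * years)
        total_excess = -np.log(s5[st])  # cumulative excess hazard, years 1-5
        hazards = total_excess * weights / weights[:5].sum()
        cond = np.exp(-hazards)
        table[st, 0, :] = cond
        table[st, 1, :] = cond
    # enforce the stage ordering I >= II >= III >= IV at every year: a
    # later stage never out-survives an earlier one, whatever the shapes
    table = np.minimum.accumulate(table, axis=0)
    table = np.clip(table, SURVIVAL_FLOOR, SURVIVAL_CEIL)
    return SurvivalTable(s=table)


def default_life_table() -> LifeTable:
    return make_life_table()


def default_survival_table() -> SurvivalTable:
    return make_survival_table()


def make_calibration_targets(
    params,
    multiplier: float = 1.0,
    age_groups: tuple[int, ...] = (30, 40, 50, 60, 70, 80),
    life_table: LifeTable | None = None,
    survival_table: SurvivalTable | None = None,
) -> CalibrationTargets:
    """Cumulative clinical CRC incidence targets from the deterministic
    cohort oracle, with the polyp-to-preclinical probabilities scaled by
    ``multiplier``.  Used for calibration recovery tests and demos."""
    from . import natural_history  # local import: avoids a cycle

    if multiplier < 0:
        raise ValueError("multiplier must be > 0")
    scaled_young = params.natural_history.p_polyp_to_preclin_young * multiplier
    scaled_old = params.natural_history.p_polyp_to_preclin_old * multiplier
    if scaled_young > 1.0 or scaled_old > 1.0:
        raise ValueError(
            f"multiplier {multiplier} scales a transition probability above 1"
        )
    life_table = life_table if life_table is not None else default_life_table()
    survival_table = (
        survival_table if survival_table is not None else default_survival_table()
    )
    entry_age = params.economics.intervention_start_age
    horizon = max(age_groups) - entry_age
    res = natural_history.cohort_oracle(
        params,
        life_table,
        survival_table,
        entry_age=entry_age,
        horizon=horizon,
        multiplier=multiplier,
    )
    values = []
    for upper in age_groups:
        t = max(0, min(upper - entry_age, horizon))
        values.append(float(res.cum_clinical[t]))
    return CalibrationTargets(age_upper=list(age_groups), cum_incidence=values)
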