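"""Regenerate the packaged synthetic-input defaults.

The life table, the stage-specific net-survival table and the entry-state
prevalence are stand-ins for inputs that are not published with the model
(national vital statistics, registry net survival, the entry cohort's
disease mix).  This script tunes them, once, so that the model reproduces
its headline outcomes, and prints the constants that are frozen into
``fapsim.synthetic_data`` and ``fapsim.parameters``:

1. stage I 5-year net survival and entry prevalence are set by a small grid
   search against the intervention arms (IDP+aspirin CRC deaths per 1000 and
   the IPAA vs IDP+aspirin incremental cost-effectiveness ratio), because
   surveillance arms diagnose almost everything at stage I;
2. the Gompertz-Makeham life-table constants and the stage II-IV survival
   inputs are then fit by least squares against the no-intervention arm
   (40-cycle CRC deaths per 1000, mean discounted QALYs, lifetime CRC death
   probability) using the deterministic cohort oracle, which is exact and
   fast.

Deterministic: the oracle is exact and the microsimulation steps use fixed
seeds.  Run from the repository root:

    python scripts/tune_synthetic.py [--full]

--full also reruns the (slower) stage-1 grid verification at n=50,000.
"""

import argparse

import numpy as np
from scipy import optimize

import fapsim
from fapsim import natural_history as nh
from fapsim.engine import RunConfig, run_all_strategies
from fapsim.synthetic_data import make_life_table, make_survival_table

# Headline outcomes the stand-ins are tuned against (printed model outputs).
TARGET_DEATHS40 = 325.26 / 1000  # no-intervention CRC deaths per person, 40 cycles
TARGET_QALY = 19.19              # no-intervention discounted QALYs per person
TARGET_LIFETIME = 0.31958        # lifetime CRC death probability
TARGET_S2_DEATHS = 30.42 / 1000  # IDP+aspirin CRC deaths per person
TARGET_ICER = 122_796.0          # IPAA vs IDP+aspirin, USD/QALY

# Feasible-intersection targets used by the least-squares stage (the printed
# lifetime value lies below the printed 40-cycle death rate, which a single
# cohort cannot achieve; see docs/methods.md).
LSQ_DEATHS40 = 0.303
LSQ_QALY = 19.40
LSQ_LIFETIME = 0.3315

STAGE1_S5 = 0.956
STAGE1_SHAPE = 0.25
ENTRY_PREV = {"I": 0.0072, "II": 0.0054, "III": 0.0036, "IV": 0.0018}
SEX_ADJUST = 0.75
SHAPES_LATE = (2.0, 2.0, 2.0)


def tune_life_and_late_stages() -> tuple[np.ndarray, float]:
    p = fapsim.default_params()

    def build(x):
        a, logb, c, s2, s3, s4 = x
        lt = make_life_table(a, np.exp(logb), c, SEX_ADJUST)
        st = make_survival_table((STAGE1_S5, s2, s3, s4), (STAGE1_SHAPE, *SHAPES_LATE))
        return lt, st

    def resid(x):
        a, logb, c, s2, s3, s4 = x
        try:
            lt, st = build(x)
        except ValueError:
            return np.full(6, 10.0)
        r40 = nh.cohort_oracle(p, lt, st, 16, 40)
        life = nh.cohort_oracle(p, lt, st, 16, 85).crc_death_fraction
        le = lt.life_expectancy_at_birth()
        return np.array(
            [
                (r40.crc_death_fraction - LSQ_DEATHS40) / 0.003,
                (r40.mean_discounted_qaly - LSQ_QALY) / 0.025,
                (life - LSQ_LIFETIME) / 0.0025,
                max(0.0, 64.0 - le) / 0.3,
                max(0.0, s3 - s2 + 0.035) / 0.004,
                max(0.0, s4 - s3 + 0.035) / 0.004,
            ]
        )

    x0 = np.array([0.00696, np.log(2.68e-5), 0.0885, 0.55, 0.50, 0.46])
    lb = [0.0005, np.log(1e-8), 0.05, 0.40, 0.20, 0.074]
    ub = [0.02, np.log(2e-3), 0.30, 0.90, 0.86, 0.60]
    sol = optimize.least_squares(resid, x0, bounds=(lb, ub), diff_step=1e-3)
    return sol.x, float(sol.cost)


def verify(full: bool) -> None:
    p = fapsim.default_params()
    lt = fapsim.default_life_table()
    st = fapsim.default_survival_table()
    orc = nh.cohort_oracle(p, lt, st, 16, 40)
    life = nh.cohort_oracle(p, lt, st, 16, 85).crc_death_fraction
    print("frozen defaults, oracle no-intervention:")
    print(f"  CRC deaths/1000 (40c): {1000 * orc.crc_death_fraction:8.2f}  target {1000 * TARGET_DEATHS40:.2f}")
    print(f"  discounted QALYs:      {orc.mean_discounted_qaly:8.3f}  target {TARGET_QALY:.2f}")
    print(f"  lifetime CRC death:    {life:8.4f}  target {TARGET_LIFETIME:.5f}")
    print(f"  life expectancy(0):    {lt.life_expectancy_at_birth():8.2f}")
    if full:
        res = run_all_strategies(RunConfig(n=50_000, horizon=40, seed=2), p, lt, st)
        d = {r.strategy: r for r in res}
        s2, s3 = d["idp_aspirin"], d["ipaa"]
        icer = (s3.mean_cost - s2.mean_cost) / (s3.mean_qaly - s2.mean_qaly)
        print("microsimulation check (n=50,000, seed 2):")
        print(f"  IDP+aspirin deaths/1000: {s2.crc_deaths_per_1000:8.2f}  target {1000 * TARGET_S2_DEATHS:.2f}")
        print(f"  ICER IPAA vs IDP+asp:    {icer:8.0f}  target {TARGET_ICER:.0f}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--full", action="store_true", help="also run the microsimulation check")
    args = ap.parse_args()
    x, cost = tune_life_and_late_stages()
    a, logb, c, s2, s3, s4 = x
    print("least-squares stage (life table + stage II-IV survival):")
    print(f"  DEFAULT_MAKEHAM_A = {a:.5f}")
    print(f"  DEFAULT_GOMPERTZ_B = {np.exp(logb):.3e}")
    print(f"  DEFAULT_GOMPERTZ_C = {c:.4f}")
    print(f"  DEFAULT_FIVE_YEAR_SURVIVAL = ({STAGE1_S5}, {s2:.3f}, {s3:.3f}, {s4:.3f})")
    print(f"  DEFAULT_CURE_SHAPE = ({STAGE1_SHAPE}, 2.0, 2.0, 2.0)")
    print(f"  p_preclin_at_entry = {ENTRY_PREV}")
    print(f"  residual cost: {cost:.3f}")
    print()
    verify(args.full)


if __name__ == "__main__":
    main()
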