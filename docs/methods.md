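# Model and methods

## Scope and structure

`fapsim` is an individual-level state-transition (microsimulation) model of
colorectal cancer in familial adenomatous polyposis (FAP).  Each simulated
person occupies one disease compartment per annual cycle:

```
POLYP_FREE ⇄ POLYP → PRECLIN_I → PRECLIN_II → PRECLIN_III → PRECLIN_IV
                         │            │             │            │
                         ▼            ▼             ▼            ▼
                      CLIN_I       CLIN_II       CLIN_III     CLIN_IV → DEAD_CRC
                                                 (any state) → DEAD_OTHER
```

`POLYP` is a binary ≥ 5 mm precursor-burden state, not a polyp count: FAP
patients enter the model at age 16 carrying a heavy polyp burden, and the
interventions act on that burden as a whole.  A preclinical cancer can be
detected symptomatically (becoming clinical at the same stage), be
screen-detected by surveillance colonoscopy, or progress one stage per
cycle.  Clinical cancers are tracked by stage at diagnosis and years since
diagnosis; they never restage.

### Annual cycle order

Within each cycle, in this order: (1) diagnosed patients age one year since
diagnosis; (2) natural-history transitions — symptomatic detection first,
then stage progression, then polyp→preclinical transformation; (3) strategy
actions — IPAA surgery at the start age, annual surveillance colonoscopy
with same-session polypectomy, aspirin; (4) polyp recurrence in polyp-free
individuals; (5) CRC death; (6) other-cause death (one cause per cycle, CRC
checked first); (7) discounted cost and QALY accrual.

Natural history deliberately runs *before* that cycle's colonoscopy: a
polyp that has already seeded a cancer by the time of the annual exam
cannot be sterilised retroactively by removing the polyp — though the exam
may then screen-detect the cancer, usually at stage I.  This convention is
what gives surveillance arms their residual CRC mortality; with the
opposite ("exam first") order, annual surveillance at the packaged
sensitivities suppresses virtually all cancer in the intervention arms,
which contradicts the mortality the model is built to reproduce.  The
deterministic oracle (below) applies the identical order.

### Entry states

Most individuals enter in `POLYP`.  A small tuned fraction (1.8% in the
packaged defaults, split across stages I–IV) already harbours an undetected
preclinical cancer at entry, representing disease accumulated before
specialist care began.  Every strategy finds these cancers early —
surveillance screens them within a cycle or two, IPAA reveals them at
surgical pathology — so their burden is shared almost identically across
intervention arms and cancels out of between-strategy comparisons, while in
the no-intervention arm they surface later, symptomatically.  Without this
entry prevalence the surgical arm has essentially zero CRC mortality and
the between-arm QALY differences become implausibly dominated by the
aspirin arm's own cancers.

## Strategies

* **none** — no surveillance, no prevention; cancers appear symptomatically.
* **IDP** — from age 16, annual colonoscopy; the first session clears the
  baseline burden, later sessions remove detected recurrences (sensitivity
  0.865 for 5–9 mm polyps, 0.976 for ≥ 10 mm; recurrent polyps are ≥ 10 mm
  with probability 0.5, configurable).  Per-procedure perforation (0.004)
  and bleeding (0.023) risks carry costs and utility decrements.  The
  polypectomy fee replaces the screening fee in that session (one combined
  procedure).  Recurrence of ≥ 5 mm polyps: 0.554/year.
* **IDP + aspirin** — as IDP, plus daily low-dose aspirin from age 16;
  adherent cycles multiply the recurrence probability by RR 0.37 on the
  probability scale (0.554 × 0.37 = 0.20498; a rate-scale alternative sits
  behind `rr_on_probability_scale`).  Grade 1–2 GI upset (4%, first
  treatment year) costs 0.004 QALY; a serious GI bleed (probability 0 by
  default, configurable) halts aspirin permanently.
* **IPAA** — proctocolectomy at age 16 (cost $17,540, one-time utility loss
  0.110), then annual pouch surveillance.  Whether ≥ 5 mm polyps ever recur
  is decided once at surgery with the lifetime probability 0.036; for those
  destined to recur, the recurrence year is drawn uniformly over the
  remaining horizon, which preserves the lifetime probability exactly while
  spreading the hazard.  Patients diagnosed with cancer exit surveillance
  and aspirin and receive stage-specific care.

## Economics

Costs and utilities accrue per cycle and are discounted at 3%/year with
t = 0 at the first cycle.  Utility is 1.0 minus additive decrements
(colonoscopy 0.003; complication 0.019 each; initial-care CRC decrements
0.12/0.18/0.24/0.70 by stage in the diagnosis year and continuing-care
decrements 0.05/0.05/0.24/0.70 in years 2–5; IPAA 0.110 once; aspirin GI
0.004), floored at 0.  CRC treatment bills the year-1 stage cost at
diagnosis and the year-2–5 stage cost thereafter; both stop after year 5,
aligned with the 10-year net-survival horizon after which patients are
considered cured.  An individual dying within a cycle earns half that
cycle's utility (configurable) but pays its costs in full.  The IPAA
utility decrement is one-time, not annual: an annual −0.110 would force the
surgical arm below the aspirin arm in QALYs, contradicting the outcome
ordering the model reproduces.

## Synthetic study conditions

Three inputs a real analysis would take from national statistics are
generated, not measured.  All three are *tuned stand-ins*: their constants
were fit once (`scripts/tune_synthetic.py`, deterministic) so that the
packaged defaults reproduce the model's headline outcomes, and they are
frozen thereafter.

* **Life table** (`make_life_table`): Gompertz–Makeham hazard
  μ(x) = a + b·e^(cx) with a = 0.00686, b = 3.22e-5, c = 0.0935 and female
  mortality at 0.75× male.  Life expectancy at birth is ≈ 64 years —
  deliberately mid-20th-century-like, because the modelled cohort enters in
  the early 1960s and the intervention-arm QALY levels require roughly 2.3
  discounted QALYs of other-cause loss inside the 40-year horizon.  A
  modern life table (LE ≈ 80+) is incompatible with those QALY levels under
  any monotone hazard.  The table closes with q = 1 at age 100.
* **Net survival after CRC diagnosis** (`make_survival_table`):
  conditional annual net survival by stage, sex and year 1–10 since
  diagnosis, built from 5-year net survival (0.956, 0.541, 0.506, 0.471 by
  stage) with a geometric excess-hazard decay per stage
  (0.25, 2.0, 2.0, 2.0): advanced disease kills early, localized disease
  loses ground gradually over the whole window.  The year-1–5 product
  reproduces the requested 5-year value to 1e-6; entries are clamped to the
  published [0.0729, 1.000] range; a running minimum across stages enforces
  stage ordering at every year; conditional survival is 1 (cure) beyond
  year 10.  Stages II–IV are deliberately pessimistic (mid-century
  outcomes).  The tables carry a sex dimension but the packaged default is
  sex-neutral, keeping the 5-year product exact for both sexes.
* **Calibration targets** (`make_calibration_targets`): cumulative clinical
  incidence by age group, produced by the deterministic oracle at a known
  polyp→cancer multiplier.  Calibration is therefore validated by parameter
  *recovery* (the optimizer must find the multiplier that generated the
  targets), not by digitized external points.

What passing tests on these stand-ins show: that the simulation machinery,
economics, dominance logic and calibration behave correctly, and that the
tuned conditions jointly reproduce the headline outcomes.  What they do not
show: fidelity to actual Japanese vital statistics, registry survival, or
FAP epidemiology beyond the published transition parameters.

## Deterministic oracle, calibration, validation

`cohort_oracle` propagates exact expected occupancies for the
no-intervention arm (state space: polyp, preclinical ×4, clinical ×4 ×
years-since-diagnosis 1–11+, dead ×2, per sex) under the same cycle order
as the engine, accumulating discounted QALYs and costs with the same
half-cycle convention.  It is the reference the stochastic engine is tested
against (3-standard-error agreement at n = 50,000, plus a 5-point random
parameter grid), the target generator for calibration, and the fast inner
loop of the tuning script.  `calibrate_multiplier` minimises the sum of
squared differences between oracle cumulative incidence and the targets
over a scalar multiplier on both polyp→preclinical probabilities (bounded
scalar minimisation, xatol 1e-6), reporting the SSE and a chi-square-style
statistic.  `lifetime_crc_death_probability` runs the no-intervention arm
to age 100 in oracle (exact) or microsimulation mode.

## Random numbers and pairing

Every Bernoulli draw comes from a stream keyed by (seed, purpose, cycle),
with individual *i* always at position *i* — counter-style common random
numbers.  Two strategies run at the same seed therefore see identical
draws for the same person, cycle and purpose, making between-strategy
differences paired: an aspirin-adherent cycle can only *remove* a
recurrence that the IDP-only arm would have had, never add one.  Disabling
`use_common_random_numbers` keys the streams by strategy as well.
Probabilistic sensitivity analysis draws parameters per outer draw
(beta for the aspirin RR, gamma for costs) and runs the strategies paired
within each draw on a fresh inner cohort.

Distribution fitting: gamma costs use mean = base and
SD = (high − base)/1.96, so the published ±20% range approximates a 95%
interval.  The aspirin RR beta anchors its mean at the trial point estimate
0.37 with the SD implied by the 95% range (0.16–0.86); percentile matching
of the range is available (`method="percentile"`) but shifts the draw mean
to 0.51, which distorts the acceptability fractions the analysis reports.

## Numerical and interface choices

* Annual probabilities are used as printed; no half-cycle correction is
  applied to transitions (only the death-cycle utility credit).
* ICERs are exact ratios internally; rounding happens only at display.
* Frontier ties in cost sort by higher QALY first; extended dominance is
  removed iteratively until the frontier ICER sequence strictly increases.
* The cohort's sex split is deterministic (exactly round(n·f) females,
  positions shuffled by seed); entry age defaults to 16, the intervention
  start age, since earlier cycles would add discounting but no strategy
  contrast.
* Degenerate inputs: an all-ones survival table produces zero CRC deaths;
  zero transition probabilities freeze the disease process; a zero horizon
  is rejected.
* Default problem sizes: 100,000 individuals × 40 cycles for headline
  runs; the probabilistic sensitivity analysis defaults to 500 outer draws
  × 10,000-person inner cohorts, with the second-order Monte Carlo error of
  any reported fraction available from the result object (≈ 2 percentage
  points at 500 draws).

## Known limitations

* Desmoid tumours, duodenal adenomas, the ileorectal-anastomosis surgical
  variant, societal/productivity costs and smoking stratification are out
  of scope.
* The synthetic inputs are calibrated stand-ins; absolute cost and QALY
  levels inherit their assumptions.  The entry-prevalence stage mix in
  particular is a reduced-form device for cohort heterogeneity, not an
  epidemiological estimate.
* Between-strategy QALY differences respond near-linearly to the aspirin
  relative risk in this structure; acceptability fractions at two
  willingness-to-pay thresholds simultaneously are reproduced only to
  within a few percentage points (see the Monte Carlo error above).
* The model is single-threaded by contract; reproducibility is exact for a
  given seed, package version and platform numpy.
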