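# fapsim

Microsimulation cost-effectiveness model of colorectal cancer (CRC)
prevention in familial adenomatous polyposis (FAP).

FAP patients carry hundreds of colorectal adenomas and, untreated, face a
near-certain progression to CRC through the adenoma–carcinoma sequence.
`fapsim` simulates individual FAP patients year by year through that
sequence — polyp burden → preclinical cancer (stages I–IV) → clinically
diagnosed cancer → death from CRC or other causes — and compares four
management strategies from a healthcare-payer perspective:

1. **no intervention**,
2. **IDP** — intensive downstaging polypectomy (annual colonoscopy with
   endoscopic removal of all polyps ≥ 5 mm),
3. **IDP + low-dose aspirin** (aspirin multiplies the annual probability of
   recurrent ≥ 5 mm polyps by a relative risk of 0.37), and
4. **IPAA** — prophylactic proctocolectomy with ileal pouch-anal anastomosis
   at age 16.

Each strategy is scored on CRC deaths per 1000 patients, discounted
quality-adjusted life-years (QALYs) and discounted cost per person
(2020 USD under the Japanese national fee schedule, 3%/year discounting,
40 annual cycles from age 16, 100,000 simulated individuals).  Strategies
are then ranked by incremental cost-effectiveness ratio
(ICER = ΔC/ΔQ) with strong/extended dominance pruning and a
willingness-to-pay threshold of $50,000 per QALY.  One-way (tornado) and
probabilistic sensitivity analyses (beta/gamma parameter draws, paired runs
under common random numbers, cost-effectiveness acceptability curves) are
built in, as are a deterministic expectation "oracle" of the cohort model
and a calibration routine that fits the polyp-to-cancer transition scale to
cumulative-incidence targets.

The external inputs a real analysis would take from vital statistics and
cancer registries — the other-cause life table, stage/sex/year-specific
conditional net survival after CRC diagnosis, the entry cohort's occult
cancer prevalence, and calibration targets — are not published, so the
package generates documented synthetic stand-ins
(`fapsim.synthetic_data`), tuned once by `scripts/tune_synthetic.py` so the
packaged defaults reproduce the model's headline outcomes.  See
`docs/methods.md` for the model, its assumptions, and what the stand-ins do
and do not represent.

## Worked example

Run all four strategies on the packaged defaults:

```bash
fapsim run --strategy all --n 100000 --seed 1 --out results/
```

prints (and writes to `results/results.csv`):

```
   strategy  crc_deaths_per_1000   qaly_pp      cost_pp      n             status          icer
       none               298.50 19.322871 11512.057030 100000 strongly_dominated           NaN
        idp                48.15 20.876085 17906.445349 100000 strongly_dominated           NaN
idp_aspirin                30.77 21.069265 11511.973361 100000        on_frontier           NaN
       ipaa                 7.49 21.160944 21046.849637 100000        on_frontier 104002.753434
```

Reading the table: without intervention, 298.5 of every 1000 FAP patients
die of CRC within the 40-year horizon, accruing 19.32 discounted QALYs and
$11,512 of discounted cost (almost entirely cancer treatment).  Annual
downstaging polypectomy alone cuts CRC deaths six-fold but is expensive
($17,906/person, driven by repeated polypectomies at $1,222.50 each).
Adding low-dose aspirin ($19.50/year) suppresses polyp recurrence enough
that the strategy costs essentially the same as doing nothing
($11,512/person) while saving 268 lives per 1000 — so both "no
intervention" and IDP-only are strongly dominated.  Prophylactic surgery
(IPAA) prevents the most CRC deaths but costs $21,047/person; its ICER
against IDP + aspirin is ≈ $104,000 per QALY, above the $50,000
willingness-to-pay threshold, so IDP + aspirin is the cost-effective
strategy.

The library surface mirrors the CLI:

```python
import fapsim
from fapsim.engine import RunConfig, run_all_strategies
from fapsim.cea import build_frontier, decide

params = fapsim.default_params()
life, surv = fapsim.default_life_table(), fapsim.default_survival_table()
runs = run_all_strategies(RunConfig(n=100_000, seed=1), params, life, surv)
frontier = build_frontier([(r.strategy, r.mean_cost, r.mean_qaly) for r in runs])
print(decide(frontier, wtp=50_000).strategy)   # idp_aspirin
```

Other subcommands: `fapsim psa` (probabilistic sensitivity analysis:
per-draw scatter, CEAC table, acceptability fractions), `fapsim owsa`
(tornado analysis of the IPAA vs IDP+aspirin ICER), `fapsim calibrate`
(fit the polyp-to-cancer multiplier to cumulative-incidence targets) and
`fapsim synth` (write the synthetic life/survival/target tables as CSV).

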