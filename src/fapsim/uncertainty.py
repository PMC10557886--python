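"""Deterministic (one-way) and probabilistic sensitivity analysis.

The one-way analysis (tornado) reruns the paired IPAA vs IDP+aspirin
comparison with one parameter at a time pushed to its published low/high
value, everything else at base, under common random numbers.  The
probabilistic analysis redraws every non-fixed parameter from its
distribution, reruns the strategies per draw (again paired within a draw),
and summarises cost-effectiveness acceptability across a willingness-to-pay
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _rng
from .engine import RunConfig, run_strategy
from .interventions import ALL_STRATEGY_KINDS, Strategy, StrategyKind
from .parameters import ParamDistribution, ParameterSet, resolve_distribution, sample_psa_draw
from .synthetic_data import LifeTable, SurvivalTable

PSA_PAIR = (StrategyKind.IDP_ASPIRIN, StrategyKind.IPAA)


@dataclass
class OWSAEntry:
    target: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass
class OWSAResult:
    base_icer: float
    entries: list[OWSAEntry]  # descending ICER span (tornado order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.target,
                    "low": e.low,
                    "high": e.high,
                    "icer_low": e.icer_at_low,
                    "icer_high": e.icer_at_high,
                    "span": e.span,
                }
                for e in self.entries
            ]
        )


def _pair_icer(
    params: ParameterSet,
    life_table: LifeTable,
    survival_table: SurvivalTable,
    cfg: RunConfig,
) -> float:
    """ICER of IPAA over IDP+aspirin from one paired (CRN) run of the two
    strategies; negative values pass through unchanged (dominance flips the
    sign when IPAA yields fewer QALYs at higher cost)."""
    out = {}
    for kind in PSA_PAIR:
        strat = Strategy(
            kind=kind,
            start_age=params.economics.intervention_start_age,
            adherence_aspirin=params.economics.adherence_aspirin,
        )
        scfg = RunConfig(
            n=cfg.n, horizon=cfg.horizon, seed=cfg.seed, strategy=strat,
            entry_age=cfg.entry_age, female_fraction=cfg.female_fraction,
            use_common_random_numbers=cfg.use_common_random_numbers,
        )
        out[kind] = run_strategy(scfg, params, life_table, survival_table)
    s2, s3 = out[StrategyKind.IDP_ASPIRIN], out[StrategyKind.IPAA]
    return (s3.mean_cost - s2.mean_cost) / (s3.mean_qaly - s2.mean_qaly)


def run_owsa(
    params: ParameterSet,
    life_table: LifeTable,
    survival_table: SurvivalTable,
    param_specs: list[ParamDistribution] | None = None,
    run_cfg: RunConfig | None = None,
) -> OWSAResult:
    """One-way deterministic sensitivity analysis on the IPAA vs IDP+aspirin
    ICER.  Each spec is evaluated at its low and high bound with every other
    input at base, using the same seed throughout (paired comparisons)."""
    specs = param_specs if param_specs is not None else params.owsa
    cfg = run_cfg if run_cfg is not None else RunConfig(n=20_000)
    for spec in specs:
        try:
            params.get(spec.target)
        except AttributeError as exc:
            raise KeyError(f"unknown parameter path {spec.target!r}") from exc
    base_icer = _pair_icer(params, life_table, survival_table, cfg)
    entries = []
    for spec in specs:
        icers = []
        for value in (spec.range_low, spec.range_high):
            p = params.copy()
            p.set(spec.target, value)
            if value == params.get(spec.target):
                icers.append(base_icer)
            else:
                icers.append(_pair_icer(p, life_table, survival_table, cfg))
        entries.append(
            OWSAEntry(
                target=spec.target,
                low=spec.range_low,
                high=spec.range_high,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
            )
        )
    entries.sort(key=lambda e: -e.span)
    return OWSAResult(base_icer=base_icer, entries=entries)


@dataclass
class PSAResult:
    """Per-draw strategy outcomes and the derived acceptability summaries."""

    strategies: list[str]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    wtp_grid: np.ndarray
    seed: int
    n_inner: int
    ceac: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for wtp in self.wtp_grid:
            nmb = self.qalys * wtp - self.costs
            winner = np.argmax(nmb, axis=1)
            row = {"wtp": float(wtp)}
            for j, s in enumerate(self.strategies):
                row[s] = float(np.mean(winner == j))
            rows.append(row)
        self.ceac = pd.DataFrame(rows)

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def _idx(self, strategy: str) -> int:
        return self.strategies.index(strategy)

    def fraction_cost_effective(
        self, wtp: float, strategy: str = "idp_aspirin", versus: str = "ipaa"
    ) -> float:
        """Fraction of draws in which ``strategy`` has net monetary benefit
        at least that of ``versus`` at the given threshold."""
        a, b = self._idx(strategy), self._idx(versus)
        nmb = self.qalys * wtp - self.costs
        return float(np.mean(nmb[:, a] >= nmb[:, b]))

    def fraction_dominated(
        self, strategy: str = "ipaa", by: str = "idp_aspirin"
    ) -> float:
        """Fraction of draws in which ``strategy`` is strongly dominated."""
        a, b = self._idx(strategy), self._idx(by)
        worse_cost = self.costs[:, a] >= self.costs[:, b]
        worse_qaly = self.qalys[:, a] <= self.qalys[:, b]
        strict = (self.costs[:, a] > self.costs[:, b]) | (
            self.qalys[:, a] < self.qalys[:, b]
        )
        return float(np.mean(worse_cost & worse_qaly & strict))

    def fraction_icer_above(
        self, wtp: float, strategy: str = "ipaa", versus: str = "idp_aspirin"
    ) -> float:
        """Fraction of draws in which ``strategy`` gains QALYs over
        ``versus`` but at an ICER above the threshold."""
        a, b = self._idx(strategy), self._idx(versus)
        dq = self.qalys[:, a] - self.qalys[:, b]
        dc = self.costs[:, a] - self.costs[:, b]
        gains = dq > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(gains, dc / np.where(gains, dq, 1.0), np.nan)
        return float(np.mean(gains & (ratio > wtp)))

    def monte_carlo_se(self, fraction: float) -> float:
        """Second-order Monte Carlo standard error of a reported fraction."""
        return float(np.sqrt(max(fraction * (1.0 - fraction), 0.0) / self.n_draws))

    def scatter_frame(self) -> pd.DataFrame:
        rows = []
        for d in range(self.n_draws):
            for j, s in enumerate(self.strategies):
                rows.append(
                    {"draw": d, "strategy": s, "cost": self.costs[d, j], "qaly": self.qalys[d, j]}
                )
        return pd.DataFrame(rows)


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    survival_table: SurvivalTable,
    n_draws: int = 500,
    run_cfg: RunConfig | None = None,
    wtp_grid: tuple[float, ...] = (0, 25_000, 50_000, 75_000, 100_000, 150_000, 200_000),
    strategy_kinds: tuple[StrategyKind, ...] = ALL_STRATEGY_KINDS,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw samples the non-fixed parameters from their distributions and
    reruns every requested strategy on a fresh inner cohort under common
    random numbers (paired within the draw); draws differ in both parameters
    and inner-cohort randomness.  The default scale (500 draws x 10,000
    individuals) keeps a desk-scale runtime; the second-order Monte Carlo
    error of a reported fraction is available from the result.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cfg = run_cfg if run_cfg is not None else RunConfig(n=10_000)
    base = params.copy()
    base.psa = [resolve_distribution(s) for s in base.psa]
    names = [k.value for k in strategy_kinds]
    costs = np.zeros((n_draws, len(names)))
    qalys = np.zeros((n_draws, len(names)))
    for d in range(n_draws):
        rng = _rng.stream((cfg.seed, d), "psa_param_draw")
        p_d = sample_psa_draw(base, rng)
        inner_seed = int(
            np.random.SeedSequence([cfg.seed, 90_001, d]).generate_state(1)[0] % (2**31)
        )
        for j, kind in enumerate(strategy_kinds):
            strat = Strategy(
                kind=kind,
                start_age=p_d.economics.intervention_start_age,
                adherence_aspirin=p_d.economics.adherence_aspirin,
            )
            scfg = RunConfig(
                n=cfg.n, horizon=cfg.horizon, seed=inner_seed, strategy=strat,
                entry_age=cfg.entry_age, female_fraction=cfg.female_fraction,
            )
            res = run_strategy(scfg, p_d, life_table, survival_table)
            costs[d, j] = res.mean_cost
            qalys[d, j] = res.mean_qaly
    return PSAResult(
        strategies=names,
        costs=costs,
        qalys=qalys,
        wtp_grid=np.asarray(wtp_grid, dtype=float),
        seed=cfg.seed,
        n_inner=cfg.n,
    )
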