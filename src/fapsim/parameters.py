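"""Model inputs: natural history, test characteristics, effectiveness, harms,
utilities, costs, and economic settings, plus their sensitivity-analysis
distributions.

Every input carries a packaged default taken from the national fee schedule /
published FAP literature that the model was built around.  A ``ParameterSet``
is the single source of truth handed to the simulation engine; probabilistic
sensitivity analysis perturbs a copy of it, never the original.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from scipy import optimize, stats

STAGES = ("I", "II", "III", "IV")
PROGRESSION_KEYS = ("I->II", "II->III", "III->IV")


@dataclass
class NaturalHistoryParams:
    """Annual transition probabilities of the adenoma-carcinoma sequence.

    The polyp-to-cancer probability is age-banded: FAP polyp burden becomes
    markedly more dangerous from age 30 on.
    """

    p_polyp_to_preclin_young: float = 0.015982
    p_polyp_to_preclin_old: float = 0.113758
    age_band_cut: int = 30
    p_preclin_progress: dict[str, float] = field(
        default_factory=lambda: {"I->II": 0.24022, "II->III": 0.22290, "III->IV": 0.27487}
    )
    p_clinical_detect: dict[str, float] = field(
        default_factory=lambda: {"I": 0.07202, "II": 0.11011, "III": 0.18989, "IV": 0.87577}
    )
    #: Probability that a patient already harbours an undetected preclinical
    #: cancer of each stage when entering the model.  FAP patients reach
    #: specialist care with a longstanding polyp burden, so part of the
    #: cohort starts beyond the polyp state; the packaged values are tuned
    #: alongside the synthetic tables (scripts/tune_synthetic.py).
    p_preclin_at_entry: dict[str, float] = field(
        default_factory=lambda: {"I": 0.0072, "II": 0.0054, "III": 0.0036, "IV": 0.0018}
    )


@dataclass
class TestCharacteristics:
    """Colonoscopy surveillance performance."""

    sens_low_risk_polyp: float = 0.865
    sens_high_risk_polyp: float = 0.976
    #: Sensitivity for an undiagnosed preclinical cancer.  Not separately
    #: published; defaults to the high-risk-polyp sensitivity on the grounds
    #: that a preclinical carcinoma is at least as conspicuous as a 10+ mm
    #: polyp.  Configurable.
    sens_preclinical_crc: float = 0.976
    specificity: float = 1.0
    p_perforation_no_polypectomy: float = 0.0001


@dataclass
class EffectivenessParams:
    """Prevention effect sizes."""

    p_polyp_recur_after_idp: float = 0.554
    p_polyp_after_ipaa_lifetime: float = 0.036
    rr_polyp_with_aspirin: float = 0.37
    #: Apply the aspirin relative risk on the probability scale
    #: (0.554 x 0.37); set False for the rate-scale alternative
    #: 1 - (1 - 0.554)**RR.
    rr_on_probability_scale: bool = True
    #: Fraction of recurrent (post-intervention) polyps that are high-risk
    #: (10+ mm) for surveillance-sensitivity purposes.
    recurrent_polyp_high_fraction: float = 0.5


@dataclass
class AdverseEventParams:
    p_aspirin_gi_minor: float = 0.04  # first treatment year, 3-day event
    p_idp_perforation: float = 0.004
    p_idp_bleeding: float = 0.023
    #: Serious aspirin GI bleed (halts aspirin permanently).  Not published;
    #: defaults to 0 with this config hook.
    p_aspirin_serious_bleed: float = 0.0
    #: If True the 4% minor GI event can occur in every aspirin year rather
    #: than only the first.
    aspirin_gi_every_year: bool = False


@dataclass
class UtilitySchedule:
    """Utility weights: baseline 1.0 minus additive per-event decrements."""

    u_baseline: float = 1.0
    d_colonoscopy: float = 0.003
    d_colonoscopy_complication: float = 0.019
    d_crc_initial: dict[str, float] = field(
        default_factory=lambda: {"I": 0.12, "II": 0.18, "III": 0.24, "IV": 0.70}
    )
    d_crc_continuing: dict[str, float] = field(
        default_factory=lambda: {"I": 0.05, "II": 0.05, "III": 0.24, "IV": 0.70}
    )
    d_ipaa: float = 0.110  # one-time, surgery cycle
    d_aspirin_gi: float = 0.004
    #: Credit half the cycle's utility in the cycle of death.
    half_cycle_death: bool = True


@dataclass
class CostSchedule:
    """2020 USD under the Japanese national fee schedule (106.725 JPY/USD)."""

    c_colonoscopy: float = 145.2
    c_ipaa: float = 17_540.0
    c_idp: float = 1_222.5
    c_aspirin_year: float = 19.5
    c_crc_year1: dict[str, float] = field(
        default_factory=lambda: {"I": 12_367.0, "II": 13_109.0, "III": 21_929.0, "IV": 25_178.0}
    )
    c_crc_year2to5: dict[str, float] = field(
        default_factory=lambda: {"I": 333.0, "II": 333.0, "III": 421.0, "IV": 23_846.0}
    )
    c_perforation: float = 12_376.9
    c_bleeding: float = 2_169.7


@dataclass
class EconomicSettings:
    discount_rate: float = 0.03
    wtp_threshold: float = 50_000.0
    horizon_cycles: int = 40
    cohort_size: int = 100_000
    intervention_start_age: int = 16
    adherence_aspirin: float = 1.0


@dataclass
class ParamDistribution:
    """Sensitivity-analysis description of one scalar parameter.

    ``target`` is a dot path into the ParameterSet, e.g.
    ``"costs.c_colonoscopy"``.  ``dist_args`` is filled by
    :func:`resolve_distribution`.
    """

    target: str
    kind: str  # fixed | beta | gamma
    base: float
    range_low: float
    range_high: float
    dist_args: dict[str, float] = field(default_factory=dict)
    #: beta fitting method: "mean" anchors the mean at ``base`` with the SD
    #: implied by the stated 95% range; "percentile" matches (range_low,
    #: range_high) to the 2.5th/97.5th percentiles instead.
    method: str = "mean"


def _default_psa_specs() -> list[ParamDistribution]:
    return [
        ParamDistribution("effectiveness.rr_polyp_with_aspirin", "beta", 0.37, 0.16, 0.86),
        ParamDistribution("costs.c_colonoscopy", "gamma", 145.2, 116.0, 174.0),
        ParamDistribution("costs.c_ipaa", "gamma", 17_540.0, 14_032.0, 21_048.0),
        ParamDistribution("costs.c_idp", "gamma", 1_222.5, 978.0, 1_467.0),
        ParamDistribution("costs.c_aspirin_year", "gamma", 19.5, 16.0, 23.0),
        ParamDistribution("costs.c_perforation", "gamma", 12_376.9, 9_901.0, 14_852.0),
        ParamDistribution("costs.c_bleeding", "gamma", 2_169.7, 1_736.0, 2_604.0),
    ]


def _default_owsa_specs() -> list[ParamDistribution]:
    return [
        ParamDistribution("effectiveness.rr_polyp_with_aspirin", "fixed", 0.37, 0.16, 0.86),
        ParamDistribution("economics.discount_rate", "fixed", 0.03, 0.0, 0.04),
        ParamDistribution("economics.adherence_aspirin", "fixed", 1.0, 0.80, 1.0),
        ParamDistribution("costs.c_colonoscopy", "fixed", 145.2, 116.0, 174.0),
        ParamDistribution("costs.c_ipaa", "fixed", 17_540.0, 14_032.0, 21_048.0),
        ParamDistribution("costs.c_idp", "fixed", 1_222.5, 978.0, 1_467.0),
        ParamDistribution("costs.c_aspirin_year", "fixed", 19.5, 16.0, 23.0),
        ParamDistribution("costs.c_perforation", "fixed", 12_376.9, 9_901.0, 14_852.0),
        ParamDistribution("costs.c_bleeding", "fixed", 2_169.7, 1_736.0, 2_604.0),
    ]


@dataclass
class ParameterSet:
    """Everything the simulation needs, in one validated bundle."""

    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    tests: TestCharacteristics = field(default_factory=TestCharacteristics)
    effectiveness: EffectivenessParams = field(default_factory=EffectivenessParams)
    adverse_events: AdverseEventParams = field(default_factory=AdverseEventParams)
    utilities: UtilitySchedule = field(default_factory=UtilitySchedule)
    costs: CostSchedule = field(default_factory=CostSchedule)
    economics: EconomicSettings = field(default_factory=EconomicSettings)
    #: FAP prevalence in the general population; metadata only (the simulated
    #: cohort is all-FAP).
    fap_prevalence: float = 0.00006
    #: Provenance: JPY per USD used when the cost schedule was converted.
    jpy_per_usd: float = 106.725
    psa: list[ParamDistribution] = field(default_factory=_default_psa_specs)
    owsa: list[ParamDistribution] = field(default_factory=_default_owsa_specs)

    # -- dot-path access -------------------------------------------------
    def get(self, path: str) -> float:
        obj: object = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
        last = parts[-1]
        return obj[last] if isinstance(obj, dict) else getattr(obj, last)

    def set(self, path: str, value: float) -> None:
        obj: object = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
        last = parts[-1]
        if isinstance(obj, dict):
            obj[last] = value
        else:
            setattr(obj, last, value)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class Violation:
    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates: {self.rule}"


class ParameterError(ValueError):
    """Raised when a parameter file is malformed or out of range."""


def _probability_fields(p: ParameterSet) -> Iterator[tuple[str, float]]:
    nh = p.natural_history
    yield "natural_history.p_polyp_to_preclin_young", nh.p_polyp_to_preclin_young
    yield "natural_history.p_polyp_to_preclin_old", nh.p_polyp_to_preclin_old
    for k, v in nh.p_preclin_progress.items():
        yield f"natural_history.p_preclin_progress.{k}", v
    for k, v in nh.p_clinical_detect.items():
        yield f"natural_history.p_clinical_detect.{k}", v
    t = p.tests
    yield "tests.sens_low_risk_polyp", t.sens_low_risk_polyp
    yield "tests.sens_high_risk_polyp", t.sens_high_risk_polyp
    yield "tests.sens_preclinical_crc", t.sens_preclinical_crc
    yield "tests.specificity", t.specificity
    yield "tests.p_perforation_no_polypectomy", t.p_perforation_no_polypectomy
    e = p.effectiveness
    yield "effectiveness.p_polyp_recur_after_idp", e.p_polyp_recur_after_idp
    yield "effectiveness.p_polyp_after_ipaa_lifetime", e.p_polyp_after_ipaa_lifetime
    yield "effectiveness.recurrent_polyp_high_fraction", e.recurrent_polyp_high_fraction
    a = p.adverse_events
    yield "adverse_events.p_aspirin_gi_minor", a.p_aspirin_gi_minor
    yield "adverse_events.p_idp_perforation", a.p_idp_perforation
    yield "adverse_events.p_idp_bleeding", a.p_idp_bleeding
    yield "adverse_events.p_aspirin_serious_bleed", a.p_aspirin_serious_bleed
    yield "economics.adherence_aspirin", p.economics.adherence_aspirin


def validate_params(p: ParameterSet) -> list[Violation]:
    """Report every invariant violation; never raises."""
    out: list[Violation] = []
    for name, v in _probability_fields(p):
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            out.append(Violation(name, v, "probability must be in [0, 1]"))
    if len(p.natural_history.p_preclin_progress) != 3 or set(
        p.natural_history.p_preclin_progress
    ) != set(PROGRESSION_KEYS):
        out.append(
            Violation(
                "natural_history.p_preclin_progress",
                sorted(p.natural_history.p_preclin_progress),
                "progression map must have exactly the 3 stage steps I->II, II->III, III->IV",
            )
        )
    entry = p.natural_history.p_preclin_at_entry
    if set(entry) != set(STAGES):
        out.append(
            Violation(
                "natural_history.p_preclin_at_entry",
                sorted(entry),
                "entry prevalence map must have exactly the 4 stages I-IV",
            )
        )
    else:
        for k, v in entry.items():
            if not 0.0 <= v <= 1.0:
                out.append(
                    Violation(
                        f"natural_history.p_preclin_at_entry.{k}", v, "probability must be in [0, 1]"
                    )
                )
        if sum(entry.values()) > 1.0:
            out.append(
                Violation(
                    "natural_history.p_preclin_at_entry",
                    sum(entry.values()),
                    "total entry prevalence must not exceed 1",
                )
            )
    if len(p.natural_history.p_clinical_detect) != 4 or set(
        p.natural_history.p_clinical_detect
    ) != set(STAGES):
        out.append(
            Violation(
                "natural_history.p_clinical_detect",
                sorted(p.natural_history.p_clinical_detect),
                "detection map must have exactly the 4 stages I-IV",
            )
        )
    if not p.effectiveness.rr_polyp_with_aspirin > 0:
        out.append(
            Violation(
                "effectiveness.rr_polyp_with_aspirin",
                p.effectiveness.rr_polyp_with_aspirin,
                "relative risk must be > 0",
            )
        )
    u = p.utilities
    decs = {
        "utilities.d_colonoscopy": u.d_colonoscopy,
        "utilities.d_colonoscopy_complication": u.d_colonoscopy_complication,
        "utilities.d_ipaa": u.d_ipaa,
        "utilities.d_aspirin_gi": u.d_aspirin_gi,
        **{f"utilities.d_crc_initial.{k}": v for k, v in u.d_crc_initial.items()},
        **{f"utilities.d_crc_continuing.{k}": v for k, v in u.d_crc_continuing.items()},
    }
    for name, v in decs.items():
        if not 0.0 <= v <= 1.0:
            out.append(Violation(name, v, "utility decrement must be in [0, 1]"))
    c = p.costs
    cost_fields = {
        "costs.c_colonoscopy": c.c_colonoscopy,
        "costs.c_ipaa": c.c_ipaa,
        "costs.c_idp": c.c_idp,
        "costs.c_aspirin_year": c.c_aspirin_year,
        "costs.c_perforation": c.c_perforation,
        "costs.c_bleeding": c.c_bleeding,
        **{f"costs.c_crc_year1.{k}": v for k, v in c.c_crc_year1.items()},
        **{f"costs.c_crc_year2to5.{k}": v for k, v in c.c_crc_year2to5.items()},
    }
    for name, v in cost_fields.items():
        if not v >= 0:
            out.append(Violation(name, v, "cost must be >= 0"))
    ec = p.economics
    if not ec.discount_rate >= 0:
        out.append(Violation("economics.discount_rate", ec.discount_rate, "discount rate must be >= 0"))
    if not ec.horizon_cycles >= 1:
        out.append(Violation("economics.horizon_cycles", ec.horizon_cycles, "horizon must be >= 1"))
    if not ec.cohort_size >= 1:
        out.append(Violation("economics.cohort_size", ec.cohort_size, "cohort size must be >= 1"))
    for spec in list(p.psa) + list(p.owsa):
        if spec.kind not in ("fixed", "beta", "gamma"):
            out.append(Violation(f"dist:{spec.target}", spec.kind, "kind must be fixed|beta|gamma"))
        if not spec.range_low <= spec.base <= spec.range_high:
            out.append(
                Violation(
                    f"dist:{spec.target}",
                    (spec.range_low, spec.base, spec.range_high),
                    "range_low <= base <= range_high",
                )
            )
        if spec.kind == "beta" and not (0 < spec.range_low and spec.range_high < 1):
            out.append(Violation(f"dist:{spec.target}", (spec.range_low, spec.range_high), "beta support must be within (0, 1)"))
        if spec.kind == "gamma" and not spec.range_low > 0:
            out.append(Violation(f"dist:{spec.target}", spec.range_low, "gamma support must be > 0"))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "natural_history": NaturalHistoryParams,
    "tests": TestCharacteristics,
    "effectiveness": EffectivenessParams,
    "adverse_events": AdverseEventParams,
    "utilities": UtilitySchedule,
    "costs": CostSchedule,
    "economics": EconomicSettings,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in section '{section}'")
    return cls(**data)


def load_params(path: str | Path | None = None) -> ParameterSet:
    """Load a YAML parameter file, filling gaps with packaged defaults.

    An empty or missing file yields the packaged defaults.  Out-of-range
    values raise :class:`ParameterError` naming the parameter and bound.
    """
    merged: dict = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ParameterError(f"cannot read parameter file {path}: {exc}") from exc
        try:
            user = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise ParameterError(f"malformed YAML in {path}{line}: {exc}") from exc
        if not isinstance(user, dict):
            raise ParameterError(f"parameter file {path} must contain a mapping")
        merged = user
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        data = merged.get(section, {})
        if not isinstance(data, dict):
            raise ParameterError(f"section '{section}' must be a mapping")
        kwargs[section] = _build_section(cls, data, section)
    for scalar in ("fap_prevalence", "jpy_per_usd"):
        if scalar in merged:
            kwargs[scalar] = float(merged[scalar])
    for dist_key in ("psa", "owsa"):
        if dist_key in merged:
            kwargs[dist_key] = [ParamDistribution(**d) for d in merged[dist_key]]
    pset = ParameterSet(**kwargs)
    violations = validate_params(pset)
    if violations:
        raise ParameterError("; ".join(str(v) for v in violations))
    return pset


def default_params() -> ParameterSet:
    """The packaged base-case parameter set."""
    with resources.as_file(
        resources.files("fapsim.data").joinpath("table1_defaults.yaml")
    ) as f:
        return load_params(f)


# ---------------------------------------------------------------------------
# Sensitivity-analysis distributions
# ---------------------------------------------------------------------------

def _fit_beta_percentiles(low: float, high: float, tol: float = 1e-3) -> tuple[float, float]:
    """Shape parameters (a, b) with 2.5th/97.5th percentiles at (low, high)."""

    def resid(x):
        a, b = np.exp(x)
        return [
            stats.beta.ppf(0.025, a, b) - low,
            stats.beta.ppf(0.975, a, b) - high,
        ]

    sol = optimize.root(resid, x0=[np.log(2.0), np.log(2.0)], method="hybr")
    a, b = np.exp(sol.x)
    err = max(
        abs(stats.beta.ppf(0.025, a, b) - low),
        abs(stats.beta.ppf(0.975, a, b) - high),
    )
    if not sol.success or err > tol:
        raise ParameterError(
            f"cannot match beta percentiles to ({low}, {high}); widen the support"
        )
    return float(a), float(b)


def _fit_beta_mean(base: float, low: float, high: float) -> tuple[float, float]:
    """Shape parameters with mean = base and SD = (high - low) / (2 * 1.96)."""
    sd = (high - low) / (2 * 1.96)
    var = sd**2
    nu = base * (1 - base) / var - 1
    if nu <= 0:
        raise ParameterError(f"beta variance {var} infeasible for mean {base}")
    return base * nu, (1 - base) * nu


def resolve_distribution(spec: ParamDistribution) -> ParamDistribution:
    """Fill ``dist_args`` so the spec can be sampled.

    beta: percentile-matched to the stated range (or mean-anchored when
    ``spec.method == "mean"``).  gamma: mean = base,
    SD = (range_high - base) / 1.96 so that the +-20% range approximates a
    95% interval.  fixed: degenerate at base.
    """
    out = dataclasses.replace(spec)
    if spec.kind == "fixed":
        out.dist_args = {}
    elif spec.kind == "beta":
        if spec.method == "mean":
            a, b = _fit_beta_mean(spec.base, spec.range_low, spec.range_high)
        else:
            a, b = _fit_beta_percentiles(spec.range_low, spec.range_high)
        out.dist_args = {"a": a, "b": b}
    elif spec.kind == "gamma":
        sd = (spec.range_high - spec.base) / 1.96
        if sd <= 0:
            raise ParameterError(f"gamma spec for {spec.target} needs range_high > base")
        shape = (spec.base / sd) ** 2
        scale = sd**2 / spec.base
        out.dist_args = {"shape": shape, "scale": scale}
    else:
        raise ParameterError(f"unknown distribution kind {spec.kind!r}")
    return out


def sample_psa_draw(p: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One probabilistic-sensitivity draw: a fresh ParameterSet with each
    non-fixed parameter replaced by a random value; the input is untouched."""
    out = p.copy()
    for spec in p.psa:
        if spec.kind == "fixed":
            continue
        resolved = spec if spec.dist_args else resolve_distribution(spec)
        if spec.kind == "beta":
            value = rng.beta(resolved.dist_args["a"], resolved.dist_args["b"])
        else:
            value = rng.gamma(resolved.dist_args["shape"], resolved.dist_args["scale"])
        out.set(spec.target, float(value))
    return out
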