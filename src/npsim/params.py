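"""Scenario parameterization: definition, validation, I/O and sweep sampling.

A :class:`ScenarioParams` object holds every rate, schedule and modifier that
defines one simulation scenario.  The default set describes a Sub-Saharan
African (Kenya-like) population: marriage and partnership-turnover rates and
condom coverage derived from Demographic and Health Survey data, a normal
gestation model, and age schedules for effective fecundability, coital
frequency and mortality.

Age schedules are step functions given as ``(age, value)`` pairs, interpreted
as constant on ``[age_i, age_{i+1})``; ages below the first knot map to 0 and
ages at or beyond the last knot take the last value.  The time modifier
``h(t)`` on nonmarital partnering rates is piecewise linear in years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "AgeTable",
    "ParamsError",
    "ScenarioParams",
    "default_params",
    "load_params",
    "save_params",
    "sample_sweep_params",
]

DAYS_PER_YEAR = 365.0

#: Partnership classes used throughout the package.
PREMARITAL, MARITAL, EXTRAMARITAL = "premarital", "marital", "extramarital"


class ParamsError(ValueError):
    """A scenario parameter failed validation; the message names the field."""


class AgeTable:
    """Right-open step function of age, defined by ``(age, value)`` knots."""

    def __init__(self, pairs: Sequence[tuple[float, float]]):
        if len(pairs) == 0:
            raise ParamsError("age table must contain at least one (age, value) pair")
        pairs = sorted((float(a), float(v)) for a, v in pairs)
        self.ages = np.array([a for a, _ in pairs])
        self.values = np.array([v for _, v in pairs])
        if np.any(np.diff(self.ages) <= 0):
            raise ParamsError("age table knots must have strictly increasing ages")

    def __call__(self, age):
        """Evaluate at (array of) ages; below the first knot the value is 0."""
        idx = np.searchsorted(self.ages, age, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if np.ndim(age) else float(out)

    def dense(self, max_age: int = 120) -> np.ndarray:
        """Values at integer ages 0..max_age, for fast per-step lookup."""
        return self(np.arange(max_age + 1, dtype=float))

    def as_pairs(self) -> list[list[float]]:
        return [[float(a), float(v)] for a, v in zip(self.ages, self.values)]

    def __eq__(self, other):
        return (
            isinstance(other, AgeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self):
        return f"AgeTable({self.as_pairs()!r})"


def _table(pairs):
    return AgeTable(pairs)


@dataclass
class ScenarioParams:
    """All rates, schedules and modifiers defining one simulation scenario.

    Rates are per year, durations in the units their names state, and
    probabilities dimensionless.  ``phi_m`` is the fraction of a married
    woman's coital acts that are with her spouse rather than an extramarital
    partner.
    """

    # partnership dynamics
    marriage_rate_alpha: float = 0.12          # per year, women > 15 y
    marital_duration_mean_years: float = 20.0  # 1 / mu_marital
    casual_duration_months: float = 6.0        # 1 / mu_casual
    # gestation
    gestation_mean_days: float = 267.0
    gestation_sd_days: float = 10.0
    # nonmarital partnering (new partnerships per woman-year)
    premarital_rate_mean: float = 0.32
    premarital_rate_var: float = 0.0087
    extramarital_rate_mean: float = 0.0088
    extramarital_rate_var: float = 0.0
    # coital act allocation and condoms
    phi_m: float = 0.7
    condom_coverage: dict = field(
        default_factory=lambda: {"unmarried": 0.23, "marital": 0.019, "extramarital": 0.074}
    )
    condom_efficacy: float = 0.90
    # age schedules
    fecundability_by_age: AgeTable = None      # per-coital-act conception prob
    coital_frequency_by_age: AgeTable = None   # acts per year
    mortality_by_age: AgeTable = None          # per-year death hazard
    nonmarital_age_multiplier: AgeTable = None # multiplier on nonmarital rates
    # time modifier on nonmarital partnering rates: piecewise-linear (year, value)
    h_of_t: list = field(default_factory=lambda: [[0.0, 1.0]])
    # population and run control
    initial_population: int = 20_000
    time_step_days: float = 7.0
    burn_in_years: float = 50.0
    horizon_years: float = 150.0
    max_fertile_age: float = 49.0
    seed: int = 0

    def __post_init__(self):
        if self.fecundability_by_age is None:
            self.fecundability_by_age = _default_fecundability()
        if self.coital_frequency_by_age is None:
            self.coital_frequency_by_age = _default_coital_frequency()
        if self.mortality_by_age is None:
            self.mortality_by_age = _default_mortality()
        if self.nonmarital_age_multiplier is None:
            self.nonmarital_age_multiplier = AgeTable([(15.0, 1.0)])
        for name in (
            "fecundability_by_age",
            "coital_frequency_by_age",
            "mortality_by_age",
            "nonmarital_age_multiplier",
        ):
            v = getattr(self, name)
            if not isinstance(v, AgeTable):
                setattr(self, name, AgeTable(v))

    # -- derived rates -----------------------------------------------------
    @property
    def mu_marital(self) -> float:
        return 1.0 / self.marital_duration_mean_years

    @property
    def mu_casual(self) -> float:
        """Per-year dissolution hazard of nonmarital partnerships."""
        return 12.0 / self.casual_duration_months

    def h(self, t_years):
        """Time modifier on nonmarital partnering rates (piecewise linear)."""
        pts = np.asarray(self.h_of_t, dtype=float)
        return np.interp(t_years, pts[:, 0], pts[:, 1])

    # -- validation --------------------------------------------------------
    def validate(self) -> "ScenarioParams":
        def req(cond, msg):
            if not cond:
                raise ParamsError(msg)

        req(self.marriage_rate_alpha >= 0, "marriage_rate_alpha must be >= 0")
        req(self.marital_duration_mean_years > 0, "marital_duration_mean_years must be > 0")
        req(self.casual_duration_months > 0, "casual_duration_months must be > 0")
        req(self.gestation_mean_days > 0, "gestation_mean_days must be > 0")
        req(self.gestation_sd_days >= 0, "gestation_sd_days must be >= 0")
        for name in ("premarital_rate_mean", "extramarital_rate_mean"):
            req(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("premarital_rate_var", "extramarital_rate_var"):
            req(getattr(self, name) >= 0, f"{name} must be >= 0")
        req(0.0 < self.phi_m < 1.0, "phi_m must lie in the open interval (0, 1)")
        req(
            set(self.condom_coverage) == {"unmarried", "marital", "extramarital"},
            "condom_coverage must map the keys unmarried/marital/extramarital",
        )
        for k, v in self.condom_coverage.items():
            req(0.0 <= v <= 1.0, f"condom_coverage[{k}] must lie in [0, 1]")
        req(0.0 <= self.condom_efficacy <= 1.0, "condom_efficacy must lie in [0, 1]")
        f = self.fecundability_by_age
        req(np.all((f.values >= 0) & (f.values <= 1)), "fecundability values must lie in [0, 1]")
        req(f.ages[0] <= 15 and f.ages[-1] >= 49, "fecundability_by_age must cover ages 15-49")
        c = self.coital_frequency_by_age
        req(np.all(c.values >= 0), "coital_frequency values must be >= 0")
        req(c.ages[0] <= 15 and c.ages[-1] >= 49, "coital_frequency_by_age must cover ages 15-49")
        d = self.mortality_by_age
        req(np.all(d.values >= 0), "mortality values must be >= 0")
        req(d.ages[0] <= 0, "mortality_by_age must cover age 0 upward")
        req(np.all(self.nonmarital_age_multiplier.values >= 0),
            "nonmarital_age_multiplier values must be >= 0")
        pts = np.asarray(self.h_of_t, dtype=float)
        req(pts.ndim == 2 and pts.shape[1] == 2, "h_of_t must be a list of (year, value) pairs")
        req(np.all(pts[:, 1] >= 0), "h_of_t values must be >= 0")
        req(self.initial_population >= 0, "initial_population must be >= 0")
        req(self.time_step_days > 0, "time_step_days must be > 0")
        req(self.burn_in_years >= 0, "burn_in_years must be >= 0")
        req(self.horizon_years > 0, "horizon_years must be > 0")
        req(self.max_fertile_age > 15, "max_fertile_age must exceed 15")
        return self

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            out[f_.name] = v.as_pairs() if isinstance(v, AgeTable) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioParams":
        known = {f_.name for f_ in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParamsError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**d).validate()

    def replace(self, **kw) -> "ScenarioParams":
        return dataclasses.replace(self, **kw)

    def __eq__(self, other):
        if not isinstance(other, ScenarioParams):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _default_fecundability() -> AgeTable:
    # Effective per-act conception probability.  Calibrated once so that the
    # default scenario is demographically near-stationary (completed
    # fertility ~3 births per woman surviving to adulthood, matching the
    # default mortality schedule): the model has no birth-spacing mechanisms
    # (lactational amenorrhea, postpartum abstinence, non-condom
    # contraception), so these values absorb them rather than represent raw
    # biological fecundability.
    return AgeTable(
        [
            (15, 0.0026),
            (20, 0.0037),
            (25, 0.0034),
            (30, 0.0029),
            (35, 0.0021),
            (40, 0.0012),
            (45, 0.0004),
            (50, 0.0),
        ]
    )


def _default_coital_frequency() -> AgeTable:
    # Acts per year; ~8/month at 20 y declining to ~3/month by 49 y.
    return AgeTable(
        [
            (15, 96.0),
            (25, 84.0),
            (30, 72.0),
            (35, 60.0),
            (40, 48.0),
            (45, 40.0),
            (50, 36.0),
            (65, 12.0),
        ]
    )


def _default_mortality() -> AgeTable:
    # Per-year hazard; abridged life-table shape with elevated infant/child
    # mortality (pre-transition regime, e0 ~ 45-50 y) so the default scenario
    # is near-stationary over multi-century horizons.
    return AgeTable(
        [
            (0, 0.15),
            (1, 0.028),
            (5, 0.008),
            (10, 0.004),
            (15, 0.005),
            (20, 0.006),
            (25, 0.007),
            (30, 0.008),
            (35, 0.009),
            (40, 0.011),
            (45, 0.014),
            (50, 0.019),
            (55, 0.027),
            (60, 0.039),
            (65, 0.058),
            (70, 0.088),
            (75, 0.135),
            (80, 0.21),
            (90, 0.36),
        ]
    )


def default_params() -> ScenarioParams:
    """The default (Kenya-like DHS-derived) scenario parameter set."""
    return ScenarioParams().validate()


def save_params(params: ScenarioParams, path) -> None:
    """Write a scenario to a YAML file (round-trips with :func:`load_params`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(path) -> ScenarioParams:
    """Load and validate a scenario from a YAML file.

    Omitted fields take their defaults; unknown fields and invariant
    violations raise :class:`ParamsError` naming the offending field.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            d = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ParamsError(f"could not parse {path}: {e}") from e
    if not isinstance(d, dict):
        raise ParamsError(f"{path} does not contain a parameter mapping")
    return ScenarioParams.from_dict(d)


#: Sweep ranges for nonmarital partnering rates across Sub-Saharan Africa:
#: (premarital mean, premarital var, extramarital mean, extramarital var).
SSA_SWEEP_RANGES = {
    "premarital_rate_mean": (0.0, 1.0),
    "premarital_rate_var": (0.0, 2.0),
    "extramarital_rate_mean": (0.0, 0.5),
    "extramarital_rate_var": (0.0, 1.0),
}


def sample_sweep_params(
    base: ScenarioParams, rng: np.random.Generator, n: int
) -> list[ScenarioParams]:
    """Draw ``n`` scenarios with nonmarital rate means/variances uniform on
    the Sub-Saharan-Africa ranges; all other fields copied from ``base``."""
    if n < 1:
        raise ParamsError("n must be >= 1")
    out = []
    for _ in range(n):
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in SSA_SWEEP_RANGES.items()}
        out.append(base.replace(**draws))
    return out
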