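"""Female population dynamics: aging, death, marriage and nonmarital partnering.

All per-step event probabilities are ``1 - exp(-rate * dt)`` for the
appropriate per-year hazard.  Women are eligible for partnership formation
above age 15; marriage is monogamous (at most one husband at a time) and
remarriage uses the same formation hazard as first marriage.  Each woman
carries individual premarital and extramarital partnering rates drawn from a
Gamma distribution with the scenario's mean and variance, giving the
population-level heterogeneity in partner acquisition that drives the
spread of the extramarital-partnership ratio across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .params import DAYS_PER_YEAR, ScenarioParams
from .state import (
    CLS_EXTRAMARITAL,
    CLS_MARITAL,
    CLS_PREMARITAL,
    INF,
    PopulationState,
)

ELIGIBLE_AGE = 15.0  # years; no partnership or marriage at or below this age
MAX_AGE = 120


@dataclass
class StepCache:
    """Per-integer-age lookups and per-step scalars, precomputed once per run."""

    dt_days: float
    dt_years: float
    p_death: np.ndarray       # per-step death probability by integer age
    acts_mean: np.ndarray     # mean coital acts per step by integer age
    fecundability: np.ndarray # per-act conception probability by integer age
    age_multiplier: np.ndarray
    p_marry: float
    p_divorce: float
    p_casual_end: float
    p_act_marital: np.ndarray
    p_act_extramarital: np.ndarray
    p_act_premarital: np.ndarray

    @classmethod
    def build(cls, params: ScenarioParams) -> "StepCache":
        dt_days = params.time_step_days
        dt_years = dt_days / DAYS_PER_YEAR
        ages = np.arange(MAX_AGE + 1, dtype=float)
        d = params.mortality_by_age(ages)
        fec = params.fecundability_by_age(ages)
        eff = params.condom_efficacy
        cov = params.condom_coverage
        return cls(
            dt_days=dt_days,
            dt_years=dt_years,
            p_death=-np.expm1(-d * dt_years),
            acts_mean=params.coital_frequency_by_age(ages) * dt_years,
            fecundability=fec,
            age_multiplier=params.nonmarital_age_multiplier(ages),
            p_marry=-np.expm1(-params.marriage_rate_alpha * dt_years),
            p_divorce=-np.expm1(-params.mu_marital * dt_years),
            p_casual_end=-np.expm1(-params.mu_casual * dt_years),
            p_act_marital=fec * (1.0 - eff * cov["marital"]),
            p_act_extramarital=fec * (1.0 - eff * cov["extramarital"]),
            p_act_premarital=fec * (1.0 - eff * cov["unmarried"]),
        )


def _age_index(state: PopulationState, t: float) -> np.ndarray:
    a = (t - state.women.birth_day) / DAYS_PER_YEAR
    return np.clip(a.astype(np.int64), 0, MAX_AGE)


def draw_rate(mean, variance, rng: np.random.Generator, size=None):
    """Draw individual per-year partnering rate(s) with given mean/variance.

    Gamma-distributed (shape = mean^2/var, scale = var/mean); a zero variance
    or zero mean degenerates to the mean itself.
    """
    mean = float(mean)
    variance = float(variance)
    if mean < 0 or variance < 0:
        raise ValueError("mean and variance must be nonnegative")
    if mean == 0.0 or variance == 0.0:
        out = np.full(size, mean) if size is not None else mean
        return out
    shape = mean * mean / variance
    scale = variance / mean
    return rng.gamma(shape, scale, size=size)


def stationary_married_fraction(alpha: float, mu: float, age):
    """Married prevalence at age ``a`` under the two-state marriage model.

    p(a) = alpha/(alpha+mu) * (1 - exp(-(alpha+mu)(a-15))) for a > 15, else 0.
    """
    age = np.asarray(age, dtype=float)
    s = alpha + mu
    if s == 0.0:
        return np.zeros_like(age)
    p = alpha / s * -np.expm1(-s * np.clip(age - ELIGIBLE_AGE, 0.0, None))
    return np.where(age > ELIGIBLE_AGE, p, 0.0)


def _stationary_age_sample(params: ScenarioParams, rng, n: int) -> np.ndarray:
    """Sample ages (years) from the stationary age pyramid of the mortality table."""
    grid = np.arange(0.0, MAX_AGE + 1.0)
    haz = params.mortality_by_age(grid)
    survivorship = np.exp(-np.concatenate([[0.0], np.cumsum(haz[:-1])]))
    w = survivorship / survivorship.sum()
    ages = rng.choice(grid, size=n, p=w) + rng.uniform(0.0, 1.0, size=n)
    return ages


def init_population(params: ScenarioParams, rng: np.random.Generator) -> PopulationState:
    """Create the t=0 population of women.

    Ages follow the stationary pyramid of the mortality schedule; marital
    status is seeded from the stationary married fraction implied by the
    marriage formation/dissolution hazards, so burn-in converges quickly.
    """
    state = PopulationState()
    n = int(params.initial_population)
    if n == 0:
        return state
    ages = _stationary_age_sample(params, rng, n)
    married = rng.random(n) < stationary_married_fraction(
        params.marriage_rate_alpha, params.mu_marital, ages
    )
    husbands = np.full(n, -1, dtype=np.int64)
    husbands[married] = state.new_partner_tokens(int(married.sum()))
    idx = state.women.append(
        birth_day=-ages * DAYS_PER_YEAR,
        death_day=INF,
        married=married,
        husband=husbands,
        marriage_row=-1,
        rate_pre=draw_rate(params.premarital_rate_mean, params.premarital_rate_var, rng, n),
        rate_extra=draw_rate(params.extramarital_rate_mean, params.extramarital_rate_var, rng, n),
        gest_due=np.nan,
        gest_father=-1,
        gest_putative=-1,
        gest_nonpat=False,
        registry_row=-1,
    )
    m_idx = idx[married]
    rows = state.episodes.append(
        woman=m_idx,
        partner=husbands[married],
        cls=CLS_MARITAL,
        start_day=0.0,
        end_day=INF,
    )
    state.women.marriage_row[m_idx] = rows
    return state


def _close_episodes_of(state: PopulationState, woman_idx: np.ndarray, t: float) -> None:
    """Close all open episodes (marital and nonmarital) of the given women."""
    if woman_idx.size == 0:
        return
    mrows = state.women.marriage_row[woman_idx]
    open_m = mrows >= 0
    state.episodes.end_day[mrows[open_m]] = t
    state.women.marriage_row[woman_idx] = -1
    flag = np.zeros(state.n_women, dtype=bool)
    flag[woman_idx] = True
    hit = flag[state.pn_woman]
    state.episodes.end_day[state.pn_row[hit]] = t
    keep = ~hit
    state.pn_woman = state.pn_woman[keep]
    state.pn_partner = state.pn_partner[keep]
    state.pn_row = state.pn_row[keep]


def step_demography(
    state: PopulationState,
    params: ScenarioParams,
    rng: np.random.Generator,
    t: float,
    cache: StepCache | None = None,
) -> PopulationState:
    """Apply age-specific mortality to women and to registry-only children.

    A woman's death closes her open partnerships at time ``t`` and clears any
    gestation.  Boys exist only in the registry and die by the same hazard;
    girls' registry rows are synchronised with their women rows.
    """
    cache = cache or StepCache.build(params)
    if state.n_women:
        ai = _age_index(state, t)
        alive = state.alive_mask()
        die = alive & (rng.random(state.n_women) < cache.p_death[ai])
        dead_idx = np.flatnonzero(die)
        if dead_idx.size:
            state.women.death_day[dead_idx] = t
            state.women.married[dead_idx] = False
            state.women.husband[dead_idx] = -1
            state.women.gest_due[dead_idx] = np.nan
            _close_episodes_of(state, dead_idx, t)
            reg = state.women.registry_row[dead_idx]
            reg = reg[reg >= 0]
            state.registry.death_day[reg] = t
    # boys: registry rows without a women-array counterpart
    if len(state.registry):
        boy = (state.registry.woman_idx < 0) & np.isinf(state.registry.death_day)
        bidx = np.flatnonzero(boy)
        if bidx.size:
            ai = np.clip(
                ((t - state.registry.birth_day[bidx]) / DAYS_PER_YEAR).astype(np.int64),
                0,
                MAX_AGE,
            )
            dies = rng.random(bidx.size) < cache.p_death[ai]
            state.registry.death_day[bidx[dies]] = t
    return state


def step_partnerships(
    state: PopulationState,
    params: ScenarioParams,
    rng: np.random.Generator,
    t: float,
    cache: StepCache | None = None,
) -> PopulationState:
    """One step of marriage and nonmarital partnership formation/dissolution.

    Formation and dissolution probabilities are evaluated on the start-of-step
    state: a marriage formed this step cannot dissolve within it, and a woman
    whose marriage dissolves this step can remarry only from the next step.
    Nonmarital formation rates are the woman's individual rate scaled by the
    time modifier ``h(t)`` and the age multiplier; the episode class is frozen
    at formation (extramarital iff the woman is married when it forms).
    """
    cache = cache or StepCache.build(params)
    n = state.n_women
    if n == 0:
        return state
    alive = state.alive_mask()
    ages = state.ages_years(t)
    ai = _age_index(state, t)
    eligible = alive & (ages > ELIGIBLE_AGE)
    married0 = state.women.married.copy()

    # marital dissolution (snapshot)
    div = married0 & alive & (rng.random(n) < cache.p_divorce)
    div_idx = np.flatnonzero(div)
    if div_idx.size:
        rows = state.women.marriage_row[div_idx]
        state.episodes.end_day[rows[rows >= 0]] = t
        state.women.married[div_idx] = False
        state.women.husband[div_idx] = -1
        state.women.marriage_row[div_idx] = -1

    # marriage formation (snapshot: previously unmarried only); a new
    # marriage supplants the woman's ongoing premarital partnerships, which
    # dissolve at the marriage time
    form = eligible & ~married0 & (rng.random(n) < cache.p_marry)
    f_idx = np.flatnonzero(form)
    if f_idx.size:
        _close_episodes_of(state, f_idx, t)
        husbands = state.new_partner_tokens(f_idx.size)
        rows = state.episodes.append(
            woman=f_idx, partner=husbands, cls=CLS_MARITAL, start_day=t, end_day=INF
        )
        state.women.married[f_idx] = True
        state.women.husband[f_idx] = husbands
        state.women.marriage_row[f_idx] = rows

    # nonmarital dissolution (pre-existing partnerships)
    if state.pn_woman.size:
        end = rng.random(state.pn_woman.size) < cache.p_casual_end
        if end.any():
            state.episodes.end_day[state.pn_row[end]] = t
            keep = ~end
            state.pn_woman = state.pn_woman[keep]
            state.pn_partner = state.pn_partner[keep]
            state.pn_row = state.pn_row[keep]

    # nonmarital formation at rate lambda_i * h(t) * age_multiplier(a)
    h = float(params.h(t / DAYS_PER_YEAR))
    if h > 0.0:
        married_now = state.women.married
        rate = np.where(married_now, state.women.rate_extra, state.women.rate_pre)
        rate = rate * (h * cache.age_multiplier[ai])
        p_form = -np.expm1(-rate * cache.dt_years)
        newp = eligible & (rng.random(n) < p_form)
        np_idx = np.flatnonzero(newp)
        if np_idx.size:
            partners = state.new_partner_tokens(np_idx.size)
            cls = np.where(married_now[np_idx], CLS_EXTRAMARITAL, CLS_PREMARITAL).astype(np.int8)
            rows = state.episodes.append(
                woman=np_idx, partner=partners, cls=cls, start_day=t, end_day=INF
            )
            state.pn_woman = np.concatenate([state.pn_woman, np_idx])
            state.pn_partner = np.concatenate([state.pn_partner, partners])
            state.pn_row = np.concatenate([state.pn_row, rows])
    return state


def fit_marriage_rate(target, mu_marital: float) -> float:
    """Least-squares fit of the marriage formation rate to married prevalence.

    ``target`` is a sequence of ``(age, prevalence)`` pairs; the fitted model
    is the closed-form two-state prediction
    ``p(a) = alpha/(alpha+mu) * (1 - exp(-(alpha+mu)(a-15)))`` for a > 15.
    Deterministic; if the target is identically zero the never-married rate
    alpha = 0 is returned.  When the target carries asymptote-only
    information, the bounded minimizer returns the smallest alpha attaining
    the optimum within [0, 10]/year (documented tie-break).
    """
    target = np.asarray(target, dtype=float)
    if target.size == 0:
        raise ValueError("target prevalence table is empty")
    ages, prev = target[:, 0], target[:, 1]
    if np.any((prev < 0) | (prev > 1)):
        raise ValueError("prevalence values must lie in [0, 1]")
    if np.all(prev == 0.0):
        return 0.0

    def sse(alpha):
        return float(np.sum((stationary_married_fraction(alpha, mu_marital, ages) - prev) ** 2))

    res = minimize_scalar(sse, bounds=(0.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)
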