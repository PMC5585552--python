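"""Coital-act allocation, conception, gestation and birth registration.

Act allocation among a married woman's partners follows the spouse-share
parameter ``phi_m``: an expected fraction ``phi_m`` of her acts are with the
spouse and the rest are split uniformly among her active nonmarital partners
(all of them, if she has any); with no such partner all acts are marital.
Unmarried women split acts uniformly among active partners.  Acts are drawn
per channel by Poisson thinning of the age-specific total act rate, which is
distributionally identical to drawing a Poisson total and splitting it
multinomially.

A conception sets a due date drawn from the normal gestation model and
freezes the nonpaternity bookkeeping at conception time: the putative father
is the mother's husband at conception (if any), and the birth is a
nonpaternity event iff she was married and the biological father differs
from the husband.
"""

from __future__ import annotations

import numpy as np

from .params import DAYS_PER_YEAR, ScenarioParams
from .population import ELIGIBLE_AGE, MAX_AGE, StepCache, _age_index, draw_rate
from .state import INF, PopulationState

__all__ = [
    "conception_prob_per_act",
    "allocate_acts",
    "attempt_conceptions",
    "deliver_births",
]

_COVERAGE_KEY = {"marital": "marital", "extramarital": "extramarital", "premarital": "unmarried"}


def conception_prob_per_act(age, partnership_class: str, params: ScenarioParams):
    """Per-act conception probability ``f(age) * (1 - Eff * C_v(class))``.

    ``partnership_class`` is one of ``premarital``/``marital``/``extramarital``
    (premarital acts use the unmarried condom coverage).  Ages outside the
    fecundability table yield 0.
    """
    cov = params.condom_coverage[_COVERAGE_KEY[partnership_class]]
    f = params.fecundability_by_age(age)
    return f * (1.0 - params.condom_efficacy * cov)


def allocate_acts(
    state: PopulationState,
    params: ScenarioParams,
    rng: np.random.Generator,
    cache: StepCache | None = None,
    t: float | None = None,
):
    """Draw this step's coital acts per channel.

    Returns ``(spouse_acts, row_acts)``: ``spouse_acts`` is per woman (0 for
    unmarried/ineligible women) and ``row_acts`` aligns with the active
    nonmarital partnership arrays ``state.pn_*``.
    """
    cache = cache or StepCache.build(params)
    t = state.t if t is None else t
    n = state.n_women
    ages = state.ages_years(t)
    ai = _age_index(state, t)
    active = state.alive_mask() & (ages > ELIGIBLE_AGE)
    total_mean = np.where(active, cache.acts_mean[ai], 0.0)

    k_part = np.bincount(state.pn_woman, minlength=n) if state.pn_woman.size else np.zeros(
        n, dtype=np.int64
    )
    married = state.women.married
    spouse_mean = np.where(
        married, np.where(k_part > 0, params.phi_m, 1.0) * total_mean, 0.0
    )
    spouse_acts = rng.poisson(spouse_mean)

    if state.pn_woman.size:
        w = state.pn_woman
        share = np.where(married[w], 1.0 - params.phi_m, 1.0) / k_part[w]
        row_acts = rng.poisson(total_mean[w] * share)
    else:
        row_acts = np.zeros(0, dtype=np.int64)
    return spouse_acts, row_acts


def attempt_conceptions(
    state: PopulationState,
    params: ScenarioParams,
    rng: np.random.Generator,
    t: float,
    cache: StepCache | None = None,
) -> PopulationState:
    """Attempt conception for every non-gestating woman with allocated acts.

    Each channel (spouse, or one active nonmarital partner) conceives
    independently with probability ``1 - (1 - p_act)^n_acts``; if more than
    one channel succeeds in the same step (rare at weekly resolution) one is
    chosen uniformly at random as the biological father.  Gestating women
    never conceive.
    """
    cache = cache or StepCache.build(params)
    n = state.n_women
    if n == 0:
        return state
    ai = _age_index(state, t)
    fecund = (
        state.alive_mask()
        & ~state.gestating_mask()
        & (state.ages_years(t) > ELIGIBLE_AGE)
        & (state.ages_years(t) <= params.max_fertile_age)
        & (cache.fecundability[ai] > 0.0)
    )
    spouse_acts, row_acts = allocate_acts(state, params, rng, cache, t)

    married = state.women.married
    p_sp = np.where(fecund & married, cache.p_act_marital[ai], 0.0)
    q_sp = 1.0 - (1.0 - p_sp) ** spouse_acts
    succ_sp = rng.random(n) < q_sp

    if state.pn_woman.size:
        w = state.pn_woman
        p_row = np.where(
            married[w], cache.p_act_extramarital[ai[w]], cache.p_act_premarital[ai[w]]
        )
        p_row = np.where(fecund[w], p_row, 0.0)
        q_row = 1.0 - (1.0 - p_row) ** row_acts
        succ_row = rng.random(w.size) < q_row
    else:
        w = np.empty(0, dtype=np.int64)
        succ_row = np.zeros(0, dtype=bool)

    n_succ = np.bincount(w[succ_row], minlength=n) + succ_sp.astype(np.int64)
    conceiving = np.flatnonzero(n_succ > 0)
    if conceiving.size == 0:
        return state

    father = np.where(succ_sp, state.women.husband, -1)
    multi = np.flatnonzero(n_succ > 1)
    single_row = np.flatnonzero((n_succ == 1) & ~succ_sp)
    if single_row.size:
        rows_by_woman = {}
        wr = w[succ_row]
        pr = state.pn_partner[succ_row]
        for wi, pi in zip(wr, pr):
            rows_by_woman.setdefault(wi, []).append(pi)
        for wi in single_row:
            father[wi] = rows_by_woman[wi][0]
    for wi in multi:  # rare: several channels conceived; pick one at random
        cands = []
        if succ_sp[wi]:
            cands.append(state.women.husband[wi])
        cands.extend(state.pn_partner[succ_row & (w == wi)])
        father[wi] = cands[rng.integers(len(cands))]

    gest = np.maximum(
        1.0,
        np.round(rng.normal(params.gestation_mean_days, params.gestation_sd_days, conceiving.size)),
    )
    state.women.gest_due[conceiving] = t + gest
    state.women.gest_father[conceiving] = father[conceiving]
    is_married = married[conceiving]
    state.women.gest_putative[conceiving] = np.where(
        is_married, state.women.husband[conceiving], -1
    )
    state.women.gest_nonpat[conceiving] = is_married & (
        father[conceiving] != state.women.husband[conceiving]
    )
    return state


def deliver_births(
    state: PopulationState,
    params: ScenarioParams,
    rng: np.random.Generator,
    t: float,
) -> PopulationState:
    """Deliver every gestation at or past its due date.

    Creates one registry row per birth with the nonpaternity flag frozen at
    conception; sex is assigned 1:1 and girls additionally enter the female
    population (becoming eligible for partnering at 15 y), which keeps long
    runs self-sustaining.
    """
    due = np.flatnonzero(state.alive_mask() & (state.women.gest_due <= t))
    if due.size == 0:
        return state
    female = rng.random(due.size) < 0.5
    rows = state.registry.append(
        mother=due,
        bio_father=state.women.gest_father[due],
        putative_father=state.women.gest_putative[due],
        birth_day=state.women.gest_due[due],
        death_day=INF,
        nonpaternity=state.women.gest_nonpat[due],
        female=female,
        woman_idx=-1,
    )
    g = np.flatnonzero(female)
    if g.size:
        widx = state.women.append(
            birth_day=state.women.gest_due[due][g],
            death_day=INF,
            married=False,
            husband=-1,
            marriage_row=-1,
            rate_pre=draw_rate(params.premarital_rate_mean, params.premarital_rate_var, rng, g.size),
            rate_extra=draw_rate(
                params.extramarital_rate_mean, params.extramarital_rate_var, rng, g.size
            ),
            gest_due=np.nan,
            gest_father=-1,
            gest_putative=-1,
            gest_nonpat=False,
            registry_row=rows[g],
        )
        state.registry.woman_idx[rows[g]] = widx
    state.women.gest_due[due] = np.nan
    state.women.gest_father[due] = -1
    state.women.gest_putative[due] = -1
    state.women.gest_nonpat[due] = False
    return state
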