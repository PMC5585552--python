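"""Shared fixtures: small seeded simulation runs reused across test modules."""

import numpy as np
import pytest

import npsim


def _zero_mortality():
    return [(0, 0.0)]


@pytest.fixture(scope="session")
def small_params():
    """Small, fast scenario with elevated nonmarital rates (busy logs)."""
    return npsim.default_params().replace(
        initial_population=400,
        horizon_years=40,
        burn_in_years=20,
        premarital_rate_mean=0.5,
        premarital_rate_var=0.1,
        extramarital_rate_mean=0.3,
        extramarital_rate_var=0.05,
    )


@pytest.fixture(scope="session")
def small_run(small_params):
    return npsim.run_simulation(small_params, seed=11)


@pytest.fixture(scope="session")
def nomort_run():
    """Mortality-free run: cohorts never shrink, so NPR_x back-projects NPR."""
    p = npsim.default_params().replace(
        initial_population=300,
        horizon_years=30,
        burn_in_years=5,
        mortality_by_age=_zero_mortality(),
        extramarital_rate_mean=0.3,
        extramarital_rate_var=0.0,
    )
    return npsim.run_simulation(p, seed=5)


def make_state(params, n, age_years, married, partners_per_woman=0, rng=None):
    """Hand-built population state: n identical women for channel-level tests."""
    from npsim.state import CLS_EXTRAMARITAL, CLS_MARITAL, CLS_PREMARITAL, INF, PopulationState

    rng = rng or np.random.default_rng(0)
    state = PopulationState()
    husbands = state.new_partner_tokens(n) if married else np.full(n, -1)
    idx = state.women.append(
        birth_day=np.full(n, -age_years * 365.0),
        death_day=INF,
        married=married,
        husband=husbands,
        marriage_row=-1,
        rate_pre=params.premarital_rate_mean,
        rate_extra=params.extramarital_rate_mean,
        gest_due=np.nan,
        gest_father=-1,
        gest_putative=-1,
        gest_nonpat=False,
        registry_row=-1,
    )
    if married:
        rows = state.episodes.append(
            woman=idx, partner=husbands, cls=CLS_MARITAL, start_day=0.0, end_day=INF
        )
        state.women.marriage_row[idx] = rows
    for _ in range(partners_per_woman):
        partners = state.new_partner_tokens(n)
        cls = CLS_EXTRAMARITAL if married else CLS_PREMARITAL
        rows = state.episodes.append(
            woman=idx, partner=partners, cls=cls, start_day=0.0, end_day=INF
        )
        state.pn_woman = np.concatenate([state.pn_woman, idx])
        state.pn_partner = np.concatenate([state.pn_partner, partners])
        state.pn_row = np.concatenate([state.pn_row, rows])
    return state
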