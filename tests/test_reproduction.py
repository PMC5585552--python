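"""Act allocation, conception, gestation and nonpaternity bookkeeping."""

import numpy as np
import pytest

import npsim
from npsim.population import StepCache
from npsim.reproduction import (
    allocate_acts,
    attempt_conceptions,
    conception_prob_per_act,
    deliver_births,
)

from conftest import make_state


def flat_fec(params, f):
    return params.replace(fecundability_by_age=[(15, f), (50, 0.0)])


class TestConceptionProbPerAct:
    def test_marital_condom_adjustment(self):
        # f=0.03, Eff=0.90, C_v=0.019 -> 0.03 * (1 - 0.0171) = 0.029487
        p = flat_fec(npsim.default_params(), 0.03)
        assert conception_prob_per_act(30.0, "marital", p) == pytest.approx(0.029487)

    def test_no_condom_effect(self):
        p = flat_fec(npsim.default_params().replace(condom_efficacy=0.0), 0.03)
        assert conception_prob_per_act(30.0, "premarital", p) == 0.03

    def test_full_protection(self):
        p = flat_fec(
            npsim.default_params().replace(
                condom_efficacy=1.0,
                condom_coverage={"unmarried": 1.0, "marital": 1.0, "extramarital": 1.0},
            ),
            0.03,
        )
        assert conception_prob_per_act(30.0, "marital", p) == 0.0

    def test_age_outside_table_is_zero(self):
        p = npsim.default_params()
        assert conception_prob_per_act(80.0, "marital", p) == 0.0
        assert conception_prob_per_act(5.0, "marital", p) == 0.0


class TestAllocateActs:
    def test_married_without_partner_gets_all_acts(self):
        p = npsim.default_params()
        n = 20_000
        state = make_state(p, n, age_years=25.0, married=True)
        spouse, rows = allocate_acts(state, p, np.random.default_rng(0), t=0.0)
        assert rows.size == 0
        mean = p.coital_frequency_by_age(25.0) * p.time_step_days / 365.0
        se = np.sqrt(mean / n)
        assert abs(spouse.mean() - mean) < 3 * se

    def test_spouse_share_matches_phi(self):
        # married + 1 extramarital partner: expected spouse share phi_m = 0.7
        p = npsim.default_params()
        n = 20_000
        state = make_state(p, n, age_years=25.0, married=True, partners_per_woman=1)
        spouse, rows = allocate_acts(state, p, np.random.default_rng(1), t=0.0)
        total = spouse.sum() + rows.sum()
        share = spouse.sum() / total
        se = np.sqrt(0.7 * 0.3 / total)
        assert abs(share - 0.7) < 3 * se

    def test_unmarried_without_partners_no_allocation(self):
        p = npsim.default_params()
        state = make_state(p, 100, age_years=25.0, married=False)
        spouse, rows = allocate_acts(state, p, np.random.default_rng(0), t=0.0)
        assert spouse.sum() == 0 and rows.size == 0


class TestAttemptConceptions:
    def test_step_conception_probability(self):
        # N ~ Poisson(mu) acts at per-act p: P(conceive) = 1 - exp(-mu * p)
        p = flat_fec(npsim.default_params(), 0.05)
        n = 100_000
        state = make_state(p, n, age_years=25.0, married=True)
        attempt_conceptions(state, p, np.random.default_rng(3), t=7.0)
        mu = p.coital_frequency_by_age(25.0) * 7.0 / 365.0
        pa = 0.05 * (1 - 0.9 * 0.019)
        p_exp = 1 - np.exp(-mu * pa)
        frac = state.gestating_mask().mean()
        assert abs(frac - p_exp) < 3 * np.sqrt(p_exp * (1 - p_exp) / n)

    def test_gestating_women_never_conceive_again(self):
        p = flat_fec(npsim.default_params(), 0.9)
        state = make_state(p, 200, age_years=25.0, married=True)
        state.women.gest_due[:] = 500.0
        state.women.gest_father[:] = 777
        attempt_conceptions(state, p, np.random.default_rng(0), t=7.0)
        assert np.all(state.women.gest_due == 500.0)
        assert np.all(state.women.gest_father == 777)

    def test_sterile_population_never_conceives(self):
        p = flat_fec(npsim.default_params(), 0.0)
        state = make_state(p, 500, age_years=25.0, married=True, partners_per_woman=1)
        for k in range(10):
            attempt_conceptions(state, p, np.random.default_rng(k), t=7.0 * (k + 1))
        assert not state.gestating_mask().any()

    def test_gestation_duration_moments(self):
        p = flat_fec(npsim.default_params(), 0.95)
        n = 20_000
        state = make_state(p, n, age_years=25.0, married=True)
        t = 7.0
        attempt_conceptions(state, p, np.random.default_rng(4), t=t)
        dur = state.women.gest_due[state.gestating_mask()] - t
        assert dur.size > 10_000
        assert abs(dur.mean() - 267.0) < 3 * 10.0 / np.sqrt(dur.size)
        assert abs(dur.std(ddof=1) - 10.0) < 0.05 * 10.0


class TestNonpaternityBookkeeping:
    def _one_gestating(self, married, father_is_husband):
        p = npsim.default_params()
        state = make_state(p, 1, age_years=25.0, married=married)
        husband = state.women.husband[0]
        father = husband if father_is_husband else state.new_partner_tokens(1)[0]
        state.women.gest_due[0] = 100.0
        state.women.gest_father[0] = father
        state.women.gest_putative[0] = husband if married else -1
        state.women.gest_nonpat[0] = bool(married and father != husband)
        return p, state

    def test_spouse_conception_is_not_nonpaternity(self):
        p, state = self._one_gestating(married=True, father_is_husband=True)
        deliver_births(state, p, np.random.default_rng(0), t=100.0)
        assert not state.registry.nonpaternity[0]

    def test_extramarital_conception_is_nonpaternity(self):
        p, state = self._one_gestating(married=True, father_is_husband=False)
        deliver_births(state, p, np.random.default_rng(0), t=100.0)
        assert state.registry.nonpaternity[0]
        assert state.registry.putative_father[0] >= 0
        assert state.registry.bio_father[0] != state.registry.putative_father[0]

    def test_status_at_conception_governs(self):
        # conceived premaritally, marries during gestation: not a nonpaternity event
        p, state = self._one_gestating(married=False, father_is_husband=False)
        state.women.married[0] = True
        state.women.husband[0] = state.new_partner_tokens(1)[0]
        deliver_births(state, p, np.random.default_rng(0), t=100.0)
        assert not state.registry.nonpaternity[0]
        assert state.registry.putative_father[0] == -1

    def test_nonpaternity_ledger_equality(self, small_run):
        """Nonpaternity births are exactly the married-at-conception births
        whose biological father is not the husband of record."""
        reg = small_run.registry
        married_at_conception = reg["putative_father_id"].to_numpy() >= 0
        mismatch = reg["bio_father_id"].to_numpy() != reg["putative_father_id"].to_numpy()
        expected = married_at_conception & mismatch
        np.testing.assert_array_equal(reg["nonpaternity"].to_numpy(), expected)
        assert expected.sum() > 0  # scenario busy enough to exercise the flag

    def test_nonpaternity_fathers_are_nonmarital_partners(self, small_run):
        """Each nonpaternity birth's biological father appears in a
        nonmarital episode of the same mother (extramarital-class, or a
        premarital-class partnership still active after she married — the
        episode class is frozen at formation)."""
        reg = small_run.registry
        epi = small_run.episodes
        nm = epi[epi["cls"] != "marital"]
        nm_pairs = set(zip(nm["woman_id"], nm["partner_id"]))
        npat = reg[reg["nonpaternity"]]
        assert len(npat) > 0
        for _, row in npat.iterrows():
            assert (row["mother_id"], row["bio_father_id"]) in nm_pairs

    def test_phi_near_one_eliminates_nonpaternity(self):
        p = npsim.default_params().replace(
            initial_population=300,
            horizon_years=20,
            burn_in_years=0,
            phi_m=1.0 - 1e-12,
            extramarital_rate_mean=0.5,
            extramarital_rate_var=0.0,
        )
        res = npsim.run_simulation(p, seed=6)
        assert len(res.registry) > 50
        assert res.registry["nonpaternity"].sum() == 0


class TestDeliverBirths:
    def test_daughters_enter_female_population(self):
        p = npsim.default_params()
        n = 400
        state = make_state(p, n, age_years=25.0, married=True)
        state.women.gest_due[:] = 50.0
        state.women.gest_father[:] = state.women.husband
        state.women.gest_putative[:] = state.women.husband
        deliver_births(state, p, np.random.default_rng(1), t=50.0)
        assert len(state.registry) == n
        girls = state.registry.female.sum()
        assert state.n_women == n + girls
        # girls' registry rows point back at their women rows
        widx = state.registry.woman_idx[state.registry.female]
        assert np.all(widx >= n)
        assert not state.gestating_mask().any()
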