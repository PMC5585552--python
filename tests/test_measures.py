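"""The four measures against fixtures, brute-force oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import npsim
from npsim.experiments import generate_fixture_registry
from npsim.measures import (
    compute_epr,
    compute_hsr,
    compute_npr,
    compute_npr_x,
    hsr_series,
    measure_series,
    moving_average,
    npr_x_profile,
)

from _oracles import epr_bruteforce, hsr_bruteforce, npr_bruteforce, npr_x_bruteforce


@pytest.fixture(scope="module")
def fixture_tables():
    spec = {
        "n_births": 8,
        "n_nonpaternity": 2,
        "sibships": [("A", "A", "B"), ("C", "C")],
        "episodes": {"marital": 12, "extramarital": 3},
        "t_end": 3650.0,
    }
    return generate_fixture_registry(spec)


class TestNPR:
    def test_fixture_count(self, fixture_tables):
        registry, _ = fixture_tables
        assert compute_npr(registry, 3650.0) == pytest.approx(2 / 8)

    def test_empty_window_is_undefined(self, fixture_tables):
        registry, _ = fixture_tables
        assert np.isnan(compute_npr(registry, 20_000.0))

    def test_zero_extramarital_scenario_yields_zero(self):
        p = npsim.default_params().replace(
            initial_population=300, horizon_years=20, burn_in_years=10,
            extramarital_rate_mean=0.0, extramarital_rate_var=0.0,
        )
        res = npsim.run_simulation(p, seed=1)
        s = measure_series(res)
        defined = s.npr[~np.isnan(s.npr)]
        assert defined.size > 0 and np.all(defined == 0.0)

    def test_matches_bruteforce(self, small_run):
        t = small_run.final_day
        assert compute_npr(small_run.registry, t) == pytest.approx(
            npr_bruteforce(small_run.registry, t)
        )


class TestNPRx:
    def test_fixture_band(self, fixture_tables):
        registry, _ = fixture_tables
        # the 8 window births are all aged < 1 at t_end and alive
        assert compute_npr_x(registry, 3650.0, 0) == pytest.approx(2 / 8)

    def test_empty_band_is_undefined(self, fixture_tables):
        registry, _ = fixture_tables
        assert np.isnan(compute_npr_x(registry, 3650.0, 30))

    def test_back_projection_identity_without_mortality(self, nomort_run):
        """NPR_x(t) = NPR(t - x) exactly when no child ever dies."""
        t = nomort_run.final_day
        prof = npr_x_profile(nomort_run.registry, t, max_age=10)
        for x in range(11):
            expected = compute_npr(nomort_run.registry, t - x * 365.0)
            if np.isnan(expected):
                assert np.isnan(prof[x])
            else:
                assert prof[x] == pytest.approx(expected)

    def test_profile_matches_scalar_and_bruteforce(self, small_run):
        t = small_run.final_day
        prof = npr_x_profile(small_run.registry, t, max_age=8)
        for x in range(9):
            scalar = compute_npr_x(small_run.registry, t, x)
            brute = npr_x_bruteforce(small_run.registry, t, x)
            if np.isnan(scalar):
                assert np.isnan(prof[x]) and np.isnan(brute)
            else:
                assert prof[x] == pytest.approx(scalar) == pytest.approx(brute)


class TestEPR:
    def test_fixture_count(self, fixture_tables):
        _, episodes = fixture_tables
        assert compute_epr(episodes, 3650.0) == pytest.approx(3 / 15)

    def test_no_married_women_is_undefined(self):
        episodes = pd.DataFrame(
            [{"woman_id": 1, "partner_id": 2, "cls": "premarital",
              "start_day": 0.0, "end_day": np.inf}]
        )
        assert np.isnan(compute_epr(episodes, 365.0))

    def test_matches_bruteforce_rescan(self, small_run):
        for t in [small_run.final_day, small_run.final_day - 5 * 365.0]:
            assert compute_epr(small_run.episodes, t) == pytest.approx(
                epr_bruteforce(small_run.episodes, t)
            )


class TestHSR:
    def test_single_mixed_sibship(self):
        # (A,A,B): pairs AA same, AB diff, AB diff -> 2/3
        registry, _ = generate_fixture_registry({"sibships": [("A", "A", "B")]})
        assert compute_hsr(registry, 365.0) == pytest.approx(2 / 3)

    def test_mixed_sibships(self, fixture_tables):
        registry, _ = fixture_tables
        # (A,A,B) contributes 2 different-father pairs of 3; (C,C) one same pair
        assert compute_hsr(registry, 3650.0) == pytest.approx(2 / 4)

    def test_single_father_sibships_give_zero(self):
        registry, _ = generate_fixture_registry({"sibships": [("A", "A"), ("B", "B", "B")]})
        assert compute_hsr(registry, 365.0) == 0.0

    def test_undefined_without_sibships(self):
        registry, _ = generate_fixture_registry({"n_births": 3})
        assert np.isnan(compute_hsr(registry, 365.0))

    def test_matches_bruteforce_pairs(self, small_run):
        t = small_run.final_day
        assert compute_hsr(small_run.registry, t) == pytest.approx(
            hsr_bruteforce(small_run.registry, t)
        )
        assert compute_hsr(small_run.registry, t, scope="all") == pytest.approx(
            hsr_bruteforce(small_run.registry, t, marital_scope=False)
        )

    def test_series_matches_pointwise(self, small_run):
        days = small_run.census_days()[::5]
        series = hsr_series(small_run.registry, days)
        for t, v in zip(days, series):
            assert v == pytest.approx(compute_hsr(small_run.registry, t))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.lists(hst.lists(hst.integers(0, 3), min_size=1, max_size=6),
                     min_size=1, max_size=8),
           hst.data())
    def test_appending_halfsib_never_decreases_hsr(self, sibships, data):
        registry, _ = generate_fixture_registry(
            {"sibships": [tuple(s) for s in sibships]}
        )
        hsr0 = compute_hsr(registry, 1e9)
        mother = data.draw(
            hst.sampled_from(sorted(registry["mother_id"].unique()))
        )
        fresh_father = registry["bio_father_id"].max() + 1  # differs from all
        new = pd.DataFrame(
            [{"child_id": 9999, "mother_id": mother, "bio_father_id": fresh_father,
              "putative_father_id": fresh_father, "birth_day": 0.0,
              "death_day": np.inf, "nonpaternity": False}]
        )
        hsr1 = compute_hsr(pd.concat([registry, new], ignore_index=True), 1e9)
        if not np.isnan(hsr0):
            assert hsr1 >= hsr0


class TestInvariances:
    def test_row_order_and_relabeling(self, fixture_tables):
        registry, episodes = fixture_tables
        rng = np.random.default_rng(0)
        reg2 = registry.sample(frac=1, random_state=1).reset_index(drop=True)
        reg2["mother_id"] = reg2["mother_id"] * 7 + 3
        reg2["bio_father_id"] = reg2["bio_father_id"] * 7 + 3
        reg2["putative_father_id"] = np.where(
            reg2["putative_father_id"] >= 0, reg2["putative_father_id"] * 7 + 3, -1
        )
        epi2 = episodes.sample(frac=1, random_state=2).reset_index(drop=True)
        epi2["woman_id"] = epi2["woman_id"] + 1000
        t = 3650.0
        assert compute_npr(reg2, t) == compute_npr(registry, t)
        assert compute_hsr(reg2, t) == compute_hsr(registry, t)
        assert compute_epr(epi2, t) == compute_epr(episodes, t)

    def test_measures_defined_values_in_unit_interval(self, small_run):
        s = measure_series(small_run)
        for arr in (s.npr, s.epr, s.hsr):
            defined = arr[~np.isnan(arr)]
            assert np.all((defined >= 0) & (defined <= 1))


class TestMovingAverage:
    def test_constant_series_is_fixed_point(self):
        x = np.full(25, 0.3)
        np.testing.assert_allclose(moving_average(x, 10), x)

    def test_alternating_series_interior(self):
        x = np.tile([0.0, 1.0], 15)
        sm = moving_average(x, 10)
        np.testing.assert_allclose(sm[5:-5], 0.5)

    def test_variance_reduction_on_white_noise(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        assert moving_average(x, 10).var() < x.var()

    def test_window_exceeding_series_gives_global_mean(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(moving_average(x, 10), 2.0)

    def test_nan_values_excluded(self):
        x = np.array([1.0, np.nan, 3.0])
        np.testing.assert_allclose(moving_average(x, 3), [1.0, 2.0, 3.0])
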