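"""The simulation loop: one run of the individual-based model.

Each step of ``time_step_days`` applies, in order: delivery of due births,
mortality, marriage and partnership dynamics, and conception attempts.  The
run returns a :class:`SimulationResult` holding the birth registry, the
partnership episode log and the women's vital records, from which all
epidemiologic measures are computed after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import DAYS_PER_YEAR, ScenarioParams
from .population import StepCache, init_population, step_demography, step_partnerships
from .reproduction import attempt_conceptions, deliver_births
from .state import PopulationState

__all__ = ["SimulationResult", "run_simulation"]


@dataclass
class SimulationResult:
    """Raw output of one simulation run.

    ``registry``/``episodes`` use the package's CSV schemas (see
    :mod:`npsim.measures`); ``women`` carries birth/death days of every woman
    for census denominators.
    """

    params: ScenarioParams
    seed: int | None
    registry: pd.DataFrame
    episodes: pd.DataFrame
    women: pd.DataFrame
    final_day: float
    state: PopulationState = field(repr=False, default=None)

    @property
    def burn_in_day(self) -> float:
        return self.params.burn_in_years * DAYS_PER_YEAR

    def census_days(self, start_year: float | None = None) -> np.ndarray:
        """Annual census times (days), by default the post-burn-in years."""
        first = self.params.burn_in_years + 1.0 if start_year is None else start_year
        years = np.arange(first, self.params.horizon_years + 1e-9)
        return years * DAYS_PER_YEAR


def run_simulation(
    params: ScenarioParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run the individual-based model once and return its raw output.

    Bit-reproducible for a given ``(params, seed)``; a woman's entire event
    history is a deterministic function of the seeded generator stream.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    cache = StepCache.build(params)
    state = init_population(params, rng)
    dt = params.time_step_days
    horizon_days = params.horizon_years * DAYS_PER_YEAR
    t = 0.0
    while t < horizon_days:
        t += dt
        deliver_births(state, params, rng, t)
        step_demography(state, params, rng, t, cache)
        step_partnerships(state, params, rng, t, cache)
        attempt_conceptions(state, params, rng, t, cache)
        state.t = t
    registry = state.registry_frame()
    # girls' vital status lives in the women arrays; mirror it into the registry
    girls = registry["woman_idx"].to_numpy() >= 0
    registry.loc[girls, "death_day"] = state.women.death_day[
        registry.loc[girls, "woman_idx"].to_numpy()
    ]
    women = pd.DataFrame(
        {"birth_day": state.women.birth_day.copy(), "death_day": state.women.death_day.copy()}
    )
    return SimulationResult(
        params=params,
        seed=seed,
        registry=registry,
        episodes=state.episode_frame(),
        women=women,
        final_day=t,
        state=state,
    )
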