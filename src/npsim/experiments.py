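"""The four end-to-end simulation experiments, plus a fixture generator.

1. NPR vs EPR — across runs whose nonmarital partnering rates are drawn from
   Sub-Saharan-Africa ranges, correlate the nonpaternity ratio at T with the
   extramarital partnership ratio at T - 1 (the one-year lag accommodates
   gestation).
2. HSR vs EPR — same design with the half-siblings ratio.
3. Historical back-casting — modulate nonmarital partnering with a
   time-dependent factor h(t) (steady decline to a plateau, or a transient
   drop with recovery) and correlate the age-specific nonpaternity profile
   NPR_x(T) with EPR(T - x - 1), raw and after 10-year moving-average
   smoothing.
4. phi_m sweep — at fixed (Kenya-like) nonmarital rates, sweep the spouse
   share of coital acts and tabulate mean NPR with a 95% interval.

Every experiment is deterministic given (params, seed): per-run generators
are spawned from a single seed sequence, and scale (population, number of
runs, horizon) enters only through configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .engine import SimulationResult, run_simulation
from .measures import MeasureSeries, measure_series, moving_average
from .params import DAYS_PER_YEAR, ScenarioParams, sample_sweep_params
from .stats import CorrelationResult, correlate, paired_lagged_series

__all__ = [
    "HistoricalScenario",
    "ExperimentReport",
    "run_measure_batch",
    "run_npr_epr_experiment",
    "run_hsr_epr_experiment",
    "run_historical_experiment",
    "run_phi_sweep",
    "generate_fixture_registry",
]

NPR_X_MAX_AGE = 50


@dataclass
class HistoricalScenario:
    """A shape for the time modifier h(t) on nonmarital partnering rates.

    ``steady_decline``: h falls linearly from ``peak_level`` to
    ``floor_level`` over ``decline_duration_years`` and plateaus.
    ``transient_drop``: h falls to the floor and recovers linearly over
    ``recovery_duration_years``.  ``decline_start_year`` defaults to 40 years
    before the run horizon so the change lies inside the back-cast window of
    the age profile.
    """

    shape: str = "steady_decline"
    peak_level: float = 1.0
    floor_level: float = 0.3
    decline_start_year: float | None = None
    decline_duration_years: float = 10.0
    recovery_duration_years: float = 5.0

    def __post_init__(self):
        if self.shape not in ("steady_decline", "transient_drop"):
            raise ValueError("shape must be 'steady_decline' or 'transient_drop'")
        if not 0.0 <= self.floor_level <= self.peak_level:
            raise ValueError("need 0 <= floor_level <= peak_level")
        if self.decline_duration_years <= 0 or self.recovery_duration_years <= 0:
            raise ValueError("durations must be > 0")

    @classmethod
    def steady_decline(cls, **kw) -> "HistoricalScenario":
        return cls(shape="steady_decline", **kw)

    @classmethod
    def transient_drop(cls, **kw) -> "HistoricalScenario":
        kw.setdefault("decline_duration_years", 5.0)
        return cls(shape="transient_drop", **kw)

    def h_breakpoints(self, horizon_years: float) -> list[list[float]]:
        start = (
            self.decline_start_year
            if self.decline_start_year is not None
            else horizon_years - 40.0
        )
        if start < 0:
            raise ValueError("decline starts before the run does")
        pts = [[0.0, self.peak_level], [start, self.peak_level],
               [start + self.decline_duration_years, self.floor_level]]
        if self.shape == "transient_drop":
            pts.append(
                [start + self.decline_duration_years + self.recovery_duration_years,
                 self.peak_level]
            )
        return pts


@dataclass
class ExperimentReport:
    """Everything an experiment computed, recomputable from its stored series."""

    name: str
    seed: int
    n_sims: int
    series: list = field(default_factory=list)          # per-run MeasureSeries
    correlations: dict = field(default_factory=dict)    # label -> CorrelationResult
    sweep_table: pd.DataFrame | None = None
    scenario: HistoricalScenario | None = None
    params_hash: str = ""
    run_params: list = field(default_factory=list, repr=False)

    def correlation_frame(self) -> pd.DataFrame:
        rows = [
            {"experiment": self.name, "pairing": c.pairing, "r": c.r, "n": c.n,
             "ci_low": c.ci_low, "ci_high": c.ci_high}
            for c in self.correlations.values()
        ]
        return pd.DataFrame(rows)


def _params_hash(params: ScenarioParams) -> str:
    return sha256(yaml.safe_dump(params.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_measure_batch(
    base_params: ScenarioParams,
    n_sims: int,
    seed: int,
    sweep: bool = True,
    npr_x_max_age: int | None = None,
) -> tuple[list[MeasureSeries], list[ScenarioParams], list[SimulationResult]]:
    """Run ``n_sims`` seeded simulations and compute their measure series.

    With ``sweep=True`` each run draws nonmarital rate means/variances from
    the Sub-Saharan-Africa ranges; otherwise all runs use ``base_params``.
    """
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    plist = (
        sample_sweep_params(base_params, master, n_sims)
        if sweep
        else [base_params] * n_sims
    )
    series, results = [], []
    for i, (p, child) in enumerate(zip(plist, ss.spawn(n_sims + 1)[1:])):
        res = run_simulation(p, rng=np.random.default_rng(child))
        res.seed = i
        series.append(measure_series(res, npr_x_max_age=npr_x_max_age))
        res.state = None  # drop the mutable state; frames carry everything
        results.append(res)
    return series, plist, results


def _lagged_correlation_report(
    name: str, y_measure: str, base_params: ScenarioParams, n_sims: int, seed: int
) -> ExperimentReport:
    series, plist, _ = run_measure_batch(base_params, n_sims, seed, sweep=True)
    x, y = paired_lagged_series(series, lag_years=1, y_measure=y_measure)
    corr = correlate(x, y, n_runs=n_sims, pairing=f"{y_measure}(T) ~ epr(T-1)")
    return ExperimentReport(
        name=name,
        seed=seed,
        n_sims=n_sims,
        series=series,
        correlations={"pooled": corr},
        params_hash=_params_hash(base_params),
        run_params=plist,
    )


def run_npr_epr_experiment(
    base_params: ScenarioParams, n_sims: int = 100, seed: int = 0
) -> ExperimentReport:
    """Correlate NPR(T) with EPR(T-1) across sweep-drawn runs."""
    return _lagged_correlation_report("npr_epr", "npr", base_params, n_sims, seed)


def run_hsr_epr_experiment(
    base_params: ScenarioParams, n_sims: int = 100, seed: int = 0
) -> ExperimentReport:
    """Correlate HSR(T) with EPR(T-1) across sweep-drawn runs."""
    return _lagged_correlation_report("hsr_epr", "hsr", base_params, n_sims, seed)


def historical_pairs(
    series_list: list[MeasureSeries], smooth_window: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (EPR(T-x-1), NPR_x(T)) pairs for x = 0..max_age across runs.

    With ``smooth_window`` set, both the EPR history and the NPR_x age
    profile are moving-average smoothed before pairing.
    """
    xs, ys = [], []
    for s in series_list:
        if s.npr_x is None:
            raise ValueError("series lack an NPR_x profile; rerun with npr_x_max_age")
        epr = moving_average(s.epr, smooth_window) if smooth_window else s.epr
        prof = moving_average(s.npr_x, smooth_window) if smooth_window else s.npr_x
        T = s.npr_x_census_year
        for x in range(prof.size):
            target_year = T - x - 1
            j = np.searchsorted(s.t_years, target_year)
            if j >= s.t_years.size or abs(s.t_years[j] - target_year) > 1e-6:
                continue
            if np.isnan(epr[j]) or np.isnan(prof[x]):
                continue
            xs.append(epr[j])
            ys.append(prof[x])
    return np.asarray(xs), np.asarray(ys)


def run_historical_experiment(
    base_params: ScenarioParams,
    scenario: HistoricalScenario,
    n_sims: int = 100,
    seed: int = 0,
) -> ExperimentReport:
    """Back-cast a historical change in nonmarital partnering from NPR_x.

    The scenario's floor corresponds to the base (self-reported, Kenya-like)
    nonmarital rates: base rate means are divided by ``floor_level`` so the
    plateau of ``h(t) * rate`` equals the base rates while h itself ramps
    from the peak (1.0) to the floor.  Correlates NPR_x(T) at the final
    census with EPR(T - x - 1), raw and 10-year-smoothed.
    """
    horizon = base_params.horizon_years
    params = base_params.replace(
        h_of_t=scenario.h_breakpoints(horizon),
        premarital_rate_mean=base_params.premarital_rate_mean / scenario.floor_level,
        extramarital_rate_mean=base_params.extramarital_rate_mean / scenario.floor_level,
    )
    series, plist, _ = run_measure_batch(
        params, n_sims, seed, sweep=False, npr_x_max_age=NPR_X_MAX_AGE
    )
    corrs = {}
    x, y = historical_pairs(series)
    corrs["raw"] = correlate(x, y, n_runs=n_sims, pairing="npr_x(T) ~ epr(T-x-1)")
    xs, ys = historical_pairs(series, smooth_window=10)
    corrs["smoothed"] = correlate(
        xs, ys, n_runs=n_sims, pairing="ma10 npr_x(T) ~ ma10 epr(T-x-1)"
    )
    return ExperimentReport(
        name=f"historical_{scenario.shape}",
        seed=seed,
        n_sims=n_sims,
        series=series,
        correlations=corrs,
        scenario=scenario,
        params_hash=_params_hash(params),
        run_params=plist,
    )


def run_phi_sweep(
    base_params: ScenarioParams,
    phi_values=None,
    n_sims: int = 100,
    seed: int = 0,
) -> ExperimentReport:
    """Sweep the spouse share of coital acts phi_m at fixed nonmarital rates.

    For each phi_m, ``n_sims`` runs at the base (Kenya-like) rates; each
    run's NPR is summarised by its mean over defined census years, and the
    across-run mean with a 95% t-interval is tabulated.
    """
    if phi_values is None:
        phi_values = np.round(np.arange(0.1, 0.95, 0.1), 10)
    rows = []
    all_series = []
    for k, phi in enumerate(phi_values):
        if not 0.0 < phi < 1.0:
            raise ValueError("phi values must lie in (0, 1)")
        p = base_params.replace(phi_m=float(phi))
        series, _, _ = run_measure_batch(p, n_sims, seed + k, sweep=False)
        run_means = np.array([np.nanmean(s.npr) if np.any(~np.isnan(s.npr)) else np.nan
                              for s in series])
        run_means = run_means[~np.isnan(run_means)]
        m = run_means.mean() if run_means.size else np.nan
        if run_means.size >= 2 and run_means.std(ddof=1) > 0:
            lo, hi = sps.t.interval(
                0.95, run_means.size - 1, loc=m, scale=sps.sem(run_means)
            )
        else:
            lo = hi = m
        rows.append({"phi_m": float(phi), "mean_npr": m, "ci_low": lo, "ci_high": hi,
                     "n_runs": int(run_means.size)})
        all_series.append(series)
    return ExperimentReport(
        name="phi_sweep",
        seed=seed,
        n_sims=n_sims,
        series=all_series,
        sweep_table=pd.DataFrame(rows),
        params_hash=_params_hash(base_params),
    )


# ---------------------------------------------------------------------------
# fixture generation for measure-level tests


def generate_fixture_registry(spec: dict, rng: np.random.Generator | None = None):
    """Build a synthetic registry and episode log with exactly known counts.

    ``spec`` keys (all optional):

    ``n_births``, ``n_nonpaternity``
        births inside the window ``(t_end - 365, t_end]``, each to a distinct
        mother, with exactly ``n_nonpaternity`` nonpaternity events;
    ``sibships``
        list of father-label tuples, one per additional mother, whose
        children are born *before* the window (so NPR counts are untouched);
    ``episodes``
        mapping class -> count; marital episodes are given to distinct
        women, nonmarital episodes attached round-robin to those married
        women so all land in the EPR denominator;
    ``t_end``
        window end in days (default 365.0).

    Every count is exact by construction, so each measure has a closed-form
    expected value.  Inconsistent specs raise ``ValueError``.
    """
    rng = rng or np.random.default_rng(0)
    t_end = float(spec.get("t_end", 365.0))
    n_births = int(spec.get("n_births", 0))
    n_np = int(spec.get("n_nonpaternity", 0))
    if n_np > n_births:
        raise ValueError("n_nonpaternity cannot exceed n_births")
    sibships = spec.get("sibships", [])
    episodes_spec = dict(spec.get("episodes", {}))
    bad = set(episodes_spec) - {"marital", "extramarital", "premarital"}
    if bad:
        raise ValueError(f"unknown episode classes: {sorted(bad)}")
    if (episodes_spec.get("extramarital", 0) or episodes_spec.get("premarital", 0)) and not episodes_spec.get("marital", 0):
        raise ValueError("nonmarital episodes require at least one marital episode "
                         "(EPR is defined among married women)")

    reg_rows = []
    child = 0
    mother = 0
    father = 10_000
    for i in range(n_births):
        putative = father
        bio = father if i >= n_np else father + 1
        reg_rows.append(
            dict(child_id=child, mother_id=mother, bio_father_id=bio,
                 putative_father_id=putative, birth_day=t_end - 365.0 + (i + 1) * 365.0 / (n_births + 1),
                 death_day=np.inf, nonpaternity=i < n_np)
        )
        child += 1
        mother += 1
        father += 2
    label_map: dict = {}
    for sib in sibships:
        for j, lab in enumerate(sib):
            fid = label_map.setdefault((mother, lab), father + len(label_map))
            reg_rows.append(
                dict(child_id=child, mother_id=mother, bio_father_id=fid,
                     putative_father_id=fid, birth_day=t_end - 365.0 * (len(sib) + 2) + j,
                     death_day=np.inf, nonpaternity=False)
            )
            child += 1
        mother += 1
    registry = pd.DataFrame(
        reg_rows,
        columns=["child_id", "mother_id", "bio_father_id", "putative_father_id",
                 "birth_day", "death_day", "nonpaternity"],
    )

    epi_rows = []
    n_mar = int(episodes_spec.get("marital", 0))
    wives = list(range(100_000, 100_000 + n_mar))
    for i, w in enumerate(wives):
        epi_rows.append(dict(woman_id=w, partner_id=father + 1000 + i, cls="marital",
                             start_day=t_end - 400.0, end_day=np.inf))
    for cls in ("extramarital", "premarital"):
        for i in range(int(episodes_spec.get(cls, 0))):
            w = wives[i % len(wives)]
            epi_rows.append(dict(woman_id=w, partner_id=father + 2000 + i, cls=cls,
                                 start_day=t_end - 200.0 + i, end_day=t_end - 100.0 + i))
    episodes = pd.DataFrame(
        epi_rows, columns=["woman_id", "partner_id", "cls", "start_day", "end_day"]
    )
    return registry, episodes
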