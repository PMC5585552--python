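"""The four epidemiologic measures of extramarital sex, plus trend smoothing.

All measures are plain functions of the birth registry and/or the
partnership episode log, so they can be computed either from a simulation
result or from external CSV tables with the same schema:

registry columns
    ``child_id, mother_id, bio_father_id, putative_father_id, birth_day,
    death_day, nonpaternity`` (``death_day`` may be +inf/missing = alive)
episode-log columns
    ``woman_id, partner_id, cls`` (one of ``premarital``/``marital``/
    ``extramarital``), ``start_day, end_day`` (+inf = still open)

Measures:

* ``NPR(t)`` — nonpaternity births over the last 12 months / all births in
  that window.
* ``NPR_x(t)`` — among individuals aged [x, x+1) and alive at t, the
  fraction that are nonpaternity events; back-projects ``NPR(t - x)``.
* ``EPR(t)`` — among women married at some point in the last 12 months,
  extramarital partnership episodes overlapping the window / all their
  episodes overlapping the window.
* ``HSR(t)`` — over all children born by t, the fraction of same-mother
  child pairs with different biological fathers.

Undefined ratios (empty denominators) are returned as NaN, never as 0.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import DAYS_PER_YEAR

__all__ = [
    "MeasureSeries",
    "compute_npr",
    "compute_npr_x",
    "npr_x_profile",
    "compute_epr",
    "compute_hsr",
    "hsr_series",
    "measure_series",
    "moving_average",
]

WINDOW_DAYS = 365.0  # "over the last 12 months"


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def compute_npr(registry: pd.DataFrame, t: float) -> float:
    """Nonpaternity ratio at day ``t``: nonpaternity births / all births in
    the window ``(t - 365, t]``.  NaN when there were no births."""
    b = registry["birth_day"].to_numpy()
    in_win = (b > t - WINDOW_DAYS) & (b <= t)
    return _ratio(
        float(registry["nonpaternity"].to_numpy()[in_win].sum()), float(in_win.sum())
    )


def _alive_ages(registry: pd.DataFrame, t: float) -> tuple[np.ndarray, np.ndarray]:
    b = registry["birth_day"].to_numpy()
    d = registry["death_day"].to_numpy() if "death_day" in registry else np.full(b.size, np.inf)
    d = np.where(np.isnan(d), np.inf, d)
    alive = (b <= t) & (d > t)
    return alive, (t - b) / DAYS_PER_YEAR


def compute_npr_x(registry: pd.DataFrame, t: float, x: int) -> float:
    """Age-specific nonpaternity ratio among those aged ``[x, x+1)`` and
    alive at day ``t``."""
    alive, age = _alive_ages(registry, t)
    band = alive & (age >= x) & (age < x + 1)
    return _ratio(float(registry["nonpaternity"].to_numpy()[band].sum()), float(band.sum()))


def npr_x_profile(registry: pd.DataFrame, t: float, max_age: int = 50) -> np.ndarray:
    """``NPR_x(t)`` for integer ages x = 0..max_age (NaN for empty bands)."""
    alive, age = _alive_ages(registry, t)
    band = alive & (age >= 0) & (age < max_age + 1)
    ax = np.floor(age[band]).astype(np.int64)
    npat = registry["nonpaternity"].to_numpy()[band]
    den = np.bincount(ax, minlength=max_age + 1).astype(float)
    num = np.bincount(ax, weights=npat.astype(float), minlength=max_age + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def compute_epr(episodes: pd.DataFrame, t: float) -> float:
    """Extramarital partnership ratio at day ``t``.

    Restricted to women married at any point in ``(t - 365, t]`` (i.e. with a
    marital episode overlapping the window): extramarital episodes
    overlapping the window over all their episodes overlapping the window.
    """
    start = episodes["start_day"].to_numpy()
    end = episodes["end_day"].to_numpy()
    end = np.where(np.isnan(end), np.inf, end)
    overlap = (start <= t) & (end > t - WINDOW_DAYS)
    cls = episodes["cls"].to_numpy()
    woman = episodes["woman_id"].to_numpy()
    married_women = np.unique(woman[overlap & (cls == "marital")])
    if married_women.size == 0:
        return np.nan
    of_married = overlap & np.isin(woman, married_women)
    return _ratio(float((cls[of_married] == "extramarital").sum()), float(of_married.sum()))


def _hsr_scope(registry: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "all":
        return registry
    if scope == "marital":
        if "putative_father_id" not in registry:
            raise ValueError(
                "scope='marital' needs a putative_father_id column; "
                "use scope='all' for registries without one"
            )
        return registry[registry["putative_father_id"].to_numpy() >= 0]
    raise ValueError("scope must be 'marital' or 'all'")


def compute_hsr(
    registry: pd.DataFrame, t: float, definition: str = "pairs", scope: str = "marital"
) -> float:
    """Half-siblings ratio among children born by day ``t``.

    The measure targets partnership turnover among married women —
    extramarital fathering and remarriage — so by default
    (``scope="marital"``) sibships are formed from children conceived within
    a marriage (those with a putative father); ``scope="all"`` additionally
    counts premarital births.

    ``definition="pairs"`` (default): fraction of unordered same-mother child
    pairs whose biological fathers differ.  ``definition="children"``:
    children with at least one half-sibling over children with at least one
    sibling.  NaN when no mother has two children.  Children are counted
    whether or not they are still alive.
    """
    registry = _hsr_scope(registry, scope)
    born = registry[registry["birth_day"].to_numpy() <= t]
    if definition == "pairs":
        total = 0.0
        diff = 0.0
        for _, grp in born.groupby("mother_id")["bio_father_id"]:
            k = len(grp)
            if k < 2:
                continue
            total += k * (k - 1) / 2
            same = sum(c * (c - 1) / 2 for c in grp.value_counts())
            diff += k * (k - 1) / 2 - same
        return _ratio(diff, total)
    if definition == "children":
        with_sib = 0.0
        with_half = 0.0
        for _, grp in born.groupby("mother_id")["bio_father_id"]:
            k = len(grp)
            if k < 2:
                continue
            with_sib += k
            counts = grp.value_counts()
            if len(counts) > 1:
                with_half += sum(c for c in counts)  # every child has a half-sib
                with_half -= sum(c for c in counts if c == k)
        return _ratio(with_half, with_sib)
    raise ValueError("definition must be 'pairs' or 'children'")


def hsr_series(
    registry: pd.DataFrame, census_days: np.ndarray, scope: str = "marital"
) -> np.ndarray:
    """``HSR(t)`` (pair definition) at each census day, computed incrementally."""
    registry = _hsr_scope(registry, scope)
    order = np.argsort(registry["birth_day"].to_numpy(), kind="stable")
    b = registry["birth_day"].to_numpy()[order]
    mother = registry["mother_id"].to_numpy()[order]
    father = registry["bio_father_id"].to_numpy()[order]
    n_children: dict = defaultdict(int)
    n_by_father: dict = defaultdict(int)
    total = 0.0
    diff = 0.0
    out = np.empty(len(census_days))
    i = 0
    for j, t in enumerate(census_days):
        while i < b.size and b[i] <= t:
            m, f = mother[i], father[i]
            total += n_children[m]
            diff += n_children[m] - n_by_father[(m, f)]
            n_children[m] += 1
            n_by_father[(m, f)] += 1
            i += 1
        out[j] = _ratio(diff, total)
    return out


@dataclass
class MeasureSeries:
    """Annual time series of the measures for one simulation run."""

    t_years: np.ndarray
    npr: np.ndarray
    epr: np.ndarray
    hsr: np.ndarray
    #: NPR_x profile (x = 0..max_age) at the final census, when requested
    npr_x: np.ndarray | None = field(default=None)
    npr_x_census_year: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, measure, value) table."""
        rows = []
        for name in ("npr", "epr", "hsr"):
            vals = getattr(self, name)
            rows.append(
                pd.DataFrame({"time": self.t_years, "measure": name, "value": vals})
            )
        return pd.concat(rows, ignore_index=True)


def measure_series(result, census_days: np.ndarray | None = None,
                   npr_x_max_age: int | None = None) -> MeasureSeries:
    """Compute annual NPR/EPR/HSR series (and optionally the final-census
    NPR_x profile) from a :class:`~npsim.engine.SimulationResult`."""
    if census_days is None:
        census_days = result.census_days()
    census_days = np.asarray(census_days, dtype=float)
    reg, epi = result.registry, result.episodes

    b = np.sort(reg["birth_day"].to_numpy(), kind="stable")
    order = np.argsort(reg["birth_day"].to_numpy(), kind="stable")
    np_cum = np.concatenate(
        [[0.0], np.cumsum(reg["nonpaternity"].to_numpy()[order].astype(float))]
    )
    hi = np.searchsorted(b, census_days, side="right")
    lo = np.searchsorted(b, census_days - WINDOW_DAYS, side="right")
    den = (hi - lo).astype(float)
    num = np_cum[hi] - np_cum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        npr = num / den
    npr[den == 0] = np.nan

    epr = np.array([compute_epr(epi, t) for t in census_days])
    hsr = hsr_series(reg, census_days)

    kwargs = {}
    if npr_x_max_age is not None:
        kwargs["npr_x"] = npr_x_profile(reg, census_days[-1], npr_x_max_age)
        kwargs["npr_x_census_year"] = census_days[-1] / DAYS_PER_YEAR
    return MeasureSeries(
        t_years=census_days / DAYS_PER_YEAR, npr=npr, epr=epr, hsr=hsr, **kwargs
    )


def moving_average(series, window: int = 10) -> np.ndarray:
    """Centered moving average over the defined (non-NaN) values.

    The window covers ``window`` consecutive samples (for an even window the
    extra sample falls on the left); at the edges the window is truncated.
    NaNs are excluded from each local mean; a window with no defined values
    yields NaN.  A window at least as long as the series returns the global
    mean everywhere.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = x.size
    left = window // 2
    right = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        seg = x[max(0, i - left) : min(n, i + right + 1)]
        seg = seg[~np.isnan(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out
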