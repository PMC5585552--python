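"""Pearson correlation with Fisher z confidence intervals, and pair pooling.

The correlation analyses pool (EPR(T - lag), measure(T)) pairs across
simulation runs and census times and report the product-moment correlation
with a normal-theory interval on the Fisher z scale.  Because consecutive
annual censuses within one run are autocorrelated, the pooled pair count
overstates the information content; by default the interval is therefore
computed with an effective sample size equal to the number of simulation
runs (``n_eff="runs"``), with the literal pooled count available via
``n_eff="pairs"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "pearson", "fisher_ci", "correlate", "paired_lagged_series"]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (too few pairs or zero variance)."""


@dataclass
class CorrelationResult:
    """A Pearson coefficient with its Fisher-z confidence interval."""

    r: float
    n: int            # effective sample size used for the interval
    ci_low: float
    ci_high: float
    n_pairs: int      # number of pooled pairs the coefficient was computed on
    pairing: str = ""
    level: float = 0.95

    def __post_init__(self):
        assert -1.0 <= self.ci_low <= self.r <= self.ci_high <= 1.0


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Pairs with a NaN in either coordinate are dropped first.  Fewer than
    three complete pairs, or zero variance in either vector, raises
    :class:`UndefinedCorrelationError` (never silently 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UndefinedCorrelationError(f"only {x.size} complete pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(sps.pearsonr(x, y).statistic)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transformation confidence interval for a correlation.

    ``z = atanh(r)`` with standard error ``1/sqrt(n - 3)``; the interval is
    back-transformed with tanh.  ``|r| = 1`` yields the degenerate interval
    ``(r, r)``.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return (r, r)
    if n < 4:
        raise ValueError("n must be >= 4 for a Fisher interval")
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlate(x, y, n_runs: int | None = None, n_eff: str = "runs",
              pairing: str = "", level: float = 0.95) -> CorrelationResult:
    """Pearson r on pooled pairs with a Fisher-z interval.

    ``n_eff="runs"`` (default) uses ``n_runs`` as the interval's sample size;
    ``n_eff="pairs"`` uses the pooled pair count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    r = pearson(x, y)
    if n_eff == "runs":
        if n_runs is None:
            raise ValueError("n_runs required when n_eff='runs'")
        n = int(n_runs)
    elif n_eff == "pairs":
        n = int(ok.sum())
    else:
        raise ValueError("n_eff must be 'runs' or 'pairs'")
    lo, hi = fisher_ci(r, n, level) if n >= 4 else (-1.0, 1.0)
    return CorrelationResult(
        r=r, n=n, ci_low=lo, ci_high=hi, n_pairs=int(ok.sum()), pairing=pairing, level=level
    )


def paired_lagged_series(series_list, lag_years: int, y_measure: str = "npr",
                         per_run_mean: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Pool ``(EPR(T - lag), measure(T))`` pairs across runs and census times.

    ``series_list`` is a list of :class:`~npsim.measures.MeasureSeries` on a
    common annual grid; ``y_measure`` selects ``npr`` or ``hsr``.  Pairs with
    an undefined value in either coordinate are dropped.  With
    ``per_run_mean=True`` each run contributes a single (mean x, mean y)
    pair.  Raises if no defined pairs remain.
    """
    if lag_years < 0:
        raise ValueError("lag must be >= 0")
    xs, ys = [], []
    for s in series_list:
        y = getattr(s, y_measure)
        if lag_years >= y.size:
            continue
        x = s.epr[: y.size - lag_years] if lag_years else s.epr
        yv = y[lag_years:]
        ok = ~(np.isnan(x) | np.isnan(yv))
        if per_run_mean:
            if ok.any():
                xs.append(np.mean(x[ok]))
                ys.append(np.mean(yv[ok]))
        else:
            xs.append(x[ok])
            ys.append(yv[ok])
    if not xs:
        raise UndefinedCorrelationError("no defined pairs at this lag")
    x = np.asarray(xs) if per_run_mean else np.concatenate(xs)
    y = np.asarray(ys) if per_run_mean else np.concatenate(ys)
    if x.size == 0:
        raise UndefinedCorrelationError("no defined pairs at this lag")
    return x, y
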