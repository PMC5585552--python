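"""Struct-of-arrays population state shared by the dynamics modules.

The simulated units are women, held in parallel numpy arrays for speed
(thousands of women over thousands of weekly steps).  Children are recorded
in a birth registry; boys live only there, girls additionally get a row in
the women arrays and become eligible for partnering at 15 y.  Every
partnership episode (premarital, marital, extramarital) is logged with start
and end times for the extramarital-partnership-ratio computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INF = np.inf

#: integer partnership-class codes used in the episode log
CLS_PREMARITAL, CLS_MARITAL, CLS_EXTRAMARITAL = 0, 1, 2
CLS_NAMES = np.array(["premarital", "marital", "extramarital"])


class _Table:
    """Growable struct-of-arrays with amortised appends."""

    def __init__(self, schema: dict[str, np.dtype], capacity: int = 1024):
        self.schema = schema
        self.n = 0
        self._cols = {k: np.empty(capacity, dtype=dt) for k, dt in schema.items()}

    def __len__(self):
        return self.n

    def __getattr__(self, name):
        cols = object.__getattribute__(self, "_cols")
        if name in cols:
            return cols[name][: self.n]
        raise AttributeError(name)

    def _grow(self, extra):
        cap = len(next(iter(self._cols.values())))
        if self.n + extra <= cap:
            return
        new_cap = max(cap * 2, self.n + extra)
        for k, arr in self._cols.items():
            new = np.empty(new_cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            self._cols[k] = new

    def append(self, **cols) -> np.ndarray:
        """Append rows given as equal-length arrays; returns their indices."""
        arr_sizes = [np.size(v) for v in cols.values() if np.ndim(v) > 0]
        k = max(arr_sizes) if arr_sizes else 1
        if arr_sizes and min(arr_sizes) == 0:
            k = 0
        if k == 0:
            return np.empty(0, dtype=np.int64)
        self._grow(k)
        idx = np.arange(self.n, self.n + k)
        for name, arr in self._cols.items():
            arr[self.n : self.n + k] = cols[name]
        self.n += k
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: self._cols[k][: self.n].copy() for k in self.schema})


def _women_table(capacity=1024):
    return _Table(
        {
            "birth_day": np.float64,
            "death_day": np.float64,   # +inf while alive
            "married": np.bool_,
            "husband": np.int64,       # partner token, -1 if unmarried
            "marriage_row": np.int64,  # open marital episode row in the log
            "rate_pre": np.float64,    # individual premarital partnering rate (/y)
            "rate_extra": np.float64,  # individual extramarital partnering rate (/y)
            "gest_due": np.float64,    # NaN if not gestating
            "gest_father": np.int64,
            "gest_putative": np.int64,
            "gest_nonpat": np.bool_,
            "registry_row": np.int64,  # -1 for founder women
        },
        capacity,
    )


def _registry_table(capacity=1024):
    return _Table(
        {
            "mother": np.int64,          # index into women arrays
            "bio_father": np.int64,      # partner token
            "putative_father": np.int64, # husband at conception, -1 if unmarried
            "birth_day": np.float64,
            "death_day": np.float64,
            "nonpaternity": np.bool_,
            "female": np.bool_,
            "woman_idx": np.int64,       # girls: row in women arrays; boys: -1
        },
        capacity,
    )


def _episode_table(capacity=4096):
    return _Table(
        {
            "woman": np.int64,
            "partner": np.int64,
            "cls": np.int8,
            "start_day": np.float64,
            "end_day": np.float64,  # +inf while open
        },
        capacity,
    )


class PopulationState:
    """Mutable simulation state: women, birth registry, partnerships, log."""

    def __init__(self):
        self.women = _women_table()
        self.registry = _registry_table()
        self.episodes = _episode_table()
        # active nonmarital partnerships (compact parallel arrays)
        self.pn_woman = np.empty(0, dtype=np.int64)
        self.pn_partner = np.empty(0, dtype=np.int64)
        self.pn_row = np.empty(0, dtype=np.int64)  # episode-log row
        self._next_partner = 0
        self.t = 0.0

    # -- tokens ------------------------------------------------------------
    def new_partner_tokens(self, k: int) -> np.ndarray:
        out = np.arange(self._next_partner, self._next_partner + k, dtype=np.int64)
        self._next_partner += k
        return out

    # -- convenience views ---------------------------------------------------
    @property
    def n_women(self) -> int:
        return len(self.women)

    def alive_mask(self) -> np.ndarray:
        return np.isinf(self.women.death_day)

    def ages_years(self, t: float) -> np.ndarray:
        return (t - self.women.birth_day) / 365.0

    def gestating_mask(self) -> np.ndarray:
        return ~np.isnan(self.women.gest_due)

    # -- exports -------------------------------------------------------------
    def registry_frame(self) -> pd.DataFrame:
        """Birth registry as a DataFrame (the standalone-measure CSV schema)."""
        df = self.registry.to_frame()
        df.insert(0, "child_id", np.arange(len(df)))
        df = df.rename(columns={"mother": "mother_id", "bio_father": "bio_father_id",
                                "putative_father": "putative_father_id"})
        return df

    def episode_frame(self) -> pd.DataFrame:
        df = self.episodes.to_frame()
        df["cls"] = CLS_NAMES[df["cls"].to_numpy()]
        df = df.rename(columns={"woman": "woman_id", "partner": "partner_id"})
        return df
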