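"""Monthly climate series and bootstrap forcing construction.

A forcing series for the simulator is built by splicing short windows of
recent observed climate (emulating CRU TS grid-cell extracts, 1934-2013)
onto a long simulated paleo series: windows are drawn at random from the
recent record, bound together to cover the pre-observational span, and
each window is adjusted so that its window-mean temperature and
precipitation match the corresponding window of the paleo series.  This
conserves realistic month-to-month and year-to-year variability while
following the long-term paleo trend.  The observed overlap years are kept
verbatim at the end of the series.  Site variants are derived from the
master series by shifting temperature additively and scaling
precipitation by the ratio of site to master means over the overlap
years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimateYear",
    "ClimateSeries",
    "ForcingRecipe",
    "load_climate_table",
    "write_climate_table",
    "assemble_master_forcing",
    "site_adjust_series",
    "overlap_means",
]

TMEAN_MIN, TMEAN_MAX = -70.0, 45.0


@dataclass(frozen=True)
class MonthlyClimateYear:
    """One calendar (or model) year of monthly climate.

    Parameters
    ----------
    year : int
        Calendar or model year; may be negative (year -3982 lies 3982
        years before year 1).
    tmean : array of 12 floats
        Monthly mean temperatures, degrees Celsius.
    prec : array of 12 floats
        Monthly precipitation sums, mm; non-negative.
    """

    year: int
    tmean: np.ndarray
    prec: np.ndarray

    def __post_init__(self):
        tmean = np.asarray(self.tmean, dtype=float)
        prec = np.asarray(self.prec, dtype=float)
        if tmean.shape != (12,) or prec.shape != (12,):
            raise ValueError("tmean and prec must each hold exactly 12 monthly values")
        if np.any(prec < 0):
            raise ValueError(f"negative precipitation in year {self.year}")
        if np.any((tmean < TMEAN_MIN) | (tmean > TMEAN_MAX)):
            raise ValueError(
                f"temperature outside [{TMEAN_MIN}, {TMEAN_MAX}] degC in year {self.year}"
            )
        object.__setattr__(self, "tmean", tmean)
        object.__setattr__(self, "prec", prec)


class ClimateSeries:
    """Contiguous run of years, each with 12 monthly temperature means
    and precipitation sums.

    Stored internally as dense arrays: ``tmean`` and ``prec`` have shape
    ``(n_years, 12)`` and ``years`` is strictly consecutive.
    """

    def __init__(self, years, tmean, prec, label: str = "", meta: dict | None = None):
        years = np.asarray(years, dtype=int)
        tmean = np.asarray(tmean, dtype=float)
        prec = np.asarray(prec, dtype=float)
        if years.ndim != 1 or len(years) == 0:
            raise ValueError("series must contain at least one year")
        if tmean.shape != (len(years), 12) or prec.shape != (len(years), 12):
            raise ValueError("tmean/prec must have shape (n_years, 12)")
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be strictly consecutive")
        if np.any(prec < 0):
            bad = years[np.any(prec < 0, axis=1)][0]
            raise ValueError(f"negative precipitation in year {bad}")
        self.years = years
        self.tmean = tmean
        self.prec = prec
        self.label = label
        self.meta = dict(meta or {})

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[MonthlyClimateYear], label: str = ""):
        years = [r.year for r in records]
        return cls(
            years,
            np.vstack([r.tmean for r in records]),
            np.vstack([r.prec for r in records]),
            label=label,
        )

    # -- access -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.years)

    @property
    def start(self) -> int:
        return int(self.years[0])

    @property
    def end(self) -> int:
        return int(self.years[-1])

    def index_of(self, year: int) -> int:
        i = int(year) - self.start
        if i < 0 or i >= len(self):
            raise KeyError(f"year {year} not in series [{self.start}, {self.end}]")
        return i

    def year_record(self, year: int) -> MonthlyClimateYear:
        i = self.index_of(year)
        return MonthlyClimateYear(int(year), self.tmean[i].copy(), self.prec[i].copy())

    def __iter__(self):
        for i, y in enumerate(self.years):
            yield MonthlyClimateYear(int(y), self.tmean[i].copy(), self.prec[i].copy())

    def slice_years(self, first: int, last: int) -> "ClimateSeries":
        i, j = self.index_of(first), self.index_of(last)
        return ClimateSeries(
            self.years[i : j + 1],
            self.tmean[i : j + 1].copy(),
            self.prec[i : j + 1].copy(),
            label=self.label,
        )

    def __eq__(self, other):
        return (
            isinstance(other, ClimateSeries)
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.tmean, other.tmean)
            and np.array_equal(self.prec, other.prec)
        )


@dataclass
class ForcingRecipe:
    """Parameters of the window-bootstrap forcing construction.

    ``window_len``-year windows of the real record (drawn from the
    ``overlap`` span) are spliced over ``target_start..splice_end`` and
    adjusted to the simulated series; the overlap years are appended
    verbatim.
    """

    window_len: int = 19
    target_start: int = -3982
    splice_end: int = 1933
    overlap: tuple[int, int] = (1934, 2013)
    temp_adjust: str = "additive"
    prec_adjust: str = "multiplicative"
    mean_mode: str = "pooled"  # or "per_month"
    rng_seed: int = 0
    prec_floor: float = 0.0

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.target_start > self.splice_end:
            raise ValueError("target_start must not exceed splice_end")
        if self.overlap[0] != self.splice_end + 1:
            raise ValueError("overlap must immediately follow splice_end")
        if self.overlap[1] < self.overlap[0]:
            raise ValueError("empty overlap span")
        if self.temp_adjust not in {"additive"}:
            raise ValueError("temp_adjust must be 'additive'")
        if self.prec_adjust not in {"multiplicative", "additive"}:
            raise ValueError("prec_adjust must be 'multiplicative' or 'additive'")
        if self.mean_mode not in {"pooled", "per_month"}:
            raise ValueError("mean_mode must be 'pooled' or 'per_month'")
        if self.prec_floor < 0:
            raise ValueError("prec_floor must be >= 0")


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------

_DEFAULT_DIALECT = {"year": "year", "month": "month", "tmean": "tmean_c", "prec": "prec_mm"}


def load_climate_table(path, dialect: Mapping[str, str] | None = None, label: str = "") -> ClimateSeries:
    """Read a monthly climate CSV (columns year, month, tmean_c, prec_mm).

    All 12 months must be present for every year and years must be
    contiguous; values are preserved bit-exactly.
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"climate table {path} missing columns {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    if df["prec"].lt(0).any():
        bad = df.loc[df["prec"].lt(0)].iloc[0]
        raise ValueError(f"negative precipitation at year {int(bad['year'])} month {int(bad['month'])}")
    years = np.sort(df["year"].unique())
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("years in climate table are not contiguous")
    n = len(years)
    tmean = np.full((n, 12), np.nan)
    prec = np.full((n, 12), np.nan)
    yidx = {int(y): i for i, y in enumerate(years)}
    for row in df.itertuples(index=False):
        m = int(row.month)
        if not 1 <= m <= 12:
            raise ValueError(f"month {m} out of range in year {int(row.year)}")
        tmean[yidx[int(row.year)], m - 1] = row.tmean
        prec[yidx[int(row.year)], m - 1] = row.prec
    if np.isnan(tmean).any() or np.isnan(prec).any():
        iy, im = np.argwhere(np.isnan(tmean) | np.isnan(prec))[0]
        raise ValueError(f"missing month: ({int(years[iy])}, {im + 1})")
    return ClimateSeries(years, tmean, prec, label=label or str(path))


def write_climate_table(series: ClimateSeries, path, sidecar: dict | None = None) -> None:
    """Write a series as CSV (bit round-trippable through ``repr``), with
    an optional JSON sidecar holding the recipe/seed/window provenance."""
    n = len(series)
    df = pd.DataFrame(
        {
            "year": np.repeat(series.years, 12),
            "month": np.tile(np.arange(1, 13), n),
            "tmean_c": series.tmean.ravel(),
            "prec_mm": series.prec.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


# ---------------------------------------------------------------------
# Forcing assembly
# ---------------------------------------------------------------------

def _window_means(tmean: np.ndarray, prec: np.ndarray, mode: str):
    if mode == "pooled":
        return tmean.mean(), prec.mean()
    return tmean.mean(axis=0), prec.mean(axis=0)


def _adjust_block(bt, bp, st_mean, sp_mean, bt_mean, bp_mean, recipe: ForcingRecipe):
    bt = bt + (st_mean - bt_mean)  # additive temperature offset
    if recipe.prec_adjust == "multiplicative":
        bp_scalar_zero = np.any(np.asarray(bp_mean) == 0)
        if bp_scalar_zero:
            if np.all(np.asarray(sp_mean) == 0):
                factor = np.ones_like(np.asarray(bp_mean, dtype=float))
            else:
                raise ValueError("zero window-mean precipitation in real block with nonzero simulated mean")
        else:
            factor = np.asarray(sp_mean, dtype=float) / np.asarray(bp_mean, dtype=float)
        bp = bp * factor
    else:
        bp = bp + (np.asarray(sp_mean, dtype=float) - np.asarray(bp_mean, dtype=float))
    bp = np.maximum(bp, recipe.prec_floor)
    return bt, bp


def assemble_master_forcing(
    real: ClimateSeries, simulated: ClimateSeries, recipe: ForcingRecipe
) -> ClimateSeries:
    """Build the master forcing by window bootstrap.

    The pre-overlap span (``target_start..splice_end``) is a
    concatenation of ``window_len``-year blocks drawn uniformly at random
    (with replacement, seeded) from the real record's overlap years, each
    adjusted so its window means match the corresponding simulated
    window (temperature additively, precipitation per
    ``recipe.prec_adjust``).  The final block is truncated to the
    remaining years.  The overlap years are the real series verbatim.

    The chosen window start-years are recorded in ``result.meta`` for
    exact replay.
    """
    ov0, ov1 = recipe.overlap
    if real.start > ov0 or real.end < ov1:
        raise ValueError(f"real series must cover the overlap span {ov0}-{ov1}")
    if simulated.start > recipe.target_start or simulated.end < recipe.splice_end:
        raise ValueError("simulated series must cover target_start..splice_end")
    n_real_overlap = ov1 - ov0 + 1
    if n_real_overlap < recipe.window_len:
        raise ValueError("real overlap span shorter than window_len")

    rng = np.random.default_rng(recipe.rng_seed)
    n_pre = recipe.splice_end - recipe.target_start + 1
    n_blocks = -(-n_pre // recipe.window_len)  # ceil
    lo, hi = ov0, ov1 - recipe.window_len + 1
    starts = rng.integers(lo, hi + 1, size=n_blocks)

    out_t, out_p = [], []
    pos = recipe.target_start
    for b, s in enumerate(starts):
        blen = min(recipe.window_len, recipe.splice_end - pos + 1)
        i = real.index_of(int(s))
        bt = real.tmean[i : i + blen].copy()
        bp = real.prec[i : i + blen].copy()
        j = simulated.index_of(pos)
        st = simulated.tmean[j : j + blen]
        sp = simulated.prec[j : j + blen]
        st_mean, sp_mean = _window_means(st, sp, recipe.mean_mode)
        bt_mean, bp_mean = _window_means(bt, bp, recipe.mean_mode)
        bt, bp = _adjust_block(bt, bp, st_mean, sp_mean, bt_mean, bp_mean, recipe)
        out_t.append(bt)
        out_p.append(bp)
        pos += blen

    i0, i1 = real.index_of(ov0), real.index_of(ov1)
    out_t.append(real.tmean[i0 : i1 + 1].copy())
    out_p.append(real.prec[i0 : i1 + 1].copy())

    years = np.arange(recipe.target_start, ov1 + 1)
    series = ClimateSeries(
        years,
        np.vstack(out_t),
        np.vstack(out_p),
        label="master-forcing",
        meta={
            "recipe": recipe.__dict__.copy(),
            "window_starts": [int(s) for s in starts],
        },
    )
    return series


def overlap_means(series: ClimateSeries, overlap: tuple[int, int] = (1934, 2013)) -> tuple[float, float]:
    """Pooled monthly-mean temperature (degC) and mean annual
    precipitation sum (mm/yr) over the overlap years."""
    sub = series.slice_years(max(overlap[0], series.start), min(overlap[1], series.end))
    return float(sub.tmean.mean()), float(sub.prec.sum(axis=1).mean())


def site_adjust_series(
    master: ClimateSeries,
    master_overlap_means: tuple[float, float],
    site_overlap_means: tuple[float, float],
    prec_floor: float = 0.0,
    label: str = "",
) -> ClimateSeries:
    """Derive a site series: shift all temperatures by the site-minus-
    master overlap mean difference and scale all precipitation by the
    site/master overlap-mean ratio (floored at ``prec_floor``)."""
    mt, mp = master_overlap_means
    st, sp = site_overlap_means
    tmean = master.tmean + (st - mt)
    if mp == 0:
        if sp != 0:
            raise ValueError("master overlap mean precipitation is zero: ratio undefined")
        prec = master.prec.copy()
    else:
        prec = master.prec * (sp / mp)
    prec = np.maximum(prec, prec_floor)
    return ClimateSeries(master.years.copy(), tmean, prec, label=label or f"{master.label}-site")
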