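"""Non-linear thermal time for grapevine development.

Development is tracked in *development days* (DD): each hour contributes an
hourly development-day value hDD in [0, 1] from a beta-distribution-like
response to air temperature, parametrized by the three cardinal temperatures
(base, optimum, upper limit).  The daily contribution DD is the mean of the
24 hourly values, and cumulative development days (CDD) are the running sum
of DD from a start day (by default 1 January).  CDD is the thermal clock on
which budburst, organ appearance and internode growth are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CardinalTemperatures",
    "DevelopmentCalendar",
    "hourly_development",
    "daily_development",
    "build_calendar",
    "threshold_to_doy",
    "read_weather_csv",
    "validate_hourly_series",
]


class CardinalOrderingError(ValueError):
    """Raised when t_base < t_opt < t_upper does not hold."""


class HourCountError(ValueError):
    """Raised when a day does not contribute exactly 24 hourly values."""


class MissingDaysError(ValueError):
    """Raised when the hourly series has gaps in the requested day range."""

    def __init__(self, missing_dates):
        self.missing_dates = list(missing_dates)
        super().__init__(f"hourly series is missing {len(self.missing_dates)} day(s): "
                         f"{self.missing_dates[:5]}{'...' if len(self.missing_dates) > 5 else ''}")


@dataclass(frozen=True)
class CardinalTemperatures:
    """Cardinal temperature triplet with the derived shape exponent.

    alpha = ln(2) / ln((t_upper - t_base) / (t_opt - t_base)); with this
    exponent the response attains exactly 1 at t_opt and 0 at both t_base
    and t_upper.
    """

    t_base: float
    t_opt: float
    t_upper: float

    def __post_init__(self):
        if not (self.t_base < self.t_opt < self.t_upper):
            raise CardinalOrderingError(
                f"cardinal temperatures must satisfy t_base < t_opt < t_upper, "
                f"got ({self.t_base}, {self.t_opt}, {self.t_upper})")

    @property
    def alpha(self) -> float:
        return math.log(2.0) / math.log((self.t_upper - self.t_base) / (self.t_opt - self.t_base))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t_base, self.t_opt, self.t_upper)


def hourly_development(th, ct: CardinalTemperatures):
    """Hourly development-day contribution hDD in [0, 1].

    Zero outside the closed interval [t_base, t_upper]; inside, the
    beta-like response 2 u^alpha - u^(2 alpha) with
    u = ((th - t_base) / (t_opt - t_base))^... expressed through the shared
    exponent so that the maximum of exactly 1 sits at t_opt.

    Accepts scalars or arrays.
    """
    th = np.asarray(th, dtype=float)
    a = ct.alpha
    num = np.clip(th - ct.t_base, 0.0, None)
    den = ct.t_opt - ct.t_base
    with np.errstate(invalid="ignore"):
        x = (num / den) ** a
    hdd = 2.0 * x - x ** 2
    hdd = np.where((th < ct.t_base) | (th > ct.t_upper), 0.0, hdd)
    hdd = np.clip(hdd, 0.0, 1.0)
    if hdd.ndim == 0:
        return float(hdd)
    return hdd


def daily_development(hours, ct: CardinalTemperatures) -> float:
    """Mean hDD of exactly 24 hourly temperatures."""
    hours = np.asarray(hours, dtype=float)
    if hours.shape != (24,):
        raise HourCountError(f"expected exactly 24 hourly temperatures, got shape {hours.shape}")
    return float(np.mean(hourly_development(hours, ct)))


@dataclass
class DevelopmentCalendar:
    """Per-day development (dd) and its running sum (cdd) from doy0 for one year."""

    year: int
    doy0: int
    doy: np.ndarray
    dd: np.ndarray
    cdd: np.ndarray = field(default=None)

    def __post_init__(self):
        self.doy = np.asarray(self.doy, dtype=int)
        self.dd = np.asarray(self.dd, dtype=float)
        if self.cdd is None:
            self.cdd = np.cumsum(self.dd)
        else:
            self.cdd = np.asarray(self.cdd, dtype=float)

    def cdd_at(self, doy) -> float:
        """CDD accumulated through the end of the given day of year."""
        doy = np.asarray(doy)
        idx = doy - self.doy0
        if np.any(idx < 0) or np.any(idx >= len(self.doy)):
            raise ValueError(f"doy {doy} outside calendar range "
                             f"[{self.doy0}, {self.doy0 + len(self.doy) - 1}]")
        out = self.cdd[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.year, "doy": self.doy,
                             "dd": self.dd, "cdd": self.cdd})


def validate_hourly_series(series: pd.DataFrame, *, allow_partial: bool = False) -> pd.DataFrame:
    """Check an hourly weather frame (columns ``timestamp``, ``t_air_c``).

    Each covered civil date must carry exactly 24 records.  Partial days at
    the boundaries are rejected by default; with ``allow_partial`` they are
    dropped and flagged via a ``partial_days`` attribute on the result.
    """
    df = series.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp").reset_index(drop=True)
    if df["timestamp"].duplicated().any():
        raise ValueError("duplicate timestamps in hourly series")
    dates = df["timestamp"].dt.normalize()
    counts = dates.value_counts()
    partial = counts[counts != 24]
    if len(partial) > 0:
        if not allow_partial:
            raise HourCountError(
                f"{len(partial)} day(s) without exactly 24 hourly records, e.g. "
                f"{partial.index[0].date()} with {partial.iloc[0]}")
        df = df[~dates.isin(partial.index)].reset_index(drop=True)
    df.attrs["partial_days"] = [d.date() for d in partial.index]
    return df


def build_calendar(series: pd.DataFrame, ct: CardinalTemperatures, doy0: int = 1,
                   *, year: int | None = None, allow_partial: bool = False) -> DevelopmentCalendar:
    """Aggregate an hourly series into a development calendar from ``doy0``.

    The series must cover every day from doy0 through its last complete day;
    missing days raise :class:`MissingDaysError` naming the gaps.
    """
    df = validate_hourly_series(series, allow_partial=allow_partial)
    ts = df["timestamp"]
    if year is None:
        year = int(ts.dt.year.iloc[0])
    df = df[ts.dt.year == year]
    ts = df["timestamp"]
    doys = ts.dt.dayofyear.to_numpy()
    temps = df["t_air_c"].to_numpy(dtype=float)

    mask = doys >= doy0
    doys, temps = doys[mask], temps[mask]
    if len(doys) == 0:
        raise MissingDaysError([f"{year}-doy{doy0}"])
    last = int(doys.max())
    wanted = np.arange(doy0, last + 1)
    present = np.unique(doys)
    missing = np.setdiff1d(wanted, present)
    if len(missing) > 0:
        raise MissingDaysError([f"{year}-doy{int(d)}" for d in missing])

    hdd = hourly_development(temps, ct)
    order = np.argsort(doys, kind="stable")
    # 24 records per day guaranteed by validation
    dd = hdd[order].reshape(len(wanted), 24).mean(axis=1)
    return DevelopmentCalendar(year=year, doy0=doy0, doy=wanted, dd=dd)


def threshold_to_doy(calendar: DevelopmentCalendar, threshold: float):
    """First day of year whose CDD reaches the threshold, or None if never."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    idx = np.searchsorted(calendar.cdd, threshold, side="left")
    # searchsorted gives first index with cdd >= threshold (cdd non-decreasing)
    if idx >= len(calendar.cdd):
        return None
    return int(calendar.doy[idx])


def read_weather_csv(path, *, column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited weather file into the canonical two-column frame.

    ``column_map`` renames source columns to ``timestamp`` / ``t_air_c``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"timestamp", "t_air_c"} - set(df.columns)
    if missing:
        raise ValueError(f"weather file lacks columns {sorted(missing)}")
    return df[["timestamp", "t_air_c"]]
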