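"""Monitoring-campaign I/O, HRT regimes and descriptive summaries.

A campaign is a set of dated water-quality observations at four stations:
``MD`` (the mine-drainage stream), ``A0`` (the storage tank feeding the
treatment column, i.e. the model inlet), ``A1`` (the limestone bioreactor
outlet) and ``A2`` (the downstream fibre-filter tank).  The column was run
under a staged schedule of hydraulic retention times (HRTs); every descriptive
quantity reported here — means, removal efficiencies, molar ratios — is
computed per HRT regime.

CSV schema (UTF-8, header row)::

    date,station,mn_mg_l,zn_mg_l,ph,do_mg_l,ec_us_cm,orp_mv,temp_c

``date`` is ISO-8601 (YYYY-MM-DD); empty cells are missing values.  The HRT
schedule file has columns ``start_date,end_date,hrt_a1_days,hrt_total_days``.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, SchemaError, ValidationError
from .transport import MM_MN, MM_ZN, InletSeries

MONITORING_COLUMNS = ["date", "station", "mn_mg_l", "zn_mg_l",
                      "ph", "do_mg_l", "ec_us_cm", "orp_mv", "temp_c"]
_REQUIRED = MONITORING_COLUMNS[:4]
SCHEDULE_COLUMNS = ["start_date", "end_date", "hrt_a1_days", "hrt_total_days"]


class Station(str, enum.Enum):
    MD = "MD"
    A0 = "A0"
    A1 = "A1"
    A2 = "A2"


@dataclass(frozen=True)
class MonitoringRecord:
    """One dated water-quality observation at one station."""

    date: dt.date
    station: Station
    mn: Optional[float] = None  # mg/L
    zn: Optional[float] = None  # mg/L
    ph: Optional[float] = None
    do: Optional[float] = None  # mg/L
    ec: Optional[float] = None  # uS/cm
    orp: Optional[float] = None  # mV
    temp: Optional[float] = None  # degC

    def __post_init__(self):
        for name in ("mn", "zn"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.ph is not None and not 0 <= self.ph <= 14:
            raise ValidationError(f"ph must be in [0, 14], got {self.ph}")


@dataclass(frozen=True)
class HRTRegime:
    start: dt.date
    end: dt.date
    hrt_a1_days: float
    hrt_total_days: float

    @property
    def label(self) -> str:
        return f"HRT{self.hrt_a1_days:g}"

    def contains(self, date: dt.date) -> bool:
        """Half-open membership: start <= date < end."""
        return self.start <= date < self.end


@dataclass
class HRTSchedule:
    """Ordered, non-overlapping HRT regimes of a campaign."""

    regimes: list[HRTRegime]

    def __post_init__(self):
        if not self.regimes:
            raise ValidationError("schedule must contain at least one regime")
        for r in self.regimes:
            if r.end <= r.start:
                raise ValidationError(f"regime {r.label}: end must be after start")
            if r.hrt_a1_days <= 0 or r.hrt_total_days <= 0:
                raise ValidationError(f"regime {r.label}: HRT values must be > 0")
        for a, b in zip(self.regimes, self.regimes[1:]):
            if b.start < a.end:
                raise ValidationError("regimes must be ordered and non-overlapping")

    @property
    def start(self) -> dt.date:
        return self.regimes[0].start

    @property
    def end(self) -> dt.date:
        return self.regimes[-1].end

    def regime_for(self, date: dt.date) -> Optional[HRTRegime]:
        for r in self.regimes:
            if r.contains(date):
                return r
        return None

    def label_for(self, date: dt.date) -> Optional[str]:
        r = self.regime_for(date)
        return r.label if r else None

    def by_label(self, label: str) -> HRTRegime:
        for r in self.regimes:
            if r.label == label:
                return r
        raise KeyError(f"no regime labelled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regimes]

    def spans(self, origin: Optional[dt.date] = None):
        """Numeric ``(start_day, end_day, hrt_a1_days)`` spans for the solver."""
        origin = origin or self.start
        return [((r.start - origin).days, (r.end - origin).days, r.hrt_a1_days)
                for r in self.regimes]

    @classmethod
    def from_day_offsets(cls, origin: dt.date,
                         segments: Sequence[tuple[float, float, float]]) -> "HRTSchedule":
        """Build from ``(length_days, hrt_a1, hrt_total)`` segments in order."""
        regimes, day = [], 0.0
        for length, a1, total in segments:
            start = origin + dt.timedelta(days=day)
            end = origin + dt.timedelta(days=day + length)
            regimes.append(HRTRegime(start, end, a1, total))
            day += length
        return cls(regimes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "start_date": r.start.isoformat(), "end_date": r.end.isoformat(),
            "hrt_a1_days": r.hrt_a1_days, "hrt_total_days": r.hrt_total_days,
        } for r in self.regimes])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_schedule_csv(path) -> HRTSchedule:
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"schedule file missing columns: {missing}")
    regimes = [HRTRegime(dt.date.fromisoformat(str(row.start_date)),
                         dt.date.fromisoformat(str(row.end_date)),
                         float(row.hrt_a1_days), float(row.hrt_total_days))
               for row in df.itertuples()]
    return HRTSchedule(regimes)


def read_monitoring_csv(path) -> list[MonitoringRecord]:
    """Read a monitoring CSV into validated records.

    Unparseable numeric cells become missing values (never silent zeros);
    an unknown station code raises a :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"monitoring file missing mandatory columns: {missing}")
    records = []
    valid_codes = {s.value for s in Station}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        code = str(getattr(row, "station")).strip()
        if code not in valid_codes:
            raise ValidationError(f"line {i}: unknown station code {code!r}")
        try:
            date = dt.date.fromisoformat(str(getattr(row, "date")).strip())
        except ValueError as exc:
            raise ValidationError(f"line {i}: bad date {getattr(row, 'date')!r}") from exc

        def num(col):
            raw = getattr(row, col, "")
            raw = str(raw).strip()
            if not raw:
                return None
            try:
                return float(raw)
            except ValueError:
                return None  # unparseable -> missing, never zero

        try:
            records.append(MonitoringRecord(
                date=date, station=Station(code),
                mn=num("mn_mg_l"), zn=num("zn_mg_l"), ph=num("ph"),
                do=num("do_mg_l"), ec=num("ec_us_cm"), orp=num("orp_mv"),
                temp=num("temp_c")))
        except ValidationError as exc:
            raise ValidationError(f"line {i}: {exc}") from exc
    return records


def records_to_frame(records: Iterable[MonitoringRecord]) -> pd.DataFrame:
    rows = [{"date": r.date.isoformat(), "station": r.station.value,
             "mn_mg_l": r.mn, "zn_mg_l": r.zn, "ph": r.ph, "do_mg_l": r.do,
             "ec_us_cm": r.ec, "orp_mv": r.orp, "temp_c": r.temp}
            for r in records]
    return pd.DataFrame(rows, columns=MONITORING_COLUMNS)


def write_monitoring_csv(records: Iterable[MonitoringRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


@dataclass
class StationSeries:
    """Ordered (date, Mn, Zn) series at one station."""

    station: Station
    dates: list[dt.date]
    mn: np.ndarray  # mg/L, NaN = missing
    zn: np.ndarray  # mg/L, NaN = missing
    regime_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.mn = np.asarray(self.mn, dtype=float)
        self.zn = np.asarray(self.zn, dtype=float)
        if not (len(self.dates) == len(self.mn) == len(self.zn)):
            raise ValidationError("dates, mn and zn must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValidationError("dates must be strictly increasing")

    def __len__(self):
        return len(self.dates)

    @classmethod
    def from_records(cls, records: Iterable[MonitoringRecord],
                     station: Station,
                     schedule: Optional[HRTSchedule] = None) -> "StationSeries":
        rows = sorted((r for r in records if r.station == station),
                      key=lambda r: r.date)
        dates = [r.date for r in rows]
        mn = np.array([np.nan if r.mn is None else r.mn for r in rows])
        zn = np.array([np.nan if r.zn is None else r.zn for r in rows])
        labels = [schedule.label_for(d) for d in dates] if schedule else []
        return cls(station=station, dates=dates, mn=mn, zn=zn,
                   regime_labels=labels)

    def values(self, analyte: str) -> np.ndarray:
        if analyte not in ("mn", "zn"):
            raise ValidationError(f"analyte must be 'mn' or 'zn', got {analyte!r}")
        return self.mn if analyte == "mn" else self.zn

    def in_regime(self, schedule: HRTSchedule, label: str) -> "StationSeries":
        r = schedule.by_label(label)
        keep = [i for i, d in enumerate(self.dates) if r.contains(d)]
        return StationSeries(station=self.station,
                             dates=[self.dates[i] for i in keep],
                             mn=self.mn[keep], zn=self.zn[keep])

    def days(self, origin: dt.date) -> np.ndarray:
        return np.array([(d - origin).days for d in self.dates], dtype=float)

    def to_inlet(self, origin: dt.date) -> InletSeries:
        """Step-interpolated inlet boundary for the transport solver
        (missing values are carried forward from the previous observation)."""
        mn = pd.Series(self.mn).ffill().bfill().to_numpy()
        zn = pd.Series(self.zn).ffill().bfill().to_numpy()
        return InletSeries(self.days(origin), mn, zn)


def molar_ratio(mn: float, zn: float) -> float:
    """Mn/Zn mole ratio from mg/L concentrations (Mn 54.938, Zn 65.38 g/mol)."""
    if zn <= 0:
        raise ZeroDivisionError("zn must be > 0 to form a mole ratio")
    return (mn / MM_MN) / (zn / MM_ZN)


def removal_efficiency(inlet: StationSeries, outlet: StationSeries,
                       schedule: HRTSchedule, label: str, analyte: str,
                       mode: str = "mean") -> float:
    """Percent removal between two stations over one HRT regime.

    ``mode='mean'`` (default) compares regime means of the two stations —
    sampling dates need not coincide.  ``mode='paired'`` restricts to dates
    sampled at both stations and averages the same-day differences.
    """
    si = inlet.in_regime(schedule, label)
    so = outlet.in_regime(schedule, label)
    vi, vo = si.values(analyte), so.values(analyte)
    vi, vo = vi[~np.isnan(vi)], vo[~np.isnan(vo)]
    if mode == "paired":
        common = sorted(set(si.dates) & set(so.dates))
        if not common:
            raise InsufficientDataError(
                f"no paired dates in regime {label!r}")
        ii = [si.dates.index(d) for d in common]
        oo = [so.dates.index(d) for d in common]
        vi = si.values(analyte)[ii]
        vo = so.values(analyte)[oo]
        keep = ~(np.isnan(vi) | np.isnan(vo))
        vi, vo = vi[keep], vo[keep]
    if vi.size == 0 or vo.size == 0:
        raise InsufficientDataError(
            f"regime {label!r}: need >=1 observation at both stations")
    mean_in, mean_out = float(vi.mean()), float(vo.mean())
    if mean_in <= 0:
        raise InsufficientDataError(f"regime {label!r}: mean inlet must be > 0")
    return 100.0 * (mean_in - mean_out) / mean_in


def summarise_station(series: StationSeries,
                      schedule: Optional[HRTSchedule] = None) -> pd.DataFrame:
    """Per-regime (or whole-series) mean/min/max per analyte.

    Missing values are excluded from the statistics and counted in
    ``n_missing``.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot summarise an empty series")
    groups = ([(r.label, series.in_regime(schedule, r.label))
               for r in schedule.regimes] if schedule else [("all", series)])
    rows = []
    for label, sub in groups:
        for analyte in ("mn", "zn"):
            v = sub.values(analyte)
            ok = v[~np.isnan(v)]
            rows.append({
                "station": series.station.value, "regime": label,
                "analyte": analyte,
                "mean": float(ok.mean()) if ok.size else np.nan,
                "min": float(ok.min()) if ok.size else np.nan,
                "max": float(ok.max()) if ok.size else np.nan,
                "n": int(ok.size), "n_missing": int(v.size - ok.size),
            })
    return pd.DataFrame(rows)
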