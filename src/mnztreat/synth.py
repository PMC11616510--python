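"""Synthetic monitoring campaigns with known ground truth.

Emulates the statistical structure of the 152-day pilot campaign: a staged
HRT schedule (2 d for 16 days, 0.5 d for 97 days, 0.3 d for the remainder),
an inlet whose Mn level drifts from 19 to 25 mg/L and Zn from 8 to 9.5 mg/L
late in the season, periodic sampling, and multiplicative measurement noise
(ICP-OES error scales with concentration).  The A-1 outlet series is produced
by running the forward transport model under the spec'd true parameters, so
every generated campaign carries an exact ground truth against which parameter
recovery can be measured.

The generator deliberately omits features of the real campaign it cannot
know: source-water excursions beyond the seasonal drift, mineralogical
variability, and the true sorbent inventory of the limestone bed.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .inverse import FitDataset
from .monitoring import (HRTSchedule, MonitoringRecord, Station, StationSeries,
                         write_monitoring_csv)
from .transport import (KineticParameters, ReactorConfig, SimulationResult,
                        simulate_schedule)

DEFAULT_START = dt.date(2022, 6, 1)
#: (length_days, hrt_a1_days, hrt_total_days) stages of the default campaign.
DEFAULT_STAGES = ((16.0, 2.0, 6.0), (97.0, 0.5, 1.5), (39.0, 0.3, 1.0))


def _piecewise(levels: Sequence[tuple[float, float]], t: np.ndarray,
               ramp: bool) -> np.ndarray:
    """Evaluate piecewise (start_day, level) pairs; step or linear ramp."""
    starts = np.array([s for s, _ in levels], dtype=float)
    vals = np.array([v for _, v in levels], dtype=float)
    if ramp and len(levels) > 1:
        return np.interp(t, starts, vals)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
    return vals[idx]


class PiecewiseInlet:
    """Noiseless inlet skeleton of a campaign: step (or ramped) Mn/Zn levels."""

    def __init__(self, mn_levels, zn_levels, ramp: bool = False):
        self.mn_levels, self.zn_levels, self.ramp = mn_levels, zn_levels, ramp

    def __call__(self, t_days: float) -> tuple[float, float]:
        t = np.asarray([t_days], dtype=float)
        return (float(_piecewise(self.mn_levels, t, self.ramp)[0]),
                float(_piecewise(self.zn_levels, t, self.ramp)[0]))

    def values_at(self, t_days):
        t = np.asarray(t_days, dtype=float)
        return (_piecewise(self.mn_levels, t, self.ramp),
                _piecewise(self.zn_levels, t, self.ramp))


@dataclass
class CampaignSpec:
    """Study conditions of one synthetic campaign.

    Defaults reproduce the pilot study: 152 days, 5-day sampling, inlet Mn
    19 -> 25 mg/L and Zn 8 -> 9.5 mg/L at day 120, 5 % multiplicative noise,
    and the fitted kinetic constants as ground truth.
    """

    duration_days: float = 152.0
    sampling_interval_days: float = 5.0
    mn_levels: tuple = ((0.0, 19.0), (120.0, 25.0))  # (start_day, mg/L)
    zn_levels: tuple = ((0.0, 8.0), (120.0, 9.5))
    ramp: bool = False  # linear ramp between levels instead of a step
    stages: tuple = DEFAULT_STAGES
    start_date: dt.date = DEFAULT_START
    noise_cv: float = 0.05
    seed: int = 0
    true_params: KineticParameters = field(default_factory=KineticParameters)
    config: ReactorConfig = field(default_factory=ReactorConfig)

    def __post_init__(self):
        if self.duration_days <= 0 or self.sampling_interval_days <= 0:
            raise ValidationError("duration and sampling interval must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for levels in (self.mn_levels, self.zn_levels):
            if any(v <= 0 for _, v in levels):
                raise ValidationError("inlet levels must be > 0")
        if sum(s[0] for s in self.stages) < self.duration_days:
            raise ValidationError("HRT stages must cover the campaign duration")

    @property
    def schedule(self) -> HRTSchedule:
        return HRTSchedule.from_day_offsets(self.start_date, list(self.stages))

    @property
    def sampling_days(self) -> np.ndarray:
        step = self.sampling_interval_days
        return np.arange(step, self.duration_days + 1e-9, step)

    @property
    def inlet_fn(self) -> PiecewiseInlet:
        """Noiseless inlet skeleton, mg/L versus day."""
        return PiecewiseInlet(self.mn_levels, self.zn_levels, self.ramp)


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise, truncated at 1 % of the level."""
    if cv == 0:
        return values.copy()
    factors = np.maximum(1.0 + cv * rng.standard_normal(values.shape), 0.01)
    return values * factors


def generate_inlet_series(spec: CampaignSpec,
                          rng: np.random.Generator | None = None) -> StationSeries:
    """Noisy A-0 inlet series at the campaign's sampling dates."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    days = spec.sampling_days
    mn0 = _piecewise(spec.mn_levels, days, spec.ramp)
    zn0 = _piecewise(spec.zn_levels, days, spec.ramp)
    dates = [spec.start_date + dt.timedelta(days=float(d)) for d in days]
    return StationSeries(station=Station.A0, dates=dates,
                         mn=_noisy(mn0, spec.noise_cv, rng),
                         zn=_noisy(zn0, spec.noise_cv, rng))


@dataclass
class Campaign:
    """A generated campaign: noisy station series plus exact ground truth."""

    spec: CampaignSpec
    a0: StationSeries
    a1: StationSeries
    truth: dict
    simulation: SimulationResult

    @property
    def schedule(self) -> HRTSchedule:
        return self.spec.schedule

    def records(self) -> list[MonitoringRecord]:
        rng = np.random.default_rng(int(self.spec.seed) + 2_000_003)
        recs = []
        for series in (self.a0, self.a1):
            for date, mn, zn in zip(series.dates, series.mn, series.zn):
                z = rng.standard_normal(5)
                recs.append(MonitoringRecord(
                    date=date, station=series.station,
                    mn=float(mn), zn=float(zn),
                    ph=float(np.clip(7.1 + 0.05 * z[0], 0, 14)),
                    do=float(max(9.3 + 0.3 * z[1], 0.0)),
                    ec=float(max(1138 + 20 * z[2], 0.0)),
                    orp=float(138 + 5 * z[3]),
                    temp=float(15 + 1.0 * z[4])))
        return sorted(recs, key=lambda r: (r.date, r.station.value))

    def fit_dataset(self, role: str = "calibration",
                    label: str = "synthetic") -> FitDataset:
        return FitDataset(inlet=self.a0, observed=self.a1,
                          schedule=self.schedule, role=role, label=label)

    def write(self, outdir) -> dict:
        """Write monitoring CSV, schedule CSV and ground_truth.json."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "monitoring": outdir / "monitoring.csv",
            "schedule": outdir / "hrt_schedule.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_monitoring_csv(self.records(), paths["monitoring"])
        self.schedule.to_csv(paths["schedule"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return {k: str(v) for k, v in paths.items()}


def generate_campaign(spec: CampaignSpec) -> Campaign:
    """Generate a full campaign: noisy A-0 and A-1 series plus ground truth.

    The A-1 series is the forward simulation under ``spec.true_params``,
    driven by the *noiseless* inlet skeleton and sampled at the campaign
    dates; sampling noise at A-0 and A-1 is independent.  A fixed seed gives
    an identical campaign; different seeds share the noiseless skeleton.
    """
    rng = np.random.default_rng(spec.seed)
    days = spec.sampling_days
    origin = spec.start_date
    spans = [(a, min(b, spec.duration_days), h)
             for a, b, h in spec.schedule.spans(origin) if a < spec.duration_days]
    sim = simulate_schedule(spec.config, spec.true_params, spec.inlet_fn, spans)

    mn_in0 = _piecewise(spec.mn_levels, days, spec.ramp)
    zn_in0 = _piecewise(spec.zn_levels, days, spec.ramp)
    mn_out0 = sim.outlet_at(days, "mn")
    zn_out0 = sim.outlet_at(days, "zn")

    dates = [origin + dt.timedelta(days=float(d)) for d in days]
    a0 = StationSeries(station=Station.A0, dates=dates,
                       mn=_noisy(mn_in0, spec.noise_cv, rng),
                       zn=_noisy(zn_in0, spec.noise_cv, rng))
    a1 = StationSeries(station=Station.A1, dates=dates,
                       mn=_noisy(mn_out0, spec.noise_cv, rng),
                       zn=_noisy(zn_out0, spec.noise_cv, rng))
    truth = {
        "seed": int(spec.seed),
        "noise_cv": spec.noise_cv,
        "params": {"k1_per_s": spec.true_params.k1,
                   "km_per_s": spec.true_params.km,
                   "kd_l_per_g": spec.true_params.kd,
                   "k2": spec.true_params.k2},
        "sampling_days": days.tolist(),
        "a0_mn_noiseless_mg_l": mn_in0.tolist(),
        "a0_zn_noiseless_mg_l": zn_in0.tolist(),
        "a1_mn_noiseless_mg_l": mn_out0.tolist(),
        "a1_zn_noiseless_mg_l": zn_out0.tolist(),
    }
    return Campaign(spec=spec, a0=a0, a1=a1, truth=truth, simulation=sim)
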