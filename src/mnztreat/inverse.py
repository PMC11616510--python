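"""Inverse estimation of the kinetic constants from monitoring series.

The calibration mirrors the field study's scheme: the A-0 series drives the
transport model as its inlet boundary, the A-1 series is the observed outlet,
and a weighted least-squares objective over the simulated-minus-observed
residuals is minimised.  The Mn fit estimates k1 alone; the Zn fit estimates
(km, Kd) jointly with the Mn-fitted k1 held fixed, because the sorbent
inventory grows with precipitated MnO2.  Parameters are searched in log10
space within positivity bounds (k1 in [1e-8, 1e-2] 1/s, km in [1e-6, 1] 1/s,
Kd in [1e-3, 1e3] L/g).  Datasets marked ``validation`` are scored with the
fitted parameters but never enter the objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, ValidationError
from .metrics import mae, metric_suite, nrmse, r2, rmse  # noqa: F401 (re-export)
from .monitoring import HRTSchedule, StationSeries
from .transport import KineticParameters, ReactorConfig, simulate_schedule

DEFAULT_BOUNDS = {
    "k1": (1e-8, 1e-2),
    "km": (1e-6, 1.0),
    "kd": (1e-3, 1e3),
}


@dataclass
class FitDataset:
    """One calibration or validation dataset: inlet, observed outlet, schedule."""

    inlet: StationSeries
    observed: StationSeries
    schedule: HRTSchedule
    role: str = "calibration"
    label: str = ""

    def __post_init__(self):
        if self.role not in ("calibration", "validation"):
            raise ValidationError(f"role must be calibration|validation, got {self.role!r}")
        origin = self.schedule.start
        obs_days = self.observed.days(origin)
        span = (self.schedule.end - self.schedule.start).days
        if obs_days.size and (obs_days.min() < 0 or obs_days.max() > span):
            raise ValidationError(
                f"dataset {self.label!r}: observations outside the HRT schedule")
        if self.role == "calibration" and len(self.observed) < 3:
            raise ValidationError(
                f"dataset {self.label!r}: calibration needs >=3 observations")


def _simulate_dataset(params: KineticParameters, dataset: FitDataset,
                      config: ReactorConfig, analyte: str) -> np.ndarray:
    origin = dataset.schedule.start
    result = simulate_schedule(config, params,
                               dataset.inlet.to_inlet(origin),
                               dataset.schedule.spans(origin))
    return result.outlet_at(dataset.observed.days(origin), analyte)


def residuals(params: KineticParameters, dataset: FitDataset,
              config: ReactorConfig, analyte: str) -> np.ndarray:
    """Simulated-minus-observed outlet concentration at each observation date.

    Observations with missing values for the analyte are dropped.
    """
    try:
        sim = _simulate_dataset(params, dataset, config, analyte)
    except Exception as exc:
        raise type(exc)(f"dataset {dataset.label!r}: {exc}") from exc
    obs = dataset.observed.values(analyte)
    keep = ~np.isnan(obs)
    return sim[keep] - obs[keep]


@dataclass
class FitResult:
    """Estimated parameters plus objective, per-dataset metrics and a fit log."""

    params: KineticParameters
    objective: float  # weighted SSE at the optimum
    metrics: dict  # label -> metric suite (calibration and validation alike)
    fitted_names: tuple
    n_eval: int
    success: bool
    message: str
    initial_objective: float = np.nan
    log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": {"k1_per_s": self.params.k1, "km_per_s": self.params.km,
                       "kd_l_per_g": self.params.kd, "k2": self.params.k2},
            "objective": self.objective,
            "initial_objective": self.initial_objective,
            "fitted": list(self.fitted_names),
            "metrics": self.metrics,
            "n_eval": self.n_eval,
            "success": self.success,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _weights_for(dataset: FitDataset, analyte: str, scheme: str) -> np.ndarray:
    obs = dataset.observed.values(analyte)
    obs = obs[~np.isnan(obs)]
    if scheme == "uniform":
        return np.ones_like(obs)
    if scheme == "inverse":
        return 1.0 / np.maximum(obs, 1e-6)
    raise ValidationError(f"unknown weighting scheme {scheme!r}")


def fit(initial: KineticParameters, datasets: Sequence[FitDataset],
        config: ReactorConfig, analyte: str,
        bounds: Optional[dict] = None, weights: str = "uniform",
        max_nfev: int = 200) -> FitResult:
    """Weighted least-squares estimation of the kinetic constants.

    ``analyte='mn'`` fits k1; ``analyte='zn'`` fits (km, kd) with k1 fixed at
    its value in ``initial``.  Minimisation runs over log10-transformed
    parameters with a trust-region reflective solver; convergence when the
    relative objective change falls below 1e-10 or the log-parameter step
    below 1e-10.
    """
    cal = [d for d in datasets if d.role == "calibration"]
    if not cal:
        raise ValidationError("need at least one calibration dataset")
    if analyte == "mn":
        names = ("k1",)
    elif analyte == "zn":
        names = ("km", "kd")
    else:
        raise ValidationError(f"analyte must be 'mn' or 'zn', got {analyte!r}")
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for n in names:
        lo, hi = bnds[n]
        if lo <= 0 or hi <= lo:
            raise ValidationError(f"bounds for {n} must be positive and ordered")
    lo = np.log10([bnds[n][0] for n in names])
    hi = np.log10([bnds[n][1] for n in names])
    x0 = np.clip(np.log10([getattr(initial, n) for n in names]), lo, hi)
    w = np.concatenate([_weights_for(d, analyte, weights) for d in cal])
    sqrt_w = np.sqrt(w)
    log: list[tuple] = []

    def make_params(x) -> KineticParameters:
        return initial.with_(**{n: 10.0 ** xi for n, xi in zip(names, x)})

    def resfun(x):
        p = make_params(x)
        r = np.concatenate([residuals(p, d, config, analyte) for d in cal])
        log.append((tuple(x), float(np.sum(w * r * r))))
        return sqrt_w * r

    r0 = resfun(x0)
    initial_objective = float(np.sum(r0 * r0))
    sol = least_squares(resfun, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-12, max_nfev=max_nfev)
    fitted = make_params(sol.x)
    result = FitResult(
        params=fitted, objective=float(2.0 * sol.cost),
        metrics={}, fitted_names=names, n_eval=int(sol.nfev),
        success=bool(sol.success), message=str(sol.message),
        initial_objective=initial_objective, log=log)
    for d in datasets:
        obs = d.observed.values(analyte)
        keep = ~np.isnan(obs)
        sim = _simulate_dataset(fitted, d, config, analyte)[keep]
        suite = metric_suite(obs[keep], sim)
        suite["role"] = d.role
        result.metrics[d.label or d.role] = suite
    if not sol.success:
        raise ConvergenceError(
            f"fit did not converge within {max_nfev} evaluations: {sol.message}",
            best=result)
    return result
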