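"""Model-evaluation metrics: MAE, RMSE, NRMSE and the coefficient of efficiency.

All four operate on paired observed/predicted vectors in mg/L.  NRMSE is
normalised by the observed range by default (a mean-normalised variant is
available) and expressed in percent.  R² is the Nash–Sutcliffe coefficient of
efficiency ``1 - SS_res/SS_tot`` — it can be negative for a model worse than
the observed mean, unlike a squared correlation.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError, ValidationError


def _pair(obs, pred, min_n=1):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError("obs and pred must be 1-D vectors of equal length")
    if obs.size < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {obs.size}")
    return obs, pred


def mae(obs, pred) -> float:
    """Mean absolute error, mg/L."""
    obs, pred = _pair(obs, pred)
    return float(np.mean(np.abs(pred - obs)))


def rmse(obs, pred) -> float:
    """Root mean square error, mg/L."""
    obs, pred = _pair(obs, pred)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def nrmse(obs, pred, norm: str = "range") -> float:
    """Normalised RMSE in percent: 100*RMSE/(max(obs)-min(obs)) by default.

    ``norm='mean'`` divides by the observed mean instead.
    """
    obs, pred = _pair(obs, pred, min_n=2)
    if norm == "range":
        denom = float(obs.max() - obs.min())
    elif norm == "mean":
        denom = float(obs.mean())
    else:
        raise ValidationError(f"norm must be 'range' or 'mean', got {norm!r}")
    if denom == 0:
        raise DegenerateInputError("observed values have zero range/mean")
    return 100.0 * rmse(obs, pred) / denom


def r2(obs, pred) -> float:
    """Coefficient of efficiency: 1 - sum(r^2)/sum((obs - mean obs)^2)."""
    obs, pred = _pair(obs, pred, min_n=2)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("observed values have zero variance")
    ss_res = float(np.sum((pred - obs) ** 2))
    return 1.0 - ss_res / ss_tot


def metric_suite(obs, pred) -> dict:
    """All four metrics plus the sample size, as a plain dict."""
    return {"mae_mg_l": mae(obs, pred), "rmse_mg_l": rmse(obs, pred),
            "nrmse_pct": nrmse(obs, pred), "r2": r2(obs, pred),
            "n": int(np.asarray(obs).size)}
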