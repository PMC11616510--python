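"""Linear-combination fitting (LCF) of normalised XANES spectra.

A sample spectrum is expressed as a convex mixture of reference spectra over a
window relative to the absorption edge (default -20 to +30 eV): least squares
subject to non-negative weights that sum to one, solved with an active-set
method on the equality-constrained normal equations.  The fit quality is the
R-factor, ``sum(residual^2) / sum(sample^2)`` over the window.

The synthetic references used in the test suite are edge-step curves with
Gaussian white lines at distinct energies (6555/6559/6562 eV — the Mn(II)/
Mn(III)/Mn(IV) white-line positions), which mimics the oxidation-state
contrast that LCF exploits in practice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.special import erf

from .exceptions import ValidationError


@dataclass
class Spectrum:
    """A normalised absorption spectrum on a strictly increasing energy grid."""

    energy: np.ndarray  # eV
    mu: np.ndarray  # normalised absorbance
    label: str = ""
    e0: float = 0.0  # edge energy, eV

    def __post_init__(self):
        self.energy = np.asarray(self.energy, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.energy.ndim != 1 or self.energy.size < 2:
            raise ValidationError("spectrum needs a 1-D grid with >=2 points")
        if self.energy.shape != self.mu.shape:
            raise ValidationError("energy and mu must have the same shape")
        if np.any(np.diff(self.energy) <= 0):
            raise ValidationError("energy grid must be strictly increasing")
        if not (np.all(np.isfinite(self.energy)) and np.all(np.isfinite(self.mu))):
            raise ValidationError("spectrum contains non-finite values")

    @classmethod
    def from_file(cls, path, label: str = "", e0: float = 0.0) -> "Spectrum":
        """Two-column text (energy_eV, normalised_mu); whitespace or comma."""
        try:
            data = np.loadtxt(path)
        except ValueError:
            data = np.loadtxt(path, delimiter=",")
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValidationError(f"{path}: expected two columns")
        return cls(energy=data[:, 0], mu=data[:, 1],
                   label=label or str(path), e0=e0)

    def to_file(self, path) -> None:
        np.savetxt(path, np.column_stack([self.energy, self.mu]),
                   fmt="%.6f", header="energy_eV normalised_mu")


def interpolate_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linear interpolation onto ``grid``; extrapolation is refused."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < spectrum.energy[0] or grid.max() > spectrum.energy[-1]:
        raise ValidationError(
            f"target grid [{grid.min()}, {grid.max()}] outside spectrum span "
            f"[{spectrum.energy[0]}, {spectrum.energy[-1]}]")
    return Spectrum(energy=grid, mu=np.interp(grid, spectrum.energy, spectrum.mu),
                    label=spectrum.label, e0=spectrum.e0)


@dataclass
class LCFResult:
    weights: dict  # reference label -> fraction
    r_factor: float
    window_ev: tuple  # relative to E0
    sum_constrained: bool

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"weights": self.weights, "r_factor": self.r_factor,
                       "window_ev": list(self.window_ev),
                       "sum_constrained": self.sum_constrained}, fh, indent=2)


def _sum_constrained_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A w - b||^2  s.t.  w >= 0, sum(w) = 1 (active-set on the KKT system)."""
    k = A.shape[1]
    G = 2.0 * A.T @ A
    c = 2.0 * A.T @ b
    clamped = np.zeros(k, dtype=bool)
    for _ in range(3 * k + 3):
        free = np.flatnonzero(~clamped)
        nf = free.size
        # KKT: [G_ff 1; 1^T 0] [w_f; mu] = [c_f; 1]
        M = np.zeros((nf + 1, nf + 1))
        M[:nf, :nf] = G[np.ix_(free, free)]
        M[:nf, nf] = 1.0
        M[nf, :nf] = 1.0
        rhs = np.append(c[free], 1.0)
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("reference set is singular (duplicated reference?); "
                          "returning a minimum-norm solution", RuntimeWarning)
            sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
        w = np.zeros(k)
        w[free] = sol[:nf]
        mu = sol[nf]
        if w[free].min() < -1e-12:
            clamped[free[np.argmin(w[free])]] = True
            continue
        # KKT multipliers of clamped components must be >= 0, else release
        if clamped.any():
            lam = G @ w - c + mu
            bad = np.flatnonzero(clamped & (lam < -1e-9))
            if bad.size:
                clamped[bad[np.argmin(lam[bad])]] = False
                continue
        return np.maximum(w, 0.0)
    return np.maximum(w, 0.0)  # pragma: no cover - cycling guard


def lcf_fit(sample: Spectrum, references: Sequence[Spectrum],
            window: tuple[float, float] = (-20.0, 30.0),
            sum_to_one: bool = True) -> LCFResult:
    """Fit a sample spectrum as a non-negative mixture of references.

    The fit runs on the sample's grid points inside ``[e0+lo, e0+hi]``;
    references are interpolated onto those points and must cover the window.
    With ``sum_to_one=False`` the weights are only constrained non-negative.
    """
    if len(references) < 2:
        raise ValidationError("need at least two reference spectra")
    lo, hi = sample.e0 + window[0], sample.e0 + window[1]
    mask = (sample.energy >= lo) & (sample.energy <= hi)
    if mask.sum() < len(references) + 1:
        raise ValidationError("fitting window contains too few sample points")
    grid = sample.energy[mask]
    b = sample.mu[mask]
    A = np.column_stack([interpolate_to_grid(r, grid).mu for r in references])
    cond = np.linalg.cond(A)
    if cond > 1e10:
        warnings.warn(f"reference set is ill-conditioned (cond={cond:.2g}); "
                      "weights may not be unique", RuntimeWarning)
    if sum_to_one:
        w = _sum_constrained_nnls(A, b)
        w = w / w.sum()  # exact renormalisation against round-off
    else:
        w, _ = nnls(A, b)
    resid = b - A @ w
    r_factor = float(np.sum(resid ** 2) / np.sum(b ** 2))
    labels = [r.label or f"ref{i}" for i, r in enumerate(references)]
    seen: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab in seen:
            seen[lab] += 1
            labels[i] = f"{lab}#{seen[lab]}"
        else:
            seen[lab] = 1
    return LCFResult(weights=dict(zip(labels, w.tolist())),
                     r_factor=r_factor, window_ev=tuple(window),
                     sum_constrained=sum_to_one)


def synthetic_reference_spectra(
        white_lines: Sequence[float] = (6555.0, 6559.0, 6562.0),
        labels: Sequence[str] | None = None,
        e0: float = 6546.0,
        grid: np.ndarray | None = None) -> list[Spectrum]:
    """Gaussian-broadened edge-step reference spectra (synthetic).

    Each reference is a normalised edge step (erf) at its white-line energy
    plus a Gaussian white-line peak — a minimal stand-in for oxidation-state
    reference compounds, adequate for exercising the LCF machinery.
    """
    if grid is None:
        grid = np.arange(6500.0, 6650.0, 0.5)
    labels = labels or [f"ref_{w:g}eV" for w in white_lines]
    out = []
    for wl, lab in zip(white_lines, labels):
        step = 0.5 * (1.0 + erf((grid - wl + 2.0) / 3.0))
        peak = 0.8 * np.exp(-0.5 * ((grid - wl) / 2.5) ** 2)
        out.append(Spectrum(energy=grid.copy(), mu=step + peak,
                            label=lab, e0=e0))
    return out
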