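"""1D advective reactive transport through a limestone bioreactor.

The treatment column is modelled as a chain of well-mixed cells (cells-in-series).
Each time step ``dt = HRT/n_cells`` the aqueous contents of every cell shift one
cell downstream (the inlet parcel enters cell 0, the last cell's parcel exits),
an optional two-sided mixing pass emulates hydrodynamic dispersion, and the
kinetic reactions are integrated within each cell.  With zero dispersivity the
scheme is an exact plug-flow reactor: a water parcel spends exactly one HRT in
the column and experiences the reactions for exactly that long, so a constant
inlet with first-order Mn removal reproduces ``c_in * exp(-k1 * HRT)`` to
machine precision regardless of ``n_cells``.

Reactions (per litre of pore water, concentrations in mol/L internally):

* Mn(II) bio-oxidation, pseudo-first order with an optional autocatalytic term
  that is off by default (the field system is bacterially controlled at
  circumneutral pH, where autocatalysis on the oxide surface is negligible)::

      d[Mn2+]/dt = -(k1 + k2*[MnOx]) * [Mn2+]

  Every mole of Mn oxidised precipitates one mole of MnO2 (birnessite),
  optionally growing the Zn sorbent inventory.

* Zn(II) linear-driving-force sorption on the birnessite inventory::

      d[Zn2+]/dt = -km * ([Zn2+] - s_Zn / Kd)

  with ``s_Zn`` the sorbed load (mol per gram of sorbent) and ``Kd`` the
  distribution coefficient (L/g).  The sorbed phase is tracked internally as
  ``u = s_Zn * m_solid`` (mol per litre of pore water) so that sorbent growth,
  which adds Zn-free MnO2 mass, dilutes ``s_Zn`` without creating sorbed Zn.

Within one step both reactions are integrated with their closed forms (the
sorbent mass is frozen during the Zn exchange), which keeps every state
variable non-negative and closes the Mn and Zn mass budgets to round-off.

A note on units: the operative Zn mass-transfer coefficient used throughout is
expressed in 1/s; the literature often quotes 1/h (equilibrium sorption is
typically reached for 1-100 1/h).  11.43 1/h = 3.175e-3 1/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import NumericalError, ValidationError

MM_MN = 54.938  # g/mol
MM_ZN = 65.38  # g/mol
MM_MNO2 = 86.94  # g/mol
SECONDS_PER_DAY = 86400.0

#: Operative Zn mass-transfer coefficient, 1/s (= 11.43 1/h).
KM_DEFAULT = 11.43 / 3600.0

#: Fitted kinetic constants used as package-wide defaults:
#: k1 = 1.03e-4 1/s (Mn oxidation), km = 11.43 1/h, Kd = 4.49 L/g.
K1_DEFAULT = 1.03e-4
KD_DEFAULT = 4.49


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic constants of the coupled Mn/Zn removal model.

    Parameters
    ----------
    k1 : float
        Pseudo-first-order Mn(II) oxidation rate constant, 1/s.
    km : float
        Zn(II) mass-transfer coefficient of the linear driving force, 1/s.
    kd : float
        Zn(II) distribution coefficient on the sorbent, L/g.
    k2 : float, optional
        Autocatalytic Mn oxidation constant, (mol/L)^-1 s^-1.  Zero by
        default; the homogeneous first-order law is the operative model.
    """

    k1: float = K1_DEFAULT
    km: float = KM_DEFAULT
    kd: float = KD_DEFAULT
    k2: float = 0.0

    def __post_init__(self):
        for name in ("k1", "km", "kd", "k2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    def with_(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ReactorConfig:
    """Geometry and numerical configuration of the A-1 limestone column.

    ``length_m`` and ``porosity`` describe the physical bed (1.6 m flow path,
    48 % porosity); they are carried for provenance — the solver is driven
    directly by the hydraulic retention time, so the flow rate implied by the
    pore volume never has to be computed here.  ``initial_sorbent_g_per_l`` is
    the birnessite inventory per litre of pore water at start-up, the single
    largest unconstrained quantity of the system; when ``sorbent_growth`` is
    on, every mole of Mn oxidised adds 86.94 g of MnO2 to the inventory.
    """

    length_m: float = 1.6
    n_cells: int = 16
    porosity: float = 0.48
    dispersivity_m: float = 0.0
    initial_sorbent_g_per_l: float = 1.0
    sorbent_growth: bool = True
    mno2_molar_mass: float = MM_MNO2

    def __post_init__(self):
        if self.length_m <= 0:
            raise ValidationError(f"length_m must be > 0, got {self.length_m}")
        if self.n_cells < 2:
            raise ValidationError(f"n_cells must be >= 2, got {self.n_cells}")
        if not 0 < self.porosity <= 1:
            raise ValidationError(f"porosity must be in (0, 1], got {self.porosity}")
        if self.dispersivity_m < 0:
            raise ValidationError("dispersivity_m must be >= 0")
        if self.initial_sorbent_g_per_l < 0:
            raise ValidationError("initial_sorbent_g_per_l must be >= 0")

    def with_(self, **kwargs) -> "ReactorConfig":
        return replace(self, **kwargs)


@dataclass
class CellState:
    """State of one well-mixed cell, per litre of pore water.

    ``s_zn`` is the sorbed Zn load in mol per gram of sorbent; ``mno2_cum`` the
    cumulative MnO2 precipitated in the cell (mol/L).
    """

    c_mn: float = 0.0  # mol/L
    c_zn: float = 0.0  # mol/L
    s_zn: float = 0.0  # mol/g
    m_solid: float = 1.0  # g/L
    mno2_cum: float = 0.0  # mol/L


def mn_rate(c_mn: float, params: KineticParameters, c_mnox: float = 0.0) -> float:
    """Mn(II) oxidation rate (mol/L/s); positive = loss from solution.

    ``c_mnox`` is the oxide concentration driving the (optional) autocatalytic
    term.
    """
    if c_mn < 0:
        raise ValidationError(f"c_mn must be >= 0, got {c_mn}")
    return params.k1 * c_mn + params.k2 * c_mnox * c_mn


def zn_rate(c_zn: float, s_zn: float, params: KineticParameters) -> float:
    """Zn(II) linear-driving-force sorption rate (mol/L/s).

    Positive = net sorption (loss from solution); negative = desorption.
    """
    if c_zn < 0 or s_zn < 0:
        raise ValidationError("c_zn and s_zn must be >= 0")
    if params.kd <= 0:
        if s_zn > 0:
            raise ValidationError("kd = 0 with sorbed Zn present is undefined")
        return params.km * c_zn
    return params.km * (c_zn - s_zn / params.kd)


def plugflow_outlet(c_in: float, k1: float, hrt_days: float) -> float:
    """Closed-form plug-flow outlet for first-order decay, mg/L.

    ``c_in * exp(-k1 * HRT)`` — the analytic oracle the cells-in-series scheme
    must reproduce at zero dispersivity.
    """
    if c_in < 0 or k1 < 0 or hrt_days < 0:
        raise ValidationError("c_in, k1 and hrt_days must all be >= 0")
    return c_in * math.exp(-k1 * hrt_days * SECONDS_PER_DAY)


def _react(c_mn, c_zn, u, m, cum, params: KineticParameters,
           config: ReactorConfig, dt: float):
    """Integrate the in-cell kinetics over ``dt`` seconds (arrays or scalars).

    Exact exponential update for Mn decay; exact relaxation towards sorption
    equilibrium for Zn with the sorbent mass frozen at its post-growth value.
    Returns updated (c_mn, c_zn, u, m, cum).
    """
    k1, km, kd, k2 = params.k1, params.km, params.kd, params.k2
    if k2 > 0.0:
        # Autocatalytic branch: quasi-exact with the oxide pool frozen per
        # substep.  8 substeps keep the splitting error far below the
        # measurement scale for any plausible k2.
        nsub = 8
        h = dt / nsub
        for _ in range(nsub):
            decay = np.exp(-(k1 + k2 * cum) * h)
            c_new = c_mn * decay
            cum = cum + (c_mn - c_new)
            c_mn = c_new
    else:
        decay = math.exp(-k1 * dt)
        c_new = c_mn * decay
        d = c_mn - c_new
        cum = cum + d
        c_mn = c_new
    if config.sorbent_growth:
        m = config.initial_sorbent_g_per_l + cum * config.mno2_molar_mass

    if km > 0.0 and kd > 0.0:
        total = c_zn + u
        denom = 1.0 + m * kd
        c_eq = total / denom
        lam = km * (1.0 + 1.0 / (m * kd)) if np.all(np.asarray(m) > 0) else None
        if lam is None:
            # mixed zero/positive sorbent masses: vectorised guard
            m_arr = np.asarray(m, dtype=float)
            pos = m_arr > 0
            lam = np.where(pos, km * (1.0 + 1.0 / np.where(pos, m_arr * kd, 1.0)), 0.0)
            c_eq = np.where(pos, c_eq, c_zn)
        c_zn = c_eq + (c_zn - c_eq) * np.exp(-lam * dt)
        u = total - c_zn
    return c_mn, c_zn, u, m, cum


def step_reaction(cell: CellState, params: KineticParameters,
                  config: ReactorConfig, dt: float) -> CellState:
    """Advance the kinetics of a single cell over ``dt`` seconds."""
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    u = cell.s_zn * cell.m_solid
    c_mn, c_zn, u, m, cum = _react(
        cell.c_mn, cell.c_zn, u, cell.m_solid, cell.mno2_cum, params, config, dt)
    if not all(np.isfinite([c_mn, c_zn, u, m, cum])):
        raise NumericalError(f"non-finite cell state after dt={dt}")
    s = u / m if m > 0 else 0.0
    return CellState(c_mn=c_mn, c_zn=c_zn, s_zn=s, m_solid=m, mno2_cum=cum)


class InletSeries:
    """Step-interpolated inlet boundary: mg/L of Mn and Zn versus time (days).

    The value at time ``t`` is the most recent tabulated value at or before
    ``t`` (held constant before the first tabulated day).
    """

    def __init__(self, days: Sequence[float], mn: Sequence[float],
                 zn: Sequence[float]):
        days = np.asarray(days, dtype=float)
        mn = np.asarray(mn, dtype=float)
        zn = np.asarray(zn, dtype=float)
        if days.ndim != 1 or days.size == 0:
            raise ValidationError("inlet series needs at least one point")
        if np.any(np.diff(days) < 0):
            order = np.argsort(days)
            days, mn, zn = days[order], mn[order], zn[order]
        self.days, self.mn, self.zn = days, mn, zn

    def __call__(self, t_days: float) -> tuple[float, float]:
        i = int(np.searchsorted(self.days, t_days, side="right")) - 1
        i = max(i, 0)
        return float(self.mn[i]), float(self.zn[i])

    def values_at(self, t_days) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised lookup used by the solver's step loop."""
        idx = np.clip(np.searchsorted(self.days, t_days, side="right") - 1, 0, None)
        return self.mn[idx], self.zn[idx]


def as_inlet(inlet) -> Callable[[float], tuple[float, float]]:
    """Normalise the accepted inlet forms to ``f(t_days) -> (mn, zn)`` mg/L."""
    if callable(inlet):
        return inlet
    if isinstance(inlet, tuple) and len(inlet) == 2:
        mn, zn = float(inlet[0]), float(inlet[1])
        return lambda t: (mn, zn)
    if isinstance(inlet, pd.DataFrame):
        return InletSeries(inlet["day"].to_numpy(),
                           inlet["mn"].to_numpy(), inlet["zn"].to_numpy())
    raise ValidationError(f"unsupported inlet specification: {type(inlet)!r}")


@dataclass
class SimulationResult:
    """Outlet time series plus budgets and the final column state.

    ``times_days`` are parcel exit times; outlet concentrations are mg/L.
    ``mno2_cum_mol_per_l`` is the column-average cumulative MnO2 (per litre of
    pore water) at each exit time.  Budgets are in mol per cell volume
    (all cells have equal pore volume, so the unit cancels in closures).
    """

    times_days: np.ndarray
    outlet_mn_mg_l: np.ndarray
    outlet_zn_mg_l: np.ndarray
    mno2_cum_mol_per_l: np.ndarray
    budgets: dict
    config: ReactorConfig
    params: KineticParameters
    snapshots: list = field(default_factory=list)
    final_state: dict = field(default_factory=dict)

    def mn_budget_closure(self) -> float:
        """Relative Mn budget gap: |in - out - d(aqueous) - precipitated| / in."""
        b = self.budgets
        gap = (b["mn_in"] - b["mn_out"]
               - (b["mn_aq_final"] - b["mn_aq_init"]) - b["mn_precip_final"])
        return abs(gap) / max(b["mn_in"], 1e-300)

    def zn_budget_closure(self) -> float:
        """Relative Zn budget gap: |in - out - d(aqueous) - d(sorbed)| / in."""
        b = self.budgets
        gap = (b["zn_in"] - b["zn_out"]
               - (b["zn_aq_final"] - b["zn_aq_init"])
               - (b["zn_sorbed_final"] - b["zn_sorbed_init"]))
        return abs(gap) / max(b["zn_in"], 1e-300)

    def outlet_at(self, days, analyte: str = "mn") -> np.ndarray:
        """Outlet concentration observed at the given days (piecewise-constant:
        the most recent parcel that exited at or before each day)."""
        series = self.outlet_mn_mg_l if analyte == "mn" else self.outlet_zn_mg_l
        days = np.atleast_1d(np.asarray(days, dtype=float))
        idx = np.searchsorted(self.times_days, days, side="right") - 1
        out = np.where(idx >= 0, series[np.clip(idx, 0, None)], 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times_days,
            "outlet_mn_mg_l": self.outlet_mn_mg_l,
            "outlet_zn_mg_l": self.outlet_zn_mg_l,
            "mno2_cum_mol_per_l": self.mno2_cum_mol_per_l,
        })


class _Column:
    """Mutable cells-in-series column state with budget accounting."""

    def __init__(self, config: ReactorConfig, params: KineticParameters):
        n = config.n_cells
        self.config = config
        self.params = params
        self.c_mn = np.zeros(n)
        self.c_zn = np.zeros(n)
        self.u = np.zeros(n)  # sorbed Zn, mol per litre of pore water
        self.m = np.full(n, float(config.initial_sorbent_g_per_l))
        self.cum = np.zeros(n)
        self.budgets = {
            "mn_in": 0.0, "mn_out": 0.0, "zn_in": 0.0, "zn_out": 0.0,
            "mn_aq_init": 0.0, "zn_aq_init": 0.0, "zn_sorbed_init": 0.0,
        }
        # recorder
        self.times: list[float] = []
        self.out_mn: list[float] = []
        self.out_zn: list[float] = []
        self.out_cum: list[float] = []
        self.snapshots: list[dict] = []

    def run(self, inlet_fn, hrt_days: float, t0_days: float, t1_days: float,
            snapshot_every: int = 0):
        """Advance from ``t0`` to ``t1`` (days) at a fixed HRT."""
        cfg, params = self.config, self.params
        n = cfg.n_cells
        dt_days = hrt_days / n
        dt_s = dt_days * SECONDS_PER_DAY
        if dt_s <= 0:
            raise ValidationError(f"time step must be > 0 (hrt={hrt_days} d)")
        n_steps = int(round((t1_days - t0_days) / dt_days))
        if n_steps <= 0:
            return

        f_mix = cfg.dispersivity_m * n / cfg.length_m
        n_mix = int(math.ceil(f_mix / 0.4)) if f_mix > 0 else 0
        f_sub = f_mix / n_mix if n_mix else 0.0

        # inlet boundary for every step, vectorised where the inlet allows
        ts = t0_days + np.arange(n_steps) * dt_days
        if hasattr(inlet_fn, "values_at"):
            mn_in_arr, zn_in_arr = inlet_fn.values_at(ts)
        else:
            pairs = [inlet_fn(float(t)) for t in ts]
            mn_in_arr = np.array([p[0] for p in pairs])
            zn_in_arr = np.array([p[1] for p in pairs])
        c_mn_in_arr = np.asarray(mn_in_arr, dtype=float) / (MM_MN * 1000.0)
        c_zn_in_arr = np.asarray(zn_in_arr, dtype=float) / (MM_ZN * 1000.0)

        # fast in-loop kinetics: exact exponential updates (see _react); the
        # general path is only needed for autocatalysis or a zero-mass sorbent
        k1, km, kd, k2 = params.k1, params.km, params.kd, params.k2
        fast = k2 == 0.0 and (cfg.initial_sorbent_g_per_l > 0
                              or not (km > 0 and kd > 0))
        decay = math.exp(-k1 * dt_s)
        sorb = km > 0.0 and kd > 0.0
        growth = cfg.sorbent_growth
        if fast and sorb and not growth:
            denom_const = 1.0 + self.m * kd
            ez_const = np.exp(-km * (1.0 + 1.0 / (self.m * kd)) * dt_s)
        m_base = cfg.initial_sorbent_g_per_l
        inv_n = 1.0 / n

        b = self.budgets
        for j in range(n_steps):
            # 1) advect: last parcel exits, inlet parcel enters cell 0
            out_mn, out_zn = self.c_mn[-1], self.c_zn[-1]
            self.c_mn[1:] = self.c_mn[:-1]
            self.c_zn[1:] = self.c_zn[:-1]
            self.c_mn[0] = c_mn_in_arr[j]
            self.c_zn[0] = c_zn_in_arr[j]
            b["mn_in"] += c_mn_in_arr[j]
            b["zn_in"] += c_zn_in_arr[j]
            b["mn_out"] += out_mn
            b["zn_out"] += out_zn
            self.times.append(ts[j] + dt_days)
            self.out_mn.append(out_mn * MM_MN * 1000.0)
            self.out_zn.append(out_zn * MM_ZN * 1000.0)
            # 2) dispersive mixing (aqueous phases only, reflective ends)
            for _ in range(n_mix):
                for arr in (self.c_mn, self.c_zn):
                    lap = np.empty_like(arr)
                    lap[1:-1] = arr[:-2] - 2.0 * arr[1:-1] + arr[2:]
                    lap[0] = arr[1] - arr[0]
                    lap[-1] = arr[-2] - arr[-1]
                    arr += f_sub * lap
            # 3) react every cell over dt
            if fast:
                c_new = self.c_mn * decay
                self.cum += self.c_mn - c_new
                self.c_mn = c_new
                if growth:
                    self.m = m_base + self.cum * cfg.mno2_molar_mass
                if sorb:
                    if growth:
                        denom = 1.0 + self.m * kd
                        ez = np.exp(-km * (1.0 + 1.0 / (self.m * kd)) * dt_s)
                    else:
                        denom, ez = denom_const, ez_const
                    total = self.c_zn + self.u
                    c_eq = total / denom
                    self.c_zn = c_eq + (self.c_zn - c_eq) * ez
                    self.u = total - self.c_zn
            else:
                self.c_mn, self.c_zn, self.u, self.m, self.cum = _react(
                    self.c_mn, self.c_zn, self.u, self.m, self.cum,
                    params, cfg, dt_s)
            self.out_cum.append(self.cum.sum() * inv_n)
            if snapshot_every and (j + 1) % snapshot_every == 0:
                self.snapshots.append({
                    "t_days": ts[j] + dt_days,
                    "c_mn": self.c_mn.copy(), "c_zn": self.c_zn.copy(),
                    "u": self.u.copy(), "m": self.m.copy(),
                    "mno2_cum": self.cum.copy(),
                })
        if not np.all(np.isfinite(self.c_mn)) or not np.all(np.isfinite(self.c_zn)):
            bad = int(np.argmax(~np.isfinite(self.c_mn + self.c_zn)))
            raise NumericalError(f"non-finite state in cell {bad} at t={t1_days} d")
        # analytic steps are positivity-preserving; clip guards round-off only
        for arr in (self.c_mn, self.c_zn, self.u):
            neg = arr < 0
            if np.any(neg):
                if float(-arr[neg].min()) > 1e-12:
                    warnings.warn("positivity clip exceeded 1e-12 mol/L",
                                  RuntimeWarning, stacklevel=2)
                arr[neg] = 0.0

    def result(self) -> SimulationResult:
        return SimulationResult(
            times_days=np.asarray(self.times),
            outlet_mn_mg_l=np.asarray(self.out_mn),
            outlet_zn_mg_l=np.asarray(self.out_zn),
            mno2_cum_mol_per_l=np.asarray(self.out_cum),
            budgets={
                **self.budgets,
                "mn_aq_final": float(self.c_mn.sum()),
                "zn_aq_final": float(self.c_zn.sum()),
                "zn_sorbed_final": float(self.u.sum()),
                "mn_precip_final": float(self.cum.sum()),
            },
            config=self.config,
            params=self.params,
            snapshots=self.snapshots,
            final_state={
                "c_mn": self.c_mn.copy(), "c_zn": self.c_zn.copy(),
                "u": self.u.copy(), "m": self.m.copy(),
                "mno2_cum": self.cum.copy(),
            },
        )


def simulate(config: ReactorConfig, params: KineticParameters, inlet,
             hrt_a1_days: float, duration_days: float,
             snapshot_every: int = 0) -> SimulationResult:
    """Forward simulation at a single fixed HRT.

    Parameters
    ----------
    inlet
        A ``(mn, zn)`` mg/L tuple for a constant feed, a callable
        ``t_days -> (mn, zn)``, an :class:`InletSeries`, or a DataFrame with
        columns ``day, mn, zn`` (step-interpolated).
    hrt_a1_days
        Hydraulic retention time of the column, days; the advection step is
        ``HRT / n_cells``.
    """
    if duration_days <= 0:
        raise ValidationError("duration_days must be > 0")
    if hrt_a1_days <= 0:
        raise ValidationError("hrt_a1_days must be > 0")
    col = _Column(config, params)
    col.run(as_inlet(inlet), hrt_a1_days, 0.0, duration_days,
            snapshot_every=snapshot_every)
    return col.result()


def simulate_schedule(config: ReactorConfig, params: KineticParameters, inlet,
                      spans: Iterable[tuple[float, float, float]],
                      snapshot_every: int = 0) -> SimulationResult:
    """Forward simulation across a staged HRT schedule.

    ``spans`` is an iterable of ``(start_day, end_day, hrt_days)`` covering the
    campaign in order; the column state carries over between regimes.
    """
    inlet_fn = as_inlet(inlet)
    col = _Column(config, params)
    for start, end, hrt in spans:
        if end <= start:
            raise ValidationError(f"empty regime window [{start}, {end})")
        col.run(inlet_fn, hrt, start, end, snapshot_every=snapshot_every)
    return col.result()
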