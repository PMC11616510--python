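# Methods

## System and model

`mnztreat` models a limestone bioreactor treating circumneutral mine drainage.
Water enters from a storage tank (station A-0), percolates through a 1.6 m
limestone bed (porosity 48 %, tank volume 600 L) and leaves at station A-1.
Two processes remove metals:

1. **Bacterial Mn(II) oxidation.** Manganese-oxidising bacteria colonising the
   limestone oxidise Mn²⁺ to MnO₂ (birnessite). At circumneutral pH the
   surface-autocatalytic pathway is negligible, so the operative rate law is
   homogeneous pseudo-first order, `R_Mn = k₁[Mn²⁺]`. The autocatalytic term
   `k₂[MnOₓ][Mn²⁺]` is implemented but defaults to `k₂ = 0`; it exists so the
   sensitivity of that assumption can be explored, not because the default
   workflow uses it.
2. **Zn(II) sorption on birnessite.** Zn²⁺ exchange with the oxide inventory
   is modelled as a linear driving force towards partition equilibrium,
   `R_Zn = k_m([Zn²⁺] − S_Zn/K_d)`, the standard two-parameter description of
   kinetically limited sorption in transport codes. Each mole of Mn oxidised
   adds one mole (86.94 g) of MnO₂ to the local sorbent inventory, coupling
   the two laws.

Rates carry no explicit pH, temperature, DO or carbonate dependence: those
variables are recorded as metadata but the rate laws above do not contain
them, so their influence is absorbed into the fitted constants. There is no
geochemical speciation, calcite/gypsum equilibria or oxygen balance, and the
downstream polishing tank (A-2) is out of scope — the model describes the
A-0 → A-1 reach where the dominant removal occurs.

## Transport scheme

The column is discretised as `n_cells` equal well-mixed cells in series. Each
step `Δt = HRT/n_cells` the aqueous contents shift one cell downstream (the
inlet parcel enters cell 0, the last parcel exits), an optional mixing pass
emulates dispersion, and the kinetics are integrated within each cell. The
whole-cell shift makes the scheme free of numerical dispersion: a parcel
resides exactly one HRT and reacts for exactly that long, so at zero
dispersivity the steady Mn outlet equals the plug-flow closed form
`c_in·e^(−k₁·HRT)` to round-off for *any* `n_cells` (the acceptance suite
verifies < 1 % over a (k₁, HRT) grid; in practice agreement is ~1e-13).

Dispersion, when requested, is an explicit conservative exchange between
neighbouring cells with no-flux ends. The per-step mixing fraction
`f = α·n_cells/L` reproduces a dispersion coefficient `D = α·v`; it is
sub-iterated in increments ≤ 0.4 so any dispersivity `α` remains stable.

**In-cell integration.** Both rate laws are linear in their state, so they
are integrated with closed forms rather than a generic ODE stepper: Mn decays
exponentially over the step; Zn relaxes exponentially towards the local
partition equilibrium `c_eq = (c + u)/(1 + m·K_d)` with rate
`λ = k_m(1 + 1/(m·K_d))`, with the sorbent mass `m` frozen at its post-growth
value within the step. The sorbed phase is tracked as `u = S_Zn·m` (mol per
litre of pore water) so that sorbent growth — which adds Zn-free MnO₂ —
dilutes the load `S_Zn` without creating or destroying sorbed Zn. This makes
the update exact, unconditionally positive and exactly conservative; the
Mn and Zn budget closures over a full 152-day staged campaign are ~1e-13
(criterion: ≤ 1e-8). Positivity clipping exists only as a round-off guard and
warns if it ever exceeds 1e-12 mol/L. With `k₂ > 0` the Mn update switches to
8 frozen-coefficient exponential substeps per step.

Units are mg/L at every public interface and mol/L internally (molar masses
Mn 54.938, Zn 65.38, MnO₂ 86.94 g/mol).

## Parameters

| Parameter | Meaning | Units | Default | Why |
|---|---|---|---|---|
| `k1` | Mn(II) oxidation constant | 1/s | 1.03e-4 | field-calibrated value for this bioreactor |
| `km` | Zn mass-transfer coefficient | 1/s | 3.175e-3 (= 11.43 1/h) | field-calibrated; sits in the 1–100 1/h range typical of near-equilibrium sorption |
| `kd` | Zn distribution coefficient | L/g | 4.49 | field-calibrated; same order as batch-derived constants for Zn on birnessite |
| `k2` | autocatalytic constant | (mol/L)⁻¹s⁻¹ | 0 | negligible at circumneutral pH |
| `length_m` / `porosity` | bed geometry | m / – | 1.6 / 0.48 | pilot column; carried for provenance (the solver is driven by HRT directly) |
| `n_cells` | discretisation | – | 16 | plug flow is exact at any value; 16 gives fine outlet time resolution |
| `dispersivity_m` | longitudinal dispersivity | m | 0 | pure advection; exposed because the field value is unknown |
| `initial_sorbent_g_per_l` | birnessite inventory per litre of pore water | g/L | 1.0 | see below |
| `sorbent_growth` | couple MnO₂ precipitation into the inventory | – | on | Reaction stoichiometry, 1:1 |

A unit note on `km`: quoted values of this coefficient appear in both 1/s and
1/h in the literature and transcription slips between the two are easy (a
printed pair "4.11e4 s⁻¹ (11.43 h⁻¹)" is mutually inconsistent by eight
orders of magnitude). The operative default here is the 1/h-anchored value,
11.43 1/h = 3.175e-3 1/s, which is the physically plausible one: 4e4 1/s
would equilibrate in microseconds and be numerically indistinguishable from
instantaneous equilibrium.

**The sorbent inventory is the largest unconstrained quantity.** The sorbed
load is defined per gram of sediment, but the mass of reactive birnessite per
litre of pore water in a coated limestone bed is not measurable from
monitoring data alone, and outlet Zn is insensitive to it once the bed
saturates. The default of 1 g/L is an order-of-magnitude choice; both the
initial inventory and the growth coupling are configurable, and any
field-scale Zn conclusion should be read conditional on this setting (see
Limitations).

## Inverse estimation

Calibration mirrors the field procedure: the A-0 series (step-interpolated)
drives the model, and simulated-minus-observed A-1 residuals at the sampling
dates enter a weighted least-squares objective (uniform weights by default;
an inverse-observation option exists because monitoring-data weighting
conventions vary). `k₁` is fitted from the Mn series alone; `(k_m, K_d)` are
then fitted jointly from the Zn series with `k₁` held fixed, since sorbent
growth depends on it. Parameters are searched as log₁₀ values under a
trust-region reflective solver within bounds k₁ ∈ [1e-8, 1e-2] 1/s,
k_m ∈ [1e-6, 1] 1/s, K_d ∈ [1e-3, 1e3] L/g; convergence at relative
objective change < 1e-10 or log-step < 1e-10. Validation datasets are scored
with the fitted parameters but never enter the objective.

NRMSE is normalised by the observed range (a mean-normalised option exists,
as the convention differs between authors), and R² is the Nash–Sutcliffe
coefficient of efficiency `1 − SS_res/SS_tot`, which can be negative — not a
squared correlation.

Identifiability: `k₁` and `K_d` are well determined by campaign data (`K_d`
through both the breakthrough timing and the quasi-steady removal level).
`k_m` is only weakly identified whenever sorption is near equilibrium within
one advection step (`λ·Δt ≫ 1`), which holds at the default values; its
fitted value should then be read as "large enough", not as a measurement.

## HRT optimisation

`steady_outlet` runs a constant-inlet simulation until the outlet changes by
< 0.1 % per flush (one pore-volume replacement; the outlet is piecewise
constant between flushes in the shifting scheme) and `min_hrt_for_limit`
bisects the monotone HRT–outlet relation to relative 1e-4. Stress inlets
default to the campaign maxima (Mn 25 mg/L, Zn 9.5 mg/L); effluent limits to
the Japanese national standards (Mn 10, Zn 2 mg/L).

For Mn the pure plug-flow answer at the default `k₁` is
`ln(25/10)/k₁ = 0.103 d`; with dispersivity up to 0.2 m the required HRT
rises monotonically to ≈ 0.113 d. Field experience with this system quotes a
slightly more conservative ≥ 0.12 d; the model's answer stays bracketed by
the plug-flow value and that field threshold over the whole dispersivity
range, and the residual gap is consistent with transport settings (dispersion,
discretisation) that monitoring data cannot pin down. Under the default
sorbent inventory the quasi-steady Zn removal fraction is set by sorbent
*growth* (≈ K_d·M_MnO₂·c_Mn,in ≈ 13 %) and is independent of residence time,
so no HRT meets the 2 mg/L Zn limit at steady state — `min_hrt_for_limit`
raises an infeasibility error rather than returning a misleading number, and
the HRT tooling reports steady Zn outlets at candidate HRTs instead. A
sustained field-scale Zn removal of 70–95 % implies a far larger reactive
inventory (tens of g/L, i.e. the coated bed itself) than the 1 g/L default.

## Synthetic campaigns

`synth.generate_campaign` produces the package's test bed: the noiseless
inlet skeleton (step change at day 120; a linear-ramp option exists because
seasonal drift is gradual in reality) drives the forward model under known
true parameters across the staged HRT schedule; both stations are then
sampled every 5 days (sampling cadence in the field was "periodic" without a
stated interval; 5 days gives n = 30 over 152 days) with independent
multiplicative Gaussian noise, cv 5 %, truncated at 1 % of the level.
Auxiliary fields (pH 7.1, DO 9.3 mg/L, EC 1138 µS/cm, ORP 138 mV, 15 °C) are
constants with noise.

What passing recovery tests on these campaigns shows: the estimator is
unbiased and precise *under the model that generated the data*. What it does
not show: robustness to source-water excursions, non-first-order Mn kinetics,
a mis-specified sorbent inventory, or correlated measurement error — none of
which the generator emulates.

## XANES LCF

`lcf_fit` solves `min ‖A·w − b‖²` over a window relative to the edge energy
(default −20 to +30 eV) subject to `w ≥ 0` and `Σw = 1` (the sum constraint
is the default because phase compositions are reported as percentages; a
free-sum mode exists). The solver is an active-set iteration on the
equality-constrained KKT system, exact for interior solutions; duplicated or
near-collinear references trigger a conditioning warning but still return a
solution. Fit quality is the R-factor `Σr²/Σb²`. Synthetic references for
testing are erf edge steps with Gaussian white lines at 6555/6559/6562 eV
(the Mn(II)/Mn(III)/Mn(IV) white-line energies), reproducing the
oxidation-state contrast real LCF exploits. Published phase fractions from
any particular study are not reproducible here because the underlying spectra
are not distributed; the module is validated on constructed mixtures
(recovery to 1e-6 noiseless, within 3σ under added noise).

## Numerical and design choices

- Regime membership of an observation date is half-open (`start ≤ d < end`),
  so boundary dates are assigned unambiguously.
- Removal efficiencies default to regime-mean comparison (stations are not
  always sampled the same day); a date-paired mode is provided.
- Missing values are excluded from statistics and counted, never imputed;
  unparseable numeric cells in input CSVs become missing, never zero.
- Steady-state detection is per flush, tolerance 0.1 %; bisection bracket
  for the minimum HRT is [1e-3, 10] days.
- The fitted-parameter seed path: all randomness flows from
  `numpy.random.default_rng(seed)`; identical seeds give byte-identical
  campaigns and fits.
- Problem sizes used by the automated checks: campaigns of n = 30
  observations; the recovery study uses 20 seeded campaigns; LCF recovery
  uses 10 random mixtures of 3 references.

## Limitations

- Zero-dimensional chemistry: no pH/carbonate/O₂ feedbacks; constants are
  effective, site-specific values.
- The Zn pathway lumps co-precipitation and adsorption into one
  linear-driving-force law with a single `K_d`.
- Field-scale Zn predictions (removal efficiencies, compliant HRT) are
  conditional on the unconstrained sorbent inventory; the Mn pathway has no
  such dependence.
- `k_m` is structurally unidentifiable in the near-equilibrium regime.
- The generator's noise model (independent multiplicative Gaussian) is
  idealised; real ICP-OES campaigns show drift and occasional outliers.
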