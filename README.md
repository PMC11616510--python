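# mnztreat

Reactive-transport modelling, inverse kinetics and hydraulic-retention-time
(HRT) optimisation for **passive treatment of manganese and zinc in mine
drainage**.

Legacy mine drainage often carries dissolved Mn²⁺ and Zn²⁺ at concentrations
far above effluent limits. In a limestone bioreactor operated at
circumneutral pH, manganese-oxidising bacteria catalyse

    Mn²⁺ + ½ O₂(aq) + H₂O → MnO₂ (birnessite) + 2 H⁺

and the freshly precipitated birnessite in turn sorbs Zn²⁺ by surface
complexation and co-precipitation. `mnztreat` is a toolkit for scientists and
engineers who run such pilot- or full-scale systems and want to turn routine
inlet/outlet monitoring data into kinetic parameters and design numbers —
without dedicated batch or column experiments.

## The model

The treatment column is a 1D advective reactor (cells-in-series; optional
hydrodynamic dispersion) carrying two coupled kinetic laws per litre of pore
water:

* **Mn(II) bio-oxidation** — pseudo-first order,
  `R_Mn = −d[Mn²⁺]/dt = k₁[Mn²⁺]`
  (an autocatalytic term `k₂[MnOₓ][Mn²⁺]` is available but off by default);
  each mole oxidised adds one mole of MnO₂ to the sorbent inventory.
* **Zn(II) sorption** — linear driving force towards partition equilibrium
  with the birnessite inventory,
  `R_Zn = −d[Zn²⁺]/dt = k_m([Zn²⁺] − S_Zn/K_d)`,
  with `S_Zn` the sorbed load (mol/g) and `K_d` the distribution
  coefficient (L/g).

The three constants `(k₁, k_m, K_d)` are estimated by weighted least squares
against A-0 (inlet) / A-1 (outlet) monitoring series, searched in log₁₀ space;
fits are scored with MAE, RMSE, range-normalised RMSE and the Nash–Sutcliffe
coefficient of efficiency (R²). A forward HRT sweep plus bisection then gives
the minimum residence time that meets an effluent limit (defaults: Mn 10 mg/L,
Zn 2 mg/L).

A synthetic-campaign generator reproduces the statistical structure of the
pilot study (152 days; staged A-1 HRTs of 2, 0.5 and 0.3 days; inlet Mn
drifting 19→25 mg/L and Zn 8→9.5 mg/L; 5 % multiplicative sampling noise)
with known ground truth, so the whole pipeline is testable offline. An
auxiliary module performs linear-combination fitting (LCF) of normalised
XANES spectra — non-negative weights summing to one — to quantify mineral
fractions in the precipitate.

## Worked example

```python
from mnztreat import (CampaignSpec, KineticParameters, ReactorConfig,
                      fit, generate_campaign, min_hrt_for_limit)

config = ReactorConfig()                        # 1.6 m path, 16 cells, 48 % porosity
camp = generate_campaign(CampaignSpec(seed=1))  # 152-day campaign, 5 % noise
dataset = camp.fit_dataset()

start = KineticParameters(k1=3e-5, km=1e-3, kd=1.0)
mn_fit = fit(start, [dataset], config, "mn")
zn_fit = fit(start.with_(k1=mn_fit.params.k1), [dataset], config, "zn")
print(f"k1 = {mn_fit.params.k1:.3e} 1/s   (truth 1.030e-04)")
print(f"Kd = {zn_fit.params.kd:.2f} L/g      (truth 4.49)")
print(f"Mn calibration NRMSE = {mn_fit.metrics['synthetic']['nrmse_pct']:.1f} %")

h = min_hrt_for_limit(config, mn_fit.params, 25.0, 10.0, "mn")
print(f"minimum HRT for Mn <= 10 mg/L at 25 mg/L inlet: {h:.3f} days")
```

prints

```
k1 = 1.023e-04 1/s   (truth 1.030e-04)
Kd = 4.77 L/g      (truth 4.49)
Mn calibration NRMSE = 3.7 %
minimum HRT for Mn <= 10 mg/L at 25 mg/L inlet: 0.104 days
```

The Mn oxidation constant is recovered within 1 % and the Zn distribution
coefficient within a few percent from a single noisy campaign; the design
answer — the shortest residence time keeping a 25 mg/L Mn feed under the
10 mg/L limit — follows directly from the calibrated forward model
(`ln(25/10)/k₁ ≈ 0.103 d` in the pure plug-flow limit; dispersion pushes it
upward).

The same workflow is available from the shell:

```sh
mnztreat synth --out campaign --seed 1
mnztreat fit --config config.yml --monitoring campaign/monitoring.csv \
             --schedule campaign/hrt_schedule.csv --analyte mn --out fit.json
mnztreat optimize-hrt --config config.yml --analyte mn --out curve.csv
```

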