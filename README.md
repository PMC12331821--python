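# dielmetab

Estimates of estuarine ecosystem metabolism — gross primary production
(GPP), ecosystem respiration (ER) and net ecosystem production
(NEP = GPP − ER) — from open-water diel dissolved-oxygen records, for
coastal scientists running multi-day sonde deployments paired with buoy
meteorology.

## Method

A well-mixed water column of depth *H* obeys the oxygen mass balance

```
H d[O2]/dt = GPP − ER + F,        F = k_w ([O2]sat − [O2])
```

where `[O2]` is the dissolved-oxygen concentration (mmol m⁻³), *F* the
air–sea flux, `k_w = 0.251 U₁₀² (Sc/660)^(−1/2)` the wind-driven gas
transfer velocity (Schmidt number *Sc* from temperature and salinity) and
`[O2]sat` the equilibrium concentration at ambient temperature, salinity
and barometric pressure (Benson–Krause solubility).

All inputs are averaged to clock-aligned 30-min blocks, and the record is
cut into **metabolic days** — sunrise to next sunrise from the NOAA solar
equations. For each interval pair the biological rate is
`H·Δ[O2]/Δt − F` (mmol O2 m⁻² d⁻¹). Per metabolic day:

* **ER** = −(mean nighttime rate), extrapolated to 24 h;
* **GPP** = (mean daytime rate + ER) × daylight_hours / 24;
* **NEP** = GPP − ER.

Negative daily GPP or ER is physically anomalous (unmodelled transport);
such days are flagged and *kept* in all averages. Deployment and bay means
carry standard errors sd/√n_days; carbon units use the C:O₂ = 106:154
remineralisation ratio.

The package also contains a forward simulator that integrates the same
mass balance with prescribed GPP/ER, tidal depth/salinity harmonics, diel
temperature, AR(1) wind and configurable transport/observation noise, so
the estimator can be validated against known truth without field data.

## Worked example

```python
from dielmetab import OpenWaterMetabolism, SimulationConfig, simulate_deployment

cfg = SimulationConfig(seed=5)          # 10 days, true GPP 200, ER 185
sonde, met, truth = simulate_deployment(cfg)
res = OpenWaterMetabolism.from_records(sonde, met, cfg.station).fit()
print(res.summary())
```

prints

```
Open-water diel oxygen metabolism
=================================================
Station:            SIM1
Metabolic days:     9
Anomalous rates:    0
Mean diel O2 range:     43.1 mmol m-3
-------------------------------------------------
           mmol O2 m-2 d-1   g C m-2 d-1
GPP      201.7 (+/-   5.2)          1.67
ER       184.2 (+/-   5.2)          1.52
NEP       17.5 (+/-   2.7)          0.14
-------------------------------------------------
Annual GPP:    609 g C m-2 y-1
```

Nine complete sunrise-to-sunrise days were recovered from the 10-day
record; the deployment-mean GPP of 201.7 ± 5.2 (± 2 SE) and ER of
184.2 ± 5.2 mmol O2 m⁻² d⁻¹ bracket the prescribed 200 and 185, NEP is
mildly autotrophic, and the 43 mmol m⁻³ mean diel oxygen swing is the
signal the budget integrates. `res.daily` holds the per-day table and
`res.diagnostics()` the per-interval physics (saturation, k_w, flux,
instantaneous rates, day/night labels).

The same pipeline runs from the shell:

```
dielmetab simulate --seed 5 --out deploy/
dielmetab run --config deploy/config.yaml --out results/
dielmetab summarize --rates results/daily_rates.csv --group all
```

with sonde CSV, simple met CSV or NDBC standard meteorological text files
as inputs (see `dielmetab run --help`).

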