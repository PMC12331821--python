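# Methods

## The oxygen mass balance and its inversion

The estimator treats a shallow estuarine water column as a single
well-mixed box. Oxygen changes through photosynthesis, respiration and
air–sea exchange:

    H d[O2]/dt = GPP − ER + F,      F = k_w ([O2]sat − [O2])

with *H* the (tidally varying) water depth in m, `[O2]` in mmol m⁻³, and
all rates areal (mmol O2 m⁻² d⁻¹). Lateral advection is deliberately
absent: transport errors are assumed random with zero mean over a
deployment, so they inflate the day-to-day spread (and hence the standard
errors) without biasing deployment means. Days on which transport
dominates can push daily GPP or ER negative; these are flagged
`anomalous_*` and retained in every average rather than censored, so the
reported means and SEs reflect the method's real error structure.

Processing steps, in order:

1. **Block averaging.** Every input (oxygen, temperature, salinity, depth,
   wind, pressure) is averaged over clock-aligned 30-min windows
   `[hh:00, hh:30)`. This suppresses sensor noise and the sharp
   sunrise/sunset transients that otherwise leak between the day and night
   budgets. Empty blocks stay missing; one missing block may be bridged by
   the finite difference, longer gaps break the chain.
2. **Derived physics.** Salinity from conductivity (PSS-78), depth from
   absolute pressure (fixed 1010 hPa atmospheric reference for
   fixed-reference loggers) plus the 0.30 m sensor-height offset,
   `[O2]sat` (Benson–Krause with the total-pressure/vapour-pressure
   factor), Schmidt number and `k_w` (quadratic wind-speed relation,
   coefficient 0.251 cm h⁻¹ per (m s⁻¹)², referenced to Sc = 660).
   Winds measured off 10 m are corrected by the neutral log profile with
   roughness length 10⁻⁴ m when an anemometer height is configured;
   otherwise they are taken as 10-m winds.
3. **Metabolic days.** Sunrise/sunset from the NOAA solar-position
   equations at zenith 90.833° (refraction + solar radius). A metabolic
   day runs sunrise → next sunrise; intervals are labelled day/night by
   their midpoints relative to sunset. A day is complete only if ≥ 80% of
   the expected day intervals *and* ≥ 80% of the expected night intervals
   are present; incomplete and partial edge windows yield no rates.
4. **Budgets.** Instantaneous biological rate between consecutive blocks:
   `r = H̄ Δ[O2]/Δt − F̄`, with `H̄`, `F̄` means of the bounding blocks and
   `r` assigned to the later block's label (a deterministic tie-break;
   with 30-min blocks the alternatives differ by far less than transport
   noise). Then ER = −mean(night r) — i.e. the nighttime hourly rate
   extrapolated to 24 h — GPP = (mean(day r) + ER)·daylight/24 and
   NEP = GPP − ER, which makes the NEP identity exact by construction.
   The photoperiod-scaled GPP formulation was chosen over trapezoidal
   integration of the daytime curve: it is the form implied by separate
   day/night budget means and keeps all three quantities consistent.

Uncertainty on any group mean (station, deployment, bay) is the standard
error sd/√n over metabolic days, displayed as ± 2 SE. Bay-level means pool
*all* days across stations (day-weighted), not means of deployment means.
Carbon conversion multiplies by (106/154)·12.011/1000 g C per mmol O2;
annual rates use 365 d.

## Physical-chemistry parameterisations

* **PSS-78 practical salinity** (conductivity ratio against 42.914 mS cm⁻¹,
  temperature and pressure factors, double polynomial in √Rt). Exact at
  the definition point (ratio 1, 15 °C → 35) and at the standard
  high-pressure check value. Valid 2–42; computed values outside [0, 50]
  are masked.
* **Oxygen solubility**: Benson–Krause equations (quartic in 1/T with a
  salinity factor), times the total-pressure correction
  `(P−u)(1−θP)/[(1−u)(1−θ)]`. Agreement with an independent published
  fit of the same data is within 0.03% over 5–35 °C × 0–35 PSU.
* **Schmidt number**: fourth-order temperature polynomials for fresh and
  S = 35 seawater, linear interpolation in salinity between them
  (estuarine salinities span the whole range).
* **Depth from pressure**: hydrostatic conversion with the one-atmosphere
  seawater density polynomial and g = 9.81 m s⁻².

All constants sit in `dielmetab.seawater.CONSTANTS`.

## The forward simulator

`simulate_deployment` integrates the same mass balance by explicit Euler
at the 10-min sampling interval (halving the step moves daily truth
integrals by < 0.5%). It emulates: a half-sinusoidal GPP over daylight
whose integral per metabolic day equals the prescribed value; respiration
with an optional Q10 temperature response (default Q10 = 1, constant ER);
semidiurnal (12.42 h) tidal harmonics in depth and salinity; a diel
temperature cycle peaking at 15:00 local; AR(1) wind truncated at zero;
constant barometric pressure.

Defaults describe a shallow subtropical deployment: 10 days, GPP 200 and
ER 185 mmol O2 m⁻² d⁻¹, mean depth 2.5 m with 0.5 m tidal amplitude,
28 ± 1.5 °C, salinity 35 ± 0.5, wind 4 m s⁻¹ (AR(1) coefficient 0.9,
innovation sd 1 m s⁻¹), 1015 hPa. These give a mean diel oxygen range of
roughly 45 mmol m⁻³, the scale at which the open-water method is known to
work well. Observation noise defaults to 2 mmol m⁻³ iid on emitted oxygen
(≈1% of saturation, a realistic optode figure); transport error defaults
to zero and is switched on as either a Gaussian random walk in
concentration (the mean-zero assumption) or a 12.42-h harmonic (the
tidally correlated failure mode).

What the simulator does **not** emulate: stratification, spatial
structure, storm events, sensor drift/fouling, and real tidal advection
of alongshore gradients. Recovery tests therefore demonstrate that the
estimator correctly inverts the stated model under realistic noise — not
that field estimates are free of transport bias when the mean-zero
assumption fails.

## Numerical and design choices

* Forward differencing between consecutive blocks with bounding-interval
  means for H and F; simple, and consistent with interpreting the budgets
  as day/night integrals.
* Timestamps are held in UTC internally; the station UTC offset enters
  only solar geometry and display, which keeps deployments spanning
  daylight-saving changes unambiguous.
* Duplicate raw timestamps: first kept, count logged. Met records are
  block-averaged to the same grid as the sonde data before pairing.
* Missing salinity (or conductivity) blocks metabolism for the deployment
  rather than silently assuming freshwater.
* Oxygen molar mass 31.998 g mol⁻¹ for mg L⁻¹ conversion.
* Single-day groups report a mean but no SE.
* Pearson correlations and the tie-corrected Kruskal–Wallis test (for
  station comparisons of daily rates) are delegated to scipy.stats;
  p-values are reported raw, with no multiple-testing correction.

## Validation scale and known limitations

The test suite and acceptance script use 10-day simulated deployments and
20-seed batches — enough for 9 metabolic days per deployment and stable
medians while keeping the whole suite fast. Noise-free recovery of
deployment-mean GPP and ER is within 1% (the residual is 30-min
discretisation plus day/night boundary assignment); with random-walk
transport noise of sd 2 mmol m⁻³ per step the median deployment-mean
error is roughly 10%, and individual seeds can exceed it — consistent
with a random walk whose daily integral rivals the biological signal.
Because those daily errors are autocorrelated, the iid-based SE slightly
understates uncertainty, and ± 2 SE coverage of truth sits near, not
above, its nominal level. The estimator requires |latitude| < 66.5° (a
sunrise and sunset every day) and a well-mixed column; neither twilight
gradations nor detiding regressions are implemented — the latter is
inappropriate for deployments of only a few days.
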