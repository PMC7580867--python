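# phlux

Long-term, plate-scale quantification of metabolite production by
**non-growing** bacterial cells from fluorescent pH-indicator readings —
and the decay kinetics of that activity.

Translationally blocked lactic acid bacteria (e.g. *Lactococcus lactis*
held non-growing with erythromycin) keep fermenting for weeks. In a
384-well plate with a carboxyfluorescein indicator, their lactic-acid
production (or, in arginine-catabolizing mode, ammonium production)
shows up as a slow pH drift that a plate reader can follow every 30
minutes for weeks. `phlux` turns those raw relative-fluorescence (RFU)
traces into cumulative production curves and fitted rate-decline laws.
It is written for microbial physiologists and fermentation scientists
who have such plate exports, and comes with a mechanistic simulator so
every stage is verifiable by parameter recovery without any
experimental data.

## The method

Per well, the analysis chain is

1. **Calibration** — standards (pH 4.0–7.0) fit a 4-parameter
   log-sigmoid `RFU(pH) = R_min + (R_max − R_min)/(1 + 10^{h(pK'−pH)})`,
   inverted analytically to convert each reading to pH.
2. **Buffering correction** — the pH is converted to the free
   proton equivalent `10^(−pH)` and then, through the inverse of a
   titration curve (added acid/base equivalents vs pH, empirical or
   modelled from a charge-balance buffer model), to cumulative
   production *P(t)* in mol/L. The medium buffers far more strongly
   near neutrality than at pH 5.5, so this inversion is what makes the
   curve quantitative.
3. **Noise censoring** — negative-control wells (medium + indicator, no
   active cells) processed identically define a noise threshold; the
   initial below-threshold production region is censored.
4. **Rate kinetics** — production rates `r = ΔP/Δt` are computed over
   equal *production* intervals (default 1 mM), so fast and slow wells
   are compared at equal catalytic turnover. The decline of `r` versus
   time (or versus cumulative product) is fitted by OLS as first order
   (`ln r` linear, `r(x) = r₀e^{−kx}`) or second order (`1/r` linear,
   `r(x) = r₀/(1 + r₀kx)`), giving the initial rate `r₀`, decay
   constant `k`, fold decline, and extrapolated yields such as
   `(r₀/k)(1 − e^{−kT})` at a two-month horizon.

The `simulate` module runs the same physics forward — decaying flux →
charge balance → indicator sigmoid → Gaussian read noise — with known
ground truth.

## Worked example

```python
import phlux as px

well, truth = px.simulate_well(px.SimulationParams(seed=11))
cal = px.default_fluorophore()
tit = px.make_titration_table(mode="acid")

prod = px.well_to_production(well, cal, tit, smooth=True)
rates = px.bin_rates(px.censor_below_threshold(prod, 0.003))
fit = px.fit_decay(rates, order=1, x_variable="time")
print(fit.initial_rate_r0, fit.decay_constant_k, fit.r_squared)
```

Running `python examples/04_decay_kinetics.py` (noiseless variant)
prints:

```
order 1: r0=1.299e-04 M/h  k=8.198e-03/h  r2=1.00000
order 2: r0=3.081e-04 M/h  k=1.774e+02/h  r2=0.92783
true parameters: r0=1.300e-04 M/h, k=8.225e-03/h
extrapolated yield at 2 months: 15.8 mM (asymptotic yield r0/k = 15.8 mM)
```

i.e. the first-order law (the one the data were generated under) is
recovered essentially exactly and flagged by its higher r², and the
fitted parameters predict the long-horizon lactate yield. The other
scripts in `examples/` walk through the buffer chemistry, calibration,
single-well quantification and the full file-based pipeline; a thin CLI
(`phlux simulate|calibrate|quantify|fit|run|report`) wraps the same
functions for shell use.

## Layout

```
src/phlux/       chemistry, calibration, quantify, kinetics, simulate,
                 pipeline (file I/O + orchestration), cli
examples/        one narrative script per capability
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  model assumptions, parameter choices, limitations
```
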