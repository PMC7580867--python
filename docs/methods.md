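# Methods

This note records the models behind `phlux`, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about. No
empirical claim is made here beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Acid–base model

The assay medium is modelled as a set of polyprotic buffer species plus
a net strong-ion term. Each species is described by its ascending pKa
list, total concentration and fully protonated charge; protonation-state
fractions follow the Henderson–Hasselbalch ladder (computed in log10
space for stability far from the pKas). The pH of a system is the
unique root of the charge balance

    [H+] − Kw/[H+] + Σᵢ Cᵢ·z̄ᵢ(pH) − A = 0

where `A` counts strong-acid equivalents (negative for strong base).
The residual is strictly decreasing in pH, so bracketed root finding
(Brent, tolerance 1e-10 pH; a 60-step vectorized bisection for arrays)
is exact for all well-posed systems, and adding strong acid can never
raise the solved pH. Activity coefficients are 1, pKas are treated as
temperature-independent, and the water ion product is fixed at 1e-14 —
the assay runs isothermally at 30 °C and stays between pH 4 and 7,
where these simplifications are inconsequential compared with read
noise.

Produced lactate (pKa 3.8, ≥99% dissociated above pH 5.5) enters the
balance as strong acid; ammonium production (pKa 9.25, ≥99% protonated
below pH 7, consuming one proton per molecule) as strong base. CO₂ from
arginine catabolism is assumed to escape the open wells; a carbonate
system can be added as a species if needed.

### The medium surrogate

The defined medium's full composition is not enumerated; the default
surrogate is 20 mM phosphate (pKa 2.15/7.20/12.35) plus one lumped
monoprotic "medium buffering" species, default 30 mM at pKa 6.2,
standing in for amino acids, organic phosphates and the cells' own
surface buffering. These defaults make the modelled acid-mode titration
require ≈14.8 mM of strong acid to move from pH 6.5 to 5.75 — i.e. a
full two-week acidification run stays under 20 mM lactate, the regime
the assay is designed for. Both concentration and pKa are ordinary
constructor arguments.

### Titration curves and their inversion

Modelled curves solve the charge balance on a dense added-equivalents
grid (default 0.05 mM steps; acid curves 0→24.5 mM spanning pH
6.5→<4.0, base curves 0→30.5 mM spanning 5.5→>7.0). Curve construction
fails loudly if the requested assay window is not covered. Inversion —
the buffering-capacity correction — interpolates added equivalents
piecewise-linearly in log10 proton-equivalent space (equivalently, −pH);
at 0.05 mM node spacing the interpolation error is below 1e-7 mol/L,
and empirical titration tables of any shape can be dropped in through
the same code path. A single log-linear fit over the whole curve is
available (`method="loglinear"`) for comparison with one-parameter
logarithmic treatments.

The two ends of the operational window are treated asymmetrically.
Past the *far* end (low pH in acid mode) a reading means the signal has
left the titrated range: up to 0.05 pH is clamped with a warning,
anything further is an error naming the window. Past the *resting-pH*
end, readings are pure detector noise above the starting pH and clamp
to zero production without error — a control well at pH 6.5 with
realistic noise has roughly half its readings there, and they carry no
production information.

## Calibration

The indicator response is fitted as a 4-parameter monotone log-sigmoid
(apparent pKa ≈6.4 and unit Hill slope for a carboxyfluorescein-type
indicator; both are fitted, not assumed). Fitting requires ≥4 standards
spanning ≥1.5 pH units and an RFU trend monotone up to a noise
tolerance (default 10% of the dynamic range). If the sigmoid cannot
describe the standards (no convergence, or residual RMS above a
configurable ceiling, default 5% of the fitted range), the curve falls
back to shape-free monotone interpolation of the isotonic-regressed
standards. The sigmoid inverse is analytic; readings mapping up to 0.05
pH outside the calibrated range are clamped with a warning. No
photobleaching/drift term is fitted by default, reflecting signal
stability over weeks at this gain; drift would first appear as a slowly
moving baseline in the negative controls.

## Quantification

Per well: RFU → pH → added equivalents, then baseline anchoring so
production at t = 0 is zero. The anchor is the Theil–Sen intercept of
the first k points (default 5): a plain median of those points would
subtract the signal accrued during the anchor window (~0.13 mM at
default rates, enough to violate the pipeline's own noiseless identity
budget of 0.1 mM), while the robust intercept extrapolates to t = 0 and
retains the median's tolerance of single-read glitches. Anchoring
removes constant RFU offsets to first order; exact offset invariance is
impossible because the calibration map is nonlinear (a 200-RFU offset
leaves a residual below 0.2 mM across a default well).

The noise threshold is `multiplier × max |apparent production|` over
the negative controls (default multiplier 1), reported together with
the per-control maxima. Thresholds above 12.5 mM trigger a warning —
typical bands at realistic noise are low-millimolar — but are never
silently replaced: the threshold must come from the run's own controls
(or be set explicitly). Censoring marks the maximal below-threshold
prefix; cumulative values are never altered, and the operation is
idempotent and monotone in the threshold.

### Monotone pre-smoothing

`smooth_production` applies a centered moving average (default 12 h,
i.e. 25 half-hourly reads, windows shrinking symmetrically at the ends
so edge estimates stay unbiased) followed by isotonic regression. It is
**off by default**: equal-production binning already tolerates slowly
drifting detector noise, the common case. It matters when per-read
noise is *independent* and comparable to the bin width: at 1250 RFU iid
noise (≈0.8 mM per-point production noise against 1 mM bins), bin-edge
crossings on the raw series are systematically early and the fitted
decay constant is biased by ~−13%; with pre-smoothing the same study
recovers k and r₀ with ~4–6% median error and no detectable bias
(20-seed sign test). The moving-average bias on a week-scale decay
curve is below 0.01 mM. Controls are always left unsmoothed when
estimating thresholds, because the threshold characterizes the raw
conversion-chain noise; thresholding smoothed controls was measured to
drop the threshold into the correlated-noise region and re-bias k by
−6%.

## Rate binning and decay fits

Rates are computed over equal production intervals (default 1 mM,
configurable) rather than equal time intervals, comparing wells at
equal turnover per enzyme. Bin edges start at the first uncensored
cumulative value; each edge's crossing time is located by scanning for
the first sample at or above the edge and interpolating linearly within
that sampling interval; the rate is bin width over traversal time, and
the bin is labelled with its mid-time and mid-production.

Decay fits are ordinary (unweighted) least squares on the transformed
rate — `ln r` for first order, `1/r` for second — against either
elapsed time or cumulative product. The abscissa is deliberately a
*required* argument with no silent default: the two conventions give
differently scaled decay constants, and reports always state which was
used. Back-transformed parameters are `r₀ = e^intercept, k = −slope`
(order 1) and `r₀ = 1/intercept, k = slope` (order 2). When both orders
are requested the report carries both r² values and flags the higher;
there is no automatic silent selection. Note one inherent limit:
because a bin's `w/Δt` is the *average* rate over the bin rather than
the instantaneous rate at the bin mid-time, even noiseless binned data
recover (r₀, k) only to ≈0.3–2% (late, long bins contribute the
curvature); exact recovery is expected — and tested — only on exact
rate series.

Yield extrapolation integrates the fitted law from 0 to a horizon:
`(r₀/k)(1 − e^{−kT})` (order 1, asymptote r₀/k) or `ln(1 + r₀kT)/k`
(order 2, unbounded), with the linear limit as k→0. It is defined only
for time-axis fits — a rate-vs-cumulative-product fit has no time axis
to integrate over.

## The synthetic-data generator

The generator emulates the long-term acidification assay: 30-minute
sampling over 336 h, 384-well geometry with ≥4 replicates per condition
and negative controls at both start pH values (6.5 acid / 5.5 base),
cell-density metadata of 1–2.5×10⁷/mL, a sigmoid indicator reading
≈37,000 RFU at pH 6.5, and additive Gaussian read noise of sd 1250 RFU
(the 1,000–1,500 RFU scale of real traces). Production follows a
closed-form order-0/1/2 decay law; the default decay constant
`k = ln(15.86)/336 h ≈ 8.22×10⁻³/h` encodes a 15.9-fold decline over
two weeks (the ratio of a 3.98×10⁻⁴ to a 2.51×10⁻⁵ M/h rate), and the
default initial rate r₀ = 1.3×10⁻⁴ M/h is chosen so the default well
traverses exactly the intended operating regime — pH 6.5→5.75 with
≈14.8 mM lactate — on the default medium. (A well at 4×10⁻⁴ M/h with
the same decline would integrate to ≈46 mM, overrunning the medium's
≈23.5 mM buffering capacity to pH 4; such published example rates
correspond to other, unprinted media/densities, so they are available
as parameters but not as defaults.) All randomness flows through one
seeded generator; plates spawn per-well streams from a single seed and
are byte-reproducible.

What the generator does **not** emulate — and what passing recovery
tests therefore cannot certify on real data: correlated/drifting
detector noise, photobleaching, evaporation and plate-edge effects,
population heterogeneity (VBNC fractions, persisters, biphasic decay),
product inhibition at low starting pH, and mixed-acid chemistry beyond
strong-acid equivalents. The decay law is an *effective* description;
the generator deliberately does not separate enzyme inactivation from
cell death.

## Numerical and design choices

- Charge-balance solver tolerance 1e-10 pH (spec'd oracle agreement:
  1e-4 against a 1e-5-resolution brute-force grid scan).
- Titration inversion: piecewise-linear in −pH; round trip add-x/invert
  is exact at nodes and <1e-4 mol/L off-grid.
- Degenerate inputs fail loudly with typed exceptions: <4 standards,
  non-monotone standards, mode mismatches between wells/titration/
  config (rejected before any computation), duplicated (well, time)
  rows with line numbers, entirely censored series ("insufficient
  signal"), nonpositive rates listing the offending bins.
- A failing well never aborts a plate run; it is recorded per well in
  the result and the report.
- Times are hours; concentrations are mol/L in every file format and
  millimolar only in human-readable text. Exit codes: 0 success, 2
  validation error, 3 runtime error.
- Problem sizes in the test and acceptance studies — 20 seeds, 4
  controls + 1 sample per seed, 100 random buffer systems, 673-point
  wells — were chosen as the smallest sizes at which the medians and
  sign tests are stable; they complete in about a minute.

## Known limitations

- The buffering model ignores ionic-strength and temperature effects on
  pKa; for media far from the defaults, supply an empirical titration
  table rather than the surrogate.
- Equal-production binning biases late-bin rates slightly high (average
  vs instantaneous rate); fits over many bins inherit a ≲2% bias on k.
- The abrupt activity halts seen with some substrates are not described
  by either decay law; changepoint handling is future work, and such
  wells surface as poor r² in both orders.
- The agreement statistic (`agreement_r2`) compares indicator-derived
  production to an external reference series; it is implemented and
  tested on constructed data, but no claim is made about any particular
  instrument pairing.
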