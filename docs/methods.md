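# Methods

## The model

`stickyhab` treats the reproduction of sticky-egg spawners as two
sequential phases with different environmental controls.

**Spawning** is governed by hydraulic preference. Each environmental
variable gets a piecewise-linear suitability curve: SI = 1 on the
optimal band observed in littoral egg surveys, falling linearly to
SI = 0 at the limits of the observed range, and 0 beyond. The packaged
defaults for carp and crucian carp are velocity support 0–0.5 m/s with
optimum 0–0.2 m/s, depth support 0.2–0.8 m with optimum 0.4–0.6 m, and
temperature support 15–30 °C with optimum 20–23 °C. Where an optimal
edge coincides with a support edge (velocity at 0 m/s) the limb is
degenerate and the shared edge keeps SI = 1: still water is the
species' preference, and assigning 0 there would contradict the
optimal-band rule.

**Hatching** additionally requires a stable waterline for roughly five
days: about two days from deposition to hatch plus three to four days
until larvae can swim freely. The controlling variable is the
cumulative 5-day drop

    D(t) = max(0, level(t) − min_{k=1..5} level(t+k)).

The *minimum* over the window, not the endpoint difference, is used:
stranding is irreversible, so an egg exposed mid-window dies even if
the level recovers. For monotone declines the two definitions
coincide; the endpoint variant is available via `endpoint_only=True`
for sensitivity analysis. D(t) is attributed to the spawning day t
(forward-looking window), which is also why validation against larvae
counts shifts SI_L five days *earlier* than the observation date.

The drawdown suitability index is SI_L(d) = 1 − F(d), with F the
cumulative fraction of eggs deposited at depths ≤ d. Because stranding
is a sharp depth threshold, SI_L is literally the expected surviving
fraction of a cohort whose depths follow the frequency table; the
`validate.cohort_survival` Monte-Carlo simulation is the independent
oracle of this identity and agrees within binomial error by
construction of the model, not by tuning. Knots are placed at d = 0
(SI = 1) and at every bin upper edge, computed from raw counts (the
table's rounded percent column sums to 100.1% and is not used). A
rising or stable level maps to SI_L = 1; a drop beyond the deepest
deposition depth (0.8 m for the packaged table) maps to 0. From the
zero point follows the regulation threshold: a constant decline is
sustainable only up to 0.8 m / 5 d = 0.16 m/day.

**Composites and aggregation.** Per cell, spawning
HSI = f(SI_V, SI_H, SI_T) and hatching HSI = f(SI_V, SI_H, SI_T, SI_L).
The default `f` is the geometric mean (cube / fourth root of the
product); a plain-product mode is provided as a configuration switch
and the active mode is recorded in every output file. The two modes
differ materially: in product mode hatching WUA ≤ spawning WUA always,
with equality exactly at SI_L = 1, which matches the narrative of
hatching area tracking at or below spawning area; the geometric mean
does **not** guarantee that ordering (a fourth root can exceed a cube
root when all factors are below 1), which is why both are implemented
and the product mode is used for ordering-sensitive comparisons.
SI_L is a spatially uniform scalar per date, reflecting a single stage
gauge; a per-cell extension would only need a vector argument.
Weighted usable area is WUA = Σ A_i · HSI_i, and cells are classed
into five bands — very_low [0, 0.2), low [0.2, 0.4), medium
[0.4, 0.6), high [0.6, 0.8), very_high [0.8, 1.0] — half-open on the
left so boundary values deterministically go to the upper class.

The per-class relative change reported by `class_area_table` is
100 × (hatching − spawning) / spawning per class. Published
multi-year tables of this kind are sometimes aggregated differently
(area-weighted or pre-rounding), so cross-study comparisons of that
column should be qualitative.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_days` | 5 | d | egg-to-free-swimming duration for carp/crucian carp |
| HSI mode | `geometric_mean` | — | the conventional multi-factor HSI combination; `product` preserves WUA ordering |
| class edges | 0.2/0.4/0.6/0.8 | — | standard five-band HSI classification |
| post-dam mean daily change | −0.22 (Apr), −0.32 (May) | m/day | observed spring drawdown rates at a reservoir-tributary gauge |
| max daily drop | −0.61 | m/day | observed single-day extreme; truncation bound |
| `daily_spread` | 0.08 | m/day | day-to-day variability; free parameter, chosen so 30-day realized means recover the regime means within sampling error |
| pre-dam pulse probability / magnitude | 0.10 / 0.4 | —, m | occasional rainfall rises that recede over following days |
| larvae noise sigma | 0.7 | — | log-normal observation noise, calibrated by simulation so the recovered lagged Pearson r is moderate (≈ 0.5–0.7), the regime seen in field counts |
| field ranges | v 0–1.4 m/s, h 0–14.5 m, T 13.7–29.2 °C | | envelope of simulated tributary hydraulics |

## What the synthetic data emulates — and what it does not

`gen_stage_series` draws daily level changes from a truncated normal
around the monthly mean — the minimal distribution consistent with a
stated mean and extreme. The post-dam regime is truncated above at 0
(a managed drawdown never rises), so it is *harsher* than a real gauge
record, which mixes decline with brief rises; synthetic post-dam mean
SI_L is therefore near 0 rather than the 0.05–0.3 a real record can
produce. The pre-dam regime superimposes exponential rainfall pulses
with geometric decay on a zero-mean base.

`gen_hydro_field` places cells on a longitudinal coordinate x (depth
growing downstream as x^0.8, temperature cooling linearly from 22.9 to
20.6 °C mean) and a cross-channel coordinate y (velocity core ≈ 0.3 m/s
mid-channel with a skewed tail of faster reaches, parabolic depth
shallowing toward the banks). It reproduces marginal ranges and the
qualitative structure — shallow slow warm margins suitable for
spawning as a small minority (~2–3% of cells with HSI > 0.6) of a
mostly deep, unsuitable reach — but no real bathymetry, no momentum
balance, and no correlation between dates. Passing tests therefore
demonstrate correctness of the *model pipeline* under realistic
structure, not calibration to any specific river.

`gen_egg_depths` samples bin-proportionally with uniform within-bin
placement; `gen_larvae_density` is proportional to lagged SI_L under
multiplicative log-normal noise. All generators take one seed and are
bit-reproducible.

## Numerical choices

- Curve evaluation is `np.interp` on validated knots; non-finite input
  raises rather than silently mapping to 0.
- Display rounding is half-up (0.9939 → 0.994); all internal
  computation keeps full precision and curve knots come from raw
  counts.
- The regulation threshold takes the *smallest knot* with SI = 0 (a
  linear segment between positive knots cannot cross zero), and errors
  if the curve never reaches 0.
- Trailing days without a full forward window carry no SI_L value and
  are excluded from period means, never padded.
- Output floats are written at six significant digits for
  platform-stable, byte-identical reruns; curve JSON round-trips
  bit-exactly.
- Degenerate inputs fail fast with named offenders: calendar gaps list
  the missing dates, field validation names the offending cell.

## Problem sizes

Tests run on fields of 200–2000 cells, stage series of 10–180 days,
and Monte-Carlo cohorts of 10⁵ eggs (binomial standard error ≈ 10⁻³),
sizes at which every stochastic assertion has comfortable margin; the
whole suite completes in a few seconds.

## Known limitations

- SI_L is uniform in space: one gauge represents the whole reach.
- Stranding is a sharp threshold; no partial-exposure mortality, no
  re-wetting survival.
- Depth-averaged (2-D) hydraulics: near-bed velocity and vertical
  temperature structure, which can rescue eggs that surface values
  would condemn, are not represented.
- Substrate (vegetation presence) is implicit in the depth preference,
  not modelled separately.
- The geometric-mean/product ambiguity is exposed, not resolved; users
  comparing WUA across stages should use product mode.
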