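# Methods

## Indices and psychrometric conversions

The twelve indices are evaluated exactly as published, in °C unless a formula
is Fahrenheit-native (THI4, THI6; the API accepts °C and converts with
T° = 1.8·T + 32). The wet-bulb, dew-point and black-globe temperatures they
consume come from empirical regression fits, not from thermodynamic
psychrometrics:

* dew point: Tdp = (0.198 + 0.0017·T)·RH + 0.84·T − 19.2 — linear in RH,
  hence finite (0.84·T − 19.2) at RH = 0 where the physical dew point
  diverges; kept as printed because the iso-line analysis evaluates it there;
* wet bulb: a single rational expression, the whole 5-term numerator over the
  whole 6-term denominator. This reading gives Twb(22, 70) = 18.28 °C,
  consistent with standard psychrometrics (≈18.4 °C), and reproduces the
  downstream THI8 results; the fit may exceed the dry-bulb temperature by a
  few tenths of a degree near saturation;
* black globe: 0.567·T + 0.393·e + 3.94 with Magnus-type vapor pressure
  e = (RH/100)·6.105·exp(17.27·T/(237.7 + T)).

The fits are calibrated for roughly 10–46 °C; the package declares a
[−10, 50] °C validity window and emits a `ValidityWarning` (never an error)
outside it, because the comparison analyses legitimately probe a few degrees
past the window. Barometric pressure defaults to 760 mmHg.

Two deliberately literal formula readings, each fixed by requiring the
printed downstream numbers to reproduce:

* ET's velocity term is −1.0·(42 − T)·(v^0.66 − 0.2^0.66). This yields the
  winter reference ET(10, 60, 0) = 21.21 °C and both published
  crossing-velocity windows (0.4–0.5 and 1.1–1.2 m/s) to three figures.
* ETIS contains −4.79·(1.0086·38 − T), a *product* 1.0086·38 = 38.33, not an
  exponentiation, plus the additive radiation term
  4.8957·10⁻⁸·((38 + 273.15)⁴ − (T + 273.15)⁴). The literal reading yields
  ETIS(10, 60, 0) = 18.56 °C (published 18.6), the upward velocity slope at
  40 °C, and the steep growth of the equivalent-temperature change toward
  40 °C. Whether the originally derived ETIS used 1.0086^(38−T) is unknown;
  that reading does not reproduce any of the printed values here.

Threshold tables (THI1, THI2, THI3, THI5, THI6, ETIS only) are encoded with
the printed boundary openness; printed gaps (THI5 between 78 and 83, THI1
below 61) classify as `unclassified` rather than being interpolated. The
THI3 row's "THI2 ≥ 28" is read as THI3 ≥ 28 — it sits in the THI3 row and
THI3 is the only wet-bulb-weighted index on that scale.

### Monotonicity and the ETIS derivative

Every index is strictly increasing in T at fixed RH over [10, 40] °C, with
one caveat: the quartic radiation term makes dETIS/dT cross zero at ≈41.7 °C
for u = 1 m/s but already at ≈36.2 °C in still air (the convection term
contributes +0.3132·u^0.6827 to the derivative). Consequently

* equivalence solving (done at the cross-index comparison velocity of 1 m/s)
  brackets ETIS below 42 °C and is monotone there;
* iso-line tracing (done at v = 0) cannot assume monotonicity: the tracer
  pre-scans its bracket in 0.5 °C steps and bisects the *first* sign change,
  returning the coolest root — the physically relevant branch.

## Equivalent-temperature analysis

For each index and each T₁ ∈ {25, 30, 35, 40} °C, the solver holds the index
constant while RH rises 50 → 60 % and bisects I(T₂, 60) = I(T₁, 50) on
[T₁ − 15, min(T₁ + 15, 42)] °C to an index residual < 10⁻⁹ (bisection rather
than Newton: the rational wet-bulb fit makes derivatives awkward and the
problem is 1-D and monotone). T_equ = T₁ − T₂ is positive iff the index
increases with RH at the solution, an identity the tests verify numerically.
A target that cannot be bracketed (e.g. drying to RH = 1 % under enthalpy)
is reported as a flagged failure, not extrapolated. An independent
0.001 °C grid-scan oracle agrees with the bisection root to < 0.002 °C for
all 48 cases.

## Velocity response

ET and ETIS are sampled on v ∈ [0, 4] m/s (step 0.01) at RH 60 %. v = 0 is
legal in both formulas (0^0.66 = 0); no epsilon floor is applied. Crossings
with the winter baselines (ET_winter = 21.21 °C, ETIS_winter = 18.56 °C at
10 °C / 60 % / 0 m/s, always recomputed) are bisected to |Δv| < 10⁻⁶;
absence of a sign change on [0, 4] is a result ("no crossing"), not an
error. The published temperature sets disagree between the methods text
(25/30/35/40 °C) and the figure caption (20/30/35/40 °C); the package sweeps
{20, 25, 30, 35, 40} and the headline checks use 25 and 30 °C.

## Iso-index lines

Each line is anchored at I(22 °C, 70 % RH) with v = 0 and Pm = 760 mmHg, and
traced over RH = 0…100 % in 1 % steps by solving I(T, RH) = I_ref for T on
[0, 50] °C (capped at 42 °C for ETIS); grid points with no root are kept as
gaps, and points whose solved temperature leaves the validity window are
flagged rather than dropped. Line slope satisfies the implicit-function
identity dT/dRH = −(∂I/∂RH)/(∂I/∂T), which the tests check numerically.

### Known discrepancies of the printed formulas

Recomputing from the printed formulas does not reproduce four published
anchor values; they are documented here (and pinned by regression tests)
rather than silently "fixed":

| published claim | literal recomputation |
|---|---|
| BGHI iso-line meets RH = 0 % at 31.6 °C | 37.17 °C |
| THI6 iso-line meets RH = 100 % at 25.4 °C | 24.77 °C |
| ETIS iso-line meets RH = 100 % at 23.34 °C | 21.50 °C |
| ETIS curves at 20/30/35 °C never cross ETIS_winter | the 20 °C curve crosses at ≈2.70 m/s; 25/30/35 °C curves never cross |

The reproducible anchors — H at 46.0 °C, THI8 at 37.41 °C, THI7 at 28.42 °C
(closed form (I_ref − 7.975)/0.45), THI2 within 0.3 °C of THI7 — are part of
the acceptance checks.

## Barn surrogate

The reference comparison used a 3-D RANS simulation of the 10-sow barn; this
package replaces it with a seeded 1-D zonal energy balance, which preserves
the *structure* the correlation analysis needs (a ventilation gradient that
drives convective heat loss) at desk scale. Scheme and defaults:

* ventilation mass flow ṁ = ρ·v_out·A_open with ρ = 1.164 kg/m³,
  c_p = 1006 J/(kg·K), v_out = 1 m/s, A_open = 2.25 m²;
* local air speed u(x) = v_out·exp(−x/3 m) + 0.05 m/s — the simplest profile
  giving the fast-cool inlet end and near-still animal zone the reference
  flow field shows (u spans ≈0.95 → 0.18 m/s across the row);
* film coefficient h = max(2.8, 3.2·u^0.66) W/(m²·K) — natural-convection
  floor with a forced-convection power law sharing ET's 0.66 exponent; with
  the default geometry only the inlet-nearest sow is in the forced regime,
  which is what makes dissipation "drop then flatten" along the row;
* march: Q_i = h_i·2.775 m²·(38 °C − T_i), T_{i+1} = T_i + Q_i/(ṁ·c_p),
  clamped at 34 °C (the hottest air the reference field reaches; the default
  scenario never triggers the clamp, and absent clamping the march conserves
  energy identically, Σ Q_i = ṁ·c_p·(T_exit − T_inlet));
* four sample points per sow (0.1 m off the body) receive Gaussian jitter
  (σ = 0.1 °C on T, 0.02 m/s on u, truncated at 0), drawn as one 4-vector
  per quantity per sow from `numpy.random.default_rng(seed)`, default seed
  42; their mean is the sow's local air state. RH is held at the inlet 60 %
  throughout — the reference contours vary T and u only.

What the surrogate does *not* emulate: 3-D recirculation, turbulence,
radiative exchange, latent (evaporative) heat loss, and buoyancy. Q here is
sensible convective heat only.

## Correlation and ranking

Each index is evaluated at the 10 per-sow mean local states (not the 40 raw
sample points) and Q is regressed on the index value by ordinary least
squares; R² = 1 − SS_res/SS_tot, indices ranked by descending R² with ties
broken by enumeration order. An index with zero variance across sows has no
defined R² and is reported as missing.

With noise off, the ranking is structural: every temperature–humidity index
is a monotone (locally near-affine) transform of zone temperature, blind to
the velocity gradient that actually shapes Q, so ET and ETIS (R² ≈ 0.59)
beat all ten others (R² ≤ 0.48). With the default sampling noise the strict
ranking additionally reflects the noise realization: the temperature signal
across the row (≈0.2 °C) is comparable to the jitter, so the
temperature-only R² values scatter widely around ≈0.45 and on a minority of
seeds (~10 %) one of them can exceed ET/ETIS. The packaged default seed
satisfies the strict ranking; the published R² values themselves
(0.9883 for ET, etc.) are properties of the full CFD field and are
reproduced as an *ordering*, not numerically. Passing these tests therefore
shows the analysis machinery is sound and the ordering argument holds under
the surrogate's assumptions — not that the surrogate predicts real-barn R².

## Numerical conventions

Bisection everywhere (scipy.optimize.bisect), brackets as above, index-value
tolerance 10⁻⁹, velocity tolerance 10⁻⁶ m/s; solver outputs are compared to
brute-force grid-scan oracles in the tests (0.001-step, agreement < 0.002).
CSV outputs are comma-separated, UTF-8, '.' decimal, 6 significant digits,
with the seed recorded in a `#` header comment. All analyses run in seconds
on one core; the problem sizes (101-point RH grids, 401-point velocity
grids, 10 sows) are the package defaults and match the published scenario.
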