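# sowtherm

Heat stress is a major production and welfare problem in sow housing, and a
dozen competing scalar indices are in everyday use to quantify it: eight
temperature–humidity indices (THI1–THI8), the black-globe humidity index
(BGHI), effective temperature (ET), the equivalent temperature index of sows
(ETIS), and moist-air enthalpy (H). They weight temperature, humidity, air
velocity and radiation very differently, so they can disagree about whether a
barn is comfortable. `sowtherm` implements all twelve indices (with the
empirical dew-point, wet-bulb and black-globe conversions they consume and
their published heat-stress threshold zones) and the four analyses used to
compare them, for engineers and researchers choosing an index for sow-barn
environmental control:

1. **Equivalent temperature change** — hold an index constant under a humidity
   shift, `I(T₁, RH₁) = I(T₂, RH₂)`, solve for `T₂` by bisection, and report
   `T_equ = T₁ − T₂`: the warming a humidity rise is "worth" according to that
   index. A physiologically sensible index gives `T_equ > 0`; THI6 gives
   negative values because its humidity term decreases with RH above 14.4 °C.
2. **Air-velocity response** — sweep ET and ETIS over v ∈ [0, 4] m/s at fixed
   T/RH and find where warm-season curves cross the still-air winter baseline
   (10 °C, 60 % RH): ET(25 °C) equals its winter value at ≈0.45 m/s, which no
   pig would agree with; warm ETIS curves (25–35 °C) never reach theirs.
3. **Iso-index lines** — trace the locus `I(T, RH) = I(22 °C, 70 %)` across
   the psychrometric plane. The enthalpy, THI8 and BGHI lines climb past
   37 °C in dry air; the ETIS line stays within ≈1.8 °C of the anchor.
4. **Barn surrogate + correlation** — a seeded 1-D zonal energy-balance model
   of a ventilated 10-sow barn (7.15 × 3 × 3 m, inlet 30 °C / 60 % RH, outlet
   1 m/s, sow skin 38 °C) yields per-sow local air states and convective heat
   dissipation `Q = h·A·(38 − T)`; regressing Q on each index ranks the
   velocity-aware ET and ETIS above every temperature–humidity-only index.

## Worked example

Evaluate every index in a warm, humid, nearly-still barn corner:

```
$ sowtherm index --temp 30 --rh 60 --vel 0.2 --classify
THI1    80.0895 unclassified
THI2    79.76   moderate
THI3    27.8509 unclassified
THI4    79.84
THI5    79.379  unclassified
THI6    76.76   mild
THI7    26.59
THI8    74.3807
BGHI    79.9597
ET      30.45
ETIS    34.8631 moderate
H       61.9156
```

THI2 and ETIS both call this *moderate* heat stress (THI2 = 79.76 sits in its
78–82 band; ETIS = 34.86 °C in its 34.5–35.9 °C band), while THI6 — whose
humidity term points the wrong way — reads only *mild*. Indices without a
published threshold table print no zone. The velocity-response diagnostic:

```
$ sowtherm velocity-scan --id ET --temp 25 --rh 60 --find-crossing winter -o curve.csv
winter reference 21.2119; crossing: 0.45024
```

i.e. at 25 °C a draught of 0.45 m/s already drags ET down to its winter
(10 °C) value — the over-aggressive wind-chill term that makes ET unreliable
for ventilation control. Other subcommands: `convert`, `batch`, `equiv-temp`,
`isoline`, `barn-sim`, `correlate`, and `reproduce` (which regenerates every
comparison table plus a `checks.json` of self-validation assertions).

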