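# Methods

## The measurement being modelled

A variable-aperture collimator forms an approximately circular photon field
whose diameter d (5–60 mm, specified at SAD 800 mm) must be verified
periodically against the manufacturer's ±0.2 mm reproducibility
specification. A large-area parallel-plate chamber (sensitive diameter
81.6 mm) mounted at SAD 791 mm intercepts the entire field, so its reading
is a dose-area product

    DAP(d) = OF(d) · ∫₀^rmax OCR(r, d) · 2πr dr ,

the radial integral of the off-center ratio OCR over the chamber area,
weighted by the output factor OF. QA monitors the quotient
θ(d) = DAP_Iris(d)/DAP_Fixed(60 mm) — the fixed 60 mm reference cone
cancels output and daily factors — and its percentage deviation
δ(d) = (θ/θ_baseline − 1)·100 from a commissioning baseline. Readings are
used uncorrected (no temperature-pressure, polarity or recombination
corrections): all such factors cancel in θ.

## Beam model

The profile is radially symmetric: a flat core with an erfc-shaped
penumbra,

    OCR(r) ∝ ½ erfc((r − R) k / p) ,

normalized to 1 on the central axis, where R is the projected field radius
(R = d/2 · 791/800) and p the 80–20 penumbra width (k = 2·erfinv(0.6)
makes p carry exactly that meaning). The central-axis normalization
matters for the smallest fields: at d = 5 mm the default 3 mm penumbra
reaches the axis, so the unnormalized sigmoid would give OCR(0) < 1. A
consequence worth knowing is that the field-edge value is exactly 0.5 only
when the penumbra is well separated from the axis (d ≳ 15 mm at p = 3 mm),
and that DAP is measurably *sub-quadratic* in d at 5–10 mm — a −0.2 mm
aperture error at 5 mm changes DAP by about −4.5%, not the −7.84% of pure
area scaling. Tests of parameter recovery therefore compare against the
forward model's own DAP ratio, with the area-scaling value asserted as a
proxy only at 60 mm where it is accurate to < 0.05%.

Parameters, defaults, and why:

| parameter | default | meaning |
|---|---|---|
| `penumbra_mm` | 3.0 | 80–20 fall-off width at the chamber plane; plausible for a 6 MV FFF-type beam. `0` degenerates to an ideal step profile used for closed-form checks. |
| `flatness` | 0.0 | optional mild quadratic "horn" of the core, `1 + f·(r/R)²`. |
| `detune_level` | 0.0 | multiplicative shoulder depression: the region 0.5R–0.9R loses `4·level` percent (cosine tapers to 0.4R and R), emulating the worst clinically tolerated mistuning; level 1 ≈ 4% shoulder loss. |
| chamber | r_max 40.8 mm, SAD 791 mm | geometry of the large-area chamber. |

The real profile and output factors are clinic-specific commissioning data
that are not published; the model is a parametric stand-in and everything
derived from its *shape* (absolute misalignment sensitivities, the exact
small-field limit values) is model-dependent. Quantities that depend only
on the method's arithmetic — conversions, area-scaling limits, error
propagation, all the δ statistics — are independent of it.

### Output factors

`OutputFactorTable` interpolates OF linearly between the 12 tabulated
diameters. Within a ±0.2 mm slack beyond the endpoints the table
extrapolates **flat** (clamped) by default; farther outside is an error.
The default table is synthetic: a monotone saturating curve from 0.68 at
5 mm to 0.951 at 60 mm, normalized to the fixed 60 mm reference cone
(OF = 1), so the ideal-model θ(60) ≈ 0.951 matches the scale of measured
quotients. An optional `extrapolation="linear"` mode continues the endmost
segment's slope; because the small-field OF gradient is steep, this
widens the negative calculated limit at 5 mm beyond the pure-area value —
the mechanism behind the strongly asymmetric published small-field limits —
at the cost of extrapolating below the smallest measured aperture.
Clamping was kept as the default because it is the conservative choice
when nothing is known below the table.

## DAP integration

Aligned chambers use adaptive Gauss–Kronrod quadrature of the 1-D radial
integral (relative tolerance 1e-10, breakpoints at the field edge,
detuning window edges and penumbra extent). For a chamber offset by s, the
2-D integral of the radial OCR over the offset disk is reduced *exactly*
to one dimension: a circle of radius u about the beam axis lies inside the
chamber along an arc of angle

    α(u) = 2π                   for u ≤ rmax − s,
    α(u) = 2 arccos((u² + s² − rmax²)/(2us))   in the partial band,
    α(u) = 0                    for u ≥ rmax + s,

so DAP = OF · ∫ OCR(u) α(u) u du (tolerance 1e-9, breakpoints additionally
at rmax ∓ s). This is deterministic, fast, and agrees with the aligned
integral identically at s = 0. Step profiles bypass quadrature entirely
(disk and lens areas in closed form). The test suite verifies both routes
against independent brute-force oracles: a 1e5-point midpoint rule for the
radial integral and a chamber-centered 2-D midpoint grid (2000×2000) for
offsets, at 1e-6 and 1e-4 relative respectively.

Quadrature failure (error estimate above tolerance) raises a diagnostic
`IntegrationError` rather than returning a silently degraded value.

## Tolerance limits

The ±0.2 mm specification is converted to δ limits two ways:

* **calculated** — DAP at d ± 0.2 mm over DAP at d, with the field radius
  rescaled at the nominal plane and projected (penumbra width unchanged)
  and OF′ interpolated at the perturbed diameter. The fixed-reference
  denominator of θ is unperturbed and cancels. With an ideal step profile
  and flat OF this reduces to ((d ± 0.2)²/d² − 1)·100 — ±0.67% at 60 mm,
  +1.34/−1.33% at 30 mm.
* **measured-style** — θ means from sessions acquired with the aperture
  deliberately set to d ± 0.2, put through the same δ formula against
  baseline.

A δ exactly on a limit counts as a **pass**: the specification is stated
inclusively. Apertures are judged independently with no multiplicity
correction — these are engineering tolerances, not hypothesis tests.

## The percent↔mm ruler

δ↔mm conversion assumes pure area scaling, DAP ∝ d²:
Δd = d(√(1 + δ/100) − 1) and its exact inverse ((d + Δd)²/d² − 1)·100.
It deliberately excludes OF variation and penumbra effects: it is the
*reporting ruler* that makes deviations comparable across apertures, and
it reproduces every published conversion (3.63% at 5 mm → 0.090 mm;
−0.82% at 20 mm → −0.082 mm; 0.63% at 60 mm → 0.189 mm; 0.2% at 5 mm →
0.005 mm; 0.1 mm at 7.5 mm → 2.7%). Note that 0.1 mm at 60 mm is exactly
0.334%, sometimes quoted rounded as 0.34%. Under this quadratic rule the
0.2% combined error corresponds to 0.060 mm at 60 mm (not 0.012 mm, a
figure sometimes quoted that is inconsistent with the quadratic
conversion; the quadratic rule is implemented).

## Error budget

Independent components (output drift, MU-delivery uncertainty,
misalignment allowance, chamber term) combine as a root-sum-square, which
is permutation-invariant, at least the largest component, and at most the
plain sum. The characterized working point (0.04, 0.04, 0.10)% combines to
0.115%; a conservative **0.2% envelope** is carried alongside because the
published working value exceeds the strict quadrature of its stated
components and the combination rule behind it is not documented — the
package reports both and asserts neither as the other.

Misalignment deviations are evaluated per collimator (misaligned over
aligned DAP): a chamber shift in a given setup applies equally to the
reference cone, so it would cancel in θ; only the DAP-level ratio exhibits
the published size-dependence (a 10 mm shift clips the 60 mm field's
penumbra at the chamber edge, small fields are untouched; at 2 mm shifts
all fields are essentially unaffected).

## Synthetic sessions

`simulate_session` emulates the acquisition protocol (n_repeats = 5
exposures of 100 MU per aperture, 12 iris apertures plus the fixed 60 mm
reference). Per exposure: the true iris diameter is nominal + systematic
offset + N(0, 0.02 mm) jitter (fixed cones get no size jitter); the
reading is the forward-model DAP at the true diameter (OF interpolated
there, chamber offset by the configured misalignment), scaled to nC so the
fixed reference reads ≈143.4 nC, times (1 + output drift)(1 + MU noise)
with both drawn N(0, 0.04%). All draws are independent normals — the
long-term data characterize only SDs, not correlation structure — and the
jitter distribution is an assumption (only an upper bound ≈0.05 mm is
characterized). Randomness is split per session via `SeedSequence.spawn`,
so a fixed seed is bit-reproducible and sessions are independent;
`calibration_drift_mm_per_session` optionally grows a linear systematic
offset across a series. The generator clamps its OF query into the
table's supported range (endpoint ± 0.2 mm) so jitter at the extreme
apertures cannot step over the interpolation slack.

What passing tests on synthetic data do and do not show: they validate the
statistics, limit derivations, noise propagation and the QA decision logic
end-to-end; they cannot validate the clinic-specific profile shape, OF
values, detector response or any correlated drift structure of a real
machine.

## Characterization fits

DAP vs d is fitted as b·dᶜ in log-log space (scale-free weighting across
the ~120× dynamic range; raw nonlinear least squares is available as an
option and weights the large apertures instead). θ vs aperture area uses
the through-origin slope Σxy/Σx². On the three published DAP means the
log-log exponent is 1.942, consistent with the published 12-point value
1.935 ± 0.004; on the ideal model the exponent is exactly 2.

## Problem sizes and runtime

Defaults used by the test suite: long-term series of 31 sessions × 13
apertures × 5 repeats (the scale of a two-year monthly program), 60
exposures for the output-drift recovery, 2000×2000 brute-force oracle
grids. The full suite runs in well under two minutes on one core.

## Known limitations

* The beam profile and OF table are parametric stand-ins; absolute
  misalignment percentages and small-field limit values are
  model-dependent (the published measured values cannot be reproduced
  without the clinic's beam data, only their structural patterns).
* The aperture is treated as circular; the 12-sided shape, head scatter
  and leaf geometry are not modelled.
* No radiation transport: the chamber is an ideal area integrator of the
  profile.
* Control-chart rule systems beyond the linear trend statistic are out of
  scope.
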