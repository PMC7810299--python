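# Methods

## Model and assumptions

The specimen is treated as a linear-elastic Euler–Bernoulli cantilever with
a solid circular cross-section, fixed at the ground (height 0) and free at
the top (height `H`). A horizontal load distribution `f(h)` with a single
azimuth `D` produces, at gauge height `h₀`, the bending moment

    M(h₀) = Σᵢ mᵢ (hᵢ − h₀)   over point loads (hᵢ, mᵢ) with hᵢ > h₀,

the point-load discretisation of `∫ (h − h₀) f(h) dh`. Dense point sets
represent continuous profiles; the simulator's `moment_at` is checked
against numerical integration of a continuous profile in the test suite.

Assumptions the estimates inherit:

- **No load below `h_t`.** The moment-difference identities for F and C are
  exact only when `f(h) = 0` beneath the upper gauges — reasonable when the
  gauges sit low on the trunk and the crown carries the load. The simulator
  accepts scenarios that violate this; the estimator still runs, and the
  discrepancy shows up as estimation error rather than an exception.
- **Small deflections.** Strain is proportional to moment (`ε = M/(EZ)` at
  the extreme fiber); at large strains (≳1000 με on real stems) linearity
  and the neglect of self-weight both break down.
- **Solid circular section**: `Z = π d³/32`, with distinct diameters
  allowed at the two gauge heights to accommodate taper (equal diameters
  are the untapered special case).
- **Single load azimuth per sample.** The direction estimates at the two
  heights, `D_t` and `D_b`, are reported separately and never merged; for a
  single-azimuth load they agree, and their divergence is a useful
  diagnostic for violated assumptions.

## Sign and angle conventions

Strain is tension-positive, so a gauge facing the load (`θ_g = D`) is on
the compressed side and reads negative: the working model is
`ε = −|M| cos(D − θ_g)/(EZ)`. Calibrating with the unsigned cosine would
flip every `θ_g` by 180°; a unit test pins the signed form. All azimuths
are stored in `[0, 360)`; angular errors take the shorter arc (wrapped to
`[0, 180]`), since circumferential loading makes seam-crossing differences
routine. Units at the API boundary are με, GPa, m, N and degrees; the
conversion to coherent SI (`×1e-6`, `×1e9`) happens in exactly two internal
helpers, so no caller ever mixes scales.

## Calibration

Each pull of known force, height and azimuth applies a known moment
`|M| = F·(pull height − gauge height)` at a gauge. The normalised response
`y = εZ/|M| = −(1/E)cos(D − θ_g)` is linear in `(a, b)` after
`y = a cos D + b sin D`, with `a = −cos θ_g/E`, `b = −sin θ_g/E`; ordinary
least squares solves this class exactly, with no initialisation or
convergence concerns, hence no nonlinear optimiser. Then `E = 1/√(a²+b²)`
and `θ_g = atan2(−b, −a)`. The test suite cross-checks the solution against
a brute-force grid minimiser of the nonlinear sum of squares.

Identifiability requires ≥ 3 pulls whose directions are not all congruent
modulo 180° (a rank-2 design); an all-zero response leaves `E` undefined.
Both are hard errors naming the gauge (and replicate, when batch
calibrating). `R²` is computed as `1 − SS_res/SS_tot` about the mean of
`y`. Across replicates, `E` is averaged arithmetically and `θ_g` via the
circular (resultant-vector) mean, which survives the 0°/360° seam.
Baseline (pre-load) subtraction of the strain channels is assumed to happen
upstream in the logger.

## Estimation

Per sample: (1) `D_t` from `(td1, td2)` and `D_b` from `(bd1, bd2)` via the
arctangent of the response ratio; (2) the moment at each height by least
squares over its two gauges, `M̂ = Σ yᵢcᵢ/Σ cᵢ²` with `yᵢ = εᵢEᵢZᵢ` and
`cᵢ = −cos(D − θ_g,i)`, computed with that height's own direction estimate;
(3) `F` and `C` from the moment difference.

Numerical choices:

- **Quadrant resolution.** The arctangent cannot tell `D` from `D + 180°`.
  Of the two candidates, the one whose predicted strain signs match the
  observed signs is kept, trusting first the gauge farther from its neutral
  axis (larger `|cᵢ|`), where the sign is most reliable.
- **Two-gauge moment.** The least-squares combination is optimal under
  i.i.d. strain noise and reduces smoothly to single-gauge inversion when
  the other gauge sits on its neutral axis. A conditioning floor
  `|cᵢ| ≥ 1e-6` drops near-node gauges; if both fall below it the sample is
  flagged ill-conditioned.
- **Per-sample operation.** No smoothing or filtering is applied to time
  series; loggers sample fast (0.1 s) and filtering choices belong to the
  caller. Samples that fail partially (all-zero quartet ⇒ `F = 0` but `C`,
  `D` undefined; one quiet height ⇒ moment known to be zero, direction not)
  produce NaN fields plus a flag instead of aborting the series.
- **Moment signs.** `M̂ < 0` means the direction estimate points the wrong
  way for that height; the sign is folded into `D` (+180°) so reported
  moments are magnitudes.

The degraded parameter assignments — `right_angle` (pin `θ_d2 = θ_d1+90°`),
`common_E` (all E replaced by the four-gauge mean), and their combination —
are implemented as calibration transforms, so the estimator itself is
identical across modes. They exist as baselines: on a misaligned,
heterogeneous specimen the full calibration strictly reduces the errors,
and the suite asserts that ordering (the *magnitude* of the degradation is
specimen-dependent, so only the ordering is asserted).

## What the simulator does and does not emulate

The generator reproduces the two bench validation experiments:

- **Distributed load**: eleven weight patterns on five stations at 0.095,
  0.194, 0.294, 0.393 and 0.493 m above the upper gauges (weights 0.20 to
  0.98 N, totals 0.98 to 2.85 N), on a 0.01 m pole with gauges 0.2 m apart.
  The rig was a horizontal cantilever with vertical weights, so the load
  azimuth is fixed and these fixtures do not exercise direction estimation.
- **Circumferential pulls**: 8 azimuths every 45° × forces (0.5, 1.0, 1.5,
  2.0 N) × 3 replicates at a configurable pull height, optionally with
  per-trial direction jitter to mimic approximate placement (the jittered
  azimuth is the recorded truth).
- The default misaligned layout (`TABLE2_WOOD_POLE_LAYOUT`) carries the
  parameter magnitudes found on a calibrated pole: apparent E of 10.5–11.2
  GPa varying gauge to gauge, and d1–d2 angles about 10° off a right angle.

Noise is additive i.i.d. Gaussian on the strain channels with an explicit
seed — a deliberately minimal stand-in for instrument and material noise.
Real data additionally contain drift, temperature effects, wood
viscoelasticity, dynamic (inertial) response and spatially correlated
material heterogeneity, none of which are modelled. Passing the synthetic
suites therefore demonstrates the *inversion mathematics* (exactness at
zero noise, graceful degradation with noise, the value of per-gauge
calibration) — not robustness to every artefact of field records.

Problem sizes in the test and acceptance runs (1000 randomized scenarios
for the exact-inversion sweep, 200 replicates per noise level for the
calibration bias check, 96-trial pulling protocols) were chosen as the
smallest sets that make the statistical assertions stable across seeds.

## Known limitations

- Centroid precision collapses as `M_b → M_t` (near-zero net force): the
  estimator flags the sample rather than reporting a wild `C`.
- `E` absorbs the gauge factor and local wood properties; it is an
  *apparent* modulus tied to one gauge's bond, valid only with that gauge's
  own `θ_g`. Self-weight during calibration biases apparent E slightly low
  on vertical stems and is not corrected.
- No hollow or non-circular sections, no bark/wood composite mechanics,
  no large-deflection geometry.
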