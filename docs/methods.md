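# Methods

## Model overview

The package simulates a projector–camera feedback system in which an RGB
light-dot matrix backlights a Petri plate and a camera observes the result.
The chain is collapsed into a linear radiometric model

    image(p) = clip( round( g · L(p) · T(p, t) + noise ) ),   L = W u,

where `u` is the per-texel action vector (each in [0, 765]), `W` a sparse
pixel×texel weight matrix describing the point-spread of the texels, `T` the
per-pixel scene transmittance in [0, 1], and `g` the gain in grey levels per
control unit. Display nonlinearity, integration time and sensor response are
not modelled separately: the controller only requires a monotone plant, and
a single linear gain is the simplest model consistent with negligible plant
dynamics. The default gain `g = 48/445` is *unit-normalized*: the nominal
uniform action 445 on a transparent plate renders exactly the reference
background 48, anchoring the simulated plant to the method's documented
operating point.

### Point-spread modes

* `gaussian` (diffuser mounted): truncated (3σ) Gaussian weights,
  normalized per pixel so the weights over texels form a partition of
  unity. A uniform pattern therefore renders perfectly flat, rendering is
  exactly linear in `u`, and the response to a single-texel impulse is
  position-independent away from borders. Default σ = 1.0 texel pitch: the
  smallest width that removes dead zones while keeping neighbour coupling
  local.
* `none` (bare display): each texel directly lights a 6×5-px box footprint;
  the gaps between footprints form the dark reticule of control dead zones.
  A faint halation skirt (amplitude 0.12 of the core, σ = 3 px) extends
  outside the footprint, so a texel railed to maximum perturbs nearby
  pixels — the mechanism behind the calibration-error instability — while
  the dead zones remain dark.

### Scene

The default plate is 132 px in radius on a 280×280 image over a 68×68 texel
grid at 4-px pitch, i.e. ~66 texels across the plate. This ratio matters:
the wall-refraction ring occupies 6 % of the plate area, which at this
scale is a ~4-px annulus spanning about one texel pitch, as in a physical
rig. (At coarser grids the ring becomes a sub-pitch feature that per-texel
control fundamentally cannot compensate without disturbing neighbours, and
the residual halo dominates the background statistics.) The ring is purely
absorptive (transmittance ×0.10); mirror-like wall reflections are not
modelled. Worms are constant-width tubes (width 3 px, length 22 px) along
random smooth curves placed in the central lawn region, with transmittance
0.02 — opacity and scale are what matter to the controller, not shape
realism. The media field is a band-limited Gaussian random field (mean
0.848, peak amplitude 0.05, correlation length 36 px); an optional radial
vignette `1 − s·(r/R)^p` models the optical-path falloff that makes wall
zones dimmer under uniform light (off by default; the spatial-variability
scene uses s = 0.25, p = 2, giving an uncontrolled field spanning ~17 grey
levels).

### Temporal processes

* **Media drift**: transmittance is multiplied by 0.98911 per imaged day,
  calibrated so the uncontrolled white-backlight mean declines from ~70 to
  ~55 grey levels across a 33-calendar-day assay imaged daily except
  weekends (~23 imaging days).
* **Condensation**: a smooth occlusion field `C ∈ [0, 0.30]` acts as
  `T ← T · (1 − C)^{s(t)}` with `s` growing linearly to 2.0 over the 2-hour
  analogue, producing a frozen-pattern mean drop of 10–18 grey levels.
* **Camera noise**: Gaussian σ = 0.25 grey levels plus ±2-level spikes at
  rate 0.005 per pixel per frame. Display refresh is not modelled.

## Controller

Per texel, with error `e_k = ref − y_k` sensed at the texel's single lookup
pixel, the tied-gain law `u_k = k_p e_k + u_{k−1}` (k_p = 0.9) is applied
and clamped to [0, 765]; the clamp doubles as integrator anti-windup. A
general incremental PID form is available for untied gains. Actions are
held as floats and quantized only at the RGB encoding, avoiding limit
cycles at actuator resolution. Texels whose projection falls off-image are
driven at the nominal action and excluded from the mean error.

The mean error `E_k` is the *signed* mean over sampled texels, exactly as
the summary statistic is defined (an absolute-value variant exists behind a
flag, default off; a spatially balanced error field could in principle
cancel). The fix event fires at the first `k ≥ 10` with
`S = Σ|E_k − E_{k−1}| ≤ 5` over the last 10 instants; it cannot fire
earlier because S is undefined on a shorter history. Recompensation
triggers when the background mean error reaches −3 grey levels (one-sided:
brightening never triggers), and the new series starts from the frozen
pattern — the per-texel integral continues rather than resetting.

With the unit-normalized gain the scalar loop factor is
`1 − k_p·g·T ≈ 0.90`, giving a settling time (|E| ≤ 1) of ~3.7 s from the
zero pattern — well inside the 15-s requirement — and fix events typically
at the earliest admissible instant when a run starts near the operating
point.

### Known behavioural consequences of the stopping rule

Two documented behaviours follow from the S ≤ 5 rule and the small loop
gain; both are properties of the method as printed, not implementation
artifacts:

1. The rule watches the *flatness* of the error trace, not its size. A loop
   whose dead-zone texels have railed to 765 settles to a flat, large E and
   still fires the event. The no-diffuser calibration-error scenario is
   therefore diagnosed by its settled residual error (≈ 9 grey levels vs
   ≈ 0 with the diffuser), not by the event failing to fire: with this gain
   every trajectory settles, since a sustained S > 5 would require a limit
   cycle with a per-step overshoot the actuator gain cannot produce.
2. A series starting near the operating point (initial |E| ≈ 3, e.g. a
   recompensation triggered at −3) fires at k = 10 with residual
   `E₀(1 − k_p g T)^{10} ≈ 1.3` grey levels, so recompensation restores the
   mean to ≈ 46.6 rather than exactly 48. Across consecutive daily runs the
   carried-over pattern shrinks this residual geometrically, which is why
   multi-day means converge to ~47.7.

## Evaluation

The Fisher index uses population variances and the sum-of-variances
denominator `|μ+ − μ−| / (σ+² + σ−²)`. Class samples come from the
generator's ground-truth masks (background = in-plate, excluding wall ring
and worms). Segmentation is fixed-threshold (default 24 = ref/2, strictly
below), 8-connected, with components under 20 px discarded; morphological
post-processing is available but off by default.

## Problem sizes and determinism

Default experiment sizes — 280×280 px, 68×68 texels, 21 assay days, 2-hour
condensation analogue sampled every 120 s, 500-iteration instability runs —
complete in seconds on one CPU. Every stochastic path takes an explicit
seed; the same configuration and seed reproduce traces bit-identically.

## What the synthetic plant does and does not show

The plant preserves the properties the controller relies on (monotone,
approximately linear response; a calibrated but imperfect texel→pixel map;
opaque and semi-opaque scene structure; slow multiplicative drifts) and the
printed operating-point anchors. It omits refraction ray tracing, wall
mirror reflections, E. coli lawn texture, worm locomotion, display
radiometric nonlinearity and wavelength-dependent dispersion. Passing tests
therefore demonstrate the control, calibration and evaluation logic under
realistic geometry and disturbance magnitudes — not photometric fidelity to
any particular physical rig; absolute quantities that depend on real optics
(e.g. Fisher-index magnitudes, absolute times-to-fix) should be read as
directional.
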