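# activelight

Closed-loop **active backlight** simulation for *C. elegans* Petri-plate
imaging.

Lifespan and healthspan machines image worms as dark silhouettes against a
bright transilluminated background. In practice that background is anything
but constant: the growth medium (NGM) becomes more opaque over assay days,
condensation forms on the lid, the light source ages, and the plate wall
refracts light away from the camera. Fixed segmentation thresholds then
fail, and image-processing patches only partially recover the lost signal.

The alternative simulated here is to fix the *image* rather than the
segmentation: drive every dot (texel) of an RGB illumination matrix with
its own feedback regulator so that each background pixel converges to a
target grey level. This package implements the full method — geometric
calibration, per-texel control with a wavelength-cascade encoding, the
pattern-freezing and recompensation logic, and segmentation-quality
evaluation — against a synthetic optical plant, so the whole loop runs and
can be tested without hardware.

## The method

**Calibration.** A 3×3 homography ${}^pH_t$ maps texel coordinates to
camera pixels, estimated by normalized DLT from sub-pixel centroids of an
asymmetric circle grid; a rounded lookup table gives each texel its one
feedback pixel.

**Control.** Each texel carries a scalar action $u \in [0, 765]$ (the sum
of its 8-bit R, G, B intensities). With error $e_k = \mathrm{ref} - y_k$
and the integral gain tied to the proportional gain ($k_i = k_p$,
$k_d = 0$) the regulator reduces to the incremental law

$$u_k = k_p\,e_k + u_{k-1}, \qquad k_p = 0.9,\ \mathrm{ref} = 48,\ T_{sa} = 0.11\,\mathrm{s},$$

clamped to the actuator range. The scalar action is emitted as an RGB
triple through a **wavelength cascade**: red fills first to 255, then
green, then blue — blue light, the most stressful to worms, is used only as
a last resort. The nominal operating point is $u = 445$, i.e. 58 % of full
scale, encoded (255, 190, 0).

**Fix event.** The mean image error $E_k$ is tracked; when the windowed sum
$S = \sum_{k-10}^{k} |\dot E_k|$ falls to $\le 5$ the pattern is frozen.
If the image later darkens by 3 grey levels (condensation), a new control
series runs from the frozen pattern — **recompensation**.

**Evaluation.** Worm/background separability is scored with the Fisher
index $F = |\mu_+ - \mu_-| \,/\, (\sigma_+^2 + \sigma_-^2)$ and by
fixed-threshold connected-component segmentation against the generator's
ground-truth worm masks.

**Synthetic plant.** A sparse pixel×texel weight matrix (box footprints
with dead zones, or a Gaussian diffuser) models the optics; a transmittance
field models the plate: smooth media opacity, an absorptive wall ring
(~6 % of plate area), near-opaque worms, daily opacity drift, a growing
condensation field and camera noise. The default gain is *unit-normalized*:
uniform action 445 on a transparent plate renders background 48 exactly.

## Worked example

```bash
python examples/04_temporal_assay.py
```

```
day  uncontrolled  compensated (mean +/- std)   mean u
  0        69.3        45.2 +/- 1.84      574
  4        66.4        47.5 +/- 0.80      608
  8        63.5        47.6 +/- 0.63      625
 12        60.8        47.6 +/- 0.58      643
 16        58.2        47.5 +/- 0.55      662
 20        55.7        47.5 +/- 0.55      682

uncontrolled drift over 21 days: 13.6 grey levels
largest per-day compensated std: 1.84 grey levels
control signal rose 574 -> 682 to counter the opacity increase
```

Under a fixed white backlight the background mean drifts from ~70 toward
~55 grey levels as the medium clouds; with daily recompensation the
background stays pinned near the reference with a standard deviation under
2 grey levels, at the cost of a steadily rising light command. The other
examples cover calibration accuracy (`01`), a single control run (`02`),
the Fisher-index comparison (`03`, compensated beats uncontrolled ~5×),
condensation recompensation (`05`) and the diffuser/dead-zone instability
dichotomy (`06`).

A thin CLI wraps the same functionality:

```bash
activelight demo --seed 0
activelight run-loop --seed 0 --out-dir out/
activelight simulate-assay --scenario temporal_media --seed 1 --out-dir out/
```

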