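"""Synthetic optical plant: Petri plate, diffuser and camera simulation.

Stands in for the physical rig: given a per-texel illumination pattern it
renders the 8-bit greyscale image the camera would capture.  The optical
chain is modelled as

    image(p) = clip(round( g * L(p) * T(p, t) + noise ))

where ``L(p) = sum_t w_t(p) u_t`` spreads the texel actions onto pixels
through a point-spread weight matrix, ``T`` is the scene transmittance
(media field x wall ring x worms x condensation, all in [0, 1]) and ``g`` is
the plant gain in grey levels per control unit.  The default gain 48/445 is
*unit-normalized*: the nominal uniform action 445 on a fully transparent
plate yields the reference background level 48.

Two PSF modes are provided:

``none``
    Each texel illuminates only a 6x5-px box footprint centred on its
    projection; the gaps between footprints receive no light, producing the
    dark reticule (and the control dead zones) seen without a diffuser.
``gaussian``
    Gaussian weights normalized per pixel (a partition of unity over
    texels), so a uniform pattern produces a perfectly uniform field.

Temporal disturbances: a multiplicative day-by-day media-opacity drift, a
smoothly growing condensation occlusion field, and camera noise (Gaussian
plus rare 2-level spikes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage, sparse

from .calibration import TexelPixelMap, build_lookup, project_points

WORM_TRANSMITTANCE = 0.02


class ConfigError(ValueError):
    """Raised for non-physical scene configurations."""


@dataclass(frozen=True)
class DiffuserPSF:
    """Point-spread configuration of the light matrix as seen by the camera.

    ``footprint`` is the (width, height) in pixels of the directly lit box
    per texel when no diffuser is mounted; ``sigma_pitches`` the Gaussian
    width in texel pitches when one is.
    """

    mode: Literal["none", "gaussian"] = "gaussian"
    sigma_pitches: float = 1.0
    footprint: tuple[int, int] = (6, 5)  # (x extent, y extent), px
    # halation skirt of a bare texel: faint light outside the direct
    # footprint (wavelength dispersion / display glow); the dead zones stay
    # dark but are not perfectly black, which is what lets a railed texel
    # perturb a neighbour's lookup pixel
    tail_amplitude: float = 0.12
    tail_sigma_px: float = 3.0


@dataclass(frozen=True)
class TemporalProcesses:
    """Disturbance processes acting on the scene over time.

    media_drift_per_day
        Multiplicative factor applied to the media transmittance each imaged
        day; the default follows an uncontrolled white-backlight mean
        decline from ~70 to ~55 grey levels across a 33-calendar-day assay
        imaged once per day except weekends (~23 imaging days).
    condensation_cmax, condensation_exponent_rate
        The condensation occlusion multiplies transmittance by
        ``(1 - C)**s(t)`` with ``C`` a smooth field in [0, c_max] and
        ``s(t) = rate * t`` growing linearly in elapsed seconds.
    noise_sigma, spike_rate, spike_amplitude
        Camera noise: zero-mean Gaussian (grey levels) plus spikes of the
        given amplitude occurring independently per pixel per frame.
    """

    media_drift_per_day: float = (55.0 / 70.0) ** (1.0 / 22.0)
    condensation_cmax: float = 0.30
    condensation_exponent_rate: float = 2.0 / 7200.0  # s=2 after the 2-h analogue
    noise_sigma: float = 0.25
    spike_rate: float = 0.005
    spike_amplitude: float = 2.0


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic plate scene."""

    image_shape: tuple[int, int] = (280, 280)  # (rows, cols) px
    grid_shape: tuple[int, int] = (68, 68)  # texels
    texel_pitch: float = 4.0  # px per texel at the true homography
    grid_offset: tuple[float, float] = (6.0, 6.0)  # (x, y) px of texel (0,0)
    plate_center: tuple[float, float] = (140.0, 140.0)  # (x, y) px
    plate_radius: float = 132.0
    wall_ring_fraction: float = 0.06  # of plate area
    wall_ring_transmittance: float = 0.10
    media_mean: float = 0.848  # base transmittance level
    media_amplitude: float = 0.05  # peak spatial deviation
    media_corr_px: float = 36.0  # smoothing length of the media field
    n_worms: int = 5
    worm_length_px: float = 22.0
    worm_width_px: float = 3.0
    # radial optical-path falloff: less of the light entering near the plate
    # wall reaches the camera, so zones near the wall need more light than
    # the centre; transmittance is multiplied by 1 - strength*(r/R)^power
    vignette_strength: float = 0.0
    vignette_power: float = 2.0
    gain: float = 48.0 / 445.0  # grey levels per control unit ("unit-normalized")
    diffuser: DiffuserPSF = field(default_factory=DiffuserPSF)
    temporal: TemporalProcesses = field(default_factory=TemporalProcesses)
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigError("plant gain must be positive")
        if not 0 <= self.wall_ring_fraction <= 0.2:
            raise ConfigError("wall ring fraction must be in [0, 0.2]")
        if not 0 < self.media_mean <= 1 or self.media_amplitude < 0:
            raise ConfigError("media transmittance parameters non-physical")
        if self.media_mean + self.media_amplitude > 1.0 + 1e-9:
            raise ConfigError("media transmittance would exceed 1")

    def true_homography(self) -> np.ndarray:
        """The rendering (ground-truth) texel -> pixel map: scale + offset."""
        ox, oy = self.grid_offset
        return np.array(
            [[self.texel_pitch, 0.0, ox], [0.0, self.texel_pitch, oy], [0.0, 0.0, 1.0]]
        )


def coarse_scene_config(**overrides) -> SceneConfig:
    """Coarse-pitch scene matching the printed no-diffuser texel footprint.

    Texel pitch 8 px with 6x5-px direct footprints leaves 2-3-px dead zones
    between texels, the regime in which calibration errors of a couple of
    pixels destabilize the loop.  Used by the instability scenario; pass
    ``diffuser=DiffuserPSF(mode="gaussian")`` for the diffuser arm.

    No plate is mounted (uniform transmittance 1), matching how the fixing
    and dead-zone behaviour was characterised.
    """
    base = dict(
        image_shape=(128, 128),
        grid_shape=(14, 14),
        texel_pitch=8.0,
        grid_offset=(12.0, 12.0),
        plate_center=(64.0, 64.0),
        plate_radius=120.0,  # covers the full frame: no wall in view
        wall_ring_fraction=0.0,
        media_mean=1.0,
        media_amplitude=0.0,
        media_corr_px=24.0,
        n_worms=0,
        diffuser=DiffuserPSF(mode="none"),
    )
    base.update(overrides)
    return SceneConfig(**base)


def spatial_scene_config(**overrides) -> SceneConfig:
    """Scene with pronounced uncontrolled spatial variability.

    Adds the radial optical-path vignette seen under a standard uniform
    backlight (centre bright, wall zones dim by ~17 grey levels), the
    condition under which compensated illumination shows its largest
    segmentation-quality advantage.
    """
    base = dict(vignette_strength=0.25, vignette_power=2.0)
    base.update(overrides)
    return SceneConfig(**base)


def _smooth_field(shape: tuple[int, int], corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited random field, zero mean, unit peak amplitude."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, corr_px / 2.0, mode="reflect")
    peak = np.abs(sm).max()
    return sm / peak if peak > 0 else sm


def _worm_mask(
    cfg: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of worm pixels: constant-width tubes along smooth curves.

    Worms are placed inside the lawn region (central disc, clear of the wall
    ring) to mirror plates where the E. coli lawn sits in the middle.
    """
    h, w = cfg.image_shape
    mask = np.zeros((h, w), dtype=bool)
    cx, cy = cfg.plate_center
    r_in = cfg.plate_radius * np.sqrt(1.0 - cfg.wall_ring_fraction)
    lawn_r = 0.8 * r_in
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_worms):
        for _attempt in range(50):
            ang = rng.uniform(0, 2 * np.pi)
            rad = lawn_r * np.sqrt(rng.uniform(0, 0.8))
            x0, y0 = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            heading = rng.uniform(0, 2 * np.pi)
            n_seg = 8
            step = cfg.worm_length_px / n_seg
            pts = [(x0, y0)]
            ok = True
            for _ in range(n_seg):
                heading += rng.normal(0, 0.45)
                x0, y0 = x0 + step * np.cos(heading), y0 + step * np.sin(heading)
                if (x0 - cx) ** 2 + (y0 - cy) ** 2 > lawn_r**2:
                    ok = False
                    break
                pts.append((x0, y0))
            if ok:
                break
        half_w = cfg.worm_width_px / 2.0
        for (xa, ya), (xb, yb) in zip(pts[:-1], pts[1:]):
            # distance from pixel centers to the segment
            dx, dy = xb - xa, yb - ya
            L2 = dx * dx + dy * dy
            t = np.clip(((xx - xa) * dx + (yy - ya) * dy) / max(L2, 1e-12), 0, 1)
            d2 = (xx - (xa + t * dx)) ** 2 + (yy - (ya + t * dy)) ** 2
            mask |= d2 <= half_w**2
    return mask


def _weight_matrix(cfg: SceneConfig) -> sparse.csr_matrix:
    """Sparse pixel x texel illumination weight matrix W.

    ``L = (W @ u.ravel()).reshape(image)``.  Gaussian weights are truncated
    at 3 sigma and normalized per pixel (a partition of unity wherever the
    grid covers the pixel), so a uniform pattern renders perfectly flat.
    Box ("none") weights are 1 inside each texel's footprint, 0 elsewhere.
    """
    h, w = cfg.image_shape
    rows, cols = cfg.grid_shape
    H = cfg.true_homography()
    rr, cc = np.mgrid[0:rows, 0:cols]
    centers = project_points(
        H, np.column_stack([cc.ravel().astype(float), rr.ravel().astype(float)])
    )  # (n_tex, 2) as (x, y)
    if cfg.diffuser.mode == "gaussian":
        sig = cfg.diffuser.sigma_pitches * cfg.texel_pitch
        reach = 3.0 * sig
    elif cfg.diffuser.mode == "none":
        fx, fy = cfg.diffuser.footprint
        reach = max(fx, fy) / 2.0
        if cfg.diffuser.tail_amplitude > 0:
            reach = max(reach, 3.0 * cfg.diffuser.tail_sigma_px)
    else:  # pragma: no cover
        raise ConfigError(f"unknown diffuser mode {cfg.diffuser.mode!r}")
    data, pix_idx, tex_idx = [], [], []
    for t, (px, py) in enumerate(centers):
        x0, x1 = max(0, int(np.floor(px - reach))), min(w - 1, int(np.ceil(px + reach)))
        y0, y1 = max(0, int(np.floor(py - reach))), min(h - 1, int(np.ceil(py + reach)))
        if x0 > x1 or y0 > y1:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        dx = xs[None, :] - px
        dy = ys[:, None] - py
        if cfg.diffuser.mode == "gaussian":
            wts = np.exp(-(dx**2 + dy**2) / (2.0 * sig**2))
        else:
            wts = ((np.abs(dx) <= fx / 2.0) & (np.abs(dy) <= fy / 2.0)).astype(float)
            ta, ts = cfg.diffuser.tail_amplitude, cfg.diffuser.tail_sigma_px
            if ta > 0:
                wts = np.maximum(
                    wts, ta * np.exp(-(dx**2 + dy**2) / (2.0 * ts**2))
                )
        keep = wts > 1e-6
        yy_i, xx_i = np.nonzero(keep)
        data.append(wts[keep])
        pix_idx.append((ys[yy_i] * w + xs[xx_i]))
        tex_idx.append(np.full(keep.sum(), t))
    Wm = sparse.csr_matrix(
        (
            np.concatenate(data),
            (np.concatenate(pix_idx), np.concatenate(tex_idx)),
        ),
        shape=(h * w, rows * cols),
        dtype=np.float32,
    )
    if cfg.diffuser.mode == "gaussian":
        norm = np.asarray(Wm.sum(axis=1)).ravel()
        inv = np.where(norm > 1e-12, 1.0 / norm, 0.0)
        Wm = sparse.diags(inv.astype(np.float32)) @ Wm
    return Wm.tocsr()


@dataclass
class PlantState:
    """Instantiated scene: weight matrix, transmittance layers, clocks."""

    config: SceneConfig
    weights: np.ndarray = field(repr=False)
    media: np.ndarray = field(repr=False)  # base media transmittance x vignette
    plate_mask: np.ndarray = field(repr=False)
    wall_ring_mask: np.ndarray = field(repr=False)
    worm_mask: np.ndarray = field(repr=False)
    condensation_field: np.ndarray = field(repr=False)  # C in [0, c_max]
    day: int = 0
    condensation_s: float = 0.0  # current exponent s(t)
    drift_factor: float = 1.0
    _corrupted_map: TexelPixelMap | None = field(default=None, repr=False)
    _rng: np.random.Generator = field(default=None, repr=False)  # type: ignore

    # -- scene queries ------------------------------------------------------

    @property
    def background_mask(self) -> np.ndarray:
        """In-plate background: inside the plate, outside wall ring and worms."""
        return self.plate_mask & ~self.wall_ring_mask & ~self.worm_mask

    def transmittance(self) -> np.ndarray:
        """Current per-pixel transmittance in [0, 1]."""
        t = self.media * self.drift_factor
        t = np.clip(t, 0.0, 1.0)
        t = np.where(self.wall_ring_mask, t * self.config.wall_ring_transmittance, t)
        t = np.where(self.worm_mask, WORM_TRANSMITTANCE, t)
        t = np.where(self.plate_mask, t, 0.0)
        if self.condensation_s > 0:
            t = t * (1.0 - self.condensation_field) ** self.condensation_s
        return np.clip(t, 0.0, 1.0)

    def texel_map(self) -> TexelPixelMap:
        """Ground-truth texel -> pixel lookup map from the true homography."""
        return build_lookup(
            self.config.true_homography(), self.config.grid_shape, self.config.image_shape
        )

    # -- rendering ----------------------------------------------------------

    def render(self, pattern: np.ndarray | float, *, noise: bool | None = None) -> np.ndarray:
        """Render the 8-bit camera image produced by an action pattern."""
        cfg = self.config
        rows, cols = cfg.grid_shape
        u = np.asarray(pattern, dtype=float)
        if u.ndim == 0:
            u = np.full((rows, cols), float(u))
        if u.shape != (rows, cols):
            raise ConfigError(
                f"pattern shape {u.shape} does not match grid {cfg.grid_shape}"
            )
        L = (self.weights @ u.ravel().astype(np.float32)).reshape(cfg.image_shape)
        img = cfg.gain * L * self.transmittance()
        use_noise = cfg.noise if noise is None else noise
        if use_noise:
            tp = cfg.temporal
            img = img + self._rng.normal(0.0, tp.noise_sigma, img.shape)
            if tp.spike_rate > 0:
                spikes = self._rng.random(img.shape) < tp.spike_rate
                signs = self._rng.choice([-1.0, 1.0], size=img.shape)
                img = img + spikes * signs * tp.spike_amplitude
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    def renderer(self, **kw):
        """Bound render callable for :func:`activelight.control.run_control_loop`."""
        return lambda pattern: self.render(pattern, **kw)


def make_scene(config: SceneConfig) -> PlantState:
    """Instantiate a deterministic scene from its configuration and seed."""
    h, w = config.image_shape
    rng = np.random.default_rng(config.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = config.plate_center
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    plate = r2 <= config.plate_radius**2
    r_in = config.plate_radius * np.sqrt(1.0 - config.wall_ring_fraction)
    wall = plate & (r2 > r_in**2)
    media = config.media_mean + config.media_amplitude * _smooth_field(
        (h, w), config.media_corr_px, rng
    )
    if config.vignette_strength > 0:
        rad = np.sqrt(r2) / config.plate_radius
        media = media * (1.0 - config.vignette_strength * rad**config.vignette_power)
    media = np.clip(media, 0.0, 1.0)
    worms = _worm_mask(config, rng) if config.n_worms > 0 else np.zeros((h, w), bool)
    cond_raw = _smooth_field((h, w), config.media_corr_px, rng)
    cond = config.temporal.condensation_cmax * (cond_raw - cond_raw.min()) / max(
        np.ptp(cond_raw), 1e-12
    )
    return PlantState(
        config=config,
        weights=_weight_matrix(config),
        media=media,
        plate_mask=plate,
        wall_ring_mask=wall,
        worm_mask=worms,
        condensation_field=cond,
        _rng=rng,
    )


# ---------------------------------------------------------------------------
# Temporal evolution and fault injection


def advance_day(plant: PlantState, days: int = 1) -> PlantState:
    """Apply the daily media-opacity drift (multiplicative, clamped to [0,1])."""
    plant.day += days
    plant.drift_factor *= plant.config.temporal.media_drift_per_day**days
    return plant


def advance_condensation(plant: PlantState, elapsed_s: float) -> PlantState:
    """Grow the condensation occlusion by ``elapsed_s`` simulated seconds."""
    if elapsed_s < 0:
        raise ConfigError("elapsed time must be non-negative")
    plant.condensation_s += plant.config.temporal.condensation_exponent_rate * elapsed_s
    return plant


def calibration_error_injection(plant: PlantState, offset_px: float) -> PlantState:
    """Give the controller a corrupted homography while rendering stays true.

    The corruption is a smooth sinusoidal warp of amplitude ``offset_px`` in
    both axes composed with the true map, emulating local calibration errors
    of a few pixels that can push lookup pixels into dead zones or onto
    neighbouring texels' footprints.
    """
    if offset_px < 0:
        raise ConfigError("offset must be non-negative")
    if offset_px == 0:
        plant._corrupted_map = None
        return plant
    # the warp is not projective, so the corrupted lookup is built pointwise
    cfg = plant.config
    Htrue = cfg.true_homography()
    tmap = build_lookup(Htrue, cfg.grid_shape, cfg.image_shape)
    rows, cols = cfg.grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    # smooth displacement field whose magnitude averages offset_px (the
    # quoted calibration error is a mean over points; individual points err
    # further, which is what reaches the dead zones)
    mag = offset_px * (1.0 + 0.4 * np.sin(2.0 * np.pi * (1.3 * rr + 0.9 * cc) / max(rows, cols)))
    ang = 2.0 * np.pi * (0.7 * cc / max(cols - 1, 1) + 0.4 * rr / max(rows - 1, 1))
    dx = mag * np.cos(ang)
    dy = mag * np.sin(ang)
    warped = tmap.lookup.astype(float)
    warped[..., 0] += dx
    warped[..., 1] += dy
    lut = np.rint(warped).astype(int)
    h, w = cfg.image_shape
    unsampled = (
        (lut[..., 0] < 0) | (lut[..., 0] >= w) | (lut[..., 1] < 0) | (lut[..., 1] >= h)
    )
    plant._corrupted_map = TexelPixelMap(
        homography=Htrue,
        grid_shape=cfg.grid_shape,
        image_shape=cfg.image_shape,
        lookup=lut,
        unsampled=unsampled,
    )
    return plant


def controller_map(plant: PlantState) -> TexelPixelMap:
    """The texel->pixel map the controller actually uses for feedback."""
    return plant._corrupted_map if plant._corrupted_map is not None else plant.texel_map()
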