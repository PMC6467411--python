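"""Experiment runners reproducing the study's four scenario families.

Each runner instantiates a synthetic plate scene, drives the closed-loop
illumination controller against it, and returns a result object carrying the
measurements of interest (plus optional on-disk artifacts when an output
directory is supplied).

Scenarios
---------
spatial
    One scene imaged under (a) uncontrolled uniform light and (b) the
    converged compensated pattern; quality reports and fixed-threshold
    segmentations for both.
temporal_media
    A multi-day assay with daily media-opacity drift and a fresh
    compensation each day; per-day compensated/uncontrolled statistics.
condensation
    Compensate once, freeze the pattern, let condensation grow; each time
    the frozen pattern's mean error drops past the recompensation threshold
    a new control series is run.  The first frozen pattern is re-applied
    before each new fix to build the reference darkening series.
instability
    The same scene with a 2.5-px calibration error injected, run with and
    without the diffuser, reporting which loop reaches the fix event.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import control, metrics, plant
from .control import ControllerParams, run_control_loop
from .plant import DiffuserPSF, PlantState, SceneConfig, TemporalProcesses

WHITE_ACTION = 765.0


def _compensate(
    scene: PlantState,
    params: ControllerParams,
    *,
    initial_pattern=control.U_NOMINAL,
    max_iterations: int = 500,
    tmap=None,
):
    tmap = scene.texel_map() if tmap is None else tmap
    return run_control_loop(
        scene.renderer(),
        tmap,
        params,
        initial_pattern=initial_pattern,
        max_iterations=max_iterations,
    )


def _mean_error(scene: PlantState, pattern: np.ndarray, params: ControllerParams) -> float:
    """Signed background mean error (image - ref): negative when darker."""
    img = scene.render(pattern)
    return float(img[scene.background_mask].mean() - params.ref)


# ---------------------------------------------------------------------------


@dataclass
class SpatialResult:
    compensated_image: np.ndarray
    uncontrolled_image: np.ndarray
    compensated_report: metrics.QualityReport
    uncontrolled_report: metrics.QualityReport
    compensated_seg: metrics.SegmentationResult
    uncontrolled_seg: metrics.SegmentationResult
    k_m: int | None
    state: control.ControllerState


def run_spatial_experiment(
    scene_config: SceneConfig,
    params: ControllerParams | None = None,
    *,
    uncontrolled_action: float = WHITE_ACTION,
    seg_threshold: float = 24.0,
    seg_min_area: int = 20,
    out_dir: str | Path | None = None,
) -> SpatialResult:
    """Compare compensated vs uncontrolled illumination on one scene."""
    params = params or ControllerParams()
    scene = plant.make_scene(scene_config)
    state, _trace = _compensate(scene, params)
    comp = scene.render(state.actions)
    unc = scene.render(np.full(scene_config.grid_shape, uncontrolled_action))
    bg, worms = scene.background_mask, scene.worm_mask
    if worms.any():
        comp_report = metrics.quality_report(comp, bg, worms)
        unc_report = metrics.quality_report(unc, bg, worms)
    else:  # wormless scene: background statistics only, no Fisher score
        s_c, s_u = metrics.image_statistics(comp, bg), metrics.image_statistics(unc, bg)
        comp_report = metrics.QualityReport(
            fisher=float("nan"), background_mean=s_c.mean, background_std=s_c.std,
            worm_mean=float("nan"), worm_std=float("nan"), histogram=s_c.histogram,
        )
        unc_report = metrics.QualityReport(
            fisher=float("nan"), background_mean=s_u.mean, background_std=s_u.std,
            worm_mean=float("nan"), worm_std=float("nan"), histogram=s_u.histogram,
        )
    result = SpatialResult(
        compensated_image=comp,
        uncontrolled_image=unc,
        compensated_report=comp_report,
        uncontrolled_report=unc_report,
        compensated_seg=metrics.threshold_segment(
            comp, seg_threshold, seg_min_area, region=scene.plate_mask & ~scene.wall_ring_mask
        ),
        uncontrolled_seg=metrics.threshold_segment(
            unc, seg_threshold, seg_min_area, region=scene.plate_mask & ~scene.wall_ring_mask
        ),
        k_m=state.k_m,
        state=state,
    )
    if out_dir is not None:
        _write_spatial(Path(out_dir), scene, result, params)
    return result


# ---------------------------------------------------------------------------


@dataclass
class TemporalResult:
    """Per-day traces of a multi-day media-drift assay."""

    days: np.ndarray
    uncontrolled_mean: np.ndarray
    compensated_mean: np.ndarray
    compensated_std: np.ndarray
    mean_control_signal: np.ndarray
    k_m: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.days,
                "uncontrolled_mean": self.uncontrolled_mean,
                "compensated_mean": self.compensated_mean,
                "compensated_std": self.compensated_std,
                "mean_control_signal": self.mean_control_signal,
                "k_m": self.k_m,
            }
        )


def run_temporal_experiment(
    scene_config: SceneConfig,
    params: ControllerParams | None = None,
    *,
    days: int = 33,
    out_dir: str | Path | None = None,
) -> TemporalResult:
    """Multi-day assay: drift the media daily and recompensate from scratch."""
    if days < 1:
        raise ValueError("days must be >= 1")
    params = params or ControllerParams()
    scene = plant.make_scene(scene_config)
    tmap = scene.texel_map()
    rows = []
    prev_actions = None
    for day in range(days):
        if day > 0:
            plant.advance_day(scene)
        unc = scene.render(np.full(scene_config.grid_shape, WHITE_ACTION))
        init = control.U_NOMINAL if prev_actions is None else prev_actions
        state, _ = _compensate(scene, params, initial_pattern=init, tmap=tmap)
        prev_actions = state.actions
        comp = scene.render(state.actions)
        bg = scene.background_mask
        rows.append(
            (
                day,
                float(unc[bg].mean()),
                float(comp[bg].mean()),
                float(comp[bg].std()),
                float(state.actions[~tmap.unsampled].mean()),
                -1 if state.k_m is None else state.k_m,
            )
        )
    arr = np.array(rows, dtype=float)
    result = TemporalResult(
        days=arr[:, 0].astype(int),
        uncontrolled_mean=arr[:, 1],
        compensated_mean=arr[:, 2],
        compensated_std=arr[:, 3],
        mean_control_signal=arr[:, 4],
        k_m=arr[:, 5].astype(int),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(out / "temporal_trace.csv", index=False)
    return result


# ---------------------------------------------------------------------------


@dataclass
class CondensationResult:
    """Timeline of a condensation run with recompensation events."""

    times_s: np.ndarray  # sampling instants
    frozen_mean: np.ndarray  # image mean under the currently frozen pattern
    reference_mean: np.ndarray  # image mean under the FIRST frozen pattern
    recompensation_times: list[float]
    post_recomp_means: list[float]  # background mean right after each new fix

    @property
    def n_recompensations(self) -> int:
        return len(self.recompensation_times)


def run_condensation_experiment(
    scene_config: SceneConfig,
    params: ControllerParams | None = None,
    *,
    duration_s: float = 7200.0,
    check_interval_s: float = 120.0,
    out_dir: str | Path | None = None,
) -> CondensationResult:
    """Freeze a compensated pattern, grow condensation, recompensate on demand.

    Every ``check_interval_s`` the frozen pattern's background mean error is
    evaluated; when it reaches the recompensation threshold a fresh control
    series runs to a new fix event, and the image under the *first* frozen
    pattern is recorded immediately beforehand (the reference series that
    exposes the raw darkening).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    params = params or ControllerParams()
    scene = plant.make_scene(scene_config)
    tmap = scene.texel_map()
    state, _ = _compensate(scene, params, tmap=tmap)
    first_pattern = state.actions.copy()
    frozen = state.actions.copy()
    t = 0.0
    times, frozen_means, ref_means = [], [], []
    recomp_times: list[float] = []
    post_means: list[float] = []
    bg = scene.background_mask
    while t < duration_s:
        step = min(check_interval_s, duration_s - t)
        plant.advance_condensation(scene, step)
        t += step
        img_frozen = scene.render(frozen)
        img_ref = scene.render(first_pattern)
        times.append(t)
        frozen_means.append(float(img_frozen[bg].mean()))
        ref_means.append(float(img_ref[bg].mean()))
        mean_error = frozen_means[-1] - params.ref  # negative when darkened
        if control.recompensation_trigger(mean_error, params):
            # darkened past the threshold: run a new series from the frozen pattern
            state, _ = _compensate(scene, params, initial_pattern=frozen, tmap=tmap)
            frozen = state.actions.copy()
            recomp_times.append(t)
            post_means.append(float(scene.render(frozen)[bg].mean()))
    result = CondensationResult(
        times_s=np.asarray(times),
        frozen_mean=np.asarray(frozen_means),
        reference_mean=np.asarray(ref_means),
        recompensation_times=recomp_times,
        post_recomp_means=post_means,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            {
                "time_s": result.times_s,
                "frozen_mean": result.frozen_mean,
                "reference_mean": result.reference_mean,
            }
        ).to_csv(out / "condensation_trace.csv", index=False)
    return result


# ---------------------------------------------------------------------------


@dataclass
class InstabilityResult:
    """Outcome of the calibration-error runs with and without diffuser.

    Whether the fix event fired tells only part of the story: the stopping
    rule watches the *flatness* of the mean-error trace, so a loop whose
    dead-zone texels have railed to the actuator bound still 'fixes' — on a
    corrupted pattern.  ``residual_E`` (the settled |mean error| in grey
    levels) exposes the regulation failure itself.
    """

    no_diffuser_fixed: bool
    no_diffuser_iterations: int
    no_diffuser_residual_E: float
    diffuser_fixed: bool
    diffuser_k_m: int | None
    diffuser_residual_E: float


def run_instability_experiment(
    scene_config: SceneConfig | None = None,
    params: ControllerParams | None = None,
    *,
    error_px: float = 2.5,
    max_iterations: int = 500,
) -> InstabilityResult:
    """Calibration-error dichotomy: no-diffuser loop destabilizes, diffuser fixes.

    Defaults to the coarse-pitch scene whose 6x5-px footprints leave dead
    zones between texels (:func:`activelight.plant.coarse_scene_config`).
    """
    params = params or ControllerParams()
    scene_config = scene_config or plant.coarse_scene_config()
    outcomes = {}
    for mode in ("none", "gaussian"):
        cfg = dataclasses.replace(
            scene_config, diffuser=DiffuserPSF(mode=mode), noise=False
        )
        scene = plant.make_scene(cfg)
        plant.calibration_error_injection(scene, error_px)
        tmap = plant.controller_map(scene)
        # run past the first fix event so the settled residual is visible
        state, trace = run_control_loop(
            scene.renderer(), tmap, params, max_iterations=max_iterations,
            stop_on_fix=False,
        )
        outcomes[mode] = (state.fixed, state.k_m, len(trace.k), abs(trace.E[-1]))
    return InstabilityResult(
        no_diffuser_fixed=outcomes["none"][0],
        no_diffuser_iterations=outcomes["none"][2],
        no_diffuser_residual_E=float(outcomes["none"][3]),
        diffuser_fixed=outcomes["gaussian"][0],
        diffuser_k_m=outcomes["gaussian"][1],
        diffuser_residual_E=float(outcomes["gaussian"][3]),
    )


# ---------------------------------------------------------------------------
# Artifact writing


def _write_spatial(out: Path, scene: PlantState, result: SpatialResult, params) -> None:
    import imageio.v3 as iio

    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "compensated.png", result.compensated_image)
    iio.imwrite(out / "uncontrolled.png", result.uncontrolled_image)
    iio.imwrite(out / "worm_mask.png", (scene.worm_mask * 255).astype(np.uint8))
    iio.imwrite(
        out / "compensated_seg.png", (result.compensated_seg.mask * 255).astype(np.uint8)
    )
    pattern16 = np.rint(result.state.actions).astype(np.uint16)
    iio.imwrite(out / "pattern_scalar.png", pattern16)
    iio.imwrite(out / "pattern_rgb.png", control.encode_rgb(result.state.actions))
    summary = {
        "k_m": result.k_m,
        "time_to_fix_s": None if result.k_m is None else result.k_m * params.T_sa,
        "compensated": result.compensated_report.to_dict(),
        "uncontrolled": result.uncontrolled_report.to_dict(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
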