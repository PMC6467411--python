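"""Per-texel PID illumination regulator and the RGB wavelength cascade.

Each texel of the light matrix carries an independent scalar control action
``u`` in [0, 765] (the sum of the three 8-bit channel intensities).  The
regulator is an incremental PI controller with the integral gain tied to the
proportional gain, which collapses to

    e_k = ref - y_k
    u_k = k_p * e_k + u_{k-1}

per texel, where ``y_k`` is the grey level sensed at the texel's calibrated
lookup pixel.  Actions are held as floats internally and quantized only when
encoded to RGB, avoiding limit cycles at the actuator resolution.

The scalar action maps to an (R, G, B) triple through a wavelength cascade:
red fills first up to 255, then green, then blue — blue (closest to the
wavelengths that stress C. elegans) is used only as a last resort, above
u = 510.

A compensation run terminates with a *fix event*: the mean image error trace
E_k is monitored and the pattern frozen once the windowed sum of |dE/dk| over
the last ``fix_window`` instants falls to <= ``fix_threshold``.  A frozen
pattern is later *recompensated* (a fresh control series started from it)
when the mean error drops below ``recomp_threshold`` grey levels, e.g. when
lid condensation darkens the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

U_MAX = 765.0  # 255 R + 255 G + 255 B
U_NOMINAL = 445.0  # 58% of full scale: the (255, 190, 0) operating point


class CascadeError(ValueError):
    """Raised for actions outside [0, 765] or cascade-invalid RGB triples."""


@dataclass(frozen=True)
class ControllerParams:
    """Regulator and event-logic parameters.

    k_p
        Proportional gain (dimensionless); the paper strategy ties k_i = k_p
        and k_d = 0, giving the incremental form u_k = k_p e_k + u_{k-1}.
    ref
        Target background grey level (0-255).
    T_sa
        Sampling period in seconds; one control iteration per period.
    fix_window, fix_threshold
        The fix event fires at the first k >= fix_window with
        S = sum of |E_k - E_{k-1}| over the last fix_window instants
        <= fix_threshold.
    recomp_threshold
        Mean-error level (grey levels, signed; negative = image darker than
        the reference) at or below which a frozen pattern is recompensated.
    """

    k_p: float = 0.9
    k_i: float | None = None  # None -> tied to k_p (paper strategy)
    k_d: float = 0.0
    ref: float = 48.0
    T_sa: float = 0.11
    fix_window: int = 10
    fix_threshold: float = 5.0
    recomp_threshold: float = -3.0
    abs_mean_error: bool = False  # E_k from |e_i| instead of signed e_i

    def __post_init__(self) -> None:
        if self.k_p <= 0:
            raise ValueError("k_p must be > 0")
        if not 0 <= self.ref <= 255:
            raise ValueError("ref must be a grey level in [0, 255]")
        if self.T_sa <= 0 or self.fix_window < 1:
            raise ValueError("invalid sampling period or fix window")


# ---------------------------------------------------------------------------
# PID step


def pid_step(
    params: ControllerParams,
    e_k: np.ndarray | float,
    u_prev: np.ndarray | float,
    e_prev: np.ndarray | float = 0.0,
    e_prev2: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One regulator step per texel; vectorized over texel arrays.

    With the tied gains (k_i = k_p, k_d = 0) this is exactly
    ``u_k = k_p e_k + u_{k-1}`` clamped to [0, 765].  The general PID is
    supported in incremental form,

        u_k = u_{k-1} + k_p (e_k - e_{k-1}) + k_i e_k
                      + k_d (e_k - 2 e_{k-1} + e_{k-2}),

    which reduces to the positional proportional + summed-integral +
    first-difference-derivative law.  Clamping doubles as integrator
    anti-windup: the stored action never exceeds the actuator range, so the
    integral cannot accumulate while saturated.
    """
    e_k = np.asarray(e_k, dtype=float)
    u_prev = np.asarray(u_prev, dtype=float)
    k_i = params.k_p if params.k_i is None else params.k_i
    if k_i == params.k_p and params.k_d == 0.0:
        u = u_prev + params.k_p * e_k
    else:
        e_prev = np.asarray(e_prev, dtype=float)
        e_prev2 = np.asarray(e_prev2, dtype=float)
        u = (
            u_prev
            + params.k_p * (e_k - e_prev)
            + k_i * e_k
            + params.k_d * (e_k - 2 * e_prev + e_prev2)
        )
    return np.clip(u, 0.0, U_MAX)


# ---------------------------------------------------------------------------
# RGB cascade


def encode_rgb(u: np.ndarray | float) -> np.ndarray:
    """Encode scalar actions in [0, 765] as cascade (R, G, B) triples.

    Red fills first (0-255), then green (255-510), then blue (510-765);
    the channel sums reproduce round(u) exactly.
    Output shape is ``u.shape + (3,)``, dtype uint8 for valid input.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > U_MAX):
        raise CascadeError("control action outside [0, 765]")
    q = np.rint(u)
    r = np.minimum(q, 255)
    g = np.clip(q - 255, 0, 255)
    b = np.clip(q - 510, 0, 255)
    return np.stack([r, g, b], axis=-1).astype(np.uint8)


def decode_rgb(rgb: np.ndarray | tuple[int, int, int]) -> np.ndarray:
    """Invert the cascade: a valid triple decodes to u = r + g + b.

    Raises :class:`CascadeError` for triples violating the cascade invariant
    (green lit before red saturates, or blue before green saturates).
    """
    arr = np.asarray(rgb, dtype=int)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    if np.any((arr < 0) | (arr > 255)):
        raise CascadeError("channel outside [0, 255]")
    if np.any((g > 0) & (r != 255)) or np.any((b > 0) & (g != 255)):
        raise CascadeError("invalid cascade triple: channels must saturate in R, G, B order")
    out = (r + g + b).astype(float)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Error summary and events


@dataclass(frozen=True)
class ErrorSummary:
    """Mean image error at instant k, its increment, and the windowed sum S."""

    E: float
    Edot: float
    S: float
    k: int


def error_summary(
    errors: np.ndarray,
    e_trace: list[float],
    params: ControllerParams,
) -> ErrorSummary:
    """Summarize the per-texel error field at the current instant.

    ``errors`` are the sampled texels' signed errors; ``e_trace`` is the list
    of previous E values (E_0 .. E_{k-1}).  E_k is their signed mean (or mean
    of absolutes with ``abs_mean_error``); Edot_k = E_k - E_{k-1} (0 at k=0);
    S sums |Edot| over the last ``fix_window`` instants.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("no sampled texels: cannot summarize error")
    E = float(np.abs(errors).mean() if params.abs_mean_error else errors.mean())
    k = len(e_trace)
    full = e_trace + [E]
    diffs = np.abs(np.diff(full))
    S = float(diffs[-params.fix_window:].sum()) if len(diffs) else 0.0
    Edot = float(full[-1] - full[-2]) if k >= 1 else 0.0
    return ErrorSummary(E=E, Edot=Edot, S=S, k=k)


def fix_event(summary: ErrorSummary, params: ControllerParams) -> bool:
    """True when the mean-error trace has stabilised (S <= threshold).

    Cannot fire before ``fix_window`` instants of history exist.
    """
    if summary.k < params.fix_window:
        return False
    return summary.S <= params.fix_threshold


def recompensation_trigger(mean_error: float, params: ControllerParams) -> bool:
    """True when a frozen pattern's image has darkened past the threshold.

    One-sided: a *brighter* image does not trigger recompensation.
    """
    return mean_error <= params.recomp_threshold


# ---------------------------------------------------------------------------
# Closed loop


@dataclass
class ControllerState:
    """Controller memory after a compensation run."""

    actions: np.ndarray  # per-texel u, grid-shaped, float
    prev_errors: np.ndarray
    k: int
    e_trace: list[float] = field(default_factory=list)
    fixed: bool = False
    k_m: int | None = None  # iteration at which the fix event fired
    fixed_pattern: np.ndarray | None = None

    def time_to_fix(self, params: ControllerParams) -> float | None:
        """Seconds from loop start to the fix event (k_m * T_sa)."""
        return None if self.k_m is None else self.k_m * params.T_sa

    def snapshot_fixed(self, params: ControllerParams) -> None:
        self.fixed = True
        self.k_m = self.k
        self.fixed_pattern = self.actions.copy()


@dataclass(frozen=True)
class LoopTrace:
    """Per-iteration record of a control run: E, Edot, S, fired flag."""

    k: np.ndarray
    time_s: np.ndarray
    E: np.ndarray
    Edot: np.ndarray
    S: np.ndarray
    fired: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.k,
                "time_s": self.time_s,
                "E_k": self.E,
                "Edot_k": self.Edot,
                "S": self.S,
                "fired": self.fired,
            }
        )


def sample_image(image: np.ndarray, tmap) -> np.ndarray:
    """Sense y_k: one grey level per sampled texel at its lookup pixel."""
    look = tmap.lookup[~tmap.unsampled]
    return np.asarray(image, dtype=float)[look[:, 1], look[:, 0]]


def run_control_loop(
    render: Callable[[np.ndarray], np.ndarray],
    tmap,
    params: ControllerParams,
    *,
    initial_pattern: np.ndarray | float = U_NOMINAL,
    max_iterations: int = 500,
    stop_on_fix: bool = True,
) -> tuple[ControllerState, LoopTrace]:
    """Run the closed loop until the fix event fires or iterations run out.

    ``render`` maps a grid-shaped action pattern to an 8-bit camera image.
    Unsampled texels (projections off-image) are driven at the nominal action
    and excluded from the mean error.  Returns the controller state (with
    ``fixed``/``k_m`` set when the event fired) and the full trace.
    """
    grid = tmap.grid_shape
    sampled = ~tmap.unsampled
    u = np.full(grid, float(np.mean(initial_pattern)), dtype=float)
    if np.ndim(initial_pattern) == 2:
        u = np.asarray(initial_pattern, dtype=float).copy()
    u[~sampled] = U_NOMINAL
    state = ControllerState(
        actions=u, prev_errors=np.zeros(grid), k=0, e_trace=[]
    )
    rows = {k: [] for k in ("k", "time_s", "E", "Edot", "S", "fired")}
    for k in range(max_iterations):
        image = render(state.actions)
        y = sample_image(image, tmap)
        e = params.ref - y
        summ = error_summary(e, state.e_trace, params)
        fired = fix_event(summ, params)
        rows["k"].append(k)
        rows["time_s"].append(k * params.T_sa)
        rows["E"].append(summ.E)
        rows["Edot"].append(summ.Edot)
        rows["S"].append(summ.S)
        rows["fired"].append(fired)
        state.e_trace.append(summ.E)
        state.k = k
        if fired:
            if not state.fixed:
                state.snapshot_fixed(params)
            if stop_on_fix:
                break
        # update sampled texels only; off-image texels hold the nominal action
        e_grid = np.zeros(grid)
        e_grid[sampled] = e
        u_next = pid_step(params, e_grid, state.actions, state.prev_errors)
        u_next[~sampled] = U_NOMINAL
        state.prev_errors = e_grid
        state.actions = u_next
    trace = LoopTrace(
        k=np.array(rows["k"]),
        time_s=np.array(rows["time_s"]),
        E=np.array(rows["E"]),
        Edot=np.array(rows["Edot"]),
        S=np.array(rows["S"]),
        fired=np.array(rows["fired"]),
    )
    return state, trace
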