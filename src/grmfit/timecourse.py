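"""Nuclear-NFκB time courses and their conversion to model input.

The transcription models are driven by the measured (or synthetic) nuclear
NFκB signal.  Raw immunostaining time courses are turned into the model input
``NFkB(t)`` in four steps: subtract an assay background constant, convert to
fold change relative to t = 0, rescale the fold change to span the dynamic
range 2–100, and interpolate to a 1-second grid with monotone cubic (pchip)
interpolation.  Two rescaling rules exist because the second biological
replicate was systematically dimmer: replicate 1 is scaled jointly over both
conditions, replicate 2 is anchored to its own control range so that the
scaled control peaks at 100 even when the siIκBα condition reaches higher raw
values at late times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TimeCourse",
    "InputGrid",
    "subtract_basal",
    "fold_change",
    "rescale_joint",
    "rescale_anchored",
    "interpolate_seconds",
    "prepare_inputs",
]

#: conditions recognised throughout the package
CONDITIONS = ("ctrl", "siIkBa")

#: default simulation window, seconds.  The grid starts one maximal delay
#: (tau <= 7200 s) plus one steady-state hour before stimulation so that
#: delayed lookups never fall off-grid, and ends at 180 min.
T_START_S = -14400
T_END_S = 10800


@dataclass(frozen=True)
class TimeCourse:
    """A sampled signal: ordered (time, value) pairs tagged with condition/replicate.

    Parameters
    ----------
    times : ndarray
        Sampling times in minutes, strictly ascending, starting at 0.
    values : ndarray
        Signal values (nonnegative), same length as `times`.
    condition : str
        One of ``"ctrl"`` or ``"siIkBa"``.
    replicate : int
        Biological replicate index, 1 or 2.
    """

    times: np.ndarray
    values: np.ndarray
    condition: str = "ctrl"
    replicate: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and of equal length")
        if t.size < 2:
            raise ValueError("a TimeCourse needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.replicate not in (1, 2):
            raise ValueError("replicate must be 1 or 2")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def with_values(self, values: np.ndarray) -> "TimeCourse":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class InputGrid:
    """NFκB fold change on a 1-second grid over the simulation window.

    ``values[i]`` is the signal at ``t_start_s + i`` seconds.  For every
    t < 0 the grid holds the t = 0 value (pre-stimulus steady state), so
    delayed lookups before stimulation see a constant input.
    """

    t_start_s: int
    t_end_s: int
    values: np.ndarray
    scale_lo: float = 2.0
    scale_hi: float = 100.0
    condition: str = "ctrl"
    replicate: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != self.t_end_s - self.t_start_s + 1:
            raise ValueError("values length must equal t_end_s - t_start_s + 1")
        object.__setattr__(self, "values", v)

    @property
    def v0(self) -> float:
        """Value at t = 0 (also held for all t < 0)."""
        return float(self.values[-self.t_start_s])

    def value_at(self, t_s: float) -> float:
        """Grid value at time ``t_s`` seconds, rounded to the nearest grid point."""
        i = int(round(t_s)) - self.t_start_s
        if i < 0:
            raise ValueError(f"lookup at t={t_s}s precedes grid start {self.t_start_s}s")
        if i >= self.values.size:
            raise ValueError(f"lookup at t={t_s}s beyond grid end {self.t_end_s}s")
        return float(self.values[i])

    def post_stim(self) -> np.ndarray:
        """Values on t = 0..t_end_s (the non-constant part of the grid)."""
        return self.values[-self.t_start_s:]


def subtract_basal(tc: TimeCourse, basal: float) -> TimeCourse:
    """Subtract a constant assay background from every time point.

    `basal` must lie strictly below the series minimum, otherwise the
    fold-change step downstream would divide by a nonpositive number.
    """
    if basal >= float(np.min(tc.values)):
        raise ValueError(
            f"basal {basal} must be strictly below the series minimum {np.min(tc.values)}"
        )
    return tc.with_values(tc.values - basal)


def fold_change(tc: TimeCourse) -> TimeCourse:
    """Divide the series by its t = 0 value; the output starts at exactly 1."""
    if tc.times[0] != 0:
        raise ValueError("fold change requires a sample at t = 0")
    v0 = float(tc.values[0])
    if v0 <= 0:
        raise ValueError(f"value at t=0 must be positive, got {v0}")
    return tc.with_values(tc.values / v0)


def _affine(values: np.ndarray, vmin: float, vmax: float, lo: float, hi: float) -> np.ndarray:
    if vmax <= vmin:
        raise ValueError("cannot rescale a constant series (zero range)")
    if hi <= lo:
        raise ValueError(f"degenerate target range [{lo}, {hi}]")
    return lo + (hi - lo) * (values - vmin) / (vmax - vmin)


def rescale_joint(
    ctrl: TimeCourse, si: TimeCourse, lo: float = 2.0, hi: float = 100.0
) -> tuple[TimeCourse, TimeCourse]:
    """Rescale both conditions with ONE affine map from their pooled min/max.

    Used for replicate 1: the pooled minimum maps to `lo` and the pooled
    maximum to `hi` exactly.
    """
    pooled = np.concatenate([ctrl.values, si.values])
    vmin, vmax = float(pooled.min()), float(pooled.max())
    return (
        ctrl.with_values(_affine(ctrl.values, vmin, vmax, lo, hi)),
        si.with_values(_affine(si.values, vmin, vmax, lo, hi)),
    )


def rescale_anchored(
    ctrl: TimeCourse, si: TimeCourse, lo: float = 2.0, hi: float = 100.0
) -> tuple[TimeCourse, TimeCourse]:
    """Rescale both conditions with the affine map anchored to the CONTROL range.

    Used for replicate 2, whose siIκBα condition peaks at late times: anchoring
    to the control keeps the scaled control maximum (the first NFκB peak) at
    `hi`; the scaled siIκBα series may exceed `hi`.
    """
    vmin, vmax = float(ctrl.values.min()), float(ctrl.values.max())
    return (
        ctrl.with_values(_affine(ctrl.values, vmin, vmax, lo, hi)),
        si.with_values(_affine(si.values, vmin, vmax, lo, hi)),
    )


def interpolate_seconds(
    tc: TimeCourse,
    t_start_s: int = T_START_S,
    t_end_s: int = T_END_S,
    lo: float = 2.0,
    hi: float = 100.0,
) -> InputGrid:
    """Monotone cubic (pchip) interpolation of a scaled time course to 1-s resolution.

    Knot values are reproduced exactly and, pchip being monotonicity
    preserving, interpolated values never overshoot the adjacent knots.  For
    t < 0 the grid holds the t = 0 value.
    """
    if tc.times[0] != 0 or tc.times[-1] * 60 < 10800:
        raise ValueError("time course must cover 0-180 min")
    if t_start_s > -3600:
        raise ValueError("grid must start at or before -3600 s (steady-state window)")
    if t_end_s < 10800:
        raise ValueError("grid must extend to at least 10800 s")
    interp = PchipInterpolator(tc.times * 60.0, tc.values, extrapolate=False)
    t_post = np.arange(0, t_end_s + 1, dtype=float)
    post = interp(np.minimum(t_post, tc.times[-1] * 60.0))
    pre = np.full(-t_start_s, post[0])
    return InputGrid(
        t_start_s=t_start_s,
        t_end_s=t_end_s,
        values=np.concatenate([pre, post]),
        scale_lo=lo,
        scale_hi=hi,
        condition=tc.condition,
        replicate=tc.replicate,
    )


def prepare_inputs(
    timecourses: list[TimeCourse],
    basal: float = 0.0,
    lo: float = 2.0,
    hi: float = 100.0,
    t_start_s: int = T_START_S,
    t_end_s: int = T_END_S,
) -> dict[int, dict[str, InputGrid]]:
    """Full input preparation for both replicates.

    Dispatch rule: replicate 1 is rescaled jointly over both conditions,
    replicate 2 is anchored to its own control (see `rescale_joint` /
    `rescale_anchored`).  Returns ``{replicate: {condition: InputGrid}}``.
    """
    by_key = {(tc.replicate, tc.condition): tc for tc in timecourses}
    out: dict[int, dict[str, InputGrid]] = {}
    for rep in (1, 2):
        try:
            ctrl = by_key[(rep, "ctrl")]
            si = by_key[(rep, "siIkBa")]
        except KeyError as exc:
            raise ValueError(f"missing time course for replicate {rep}: {exc}") from exc
        if basal != 0.0:
            ctrl, si = subtract_basal(ctrl, basal), subtract_basal(si, basal)
        ctrl, si = fold_change(ctrl), fold_change(si)
        rescale = rescale_joint if rep == 1 else rescale_anchored
        ctrl, si = rescale(ctrl, si, lo=lo, hi=hi)
        out[rep] = {
            "ctrl": interpolate_seconds(ctrl, t_start_s, t_end_s, lo, hi),
            "siIkBa": interpolate_seconds(si, t_start_s, t_end_s, lo, hi),
        }
    return out
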