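"""Forward simulation of the four transcription models.

The models are driven by the scaled nuclear-NFκB fold change ``NFkB(t)``
(an :class:`~grmfit.timecourse.InputGrid`):

* **simple** — mRNA synthesized at a Hill occupancy of the delayed input,
  first-order decay.
* **iffl** — incoherent feedforward loop: NFκB also induces a competitor TF
  (p50) that competes for the target promoter; mRNA synthesis saturates in
  ``(K_D1 NFkB(t-τ))^h`` against ``(K_D2 TF(t-τ_TF))^h``.  Fold-change
  detection of the input.
* **cycle3** — three-state promoter cycle closed → open → active → closed;
  the state equations are driven by the *undelayed* input and mRNA synthesis
  is proportional to the delayed active fraction ``A(t-τ)``.
* **v4** — the cycle with the IFFL competitor acting on the active-state
  synthesis term; the state equations use the *delayed* input ``NFkB(t-τ)``.

The cycle3/v4 asymmetry in where the delay enters is part of the model
definitions and is reproduced as such.  Simulation starts one hour before
stimulation from the steady state under the constant pre-stimulus input, so
the steady-state drift penalty used in fitting is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..timecourse import InputGrid
from . import kernels
from .params import ParamSet

__all__ = [
    "SimResult",
    "hill",
    "delayed_value",
    "steady_state",
    "simulate",
    "sim_fold_change",
    "mfi",
    "auc",
]

#: simulation starts at -60 min (steady-state window) and ends at 180 min
SIM_START_S = -3600
SIM_END_S = 10800

#: default evaluation grid: the 13 sampling times 0, 15, ..., 180 min
DEFAULT_EVAL_TIMES_MIN = np.arange(0.0, 181.0, 15.0)


def hill(x: float, K: float, h: float) -> float:
    """Hill occupancy (Kx)^h / ((Kx)^h + 1), in [0, 1)."""
    if x < 0:
        raise ValueError(f"hill input must be nonnegative, got {x}")
    u = (K * x) ** h
    return u / (u + 1.0)


def delayed_value(grid: InputGrid, t_s: float, tau_s: float) -> float:
    """Input value at ``t - tau``; for ``t - tau < 0`` the t=0 value (hold rule)."""
    t_lag = t_s - tau_s
    if t_lag < grid.t_start_s:
        raise ValueError(
            f"delayed lookup at t-tau={t_lag}s precedes grid start {grid.t_start_s}s"
        )
    return grid.value_at(max(t_lag, 0.0))


@dataclass(frozen=True)
class SimResult:
    """Model output sampled at the evaluation times.

    ``states`` holds the (C, O, A) promoter fractions (cycle3/v4 only) and
    ``tf`` the competitor abundance (iffl/v4 only).  ``fold_change`` is
    mRNA(t)/mRNA(0); ``mfi``/``auc`` summarize it over 0–180 min.  ``m_pre``
    is the simulated expression at the start of the steady-state window
    (-60 min), used for the steady-state drift penalty.
    """

    model_name: str
    condition: str
    eval_times: np.ndarray  # minutes
    mrna: np.ndarray
    fold_change: np.ndarray
    mfi: float
    auc: float
    m_pre: float
    tf: np.ndarray | None = None
    states: np.ndarray | None = None  # shape (n, 3): C, O, A


def _tf_steady(p: dict, n0: float) -> float:
    return hill(n0, p["K_DTF"], p["h_TF"]) / p["k_degTF"]


def _cycle_steady(p: dict, n0: float) -> tuple[float, float, float]:
    """Equilibrium (C, O, A) of the promoter cycle under constant input n0.

    With a = k_1*occ_1(n0) and b = k_2*occ_2(n0), dA/dt = 0 gives
    O(A) = (k_m2*A + sat(A))/b and substituting into dO/dt = 0 leaves a
    single monotone equation in A, bracketed on [0, 1].
    """
    a = p["k_1"] * n0 * p["K_D1"] / (n0 * p["K_D1"] + 1.0)
    b = p["k_2"] * n0 * p["K_D2"] / (n0 * p["K_D2"] + 1.0)
    km1, km2, km3, kd3 = p["k_m1"], p["k_m2"], p["k_m3"], p["K_D3"]

    def o_of(A: float) -> float:
        return (km2 * A + km3 * kd3 * A / (kd3 * A + 1.0)) / b

    def f(A: float) -> float:
        O = o_of(A)
        return a * (1.0 - O - A) - (b + km1) * O + km2 * A

    if f(0.0) <= 0.0:  # no drive: fully closed promoter
        return 1.0, 0.0, 0.0
    A = brentq(f, 0.0, 1.0, xtol=1e-15, rtol=1e-15)
    O = o_of(A)
    return 1.0 - O - A, O, A


def steady_state(params: ParamSet, n0: float) -> dict[str, float]:
    """State variables at equilibrium under constant input ``n0``.

    Returns a dict with ``mrna`` and, per model, ``tf`` and/or ``C``/``O``/``A``.
    """
    if n0 <= 0:
        raise ValueError(f"steady state requires a positive input, got n0={n0}")
    p = params.resolved()
    model = params.model_name
    out: dict[str, float] = {}
    if model == "simple":
        drive = p["k_syn"] * hill(n0, p["K_D"], p["h"])
    elif model == "iffl":
        tf = _tf_steady(p, n0)
        num = (p["K_D1"] * n0) ** p["h"]
        comp = (p["K_D2"] * tf) ** p["h"]
        drive = p["k_syn"] * num / (num + comp + 1.0)
        out["tf"] = tf
    elif model == "cycle3":
        C, O, A = _cycle_steady(p, n0)
        drive = p["k_syn"] * A
        out.update(C=C, O=O, A=A)
    elif model == "v4":
        tf = _tf_steady(p, n0)
        C, O, A = _cycle_steady(p, n0)
        num = A ** p["h"]
        comp = (p["K_DTF2"] * tf) ** p["h"]
        drive = p["k_syn"] * num / (num + comp + 1.0)
        out.update(tf=tf, C=C, O=O, A=A)
    else:  # pragma: no cover - guarded by ParamSet
        raise ValueError(f"unknown model {model!r}")
    out["mrna"] = drive / p["k_deg"]
    return out


_ZEROS_CACHE: dict[int, np.ndarray] = {}


def _zeros(n: int) -> np.ndarray:
    arr = _ZEROS_CACHE.get(n)
    if arr is None:
        arr = np.zeros(n)
        _ZEROS_CACHE[n] = arr
    return arr


def simulate(
    params: ParamSet,
    grid: InputGrid,
    eval_times_min: np.ndarray | None = None,
    y0: dict[str, float] | None = None,
    full_output: bool = False,
    light: bool = False,
) -> SimResult:
    """Integrate one model over [-60, 180] min driven by an input grid.

    The initial condition defaults to the steady state under the constant
    pre-stimulus input (``y0`` overrides it, e.g. to realise a step-response
    experiment).  Delayed lookups are rounded to the nearest grid second.
    With ``full_output`` the per-second trajectories are attached instead of
    the eval-time samples for ``tf``/``states``; ``light`` skips the
    TF/state/MFI/AUC bookkeeping (used inside the optimizer's inner loop,
    which only consumes the fold change and the steady-state drift).
    """
    if eval_times_min is None:
        eval_times_min = DEFAULT_EVAL_TIMES_MIN
    eval_times_min = np.asarray(eval_times_min, dtype=float)
    if grid.t_start_s > SIM_START_S or grid.t_end_s < SIM_END_S:
        raise ValueError("input grid does not cover the simulation window")

    p = params.resolved()
    model = params.model_name
    n0 = grid.v0
    ss = steady_state(params, n0)
    if y0 is not None:
        ss = {**ss, **y0}

    # full per-second axis t = SIM_START_S .. SIM_END_S; idx(t) = t - SIM_START_S
    i_lo = SIM_START_S - grid.t_start_s
    N = grid.values[i_lo : grid.t_end_s - grid.t_start_s + 1]
    n = N.size
    i0 = -SIM_START_S  # index of t = 0
    tau_shift = int(round(p.get("tau", params.free["tau"])))
    tf_full = None
    states_full = None

    if model == "simple":
        Nd = kernels.shift_hold(N, tau_shift)
        drive = kernels.mrna_drive(Nd, p["K_D"], _zeros(n), 0.0, p["h"], p["k_syn"])
    elif model == "iffl":
        Nd = kernels.shift_hold(N, tau_shift)
        tf_drive = kernels.mrna_drive(Nd, p["K_DTF"], _zeros(n), 0.0, p["h_TF"], 1.0)
        tf_full = kernels.linear_scan(tf_drive, p["k_degTF"], ss["tf"])
        tfd = kernels.shift_hold(tf_full, int(round(p["tau_TF"])))
        drive = kernels.mrna_drive(Nd, p["K_D1"], tfd, p["K_D2"], p["h"], p["k_syn"])
    elif model in ("cycle3", "v4"):
        Ns = kernels.shift_hold(N, tau_shift) if model == "v4" else N
        # the input (and hence the state drive) is constant before stimulation
        # reaches the promoter; states sit at steady state until then
        i_var = i0 + tau_shift if model == "v4" else i0
        O = np.full(n, ss["O"])
        A = np.full(n, ss["A"])
        if i_var < n - 1:
            O[i_var:], A[i_var:] = kernels.states_scan(
                Ns[i_var:], p["K_D1"], p["K_D2"],
                p["k_1"], p["k_2"], p["k_m1"], p["k_m2"], p["k_m3"], p["K_D3"],
                ss["O"], ss["A"],
            )
        if not light:
            states_full = np.column_stack([1.0 - O - A, O, A])
        Ad = kernels.shift_hold(A, tau_shift)
        if model == "cycle3":
            drive = kernels.scale_drive(Ad, p["k_syn"])
        else:
            # the v4 competitor depends only on the input and fixed constants,
            # so its trajectory is cached on the grid across parameter draws
            cached = getattr(grid, "_v4_tf", None)
            if cached is None:
                tf_drive = kernels.mrna_drive(N, p["K_DTF"], _zeros(n), 0.0, p["h_TF"], 1.0)
                tf_full = kernels.linear_scan(tf_drive, p["k_degTF"], ss["tf"])
                object.__setattr__(grid, "_v4_tf", tf_full)
            else:
                tf_full = cached
            tfd = kernels.shift_hold(tf_full, int(round(p["tau_TF"])))
            drive = kernels.mrna_drive(Ad, 1.0, tfd, p["K_DTF2"], p["h"], p["k_syn"])
    else:  # pragma: no cover
        raise ValueError(f"unknown model {model!r}")

    m = kernels.linear_scan(drive, p["k_deg"], ss["mrna"])
    if not np.isfinite(m[-1]):
        raise FloatingPointError(f"simulation of {model} produced non-finite mRNA")
    if np.min(m) < -1e-9:
        raise FloatingPointError(f"simulation of {model} produced negative mRNA {np.min(m)}")

    idx = (np.round(eval_times_min * 60.0).astype(int) + i0).clip(0, n - 1)
    mrna = m[idx]
    m0 = m[i0]
    if m0 <= 0:
        raise FloatingPointError("mRNA at t=0 is nonpositive; fold change undefined")
    fc = mrna / m0
    if light:
        return SimResult(
            model_name=model,
            condition=grid.condition,
            eval_times=eval_times_min,
            mrna=mrna,
            fold_change=fc,
            mfi=np.nan,
            auc=np.nan,
            m_pre=float(m[0]),
        )
    in_window = eval_times_min <= 180.0
    return SimResult(
        model_name=model,
        condition=grid.condition,
        eval_times=eval_times_min,
        mrna=mrna,
        fold_change=fc,
        mfi=mfi(fc[in_window]),
        auc=auc(fc[in_window], eval_times_min[in_window]),
        m_pre=float(m[0]),
        tf=(tf_full if full_output else tf_full[idx]) if tf_full is not None else None,
        states=(states_full if full_output else states_full[idx])
        if states_full is not None
        else None,
    )


def sim_fold_change(res: SimResult) -> SimResult:
    """Return a copy of `res` with fold change recomputed from its mRNA series."""
    m0 = res.mrna[np.argmin(np.abs(res.eval_times))]
    if m0 <= 0:
        raise ValueError("mRNA at t=0 must be positive")
    fc = res.mrna / m0
    return SimResult(
        model_name=res.model_name,
        condition=res.condition,
        eval_times=res.eval_times,
        mrna=res.mrna,
        fold_change=fc,
        mfi=mfi(fc),
        auc=auc(fc, res.eval_times),
        m_pre=res.m_pre,
        tf=res.tf,
        states=res.states,
    )


def mfi(fc: np.ndarray) -> float:
    """Max-fold induction: the maximum of a fold-change series."""
    fc = np.asarray(fc, dtype=float)
    if fc.size == 0:
        raise ValueError("mfi of an empty series")
    return float(np.max(fc))


def auc(fc: np.ndarray, times_min: np.ndarray) -> float:
    """Area under the fold-change curve (trapezoid rule), in fold x minutes."""
    fc = np.asarray(fc, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if fc.size != times_min.size:
        raise ValueError("series and times must have equal length")
    return float(np.trapezoid(fc, times_min))
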