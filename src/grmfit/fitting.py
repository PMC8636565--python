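"""Objective function and two-step multistart parameter optimization.

For one gene, one model and one input replicate the protocol is:

1. draw ``n_starts`` initial parameter vectors inside the model's global
   bounds (log-uniform for rates and affinities, uniform for the delay) and
   locally minimize the control-condition objective from each;
2. keep the optimized sets whose control nRMSD clears 0.5 (escalating to 0.6
   then 0.7 when fewer than two survive), take the per-parameter min/max of
   the survivors as narrowed bounds;
3. draw ``n_starts`` fresh vectors inside the narrowed bounds and locally
   minimize the siIκBα-condition objective; every stage-2 record is finalized
   with the nRMSD of both conditions plus MFI/AUC summaries.

The objective simulates *both* conditions, max-normalizes the simulated and
the measured fold changes jointly over the two conditions (so the pair spans
[0, 1]), and returns the nRMSD of the target condition plus a steady-state
drift penalty |m̂(0) − m̂(−60 min)| on the same normalized scale.  A failed
simulation yields a large sentinel value so the derivative-free search can
continue.

The local optimizer is a bounded Nelder–Mead simplex run in a transformed
space (log10 for scale parameters, delay in kiloseconds) so all coordinates
are O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .models import ParamSet, simulate
from .models.params import MODEL_SPECS
from .timecourse import CONDITIONS, InputGrid

__all__ = [
    "FitConfig",
    "FitRecord",
    "max_normalize",
    "nrmsd",
    "objective",
    "sample_initial",
    "local_optimize",
    "stage1_fit",
    "derive_bounds",
    "stage2_fit",
    "TwoStepFit",
    "TwoStepFitResults",
]

#: objective value returned when a simulation fails (keeps the simplex alive)
SENTINEL = 1e6


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the two-step protocol.

    Defaults follow the full protocol (100 starts per stage, generous local
    budget); `desk()` returns the reduced configuration used for synthetic
    benchmark cohorts on a single CPU (20 starts, capped local search).
    """

    n_starts: int = 100
    #: candidate pool multiplier for importance-screened starts: each stage
    #: draws ``screen_factor * n_starts`` candidates, evaluates the objective
    #: once per candidate and launches local searches from the best
    #: ``n_starts`` (1 disables screening)
    screen_factor: int = 15
    maxfev: int = 2000
    #: stage-2 searches the narrowed bounds box and needs fewer evaluations;
    #: None means "same as maxfev"
    maxfev_stage2: int | None = None
    stage1_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7)
    xatol: float = 1e-4
    fatol: float = 1e-5

    @classmethod
    def desk(cls, n_starts: int = 20, maxfev: int = 250,
             maxfev_stage2: int = 120) -> "FitConfig":
        return cls(n_starts=n_starts, maxfev=maxfev, maxfev_stage2=maxfev_stage2)


@dataclass(frozen=True)
class FitRecord:
    """One optimized parameter set and its fit-quality summaries."""

    gene_id: str
    model_name: str
    replicate: int
    params: ParamSet
    objective_value: float
    n_evals: int
    seed: int
    nrmsd_ctrl: float = np.nan
    nrmsd_si: float = np.nan
    mfi_ctrl: float = np.nan
    mfi_si: float = np.nan
    auc_ctrl: float = np.nan
    auc_si: float = np.nan

    @property
    def nrmsd_total(self) -> float:
        return self.nrmsd_ctrl + self.nrmsd_si


def max_normalize(ctrl: np.ndarray, si: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jointly min-max normalize two series so their pooled range is [0, 1]."""
    ctrl = np.asarray(ctrl, dtype=float)
    si = np.asarray(si, dtype=float)
    lo = min(ctrl.min(), si.min())
    hi = max(ctrl.max(), si.max())
    if hi <= lo:
        raise ValueError("cannot max-normalize a constant pooled series")
    span = hi - lo
    return (ctrl - lo) / span, (si - lo) / span


def nrmsd(sim_norm: np.ndarray, data_norm: np.ndarray) -> float:
    """Root-mean-square deviation between two (max-normalized) series."""
    sim_norm = np.asarray(sim_norm, dtype=float)
    data_norm = np.asarray(data_norm, dtype=float)
    if sim_norm.shape != data_norm.shape:
        raise ValueError("series length mismatch")
    return float(np.sqrt(np.mean((sim_norm - data_norm) ** 2)))


def _normalized_data(data_fc: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    c, s = max_normalize(data_fc["ctrl"], data_fc["siIkBa"])
    return {"ctrl": c, "siIkBa": s}


def objective(
    free_values,
    model: str,
    grids: dict[str, InputGrid],
    data_fc: dict[str, np.ndarray],
    target_condition: str = "ctrl",
    eval_times_min: np.ndarray | None = None,
    _data_norm: dict[str, np.ndarray] | None = None,
) -> float:
    """Two-condition fit objective for one candidate parameter vector.

    nRMSD of the jointly max-normalized simulated vs measured fold change in
    `target_condition`, plus the steady-state drift of the simulated
    expression on the normalized scale.  Returns ``SENTINEL`` when the
    simulation fails or produces non-finite output.
    """
    if target_condition not in CONDITIONS:
        raise ValueError(f"unknown condition {target_condition!r}")
    data_norm = _data_norm if _data_norm is not None else _normalized_data(data_fc)
    try:
        # guard against float fuzz at the bound edges (10**log10(lo) < lo)
        spec = MODEL_SPECS[model]
        free_values = np.clip(
            np.asarray(free_values, dtype=float),
            [spec["bounds"][nm][0] for nm in spec["free"]],
            [spec["bounds"][nm][1] for nm in spec["free"]],
        )
        params = ParamSet.from_vector(model, free_values)
        res_c = simulate(params, grids["ctrl"], eval_times_min, light=True)
        res_s = simulate(params, grids["siIkBa"], eval_times_min, light=True)
        lo = min(res_c.fold_change.min(), res_s.fold_change.min())
        hi = max(res_c.fold_change.max(), res_s.fold_change.max())
        span = hi - lo
        if not np.isfinite(span) or span <= 0:
            return SENTINEL
        target = res_c if target_condition == "ctrl" else res_s
        sim_norm = (target.fold_change - lo) / span
        nr = nrmsd(sim_norm, data_norm[target_condition])
        # steady-state drift of the target-condition simulation, same scale
        m0 = target.mrna[int(np.argmin(np.abs(target.eval_times)))]
        penalty = abs(1.0 - target.m_pre / m0) / span
        value = nr + penalty
        return value if np.isfinite(value) else SENTINEL
    except (ValueError, FloatingPointError, ZeroDivisionError, OverflowError):
        return SENTINEL


# ---------------------------------------------------------------------------
# optimizer-space transform: log10 for scale parameters, kiloseconds for tau

def _to_opt(values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    return np.array(
        [v / 1000.0 if n == "tau" else np.log10(v) for n, v in zip(names, values)]
    )


def _from_opt(z: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    return np.array(
        [zi * 1000.0 if n == "tau" else 10.0 ** zi for n, zi in zip(names, z)]
    )


def sample_initial(
    bounds: dict[str, tuple[float, float]],
    n: int = 100,
    seed=0,
    names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Draw `n` initial free-value vectors inside `bounds`.

    Rates and affinities (everything except the delay) are drawn log-uniform —
    their bounds span up to six decades — and ``tau`` uniform.  Deterministic
    given `seed`.  Returns an (n, d) array in the order of `names` (default:
    the bounds-dict order).
    """
    if n < 1:
        raise ValueError("need at least one initial set")
    if names is None:
        names = tuple(bounds)
    rng = np.random.default_rng(seed)
    cols = []
    for name in names:
        lo, hi = bounds[name]
        if not lo < hi:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if name == "tau":
            cols.append(rng.uniform(lo, hi, size=n))
        else:
            cols.append(10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n))
    return np.column_stack(cols)


def local_optimize(fun, x0, bounds, maxfev: int = 2000, xatol: float = 1e-4,
                   fatol: float = 1e-5, method: str = "Powell"):
    """Bounded derivative-free local search.

    Powell's conjugate-direction line search is the default: on these
    multi-decade, partially flat landscapes it reaches the attracting basin
    from random starts markedly more often than a simplex at the same
    evaluation budget.  ``method="Nelder-Mead"`` selects the bounded simplex
    instead.  Returns ``(x*, f*, nfev)`` with ``f* <= f(x0)`` and ``x*``
    inside bounds.
    """
    x0 = np.asarray(x0, dtype=float)
    f0 = fun(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at the starting point")
    if method == "Powell":
        options = {"maxfev": maxfev, "xtol": xatol, "ftol": fatol}
    else:
        options = {"maxfev": maxfev, "xatol": xatol, "fatol": fatol,
                   "adaptive": len(x0) > 3}
    res = minimize(fun, x0, method=method, bounds=bounds, options=options)
    if res.fun <= f0:
        x = np.clip(np.asarray(res.x), [b[0] for b in bounds], [b[1] for b in bounds])
        return x, float(res.fun), int(res.nfev)
    return x0, float(f0), int(res.nfev)


def _finalize(
    record: FitRecord,
    grids: dict[str, InputGrid],
    data_norm: dict[str, np.ndarray],
    eval_times_min: np.ndarray | None,
) -> FitRecord:
    """Fill both condition nRMSDs and the MFI/AUC summaries from one simulation."""
    res_c = simulate(record.params, grids["ctrl"], eval_times_min)
    res_s = simulate(record.params, grids["siIkBa"], eval_times_min)
    lo = min(res_c.fold_change.min(), res_s.fold_change.min())
    hi = max(res_c.fold_change.max(), res_s.fold_change.max())
    span = hi - lo
    if span <= 0 or not np.isfinite(span):
        return replace(record, nrmsd_ctrl=np.inf, nrmsd_si=np.inf)
    return replace(
        record,
        nrmsd_ctrl=nrmsd((res_c.fold_change - lo) / span, data_norm["ctrl"]),
        nrmsd_si=nrmsd((res_s.fold_change - lo) / span, data_norm["siIkBa"]),
        mfi_ctrl=res_c.mfi,
        mfi_si=res_s.mfi,
        auc_ctrl=res_c.auc,
        auc_si=res_s.auc,
    )


def _multistart(
    gene_id: str,
    model: str,
    grids: dict[str, InputGrid],
    data_fc: dict[str, np.ndarray],
    bounds: dict[str, tuple[float, float]],
    target_condition: str,
    config: FitConfig,
    seed: int,
    eval_times_min: np.ndarray | None,
    replicate: int,
    maxfev: int | None = None,
    extra_starts: np.ndarray | None = None,
) -> list[FitRecord]:
    names = MODEL_SPECS[model]["free"]
    data_norm = _normalized_data(data_fc)
    n_cand = config.n_starts * max(config.screen_factor, 1)
    candidates = sample_initial(bounds, n_cand, seed, names)
    z_bounds = [
        tuple(sorted((_to_opt(np.array([lo]), (nm,))[0], _to_opt(np.array([hi]), (nm,))[0])))
        for nm, (lo, hi) in ((nm, bounds[nm]) for nm in names)
    ]

    def fun(z):
        return objective(
            _from_opt(z, names), model, grids, data_fc, target_condition,
            eval_times_min, _data_norm=data_norm,
        )

    lows = np.array([bounds[nm][0] for nm in names])
    highs = np.array([bounds[nm][1] for nm in names])
    n_own = config.n_starts
    extra_keep = np.empty((0, len(names)))
    if extra_starts is not None and len(extra_starts):
        # seed half the starts from the supplied vectors (e.g. the other
        # replicate's optimized sets), clipped into these bounds
        extras = np.clip(np.asarray(extra_starts, dtype=float), lows, highs)
        e_vals = np.array([fun(_to_opt(e, names)) for e in extras])
        n_extra = min(config.n_starts // 2, len(extras))
        extra_keep = extras[np.argsort(e_vals, kind="stable")[:n_extra]]
        n_own = config.n_starts - n_extra
    if n_cand > n_own:
        # importance screen: one objective evaluation per candidate, local
        # searches only from the most promising ones (stable argsort keeps
        # the draw order deterministic under ties)
        values = np.array([fun(_to_opt(c, names)) for c in candidates])
        keep = np.argsort(values, kind="stable")[:n_own]
        starts = candidates[keep]
    else:
        starts = candidates[:n_own]
    if len(extra_keep):
        starts = np.vstack([starts, extra_keep])

    records = []
    budget = maxfev if maxfev is not None else config.maxfev
    for x0 in starts:
        z_star, f_star, nfev = local_optimize(
            fun, _to_opt(x0, names), z_bounds, budget, config.xatol, config.fatol
        )
        values = np.clip(
            _from_opt(z_star, names),
            [bounds[nm][0] for nm in names],
            [bounds[nm][1] for nm in names],
        )
        rec = FitRecord(
            gene_id=gene_id,
            model_name=model,
            replicate=replicate,
            params=ParamSet.from_vector(model, values),
            objective_value=f_star,
            n_evals=nfev,
            seed=seed,
        )
        records.append(_finalize(rec, grids, data_norm, eval_times_min))
    return records


def stage1_fit(
    data_fc: dict[str, np.ndarray],
    model: str,
    grids: dict[str, InputGrid],
    config: FitConfig = FitConfig(),
    seed: int = 0,
    gene_id: str = "gene",
    replicate: int = 1,
    eval_times_min: np.ndarray | None = None,
) -> list[FitRecord]:
    """Stage 1: multistart optimization of the control-condition objective
    within the model's global bounds."""
    bounds = {nm: MODEL_SPECS[model]["bounds"][nm] for nm in MODEL_SPECS[model]["free"]}
    return _multistart(
        gene_id, model, grids, data_fc, bounds, "ctrl", config, seed,
        eval_times_min, replicate,
    )


def derive_bounds(
    records: list[FitRecord],
    thresholds: tuple[float, ...] = (0.5, 0.6, 0.7),
) -> dict[str, tuple[float, float]]:
    """Narrowed per-parameter bounds from the stage-1 survivors.

    Records are filtered by control nRMSD at the first threshold admitting at
    least two survivors (0.5, escalating to 0.6 then 0.7); if even the last
    threshold leaves fewer than two, the two best records are used so the
    min/max bounds stay non-degenerate.  Bounds are clipped to the model's
    global bounds; zero-width intervals are widened by a small epsilon.
    """
    if not records:
        raise ValueError("derive_bounds needs at least one stage-1 record")
    model = records[0].model_name
    survivors: list[FitRecord] = []
    for thr in thresholds:
        survivors = [r for r in records if r.nrmsd_ctrl < thr]
        if len(survivors) >= 2:
            break
    if len(survivors) < 2:
        survivors = sorted(records, key=lambda r: r.nrmsd_ctrl)[:2]
    spec = MODEL_SPECS[model]
    out: dict[str, tuple[float, float]] = {}
    for nm in spec["free"]:
        glo, ghi = spec["bounds"][nm]
        vals = [r.params.free[nm] for r in survivors]
        lo, hi = max(min(vals), glo), min(max(vals), ghi)
        if hi <= lo:  # all survivors coincide in this coordinate
            eps = 1.0 if nm == "tau" else abs(lo) * 1e-3
            lo, hi = max(lo - eps, glo), min(hi + eps, ghi)
        out[nm] = (lo, hi)
    return out


def stage2_fit(
    data_fc: dict[str, np.ndarray],
    model: str,
    grids: dict[str, InputGrid],
    stage2_bounds: dict[str, tuple[float, float]],
    config: FitConfig = FitConfig(),
    seed: int = 0,
    gene_id: str = "gene",
    replicate: int = 1,
    eval_times_min: np.ndarray | None = None,
    extra_starts: np.ndarray | None = None,
) -> list[FitRecord]:
    """Stage 2: multistart optimization of the siIκBα objective within the
    stage-1-derived bounds; records come back finalized (both nRMSDs, MFI, AUC).

    `extra_starts` seeds up to half the starts with externally supplied
    free-value vectors (clipped into the bounds) — used to share the first
    replicate's optimized sets with the second replicate's search.
    """
    spec = MODEL_SPECS[model]
    for nm in spec["free"]:
        glo, ghi = spec["bounds"][nm]
        lo, hi = stage2_bounds[nm]
        if lo < glo or hi > ghi:
            raise ValueError(f"stage-2 bounds for {nm} not nested in global bounds")
    return _multistart(
        gene_id, model, grids, data_fc, stage2_bounds, "siIkBa", config, seed,
        eval_times_min, replicate, maxfev=config.maxfev_stage2,
        extra_starts=extra_starts,
    )


class TwoStepFit:
    """The two-step protocol for one gene, one model, one input replicate.

    A small model-object in the statsmodels mould: construct from data, call
    :meth:`fit`, get a results object.

    Parameters
    ----------
    data_fc : dict
        ``{"ctrl": fc, "siIkBa": fc}`` measured fold-change series at the
        evaluation times.
    grids : dict
        The replicate's input grids per condition.
    model_name : str
        One of simple/iffl/cycle3/v4.
    """

    def __init__(
        self,
        data_fc: dict[str, np.ndarray],
        grids: dict[str, InputGrid],
        model_name: str,
        gene_id: str = "gene",
        replicate: int = 1,
        config: FitConfig = FitConfig(),
        eval_times_min: np.ndarray | None = None,
    ) -> None:
        if model_name not in MODEL_SPECS:
            raise ValueError(f"unknown model {model_name!r}")
        self.data_fc = {k: np.asarray(v, dtype=float) for k, v in data_fc.items()}
        self.grids = grids
        self.model_name = model_name
        self.gene_id = gene_id
        self.replicate = replicate
        self.config = config
        self.eval_times_min = eval_times_min

    def fit(self, seed: int = 0,
            extra_stage2_starts: np.ndarray | None = None) -> "TwoStepFitResults":
        ss = np.random.SeedSequence(seed, spawn_key=(self.replicate,))
        s1, s2 = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
        stage1 = stage1_fit(
            self.data_fc, self.model_name, self.grids, self.config, s1,
            self.gene_id, self.replicate, self.eval_times_min,
        )
        bounds = derive_bounds(stage1, self.config.stage1_thresholds)
        stage2 = stage2_fit(
            self.data_fc, self.model_name, self.grids, bounds, self.config, s2,
            self.gene_id, self.replicate, self.eval_times_min,
            extra_starts=extra_stage2_starts,
        )
        return TwoStepFitResults(self, stage1, bounds, stage2)


@dataclass
class TwoStepFitResults:
    """Results of :class:`TwoStepFit`: stage records, narrowed bounds, best fit."""

    model: TwoStepFit
    stage1_records: list[FitRecord]
    stage2_bounds: dict[str, tuple[float, float]]
    records: list[FitRecord]  # finalized stage-2 records

    @property
    def best(self) -> FitRecord:
        """Stage-2 record with the smallest optimized (siIκBα) objective."""
        return min(self.records, key=lambda r: (r.objective_value, r.nrmsd_total))

    def summary(self) -> str:
        b = self.best
        lines = [
            f"Two-step fit: gene={b.gene_id} model={b.model_name} replicate={b.replicate}",
            f"  starts per stage: {self.model.config.n_starts}",
            f"  best record: nRMSD ctrl={b.nrmsd_ctrl:.4f} siIkBa={b.nrmsd_si:.4f}",
            f"  MFI ctrl={b.mfi_ctrl:.3f} siIkBa={b.mfi_si:.3f}; "
            f"AUC ctrl={b.auc_ctrl:.1f} siIkBa={b.auc_si:.1f}",
            "  parameters:",
        ]
        for nm in b.params.free_names:
            lo, hi = self.stage2_bounds[nm]
            lines.append(f"    {nm:8s} = {b.params.free[nm]:.6g}   (stage-2 bounds {lo:.3g} .. {hi:.3g})")
        return "\n".join(lines)
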