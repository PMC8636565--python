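"""Synthetic NFκB trajectories and gene expression tables with known truth.

The generator emulates the study conditions end to end so the whole pipeline
is testable without the deposited sequencing data:

* a control nuclear-NFκB fold-change trajectory with a dominant first peak
  near 30 min, a trough near 75 min and a dampened second peak near 120 min
  (sum of two log-normal-shaped pulses on a baseline of 1);
* an IκBα-knockdown (siIkBa) trajectory with a slower, saturating rise to a
  plateau below the control peak — prolonged activity, lower fold change;
* a second biological replicate whose amplitudes are uniformly scaled down;
* per-gene mRNA time courses simulated from any of the four transcription
  models at known parameters, optionally degraded with multiplicative
  log-normal noise.

Expression tables carry one series per condition (the study models the
replicate-mean expression; the two fitting replicates differ through the
NFκB input, not the expression data) and are generated with the replicate-1
input grids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import ParamSet, simulate
from .models.params import MODEL_NAMES
from .timecourse import InputGrid, TimeCourse

__all__ = [
    "NfkbShapeParams",
    "GroundTruthGene",
    "make_nfkb_timecourse",
    "study_timecourses",
    "cohort_genes",
    "make_gene_table",
    "make_counts_fixture",
    "DEFAULT_SAMPLE_TIMES_MIN",
]

#: expression sampling every 15 min over 0-180 min (13 points)
DEFAULT_SAMPLE_TIMES_MIN = np.arange(0.0, 181.0, 15.0)


@dataclass(frozen=True)
class NfkbShapeParams:
    """Shape of the synthetic nuclear-NFκB fold-change trajectories.

    Times in minutes, heights in fold units relative to a pre-stimulus
    baseline of 1.  `replicate_scale` multiplies all amplitudes above
    baseline (replicate 2 of the study was consistently dimmer).
    """

    peak1_time: float = 30.0
    peak1_height: float = 10.0
    trough_time: float = 75.0
    peak2_time: float = 120.0
    peak2_height: float = 5.0
    si_rise_time: float = 60.0
    si_plateau: float = 4.5
    replicate_scale: float = 1.0
    baseline: float = 1.0
    peak1_width: float = 0.32  # log-widths of the two control pulses
    peak2_width: float = 0.22

    def __post_init__(self) -> None:
        if not (self.peak1_time < self.trough_time < self.peak2_time):
            raise ValueError("need peak1_time < trough_time < peak2_time")
        if not (self.peak1_height > self.peak2_height > self.baseline):
            raise ValueError("need peak1_height > peak2_height > baseline")
        if self.si_plateau <= self.baseline:
            raise ValueError("si_plateau must exceed baseline")
        if self.replicate_scale <= 0:
            raise ValueError("replicate_scale must be positive")


def _lognormal_pulse(t_min: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth positive pulse peaking at exactly `center`, zero at t = 0."""
    out = np.zeros_like(t_min, dtype=float)
    pos = t_min > 0
    out[pos] = np.exp(-0.5 * (np.log(t_min[pos] / center) / width) ** 2)
    return out


def make_nfkb_timecourse(
    shape: NfkbShapeParams,
    condition: str,
    times: np.ndarray | None = None,
    seed: int = 0,
    replicate: int = 1,
    noise_cv: float = 0.0,
) -> TimeCourse:
    """Synthetic nuclear-NFκB activity time course for one condition.

    Control: baseline plus two log-normal pulses (peak/trough/peak ordering).
    siIkBa: saturating rise to the plateau with no post-peak decline.  The
    value at t = 0 equals the baseline exactly; multiplicative log-normal
    noise (mean 1, coefficient of variation `noise_cv`) is applied to all
    later points, deterministically given `seed`.
    """
    if times is None:
        times = np.arange(0.0, 181.0, 15.0)
    times = np.asarray(times, dtype=float)
    if times[0] != 0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly ascending")
    if times[-1] < 180:
        raise ValueError("times must cover at least 0-180 min")

    if condition == "ctrl":
        raw = (
            (shape.peak1_height - shape.baseline)
            * _lognormal_pulse(times, shape.peak1_time, shape.peak1_width)
            + (shape.peak2_height - shape.baseline)
            * _lognormal_pulse(times, shape.peak2_time, shape.peak2_width)
        )
    elif condition == "siIkBa":
        raw = (shape.si_plateau - shape.baseline) * (
            1.0 - np.exp(-((times / shape.si_rise_time) ** 2))
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")

    values = shape.baseline + shape.replicate_scale * raw
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=times.size))
        noise[0] = 1.0  # keep the baseline anchor exact
        values = values * noise
    return TimeCourse(times, values, condition, replicate)


def study_timecourses(
    shape: NfkbShapeParams | None = None,
    rep2_scale: float = 0.7,
    times: np.ndarray | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> list[TimeCourse]:
    """Both conditions for both replicates.

    Replicate 2 is dimmer by `rep2_scale` and differs mildly in pulse widths,
    second-peak height and knockdown kinetics, mimicking between-replicate
    variability.  The shape perturbations are kept small (a few percent): the
    amplitude scaling itself is undone exactly by the min-max rescaling
    downstream, and the residual shape difference is what the concordance
    step has to bridge.
    """
    shape = shape or NfkbShapeParams()
    shapes = {
        1: shape,
        2: replace(
            shape,
            replicate_scale=shape.replicate_scale * rep2_scale,
            peak1_width=shape.peak1_width * 1.03,
            peak2_height=shape.baseline + (shape.peak2_height - shape.baseline) * 1.04,
            si_plateau=shape.baseline + (shape.si_plateau - shape.baseline) * 1.03,
            si_rise_time=shape.si_rise_time * 1.03,
        ),
    }
    out = []
    for rep in (1, 2):
        for i, cond in enumerate(("ctrl", "siIkBa")):
            out.append(
                make_nfkb_timecourse(shapes[rep], cond, times, seed + 10 * rep + i, rep, noise_cv)
            )
    return out


@dataclass(frozen=True)
class GroundTruthGene:
    """A synthetic gene: generating model, true parameters, noise level, seed."""

    gene_id: str
    model_name: str
    true_params: ParamSet
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.true_params.model_name != self.model_name:
            raise ValueError("true_params.model_name mismatch")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


#: per-model "typical gene" parameters: chosen so the generated genes show the
#: study's subcluster-2 phenotype under the default inputs (higher induction
#: in control than siIkBa) with model-typical dynamics — monotone rise for the
#: simple model, fold-change-detecting reduction for iffl, post-induction
#: repression (transient) for the promoter-cycle models.
_TRUE_PARAMS = {
    "simple": dict(k_deg=1e-3, K_D=0.005, tau=900.0),
    "iffl": dict(k_deg=1.8e-3, K_D1=0.5, K_D2=0.002, tau=600.0),
    "cycle3": dict(k_1=2e-3, k_2=0.02, k_deg=1.7e-3, K_D1=0.02, K_D2=0.004, tau=300.0),
    "v4": dict(k_1=2e-3, k_2=0.01, k_deg=1.5e-3, K_D1=0.005, K_D2=0.0015,
               K_DTF2=0.005, tau=300.0),
}

#: multiplicative jitter (log10 half-width) applied per gene to scale
#: parameters, and additive jitter (s) for tau
_JITTER_LOG10 = 0.1
_JITTER_TAU_S = 300.0


def cohort_genes(
    models: list[str] | None = None,
    n_per_model: int = 5,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> list[GroundTruthGene]:
    """A cohort of synthetic genes, `n_per_model` per model, jittered around
    the per-model typical parameters and kept inside the optimization bounds."""
    models = list(models) if models is not None else list(MODEL_NAMES)
    ss = np.random.SeedSequence(seed)
    genes: list[GroundTruthGene] = []
    idx = 0
    for model in models:
        base = _TRUE_PARAMS[model]
        for j in range(n_per_model):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            free = {}
            ps0 = ParamSet.create(model, **base)
            for nm, v in base.items():
                lo, hi = ps0.bounds[nm]
                if nm == "tau":
                    val = v + rng.uniform(-_JITTER_TAU_S, _JITTER_TAU_S)
                    val = float(np.clip(val, lo + 1.0, hi - 1.0))
                else:
                    val = v * 10.0 ** rng.uniform(-_JITTER_LOG10, _JITTER_LOG10)
                    val = float(np.clip(val, lo * 1.001, hi * 0.999))
                free[nm] = val
            genes.append(
                GroundTruthGene(
                    gene_id=f"g{idx:03d}_{model}",
                    model_name=model,
                    true_params=ParamSet.create(model, **free),
                    noise_cv=noise_cv,
                    seed=int(child.generate_state(1)[0] % (2 ** 31)),
                )
            )
            idx += 1
    return genes


def make_gene_table(
    genes: list[GroundTruthGene],
    inputs: dict[str, InputGrid],
    sample_times: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-gene expression for both conditions and tabulate it.

    Returns ``(table, truth)``: the table has one row per gene and columns
    ``<condition>_t<min>``; `truth` maps gene_id to the generating model,
    parameters and seed.  With ``noise_cv = 0`` the values equal the
    noiseless simulation exactly.
    """
    if sample_times is None:
        sample_times = DEFAULT_SAMPLE_TIMES_MIN
    sample_times = np.asarray(sample_times, dtype=float)
    columns = [f"{cond}_t{int(t)}" for cond in ("ctrl", "siIkBa") for t in sample_times]
    rows = {}
    truth: dict[str, dict] = {}
    for gene in genes:
        vals = []
        rng = np.random.default_rng(gene.seed)
        sigma = np.sqrt(np.log1p(gene.noise_cv ** 2)) if gene.noise_cv > 0 else 0.0
        for cond in ("ctrl", "siIkBa"):
            res = simulate(gene.true_params, inputs[cond], sample_times)
            m = res.mrna.copy()
            if sigma > 0:
                m *= np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=m.size))
            vals.append(m)
        rows[gene.gene_id] = np.concatenate(vals)
        truth[gene.gene_id] = {
            "model": gene.model_name,
            "params": dict(gene.true_params.free),
            "noise_cv": gene.noise_cv,
            "seed": gene.seed,
        }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "gene_id"
    return table, truth


def make_counts_fixture(
    n_genes: int,
    lengths: np.ndarray,
    size_factors: np.ndarray,
    seed: int = 0,
    base_mean: float = 200.0,
) -> pd.DataFrame:
    """Poisson raw-count table with known per-sample scaling.

    Expected count of gene g in sample s is
    ``base_mean * (length_g / 1000) * size_factor_s``, so the length- and
    size-normalized expression is identical across genes and samples by
    construction — a fixture against which count normalization is verifiable.
    """
    lengths = np.asarray(lengths, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    if lengths.size != n_genes:
        raise ValueError("need one length per gene")
    rng = np.random.default_rng(seed)
    mu = base_mean * np.outer(lengths / 1000.0, size_factors)
    counts = rng.poisson(mu)
    return pd.DataFrame(
        counts,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(size_factors.size)],
    )
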