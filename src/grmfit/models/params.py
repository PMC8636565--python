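"""Parameter sets, fixed constants, and optimization bounds for the four models.

Each transcription model has a small set of free parameters optimized within
open bound intervals, plus fixed constants:

================  =====================================  ==========================================
model             free (bounds)                          fixed
================  =====================================  ==========================================
simple            k_deg (2e-5, 2e-3) 1/s                 h = 1, k_syn = 1
                  K_D (0.001, 1000)
                  tau (0, 7200) s
iffl              k_deg, K_D1, K_D2, tau                 h = 2, h_TF = 1, k_degTF = 8.022537e-6,
                                                         K_DTF = 100, tau_TF = 7200 s, k_syn = 1
cycle3            k_1 (6e-5, 6e-3), k_2 (0.007, 69.31),  k_-1 = 0.01 k_1, k_-2 = 0.01 k_2,
                  k_deg, K_D1, K_D2, tau                 k_-3 = 1, K_D3 = 0.5, k_syn = 1
v4                cycle3 free + K_DTF2 (0.001, 1000);    union of cycle3 and iffl constants
                  k_2 upper bound 69.315
================  =====================================  ==========================================

``tau`` is the delay (seconds) between nuclear NFκB and mature polyadenylated
mRNA; ``tau_TF`` the analogous fixed 2-h processing delay of the p50
competitor.  The k_2 upper bound differs in the last decimal between cycle3
(69.31) and v4 (69.315); both are kept per model as printed in the source
protocol rather than harmonized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MODEL_NAMES", "MODEL_SPECS", "ParamSet", "TAU_TF_S"]

MODEL_NAMES = ("simple", "iffl", "cycle3", "v4")

#: fixed processing delay of the p50 competitor: 2 h in seconds
TAU_TF_S = 7200.0

_KDEG = (2e-5, 2e-3)
_KD = (0.001, 1000.0)
_TAU = (0.0, 7200.0)
_K1 = (6e-5, 6e-3)

_IFFL_FIXED = {
    "h": 2.0,
    "h_TF": 1.0,
    "k_degTF": 8.022537e-6,
    "K_DTF": 100.0,
    "tau_TF": TAU_TF_S,
    "k_syn": 1.0,
}
_CYCLE_FIXED = {"k_m3": 1.0, "K_D3": 0.5, "k_syn": 1.0}

#: per-model free-parameter order (the optimization vector order), bounds and
#: fixed constants.  tau is sampled/optimized on a linear scale, everything
#: else on a log scale (bounds span up to six decades).
MODEL_SPECS: dict[str, dict] = {
    "simple": {
        "free": ("k_deg", "K_D", "tau"),
        "bounds": {"k_deg": _KDEG, "K_D": _KD, "tau": _TAU},
        "fixed": {"h": 1.0, "k_syn": 1.0},
    },
    "iffl": {
        "free": ("k_deg", "K_D1", "K_D2", "tau"),
        "bounds": {"k_deg": _KDEG, "K_D1": _KD, "K_D2": _KD, "tau": _TAU},
        "fixed": dict(_IFFL_FIXED),
    },
    "cycle3": {
        "free": ("k_1", "k_2", "k_deg", "K_D1", "K_D2", "tau"),
        "bounds": {
            "k_1": _K1,
            "k_2": (0.007, 69.31),
            "k_deg": _KDEG,
            "K_D1": _KD,
            "K_D2": _KD,
            "tau": _TAU,
        },
        "fixed": dict(_CYCLE_FIXED),
    },
    "v4": {
        "free": ("k_1", "k_2", "k_deg", "K_D1", "K_D2", "K_DTF2", "tau"),
        "bounds": {
            "k_1": _K1,
            "k_2": (0.007, 69.315),
            "k_deg": _KDEG,
            "K_D1": _KD,
            "K_D2": _KD,
            "K_DTF2": _KD,
            "tau": _TAU,
        },
        "fixed": {**_CYCLE_FIXED, **_IFFL_FIXED},
    },
}


@dataclass(frozen=True)
class ParamSet:
    """Free parameter values plus fixed constants and bounds for one model.

    Construct with :meth:`create` to pull bounds/constants from the registry::

        ParamSet.create("simple", k_deg=1e-3, K_D=0.5, tau=600.0)
    """

    model_name: str
    free: dict[str, float]
    fixed: dict[str, float]
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}; expected one of {MODEL_NAMES}")
        spec = MODEL_SPECS[self.model_name]
        missing = set(spec["free"]) - set(self.free)
        if missing:
            raise ValueError(f"missing free parameters for {self.model_name}: {sorted(missing)}")
        for name, value in self.free.items():
            lo, hi = self.bounds[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{self.model_name}.{name}={value!r} outside bounds ({lo}, {hi})"
                )

    @classmethod
    def create(cls, model_name: str, **free: float) -> "ParamSet":
        spec = MODEL_SPECS[model_name]
        return cls(
            model_name=model_name,
            free={k: float(free[k]) for k in spec["free"]},
            fixed=dict(spec["fixed"]),
            bounds={k: spec["bounds"][k] for k in spec["free"]},
        )

    @classmethod
    def from_vector(cls, model_name: str, vector) -> "ParamSet":
        """Build from a free-value vector in the registry's parameter order."""
        names = MODEL_SPECS[model_name]["free"]
        if len(vector) != len(names):
            raise ValueError(f"{model_name} expects {len(names)} free values, got {len(vector)}")
        return cls.create(model_name, **dict(zip(names, map(float, vector))))

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_SPECS[self.model_name]["free"]

    def vector(self):
        return [self.free[k] for k in self.free_names]

    def resolved(self) -> dict[str, float]:
        """All parameters as floats, including the derived backward rates."""
        p = {**self.fixed, **self.free}
        if self.model_name in ("cycle3", "v4"):
            p["k_m1"] = 0.01 * p["k_1"]
            p["k_m2"] = 0.01 * p["k_2"]
        return p

    def value(self, name: str) -> float:
        return self.resolved()[name]
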