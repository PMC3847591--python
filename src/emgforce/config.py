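"""Run configuration: one file drives all three estimators.

Keeping every shared parameter (envelope, activation, muscle-tendon,
joint) in a single config means model comparisons differ only in the
contractile-element dynamics, never in the surrounding processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activation import DEFAULT_C1, DEFAULT_C2, DEFAULT_DELAY_S
from .emg import EnvelopeConfig
from .hill import MuscleTendonParams
from .joint import DEFAULT_MOMENT_ARMS
from .physio import (
    DEFAULT_KM_OVER_FM,
    DEFAULT_THRESHOLD_FRAC,
    DEFAULT_UC,
    DEFAULT_UR,
    PhysioParams,
)

MODELS = ("hill_linear", "hill_nonlinear", "physio")


@dataclass(frozen=True)
class ActivationConfig:
    d_ms: float = DEFAULT_DELAY_S * 1000.0
    C1: float = DEFAULT_C1
    C2: float = DEFAULT_C2
    A: float = -1.7


@dataclass(frozen=True)
class PhysioConfig:
    Uc: float = DEFAULT_UC
    Ur: float = DEFAULT_UR
    km_over_Fm: float = DEFAULT_KM_OVER_FM
    threshold_frac_mvc: float = DEFAULT_THRESHOLD_FRAC
    recruitment_mode: str = "continuous"
    dt_int_ms: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    model: str = "physio"
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    muscles: dict[str, MuscleTendonParams] = field(default_factory=dict)
    physio: PhysioConfig = field(default_factory=PhysioConfig)
    moment_arms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MOMENT_ARMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not self.muscles:
            object.__setattr__(
                self,
                "muscles",
                {
                    "gas": MuscleTendonParams.gastrocnemius(),
                    "sol": MuscleTendonParams.soleus(),
                },
            )
        for name in self.muscles:
            if name not in self.moment_arms:
                raise ValueError(f"no moment arm configured for muscle {name!r}")

    def physio_params(self, muscle: str) -> PhysioParams:
        mt = self.muscles[muscle]
        return PhysioParams.from_muscle(
            mt,
            Uc=self.physio.Uc,
            Ur=self.physio.Ur,
            km0=self.physio.km_over_Fm * mt.Fm0,
        )


def _build(cls, section: dict, where: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**section)


def _muscle_from_dict(d: dict, name: str) -> MuscleTendonParams:
    keys = {
        "Fm_N": "Fm0",
        "Lc0_cm": "Lc0",
        "Lt0_cm": "Lt0",
        "pennation_deg": "phi",
        "kt_N_per_mm": "kt",
        "b": "b",
        "Vsh": "Vsh",
        "vmax_Lc0_per_s": "vmax",
    }
    unknown = set(d) - set(keys)
    if unknown:
        raise ValueError(f"unknown keys in muscle.{name}: {sorted(unknown)}")
    kw: dict[str, float] = {}
    for src, dst in keys.items():
        if src not in d:
            continue
        v = float(d[src])
        if src.endswith("_cm"):
            v /= 100.0
        elif src == "pennation_deg":
            v = math.radians(v)
        elif src == "kt_N_per_mm":
            v *= 1000.0
        kw[dst] = v
    if "vmax" in kw:
        kw["vmax"] *= kw.get("Lc0", 1.0)
    return MuscleTendonParams(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    top_allowed = {"model", "envelope", "activation", "muscle", "physio", "joint", "seed"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kw: dict = {}
    if "model" in raw:
        kw["model"] = raw["model"]
    if "seed" in raw:
        kw["seed"] = int(raw["seed"])
    if "envelope" in raw:
        kw["envelope"] = _build(EnvelopeConfig, raw["envelope"], "envelope")
    if "activation" in raw:
        kw["activation"] = _build(ActivationConfig, raw["activation"], "activation")
    if "physio" in raw:
        kw["physio"] = _build(PhysioConfig, raw["physio"], "physio")
    if "muscle" in raw:
        kw["muscles"] = {
            name: _muscle_from_dict(sec, name) for name, sec in raw["muscle"].items()
        }
    if "joint" in raw:
        sec = dict(raw["joint"])
        arms = sec.pop("moment_arm_m", None)
        if sec:
            raise ValueError(f"unknown keys in joint: {sorted(sec)}")
        if arms:
            kw["moment_arms"] = {k: float(v) for k, v in arms.items()}
    return RunConfig(**kw)
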