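"""Model parameters and state-variable naming.

The model couples a temperature-sensing/heat-shock-response cascade (thermo-TRP
surrogates TS1/TS2, HSF1 activation, HSF1-induced HSP) to a prototypical
mammalian peripheral clock gene network (Per/Cry–Bmal1 transcriptional–
translational feedback loops).  ``ModelParameters`` holds the 41 named rate
constants, capacities and Hill coefficients with their nominal values; state
variables are ordered as in :data:`STATE_NAMES` everywhere in the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = [
    "ModelParameters",
    "PARAM_NAMES",
    "STATE_NAMES",
    "HILL_EXPONENTS",
    "CASCADE_PARAMS",
    "CLOCK_PARAMS",
]

#: Frozen state ordering used by every trajectory/array in the package.
STATE_NAMES = (
    "TS1",
    "TS2",
    "actHSF1",
    "indHSP",
    "PerCry_mRNA",
    "PERCRY",
    "nucPERCRY",
    "Bmal1_mRNA",
    "BMAL1",
    "nucBMAL1",
    "CLOCKBMAL1",
)

#: Hill/stoichiometry exponents (dimensionless integers >= 1).
HILL_EXPONENTS = ("n", "p", "q", "r")


@dataclass(frozen=True)
class ModelParameters:
    """The 41 model parameters with nominal defaults.

    Units: production rates in nM/h (per degC where temperature enters),
    first-order rates in 1/h, Michaelis/inhibition constants in nM, Hill
    exponents and coupling strengths dimensionless unless noted.
    """

    # --- temperature sensing / transduction cascade ---
    vact0_ts1: float = 0.13   # TS1 activation by temperature magnitude (nM/h/degC)
    vact1_ts1: float = 0.65   # TS1 activation by temperature variation (nM/h/degC)
    vina_ts1: float = 0.65    # TS1 inactivation (1/h)
    vb_ts2: float = 8.0       # maximal TS2 production (nM/h)
    kb_ts2: float = 20.0      # Michaelis constant of TS2 production (nM)
    n: float = 3.0            # Hill coefficient of TS2 production
    vd_ts2: float = 0.45      # TS2 degradation (1/h)
    kT: float = 27.17         # strength of transduced temperature input
    KT: float = 3.68          # Michaelis constant of transduced input (nM)
    vact_hsf1: float = 0.33   # HSF1 activation (nM/h)
    HSF1tot: float = 20.89    # total HSF1 pool (nM)
    vina_hsf1: float = 20.65  # HSF1 inactivation (1/h)
    vb_hsp: float = 8.72      # HSF1-induced HSP production (nM/h)
    vd_hsp: float = 2.37      # HSP degradation (1/h)
    khsf1: float = 39.97      # coupling of active HSF1 onto Per/Cry transcription
    Khsf1: float = 1.07       # Michaelis constant of that coupling (nM)
    khsf1_ci: float = 1.0     # competitive-inhibition weight of HSP vs CLOCK/BMAL1 (nM)
    # --- peripheral clock gene network ---
    v1b: float = 9.0          # maximal Per/Cry transcription (nM/h)
    c: float = 0.01           # constitutive activator (nM)
    k1b: float = 1.0          # Michaelis constant of Per/Cry transcription (nM)
    k1i: float = 0.56         # inhibition constant of Per/Cry transcription (nM)
    p: float = 8.0            # Hill coefficient of Per/Cry inhibition
    k1d: float = 0.12         # Per/Cry mRNA degradation (1/h)
    k2b: float = 0.3          # PER/CRY complex formation (1/nM/h)
    q: float = 2.0            # PER/CRY forming subunits
    k2d: float = 0.05         # cytoplasmic PER/CRY degradation (1/h)
    k2t: float = 0.24         # PER/CRY nuclear import (1/h)
    k3t: float = 0.02         # PER/CRY nuclear export (1/h)
    k3d: float = 0.12         # nuclear PER/CRY degradation (1/h)
    v4b: float = 3.6          # maximal Bmal1 transcription (nM/h)
    k4b: float = 2.16         # Michaelis constant of Bmal1 transcription (nM)
    r: float = 3.0            # Hill coefficient of Bmal1 activation
    k4d: float = 0.75         # Bmal1 mRNA degradation (1/h)
    k5b: float = 0.24         # BMAL1 translation (1/h)
    k5d: float = 0.06         # cytoplasmic BMAL1 degradation (1/h)
    k5t: float = 0.45         # BMAL1 nuclear import (1/h)
    k6t: float = 0.06         # BMAL1 nuclear export (1/h)
    k6d: float = 0.12         # nuclear BMAL1 degradation (1/h)
    k6a: float = 0.09         # CLOCK/BMAL1 activation (1/h)
    k7a: float = 0.003        # CLOCK/BMAL1 deactivation (1/h)
    k7d: float = 0.09         # CLOCK/BMAL1 degradation (1/h)

    def __post_init__(self) -> None:
        problems = []
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                problems.append(f"{f.name} is not finite ({v})")
            elif v < 0:
                problems.append(f"{f.name} must be >= 0, got {v}")
        for name in HILL_EXPONENTS:
            if getattr(self, name) < 1:
                problems.append(f"Hill exponent {name} must be >= 1, got "
                                f"{getattr(self, name)}")
        if problems:
            raise ConfigError(problems)

    # -- conversions -------------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = sorted(set(d) - set(PARAM_NAMES))
        if unknown:
            raise ConfigError([f"unknown parameter key: {k}" for k in unknown])
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **overrides) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)

    def as_array(self) -> np.ndarray:
        """Parameter vector in :data:`PARAM_NAMES` order (used by the solvers)."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ConfigError(f"expected {len(PARAM_NAMES)} parameters, got "
                              f"shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    # -- file round-trip ---------------------------------------------------
    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(d)


PARAM_NAMES = tuple(f.name for f in fields(ModelParameters))

#: Cascade (temperature signalling) parameter names, Table-1 order.
CASCADE_PARAMS = PARAM_NAMES[: PARAM_NAMES.index("v1b")]
#: Clock gene network parameter names.
CLOCK_PARAMS = PARAM_NAMES[PARAM_NAMES.index("v1b"):]
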