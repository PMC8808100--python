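"""Model parameters for the N1/N2 tumour-associated-neutrophil system.

All rates are per day; concentrations and densities are dimensionless.
The defaults are the published calibration of the lung-cancer TAN model:
the N2 complex *C* lumps Treg/Th17/N2 cells, the N1 complex *I* lumps
N1/IL-12/CD8+ cells, and the two complexes mutually inhibit each other
through Hill-type terms, which is what produces bistability.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParameters"]

# Fields that may legitimately be zero (switching off a pathway or an
# inhibition arm); every other rate must be strictly positive.
_NONNEG_ONLY = {"lambda_il6", "lambda_G", "lambda_S", "delta", "gamma1", "alpha", "beta"}


@dataclass
class ModelParameters:
    """Rate constants and thresholds of the TAN regulation model.

    Parameters
    ----------
    lambda_il6 : float
        Constitutive IL-6 source of the N2 complex (λ).
    lambda_G, lambda_S : float
        Coefficients coupling TGF-β (G) into the C equation and IFN-β (S)
        into the I equation.  Not tabulated in the source calibration;
        unit defaults reproduce the published bifurcation structure.
    k1, k2 : float
        Self-regulation (mutual-inhibition numerator) rates of C and I.
    k3, k4 : float
        Hill scaling parameters.
    alpha, beta : float
        Suppression strengths: N1→N2 (α) and N2→N1 (β).
    mu : float
        Decay rate of the N1 complex; the N2 complex decays at unit rate.
    r, K, gamma1, T0, delta : float
        Tumour growth rate, scaling constant, immune suppression strength
        in the growth term, carrying capacity, and N1-mediated kill rate.
    GS, mu_G, gamma_L, mu_L, mu_S : float
        TGF-β source and decay, inhibitor-mediated TGF-β degradation,
        inhibitor decay and IFN-β decay.
    C_th, I_th : float
        Phenotype thresholds: the microenvironment is N1-dominant when
        C < C_th and I > I_th.
    """

    lambda_il6: float = 0.01
    lambda_G: float = 1.0
    lambda_S: float = 1.0
    k1: float = 4.0
    k2: float = 4.0
    k3: float = 1.0
    k4: float = 1.0
    alpha: float = 1.5
    beta: float = 1.0
    mu: float = 1.0
    r: float = 0.05
    K: float = 1.0
    gamma1: float = 0.1
    T0: float = 100.0
    delta: float = 0.05
    GS: float = 0.826
    mu_G: float = 0.826
    gamma_L: float = 100.0
    mu_L: float = 6.6
    mu_S: float = 3.96
    C_th: float = 1.81
    I_th: float = 1.29

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be a finite number, got {v!r}")
            v = float(v)
            object.__setattr__(self, f.name, v)
            if f.name in _NONNEG_ONLY:
                if v < 0:
                    raise ValueError(f"parameter {f.name!r} must be non-negative, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {v}")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
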