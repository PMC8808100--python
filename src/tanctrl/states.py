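"""State containers for the reduced (C, I, T) and full (L, G, C, S, I, T) systems."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ReducedState", "FullState", "ControlSignal", "FULL_STATE_NAMES"]

#: canonical ordering of the full controlled system
FULL_STATE_NAMES = ("L", "G", "C", "S", "I", "T")


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"state component {name!r} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"state component {name!r} must be non-negative, got {value}")
    return value


@dataclass
class ReducedState:
    """N2 complex density C, N1 complex density I and (optional) tumour volume T."""

    C: float
    I: float
    T: float = 0.0

    def __post_init__(self) -> None:
        self.C = _check_nonneg("C", self.C)
        self.I = _check_nonneg("I", self.I)
        self.T = _check_nonneg("T", self.T)

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.I, self.T], dtype=float)


@dataclass
class FullState:
    """Inhibitor L, TGF-β G, N2 complex C, IFN-β S, N1 complex I, tumour T."""

    L: float
    G: float
    C: float
    S: float
    I: float
    T: float

    def __post_init__(self) -> None:
        for name in FULL_STATE_NAMES:
            setattr(self, name, _check_nonneg(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FULL_STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "FullState":
        return cls(*(float(v) for v in x))

    def reduced(self) -> ReducedState:
        return ReducedState(C=self.C, I=self.I, T=self.T)


@dataclass
class ControlSignal:
    """Time-dependent infusion rates with box bounds 0 ≤ u_i(t) ≤ u_i_max.

    ``u_L``/``u_S`` are callables of time (days) returning dose units/day;
    constants are accepted and wrapped.
    """

    u_L: Callable[[float], float] | float = 0.0
    u_S: Callable[[float], float] | float = 0.0
    u_L_max: float = np.inf
    u_S_max: float = np.inf

    def __post_init__(self) -> None:
        if not callable(self.u_L):
            c = float(self.u_L)
            self.u_L = lambda t, _c=c: _c
        if not callable(self.u_S):
            c = float(self.u_S)
            self.u_S = lambda t, _c=c: _c

    def values(self, t: float) -> tuple[float, float]:
        """Evaluate both controls at time ``t``, enforcing the admissibility box."""
        uL, uS = float(self.u_L(t)), float(self.u_S(t))
        for name, val, hi in (("u_L", uL, self.u_L_max), ("u_S", uS, self.u_S_max)):
            if val < -1e-12 or val > hi + 1e-12:
                raise ValueError(
                    f"control {name}={val} at t={t} outside admissible box [0, {hi}]"
                )
        return uL, uS
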