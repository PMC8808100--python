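"""Synthetic patient cohorts: the four canonical initial phenotype states
plus seeded random sampling from the threshold-defined risk regions.

A "patient" is an initial (C0, I0) pair; its risk region is the quadrant
of the (C_th, I_th) threshold cross.  Optional log-normal jitter perturbs
selected model parameters while preserving positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .protocol import classify_risk

__all__ = ["CohortSpec", "Patient", "preset_states", "sample_cohort", "cohort_to_csv", "cohort_from_csv"]

REGIONS = ("low_risk_high", "risk_free", "low_risk_low", "high_risk")

#: canonical initial phenotype states used throughout the study
_PRESETS = {
    "Q1": (3.0, 2.0),  # low-risk: both complexes above threshold
    "Q2": (1.0, 2.0),  # risk-free: N1-dominant
    "Q3": (1.0, 0.5),  # low-risk: both low
    "Q4": (4.0, 0.3),  # high-risk: N2-dominant
}


def preset_states() -> dict[str, tuple[float, float]]:
    """The four canonical (C0, I0) presets Q1–Q4."""
    return dict(_PRESETS)


@dataclass
class Patient:
    id: str
    region: str
    C0: float
    I0: float
    params: ModelParameters | None = None  # jittered per-patient parameters


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    ``weights`` gives the expected fraction of patients per region (they
    are normalised); sampling is uniform within each region's part of the
    box [0, C_box] × [0, I_box].  ``jitter`` is the relative standard
    deviation of multiplicative log-normal noise applied to
    ``jitter_params``; 0 returns the baseline parameters bit-identically.
    """

    n: int = 100
    weights: dict[str, float] = field(
        default_factory=lambda: {r: 0.25 for r in REGIONS}
    )
    C_box: float = 5.0
    I_box: float = 3.0
    jitter: float = 0.0
    jitter_params: tuple[str, ...] = ("k1", "k2", "alpha", "beta", "mu")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        unknown = set(self.weights) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()) or sum(self.weights.values()) <= 0:
            raise ValueError("region weights must be non-negative and not all zero")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


def sample_cohort(spec: CohortSpec, params: ModelParameters) -> list[Patient]:
    """Draw a labelled cohort by rejection sampling within each region.

    Deterministic under a fixed seed; every sample's classified region
    equals its requested label.
    """
    if not (0 < params.C_th < spec.C_box and 0 < params.I_th < spec.I_box):
        raise ValueError("sampling box must contain the thresholds strictly inside")
    rng = np.random.default_rng(spec.seed)
    regions = [r for r in REGIONS if spec.weights.get(r, 0.0) > 0]
    probs = np.array([spec.weights[r] for r in regions], float)
    probs /= probs.sum()
    labels = rng.choice(len(regions), size=spec.n, p=probs)

    patients: list[Patient] = []
    for i, li in enumerate(labels):
        region = regions[li]
        for _ in range(10_000):
            C0 = rng.uniform(0.0, spec.C_box)
            I0 = rng.uniform(0.0, spec.I_box)
            if classify_risk(C0, I0, params) == region:
                break
        else:  # pragma: no cover - box always intersects every region here
            raise RuntimeError(f"region {region!r} empty within the sampling box")
        pp = params
        if spec.jitter > 0:
            sigma = np.sqrt(np.log1p(spec.jitter**2))
            factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(spec.jitter_params))
            pp = params.replace(
                **{
                    name: getattr(params, name) * f
                    for name, f in zip(spec.jitter_params, factors)
                }
            )
        patients.append(Patient(id=f"P{i:04d}", region=region, C0=C0, I0=I0, params=pp))
    return patients


def cohort_to_csv(patients: list[Patient], path: str | Path) -> None:
    rows = []
    for p in patients:
        row = {"id": p.id, "region": p.region, "C0": p.C0, "I0": p.I0}
        if p.params is not None:
            row.update({f"param_{k}": v for k, v in p.params.to_dict().items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[Patient]:
    df = pd.read_csv(path)
    out = []
    param_cols = [c for c in df.columns if c.startswith("param_")]
    for _, row in df.iterrows():
        pp = None
        if param_cols:
            pp = ModelParameters.from_dict({c[6:]: row[c] for c in param_cols})
        out.append(Patient(id=str(row["id"]), region=str(row["region"]), C0=float(row["C0"]), I0=float(row["I0"]), params=pp))
    return out
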