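"""Synthetic expression tables and metabolite fixtures.

Emulates the study design the pipeline consumes: a normoxia/hypoxia
expression table for the mapped tryptophan-pathway genes (KP genes and the
LAT transporters down-regulated under hypoxia, Ddc/Inmt up, Tph1 weakly up,
Ndrg1 up as an unmapped hypoxia marker), with multiplicative log-normal
replicate noise, three replicates per condition, and a fixed seed.

Fold-change magnitudes encode only the qualitative regulation directions;
they are deliberate fixture choices, configurable, and not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .model import ModelDefinition, ParameterSet
from .steady_state import solve_steady_state

__all__ = [
    "RegulationProfile",
    "NoiseModel",
    "generate_expression",
    "generate_metabolite_fixture",
    "DEFAULT_FOLD_CHANGES",
]

#: hypoxia/normoxia expression ratios encoding the regulation directions:
#: KP enzymes and LAT transporters down, Ddc/Inmt up, Tph1 weakly up,
#: Il4i1 unchanged, Ndrg1 strongly up (hypoxia marker, maps to no reaction)
DEFAULT_FOLD_CHANGES = {
    "Tdo2": 0.1,
    "Kmo": 0.4,
    "Kynu": 0.5,
    "Kyat1": 0.5,
    "Slc7a5": 0.5,
    "Slc7a8": 0.5,
    "Haao": 0.6,
    "Qprt": 0.6,
    "Ddc": 2.0,
    "Inmt": 2.5,
    "Tph1": 1.3,
    "Il4i1": 1.0,
    "Ndrg1": 8.0,
}

DEFAULT_BASELINE_MEAN = 100.0  # arbitrary linear-intensity scale


@dataclass
class RegulationProfile:
    """Per-gene hypoxic fold change and normoxic baseline mean."""

    fold_change: dict = field(default_factory=lambda: dict(DEFAULT_FOLD_CHANGES))
    baseline_mean: dict = field(default_factory=dict)

    def __post_init__(self):
        for g, fc in self.fold_change.items():
            if not fc > 0:
                raise ValueError(f"fold_change[{g!r}] must be > 0, got {fc}")
        for g in self.fold_change:
            self.baseline_mean.setdefault(g, DEFAULT_BASELINE_MEAN)
        for g, m in self.baseline_mean.items():
            if not m > 0:
                raise ValueError(f"baseline_mean[{g!r}] must be > 0, got {m}")

    @property
    def genes(self) -> list:
        return sorted(self.fold_change)


@dataclass
class NoiseModel:
    """Multiplicative log-normal replicate noise.

    ``replicate_cv`` is the coefficient of variation; the log-normal factor
    has mean 1 (mu = -sigma^2/2 with sigma^2 = ln(1 + cv^2)) so sample
    means converge to the profile means.
    """

    replicate_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.replicate_cv**2))

    def factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.replicate_cv == 0:
            return np.ones(n)
        s = self.sigma
        return np.exp(rng.normal(-0.5 * s * s, s, size=n))


def generate_expression(
    profile: RegulationProfile | None = None,
    noise: NoiseModel | None = None,
    conditions: tuple = ("normoxia", "hypoxia"),
) -> ExpressionTable:
    """Draw a two-condition expression table; deterministic given the seed.

    For each gene, normoxia replicates are ``baseline_mean * factor`` and
    hypoxia replicates ``baseline_mean * fold_change * factor`` with
    independent mean-one log-normal factors.
    """
    profile = profile or RegulationProfile()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    ref, test = conditions
    rows = []
    for gene in profile.genes:
        base = profile.baseline_mean[gene]
        for condition, level in ((ref, base), (test, base * profile.fold_change[gene])):
            values = level * noise.factors(rng, noise.n_replicates)
            for rep, val in enumerate(values, start=1):
                rows.append({"gene": gene, "condition": condition,
                             "replicate": rep, "value": float(val)})
    return ExpressionTable(pd.DataFrame(rows))


def generate_metabolite_fixture(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    noise: NoiseModel | None = None,
    lod: float | dict = 0.0,
) -> pd.DataFrame:
    """Noisy steady-state metabolite measurements with detection limits.

    Simulates the model to steady state, perturbs each dynamic species'
    concentration with multiplicative log-normal noise per replicate, and
    left-censors values below the limit of detection: censored entries get
    ``value`` NaN, ``censored`` True and the limit recorded.

    ``lod`` is a single limit or a per-metabolite dict (absent -> 0).
    """
    noise = noise or NoiseModel()
    result = solve_steady_state(model, params)
    if not result.converged:
        raise ValueError("parameters do not yield a converged steady state")
    rng = np.random.default_rng(noise.seed)
    lod_for = (lambda s: lod.get(s, 0.0)) if isinstance(lod, dict) else (lambda s: lod)
    rows = []
    for sid in model.dynamic_ids:
        conc = result.concentrations[sid]
        values = conc * noise.factors(rng, noise.n_replicates)
        limit = lod_for(sid)
        for rep, val in enumerate(values, start=1):
            censored = val < limit
            rows.append({
                "metabolite": sid,
                "replicate": rep,
                "value": math.nan if censored else float(val),
                "censored": censored,
                "lod": limit,
            })
    return pd.DataFrame(rows)
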