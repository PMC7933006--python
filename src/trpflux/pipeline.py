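"""End-to-end pipeline: expression -> scaled models -> steady states ->
differential table -> sign-pattern report.

One :class:`PipelineConfig` (YAML-serialisable) drives the whole run; all
randomness flows from its seed, numeric outputs are written with fixed
precision (12 significant digits), and a manifest records input hashes and
the resolved configuration so runs are reproducible and diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import DEFAULT_EXPECTATIONS, compare_conditions, sign_pattern
from .expression import (
    ExpressionTable,
    GeneReactionMap,
    compute_scaling_factors,
    ratios_for_replicate,
    scale_parameters,
)
from .model import ModelConfig, ParameterSet, build_default_model
from .steady_state import SteadyStateResult, solve_steady_state
from .synth import NoiseModel, RegulationProfile, generate_expression

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "InputError",
    "save_parameters",
    "load_parameters",
    "write_steady_state_tsv",
    "write_differential_tsv",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


class InputError(ValueError):
    """Unresolvable or invalid pipeline input."""


# -- small I/O helpers -------------------------------------------------------

def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def load_parameters(path) -> ParameterSet:
    with open(path) as fh:
        return ParameterSet.from_dict(yaml.safe_load(fh))


def _fmt(x) -> str:
    return FLOAT_FMT % x if isinstance(x, float) else str(x)


def write_steady_state_tsv(result: SteadyStateResult, path) -> None:
    """One row per species then per reaction, fixed 12-digit precision."""
    with open(path, "w") as fh:
        fh.write("kind\tid\tvalue\n")
        for sid, c in result.concentrations.items():
            fh.write(f"concentration\t{sid}\t{_fmt(c)}\n")
        for rid, v in result.fluxes.items():
            fh.write(f"flux\t{rid}\t{_fmt(v)}\n")


def write_differential_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# -- configuration -----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Fully-resolved run description.

    Expression comes either from ``expression_path`` (CSV/TSV with columns
    gene,condition,replicate,value) or, when that is None, from the
    synthetic generator using ``fold_changes`` / ``replicate_cv`` /
    ``n_replicates`` and the run seed.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    parameter_file: str | None = None
    expression_path: str | None = None
    fold_changes: dict | None = None
    baseline_means: dict | None = None
    replicate_cv: float = 0.1
    n_replicates: int = 3
    reference_condition: str = "normoxia"
    test_condition: str = "hypoxia"
    tol: float = 1e-9
    stat_test: str = "welch"
    output_dir: str = "trpflux_run"
    seed: int = 1

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "model"}
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        model = ModelConfig.from_dict(d.pop("model", {}))
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(model=model, **known)

    @classmethod
    def read_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory handles plus the paths of everything written."""

    config: PipelineConfig
    expression: ExpressionTable
    steady_states: dict  # condition -> {replicate -> SteadyStateResult}
    differential: pd.DataFrame
    report: "object"
    output_dir: Path
    manifest: dict

    @property
    def all_converged(self) -> bool:
        return all(r.converged for reps in self.steady_states.values() for r in reps.values())


# -- the pipeline ------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write artifacts under ``config.output_dir``.

    Deterministic given config + seed.  Raises :class:`InputError` before
    any output is written when inputs cannot be resolved.
    """
    t_start = time.perf_counter()
    timings: dict = {}

    # resolve all inputs before touching the output directory
    if config.expression_path is not None and not Path(config.expression_path).exists():
        raise InputError(f"expression file not found: {config.expression_path}")
    if config.parameter_file is not None and not Path(config.parameter_file).exists():
        raise InputError(f"parameter file not found: {config.parameter_file}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = build_default_model(config.model)
    baseline = model.baseline_params
    if config.parameter_file:
        baseline = load_parameters(config.parameter_file)
        baseline.validate()

    # expression: load or synthesise
    t0 = time.perf_counter()
    if config.expression_path:
        expression = ExpressionTable.read_csv(config.expression_path)
        source = config.expression_path
    else:
        if config.fold_changes:
            profile = RegulationProfile(fold_change=dict(config.fold_changes),
                                        baseline_mean=dict(config.baseline_means or {}))
        else:
            profile = RegulationProfile(baseline_mean=dict(config.baseline_means or {}))
        noise = NoiseModel(replicate_cv=config.replicate_cv,
                           n_replicates=config.n_replicates, seed=config.seed)
        expression = generate_expression(profile, noise,
                                         conditions=(config.reference_condition,
                                                     config.test_condition))
        source = "synthetic"
        expression.write_csv(out / "expression.csv",
                             header_comment=f"synthetic expression table, seed={config.seed}, "
                                            f"cv={config.replicate_cv}")
    if config.reference_condition not in expression.conditions:
        raise InputError(
            f"reference condition {config.reference_condition!r} absent from expression table"
        )
    if config.test_condition not in expression.conditions:
        raise InputError(
            f"test condition {config.test_condition!r} absent from expression table"
        )
    timings["expression"] = time.perf_counter() - t0

    # per-replicate scaled steady states
    t0 = time.perf_counter()
    gene_map = GeneReactionMap()
    gene_map.validate_against(model)
    factors = compute_scaling_factors(expression, config.reference_condition)
    steady_states: dict = {}
    for condition in (config.reference_condition, config.test_condition):
        steady_states[condition] = {}
        for rep in expression.replicates(condition):
            ratios = ratios_for_replicate(factors, condition, rep)
            params = scale_parameters(baseline, ratios, gene_map)
            result = solve_steady_state(model, params, tol=config.tol)
            if not result.converged:
                log.warning("replicate %s/%s did not converge (residual %.3g)",
                            condition, rep, result.residual_norm)
            steady_states[condition][rep] = result
            write_steady_state_tsv(result, out / f"steady_state_{condition}_rep{rep}.tsv")
            with open(out / f"steady_state_{condition}_rep{rep}.json", "w") as fh:
                json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
    timings["steady_states"] = time.perf_counter() - t0

    # differential statistics + sign pattern
    t0 = time.perf_counter()
    differential = compare_conditions(
        list(steady_states[config.reference_condition].values()),
        list(steady_states[config.test_condition].values()),
        test=config.stat_test,
    )
    write_differential_tsv(differential, out / "differential.tsv")
    with open(out / "differential.json", "w") as fh:
        json.dump(differential.to_dict("records"), fh, indent=2, sort_keys=True)
    report = sign_pattern(differential, DEFAULT_EXPECTATIONS)
    with open(out / "sign_pattern.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    timings["statistics"] = time.perf_counter() - t0

    config.write_yaml(out / "resolved_config.yaml")
    manifest = {
        "trpflux_version": __version__,
        "seed": config.seed,
        "expression_source": source,
        "expression_sha256": _sha256(out / "expression.csv") if source == "synthetic"
        else _sha256(config.expression_path),
        "n_replicates": {c: len(r) for c, r in steady_states.items()},
        "all_converged": all(r.converged for reps in steady_states.values()
                             for r in reps.values()),
        "sign_pattern_passed": report.passed,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "total_s": round(time.perf_counter() - t_start, 4),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(config=config, expression=expression,
                          steady_states=steady_states, differential=differential,
                          report=report, output_dir=out, manifest=manifest)
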