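"""Steady-state computation: stiff ODE relaxation with Newton polish.

The steady state of dC/dt = N v(C) (boundary species clamped) is found by
integrating with a stiff-capable solver until the scaled rate criterion
max_i |dC_i/dt| <= tol * max(1, |C_i|) holds, then optionally polishing the
root with a damped Newton iteration.  The two routes serve as mutual
cross-checks: relaxation is globally robust, Newton delivers
machine-precision residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelDefinition, ParameterSet, evaluate_rates, stoichiometric_matrix

__all__ = [
    "SteadyStateResult",
    "simulate_to_steady_state",
    "refine_newton",
    "compute_fluxes",
    "solve_steady_state",
    "SteadyStateError",
]

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-9


class SteadyStateError(RuntimeError):
    """Numerical failure during steady-state computation."""

    def __init__(self, message: str, last_state: dict | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class SteadyStateResult:
    """Converged concentrations and fluxes for one parameterisation."""

    concentrations: dict
    fluxes: dict
    converged: bool
    residual_norm: float
    method: str  # relaxation | newton | hybrid
    diagnostics: dict = field(default_factory=dict)

    def concentration_vector(self, species_ids) -> np.ndarray:
        return np.array([self.concentrations[s] for s in species_ids])

    def flux_vector(self, reaction_ids) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])

    def to_dict(self) -> dict:
        return {
            "concentrations": dict(self.concentrations),
            "fluxes": dict(self.fluxes),
            "converged": bool(self.converged),
            "residual_norm": float(self.residual_norm),
            "method": self.method,
            "diagnostics": dict(self.diagnostics),
        }


def _rhs_factory(model: ModelDefinition, params: ParameterSet):
    """Return (f(y), dyn_ids, full_state(y)) for the clamped-boundary ODE."""
    dyn_ids = model.dynamic_ids
    boundary = {s.id: s.initial_concentration for s in model.species if s.is_boundary}
    n_mat = stoichiometric_matrix(model)

    def full_state(y: np.ndarray) -> dict:
        state = dict(boundary)
        state.update(zip(dyn_ids, y))
        return state

    def f(y: np.ndarray) -> np.ndarray:
        # transient small negatives from the integrator are evaluated at 0
        state = full_state(np.maximum(y, 0.0))
        return n_mat @ evaluate_rates(model, state, params)

    return f, dyn_ids, full_state


def _scaled_residual(dydt: np.ndarray, y: np.ndarray) -> float:
    return float(np.max(np.abs(dydt) / np.maximum(1.0, np.abs(y))))


def _clamp_small_negatives(y: np.ndarray) -> np.ndarray:
    floor = -10 * np.finfo(float).eps * max(1.0, float(np.max(np.abs(y), initial=1.0)))
    bad = y < floor
    if np.any(bad):
        raise SteadyStateError(f"negative concentrations beyond tolerance: {y[bad]}")
    if np.any(y < 0):
        log.info("clamping %d slightly negative concentrations to 0", int(np.sum(y < 0)))
    return np.maximum(y, 0.0)


def simulate_to_steady_state(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    init: dict | None = None,
    tol: float = DEFAULT_TOL,
    t_max: float = 1e7,
) -> SteadyStateResult:
    """Relax dC/dt = N v(C) to steady state with a stiff integrator.

    Integrates in geometrically growing spans until the scaled rate
    criterion is met or ``t_max`` is exhausted; ``converged`` reports which.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    params = params if params is not None else model.baseline_params
    f, dyn_ids, full_state = _rhs_factory(model, params)

    if init is None:
        init = model.initial_state()
    y = np.array([init[s] for s in dyn_ids], dtype=float)
    if np.any(y < 0):
        raise ValueError("initial concentrations must be non-negative")

    t, span = 0.0, 10.0
    n_spans = 0
    residual = _scaled_residual(f(y), y)
    while residual > tol and t < t_max:
        sol = solve_ivp(
            lambda _t, yy: f(yy),
            (t, min(t + span, t_max)),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise SteadyStateError(
                f"integration failed at t={t}: {sol.message}",
                last_state=full_state(y),
            )
        y = sol.y[:, -1]
        t = sol.t[-1]
        span *= 4.0
        n_spans += 1
        residual = _scaled_residual(f(y), y)

    y = _clamp_small_negatives(y)
    residual = _scaled_residual(f(y), y)
    converged = residual <= tol
    state = full_state(y)
    fluxes = evaluate_rates(model, state, params)
    return SteadyStateResult(
        concentrations={s: float(state[s]) for s in model.species_ids},
        fluxes=dict(zip(model.reaction_ids, map(float, fluxes))),
        converged=converged,
        residual_norm=residual,
        method="relaxation",
        diagnostics={"t_final": t, "n_spans": n_spans, "tol": tol},
    )


def refine_newton(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    guess: dict | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = 50,
) -> SteadyStateResult:
    """Damped Newton iteration on F(C) = N v(C).

    Uses a finite-difference Jacobian; steps that would push a
    concentration negative, or that fail to reduce ||F||, are halved.
    Never silently diverges: ``converged`` is False when the iteration
    stalls or the Jacobian is singular after damping.
    """
    params = params if params is not None else model.baseline_params
    f, dyn_ids, full_state = _rhs_factory(model, params)
    if guess is None:
        guess = model.initial_state()
    y = np.array([guess[s] for s in dyn_ids], dtype=float)
    if np.any(y < 0):
        raise ValueError("guess concentrations must be non-negative")

    n = len(y)
    converged = False
    n_iter = 0
    fy = f(y)
    for n_iter in range(1, max_iter + 1):
        if _scaled_residual(fy, y) <= tol:
            converged = True
            n_iter -= 1
            break
        # finite-difference Jacobian
        jac = np.empty((n, n))
        for k in range(n):
            h = 1e-7 * max(abs(y[k]), 1e-6)
            yk = y.copy()
            yk[k] += h
            jac[:, k] = (f(yk) - fy) / h
        try:
            step = np.linalg.solve(jac, -fy)
        except np.linalg.LinAlgError:
            log.warning("singular Jacobian in Newton iteration %d", n_iter)
            break
        # damping: keep concentrations non-negative and ||F|| decreasing
        lam = 1.0
        accepted = False
        norm0 = np.linalg.norm(fy)
        for _ in range(40):
            y_new = y + lam * step
            if np.all(y_new >= 0):
                fy_new = f(y_new)
                if np.linalg.norm(fy_new) < norm0 or _scaled_residual(fy_new, y_new) <= tol:
                    y, fy = y_new, fy_new
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            log.warning("Newton stalled at iteration %d", n_iter)
            break
    else:
        n_iter = max_iter
    if _scaled_residual(fy, y) <= tol:
        converged = True

    state = full_state(y)
    fluxes = evaluate_rates(model, state, params)
    return SteadyStateResult(
        concentrations={s: float(state[s]) for s in model.species_ids},
        fluxes=dict(zip(model.reaction_ids, map(float, fluxes))),
        converged=converged,
        residual_norm=_scaled_residual(fy, y),
        method="newton",
        diagnostics={"iterations": n_iter, "tol": tol},
    )


def solve_steady_state(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    init: dict | None = None,
    tol: float = DEFAULT_TOL,
    t_max: float = 1e7,
) -> SteadyStateResult:
    """Hybrid strategy: relaxation to near-steady, Newton polish.

    Falls back to the relaxation result when Newton fails (singular
    Jacobian, stall); the returned ``method`` records which route produced
    the answer.
    """
    relax = simulate_to_steady_state(model, params, init=init, tol=max(tol, 1e-6), t_max=t_max)
    newton = refine_newton(model, params, guess=relax.concentrations, tol=tol)
    if newton.converged:
        newton.method = "hybrid"
        newton.diagnostics["relaxation_t_final"] = relax.diagnostics.get("t_final")
        return newton
    if relax.residual_norm <= tol:
        return relax
    # retry relaxation at the requested tolerance before giving up
    relax = simulate_to_steady_state(model, params, init=init, tol=tol, t_max=t_max)
    return relax


def compute_fluxes(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    steady: dict | None = None,
    tol: float = 1e-6,
) -> dict:
    """Reaction fluxes at a converged steady state.

    Verifies the balance ||N v||_inf <= tol before returning.
    """
    params = params if params is not None else model.baseline_params
    if steady is None:
        raise ValueError("steady concentrations required")
    v = evaluate_rates(model, steady, params)
    n_mat = stoichiometric_matrix(model)
    resid = float(np.max(np.abs(n_mat @ v)))
    if resid > tol:
        raise SteadyStateError(
            f"state is not a steady state: ||N v||_inf = {resid:g} > {tol:g}"
        )
    return dict(zip(model.reaction_ids, map(float, v)))
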