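"""Steady-state solver: closed forms, oracle equivalence, balances."""

import numpy as np
import pytest

from trpflux.model import ModelConfig, build_default_model, stoichiometric_matrix
from trpflux.steady_state import (
    SteadyStateError,
    compute_fluxes,
    refine_newton,
    simulate_to_steady_state,
    solve_steady_state,
)

from conftest import make_toy_model


class TestToyClosedForm:
    def test_steady_state_matches_algebra(self, toy_model):
        """Source k0 = 1, MM consumption (Vmax = 2, Km = 1):
        S* = Km k0 / (Vmax - k0) = 1, outflux = 1."""
        result = simulate_to_steady_state(toy_model, tol=1e-12)
        assert result.converged
        assert result.concentrations["S"] == pytest.approx(1.0, rel=1e-8)
        assert result.fluxes["R_out"] == pytest.approx(1.0, rel=1e-8)

    def test_capacity_below_inflow_never_converges(self):
        model = make_toy_model(vmax_out=0.5)  # max removal 0.5 < inflow 1
        result = simulate_to_steady_state(model, tol=1e-9, t_max=2000.0)
        assert not result.converged
        # S keeps growing: far beyond any steady value
        assert result.concentrations["S"] > 100.0

    def test_newton_from_relaxation_confirms_root(self, toy_model):
        relax = simulate_to_steady_state(toy_model, tol=1e-10)
        newton = refine_newton(toy_model, guess=relax.concentrations, tol=1e-12)
        assert newton.converged
        assert newton.diagnostics["iterations"] <= 3
        assert newton.concentrations["S"] == pytest.approx(relax.concentrations["S"], rel=1e-8)

    def test_newton_at_exact_root_is_fixed_point(self, toy_model):
        exact = {"X_ext": 1.0, "S": 1.0}
        newton = refine_newton(toy_model, guess=exact, tol=1e-10)
        assert newton.converged
        assert newton.diagnostics["iterations"] == 0
        assert newton.concentrations["S"] == pytest.approx(1.0, abs=1e-12)

    def test_all_capacities_zero_root_is_origin(self):
        from trpflux.model import ModelDefinition, ParameterSet, ReactionDef, SpeciesDef

        species = [SpeciesDef("B", is_boundary=True, initial_concentration=1.0),
                   SpeciesDef("S")]
        reactions = [ReactionDef("X_S", None, [("S", 1)], [], "first_order_clearance")]
        params = ParameterSet(kclear={"X_S": 1.0})
        model = ModelDefinition(species=species, reactions=reactions, baseline_params=params)
        newton = refine_newton(model, guess={"B": 1.0, "S": 0.7}, tol=1e-12)
        assert newton.converged
        assert newton.concentrations["S"] == pytest.approx(0.0, abs=1e-10)


class TestDefaultModel:
    def test_converges_from_default_init(self, baseline_steady):
        assert baseline_steady.converged
        assert baseline_steady.residual_norm <= 1e-9
        assert all(c >= 0 for c in baseline_steady.concentrations.values())

    def test_unique_steady_state_from_random_init(self, default_model, baseline_steady, rng):
        init = {s.id: (s.initial_concentration if s.is_boundary else float(rng.uniform(0, 2)))
                for s in default_model.species}
        other = solve_steady_state(default_model, init=init)
        assert other.converged
        for sid in default_model.dynamic_ids:
            assert other.concentrations[sid] == pytest.approx(
                baseline_steady.concentrations[sid], rel=1e-6, abs=1e-10)

    def test_conservation_at_steady_state(self, default_model, baseline_steady):
        n = stoichiometric_matrix(default_model)
        v = baseline_steady.flux_vector(default_model.reaction_ids)
        assert np.max(np.abs(n @ v)) <= 1e-9

    def test_kyn_node_balance(self, default_model, baseline_steady):
        """flux(TDO2) = flux(KMO) + flux(KAT) + flux(KYNU_a) + net Kyn
        export through the antiporters."""
        f = baseline_steady.fluxes
        lhs = f["R_TDO2"]
        rhs = f["R_KMO"] + f["R_KAT"] + f["R_KYNU_a"] + f["R_LAT1"] + f["R_LAT2"]
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_chain_fluxes_equal_in_series(self, default_model, baseline_steady):
        # HKyn3 -> HAA3 -> Quin -> sink is a linear chain at steady state
        f = baseline_steady.fluxes
        assert f["R_KYNU_b"] == pytest.approx(f["R_HAAO"], rel=1e-8)
        assert f["R_HAAO"] == pytest.approx(f["R_QPRT"], rel=1e-8)

    def test_compute_fluxes_validates_state(self, default_model, baseline_steady):
        fluxes = compute_fluxes(default_model, steady=baseline_steady.concentrations)
        assert fluxes == pytest.approx(baseline_steady.fluxes)
        bad = dict(baseline_steady.concentrations)
        bad["Kyn"] *= 7.0
        with pytest.raises(SteadyStateError, match="not a steady state"):
            compute_fluxes(default_model, steady=bad)

    def test_negative_init_rejected(self, default_model):
        init = default_model.initial_state()
        init["Kyn"] = -0.1
        with pytest.raises(ValueError):
            simulate_to_steady_state(default_model, init=init)


class TestSolverProperties:
    def test_relaxation_newton_oracle_equivalence(self, default_model, rng):
        """The two routes agree to 1e-6 relative on randomized parameters."""
        for _ in range(5):
            params = default_model.baseline_params.copy()
            for rid in params.vmax:
                params.vmax[rid] *= float(rng.uniform(0.5, 2.0))
            relax = simulate_to_steady_state(default_model, params, tol=1e-11)
            newton = refine_newton(default_model, params, guess=relax.concentrations, tol=1e-12)
            assert relax.converged and newton.converged
            for sid in default_model.dynamic_ids:
                assert newton.concentrations[sid] == pytest.approx(
                    relax.concentrations[sid], rel=1e-6, abs=1e-12)
            for rid in default_model.reaction_ids:
                assert newton.fluxes[rid] == pytest.approx(
                    relax.fluxes[rid], rel=1e-6, abs=1e-12)

    def test_tdo2_flux_monotone_in_tdo2_capacity(self, default_model):
        """Steady-state TDO2 flux is non-decreasing in Vmax(TDO2) over a
        100-fold sweep."""
        fluxes = []
        for factor in np.geomspace(0.1, 10.0, 7):
            params = default_model.baseline_params.copy()
            params.vmax["R_TDO2"] *= float(factor)
            result = solve_steady_state(default_model, params)
            assert result.converged
            fluxes.append(result.fluxes["R_TDO2"])
        diffs = np.diff(fluxes)
        assert np.all(diffs >= -1e-9 * np.abs(fluxes[:-1]))

    @pytest.mark.parametrize("lam", [0.5, 2.0])
    def test_global_capacity_scaling_neutrality(self, default_model, baseline_steady, lam):
        """Scaling every Vmax and clearance by lambda leaves concentrations
        unchanged and scales all fluxes by lambda."""
        params = default_model.baseline_params.copy()
        for rid in params.vmax:
            params.vmax[rid] *= lam
        for rid in params.kclear:
            params.kclear[rid] *= lam
        result = solve_steady_state(default_model, params)
        assert result.converged
        for sid in default_model.dynamic_ids:
            assert result.concentrations[sid] == pytest.approx(
                baseline_steady.concentrations[sid], rel=1e-6, abs=1e-12)
        for rid in default_model.reaction_ids:
            assert result.fluxes[rid] == pytest.approx(
                lam * baseline_steady.fluxes[rid], rel=1e-6, abs=1e-12)

    def test_oxygen_term_model_reaches_steady_state(self):
        model = build_default_model(ModelConfig(oxygen_term=True, oxygen_level=0.2))
        result = solve_steady_state(model)
        assert result.converged
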