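"""Network construction, stoichiometry and rate-law evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trpflux.model import (
    ConfigurationError,
    ModelConfig,
    ModelDefinition,
    ParameterSet,
    ReactionDef,
    SpeciesDef,
    build_default_model,
    evaluate_rates,
    stoichiometric_matrix,
)

ENZYMES = ["R_TDO2", "R_KAT", "R_KMO", "R_KYNU_a", "R_KYNU_b", "R_HAAO",
           "R_QPRT", "R_DDC_trp", "R_TPH1", "R_DDC_5htp", "R_IL4I1",
           "R_INMT_1", "R_INMT_2"]
TRANSPORTERS = ["R_LAT1", "R_LAT2"]


class TestDefaultModel:
    def test_contains_all_enzymes_and_transporters(self, default_model):
        rids = set(default_model.reaction_ids)
        assert set(ENZYMES) <= rids
        assert set(TRANSPORTERS) <= rids
        # 9 named enzymes drive 13 enzymatic reactions (gene fan-out) plus
        # 2 transporters and the facilitated uptake step
        non_clearance = [r for r in default_model.reactions
                         if r.rate_law != "first_order_clearance"]
        assert len(non_clearance) == 16

    def test_boundary_trp_clamped_at_10(self, default_model):
        trp_ext = default_model.species_by_id("Trp_ext")
        assert trp_ext.is_boundary
        assert trp_ext.initial_concentration == 10.0

    def test_oxygen_dependence_flags(self, default_model):
        oxy = {r.id for r in default_model.reactions if r.oxygen_dependent}
        assert oxy == {"R_TDO2", "R_KMO", "R_HAAO", "R_TPH1", "R_IL4I1"}
        # DDC works without oxygen
        assert not default_model.reaction_by_id("R_DDC_trp").oxygen_dependent

    def test_il4i1_branch_toggle(self):
        model = build_default_model(ModelConfig(include_il4i1=False))
        assert "R_IL4I1" not in model.reaction_ids
        assert "I3P" not in model.species_ids
        # everything else intact
        assert set(ENZYMES) - {"R_IL4I1"} <= set(model.reaction_ids)

    def test_trp_ext_configurable(self):
        model = build_default_model(ModelConfig(trp_ext=0.05))
        assert model.species_by_id("Trp_ext").initial_concentration == 0.05

    def test_duplicate_species_rejected(self):
        species = [SpeciesDef("A", is_boundary=True, initial_concentration=1.0),
                   SpeciesDef("A")]
        with pytest.raises(ConfigurationError, match="duplicate"):
            ModelDefinition(species=species, reactions=[], baseline_params=ParameterSet())

    def test_orphan_species_rejected(self):
        species = [SpeciesDef("A", is_boundary=True, initial_concentration=1.0),
                   SpeciesDef("B")]
        with pytest.raises(ConfigurationError, match="orphan"):
            ModelDefinition(species=species, reactions=[], baseline_params=ParameterSet())

    def test_antiport_needs_two_by_two(self):
        with pytest.raises(ConfigurationError, match="antiport"):
            ReactionDef("R_x", None, [("A", 1)], [("B", 1)], "antiport_exchange")


class TestStoichiometry:
    def test_toy_chain(self):
        species = [SpeciesDef("Src", is_boundary=True, initial_concentration=1.0),
                   SpeciesDef("A"), SpeciesDef("B"), SpeciesDef("C")]
        reactions = [
            ReactionDef("r0", None, [("Src", 1)], [("A", 1)], "irreversible_mm"),
            ReactionDef("r1", None, [("A", 1)], [("B", 1)], "irreversible_mm"),
            ReactionDef("r2", None, [("B", 1)], [("C", 1)], "irreversible_mm"),
        ]
        params = ParameterSet(vmax={"r0": 1, "r1": 1, "r2": 1},
                              km={"r0": {"Src": 1}, "r1": {"A": 1}, "r2": {"B": 1}})
        model = ModelDefinition(species=species, reactions=reactions, baseline_params=params)
        n = stoichiometric_matrix(model)
        # rows A, B, C; columns r0, r1, r2
        assert n.tolist() == [[1, -1, 0], [0, 1, -1], [0, 0, 1]]

    def test_antiport_column_excludes_boundary(self, default_model):
        n = stoichiometric_matrix(default_model)
        dyn = default_model.dynamic_ids
        j = default_model.reaction_ids.index("R_LAT1")
        col = {sid: n[i, j] for i, sid in enumerate(dyn) if n[i, j] != 0}
        assert col == {"Trp": 1.0, "Kyn": -1.0}

    def test_clearance_columns_single_minus_one(self, default_model):
        n = stoichiometric_matrix(default_model)
        for j, r in enumerate(default_model.reactions):
            if r.rate_law == "first_order_clearance":
                col = n[:, j]
                assert np.count_nonzero(col) == 1
                assert col.sum() == -1.0


class TestRateLaws:
    def test_half_saturation(self, toy_model):
        # S = Km -> v = Vmax / 2
        v = evaluate_rates(toy_model, {"X_ext": 1.0, "S": 1.0})
        assert v[toy_model.reaction_ids.index("R_out")] == pytest.approx(1.0)  # Vmax=2

    def test_zero_concentrations_zero_rates(self, default_model):
        conc = {s: 0.0 for s in default_model.species_ids}
        v = evaluate_rates(default_model, conc)
        assert np.all(v == 0.0)

    def test_antiport_equilibrium_is_zero(self, default_model):
        # Trp_ext * Kyn_in == Trp_in * Kyn_ext with keq_bias = 1 -> net 0
        conc = {s: 0.0 for s in default_model.species_ids}
        conc.update({"Trp_ext": 10.0, "Kyn_ext": 0.1, "Trp": 5.0, "Kyn": 0.05})
        v = evaluate_rates(default_model, conc)
        for rid in ("R_LAT1", "R_LAT2"):
            assert v[default_model.reaction_ids.index(rid)] == pytest.approx(0.0, abs=1e-15)

    def test_negative_concentration_rejected(self, default_model):
        conc = {s: 0.0 for s in default_model.species_ids}
        conc["Trp"] = -1e-3
        with pytest.raises(ValueError, match="negative concentration"):
            evaluate_rates(default_model, conc)

    @settings(deadline=None, max_examples=25)
    @given(factor=st.floats(0.01, 100), data=st.data())
    def test_vmax_homogeneity(self, default_model, factor, data):
        """Doubling (or any scaling of) a reaction's Vmax scales exactly
        that reaction's rate at fixed concentrations."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        conc = {s.id: (s.initial_concentration if s.is_boundary else float(rng.uniform(0, 2)))
                for s in default_model.species}
        params = default_model.baseline_params
        v0 = evaluate_rates(default_model, conc, params)
        rid = data.draw(st.sampled_from(sorted(params.vmax)))
        scaled = params.copy()
        scaled.vmax[rid] *= factor
        v1 = evaluate_rates(default_model, conc, scaled)
        j = default_model.reaction_ids.index(rid)
        assert v1[j] == pytest.approx(factor * v0[j], rel=1e-12)
        mask = np.arange(len(v0)) != j
        np.testing.assert_allclose(v1[mask], v0[mask], rtol=0)

    def test_irreversible_rates_nonnegative(self, default_model, rng):
        for _ in range(20):
            conc = {s.id: (s.initial_concentration if s.is_boundary
                           else float(rng.uniform(0, 5)))
                    for s in default_model.species}
            v = evaluate_rates(default_model, conc)
            for j, r in enumerate(default_model.reactions):
                if r.rate_law != "antiport_exchange":
                    assert v[j] >= 0.0

    def test_oxygen_limit_matches_disabled(self):
        """oxygen_level = 1 with Km_O2 -> 0 recovers the oxygen-free rates."""
        plain = build_default_model(ModelConfig(oxygen_term=False))
        oxy = build_default_model(ModelConfig(oxygen_term=True, oxygen_level=1.0))
        oxy.baseline_params.km_oxygen = {r: 1e-15 for r in oxy.baseline_params.km_oxygen}
        conc = {s.id: (s.initial_concentration if s.is_boundary else 0.5)
                for s in plain.species}
        v_plain = evaluate_rates(plain, conc)
        v_oxy = evaluate_rates(oxy, conc, oxy.baseline_params)
        np.testing.assert_allclose(v_oxy, v_plain, rtol=1e-12)

    def test_oxygen_term_reduces_oxygen_dependent_rates(self):
        hypoxic = build_default_model(ModelConfig(oxygen_term=True, oxygen_level=0.05))
        conc = {s.id: (s.initial_concentration if s.is_boundary else 0.5)
                for s in hypoxic.species}
        v_hyp = evaluate_rates(hypoxic, conc)
        normal = build_default_model(ModelConfig(oxygen_term=False))
        v_norm = evaluate_rates(normal, conc)
        for j, r in enumerate(hypoxic.reactions):
            if r.oxygen_dependent:
                assert v_hyp[j] < v_norm[j]
            elif r.rate_law != "antiport_exchange":
                assert v_hyp[j] == pytest.approx(v_norm[j])


def test_stoichiometry_times_flux_equals_derivative(default_model, rng):
    """N v matches the simulator's right-hand side on random states."""
    from trpflux.steady_state import _rhs_factory

    f, dyn_ids, _ = _rhs_factory(default_model, default_model.baseline_params)
    n = stoichiometric_matrix(default_model)
    boundary = {s.id: s.initial_concentration for s in default_model.species if s.is_boundary}
    for _ in range(10):
        y = rng.uniform(0, 3, size=len(dyn_ids))
        conc = dict(boundary)
        conc.update(zip(dyn_ids, y))
        v = evaluate_rates(default_model, conc)
        np.testing.assert_allclose(f(y), n @ v, rtol=1e-12)
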