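"""Scale enzyme capacities with expression and watch the flux rewiring.

Generates a noiseless synthetic expression table (so the effect is exactly
the regulation profile), scales each Vmax by the hypoxia/normoxia
expression ratio of its gene, and compares the two steady states.  Ratios
below 1 mean hypoxia lowers that flux or concentration.
"""

from trpflux import (
    NoiseModel,
    build_default_model,
    compute_scaling_factors,
    generate_expression,
    scale_parameters,
    solve_steady_state,
)
from trpflux.expression import ratios_for_replicate

model = build_default_model()
table = generate_expression(noise=NoiseModel(replicate_cv=0.0, n_replicates=2, seed=0))
factors = compute_scaling_factors(table, reference_condition="normoxia")

normoxia = solve_steady_state(model)
hypoxia_params = scale_parameters(model.baseline_params,
                                  ratios_for_replicate(factors, "hypoxia", 1))
hypoxia = solve_steady_state(model, hypoxia_params)

print("flux               normoxia    hypoxia    ratio")
for rid in ("R_LAT1", "R_LAT2", "R_TDO2", "R_KMO", "R_KAT", "R_KYNU_a",
            "R_HAAO", "R_QPRT", "R_DDC_trp", "R_INMT_1", "R_TPH1"):
    a, b = normoxia.fluxes[rid], hypoxia.fluxes[rid]
    print(f"{rid:15s} {a:10.4f} {b:10.4f} {b / a:8.3f}")

print("\nconcentration      normoxia    hypoxia    ratio")
for sid in ("Kyn", "HAA3", "Quin", "Trypta"):
    a, b = normoxia.concentrations[sid], hypoxia.concentrations[sid]
    print(f"{sid:15s} {a:10.4f} {b:10.4f} {b / a:8.3f}")

print("\nratios < 1 across the kynurenine pathway and > 1 for the tryptamine")
print("branch show the hypoxic rerouting of Trp flux away from Kyn.")
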