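"""Simulated metabolite measurements with detection limits.

Perturbs the steady-state concentrations with multiplicative log-normal
noise per replicate and left-censors values below a per-metabolite limit
of detection, mimicking instrument panels where low-abundance metabolites
appear as "n.d." (not detected).
"""

from trpflux import NoiseModel, build_default_model, generate_metabolite_fixture

model = build_default_model()
fixture = generate_metabolite_fixture(
    model,
    noise=NoiseModel(replicate_cv=0.15, n_replicates=3, seed=42),
    lod={"DMT": 0.2, "HTP5": 0.05},
)

print(fixture.to_string(index=False, float_format="%.4f"))
n_cens = int(fixture.censored.sum())
print(f"\n{n_cens} of {len(fixture)} entries censored (value below the limit "
      "of detection; reported as NaN with the limit recorded).")
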