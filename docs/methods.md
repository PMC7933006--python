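# Methods

## The model

`trpflux` models tryptophan (Trp) metabolism in a single hepatocyte as a
system of ordinary differential equations

    dC/dt = N v(C),

where `C` is the vector of intracellular metabolite concentrations, `N` the
stoichiometric matrix and `v(C)` the vector of reaction rates. Extracellular
Trp and kynurenine (Kyn) are *boundary species*: their concentrations are
clamped and they contribute no row to `N`. The default extracellular Trp is
10 model units, configurable via `ModelConfig(trp_ext=...)`. The printed unit
label is "mM-equivalent": 10 mM is far above typical free plasma Trp
(tens of µM), so the value should be read as a model convention rather than a
physical millimolar concentration; it is exposed as configuration and not
silently corrected.

The network comprises:

- **Kynurenine pathway (KP):** TDO2 (Trp→Kyn, lumping the
  N-formylkynurenine formamidase step), KAT (Kyn→kynurenic acid), KMO
  (Kyn→3-hydroxykynurenine), KYNU acting twice (Kyn→anthranilic acid and
  3-hydroxykynurenine→3-hydroxyanthranilic acid), HAAO
  (3HAA→quinolinate, lumping the non-enzymatic ACMS cyclisation) and QPRT
  (quinolinate→a NaMN sink pool).
- **Tryptamine branch:** DDC (Trp→tryptamine) and two sequential INMT
  methylations (tryptamine→N-methyltryptamine→DMT).
- **Serotonin branch:** TPH1 (Trp→5-HTP) and DDC (5-HTP→serotonin).
- **IL4I1 branch:** Trp→indole-3-pyruvate.
- **Transport:** LAT1/LAT2 (SLC7A5/SLC7A8) antiporters exchanging
  extracellular Trp for intracellular Kyn, plus a gene-independent
  facilitated uptake step `R_TRP_UPTAKE`.
- **Clearances:** first-order sinks for every terminal metabolite
  (kynurenic acid, anthranilic acid, NaMN pool, serotonin,
  indole-3-pyruvate, DMT, and a tryptamine clearance representing
  monoamine oxidase), so that a steady state exists at all.

**Why the uptake step exists.** If the antiport were the only Trp entry,
mass balance would force every branch flux to zero at steady state: the
antiport couples Trp import 1:1 to Kyn export, while every Kyn molecule is
itself made from imported Trp by TDO2. Adding the Trp and Kyn node balances
then gives `0 = v_KAT + v_KMO + v_KYNU_a + v_DDC + v_TPH1 + v_IL4I1`, which
for irreversible (non-negative) rates means all zero. Hepatocytes in fact
take up Trp through more than the two LATs; `R_TRP_UPTAKE` represents that
residual entry as a Michaelis–Menten step on the clamped extracellular pool
(hence a constant influx), keeping the network open. It carries no gene and
is never scaled by expression.

IDO1/IDO2 are omitted (hepatic KP entry is dominated by constitutive TDO2),
as are the xanthurenate branch, NAD salvage, reversible thermodynamics and
albumin-bound/free Trp partitioning. KATs are represented by one reaction
assigned to the gene *Kyat1*.

## Rate laws

- `irreversible_mm`: `v = Vmax · S / (Km + S)`.
- `antiport_exchange` (LAT1/2):
  `v = Vmax · (S_out·C_in − b·S_in·C_out) / ((Km_S + S_out + S_in)(Km_C + C_in + C_out))`
  with `S` = Trp, `C` = Kyn, bias `b = 1` by default; positive `v` is net
  Trp import / Kyn export, and `v = 0` exactly at exchange equilibrium
  `S_out·C_in = S_in·C_out`.
- `first_order_clearance`: `v = k_clear · S`.
- Optional oxygen term (off by default): each oxygen-requiring reaction
  (TDO2, KMO, HAAO, TPH1, IL4I1 — dioxygenase/monooxygenase/oxidase
  chemistry; DDC, KATs, KYNU, QPRT, INMT and the transporters need no O2)
  is multiplied by `O2/(Km_O2 + O2)` with dimensionless `O2 ∈ [0,1]`. The
  default analysis encodes hypoxia purely through expression scaling; the
  O2 term is an optional mechanistic extension, and with `O2 = 1`,
  `Km_O2 → 0` it reduces exactly to the plain rates.

## Parameters

Kinetic constants are model design choices (units: concentration in
mM-equivalents, time in hours), set by two rules:

1. at the baseline steady state every enzyme operates below saturation
   (substrate within ~10× of its Km), so that capacity changes propagate
   into flux changes instead of being masked by saturation;
2. the KP carries the majority of baseline Trp flux, with the tryptamine,
   serotonin and IL4I1 branches minor — the expected situation for
   hepatocytes where TDO2 dominates.

Defaults live in `trpflux.model.default_parameter_set()` and serialise to
YAML (`pipeline.save_parameters` / `load_parameters`). The extracellular
Kyn boundary defaults to 0.1 (non-zero so the antiport law is well-posed).
Because `v(C)` is homogeneous of degree 1 in the capacity/clearance vector,
multiplying *all* Vmax and clearance constants by λ rescales all fluxes by
λ and leaves concentrations unchanged — absolute capacities set only the
time/flux scale, while the *ratios* between capacities shape the steady
state. The differential analysis therefore depends on the expression fold
changes, not on the absolute parameter scale (this invariance is tested).

## Expression integration

Expression tables are long-format `(gene, condition, replicate, value)` on
a linear scale. For each gene, each value is divided by the mean of the
reference-condition (normoxia) replicates, giving per-replicate ratios with
reference mean mapping to 1. Each ratio multiplies the Vmax of every
reaction mapped to the gene (Ddc, Kynu and Inmt each drive two reactions);
Km, clearances and boundary concentrations are untouched. The transform is
linear (capacity ∝ expression); gene symbols are matched case-insensitively
after trimming, and unmapped genes (e.g. the hypoxia marker Ndrg1) are
inert. Scaling per replicate — not per condition mean — preserves the
replicate structure for the statistics (n = 3 per condition by default).

## Steady-state solver

Two routes, used as mutual cross-checks:

- **Relaxation:** LSODA integration of the clamped ODE system over
  geometrically growing time spans until
  `max_i |dC_i/dt| ≤ tol · max(1, |C_i|)` (default `tol = 1e-9` per hour).
- **Newton:** damped Newton on `F(C) = N v(C)` with finite-difference
  Jacobian; steps are halved if they would make a concentration negative or
  fail to reduce `‖F‖`, and a singular Jacobian or stall is reported as
  non-convergence rather than silent divergence.

The default `solve_steady_state` is the hybrid: relaxation to `1e-6`, Newton
polish to `1e-9`, with fallback to pure relaxation if Newton fails. The
default initial state is all dynamic species at 0 except intracellular Trp
at 1% of the extracellular value (deterministic; it also breaks the trivial
all-zero fixed point, which is unstable but exact). Concentrations more
negative than `−10·eps` fail the run; smaller negatives are clamped to 0
with a logged notice. The toy one-species model with consumption capacity
below the constant inflow has no steady state and is reported as
non-converged at the horizon, by design.

## Differential statistics

For each reaction flux and each species concentration, replicate values of
the two conditions are compared with an unpaired two-tailed t-test — Welch
(unequal variances) by default, classic pooled-variance Student's as an
option; both p-values are always present in the output since at n = 3 the
choice can matter. Summaries are mean ± SEM and fold change
(test/reference on the linear scale). Significance codes: `*` p ≤ 0.05,
`**` ≤ 0.01, `***` ≤ 0.001, `****` ≤ 0.0001, else `ns`. If both arms have
(numerically) zero variance the test degenerates to an equality check:
p = 1 for equal means, p = 0 otherwise — this makes noiseless (cv = 0)
runs exactly deterministic instead of producing NaNs. No multiple-testing
correction is applied to the codes; a Benjamini–Hochberg column is emitted
as supplementary output only.

The *sign-pattern* check compares significant directions with an
expectation set. The shipped default encodes the hypoxic rewiring: fluxes
down through LAT1, LAT2, TDO2, KAT, both KYNU steps, KMO, HAAO, QPRT;
fluxes up through DDC (Trp→tryptamine) and both INMT steps; concentrations
down for Kyn, 3HAA, Quin and up for tryptamine. TPH1 flux, kynurenic acid
and indole-3-pyruvate are deliberately unconstrained.

## Synthetic data

The generator emulates the *design* of a normoxia/hypoxia hepatocyte
expression experiment: 13 genes (the 12 mapped ones plus Ndrg1), two
conditions, n = 3 replicates, multiplicative log-normal noise. The noise
factor is mean-one (`exp(N(−σ²/2, σ²))`, `σ² = ln(1 + cv²)`, default
cv = 0.1) so replicate means converge to the profile means. Default fold
changes (hypoxia/normoxia) encode regulation *directions* only — Tdo2 0.1,
Kmo 0.4, Kynu/Kyat1/Slc7a5/Slc7a8 0.5, Haao/Qprt 0.6, Tph1 1.3, Il4i1 1.0,
Ddc 2.0, Inmt 2.5, Ndrg1 8.0 — with magnitudes as configurable fixture
choices, not measured values; baseline means are a flat 100 on an arbitrary
linear-intensity scale. What passing tests show is therefore that the
*pipeline* turns a down-TDO2/up-DDC transcriptional state into the
corresponding flux rewiring with correct statistics — not that these
magnitudes match any particular microarray. Probe-level artefacts,
normalisation effects, gene–gene correlations and heavier-tailed biological
noise are not emulated.

The metabolite-fixture generator perturbs steady-state concentrations with
the same noise model and left-censors values below a limit of detection
(`value = NaN`, `censored = True`, limit recorded), mimicking "n.d."
entries of instrument panels.

## Determinism and precision

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduce byte-identical
tables (floats are written with 12 significant digits). The pipeline writes
a manifest with input hashes, package version, seed and stage timings.

## Known limitations

- At n = 3 with cv = 0.1 the weakest constrained effect (the tryptamine
  concentration, fold ≈ 1.2–1.4) has limited power: with an unlucky noise
  draw its Welch p-value can exceed 0.05 and the sign-pattern check then
  reports that single mismatch. This is a property of three-replicate
  designs, not of the solver; cv = 0 runs are exact.
- Kinetic constants are design choices satisfying structural constraints,
  not fitted values; only direction-of-change conclusions should be read
  from the defaults.
- The SBML writer/reader pair is minimal: it produces standard-shaped
  Level 3 documents (clamped boundary species, MathML kinetic laws, local
  parameters) and reads back what it writes, but it is not a general SBML
  parser.
- No multistability or bifurcation analysis is attempted; a uniqueness
  probe from random initial states is part of the test suite, not a proof.
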