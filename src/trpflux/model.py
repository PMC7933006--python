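"""Kinetic network of hepatic tryptophan metabolism.

The model describes how a hepatocyte partitions tryptophan (Trp) taken up
from the extracellular medium between the kynurenine pathway (KP) --
TDO2 -> kynurenine -> (kynurenic acid | 3-hydroxykynurenine ->
3-hydroxyanthranilic acid -> quinolinic acid -> NaMN) -- and the minor
routes: decarboxylation to tryptamine (DDC) with downstream methylation by
INMT to methyltryptamine and DMT, hydroxylation to 5-HTP and serotonin
(TPH1/DDC), and oxidative deamination to indole-3-pyruvate (IL4I1).

Extracellular Trp and Kyn are boundary species with clamped concentrations.
Trp enters the cell through the large neutral amino acid antiporters
LAT1/LAT2 (SLC7A5/SLC7A8), which exchange extracellular Trp for
intracellular Kyn, and through a gene-independent facilitated uptake step
(the antiport alone cannot sustain a non-trivial steady state: it couples
Trp import 1:1 to Kyn export, while every Kyn molecule derives from
imported Trp, so all branch fluxes would be forced to zero).  Terminal
metabolites are removed by first-order clearance so that a steady state
exists.

Rate laws are deliberately simple: irreversible Michaelis-Menten for
enzymes, a reversible bi-substrate exchange law for the antiporters, and
first-order clearance for sinks.  Enzyme capacities (Vmax) are the handle
through which per-replicate gene expression is injected (see
:mod:`trpflux.expression`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ParameterSet",
    "ModelDefinition",
    "ModelConfig",
    "ConfigurationError",
    "build_default_model",
    "stoichiometric_matrix",
    "evaluate_rates",
    "DEFAULT_GENE_MAP",
]

RATE_LAWS = ("irreversible_mm", "antiport_exchange", "first_order_clearance")


class ConfigurationError(ValueError):
    """Raised when a model configuration is internally inconsistent."""


@dataclass(frozen=True)
class SpeciesDef:
    """A metabolite pool.

    Boundary species have a clamped (fixed) concentration and contribute no
    row to the stoichiometric matrix; dynamic species evolve under
    dC/dt = N v(C).
    """

    id: str
    display_name: str = ""
    compartment: str = "intracellular"  # or "extracellular"
    is_boundary: bool = False
    initial_concentration: float = 0.0

    def __post_init__(self):
        if self.compartment not in ("intracellular", "extracellular"):
            raise ConfigurationError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.is_boundary:
            c = self.initial_concentration
            if not np.isfinite(c) or c < 0:
                raise ConfigurationError(
                    f"boundary species {self.id!r} needs a finite concentration >= 0"
                )


@dataclass(frozen=True)
class ReactionDef:
    """A reaction with one of three rate-law forms.

    ``substrates``/``products`` are lists of ``(species_id, stoichiometric
    coefficient)``.  For ``antiport_exchange`` the convention is
    substrates = [(S_out, 1), (C_in, 1)], products = [(S_in, 1), (C_out, 1)]
    with S the inward-moving substrate (Trp) and C the counter-substrate
    (Kyn); positive rate means net inward S transport.
    """

    id: str
    gene: str | None = None
    substrates: tuple = ()
    products: tuple = ()
    rate_law: str = "irreversible_mm"
    oxygen_dependent: bool = False

    def __post_init__(self):
        object.__setattr__(self, "substrates", tuple((s, float(c)) for s, c in self.substrates))
        object.__setattr__(self, "products", tuple((s, float(c)) for s, c in self.products))
        if self.rate_law not in RATE_LAWS:
            raise ConfigurationError(f"reaction {self.id!r}: unknown rate law {self.rate_law!r}")
        if self.rate_law == "antiport_exchange":
            if len(self.substrates) != 2 or len(self.products) != 2:
                raise ConfigurationError(
                    f"antiport reaction {self.id!r} must have exactly 2 substrates and 2 products"
                )
        if self.rate_law == "first_order_clearance":
            if len(self.substrates) != 1 or len(self.products) != 0:
                raise ConfigurationError(
                    f"clearance reaction {self.id!r} must have exactly 1 substrate and no products"
                )

    @property
    def species_ids(self) -> tuple:
        return tuple(s for s, _ in self.substrates) + tuple(s for s, _ in self.products)


@dataclass
class ParameterSet:
    """Kinetic parameters; one (possibly expression-scaled) copy per replicate.

    vmax
        reaction id -> capacity (concentration / time).
    km
        reaction id -> {species id -> Michaelis constant}.  For antiport
        reactions the Km of the exchanged substrate applies jointly to its
        internal + external pools.
    keq_bias
        reaction id -> dimensionless reversibility bias for antiport
        (1 = symmetric exchange).
    kclear
        reaction id -> first-order clearance constant (1 / time).
    oxygen_level
        dimensionless ambient oxygen in [0, 1]; only consulted when the
        model's optional oxygen term is enabled.
    km_oxygen
        reaction id -> oxygen Michaelis constant for oxygen-dependent steps.
    """

    vmax: dict = field(default_factory=dict)
    km: dict = field(default_factory=dict)
    keq_bias: dict = field(default_factory=dict)
    kclear: dict = field(default_factory=dict)
    oxygen_level: float = 1.0
    km_oxygen: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, d in (("vmax", self.vmax), ("kclear", self.kclear), ("km_oxygen", self.km_oxygen)):
            for rid, v in d.items():
                if not v > 0:
                    raise ConfigurationError(f"{name}[{rid!r}] must be > 0, got {v}")
        for rid, kms in self.km.items():
            for sid, v in kms.items():
                if not v > 0:
                    raise ConfigurationError(f"km[{rid!r}][{sid!r}] must be > 0, got {v}")
        if not 0.0 <= self.oxygen_level <= 1.0:
            raise ConfigurationError(f"oxygen_level must lie in [0, 1], got {self.oxygen_level}")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "vmax": dict(self.vmax),
            "km": {r: dict(k) for r, k in self.km.items()},
            "keq_bias": dict(self.keq_bias),
            "kclear": dict(self.kclear),
            "oxygen_level": self.oxygen_level,
            "km_oxygen": dict(self.km_oxygen),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            vmax=dict(d.get("vmax", {})),
            km={r: dict(k) for r, k in d.get("km", {}).items()},
            keq_bias=dict(d.get("keq_bias", {})),
            kclear=dict(d.get("kclear", {})),
            oxygen_level=float(d.get("oxygen_level", 1.0)),
            km_oxygen=dict(d.get("km_oxygen", {})),
        )


@dataclass
class ModelDefinition:
    """The reaction network plus its baseline parameters and unit labels."""

    species: list
    reactions: list
    baseline_params: ParameterSet
    units: dict = field(default_factory=lambda: {"concentration": "mM-equivalent", "time": "h"})
    oxygen_term_enabled: bool = False

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def species_ids(self) -> list:
        return [s.id for s in self.species]

    @property
    def dynamic_species(self) -> list:
        return [s for s in self.species if not s.is_boundary]

    @property
    def dynamic_ids(self) -> list:
        return [s.id for s in self.dynamic_species]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    def species_by_id(self, sid: str) -> SpeciesDef:
        return self._species_map[sid]

    def reaction_by_id(self, rid: str) -> ReactionDef:
        return self._reaction_map[rid]

    def initial_state(self) -> dict:
        return {s.id: s.initial_concentration for s in self.species}

    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ConfigurationError("duplicate reaction ids")
        self._species_map = {s.id: s for s in self.species}
        self._reaction_map = {r.id: r for r in self.reactions}
        for r in self.reactions:
            for sid in r.species_ids:
                if sid not in self._species_map:
                    raise ConfigurationError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
        if not any(s.is_boundary for s in self.species):
            raise ConfigurationError("model needs at least one boundary species")
        used = {sid for r in self.reactions for sid in r.species_ids}
        orphans = [s.id for s in self.dynamic_species if s.id not in used]
        if orphans:
            raise ConfigurationError(f"orphan dynamic species: {orphans}")
        self.baseline_params.validate()


@dataclass
class ModelConfig:
    """Build-time switches for the default hepatocyte network.

    trp_ext
        clamped extracellular Trp concentration (model units).  The default
        of 10 follows the study condition; it is configurable and not
        silently corrected.
    kyn_ext
        clamped extracellular Kyn concentration; non-zero so the antiport
        exchange is well-posed.
    include_il4i1 / include_serotonin / include_tryptamine
        branch toggles; disabling a branch removes its reactions and any
        species that become orphaned.
    oxygen_term
        enable the optional O2/(Km_O2+O2) Michaelis factor on
        oxygen-dependent reactions.  Off by default: the hypoxic condition
        is encoded purely through expression scaling.
    """

    trp_ext: float = 10.0
    kyn_ext: float = 0.1
    include_il4i1: bool = True
    include_serotonin: bool = True
    include_tryptamine: bool = True
    oxygen_term: bool = False
    oxygen_level: float = 1.0
    concentration_unit: str = "mM-equivalent"
    time_unit: str = "h"

    def to_dict(self) -> dict:
        return {
            "trp_ext": self.trp_ext,
            "kyn_ext": self.kyn_ext,
            "include_il4i1": self.include_il4i1,
            "include_serotonin": self.include_serotonin,
            "include_tryptamine": self.include_tryptamine,
            "oxygen_term": self.oxygen_term,
            "oxygen_level": self.oxygen_level,
            "concentration_unit": self.concentration_unit,
            "time_unit": self.time_unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# Default network
# ---------------------------------------------------------------------------

#: gene symbol -> reaction ids driven by that gene (capacity scaling targets)
DEFAULT_GENE_MAP = {
    "Slc7a5": ["R_LAT1"],
    "Slc7a8": ["R_LAT2"],
    "Tdo2": ["R_TDO2"],
    "Kyat1": ["R_KAT"],
    "Kmo": ["R_KMO"],
    "Kynu": ["R_KYNU_a", "R_KYNU_b"],
    "Haao": ["R_HAAO"],
    "Qprt": ["R_QPRT"],
    "Ddc": ["R_DDC_trp", "R_DDC_5htp"],
    "Tph1": ["R_TPH1"],
    "Il4i1": ["R_IL4I1"],
    "Inmt": ["R_INMT_1", "R_INMT_2"],
}

_SPECIES_TABLE = [
    # id, display name, compartment, boundary, initial
    ("Trp_ext", "extracellular tryptophan", "extracellular", True, 10.0),
    ("Kyn_ext", "extracellular kynurenine", "extracellular", True, 0.1),
    ("Trp", "tryptophan", "intracellular", False, 0.0),
    ("Kyn", "kynurenine", "intracellular", False, 0.0),
    ("KynA", "kynurenic acid", "intracellular", False, 0.0),
    ("HKyn3", "3-hydroxykynurenine", "intracellular", False, 0.0),
    ("HAA3", "3-hydroxyanthranilic acid", "intracellular", False, 0.0),
    ("AA", "anthranilic acid", "intracellular", False, 0.0),
    ("Quin", "quinolinic acid", "intracellular", False, 0.0),
    ("NaMN_sinkpool", "NaMN sink pool", "intracellular", False, 0.0),
    ("Trypta", "tryptamine", "intracellular", False, 0.0),
    ("MeTrypta", "N-methyltryptamine", "intracellular", False, 0.0),
    ("DMT", "N,N-dimethyltryptamine", "intracellular", False, 0.0),
    ("HTP5", "5-hydroxytryptophan", "intracellular", False, 0.0),
    ("Serotonin", "serotonin", "intracellular", False, 0.0),
    ("I3P", "indole-3-pyruvate", "intracellular", False, 0.0),
]

# oxygen-requiring steps: dioxygenase/monooxygenase/oxidase chemistry
_OXYGEN_DEPENDENT = {"R_TDO2", "R_KMO", "R_HAAO", "R_TPH1", "R_IL4I1"}

_BRANCH_REACTIONS = {
    "il4i1": ["R_IL4I1", "X_I3P"],
    "serotonin": ["R_TPH1", "R_DDC_5htp", "X_Serotonin"],
    "tryptamine": ["R_DDC_trp", "R_INMT_1", "R_INMT_2", "X_Trypta", "X_DMT"],
}


def _default_reactions() -> list:
    mm = "irreversible_mm"
    rxns = [
        # gene-independent facilitated Trp uptake; keeps the network open so
        # a non-trivial steady state exists (see module docstring)
        ReactionDef("R_TRP_UPTAKE", None, [("Trp_ext", 1)], [("Trp", 1)], mm, False),
        ReactionDef("R_LAT1", "Slc7a5", [("Trp_ext", 1), ("Kyn", 1)],
                    [("Trp", 1), ("Kyn_ext", 1)], "antiport_exchange", False),
        ReactionDef("R_LAT2", "Slc7a8", [("Trp_ext", 1), ("Kyn", 1)],
                    [("Trp", 1), ("Kyn_ext", 1)], "antiport_exchange", False),
        # TDO2 lumps N-formylkynurenine hydrolysis into a single Trp -> Kyn step
        ReactionDef("R_TDO2", "Tdo2", [("Trp", 1)], [("Kyn", 1)], mm, True),
        ReactionDef("R_KAT", "Kyat1", [("Kyn", 1)], [("KynA", 1)], mm, False),
        ReactionDef("R_KMO", "Kmo", [("Kyn", 1)], [("HKyn3", 1)], mm, True),
        ReactionDef("R_KYNU_a", "Kynu", [("Kyn", 1)], [("AA", 1)], mm, False),
        ReactionDef("R_KYNU_b", "Kynu", [("HKyn3", 1)], [("HAA3", 1)], mm, False),
        # HAAO lumps the non-enzymatic ACMS cyclisation into HAA3 -> Quin
        ReactionDef("R_HAAO", "Haao", [("HAA3", 1)], [("Quin", 1)], mm, True),
        ReactionDef("R_QPRT", "Qprt", [("Quin", 1)], [("NaMN_sinkpool", 1)], mm, False),
        ReactionDef("R_DDC_trp", "Ddc", [("Trp", 1)], [("Trypta", 1)], mm, False),
        ReactionDef("R_TPH1", "Tph1", [("Trp", 1)], [("HTP5", 1)], mm, True),
        ReactionDef("R_DDC_5htp", "Ddc", [("HTP5", 1)], [("Serotonin", 1)], mm, False),
        ReactionDef("R_IL4I1", "Il4i1", [("Trp", 1)], [("I3P", 1)], mm, True),
        ReactionDef("R_INMT_1", "Inmt", [("Trypta", 1)], [("MeTrypta", 1)], mm, False),
        ReactionDef("R_INMT_2", "Inmt", [("MeTrypta", 1)], [("DMT", 1)], mm, False),
    ]
    # terminal sinks; X_Trypta represents monoamine-oxidase degradation
    for sid in ("KynA", "AA", "NaMN_sinkpool", "Serotonin", "I3P", "DMT", "Trypta"):
        rxns.append(ReactionDef(f"X_{sid}", None, [(sid, 1)], [],
                                "first_order_clearance", False))
    return rxns


def default_parameter_set() -> ParameterSet:
    """Baseline kinetic parameters (concentration: mM-equivalent, time: h).

    Chosen so that at the normoxic steady state every enzyme operates below
    saturation (substrate within ~10x of its Km); capacity changes then
    propagate into flux changes instead of being masked by saturation.
    """
    vmax = {
        "R_TRP_UPTAKE": 2.0,
        "R_LAT1": 12.0,
        "R_LAT2": 6.0,
        "R_TDO2": 6.0,
        "R_KAT": 0.8,
        "R_KMO": 1.6,
        "R_KYNU_a": 0.4,
        "R_KYNU_b": 2.0,
        "R_HAAO": 2.5,
        "R_QPRT": 2.0,
        "R_DDC_trp": 0.8,
        "R_TPH1": 0.25,
        "R_DDC_5htp": 1.5,
        "R_IL4I1": 0.4,
        "R_INMT_1": 1.2,
        "R_INMT_2": 1.0,
    }
    km = {
        "R_TRP_UPTAKE": {"Trp_ext": 10.0},
        "R_LAT1": {"Trp_ext": 2.0, "Kyn": 0.2},
        "R_LAT2": {"Trp_ext": 2.0, "Kyn": 0.2},
        "R_TDO2": {"Trp": 0.5},
        "R_KAT": {"Kyn": 0.4},
        "R_KMO": {"Kyn": 0.4},
        "R_KYNU_a": {"Kyn": 0.4},
        "R_KYNU_b": {"HKyn3": 0.3},
        "R_HAAO": {"HAA3": 0.3},
        "R_QPRT": {"Quin": 0.3},
        "R_DDC_trp": {"Trp": 1.5},
        "R_TPH1": {"Trp": 1.5},
        "R_DDC_5htp": {"HTP5": 0.5},
        "R_IL4I1": {"Trp": 1.5},
        "R_INMT_1": {"Trypta": 0.4},
        "R_INMT_2": {"MeTrypta": 0.4},
    }
    keq_bias = {"R_LAT1": 1.0, "R_LAT2": 1.0}
    kclear = {f"X_{s}": 2.0
              for s in ("KynA", "AA", "NaMN_sinkpool", "Serotonin", "I3P", "DMT", "Trypta")}
    km_oxygen = {rid: 0.05 for rid in sorted(_OXYGEN_DEPENDENT)}
    return ParameterSet(vmax=vmax, km=km, keq_bias=keq_bias, kclear=kclear,
                        oxygen_level=1.0, km_oxygen=km_oxygen)


def build_default_model(config: ModelConfig | None = None) -> ModelDefinition:
    """Construct the default hepatocyte Trp network.

    Returns the 9 KP / tryptamine / serotonin / IL4I1 enzymes, the two LAT
    antiporters, a facilitated uptake step, and first-order clearances for
    terminal metabolites, honouring the branch toggles in ``config``.
    """
    config = config or ModelConfig()
    species = []
    for sid, name, comp, boundary, init in _SPECIES_TABLE:
        if sid == "Trp_ext":
            init = config.trp_ext
        elif sid == "Kyn_ext":
            init = config.kyn_ext
        elif sid == "Trp":
            init = 0.01 * config.trp_ext  # deterministic, biologically innocuous seed
        species.append(SpeciesDef(sid, name, comp, boundary, init))

    reactions = _default_reactions()
    params = default_parameter_set()

    removed: set = set()
    if not config.include_il4i1:
        removed |= set(_BRANCH_REACTIONS["il4i1"])
    if not config.include_serotonin:
        removed |= set(_BRANCH_REACTIONS["serotonin"])
    if not config.include_tryptamine:
        removed |= set(_BRANCH_REACTIONS["tryptamine"])
    if removed:
        reactions = [r for r in reactions if r.id not in removed]
        for rid in removed:
            params.vmax.pop(rid, None)
            params.km.pop(rid, None)
            params.kclear.pop(rid, None)
            params.km_oxygen.pop(rid, None)
        used = {sid for r in reactions for sid in r.species_ids}
        species = [s for s in species if s.is_boundary or s.id in used]
        kept_ids = {s.id for s in species}
        for r in reactions:
            missing = [sid for sid in r.species_ids if sid not in kept_ids]
            if missing:
                raise ConfigurationError(
                    f"reaction {r.id!r} references species {missing} removed by a branch toggle"
                )

    params.oxygen_level = config.oxygen_level
    return ModelDefinition(
        species=species,
        reactions=reactions,
        baseline_params=params,
        units={"concentration": config.concentration_unit, "time": config.time_unit},
        oxygen_term_enabled=config.oxygen_term,
    )


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: ModelDefinition) -> np.ndarray:
    """Net stoichiometric matrix N (dynamic species x reactions).

    Boundary species are excluded from the rows; their concentrations are
    clamped and do not evolve.
    """
    dyn = model.dynamic_ids
    idx = {sid: i for i, sid in enumerate(dyn)}
    n = np.zeros((len(dyn), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for sid, coeff in r.substrates:
            if sid in idx:
                n[idx[sid], j] -= coeff
        for sid, coeff in r.products:
            if sid in idx:
                n[idx[sid], j] += coeff
    return n


def evaluate_rates(
    model: ModelDefinition,
    concentrations: dict,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """Evaluate all reaction rates at the given concentrations.

    ``concentrations`` maps species id -> value (boundary species included).
    Returns a vector aligned with ``model.reactions``.
    """
    params = params if params is not None else model.baseline_params
    for sid, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for species {sid!r}: {c}")

    o2_factor = 1.0
    if model.oxygen_term_enabled:
        o2 = params.oxygen_level
        o2_km = params.km_oxygen

    v = np.empty(len(model.reactions))
    for j, r in enumerate(model.reactions):
        if r.rate_law == "irreversible_mm":
            s_id = r.substrates[0][0]
            s = concentrations[s_id]
            km = params.km[r.id][s_id]
            rate = params.vmax[r.id] * s / (km + s)
            if model.oxygen_term_enabled and r.oxygen_dependent:
                km_o2 = o2_km.get(r.id, 0.0)
                rate *= o2 / (km_o2 + o2) if (km_o2 + o2) > 0 else 0.0
            v[j] = rate
        elif r.rate_law == "antiport_exchange":
            (s_out_id, _), (c_in_id, _) = r.substrates
            (s_in_id, _), (c_out_id, _) = r.products
            s_out = concentrations[s_out_id]
            s_in = concentrations[s_in_id]
            c_in = concentrations[c_in_id]
            c_out = concentrations[c_out_id]
            km_s = params.km[r.id][s_out_id]
            km_c = params.km[r.id][c_in_id]
            bias = params.keq_bias.get(r.id, 1.0)
            num = s_out * c_in - bias * s_in * c_out
            v[j] = params.vmax[r.id] * num / ((km_s + s_out + s_in) * (km_c + c_in + c_out))
        else:  # first_order_clearance
            s_id = r.substrates[0][0]
            v[j] = params.kclear[r.id] * concentrations[s_id]
    return v
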