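"""Expression-constrained capacity scaling.

Per-replicate gene expression (linear scale) is converted into
per-replicate scaling ratios relative to the reference-condition mean, and
those ratios multiply the Vmax of every reaction driven by the gene.  This
yields one parameterisation per replicate, so downstream statistics see the
biological replicate structure (n per condition) rather than a single
condition mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model import DEFAULT_GENE_MAP, ModelDefinition, ParameterSet

__all__ = [
    "ExpressionTable",
    "GeneReactionMap",
    "compute_scaling_factors",
    "scale_parameters",
]

log = logging.getLogger(__name__)

COLUMNS = ["gene", "condition", "replicate", "value"]


@dataclass
class ExpressionTable:
    """Long-format gene x condition x replicate expression values.

    Wraps a DataFrame with columns ``gene, condition, replicate, value``;
    values are non-negative linear-scale expression.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        df = df[COLUMNS].copy()
        df["gene"] = df["gene"].astype(str).str.strip()
        df["condition"] = df["condition"].astype(str).str.strip()
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if (df["value"] < 0).any():
            bad = df.loc[df["value"] < 0, "gene"].unique()
            raise ValueError(f"negative expression values for genes: {list(bad)}")
        dup = df.duplicated(subset=["gene", "condition", "replicate"])
        if dup.any():
            raise ValueError(
                f"duplicate (gene, condition, replicate) rows: "
                f"{df.loc[dup, ['gene', 'condition', 'replicate']].to_dict('records')}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def genes(self) -> list:
        return sorted(self.data["gene"].unique())

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    def replicates(self, condition: str) -> list:
        return sorted(self.data.loc[self.data["condition"] == condition, "replicate"].unique())

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_csv(cls, path) -> "ExpressionTable":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep, comment="#"))

    def write_csv(self, path, header_comment: str | None = None) -> None:
        path = Path(path)
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.data.to_csv(fh, sep=sep, index=False)


@dataclass
class GeneReactionMap:
    """Gene symbol -> reaction ids whose capacity the gene drives.

    Matching of incoming gene symbols is case-insensitive after trimming.
    One gene may drive several reactions (Ddc, Kynu and Inmt each drive 2).
    """

    mapping: dict = field(default_factory=lambda: {g: list(r) for g, r in DEFAULT_GENE_MAP.items()})

    def __post_init__(self):
        self.mapping = {str(g).strip(): list(r) for g, r in self.mapping.items()}
        self._lower = {g.lower(): g for g in self.mapping}

    def reactions_for(self, gene: str) -> list:
        key = self._lower.get(str(gene).strip().lower())
        return list(self.mapping[key]) if key else []

    def validate_against(self, model: ModelDefinition) -> None:
        rids = set(model.reaction_ids)
        for g, rxns in self.mapping.items():
            unknown = [r for r in rxns if r not in rids]
            if unknown:
                raise ValueError(f"gene {g!r} maps to unknown reactions: {unknown}")

    @classmethod
    def read_yaml(cls, path) -> "GeneReactionMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.mapping, fh, sort_keys=True)


def compute_scaling_factors(
    table: ExpressionTable,
    reference_condition: str,
    aggregation: str = "per_replicate",
) -> pd.DataFrame:
    """Expression ratios relative to the reference-condition mean.

    Each value is divided by the mean expression of the same gene in the
    reference condition, so the reference mean maps to ratio 1.  With
    ``aggregation="mean"`` the per-condition mean replaces individual
    replicates (one ratio per gene and condition, replicate set to 0).

    Returns a DataFrame with columns ``gene, condition, replicate, ratio``.
    """
    if aggregation not in ("per_replicate", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = table.data
    if reference_condition not in set(df["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} not in table")
    ref = df[df["condition"] == reference_condition].groupby("gene")["value"].mean()
    zero_ref = ref[ref == 0]
    if len(zero_ref):
        raise ValueError(
            f"all-zero reference expression for gene(s): {list(zero_ref.index)}"
        )
    missing_ref = set(df["gene"]) - set(ref.index)
    if missing_ref:
        raise ValueError(
            f"gene(s) absent from reference condition: {sorted(missing_ref)}"
        )
    if aggregation == "mean":
        agg = df.groupby(["gene", "condition"], as_index=False)["value"].mean()
        agg["replicate"] = 0
        df = agg
    out = df.copy()
    out["ratio"] = out["value"] / out["gene"].map(ref)
    return out[["gene", "condition", "replicate", "ratio"]].reset_index(drop=True)


def scale_parameters(
    baseline: ParameterSet,
    ratios: dict,
    gene_map: GeneReactionMap | None = None,
) -> ParameterSet:
    """Multiply Vmax by the expression ratio of each mapped gene.

    ``ratios`` maps gene symbol -> ratio for ONE replicate.  Km, clearance
    constants and everything else are untouched.  Genes absent from the map
    (e.g. the hypoxia marker Ndrg1) are ignored with a logged notice.
    """
    gene_map = gene_map or GeneReactionMap()
    scaled = baseline.copy()
    for gene, ratio in ratios.items():
        if ratio < 0:
            raise ValueError(f"negative scaling ratio for gene {gene!r}: {ratio}")
        rxns = gene_map.reactions_for(gene)
        if not rxns:
            log.info("gene %r maps to no reaction; ignored", gene)
            continue
        for rid in rxns:
            if rid in scaled.vmax:
                scaled.vmax[rid] = scaled.vmax[rid] * float(ratio)
    return scaled


def ratios_for_replicate(factors: pd.DataFrame, condition: str, replicate: int) -> dict:
    """Extract the gene -> ratio mapping of a single replicate from
    :func:`compute_scaling_factors` output."""
    sel = factors[(factors["condition"] == condition) & (factors["replicate"] == replicate)]
    return dict(zip(sel["gene"], sel["ratio"]))
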