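"""Core domain types shared across the pipeline.

The pipeline relates four kinds of gene-association evidence (GWAS hits,
disease differential expression, drug-perturbation differential expression,
and drug-disease indications) to signed pathway topologies.  All tabular
evidence is carried as a long-form :class:`AssociationTable`; pathway
knowledge is carried as :class:`PathwayGraph` objects (membership plus
signed, directed edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class ContractError(ValueError):
    """An operation was called with arguments outside its precondition."""


class DegenerateDataError(ValueError):
    """Data is too degenerate for the requested statistic (e.g. zero variance)."""


class SingularPathwayError(RuntimeError):
    """The pathway perturbation system (I - B) is numerically singular."""


#: kinds of association evidence; 'effect' is mandatory exactly for the DEG kinds
DEG_KINDS = frozenset({"disease_deg", "drug_deg"})
TABLE_KINDS = frozenset({"gwas", "disease_deg", "drug_deg", "indication"})

ASSOCIATION_COLUMNS = ["entity_id", "gene_id", "effect", "source"]


@dataclass
class AssociationTable:
    """Long-form (entity, gene) association records of a single kind.

    For ``kind='indication'`` the ``gene_id`` column holds the associated
    disease identifier (the table is a drug-disease edge list reusing the
    generic two-column layout).
    """

    df: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise ValidationError(f"unknown table kind: {self.kind!r}")
        for col in ("entity_id", "gene_id"):
            if col not in self.df.columns:
                raise FormatError(f"association table is missing column {col!r}")
        df = self.df.copy()
        if "effect" not in df.columns:
            if self.kind in DEG_KINDS:
                raise ValidationError(
                    f"kind {self.kind!r} requires an 'effect' column"
                )
            df["effect"] = np.nan
        if "source" not in df.columns:
            df["source"] = ""
        df = df[ASSOCIATION_COLUMNS].reset_index(drop=True)
        if self.kind in DEG_KINDS:
            eff = pd.to_numeric(df["effect"], errors="coerce")
            if eff.isna().any():
                bad = df.index[eff.isna()].tolist()
                raise ValidationError(
                    f"kind {self.kind!r} has missing/non-numeric effects at rows {bad[:10]}"
                )
            if (eff == 0).any():
                bad = df.index[eff == 0].tolist()
                raise ValidationError(
                    f"kind {self.kind!r} has zero effects at rows {bad[:10]}"
                )
            if not np.isfinite(eff).all():
                raise ValidationError(f"kind {self.kind!r} has non-finite effects")
            df["effect"] = eff.astype(float)
        dup = df.duplicated(subset=["entity_id", "gene_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate (entity_id, gene_id) rows: {df.loc[dup, ['entity_id', 'gene_id']].values[:5]}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def entities(self) -> list[str]:
        return sorted(self.df["entity_id"].unique())

    def genes(self) -> frozenset[str]:
        return frozenset(self.df["gene_id"])

    def gene_sets(self) -> dict[str, frozenset[str]]:
        """Per-entity gene sets."""
        return {
            e: frozenset(g["gene_id"])
            for e, g in self.df.groupby("entity_id", sort=True)
        }

    def signature(self, entity_id: str) -> "GeneSignature":
        """Extract one entity's gene signature (effects where present)."""
        sub = self.df[self.df["entity_id"] == entity_id]
        genes = frozenset(sub["gene_id"])
        if self.kind in DEG_KINDS:
            delta_e = dict(zip(sub["gene_id"], sub["effect"].astype(float)))
        else:
            delta_e = {}
        return GeneSignature(entity_id=entity_id, genes=genes, delta_e=delta_e)


@dataclass(frozen=True)
class GeneSignature:
    """One entity's (disease or drug) gene set with signed expression changes.

    ``delta_e`` maps genes to signed log-fold-change-scale effects and feeds
    the perturbation model; genes without an effect contribute only to
    set-overlap statistics.
    """

    entity_id: str
    genes: frozenset[str]
    delta_e: Mapping[str, float]

    def __post_init__(self) -> None:
        extra = set(self.delta_e) - set(self.genes)
        if extra:
            raise ValidationError(f"delta_e keys outside genes: {sorted(extra)[:5]}")
        for g, v in self.delta_e.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite effect for gene {g}")

    def de_genes(self) -> frozenset[str]:
        """Genes with a nonzero effect."""
        return frozenset(g for g, v in self.delta_e.items() if v != 0)


#: relation-string to signed edge weight
RELATION_BETA = {"activation": 1.0, "inhibition": -1.0}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    beta: float
    relation: str


@dataclass(frozen=True)
class PathwayGraph:
    """A single pathway: member genes plus signed, directed regulatory edges."""

    database: str
    pathway_id: str
    members: frozenset[str]
    edges: tuple[Edge, ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(
                f"pathway {self.database}:{self.pathway_id} has no members"
            )
        for e in self.edges:
            if e.source not in self.members or e.target not in self.members:
                raise ValidationError(
                    f"edge {e.source}->{e.target} of {self.database}:{self.pathway_id} "
                    "references a gene that is not a pathway member"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.database, self.pathway_id)


@dataclass(frozen=True)
class MappingTable:
    """Static identifier harmonization: source id -> canonical id."""

    pairs: Mapping[str, str]

    def __contains__(self, source_id: str) -> bool:
        return source_id in self.pairs

    def __getitem__(self, source_id: str) -> str:
        return self.pairs[source_id]


@dataclass
class RunConfig:
    """Thresholds and policies steering the full pipeline.

    The q thresholds are Benjamini-Hochberg-adjusted p-value cutoffs: 0.05
    for the disease-DEG vs GWAS filter and for pathway significance, a much
    stricter 1e-10 for the drug-DEG vs GWAS filter (drug perturbations carry
    no intrinsic disease context, so false positives are penalized harder).
    ``corr_max`` / ``affected_min_pct`` gate the single-drug shortlist
    (correlation <= -0.4, coverage > 50%); the pair thresholds are the
    stricter two-drug equivalents (-0.50 / 80%).
    """

    q_disease_gwas: float = 0.05
    q_drug_gwas: float = 1e-10
    q_triple: float = 0.05
    q_pathway: float = 0.05
    corr_max: float = -0.4
    affected_min_pct: float = 50.0
    pair_corr_max: float = -0.50
    pair_affected_min_pct: float = 80.0
    n_boot: int = 200
    seed: int = 0
    universe_policy: str = "observed_union"
    index_policy: str = "union"
    restrict_to_indications: bool = True
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("q_disease_gwas", "q_drug_gwas", "q_triple", "q_pathway"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for name in ("corr_max", "pair_corr_max"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValidationError(f"{name} must be in [-1, 1], got {v}")
        for name in ("affected_min_pct", "pair_affected_min_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.universe_policy not in ("observed_union", "explicit"):
            raise ValidationError(f"unknown universe_policy {self.universe_policy!r}")
        if self.index_policy not in ("union", "disease_only"):
            raise ValidationError(f"unknown index_policy {self.index_policy!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
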