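"""GWAS-contextualization of expression signatures by gene-set overlap.

Three cascaded filters, each a one-sided Fisher's exact (hypergeometric)
test of gene-set over-representation followed by a joint Benjamini-Hochberg
correction:

1. disease DEG vs disease GWAS over all disease pairs (q <= 0.05 retained;
   same-disease survivors are the "disease-specific gene sets"),
2. drug DEG vs disease GWAS over candidate drug-disease pairs
   (q <= 1e-10; candidates default to indicated pairs),
3. stage-1 vs stage-2 gene sets per (drug, disease) (q <= 0.05).

Every stage is optional; the caller decides how much disease context to
impose before pathway enrichment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    AssociationTable,
    ContractError,
    GeneSignature,
    RunConfig,
)

log = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """One 2x2 over-representation test between two gene sets."""

    entity_a: str
    entity_b: str
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    odds_ratio: float
    p_value: float
    q_value: float = math.nan
    intersection: frozenset[str] = field(default_factory=frozenset)


@dataclass
class FilteredGeneSets:
    """Gene sets surviving one filtering stage, with DEG effects attached."""

    stage: str  # disease_specific | drug_in_disease | triple
    sets: dict = field(default_factory=dict)  # key -> GeneSignature


def fisher_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-sided enrichment test: P(X >= |A n B|) under hypergeometric sampling.

    The odds ratio is taken from the 2x2 contingency table; a 0/0 ratio is
    reported as NaN.
    """
    set_a, set_b, universe = frozenset(set_a), frozenset(set_b), frozenset(universe)
    if not universe:
        raise ContractError("universe must be nonempty")
    if not (set_a <= universe and set_b <= universe):
        raise ContractError("both gene sets must be subsets of the universe")
    m, a, b = len(universe), len(set_a), len(set_b)
    inter = set_a & set_b
    k = len(inter)
    p = float(hypergeom.sf(k - 1, m, a, b))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    num = k * (m - a - b + k)
    den = (a - k) * (b - k)
    if den > 0:
        odds = num / den
    elif num == 0:
        odds = math.nan  # 0/0: undefined
    else:
        odds = math.inf
    return OverlapResult(
        entity_a="",
        entity_b="",
        n_universe=m,
        n_a=a,
        n_b=b,
        n_overlap=k,
        odds_ratio=odds,
        p_value=p,
        intersection=inter,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ContractError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _attach_q(results: list[OverlapResult]) -> None:
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qi in zip(results, q):
            r.q_value = float(qi)


def _signature_from_intersection(
    entity_id: str, intersection: frozenset[str], effects: Mapping[str, float]
) -> GeneSignature:
    return GeneSignature(
        entity_id=entity_id,
        genes=intersection,
        delta_e={g: effects[g] for g in intersection if g in effects},
    )


def filter_disease_gwas(
    deg: AssociationTable,
    gwas: AssociationTable,
    cfg: RunConfig,
    universe: frozenset[str] | None = None,
) -> tuple[list[OverlapResult], FilteredGeneSets]:
    """Stage 1: test every (DEG disease, GWAS disease) pair; keep q <= cutoff.

    Same-disease survivors become disease-specific gene sets: genes both
    genetically associated and differentially expressed in that disease,
    carrying the DEG effects.
    """
    if len(deg) == 0 or len(gwas) == 0:
        log.warning("filter_disease_gwas: empty input table; nothing to test")
        return [], FilteredGeneSets(stage="disease_specific")
    if universe is None:
        universe = deg.genes() | gwas.genes()
    deg_sets = deg.gene_sets()
    gwas_sets = gwas.gene_sets()
    results: list[OverlapResult] = []
    for d_deg, genes_deg in deg_sets.items():
        for d_gwas, genes_gwas in gwas_sets.items():
            r = fisher_overlap(genes_deg, genes_gwas, universe)
            r.entity_a, r.entity_b = d_deg, d_gwas
            results.append(r)
    _attach_q(results)
    retained = FilteredGeneSets(stage="disease_specific")
    for r in results:
        if r.q_value <= cfg.q_disease_gwas and r.entity_a == r.entity_b:
            effects = dict(
                zip(
                    deg.df.loc[deg.df["entity_id"] == r.entity_a, "gene_id"],
                    deg.df.loc[deg.df["entity_id"] == r.entity_a, "effect"],
                )
            )
            retained.sets[r.entity_a] = _signature_from_intersection(
                r.entity_a, r.intersection, effects
            )
    return results, retained


def filter_drug_gwas(
    drug_deg: AssociationTable,
    gwas: AssociationTable,
    indications: AssociationTable | None,
    cfg: RunConfig,
    universe: frozenset[str] | None = None,
) -> tuple[list[OverlapResult], FilteredGeneSets]:
    """Stage 2: drug DEG vs disease GWAS for candidate (drug, disease) pairs.

    Candidates come from the indications table (``cfg.restrict_to_indications``,
    the default, mirroring the use of known trial evidence as disease
    context) or from the full drug x GWAS-disease cross product.  The much
    stricter q cutoff compensates for drug signatures carrying no intrinsic
    disease context.
    """
    if len(drug_deg) == 0 or len(gwas) == 0:
        log.warning("filter_drug_gwas: empty input table; nothing to test")
        return [], FilteredGeneSets(stage="drug_in_disease")
    if universe is None:
        universe = drug_deg.genes() | gwas.genes()
    drug_sets = drug_deg.gene_sets()
    gwas_sets = gwas.gene_sets()
    if cfg.restrict_to_indications:
        if indications is None or len(indications) == 0:
            log.warning("filter_drug_gwas: no indications; nothing to test")
            return [], FilteredGeneSets(stage="drug_in_disease")
        candidates = [
            (row.entity_id, row.gene_id)
            for row in indications.df.itertuples(index=False)
        ]
    else:
        candidates = list(itertools.product(sorted(drug_sets), sorted(gwas_sets)))
    results: list[OverlapResult] = []
    for drug, disease in candidates:
        genes_drug = drug_sets.get(drug)
        genes_gwas = gwas_sets.get(disease)
        if not genes_drug:
            log.warning("filter_drug_gwas: drug %s has an empty DEG set; skipped", drug)
            continue
        if genes_gwas is None:
            continue
        r = fisher_overlap(genes_drug, genes_gwas, universe)
        r.entity_a, r.entity_b = drug, disease
        results.append(r)
    _attach_q(results)
    retained = FilteredGeneSets(stage="drug_in_disease")
    effects_by_drug = {
        drug: dict(zip(sub["gene_id"], sub["effect"]))
        for drug, sub in drug_deg.df.groupby("entity_id", sort=True)
    }
    for r in results:
        if r.q_value <= cfg.q_drug_gwas:
            retained.sets[(r.entity_a, r.entity_b)] = _signature_from_intersection(
                r.entity_a, r.intersection, effects_by_drug[r.entity_a]
            )
    return results, retained


def filter_triple(
    disease_specific: FilteredGeneSets,
    drug_in_disease: FilteredGeneSets,
    cfg: RunConfig,
    universe: frozenset[str],
) -> tuple[list[OverlapResult], FilteredGeneSets]:
    """Stage 3: overlap of stage-1 and stage-2 survivors per (drug, disease).

    Retains drug-perturbed gene sets that are also genetically associated
    with the same disease; output gene sets inherit the drug effects and are
    subsets of both parent sets by construction.
    """
    results: list[OverlapResult] = []
    keys: list[tuple[str, str]] = []
    for (drug, disease), drug_sig in sorted(drug_in_disease.sets.items()):
        disease_sig = disease_specific.sets.get(disease)
        if disease_sig is None:
            continue
        r = fisher_overlap(drug_sig.genes, disease_sig.genes, universe)
        r.entity_a, r.entity_b = drug, disease
        results.append(r)
        keys.append((drug, disease))
    _attach_q(results)
    retained = FilteredGeneSets(stage="triple")
    for r, key in zip(results, keys):
        if r.q_value <= cfg.q_triple:
            retained.sets[key] = _signature_from_intersection(
                key[0], r.intersection, dict(drug_in_disease.sets[key].delta_e)
            )
    return results, retained
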