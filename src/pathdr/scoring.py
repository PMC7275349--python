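"""Drug prioritization by anti-correlation of pathway signature vectors.

Each entity's enrichment result is reduced to a sparse +-1 vector over
significantly dysregulated pathways (+1 activated, -1 inhibited).  A drug
is a repositioning candidate for a disease when its vector anti-correlates
with the disease vector (Pearson r <= -0.4 by default) while covering more
than half of the disease's dysregulated pathways; the mirror-image query
(strong positive correlation) nominates drugs that *simulate* the disease
signature, e.g. for building disease models.  Two-drug combinations are
formed by sign-consistent union and scored the same way against stricter
cutoffs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .model import ContractError, RunConfig
from .spia import EnrichmentRecord

log = logging.getLogger(__name__)

PathwayKey = tuple[str, str]

#: symbols for Levenshtein comparison over the {-1, 0, +1} alphabet
_LEV_SYMBOL = {-1: "d", 0: "z", 1: "u"}


@dataclass(frozen=True)
class SignatureVector:
    """Sparse pathway-level +-1 signature; pathways absent are implicitly 0."""

    entity_id: str
    values: Mapping[PathwayKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.values.values() if v not in (-1, 1)}
        if bad:
            raise ContractError(f"signature values must be +-1, got {bad}")

    @property
    def support(self) -> frozenset[PathwayKey]:
        return frozenset(self.values)

    def materialize(self, index: Sequence[PathwayKey]) -> np.ndarray:
        return np.array([self.values.get(k, 0) for k in index], dtype=float)


@dataclass
class ScoreRecord:
    """One (drug or drug pair, disease) comparison."""

    drug_key: str | tuple[str, str]
    disease: str
    correlation: float | None  # None: undefined (a constant vector)
    affected_pct: float
    levenshtein: int
    n_disease_pathways: int
    n_shared: int


def build_signature_vector(
    records: Iterable[EnrichmentRecord], q_threshold: float, entity_id: str = ""
) -> SignatureVector:
    """Keep significantly dysregulated pathways; map direction to +-1."""
    values: dict[PathwayKey, int] = {}
    for r in records:
        if r.p_g_fdr < q_threshold and r.status in ("activated", "inhibited"):
            values[(r.database, r.pathway_id)] = 1 if r.status == "activated" else -1
    return SignatureVector(entity_id=entity_id, values=values)


def _index(
    drug: SignatureVector, disease: SignatureVector, index_policy: str
) -> list[PathwayKey]:
    if index_policy == "union":
        return sorted(drug.support | disease.support)
    if index_policy == "disease_only":
        return sorted(disease.support)
    raise ContractError(f"unknown index policy {index_policy!r}")


def correlation_score(
    drug: SignatureVector, disease: SignatureVector, index_policy: str = "union"
) -> float | None:
    """Pearson correlation of the two vectors materialized over a shared index.

    Returns None (undefined) when the index set is empty or either
    materialized vector is constant - the zero-variance case in which a
    correlation cannot be computed.
    """
    index = _index(drug, disease, index_policy)
    if not index:
        return None
    x = disease.materialize(index)
    y = drug.materialize(index)
    if x.std() == 0 or y.std() == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def affected_pct(
    drug: SignatureVector, disease: SignatureVector
) -> tuple[float, int, int]:
    """Share of the disease's dysregulated pathways also hit by the drug."""
    n_disease = len(disease.support)
    if n_disease == 0:
        raise ContractError("disease has no pathway signature")
    n_shared = len(disease.support & drug.support)
    return 100.0 * n_shared / n_disease, n_shared, n_disease


def levenshtein_score(drug: SignatureVector, disease: SignatureVector) -> int:
    """Edit distance between the two signatures as {-1, 0, +1} strings.

    Both vectors are materialized over the lexicographically ordered union
    of their supports; insert/delete/substitute all cost 1.
    """
    index = sorted(drug.support | disease.support)
    s = "".join(_LEV_SYMBOL[int(v)] for v in disease.materialize(index))
    t = "".join(_LEV_SYMBOL[int(v)] for v in drug.materialize(index))
    if not s and not t:
        return 0
    return int(edlib.align(s, t, task="distance")["editDistance"])


def combine_pair(a: SignatureVector, b: SignatureVector) -> SignatureVector:
    """Elementwise sign-of-sum combination; conflicting signs cancel to 0."""
    values: dict[PathwayKey, int] = {}
    for key in a.support | b.support:
        s = a.values.get(key, 0) + b.values.get(key, 0)
        if s != 0:
            values[key] = 1 if s > 0 else -1
    return SignatureVector(entity_id=f"{a.entity_id}+{b.entity_id}", values=values)


def _score_one(
    drug_key, drug_vec: SignatureVector, disease: str, disease_vec: SignatureVector, cfg: RunConfig
) -> ScoreRecord:
    corr = correlation_score(drug_vec, disease_vec, cfg.index_policy)
    pct, n_shared, n_disease = affected_pct(drug_vec, disease_vec)
    lev = levenshtein_score(drug_vec, disease_vec)
    return ScoreRecord(
        drug_key=drug_key,
        disease=disease,
        correlation=corr,
        affected_pct=pct,
        levenshtein=lev,
        n_disease_pathways=n_disease,
        n_shared=n_shared,
    )


def score_all(
    drug_vectors: Mapping[str, SignatureVector],
    disease_vectors: Mapping[str, SignatureVector],
    cfg: RunConfig,
) -> list[ScoreRecord]:
    """Score every (drug, disease) pair.

    Diseases without any pathway signature are skipped (there is nothing to
    revert); undefined-correlation records are kept in the output - they are
    excluded later, at ranking time.
    """
    records: list[ScoreRecord] = []
    for disease in sorted(disease_vectors):
        disease_vec = disease_vectors[disease]
        if not disease_vec.support:
            log.warning("score_all: disease %s has an empty signature; skipped", disease)
            continue
        for drug in sorted(drug_vectors):
            records.append(
                _score_one(drug, drug_vectors[drug], disease, disease_vec, cfg)
            )
    return records


def score_pairs(
    drug_vectors: Mapping[str, SignatureVector],
    disease_vectors: Mapping[str, SignatureVector],
    cfg: RunConfig,
) -> list[ScoreRecord]:
    """Score every unordered two-drug combination against every disease."""
    records: list[ScoreRecord] = []
    pair_vectors = {
        (a, b): combine_pair(drug_vectors[a], drug_vectors[b])
        for a, b in itertools.combinations(sorted(drug_vectors), 2)
    }
    for disease in sorted(disease_vectors):
        disease_vec = disease_vectors[disease]
        if not disease_vec.support:
            log.warning("score_pairs: disease %s has an empty signature; skipped", disease)
            continue
        for pair in sorted(pair_vectors):
            records.append(
                _score_one(pair, pair_vectors[pair], disease, disease_vec, cfg)
            )
    return records


def _sort_key(r: ScoreRecord, descending: bool):
    c = r.correlation
    return (-c if descending else c, -r.affected_pct, str(r.drug_key))


def prioritize(
    records: Iterable[ScoreRecord],
    corr_max: float,
    affected_min_pct: float,
    mode: str = "invert",
) -> list[ScoreRecord]:
    """Shortlist and rank candidates.

    ``invert`` keeps correlation <= ``corr_max`` (default -0.4) AND coverage
    strictly greater than ``affected_min_pct``, ranked most-negative first;
    ``mimic`` keeps correlation >= ``|corr_max|`` with the same coverage
    rule, ranked most-positive first.  Undefined correlations never rank.
    Ties break by coverage (descending), then drug key - the ranking is
    total and deterministic.
    """
    if mode not in ("invert", "mimic"):
        raise ContractError(f"unknown mode {mode!r}")
    kept = []
    for r in records:
        if r.correlation is None or math.isnan(r.correlation):
            continue
        if r.affected_pct <= affected_min_pct:
            continue
        if mode == "invert" and r.correlation <= corr_max:
            kept.append(r)
        elif mode == "mimic" and r.correlation >= abs(corr_max):
            kept.append(r)
    return sorted(kept, key=lambda r: _sort_key(r, descending=(mode == "mimic")))


def rank_records(records: Iterable[ScoreRecord]) -> list[ScoreRecord]:
    """All defined-correlation records ranked most anti-correlated first."""
    defined = [
        r
        for r in records
        if r.correlation is not None and not math.isnan(r.correlation)
    ]
    return sorted(defined, key=lambda r: _sort_key(r, descending=False))
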