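"""Signed topology-based pathway enrichment (SPIA-style).

Two independent lines of evidence are combined per pathway:

* over-representation: the hypergeometric upper tail ``pNDE`` of observing
  at least the seen number of differentially expressed (DE) members;
* perturbation propagation: gene-level signed effects dE are propagated
  through the pathway's signed topology.  The perturbation factor of gene i
  is ``PF(i) = dE(i) + sum_j beta_ij * PF(j) / N_ds(j)`` summed over its
  direct upstream regulators j, with N_ds(j) the out-degree of j - a linear
  system ``(I - B) PF = dE``.  The net accumulation ``tA = sum_i (PF(i) -
  dE(i))`` carries the direction of pathway dysregulation; its significance
  ``pPERT`` comes from a bootstrap reassigning the observed DE effects to
  random pathway members.

``pG = c - c ln c`` with ``c = pNDE * pPERT`` (Fisher's product combination)
is BH-adjusted across the pathways of a run.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.stats import hypergeom

from .model import (
    ContractError,
    GeneSignature,
    PathwayGraph,
    RunConfig,
    SingularPathwayError,
)
from .overlap import bh_adjust

log = logging.getLogger(__name__)

#: a pathway system is treated as singular below this smallest singular value
SINGULAR_TOL = 1e-10


@dataclass
class EnrichmentRecord:
    """Per-pathway enrichment evidence and direction."""

    database: str
    pathway_id: str
    n_de_on_pathway: int
    p_nde: float
    t_a: float
    p_pert: float
    p_g: float
    p_g_fdr: float
    status: str  # activated | inhibited | none


@dataclass
class PerturbationSolution:
    """Gene-level perturbation factors and their accumulation."""

    pf: dict[str, float]
    acc: dict[str, float]
    t_a: float


class PathwaySystem:
    """Cached linear system (I - B) for one pathway.

    Building the LU factorization once lets the bootstrap solve all
    replicates as one multi-right-hand-side solve.
    """

    def __init__(self, graph: PathwayGraph):
        self.graph = graph
        self.members = sorted(graph.members)
        self.index = {g: i for i, g in enumerate(self.members)}
        n = len(self.members)
        outdeg: dict[str, int] = {}
        for e in graph.edges:
            outdeg[e.source] = outdeg.get(e.source, 0) + 1
        B = np.zeros((n, n))
        for e in graph.edges:
            B[self.index[e.target], self.index[e.source]] += e.beta / outdeg[e.source]
        self.A = np.eye(n) - B
        sv = np.linalg.svd(self.A, compute_uv=False)
        self.singular = bool(sv[-1] < SINGULAR_TOL)
        self._lu = None if self.singular else lu_factor(self.A)

    def de_vector(self, delta_e: Mapping[str, float]) -> np.ndarray:
        v = np.zeros(len(self.members))
        for g, x in delta_e.items():
            i = self.index.get(g)
            if i is not None:
                v[i] = x
        return v

    def solve(self, de: np.ndarray) -> np.ndarray:
        """Solve (I - B) PF = dE; ``de`` may be a vector or an (n, k) matrix."""
        if self.singular:
            raise SingularPathwayError(
                f"pathway {self.graph.database}:{self.graph.pathway_id} has a "
                "singular perturbation system"
            )
        return lu_solve(self._lu, de)


def solve_perturbation(
    graph: PathwayGraph, delta_e: Mapping[str, float]
) -> PerturbationSolution:
    """Propagate signed effects through the pathway topology.

    Genes missing from ``delta_e`` contribute dE = 0.  Raises
    :class:`SingularPathwayError` when (I - B) is singular to tolerance;
    callers skip such pathways.
    """
    sys_ = PathwaySystem(graph)
    de = sys_.de_vector(delta_e)
    pf = sys_.solve(de)
    acc = pf - de
    return PerturbationSolution(
        pf={g: float(pf[i]) for g, i in sys_.index.items()},
        acc={g: float(acc[i]) for g, i in sys_.index.items()},
        t_a=float(acc.sum()),
    )


def p_nde(
    n_universe: int, n_pathway: int, n_de_total: int, n_de_on_pathway: int
) -> float:
    """Hypergeometric upper tail P(X >= n_de_on_pathway)."""
    if not 0 <= n_de_on_pathway <= min(n_pathway, n_de_total):
        raise ContractError("n_de_on_pathway exceeds its margins")
    if max(n_pathway, n_de_total) > n_universe:
        raise ContractError("margins exceed the universe size")
    p = float(hypergeom.sf(n_de_on_pathway - 1, n_universe, n_pathway, n_de_total))
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def p_pert(
    graph: PathwayGraph,
    delta_e_observed: Mapping[str, float],
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Bootstrap significance of the observed net accumulation tA.

    Each replicate reassigns the observed nonzero effects (in shuffled
    order) to a uniformly random subset of pathway members of the same
    cardinality.  The two-sided tail is measured as distance from the null
    median, with the (1 + k) / (n_boot + 1) estimator so p is never zero.
    Returns (p, null median).
    """
    if n_boot < 1:
        raise ContractError("n_boot must be >= 1")
    sys_ = PathwaySystem(graph)
    values = np.array([v for v in delta_e_observed.values() if v != 0], dtype=float)
    k = len(values)
    if k == 0:
        return 1.0, 0.0
    if k > len(sys_.members):
        raise ContractError("more DE effects than pathway members")
    de_obs = sys_.de_vector(delta_e_observed)
    t_obs = float(sys_.solve(de_obs).sum() - de_obs.sum())
    n = len(sys_.members)
    # random k-subsets per replicate via argsort of uniforms; values shuffled
    pos = np.argsort(rng.random((n_boot, n)), axis=1)[:, :k]
    vperm = values[np.argsort(rng.random((n_boot, k)), axis=1)]
    de = np.zeros((n_boot, n))
    np.put_along_axis(de, pos, vperm, axis=1)
    pf = sys_.solve(de.T)  # (n, n_boot)
    t_null = pf.sum(axis=0) - values.sum()
    med = float(np.median(t_null))
    count = int(np.sum(np.abs(t_null - med) >= abs(t_obs - med)))
    return (1 + count) / (n_boot + 1), med


def combine_p(p_nde_: float, p_pert_: float) -> float:
    """Fisher product combination: pG = c - c ln c with c = pNDE * pPERT."""
    for v in (p_nde_, p_pert_):
        if not 0 < v <= 1:
            raise ContractError("probabilities must lie in (0, 1]")
    c = p_nde_ * p_pert_
    if c >= 1.0:
        return 1.0
    return float(c - c * np.log(c))


def _pathway_rng(base_seed: int, graph: PathwayGraph) -> np.random.Generator:
    """Bootstrap substream keyed by (seed, pathway).

    Using a pathway-keyed stream (common random numbers) means two entities
    evaluated on the same pathway see identical bootstrap reassignments, so
    their pPERT values differ only through their observed effects - paired
    comparisons between entities (e.g. a drug against its disease) are not
    blurred by independent bootstrap noise.
    """
    key = zlib.crc32(f"{graph.database}:{graph.pathway_id}".encode())
    return np.random.default_rng([base_seed % (2**31), key])


def run_enrichment(
    signature: GeneSignature,
    universe: Iterable[str],
    pathways: Sequence[PathwayGraph],
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentRecord]:
    """Score every pathway with >= 1 DE member for one entity's signature.

    dE is the signature effect (0 for non-DE members); pG is BH-adjusted
    across the pathways of this run.  Pathways with no DE member or a
    singular topology are omitted.  By default bootstrap substreams are
    derived from ``cfg.seed`` per pathway (see :func:`_pathway_rng`); pass
    ``rng`` to decouple runs instead.
    """
    universe = frozenset(universe)
    if not signature.genes <= universe:
        raise ContractError("signature genes must be contained in the universe")
    de_genes = signature.de_genes() & universe
    if not de_genes:
        log.warning("run_enrichment: %s has no DE genes", signature.entity_id)
        return []
    base_seed = cfg.seed if rng is None else int(rng.integers(2**31))
    records: list[EnrichmentRecord] = []
    for graph in pathways:
        members_u = graph.members & universe
        if not members_u:
            continue
        n_de_on = len(graph.members & de_genes)
        if n_de_on == 0:
            continue
        sys_ = PathwaySystem(graph)
        if sys_.singular:
            log.warning(
                "run_enrichment: skipping singular pathway %s:%s",
                graph.database,
                graph.pathway_id,
            )
            continue
        effects = {g: signature.delta_e.get(g, 0.0) for g in graph.members}
        de_vec = sys_.de_vector(effects)
        t_a = float(sys_.solve(de_vec).sum() - de_vec.sum())
        pn = p_nde(len(universe), len(members_u), len(de_genes), n_de_on)
        pp, _ = p_pert(graph, effects, cfg.n_boot, _pathway_rng(base_seed, graph))
        pg = combine_p(pn, pp)
        status = "activated" if t_a > 0 else ("inhibited" if t_a < 0 else "none")
        records.append(
            EnrichmentRecord(
                database=graph.database,
                pathway_id=graph.pathway_id,
                n_de_on_pathway=n_de_on,
                p_nde=pn,
                t_a=t_a,
                p_pert=pp,
                p_g=pg,
                p_g_fdr=np.nan,
                status=status,
            )
        )
    if records:
        q = bh_adjust([r.p_g for r in records])
        for r, qi in zip(records, q):
            r.p_g_fdr = float(qi)
    return records


def run_ora(
    signature: GeneSignature,
    universe: Iterable[str],
    pathways: Sequence[PathwayGraph],
) -> list[EnrichmentRecord]:
    """Topology-free fallback: over-representation with a dominant-sign direction.

    For pathway collections without edge information, pNDE alone carries the
    evidence (pPERT = 1) and the direction is the sign of the summed DE
    effects on the pathway.  An extension for topology-free gene-set
    collections, not the demonstrated enrichment path.
    """
    universe = frozenset(universe)
    if not signature.genes <= universe:
        raise ContractError("signature genes must be contained in the universe")
    de_genes = signature.de_genes() & universe
    if not de_genes:
        log.warning("run_ora: %s has no DE genes", signature.entity_id)
        return []
    records: list[EnrichmentRecord] = []
    for graph in pathways:
        members_u = graph.members & universe
        if not members_u:
            continue
        n_de_on = len(graph.members & de_genes)
        if n_de_on == 0:
            continue
        pn = p_nde(len(universe), len(members_u), len(de_genes), n_de_on)
        net = sum(signature.delta_e.get(g, 0.0) for g in graph.members)
        status = "activated" if net > 0 else ("inhibited" if net < 0 else "none")
        records.append(
            EnrichmentRecord(
                database=graph.database,
                pathway_id=graph.pathway_id,
                n_de_on_pathway=n_de_on,
                p_nde=pn,
                t_a=float(net),
                p_pert=1.0,
                p_g=combine_p(pn, 1.0),
                p_g_fdr=np.nan,
                status=status,
            )
        )
    if records:
        q = bh_adjust([r.p_g for r in records])
        for r, qi in zip(records, q):
            r.p_g_fdr = float(qi)
    return records


def simulate_null_pathways(
    pathways: Sequence[PathwayGraph],
    universe: Iterable[str],
    rng: np.random.Generator,
) -> list[PathwayGraph]:
    """Size- and topology-preserving random pathways.

    Each true pathway's member labels are replaced by a uniform draw from
    the universe (edges relabeled accordingly); enrichment on these should
    rarely be significant, which is the control for the true pathways'
    biological signal.
    """
    universe_sorted = sorted(frozenset(universe))
    out: list[PathwayGraph] = []
    for g in pathways:
        old = sorted(g.members)
        new = rng.choice(universe_sorted, size=len(old), replace=False)
        relabel = dict(zip(old, new))
        out.append(
            PathwayGraph(
                database=g.database,
                pathway_id=f"{g.pathway_id}:sim",
                members=frozenset(new),
                edges=tuple(
                    e.__class__(
                        source=relabel[e.source],
                        target=relabel[e.target],
                        beta=e.beta,
                        relation=e.relation,
                    )
                    for e in g.edges
                ),
            )
        )
    return out
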