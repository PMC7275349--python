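"""Seeded synthetic benchmark with planted, recoverable signal.

The generator emulates the statistical structure the pipeline exploits on
real data: for each synthetic disease a few "driver" pathways are planted
with a direction (+1 up, -1 down); GWAS hits and differentially expressed
genes are both enriched in driver members, so same-disease GWAS/DEG overlap
is strong while cross-disease overlap is background.  For each disease one
*inverter* drug (gene-level effects exactly negated) and one *mimicker*
(effects copied) are planted among random decoy drugs, and the indications
table labels each inverter as trialed for its disease - giving every
downstream stage a known answer.

All output is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .model import (
    AssociationTable,
    Edge,
    PathwayGraph,
    ValidationError,
)

#: effect magnitudes are drawn uniformly from this range (log-fold-change scale)
EFFECT_RANGE = (0.5, 3.0)

DATABASE = "synthdb"


@dataclass
class SynthConfig:
    """Benchmark generator settings.

    Defaults define the standard benchmark: 2,000 genes, 50 pathways of
    10-30 genes, 5 diseases with 4 driver pathways each, and per the drug
    side one inverter and one mimicker per disease plus 20 random decoys.
    Rates are per-gene Bernoulli probabilities; ``sign_noise`` flips a DEG
    sign away from its pathway's planted direction.  With
    ``decouple_drugs=True`` the planted drugs are built from a cyclically
    shifted disease assignment while keeping their labels, which removes the
    label-score coupling and yields a signal-free control for ROC analyses.
    """

    n_genes: int = 2000
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 30)
    n_diseases: int = 5
    drivers_per_disease: int = 4
    n_random_drugs: int = 20
    gwas_hit_rate_in_driver: float = 0.5
    gwas_background_rate: float = 0.01
    deg_hit_rate_in_driver: float = 0.7
    deg_background_rate: float = 0.005
    sign_noise: float = 0.05
    inhibition_edge_prob: float = 0.3
    decouple_drugs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        self.pathway_size_range = (int(lo), int(hi))
        if lo < 3:
            raise ValidationError("pathway sizes must be >= 3")
        if lo > hi:
            raise ValidationError("pathway_size_range must be (low, high)")
        if self.drivers_per_disease > self.n_pathways:
            raise ValidationError("drivers_per_disease cannot exceed n_pathways")
        for name in (
            "gwas_hit_rate_in_driver",
            "gwas_background_rate",
            "deg_hit_rate_in_driver",
            "deg_background_rate",
            "sign_noise",
            "inhibition_edge_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["pathway_size_range"] = list(self.pathway_size_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        if "pathway_size_range" in d:
            d["pathway_size_range"] = tuple(d["pathway_size_range"])
        return cls(**d)


@dataclass
class SyntheticWorld:
    """A complete generated benchmark plus its ground truth."""

    cfg: SynthConfig
    universe: frozenset[str]
    pathways: list[PathwayGraph]
    gwas: AssociationTable
    disease_deg: AssociationTable
    drug_deg: AssociationTable
    indications: AssociationTable
    #: disease -> {(database, pathway_id): planted sign}
    disease_truth: dict[str, dict[tuple[str, str], int]]
    #: drug -> (role, disease) with role in {inverter, mimicker, random}
    drug_truth: dict[str, tuple[str, str | None]]

    def diseases(self) -> list[str]:
        return sorted(self.disease_truth)

    def drugs(self) -> list[str]:
        return sorted(self.drug_truth)


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def generate_pathways(cfg: SynthConfig, rng: np.random.Generator) -> list[PathwayGraph]:
    """Draw pathway memberships and signed, weakly connected topologies.

    Member sets are disjoint slices of a permuted gene universe while genes
    last (so planted signals in different pathways do not bleed into each
    other); once the universe is exhausted, remaining pathways sample genes
    independently and may overlap.  Each topology is a random spanning tree
    (guaranteeing weak connectivity and a nontrivial perturbation system)
    plus extra random edges; each edge is inhibitory with probability
    ``inhibition_edge_prob``.
    """
    genes = _gene_names(cfg.n_genes)
    perm = rng.permutation(genes)
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    graphs: list[PathwayGraph] = []
    cursor = 0
    for p, size in enumerate(sizes):
        if cursor + size <= cfg.n_genes:
            members = list(perm[cursor : cursor + size])
            cursor += size
        else:  # universe exhausted: fall back to overlapping draws
            members = list(rng.choice(genes, size=size, replace=False))
        order = rng.permutation(members)
        edges: list[Edge] = []
        seen: set[tuple[str, str]] = set()

        def _add(u: str, v: str) -> None:
            if u == v or (u, v) in seen:
                return
            seen.add((u, v))
            beta = -1.0 if rng.random() < cfg.inhibition_edge_prob else 1.0
            relation = "inhibition" if beta < 0 else "activation"
            edges.append(Edge(source=u, target=v, beta=beta, relation=relation))

        # spanning tree over a random node order -> weak connectivity
        for i in range(1, len(order)):
            parent = order[rng.integers(0, i)]
            child = order[i]
            if rng.random() < 0.5:
                _add(parent, child)
            else:
                _add(child, parent)
        for _ in range(len(order) // 2):  # extra edges beyond the tree
            u, v = rng.choice(order, size=2, replace=False)
            _add(u, v)
        graphs.append(
            PathwayGraph(
                database=DATABASE,
                pathway_id=f"P{p:03d}",
                members=frozenset(members),
                edges=tuple(edges),
            )
        )
    return graphs


def _planted_signs(k: int, rng: np.random.Generator) -> np.ndarray:
    """Alternating +1/-1 signs in random order: mixed whenever k >= 2.

    A disease whose drivers were all planted in one direction would have a
    constant pathway signature vector, for which Pearson correlation is
    undefined; balancing the signs keeps every disease scoreable.
    """
    signs = np.array([1 if i % 2 == 0 else -1 for i in range(k)])
    rng.shuffle(signs)
    return signs


def generate_disease_data(
    cfg: SynthConfig, pathways: list[PathwayGraph], rng: np.random.Generator
) -> tuple[AssociationTable, AssociationTable, dict[str, dict[tuple[str, str], int]]]:
    """Plant driver pathways per disease and draw coupled GWAS/DEG tables.

    The planted quantity is the pathway-level dysregulation *direction*:
    gene effects in a driver pathway are drawn with the planted sign (noise
    flips each gene with prob ``sign_noise``), then the pathway's net
    accumulation is solved through its signed topology, and the whole
    pathway's effects are negated if the propagated direction disagrees with
    the planted one (exact by linearity of the perturbation system).  This
    keeps the ground truth expressed in the same currency the pipeline
    estimates.  Pathways with a singular perturbation system are not
    eligible as drivers (the enrichment step must skip them).
    """
    from .spia import PathwaySystem  # local import; no cycle at module load

    if not pathways:
        raise ValidationError("pathways must be nonempty")
    genes = _gene_names(cfg.n_genes)
    systems = {g.key: PathwaySystem(g) for g in pathways}
    eligible = [i for i, g in enumerate(pathways) if not systems[g.key].singular]
    if len(eligible) < cfg.drivers_per_disease:
        raise ValidationError("not enough non-singular pathways to plant drivers")
    gwas_rows: list[dict] = []
    deg_rows: list[dict] = []
    disease_truth: dict[str, dict[tuple[str, str], int]] = {}
    for d in range(cfg.n_diseases):
        disease = f"D{d:02d}"
        idx = rng.choice(eligible, size=cfg.drivers_per_disease, replace=False)
        signs = _planted_signs(cfg.drivers_per_disease, rng)
        truth: dict[tuple[str, str], int] = {}
        effects: dict[str, float] = {}
        for i, s in zip(idx, signs):
            graph = pathways[i]
            truth[graph.key] = int(s)
            members = sorted(graph.members)
            hit = rng.random(len(members)) < cfg.deg_hit_rate_in_driver
            flip = rng.random(len(members)) < cfg.sign_noise
            mags = rng.uniform(*EFFECT_RANGE, size=len(members))
            de = {
                m: float((-s if f else s) * mag)
                for m, h, f, mag in zip(members, hit, flip, mags)
                if h
            }
            if de:
                sys_ = systems[graph.key]
                vec = sys_.de_vector(de)
                t_a = float(sys_.solve(vec).sum() - vec.sum())
                if t_a * s < 0:  # propagated direction disagrees: negate exactly
                    de = {m: -v for m, v in de.items()}
                for m, v in de.items():
                    effects.setdefault(m, v)
        disease_truth[disease] = truth
        driver_members = frozenset().union(*(pathways[i].members for i in idx))
        is_driver = np.isin(genes, sorted(driver_members))
        p_gwas = np.where(is_driver, cfg.gwas_hit_rate_in_driver, cfg.gwas_background_rate)
        gwas_hit = rng.random(cfg.n_genes) < p_gwas
        for g in genes[gwas_hit]:
            gwas_rows.append(
                {"entity_id": disease, "gene_id": g, "effect": np.nan, "source": "synth"}
            )
        bg_hit = rng.random(cfg.n_genes) < cfg.deg_background_rate
        mags = rng.uniform(*EFFECT_RANGE, size=cfg.n_genes)
        rand_signs = rng.choice([-1, 1], size=cfg.n_genes)
        for j in np.flatnonzero(bg_hit):
            g = genes[j]
            if g not in driver_members:
                effects.setdefault(g, float(rand_signs[j] * mags[j]))
        for g in sorted(effects):
            deg_rows.append(
                {
                    "entity_id": disease,
                    "gene_id": g,
                    "effect": effects[g],
                    "source": "synth",
                }
            )
    gwas = AssociationTable(
        df=pd.DataFrame(gwas_rows, columns=["entity_id", "gene_id", "effect", "source"]),
        kind="gwas",
    )
    deg = AssociationTable(df=pd.DataFrame(deg_rows), kind="disease_deg")
    return gwas, deg, disease_truth


def generate_drug_data(
    cfg: SynthConfig,
    disease_deg: AssociationTable,
    disease_truth: dict[str, dict[tuple[str, str], int]],
    rng: np.random.Generator,
) -> tuple[AssociationTable, AssociationTable, dict[str, tuple[str, str | None]]]:
    """Plant inverter/mimicker drugs and random decoys; build indications.

    With ``cfg.decouple_drugs`` the planted drugs copy (or negate) the DEG
    signature of the *next* disease in cyclic order instead of their own,
    while labels stay attached to the original disease.
    """
    genes = _gene_names(cfg.n_genes)
    diseases = sorted(disease_truth)
    shift = 1 if cfg.decouple_drugs and len(diseases) > 1 else 0
    drug_rows: list[dict] = []
    indication_rows: list[dict] = []
    drug_truth: dict[str, tuple[str, str | None]] = {}
    deg_by_disease = {
        d: sub for d, sub in disease_deg.df.groupby("entity_id", sort=True)
    }
    sizes = []
    for i, disease in enumerate(diseases):
        source_disease = diseases[(i + shift) % len(diseases)]
        sub = deg_by_disease.get(source_disease)
        if sub is None:
            continue
        sizes.append(len(sub))
        inv, mim = f"inv_{disease}", f"mim_{disease}"
        for row in sub.itertuples(index=False):
            drug_rows.append(
                {
                    "entity_id": inv,
                    "gene_id": row.gene_id,
                    "effect": -row.effect,
                    "source": "synth",
                }
            )
            drug_rows.append(
                {
                    "entity_id": mim,
                    "gene_id": row.gene_id,
                    "effect": row.effect,
                    "source": "synth",
                }
            )
        drug_truth[inv] = ("inverter", disease)
        drug_truth[mim] = ("mimicker", disease)
        indication_rows.append(
            {"entity_id": inv, "gene_id": disease, "effect": np.nan, "source": "synth"}
        )
    n_per_random = int(round(np.mean(sizes))) if sizes else 10
    for r in range(cfg.n_random_drugs):
        drug = f"rnd_{r:03d}"
        drawn = rng.choice(genes, size=min(n_per_random, cfg.n_genes), replace=False)
        signs = rng.choice([-1, 1], size=len(drawn))
        mags = rng.uniform(*EFFECT_RANGE, size=len(drawn))
        for g, s, m in zip(drawn, signs, mags):
            drug_rows.append(
                {"entity_id": drug, "gene_id": g, "effect": float(s * m), "source": "synth"}
            )
        drug_truth[drug] = ("random", None)
    drug_deg = AssociationTable(
        df=pd.DataFrame(
            drug_rows, columns=["entity_id", "gene_id", "effect", "source"]
        ),
        kind="drug_deg",
    )
    indications = AssociationTable(
        df=pd.DataFrame(
            indication_rows, columns=["entity_id", "gene_id", "effect", "source"]
        ),
        kind="indication",
    )
    return drug_deg, indications, drug_truth


def generate_world(cfg: SynthConfig) -> SyntheticWorld:
    """Generate the full benchmark in memory (pure function of cfg)."""
    rng = np.random.default_rng(cfg.seed)
    pathways = generate_pathways(cfg, rng)
    gwas, disease_deg, disease_truth = generate_disease_data(cfg, pathways, rng)
    drug_deg, indications, drug_truth = generate_drug_data(
        cfg, disease_deg, disease_truth, rng
    )
    return SyntheticWorld(
        cfg=cfg,
        universe=frozenset(_gene_names(cfg.n_genes)),
        pathways=pathways,
        gwas=gwas,
        disease_deg=disease_deg,
        drug_deg=drug_deg,
        indications=indications,
        disease_truth=disease_truth,
        drug_truth=drug_truth,
    )


def generate_benchmark(cfg: SynthConfig, out_dir: str | Path) -> SyntheticWorld:
    """Generate the benchmark and write all fixture files plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = generate_world(cfg)
    pio.write_table(world.gwas.df, out / "gwas.tsv")
    pio.write_table(world.disease_deg.df, out / "disease_deg.tsv")
    pio.write_table(world.drug_deg.df, out / "drug_deg.tsv")
    pio.write_table(world.indications.df, out / "indications.tsv")
    pio.write_pathways(world.pathways, out / "pathways.gmt", out / "topology.tsv")
    truth = {
        "disease_truth": {
            d: {f"{db}:{pid}": s for (db, pid), s in t.items()}
            for d, t in world.disease_truth.items()
        },
        "drug_truth": {k: list(v) for k, v in world.drug_truth.items()},
    }
    manifest = {"config": cfg.to_dict(), "seed": cfg.seed, **truth}
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return world
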