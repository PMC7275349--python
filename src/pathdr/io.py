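"""Readers, writers, and identifier harmonization.

All tabular formats are UTF-8, tab-separated, with a header row.  Pathway
membership uses the standard GMT layout (name, description, member genes);
pathway topology is a SIF-like TSV with columns
``database  pathway_id  source  target  relation`` where relation is
``activation`` or ``inhibition``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    DEG_KINDS,
    RELATION_BETA,
    AssociationTable,
    Edge,
    FormatError,
    MappingTable,
    PathwayGraph,
    RunConfig,
    ValidationError,
)

log = logging.getLogger(__name__)

TOPOLOGY_COLUMNS = ["database", "pathway_id", "source", "target", "relation"]


def _collapse_duplicates(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Collapse duplicate (entity, gene) rows.

    DEG kinds keep the row with the largest absolute effect (the strongest
    perturbation survives); ties keep the first occurrence.  Other kinds are
    plain set-like deduplication.
    """
    if kind in DEG_KINDS:
        order = (
            df.assign(_abs=df["effect"].abs())
            .sort_values("_abs", ascending=False, kind="stable")
            .drop(columns="_abs")
        )
        out = order.drop_duplicates(subset=["entity_id", "gene_id"], keep="first")
        # restore a deterministic row order
        return out.sort_values(["entity_id", "gene_id"], kind="stable").reset_index(
            drop=True
        )
    return (
        df.drop_duplicates(subset=["entity_id", "gene_id"], keep="first")
        .sort_values(["entity_id", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )


def read_association_table(path: str | Path, kind: str) -> AssociationTable:
    """Read a long-form association TSV and collapse duplicate rows.

    Raises :class:`FormatError` if a required column is missing and
    :class:`ValidationError` if DEG effects are absent or zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "gene_id": str})
    for col in ("entity_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if kind in DEG_KINDS and "effect" not in df.columns:
        raise ValidationError(f"{path}: kind {kind!r} requires an 'effect' column")
    if kind in DEG_KINDS:
        eff = pd.to_numeric(df["effect"], errors="coerce")
        if eff.isna().any():
            bad = df.index[eff.isna()].tolist()
            raise ValidationError(f"{path}: missing effects at rows {bad[:10]}")
        zero = df.index[eff == 0].tolist()
        if zero:
            raise ValidationError(f"{path}: zero effects at rows {zero[:10]}")
        df["effect"] = eff
    n_raw = len(df)
    df = _collapse_duplicates(df, kind)
    if len(df) < n_raw:
        log.info("%s: collapsed %d duplicate rows", path, n_raw - len(df))
    log.info("%s: loaded %d %s associations", path, len(df), kind)
    return AssociationTable(df=df, kind=kind)


def harmonize(
    table: AssociationTable, mapping: MappingTable, on: str = "gene_id"
) -> AssociationTable:
    """Map identifiers in column ``on`` to canonical ids; drop unmappable rows.

    After mapping, duplicates that collapse onto one canonical id are merged
    with the same rule as :func:`read_association_table`.  Idempotent when the
    mapping fixes canonical ids (i.e. maps them to themselves) or omits them.
    """
    if on not in ("gene_id", "entity_id"):
        raise ValueError(f"cannot harmonize on column {on!r}")
    df = table.df.copy()
    mapped = df[on].map(mapping.pairs)
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("harmonize: dropped %d rows without a mapping", n_dropped)
    df = df.loc[keep].copy()
    df[on] = mapped[keep]
    df = _collapse_duplicates(df, table.kind)
    return AssociationTable(df=df, kind=table.kind)


def read_mapping(path: str | Path) -> MappingTable:
    """Read a two-column TSV (source_id, canonical_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "canonical_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset="source_id", keep=False)
    conflicting = df.loc[dup].groupby("source_id")["canonical_id"].nunique()
    if (conflicting > 1).any():
        raise ValidationError(
            f"{path}: conflicting canonical ids for {conflicting[conflicting > 1].index.tolist()[:5]}"
        )
    return MappingTable(pairs=dict(zip(df["source_id"], df["canonical_id"])))


def write_table(records, path: str | Path) -> None:
    """Write tabular results as TSV with reals rendered to 6 significant digits.

    ``records`` may be a DataFrame or a sequence of dataclass instances
    (column order = dataclass field order).  An empty sequence with no frame
    raises, since the header could not be inferred.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError(
                "cannot infer a header from an empty record list; pass a DataFrame"
            )
        if not dataclasses.is_dataclass(records[0]):
            raise TypeError("records must be dataclasses or a DataFrame")
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into (pathway_id, description, members) triples."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{i + 1}: GMT line needs name, description and >=1 member"
                )
            out.append((parts[0], parts[1], parts[2:]))
    return out


def read_pathways(
    gmt_path: str | Path, topology_path: str | Path, database: str = "custom"
) -> list[PathwayGraph]:
    """Load pathways from a GMT membership file plus a signed edge-list TSV.

    Edges are attached by (database, pathway_id); an edge referencing a
    non-member gene, an unknown relation string, or a pathway absent from the
    GMT raises :class:`ValidationError`.
    """
    gmt = read_gmt(gmt_path)
    topo = pd.read_csv(topology_path, sep="\t", dtype=str)
    for col in TOPOLOGY_COLUMNS:
        if col not in topo.columns:
            raise FormatError(f"{topology_path}: missing required column {col!r}")
    bad_rel = set(topo["relation"]) - set(RELATION_BETA)
    if bad_rel:
        raise ValidationError(f"unknown relation strings: {sorted(bad_rel)}")
    known = {(database, pid) for pid, _, _ in gmt}
    edges_by_key: dict[tuple[str, str], list[Edge]] = {}
    for row in topo.itertuples(index=False):
        key = (row.database, row.pathway_id)
        if key not in known:
            raise ValidationError(
                f"topology references unknown pathway {key[0]}:{key[1]}"
            )
        edges_by_key.setdefault(key, []).append(
            Edge(
                source=row.source,
                target=row.target,
                beta=RELATION_BETA[row.relation],
                relation=row.relation,
            )
        )
    graphs = []
    for pid, _desc, members in gmt:
        graphs.append(
            PathwayGraph(
                database=database,
                pathway_id=pid,
                members=frozenset(members),
                edges=tuple(edges_by_key.get((database, pid), ())),
            )
        )
    return graphs


def write_pathways(
    pathways: Sequence[PathwayGraph], gmt_path: str | Path, topology_path: str | Path
) -> None:
    """Write pathways in the formats :func:`read_pathways` accepts."""
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for g in pathways:
            fh.write(
                "\t".join([g.pathway_id, f"{g.database} pathway"] + sorted(g.members))
                + "\n"
            )
    rows = [
        {
            "database": g.database,
            "pathway_id": g.pathway_id,
            "source": e.source,
            "target": e.target,
            "relation": e.relation,
        }
        for g in pathways
        for e in g.edges
    ]
    pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS).to_csv(
        topology_path, sep="\t", index=False
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration mirroring :class:`RunConfig` fields."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
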