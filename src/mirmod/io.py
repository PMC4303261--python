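"""Readers and writers for every external format the pipeline touches.

All formats are plain text: TSV matrices, GMT gene sets, two-column edge
lists, headered TSV target/TF/segment tables, YAML marker panels. Loaders
preserve file order (samples are never reordered) and log what they drop.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ExpressionMatrix,
    GeneSampleModule,
    GeneSetCollection,
    InteractionNetwork,
    MarkerPanel,
    SegmentTrack,
    TargetTable,
    TFRelationTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix", "write_expression_matrix",
    "read_gmt", "write_gmt",
    "read_edge_list", "write_edge_list",
    "read_target_table", "write_target_table",
    "read_tf_tables", "write_tf_tables",
    "read_segments", "write_segments",
    "read_marker_panel", "write_marker_panel",
    "read_modules", "write_modules",
    "write_manifest",
]


def read_expression_matrix(path: str | Path, feature_kind: str = "gene",
                           ) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    First column holds feature ids, the header row holds sample ids. Rows
    containing any non-numeric or missing value are dropped with a logged
    count; duplicate feature or sample ids are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty expression file")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature ids: {dup}")
    dupc = df.columns[df.columns.duplicated()].unique().tolist()
    if dupc:
        raise ValueError(f"{path}: duplicate sample ids: {dupc}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing/non-numeric values",
                    path, n_dropped)
    return ExpressionMatrix(numeric.loc[~bad].astype(float), feature_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                             f"description and >=1 member")
        name, desc = parts[0], parts[1]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = {g for g in parts[2:] if g}
        if not members:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
        if desc:
            categories[name] = desc
    return GeneSetCollection(sets, categories)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.categories.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Load a two-column gene-gene edge list.

    Edges are symmetrized; self-loops are dropped with a logged count.
    """
    edges = []
    n_loops = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two gene columns")
        a, b = parts
        if a == b:
            n_loops += 1
            continue
        edges.append((a, b))
    if n_loops:
        logger.info("%s: dropped %d self-loops", path, n_loops)
    return InteractionNetwork.from_edges(edges)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(edge)) for edge in net.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


def read_target_table(path: str | Path) -> TargetTable:
    """Load a headered TSV of miRNA-target records.

    Required columns: mirna, gene, evidence; optional: provenance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "provenance" not in df.columns:
        df["provenance"] = ""
    return TargetTable(df[["mirna", "gene", "evidence", "provenance"]])


def write_target_table(table: TargetTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_tf_tables(tf_gene_path: str | Path,
                   tf_mirna_path: str | Path) -> TFRelationTable:
    """Load TF->gene targets and directed TF-miRNA relations (headered TSV)."""
    tf_gene = pd.read_csv(tf_gene_path, sep="\t", dtype=str)
    tf_mirna = pd.read_csv(tf_mirna_path, sep="\t", dtype=str)
    if "provenance" not in tf_mirna.columns:
        tf_mirna["provenance"] = ""
    return TFRelationTable(tf_gene, tf_mirna)


def write_tf_tables(table: TFRelationTable, tf_gene_path: str | Path,
                    tf_mirna_path: str | Path) -> None:
    table.tf_gene.to_csv(tf_gene_path, sep="\t", index=False)
    table.tf_mirna.to_csv(tf_mirna_path, sep="\t", index=False)


def read_segments(path: str | Path) -> SegmentTrack:
    """Load a BED-like segment file (chrom, start, end, sample, ratio).

    Input coordinates are 1-based inclusive; internally converted to
    0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    req = {"chrom", "start", "end", "sample", "ratio"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1  # 1-based incl -> 0-based half-open
    df["end"] = df["end"].astype(int)
    df["ratio"] = df["ratio"].astype(float)
    return SegmentTrack(df[["chrom", "start", "end", "sample", "ratio"]])


def write_segments(track: SegmentTrack, path: str | Path) -> None:
    out = track.records.copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Load subtype marker panels from YAML: subtype -> {gene: over/under}."""
    raw = yaml.safe_load(Path(path).read_text())
    panels = {
        subtype: [(gene, direction) for gene, direction in markers.items()]
        for subtype, markers in raw.items()
    }
    return MarkerPanel(panels)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    raw = {subtype: {g: d for g, d in markers}
           for subtype, markers in panel.panels.items()}
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def read_modules(path: str | Path) -> list[GeneSampleModule]:
    """Load modules from the long-format TSV written by write_modules.

    This doubles as the adapter for externally produced biclusters.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = {"module_id", "member_type", "member_id"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    modules = []
    for mid, grp in df.groupby("module_id", sort=False):
        genes = grp.loc[grp["member_type"] == "gene"]
        samples = set(grp.loc[grp["member_type"] == "sample", "member_id"])
        provenance = {}
        if "provenance" in grp.columns:
            provenance = dict(zip(genes["member_id"], genes["provenance"]))
        modules.append(GeneSampleModule(
            module_id=str(mid), genes=set(genes["member_id"]),
            samples=samples, provenance=provenance))
    return modules


def write_modules(modules: list[GeneSampleModule], path: str | Path) -> None:
    rows = []
    for mod in modules:
        for g in mod.sorted_genes():
            rows.append((mod.module_id, "gene", g,
                         mod.provenance.get(g, "biclustered")))
        for s in mod.sorted_samples():
            rows.append((mod.module_id, "sample", s, ""))
    pd.DataFrame(rows, columns=["module_id", "member_type", "member_id",
                                "provenance"]).to_csv(path, sep="\t",
                                                      index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=_default) + "\n")
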