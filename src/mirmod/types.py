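"""Domain containers shared across the pipeline.

All containers are thin, validated wrappers around pandas/networkx objects.
Identifiers (gene, miRNA, sample, TF) are opaque, case-sensitive strings; no
symbol mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "InteractionNetwork",
    "GeneSetCollection",
    "TargetTable",
    "TFRelationTable",
    "GeneSampleModule",
    "GeneMiRNAModule",
    "SegmentTrack",
    "MarkerPanel",
    "RegulatorModel",
    "BICResult",
    "EnrichmentResult",
    "RegulationEvidence",
]

_FEATURE_KINDS = ("gene", "miRNA")


@dataclass
class ExpressionMatrix:
    """A features x samples table of log2-ratio expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features (genes or miRNAs), columns are samples. Entries
        must be finite; rows with missing values are dropped by the loader
        before this container is built.
    feature_kind : {"gene", "miRNA"}
    """

    values: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in _FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {_FEATURE_KINDS}, "
                             f"got {self.feature_kind!r}")
        idx = self.values.index
        cols = self.values.columns
        dup_rows = idx[idx.duplicated()].unique().tolist()
        if dup_rows:
            raise ValueError(f"duplicate feature ids: {dup_rows}")
        dup_cols = cols[cols.duplicated()].unique().tolist()
        if dup_cols:
            raise ValueError(f"duplicate sample ids: {dup_cols}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        df = self.values
        if features is not None:
            df = df.loc[list(features)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df, self.feature_kind)


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction network (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), optionally tagged with a category label."""

    sets: dict[str, set[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class TargetTable:
    """miRNA -> target-gene records with an evidence class.

    Evidence classes: ``predicted`` (sequence-based prediction),
    ``direct`` (reporter assay / western blot), ``coexpression``
    (qPCR / microarray / SILAC style validation).
    """

    records: pd.DataFrame  # columns: mirna, gene, evidence, provenance

    EVIDENCE = ("predicted", "direct", "coexpression")

    def __post_init__(self) -> None:
        req = {"mirna", "gene", "evidence"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"target table missing columns: {sorted(missing)}")
        bad = set(self.records["evidence"]) - set(self.EVIDENCE)
        if bad:
            raise ValueError(f"unknown evidence classes: {sorted(bad)}")
        if self.records.duplicated(["mirna", "gene", "evidence"]).any():
            raise ValueError("duplicate (mirna, gene, evidence) triples")

    def targets_of(self, mirna: str, evidence: str | None = None) -> set[str]:
        df = self.records[self.records["mirna"] == mirna]
        if evidence is not None:
            df = df[df["evidence"] == evidence]
        return set(df["gene"])

    def pairs(self, evidence: str) -> set[tuple[str, str]]:
        df = self.records[self.records["evidence"] == evidence]
        return set(zip(df["gene"], df["mirna"]))


@dataclass
class TFRelationTable:
    """TF->gene targets plus directed TF-miRNA relations.

    ``tf_gene`` has columns (tf, gene); ``tf_mirna`` has columns
    (tf, mirna, direction, provenance) with direction in
    {"TF_regulates_miRNA", "miRNA_regulates_TF"}.
    """

    tf_gene: pd.DataFrame
    tf_mirna: pd.DataFrame

    DIRECTIONS = ("TF_regulates_miRNA", "miRNA_regulates_TF")

    def __post_init__(self) -> None:
        if not {"tf", "gene"} <= set(self.tf_gene.columns):
            raise ValueError("tf_gene table needs columns (tf, gene)")
        if not {"tf", "mirna", "direction"} <= set(self.tf_mirna.columns):
            raise ValueError("tf_mirna table needs columns (tf, mirna, direction)")
        bad = set(self.tf_mirna["direction"]) - set(self.DIRECTIONS)
        if bad:
            raise ValueError(f"unknown TF-miRNA directions: {sorted(bad)}")
        for df, cols in ((self.tf_gene, ("tf", "gene")),
                         (self.tf_mirna, ("tf", "mirna"))):
            for c in cols:
                if df[c].astype(str).str.len().eq(0).any():
                    raise ValueError(f"empty ids in column {c!r}")

    def targets_of_tf(self, tf: str) -> set[str]:
        return set(self.tf_gene.loc[self.tf_gene["tf"] == tf, "gene"])

    @property
    def tfs(self) -> set[str]:
        return set(self.tf_gene["tf"])


@dataclass
class GeneSampleModule:
    """A bicluster: a coherent gene set over a sample subset.

    ``module_avg`` is the mean off-diagonal pairwise Pearson correlation of
    the member genes over the member samples. Provenance marks whether a
    gene came from the biclustering itself or from network expansion.
    """

    module_id: str
    genes: set[str]
    samples: set[str]
    module_avg: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    provenance: dict[str, str] = field(default_factory=dict)
    score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.genes) < 2 or len(self.samples) < 2:
            raise ValueError(
                f"module {self.module_id}: needs >=2 genes and >=2 samples "
                f"(got {len(self.genes)} genes, {len(self.samples)} samples)")
        for g in self.genes:
            self.provenance.setdefault(g, "biclustered")

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)

    def sorted_samples(self) -> list[str]:
        return sorted(self.samples)


@dataclass
class GeneMiRNAModule:
    """A gene-sample module plus its selected regulating miRNAs.

    miRNAs are ordered by acceptance; ``bic_trajectory[i]`` is the network
    score after accepting ``mirnas[i]`` and is strictly increasing.
    Modules with fewer than two miRNAs are never constructed (they are
    filtered upstream as uninformative for combinatorial regulation).
    """

    base: GeneSampleModule
    mirnas: list[str]
    bic_trajectory: list[float]

    def __post_init__(self) -> None:
        if len(self.mirnas) < 2:
            raise ValueError("gene-miRNA modules need >=2 miRNAs")
        if len(self.bic_trajectory) != len(self.mirnas):
            raise ValueError("bic_trajectory length must equal miRNA count")
        diffs = np.diff(self.bic_trajectory)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("bic_trajectory must be strictly increasing")

    @property
    def module_id(self) -> str:
        return self.base.module_id


@dataclass
class SegmentTrack:
    """Segmented copy-number log ratios.

    Input coordinates are 1-based with inclusive ends; they are converted to
    0-based half-open [start, end) on load. ``records`` has columns
    (chrom, start, end, sample, ratio) in the internal convention.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "sample", "ratio"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"segment track missing columns: {sorted(missing)}")
        if (self.records["start"] >= self.records["end"]).any():
            raise ValueError("segment start must be < end")
        if (self.records["start"] < 0).any():
            raise ValueError("negative segment coordinates")
        if not np.all(np.isfinite(self.records["ratio"].to_numpy(float))):
            raise ValueError("segment ratios must be finite")


@dataclass
class MarkerPanel:
    """Subtype marker genes with expected expression direction.

    ``panels`` maps subtype name -> list of (gene id, direction) with
    direction in {"over", "under"}.
    """

    panels: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        for subtype, markers in self.panels.items():
            if not markers:
                raise ValueError(f"subtype {subtype!r} has no markers")
            for gene, direction in markers:
                if direction not in ("over", "under"):
                    raise ValueError(
                        f"marker {gene!r}: direction must be over/under, "
                        f"got {direction!r}")

    @property
    def subtypes(self) -> list[str]:
        return list(self.panels)


@dataclass
class RegulatorModel:
    """Per-gene linear-Gaussian conditional: X ~ N(a0 + a.Y, sigma2)."""

    gene: str
    parents: list[str]
    a0: float
    coef: np.ndarray
    sigma2: float
    loglik: float

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.parents):
            raise ValueError("coefficient count must equal parent count")


@dataclass
class BICResult:
    """Network score of a module configuration.

    ``logL`` is the total Gaussian log-likelihood over module genes, ``M``
    the number of genes plus miRNAs in the configuration, and
    ``bic = logL - log(M)/2`` (default scoring mode).
    """

    logL: float
    M: int
    bic: float


@dataclass
class EnrichmentResult:
    """One upper-tail hypergeometric test (Table-2 style columns)."""

    subject: str
    N: int
    m: int
    k: int
    x: int
    p: float
    q: float = float("nan")
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.x > min(self.m, self.k):
            raise ValueError("overlap cannot exceed min(set size, module size)")


@dataclass
class RegulationEvidence:
    """One piece of regulation evidence for a module."""

    module_id: str
    case: str  # direct_predicted | direct_experimental | tf_coregulation |
               # mirna_via_tf | coexpression_experimental
    participants: Mapping[str, object]
    statistics: Mapping[str, float] = field(default_factory=dict)

    CASES = ("direct_predicted", "direct_experimental", "tf_coregulation",
             "mirna_via_tf", "coexpression_experimental")

    def __post_init__(self) -> None:
        if self.case not in self.CASES:
            raise ValueError(f"unknown evidence case {self.case!r}")
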