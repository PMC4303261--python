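"""End-to-end orchestration: preprocess -> bicluster -> expand ->
miRNA selection -> validation (-> subtype, copy number).

Every stage writes a headered TSV into the run directory; a JSON
manifest records seeds, thresholds and stage counts, and a plain-text
report summarizes the cohort. Runs are deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .bicluster import SambaBiclustering
from .cna import (DEFAULT_BIN_SIZE, associate_regions_with_module,
                  bin_segments, filter_weak_regions)
from .expand import NetworkModuleExpander
from .mirna_select import GreedyMiRNASelector
from .preprocess import log2_ratio_normalize, select_de_genes, zscore_rows
from .subtype import SubtypeClusterer, module_subtype_test
from .synthetic import Bundle
from .types import ExpressionMatrix, GeneMiRNAModule
from .validate import (cancer_annotation_ratios, correlation_edges,
                       direct_regulation_evidence, explained_module_summary,
                       mirna_via_tf_evidence, overlap_ratio,
                       pathway_enrichment, tf_coregulation_evidence)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_from_bundle",
           "write_bundle", "standard_inputs"]

#: canonical file names used by ``write_bundle`` / ``standard_inputs``
_STANDARD_FILES = {
    "gene_tumor": "gene_tumor.tsv",
    "gene_normal": "gene_normal.tsv",
    "mirna_tumor": "mirna_tumor.tsv",
    "mirna_normal": "mirna_normal.tsv",
    "network": "network.tsv",
    "targets": "targets.tsv",
    "tf_gene": "tf_gene.tsv",
    "tf_mirna": "tf_mirna.tsv",
    "tf_expr": "tf_expr.tsv",
    "segments": "segments.tsv",
    "genes_bed": "genes.bed.tsv",
    "markers": "markers.yaml",
    "gene_lists": "gene_lists.gmt",
    "mirna_lists": "mirna_lists.gmt",
}


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, str]:
    """Write a synthetic bundle to disk using the standard file names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    f = {k: str(outdir / v) for k, v in _STANDARD_FILES.items()}
    mio.write_expression_matrix(bundle.gene_tumor, f["gene_tumor"])
    mio.write_expression_matrix(bundle.gene_normal, f["gene_normal"])
    mio.write_expression_matrix(bundle.mirna_tumor, f["mirna_tumor"])
    mio.write_expression_matrix(bundle.mirna_normal, f["mirna_normal"])
    mio.write_edge_list(bundle.network, f["network"])
    mio.write_target_table(bundle.targets, f["targets"])
    mio.write_tf_tables(bundle.tf_table, f["tf_gene"], f["tf_mirna"])
    mio.write_expression_matrix(bundle.tf_expr, f["tf_expr"])
    if bundle.segments is not None:
        mio.write_segments(bundle.segments, f["segments"])
    else:
        f.pop("segments")
    if bundle.genes_bed is not None:
        bundle.genes_bed.to_csv(f["genes_bed"], sep="\t", index=False)
    else:
        f.pop("genes_bed")
    mio.write_marker_panel(bundle.markers, f["markers"])
    mio.write_gmt(bundle.gene_lists, f["gene_lists"])
    mio.write_gmt(bundle.mirna_lists, f["mirna_lists"])
    mio.write_manifest(bundle.manifest, outdir / "truth_manifest.json")
    return f


def standard_inputs(indir: str | Path) -> dict[str, str]:
    """Collect the standard input file names that exist under a directory."""
    indir = Path(indir)
    return {k: str(indir / v) for k, v in _STANDARD_FILES.items()
            if (indir / v).exists()}


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    seed: int = 0
    input_scale: str = "log2"        # scale of the input matrices
    de_mode: str = "raw_p"           # raw_p | bonferroni
    de_alpha: float = 0.001
    z_threshold: float = 1.5
    lam: float = 1.0
    min_genes: int = 5
    min_samples: int = 5
    max_modules: int = 50
    overlap_factor: float = 0.5
    n_permutations: int = 1000
    q_threshold: float = 0.05
    overlap_matched: bool = True
    bicluster_method: str = "auto"
    expand_enabled: bool = True
    T_percent: float = 3.0
    bic_mode: str = "paper"          # paper | standard
    variance_floor: float = 1e-6
    max_set_size: int = 300
    pathway_q_threshold: float = 0.05
    evidence_alpha: float = 0.05
    edge_pcc_threshold: float = 0.3
    subtype_enabled: bool = False
    top_var_genes: int = 1000
    min_cluster_size: int = 30
    cna_enabled: bool = False
    bin_size: int = DEFAULT_BIN_SIZE
    cna_ratio_threshold: float = 0.2
    cna_pcc_threshold: float = 0.3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _mirna_module_table(mods: list[GeneMiRNAModule]) -> pd.DataFrame:
    rows = []
    for mod in mods:
        for rank, (mirna, bic) in enumerate(zip(mod.mirnas,
                                                mod.bic_trajectory), 1):
            rows.append((mod.module_id, mirna, rank, bic))
    return pd.DataFrame(rows, columns=["module_id", "mirna",
                                       "selection_rank", "bic"])


def run_pipeline_from_bundle(bundle: Bundle, cfg: PipelineConfig,
                             outdir: str | Path,
                             pathways=None) -> dict:
    """Run the full pipeline on an in-memory dataset bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict()}

    # --- preprocess ---------------------------------------------------
    gene_ratio = log2_ratio_normalize(bundle.gene_tumor, bundle.gene_normal,
                                      input_scale=cfg.input_scale)
    mirna_ratio = log2_ratio_normalize(bundle.mirna_tumor,
                                       bundle.mirna_normal,
                                       input_scale=cfg.input_scale)
    de_genes, pvals = select_de_genes(gene_ratio, mode=cfg.de_mode,
                                      alpha=cfg.de_alpha)
    if len(de_genes) < cfg.min_genes:
        raise RuntimeError("preprocess: fewer DE genes than min module size")
    z = zscore_rows(gene_ratio.subset(features=sorted(de_genes)))
    pvals.to_frame().to_csv(outdir / "de_pvalues.tsv", sep="\t")
    report["n_de_genes"] = len(de_genes)

    # --- bicluster ----------------------------------------------------
    bic = SambaBiclustering(
        z_threshold=cfg.z_threshold, lam=cfg.lam, min_genes=cfg.min_genes,
        min_samples=cfg.min_samples, max_modules=cfg.max_modules,
        overlap_factor=cfg.overlap_factor,
        n_permutations=cfg.n_permutations, q_threshold=cfg.q_threshold,
        overlap_matched=cfg.overlap_matched, method=cfg.bicluster_method,
        random_state=cfg.seed).fit(z)
    modules = bic.modules_
    stats = pd.DataFrame(
        [(m.module_id, len(m.genes), len(m.samples), m.module_avg,
          m.p_value, m.q_value, m.score) for m in bic.all_modules_],
        columns=["module_id", "n_genes", "n_samples", "module_avg",
                 "p_value", "q_value", "score"])
    stats.to_csv(outdir / "module_stats.tsv", sep="\t", index=False)
    mio.write_modules(bic.all_modules_, outdir / "modules_raw.tsv")
    report["n_modules_raw"] = len(bic.all_modules_)
    report["n_modules_significant"] = len(modules)

    # --- expand -------------------------------------------------------
    if cfg.expand_enabled and modules:
        before = {m.module_id: m.module_avg for m in modules}
        modules = NetworkModuleExpander().transform(
            modules, net=bundle.network, expr=gene_ratio)
        for m in modules:
            assert m.module_avg >= before[m.module_id] - 1e-12, \
                "expansion must never decrease the module average PCC"
        report["mean_genes_added"] = float(np.mean(
            [sum(1 for p in m.provenance.values() if p == "ggi_added")
             for m in modules]))
    mio.write_modules(modules, outdir / "modules_expanded.tsv")

    # --- miRNA selection ----------------------------------------------
    sel = GreedyMiRNASelector(T_percent=cfg.T_percent, mode=cfg.bic_mode,
                              variance_floor=cfg.variance_floor).fit(
        modules, gene_expr=gene_ratio, mirna_expr=mirna_ratio)
    gm_modules = sel.mirna_modules_
    for mod in gm_modules:
        assert len(mod.mirnas) >= 2
        assert np.all(np.diff(mod.bic_trajectory) > 0)
    _mirna_module_table(gm_modules).to_csv(outdir / "mirna_modules.tsv",
                                           sep="\t", index=False)
    (outdir / "discarded_modules.txt").write_text(
        "\n".join(sel.discarded_) + ("\n" if sel.discarded_ else ""))
    report["n_mirna_modules"] = len(gm_modules)
    report["n_discarded"] = len(sel.discarded_)

    # --- validation ---------------------------------------------------
    universe = set(gene_ratio.feature_ids)
    evidence_by_module: dict[str, list] = {m.module_id: [] for m in gm_modules}
    evidence_rows = []
    for mod in gm_modules:
        evs = direct_regulation_evidence(mod, bundle.targets, gene_ratio,
                                         mirna_ratio, universe)
        if len(bundle.tf_table.tf_mirna):
            evs += tf_coregulation_evidence(
                mod, bundle.tf_table, gene_ratio, mirna_ratio,
                bundle.tf_expr, universe, alpha=cfg.evidence_alpha)
            evs += mirna_via_tf_evidence(
                mod, bundle.tf_table, gene_ratio, mirna_ratio,
                bundle.tf_expr, universe, alpha=cfg.evidence_alpha)
        evidence_by_module[mod.module_id].extend(evs)
        for e in evs:
            evidence_rows.append((e.module_id, e.case,
                                  str(dict(e.participants)),
                                  e.statistics.get("p", float("nan"))))
    pd.DataFrame(evidence_rows,
                 columns=["module_id", "case", "participants", "p"]).to_csv(
        outdir / "evidence.tsv", sep="\t", index=False)
    summary = explained_module_summary(evidence_by_module)
    summary.to_csv(outdir / "explained.tsv", sep="\t")
    report["fraction_explained"] = summary.attrs["fraction_explained"]

    if pathways is not None and gm_modules:
        enriched, pw_summary = pathway_enrichment(
            gm_modules, pathways, universe, max_set_size=cfg.max_set_size,
            q_threshold=cfg.pathway_q_threshold)
        pd.DataFrame(
            [(r.subject, r.N, r.m, r.k, r.x, r.p, r.q) for r in enriched],
            columns=["subject", "N", "m", "k", "x", "p", "q"]).to_csv(
            outdir / "pathway_enrichment.tsv", sep="\t", index=False)
        report.update(pw_summary)

    ratio_rows = []
    for mod in gm_modules:
        for name, val in sorted(cancer_annotation_ratios(
                mod, bundle.gene_lists, bundle.mirna_lists).items()):
            ratio_rows.append((mod.module_id, name, val))
    pd.DataFrame(ratio_rows,
                 columns=["module_id", "list", "ratio"]).to_csv(
        outdir / "cancer_ratios.tsv", sep="\t", index=False)

    ov_rows = []
    for i, a in enumerate(gm_modules):
        for b in gm_modules[i + 1:]:
            ov_rows.append((a.module_id, b.module_id,
                            overlap_ratio(a.base.genes, b.base.genes),
                            overlap_ratio(set(a.mirnas), set(b.mirnas))))
    pd.DataFrame(ov_rows, columns=["module_1", "module_2", "gene_overlap",
                                   "mirna_overlap"]).to_csv(
        outdir / "overlaps.tsv", sep="\t", index=False)

    edge_rows = []
    for mod in gm_modules:
        edges = correlation_edges(mod, gene_ratio, mirna_ratio,
                                  threshold=cfg.edge_pcc_threshold)
        edges.insert(0, "module_id", mod.module_id)
        if len(edges):
            edge_rows.append(edges)
    (pd.concat(edge_rows) if edge_rows
     else pd.DataFrame(columns=["module_id", "gene", "mirna", "pcc"])
     ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)

    # --- subtype ------------------------------------------------------
    if cfg.subtype_enabled:
        clusterer = SubtypeClusterer(
            top_var_genes=cfg.top_var_genes,
            min_cluster_size=cfg.min_cluster_size).fit(
            gene_ratio, markers=bundle.markers)
        rows = []
        for mod in gm_modules:
            _, verdict = module_subtype_test(
                mod.base, clusterer.subtype_samples_, gene_ratio,
                bundle.markers)
            rows.append((mod.module_id, verdict or "none"))
        pd.DataFrame(rows, columns=["module_id", "subtype"]).to_csv(
            outdir / "module_subtypes.tsv", sep="\t", index=False)
        report["n_subtype_clusters"] = len(clusterer.clusters_)

    # --- copy number --------------------------------------------------
    if cfg.cna_enabled and bundle.segments is not None:
        regions = filter_weak_regions(
            bin_segments(bundle.segments, bin_size=cfg.bin_size),
            threshold=cfg.cna_ratio_threshold)
        rows = []
        for mod in gm_modules:
            assoc = associate_regions_with_module(
                mod.base, regions, gene_ratio, bundle.genes_bed,
                pcc_threshold=cfg.cna_pcc_threshold)
            assoc.insert(0, "module_id", mod.module_id)
            if len(assoc):
                rows.append(assoc)
        (pd.concat(rows) if rows
         else pd.DataFrame(columns=["module_id", "region", "pcc",
                                    "cis_genes"])
         ).to_csv(outdir / "cna_associations.tsv", sep="\t", index=False)
        report["n_cna_regions"] = len(regions)

    mio.write_manifest(report, outdir / "run_manifest.json")
    _write_report(report, outdir / "report.txt")
    report["_modules"] = gm_modules
    return report


def _write_report(report: dict, path: Path) -> None:
    lines = ["gene-miRNA module discovery run", "=" * 32]
    for key in sorted(report):
        if key.startswith("_") or key == "config":
            continue
        lines.append(f"{key}: {report[key]}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig | str | Path, inputs: dict,
                 outdir: str | Path) -> dict:
    """Run the pipeline from files on disk.

    ``inputs`` maps input names to paths: gene_tumor, gene_normal,
    mirna_tumor, mirna_normal, network, targets, tf_gene, tf_mirna,
    tf_expr, segments, genes_bed, markers, gene_lists, mirna_lists,
    pathways. Optional inputs may be omitted; dependent stages are
    skipped with a warning.
    """
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_yaml(config))

    def _need(name, reader, *args):
        if name not in inputs:
            raise FileNotFoundError(f"required input {name!r} missing")
        return reader(inputs[name], *args)

    def _opt(name, reader, *args):
        if name not in inputs:
            logger.warning("optional input %r missing; dependent stage "
                           "will be skipped or degraded", name)
            return None
        return reader(inputs[name], *args)

    from .types import GeneSetCollection, MarkerPanel, TargetTable, \
        TFRelationTable

    targets = _opt("targets", mio.read_target_table)
    if targets is None:
        targets = TargetTable(pd.DataFrame(
            columns=["mirna", "gene", "evidence", "provenance"]))
    if "tf_gene" in inputs and "tf_mirna" in inputs:
        tf_table = mio.read_tf_tables(inputs["tf_gene"], inputs["tf_mirna"])
    else:
        logger.warning("TF tables missing; TF evidence cases skipped")
        tf_table = TFRelationTable(
            pd.DataFrame(columns=["tf", "gene"]),
            pd.DataFrame(columns=["tf", "mirna", "direction", "provenance"]))
    tf_expr = _opt("tf_expr", mio.read_expression_matrix)
    if tf_expr is None:
        tf_expr = ExpressionMatrix(pd.DataFrame(
            np.zeros((0, 0)), index=[], columns=[]), "gene")

    gene_lists = _opt("gene_lists", mio.read_gmt)
    mirna_lists = _opt("mirna_lists", mio.read_gmt)
    markers = _opt("markers", mio.read_marker_panel)
    if markers is None:
        markers = MarkerPanel({"unspecified": [("__none__", "over")]})
    bundle = Bundle(
        gene_tumor=_need("gene_tumor", mio.read_expression_matrix),
        gene_normal=_need("gene_normal", mio.read_expression_matrix),
        mirna_tumor=_need("mirna_tumor", mio.read_expression_matrix,
                          "miRNA"),
        mirna_normal=_need("mirna_normal", mio.read_expression_matrix,
                           "miRNA"),
        network=_need("network", mio.read_edge_list),
        targets=targets, tf_table=tf_table, tf_expr=tf_expr,
        segments=_opt("segments", mio.read_segments),
        genes_bed=(pd.read_csv(inputs["genes_bed"], sep="\t")
                   if "genes_bed" in inputs else None),
        markers=markers,
        gene_lists=gene_lists or GeneSetCollection({"none": {"__none__"}}),
        mirna_lists=mirna_lists or GeneSetCollection({"none": {"__none__"}}),
        manifest={})
    pathways = _opt("pathways", mio.read_gmt)
    return run_pipeline_from_bundle(bundle, cfg, outdir, pathways=pathways)
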