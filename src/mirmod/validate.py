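"""Module validation: enrichment tests and regulation evidence.

Four regulation cases are assessed for each gene-miRNA module:

1. direct, predicted: a module miRNA's predicted targets (kept only when
   anti-correlated in expression) are enriched among the module genes;
2. direct, experimental: (gene, miRNA) pairs in the module confirmed by
   reporter-assay / western-blot style experiments;
3. TF co-regulation: a transcription factor whose targets are enriched
   in the module regulates both module genes and module miRNAs with
   same-sign expression correlations;
4. miRNA-via-TF: a module miRNA represses a TF (negative correlation)
   whose targets are enriched in the module;
plus coexpression-based experimental pairs. Pathway enrichment uses the
upper-tail hypergeometric test with sets capped at 300 genes and
within-module Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bicluster import bh_qvalues
from .types import (
    EnrichmentResult,
    ExpressionMatrix,
    GeneMiRNAModule,
    GeneSetCollection,
    RegulationEvidence,
    TargetTable,
    TFRelationTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_enrich",
    "direct_regulation_evidence",
    "tf_coregulation_evidence",
    "mirna_via_tf_evidence",
    "pathway_enrichment",
    "cancer_annotation_ratios",
    "overlap_ratio",
    "explained_module_summary",
    "correlation_edges",
]


def hypergeom_enrich(module_genes: set[str], subject_set: set[str],
                     universe: set[str], subject: str = "",
                     ) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene set in a module.

    p = P(X >= x) for X ~ Hypergeom(N, m, k) with N the universe size,
    m the subject set size, k the module size and x their overlap, all
    after intersection with the universe (genes outside the universe are
    dropped with a logged count).
    """
    if not universe:
        raise ValueError("empty universe")
    outside = len(module_genes) - len(module_genes & universe)
    if outside:
        logger.info("hypergeom_enrich(%s): %d module genes outside universe",
                    subject, outside)
    mod = module_genes & universe
    subj = subject_set & universe
    N, m, k = len(universe), len(subj), len(mod)
    overlap = mod & subj
    x = len(overlap)
    p = float(stats.hypergeom.sf(x - 1, N, m, k))
    return EnrichmentResult(subject=subject, N=N, m=m, k=k, x=x, p=p,
                            genes=tuple(sorted(overlap)))


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _row(expr: ExpressionMatrix, feature: str, samples: list[str]) -> np.ndarray:
    return expr.values.loc[feature, samples].to_numpy(float)


def direct_regulation_evidence(module: GeneMiRNAModule, targets: TargetTable,
                               gene_expr: ExpressionMatrix,
                               mirna_expr: ExpressionMatrix,
                               universe: set[str],
                               ) -> list[RegulationEvidence]:
    """Direct-regulation evidence for one module.

    Predicted case: per module miRNA, the target set is its predicted
    targets whose gene-miRNA Pearson correlation over the module samples
    is negative; that set is tested for enrichment among module genes.
    Experimental cases report each in-module pair present in the table
    with direct or coexpression evidence.
    """
    out: list[RegulationEvidence] = []
    samples = module.base.sorted_samples()
    have_gene = set(gene_expr.feature_ids)
    for mirna in module.mirnas:
        predicted = targets.targets_of(mirna, "predicted")
        if predicted and mirna in set(mirna_expr.feature_ids):
            y = _row(mirna_expr, mirna, samples)
            neg = set()
            for g in predicted:
                if g in have_gene:
                    r = _pcc(_row(gene_expr, g, samples), y)
                    if np.isfinite(r) and r < 0:
                        neg.add(g)
            if neg:
                enr = hypergeom_enrich(module.base.genes, neg, universe,
                                       subject=mirna)
                out.append(RegulationEvidence(
                    module_id=module.module_id, case="direct_predicted",
                    participants={"mirna": mirna, "genes": enr.genes},
                    statistics={"p": enr.p, "m": enr.m, "k": enr.k,
                                "x": enr.x}))
        for evidence, case in (("direct", "direct_experimental"),
                               ("coexpression", "coexpression_experimental")):
            for g in sorted(targets.targets_of(mirna, evidence)
                            & module.base.genes):
                out.append(RegulationEvidence(
                    module_id=module.module_id, case=case,
                    participants={"mirna": mirna, "gene": g}))
    return out


def tf_coregulation_evidence(module: GeneMiRNAModule,
                             tf_table: TFRelationTable,
                             gene_expr: ExpressionMatrix,
                             mirna_expr: ExpressionMatrix,
                             tf_expr: ExpressionMatrix,
                             universe: set[str], alpha: float = 0.05,
                             ) -> list[RegulationEvidence]:
    """Common-TF evidence: a TF regulates module genes and module miRNAs
    with same-sign (both positive or both negative) correlations.

    The TF need not belong to the module. For each TF with a
    TF->miRNA record for a module miRNA, the TF's target set is tested
    for enrichment among module genes; evidence is emitted when the
    enrichment p is below alpha and sign(PCC(TF, miRNA)) equals
    sign(PCC(TF, gene)) for the enriched genes, both nonzero.
    """
    out: list[RegulationEvidence] = []
    samples = module.base.sorted_samples()
    have_tf_expr = set(tf_expr.feature_ids)
    rel = tf_table.tf_mirna
    rel = rel[(rel["direction"] == "TF_regulates_miRNA")
              & rel["mirna"].isin(module.mirnas)]
    for tf in sorted(set(rel["tf"])):
        if tf not in have_tf_expr:
            logger.info("tf_coregulation: TF %s lacks expression row", tf)
            continue
        tf_targets = tf_table.targets_of_tf(tf)
        if not tf_targets:
            continue
        enr = hypergeom_enrich(module.base.genes, tf_targets, universe,
                               subject=tf)
        if enr.p >= alpha or not enr.genes:
            continue
        t = _row(tf_expr, tf, samples)
        gene_signs = []
        for g in enr.genes:
            r = _pcc(_row(gene_expr, g, samples), t)
            if np.isfinite(r) and r != 0:
                gene_signs.append((g, np.sign(r)))
        for mirna in sorted(set(rel.loc[rel["tf"] == tf, "mirna"])):
            if mirna not in set(mirna_expr.feature_ids):
                continue
            rm = _pcc(_row(mirna_expr, mirna, samples), t)
            if not np.isfinite(rm) or rm == 0:
                continue
            matched = [g for g, sgn in gene_signs if sgn == np.sign(rm)]
            if matched:
                out.append(RegulationEvidence(
                    module_id=module.module_id, case="tf_coregulation",
                    participants={"tf": tf, "mirna": mirna,
                                  "genes": tuple(matched)},
                    statistics={"p": enr.p, "tf_mirna_pcc": rm}))
    return out


def mirna_via_tf_evidence(module: GeneMiRNAModule,
                          tf_table: TFRelationTable,
                          gene_expr: ExpressionMatrix,
                          mirna_expr: ExpressionMatrix,
                          tf_expr: ExpressionMatrix,
                          universe: set[str], alpha: float = 0.05,
                          ) -> list[RegulationEvidence]:
    """Indirect evidence: a module miRNA represses a TF whose targets are
    enriched among module genes.

    Requires a miRNA_regulates_TF record and PCC(miRNA, TF) < 0 over the
    module samples; the TF->gene correlation sign is unconstrained.
    """
    out: list[RegulationEvidence] = []
    samples = module.base.sorted_samples()
    have_tf_expr = set(tf_expr.feature_ids)
    rel = tf_table.tf_mirna
    rel = rel[(rel["direction"] == "miRNA_regulates_TF")
              & rel["mirna"].isin(module.mirnas)]
    for _, rec in rel.iterrows():
        tf, mirna = rec["tf"], rec["mirna"]
        if tf not in have_tf_expr:
            logger.info("mirna_via_tf: TF %s lacks expression row", tf)
            continue
        if mirna not in set(mirna_expr.feature_ids):
            continue
        tf_targets = tf_table.targets_of_tf(tf)
        if not tf_targets:
            continue
        r = _pcc(_row(mirna_expr, mirna, samples), _row(tf_expr, tf, samples))
        if not np.isfinite(r) or r >= 0:
            continue
        enr = hypergeom_enrich(module.base.genes, tf_targets, universe,
                               subject=tf)
        if enr.p < alpha and enr.genes:
            out.append(RegulationEvidence(
                module_id=module.module_id, case="mirna_via_tf",
                participants={"tf": tf, "mirna": mirna, "genes": enr.genes},
                statistics={"p": enr.p, "mirna_tf_pcc": r}))
    return out


def pathway_enrichment(modules: list, pathways: GeneSetCollection,
                       universe: set[str], max_set_size: int = 300,
                       q_threshold: float = 0.05,
                       ) -> tuple[list[EnrichmentResult], dict]:
    """Per-module pathway enrichment with within-module BH correction.

    Sets with more than ``max_set_size`` genes in the universe are
    excluded as too general before testing. Returns the enrichment
    results with q < q_threshold plus a cohort summary (fraction of
    modules with at least one enriched set; mean enriched sets per
    module).
    """
    enriched: list[EnrichmentResult] = []
    per_module_counts = []
    for mod in modules:
        base = mod.base if isinstance(mod, GeneMiRNAModule) else mod
        results = []
        for name, members in sorted(pathways.items()):
            in_universe = members & universe
            if len(in_universe) > max_set_size or not in_universe:
                continue
            results.append(hypergeom_enrich(base.genes, in_universe,
                                            universe, subject=name))
        if results:
            qs = bh_qvalues([r.p for r in results])
            for r, q in zip(results, qs):
                r.q = float(q)
            hits = [r for r in results if r.q < q_threshold]
        else:
            hits = []
        for r in hits:
            r.subject = f"{base.module_id}:{r.subject}"
        enriched.extend(hits)
        per_module_counts.append(len(hits))
    n_mod = len(per_module_counts)
    summary = {
        "fraction_enriched_modules":
            (sum(c > 0 for c in per_module_counts) / n_mod) if n_mod else 0.0,
        "mean_enriched_sets_per_module":
            (sum(per_module_counts) / n_mod) if n_mod else 0.0,
    }
    return enriched, summary


def cancer_annotation_ratios(module, gene_lists: GeneSetCollection | None,
                             mirna_lists: GeneSetCollection | None) -> dict:
    """Fractions of module genes / miRNAs found in each annotation list."""
    base = module.base if isinstance(module, GeneMiRNAModule) else module
    ratios: dict[str, float] = {}
    if gene_lists is not None:
        for name, members in gene_lists.items():
            ratios[f"gene:{name}"] = (len(base.genes & members)
                                      / len(base.genes))
    if mirna_lists is not None and isinstance(module, GeneMiRNAModule):
        mirnas = set(module.mirnas)
        for name, members in mirna_lists.items():
            ratios[f"mirna:{name}"] = (len(mirnas & members) / len(mirnas))
    return ratios


def overlap_ratio(a: set, b: set) -> float:
    """Jaccard overlap |a & b| / |a | b| (0 when both sets are empty)."""
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def explained_module_summary(evidence_by_module: dict[str, list],
                             ) -> pd.DataFrame:
    """Per-module evidence-case booleans and the cohort explained fraction.

    Rows are modules, columns are the evidence cases plus ``explained``
    (any case present). The cohort fraction is attached in
    ``DataFrame.attrs['fraction_explained']``.
    """
    cases = list(RegulationEvidence.CASES)
    rows = {}
    for mid, evs in evidence_by_module.items():
        present = {e.case for e in evs}
        row = {c: (c in present) for c in cases}
        row["explained"] = bool(present)
        rows[mid] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cases + ["explained"])
    df.index.name = "module_id"
    df.attrs["fraction_explained"] = (float(df["explained"].mean())
                                      if len(df) else 0.0)
    return df


def correlation_edges(module: GeneMiRNAModule, gene_expr: ExpressionMatrix,
                      mirna_expr: ExpressionMatrix,
                      threshold: float = 0.3) -> pd.DataFrame:
    """Gene-miRNA correlation edge list for network export.

    Edges are (gene, miRNA, PCC) over the module samples with
    |PCC| > threshold.
    """
    samples = module.base.sorted_samples()
    rows = []
    for mirna in module.mirnas:
        if mirna not in set(mirna_expr.feature_ids):
            continue
        y = _row(mirna_expr, mirna, samples)
        for g in module.base.sorted_genes():
            if g not in set(gene_expr.feature_ids):
                continue
            r = _pcc(_row(gene_expr, g, samples), y)
            if np.isfinite(r) and abs(r) > threshold:
                rows.append((g, mirna, r))
    return pd.DataFrame(rows, columns=["gene", "mirna", "pcc"])
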