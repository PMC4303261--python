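"""Seeded generator of toy multi-omic datasets with planted structure.

The generator emulates the statistical shape of a tumor/normal
microarray study: log2-intensity gene and miRNA matrices over shared
tumor samples plus unmatched normals, where planted gene-sample blocks
carry a latent signal, planted miRNAs are negative linear drivers of
the block genes, transcription factors realize co-regulation and
miRNA-via-TF chains, an interaction network covers the block genes, and
target/TF tables contain the planted relations plus random decoys. A
copy-number plan adds dosage segments correlated with a module's
expression. Every planted truth is recorded in a manifest for recovery
scoring.

Generative model for one planted module with gene set G, sample set S,
effect size e and r regulators: each block sample s carries a latent
activity u_s drawn from a two-level mixture (moderately active at
0.8 e, strongly active at 1.6 e for about a third of samples, with a
0.1 e within-level spread), plus one factor f_js ~ N(0,1) per
regulator with loading g = 0.2 e. Each planted miRNA is a negative
linear function of the part of the signal it drives,
y_js = beta_j (u_s + g f_js) + noise with beta_j ~ N(coef_mean,
coef_sd) and coef_mean = -1, and genes follow the average of the
regulator signals, x_is = u_s + (g/r) sum_j f_js + noise: miRNAs are
strongly down-regulated exactly where the module genes are up, the
gene signal is exactly reconstructable from the full regulator set,
and each regulator carries factor variance the others cannot explain
(so a linear-Gaussian scorer needs all of them). Planted gene rows
additionally carry a pan-tumor baseline shift so that they are
differentially expressed cohort-wide, as selected disease genes are;
row centering removes the shift from all downstream statistics. The
whole structure scales with e, so effect 0 degenerates to pure
background noise. Outside S both genes and miRNAs are background
noise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneMiRNAModule,
    GeneSetCollection,
    InteractionNetwork,
    MarkerPanel,
    SegmentTrack,
    TargetTable,
    TFRelationTable,
)
from .validate import overlap_ratio

__all__ = ["ModulePlan", "TFPlan", "CNAPlan", "SimulationSpec",
           "Bundle", "generate", "score_recovery"]

LATENT_LOW = 0.80       # moderate block activity level, per unit effect
LATENT_RISE = 0.80      # extra activity of strongly-active samples
LATENT_HIGH_P = 1 / 3   # fraction of strongly-active block samples
LATENT_JITTER = 0.10    # within-level relative sd of the block latent
FACTOR_LOADING = 0.20   # per-regulator factor loading, per unit effect
GENE_FACTOR_RATIO = 1 / 3  # gene loading = average of regulator signals


@dataclass
class ModulePlan:
    """One planted gene-sample block and its miRNA regulators."""

    n_genes: int = 15
    n_samples: int = 20
    effect: float = 2.5
    n_regulators: int = 3
    coef_mean: float = -1.0
    coef_sd: float = 0.2
    overlap_genes: int = 0  # genes shared with the previous module


@dataclass
class TFPlan:
    """A planted TF relationship for one module.

    ``kind`` is "coregulation" (TF positively drives module genes and
    dedicated miRNAs) or "mirna_via_tf" (a module regulator represses
    the TF, whose targets are the module genes).
    """

    kind: str
    module: int
    n_mirnas: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("coregulation", "mirna_via_tf"):
            raise ValueError(f"unknown TF plan kind {self.kind!r}")


@dataclass
class CNAPlan:
    """A dosage region driving one module's samples."""

    chrom: str = "chr1"
    start_mb: int = 10
    end_mb: int = 15
    module: int = 0
    effect: float = 0.5


@dataclass
class SimulationSpec:
    """Full description of a synthetic study."""

    seed: int = 0
    n_genes: int = 80
    n_mirnas: int = 26
    n_tumor_samples: int = 300
    n_normal_samples: int = 8
    modules: list[ModulePlan] = field(
        default_factory=lambda: [ModulePlan(), ModulePlan()])
    tf_plans: list[TFPlan] = field(default_factory=list)
    cna_plans: list[CNAPlan] = field(default_factory=list)
    noise_sd: float = 0.3
    mirna_obs_sd: float = 0.05  # measurement noise on planted miRNA rows
    de_shift: float = 0.6      # pan-tumor up-shift of planted gene rows
    network_edge_p: float = 0.05
    target_tp_fraction: float = 0.6  # planted targets recorded per regulator
    target_decoys: int = 40
    modules_disjoint_samples: bool = True

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        total_genes = sum(m.n_genes - m.overlap_genes for m in self.modules)
        if total_genes > self.n_genes:
            raise ValueError("module plans need more genes than available")
        total_reg = sum(m.n_regulators for m in self.modules)
        extra = sum(p.n_mirnas for p in self.tf_plans
                    if p.kind == "coregulation")
        if total_reg + extra > self.n_mirnas:
            raise ValueError("module plans need more miRNAs than available")
        if self.modules_disjoint_samples:
            total_s = sum(m.n_samples for m in self.modules)
            if total_s > self.n_tumor_samples:
                raise ValueError("module sample plans exceed tumor samples")


@dataclass
class Bundle:
    """Everything the pipeline consumes, plus the ground-truth manifest."""

    gene_tumor: ExpressionMatrix
    gene_normal: ExpressionMatrix
    mirna_tumor: ExpressionMatrix
    mirna_normal: ExpressionMatrix
    network: InteractionNetwork
    targets: TargetTable
    tf_table: TFRelationTable
    tf_expr: ExpressionMatrix
    segments: SegmentTrack | None
    genes_bed: pd.DataFrame | None
    markers: MarkerPanel
    gene_lists: GeneSetCollection
    mirna_lists: GeneSetCollection
    manifest: dict


def generate(spec: SimulationSpec) -> Bundle:
    """Generate a complete, deterministic dataset bundle from a spec."""
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    mirnas = [f"miR-{i:03d}" for i in range(spec.n_mirnas)]
    tumor_samples = [f"T{i:03d}" for i in range(spec.n_tumor_samples)]
    normal_samples = [f"N{i:02d}" for i in range(spec.n_normal_samples)]

    # baseline log2 intensities; ratios are planted on top of them
    base_gene = rng.normal(8.0, 1.0, spec.n_genes)
    base_mirna = rng.normal(6.0, 1.0, spec.n_mirnas)

    gene_ratio = rng.normal(0.0, sd, (spec.n_genes, spec.n_tumor_samples))
    mirna_ratio = rng.normal(0.0, sd, (spec.n_mirnas, spec.n_tumor_samples))

    # assign genes / miRNAs / samples to module plans
    gene_cursor = 0
    mirna_cursor = 0
    sample_cursor = 0
    truth_modules = []
    latent_factors = {}  # module index -> (sample_idx, factors r x |S|)
    for mi, plan in enumerate(spec.modules):
        if plan.overlap_genes and truth_modules:
            prev = truth_modules[-1]["gene_idx"]
            shared = prev[-plan.overlap_genes:]
        else:
            shared = []
        n_new = plan.n_genes - len(shared)
        g_idx = shared + list(range(gene_cursor, gene_cursor + n_new))
        gene_cursor += n_new
        m_idx = list(range(mirna_cursor, mirna_cursor + plan.n_regulators))
        mirna_cursor += plan.n_regulators
        if spec.modules_disjoint_samples:
            s_idx = list(range(sample_cursor, sample_cursor + plan.n_samples))
            sample_cursor += plan.n_samples
        else:
            s_idx = sorted(rng.choice(spec.n_tumor_samples,
                                      size=plan.n_samples, replace=False))

        r = plan.n_regulators
        # two-level latent: block samples are moderately active (most) or
        # strongly active (about a third), as in tumor subpopulations;
        # both levels stay clearly above background, and the mixture keeps
        # the latent variance sizeable and stable across realizations
        high = (rng.random(plan.n_samples) < LATENT_HIGH_P).astype(float)
        u = plan.effect * (LATENT_LOW + LATENT_RISE * high
                           + LATENT_JITTER * rng.normal(size=plan.n_samples))
        gamma = FACTOR_LOADING * plan.effect
        f = rng.normal(0.0, 1.0, (r, plan.n_samples))
        beta = rng.normal(plan.coef_mean, plan.coef_sd, r)
        delta = gamma * GENE_FACTOR_RATIO
        gene_signal = u + delta * f.sum(axis=0)
        for gi in g_idx:
            # pan-tumor shift keeps planted genes robustly differentially
            # expressed; row centering makes it invisible to the z-matrix
            gene_ratio[gi, :] += spec.de_shift * (plan.effect / 2.5)
            gene_ratio[gi, s_idx] = (gene_signal
                                     + rng.normal(0.0, sd, plan.n_samples))
        for jj, mj in enumerate(m_idx):
            mirna_ratio[mj, s_idx] = (beta[jj] * (u + gamma * f[jj])
                                      + rng.normal(0.0, spec.mirna_obs_sd,
                                                   plan.n_samples))
        latent_factors[mi] = (s_idx, f)
        truth_modules.append({
            "module": mi,
            "gene_idx": g_idx,
            "genes": [genes[i] for i in g_idx],
            "samples": [tumor_samples[i] for i in s_idx],
            "mirnas": [mirnas[i] for i in m_idx],
            "coefficients": beta.tolist(),
            "effect": plan.effect,
        })

    # TF layer
    tf_ids = [f"TF{i}" for i in range(len(spec.tf_plans))]
    tf_expr_rows = np.zeros((len(spec.tf_plans), spec.n_tumor_samples))
    tf_gene_rows, tf_mirna_rows, truth_tfs = [], [], []
    for ti, plan in enumerate(spec.tf_plans):
        tf = tf_ids[ti]
        mod = truth_modules[plan.module]
        s_idx = [tumor_samples.index(s) for s in mod["samples"]]
        # TF follows the module's mean gene signal (positive with genes)
        mod_mean = gene_ratio[mod["gene_idx"]][:, s_idx].mean(axis=0)
        row = rng.normal(0.0, sd, spec.n_tumor_samples)
        row[s_idx] = mod_mean + rng.normal(0.0, sd, len(s_idx))
        tf_expr_rows[ti] = row
        for g in mod["genes"]:
            tf_gene_rows.append((tf, g))
        if plan.kind == "coregulation":
            co_idx = list(range(mirna_cursor, mirna_cursor + plan.n_mirnas))
            mirna_cursor += plan.n_mirnas
            for mj in co_idx:
                mirna_ratio[mj, s_idx] = (mod_mean
                                          + rng.normal(0.0, sd, len(s_idx)))
                tf_mirna_rows.append((tf, mirnas[mj],
                                      "TF_regulates_miRNA", "planted"))
            truth_tfs.append({"tf": tf, "kind": plan.kind,
                              "module": plan.module,
                              "mirnas": [mirnas[i] for i in co_idx]})
        else:  # mirna_via_tf: a module regulator represses the TF
            mirna = mod["mirnas"][0]
            tf_mirna_rows.append((tf, mirna, "miRNA_regulates_TF", "planted"))
            truth_tfs.append({"tf": tf, "kind": plan.kind,
                              "module": plan.module, "mirnas": [mirna]})

    # interaction network: ring+chords inside modules, ER background
    edges: set[tuple[str, str]] = set()
    for mod in truth_modules:
        g = mod["genes"]
        for i in range(len(g)):
            edges.add(tuple(sorted((g[i], g[(i + 1) % len(g)]))))
        n_chords = max(1, len(g) // 3)
        for _ in range(n_chords):
            a, b = rng.choice(len(g), size=2, replace=False)
            if a != b:
                edges.add(tuple(sorted((g[a], g[b]))))
    n_bg = int(spec.network_edge_p * spec.n_genes)
    for _ in range(n_bg * 4):
        a, b = rng.choice(spec.n_genes, size=2, replace=False)
        edges.add(tuple(sorted((genes[a], genes[b]))))
    network = InteractionNetwork.from_edges(edges)

    # target table: planted regulator->gene pairs plus decoys
    target_rows = []
    truth_targets = []
    for mod in truth_modules:
        for mirna in mod["mirnas"]:
            k = max(1, int(round(spec.target_tp_fraction * len(mod["genes"]))))
            chosen = rng.choice(mod["genes"], size=k, replace=False)
            for g in chosen:
                target_rows.append((mirna, g, "predicted", "planted"))
                truth_targets.append((mirna, g))
            # one experimentally confirmed pair per regulator
            target_rows.append((mirna, str(chosen[0]), "direct", "planted"))
    seen = {(m, g, e) for m, g, e, _ in target_rows}
    n_added = 0
    while n_added < spec.target_decoys:
        m = mirnas[int(rng.integers(spec.n_mirnas))]
        g = genes[int(rng.integers(spec.n_genes))]
        if (m, g, "predicted") not in seen:
            target_rows.append((m, g, "predicted", "decoy"))
            seen.add((m, g, "predicted"))
            n_added += 1
    targets = TargetTable(pd.DataFrame(
        target_rows, columns=["mirna", "gene", "evidence", "provenance"]))

    # copy-number plan
    segments = None
    genes_bed = None
    if spec.cna_plans:
        seg_rows = []
        bed_rows = []
        bin_ = 1_000_000
        for plan in spec.cna_plans:
            mod = truth_modules[plan.module]
            s_idx = [tumor_samples.index(s) for s in mod["samples"]]
            mod_mean_all = gene_ratio[mod["gene_idx"]].mean(axis=0)
            lo, hi = plan.start_mb * bin_, plan.end_mb * bin_
            for si, smp in enumerate(tumor_samples):
                if si in s_idx:
                    ratio = (plan.effect * mod_mean_all[si] / mod["effect"]
                             + rng.normal(0.0, 0.02))
                else:
                    ratio = rng.normal(0.0, 0.02)
                seg_rows.append((plan.chrom, lo, hi, smp, float(ratio)))
            span = hi - lo
            for gi, g in enumerate(mod["genes"]):
                start = lo + int((gi + 0.5) / len(mod["genes"]) * span)
                bed_rows.append((plan.chrom, start, start + 1000, g))
        segments = SegmentTrack(pd.DataFrame(
            seg_rows, columns=["chrom", "start", "end", "sample", "ratio"]))
        genes_bed = pd.DataFrame(bed_rows,
                                 columns=["chrom", "start", "end", "gene"])

    # marker panels: first genes of each module, over-expressed
    panels = {}
    for mod in truth_modules:
        panels[f"subtype{mod['module']}"] = [(g, "over")
                                             for g in mod["genes"][:3]]
    markers = MarkerPanel(panels)

    # cancer annotation lists: planted members plus random background
    planted_genes = sorted({g for m in truth_modules for g in m["genes"]})
    planted_mirnas = sorted({m for mod in truth_modules
                             for m in mod["mirnas"]})
    extra_g = [genes[i] for i in
               rng.choice(spec.n_genes, size=min(10, spec.n_genes),
                          replace=False)]
    gene_lists = GeneSetCollection(
        {"cancer_genes": set(planted_genes[::2]) | set(extra_g)},
        {"cancer_genes": "cancer-list"})
    mirna_lists = GeneSetCollection(
        {"cancer_mirnas": set(planted_mirnas)},
        {"cancer_mirnas": "cancer-list"})

    def _as_matrix(ratio, base, ids, samples, kind):
        vals = base[:, None] + ratio
        return ExpressionMatrix(
            pd.DataFrame(vals, index=ids, columns=samples), kind)

    gene_tumor = _as_matrix(gene_ratio, base_gene, genes, tumor_samples,
                            "gene")
    gene_normal = _as_matrix(
        rng.normal(0.0, sd, (spec.n_genes, spec.n_normal_samples)),
        base_gene, genes, normal_samples, "gene")
    mirna_tumor = _as_matrix(mirna_ratio, base_mirna, mirnas, tumor_samples,
                             "miRNA")
    mirna_normal = _as_matrix(
        rng.normal(0.0, sd, (spec.n_mirnas, spec.n_normal_samples)),
        base_mirna, mirnas, normal_samples, "miRNA")

    tf_table = TFRelationTable(
        pd.DataFrame(tf_gene_rows, columns=["tf", "gene"]),
        pd.DataFrame(tf_mirna_rows,
                     columns=["tf", "mirna", "direction", "provenance"]))
    tf_expr = ExpressionMatrix(
        pd.DataFrame(tf_expr_rows, index=tf_ids, columns=tumor_samples),
        "gene")

    manifest = {
        "seed": spec.seed,
        "modules": [{k: v for k, v in m.items() if k != "gene_idx"}
                    for m in truth_modules],
        "tfs": truth_tfs,
        "targets": truth_targets,
        "cna": [vars(p) for p in spec.cna_plans],
    }
    return Bundle(gene_tumor=gene_tumor, gene_normal=gene_normal,
                  mirna_tumor=mirna_tumor, mirna_normal=mirna_normal,
                  network=network, targets=targets, tf_table=tf_table,
                  tf_expr=tf_expr, segments=segments, genes_bed=genes_bed,
                  markers=markers, gene_lists=gene_lists,
                  mirna_lists=mirna_lists, manifest=manifest)


def score_recovery(found: list, manifest: dict,
                   match_threshold: float = 0.25) -> dict:
    """Score pipeline output against the planted truth.

    For every planted module the best-matching found module by gene
    Jaccard is located; gene/sample/miRNA precision and recall are
    computed against it, and a planted module counts as recovered when
    the best Jaccard reaches ``match_threshold``. ``module_recall`` is
    the fraction of planted modules recovered.
    """
    per_module = []
    n_recovered = 0
    for truth in manifest["modules"]:
        tg, ts = set(truth["genes"]), set(truth["samples"])
        tm = set(truth["mirnas"])
        best, best_j = None, -1.0
        for mod in found:
            base = mod.base if isinstance(mod, GeneMiRNAModule) else mod
            j = overlap_ratio(tg, base.genes)
            if j > best_j:
                best, best_j = mod, j
        entry = {"module": truth["module"], "best_jaccard": max(best_j, 0.0)}
        if best is not None and best_j >= match_threshold:
            n_recovered += 1
            base = best.base if isinstance(best, GeneMiRNAModule) else best
            entry["gene_precision"] = len(tg & base.genes) / len(base.genes)
            entry["gene_recall"] = len(tg & base.genes) / len(tg)
            entry["sample_precision"] = (len(ts & base.samples)
                                         / len(base.samples))
            entry["sample_recall"] = len(ts & base.samples) / len(ts)
            if isinstance(best, GeneMiRNAModule):
                fm = set(best.mirnas)
                entry["mirna_precision"] = (len(tm & fm) / len(fm)
                                            if fm else 0.0)
                entry["mirna_recall"] = len(tm & fm) / len(tm)
                entry["regulator_exact"] = fm == tm
        else:
            entry.update(gene_precision=0.0, gene_recall=0.0,
                         sample_precision=0.0, sample_recall=0.0,
                         mirna_precision=0.0, mirna_recall=0.0,
                         regulator_exact=False)
        per_module.append(entry)
    n = len(per_module)
    out = {
        "per_module": per_module,
        "module_recall": n_recovered / n if n else 0.0,
        "mean_gene_recall": (np.mean([e["gene_recall"] for e in per_module])
                             if n else 0.0),
        "all_regulators_exact": all(e.get("regulator_exact", False)
                                    for e in per_module) if n else False,
    }
    return out
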