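"""Bipartite heavy-subgraph biclustering with permutation significance.

The z-scored expression matrix is modelled as a bipartite graph between
genes and samples: an edge connects gene g and sample s when |z[g,s]|
exceeds a threshold, weighted by |z| and signed by the direction of
change. A bicluster (gene-sample module) is a subgraph in which most
genes are connected to most samples; it is scored additively as the sum
of present-edge weights minus a penalty lambda per absent gene-sample
pair, with sign consistency enforced per gene (edges disagreeing with
the gene's dominant sign count as absent).

Module significance is assessed by comparing the module's average
pairwise Pearson correlation against random modules of the same
dimensions; random cohorts can optionally be constructed to share the
observed pairwise gene-overlap structure of the real cohort.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSampleModule

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteGraph",
    "PermutationConfig",
    "build_bipartite_graph",
    "find_biclusters",
    "module_avg_pcc",
    "permutation_pvalue",
    "bh_qvalues",
    "SambaBiclustering",
]


@dataclass
class BipartiteGraph:
    """Weighted, signed bipartite gene-sample graph plus its z-matrix."""

    z: ExpressionMatrix
    mask: np.ndarray     # bool, genes x samples: edge present
    weights: np.ndarray  # |z| where mask, else 0
    signs: np.ndarray    # +1 / -1 where mask, else 0

    @property
    def gene_ids(self) -> list[str]:
        return self.z.feature_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.z.sample_ids

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum())


@dataclass
class PermutationConfig:
    """Settings for the permutation significance test."""

    N: int = 1000
    seed: int = 0
    overlap_matched: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("permutation count N must be >= 1")


def build_bipartite_graph(z: ExpressionMatrix,
                          z_threshold: float = 1.5) -> BipartiteGraph:
    """Threshold the z-matrix into a signed, weighted bipartite graph.

    An edge (g, s) exists iff |z[g,s]| >= z_threshold; its weight is
    |z[g,s]| and its sign records the direction of change.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    arr = z.values.to_numpy(float)
    mask = np.abs(arr) >= z_threshold
    weights = np.where(mask, np.abs(arr), 0.0)
    signs = np.where(mask, np.sign(arr), 0.0)
    return BipartiteGraph(z, mask, weights, signs)


def _gene_stats(graph: BipartiteGraph, sample_idx: np.ndarray):
    """Per-gene positive/negative edge weight sums and counts over samples."""
    w = graph.weights[:, sample_idx]
    s = graph.signs[:, sample_idx]
    posw = np.where(s > 0, w, 0.0).sum(axis=1)
    negw = np.where(s < 0, w, 0.0).sum(axis=1)
    posn = (s > 0).sum(axis=1).astype(float)
    negn = (s < 0).sum(axis=1).astype(float)
    return posw, negw, posn, negn


def _gene_contrib(posw, negw, posn, negn, n_samples: int, lam: float):
    """Score contribution of each gene given its sign-split edge stats.

    The gene's dominant sign maximizes (weight sum + lam * edge count);
    minority-sign edges are counted as absent pairs.
    """
    return np.maximum(posw + lam * posn, negw + lam * negn) - lam * n_samples


def _score_submatrix(graph: BipartiteGraph, gene_idx: np.ndarray,
                     sample_idx: np.ndarray, lam: float) -> float:
    posw, negw, posn, negn = _gene_stats(graph, sample_idx)
    contrib = _gene_contrib(posw[gene_idx], negw[gene_idx], posn[gene_idx],
                            negn[gene_idx], len(sample_idx), lam)
    return float(contrib.sum())


def _greedy_grow(graph: BipartiteGraph, seed_gene: int,
                 seed_samples: np.ndarray, lam: float,
                 max_iter: int = 500) -> tuple[set, set, float]:
    """Steepest-ascent local search over single gene/sample moves."""
    n_genes, n_samples = graph.mask.shape
    genes = {seed_gene}
    samples = set(seed_samples.tolist())
    sample_idx = np.fromiter(sorted(samples), int)
    posw, negw, posn, negn = _gene_stats(graph, sample_idx)

    w, s = graph.weights, graph.signs
    for _ in range(max_iter):
        ns = len(samples)
        contrib = _gene_contrib(posw, negw, posn, negn, ns, lam)
        gene_arr = np.fromiter(sorted(genes), int)
        in_module = np.zeros(n_genes, bool)
        in_module[gene_arr] = True

        best_delta, best_move = 0.0, None
        # gene moves: adding gene g contributes contrib[g]; removing negates
        add_deltas = np.where(~in_module, contrib, -np.inf)
        g_add = int(np.argmax(add_deltas))
        if add_deltas[g_add] > best_delta:
            best_delta, best_move = float(add_deltas[g_add]), ("add_gene", g_add)
        if len(genes) > 1:
            rem_deltas = np.where(in_module, -contrib, -np.inf)
            g_rem = int(np.argmax(rem_deltas))
            if rem_deltas[g_rem] > best_delta:
                best_delta, best_move = float(rem_deltas[g_rem]), ("rem_gene", g_rem)

        # sample moves, vectorized over every candidate sample at once
        m = len(gene_arr)
        cur_total = float(contrib[gene_arr].sum())
        pw = posw[gene_arr][:, None]
        nw = negw[gene_arr][:, None]
        pn = posn[gene_arr][:, None]
        nn = negn[gene_arr][:, None]
        W, Sg = w[gene_arr], s[gene_arr]
        pos_w, neg_w = np.where(Sg > 0, W, 0.0), np.where(Sg < 0, W, 0.0)
        pos_c, neg_c = (Sg > 0).astype(float), (Sg < 0).astype(float)
        in_s = np.zeros(n_samples, bool)
        in_s[np.fromiter(samples, int)] = True
        sign = np.where(in_s, -1.0, 1.0)[None, :]  # remove vs add
        tot = np.maximum((pw + sign * pos_w) + lam * (pn + sign * pos_c),
                         (nw + sign * neg_w) + lam * (nn + sign * neg_c)
                         ).sum(axis=0)
        new_ns = np.where(in_s, ns - 1, ns + 1)
        deltas = tot - lam * new_ns * m - cur_total
        if ns <= 1:
            deltas[in_s] = -np.inf
        smp = int(np.argmax(deltas))
        if deltas[smp] > best_delta:
            kind = "rem_sample" if in_s[smp] else "add_sample"
            best_delta, best_move = float(deltas[smp]), (kind, smp)

        if best_move is None:
            break
        kind, idx = best_move
        if kind == "add_gene":
            genes.add(idx)
        elif kind == "rem_gene":
            genes.discard(idx)
        else:
            if kind == "add_sample":
                samples.add(idx)
            else:
                samples.discard(idx)
            sample_idx = np.fromiter(sorted(samples), int)
            posw, negw, posn, negn = _gene_stats(graph, sample_idx)

    sample_idx = np.fromiter(sorted(samples), int)
    gene_idx = np.fromiter(sorted(genes), int)
    score = _score_submatrix(graph, gene_idx, sample_idx, lam)
    return genes, samples, score


def _enumerate_exact(graph: BipartiteGraph, min_genes: int, min_samples: int,
                     lam: float) -> list[tuple[set, set, float]]:
    """Exhaustive search over all gene/sample subsets meeting min sizes."""
    n_genes, n_samples = graph.mask.shape
    out = []
    gene_pool = range(n_genes)
    sample_subsets = []
    for k in range(min_samples, n_samples + 1):
        sample_subsets.extend(itertools.combinations(range(n_samples), k))
    stats_cache = {ss: _gene_stats(graph, np.array(ss, int))
                   for ss in sample_subsets}
    for k in range(min_genes, n_genes + 1):
        for gs in itertools.combinations(gene_pool, k):
            gi = np.array(gs, int)
            for ss in sample_subsets:
                posw, negw, posn, negn = stats_cache[ss]
                contrib = _gene_contrib(posw[gi], negw[gi], posn[gi],
                                        negn[gi], len(ss), lam)
                sc = float(contrib.sum())
                if sc > 0:
                    out.append((set(gs), set(ss), sc))
    return out


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def find_biclusters(graph: BipartiteGraph, min_genes: int = 5,
                    min_samples: int = 5, max_modules: int = 50,
                    overlap_factor: float = 0.5, seed: int = 0,
                    lam: float = 1.0, method: str = "auto",
                    ) -> list[GeneSampleModule]:
    """Extract ranked, overlap-controlled gene-sample modules.

    Candidates are grown by steepest-ascent local search from one seed
    per gene (the gene plus its incident samples); on problems small
    enough to enumerate the search is exact by exhaustive subset
    enumeration (``method="auto"``). Candidates are ranked by score and a
    candidate is kept only if its gene-set Jaccard overlap with every
    kept module is at most (1 - overlap_factor).
    """
    if not 0.0 <= overlap_factor <= 1.0:
        raise ValueError("overlap_factor must be in [0, 1]")
    if graph.n_edges == 0:
        return []
    n_genes, n_samples = graph.mask.shape

    if method == "auto":
        method = "exact" if (n_genes <= 10 and n_samples <= 8) else "greedy"
    if method == "exact":
        candidates = _enumerate_exact(graph, min_genes, min_samples, lam)
    elif method == "greedy":
        candidates = []
        seen: set[tuple] = set()
        degrees = graph.mask.sum(axis=1)
        for g in range(n_genes):
            if degrees[g] < min_samples:
                continue
            seed_samples = np.flatnonzero(graph.mask[g])
            genes, samples, score = _greedy_grow(graph, g, seed_samples, lam)
            if len(genes) < min_genes or len(samples) < min_samples:
                continue
            key = (frozenset(genes), frozenset(samples))
            if key in seen:
                continue
            seen.add(key)
            candidates.append((genes, samples, score))
    else:
        raise ValueError(f"unknown method {method!r}")

    # rank by score (deterministic tie-break on member ids)
    candidates.sort(key=lambda c: (-c[2], sorted(c[0]), sorted(c[1])))
    gene_ids = np.array(graph.gene_ids, object)
    sample_ids = np.array(graph.sample_ids, object)
    kept: list[GeneSampleModule] = []
    kept_gene_sets: list[set] = []
    max_overlap = 1.0 - overlap_factor
    for genes, samples, score in candidates:
        gset = {str(g) for g in gene_ids[sorted(genes)]}
        if any(_jaccard(gset, other) > max_overlap for other in kept_gene_sets):
            continue
        sset = {str(s) for s in sample_ids[sorted(samples)]}
        mod = GeneSampleModule(module_id=f"M{len(kept) + 1}", genes=gset,
                               samples=sset, score=score)
        mod.module_avg = module_avg_pcc(mod, graph.z)
        kept.append(mod)
        kept_gene_sets.append(gset)
        if len(kept) >= max_modules:
            break
    return kept


def module_avg_pcc(module: GeneSampleModule, z: ExpressionMatrix) -> float:
    """Average off-diagonal pairwise Pearson correlation of module genes
    over the module's samples."""
    return _avg_pcc(module.sorted_genes(), module.sorted_samples(), z)


def _avg_pcc(genes: list, samples: list, z: ExpressionMatrix) -> float:
    sub = z.values.loc[list(genes), list(samples)].to_numpy(float)
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("average PCC needs >=2 genes and >=2 samples")
    sd = sub.std(axis=1)
    ok = sd > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("module_avg_pcc: excluded %d zero-variance genes", n_bad)
    sub = sub[ok]
    if sub.shape[0] < 2:
        return float("nan")
    corr = np.corrcoef(sub)
    k = corr.shape[0]
    off = corr[~np.eye(k, dtype=bool)]
    return float(off.mean())


def _random_cohort_gene_sets(sizes: list[int], overlaps: np.ndarray,
                             universe: list, rng: np.random.Generator,
                             ) -> list[set]:
    """Random gene sets reproducing observed pairwise intersection sizes.

    Sets are built in cohort order; set j first draws, for each earlier
    set l, a shared pool of the observed intersection size from set l's
    members, then fills the remaining slots independently.
    """
    sets: list[set] = []
    for j, size in enumerate(sizes):
        chosen: set = set()
        for l in range(j):
            o = int(overlaps[j, l])
            room = size - len(chosen)
            if o <= 0 or room <= 0:
                continue
            pool = sorted(sets[l] - chosen)
            take = min(o, room, len(pool))
            if take:
                chosen |= set(rng.choice(pool, size=take, replace=False))
        rest = [g for g in universe if g not in chosen]
        need = size - len(chosen)
        chosen |= set(rng.choice(rest, size=need, replace=False))
        sets.append(chosen)
    return sets


def permutation_pvalue(module: GeneSampleModule, z: ExpressionMatrix,
                       cfg: PermutationConfig,
                       cohort: list[GeneSampleModule] | None = None) -> float:
    """Permutation p-value of a module's average PCC.

    p = #{i : module_avg < random_avg(i)} / N with random modules drawn
    with the module's gene and sample counts. With ``overlap_matched``,
    each permutation builds random gene sets for the whole cohort that
    reuse the observed pairwise gene-overlap counts, and the target
    module's random counterpart is scored. The strict inequality means
    p = 0 is attainable.
    """
    cohort = cohort or [module]
    if module not in cohort:
        cohort = [module] + list(cohort)
    j = cohort.index(module)
    rng = np.random.default_rng([int(cfg.seed) % (2 ** 31), j])

    genes_all = z.feature_ids
    samples_all = z.sample_ids
    sizes = [len(m.genes) for m in cohort]
    k = len(cohort)
    overlaps = np.zeros((k, k), int)
    for a in range(k):
        for b in range(k):
            if a != b:
                overlaps[a, b] = len(cohort[a].genes & cohort[b].genes)

    obs = module.module_avg
    if not np.isfinite(obs):
        obs = module_avg_pcc(module, z)
    n_samples = len(module.samples)
    exceed = 0
    for _ in range(cfg.N):
        if cfg.overlap_matched and k > 1:
            gene_sets = _random_cohort_gene_sets(sizes, overlaps, genes_all, rng)
            rand_genes = sorted(gene_sets[j])
        else:
            rand_genes = sorted(rng.choice(genes_all, size=sizes[j],
                                           replace=False))
        rand_samples = sorted(rng.choice(samples_all, size=n_samples,
                                         replace=False))
        rand_avg = _avg_pcc(rand_genes, rand_samples, z)
        if obs < rand_avg:
            exceed += 1
    return exceed / cfg.N


def bh_qvalues(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class SambaBiclustering(BaseEstimator):
    """Bipartite heavy-subgraph biclustering estimator.

    Fits on a z-scored ExpressionMatrix (or DataFrame of the same layout)
    and exposes the extracted gene-sample modules. Optionally runs the
    permutation significance test and retains only modules with
    BH q-value below ``q_threshold``.

    Parameters
    ----------
    z_threshold : float, default 1.5
        |z| cutoff for a gene-sample edge.
    lam : float, default 1.0
        Penalty per absent gene-sample pair in the module score.
    min_genes, min_samples : int, default 5
        Minimum module dimensions.
    max_modules : int, default 50
        Module count cap after ranking.
    overlap_factor : float, default 0.5
        Redundancy control in [0, 1]; 1 forbids any gene overlap.
    n_permutations : int, default 1000
        Permutations for the significance test; 0 disables the test.
    q_threshold : float, default 0.05
        Significance gate applied when the permutation test runs.
    overlap_matched : bool, default True
        Match random cohorts to the observed gene-overlap structure.
    method : {"auto", "greedy", "exact"}, default "auto"
        Search strategy; "auto" enumerates exhaustively when the matrix
        is small enough and uses greedy local search otherwise.
    random_state : int, default 0
        Seed for the permutation test.

    Attributes
    ----------
    modules_ : list of GeneSampleModule
        Extracted (and, if tested, significance-filtered) modules.
    all_modules_ : list of GeneSampleModule
        Modules before the significance gate, with p/q values filled in.
    graph_ : BipartiteGraph
    """

    def __init__(self, z_threshold: float = 1.5, lam: float = 1.0,
                 min_genes: int = 5, min_samples: int = 5,
                 max_modules: int = 50, overlap_factor: float = 0.5,
                 n_permutations: int = 1000, q_threshold: float = 0.05,
                 overlap_matched: bool = True, method: str = "auto",
                 random_state: int = 0):
        self.z_threshold = z_threshold
        self.lam = lam
        self.min_genes = min_genes
        self.min_samples = min_samples
        self.max_modules = max_modules
        self.overlap_factor = overlap_factor
        self.n_permutations = n_permutations
        self.q_threshold = q_threshold
        self.overlap_matched = overlap_matched
        self.method = method
        self.random_state = random_state

    def fit(self, X: ExpressionMatrix, y=None) -> "SambaBiclustering":
        if not isinstance(X, ExpressionMatrix):
            X = ExpressionMatrix(X)
        self.graph_ = build_bipartite_graph(X, self.z_threshold)
        modules = find_biclusters(
            self.graph_, min_genes=self.min_genes,
            min_samples=self.min_samples, max_modules=self.max_modules,
            overlap_factor=self.overlap_factor, seed=self.random_state,
            lam=self.lam, method=self.method)
        if self.n_permutations and modules:
            cfg = PermutationConfig(N=self.n_permutations,
                                    seed=self.random_state,
                                    overlap_matched=self.overlap_matched)
            for mod in modules:
                mod.p_value = permutation_pvalue(mod, X, cfg, cohort=modules)
            qs = bh_qvalues([m.p_value for m in modules])
            for mod, q in zip(modules, qs):
                mod.q_value = float(q)
            self.all_modules_ = modules
            self.modules_ = [m for m in modules
                             if m.q_value < self.q_threshold]
        else:
            self.all_modules_ = modules
            self.modules_ = modules
        return self

    def fit_predict(self, X: ExpressionMatrix, y=None) -> list[GeneSampleModule]:
        return self.fit(X).modules_
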