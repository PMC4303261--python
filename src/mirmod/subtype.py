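"""Cancer-subtype assignment for samples and modules.

Samples are clustered by average-linkage hierarchical clustering on the
correlation distance (1 - PCC) over the most variable genes, with
clusters extracted by a dynamic cut: cut heights are scanned from the
root and the dendrogram is split as long as every resulting cluster
keeps a minimum number of members. Clusters are then labelled with a
subtype when that subtype's marker genes deviate in the expected
direction (over/under) relative to the remaining samples; ambiguous
clusters (zero or several matching subtypes) stay unassigned. Finally,
each module is tested for subtype association by comparing its samples'
marker expression against the samples of the other subtypes' clusters.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .types import ExpressionMatrix, GeneSampleModule, MarkerPanel

logger = logging.getLogger(__name__)

__all__ = ["cluster_samples", "assign_cluster_subtype",
           "module_subtype_test", "SubtypeClusterer"]


def _cluster_root_heights(Z: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Height of the last merge fully inside each cluster (0 for singletons)."""
    n = len(labels)
    node_label: dict[int, int | None] = {i: int(labels[i]) for i in range(n)}
    heights: dict[int, float] = {int(lab): 0.0 for lab in np.unique(labels)}
    for k, (a, b, h, _) in enumerate(Z):
        la, lb = node_label[int(a)], node_label[int(b)]
        lab = la if (la == lb and la is not None) else None
        node_label[n + k] = lab
        if lab is not None:
            heights[lab] = max(heights[lab], float(h))
    return heights


def cluster_samples(expr: ExpressionMatrix, top_var_genes: int = 1000,
                    min_cluster_size: int = 30,
                    cohesion_ratio: float = 0.9) -> dict[int, list[str]]:
    """Cluster samples by marker-free expression similarity.

    Uses the ``top_var_genes`` most variable genes, average linkage on
    1 - PCC distance between samples, and a dynamic cut: cut heights are
    scanned from the root and a finer partition is accepted while every
    resulting cluster keeps at least ``min_cluster_size`` members and is
    internally cohesive (its own root merge height is at most
    ``cohesion_ratio`` times the cut height, so homogeneous noise is not
    split). Returns cluster id -> sample ids.
    """
    n = expr.shape[1]
    if n < 2 * min_cluster_size:
        raise ValueError(f"need >= {2 * min_cluster_size} samples, got {n}")
    variances = expr.values.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False).index[:top_var_genes]
    sub = expr.values.loc[top].to_numpy(float)
    corr = np.corrcoef(sub.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")

    heights = np.unique(Z[:, 2])[::-1]  # root downward
    samples = expr.sample_ids
    best = np.ones(n, int)
    for h in heights:
        labels = fcluster(Z, t=h - 1e-12, criterion="distance")
        counts = np.bincount(labels)[1:]
        if counts.min() < min_cluster_size:
            break  # finer cuts only shrink clusters further
        roots = _cluster_root_heights(Z, labels)
        if len(counts) > 1 and max(roots.values()) > cohesion_ratio * h:
            continue  # split does not separate cohesive groups
        if len(counts) > len(np.unique(best)):
            best = labels
    clusters: dict[int, list[str]] = {}
    for lab in np.unique(best):
        clusters[int(lab)] = [samples[i] for i in np.flatnonzero(best == lab)]
    return clusters


def _marker_tests(in_values: np.ndarray, out_values: np.ndarray,
                  direction: str, alpha: float) -> tuple[bool, float]:
    """One marker: two-sample t-test with a direction requirement."""
    t, p = stats.ttest_ind(in_values, out_values, equal_var=True)
    diff = in_values.mean() - out_values.mean()
    ok = (p < alpha) and ((diff > 0) if direction == "over" else (diff < 0))
    return bool(ok), float(p)


def assign_cluster_subtype(cluster_samples_: list[str],
                           expr: ExpressionMatrix, markers: MarkerPanel,
                           alpha: float = 0.05,
                           majority: float = 1.0) -> str | None:
    """Label one sample cluster with a subtype, or None.

    A subtype matches when at least ``majority`` of its testable markers
    deviate from the out-of-cluster samples in the expected direction at
    t-test p < alpha. Markers missing from the matrix are skipped with a
    log line. Returns None when zero or several subtypes match.
    """
    in_set = set(cluster_samples_)
    out_samples = [s for s in expr.sample_ids if s not in in_set]
    if not out_samples:
        return None
    have = set(expr.feature_ids)
    matches = []
    for subtype, marker_list in markers.panels.items():
        n_ok = n_tested = 0
        for gene, direction in marker_list:
            if gene not in have:
                logger.info("assign_cluster_subtype: marker %s missing", gene)
                continue
            iv = expr.values.loc[gene, cluster_samples_].to_numpy(float)
            ov = expr.values.loc[gene, out_samples].to_numpy(float)
            ok, _ = _marker_tests(iv, ov, direction, alpha)
            n_tested += 1
            n_ok += ok
        if n_tested and n_ok / n_tested >= majority:
            matches.append(subtype)
    return matches[0] if len(matches) == 1 else None


def module_subtype_test(module: GeneSampleModule,
                        subtype_clusters: dict[str, list[str]],
                        expr: ExpressionMatrix, markers: MarkerPanel,
                        alpha: float = 0.05, majority: float = 0.5,
                        ) -> tuple[dict[str, dict[str, float]], str | None]:
    """Associate a module with a subtype via its samples' marker profile.

    For each candidate subtype, each marker is tested by a two-sample
    t-test of its expression in the module's samples versus the samples
    of the other subtypes' clusters; the verdict is the subtype whose
    markers are significant in the expected direction for more than
    ``majority`` of the testable panel. Returns (per-subtype per-marker
    p-values, verdict or None).
    """
    mod_samples = module.sorted_samples()
    if len(mod_samples) < 2:
        raise ValueError("module subtype test needs >=2 module samples")
    have = set(expr.feature_ids)
    pvalues: dict[str, dict[str, float]] = {}
    winners = []
    for subtype, marker_list in markers.panels.items():
        others = [s for st, mem in subtype_clusters.items() if st != subtype
                  for s in mem]
        others = [s for s in others if s not in set(mod_samples)]
        if not others:
            raise ValueError(f"no comparison samples for subtype {subtype}")
        n_ok = n_tested = 0
        per_marker: dict[str, float] = {}
        for gene, direction in marker_list:
            if gene not in have:
                continue
            iv = expr.values.loc[gene, mod_samples].to_numpy(float)
            ov = expr.values.loc[gene, others].to_numpy(float)
            ok, p = _marker_tests(iv, ov, direction, alpha)
            per_marker[gene] = p
            n_tested += 1
            n_ok += ok
        pvalues[subtype] = per_marker
        if n_tested and n_ok / n_tested > majority:
            winners.append(subtype)
    verdict = winners[0] if len(winners) == 1 else None
    return pvalues, verdict


class SubtypeClusterer(BaseEstimator):
    """Marker-guided subtype assignment of samples and clusters.

    Parameters mirror :func:`cluster_samples` and
    :func:`assign_cluster_subtype`.

    Attributes
    ----------
    clusters_ : dict[int, list[str]]
        Cluster id -> member samples (a partition of all samples).
    cluster_subtypes_ : dict[int, str | None]
    subtype_samples_ : dict[str, list[str]]
        Subtype -> samples of the clusters assigned to it.
    """

    def __init__(self, top_var_genes: int = 1000, min_cluster_size: int = 30,
                 alpha: float = 0.05, majority: float = 1.0):
        self.top_var_genes = top_var_genes
        self.min_cluster_size = min_cluster_size
        self.alpha = alpha
        self.majority = majority

    def fit(self, X: ExpressionMatrix, y=None, *,
            markers: MarkerPanel) -> "SubtypeClusterer":
        self.clusters_ = cluster_samples(X, self.top_var_genes,
                                         self.min_cluster_size)
        self.cluster_subtypes_ = {
            cid: assign_cluster_subtype(members, X, markers,
                                        alpha=self.alpha,
                                        majority=self.majority)
            for cid, members in self.clusters_.items()}
        self.subtype_samples_ = {}
        for cid, st in self.cluster_subtypes_.items():
            if st is not None:
                self.subtype_samples_.setdefault(st, []).extend(
                    self.clusters_[cid])
        return self
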