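"""Network expansion of gene-sample modules.

Genes adjacent to a module in the interaction network are candidates;
they are ranked once by their average correlation with the module genes
over the module's samples and admitted one at a time while the module's
average pairwise correlation strictly increases, stopping at the first
candidate that fails.
"""

from __future__ import annotations

import copy
import logging

import numpy as np
from sklearn.base import BaseEstimator

from .bicluster import module_avg_pcc
from .types import ExpressionMatrix, GeneSampleModule, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["candidate_genes", "expand_module", "NetworkModuleExpander"]


def candidate_genes(module: GeneSampleModule, net: InteractionNetwork,
                    expr: ExpressionMatrix) -> list[tuple[str, float]]:
    """Rank network neighbours of a module by average PCC to its genes.

    Returns (gene, avg PCC) pairs for genes outside the module adjacent
    to at least one module gene, sorted by descending correlation, ties
    broken lexicographically. Candidates without expression rows are
    dropped with a logged count.
    """
    have_expr = set(expr.feature_ids)
    neighbours: set[str] = set()
    for g in module.genes:
        neighbours |= net.neighbors(g)
    neighbours -= module.genes
    missing = {g for g in neighbours if g not in have_expr}
    if missing:
        logger.info("candidate_genes: %d candidates lack expression rows",
                    len(missing))
    neighbours -= missing
    if not neighbours:
        return []

    samples = module.sorted_samples()
    mod_genes = [g for g in module.sorted_genes() if g in have_expr]
    mod = expr.values.loc[mod_genes, samples].to_numpy(float)
    cand_ids = sorted(neighbours)
    cand = expr.values.loc[cand_ids, samples].to_numpy(float)

    def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        an = np.linalg.norm(a, axis=1)
        bn = np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (a @ b.T) / np.outer(an, bn)
        return c

    corr = _corr_rows(cand, mod)  # candidates x module genes
    avg = np.nanmean(corr, axis=1)
    order = sorted(range(len(cand_ids)), key=lambda i: (-avg[i], cand_ids[i]))
    return [(cand_ids[i], float(avg[i])) for i in order]


def expand_module(module: GeneSampleModule, net: InteractionNetwork,
                  expr: ExpressionMatrix, refresh_ranking: bool = False,
                  ) -> GeneSampleModule:
    """Add ranked candidate genes while the module's average PCC rises.

    Candidates are walked in their initial ranking (or re-ranked after
    each acceptance if ``refresh_ranking``); a candidate is kept iff the
    average pairwise PCC strictly increases, and the walk stops at the
    first failure. Added genes carry provenance ``ggi_added``; the sample
    set never changes.
    """
    out = copy.deepcopy(module)
    if not np.isfinite(out.module_avg):
        out.module_avg = module_avg_pcc(out, expr)
    while True:
        ranked = candidate_genes(out, net, expr)
        if not ranked:
            return out
        progressed = False
        for gene, _ in ranked:
            trial = copy.deepcopy(out)
            trial.genes.add(gene)
            trial.provenance[gene] = "ggi_added"
            new_avg = module_avg_pcc(trial, expr)
            if new_avg > out.module_avg:
                trial.module_avg = new_avg
                out = trial
                progressed = True
                if refresh_ranking:
                    break  # re-rank against the enlarged module
            else:
                return out  # stop at first failure
        if not (refresh_ranking and progressed):
            return out


class NetworkModuleExpander(BaseEstimator):
    """Transformer that enlarges modules with interaction-network genes.

    Parameters
    ----------
    refresh_ranking : bool, default False
        Re-rank candidates after each accepted gene instead of walking
        the initial ranking once.
    """

    def __init__(self, refresh_ranking: bool = False):
        self.refresh_ranking = refresh_ranking

    def fit(self, X=None, y=None) -> "NetworkModuleExpander":
        return self

    def transform(self, modules: list[GeneSampleModule], *,
                  net: InteractionNetwork, expr: ExpressionMatrix,
                  ) -> list[GeneSampleModule]:
        return [expand_module(m, net, expr,
                              refresh_ranking=self.refresh_ranking)
                for m in modules]
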