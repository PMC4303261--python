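"""Attach regulating miRNAs to gene-sample modules.

Genes and miRNAs are modelled jointly as a linear-Gaussian network: each
module gene is normally distributed around a mean that depends linearly
on the selected miRNA set (every gene shares the same parent set).
Candidate miRNAs are pre-ranked by the mean absolute Spearman rank
correlation with the module genes (rank correlation damps outliers);
they are then admitted greedily while the network score strictly
increases, and modules ending with fewer than two miRNAs are discarded
as unable to represent combinatorial regulation.

Two scoring modes are provided. The default penalizes the log-likelihood
by log(M)/2 with M the number of genes plus miRNAs in the configuration;
``standard`` mode applies the textbook criterion logL - (k/2) log(n)
with k the total number of fitted parameters and n the sample count.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .types import BICResult, ExpressionMatrix, GeneMiRNAModule, \
    GeneSampleModule, RegulatorModel

logger = logging.getLogger(__name__)

__all__ = [
    "rank_candidate_mirnas",
    "fit_regulator_model",
    "bic_score",
    "greedy_select_mirnas",
    "GreedyMiRNASelector",
    "VARIANCE_FLOOR",
]

VARIANCE_FLOOR = 1e-6  # keeps the Gaussian likelihood finite on perfect fits


def rank_candidate_mirnas(module: GeneSampleModule,
                          gene_expr: ExpressionMatrix,
                          mirna_expr: ExpressionMatrix,
                          T_percent: float = 3.0,
                          ) -> list[tuple[str, float]]:
    """Top-T% miRNAs by mean |Spearman correlation| with module genes.

    Correlations are computed over the module's samples. Returns
    round(T/100 * total miRNA count) miRNAs (at least 1) as
    (miRNA, mean |SCC|) pairs sorted descending, ties broken by id.
    """
    if not 0 < T_percent <= 100:
        raise ValueError("T_percent must be in (0, 100]")
    samples = module.sorted_samples()
    if len(samples) < 3:
        raise ValueError("Spearman ranking needs >=3 samples")
    genes = [g for g in module.sorted_genes() if g in set(gene_expr.feature_ids)]
    g = gene_expr.values.loc[genes, samples].to_numpy(float)
    m = mirna_expr.values.loc[:, samples].to_numpy(float)
    mirna_ids = mirna_expr.feature_ids

    rho = stats.spearmanr(g.T, m.T).statistic
    n_g = len(genes)
    cross = np.atleast_2d(rho)[:n_g, n_g:]  # genes x miRNAs
    with np.errstate(invalid="ignore"):
        mean_abs = np.nanmean(np.abs(cross), axis=0)
    mean_abs = np.where(np.isfinite(mean_abs), mean_abs, 0.0)

    n_keep = max(1, round(T_percent / 100.0 * len(mirna_ids)))
    order = sorted(range(len(mirna_ids)),
                   key=lambda i: (-mean_abs[i], mirna_ids[i]))
    return [(mirna_ids[i], float(mean_abs[i])) for i in order[:n_keep]]


def fit_regulator_model(gene: str, gene_values: np.ndarray,
                        parents: list[str],
                        parent_values: np.ndarray | None = None,
                        variance_floor: float = VARIANCE_FLOOR,
                        ) -> RegulatorModel:
    """OLS fit of one gene on its miRNA parents with intercept.

    ``parent_values`` has one row per parent. The residual variance is
    the maximum-likelihood estimate RSS/n clamped at the variance floor;
    the log-likelihood is the Gaussian plug-in -(n/2)(log(2*pi*sigma2)+1).
    Collinear parents fall back to the smallest-norm solution (lstsq)
    with a logged warning.
    """
    y = np.asarray(gene_values, float)
    n = y.size
    if parent_values is None or len(parents) == 0:
        X = np.ones((n, 1))
        parents = []
    else:
        P = np.asarray(parent_values, float)
        if n < P.shape[0] + 2:
            raise ValueError(f"gene {gene}: need >= parents+2 observations")
        X = np.column_stack([np.ones(n), P.T])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("fit_regulator_model: collinear parents for gene %s; "
                       "smallest-norm solution used", gene)
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / n, variance_floor)
    loglik = -(n / 2.0) * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return RegulatorModel(gene=gene, parents=list(parents), a0=float(beta[0]),
                          coef=np.asarray(beta[1:], float), sigma2=sigma2,
                          loglik=loglik)


def bic_score(module_gene_expr: np.ndarray, gene_ids: list[str],
              selected_mirna_expr: np.ndarray | None,
              mirna_ids: list[str], mode: str = "paper",
              variance_floor: float = VARIANCE_FLOOR) -> BICResult:
    """Network score of a module with a given selected miRNA set.

    ``module_gene_expr`` is genes x samples over the module's samples;
    every gene receives the full selected miRNA set as parents. In the
    default mode the penalty is log(M)/2 with M = #genes + #miRNAs; in
    ``standard`` mode it is (k/2) log(n) with k the total fitted
    parameter count (per gene: intercept, one coefficient per parent and
    a residual variance).
    """
    n_genes = len(gene_ids)
    n_mirnas = len(mirna_ids)
    M = n_genes + n_mirnas
    if M == 0:
        raise ValueError("empty configuration: no genes or miRNAs")
    logL = 0.0
    for i, gid in enumerate(gene_ids):
        model = fit_regulator_model(
            gid, module_gene_expr[i], mirna_ids,
            selected_mirna_expr if n_mirnas else None,
            variance_floor=variance_floor)
        logL += model.loglik
    if mode == "paper":
        bic = logL - math.log(M) / 2.0
    elif mode == "standard":
        n = module_gene_expr.shape[1]
        k = n_genes * (n_mirnas + 2)
        bic = logL - (k / 2.0) * math.log(n)
    else:
        raise ValueError(f"unknown BIC mode {mode!r}")
    return BICResult(logL=logL, M=M, bic=bic)


def greedy_select_mirnas(module: GeneSampleModule,
                         gene_expr: ExpressionMatrix,
                         mirna_expr: ExpressionMatrix,
                         T_percent: float = 3.0, mode: str = "paper",
                         variance_floor: float = VARIANCE_FLOOR,
                         all_samples: bool = False,
                         ) -> GeneMiRNAModule | None:
    """Greedy forward selection of regulating miRNAs for one module.

    Candidates are walked in rank order; a miRNA is accepted iff the
    network score strictly increases over the current best, and the walk
    stops at the first rejection. Returns None (module discarded) when
    fewer than two miRNAs are accepted.
    """
    ranked = rank_candidate_mirnas(module, gene_expr, mirna_expr, T_percent)
    samples = (mirna_expr.sample_ids if all_samples
               else module.sorted_samples())
    genes = [g for g in module.sorted_genes()
             if g in set(gene_expr.feature_ids)]
    G = gene_expr.values.loc[genes, samples].to_numpy(float)

    selected: list[str] = []
    trajectory: list[float] = []
    best = bic_score(G, genes, None, [], mode=mode,
                     variance_floor=variance_floor).bic
    for mirna, _ in ranked:
        trial = selected + [mirna]
        if len(samples) < len(trial) + 2:
            break  # too few observations to fit another parent
        Y = mirna_expr.values.loc[trial, samples].to_numpy(float)
        res = bic_score(G, genes, Y, trial, mode=mode,
                        variance_floor=variance_floor)
        if res.bic > best:
            selected.append(mirna)
            trajectory.append(res.bic)
            best = res.bic
        else:
            break
    if len(selected) < 2:
        logger.info("module %s discarded: %d miRNA(s) accepted",
                    module.module_id, len(selected))
        return None
    return GeneMiRNAModule(base=module, mirnas=selected,
                           bic_trajectory=trajectory)


class GreedyMiRNASelector(BaseEstimator):
    """Estimator that attaches regulating miRNAs to gene-sample modules.

    Parameters
    ----------
    T_percent : float, default 3.0
        Candidate pool size as a percentage of all miRNAs.
    mode : {"paper", "standard"}, default "paper"
        Network scoring mode (see module docstring).
    variance_floor : float, default 1e-6
        Lower clamp on per-gene residual variance.
    all_samples : bool, default False
        Score likelihoods over all samples rather than the module's.

    Attributes
    ----------
    mirna_modules_ : list of GeneMiRNAModule
    discarded_ : list of str
        Ids of modules that ended with fewer than two miRNAs.
    """

    def __init__(self, T_percent: float = 3.0, mode: str = "paper",
                 variance_floor: float = VARIANCE_FLOOR,
                 all_samples: bool = False):
        self.T_percent = T_percent
        self.mode = mode
        self.variance_floor = variance_floor
        self.all_samples = all_samples

    def fit(self, modules: list[GeneSampleModule], *,
            gene_expr: ExpressionMatrix, mirna_expr: ExpressionMatrix,
            ) -> "GreedyMiRNASelector":
        self.mirna_modules_ = []
        self.discarded_ = []
        for mod in modules:
            gm = greedy_select_mirnas(
                mod, gene_expr, mirna_expr, T_percent=self.T_percent,
                mode=self.mode, variance_floor=self.variance_floor,
                all_samples=self.all_samples)
            if gm is None:
                self.discarded_.append(mod.module_id)
            else:
                self.mirna_modules_.append(gm)
        return self
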