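"""Normalization and differential-expression selection.

Produces the z-scored tumor log2-ratio matrix the biclustering consumes:
tumor intensities are expressed as log2 ratios against the mean of
unmatched normals, genes are filtered by a t-test against a null of no
change, and the surviving rows are z-scored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["log2_ratio_normalize", "select_de_genes", "zscore_rows"]


def log2_ratio_normalize(tumor: ExpressionMatrix, normal: ExpressionMatrix,
                         input_scale: str = "linear") -> ExpressionMatrix:
    """Express tumor samples as log2 ratios against the mean of normals.

    For linear-scale input, ratio = log2(tumor / mean(normals)); for
    log2-scale input the mean normal value is subtracted. Features missing
    from the normal matrix are dropped with a logged count.
    """
    if input_scale not in ("linear", "log2"):
        raise ValueError(f"input_scale must be linear or log2, got {input_scale!r}")
    if normal.shape[1] < 1:
        raise ValueError("need at least one normal sample")
    shared = [f for f in tumor.feature_ids if f in set(normal.feature_ids)]
    dropped = len(tumor.feature_ids) - len(shared)
    if dropped:
        logger.info("log2_ratio_normalize: dropped %d features absent from "
                    "normals", dropped)
    t = tumor.values.loc[shared]
    n_mean = normal.values.loc[shared].mean(axis=1)
    if input_scale == "linear":
        bad = t.index[(t <= 0).any(axis=1)].tolist()
        if bad:
            raise ValueError(f"non-positive linear values for genes: {bad[:5]}")
        if (n_mean <= 0).any():
            bad = n_mean.index[n_mean <= 0].tolist()
            raise ValueError(f"non-positive normal mean for genes: {bad[:5]}")
        out = np.log2(t.div(n_mean, axis=0))
    else:
        out = t.sub(n_mean, axis=0)
    return ExpressionMatrix(out, tumor.feature_kind)


def select_de_genes(matrix: ExpressionMatrix, mode: str = "raw_p",
                    alpha: float = 0.001,
                    normal: ExpressionMatrix | None = None,
                    ) -> tuple[set[str], pd.Series]:
    """Select differentially expressed genes by t-test.

    Default is a one-sample two-sided t-test of each gene's log2 ratios
    against mean 0 (the ratio matrix's natural null). If ``normal`` is
    given, a two-sample pooled-variance t-test of tumor vs normal
    intensities is used instead. ``mode`` is ``raw_p`` (keep p < alpha) or
    ``bonferroni`` (keep p * G < alpha, G = number of tested genes).
    Zero-variance genes are excluded with a logged count (t undefined).
    """
    if mode not in ("raw_p", "bonferroni"):
        raise ValueError(f"mode must be raw_p or bonferroni, got {mode!r}")
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("need >=2 samples for a t-test")
    sd = vals.std(axis=1, ddof=1)
    testable = sd > 0
    n_zero = int((~testable).sum())
    if n_zero:
        logger.info("select_de_genes: excluded %d zero-variance genes", n_zero)
    tested = vals.loc[testable]
    if normal is None:
        _, p = stats.ttest_1samp(tested.to_numpy(float), 0.0, axis=1)
    else:
        shared = [g for g in tested.index if g in set(normal.feature_ids)]
        tested = tested.loc[shared]
        _, p = stats.ttest_ind(tested.to_numpy(float),
                               normal.values.loc[shared].to_numpy(float),
                               axis=1, equal_var=True)
    pvals = pd.Series(p, index=tested.index, name="p_value")
    if mode == "raw_p":
        keep = pvals[pvals < alpha]
    else:
        keep = pvals[pvals * len(pvals) < alpha]
    return set(keep.index), pvals


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every row to mean 0 and sample standard deviation 1 (ddof=1)."""
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance rows cannot be z-scored: {zero[:5]}")
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, matrix.feature_kind)
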