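"""Copy-number extension: bin segments, filter weak aberrations, and
associate genomic regions with modules by expression correlation.

Segmented copy-number log ratios are averaged (length-weighted) into
fixed-size genomic bins per sample, entries with small absolute ratio
are zeroed (weak aberrations), and each surviving region is correlated
with a module's mean gene expression over the module samples; regions
above the correlation threshold are reported together with the module
genes located inside them (cis annotation, by gene start coordinate).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSampleModule, SegmentTrack

logger = logging.getLogger(__name__)

__all__ = ["bin_segments", "filter_weak_regions",
           "associate_regions_with_module"]

DEFAULT_BIN_SIZE = 1_000_000  # 1 Mb


def bin_segments(track: SegmentTrack, bin_size: int = DEFAULT_BIN_SIZE,
                 ) -> pd.DataFrame:
    """Average segment ratios into fixed-size bins per sample.

    Bins are derived from the observed extent of each chromosome; the
    value of a bin for a sample is the length-weighted mean of the
    overlapping segment ratios, and 0 where the sample has no coverage.
    Returns a regions x samples DataFrame indexed by
    "chrom:start-end" (0-based half-open bin coordinates).
    """
    df = track.records
    if (df["start"] < 0).any():
        raise ValueError("negative segment coordinates")
    samples = sorted(df["sample"].unique())
    sample_pos = {s: i for i, s in enumerate(samples)}
    bin_index: list[str] = []
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        extent = int(grp["end"].max())
        n_bins = int(np.ceil(extent / bin_size))
        wsum = np.zeros((n_bins, len(samples)))
        lsum = np.zeros((n_bins, len(samples)))
        for _, seg in grp.iterrows():
            s_idx = sample_pos[seg["sample"]]
            b0 = int(seg["start"] // bin_size)
            b1 = int((seg["end"] - 1) // bin_size)
            for b in range(b0, b1 + 1):
                lo = max(int(seg["start"]), b * bin_size)
                hi = min(int(seg["end"]), (b + 1) * bin_size)
                length = hi - lo
                if length > 0:
                    wsum[b, s_idx] += seg["ratio"] * length
                    lsum[b, s_idx] += length
        with np.errstate(invalid="ignore"):
            vals = np.where(lsum > 0, wsum / np.where(lsum > 0, lsum, 1), 0.0)
        for b in range(n_bins):
            bin_index.append(f"{chrom}:{b * bin_size}-{(b + 1) * bin_size}")
        rows.append(vals)
    values = np.vstack(rows) if rows else np.zeros((0, len(samples)))
    return pd.DataFrame(values, index=bin_index, columns=samples)


def filter_weak_regions(region_matrix: pd.DataFrame,
                        threshold: float = 0.2) -> pd.DataFrame:
    """Zero entries with |ratio| < threshold; drop all-zero regions."""
    out = region_matrix.where(region_matrix.abs() >= threshold, 0.0)
    return out.loc[(out != 0).any(axis=1)]


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, span = region.rsplit(":", 1)
    start, end = span.split("-")
    return chrom, int(start), int(end)


def associate_regions_with_module(module: GeneSampleModule,
                                  region_matrix: pd.DataFrame,
                                  expr: ExpressionMatrix,
                                  genes_bed: pd.DataFrame | None = None,
                                  pcc_threshold: float = 0.3,
                                  ) -> pd.DataFrame:
    """Correlate copy-number regions with a module's mean expression.

    For every region, the Pearson correlation between the region's
    per-sample value and the module's per-sample mean gene expression is
    computed over the module's samples; regions with PCC >= threshold
    are reported. With gene coordinates (columns chrom, start, end,
    gene; 0-based half-open), module genes whose start coordinate falls
    inside an associated region are listed as cis candidates.
    """
    samples = module.sorted_samples()
    missing = [s for s in samples if s not in set(region_matrix.columns)]
    if missing:
        raise ValueError(f"module samples absent from region matrix: "
                         f"{missing[:5]}")
    genes = [g for g in module.sorted_genes() if g in set(expr.feature_ids)]
    mean_expr = expr.values.loc[genes, samples].mean(axis=0).to_numpy(float)
    rows = []
    for region in region_matrix.index:
        vals = region_matrix.loc[region, samples].to_numpy(float)
        if vals.std() == 0 or mean_expr.std() == 0:
            continue
        r = float(np.corrcoef(vals, mean_expr)[0, 1])
        if r >= pcc_threshold:
            cis: list[str] = []
            if genes_bed is not None:
                chrom, lo, hi = _parse_region(region)
                hits = genes_bed[(genes_bed["chrom"] == chrom)
                                 & (genes_bed["start"] >= lo)
                                 & (genes_bed["start"] < hi)]
                cis = sorted(set(hits["gene"]) & module.genes)
            rows.append((region, r, ",".join(cis)))
    return pd.DataFrame(rows, columns=["region", "pcc", "cis_genes"])
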