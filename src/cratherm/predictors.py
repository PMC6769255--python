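"""Genomic predictors of activation strength and their relative importance.

Feature builders count how many distinct transcription factors have a
ChIP-seq peak over each site and measure the distance to the nearest active
enhancer (H3K27ac peak not overlapping a TSS).  Features and responses are
z-scaled across sites; relative importance of predictors in an ordinary
least-squares fit is decomposed by the Lindeman-Merenda-Gold (LMG) method:
the R-squared gain from adding a predictor, averaged over all orders in
which predictors can enter the model, then normalized to sum to one.
"""

from __future__ import annotations

import warnings
from math import factorial
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .chip import RegionSet

__all__ = [
    "zscale_columns",
    "correlation_matrix",
    "lmg_importance",
    "count_tf_overlaps",
    "nearest_enhancer_distance",
]


def zscale_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every column to mean 0, sample SD 1 (n-1 denominator)."""
    sd = table.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant columns cannot be z-scaled: {constant}")
    return (table - table.mean()) / sd


def correlation_matrix(table: pd.DataFrame, cluster: bool = False) -> pd.DataFrame:
    """Pearson correlations between all columns.

    With ``cluster=True`` the rows/columns are reordered by average-linkage
    hierarchical clustering on 1 - r, for display; values are unchanged.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 rows for a correlation matrix")
    corr = table.corr(method="pearson")
    if cluster:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import squareform

        dist = squareform(1.0 - corr.to_numpy(), checks=False)
        order = leaves_list(average(dist))
        corr = corr.iloc[order, order]
    return corr


def _r_squared(x: np.ndarray, y: np.ndarray, subset: tuple[int, ...]) -> float:
    # centred data, so no intercept column needed
    if not subset:
        return 0.0
    xs = x[:, subset]
    coef, *_ = np.linalg.lstsq(xs, y, rcond=None)
    resid = y - xs @ coef
    tss = float(y @ y)
    return 1.0 - float(resid @ resid) / tss


def lmg_importance(
    predictors: pd.DataFrame | np.ndarray,
    response,
    normalize: bool = True,
):
    """LMG decomposition of regression R-squared into per-predictor shares.

    The share of predictor k is its average sequential R-squared gain over
    all p! orderings, computed by the equivalent subset-weighted sum

        sum over subsets S not containing k of
        |S|! (p - |S| - 1)! / p!  *  [R2(S + {k}) - R2(S)].

    Raw shares sum to the full-model R-squared; with ``normalize=True``
    (the default) they are rescaled to sum to one.  Exact enumeration, so
    at most 10 predictors.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.asarray(predictors, dtype=float)
        names = None
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if p > 10:
        raise ValueError(f"exact LMG enumeration limited to 10 predictors, got {p}")
    if n <= p + 1:
        raise ValueError(f"need more than p+1={p + 1} observations, got {n}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    if np.linalg.matrix_rank(xc) < p:
        raise ValueError("rank-deficient predictor matrix")
    if not yc.any():
        raise ValueError("response has zero variance")

    r2 = {(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            r2[subset] = _r_squared(xc, yc, subset)

    shares = np.zeros(p)
    fp = factorial(p)
    for k in range(p):
        others = [i for i in range(p) if i != k]
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / fp
            for subset in combinations(others, size):
                with_k = tuple(sorted(subset + (k,)))
                shares[k] += w * (r2[with_k] - r2[subset])

    if normalize:
        total = shares.sum()
        if total == 0:
            raise ValueError("full-model R-squared is zero; importances undefined")
        shares = shares / total
    if names is not None:
        return pd.Series(shares, index=names, name="lmg_importance")
    return shares


def _trees_by_chrom(regions: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in regions.frame.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def count_tf_overlaps(regions: RegionSet, peak_sets: list[RegionSet]) -> pd.Series:
    """Number of distinct TFs with >= 1 peak overlapping each region.

    Each peak set is one TF's ChIP-seq peaks; several peaks of the same TF
    over one region still count once.  Overlap is >= 1 bp on half-open
    intervals.
    """
    forests = [_trees_by_chrom(ps) for ps in peak_sets]
    counts = []
    for row in regions.frame.itertuples():
        hit = 0
        for forest in forests:
            tree = forest.get(row.chrom)
            if tree is not None and tree.overlap(row.start, row.end):
                hit += 1
        counts.append(hit)
    return pd.Series(counts, index=regions.names, name="n_tfs")


def nearest_enhancer_distance(
    regions: RegionSet, peaks: RegionSet, tss: RegionSet
) -> pd.Series:
    """Distance in bp from each region to the nearest non-TSS enhancer peak.

    Peaks overlapping any TSS interval are discarded first (they proxy
    promoters, not enhancers).  Distance is 0 when the region overlaps a
    surviving peak, otherwise the gap between the half-open intervals on the
    same chromosome; NaN (with a warning) when the chromosome has no
    surviving peak.
    """
    tss_trees = _trees_by_chrom(tss)
    surviving: dict[str, list[tuple[int, int]]] = {}
    for row in peaks.frame.itertuples():
        tree = tss_trees.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end):
            continue
        surviving.setdefault(row.chrom, []).append((row.start, row.end))

    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in surviving.items():
        ivs.sort()
        starts_ends[chrom] = (
            np.array([s for s, _ in ivs]),
            np.array([e for _, e in ivs]),
        )

    dists = []
    for row in regions.frame.itertuples():
        if row.chrom not in starts_ends:
            warnings.warn(
                f"no non-TSS peak on {row.chrom}; distance for {row.name!r} is NaN"
            )
            dists.append(np.nan)
            continue
        starts, ends = starts_ends[row.chrom]
        gap_right = starts - row.end   # >= 0 when peak entirely right of region
        gap_left = row.start - ends    # >= 0 when peak entirely left of region
        gap = np.maximum(np.maximum(gap_right, gap_left), 0)
        overlap = (starts < row.end) & (ends > row.start)
        dists.append(0.0 if overlap.any() else float(gap.min()))
    return pd.Series(dists, index=regions.names, name="nearest_enhancer_bp")
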