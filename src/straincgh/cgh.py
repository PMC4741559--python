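"""Core array-CGH operations on the gene x strain log2-ratio matrix.

The matrix is a pandas DataFrame: rows indexed by gene id, one column per
strain, NaN marking missing observations.  The genome annotation is a
DataFrame with columns ``gene_id, chromosome, start, end, subtelomeric``
using 1-based closed coordinates; genome order is (chromosome, start,
gene_id).

Conventions fixed here and relied on by the selection module:
  * standard deviations are population SDs (divide by n), with missing
    values excluded pairwise and an SD only assigned to genes observed in
    at least two strains;
  * the moving-average smoother shrinks its window symmetrically at
    chromosome ends and never crosses a chromosome boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ANNOTATION_COLUMNS",
    "Segment",
    "validate_annotation",
    "genome_sorted",
    "subtelomeric_regions",
    "renormalize",
    "divergence_profile",
    "auto_penalty",
    "segment_profile",
    "call_region_events",
]

ANNOTATION_COLUMNS = ("gene_id", "chromosome", "start", "end", "subtelomeric")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if annotation["gene_id"].duplicated().any():
        dups = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"]
        raise ValueError(f"duplicate gene ids in annotation: {dups.tolist()[:5]}")
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("annotation has start > end (coordinates are 1-based closed)")
    if (annotation["start"] < 1).any():
        raise ValueError("annotation start below 1 (coordinates are 1-based closed)")
    return annotation


def genome_sorted(annotation: pd.DataFrame) -> pd.DataFrame:
    """Annotation rows in genome order: (chromosome, start, gene_id)."""
    validate_annotation(annotation)
    return annotation.sort_values(
        ["chromosome", "start", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


def subtelomeric_regions(annotation: pd.DataFrame) -> dict[str, tuple[int, int, int]]:
    """Named intervals covering the flagged subtelomeric gene blocks at each
    chromosome end: ``{name: (chromosome, start, end)}``.  Used as the
    default region set for gain/loss calls."""
    ann = genome_sorted(annotation)
    regions: dict[str, tuple[int, int, int]] = {}
    for chrom, sub in ann.groupby("chromosome", sort=True):
        flagged = sub[sub["subtelomeric"].astype(bool)]
        if flagged.empty:
            continue
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        center = (mid.min() + mid.max()) / 2.0
        fmid = (flagged["start"].to_numpy() + flagged["end"].to_numpy()) / 2.0
        left = flagged[fmid <= center]
        right = flagged[fmid > center]
        if not left.empty:
            regions[f"chr{chrom}_left"] = (
                int(chrom), int(left["start"].min()), int(left["end"].max())
            )
        if not right.empty:
            regions[f"chr{chrom}_right"] = (
                int(chrom), int(right["start"].min()), int(right["end"].max())
            )
    return regions


def renormalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Re-reference every gene to the cohort average.

    out[g, s] = in[g, s] - mean over strains of in[g, .], the strain's own
    value included and missing values excluded, so any per-gene additive bias
    shared by all strains (e.g. a common-reference hybridization bias)
    cancels exactly and every gene's cross-strain mean becomes 0.  Genes
    missing in all strains are dropped with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("re-normalization needs at least two strains")
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        dropped = matrix.index[all_missing].tolist()
        warnings.warn(
            f"dropping {len(dropped)} gene(s) missing in every strain: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        matrix = matrix.loc[~all_missing]
    return matrix.sub(matrix.mean(axis=1, skipna=True), axis=0)


def _population_sd(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene population SD across strains; NaN for genes observed in
    fewer than two strains."""
    values = matrix.to_numpy(dtype=float)
    counts = np.sum(~np.isnan(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        sd = np.nanstd(values, axis=1, ddof=0)
    sd[counts < 2] = np.nan
    return pd.Series(sd, index=matrix.index, name="sd")


def _moving_average_shrink(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrunk symmetrically near the
    sequence ends; NaNs are excluded from each window mean."""
    half = window // 2
    n = len(values)
    out = np.full(n, np.nan)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        w = values[i - h : i + h + 1]
        w = w[~np.isnan(w)]
        if w.size:
            out[i] = w.mean()
    return out


def divergence_profile(
    matrix: pd.DataFrame, annotation: pd.DataFrame, window: int = 21
) -> pd.DataFrame:
    """Per-gene cross-strain SD plus its moving-average smoothed trend.

    Genes are ordered along the genome; the smoother runs per chromosome so a
    window never crosses a chromosome boundary.  Returns a DataFrame in
    genome order with columns gene_id, chromosome, start, sd, smoothed_sd and
    the genome order index.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    ann = genome_sorted(annotation)
    unknown = matrix.index.difference(ann["gene_id"])
    if len(unknown):
        raise ValueError(
            f"matrix contains genes absent from the annotation: {list(unknown[:5])}"
        )
    ann = ann[ann["gene_id"].isin(matrix.index)].reset_index(drop=True)
    sd = _population_sd(matrix).reindex(ann["gene_id"]).to_numpy()

    smoothed = np.full(len(ann), np.nan)
    for _, idx in ann.groupby("chromosome", sort=True).indices.items():
        idx = np.sort(idx)
        smoothed[idx] = _moving_average_shrink(sd[idx], window)

    out = ann[["gene_id", "chromosome", "start"]].copy()
    out["sd"] = sd
    out["smoothed_sd"] = smoothed
    out["order"] = np.arange(len(out))
    return out


@dataclass(frozen=True)
class Segment:
    """Maximal run [first, last] (0-based, inclusive) with one fitted mean."""

    first: int
    last: int
    mean: float


def auto_penalty(values: np.ndarray) -> float:
    """Default segmentation penalty 2 * sigma^2 * ln n with sigma estimated
    robustly from first differences: MAD(diff) / (sqrt(2) * 0.6745)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        return 1e-12
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / (math.sqrt(2.0) * 0.6745)
    penalty = 2.0 * sigma * sigma * math.log(n)
    return max(penalty, 1e-12)


def segment_profile(values, penalty: float | None = None) -> list[Segment]:
    """Optimal piecewise-constant fit by dynamic programming.

    Minimizes  sum of squared residuals to segment means
             + penalty * (number of segments)
    exactly over all change-point placements (O(n^2)); cost ties are resolved
    toward fewer segments.  ``penalty=None`` uses :func:`auto_penalty`.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("segment_profile needs a non-empty 1-D array")
    if np.isnan(x).any():
        raise ValueError("segment_profile input must not contain NaN")
    if penalty is None:
        penalty = auto_penalty(x)
    if not penalty > 0:
        raise ValueError("penalty must be positive")

    n = len(x)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))

    best_cost = np.empty(n + 1)
    best_nseg = np.empty(n + 1, dtype=np.int64)
    back = np.empty(n + 1, dtype=np.int64)
    best_cost[0] = 0.0
    best_nseg[0] = 0
    for j in range(1, n + 1):
        i = np.arange(j)
        s = c1[j] - c1[i]
        sse = np.maximum(c2[j] - c2[i] - s * s / (j - i), 0.0)
        cost = best_cost[:j] + sse + penalty
        nseg = best_nseg[:j] + 1
        # lexicographic minimum of (cost, n_segments, i): exact-tie costs
        # resolve toward fewer segments, then the earlier change point
        bi = int(np.lexsort((i, nseg, cost))[0])
        best_cost[j] = cost[bi]
        best_nseg[j] = nseg[bi]
        back[j] = bi

    bounds = []
    j = n
    while j > 0:
        i = int(back[j])
        bounds.append((i, j))
        j = i
    bounds.reverse()
    return [
        Segment(first=i, last=j - 1, mean=float((c1[j] - c1[i]) / (j - i)))
        for i, j in bounds
    ]


def call_region_events(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    regions: dict[str, tuple[int, int, int]],
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Region-level gain/loss calls per strain.

    For each named region (chromosome, start, end; 1-based closed) the mean
    re-normalized log2 ratio over the genes whose midpoint falls inside it is
    computed per strain; the call is ``gain`` if mean >= +threshold, ``loss``
    if mean <= -threshold (both boundaries inclusive), else ``neutral``.
    Regions covering no gene are reported with call ``missing``.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    ann = validate_annotation(annotation)
    ann = ann[ann["gene_id"].isin(matrix.index)]
    mid = (ann["start"].to_numpy() + ann["end"].to_numpy()) / 2.0

    rows = []
    for name in sorted(regions):
        chrom, start, end = regions[name]
        mask = (ann["chromosome"].to_numpy() == chrom) & (mid >= start) & (mid <= end)
        genes = ann.loc[mask, "gene_id"]
        for strain in matrix.columns:
            if genes.empty:
                rows.append((strain, name, "missing", math.nan))
                continue
            mean = float(matrix.loc[genes, strain].mean(skipna=True))
            if math.isnan(mean):
                call = "missing"
            elif mean >= threshold:
                call = "gain"
            elif mean <= -threshold:
                call = "loss"
            else:
                call = "neutral"
            rows.append((strain, name, call, mean))
    return pd.DataFrame(rows, columns=["strain_id", "region", "call", "mean_log2"])
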