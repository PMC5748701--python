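"""Size-factor normalization and KS-based low-count threshold selection.

Serum small-RNA count distributions show three phases: sporadic
low-count noise, steady-state expression, and a few very abundant
features.  Below some count level the data are dominated by noise whose
replicate-to-replicate distributions disagree; the two-sample
Kolmogorov-Smirnov D statistic between paired samples, computed while
iteratively excluding features below a candidate minimum normalized
count, serves as a cost function: the smallest threshold at which D
first reaches (within epsilon) its minimum is taken as the minimum count
level of biological relevance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth factors.

    s_j = median over reference features i of k_ij / g_i, with g_i the
    geometric mean of feature i across samples, computed over features
    positive in every sample.
    """
    values = counts.to_numpy(dtype=float)
    ref = (values > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no feature has strictly positive counts in all samples; "
            "cannot form the median-of-ratios reference (consider a "
            "pseudo-reference fallback after pre-filtering)"
        )
    ref_vals = values[ref]
    geo = np.exp(np.log(ref_vals).mean(axis=1))
    sf = np.median(ref_vals / geo[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = counts.columns.difference(size_factors.index)
    if len(missing) > 0:
        raise ValueError(f"size factors missing for sample(s): {list(missing)}")
    sf = size_factors.reindex(counts.columns)
    if (sf <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return counts / sf


def base_means(normalized: pd.DataFrame) -> pd.Series:
    """Per-feature mean of normalized counts across samples."""
    return normalized.mean(axis=1)


def ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic D = sup |F_x - F_y| over the empirical CDFs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_distance requires two non-empty samples")
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / xs.size
    fy = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.abs(fx - fy).max())


@dataclass
class ThresholdScan:
    """Grid of candidate thresholds with their aggregated KS cost."""

    grid: np.ndarray  # ascending candidate thresholds (normalized counts)
    d_values: np.ndarray  # mean pairwise D at each threshold (NaN: invalid)
    n_retained: np.ndarray  # features retained at each threshold
    d_full: float  # D of the unfiltered data (t = 0)
    selected: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.grid, "mean_D": self.d_values, "n_retained": self.n_retained}
        )


def default_pairs(
    meta: pd.DataFrame,
    max_pairs: int = 200,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """All within-condition sample pairs, subsampled to ``max_pairs``.

    With one library per animal there are no technical replicates;
    samples sharing a condition are the closest available analogue of
    replicates for the KS cost function.
    """
    pairs: list[tuple[str, str]] = []
    for _, grp in meta.groupby("condition", sort=True):
        ids = list(grp["sample_id"])
        pairs.extend(itertools.combinations(ids, 2))
    if len(pairs) > max_pairs:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs


def threshold_scan(
    normalized: pd.DataFrame,
    pairs: list[tuple[str, str]],
    grid: np.ndarray | list[float] | None = None,
    log_transform: bool = True,
) -> ThresholdScan:
    """KS cost of excluding features below each candidate threshold.

    For each threshold t the features with base mean >= t are retained;
    for each sample pair the two-sample KS D between the pair's
    log2(normalized + 1) values over the retained features is computed,
    and the costs are averaged over pairs.  Grid points retaining fewer
    than two features are marked invalid (NaN) and excluded from
    selection.
    """
    if grid is None:
        grid = np.arange(0, 101, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be non-empty and strictly ascending")
    if not pairs:
        raise ValueError("at least one sample pair is required")
    for a, b in pairs:
        if a not in normalized.columns or b not in normalized.columns:
            raise ValueError(f"pair ({a!r}, {b!r}) references unknown sample(s)")

    bm = base_means(normalized).to_numpy()
    data = normalized.to_numpy(dtype=float)
    if log_transform:
        data = np.log2(data + 1.0)
    col_idx = {c: i for i, c in enumerate(normalized.columns)}
    pair_idx = [(col_idx[a], col_idx[b]) for a, b in pairs]

    def mean_d(mask: np.ndarray) -> float:
        sub = data[mask]
        return float(
            np.mean([ks_distance(sub[:, i], sub[:, j]) for i, j in pair_idx])
        )

    d_full = mean_d(np.ones(bm.size, dtype=bool))
    d_values = np.empty(grid.size)
    n_retained = np.empty(grid.size, dtype=int)
    for k, t in enumerate(grid):
        mask = bm >= t
        n_retained[k] = int(mask.sum())
        d_values[k] = mean_d(mask) if n_retained[k] >= 2 else np.nan
    return ThresholdScan(
        grid=grid, d_values=d_values, n_retained=n_retained, d_full=d_full
    )


def select_threshold(scan: ThresholdScan, epsilon: float = 0.01) -> float:
    """Smallest valid threshold whose cost is within epsilon of the minimum.

    This is the point at which the D statistic first reaches its low
    plateau — the minimum count level of biological relevance.
    """
    valid = ~np.isnan(scan.d_values)
    if not valid.any():
        raise ValueError("threshold scan has no valid grid point")
    d_min = np.nanmin(scan.d_values)
    ok = valid & (scan.d_values <= d_min + epsilon)
    t_star = float(scan.grid[np.flatnonzero(ok)[0]])
    scan.selected = t_star
    return t_star


def prevalence_filter(
    counts: pd.DataFrame, max_zero_fraction: float = 0.10
) -> pd.DataFrame:
    """Drop features with zero counts in more than ``max_zero_fraction`` of samples.

    The boundary is strict: a feature at exactly the cutoff is retained.
    """
    zero_frac = (counts == 0).mean(axis=1)
    return counts.loc[zero_frac <= max_zero_fraction]


def mean_filter(normalized: pd.DataFrame, t_star: float) -> pd.Index:
    """Feature ids with base mean >= t_star (inclusive boundary)."""
    if t_star < 0:
        raise ValueError(f"threshold must be >= 0, got {t_star}")
    bm = base_means(normalized)
    return normalized.index[bm >= t_star]
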