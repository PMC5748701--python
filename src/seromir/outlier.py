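"""PCA-based sample quality control.

Samples are projected onto the principal components of the
variance-stabilized, most-variable features; any sample lying more than
``n_sd`` standard deviations from a component's mean score (on any of
the inspected components) is flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


def variance_stabilize(normalized: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1).

    A shifted-log transform standing in for tool-specific
    variance-stabilizing transforms; it reproduces the rank structure
    that PCA consumes.
    """
    if (normalized.to_numpy() < 0).any():
        raise ValueError("variance_stabilize requires non-negative input")
    return np.log2(normalized + 1.0)


def top_variable_features(matrix: pd.DataFrame, n: int = 50) -> pd.Index:
    """Ids of the n features with the largest across-sample variance.

    Ties are broken by feature-id lexicographic order.  Requesting more
    features than exist returns all of them with a warning, as does a
    matrix with no variable feature at all.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > matrix.shape[0]:
        warnings.warn(
            f"requested {n} variable features but only {matrix.shape[0]} exist; "
            "returning all",
            stacklevel=2,
        )
        n = matrix.shape[0]
    variances = matrix.var(axis=1, ddof=1)
    if (variances == 0).all():
        warnings.warn("all features have zero variance", stacklevel=2)
    order = (
        pd.DataFrame({"var": variances, "fid": matrix.index})
        .sort_values(["var", "fid"], ascending=[False, True])
        .index
    )
    return pd.Index(order[:n])


@dataclass
class PCAResult:
    sample_scores: pd.DataFrame  # samples x components (PC1..PCk)
    explained_variance_fractions: np.ndarray
    feature_subset: pd.Index


def run_pca(matrix: pd.DataFrame, k: int) -> PCAResult:
    """Project samples onto the top-k principal components.

    ``matrix`` is features x samples; features are centered across
    samples.  Component signs are fixed by making each component's
    largest-magnitude feature weight positive, so results are fully
    deterministic.
    """
    n_feat, n_samp = matrix.shape
    if n_samp < 2 or n_feat < 2:
        raise ValueError("run_pca requires at least 2 samples and 2 features")
    if not 1 <= k <= min(n_feat, n_samp):
        raise ValueError(f"k={k} must be in [1, {min(n_feat, n_samp)}]")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign convention
    for c in range(k):
        w = pca.components_[c]
        if w[np.argmax(np.abs(w))] < 0:
            pca.components_[c] *= -1
            scores[:, c] *= -1
    return PCAResult(
        sample_scores=pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        explained_variance_fractions=pca.explained_variance_ratio_.copy(),
        feature_subset=matrix.index,
    )


def detect_outliers(
    pca: PCAResult,
    n_sd: float = 3.0,
    components: tuple[int, ...] = (1, 2, 3),
) -> list[str]:
    """Samples more than ``n_sd`` SDs from a component's mean score.

    A sample is flagged if on ANY inspected component its score deviates
    strictly more than ``n_sd`` standard deviations (of that component's
    scores) from the component mean.  A component with zero spread flags
    nobody.
    """
    if n_sd <= 0:
        raise ValueError(f"n_sd must be positive, got {n_sd}")
    scores = pca.sample_scores
    flagged: set[str] = set()
    for c in components:
        name = f"PC{c}"
        if name not in scores.columns:
            raise ValueError(f"component {name} not present in PCA result")
        col = scores[name]
        sd = col.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        z = (col - col.mean()).abs() / sd
        flagged.update(col.index[z > n_sd])
    return sorted(flagged)
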