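"""Synthetic serum small-RNA datasets with known ground truth.

The generator emulates the statistical structure of a circulating-miRNA
count experiment: a three-phase abundance profile (sporadic low-count
noise, steady-state expression, high abundance), a single dominant
feature carrying most of the library, negative-binomial counts with
per-sample depth (size) factors, hemolysis effects tied to a simulated
absorbance at 414 nm, small case/control condition effects, and two
half-sib family cohorts plus an unrelated cohort encoded as binary
covariates.

Counts follow

    k_ij ~ NB(mean = s_j * mu_i * 2**(x_j . beta_i), dispersion alpha)

with variance mu + alpha * mu**2, where x_j stacks the condition,
family1, family2 and (median-centred) absorbance covariates of sample j,
and beta_i holds the planted per-feature log2-scale effects, plus three
bounded per-sample latent technical factors that give the count matrix
the correlated sample-level structure (and realistic leading-PCA
variance spectrum) of real libraries.  Noise-phase features are
sporadically expressed: present in a sample with a sample-specific
occupancy probability and, when present, given an independently drawn
low mean — so their replicate distributions disagree, the property the
KS thresholding procedure exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class SynthConfigError(ValueError):
    """A simulator configuration violates one of its invariants."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic serum small-RNA experiment.

    Defaults mirror the reported characteristics of an equine serum
    cohort: 34 controls vs 37 cases, A414 absorbance in [0.53, 4] with
    median 1, condition |log2FC| in [0.27, 0.49], and a dominant feature
    holding 63% of total counts.  The dispersion default (0.1) is an
    assumption, not an estimate from published serum data.
    """

    n_control: int = 34
    n_case: int = 37
    n_features: int = 500
    phase_fractions: tuple[float, float, float] = (0.70, 0.24, 0.06)
    noise_mean_range: tuple[float, float] = (0.1, 5.0)
    steady_mean_range: tuple[float, float] = (20.0, 250.0)
    high_mean_range: tuple[float, float] = (500.0, 5000.0)
    dominant_feature_fraction: float = 0.63
    dispersion: float = 0.1
    de_fraction: float = 0.10
    de_log2fc_range: tuple[float, float] = (0.27, 0.49)
    hemo_fraction: float = 0.29
    hemo_beta_range: tuple[float, float] = (0.5, 1.2)
    absorbance_range: tuple[float, float] = (0.53, 4.0)
    absorbance_median: float = 1.0
    absorbance_condition_r: float = 0.0
    family_shift_sd: float = 0.20
    latent_factor_sd: float = 0.30
    size_factor_sd: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        n = self.n_control + self.n_case
        if n < 4:
            raise SynthConfigError(
                f"n_control + n_case must be >= 4, got {n}"
            )
        if self.n_features < 10:
            raise SynthConfigError(
                f"n_features must be >= 10, got {self.n_features}"
            )
        fracs = self.phase_fractions
        if len(fracs) != 3 or any(not 0.0 <= f <= 1.0 for f in fracs):
            raise SynthConfigError(
                f"phase_fractions must be three proportions in [0,1], got {fracs}"
            )
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise SynthConfigError(
                f"phase_fractions must sum to 1, got sum {sum(fracs)!r}"
            )
        for name in ("dominant_feature_fraction", "de_fraction", "hemo_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must be in [0,1], got {v}")
        if self.dispersion < 0:
            raise SynthConfigError(
                f"dispersion must be >= 0, got {self.dispersion}"
            )
        for name in (
            "noise_mean_range",
            "steady_mean_range",
            "high_mean_range",
            "absorbance_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SynthConfigError(
                    f"{name} must be a positive interval (lo <= hi), got ({lo}, {hi})"
                )
        for name in ("de_log2fc_range", "hemo_beta_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise SynthConfigError(
                    f"{name} is a magnitude interval and must satisfy "
                    f"0 <= lo <= hi, got ({lo}, {hi})"
                )
        lo, hi = self.absorbance_range
        if not (lo <= self.absorbance_median <= hi):
            raise SynthConfigError(
                f"absorbance_median {self.absorbance_median} outside "
                f"absorbance_range ({lo}, {hi})"
            )
        if not -1.0 < self.absorbance_condition_r < 1.0:
            raise SynthConfigError(
                "absorbance_condition_r must be in (-1, 1), "
                f"got {self.absorbance_condition_r}"
            )
        if min(self.family_shift_sd, self.size_factor_sd, self.latent_factor_sd) < 0:
            raise SynthConfigError(
                "family_shift_sd, latent_factor_sd and size_factor_sd must be >= 0"
            )


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery testing."""

    true_de: dict[str, float]  # feature id -> signed condition log2FC
    true_hemo: dict[str, float]  # feature id -> per-unit-A414 log2 coefficient
    true_size_factors: pd.Series  # sample id -> depth factor
    true_means: pd.Series  # feature id -> baseline mean (noise: realized mean)
    phase_label: pd.Series  # feature id -> {noise, steady, high}
    family_shifts: pd.DataFrame = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per feature: phase, baseline mean, planted effects."""
        df = pd.DataFrame(
            {
                "phase": self.phase_label,
                "baseline_mean": self.true_means,
                "de_log2fc": pd.Series(self.true_de, dtype=float),
                "hemo_beta": pd.Series(self.true_hemo, dtype=float),
            }
        )
        df.index.name = "feature_id"
        return df.fillna({"de_log2fc": 0.0, "hemo_beta": 0.0})


def _beta_shape_for_median(target: float, a: float = 2.0) -> float:
    """Second Beta shape parameter b such that median(Beta(a, b)) == target."""
    if not 0.0 < target < 1.0:
        return 1.0

    def f(b: float) -> float:
        return stats.beta.ppf(0.5, a, b) - target

    return optimize.brentq(f, 1e-3, 1e4)


def _simulate_absorbance(
    cfg: SynthConfig, condition: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A414 from a scaled Beta matched to range and median.

    Correlation with the case/control label (for confounding scenarios)
    is induced through a latent Gaussian copula.
    """
    lo, hi = cfg.absorbance_range
    if hi == lo:
        return np.full(condition.shape, lo)
    a = 2.0
    b = _beta_shape_for_median((cfg.absorbance_median - lo) / (hi - lo), a)
    r = cfg.absorbance_condition_r
    z = rng.standard_normal(condition.size)
    if r != 0.0 and condition.std() > 0:
        c_std = (condition - condition.mean()) / condition.std()
        z = r * c_std + math.sqrt(1.0 - r * r) * z
    u = stats.norm.cdf(z)
    return lo + (hi - lo) * stats.beta.ppf(u, a, b)


def _draw_nb(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """Draw NB counts with variance mean + alpha * mean**2 (alpha=0: Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0.0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    # gamma-Poisson mixture: numpy's negative_binomial rejects p exactly 1
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def _signed_uniform(
    rng: np.random.Generator, magnitude_range: tuple[float, float], size: int
) -> np.ndarray:
    mags = rng.uniform(magnitude_range[0], magnitude_range[1], size)
    signs = rng.choice([-1.0, 1.0], size)
    return mags * signs


def simulate_counts(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a count matrix, sample sheet and ground truth.

    Returns
    -------
    counts : DataFrame (features x samples), non-negative integers.
    meta : DataFrame with columns sample_id, condition, family1, family2,
        absorbance_414, indexed by sample_id.
    truth : GroundTruth with planted effects and realized parameters.

    Identical configs (including seed) give byte-identical outputs.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_control + cfg.n_case
    n_feat = cfg.n_features

    sample_ids = [f"s{j + 1:03d}" for j in range(n_samples)]
    condition = np.concatenate(
        [np.zeros(cfg.n_control), np.ones(cfg.n_case)]
    )

    # three cohorts: family1, family2, unrelated — random thirds
    cohort = rng.permutation(np.arange(n_samples) % 3)
    family1 = (cohort == 0).astype(int)
    family2 = (cohort == 1).astype(int)

    absorbance = _simulate_absorbance(cfg, condition, rng)
    abs_centered = absorbance - cfg.absorbance_median

    # depth factors: log-normal, geometric mean 1
    log_s = rng.normal(0.0, cfg.size_factor_sd, n_samples)
    log_s -= log_s.mean()
    size_factors = np.exp(log_s)

    # phase assignment
    n_noise = int(round(cfg.phase_fractions[0] * n_feat))
    n_steady = int(round(cfg.phase_fractions[1] * n_feat))
    n_high = n_feat - n_noise - n_steady
    if n_high < 0:
        n_steady += n_high
        n_high = 0
    phases = np.array(
        ["noise"] * n_noise + ["steady"] * n_steady + ["high"] * n_high
    )
    phases = phases[rng.permutation(n_feat)]
    feature_ids = [f"mir-{i + 1:04d}" for i in range(n_feat)]
    noise_mask = phases == "noise"
    signal_idx = np.flatnonzero(~noise_mask)

    # baseline means: log-uniform within each phase's range;
    # noise features get the range midpoint as their *expected* mean
    mu = np.empty(n_feat)
    mu[noise_mask] = 0.5 * (cfg.noise_mean_range[0] + cfg.noise_mean_range[1])
    for label, (lo, hi) in (
        ("steady", cfg.steady_mean_range),
        ("high", cfg.high_mean_range),
    ):
        m = phases == label
        mu[m] = np.exp(rng.uniform(np.log(lo), np.log(hi), m.sum()))

    # one dominant feature absorbs the configured share of expected counts
    if cfg.dominant_feature_fraction > 0 and signal_idx.size > 0:
        pool = np.flatnonzero(phases == "high")
        if pool.size == 0:
            pool = signal_idx
        dom = pool[np.argmax(mu[pool])]
        f = cfg.dominant_feature_fraction
        rest = mu.sum() - mu[dom]
        if f < 1.0:
            mu[dom] = f / (1.0 - f) * rest

    # planted condition effects: only on steady/high features
    n_de = int(round(cfg.de_fraction * signal_idx.size))
    de_idx = rng.choice(signal_idx, size=n_de, replace=False)
    de_lfc = _signed_uniform(rng, cfg.de_log2fc_range, n_de)

    # hemolysis effects: steady/high, preferring condition-null features
    n_hemo = int(round(cfg.hemo_fraction * signal_idx.size))
    non_de = np.setdiff1d(signal_idx, de_idx)
    if n_hemo <= non_de.size:
        hemo_idx = rng.choice(non_de, size=n_hemo, replace=False)
    else:
        extra = rng.choice(de_idx, size=n_hemo - non_de.size, replace=False)
        hemo_idx = np.concatenate([non_de, extra])
    hemo_beta = _signed_uniform(rng, cfg.hemo_beta_range, n_hemo)

    # family shifts on all steady/high features
    fam_beta = np.zeros((n_feat, 2))
    fam_beta[signal_idx] = rng.normal(
        0.0, cfg.family_shift_sd, (signal_idx.size, 2)
    )

    beta_cond = np.zeros(n_feat)
    beta_cond[de_idx] = de_lfc
    beta_abs = np.zeros(n_feat)
    beta_abs[hemo_idx] = hemo_beta

    # linear predictor on log2 scale: condition, family1, family2, absorbance
    log2_shift = (
        np.outer(beta_cond, condition)
        + np.outer(fam_beta[:, 0], family1)
        + np.outer(fam_beta[:, 1], family2)
        + np.outer(beta_abs, abs_centered)
    )
    # Two bounded per-sample latent factors (library preparation / RNA
    # quality style technical variation) with feature loadings on the
    # signal features: real expression matrices carry correlated
    # sample-level structure that dominates the leading PCA components.
    if cfg.latent_factor_sd > 0 and signal_idx.size > 0:
        strengths = cfg.latent_factor_sd * np.array([1.0, 0.75, 0.5])
        loadings = np.zeros((n_feat, 3))
        loadings[signal_idx] = rng.normal(
            0.0, 1.0, (signal_idx.size, 3)
        ) * strengths[None, :]
        factors = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), (3, n_samples))
        log2_shift += loadings @ factors
    mean_matrix = mu[:, None] * np.exp2(log2_shift) * size_factors[None, :]
    # Noise phase: sporadic expression — each noise feature is present in
    # a sample with a sample-specific occupancy probability and, when
    # present, has an independently drawn low mean.  Replicate
    # distributions of noise features therefore genuinely disagree
    # (present/absent mismatches and occupancy differences), the property
    # the KS thresholding procedure relies on.
    if noise_mask.any():
        lo, hi = cfg.noise_mean_range
        n_noise_feat = int(noise_mask.sum())
        occupancy = rng.uniform(0.2, 0.8, n_samples)
        present = rng.random((n_noise_feat, n_samples)) < occupancy[None, :]
        level = rng.uniform(lo, hi, (n_noise_feat, n_samples))
        noise_means = level * present
        mean_matrix[noise_mask] = noise_means * size_factors[None, :]
        mu[noise_mask] = noise_means.mean(axis=1)

    counts = _draw_nb(rng, mean_matrix, cfg.dispersion)

    counts_df = pd.DataFrame(counts, index=feature_ids, columns=sample_ids)
    counts_df.index.name = "feature_id"
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": np.where(condition == 1, "case", "control"),
            "family1": family1,
            "family2": family2,
            "absorbance_414": absorbance,
        }
    ).set_index("sample_id", drop=False)

    truth = GroundTruth(
        true_de={feature_ids[i]: float(l) for i, l in zip(de_idx, de_lfc)},
        true_hemo={feature_ids[i]: float(b) for i, b in zip(hemo_idx, hemo_beta)},
        true_size_factors=pd.Series(size_factors, index=sample_ids),
        true_means=pd.Series(mu, index=feature_ids),
        phase_label=pd.Series(phases, index=feature_ids),
        family_shifts=pd.DataFrame(
            fam_beta, index=feature_ids, columns=["family1", "family2"]
        ),
    )
    return counts_df, meta, truth


def simulate_read_lengths(
    n_reads: int,
    peak_fractions: tuple[float, float] = (0.046, 0.95),
    seed: int = 0,
    windows: tuple[tuple[int, int], tuple[int, int]] = ((21, 24), (29, 33)),
    length_range: tuple[int, int] = (15, 50),
) -> pd.Series:
    """Bimodal read-length histogram over 15-50 nt.

    Mass concentrates in the mature-miRNA window (21-24 nt) and the
    dominant longer-RNA window (29-33 nt) per ``peak_fractions``; any
    remaining mass spreads uniformly over the other lengths.  Counts sum
    to ``n_reads`` exactly.
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    f1, f2 = peak_fractions
    if not (0 <= f1 <= 1 and 0 <= f2 <= 1 and f1 + f2 <= 1 + 1e-12):
        raise ValueError(
            f"peak_fractions must be in [0,1] and sum to <= 1, got {peak_fractions}"
        )
    lengths = np.arange(length_range[0], length_range[1] + 1)
    probs = np.zeros(lengths.size)
    in1 = (lengths >= windows[0][0]) & (lengths <= windows[0][1])
    in2 = (lengths >= windows[1][0]) & (lengths <= windows[1][1])
    probs[in1] = f1 / in1.sum()
    probs[in2] += f2 / in2.sum()
    rest = ~(in1 | in2)
    remainder = max(0.0, 1.0 - f1 - f2)
    if rest.any():
        probs[rest] += remainder / rest.sum()
    else:
        probs += remainder / probs.size
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    return pd.Series(counts, index=pd.Index(lengths, name="length"), name="n_reads")


def simulate_score_table(
    n_true: int,
    n_false: int,
    score_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (3.0, 10.0),
        (0.0, 5.0),
    ),
    seed: int = 0,
    cutoffs: np.ndarray | None = None,
    n_permutations: int = 100,
) -> pd.DataFrame:
    """Precursor-score table for the score-cutoff heuristic.

    Emulates a hairpin-prediction run: ``n_true`` genuine precursors with
    scores uniform in ``score_ranges[0]`` (concentrated high) mixed with
    ``n_false`` spurious ones uniform in ``score_ranges[1]``, plus
    ``n_permutations`` permuted-control rounds that yield the mean
    estimated false-positive count at each cutoff.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("n_true and n_false must be >= 0")
    if cutoffs is None:
        cutoffs = np.arange(0.0, 10.5, 0.5)
    rng = np.random.default_rng(seed)
    t_lo, t_hi = score_ranges[0]
    f_lo, f_hi = score_ranges[1]
    true_scores = rng.uniform(t_lo, t_hi, n_true)
    false_scores = rng.uniform(f_lo, f_hi, n_false)
    perm_scores = rng.uniform(f_lo, f_hi, (n_permutations, n_false))
    rows = []
    for t in cutoffs:
        n_reported = int((true_scores >= t).sum() + (false_scores >= t).sum())
        fp_mean = float((perm_scores >= t).sum(axis=1).mean()) if n_false else 0.0
        rows.append({"cutoff": float(t), "n_reported": n_reported, "fp_mean": fp_mean})
    return pd.DataFrame(rows)
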