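"""The social-space statistic and auxiliary spatial summaries.

Social space is quantified as the number of *other* flies within four body
lengths (~1 cm for a 2.5 mm adult) of each focal fly in a settled group.
One chamber is one replicate; the replicate value is the mean of the
per-fly counts.  The module also provides nearest-neighbor distances and a
seeded permutation harness for recovering planted between-condition
differences in the replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .arena import PointConfig

__all__ = [
    "SocialSpaceResult",
    "EffectResult",
    "pairwise_distances",
    "count_within_radius",
    "nearest_neighbor_distances",
    "recover_interaction_strength",
]


@dataclass
class SocialSpaceResult:
    """Per-fly within-radius neighbor counts and their replicate mean."""

    radius_mm: float
    per_fly_counts: np.ndarray
    replicate_mean: float
    n_flies: int
    config: PointConfig | None = None


@dataclass
class EffectResult:
    """Permutation-test summary of a between-condition difference."""

    effect: float                 # mean(test) − mean(reference)
    standardized_effect: float    # effect / pooled replicate SD
    p_value: float
    direction: int                # sign of the effect (−1, 0, +1)
    n_permutations: int


def pairwise_distances(config: PointConfig) -> np.ndarray:
    """Symmetric Euclidean centre-to-centre distance matrix in mm."""
    n = config.n_flies
    if n == 0:
        return np.empty((0, 0))
    return squareform(pdist(config.coords))


def count_within_radius(
    config: PointConfig,
    radius_mm: float | None = None,
) -> SocialSpaceResult:
    """Count, per fly, the other flies at distance <= radius (inclusive).

    The default radius is four body lengths.  The self is excluded; the
    boundary is inclusive, which is determinism-friendly on gridded
    fixtures and measure-zero for continuous coordinates.
    """
    if radius_mm is None:
        radius_mm = 4.0 * config.body_length
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    n = config.n_flies
    if n == 0:
        raise ValueError("no focal flies: empty configuration")
    config.warn_if_outside_assay_range()
    d = pairwise_distances(config)
    within = (d <= radius_mm) & ~np.eye(n, dtype=bool)
    counts = within.sum(axis=1)
    return SocialSpaceResult(
        radius_mm=float(radius_mm),
        per_fly_counts=counts,
        replicate_mean=float(counts.mean()),
        n_flies=n,
        config=config,
    )


def nearest_neighbor_distances(config: PointConfig) -> np.ndarray:
    """Per-fly distance (mm) to the closest other fly."""
    n = config.n_flies
    if n < 2:
        raise ValueError("nearest-neighbor distances need >= 2 flies")
    d = pairwise_distances(config)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def recover_interaction_strength(
    means_test: np.ndarray,
    means_reference: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> EffectResult:
    """Two-sided permutation test on a difference of replicate means.

    Compares the mean within-radius count between a test condition and a
    reference condition by shuffling condition labels.  The p-value uses
    the add-one convention; identical replicate sets give p = 1.

    Parameters
    ----------
    means_test, means_reference
        Replicate means (one per chamber) for each condition; >= 5 each.
    """
    a = np.asarray(means_test, dtype=float)
    b = np.asarray(means_reference, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need >= 5 replicates per condition")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = a.mean() - b.mean()

    perm = np.tile(pooled, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    null = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    p = (1 + np.sum(np.abs(null) >= np.abs(observed) - 1e-12)) / (n_permutations + 1)

    pooled_sd = np.sqrt(
        ((n_a - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(pooled) - 2)
    )
    std_effect = observed / pooled_sd if pooled_sd > 0 else 0.0
    return EffectResult(
        effect=float(observed),
        standardized_effect=float(std_effect),
        p_value=float(min(p, 1.0)),
        direction=int(np.sign(observed)),
        n_permutations=n_permutations,
    )
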