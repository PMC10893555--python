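"""Randomization null model for dispersion of signaling niches.

The observed statistic is the mean Euclidean distance between species'
niche centroids in the 2-D signal space.  Null communities preserve the
number of species and the number of males per species, but draw every
male's (PC1, PC2) coordinates independently and uniformly within the
observed per-axis range; each null community yields a mean interspecific
centroid distance.  The dispersion Z score is
(observed - null mean) / null SD: significantly positive Z indicates
overdispersion (a partitioned signal space), significantly negative Z
indicates clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .errors import DegenerateInputError
from .trait_space import Niche, polygon_centroid

CLASSIFICATIONS = ("overdispersed", "underdispersed", "random")


def centroid_distance_matrix(
    niches: Sequence[Niche] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Pairwise Euclidean distances between niche centroids and their mean."""
    if len(niches) < 2:
        raise DegenerateInputError("need at least 2 niches/centroids")
    if isinstance(niches[0], Niche):
        pts = np.array([n.centroid for n in niches])
    else:
        pts = np.asarray(niches, dtype=float)
    d = pdist(pts)
    return squareform(d), float(d.mean())


def observed_axis_ranges(scores: pd.DataFrame) -> list[tuple[float, float]]:
    """(min, max) of the observed scores along each retained axis."""
    return [
        (float(scores[c].min()), float(scores[c].max())) for c in ("PC1", "PC2")
    ]


def _validate_ranges(axis_ranges) -> np.ndarray:
    r = np.asarray(axis_ranges, dtype=float)
    if r.shape != (2, 2):
        raise ValueError("axis_ranges must be two (min, max) pairs")
    if not np.all(np.isfinite(r)) or np.any(r[:, 0] >= r[:, 1]):
        raise DegenerateInputError("each axis range needs finite min < max")
    return r


def null_communities(
    axis_ranges,
    sizes: Sequence[int],
    n_reps: int = 10_000,
    seed: int = 0,
    centroid: str = "points",
    chunk: int = 2_000,
) -> np.ndarray:
    """Distribution of null mean interspecific centroid distances.

    Per replicate, every male of every species gets independent uniform
    coordinates inside the observed per-axis range; a species' null
    centroid is the mean of its sampled points (``centroid="points"``,
    default) or the area centroid of their convex hull
    (``centroid="hull"``, requires >= 3 males per species).
    """
    r = _validate_ranges(axis_ranges)
    sizes = np.asarray(sizes, dtype=int)
    if len(sizes) < 2:
        raise ValueError("need at least 2 species sizes")
    if np.any(sizes < 1):
        raise ValueError("species sizes must be >= 1")
    if centroid not in ("points", "hull"):
        raise ValueError("centroid must be 'points' or 'hull'")
    if centroid == "hull" and np.any(sizes < 3):
        raise DegenerateInputError("hull centroids require >= 3 males per species")
    rng = np.random.default_rng(seed)
    S = len(sizes)
    total = int(sizes.sum())
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    iu = np.triu_indices(S, k=1)
    lo, span = r[:, 0], r[:, 1] - r[:, 0]
    out = np.empty(n_reps)
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        pts = rng.random((m, total, 2)) * span + lo
        if centroid == "points":
            cents = np.add.reduceat(pts, starts, axis=1) / sizes[None, :, None]
        else:
            cents = np.empty((m, S, 2))
            for i in range(m):
                for s, (st, sz) in enumerate(zip(starts, sizes)):
                    p = pts[i, st : st + sz]
                    try:
                        hull = ConvexHull(p)
                        cents[i, s] = polygon_centroid(p[hull.vertices])
                    except QhullError:
                        cents[i, s] = p.mean(axis=0)  # collinear: fall back
        diffs = cents[:, iu[0], :] - cents[:, iu[1], :]
        out[done : done + m] = np.sqrt((diffs**2).sum(axis=2)).mean(axis=1)
        done += m
    return out


@dataclass(frozen=True)
class NullModelResult:
    """Dispersion test outcome for one observed mean centroid distance."""

    observed_mean_distance: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_replicates: int
    seed: int | None
    classification: str
    alpha: float = 0.05


def dispersion_test(
    observed: float,
    null_distribution: np.ndarray,
    sd: str = "sample",
    alpha: float = 0.05,
    seed: int | None = None,
) -> NullModelResult:
    """Z score and classification of the observed distance against the null.

    ``sd`` selects the null-SD convention: "sample" (ddof=1, default) or
    "population" (ddof=0).  The empirical two-sided p uses the
    +1/(n+1) correction.  Classification uses the two-sided normal cutoff
    at ``alpha``.
    """
    null = np.asarray(null_distribution, dtype=float)
    if len(null) < 100:
        raise ValueError("null distribution must have >= 100 replicates")
    ddof = {"sample": 1, "population": 0}[sd]
    mu = null.mean()
    sigma = null.std(ddof=ddof)
    if sigma == 0:
        raise DegenerateInputError("null distribution has zero SD")
    z = (observed - mu) / sigma
    n = len(null)
    p_emp = min(
        1.0,
        2.0 * min((1 + np.sum(null >= observed)), (1 + np.sum(null <= observed))) / (n + 1),
    )
    cut = norm.ppf(1 - alpha / 2)
    if z > cut:
        cls = "overdispersed"
    elif z < -cut:
        cls = "underdispersed"
    else:
        cls = "random"
    return NullModelResult(
        observed_mean_distance=float(observed),
        null_mean=float(mu),
        null_sd=float(sigma),
        z=float(z),
        p_empirical=float(p_emp),
        n_replicates=n,
        seed=seed,
        classification=cls,
        alpha=alpha,
    )


def community_dispersion(
    niches: Sequence[Niche],
    axis_ranges,
    n_reps: int = 10_000,
    seed: int = 0,
    centroid: str = "points",
    sd: str = "sample",
    alpha: float = 0.05,
) -> NullModelResult:
    """Community-level dispersion test from observed niches."""
    _, observed = centroid_distance_matrix(list(niches))
    sizes = [n.n_individuals for n in niches]
    null = null_communities(axis_ranges, sizes, n_reps=n_reps, seed=seed, centroid=centroid)
    return dispersion_test(observed, null, sd=sd, alpha=alpha, seed=seed)


def pairwise_dispersion(
    niches: Sequence[Niche],
    axis_ranges,
    n_reps: int = 10_000,
    seed: int = 0,
    sd: str = "sample",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-pair dispersion tests and community summary proportions.

    Each unordered pair's observed centroid distance is compared to nulls
    built by resampling only that pair (at its observed per-species sample
    sizes) uniformly within the full observed axis ranges.  The summary
    gives the proportion of pairs classified overdispersed /
    underdispersed / random.
    """
    r = _validate_ranges(axis_ranges)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(niches, 2):
        obs = float(np.linalg.norm(a.centroid - b.centroid))
        pair_seed = int(rng.integers(0, 2**31 - 1))
        null = null_communities(
            r, [a.n_individuals, b.n_individuals], n_reps=n_reps, seed=pair_seed,
            chunk=n_reps,
        )
        res = dispersion_test(obs, null, sd=sd, alpha=alpha, seed=pair_seed)
        rows.append(
            (a.species, b.species, obs, res.z, res.p_empirical, res.classification)
        )
    df = pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "observed_distance", "z", "p_empirical", "classification"],
    )
    n = len(df)
    summary = {c: float((df["classification"] == c).sum() / n) for c in CLASSIFICATIONS}
    return df, summary
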