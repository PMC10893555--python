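"""Community signal space and per-species convex-hull signaling niches.

Per-song trait records are averaged per male, standardised, and ordinated by
a PCA of the trait correlation matrix.  Components with eigenvalue > 1 are
retained (Kaiser rule); with six song traits this typically yields a 2-D
signal space in which each male is a point and each species' signaling niche
is the convex hull of its males' scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataIntegrityError, DegenerateInputError, DegenerateNicheError
from .synthetic import TRAIT_COLUMNS

META_COLUMNS = ("species", "status", "individual_id")


def per_male_means(songs: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each trait per individual male.

    Species and status labels are carried through; an individual appearing
    under two species codes is a data-integrity error.
    """
    missing = [c for c in (*META_COLUMNS, *TRAIT_COLUMNS) if c not in songs.columns]
    if missing:
        raise DataIntegrityError(f"trait table missing columns: {missing}")
    per_ind = songs.groupby("individual_id")["species"].nunique()
    bad = per_ind[per_ind > 1]
    if len(bad):
        raise DataIntegrityError(
            f"individuals under multiple species codes: {list(bad.index)}"
        )
    out = (
        songs.groupby(list(META_COLUMNS), sort=False, as_index=False)[list(TRAIT_COLUMNS)]
        .mean()
    )
    return out


class SignalSpacePCA(TransformerMixin, BaseEstimator):
    """PCA of the trait correlation matrix, Kaiser-retained components.

    scikit-learn style transformer: ``fit`` standardises each trait column
    (z-scores, SD with ddof=1), eigendecomposes the correlation matrix,
    keeps components with eigenvalue > ``eigenvalue_threshold`` in
    descending-eigenvalue order, and fixes each component's sign so its
    largest-magnitude loading is positive.  ``transform`` projects
    standardised data onto the retained components.

    Parameters
    ----------
    eigenvalue_threshold : float, default 1.0
        Strict lower bound for a component to be retained.
    trait_columns : sequence of str or None
        Trait columns to use; defaults to the six song traits.

    Attributes
    ----------
    mean_, scale_ : per-trait standardisation constants
    eigenvalues_full_ : all eigenvalues of the correlation matrix (sum = p)
    loadings_ : (p, k) retained loadings
    eigenvalues_, explained_fraction_ : per retained component
    """

    def __init__(self, eigenvalue_threshold: float = 1.0, trait_columns=None):
        self.eigenvalue_threshold = eigenvalue_threshold
        self.trait_columns = trait_columns

    def _columns(self, X: pd.DataFrame) -> list[str]:
        return list(self.trait_columns) if self.trait_columns is not None else list(TRAIT_COLUMNS)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = self._columns(X)
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise DataIntegrityError(f"missing trait columns: {missing}")
            return X[cols].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y=None):
        M = self._matrix(X)
        n, p = M.shape
        if n < 3:
            raise DegenerateInputError("need at least 3 individuals for the PCA")
        self.feature_names_in_ = np.asarray(
            self._columns(X) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(p)]
        )
        self.mean_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=1)
        zero = np.flatnonzero(self.scale_ == 0)
        if len(zero):
            names = [str(self.feature_names_in_[i]) for i in zero]
            raise DegenerateInputError(f"constant trait column(s): {names}")
        Z = (M - self.mean_) / self.scale_
        R = (Z.T @ Z) / (n - 1)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(-evals, kind="stable")  # descending, ties by trait order
        evals, evecs = evals[order], evecs[:, order]
        # sign convention: largest-|loading| entry positive
        for k in range(p):
            i = int(np.argmax(np.abs(evecs[:, k])))
            if evecs[i, k] < 0:
                evecs[:, k] = -evecs[:, k]
        self.eigenvalues_full_ = evals
        self.loadings_full_ = evecs
        # strict "> threshold" rule, with a guard so an eigenvalue equal to
        # the threshold up to floating-point noise is not retained
        keep = evals > self.eigenvalue_threshold + 1e-10
        k = int(keep.sum())
        if k < 2:
            warnings.warn(
                f"only {k} component(s) with eigenvalue > "
                f"{self.eigenvalue_threshold}; downstream 2-D geometry will not apply",
                stacklevel=2,
            )
        self.n_components_ = k
        self.loadings_ = evecs[:, :k]
        self.eigenvalues_ = evals[:k]
        self.explained_fraction_ = evals[:k] / p
        return self

    def transform(self, X) -> np.ndarray:
        M = self._matrix(X)
        Z = (M - self.mean_) / self.scale_
        return Z @ self.loadings_


@dataclass(frozen=True)
class SignalSpace:
    """Fitted community signal space with per-male scores."""

    loadings: pd.DataFrame  # traits x retained components
    eigenvalues: np.ndarray  # retained
    eigenvalues_full: np.ndarray
    explained_fraction: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    scores: pd.DataFrame  # species, status, individual_id, PC1..PCk

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def score_columns(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]


def build_signal_space(
    means: pd.DataFrame, eigenvalue_threshold: float = 1.0
) -> SignalSpace:
    """Fit the signal-space PCA on a per-male mean-trait table."""
    est = SignalSpacePCA(eigenvalue_threshold=eigenvalue_threshold).fit(means)
    scores = est.transform(means)
    pc_cols = [f"PC{i + 1}" for i in range(est.n_components_)]
    score_df = means[list(META_COLUMNS)].copy()
    for j, c in enumerate(pc_cols):
        score_df[c] = scores[:, j]
    loadings = pd.DataFrame(est.loadings_, index=list(est.feature_names_in_), columns=pc_cols)
    return SignalSpace(
        loadings=loadings,
        eigenvalues=est.eigenvalues_,
        eigenvalues_full=est.eigenvalues_full_,
        explained_fraction=est.explained_fraction_,
        mean=est.mean_,
        scale=est.scale_,
        scores=score_df,
    )


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (vertices in order)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon (vertices in order)."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        raise DegenerateInputError("zero-area polygon has no area centroid")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


@dataclass(frozen=True)
class Niche:
    """A species' signaling niche: convex hull of its males' 2-D scores."""

    species: str
    status: str
    vertices: np.ndarray  # (m, 2), counter-clockwise
    area: float
    centroid: np.ndarray
    n_individuals: int


def _require_2d(space: SignalSpace) -> None:
    if space.n_components != 2:
        raise DegenerateInputError(
            f"geometry requires exactly 2 retained components, got {space.n_components}"
        )


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points)
    return points[hull.vertices]  # scipy returns CCW order in 2-D


def build_niches(space: SignalSpace) -> list[Niche]:
    """Convex-hull niche per species from its males' (PC1, PC2) scores."""
    _require_2d(space)
    return niches_from_scores(space.scores)


def niches_from_scores(scores: pd.DataFrame) -> list[Niche]:
    """Rebuild niches from a saved scores table (species, status, PC1, PC2)."""
    niches = []
    for species, grp in scores.groupby("species", sort=False):
        pts = grp[["PC1", "PC2"]].to_numpy(dtype=float)
        if len(pts) < 3:
            raise DegenerateNicheError(species, f"only {len(pts)} individuals")
        try:
            verts = _hull_vertices(pts)
        except QhullError as exc:
            raise DegenerateNicheError(species, "collinear score points") from exc
        niches.append(
            Niche(
                species=species,
                status=str(grp["status"].iloc[0]),
                vertices=verts,
                area=shoelace_area(verts),
                centroid=polygon_centroid(verts),
                n_individuals=len(pts),
            )
        )
    return niches


def community_area(space: SignalSpace, method: str = "all_points") -> float:
    """Area of the community signal space.

    ``all_points`` (default): convex hull over every male's score — the
    spanning hull, so two disjoint clusters still yield one connected area.
    ``union``: total area of the union of the per-species hulls.
    """
    _require_2d(space)
    if method == "all_points":
        pts = space.scores[["PC1", "PC2"]].to_numpy()
        try:
            return shoelace_area(_hull_vertices(pts))
        except QhullError as exc:
            raise DegenerateInputError("all scores are collinear") from exc
    if method == "union":
        from shapely.geometry import Polygon
        from shapely.ops import unary_union

        return unary_union([Polygon(n.vertices) for n in build_niches(space)]).area
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SampleSizeRegression:
    """OLS of log niche area on sampling depth, with VIF diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    slope_pvalue: float
    n_species: int
    vif: dict[str, float]  # two-predictor variant (n, status, interaction)


def sample_size_regression(niches: list[Niche]) -> SampleSizeRegression:
    """Diagnose the effect of per-species sampling depth on niche area.

    Fits log(area) ~ n_individuals by OLS and reports variance inflation
    factors for the richer variant with migratory status and its
    interaction (VIF > 10 flags unacceptable collinearity).  Species with
    non-positive area are excluded with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    rows = [(n.species, n.status, n.n_individuals, n.area) for n in niches]
    df = pd.DataFrame(rows, columns=["species", "status", "n_individuals", "area"])
    bad = df[df["area"] <= 0]
    if len(bad):
        warnings.warn(f"excluding non-positive areas: {list(bad['species'])}", stacklevel=2)
        df = df[df["area"] > 0]
    if len(df) < 3:
        raise DegenerateInputError("need >= 3 species with positive area")
    y = np.log(df["area"].to_numpy())
    X = sm.add_constant(df["n_individuals"].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    status = (df["status"] == "migrant").to_numpy(dtype=float)
    n_ind = df["n_individuals"].to_numpy(dtype=float)
    X2 = sm.add_constant(np.column_stack([n_ind, status, n_ind * status]))
    names = ["n_individuals", "status", "n_individuals:status"]
    vif = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(names, start=1):
            try:
                v = variance_inflation_factor(X2, j)
            except Exception:
                v = np.inf
            vif[name] = float(v) if np.isfinite(v) else np.inf
    return SampleSizeRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        slope_pvalue=float(fit.pvalues[1]),
        n_species=int(len(df)),
        vif=vif,
    )
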