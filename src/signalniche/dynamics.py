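"""Niche-overlap dynamics across the reconstructed community time series.

For each 3-day community snapshot, pairwise overlap counts (by pair type)
and per-breeding-species overlap proportions are recomputed over only the
co-present species.  The time courses are modelled with a Poisson GLM
(overlap counts ~ pair type x polynomial of standardized day) and a
fixed-effects binomial GLM (overlap proportion ~ overlap type x polynomial),
with AIC comparison across polynomial degrees and Pearson-residual
dispersion diagnostics.  Day of year is centered to mean 0 and scaled to
SD 1 before building the polynomial terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DataIntegrityError, DegenerateInputError
from .overlap import PAIR_TYPES, pair_type, proportion_overlapped, _as_polygon
from .phenology import CommunitySnapshot
from .trait_space import Niche


def standardize_days(days: Sequence[float]) -> np.ndarray:
    """Center to mean 0, scale to SD 1 (ddof=1, as R's scale())."""
    d = np.asarray(days, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot standardize constant days")
    return (d - d.mean()) / sd


@dataclass(frozen=True)
class WindowOverlapTables:
    """Per-window overlap counts by pair type and per-species proportions."""

    counts: pd.DataFrame  # window_index, day, standardized_day, pair_type, n_overlaps, n_possible
    proportions: pd.DataFrame  # window_index, standardized_day, species, overlap_type, proportion


def window_overlaps(
    snapshots: Sequence[CommunitySnapshot],
    niches: Sequence[Niche],
    pair_table: pd.DataFrame | None = None,
) -> WindowOverlapTables:
    """Restrict the overlap geometry to co-present species per window.

    Counts nonzero-area overlaps per pair type among species present in
    each snapshot, and recomputes each present breeding species' proportion
    overlapped by co-present migrants, co-present other breeders, and all
    co-present others.
    """
    by_species = {n.species: n for n in niches}
    for snap in snapshots:
        missing = [s for s in snap.present_species if s not in by_species]
        if missing:
            raise DataIntegrityError(
                f"window {snap.window_index}: present species without a niche: {missing}"
            )
    if pair_table is None:
        from .overlap import overlap_table

        pair_table = overlap_table(list(niches)).pairs if len(niches) >= 2 else None
    midpoints = [0.5 * (ws + we) for ws, we in (s.window_days for s in snapshots)]
    std_days = standardize_days(midpoints)
    polys = {n.species: _as_polygon(n) for n in niches}

    count_rows, prop_rows = [], []
    for snap, day, z in zip(snapshots, midpoints, std_days):
        present = snap.present_species
        n_overlaps = dict.fromkeys(PAIR_TYPES, 0)
        n_possible = dict.fromkeys(PAIR_TYPES, 0)
        if pair_table is not None:
            both = pair_table[
                pair_table["species_a"].isin(present) & pair_table["species_b"].isin(present)
            ]
            for _, r in both.iterrows():
                n_possible[r["pair_type"]] += 1
                if r["overlaps"]:
                    n_overlaps[r["pair_type"]] += 1
        for pt in PAIR_TYPES:
            count_rows.append(
                (snap.window_index, day, z, pt, n_overlaps[pt], n_possible[pt])
            )
        breeders = sorted(s for s in present if by_species[s].status == "breeding")
        for sp in breeders:
            others = [o for o in present if o != sp]
            groups = {
                "migrant": [polys[o] for o in others if by_species[o].status == "migrant"],
                "breeding": [polys[o] for o in others if by_species[o].status == "breeding"],
                "total": [polys[o] for o in others],
            }
            for gname, hulls in groups.items():
                prop_rows.append(
                    (snap.window_index, z, sp, gname, proportion_overlapped(polys[sp], hulls))
                )
    counts = pd.DataFrame(
        count_rows,
        columns=["window_index", "day", "standardized_day", "pair_type", "n_overlaps", "n_possible"],
    )
    proportions = pd.DataFrame(
        prop_rows,
        columns=["window_index", "standardized_day", "species", "overlap_type", "proportion"],
    )
    return WindowOverlapTables(counts=counts, proportions=proportions)


def _poly_columns(df: pd.DataFrame, degree: int, orthogonal: bool) -> tuple[pd.DataFrame, list[str]]:
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    out = df.copy()
    x = out["standardized_day"].to_numpy(dtype=float)
    if orthogonal:
        V = np.vander(x, degree + 1, increasing=True)
        Q, _ = np.linalg.qr(V)
        basis = Q[:, 1:]
    else:
        basis = np.column_stack([x**k for k in range(1, degree + 1)])
    names = [f"day{k}" for k in range(1, degree + 1)]
    for j, name in enumerate(names):
        out[name] = basis[:, j]
    return out, names


@dataclass
class GLMFit:
    """A fitted GLM with the degree-comparison table and dispersion."""

    family: str
    formula: str
    degree: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    deviance: float
    aic: float
    dispersion: float  # Pearson chi2 / residual df
    aic_by_degree: dict[int, float]
    converged: bool
    diverged: bool = False
    notes: str = ""
    result: object = field(default=None, repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.result.conf_int(alpha=alpha)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(df))


def _fit_family_glm(
    df: pd.DataFrame,
    response: str,
    group_col: str,
    family,
    family_name: str,
    degree: int,
    orthogonal: bool,
    var_weights: np.ndarray | None = None,
    formula: str | None = None,
) -> GLMFit:
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    kwargs = {}
    if var_weights is not None:
        kwargs["var_weights"] = var_weights

    def _fit(fml: str, data: pd.DataFrame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(fml, data=data, family=family, **kwargs)
            try:
                return model.fit(maxiter=100, tol=1e-10), False
            except PerfectSeparationError:
                return model.fit(maxiter=3), True

    aic_by_degree: dict[int, float] = {}
    separated = False
    if formula is not None:
        res, separated = _fit(formula, df)
        aic_by_degree[degree] = float(res.aic)
    else:
        chosen = None
        for deg in (1, 2, 3):
            data, names = _poly_columns(df, deg, orthogonal)
            rhs = " + ".join(names)
            fml = f"{response} ~ {group_col} * ({rhs})"
            res_deg, sep_deg = _fit(fml, data)
            aic_by_degree[deg] = float(res_deg.aic)
            if deg == degree:
                chosen = (res_deg, fml, sep_deg)
        res, formula, separated = chosen
    df_resid = max(res.df_resid, 1)
    dispersion = float(res.pearson_chi2 / df_resid)
    diverged = (
        separated
        or bool(np.any(np.abs(res.params.to_numpy()) > 50))
        or not np.all(np.isfinite(res.bse.to_numpy()))
    )
    return GLMFit(
        family=family_name,
        formula=formula,
        degree=degree,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        deviance=float(res.deviance),
        aic=float(res.aic),
        dispersion=dispersion,
        aic_by_degree=aic_by_degree,
        converged=bool(getattr(res, "converged", True)),
        diverged=diverged,
        notes="possible separation/divergence: some |coef| > 50" if diverged else "",
        result=res,
    )


def fit_poisson_glm(
    counts: pd.DataFrame,
    degree: int = 3,
    orthogonal: bool = False,
    formula: str | None = None,
) -> GLMFit:
    """Poisson log-link GLM: n_overlaps ~ pair_type x poly(standardized_day).

    Fits degrees 1-3 for the AIC comparison and returns the requested
    degree with a Pearson overdispersion statistic.  ``formula`` overrides
    the default model (e.g. intercept-only) and skips the degree sweep.
    """
    if (counts["n_overlaps"] < 0).any():
        raise ValueError("counts must be >= 0")
    return _fit_family_glm(
        counts, "n_overlaps", "pair_type", sm.families.Poisson(), "poisson",
        degree, orthogonal, formula=formula,
    )


def fit_binomial_glm(
    proportions: pd.DataFrame,
    degree: int = 3,
    weight: float = 100.0,
    orthogonal: bool = False,
    formula: str | None = None,
) -> GLMFit:
    """Binomial logit-link GLM on overlap proportions.

    Proportions are modelled as weighted binomial observations (default
    weight 100 per row — proportions of hull area are not true counts, so
    the weight is a stated convention and the dispersion statistic flags
    its arbitrariness).  Rows with overlap_type "total" are excluded; the
    contrast of interest is migrant vs breeding overlap.
    """
    df = proportions[proportions["overlap_type"].isin(["migrant", "breeding"])].copy()
    if not ((df["proportion"] >= 0) & (df["proportion"] <= 1)).all():
        raise ValueError("proportions must lie in [0, 1]")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    return _fit_family_glm(
        df, "proportion", "overlap_type", sm.families.Binomial(), "binomial",
        degree, orthogonal, var_weights=np.full(len(df), float(weight)),
        formula=formula,
    )


def peak_windows(snapshots: Sequence[CommunitySnapshot]) -> list[int]:
    """Indices of the window(s) with maximum species richness."""
    richness = [len(s.present_species) for s in snapshots]
    top = max(richness)
    return [s.window_index for s, r in zip(snapshots, richness) if r == top]


def choose_peak_window(snapshots: Sequence[CommunitySnapshot], seed: int = 0) -> int:
    """One max-richness window, chosen with a fixed seed among ties."""
    ties = peak_windows(snapshots)
    rng = np.random.default_rng(seed)
    return int(ties[int(rng.integers(0, len(ties)))])


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired-samples t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    Degenerate cases follow the usual conventions: all-zero differences
    give t = 0, p = 1; zero-variance nonzero differences give infinite t
    with p -> 0.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)
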