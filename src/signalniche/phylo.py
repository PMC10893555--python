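"""Phylogenetic distance vs proximity in signal space.

Patristic (summed branch length) distances between all species pairs are
regressed against the log Euclidean distance between the species' niche
centroids, with a pair-type (migrant-breeding / breeding-breeding /
migrant-migrant) interaction.  Post-hoc contrasts between pair types use a
Tukey HSD (studentized-range) adjustment on type means evaluated at a
common phylogenetic distance.

A caveat inherited from the design: pairwise distances are not independent
observations, and the model makes no correction for this; ``n_pairs`` is
reported so readers can judge the effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .errors import DataIntegrityError
from .overlap import pair_type
from .trait_space import Niche


def patristic_distances(tree: str | dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip patristic distance matrix from a Newick tree."""
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        try:
            t = dendropy.Tree.get(data=str(tree), schema="newick")
        except Exception as exc:  # duplicate taxa, malformed newick, ...
            raise DataIntegrityError(f"cannot parse tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise DataIntegrityError("duplicate tip labels in tree")
    for edge in t.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise DataIntegrityError("tree has edges without branch lengths")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.taxon_namespace}
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        d = pdm.patristic_distance(taxa[a], taxa[b])
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def pair_distance_table(
    patristic: pd.DataFrame, niches: Sequence[Niche]
) -> pd.DataFrame:
    """Per-pair records joining patristic and centroid distances.

    Pairs with exactly coincident centroids (zero Euclidean distance) are
    excluded with a warning, since the response is log-transformed.
    """
    by_species = {n.species: n for n in niches}
    missing = [s for s in by_species if s not in patristic.index]
    if missing:
        raise DataIntegrityError(f"species missing from tree: {missing}")
    rows, n_zero = [], 0
    for a, b in combinations(sorted(by_species), 2):
        na, nb = by_species[a], by_species[b]
        cd = float(np.linalg.norm(na.centroid - nb.centroid))
        if cd == 0.0:
            n_zero += 1
            continue
        rows.append(
            (
                a,
                b,
                pair_type(na.status, nb.status),
                float(patristic.loc[a, b]),
                cd,
                float(np.log(cd)),
            )
        )
    if n_zero:
        warnings.warn(f"excluded {n_zero} pair(s) with identical centroids", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "species_a",
            "species_b",
            "pair_type",
            "patristic_distance",
            "centroid_distance",
            "log_centroid_distance",
        ],
    )


@dataclass
class PhyloSignalFit:
    """Interaction OLS fit with per-type slopes and Tukey contrasts."""

    params: pd.Series
    r_squared: float
    f_stat: float
    f_pvalue: float
    slopes: pd.DataFrame  # pair_type, slope, se
    tukey: pd.DataFrame  # contrast, estimate, se, t_ratio, p_adj
    n_pairs: int
    covariate_value: float
    note: str = (
        "pairwise distances are non-independent; no correction applied "
        "(inference mirrors the pairwise design)"
    )
    result: object = field(default=None, repr=False)


def fit_interaction_ols(
    records: pd.DataFrame, covariate_value: float | None = None
) -> PhyloSignalFit:
    """OLS: log centroid distance ~ pair_type * patristic distance.

    Reports per-type simple slopes with SEs and Tukey-HSD-adjusted pairwise
    contrasts of type means at ``covariate_value`` (default: the mean
    patristic distance).  A zero-variance response returns the all-zero
    slope convention with F-test p = 1.
    """
    df = records.copy()
    types = sorted(df["pair_type"].unique())
    n = len(df)
    y = df["log_centroid_distance"].to_numpy()
    if np.allclose(y.var(), 0.0):
        slopes = pd.DataFrame({"pair_type": types, "slope": 0.0, "se": 0.0})
        return PhyloSignalFit(
            params=pd.Series(dtype=float),
            r_squared=0.0,
            f_stat=0.0,
            f_pvalue=1.0,
            slopes=slopes,
            tukey=pd.DataFrame(columns=["contrast", "estimate", "se", "t_ratio", "p_adj"]),
            n_pairs=n,
            covariate_value=float(covariate_value if covariate_value is not None else df["patristic_distance"].mean()),
        )
    if len(types) < 2:
        warnings.warn("single pair type present; fitting without interaction", stacklevel=2)
        res = smf.ols("log_centroid_distance ~ patristic_distance", data=df).fit()
        slopes = pd.DataFrame(
            {
                "pair_type": types,
                "slope": [float(res.params["patristic_distance"])],
                "se": [float(res.bse["patristic_distance"])],
            }
        )
        return PhyloSignalFit(
            params=res.params,
            r_squared=float(res.rsquared),
            f_stat=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
            slopes=slopes,
            tukey=pd.DataFrame(columns=["contrast", "estimate", "se", "t_ratio", "p_adj"]),
            n_pairs=n,
            covariate_value=float(covariate_value if covariate_value is not None else df["patristic_distance"].mean()),
            result=res,
        )
    res = smf.ols("log_centroid_distance ~ pair_type * patristic_distance", data=df).fit()
    xbar = float(covariate_value if covariate_value is not None else df["patristic_distance"].mean())
    names = list(res.params.index)
    cov = res.cov_params().to_numpy()

    def _lvec(ptype: str, slope_only: bool = False) -> np.ndarray:
        """Design vector for the type mean at xbar (or the type slope)."""
        L = np.zeros(len(names))
        for i, nm in enumerate(names):
            base = 0.0
            if nm == "Intercept":
                base = 1.0
            elif nm == f"pair_type[T.{ptype}]":
                base = 1.0
            elif nm == "patristic_distance":
                base = xbar
            elif nm == f"pair_type[T.{ptype}]:patristic_distance":
                base = xbar
            L[i] = base
        if slope_only:
            L = np.zeros(len(names))
            for i, nm in enumerate(names):
                if nm == "patristic_distance":
                    L[i] = 1.0
                elif nm == f"pair_type[T.{ptype}]:patristic_distance":
                    L[i] = 1.0
        return L

    beta = res.params.to_numpy()
    slope_rows = []
    for t in types:
        L = _lvec(t, slope_only=True)
        slope_rows.append((t, float(L @ beta), float(np.sqrt(L @ cov @ L))))
    slopes = pd.DataFrame(slope_rows, columns=["pair_type", "slope", "se"])

    k = len(types)
    dfres = res.df_resid
    tukey_rows = []
    for ta, tb in combinations(types, 2):
        L = _lvec(ta) - _lvec(tb)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t_ratio = est / se if se > 0 else np.inf
        p_adj = float(studentized_range.sf(abs(t_ratio) * np.sqrt(2.0), k, dfres))
        tukey_rows.append((f"{ta} - {tb}", est, se, t_ratio, min(1.0, p_adj)))
    tukey = pd.DataFrame(tukey_rows, columns=["contrast", "estimate", "se", "t_ratio", "p_adj"])
    return PhyloSignalFit(
        params=res.params,
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        slopes=slopes,
        tukey=tukey,
        n_pairs=n,
        covariate_value=xbar,
        result=res,
    )
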