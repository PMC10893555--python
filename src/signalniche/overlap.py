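"""Pairwise and group-wise convex-hull niche overlap in 2-D signal space.

Overlap between two signaling niches is the area of the intersection of
their convex hulls.  The proportion of a focal niche covered by a set of
other niches is area(focal intersect union(others)) / area(focal), computed
by clipping each other-hull to the focal hull and taking the area of the
union of the clipped convex pieces.  A pair "overlaps" whenever its
intersection area is positive, regardless of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import DataIntegrityError, DegenerateInputError
from .trait_space import Niche

PAIR_TYPES = ("migrant-breeding", "breeding-breeding", "migrant-migrant")

#: coordinates closer than this are treated as coincident during clipping
SNAP_GRID = 1e-9
#: intersection areas below this are floating-point slivers, reported as 0
AREA_EPS = 1e-12


def pair_type(status_a: str, status_b: str) -> str:
    """Classify an unordered species pair by migratory status."""
    for s in (status_a, status_b):
        if s not in ("migrant", "breeding"):
            raise DataIntegrityError(f"unknown status {s!r}")
    if status_a == status_b:
        return f"{status_a}-{status_a}"
    return "migrant-breeding"


def classify_pairs(statuses: Mapping[str, str]) -> dict[str, int]:
    """Count possible unordered pairs by type: M*B, C(B,2), C(M,2)."""
    if len(statuses) < 2:
        raise DataIntegrityError("need at least 2 species")
    counts = dict.fromkeys(PAIR_TYPES, 0)
    for a, b in combinations(statuses, 2):
        counts[pair_type(statuses[a], statuses[b])] += 1
    counts["total"] = sum(counts[t] for t in PAIR_TYPES)
    return counts


def _as_polygon(obj) -> Polygon:
    if isinstance(obj, Niche):
        poly = Polygon(obj.vertices)
    elif isinstance(obj, Polygon):
        poly = obj
    else:
        poly = Polygon(np.asarray(obj, dtype=float))
    if poly.area <= AREA_EPS:
        raise DegenerateInputError("degenerate (zero-area) hull")
    return poly


def intersect_convex(hull_a, hull_b) -> tuple[np.ndarray, float]:
    """Intersection polygon of two convex hulls and its area.

    Accepts `Niche`, shapely `Polygon`, or vertex arrays.  Returns the
    intersection's exterior vertices (empty (0, 2) array when disjoint) and
    the area, with sub-sliver areas reported as exactly 0.
    """
    pa, pb = _as_polygon(hull_a), _as_polygon(hull_b)
    inter = shapely.intersection(pa, pb, grid_size=SNAP_GRID)
    area = inter.area
    if area < AREA_EPS:
        return np.empty((0, 2)), 0.0
    verts = np.asarray(inter.exterior.coords)[:-1]
    return verts, float(area)


def proportion_overlapped(focal, others: Sequence) -> float:
    """Fraction of the focal hull's area covered by the union of others."""
    fp = _as_polygon(focal)
    pieces = []
    for o in others:
        piece = shapely.intersection(fp, _as_polygon(o), grid_size=SNAP_GRID)
        if piece.area > AREA_EPS:
            pieces.append(piece)
    if not pieces:
        return 0.0
    prop = unary_union(pieces).area / fp.area
    return float(min(max(prop, 0.0), 1.0))


@dataclass(frozen=True)
class OverlapTables:
    """Pairwise overlaps plus per-species group-wise proportions."""

    pairs: pd.DataFrame  # species_a, species_b, pair_type, overlap_area, overlaps
    groups: pd.DataFrame  # focal_species, status, group, proportion


def overlap_table(niches: Sequence[Niche]) -> OverlapTables:
    """All pairwise overlaps and, per species, the proportion of its niche
    overlapped by migrants, by breeding species, and by all others."""
    if len(niches) < 2:
        raise DataIntegrityError("need at least 2 niches")
    seen = [n.species for n in niches]
    if len(set(seen)) != len(seen):
        raise DataIntegrityError("duplicate species among niches")
    polys = {n.species: _as_polygon(n) for n in niches}
    pair_rows = []
    for a, b in combinations(niches, 2):
        _, area = intersect_convex(polys[a.species], polys[b.species])
        pair_rows.append(
            (a.species, b.species, pair_type(a.status, b.status), area, area > 0)
        )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["species_a", "species_b", "pair_type", "overlap_area", "overlaps"],
    )
    group_rows = []
    for focal in niches:
        others = [n for n in niches if n.species != focal.species]
        by_group = {
            "migrant": [polys[n.species] for n in others if n.status == "migrant"],
            "breeding": [polys[n.species] for n in others if n.status == "breeding"],
            "total": [polys[n.species] for n in others],
        }
        for group, hulls in by_group.items():
            group_rows.append(
                (focal.species, focal.status, group, proportion_overlapped(polys[focal.species], hulls))
            )
    groups = pd.DataFrame(
        group_rows, columns=["focal_species", "status", "group", "proportion"]
    )
    return OverlapTables(pairs=pairs, groups=groups)


def chisq_gof(
    observed: Sequence[float], expected_proportions: Sequence[float] | None = None
) -> tuple[float, int, float]:
    """Pearson chi-square goodness-of-fit test.

    ``expected_proportions`` defaults to equal shares across cells (the
    convention under which the realized-overlap counts by pair type are
    tested); an availability-weighted alternative can be passed explicitly.
    Returns (statistic, df, p).
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be >= 0 with positive total")
    if expected_proportions is None:
        props = np.full(len(obs), 1.0 / len(obs))
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if len(props) != len(obs):
            raise ValueError("length mismatch between observed and proportions")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("expected proportions must sum to 1")
    expected = props * obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell count")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), len(obs) - 1, float(p)
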