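"""Packaged reference data.

`load_warbler_community` returns the published per-species summary for a
30-species SW Michigan spring warbler assemblage (11 locally breeding, 19
migrant species): per-species sampling depth, signaling-niche area in PCA
units, and the maximum proportion of each species' niche overlapped by
migrants, by breeding species, and in total when the whole community is
present.  These printed values serve as inputs for recomputing the
community-level summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

REALIZED_OVERLAP_COUNTS = {
    "migrant-breeding": 46,
    "breeding-breeding": 20,
    "migrant-migrant": 18,
}


def load_warbler_community() -> pd.DataFrame:
    """Per-species community summary table (30 warbler species)."""
    with resources.files("signalniche.data").joinpath("warbler_community.csv").open() as fh:
        return pd.read_csv(fh)


def community_summary(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Recompute the headline community statistics from per-species values.

    Means of niche area (all / breeding / migrant species), mean total
    proportion overlap, breeding-species mean overlap by migrants and by
    other breeders, and counts of species whose niches are >75% overlapped.
    """
    df = load_warbler_community() if table is None else table
    breeding = df[df["status"] == "breeding"]
    migrant = df[df["status"] == "migrant"]
    return {
        "n_species": int(len(df)),
        "n_breeding": int(len(breeding)),
        "n_migrant": int(len(migrant)),
        "mean_niche_area_all": float(df["niche_area"].mean()),
        "mean_niche_area_breeding": float(breeding["niche_area"].mean()),
        "mean_niche_area_migrant": float(migrant["niche_area"].mean()),
        "sd_niche_area_all": float(df["niche_area"].std(ddof=1)),
        "mean_total_overlap": float(df["overlap_total"].mean()),
        "mean_breeding_overlap_by_migrants": float(breeding["overlap_migrant"].mean()),
        "mean_breeding_overlap_by_breeders": float(breeding["overlap_breeding"].mean()),
        "n_breeding_overlap_gt_75pct": int((breeding["overlap_total"] > 0.75).sum()),
        "n_migrant_overlap_gt_75pct": int((migrant["overlap_total"] > 0.75).sum()),
        "total_individuals": int(df["n_individuals"].sum()),
    }
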