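"""End-to-end pipeline: inputs -> signal space -> overlap -> phenology ->
dynamics -> null model -> phylogenetic signal, with CSV outputs and a
reproducibility manifest.

Configuration is a plain dict (typically loaded from YAML).  Either real
inputs (trait CSV, checklist CSV, Newick tree) or a seeded synthetic
community may be supplied; every convention in effect (thresholds, SD and
centroid conventions, GLM degree and weights, seeds) is echoed into the
manifest so a run is reproducible from it alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, PipelineStageError
from . import dynamics, nullmodel, overlap, phenology, phylo, synthetic, trait_space


@dataclass
class PipelineConfig:
    """Validated pipeline settings with the package's default conventions."""

    out_dir: str = "signalniche_out"
    seed: int = 0
    # inputs: either paths ...
    traits_csv: str | None = None
    checklists_csv: str | None = None
    tree_newick: str | None = None
    # ... or a synthetic community
    synthetic: dict | None = None
    # analysis settings
    window_start: int = 96
    window_end: int = 158
    window_width: int = 3
    presence_threshold: float = 1.5
    date_window: tuple[int, int] = phenology.DEFAULT_DATE_WINDOW
    eigenvalue_threshold: float = 1.0
    null_reps: int = 10_000
    null_sd: str = "sample"
    null_centroid: str = "points"
    glm_degree: int = 3
    binomial_weight: float = 100.0
    pairwise_null: bool = True

    def __post_init__(self):
        if self.window_width < 1 or (self.window_end - self.window_start + 1) % self.window_width:
            raise ConfigError("window range must divide into whole windows")
        if self.null_sd not in ("sample", "population"):
            raise ConfigError("null_sd must be sample|population")
        if self.null_centroid not in ("points", "hull"):
            raise ConfigError("null_centroid must be points|hull")
        if self.glm_degree not in (1, 2, 3):
            raise ConfigError("glm_degree must be 1, 2 or 3")
        if not (self.presence_threshold >= 0):
            raise ConfigError("presence_threshold must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig):
    if cfg.traits_csv is not None:
        traits = pd.read_csv(cfg.traits_csv)
        checklists = pd.read_csv(cfg.checklists_csv) if cfg.checklists_csv else None
        newick = Path(cfg.tree_newick).read_text() if cfg.tree_newick else None
        return traits, checklists, newick
    syn = dict(cfg.synthetic or {})
    n_migrants = int(syn.get("n_migrants", 19))
    n_breeders = int(syn.get("n_breeders", 11))
    n_per_day = int(syn.get("checklists_per_day", 30))
    day_range = tuple(syn.get("day_range", (92, 167)))
    profiles = synthetic.default_community(
        seed=cfg.seed, n_migrants=n_migrants, n_breeders=n_breeders,
        detectability_scale=float(syn.get("detectability_scale", 1.0)),
    )
    traits = synthetic.simulate_traits(profiles, seed=cfg.seed + 1)
    checklists = synthetic.simulate_checklists(
        profiles, n_per_day=n_per_day, day_range=day_range, seed=cfg.seed + 2,
        violation_fraction=float(syn.get("violation_fraction", 0.05)),
    )
    newick = synthetic.simulate_tree([p.code for p in profiles], seed=cfg.seed + 3)
    return traits, checklists, newick


def run_pipeline(config: PipelineConfig | dict) -> dict[str, Any]:
    """Run every stage in order and write CSV outputs plus a manifest.

    Returns a result bundle (in-memory objects keyed by stage).  Any stage
    failure is re-raised as a `PipelineStageError` naming the stage.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {"config": cfg}
    notes: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tagged and re-raised
                raise PipelineStageError(name, exc) from exc

        return wrap

    traits, checklists, newick = stage("load_inputs")(lambda: _load_inputs(cfg))

    # trait space
    def _space():
        means = trait_space.per_male_means(traits)
        space = trait_space.build_signal_space(means, cfg.eigenvalue_threshold)
        niches = trait_space.build_niches(space)
        area = trait_space.community_area(space)
        reg = trait_space.sample_size_regression(niches)
        return means, space, niches, area, reg

    means, space, niches, comm_area, size_reg = stage("trait_space")(_space)
    results.update(means=means, space=space, niches=niches, community_area=comm_area,
                   sample_size_regression=size_reg)
    statuses = {n.species: n.status for n in niches}

    # overlap geometry
    tables = stage("overlap_geometry")(lambda: overlap.overlap_table(niches))
    pair_counts = overlap.classify_pairs(statuses)
    realized = tables.pairs.groupby("pair_type")["overlaps"].sum().astype(int).to_dict()
    obs_counts = [realized.get(t, 0) for t in overlap.PAIR_TYPES]
    chisq = overlap.chisq_gof(obs_counts) if sum(obs_counts) > 0 else (float("nan"), 2, float("nan"))
    results.update(overlap_tables=tables, pair_counts=pair_counts,
                   realized_overlaps=realized, chisq_gof=chisq)

    # phenology
    def _phenology():
        filtered, tally = phenology.filter_checklists(checklists, cfg.date_window)
        occ = phenology.occurrence_matrix(filtered, species=sorted(statuses))
        window_means, windows = phenology.window_average(
            occ, cfg.window_start, cfg.window_end, cfg.window_width
        )
        snaps = phenology.reconstruct_communities(
            window_means, windows, statuses, cfg.presence_threshold
        )
        return filtered, tally, occ, window_means, windows, snaps

    filtered, tally, occ, window_means, windows, snaps = stage("phenology")(_phenology)
    results.update(filter_tally=tally, occurrence=occ, window_means=window_means,
                   windows=windows, snapshots=snaps)
    if all(len(s.present_species) == 0 for s in snaps):
        notes.append("all community snapshots empty at the configured presence threshold")

    # temporal dynamics
    def _dynamics():
        wo = dynamics.window_overlaps(snaps, niches, pair_table=tables.pairs)
        fits = {}
        if wo.counts["n_overlaps"].sum() > 0:
            fits["poisson"] = dynamics.fit_poisson_glm(wo.counts, degree=cfg.glm_degree)
        else:
            notes.append("no realized overlaps in any window; Poisson GLM skipped")
        nonzero_props = len(wo.proportions) > 0 and wo.proportions["proportion"].gt(0).any()
        if nonzero_props and wo.proportions["window_index"].nunique() > 3:
            fits["binomial"] = dynamics.fit_binomial_glm(
                wo.proportions, degree=cfg.glm_degree, weight=cfg.binomial_weight
            )
        else:
            notes.append("insufficient nonzero proportions; binomial GLM skipped")
        ttest = None
        if snaps and any(len(s.present_species) for s in snaps):
            peak = dynamics.choose_peak_window(snaps, seed=cfg.seed)
            props = wo.proportions[wo.proportions["window_index"] == peak]
            wide = props.pivot(index="species", columns="overlap_type", values="proportion")
            if len(wide) >= 2 and {"migrant", "breeding"} <= set(wide.columns):
                ttest = dynamics.paired_t_test(wide["migrant"], wide["breeding"]) + (peak,)
        return wo, fits, ttest

    wo, glm_fits, peak_ttest = stage("temporal_dynamics")(_dynamics)
    results.update(window_overlaps=wo, glm_fits=glm_fits, peak_ttest=peak_ttest)

    # null model
    def _null():
        ranges = nullmodel.observed_axis_ranges(space.scores)
        comm = nullmodel.community_dispersion(
            niches, ranges, n_reps=cfg.null_reps, seed=cfg.seed,
            centroid=cfg.null_centroid, sd=cfg.null_sd,
        )
        pairs_df, summary = (None, None)
        if cfg.pairwise_null:
            pairs_df, summary = nullmodel.pairwise_dispersion(
                niches, ranges, n_reps=cfg.null_reps, seed=cfg.seed, sd=cfg.null_sd
            )
        return ranges, comm, pairs_df, summary

    ranges, comm_disp, pair_disp, disp_summary = stage("null_model")(_null)
    results.update(axis_ranges=ranges, community_dispersion=comm_disp,
                   pairwise_dispersion=pair_disp, dispersion_summary=disp_summary)

    # phylogenetic signal
    def _phylo():
        if newick is None:
            notes.append("no tree supplied; phylogenetic stage skipped")
            return None, None, None
        pat = phylo.patristic_distances(newick)
        rec = phylo.pair_distance_table(pat, niches)
        fit = phylo.fit_interaction_ols(rec)
        return pat, rec, fit

    patristic, pair_records, phylo_fit = stage("phylo_signal")(_phylo)
    results.update(patristic=patristic, pair_records=pair_records, phylo_fit=phylo_fit)

    # outputs
    written = stage("write_outputs")(
        lambda: _write_outputs(out, cfg, results, notes)
    )
    results["manifest"] = written
    results["notes"] = notes
    return results


def _niche_frame(niches) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (n.species, n.status, n.n_individuals, n.area, n.centroid[0], n.centroid[1])
            for n in niches
        ],
        columns=["species", "status", "n", "area", "centroid_x", "centroid_y"],
    )


def _write_outputs(out: Path, cfg: PipelineConfig, results: dict, notes: list[str]) -> dict:
    files: dict[str, pd.DataFrame] = {
        "male_means.csv": results["means"],
        "scores.csv": results["space"].scores,
        "niches.csv": _niche_frame(results["niches"]),
        "pair_overlaps.csv": results["overlap_tables"].pairs,
        "group_overlaps.csv": results["overlap_tables"].groups,
        "occurrence.csv": results["occurrence"].reset_index(),
        "window_means.csv": results["window_means"].reset_index(),
        "window_counts.csv": results["window_overlaps"].counts,
        "window_proportions.csv": results["window_overlaps"].proportions,
    }
    snaps = results["snapshots"]
    files["snapshots.csv"] = pd.DataFrame(
        [
            (s.window_index, s.window_days[0], s.window_days[1],
             ";".join(sorted(s.present_species)), s.n_migrants, s.n_breeders)
            for s in snaps
        ],
        columns=["window_index", "start_day", "end_day", "present_species", "n_migrants", "n_breeders"],
    )
    comm = results["community_dispersion"]
    files["nullmodel_community.csv"] = pd.DataFrame(
        [
            {
                "observed_mean_distance": comm.observed_mean_distance,
                "null_mean": comm.null_mean,
                "null_sd": comm.null_sd,
                "z": comm.z,
                "p_empirical": comm.p_empirical,
                "n_replicates": comm.n_replicates,
                "classification": comm.classification,
            }
        ]
    )
    if results.get("pairwise_dispersion") is not None:
        files["nullmodel_pairs.csv"] = results["pairwise_dispersion"]
    if results.get("pair_records") is not None:
        files["phylo_pairs.csv"] = results["pair_records"]
    model_rows = []
    for name, fit in results.get("glm_fits", {}).items():
        for param, value in fit.params.items():
            model_rows.append((name, fit.degree, param, value, fit.bse[param], fit.pvalues[param],
                               fit.aic, fit.dispersion))
    if results.get("phylo_fit") is not None and len(results["phylo_fit"].params):
        pf = results["phylo_fit"]
        for param, value in pf.params.items():
            model_rows.append(("phylo_ols", 1, param, value, float("nan"), float("nan"),
                               float("nan"), float("nan")))
    files["model_coefficients.csv"] = pd.DataFrame(
        model_rows,
        columns=["model", "degree", "term", "estimate", "se", "p", "aic", "dispersion"],
    )
    checksums = {}
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        checksums[name] = _sha256(path)
    manifest = {
        "package": "signalniche",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg.seed,
        "settings": {
            "window": [cfg.window_start, cfg.window_end, cfg.window_width],
            "presence_threshold": cfg.presence_threshold,
            "date_window": list(cfg.date_window),
            "eigenvalue_threshold": cfg.eigenvalue_threshold,
            "null_reps": cfg.null_reps,
            "null_sd": cfg.null_sd,
            "null_centroid": cfg.null_centroid,
            "glm_degree": cfg.glm_degree,
            "binomial_weight": cfg.binomial_weight,
            "binomial_model": "fixed-effects GLM (no species random effect)",
            "gof_expected": "equal proportions across pair types",
            "community_area_method": "hull of all points",
            "area_epsilon": overlap.AREA_EPS,
            "snap_grid": overlap.SNAP_GRID,
        },
        "pair_counts": results["pair_counts"],
        "notes": notes,
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
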