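"""End-to-end orchestration: occurrences -> niche -> suitability -> HOF ->
predicted limits -> equilibrium classes -> comparative statistics.

The pipeline is pure table-in / table-out: the background, per-species
occurrences and regional points arrive as DataFrames (or CSV paths) that
already carry climate columns, and every intermediate artifact is written
as delimited text together with a JSON manifest of seeds and parameters, so
a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import envniche, hof, predict, suitability
from .io import PipelineConfig, read_occurrences, read_plots

logger = logging.getLogger(__name__)


def species_prediction(pca: envniche.PCASpace, background_scores: np.ndarray,
                       occurrences: pd.DataFrame, regional: pd.DataFrame,
                       config: PipelineConfig, species: str,
                       seed: int) -> tuple[predict.PredictedUEL, pd.DataFrame] | None:
    """Steps 2-4 for one species; None when the species is skipped."""
    try:
        occ_scores = envniche.project(pca, occurrences)
        grid = envniche.build_grid(pca, background_scores, occ_scores,
                                   resolution=config.grid_resolution,
                                   min_occurrences=config.hof_min_presences)
    except envniche.SpeciesSkipped as exc:
        logger.warning("%s skipped at niche stage: %s", species, exc)
        return None
    niche = envniche.delineate_niche(grid, level=config.niche_level,
                                    background_corrected=config.density_correction)
    reg_scores = envniche.project(pca, regional)
    table = suitability.build_suitability_table(niche, grid, reg_scores, regional)
    elev, y_obs, flags = suitability.make_pa_series(table)
    if flags:
        logger.warning("%s: degenerate suitability series %s; skipped",
                       species, sorted(flags))
        return None
    try:
        pred = predict.resample_ob(elev, y_obs, species=species,
                                   frac=config.resample_frac,
                                   n_reps=config.resample_reps, seed=seed,
                                   n_starts=config.hof_n_starts,
                                   min_presences=config.hof_min_presences)
    except hof.UnfittableSeries as exc:
        logger.warning("%s unfittable: %s", species, exc)
        return None
    return pred, table


def run_pipeline(config: PipelineConfig,
                 background: pd.DataFrame | None = None,
                 occurrences: pd.DataFrame | None = None,
                 regional: pd.DataFrame | None = None,
                 plots: pd.DataFrame | None = None,
                 traits: pd.DataFrame | None = None,
                 write: bool = True) -> dict:
    """Run the full workflow and return a results bundle.

    Inputs not passed as DataFrames are loaded from the paths in ``config``.
    The bundle maps stage names to tables: ``suitability`` (per species),
    ``results`` (per-species predicted vs observed), ``summary`` (class
    proportions) and, when a two-epoch plot table is available, ``change``
    and ``wilcoxon``. Failures in one species never abort the rest; the
    manifest records what was skipped.
    """
    from . import stats as stats_mod

    if occurrences is None:
        occurrences = read_occurrences(config.occurrences_path,
                                       config.uncertainty_max_m)
    else:
        keep = occurrences["coordinate_uncertainty_m"] < config.uncertainty_max_m
        occurrences = occurrences.loc[keep].reset_index(drop=True)
    if background is None:
        background = pd.read_csv(config.background_path)
    if regional is None:
        raise ValueError("regional point table is required")
    uel = None
    if plots is None and config.plots_path:
        plots, uel = read_plots(config.plots_path)
    elif plots is not None:
        present = plots[plots["present"] == 1]
        uel = (present.groupby(["species", "year"], as_index=False)
               .agg(observed_uel=("plot_elevation", "max")))

    pca = envniche.fit_pca(background)
    bg_scores = envniche.project(pca, background)

    manifest = {"seed": config.seed, "species": {}, "parameters": {
        "niche_level": config.niche_level, "grid_resolution": config.grid_resolution,
        "resample_frac": config.resample_frac, "resample_reps": config.resample_reps,
        "uncertainty_max_m": config.uncertainty_max_m,
    }}
    results, suit_tables = [], {}
    species_list = sorted(occurrences["species"].unique())
    rng = np.random.default_rng(config.seed)
    for species in species_list:
        sp_seed = int(rng.integers(2**31 - 1))
        manifest["species"][species] = {"seed": sp_seed}
        occ_sp = occurrences[occurrences["species"] == species]
        out = species_prediction(pca, bg_scores, occ_sp, regional, config,
                                 species, sp_seed)
        if out is None:
            manifest["species"][species]["status"] = "skipped"
            continue
        pred, table = out
        suit_tables[species] = table
        if uel is not None:
            sp_uel = uel[uel["species"] == species].dropna(subset=["observed_uel"])
            if sp_uel.empty:
                manifest["species"][species]["status"] = "no observed UEL"
                continue
            last_year = sp_uel["year"].max()
            observed = float(sp_uel.loc[sp_uel["year"] == last_year,
                                        "observed_uel"].iloc[0])
        else:
            manifest["species"][species]["status"] = "no survey"
            continue
        results.append(predict.classify_equilibrium(observed, pred))
        manifest["species"][species]["status"] = "ok"

    bundle = {"pca": pca, "suitability": suit_tables, "manifest": manifest}
    if results:
        bundle["results"] = predict.results_table(results)
        bundle["summary"] = predict.cohort_summary(results)
        usable = bundle["results"].dropna(subset=["uel_predicted"])
        if len(usable) >= 3 and usable["uel_predicted"].nunique() > 1:
            bundle["regression"] = stats_mod.regress_obs_pred(
                usable["uel_observed"], usable["uel_predicted"])
    if uel is not None:
        years = sorted(y for y in uel["year"].unique())
        if len(years) >= 2:
            change = stats_mod.change_summary(uel, years[0], years[-1],
                                              config.stability_threshold)
            if len(change) >= 3:
                a = change[f"uel_{years[0]}"].to_numpy()
                b = change[f"uel_{years[-1]}"].to_numpy()
                w, p = stats_mod.wilcoxon_uel(a, b, paired=config.paired_wilcoxon)
                bundle["wilcoxon"] = {"W": w, "p": p,
                                      "paired": config.paired_wilcoxon}
            bundle["change"] = change
    if traits is not None and results:
        merged = bundle["results"].merge(traits, on="species")
        merged = merged.dropna(subset=["delta_std"])
        if len(merged) > 6:
            try:
                bundle["trait_anova"] = stats_mod.trait_model(
                    merged["delta_std"], merged)
            except ValueError as exc:
                logger.warning("trait model skipped: %s", exc)

    if write:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for species, table in bundle["suitability"].items():
        table.to_csv(out / f"suitability_{species}.csv", index=False)
    for key in ("results", "summary", "change"):
        if key in bundle:
            bundle[key].to_csv(out / f"{key}.csv", index=False)
    if "trait_anova" in bundle:
        bundle["trait_anova"].to_csv(out / "trait_anova.csv")
    scalars = {}
    if "wilcoxon" in bundle:
        scalars["wilcoxon"] = bundle["wilcoxon"]
    if "regression" in bundle:
        r = bundle["regression"]
        scalars["regression"] = {
            "n": r.n, "slope": r.slope, "intercept": r.intercept,
            "se_slope": r.se_slope, "r2": r.r2, "t_corr": r.t_corr,
            "p_corr": r.p_corr, "t_slope1": r.t_slope1, "p_slope1": r.p_slope1,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump({"manifest": bundle["manifest"], "stats": scalars}, fh,
                  indent=2, sort_keys=True)
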