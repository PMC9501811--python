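"""Readers, configuration and validation for the pipeline's table formats.

All tables are comma-delimited text with a header. Occurrence tables carry
``species, lon, lat, coordinate_uncertainty_m`` (plus optional pre-extracted
climate columns); plot tables carry ``road, year, plot_elevation, species,
present``. Climate always arrives as pre-extracted columns — there is no
raster I/O in this package.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ("species", "lon", "lat", "coordinate_uncertainty_m")
PLOT_COLUMNS = ("road", "year", "plot_elevation", "species", "present")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, validated at load time."""

    occurrences_path: str | None = None
    background_path: str | None = None
    plots_path: str | None = None
    output_dir: str = "uelshift_out"
    uncertainty_max_m: float = 1000.0
    niche_level: float = 0.99
    grid_resolution: int = 100
    hof_min_presences: int = 5
    hof_n_starts: int = 10
    resample_frac: float = 0.25
    resample_reps: int = 100
    seed: int = 0
    paired_wilcoxon: bool = False
    density_correction: bool = False
    stability_threshold: float = 0.0

    def __post_init__(self):
        if self.uncertainty_max_m <= 0:
            raise ValueError("uncertainty_max_m must be positive")
        if not 0.0 < self.niche_level <= 1.0:
            raise ValueError("niche_level must be in (0, 1]")
        if self.grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")
        if not 0.0 < self.resample_frac <= 1.0:
            raise ValueError("resample_frac must be in (0, 1]")
        if self.resample_reps < 1 or self.hof_n_starts < 1:
            raise ValueError("resample_reps and hof_n_starts must be >= 1")
        if self.hof_min_presences < 1:
            raise ValueError("hof_min_presences must be >= 1")
        if self.stability_threshold < 0:
            raise ValueError("stability_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_occurrences(path: str | Path, uncertainty_max_m: float = 1000.0) -> pd.DataFrame:
    """Read and filter an occurrence table.

    Rows are dropped when the coordinate uncertainty is not strictly below
    ``uncertainty_max_m`` (the 1 km filter is strict), when coordinates are
    missing, or when they fall outside [-180, 180] x [-90, 90]; retained
    counts are logged per species.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table lacks column(s): {missing}")
    n0 = len(table)
    ok_coord = (table["lon"].between(-180, 180) & table["lat"].between(-90, 90)
                & table["lon"].notna() & table["lat"].notna())
    bad = table.loc[~ok_coord]
    for _, row in bad.iterrows():
        logger.warning("row rejected: coordinates out of range (%s, %s)",
                       row["lon"], row["lat"])
    ok_unc = table["coordinate_uncertainty_m"] < uncertainty_max_m
    table = table.loc[ok_coord & ok_unc].reset_index(drop=True)
    for sp, n in table.groupby("species").size().items():
        logger.info("%s: %d of %d occurrences retained", sp, n, n0)
    for sp in set(bad["species"]) - set(table["species"]):
        logger.warning("%s: zero occurrences after filtering; skipped", sp)
    return table


def read_plots(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a survey plot table; return (plots, per-species UEL per year).

    The observed UEL of a species in a year is the maximum elevation of any
    plot where it is present, pooled across roads (the two roads overlap in
    elevation; a single per-species maximum is the documented rule).
    Duplicate rows are dropped with a warning. A species absent in a year
    gets a missing UEL for that year.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plot table lacks column(s): {missing}")
    n0 = len(table)
    table = table.drop_duplicates().reset_index(drop=True)
    if len(table) < n0:
        logger.warning("dropped %d duplicated plot rows", n0 - len(table))
    present = table[table["present"] == 1]
    uel = (present.groupby(["species", "year"], as_index=False)
           .agg(observed_uel=("plot_elevation", "max")))
    years = sorted(table["year"].unique())
    full = pd.MultiIndex.from_product(
        [sorted(table["species"].unique()), years], names=["species", "year"])
    uel = uel.set_index(["species", "year"]).reindex(full).reset_index()
    return table, uel
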