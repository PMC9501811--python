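"""Intersect the global niche with the regional environmental space.

Each regional point is mapped to its enclosing cell of the environmental
grid and labelled zone A (climatically suitable: the cell belongs to the
niche region) or zone B (unsuitable). Points falling outside the grid
ranges lie outside the global environmental envelope and are therefore
unsuitable by definition. Attaching elevations to the labelled points gives
the presence/absence-along-elevation series that the response-curve stage
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envniche import EnvGrid, NicheRegion


@dataclass(frozen=True)
class DemGrid:
    """A minimal digital elevation model: a regular grid of elevations with
    geographic bounds, sampled by nearest cell (no interpolation)."""

    values: np.ndarray          # (ny, nx), row 0 = ymax (north-up)
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        outside = ((x < self.x_min) | (x > self.x_max)
                   | (y < self.y_min) | (y > self.y_max))
        if outside.any():
            ids = np.flatnonzero(outside)
            raise ValueError(f"points outside DEM extent: ids {ids[:10].tolist()}")
        ny, nx = self.values.shape
        col = np.clip(((x - self.x_min) / (self.x_max - self.x_min) * nx).astype(int),
                      0, nx - 1)
        row = np.clip(((self.y_max - y) / (self.y_max - self.y_min) * ny).astype(int),
                      0, ny - 1)
        return self.values[row, col]


def classify_points(niche: NicheRegion, grid: EnvGrid,
                    regional_scores: np.ndarray) -> np.ndarray:
    """Label regional environmental-space points 'A' or 'B'.

    A point is zone A iff its enclosing grid cell is in the niche mask;
    points outside the grid ranges are zone B.
    """
    scores = np.atleast_2d(np.asarray(regional_scores, dtype=float))
    if scores.shape[0] == 0:
        raise ValueError("empty regional point set")
    ix = np.searchsorted(grid.x_edges, scores[:, 0], side="right") - 1
    iy = np.searchsorted(grid.y_edges, scores[:, 1], side="right") - 1
    r = grid.resolution
    in_range = (ix >= 0) & (ix < r) & (iy >= 0) & (iy < r)
    # points exactly on the top edge belong to the last cell
    on_x_top = scores[:, 0] == grid.x_edges[-1]
    on_y_top = scores[:, 1] == grid.y_edges[-1]
    ix = np.where(on_x_top, r - 1, ix)
    iy = np.where(on_y_top, r - 1, iy)
    in_range |= (on_x_top & (iy >= 0) & (iy < r)) | (on_y_top & (ix >= 0) & (ix < r))

    zones = np.full(scores.shape[0], "B", dtype="<U1")
    ok = in_range
    zones[ok] = np.where(niche.mask[ix[ok], iy[ok]], "A", "B")
    return zones


def attach_elevation(points: pd.DataFrame, dem: DemGrid | None = None,
                     x_col: str = "lon", y_col: str = "lat") -> pd.DataFrame:
    """Attach an ``elevation`` column to labelled regional points.

    Synthetic regions that already carry elevations bypass the DEM; real
    points are sampled from ``dem`` at their coordinates (nearest cell).
    """
    out = points.copy()
    if "elevation" in out.columns and dem is None:
        return out
    if dem is None:
        raise ValueError("points lack an elevation column and no DEM was given")
    out["elevation"] = dem.sample(out[x_col].to_numpy(), out[y_col].to_numpy())
    return out


def build_suitability_table(niche: NicheRegion, grid: EnvGrid,
                            regional_scores: np.ndarray,
                            regional_points: pd.DataFrame,
                            dem: DemGrid | None = None) -> pd.DataFrame:
    """Full labelled table: id, axis scores, zone, elevation."""
    zones = classify_points(niche, grid, regional_scores)
    scores = np.atleast_2d(np.asarray(regional_scores, dtype=float))
    table = attach_elevation(regional_points, dem)
    out = pd.DataFrame({
        "id": table["point_id"].to_numpy() if "point_id" in table.columns
        else np.arange(len(table)),
        "pc1": scores[:, 0],
        "pc2": scores[:, 1],
        "zone": zones,
        "elevation": table["elevation"].to_numpy(dtype=float),
    })
    return out


def make_pa_series(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, dict]:
    """Convert a suitability table to (elevation, presence-indicator) series.

    Zone A maps to 1, zone B to 0; the series is sorted by elevation. The
    returned flags dict records degenerate contrasts (all suitable / all
    unsuitable), which downstream response-curve fitting cannot resolve.
    """
    if len(table) == 0:
        raise ValueError("empty suitability table")
    order = np.argsort(table["elevation"].to_numpy(), kind="stable")
    elev = table["elevation"].to_numpy(dtype=float)[order]
    y = (table["zone"].to_numpy() == "A")[order].astype(int)
    flags = {}
    if y.all():
        flags["no_upper_contrast"] = True
    if not y.any():
        flags["no_presences"] = True
    return elev, y, flags
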