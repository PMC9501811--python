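"""Synthetic worlds, species and surveys with known true range limits.

The generator mimics the statistical structure the niche/limit analysis
assumes: a global background of points whose climate variables are noisy
linear mixtures of a few latent gradients (so they are strongly collinear,
like bioclim layers), a mountain-road region whose temperature-like latent
falls linearly with elevation at a fixed adiabatic lapse rate, species with
Gaussian niches in latent space (hence an analytically known upper
elevational limit), and noisy two-epoch roadside presence surveys.

Because the elevation-to-climate map is deterministic by default, the
highest climatically suitable elevation of a species — its true upper
elevational limit (UEL) — has a closed form, and every downstream stage
(niche delineation, suitability classification, response-curve fitting,
resampling CIs) can be checked against it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: chi-square quantile defining the niche ellipsoid: a point belongs to the
#: niche if its squared standardized distance from the niche centre is below
#: the 99% quantile, mirroring the 99% density surface used downstream.
NICHE_LEVEL = 0.99

LATENT_COLUMNS = ("latent_temp", "latent_moisture", "latent_season")
DISPERSAL_MODES = ("wind", "animal", "non-assisted")
LIFE_SPANS = ("annual", "biennial", "perennial")


def _default_loadings(n_vars: int, latent_dim: int) -> np.ndarray:
    """Deterministic latent-to-variable loading matrix.

    Variable 0 is a pure copy of the first (temperature-like) latent so the
    lapse-rate contract is visible in a named column; the remaining
    variables mix the latents with smoothly varying weights, giving the
    strong collinearity typical of bioclim layers.
    """
    load = np.zeros((n_vars, latent_dim))
    load[0, 0] = 1.0
    for i in range(1, n_vars):
        for j in range(latent_dim):
            load[i, j] = np.cos(0.5 * i + 2.1 * j) + 0.3 * np.sin(1.3 * i * (j + 1))
    return load


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic global background."""

    n_background: int = 10_000
    n_climate_vars: int = 19
    latent_dim: int = 3
    loading_matrix: np.ndarray | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_background <= 0:
            raise ValueError("n_background must be positive")
        if not (self.n_climate_vars >= self.latent_dim >= 1):
            raise ValueError("need n_climate_vars >= latent_dim >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def loadings(self) -> np.ndarray:
        if self.loading_matrix is not None:
            mat = np.asarray(self.loading_matrix, dtype=float)
            if mat.shape != (self.n_climate_vars, self.latent_dim):
                raise ValueError("loading_matrix shape mismatch")
            return mat
        return _default_loadings(self.n_climate_vars, self.latent_dim)

    @property
    def climate_columns(self) -> list[str]:
        return [f"bio{i + 1}" for i in range(self.n_climate_vars)]


@dataclass(frozen=True)
class RegionConfig:
    """A mountain-road region: an elevation gradient coupled to climate.

    Temperature (the first latent) decreases from ``base_temp`` at
    ``elev_min`` by ``lapse_rate`` degrees C per km of elevation gain; the
    other latents are held at the regional mean (0). The defaults span the
    1900-3600 m road and the ~6.1 degC/km adiabatic lapse rate of a
    Mediterranean-Andean study region.
    """

    elev_min: float = 1900.0
    elev_max: float = 3600.0
    elev_step: float | None = None
    lapse_rate: float = 6.1  # degC per km
    base_temp: float = 7.1  # degC at elev_min
    n_points: int = 2000
    microclimate_sd: float = 0.0

    def __post_init__(self):
        if not self.elev_min < self.elev_max:
            raise ValueError("empty elevation span: elev_min must be < elev_max")
        if self.lapse_rate < 0:
            raise ValueError("lapse_rate must be non-negative")
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")

    def temperature_at(self, elevation) -> np.ndarray:
        """Temperature-like latent at an elevation (deterministic part)."""
        elevation = np.asarray(elevation, dtype=float)
        return self.base_temp - self.lapse_rate * (elevation - self.elev_min) / 1000.0

    def elevation_at(self, temperature: float) -> float:
        """Inverse of :meth:`temperature_at`; requires lapse_rate > 0."""
        if self.lapse_rate <= 0:
            raise ValueError("elevation_at undefined for zero lapse rate")
        return self.elev_min + (self.base_temp - temperature) / self.lapse_rate * 1000.0

    def elevation_levels(self) -> np.ndarray:
        if self.elev_step is None:
            return np.array([])
        return np.arange(self.elev_min, self.elev_max + 1e-9, self.elev_step)


@dataclass(frozen=True)
class SyntheticSpecies:
    """A species with a Gaussian niche in latent climate space.

    ``dispersal_deficit`` is the number of metres its realized (survey)
    upper limit sits below the climatic limit: 0 means climatic equilibrium.
    """

    name: str
    niche_center: tuple[float, ...]
    niche_sd: tuple[float, ...]
    detection_prob: float = 1.0
    dispersal_deficit: float = 0.0

    def __post_init__(self):
        if any(s <= 0 for s in self.niche_sd):
            raise ValueError("niche_sd must be positive component-wise")
        if len(self.niche_center) != len(self.niche_sd):
            raise ValueError("niche_center and niche_sd lengths differ")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")

    def mahalanobis_sq(self, latents: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(latents, dtype=float))
        c = np.asarray(self.niche_center, dtype=float)
        s = np.asarray(self.niche_sd, dtype=float)
        return np.sum(((z - c) / s) ** 2, axis=1)

    def suitability(self, latents: np.ndarray) -> np.ndarray:
        """Unnormalized Gaussian suitability in (0, 1], 1 at the centre."""
        return np.exp(-0.5 * self.mahalanobis_sq(latents))


def _latent_columns(dim: int) -> list[str]:
    return list(LATENT_COLUMNS[:dim]) + [f"latent_{i}" for i in range(3, dim)]


def make_world(config: WorldConfig) -> pd.DataFrame:
    """Generate the global background sample.

    Latents are tied to synthetic geography: the temperature latent falls
    with |latitude|, the moisture latent varies sinusoidally with longitude,
    further latents are free. Climate = loadings @ latents + Gaussian noise.

    Returns a DataFrame with lon, lat, the latent columns, and one column
    per climate variable.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_background
    lon = rng.uniform(-180.0, 180.0, n)
    lat = rng.uniform(-60.0, 75.0, n)

    latents = np.zeros((n, config.latent_dim))
    latents[:, 0] = 28.0 - 0.55 * np.abs(lat) + rng.normal(0.0, 3.0, n)
    if config.latent_dim >= 2:
        latents[:, 1] = 4.0 * np.sin(np.radians(lon)) + rng.normal(0.0, 2.0, n)
    for j in range(2, config.latent_dim):
        latents[:, j] = rng.normal(0.0, 2.0, n)

    climate = latents @ config.loadings.T
    if config.noise_sd > 0:
        climate = climate + rng.normal(0.0, config.noise_sd, climate.shape)

    out = pd.DataFrame({"lon": lon, "lat": lat})
    for j, col in enumerate(_latent_columns(config.latent_dim)):
        out[col] = latents[:, j]
    for j, col in enumerate(config.climate_columns):
        out[col] = climate[:, j]
    return out


def region_latents(region: RegionConfig, elevations: np.ndarray, latent_dim: int,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Latent climate at regional elevations: temperature from the lapse
    rate, other latents at the regional mean (0), plus optional
    microclimate noise on the temperature latent."""
    elevations = np.asarray(elevations, dtype=float)
    z = np.zeros((elevations.size, latent_dim))
    z[:, 0] = region.temperature_at(elevations)
    if region.microclimate_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        z[:, 0] += rng.normal(0.0, region.microclimate_sd, elevations.size)
    return z


def make_region(region: RegionConfig, world: WorldConfig,
                seed: int | None = None) -> pd.DataFrame:
    """Generate the regional environmental sample along the road gradient.

    If ``elev_step`` is set, points sit on the regular elevation levels
    (cycled to fill ``n_points``); otherwise elevations are drawn uniformly
    over the span. Climate is the noiseless image of the latents under the
    world's loading matrix, so elevation -> climate is deterministic unless
    ``microclimate_sd`` > 0.
    """
    rng = np.random.default_rng(world.seed + 1 if seed is None else seed)
    levels = region.elevation_levels()
    if levels.size:
        reps = int(np.ceil(region.n_points / levels.size))
        elev = np.tile(levels, reps)[: region.n_points]
    else:
        elev = np.sort(rng.uniform(region.elev_min, region.elev_max, region.n_points))

    z = region_latents(region, elev, world.latent_dim,
                       rng if region.microclimate_sd > 0 else None)
    climate = z @ world.loadings.T

    out = pd.DataFrame({"point_id": np.arange(elev.size), "elevation": elev})
    for j, col in enumerate(_latent_columns(world.latent_dim)):
        out[col] = z[:, j]
    for j, col in enumerate(world.climate_columns):
        out[col] = climate[:, j]
    return out


def sample_occurrences(species: SyntheticSpecies, background: pd.DataFrame,
                       n: int, seed: int = 0,
                       latent_dim: int | None = None) -> pd.DataFrame:
    """Draw global occurrence records for a species from the background.

    Each background point is accepted independently with probability equal
    to the species' Gaussian suitability at its latent position; if more
    than ``n`` points are accepted, ``n`` are kept at random. If fewer are
    achievable a warning is emitted and all accepted points are returned —
    never silently padded.

    Records carry a lognormal ``coordinate_uncertainty_m`` column (median
    300 m) so the <1 km coordinate-error filter has something to remove.
    """
    rng = np.random.default_rng(seed)
    if latent_dim is None:
        latent_dim = len(species.niche_center)
    cols = _latent_columns(latent_dim)
    z = background[cols].to_numpy()
    p = species.suitability(z)
    accepted = np.flatnonzero(rng.uniform(size=len(background)) < p)
    if accepted.size > n:
        accepted = np.sort(rng.choice(accepted, size=n, replace=False))
    elif accepted.size < n:
        warnings.warn(
            f"{species.name}: only {accepted.size} of {n} requested occurrences "
            "achievable under the niche suitability", stacklevel=2)
    occ = background.iloc[accepted].copy()
    occ.insert(0, "species", species.name)
    occ["coordinate_uncertainty_m"] = rng.lognormal(np.log(300.0), 1.0, accepted.size)
    return occ.reset_index(drop=True)


def true_uel(species: SyntheticSpecies, region: RegionConfig,
             level: float = NICHE_LEVEL) -> tuple[float | None, str]:
    """Analytic upper elevational limit of the species' climatic niche.

    The niche is the ``level`` (default 99%) quantile ellipsoid of the
    species' latent Gaussian. Along the road only the temperature latent
    varies, so suitability along elevation reduces to a closed-form
    interval in temperature, inverted through the lapse rate.

    Returns ``(elevation, flag)`` with flag in {"ok", "absent",
    "unbounded_above"}; elevation is None when the niche excludes the whole
    region, and equals ``elev_max`` when the niche still contains the top.
    """
    dim = len(species.niche_center)
    q = stats.chi2.ppf(level, df=dim)
    c = np.asarray(species.niche_center, dtype=float)
    s = np.asarray(species.niche_sd, dtype=float)
    # non-temperature latents are fixed at 0 in the region
    resid = q - np.sum((c[1:] / s[1:]) ** 2)
    if resid < 0:
        return None, "absent"
    half_width = s[0] * np.sqrt(resid)
    t_lo, t_hi = c[0] - half_width, c[0] + half_width

    if region.lapse_rate == 0:
        inside = t_lo <= region.base_temp <= t_hi
        return (region.elev_max, "unbounded_above") if inside else (None, "absent")

    # temperature decreases with elevation: coldest tolerated -> highest elev
    e_hi = region.elevation_at(t_lo)
    e_lo = region.elevation_at(t_hi)
    if e_hi < region.elev_min or e_lo > region.elev_max:
        return None, "absent"
    if e_hi >= region.elev_max:
        return region.elev_max, "unbounded_above"
    return float(e_hi), "ok"


@dataclass(frozen=True)
class SurveyConfig:
    """Roadside presence survey layout: one plot per ``plot_step`` metres of
    elevation gain, per road."""

    plot_step: float = 100.0
    epochs: tuple[int, ...] = (2008, 2018)
    roads: tuple[str, ...] = ("road1",)
    trait_effect: float = 0.0  # >0 couples residence time to the deficit


def random_species(n: int, region: RegionConfig, seed: int = 0,
                   latent_dim: int = 3, dispersal_deficit: float = 0.0,
                   detection_prob: float = 1.0,
                   niche_sd_range: tuple[float, float] = (1.5, 4.0)) -> list[SyntheticSpecies]:
    """Species whose temperature niches straddle the regional gradient, so
    their true UELs fall inside the survey span."""
    rng = np.random.default_rng(seed)
    t_top = region.temperature_at(region.elev_max)
    t_bot = region.base_temp
    out = []
    for i in range(n):
        sd = rng.uniform(*niche_sd_range, size=latent_dim)
        # place the cold edge of the niche inside the gradient
        t_edge = rng.uniform(t_top + 0.1 * (t_bot - t_top), t_bot - 0.1 * (t_bot - t_top))
        q = stats.chi2.ppf(NICHE_LEVEL, df=latent_dim)
        center = np.concatenate([[t_edge + sd[0] * np.sqrt(q) * 0.95],
                                 rng.normal(0.0, 0.5, latent_dim - 1)])
        out.append(SyntheticSpecies(
            name=f"sp{i:03d}", niche_center=tuple(center), niche_sd=tuple(sd),
            detection_prob=detection_prob, dispersal_deficit=dispersal_deficit))
    return out


def make_survey(species_list: list[SyntheticSpecies], region: RegionConfig,
                survey: SurveyConfig | None = None, seed: int = 0,
                merge_roads: bool = True) -> dict:
    """Simulate a two-epoch roadside presence survey plus species traits.

    A species is present in a plot when the plot's climate is inside its
    niche and the plot lies at or below its realized limit
    (true UEL − dispersal deficit); each presence is detected with
    probability ``detection_prob``. The observed UEL per epoch is the
    highest plot with a detection. Traits (residence time, dispersal mode,
    life span) are drawn independently of the dynamics unless
    ``trait_effect`` couples residence time to the deficit.

    Returns a dict with keys ``plots`` (long presence table), ``uel``
    (per-species observed UEL per epoch; per road unless ``merge_roads``)
    and ``traits``.
    """
    if survey is None:
        survey = SurveyConfig()
    rng = np.random.default_rng(seed)
    plot_elevs = np.arange(region.elev_min, region.elev_max + 1e-9, survey.plot_step)

    rows, uel_rows, trait_rows = [], [], []
    for sp in species_list:
        uel, flag = true_uel(sp, region)
        if flag == "absent":
            logger.info("%s absent from the region; excluded from survey", sp.name)
            continue
        realized = uel - sp.dispersal_deficit
        z = region_latents(region, plot_elevs, len(sp.niche_center))
        dim = len(sp.niche_center)
        inside = sp.mahalanobis_sq(z) <= stats.chi2.ppf(NICHE_LEVEL, df=dim)
        occupied = inside & (plot_elevs <= realized)

        residence = float(rng.integers(20, 160))
        trait_rows.append({
            "species": sp.name,
            "residence_time": residence,
            "dispersal_mode": rng.choice(DISPERSAL_MODES),
            "life_span": rng.choice(LIFE_SPANS),
        })
        for road in survey.roads:
            for year in survey.epochs:
                detected = occupied & (rng.uniform(size=plot_elevs.size) < sp.detection_prob)
                for e, d in zip(plot_elevs, detected):
                    rows.append({"road": road, "year": year, "plot_elevation": e,
                                 "species": sp.name, "present": int(d)})
                obs = plot_elevs[detected]
                uel_rows.append({
                    "species": sp.name, "road": road, "year": year,
                    "observed_uel": float(obs.max()) if obs.size else np.nan,
                    "true_uel": uel, "realized_limit": realized, "flag": flag,
                })
        if not any(r["species"] == sp.name and np.isfinite(r["observed_uel"])
                   for r in uel_rows):
            logger.info("%s never detected in survey; downstream stages will "
                        "exclude it", sp.name)

    uel_df = pd.DataFrame(uel_rows)
    if merge_roads and not uel_df.empty:
        uel_df = (uel_df.groupby(["species", "year"], as_index=False)
                  .agg(observed_uel=("observed_uel", "max"),
                       true_uel=("true_uel", "first"),
                       realized_limit=("realized_limit", "first"),
                       flag=("flag", "first")))
    return {"plots": pd.DataFrame(rows), "uel": uel_df,
            "traits": pd.DataFrame(trait_rows)}
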