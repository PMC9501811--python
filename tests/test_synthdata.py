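"""Generator contracts: seeding, lapse rate, analytic true limits, surveys."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uelshift import envniche, synthdata as sd


class TestWorld:
    def test_seed_determinism_and_distinct_seeds(self):
        cfg = sd.WorldConfig(n_background=300, seed=1)
        a = sd.make_world(cfg)
        b = sd.make_world(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = sd.make_world(sd.WorldConfig(n_background=300, seed=2))
        assert not a["bio1"].equals(c["bio1"])

    def test_requested_size_and_columns(self):
        cfg = sd.WorldConfig(n_background=250, seed=3)
        world = sd.make_world(cfg)
        assert len(world) == 250
        assert all(c in world.columns for c in cfg.climate_columns)

    def test_zero_noise_single_latent_rank_correlates_all_vars(self):
        cfg = sd.WorldConfig(n_background=200, latent_dim=1, noise_sd=0.0, seed=4)
        world = sd.make_world(cfg)
        base = world["bio1"].rank()
        for col in cfg.climate_columns[1:]:
            rho = np.corrcoef(base, world[col].rank())[0, 1]
            assert abs(rho) == pytest.approx(1.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sd.WorldConfig(n_background=0)
        with pytest.raises(ValueError):
            sd.WorldConfig(n_climate_vars=2, latent_dim=3)
        with pytest.raises(ValueError):
            sd.WorldConfig(noise_sd=-0.1)

    def test_latent_collinearity_supports_pca(self, background):
        # 3 latents + small noise: first 3 PCs carry >= 95% of variance
        x = background[[f"bio{i}" for i in range(1, 20)]].to_numpy()
        z = (x - x.mean(0)) / x.std(0)
        ev = np.linalg.svd(z, compute_uv=False) ** 2
        assert (ev[:3].sum() / ev.sum()) >= 0.95


class TestRegion:
    def test_lapse_rate_temperature_drop(self):
        region = sd.RegionConfig(elev_min=2000, elev_max=3000, n_points=11,
                                 elev_step=100)
        world = sd.WorldConfig(n_background=10, seed=0)
        reg = sd.make_region(region, world)
        drop = reg["bio1"].iloc[0] - reg.loc[reg["elevation"] == 3000, "bio1"].iloc[0]
        assert drop == pytest.approx(6.1)

    def test_zero_lapse_constant_climate(self):
        region = sd.RegionConfig(lapse_rate=0.0, n_points=40)
        reg = sd.make_region(region, sd.WorldConfig(n_background=10, seed=0))
        assert reg["bio1"].nunique() == 1

    def test_step_yields_expected_bands(self):
        region = sd.RegionConfig(elev_min=1900, elev_max=3600, elev_step=100,
                                 n_points=180)
        assert len(region.elevation_levels()) == 18
        reg = sd.make_region(region, sd.WorldConfig(n_background=10, seed=0))
        assert reg["elevation"].nunique() == 18

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            sd.RegionConfig(elev_min=3000, elev_max=3000)


class TestOccurrences:
    def test_flat_suitability_accepts_uniformly(self, background):
        sp = sd.SyntheticSpecies("flat", (0.0, 0.0, 0.0), (1e9, 1e9, 1e9))
        occ = sd.sample_occurrences(sp, background, 500, seed=5)
        assert len(occ) == 500
        # acceptance independent of temperature: occurrence mean close to background
        assert abs(occ["bio1"].mean() - background["bio1"].mean()) < 2.0

    def test_cold_niche_occurrences_are_cold(self, background):
        sp = sd.SyntheticSpecies("cold", (-5.0, 0.0, 0.0), (2.0, 2.0, 2.0))
        occ = sd.sample_occurrences(sp, background, 300, seed=6)
        assert occ["bio1"].mean() < background["bio1"].mean()

    def test_seed_fixed_identical_set(self, background):
        sp = sd.SyntheticSpecies("s", (5.0, 0.0, 0.0), (3.0, 3.0, 3.0))
        a = sd.sample_occurrences(sp, background, 200, seed=7)
        b = sd.sample_occurrences(sp, background, 200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_unachievable_count_warns_never_pads(self, background):
        sp = sd.SyntheticSpecies("rare", (-40.0, 0.0, 0.0), (0.5, 0.5, 0.5))
        with pytest.warns(UserWarning, match="achievable"):
            occ = sd.sample_occurrences(sp, background, 10**6, seed=8)
        assert len(occ) < 10**6

    def test_uncertainty_filter_removes_stable_fraction(self, background):
        sp = sd.SyntheticSpecies("s", (5.0, 0.0, 0.0), (4.0, 4.0, 4.0))
        occ = sd.sample_occurrences(sp, background, 1000, seed=9)
        frac = (occ["coordinate_uncertainty_m"] >= 1000).mean()
        assert 0.02 < frac < 0.4  # lognormal(median 300): nontrivial tail


class TestTrueUEL:
    def test_constructed_edge_at_3000(self):
        region = sd.RegionConfig(n_points=100)
        q = stats.chi2.ppf(0.99, df=1)
        t3000 = region.temperature_at(3000.0)
        sp = sd.SyntheticSpecies("s", (t3000 + 2.0 * np.sqrt(q),), (2.0,))
        uel, flag = sd.true_uel(sp, region)
        assert flag == "ok"
        assert uel == pytest.approx(3000.0, abs=1e-6)

    def test_absent_and_unbounded_flags(self):
        region = sd.RegionConfig(n_points=100)
        hot = sd.SyntheticSpecies("hot", (60.0,), (1.0,))
        assert sd.true_uel(hot, region) == (None, "absent")
        generalist = sd.SyntheticSpecies("g", (5.0,), (50.0,))
        uel, flag = sd.true_uel(generalist, region)
        assert flag == "unbounded_above" and uel == region.elev_max

    def test_matches_bruteforce_scan_for_random_species(self):
        region = sd.RegionConfig(n_points=100)
        world = sd.WorldConfig(seed=0)
        elev_lattice = np.arange(region.elev_min, region.elev_max + 0.5, 1.0)
        rng = np.random.default_rng(10)
        checked = 0
        for _ in range(100):
            dim = int(rng.integers(1, 4))
            sp = sd.SyntheticSpecies(
                "s", tuple(rng.uniform(-10, 15, dim)),
                tuple(rng.uniform(0.5, 6.0, dim)))
            z = sd.region_latents(region, elev_lattice, dim)
            inside = sp.mahalanobis_sq(z) <= stats.chi2.ppf(0.99, df=dim)
            uel, flag = sd.true_uel(sp, region)
            if not inside.any():
                assert flag == "absent"
            elif inside[-1]:
                assert flag == "unbounded_above" and uel == region.elev_max
            else:
                brute = elev_lattice[np.flatnonzero(inside)[-1]]
                assert abs(uel - brute) <= 1.0
                checked += 1
        assert checked >= 20

    def test_monotone_under_warming_center(self):
        region = sd.RegionConfig(n_points=100)
        uels = []
        for c in np.linspace(-2.0, 12.0, 15):
            sp = sd.SyntheticSpecies("s", (c,), (1.5,))
            uel, flag = sd.true_uel(sp, region)
            uels.append(region.elev_min if flag == "absent" else uel)
        assert all(a >= b - 1e-9 for a, b in zip(uels, uels[1:]))


class TestSurvey:
    def _species(self, region, deficit=0.0, detection=1.0, edge=3050.0):
        q = stats.chi2.ppf(0.99, df=1)
        t_edge = region.temperature_at(edge)
        return sd.SyntheticSpecies("s", (t_edge + 1.5 * np.sqrt(q),), (1.5,),
                                   detection_prob=detection,
                                   dispersal_deficit=deficit)

    def test_perfect_detection_hits_nearest_plot_below_limit(self):
        region = sd.RegionConfig(n_points=100)
        sp = self._species(region)  # true limit 3050 -> nearest plot 3000
        survey = sd.make_survey([sp], region, seed=1)
        uel, _ = sd.true_uel(sp, region)
        assert uel == pytest.approx(3050.0, abs=1e-6)
        assert (survey["uel"]["observed_uel"] == 3000.0).all()

    def test_dispersal_deficit_shifts_realized_limit(self):
        region = sd.RegionConfig(n_points=100)
        sp = self._species(region, deficit=500.0)
        survey = sd.make_survey([sp], region, seed=2)
        uel, _ = sd.true_uel(sp, region)
        assert (survey["uel"]["realized_limit"] == uel - 500.0).all()
        assert (survey["uel"]["observed_uel"] <= uel - 500.0).all()

    def test_zero_detection_species_absent(self):
        region = sd.RegionConfig(n_points=100)
        sp = self._species(region, detection=0.0)
        survey = sd.make_survey([sp], region, seed=3)
        assert survey["uel"]["observed_uel"].isna().all()

    def test_two_epochs_unbiased_change(self):
        # same parameters in both epochs: mean UEL change ~ 0 over many seeds
        region = sd.RegionConfig(n_points=100)
        sp = self._species(region, detection=0.7)
        deltas = []
        for seed in range(200):
            uel = sd.make_survey([sp], region, seed=seed)["uel"]
            w = uel.pivot_table(index="species", columns="year",
                                values="observed_uel")
            if w.notna().all(axis=None):
                deltas.append(float(w[2018].iloc[0] - w[2008].iloc[0]))
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 4 * se + 1e-9

    def test_traits_drawn_from_closed_sets(self):
        region = sd.RegionConfig(n_points=100)
        species = sd.random_species(10, region, seed=4)
        traits = sd.make_survey(species, region, seed=5)["traits"]
        assert set(traits["dispersal_mode"]) <= set(sd.DISPERSAL_MODES)
        assert set(traits["life_span"]) <= set(sd.LIFE_SPANS)
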