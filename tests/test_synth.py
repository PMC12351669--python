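import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lepitrend as lt
from lepitrend.synth import (
    GenerativeParams,
    SurveyConfig,
    attach_groupings,
    generate_host_records,
    generate_occurrence_grid,
    generate_survey,
    simulate_counts,
)
from lepitrend.traits import compute_sti


def flat_season(doy):
    return np.zeros_like(np.asarray(doy, dtype=float))


class TestConfigValidation:
    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            SurveyConfig(n_sites=1)
        with pytest.raises(ValueError):
            SurveyConfig(year_range=(2000, 1999))
        with pytest.raises(ValueError):
            SurveyConfig(elev_range=(100, 6000))
        with pytest.raises(ValueError):
            GenerativeParams(phi=0.0)
        with pytest.raises(ValueError):
            GenerativeParams(sigma_site=-0.1)


class TestGenerateSurvey:
    def test_degenerate_zero_nights(self):
        cfg = SurveyConfig(n_sites=2, year_range=(2000, 2000), nights_per_site_year=0, seed=1)
        sites, nights, records, species = generate_survey(cfg)
        assert len(sites) == 2
        assert len(nights) == 0
        assert len(records) == 0

    def test_determinism(self):
        cfg = SurveyConfig(n_sites=4, year_range=(2000, 2004), n_species=10,
                           nights_per_site_year=5, seed=42)
        out1 = generate_survey(cfg)
        out2 = generate_survey(cfg)
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b)

    def test_design_levels_all_present(self, small_survey):
        _, sites, nights, records, species = small_survey
        assert set(nights["trap_type"]) == {"fixed1", "fixed2", "manual"}
        assert len(set(nights["lamp_type"])) == 4
        assert set(nights["n_traps"]) == {1, 2, 3, 4}

    def test_night_contract(self, small_survey):
        """Duration only for manual traps; day_of_year consistent with date."""
        _, sites, nights, records, species = small_survey
        manual = nights["trap_type"] == "manual"
        assert nights.loc[~manual, "duration_h"].isna().all()
        known = nights.loc[manual, "duration_h"].dropna()
        assert ((known >= 1) & (known <= 13)).all()
        # ~30% of manual nights lack duration
        frac_missing = nights.loc[manual, "duration_h"].isna().mean()
        assert 0.1 < frac_missing < 0.5
        doy = pd.to_datetime(nights["date"]).dt.dayofyear
        np.testing.assert_array_equal(doy.to_numpy(), nights["day_of_year"].to_numpy())

    def test_sites_span_elevation_range(self, small_survey):
        cfg, sites, *_ = small_survey
        lo, hi = cfg.elev_range
        assert sites["elev_m"].between(lo, hi).all()
        assert sites["elev_m"].max() - sites["elev_m"].min() > 0.5 * (hi - lo)

    def test_weather_elevation_lapse(self, small_survey):
        _, sites, nights, *_ = small_survey
        # site mean temperature decreases with elevation (lapse rate)
        site_means = nights.groupby("site_id")["temp2d_degC"].mean()
        elev = sites.set_index("site_id")["elev_m"].loc[site_means.index]
        rho = stats.spearmanr(elev, site_means).statistic
        assert rho < -0.7


class TestSimulateCounts:
    def _nights(self, n=400, seed=0):
        cfg = SurveyConfig(n_sites=4, year_range=(2000, 2004), n_species=1,
                           nights_per_site_year=25, seed=seed)
        rng = np.random.default_rng(seed)
        from lepitrend.synth import generate_nights, generate_sites
        sites = generate_sites(cfg, rng)
        nights = generate_nights(cfg, sites, rng)
        nights = nights.merge(sites[["site_id", "elev_m"]], on="site_id")
        return attach_groupings(nights, sites)

    def test_all_zero_when_pi_one(self):
        nights = self._nights()
        species = pd.DataFrame(
            {"species_id": ["s0"], "trait_group": ["mid"], "species_effect_raw": [0.0]}
        )
        params = GenerativeParams(pi0=1.0)
        rec = simulate_counts(nights, species, params, seed=1)
        assert len(rec) == 0

    def test_mean_matches_closed_form_without_heterogeneity(self):
        nights = self._nights()
        n_species = 15
        species = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(n_species)],
                "trait_group": ["mid"] * n_species,
                "species_effect_raw": np.zeros(n_species),
            }
        )
        beta0 = 0.4
        params = GenerativeParams(
            beta0=beta0, beta_year=0, beta_elev=0, beta_yx=0, pi0=0.0, phi=2.0,
            sigma_site=0, sigma_siteyear=0, sigma_night=0, sigma_cluster=0,
            sigma_species=0, season_curve=flat_season,
        )
        rec = simulate_counts(nights, species, params, seed=3)
        totals = rec.groupby("night_id")["count"].sum().reindex(
            nights["night_id"], fill_value=0
        )
        mu = np.exp(beta0)
        expected = n_species * mu
        # NB variance per cell: mu(1+mu/phi); SE of night-total mean
        se = np.sqrt(n_species * mu * (1 + mu / 2.0) / len(nights))
        assert abs(totals.mean() - expected) < 3 * se

    def test_positive_interaction_induces_positive_correlation(self):
        nights = self._nights(n=400, seed=5).head(200)
        species = pd.DataFrame(
            {"species_id": ["s0"], "trait_group": ["mid"], "species_effect_raw": [0.0]}
        )
        params = GenerativeParams(
            beta0=1.0, beta_year=0, beta_elev=0, beta_yx=0.8, pi0=0.0,
            sigma_site=0, sigma_siteyear=0, sigma_night=0, sigma_cluster=0,
            sigma_species=0, season_curve=flat_season,
        )
        rec = simulate_counts(nights, species, params, seed=6)
        counts = rec.set_index("night_id")["count"].reindex(nights["night_id"], fill_value=0)
        zy = stats.zscore(nights["year"])
        ze = stats.zscore(nights["elev_m"])
        r = np.corrcoef(zy * ze, np.log1p(counts))[0, 1]
        assert r > 0

    def test_zero_fraction_matches_monte_carlo_oracle(self):
        """Empirical P(y=0) within 0.05 of a brute-force MC estimate that
        redraws linear predictors and random effects from the same law."""
        cfg = SurveyConfig(n_sites=20, year_range=(2000, 2009), n_species=30,
                           nights_per_site_year=30, seed=1)
        sites, nights, records, species = generate_survey(cfg)
        empirical = len(records) / (len(nights) * len(species))
        p = cfg.true_params
        rng = np.random.default_rng(12345)
        n_mc = 1_000_000
        year = nights["year"].to_numpy(dtype=float)
        elev = nights["elev_m"].to_numpy(dtype=float)
        zy = (year - year.mean()) / year.std()
        ze = (elev - elev.mean()) / elev.std()
        i_night = rng.integers(0, len(nights), n_mc)
        i_sp = rng.integers(0, len(species), n_mc)
        sp_eff = p.sigma_species * species["species_effect_raw"].to_numpy()
        re_sd = np.sqrt(p.sigma_site**2 + p.sigma_siteyear**2
                        + p.sigma_night**2 + p.sigma_cluster**2)
        eta = (
            p.beta0
            + p.beta_year * zy[i_night]
            + p.beta_elev * ze[i_night]
            + p.beta_yx * (zy * ze)[i_night]
            + p.season_curve(nights["day_of_year"].to_numpy())[i_night]
            + sp_eff[i_sp]
            + re_sd * rng.normal(size=n_mc)
        )
        mu = np.exp(eta)
        p_zero = p.pi0 + (1 - p.pi0) * (p.phi / (p.phi + mu)) ** p.phi
        mc_nonzero = float(np.mean(1 - p_zero))
        assert abs(empirical - mc_nonzero) < 0.05


class TestOccurrenceGrid:
    def test_single_cell_sti(self):
        species = pd.DataFrame({"species_id": ["x"], "latent_niche_degC": [7.0]})
        cells = pd.Series({"c0": 7.0}, name="temp_degC")
        occ = pd.DataFrame({"species_id": ["x"], "cell_id": ["c0"]})
        assert compute_sti(occ, cells)["x"] == pytest.approx(7.0)

    def test_sti_recovers_niche_ranking(self):
        rng = np.random.default_rng(3)
        species = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(40)],
                "latent_niche_degC": rng.uniform(2, 12, 40),
            }
        )
        cells, occ = generate_occurrence_grid(species, 500, seed=3)
        sti = compute_sti(occ, cells)
        merged = species.set_index("species_id").join(sti).dropna()
        rho = stats.spearmanr(merged["latent_niche_degC"], merged["sti_degC"]).statistic
        assert rho > 0.9

    def test_zero_occupancy_species_absent(self):
        species = pd.DataFrame(
            {"species_id": ["far"], "latent_niche_degC": [100.0]}
        )
        cells, occ = generate_occurrence_grid(species, 50, seed=1)
        assert "far" not in set(occ["species_id"])

    def test_n_cells_validated(self):
        species = pd.DataFrame({"species_id": ["x"], "latent_niche_degC": [5.0]})
        with pytest.raises(ValueError):
            generate_occurrence_grid(species, 0, seed=1)


class TestHostRecords:
    def test_every_species_classifiable(self, small_survey):
        _, _, _, _, species = small_survey
        hosts = generate_host_records(species, seed=2)
        from lepitrend.traits import classify_food_specialisation

        cls = classify_food_specialisation(hosts)
        assert set(cls.index) == set(species["species_id"])
        assert set(cls.unique()) <= {"monophagous", "oligophagous", "polyphagous"}
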