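import warnings

import numpy as np
import pandas as pd
import pytest

from budburst.covariates import fit_frost_curve, frost_indicator
from budburst.synthetic import (DEFAULT_SITES, SiteClimateParams, StudyDesign,
                                TransitionHazardParams, default_scenario,
                                simulate_buds, simulate_weather)
from budburst.transitions import BUD_KEY, STAGES, TRANSITIONS

RANK = {s: i for i, s in enumerate(STAGES)}


class TestWeather:
    def test_noiseless_limit_is_exact_sinusoid(self):
        p = SiteClimateParams("s", 47.0, 3.0, 17.0, 200.0, 10.0, ar1_rho=0.0,
                              noise_sd=0.0)
        w = simulate_weather(p, 2016, seed=1)
        doy = w["doy"].to_numpy()
        expected = 3.0 + 17.0 * np.cos(2 * np.pi * (doy - 200.0) / 365.25)
        assert np.allclose(w["tmean"], expected)
        assert np.allclose(w["tmax"] - w["tmin"], 10.0)

    def test_seed_contract(self):
        p = DEFAULT_SITES["temperate"]
        a = simulate_weather(p, 2016, seed=42)
        b = simulate_weather(p, 2016, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_weather(p, 2016, seed=43)
        assert not np.allclose(a["tmean"], c["tmean"])

    def test_temperature_ordering_enforced(self):
        p = SiteClimateParams("s", 47.0, 3.0, 17.0, 200.0, 2.0, noise_sd=6.0)
        w = simulate_weather(p, 2017, seed=3)
        assert (w["tmin"] <= w["tmean"]).all()
        assert (w["tmean"] <= w["tmax"]).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SiteClimateParams("s", 47.0, 3.0, 17.0, 200.0, 10.0, noise_sd=-1.0)
        with pytest.raises(ValueError, match="ar1_rho"):
            SiteClimateParams("s", 47.0, 3.0, 17.0, 200.0, 10.0, ar1_rho=1.0)

    def test_boreal_frost_declines_later_than_temperate(self):
        """The colder site's fitted frost curve reaches the 0.10 level
        later in nearly every seed (full-season fit anchors the tail)."""
        later = 0
        for seed in range(100):
            doy10 = {}
            for name in ("temperate", "boreal"):
                w = pd.concat([simulate_weather(DEFAULT_SITES[name], y, seed)
                               for y in (2016, 2017)])
                m = fit_frost_curve(frost_indicator(w), w["doy"])
                doy10[name] = (np.log(1 / 9) - m.beta0) / m.beta1
            if doy10["boreal"] > doy10["temperate"]:
                later += 1
        assert later >= 95


def flat_hazards(beta0, sigma_tree=0.0, sigma_year=0.0, driver="gdd_mean",
                 beta1=0.0):
    return {("w", "local"): {
        t: TransitionHazardParams(t, driver, beta0, beta1, sigma_tree, sigma_year)
        for t in TRANSITIONS}}


def one_site_design(trees=10, buds=2):
    return StudyDesign(sites=["temperate"], years=[2016],
                       groups=[{"species": "w", "seed_source": "local"}],
                       latitudes={"temperate": 47.29},
                       trees_per_group=trees, buds_per_tree=buds)


@pytest.fixture(scope="module")
def one_site_weather():
    return simulate_weather(DEFAULT_SITES["temperate"], 2016, seed=5)


class TestBuds:
    def test_zero_hazard_keeps_every_bud_dormant(self, one_site_weather):
        obs, _ = simulate_buds(one_site_design(), flat_hazards(-50.0),
                               one_site_weather, seed=2)
        assert (obs["stage"] == 0).all()

    def test_conservation_one_record_per_bud_and_census(self, one_site_weather):
        design = one_site_design(trees=7, buds=3)
        obs, _ = simulate_buds(design, flat_hazards(-2.0), one_site_weather, seed=2)
        n_buds = obs.groupby(BUD_KEY).ngroups
        assert n_buds == 7 * 3
        assert len(obs) == n_buds * len(design.schedule)

    def test_monotone_trajectories(self, one_site_weather):
        obs, _ = simulate_buds(one_site_design(trees=30), flat_hazards(-1.5),
                               one_site_weather, seed=9)
        for _, grp in obs.groupby(BUD_KEY):
            ranks = grp.sort_values("doy")["stage"].map(RANK)
            assert (ranks.diff().dropna() >= 0).all()

    def test_seed_reproducibility(self, one_site_weather):
        a, _ = simulate_buds(one_site_design(), flat_hazards(-2.0),
                             one_site_weather, seed=4)
        b, _ = simulate_buds(one_site_design(), flat_hazards(-2.0),
                             one_site_weather, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_schedule_outside_weather_rejected(self, one_site_weather):
        design = one_site_design()
        design.schedule = np.array([240, 247])
        with pytest.raises(ValueError, match="outside weather"):
            simulate_buds(design, flat_hazards(-2.0), one_site_weather, seed=1)

    def test_missing_transition_hazard_rejected(self, one_site_weather):
        hz = flat_hazards(-2.0)
        del hz[("w", "local")]["4->5"]
        with pytest.raises(ValueError, match="missing hazards"):
            simulate_buds(one_site_design(), hz, one_site_weather, seed=1)

    def test_tree_variance_widens_budbreak_spread(self, one_site_weather):
        """Between-tree SD of the first stage>=5 DOY grows with sigma_tree.

        Hazards are calibrated so the noiseless transitions fall mid-window
        (targets DOY 138-158); the same weather stream is used for both
        settings.
        """
        from budburst.covariates import build_covariate_table
        from budburst.synthetic import calibrate_hazards, make_standardizer

        cov, _ = build_covariate_table(one_site_weather, {"temperate": 47.29})
        std = make_standardizer(cov)

        def tree_spread(sigma):
            targets = {("w", "local"): dict(zip(TRANSITIONS,
                                                (138, 143, 148, 153, 158)))}
            hz = calibrate_hazards(cov, std, targets,
                                   {t: "gdd_mean" for t in TRANSITIONS},
                                   reference=("temperate", 2016),
                                   sigma_tree=sigma, sigma_year=0.0)
            design = one_site_design(trees=200, buds=1)
            obs, _ = simulate_buds(design, hz, one_site_weather, seed=31,
                                   covariates=cov, standardizer=std)
            reached = obs[obs["stage"].map(RANK) >= RANK[5]]
            first = reached.groupby("tree")["doy"].min()
            return first.std()

        assert tree_spread(2.0) > tree_spread(0.0)


class TestScenario:
    def test_calibrated_crossings_near_targets(self, small_scenario):
        """Median observed budbreak tracks the calibrated hazard targets."""
        truth = small_scenario.truth.crossings
        ref = truth[(truth["site"] == "temperate") & (truth["year"] == 2016)
                    & (truth["species"] == "white_spruce")]
        got = dict(zip(ref["transition"], ref["daily_crossing"]))
        for tid, target in zip(TRANSITIONS, (140, 146, 151, 156, 161)):
            assert got[tid] == pytest.approx(target, abs=1.0)

    def test_median_budbreak_within_one_census_of_target(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = default_scenario(21, trees_per_group=40, buds_per_tree=2,
                                  sigma_tree=0.0, sigma_year=0.0)
        obs = sc.observations
        sub = obs[(obs["site"] == "temperate") & (obs["year"] == 2016)
                  & (obs["species"] == "white_spruce")]
        reached = sub[sub["stage"].map(RANK) >= RANK[5]]
        median_break = reached.groupby(["tree", "bud"])["doy"].min().median()
        # 4->5 calibrated to cross at DOY 156 at this site-year
        assert abs(median_break - 156) <= 7

    def test_truth_crossings_inside_season(self, small_scenario):
        cr = small_scenario.truth.crossings
        assert cr["interval_crossing"].notna().all()
        assert cr["interval_crossing"].between(100, 243).all()

    def test_species_ordering_matches_calibration(self, small_scenario):
        cr = small_scenario.truth.crossings
        piv = cr.pivot_table(index=["site", "year", "transition"],
                             columns="species", values="interval_crossing")
        assert (piv["white_spruce"] < piv["black_spruce"]).all()
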