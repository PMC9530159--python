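import math

import numpy as np
import pytest
import shapely
from scipy.spatial import cKDTree

import ratdetect as rd
from ratdetect.eradication import (
    ConfigurationError,
    EradicationConfig,
    SimRat,
    _attach_neighbours,
    build_grid,
    growth_step,
    init_population,
    nightly_step,
    run_eradication,
)
from ratdetect.history import BehaviourState


class TestBuildGrid:
    @pytest.mark.parametrize("spacing,expected", [(25, 16), (50, 4), (100, 1)])
    def test_one_hectare_counts(self, spacing, expected):
        assert len(build_grid(rd.square_area(1.0), spacing)) == expected

    def test_large_area_density(self):
        n = len(build_grid(rd.square_area(1475.0), 25))
        assert abs(n - 16 * 1475) / (16 * 1475) < 0.01

    def test_all_stations_inside_polygon(self):
        area = rd.square_area(9.0)
        pts = build_grid(area, 40)
        assert shapely.contains_xy(area.polygon, pts[:, 0], pts[:, 1]).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            build_grid(rd.square_area(0.01), 500)


class TestConfig:
    def test_breeding_season_length(self):
        cfg = EradicationConfig()
        assert cfg.season_length_days == 242  # September through April

    def test_daily_multiplier_compounds_to_rmax(self):
        cfg = EradicationConfig()
        assert cfg.daily_multiplier**cfg.season_length_days == pytest.approx(3.57)

    def test_month_cycle(self):
        cfg = EradicationConfig()
        assert cfg.month_of_day(0) == 9
        assert cfg.month_of_day(30) == 10
        assert cfg.month_of_day(364) == 8  # wraps to late August
        assert cfg.month_of_day(365) == 9

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            EradicationConfig(spacing=-1)
        with pytest.raises(ConfigurationError):
            EradicationConfig(bycatch_prob=1.5)


class TestInitPopulation:
    def test_reference_population_size(self, surrogate_post, rng):
        rats = init_population(rd.square_area(1475.0), 0.26, surrogate_post, rng)
        assert len(rats) == 384  # round(0.26 * 1475)

    def test_zero_density_empty(self, surrogate_post, rng):
        assert init_population(rd.square_area(10.0), 0.0, surrogate_post, rng) == []

    def test_centres_inside_polygon(self, surrogate_post, rng):
        area = rd.square_area(25.0)
        rats = init_population(area, 2.0, surrogate_post, rng)
        xs = np.array([r.x for r in rats])
        ys = np.array([r.y for r in rats])
        assert shapely.contains_xy(area.polygon, xs, ys).all()

    def test_empty_posterior_rejected(self, surrogate_post, rng):
        import pandas as pd

        from ratdetect.posterior import PosteriorDraws

        empty = PosteriorDraws(
            globals_=surrogate_post.globals_.iloc[:0],
            sigma=surrogate_post.sigma[:0],
            delta=surrogate_post.delta[:0],
            rho=surrogate_post.rho[:0],
            rat_ids=surrogate_post.rat_ids,
            sexes=surrogate_post.sexes,
        )
        with pytest.raises(ValueError):
            init_population(rd.square_area(10.0), 1.0, empty, rng)


def _rat(x=0.0, y=0.0, sigma=25.0, eps0=0.4, tau=0.359, theta=0.3):
    return SimRat(x=x, y=y, sigma=sigma, eps0=eps0, tau=tau, theta=theta, sex=0)


class TestNightlyStep:
    def test_empty_stations_remove_nothing(self, rng):
        xy = np.array([[0.0, 0.0]])
        rat = _rat(eps0=1.0, theta=1.0)
        _attach_neighbours(rat, cKDTree(xy), xy)
        doses = np.zeros(1, dtype=int)
        assert nightly_step([rat], doses, 1, rng) == 0
        assert rat.alive

    def test_certain_catch_at_station_position(self, rng):
        xy = np.array([[0.0, 0.0]])
        rat = _rat(eps0=1.0, theta=1.0)
        _attach_neighbours(rat, cKDTree(xy), xy)
        doses = np.array([5])
        assert nightly_step([rat], doses, 1, rng) == 1
        assert not rat.alive and doses[0] == 4

    def test_removal_rate_matches_closed_form(self):
        # fresh naive rat each replicate: P(removal) = p_enc * theta
        rng = np.random.default_rng(8)
        d, sigma, eps0, theta = 18.0, 25.0, 0.42, 0.31
        xy = np.array([[d, 0.0]])
        tree = cKDTree(xy)
        n = 20000
        removed = 0
        for _ in range(n):
            rat = _rat(sigma=sigma, eps0=eps0, theta=theta)
            _attach_neighbours(rat, tree, xy)
            doses = np.array([1])
            removed += nightly_step([rat], doses, 1, rng)
        p = rd.encounter_prob(d, sigma, eps0, 0.359, 0) * theta
        se = math.sqrt(p * (1 - p) / n)
        assert abs(removed / n - p) < 3 * se

    def test_experience_exponent_applies_after_first_encounter(self, rng):
        rat = _rat(eps0=0.5, tau=0.359, theta=0.0)  # never removed, theta 0
        xy = np.array([[0.0, 0.0]])
        _attach_neighbours(rat, cKDTree(xy), xy)
        rat.estar.record(3)
        doses = np.array([10])
        # survives because theta = 0; indicator active on night 4
        assert rat.estar.indicator(4)
        nightly_step([rat], doses, 4, rng)
        assert rat.alive

    def test_survival_matches_product_form_without_dynamics(self):
        # tau = 1 (no behavioural response), one station, infinite doses:
        # survival over T nights is (1 - p*theta)^T
        rng = np.random.default_rng(13)
        d, sigma, eps0, theta, T = 15.0, 25.0, 0.5, 0.4, 30
        xy = np.array([[d, 0.0]])
        tree = cKDTree(xy)
        n = 3000
        survived = 0
        for _ in range(n):
            rat = _rat(sigma=sigma, eps0=eps0, tau=1.0, theta=theta)
            _attach_neighbours(rat, tree, xy)
            doses = np.array([10**9])
            for t in range(1, T + 1):
                nightly_step([rat], doses, t, rng)
                if not rat.alive:
                    break
            survived += rat.alive
        p_night = rd.encounter_prob(d, sigma, eps0, 1.0, 0) * theta
        expect = (1 - p_night) ** T
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(survived / n - expect) < 3 * se


class TestGrowthStep:
    def test_no_births_at_carrying_capacity(self, surrogate_post, rng):
        area = rd.square_area(10.0)
        cfg = EradicationConfig(initial_density=3.0, carrying_capacity=3.0)
        xy = build_grid(area, 50)
        tree = cKDTree(xy)
        rats = init_population(area, 3.0, surrogate_post, rng)
        births = sum(
            growth_step(rats, day, cfg, area, surrogate_post, tree, xy, rng)
            for day in range(1, 30)
        )
        assert births == 0

    def test_no_births_outside_breeding_season(self, surrogate_post, rng):
        area = rd.square_area(10.0)
        cfg = EradicationConfig(start_month=5, breeding_months=(9, 10))  # May start
        xy = build_grid(area, 50)
        rats = init_population(area, 0.5, surrogate_post, rng)
        assert growth_step(rats, 1, cfg, area, surrogate_post, cKDTree(xy), xy, rng) == 0

    def test_unbaited_population_approaches_carrying_capacity(self, surrogate_post):
        # logistic limit: with no stations the population grows towards K
        area = rd.square_area(5.0)
        post = surrogate_post
        cfg = EradicationConfig(
            initial_density=0.26, carrying_capacity=3.0, horizon_days=1500, n_reps=1,
            bycatch_prob=0.0, seed=17,
        )
        rng = np.random.default_rng(1)
        rats = init_population(area, cfg.initial_density, post, rng)
        xy = np.empty((0, 2))
        tree = None
        for day in range(1, cfg.horizon_days + 1):
            if cfg.month_of_day(day) in cfg.breeding_months:
                alive = [r for r in rats if r.alive]
                n = len(alive)
                k_total = cfg.carrying_capacity * area.area_ha
                lam = cfg.daily_multiplier
                expected = n * (lam - 1.0) * max(0.0, 1.0 - n / k_total)
                for _ in range(rng.poisson(expected)):
                    mother = alive[int(rng.integers(n))]
                    rats.append(_rat(x=mother.x, y=mother.y))
        n_final = len(rats)
        assert 10 <= n_final <= 18  # K * area = 15


class TestRunEradication:
    def test_zero_theta_means_no_eradication_and_growth(self, surrogate_post):
        post = surrogate_post
        zero = rd.PosteriorDraws(
            globals_=post.globals_.assign(lambda0=-40.0),
            sigma=post.sigma, delta=post.delta, rho=post.rho * 0,
            rat_ids=post.rat_ids, sexes=post.sexes, chain=post.chain,
        )
        cfg = EradicationConfig(spacing=50, horizon_days=250, n_reps=2, seed=3)
        res = run_eradication(cfg, rd.square_area(20.0), zero)
        assert res.eradication_probability == 0.0
        assert (res.final_population >= res.trajectories[:, 0]).all()

    def test_population_never_negative_and_monotone_to_zero(self, surrogate_post):
        cfg = EradicationConfig(spacing=25, horizon_days=120, n_reps=3, seed=6)
        res = run_eradication(cfg, rd.square_area(30.0), surrogate_post)
        assert (res.trajectories >= 0).all()
        # once zero, stays zero
        for row in res.trajectories:
            z = np.flatnonzero(row == 0)
            if z.size:
                assert (row[z[0]:] == 0).all()

    def test_eradication_monotone_in_spacing_and_horizon(self, surrogate_post):
        area = rd.square_area(100.0)
        probs = {}
        for spacing in (25, 50, 100):
            cfg = EradicationConfig(spacing=spacing, horizon_days=200, n_reps=8, seed=31)
            res = run_eradication(cfg, area, surrogate_post)
            probs[spacing] = (res.eradication_by(100), res.eradication_probability)
        for spacing in probs:
            assert probs[spacing][0] <= probs[spacing][1]  # horizon monotone
        assert probs[25][1] >= probs[50][1] >= probs[100][1]  # spacing monotone

    def test_summary_fields(self, surrogate_post):
        cfg = EradicationConfig(spacing=25, horizon_days=60, n_reps=2, seed=1)
        res = run_eradication(cfg, rd.square_area(10.0), surrogate_post)
        s = res.summary()
        assert 0.0 <= s["eradication_probability"] <= 1.0
        assert s["n_reps"] == 2
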