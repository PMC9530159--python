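"""Individual-based bait-station eradication simulation.

Each replicate places a square bait-station lattice over the study polygon,
seeds a rat population whose detection parameters (sigma, delta, rho and
the regression coefficients) come from posterior draws, and then iterates
nights: every live rat may encounter stations that still hold bait doses
(half-normal kernel with the behavioural exponent tau), and an encounter
converts to a removal with its interaction probability theta. Stations are
multiple-capture: each removal consumes one of max_catch doses, stations
are refilled at every check interval, and a nightly 1% by-catch chance per
station drains doses to non-targets. Population growth is a daily discrete
logistic restricted to the breeding season with annual multiplier r_max —
an openly stated surrogate for the unpublished internals of the original
removal simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .data_io import StudyArea
from .history import BehaviourState
from .kernels import CUTOFF_MULTIPLIER, PROB_FLOOR, clipped_expit
from .posterior import PosteriorDraws

_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class ConfigurationError(ValueError):
    pass


@dataclass
class EradicationConfig:
    """Scenario knobs for the removal simulation."""

    spacing: float = 25.0
    check_interval: int = 7
    horizon_days: int = 1000
    n_reps: int = 100
    r_max: float = 3.57
    breeding_months: tuple = (9, 10, 11, 12, 1, 2, 3, 4)  # September-April
    start_month: int = 9  # simulations begin at the start of the breeding season
    initial_density: float = 0.26  # rats per ha
    carrying_capacity: float = 3.0  # rats per ha
    bycatch_prob: float = 0.01
    max_catch_per_station: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.check_interval <= 0 or self.horizon_days <= 0:
            raise ConfigurationError("spacing, check_interval and horizon_days must be > 0")
        if not 0 <= self.bycatch_prob <= 1:
            raise ConfigurationError("bycatch_prob must be in [0, 1]")
        if self.initial_density < 0 or self.carrying_capacity <= 0 or self.r_max <= 0:
            raise ConfigurationError("densities and r_max must be positive")

    @property
    def season_length_days(self) -> int:
        return sum(_MONTH_DAYS[m - 1] for m in self.breeding_months)

    @property
    def daily_multiplier(self) -> float:
        return float(np.exp(np.log(self.r_max) / self.season_length_days))

    def month_of_day(self, day: int) -> int:
        doy = (sum(_MONTH_DAYS[: self.start_month - 1]) + day) % 365
        m = 0
        while doy >= _MONTH_DAYS[m]:
            doy -= _MONTH_DAYS[m]
            m += 1
        return m + 1


def build_grid(area: StudyArea, spacing: float, offset: tuple[float, float] | None = None) -> np.ndarray:
    """Square lattice of station coordinates clipped to the polygon.

    The lattice is shifted by `offset` (default spacing/2 on both axes) from
    the lower-left corner of the polygon's bounding box, giving ~1/spacing^2
    stations per square metre.
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be > 0")
    minx, miny, maxx, maxy = area.polygon.bounds
    ox, oy = (spacing / 2.0, spacing / 2.0) if offset is None else offset
    xs = np.arange(minx + ox, maxx, spacing)
    ys = np.arange(miny + oy, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(area.polygon, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if len(pts) == 0:
        raise ConfigurationError("no station falls inside the polygon")
    return pts


@dataclass
class SimRat:
    """One simulated individual with its own detection parameters."""

    x: float
    y: float
    sigma: float
    eps0: float  # bait-station eps0 at this rat's sigma and delta
    tau: float
    theta: float  # bait-station interaction probability (rho included)
    sex: int
    birth_day: int = 0
    alive: bool = True
    estar: BehaviourState = field(default_factory=BehaviourState)
    neigh_idx: np.ndarray | None = None
    neigh_base: np.ndarray | None = None  # eps0 * exp(-d^2/2sigma^2), floored


def _uniform_in_polygon(area: StudyArea, n: int, rng) -> np.ndarray:
    minx, miny, maxx, maxy = area.polygon.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(16, 2 * (n - filled))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        ok = cand[shapely.contains_xy(area.polygon, cand[:, 0], cand[:, 1])]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _make_rat(x, y, posterior: PosteriorDraws, rng, birth_day=0) -> SimRat:
    row = int(rng.integers(posterior.n_draws))
    j = int(rng.integers(posterior.n_rats))
    g = posterior.globals_.iloc[row]
    sigma = float(posterior.sigma[row, j])
    delta = float(posterior.delta[row, j])
    rho = float(posterior.rho[row, j])
    eps0 = float(clipped_expit(g["alpha0"] + g["alpha1"] * np.log(sigma) + delta))
    theta = float(clipped_expit(g["lambda0"] + rho))
    return SimRat(
        x=float(x),
        y=float(y),
        sigma=sigma,
        eps0=eps0,
        tau=float(g["tau"]),
        theta=theta,
        sex=int(rng.random() < 0.5),
        birth_day=birth_day,
    )


def init_population(
    area: StudyArea, density: float, posterior: PosteriorDraws, rng
) -> list[SimRat]:
    """N = round(density * area_ha) rats, centres uniform in the polygon."""
    if posterior.n_draws == 0:
        raise ValueError("posterior is empty")
    n = int(round(density * area.area_ha))
    pts = _uniform_in_polygon(area, n, rng)
    return [_make_rat(x, y, posterior, rng, birth_day=0) for x, y in pts]


def _attach_neighbours(rat: SimRat, tree: cKDTree, station_xy: np.ndarray) -> None:
    radius = CUTOFF_MULTIPLIER * rat.sigma
    idx = np.asarray(tree.query_ball_point([rat.x, rat.y], radius), dtype=int)
    if idx.size:
        d = np.hypot(station_xy[idx, 0] - rat.x, station_xy[idx, 1] - rat.y)
        rat.neigh_idx = idx
        rat.neigh_base = np.maximum(rat.eps0 * np.exp(-(d**2) / (2 * rat.sigma**2)), PROB_FLOOR)
    else:
        rat.neigh_idx = np.empty(0, dtype=int)
        rat.neigh_base = np.empty(0)


def nightly_step(rats: list[SimRat], doses: np.ndarray, night: int, rng) -> int:
    """One night of encounters and removals; returns the number removed."""
    removals = 0
    order = rng.permutation(len(rats))
    for k in order:
        rat = rats[k]
        if not rat.alive:
            continue
        idx = rat.neigh_idx
        if idx is None or idx.size == 0:
            continue
        active = doses[idx] > 0
        if not active.any():
            continue
        p = rat.neigh_base[active]
        if rat.estar.indicator(night):
            p = p**rat.tau
        hit = rng.random(p.size) < p
        if not hit.any():
            continue
        rat.estar.record(night)
        stations = idx[active][hit]
        for m in stations[rng.permutation(stations.size)]:
            if doses[m] <= 0:
                continue
            if rng.random() < rat.theta:
                rat.alive = False
                doses[m] -= 1
                removals += 1
                break
    return removals


def growth_step(
    rats: list[SimRat],
    day: int,
    config: EradicationConfig,
    area: StudyArea,
    posterior: PosteriorDraws,
    tree: cKDTree,
    station_xy: np.ndarray,
    rng,
) -> int:
    """Season-restricted daily logistic births; returns number of births."""
    if config.month_of_day(day) not in config.breeding_months:
        return 0
    alive = [r for r in rats if r.alive]
    n = len(alive)
    if n == 0:
        return 0
    k_total = config.carrying_capacity * area.area_ha
    expected = n * (config.daily_multiplier - 1.0) * max(0.0, 1.0 - n / k_total)
    births = int(rng.poisson(expected))
    for _ in range(births):
        mother = alive[int(rng.integers(n))]
        for _ in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            rad = 2.0 * mother.sigma * np.sqrt(rng.random())
            x, y = mother.x + rad * np.cos(ang), mother.y + rad * np.sin(ang)
            if shapely.contains_xy(area.polygon, x, y):
                break
        else:
            x, y = mother.x, mother.y
        pup = _make_rat(x, y, posterior, rng, birth_day=day)
        _attach_neighbours(pup, tree, station_xy)
        rats.append(pup)
    return births


@dataclass
class EradicationResult:
    """Per-replicate trajectories and the headline eradication probability."""

    trajectories: np.ndarray  # (n_reps, horizon_days + 1) live population
    config: EradicationConfig

    def __post_init__(self) -> None:
        if (self.trajectories < 0).any():
            raise ValueError("negative population")

    @property
    def final_population(self) -> np.ndarray:
        return self.trajectories[:, -1]

    @property
    def eradication_probability(self) -> float:
        return float((self.final_population == 0).mean())

    def eradication_by(self, day: int) -> float:
        """Share of replicates already at zero on the given day."""
        return float((self.trajectories[:, day] == 0).mean())

    def summary(self) -> dict:
        fp = self.final_population
        return {
            "spacing": self.config.spacing,
            "check_interval": self.config.check_interval,
            "n_reps": self.config.n_reps,
            "horizon_days": self.config.horizon_days,
            "median_final_population": float(np.median(fp)),
            "final_population_ci90": [float(np.percentile(fp, 5)), float(np.percentile(fp, 95))],
            "eradication_probability": self.eradication_probability,
        }


def run_eradication(
    config: EradicationConfig, area: StudyArea, posterior: PosteriorDraws
) -> EradicationResult:
    """Replicated removal simulation; each replicate re-draws the station
    lattice offset and all rat placements/parameters."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    traj = np.zeros((config.n_reps, config.horizon_days + 1), dtype=int)
    for rep in range(config.n_reps):
        rng = np.random.default_rng(children[rep])
        offset = tuple(rng.uniform(0, config.spacing, 2))
        station_xy = build_grid(area, config.spacing, offset)
        tree = cKDTree(station_xy)
        doses = np.full(len(station_xy), config.max_catch_per_station, dtype=int)
        rats = init_population(area, config.initial_density, posterior, rng)
        for rat in rats:
            _attach_neighbours(rat, tree, station_xy)
        traj[rep, 0] = len(rats)
        for day in range(1, config.horizon_days + 1):
            if (day - 1) % config.check_interval == 0:
                doses[:] = config.max_catch_per_station
            nightly_step(rats, doses, day, rng)
            if config.bycatch_prob > 0:
                active = doses > 0
                lost = rng.random(int(active.sum())) < config.bycatch_prob
                doses[np.flatnonzero(active)[lost]] -= 1
            growth_step(rats, day, config, area, posterior, tree, station_xy, rng)
            traj[rep, day] = sum(r.alive for r in rats)
            if traj[rep, day] == 0 and config.month_of_day(day) not in config.breeding_months:
                # population extinct and no births possible: short-circuit
                traj[rep, day:] = 0
                break
            if traj[rep, day] == 0:
                traj[rep, day:] = 0
                break
    return EradicationResult(trajectories=traj, config=config)
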