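"""Synthetic data with exactly the statistical structure the model assumes.

The generator emulates the field study end to end: lognormal home-range
heterogeneity, symmetric bivariate-normal telemetry about fixed centres,
one device of each type placed at random within each rat's home range,
Bernoulli encounters with half-normal distance decay plus behavioural
dynamics (E*), optional exponential spatial covariance on the logit scale,
and Bernoulli interactions given encounter with their own dynamics (I*).
Every Bernoulli outcome's generating probability is recorded in a
TruthBundle so that recovery tests can compare against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    DeviceTable,
    EncounterLog,
    InteractionLog,
    StudyArea,
    TelemetryTable,
    square_area,
)
from .history import BehaviourState
from .kernels import CUTOFF_MULTIPLIER, clipped_expit, encounter_prob, spatial_covariance
from .params import (
    DeviceLayoutSpec,
    EncounterParams,
    InteractionParams,
    PopulationSpec,
)


class PlacementError(RuntimeError):
    """Rejection sampling could not satisfy the device-layout constraints."""


@dataclass
class TruthBundle:
    """Ground truth for a synthetic dataset: latent states and probabilities."""

    rats: pd.DataFrame  # rat_id, sex, x, y, sigma, delta, rho
    encounter_params: EncounterParams
    interaction_params: InteractionParams
    truth_enc: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth_int: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for df, col in ((self.truth_enc, "gamma"), (self.truth_int, "theta")):
            if len(df) and not ((df[col] >= 0) & (df[col] <= 1)).all():
                raise ValueError(f"generating probabilities {col} outside [0, 1]")


def draw_sigmas(spec: PopulationSpec, sexes, rng: np.random.Generator) -> np.ndarray:
    """Per-rat home-range scales: ln(sigma_i) ~ N(beta0 + beta1*sex_i, V)."""
    if spec.fixed_sigmas is not None:
        return np.asarray(spec.fixed_sigmas, dtype=float)
    hr = spec.home_range
    mu = hr.beta0 + hr.beta1 * np.asarray(sexes, dtype=float)
    return np.exp(rng.normal(mu, np.sqrt(hr.V)))


def draw_population(spec: PopulationSpec, rng: np.random.Generator, area: StudyArea) -> pd.DataFrame:
    """Rats with sex, home-range centre, sigma and individual effects."""
    n = spec.n_rats
    sexes = (rng.random(n) < spec.sex_ratio).astype(int)
    sigmas = draw_sigmas(spec, sexes, rng)
    minx, miny, maxx, maxy = area.polygon.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    return pd.DataFrame(
        {
            "rat_id": [f"r{i:03d}" for i in range(n)],
            "sex": sexes,
            "x": xs,
            "y": ys,
            "sigma": sigmas,
            "delta": rng.normal(0.0, spec.delta_sd, n),
            "rho": rng.normal(0.0, spec.rho_sd, n),
        }
    )


def simulate_telemetry(
    centres, sigmas, fixes_per_rat: int, rng: np.random.Generator, sexes=None, rat_ids=None
) -> TelemetryTable:
    """Independent bivariate-normal fixes about each centre, sd sigma_i per axis."""
    centres = np.asarray(centres, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("sigma must be >= 0")
    if fixes_per_rat < 1:
        raise ValueError("fixes_per_rat must be >= 1")
    n = len(sigmas)
    sexes = np.zeros(n, dtype=int) if sexes is None else np.asarray(sexes, dtype=int)
    rat_ids = [f"r{i:03d}" for i in range(n)] if rat_ids is None else list(rat_ids)
    rows = []
    for i in range(n):
        dx = rng.normal(0.0, sigmas[i], fixes_per_rat)
        dy = rng.normal(0.0, sigmas[i], fixes_per_rat)
        rows.append(
            pd.DataFrame(
                {
                    "rat_id": rat_ids[i],
                    "sex": sexes[i],
                    "night": np.arange(fixes_per_rat),
                    "x": centres[i, 0] + dx,
                    "y": centres[i, 1] + dy,
                }
            )
        )
    return TelemetryTable(pd.concat(rows, ignore_index=True))


def place_devices(
    centres,
    layout: DeviceLayoutSpec,
    rng: np.random.Generator,
    n_nights: int = 20,
    area: StudyArea | None = None,
    max_attempts: int = 10_000,
) -> DeviceTable:
    """One device of each type per rat (field protocol) or a square lattice."""
    from .eradication import build_grid  # grid mode shares the lattice helper

    nights = frozenset(range(n_nights))
    if layout.mode == "grid":
        if area is None:
            raise ValueError("grid mode needs a study area")
        stations = build_grid(area, layout.spacing)
        df = pd.DataFrame(
            {
                "device_id": [f"g{k:05d}" for k in range(len(stations))],
                "device_type": "baitstation",
                "x": stations[:, 0],
                "y": stations[:, 1],
            }
        )
        return DeviceTable(df, {d: nights for d in df["device_id"]})

    centres = np.asarray(centres, dtype=float)
    types = ("baitstation", "chewcard", "waxtag")
    recs = []
    avail: dict[str, frozenset[int]] = {}
    for i, (cx, cy) in enumerate(centres):
        for attempt in range(max_attempts + 1):
            if attempt == max_attempts:
                raise PlacementError(
                    f"could not place 3 devices within {layout.max_distance} m of rat {i} "
                    f"with pairwise separation > {layout.min_separation} m"
                )
            dist = layout.max_distance * (1.0 - rng.random(3))  # uniform on (0, max]
            ang = rng.uniform(0.0, 2.0 * np.pi, 3)
            pos = np.column_stack([cx + dist * np.cos(ang), cy + dist * np.sin(ang)])
            d01 = np.hypot(*(pos[0] - pos[1]))
            d02 = np.hypot(*(pos[0] - pos[2]))
            d12 = np.hypot(*(pos[1] - pos[2]))
            if min(d01, d02, d12) > layout.min_separation:
                break
        for t, (px, py) in zip(types, pos):
            did = f"d{i:03d}_{t}"
            recs.append((did, t, px, py))
            avail[did] = nights
    df = pd.DataFrame(recs, columns=["device_id", "device_type", "x", "y"])
    return DeviceTable(df, avail)


def _device_type_offsets(devices: DeviceTable, params) -> np.ndarray:
    mapping = {
        "baitstation": 0.0,
        "chewcard": params[0],
        "waxtag": params[1],
    }
    return devices.df["device_type"].map(mapping).to_numpy(dtype=float)


def simulate_encounter_history(
    rats: pd.DataFrame,
    devices: DeviceTable,
    n_nights: int,
    params: EncounterParams,
    rng: np.random.Generator,
    use_spatial: bool = False,
    shared_field: bool = False,
) -> tuple[EncounterLog, pd.DataFrame]:
    """Nightly Bernoulli encounters for every in-range available device-night.

    Returns the log plus a truth frame holding, per simulated cell, the
    distance, behavioural state E*, the kernel probability P and the
    (possibly spatially perturbed) generating probability gamma.
    """
    if params.tau <= 0:
        raise ValueError("tau must be > 0")
    dev_xy = devices.df[["x", "y"]].to_numpy(dtype=float)
    dev_ids = devices.df["device_id"].to_numpy()
    type_off = _device_type_offsets(devices, (params.alpha2, params.alpha3))
    avail_sets = devices.availability

    rat_xy = rats[["x", "y"]].to_numpy(dtype=float)
    sigmas = rats["sigma"].to_numpy(dtype=float)
    deltas = rats["delta"].to_numpy(dtype=float)
    dist = np.hypot(
        rat_xy[:, 0:1] - dev_xy[None, :, 0], rat_xy[:, 1:2] - dev_xy[None, :, 1]
    )  # (R, M)
    # static candidate pairs: within the screening radius at the generating sigma
    cand = dist <= CUTOFF_MULTIPLIER * sigmas[:, None]

    logit_eps = (
        params.alpha0
        + params.alpha1 * np.log(sigmas)[:, None]
        + type_off[None, :]
        + deltas[:, None]
    )
    eps0 = clipped_expit(logit_eps)

    states = [BehaviourState() for _ in range(len(rats))]
    rows: list[dict] = []
    for t in range(n_nights):
        avail = np.array([t in avail_sets[d] for d in dev_ids])
        shared_draw = None
        if use_spatial and shared_field and avail.sum() > 0:
            cov = spatial_covariance(dev_xy[avail], params.nu2, params.phi)
            shared_draw = np.full(len(dev_ids), np.nan)
            shared_draw[avail] = rng.multivariate_normal(np.zeros(avail.sum()), cov)
        for i in range(len(rats)):
            cols = np.flatnonzero(cand[i] & avail)
            if cols.size == 0:
                continue
            estar = states[i].indicator(t)
            p = encounter_prob(dist[i, cols], sigmas[i], eps0[i, cols], params.tau, estar)
            p = np.atleast_1d(np.asarray(p, dtype=float))
            gamma = p
            if use_spatial:
                if shared_field:
                    noise = shared_draw[cols]
                else:
                    cov = spatial_covariance(dev_xy[cols], params.nu2, params.phi)
                    noise = rng.multivariate_normal(np.zeros(cols.size), cov)
                gamma = clipped_expit(np.log(p / (1.0 - p)) + noise)
            enc = (rng.random(cols.size) < gamma).astype(int)
            if enc.any():
                states[i].record(t)
            for k, m in enumerate(cols):
                rows.append(
                    {
                        "rat_id": rats["rat_id"].iat[i],
                        "device_id": dev_ids[m],
                        "night": t,
                        "distance": dist[i, m],
                        "estar": int(estar),
                        "p": p[k],
                        "gamma": gamma[k],
                        "encountered": enc[k],
                    }
                )
    truth = pd.DataFrame(
        rows,
        columns=["rat_id", "device_id", "night", "distance", "estar", "p", "gamma", "encountered"],
    )
    log = EncounterLog(truth[["rat_id", "device_id", "night", "encountered"]].copy())
    return log, truth


def simulate_interaction_history(
    encounters: EncounterLog,
    rats: pd.DataFrame,
    devices: DeviceTable,
    params: InteractionParams,
    rng: np.random.Generator,
) -> tuple[InteractionLog, pd.DataFrame]:
    """Bernoulli interactions for every encountered (rat, device, night)."""
    enc = encounters.df
    enc = enc[enc["encountered"] == 1].sort_values(["rat_id", "night", "device_id"])
    type_of = dict(zip(devices.df["device_id"], devices.df["device_type"]))
    rho_of = dict(zip(rats["rat_id"], rats["rho"]))
    offsets = {"baitstation": 0.0, "chewcard": params.lambda1, "waxtag": params.lambda2}

    states: dict[str, BehaviourState] = {}
    rows: list[dict] = []
    for rat_id, sub in enc.groupby("rat_id", sort=True):
        st = states.setdefault(rat_id, BehaviourState())
        for night, night_sub in sub.groupby("night", sort=True):
            istar = st.indicator(int(night))
            interacted_any = False
            for r in night_sub.itertuples():
                lp = (
                    params.lambda0
                    + offsets[type_of[r.device_id]]
                    + params.lambda3 * istar
                    + rho_of[rat_id]
                )
                theta = float(clipped_expit(lp))
                hit = int(rng.random() < theta)
                interacted_any = interacted_any or bool(hit)
                rows.append(
                    {
                        "rat_id": rat_id,
                        "device_id": r.device_id,
                        "night": int(night),
                        "istar": int(istar),
                        "theta": theta,
                        "interacted": hit,
                    }
                )
            if interacted_any:
                st.record(int(night))
    truth = pd.DataFrame(
        rows, columns=["rat_id", "device_id", "night", "istar", "theta", "interacted"]
    )
    log = InteractionLog(truth[["rat_id", "device_id", "night", "interacted"]].copy())
    return log, truth


def generate_dataset(
    pop_spec: PopulationSpec,
    layout_spec: DeviceLayoutSpec,
    n_nights: int,
    enc_params: EncounterParams,
    int_params: InteractionParams,
    seed: int,
    area: StudyArea | None = None,
    fixes_per_rat: int = 43,
    use_spatial: bool = False,
    shared_field: bool = False,
) -> tuple[TelemetryTable, DeviceTable, EncounterLog, InteractionLog, TruthBundle]:
    """Compose the full generator under a single seed (deterministic)."""
    rng = np.random.default_rng(seed)
    if area is None:
        # ~4 ha per rat keeps densities in the observed range without
        # forcing unrelated home ranges to overlap
        area = square_area(max(1.0, 4.0 * pop_spec.n_rats))
    rats = draw_population(pop_spec, rng, area)
    tel = simulate_telemetry(
        rats[["x", "y"]].to_numpy(),
        rats["sigma"].to_numpy(),
        fixes_per_rat,
        rng,
        sexes=rats["sex"].to_numpy(),
        rat_ids=rats["rat_id"].tolist(),
    )
    devices = place_devices(
        rats[["x", "y"]].to_numpy(), layout_spec, rng, n_nights=n_nights, area=area
    )
    enc_log, truth_enc = simulate_encounter_history(
        rats, devices, n_nights, enc_params, rng, use_spatial, shared_field
    )
    int_log, truth_int = simulate_interaction_history(enc_log, rats, devices, int_params, rng)
    truth = TruthBundle(rats, enc_params, int_params, truth_enc, truth_int)
    return tel, devices, enc_log, int_log, truth
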