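"""Joint likelihood of the hierarchical detection model.

Three observation processes share parameters:

* telemetry: fixes are symmetric bivariate normal about a known centre
  (the centroid of each rat's fixes), with per-rat scale sigma_i;
* encounters: nightly Bernoulli with half-normal distance decay, device-type
  and individual (delta_i) effects on the logit of eps0, a behavioural
  exponent tau on nights with recent encounters, and (optionally) an
  exponential spatially correlated error on the logit scale;
* interactions: Bernoulli given encounter, with device-type, behavioural
  (lambda3 * I*) and individual (rho_i) effects on the logit.

ln(sigma_i) is hierarchically normal in sex with variance V, so sigma_i is
informed jointly by the telemetry and the encounter data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .data_io import DeviceTable, EncounterLog, InteractionLog, TelemetryTable
from .history import indicator_from_events
from .kernels import (
    CUTOFF_MULTIPLIER,
    PROB_FLOOR,
    clipped_expit,
    spatial_covariance,
)
from .params import Priors

_LOG_TINY = np.log(1e-300)

#: Candidate (rat, device) pairs are kept when the distance is below
#: CUTOFF_MULTIPLIER * exp(ln sigma_hat + CANDIDATE_MARGIN); sigma draws are
#: pinned by the telemetry far inside this envelope.
CANDIDATE_MARGIN = 0.6


def home_range_centres(tel: TelemetryTable) -> pd.DataFrame:
    """Centroid of all fixes per rat, treated as perfectly observed."""
    g = tel.df.groupby("rat_id")
    out = g[["x", "y"]].mean()
    out["sex"] = g["sex"].first()
    out["n_fixes"] = g.size()
    return out.reset_index()


def telemetry_loglik(sigma: float, deviations) -> float:
    """Log-likelihood of fix-minus-centre offsets under N(0, sigma^2) per axis."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    dev = np.asarray(deviations, dtype=float).reshape(-1, 2)
    n = dev.shape[0]
    ss = float((dev**2).sum())
    return -2.0 * n * np.log(sigma) - n * np.log(2.0 * np.pi) - ss / (2.0 * sigma**2)


@dataclass
class ModelData:
    """Flattened, validated model inputs ready for vectorised likelihoods."""

    rat_ids: list[str]
    sexes: np.ndarray  # (R,)
    n_fixes: np.ndarray  # fixes per rat (per-axis count L_i)
    ss: np.ndarray  # sum of squared x+y deviations per rat
    centres: np.ndarray  # (R, 2)
    # encounter cells
    e_rat: np.ndarray
    e_dist: np.ndarray
    e_cc: np.ndarray
    e_wt: np.ndarray
    e_estar: np.ndarray
    e_y: np.ndarray
    e_night: np.ndarray
    e_dev_xy: np.ndarray  # (C, 2) device coordinates per cell
    # interaction cells
    i_rat: np.ndarray
    i_cc: np.ndarray
    i_wt: np.ndarray
    i_istar: np.ndarray
    i_y: np.ndarray
    sigma_hat: np.ndarray = field(default=None)  # type: ignore[assignment]
    # spatial blocks: (rat, night, cell indices) with d <= 3.72 sigma_hat;
    # fixed support for the latent logit-gamma vectors when the spatial
    # term is on (sigma draws move well inside the candidate envelope)
    spatial_groups: list = field(default_factory=list)
    in_group: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma_hat is None:
            self.sigma_hat = np.sqrt(self.ss / (2.0 * np.maximum(self.n_fixes, 1)))
        if self.in_group is None:
            self.in_group = np.zeros(len(self.e_rat), dtype=bool)
            for _, _, idx in self.spatial_groups:
                self.in_group[idx] = True

    @property
    def n_rats(self) -> int:
        return len(self.rat_ids)

    @classmethod
    def from_tables(
        cls,
        tel: TelemetryTable,
        devices: DeviceTable,
        encounters: EncounterLog,
        interactions: InteractionLog,
        candidate_margin: float = CANDIDATE_MARGIN,
    ) -> "ModelData":
        encounters.validate_against(devices)
        interactions.validate_against(encounters)
        centres = home_range_centres(tel)
        rat_ids = centres["rat_id"].tolist()
        rat_idx = {r: k for k, r in enumerate(rat_ids)}
        cxy = centres[["x", "y"]].to_numpy(dtype=float)

        g = tel.df.groupby("rat_id")
        n_fixes = g.size().loc[rat_ids].to_numpy(dtype=float)
        dev = tel.df[["x", "y"]].to_numpy(dtype=float) - cxy[
            tel.df["rat_id"].map(rat_idx).to_numpy()
        ]
        ss = np.bincount(
            tel.df["rat_id"].map(rat_idx).to_numpy(), weights=(dev**2).sum(axis=1),
            minlength=len(rat_ids),
        )
        sigma_hat = np.sqrt(ss / (2.0 * n_fixes))

        dxy = devices.df[["x", "y"]].to_numpy(dtype=float)
        dev_ids = devices.df["device_id"].tolist()
        dev_idx = {d: k for k, d in enumerate(dev_ids)}
        is_cc = (devices.df["device_type"] == "chewcard").to_numpy(dtype=float)
        is_wt = (devices.df["device_type"] == "waxtag").to_numpy(dtype=float)

        dist = np.hypot(cxy[:, 0:1] - dxy[None, :, 0], cxy[:, 1:2] - dxy[None, :, 1])
        radius = CUTOFF_MULTIPLIER * np.exp(np.log(sigma_hat) + candidate_margin)
        cand = dist <= radius[:, None]
        # always keep pairs with an observed record, wherever they lie
        enc = encounters.df
        for r in enc.itertuples():
            cand[rat_idx[r.rat_id], dev_idx[r.device_id]] = True

        obs = {
            (rat_idx[r.rat_id], dev_idx[r.device_id], r.night): r.encountered
            for r in enc.itertuples()
        }
        event_nights = {
            i: enc.loc[(enc["encountered"] == 1) & (enc["rat_id"] == rid), "night"].to_numpy()
            for rid, i in rat_idx.items()
        }

        e_rat, e_dist, e_cc, e_wt, e_night, e_y, e_dev = [], [], [], [], [], [], []
        for i in range(len(rat_ids)):
            for m in np.flatnonzero(cand[i]):
                for t in sorted(devices.availability[dev_ids[m]]):
                    e_rat.append(i)
                    e_dist.append(dist[i, m])
                    e_cc.append(is_cc[m])
                    e_wt.append(is_wt[m])
                    e_night.append(t)
                    e_y.append(obs.get((i, m, t), 0))
                    e_dev.append(m)
        e_rat = np.asarray(e_rat, dtype=int)
        e_night = np.asarray(e_night, dtype=int)
        e_estar = np.zeros(len(e_rat), dtype=bool)
        for i, nights in event_nights.items():
            mask = e_rat == i
            e_estar[mask] = indicator_from_events(nights, e_night[mask])

        inter = interactions.df
        int_events = {
            rid: inter.loc[(inter["interacted"] == 1) & (inter["rat_id"] == rid), "night"].to_numpy()
            for rid in rat_idx
        }
        i_rat = inter["rat_id"].map(rat_idx).to_numpy(dtype=int)
        types = inter["device_id"].map(
            dict(zip(devices.df["device_id"], devices.df["device_type"]))
        )
        i_cc = (types == "chewcard").to_numpy(dtype=float)
        i_wt = (types == "waxtag").to_numpy(dtype=float)
        i_istar = np.zeros(len(inter), dtype=bool)
        nights_arr = inter["night"].to_numpy(dtype=int)
        for rid, i in rat_idx.items():
            mask = i_rat == i
            i_istar[mask] = indicator_from_events(int_events[rid], nights_arr[mask])

        e_rat_arr = e_rat
        e_night_arr = e_night
        e_dist_arr = np.asarray(e_dist, dtype=float)
        groups = []
        strict = e_dist_arr <= CUTOFF_MULTIPLIER * sigma_hat[e_rat_arr]
        for i in range(len(rat_ids)):
            for t in np.unique(e_night_arr[e_rat_arr == i]):
                idx = np.flatnonzero((e_rat_arr == i) & (e_night_arr == t) & strict)
                if idx.size:
                    groups.append((i, int(t), idx))

        return cls(
            rat_ids=rat_ids,
            sexes=centres["sex"].to_numpy(dtype=float),
            n_fixes=n_fixes,
            ss=ss,
            centres=cxy,
            e_rat=e_rat,
            e_dist=np.asarray(e_dist, dtype=float),
            e_cc=np.asarray(e_cc, dtype=float),
            e_wt=np.asarray(e_wt, dtype=float),
            e_estar=e_estar,
            e_y=np.asarray(e_y, dtype=float),
            e_night=e_night,
            e_dev_xy=dxy[np.asarray(e_dev, dtype=int)],
            i_rat=i_rat,
            i_cc=i_cc,
            i_wt=i_wt,
            i_istar=i_istar,
            i_y=inter["interacted"].to_numpy(dtype=float),
            sigma_hat=sigma_hat,
            spatial_groups=groups,
        )


@dataclass
class ModelState:
    """One point in parameter space (s = ln sigma per rat)."""

    s: np.ndarray
    delta: np.ndarray
    rho: np.ndarray
    beta0: float
    beta1: float
    V: float
    alpha: np.ndarray  # (4,)
    tau: float
    lam: np.ndarray  # (4,)
    nu2: float = np.e**3
    phi: float = np.e
    latent: dict | None = None  # (rat, night) -> logit-gamma vector (spatial on)

    def copy(self) -> "ModelState":
        return ModelState(
            self.s.copy(), self.delta.copy(), self.rho.copy(), self.beta0, self.beta1,
            self.V, self.alpha.copy(), self.tau, self.lam.copy(), self.nu2, self.phi,
            None if self.latent is None else {k: v.copy() for k, v in self.latent.items()},
        )


# ---------------------------------------------------------------------------
# Likelihood pieces (all return per-rat vectors where useful)


def telemetry_loglik_per_rat(data: ModelData, s: np.ndarray) -> np.ndarray:
    sig2 = np.exp(2.0 * s)
    return -2.0 * data.n_fixes * s - data.n_fixes * np.log(2 * np.pi) - data.ss / (2.0 * sig2)


def hierarchy_loglik_per_rat(data: ModelData, s, beta0, beta1, V) -> np.ndarray:
    mu = beta0 + beta1 * data.sexes
    return -0.5 * np.log(2 * np.pi * V) - (s - mu) ** 2 / (2.0 * V)


def encounter_cell_probs(data: ModelData, s, delta, alpha, tau) -> np.ndarray:
    """Kernel probability P for every encounter cell at the given state."""
    sr = s[data.e_rat]
    sig = np.exp(sr)
    lp = alpha[0] + alpha[1] * sr + alpha[2] * data.e_cc + alpha[3] * data.e_wt + delta[data.e_rat]
    eps0 = clipped_expit(lp)
    base = np.maximum(eps0 * np.exp(-(data.e_dist**2) / (2.0 * sig**2)), PROB_FLOOR)
    expo = np.where(data.e_estar, tau, 1.0)
    inside = data.e_dist <= CUTOFF_MULTIPLIER * sig
    return np.where(inside, base**expo, 0.0)


def _bernoulli_ll(y, p) -> np.ndarray:
    p = np.minimum(p, 1.0 - 1e-12)
    return np.where(y == 1, np.log(np.maximum(p, 1e-300)), np.log1p(-p))


def encounter_loglik_per_rat(
    data: ModelData, s, delta, alpha, tau, latent=None, nu2=None, phi=None
) -> np.ndarray:
    """Per-rat encounter log-likelihood.

    With the spatial term off, gamma == P and this is a plain Bernoulli
    likelihood. With latent logit-gamma vectors supplied, each in-range
    rat-night block contributes Bernoulli(y | expit(u)) plus the
    multivariate-normal density of u about logit(P) with exponential
    covariance over that night's device positions.
    """
    p = encounter_cell_probs(data, s, delta, alpha, tau)
    if latent is None:
        ll = _bernoulli_ll(data.e_y, p)
        return np.bincount(data.e_rat, weights=ll, minlength=data.n_rats)

    out = np.zeros(data.n_rats)
    # cells outside every spatial block keep gamma = P
    idx_out = np.flatnonzero(~data.in_group)
    ll_out = _bernoulli_ll(data.e_y[idx_out], p[idx_out])
    out += np.bincount(data.e_rat[idx_out], weights=ll_out, minlength=data.n_rats)
    for i, t, cells in data.spatial_groups:
        u = latent[(i, t)]
        if cells.size != u.size:
            raise ValueError(f"latent vector for rat {i} night {t} has wrong length")
        pc = np.clip(p[cells], PROB_FLOOR, 1.0 - 1e-12)
        mean = np.log(pc / (1.0 - pc))
        cov = spatial_covariance(data.e_dev_xy[cells], nu2, phi)
        gamma = clipped_expit(u)
        out[i] += _bernoulli_ll(data.e_y[cells], gamma).sum()
        out[i] += multivariate_normal.logpdf(u, mean=mean, cov=cov, allow_singular=True)
    return out


def interaction_loglik_per_rat(data: ModelData, rho, lam) -> np.ndarray:
    if data.i_y.size == 0:
        return np.zeros(data.n_rats)
    lp = lam[0] + lam[1] * data.i_cc + lam[2] * data.i_wt + lam[3] * data.i_istar + rho[data.i_rat]
    theta = clipped_expit(lp)
    ll = _bernoulli_ll(data.i_y, theta)
    return np.bincount(data.i_rat, weights=ll, minlength=data.n_rats)


def interaction_loglik(data: ModelData, rho, lam) -> float:
    return float(interaction_loglik_per_rat(data, rho, lam).sum())


def log_prior(state: ModelState, priors: Priors, spatial: bool = False) -> float:
    def normal_lp(x, var):
        x = np.asarray(x, dtype=float)
        return float((-0.5 * np.log(2 * np.pi * var) - x**2 / (2 * var)).sum())

    if state.tau <= 0 or state.V <= 0:
        return -np.inf
    lp = 0.0
    lp += normal_lp([state.beta0, state.beta1], priors.coef_var)
    lp += normal_lp(state.alpha, priors.coef_var)
    lp += normal_lp(state.lam, priors.coef_var)
    lp += normal_lp(state.delta, priors.effect_var)
    lp += normal_lp(state.rho, priors.effect_var)
    # tau ~ Gamma(shape, rate)
    a, b = priors.tau_shape, priors.tau_rate
    lp += a * np.log(b) - math.lgamma(a) + (a - 1) * np.log(state.tau) - b * state.tau
    # V ~ InverseGamma(a, b)
    av, bv = priors.v_a, priors.v_b
    lp += av * np.log(bv) - math.lgamma(av) - (av + 1) * np.log(state.V) - bv / state.V
    if spatial:
        for x, m, sd in (
            (state.nu2, priors.nu2_logmean, priors.nu2_logsd),
            (state.phi, priors.phi_logmean, priors.phi_logsd),
        ):
            if x <= 0:
                return -np.inf
            lp += -np.log(x * sd * np.sqrt(2 * np.pi)) - (np.log(x) - m) ** 2 / (2 * sd**2)
    return lp


def log_posterior(data: ModelData, state: ModelState, priors: Priors, spatial: bool = False) -> float:
    """Total log-posterior; the quantity the MCMC explores."""
    ll = telemetry_loglik_per_rat(data, state.s).sum()
    ll += hierarchy_loglik_per_rat(data, state.s, state.beta0, state.beta1, state.V).sum()
    latent = state.latent if spatial else None
    ll += encounter_loglik_per_rat(
        data, state.s, state.delta, state.alpha, state.tau, latent, state.nu2, state.phi
    ).sum()
    ll += interaction_loglik_per_rat(data, state.rho, state.lam).sum()
    return float(ll) + log_prior(state, priors, spatial)
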