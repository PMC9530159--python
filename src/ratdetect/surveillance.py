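"""Proof-of-absence surveillance design.

A surviving individual with home-range scale sigma and centre-point
detection probability g0 is missed by one device-night at distance d with
probability 1 - g0*exp(-d^2/2sigma^2). Integrating the resulting detection
hazard over a uniformly dense network gives the closed (cloglog) form of
surveillance-system sensitivity,

    SSe = 1 - exp(-nights * D * g0 * 2*pi*sigma^2),

with D the device density per square metre. Bayes' rule then converts a
manager's prior that eradication succeeded into a posterior probability of
absence (PoA) given no detections, and the inversion of that chain yields
the minimum device density that certifies eradication at a target PoA.
The closed form makes the required density exactly inversely proportional
to the number of surveillance nights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import clipped_expit
from .posterior import PosteriorDraws


@dataclass
class SurveillanceConfig:
    """Scenario for a proof-of-absence design calculation."""

    prior: float = 0.65
    nights: int = 14
    target_poa: float = 0.95
    device_type: str = "chewcard"
    area_ha: float = 1475.0
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prior < 1 and 0 < self.target_poa < 1):
            raise ValueError("prior and target_poa must be in (0, 1)")
        if self.nights < 1 or self.n_draws < 1 or self.area_ha <= 0:
            raise ValueError("nights, n_draws and area_ha must be positive")
        if self.device_type not in ("chewcard", "waxtag", "baitstation"):
            raise ValueError(f"unknown device type {self.device_type!r}")


def system_sensitivity(density: float, sigma: float, g0: float, nights: float) -> float:
    """Probability the network detects a surviving individual.

    density is devices per hectare; sigma in metres; g0 the nightly
    centre-point detection probability; nights the deployment length.
    """
    if np.any(np.asarray([sigma, g0]) <= 0) or nights <= 0 or np.any(np.asarray(density) < 0):
        raise ValueError("inputs must be positive (density >= 0)")
    d_m2 = np.asarray(density, dtype=float) / 1e4
    out = 1.0 - np.exp(-nights * d_m2 * g0 * 2.0 * np.pi * sigma**2)
    return out if out.ndim else float(out)


def system_sensitivity_grid(
    station_xy, centre, sigma: float, g0: float, nights: float
) -> float:
    """Cross-check form: explicit product over device positions.

    Complements the closed form by evaluating the same hazard over an
    explicit grid for one home-range centre.
    """
    xy = np.asarray(station_xy, dtype=float)
    d2 = ((xy - np.asarray(centre, dtype=float)) ** 2).sum(axis=1)
    p_night = g0 * np.exp(-d2 / (2 * sigma**2))
    return float(1.0 - np.exp(nights * np.log1p(-p_night).sum()))


def probability_of_absence(prior: float, sse) -> float:
    """Posterior probability of absence given no detections."""
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    sse = np.asarray(sse, dtype=float)
    if np.any((sse < 0) | (sse > 1)):
        raise ValueError("sse must be in [0, 1]")
    out = prior / (prior + (1.0 - prior) * (1.0 - sse))
    return out if out.ndim else float(out)


def required_sensitivity(prior: float, target_poa: float) -> float:
    """SSe needed so that PoA reaches the target given the prior."""
    if target_poa <= prior:
        return 0.0
    return float(1.0 - prior * (1.0 - target_poa) / (target_poa * (1.0 - prior)))


def required_density(
    prior: float, target_poa: float, sigma: float, g0: float, nights: float
) -> float:
    """Minimum device density (per ha) achieving the target PoA."""
    if target_poa <= prior:
        warnings.warn("target PoA does not exceed the prior; no surveillance needed")
        return 0.0
    sse_req = required_sensitivity(prior, target_poa)
    return float(-np.log(1.0 - sse_req) / (nights * g0 * 2.0 * np.pi * sigma**2) * 1e4)


@dataclass
class DesignResult:
    """Per-draw required densities and their summaries."""

    densities: np.ndarray  # devices per ha, one per posterior draw
    config: SurveillanceConfig

    @property
    def counts(self) -> np.ndarray:
        return np.ceil(self.densities * self.config.area_ha).astype(int)

    def summary(self) -> dict:
        d, c = self.densities, self.counts
        return {
            "device_type": self.config.device_type,
            "prior": self.config.prior,
            "nights": self.config.nights,
            "target_poa": self.config.target_poa,
            "area_ha": self.config.area_ha,
            "median_density_per_ha": float(np.median(d)),
            "density_ci90": [float(np.percentile(d, 5)), float(np.percentile(d, 95))],
            "median_device_count": int(np.median(c)),
            "count_ci90": [int(np.percentile(c, 5)), int(np.percentile(c, 95))],
        }


def draw_level_parameters(posterior: PosteriorDraws, device_type: str) -> pd.DataFrame:
    """Population-level sigma and device-specific g0 per posterior draw.

    The population individual has delta = rho = 0 and a naive behavioural
    state; sigma is the population geometric mean implied by each draw
    (mean of ln sigma_i over the draw's rats).
    """
    g = posterior.globals_
    ln_sigma = np.log(posterior.sigma).mean(axis=1)
    off_eps = {"baitstation": 0.0, "chewcard": g["alpha2"], "waxtag": g["alpha3"]}[device_type]
    off_th = {"baitstation": 0.0, "chewcard": g["lambda1"], "waxtag": g["lambda2"]}[device_type]
    eps0 = clipped_expit(g["alpha0"] + g["alpha1"] * ln_sigma + off_eps)
    theta = clipped_expit(g["lambda0"] + off_th)
    return pd.DataFrame(
        {"sigma": np.exp(ln_sigma), "eps0": eps0, "theta": theta, "g0": eps0 * theta}
    )


def design_over_draws(config: SurveillanceConfig, posterior: PosteriorDraws) -> DesignResult:
    """Required density per posterior draw, summarised as median and 90% CI."""
    n = min(config.n_draws, posterior.n_draws)
    pars = draw_level_parameters(posterior, config.device_type).iloc[:n]
    sse_req = required_sensitivity(config.prior, config.target_poa)
    if sse_req == 0.0:
        warnings.warn("target PoA does not exceed the prior; no surveillance needed")
        return DesignResult(np.zeros(n), config)
    dens = (
        -np.log(1.0 - sse_req)
        / (config.nights * pars["g0"].to_numpy() * 2.0 * np.pi * pars["sigma"].to_numpy() ** 2)
        * 1e4
    )
    return DesignResult(dens, config)
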