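"""Posterior summaries of the detection parameters eps0, theta and g0.

g0 — the nightly probability of encountering AND interacting with a device
at the home-range centre — is the product eps0 * theta, evaluated per rat
and device type at the posterior-mean coefficients with that rat's
posterior-mean individual effects (delta_i, rho_i) and a naive behavioural
state (E* = I* = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DEVICE_TYPES
from .kernels import clipped_expit, home_range_area
from .posterior import PosteriorDraws


@dataclass
class DetectionSummary:
    """Parameter summaries plus individual-level detection probabilities."""

    params: pd.DataFrame  # mean, ci5, ci95 per global parameter
    per_rat: pd.DataFrame  # rat_id x device_type -> eps0, theta, g0, sigma
    population: pd.DataFrame  # mean/sd per device type and pooled

    def __post_init__(self) -> None:
        pr = self.per_rat
        if len(pr):
            if not np.allclose(pr["g0"], pr["eps0"] * pr["theta"]):
                raise ValueError("g0 must equal eps0 * theta")
            for col in ("eps0", "theta", "g0"):
                if ((pr[col] < 0) | (pr[col] > 1)).any():
                    raise ValueError(f"{col} outside [0, 1]")


def derive_detection(draws: PosteriorDraws) -> DetectionSummary:
    params = draws.summary()
    m = draws.mean()
    sigma_bar = draws.sigma.mean(axis=0)
    delta_bar = draws.delta.mean(axis=0)
    rho_bar = draws.rho.mean(axis=0)

    type_off_eps = {"baitstation": 0.0, "chewcard": m["alpha2"], "waxtag": m["alpha3"]}
    type_off_th = {"baitstation": 0.0, "chewcard": m["lambda1"], "waxtag": m["lambda2"]}

    rows = []
    for j, rid in enumerate(draws.rat_ids):
        for dt in DEVICE_TYPES:
            eps0 = float(
                clipped_expit(
                    m["alpha0"]
                    + m["alpha1"] * np.log(sigma_bar[j])
                    + type_off_eps[dt]
                    + delta_bar[j]
                )
            )
            theta = float(clipped_expit(m["lambda0"] + type_off_th[dt] + rho_bar[j]))
            rows.append(
                {
                    "rat_id": rid,
                    "device_type": dt,
                    "sigma": sigma_bar[j],
                    "home_range_ha": home_range_area(sigma_bar[j]),
                    "eps0": eps0,
                    "theta": theta,
                    "g0": eps0 * theta,
                }
            )
    per_rat = pd.DataFrame(rows)

    pops = []
    for dt, sub in per_rat.groupby("device_type"):
        pops.append(
            {
                "device_type": dt,
                "eps0_mean": sub["eps0"].mean(),
                "eps0_sd": sub["eps0"].std(ddof=1),
                "theta_mean": sub["theta"].mean(),
                "theta_sd": sub["theta"].std(ddof=1),
                "g0_mean": sub["g0"].mean(),
                "g0_sd": sub["g0"].std(ddof=1),
            }
        )
    pooled = {
        "device_type": "all",
        "eps0_mean": per_rat["eps0"].mean(),
        "eps0_sd": per_rat["eps0"].std(ddof=1),
        "theta_mean": per_rat["theta"].mean(),
        "theta_sd": per_rat["theta"].std(ddof=1),
        "g0_mean": per_rat["g0"].mean(),
        "g0_sd": per_rat["g0"].std(ddof=1),
    }
    population = pd.DataFrame(pops + [pooled])
    return DetectionSummary(params=params, per_rat=per_rat, population=population)
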