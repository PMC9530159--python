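"""Closed-form pieces of the detection process.

The encounter process is a half-normal kernel: a rat whose home-range
utilisation is symmetric bivariate normal with scale sigma encounters a
device at distance d with nightly probability eps0 * exp(-d^2 / (2 sigma^2)),
where eps0 is the encounter probability for a device at the home-range
centre. Devices further than CUTOFF_MULTIPLIER * sigma are treated as
never encountered. A behavioural response enters as an exponent tau on the
nightly probability once the animal has encountered any device in the
previous RESET_WINDOW nights (tau < 1: device-happy, tau > 1: device-shy).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

#: Devices beyond this multiple of sigma from a home-range centre are ignored.
CUTOFF_MULTIPLIER = 3.72

#: Nights without an encounter/interaction after which the behavioural
#: indicator (E*/I*) resets to naive.
RESET_WINDOW = 20

#: Linear predictors are clipped to +/- this value before the inverse logit.
LINPRED_CLIP = 35.0

#: Floor applied to the base encounter probability before exponentiation.
PROB_FLOOR = 1e-12

_Q95 = float(np.sqrt(chi2.ppf(0.95, df=2)))  # ~2.4477


def clipped_expit(linpred):
    """Inverse logit with the linear predictor clipped to +/-35."""
    return expit(np.clip(linpred, -LINPRED_CLIP, LINPRED_CLIP))


def epsilon0_linpred(sigma, device_type, delta, alphas):
    """Maximum nightly encounter probability eps0 for one rat/device type.

    logit(eps0) = a0 + a1*ln(sigma) + a2*[chewcard] + a3*[waxtag] + delta,
    with bait station as the reference category.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    a0, a1, a2, a3 = alphas
    offset = {"baitstation": 0.0, "chewcard": a2, "waxtag": a3}[device_type]
    return clipped_expit(a0 + a1 * np.log(sigma) + offset + delta)


def theta_linpred(device_type, istar, rho, lambdas):
    """Conditional nightly interaction probability theta given an encounter.

    logit(theta) = l0 + l1*[chewcard] + l2*[waxtag] + l3*I* + rho.
    """
    l0, l1, l2, l3 = lambdas
    offset = {"baitstation": 0.0, "chewcard": l1, "waxtag": l2}[device_type]
    return clipped_expit(l0 + offset + l3 * np.asarray(istar, dtype=float) + rho)


def encounter_prob(d, sigma, eps0, tau, estar):
    """Nightly encounter probability at distance d from the centre.

    p = (eps0 * exp(-d^2 / 2 sigma^2)) ** (tau if estar else 1), and exactly 0
    beyond the CUTOFF_MULTIPLIER * sigma screening radius. The base
    probability is floored at PROB_FLOOR before exponentiation so p**tau is
    well behaved near zero.
    """
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be > 0")
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    base = np.maximum(eps0 * np.exp(-(d**2) / (2.0 * sigma**2)), PROB_FLOOR)
    expo = np.where(np.asarray(estar, dtype=bool), tau, 1.0)
    p = np.where(d <= CUTOFF_MULTIPLIER * sigma, base**expo, 0.0)
    return p if p.ndim else float(p)


def spatial_covariance(coords, nu2, phi, jitter=1e-10):
    """Exponential spatial covariance over device coordinates.

    Sigma_jk = nu2 * exp(-phi * r_jk) with r the pairwise distance in
    metres; a small diagonal jitter keeps the matrix positive definite at
    machine precision. Recomputed per night over the available devices only.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 1:
        raise ValueError("need at least one device")
    if nu2 <= 0 or phi <= 0:
        raise ValueError("nu2 and phi must be > 0")
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    cov = nu2 * np.exp(-phi * r)
    cov[np.diag_indices_from(cov)] += jitter * nu2
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise FloatingPointError("spatial covariance is not positive definite") from exc
    return cov


def home_range_area(sigma) -> float:
    """Area (ha) of the circular 95% activity contour for scale sigma (m).

    The contour radius is sigma * sqrt(chi2_{0.95, 2}) ~ 2.448 sigma.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    area = np.pi * (sigma * _Q95) ** 2 / 1e4
    return area if area.ndim else float(area)


def sigma_for_area(area_ha) -> float:
    """Inverse of :func:`home_range_area`."""
    area_ha = np.asarray(area_ha, dtype=float)
    if np.any(area_ha <= 0):
        raise ValueError("area must be > 0")
    sigma = np.sqrt(area_ha * 1e4 / np.pi) / _Q95
    return sigma if sigma.ndim else float(sigma)
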