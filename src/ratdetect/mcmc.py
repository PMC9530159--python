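"""Random-walk Metropolis sampler for the joint detection model.

The variance of the home-range hierarchy (V) is conjugate and sampled from
its inverse-gamma full conditional; everything else is updated by Gaussian
random-walk Metropolis in blocks (per-rat ln sigma, per-rat delta and rho,
the encounter coefficients and tau, the interaction coefficients, and the
hierarchy means). Proposal scales adapt towards ~0.3 acceptance during
burn-in and are frozen afterwards. Because the encounter and interaction
likelihoods factorise over rats once the spatial term is off, the per-rat
blocks are proposed and accepted in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invgamma

from .model import (
    ModelData,
    ModelState,
    encounter_loglik_per_rat,
    hierarchy_loglik_per_rat,
    interaction_loglik_per_rat,
    log_posterior,
    telemetry_loglik_per_rat,
)
from .params import Priors
from .posterior import GLOBAL_PARAMS, PosteriorDraws


@dataclass
class MCMCConfig:
    """Chain geometry and tuning knobs."""

    n_chains: int = 4
    n_samples: int = 3000  # retained draws per chain
    burn_in: int = 2000
    thin: int = 30
    seed: int = 0
    spatial: bool = False
    target_accept: float = 0.3
    adapt_interval: int = 50
    init_jitter: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_samples", "burn_in", "thin"):
            if getattr(self, name) < 1 and not (name == "burn_in" and self.burn_in == 0):
                raise ValueError(f"{name} must be positive")


def sample_V_full_conditional(
    ln_sigmas, beta0, beta1, sexes, rng, a: float = 0.01, b: float = 0.01
) -> float:
    """Gibbs draw of V ~ InverseGamma(a + n/2, b + SS/2)."""
    s = np.asarray(ln_sigmas, dtype=float)
    n = s.size
    if n == 0:
        return float(invgamma.rvs(a, scale=b, random_state=rng))
    ss = float(((s - beta0 - beta1 * np.asarray(sexes, dtype=float)) ** 2).sum())
    return float(invgamma.rvs(a + n / 2.0, scale=b + ss / 2.0, random_state=rng))


class _Adaptive:
    """A named proposal scale (scalar or vector) with windowed adaptation."""

    def __init__(self, value, target: float, interval: int):
        self.scale = np.asarray(value, dtype=float)
        self.target = target
        self.interval = interval
        self.accepts = np.zeros_like(self.scale)
        self.tries = 0
        self.cum_accepts = np.zeros_like(self.scale)
        self.cum_tries = 0

    def register(self, accepted) -> None:
        self.accepts = self.accepts + accepted
        self.tries += 1

    def maybe_adapt(self, adapting: bool) -> None:
        if self.tries < self.interval:
            return
        if adapting:
            rate = self.accepts / self.tries
            self.scale = np.clip(self.scale * np.exp(rate - self.target), 1e-4, 20.0)
        else:  # frozen scales: accumulate the sampling-phase acceptance rate
            self.cum_accepts = self.cum_accepts + self.accepts
            self.cum_tries += self.tries
        self.accepts = np.zeros_like(self.scale)
        self.tries = 0

    @property
    def rate(self) -> np.ndarray:
        if self.cum_tries:
            return self.cum_accepts / self.cum_tries
        return self.accepts / max(self.tries, 1)


def _init_state(data: ModelData, rng, config: MCMCConfig, priors: Priors) -> ModelState:
    s0 = np.log(np.maximum(data.sigma_hat, 1e-3))
    j = config.init_jitter
    state = ModelState(
        s=s0 + rng.normal(0, j, data.n_rats),
        delta=np.zeros(data.n_rats),
        rho=np.zeros(data.n_rats),
        beta0=float(rng.normal(0, j)),
        beta1=float(rng.normal(0, j)),
        V=1.0,
        alpha=rng.normal(0, j, 4),
        tau=1.0,
        lam=rng.normal(0, j, 4),
        nu2=float(np.exp(priors.nu2_logmean)),
        phi=float(np.exp(priors.phi_logmean)),
    )
    if config.spatial:
        from .kernels import PROB_FLOOR
        from .model import encounter_cell_probs

        p = np.clip(
            encounter_cell_probs(data, state.s, state.delta, state.alpha, state.tau),
            PROB_FLOOR,
            1 - 1e-12,
        )
        state.latent = {
            (i, t): np.log(p[idx] / (1 - p[idx])) for i, t, idx in data.spatial_groups
        }
    return state


def _run_chain(data: ModelData, config: MCMCConfig, priors: Priors, rng: np.random.Generator):
    st = _init_state(data, rng, config, priors)
    lp0 = log_posterior(data, st, priors, config.spatial)
    if not np.isfinite(lp0):
        raise RuntimeError("non-finite log-posterior at initial values")

    n_iter = config.burn_in + config.n_samples * config.thin
    R = data.n_rats
    ti = config.adapt_interval
    sc = {
        "s": _Adaptive(np.full(R, 0.1), config.target_accept, ti),
        "delta": _Adaptive(np.full(R, 0.3), config.target_accept, ti),
        "rho": _Adaptive(np.full(R, 0.3), config.target_accept, ti),
        "beta": _Adaptive(np.full(2, 0.1), config.target_accept, ti),
        "alpha": _Adaptive(np.full(4, 0.15), config.target_accept, ti),
        "tau": _Adaptive(0.15, config.target_accept, ti),
        "lam": _Adaptive(np.full(4, 0.15), config.target_accept, ti),
    }
    if config.spatial:
        sc["latent"] = _Adaptive(np.full(len(data.spatial_groups), 0.5), config.target_accept, ti)
        sc["cov"] = _Adaptive(np.full(2, 0.2), config.target_accept, ti)

    latent = st.latent if config.spatial else None

    def enc_per_rat(s=None, delta=None, alpha=None, tau=None):
        return encounter_loglik_per_rat(
            data,
            st.s if s is None else s,
            st.delta if delta is None else delta,
            st.alpha if alpha is None else alpha,
            st.tau if tau is None else tau,
            latent,
            st.nu2,
            st.phi,
        )

    enc_ll = enc_per_rat()
    int_ll = interaction_loglik_per_rat(data, st.rho, st.lam)

    draws = {k: [] for k in GLOBAL_PARAMS}
    sig_draws, del_draws, rho_draws = [], [], []

    def norm_lp(x, var):
        return -(np.asarray(x) ** 2) / (2 * var)

    for it in range(n_iter):
        adapting = it < config.burn_in
        # --- per-rat ln sigma ------------------------------------------------
        prop = st.s + sc["s"].scale * rng.standard_normal(R)
        cur = (
            telemetry_loglik_per_rat(data, st.s)
            + hierarchy_loglik_per_rat(data, st.s, st.beta0, st.beta1, st.V)
            + enc_ll
        )
        enc_prop = enc_per_rat(s=prop)
        new = (
            telemetry_loglik_per_rat(data, prop)
            + hierarchy_loglik_per_rat(data, prop, st.beta0, st.beta1, st.V)
            + enc_prop
        )
        acc = np.log(rng.random(R)) < new - cur
        st.s = np.where(acc, prop, st.s)
        enc_ll = np.where(acc, enc_prop, enc_ll)
        sc["s"].register(acc)

        # --- per-rat delta ----------------------------------------------------
        prop = st.delta + sc["delta"].scale * rng.standard_normal(R)
        enc_prop = enc_per_rat(delta=prop)
        logr = (enc_prop + norm_lp(prop, priors.effect_var)) - (
            enc_ll + norm_lp(st.delta, priors.effect_var)
        )
        acc = np.log(rng.random(R)) < logr
        st.delta = np.where(acc, prop, st.delta)
        enc_ll = np.where(acc, enc_prop, enc_ll)
        sc["delta"].register(acc)

        # --- encounter coefficients and tau ----------------------------------
        acc_a = np.zeros(4, dtype=bool)
        for k in range(4):
            prop_alpha = st.alpha.copy()
            prop_alpha[k] += sc["alpha"].scale[k] * rng.standard_normal()
            enc_prop = enc_per_rat(alpha=prop_alpha)
            logr = enc_prop.sum() + norm_lp(prop_alpha[k], priors.coef_var) - (
                enc_ll.sum() + norm_lp(st.alpha[k], priors.coef_var)
            )
            if np.log(rng.random()) < logr:
                st.alpha = prop_alpha
                enc_ll = enc_prop
                acc_a[k] = True
        sc["alpha"].register(acc_a)

        ltau = np.log(st.tau) + sc["tau"].scale * rng.standard_normal()
        prop_tau = float(np.exp(ltau))
        enc_prop = enc_per_rat(tau=prop_tau)
        a, b = priors.tau_shape, priors.tau_rate
        logr = (
            enc_prop.sum()
            + a * np.log(prop_tau)  # Gamma prior + log-scale Jacobian
            - b * prop_tau
            - (enc_ll.sum() + a * np.log(st.tau) - b * st.tau)
        )
        acc_t = np.log(rng.random()) < logr
        if acc_t:
            st.tau = prop_tau
            enc_ll = enc_prop
        sc["tau"].register(float(acc_t))

        # --- hierarchy means and variance ------------------------------------
        acc_b = np.zeros(2, dtype=bool)
        for k, name in enumerate(("beta0", "beta1")):
            cur_v = getattr(st, name)
            prop_v = cur_v + sc["beta"].scale[k] * rng.standard_normal()
            hier_cur = hierarchy_loglik_per_rat(data, st.s, st.beta0, st.beta1, st.V).sum()
            b0 = prop_v if name == "beta0" else st.beta0
            b1 = prop_v if name == "beta1" else st.beta1
            hier_prop = hierarchy_loglik_per_rat(data, st.s, b0, b1, st.V).sum()
            logr = hier_prop + norm_lp(prop_v, priors.coef_var) - (
                hier_cur + norm_lp(cur_v, priors.coef_var)
            )
            if np.log(rng.random()) < logr:
                setattr(st, name, float(prop_v))
                acc_b[k] = True
        sc["beta"].register(acc_b)

        st.V = sample_V_full_conditional(
            st.s, st.beta0, st.beta1, data.sexes, rng, priors.v_a, priors.v_b
        )

        # --- per-rat rho and interaction coefficients ------------------------
        prop = st.rho + sc["rho"].scale * rng.standard_normal(R)
        int_prop = interaction_loglik_per_rat(data, prop, st.lam)
        logr = (int_prop + norm_lp(prop, priors.effect_var)) - (
            int_ll + norm_lp(st.rho, priors.effect_var)
        )
        acc = np.log(rng.random(R)) < logr
        st.rho = np.where(acc, prop, st.rho)
        int_ll = np.where(acc, int_prop, int_ll)
        sc["rho"].register(acc)

        acc_l = np.zeros(4, dtype=bool)
        for k in range(4):
            prop_lam = st.lam.copy()
            prop_lam[k] += sc["lam"].scale[k] * rng.standard_normal()
            int_prop = interaction_loglik_per_rat(data, st.rho, prop_lam)
            logr = int_prop.sum() + norm_lp(prop_lam[k], priors.coef_var) - (
                int_ll.sum() + norm_lp(st.lam[k], priors.coef_var)
            )
            if np.log(rng.random()) < logr:
                st.lam = prop_lam
                int_ll = int_prop
                acc_l[k] = True
        sc["lam"].register(acc_l)

        # --- spatial term -----------------------------------------------------
        if config.spatial:
            _update_spatial(data, st, priors, rng, sc)
            latent = st.latent
            enc_ll = enc_per_rat()

        for block in sc.values():
            block.maybe_adapt(adapting)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            for name, val in zip(
                GLOBAL_PARAMS,
                (
                    st.beta0, st.beta1, st.V, *st.alpha, st.tau, *st.lam,
                ),
            ):
                draws[name].append(float(val))
            sig_draws.append(np.exp(st.s))
            del_draws.append(st.delta.copy())
            rho_draws.append(st.rho.copy())

    globals_ = pd.DataFrame(draws)
    if config.spatial:
        globals_["nu2"] = st.nu2  # last value; full traces kept only for core params
        globals_["phi"] = st.phi
    rates = {k: float(np.mean(v.rate)) for k, v in sc.items()}
    return globals_, np.array(sig_draws), np.array(del_draws), np.array(rho_draws), rates


def _update_spatial(data: ModelData, st: ModelState, priors: Priors, rng, sc) -> None:
    """Metropolis updates for the latent logit-gamma vectors and nu2/phi."""
    from scipy.stats import multivariate_normal

    from .kernels import PROB_FLOOR, clipped_expit, spatial_covariance
    from .model import _bernoulli_ll, encounter_cell_probs

    p = np.clip(
        encounter_cell_probs(data, st.s, st.delta, st.alpha, st.tau), PROB_FLOOR, 1 - 1e-12
    )
    acc_vec = np.zeros(len(data.spatial_groups))
    for g, (i, t, idx) in enumerate(data.spatial_groups):
        u = st.latent[(i, t)]
        mean = np.log(p[idx] / (1 - p[idx]))
        cov = spatial_covariance(data.e_dev_xy[idx], st.nu2, st.phi)
        prop = u + sc["latent"].scale[g] * rng.standard_normal(u.size)

        def blk(vec):
            return _bernoulli_ll(data.e_y[idx], clipped_expit(vec)).sum() + (
                multivariate_normal.logpdf(vec, mean=mean, cov=cov, allow_singular=True)
            )

        if np.log(rng.random()) < blk(prop) - blk(u):
            st.latent[(i, t)] = prop
            acc_vec[g] = 1.0
    sc["latent"].register(acc_vec)

    def cov_lp(nu2, phi):
        out = 0.0
        for (i, t), u in st.latent.items():
            idx = next(ix for (ri, rt, ix) in data.spatial_groups if ri == i and rt == t)
            mean = np.log(p[idx] / (1 - p[idx]))
            cov = spatial_covariance(data.e_dev_xy[idx], nu2, phi)
            out += multivariate_normal.logpdf(u, mean=mean, cov=cov, allow_singular=True)
        for x, m, sd in ((nu2, priors.nu2_logmean, priors.nu2_logsd), (phi, priors.phi_logmean, priors.phi_logsd)):
            out += -np.log(x) - (np.log(x) - m) ** 2 / (2 * sd**2)
        return out

    acc_cov = np.zeros(2)
    for k, name in enumerate(("nu2", "phi")):
        cur = getattr(st, name)
        prop = float(np.exp(np.log(cur) + sc["cov"].scale[k] * rng.standard_normal()))
        kwargs = {"nu2": st.nu2, "phi": st.phi}
        kwargs[name] = prop
        # log-scale proposal: Jacobian log(prop/cur)
        if np.log(rng.random()) < cov_lp(**kwargs) - cov_lp(st.nu2, st.phi) + np.log(prop / cur):
            setattr(st, name, prop)
            acc_cov[k] = 1.0
    sc["cov"].register(acc_cov)


def run_mcmc(data: ModelData, config: MCMCConfig, priors: Priors | None = None) -> PosteriorDraws:
    """Run all chains and pool retained draws into a PosteriorDraws."""
    priors = priors or Priors()
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    frames, sigs, dels, rhos, chains, all_rates = [], [], [], [], [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(children[c])
        g, sg, dl, rh, rates = _run_chain(data, config, priors, rng)
        frames.append(g)
        sigs.append(sg)
        dels.append(dl)
        rhos.append(rh)
        chains.append(np.full(len(g), c))
        all_rates.append(rates)
    return PosteriorDraws(
        globals_=pd.concat(frames, ignore_index=True),
        sigma=np.vstack(sigs),
        delta=np.vstack(dels),
        rho=np.vstack(rhos),
        rat_ids=data.rat_ids,
        sexes=data.sexes.astype(int),
        chain=np.concatenate(chains),
        diagnostics={"acceptance": all_rates},
    )


def gelman_rubin(draws: PosteriorDraws, include_per_rat: bool = True) -> pd.Series:
    """Split potential-scale-reduction factor per parameter.

    Each chain is split in half; a fit is flagged unconverged when any
    parameter has R-hat >= 1.05.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat needs at least 2 chains")
    frame = draws.to_frame() if include_per_rat else draws.globals_.assign(chain=draws.chain)
    cols = [c for c in frame.columns if c != "chain"]
    chains = frame["chain"].to_numpy() if "chain" in frame else draws.chain
    out = {}
    per_chain = [frame.loc[chains == c, cols].to_numpy(dtype=float) for c in range(draws.n_chains)]
    n = min(len(x) for x in per_chain)
    n2 = n // 2
    if n2 < 2:
        raise ValueError("chains too short to split for R-hat")
    halves = []
    for x in per_chain:
        halves.append(x[:n2])
        halves.append(x[n2 : 2 * n2])
    arr = np.stack(halves)  # (m, n2, P)
    means = arr.mean(axis=1)
    varis = arr.var(axis=1, ddof=1)
    W = varis.mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    var_plus = (n2 - 1) / n2 * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where((W == 0) & (B_over_n == 0), 1.0, rhat)
    for c, r in zip(cols, rhat):
        out[c] = float(r)
    return pd.Series(out, name="rhat")


def converged(draws: PosteriorDraws, threshold: float = 1.05) -> bool:
    return bool((gelman_rubin(draws) < threshold).all())
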