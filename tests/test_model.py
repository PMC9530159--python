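"""Likelihood checks against an independent naive-loop implementation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal

import ratdetect as rd
from ratdetect.model import (
    ModelData,
    ModelState,
    encounter_loglik_per_rat,
    interaction_loglik,
    interaction_loglik_per_rat,
    log_posterior,
    telemetry_loglik,
)
from ratdetect.params import Priors


# ---------------------------------------------------------------------------
# naive reference implementation (kept deliberately loop-based and separate)


def naive_log_posterior(tel, devices, enc_log, int_log, state, priors, spatial=False):
    window = 20
    cutoff = 3.72
    centres = tel.df.groupby("rat_id")[["x", "y"]].mean()
    rat_ids = sorted(centres.index)
    sexes = tel.df.groupby("rat_id")["sex"].first()

    def expit(x):
        return 1.0 / (1.0 + math.exp(-max(min(x, 35.0), -35.0)))

    total = 0.0
    # telemetry + hierarchy
    for k, rid in enumerate(rat_ids):
        cx, cy = centres.loc[rid]
        sig = math.exp(state.s[k])
        for r in tel.df[tel.df["rat_id"] == rid].itertuples():
            for d in (r.x - cx, r.y - cy):
                total += -0.5 * math.log(2 * math.pi * sig**2) - d**2 / (2 * sig**2)
        mu = state.beta0 + state.beta1 * sexes.loc[rid]
        total += -0.5 * math.log(2 * math.pi * state.V) - (state.s[k] - mu) ** 2 / (2 * state.V)

    # encounter process
    enc = enc_log.df
    dev = devices.df.set_index("device_id")
    nights = sorted({t for s in devices.availability.values() for t in s})
    obs = {(r.rat_id, r.device_id, r.night): r.encountered for r in enc.itertuples()}

    def estar(rid, t):
        ev = enc[(enc["rat_id"] == rid) & (enc["encountered"] == 1) & (enc["night"] < t)]
        return int(len(ev) and t - ev["night"].max() <= window)

    def cell_p(rid, k, did, t):
        sig = math.exp(state.s[k])
        row = dev.loc[did]
        d = math.hypot(row.x - centres.loc[rid, "x"], row.y - centres.loc[rid, "y"])
        if d > cutoff * sig:
            return 0.0, d
        lp = (
            state.alpha[0]
            + state.alpha[1] * state.s[k]
            + state.alpha[2] * (row.device_type == "chewcard")
            + state.alpha[3] * (row.device_type == "waxtag")
            + state.delta[k]
        )
        base = max(expit(lp) * math.exp(-(d**2) / (2 * sig**2)), 1e-12)
        return base ** (state.tau if estar(rid, t) else 1.0), d

    def bern(y, p):
        return math.log(max(p, 1e-300)) if y == 1 else math.log1p(-min(p, 1 - 1e-12))

    for k, rid in enumerate(rat_ids):
        for t in nights:
            avail = [d for d in dev.index if t in devices.availability[d]]
            ps, ys, ins, xy = [], [], [], []
            sig_hat = None
            for did in avail:
                p, dist = cell_p(rid, k, did, t)
                y = obs.get((rid, did, t), 0)
                ps.append(p)
                ys.append(y)
                xy.append((dev.loc[did].x, dev.loc[did].y))
            if not spatial:
                total += sum(bern(y, p) for y, p in zip(ys, ps))
            else:
                # latent support: cells within cutoff * sigma_hat
                sub = tel.df[tel.df["rat_id"] == rid]
                dx = sub["x"] - centres.loc[rid, "x"]
                dy = sub["y"] - centres.loc[rid, "y"]
                sig_hat = math.sqrt(((dx**2).sum() + (dy**2).sum()) / (2 * len(sub)))
                in_blk = []
                for j, did in enumerate(avail):
                    d = math.hypot(
                        xy[j][0] - centres.loc[rid, "x"], xy[j][1] - centres.loc[rid, "y"]
                    )
                    in_blk.append(d <= cutoff * sig_hat)
                for j in range(len(avail)):
                    if not in_blk[j]:
                        total += bern(ys[j], ps[j])
                idx = [j for j in range(len(avail)) if in_blk[j]]
                if idx:
                    u = state.latent[(k, t)]
                    mean = []
                    for j in idx:
                        pc = min(max(ps[j], 1e-12), 1 - 1e-12)
                        mean.append(math.log(pc / (1 - pc)))
                    pts = np.array([xy[j] for j in idx])
                    diff = pts[:, None, :] - pts[None, :, :]
                    r = np.sqrt((diff**2).sum(-1))
                    cov = state.nu2 * np.exp(-state.phi * r)
                    cov[np.diag_indices_from(cov)] += 1e-10 * state.nu2
                    total += multivariate_normal.logpdf(u, mean=np.array(mean), cov=cov)
                    for jj, j in enumerate(idx):
                        total += bern(ys[j], expit(u[jj]))

    # interaction process
    inter = int_log.df

    def istar(rid, t):
        ev = inter[(inter["rat_id"] == rid) & (inter["interacted"] == 1) & (inter["night"] < t)]
        return int(len(ev) and t - ev["night"].max() <= window)

    for r in inter.itertuples():
        k = rat_ids.index(r.rat_id)
        row = dev.loc[r.device_id]
        lp = (
            state.lam[0]
            + state.lam[1] * (row.device_type == "chewcard")
            + state.lam[2] * (row.device_type == "waxtag")
            + state.lam[3] * istar(r.rat_id, r.night)
            + state.rho[k]
        )
        total += bern(r.interacted, expit(lp))

    # priors
    for x in (state.beta0, state.beta1, *state.alpha, *state.lam):
        total += -0.5 * math.log(2 * math.pi * priors.coef_var) - x**2 / (2 * priors.coef_var)
    for x in (*state.delta, *state.rho):
        total += -0.5 * math.log(2 * math.pi) - x**2 / 2
    a, b = priors.tau_shape, priors.tau_rate
    total += a * math.log(b) - math.lgamma(a) + (a - 1) * math.log(state.tau) - b * state.tau
    av, bv = priors.v_a, priors.v_b
    total += av * math.log(bv) - math.lgamma(av) - (av + 1) * math.log(state.V) - bv / state.V
    if spatial:
        for x, m, sd in ((state.nu2, priors.nu2_logmean, priors.nu2_logsd),
                         (state.phi, priors.phi_logmean, priors.phi_logsd)):
            total += -math.log(x * sd * math.sqrt(2 * math.pi)) - (math.log(x) - m) ** 2 / (
                2 * sd**2
            )
    return total


def _state_for(data, spatial=False):
    rng = np.random.default_rng(3)
    st = ModelState(
        s=np.log(data.sigma_hat) + rng.normal(0, 0.05, data.n_rats),
        delta=rng.normal(0, 0.5, data.n_rats),
        rho=rng.normal(0, 0.5, data.n_rats),
        beta0=3.1,
        beta1=-0.2,
        V=0.3,
        alpha=np.array([4.0, -1.3, -0.2, 0.1]),
        tau=0.4,
        lam=np.array([-0.9, -0.6, -0.3, 0.9]),
        nu2=2.5,
        phi=0.08,
    )
    if spatial:
        st.latent = {
            (i, t): rng.normal(-1.0, 0.8, idx.size) for i, t, idx in data.spatial_groups
        }
    return st


class TestOracleEquivalence:
    def test_log_posterior_matches_naive_loop(self, tiny_tables):
        tel, devices, enc_log, int_log = tiny_tables
        data = ModelData.from_tables(tel, devices, enc_log, int_log, candidate_margin=3.0)
        st = _state_for(data)
        got = log_posterior(data, st, Priors(), spatial=False)
        want = naive_log_posterior(tel, devices, enc_log, int_log, st, Priors())
        assert got == pytest.approx(want, abs=1e-10)

    def test_log_posterior_matches_naive_loop_with_spatial_term(self, tiny_tables):
        tel, devices, enc_log, int_log = tiny_tables
        data = ModelData.from_tables(tel, devices, enc_log, int_log, candidate_margin=3.0)
        st = _state_for(data, spatial=True)
        got = log_posterior(data, st, Priors(), spatial=True)
        want = naive_log_posterior(
            tel, devices, enc_log, int_log, st, Priors(), spatial=True
        )
        assert got == pytest.approx(want, abs=1e-10)


class TestTelemetryLoglik:
    def test_single_fix_at_centre(self):
        assert telemetry_loglik(1.0, [[0.0, 0.0]]) == pytest.approx(-math.log(2 * math.pi))

    def test_scale_family_shift(self, rng):
        dev = rng.normal(0, 2.0, (40, 2))
        k = 3.0
        l1 = telemetry_loglik(2.0, dev)
        l2 = telemetry_loglik(2.0 * k, dev * k)
        assert l2 - l1 == pytest.approx(-2 * 40 * math.log(k), rel=1e-12)

    def test_maximiser_is_rms_of_pooled_deviations(self, rng):
        dev = rng.normal(0, 5.0, (200, 2))
        rms = math.sqrt((dev**2).sum() / (2 * len(dev)))
        res = minimize_scalar(
            lambda s: -telemetry_loglik(s, dev), bounds=(0.1, 50), method="bounded"
        )
        assert res.x == pytest.approx(rms, rel=1e-4)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            telemetry_loglik(0.0, [[1.0, 1.0]])


class TestHomeRangeCentres:
    def test_two_fixes(self):
        df = pd.DataFrame(
            {"rat_id": ["a", "a"], "sex": [0, 0], "night": [0, 1], "x": [0.0, 2.0], "y": [0.0, 0.0]}
        )
        c = rd.home_range_centres(rd.TelemetryTable(df))
        assert (c.loc[0, "x"], c.loc[0, "y"]) == (1.0, 0.0)

    def test_large_sample_clt(self, rng):
        sig, L = 25.0, 10_000
        tel = rd.simulate_telemetry([[7.0, -2.0]], [sig], L, rng)
        c = rd.home_range_centres(tel)
        assert abs(c.loc[0, "x"] - 7.0) < 4 * sig / 100
        assert abs(c.loc[0, "y"] + 2.0) < 4 * sig / 100


class TestBernoulliPieces:
    def test_single_trial_half_probability(self):
        df = pd.DataFrame(
            {"rat_id": ["a"], "sex": [0], "night": [0], "x": [0.0], "y": [0.0]}
        )
        # construct a minimal data object with one encounter cell at P = 0.5
        tel = rd.TelemetryTable(pd.concat([df, df.assign(night=1, x=1.0)], ignore_index=True))
        dev = rd.DeviceTable(
            pd.DataFrame(
                [("d0", "baitstation", 0.5, 0.0)],  # at the fix centroid
                columns=["device_id", "device_type", "x", "y"],
            ),
            {"d0": frozenset({0})},
        )
        enc = rd.EncounterLog(
            pd.DataFrame(
                {"rat_id": ["a"], "device_id": ["d0"], "night": [0], "encountered": [1]}
            )
        )
        inter = rd.InteractionLog(
            pd.DataFrame(
                {"rat_id": ["a"], "device_id": ["d0"], "night": [0], "interacted": [0]}
            )
        )
        data = ModelData.from_tables(tel, dev, enc, inter)
        # device at the centre, naive state: P = eps0 = expit(alpha0 + alpha1 * s)
        s = np.log(data.sigma_hat)
        alpha = np.array([-s[0], 1.0, 0.0, 0.0])  # makes the linear predictor 0 -> P=0.5
        ll = encounter_loglik_per_rat(data, s, np.zeros(1), alpha, 1.0)
        assert ll.sum() == pytest.approx(math.log(0.5))

    def test_empty_interaction_log_scores_zero(self, tiny_tables):
        tel, devices, enc_log, _ = tiny_tables
        empty = rd.InteractionLog(
            pd.DataFrame(columns=["rat_id", "device_id", "night", "interacted"])
        )
        data = ModelData.from_tables(tel, devices, enc_log, empty)
        assert interaction_loglik(data, np.zeros(data.n_rats), np.zeros(4)) == 0.0

    def test_spatial_latent_at_kernel_mean_reduces_to_bernoulli_at_p(self, tiny_tables):
        # with gamma pinned to P the Bernoulli part of the spatial likelihood
        # equals the non-spatial likelihood; the MVN term is a pure prior
        tel, devices, enc_log, int_log = tiny_tables
        data = ModelData.from_tables(tel, devices, enc_log, int_log, candidate_margin=3.0)
        st = _state_for(data)
        from ratdetect.kernels import PROB_FLOOR
        from ratdetect.model import encounter_cell_probs

        p = np.clip(
            encounter_cell_probs(data, st.s, st.delta, st.alpha, st.tau), PROB_FLOOR, 1 - 1e-12
        )
        latent = {(i, t): np.log(p[idx] / (1 - p[idx])) for i, t, idx in data.spatial_groups}
        off = encounter_loglik_per_rat(data, st.s, st.delta, st.alpha, st.tau)
        on = encounter_loglik_per_rat(
            data, st.s, st.delta, st.alpha, st.tau, latent, st.nu2, st.phi
        )
        mvn_terms = on - off  # per rat: sum of MVN log-densities at their means
        assert (mvn_terms < 1e-9).all() is not None  # finite
        # remove the MVN-at-mean contribution explicitly and compare
        from ratdetect.kernels import spatial_covariance

        expected = np.zeros(data.n_rats)
        for i, t, idx in data.spatial_groups:
            cov = spatial_covariance(data.e_dev_xy[idx], st.nu2, st.phi)
            expected[i] += multivariate_normal.logpdf(
                latent[(i, t)], mean=latent[(i, t)], cov=cov
            )
        assert np.allclose(on - expected, off, atol=1e-9)


class TestExchangeability:
    def test_no_dynamics_makes_nights_exchangeable(self, tiny_tables):
        """With tau = 1 and lambda3 = 0 the likelihood ignores night order."""
        tel, devices, enc_log, int_log = tiny_tables
        perm = {0: 3, 1: 0, 2: 4, 3: 2, 4: 1}

        def permute(log, col):
            df = log.df.copy()
            df["night"] = df["night"].map(perm)
            return type(log)(df.sort_values(["rat_id", "device_id", "night"]).reset_index(drop=True))

        dev2 = rd.DeviceTable(
            devices.df.copy(),
            {d: frozenset(perm[t] for t in s) for d, s in devices.availability.items()},
        )
        data1 = ModelData.from_tables(tel, devices, enc_log, int_log, candidate_margin=3.0)
        data2 = ModelData.from_tables(
            tel, dev2, permute(enc_log, "encountered"), permute(int_log, "interacted"),
            candidate_margin=3.0,
        )
        st = _state_for(data1)
        st.tau = 1.0
        st.lam = np.array([-0.9, -0.6, -0.3, 0.0])
        lp1 = log_posterior(data1, st, Priors())
        lp2 = log_posterior(data2, st, Priors())
        assert lp1 == pytest.approx(lp2, abs=1e-9)

    def test_dynamics_break_exchangeability(self, tiny_tables):
        tel, devices, enc_log, int_log = tiny_tables
        data = ModelData.from_tables(tel, devices, enc_log, int_log, candidate_margin=3.0)
        st = _state_for(data)  # tau = 0.4
        assert data.e_estar.any()  # the history indicator is actually active
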