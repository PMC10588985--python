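"""Joint posterior density in the unconstrained sampling space, with gradient.

The sampling parameterisation is non-centred: participant slopes are
``beta = diag(sigma_beta) L z / sqrt(u)`` with ``z ~ N(0, I)`` and
``u ~ Gamma(nu/2, nu/2)`` (the scale-mixture form of the multivariate t),
electrode slopes are ``delta = sigma_delta * z``, scales are sampled on the
log scale, and the slope correlation is parameterised by canonical partial
correlations (CPCs) through ``tanh``, whose Beta factorisation is exactly the
LKJ prior.  The composed variance link collapses to
``gamma = softplus(alpha_c + beta_pc + delta_ce)``.

Two equivalent implementations of the density-and-gradient are provided: a
numba-compiled kernel used by the sampler, and a vectorised numpy reference
used to cross-check it in the test-suite.  All gradients are analytic
(finite-difference-verified); the Cholesky-from-CPC derivative uses the
closed form L[i, j] = z_ij * prod_{k<j} sqrt(1 - z_ik^2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import betaln, digamma, expit, gammaln

from .model import (
    ExperimentLayout,
    ModelParams,
    PhaseDataset,
    PriorConfig,
    _cholesky_from_cpc,
    _cpc_beta_shapes,
)

_LOG_TWO_PI = np.log(2.0 * np.pi)


def _softplus(x):
    return np.logaddexp(0.0, x)


class UnconstrainedModel:
    """Pack/unpack, joint log-density and gradient for one dataset.

    ``gamma_scale`` multiplies every cell's wrapped-Cauchy scale inside the
    likelihood; it exists so calibration experiments can run a deliberately
    corrupted likelihood as a negative control.  ``use_likelihood=False``
    targets the prior alone.
    """

    def __init__(self, layout: ExperimentLayout, cfg: PriorConfig,
                 data: PhaseDataset | None = None, *, gamma_scale: float = 1.0,
                 use_likelihood: bool = True):
        self.layout = layout
        self.cfg = cfg
        self.gamma_scale = float(gamma_scale)
        P, C, E = layout.n_participants, layout.n_conditions, layout.n_electrodes
        self.P, self.C, self.E = P, C, E
        self.ncell = P * C * E
        self.ncorr = C * (C - 1) // 2
        self.estimate_nu = cfg.estimate_nu
        self._cpc_shapes = (_cpc_beta_shapes(C, cfg.lkj_eta) if C > 1
                            else np.empty(0))

        if data is not None and use_likelihood:
            if data.layout.shape[:3] != (P, C, E):
                raise ValueError("dataset layout does not match model layout")
            mask = data.mask
            cell_grid = np.arange(self.ncell).reshape(P, C, E)
            cell_of_trial = np.broadcast_to(cell_grid[..., None], mask.shape)
            self.theta = np.ascontiguousarray(data.phases[mask])
            self.cell_idx = np.ascontiguousarray(cell_of_trial[mask])
            self.K_cell = np.bincount(self.cell_idx,
                                      minlength=self.ncell).astype(float)
        else:
            self.theta = np.empty(0)
            self.cell_idx = np.empty(0, dtype=np.int64)
            self.K_cell = np.zeros(self.ncell)
        self.n_obs = self.theta.size
        self._data = data

        # block offsets in the packed vector
        sizes = [("alpha", C), ("z_beta", P * C), ("w_u", P),
                 ("z_delta", C * E), ("x", self.ncell), ("y", self.ncell),
                 ("log_sb", C), ("log_sd", C), ("z_corr", self.ncorr)]
        if self.estimate_nu:
            sizes.append(("t_nu", 1))
        self.slices: dict[str, slice] = {}
        off = 0
        for name, n in sizes:
            self.slices[name] = slice(off, off + n)
            off += n
        self.dim = off

    # -- packing helpers ---------------------------------------------------

    def _unpack(self, q: np.ndarray) -> dict[str, np.ndarray]:
        P, C, E = self.P, self.C, self.E
        s = self.slices
        out = {
            "alpha": q[s["alpha"]],
            "z_beta": q[s["z_beta"]].reshape(P, C),
            "w_u": q[s["w_u"]],
            "z_delta": q[s["z_delta"]].reshape(C, E),
            "x": q[s["x"]],
            "y": q[s["y"]],
            "log_sb": q[s["log_sb"]],
            "log_sd": q[s["log_sd"]],
            "z_corr": q[s["z_corr"]],
        }
        out["t_nu"] = q[s["t_nu"]] if self.estimate_nu else None
        return out

    def _nu(self, v) -> float:
        if self.estimate_nu:
            return 2.0 + float(np.exp(v["t_nu"][0]))
        return float(self.cfg.nu)

    def _chol(self, z_corr: np.ndarray) -> np.ndarray:
        if self.C == 1:
            return np.ones((1, 1))
        return _cholesky_from_cpc(np.tanh(z_corr), self.C).real

    def _centred(self, v) -> dict[str, np.ndarray]:
        sb = np.exp(v["log_sb"])
        sd = np.exp(v["log_sd"])
        L = self._chol(v["z_corr"])
        u = np.exp(v["w_u"])
        beta = (v["z_beta"] @ L.T) * sb[None, :] / np.sqrt(u)[:, None]
        delta = sd[:, None] * v["z_delta"]
        return {"sb": sb, "sd": sd, "L": L, "u": u, "beta": beta, "delta": delta}

    def to_params(self, q: np.ndarray) -> ModelParams:
        v = self._unpack(q)
        c = self._centred(v)
        mu_xy = np.stack([v["x"], v["y"]], axis=-1).reshape(
            self.P, self.C, self.E, 2)
        return ModelParams(
            alpha=v["alpha"].copy(), beta=c["beta"], delta=c["delta"],
            mu_xy=mu_xy, sigma_beta=c["sb"], corr_beta=c["L"] @ c["L"].T,
            sigma_delta=c["sd"], nu=self._nu(v))

    def derived(self, q: np.ndarray, *, store_cells: bool = True
                ) -> dict[str, np.ndarray]:
        """Centred quantities stored per posterior draw."""
        v = self._unpack(q)
        c = self._centred(v)
        out = {
            "alpha": v["alpha"].copy(),
            "beta": c["beta"],
            "delta": c["delta"],
            "sigma_beta": c["sb"],
            "sigma_delta": c["sd"],
        }
        if self.C > 1:
            R = c["L"] @ c["L"].T
            iu = np.triu_indices(self.C, k=1)
            out["corr_beta"] = R[iu]
        if self.estimate_nu:
            out["nu"] = np.array([self._nu(v)])
        if store_cells:
            out["mu"] = np.arctan2(v["y"], v["x"]).reshape(self.P, self.C, self.E)
            out["mu_x"] = v["x"].reshape(self.P, self.C, self.E).copy()
            out["mu_y"] = v["y"].reshape(self.P, self.C, self.E).copy()
        return out

    def initial_point(self, rng, jitter: float = 0.1) -> np.ndarray:
        """Data-informed start: cell mean phases for (x, y), prior-mean S_c."""
        cfg = self.cfg
        q = np.zeros(self.dim)
        s = self.slices
        S0 = cfg.S_prior_a / (cfg.S_prior_a + cfg.S_prior_b)
        q[s["alpha"]] = np.log(S0) - np.log1p(-S0)
        xs = np.ones(self.ncell)
        ys = np.zeros(self.ncell)
        if self.n_obs:
            zsum = np.bincount(self.cell_idx, weights=np.cos(self.theta),
                               minlength=self.ncell) + 1j * np.bincount(
                self.cell_idx, weights=np.sin(self.theta), minlength=self.ncell)
            mod = np.abs(zsum)
            ok = mod > 1e-8
            xs[ok] = (zsum.real[ok] / mod[ok])
            ys[ok] = (zsum.imag[ok] / mod[ok])
        q[s["x"]] = xs
        q[s["y"]] = ys
        q[s["log_sb"]] = np.log(0.5 * cfg.sigma_beta_scale)
        q[s["log_sd"]] = np.log(0.5 * cfg.sigma_delta_scale)
        if self.estimate_nu:
            q[s["t_nu"]] = np.log(30.0 - 2.0)
        q = q + jitter * rng.standard_normal(self.dim)
        return q

    # -- density (numba fast path) ------------------------------------------

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        lp, grad = _core_logp_grad(
            np.ascontiguousarray(q, dtype=np.float64),
            self.P, self.C, self.E, self.estimate_nu, self.gamma_scale,
            self.theta, self.cell_idx, self.K_cell,
            self.cfg.S_prior_a, self.cfg.S_prior_b,
            self.cfg.radial_shape, self.cfg.radial_rate,
            self.cfg.sigma_beta_scale, self.cfg.sigma_delta_scale,
            self._cpc_shapes,
            float(self.cfg.nu) if not self.estimate_nu else 30.0,
            self.cfg.nu_prior_shape, self.cfg.nu_prior_rate)
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.dim)
        return float(lp), grad

    # -- density (numpy reference, cross-checked in tests) -------------------

    def logp_grad_reference(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        P, C, E = self.P, self.C, self.E
        cfg = self.cfg
        s = self.slices
        v = self._unpack(q)
        with np.errstate(over="raise", invalid="raise", divide="raise"):
            try:
                return self._reference_inner(P, C, E, cfg, s, v)
            except FloatingPointError:
                return -np.inf, np.zeros(self.dim)

    def _reference_inner(self, P, C, E, cfg, s, v):
        alpha, Zb, w, Zd = v["alpha"], v["z_beta"], v["w_u"], v["z_delta"]
        x, y, log_sb, log_sd, z_corr = (v["x"], v["y"], v["log_sb"],
                                        v["log_sd"], v["z_corr"])
        grad = np.zeros(self.dim)
        nu = self._nu(v)
        half_nu = 0.5 * nu
        sb = np.exp(log_sb)
        sd = np.exp(log_sd)
        u = np.exp(w)
        su = np.sqrt(u)
        L = self._chol(z_corr)
        M = Zb @ L.T                                    # (P, C)
        beta = sb[None, :] * M / su[:, None]
        delta = sd[:, None] * Zd                        # (C, E)

        ups = (alpha[None, :, None] + beta[:, :, None] + delta[None, :, :])
        ups_flat = ups.reshape(-1)                      # (ncell,)
        gamma = self.gamma_scale * _softplus(ups_flat)
        if np.any(gamma <= 1e-12) or not np.all(np.isfinite(gamma)):
            return -np.inf, grad

        lp = 0.0
        g_beta = np.zeros((P, C))
        g_delta = np.zeros((C, E))
        g_alpha = np.zeros(C)
        g_x = np.zeros(self.ncell)
        g_y = np.zeros(self.ncell)
        g_L = np.zeros((C, C))

        # --- likelihood -----------------------------------------------------
        if self.n_obs:
            mu = np.arctan2(y, x)
            a = np.exp(-gamma)
            one_m_a2 = -np.expm1(-2.0 * gamma)          # 1 - a^2, stable
            a_t = a[self.cell_idx]
            d = self.theta - mu[self.cell_idx]
            cosd = np.cos(d)
            sind = np.sin(d)
            D = 1.0 + a_t * a_t - 2.0 * a_t * cosd
            lp += float(np.dot(self.K_cell, np.log(one_m_a2))
                        - np.sum(np.log(D)) - self.n_obs * _LOG_TWO_PI)

            g_gamma = (self.K_cell * (2.0 * a * a / one_m_a2)
                       + np.bincount(self.cell_idx,
                                     weights=2.0 * a_t * (a_t - cosd) / D,
                                     minlength=self.ncell))
            g_mu = np.bincount(self.cell_idx, weights=2.0 * a_t * sind / D,
                               minlength=self.ncell)
            g_ups = (g_gamma * self.gamma_scale * expit(ups_flat)).reshape(P, C, E)
            g_alpha += g_ups.sum(axis=(0, 2))
            g_beta += g_ups.sum(axis=2)
            g_delta += g_ups.sum(axis=0)
            rho2 = x * x + y * y
            g_x += g_mu * (-y / rho2)
            g_y += g_mu * (x / rho2)

        # --- prior: condition effects through the Beta on S_c ---------------
        S = expit(alpha)
        lp += float(np.sum(cfg.S_prior_a * (-_softplus(-alpha))
                           + cfg.S_prior_b * (-_softplus(alpha)))
                    - C * betaln(cfg.S_prior_a, cfg.S_prior_b))
        g_alpha += cfg.S_prior_a * (1.0 - S) - cfg.S_prior_b * S

        # --- prior: participant slopes (non-centred multivariate t) ---------
        lp += float(-0.5 * np.sum(Zb * Zb) - 0.5 * P * C * _LOG_TWO_PI)
        g_M = g_beta * sb[None, :] / su[:, None]
        g_Zb = -Zb + g_M @ L
        g_L += np.tril(g_M.T @ Zb)
        g_log_sb = np.sum(g_beta * beta, axis=0)
        g_w = -0.5 * np.sum(g_beta * beta, axis=1)

        lp += float(P * (half_nu * np.log(half_nu) - gammaln(half_nu))
                    + half_nu * np.sum(w) - half_nu * np.sum(u))
        g_w += half_nu - half_nu * u

        # --- prior: electrode slopes ----------------------------------------
        lp += float(-0.5 * np.sum(Zd * Zd) - 0.5 * C * E * _LOG_TWO_PI)
        g_Zd = -Zd + g_delta * sd[:, None]
        g_log_sd = np.sum(g_delta * delta, axis=1)

        # --- prior: Bundt on (x, y) -----------------------------------------
        k_r, rate = cfg.radial_shape, cfg.radial_rate
        rho = np.hypot(x, y)
        if np.any(rho == 0.0):
            return -np.inf, grad
        lp += float(np.sum((k_r - 1.0) * np.log(rho) - rate * rho)
                    + self.ncell * (k_r * np.log(rate) - gammaln(k_r)))
        dlp_rho = (k_r - 1.0) / rho - rate
        g_x += dlp_rho * x / rho
        g_y += dlp_rho * y / rho

        # --- hyperpriors on the scales (half-normal, log-space) -------------
        for sig, scale, g_log in ((sb, cfg.sigma_beta_scale, g_log_sb),
                                  (sd, cfg.sigma_delta_scale, g_log_sd)):
            lp += float(np.sum(-0.5 * (sig / scale) ** 2 + np.log(sig))
                        + C * (0.5 * np.log(2.0 / np.pi) - np.log(scale)))
            g_log[...] += -(sig / scale) ** 2 + 1.0

        # --- prior: slope correlation (CPC-Beta == LKJ) ----------------------
        if self.C > 1:
            zc = np.tanh(z_corr)
            a_sh = self._cpc_shapes
            lp += float(np.sum(
                (a_sh - 1.0) * (np.log1p(zc) + np.log1p(-zc) - 2.0 * np.log(2.0))
                - betaln(a_sh, a_sh) - np.log(2.0) + np.log1p(-zc * zc)))
            g_zcorr = -2.0 * zc * a_sh
            if np.any(g_L != 0.0):
                g_zcorr += _chol_chain(zc, g_L, self.C) * (1.0 - zc * zc)
            grad[s["z_corr"]] = g_zcorr

        # --- prior on nu (if estimated) --------------------------------------
        if self.estimate_nu:
            t = v["t_nu"][0]
            lp += float(cfg.nu_prior_shape * t - cfg.nu_prior_rate * np.exp(t)
                        + cfg.nu_prior_shape * np.log(cfg.nu_prior_rate)
                        - gammaln(cfg.nu_prior_shape))
            g_t = cfg.nu_prior_shape - cfg.nu_prior_rate * np.exp(t)
            dlp_dnu = 0.5 * np.sum(
                np.log(half_nu) + 1.0 - digamma(half_nu) + w - u)
            g_t += dlp_dnu * np.exp(t)
            grad[s["t_nu"]] = g_t

        grad[s["alpha"]] = g_alpha
        grad[s["z_beta"]] = g_Zb.reshape(-1)
        grad[s["w_u"]] = g_w
        grad[s["z_delta"]] = g_Zd.reshape(-1)
        grad[s["x"]] = g_x
        grad[s["y"]] = g_y
        grad[s["log_sb"]] = g_log_sb
        grad[s["log_sd"]] = g_log_sd

        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.dim)
        return float(lp), grad


def _chol_chain(zc: np.ndarray, g_L: np.ndarray, C: int) -> np.ndarray:
    """d(sum g_L * L)/dz for the Cholesky-from-CPC map, closed form.

    Uses L[i, j] = z_ij * prod_{k<j} sqrt(1 - z_ik^2) (and the diagonal with
    the full product), so dL[i, j]/dz_im = -z_im L[i, j] / (1 - z_im^2) for
    m < j, and the prefix product itself for m = j.
    """
    out = np.zeros(zc.size)
    idx = 0
    for i in range(1, C):
        z_row = zc[idx:idx + i]
        pref = np.ones(i + 1)
        for k in range(i):
            pref[k + 1] = pref[k] * np.sqrt(1.0 - z_row[k] ** 2)
        L_row = np.empty(i + 1)
        L_row[:i] = z_row * pref[:i]
        L_row[i] = pref[i]
        gl = g_L[i, :i + 1]
        # suffix sums of gl * L over columns strictly right of m
        tail = np.cumsum((gl * L_row)[::-1])[::-1]
        for m in range(i):
            out[idx + m] = (gl[m] * pref[m]
                            - z_row[m] / (1.0 - z_row[m] ** 2) * tail[m + 1])
        idx += i
    return out


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_digamma(x: float) -> float:
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    return (r + math.log(x) - 0.5 / x
            - f * (1.0 / 12.0 - f * (1.0 / 120.0 - f * (1.0 / 252.0
                   - f * (1.0 / 240.0 - f * (1.0 / 132.0))))))


@njit(cache=True)
def _core_logp_grad(q, P, C, E, estimate_nu, gamma_scale,
                    theta, cell_idx, K_cell,
                    aS, bS, k_r, rate_r, sb_scale, sd_scale, cpc_shapes,
                    nu_fixed, nu_shape, nu_rate):
    LOG2PI = math.log(2.0 * math.pi)
    ncell = P * C * E
    ncorr = C * (C - 1) // 2
    n_obs = theta.size
    o_alpha = 0
    o_zb = o_alpha + C
    o_w = o_zb + P * C
    o_zd = o_w + P
    o_x = o_zd + C * E
    o_y = o_x + ncell
    o_lsb = o_y + ncell
    o_lsd = o_lsb + C
    o_zc = o_lsd + C
    o_t = o_zc + ncorr
    dim = o_t + (1 if estimate_nu else 0)
    grad = np.zeros(dim)
    bad = (-np.inf, grad)

    for i in range(dim):
        if not np.isfinite(q[i]):
            return bad

    if estimate_nu:
        t_nu = q[o_t]
        if t_nu > 30.0:
            return bad
        nu = 2.0 + math.exp(t_nu)
    else:
        nu = nu_fixed
    half_nu = 0.5 * nu

    sb = np.empty(C)
    sd = np.empty(C)
    for c in range(C):
        if q[o_lsb + c] > 300.0 or q[o_lsd + c] > 300.0:
            return bad
        sb[c] = math.exp(q[o_lsb + c])
        sd[c] = math.exp(q[o_lsd + c])
    u = np.empty(P)
    su = np.empty(P)
    for p in range(P):
        if q[o_w + p] > 300.0 or q[o_w + p] < -300.0:
            return bad
        u[p] = math.exp(q[o_w + p])
        su[p] = math.sqrt(u[p])

    # Cholesky factor from canonical partial correlations
    Lc = np.zeros((C, C))
    zc = np.empty(ncorr)
    Lc[0, 0] = 1.0
    idx = 0
    for i in range(1, C):
        pref = 1.0
        for j in range(i):
            if abs(q[o_zc + idx]) > 18.0:   # tanh rounds to +/-1 past ~19
                return bad
            zc[idx] = math.tanh(q[o_zc + idx])
            Lc[i, j] = zc[idx] * pref
            pref *= math.sqrt(1.0 - zc[idx] * zc[idx])
            idx += 1
        Lc[i, i] = pref

    # centred slopes
    beta = np.empty((P, C))
    for p in range(P):
        for c in range(C):
            acc = 0.0
            for j in range(c + 1):
                acc += Lc[c, j] * q[o_zb + p * C + j]
            beta[p, c] = sb[c] * acc / su[p]
    delta = np.empty((C, E))
    for c in range(C):
        for e in range(E):
            delta[c, e] = sd[c] * q[o_zd + c * E + e]

    # cell-level links
    gamma = np.empty(ncell)
    a_cell = np.empty(ncell)
    sig_ups = np.empty(ncell)
    mu = np.empty(ncell)
    lp = 0.0
    cell = 0
    for p in range(P):
        for c in range(C):
            for e in range(E):
                ups = q[o_alpha + c] + beta[p, c] + delta[c, e]
                if ups > 0.0:
                    g0 = ups + math.log1p(math.exp(-ups))
                    sig_ups[cell] = 1.0 / (1.0 + math.exp(-ups))
                else:
                    g0 = math.log1p(math.exp(ups))
                    sig_ups[cell] = math.exp(ups) / (1.0 + math.exp(ups))
                g = gamma_scale * g0
                # reject states whose scale underflows: at a = exp(-gamma)
                # rounding to 1 the density denominator can vanish
                if not (g > 1e-12) or not np.isfinite(ups):
                    return bad
                gamma[cell] = g
                a_cell[cell] = math.exp(-g)
                xv = q[o_x + cell]
                yv = q[o_y + cell]
                if xv == 0.0 and yv == 0.0:
                    return bad
                mu[cell] = math.atan2(yv, xv)
                cell += 1

    g_gamma = np.zeros(ncell)
    g_mu = np.zeros(ncell)

    # likelihood over observed trials
    for t in range(n_obs):
        cl = cell_idx[t]
        a = a_cell[cl]
        d = theta[t] - mu[cl]
        cosd = math.cos(d)
        sind = math.sin(d)
        Dv = 1.0 + a * a - 2.0 * a * cosd
        if Dv <= 0.0:
            return bad
        lp -= math.log(Dv)
        g_gamma[cl] += 2.0 * a * (a - cosd) / Dv
        g_mu[cl] += 2.0 * a * sind / Dv
    if n_obs > 0:
        lp -= n_obs * LOG2PI
        for cl in range(ncell):
            if K_cell[cl] > 0.0:
                one_m_a2 = -math.expm1(-2.0 * gamma[cl])
                lp += K_cell[cl] * math.log(one_m_a2)
                g_gamma[cl] += K_cell[cl] * 2.0 * a_cell[cl] * a_cell[cl] / one_m_a2

    # chain likelihood gradients into the linear predictor and (x, y)
    g_alpha = np.zeros(C)
    g_beta = np.zeros((P, C))
    g_delta = np.zeros((C, E))
    g_x = np.zeros(ncell)
    g_y = np.zeros(ncell)
    cell = 0
    for p in range(P):
        for c in range(C):
            for e in range(E):
                gu = g_gamma[cell] * gamma_scale * sig_ups[cell]
                g_alpha[c] += gu
                g_beta[p, c] += gu
                g_delta[c, e] += gu
                xv = q[o_x + cell]
                yv = q[o_y + cell]
                rho2 = xv * xv + yv * yv
                g_x[cell] = -g_mu[cell] * yv / rho2
                g_y[cell] = g_mu[cell] * xv / rho2
                cell += 1

    # prior: Beta(aS, bS) on S_c = logistic(alpha_c), with logit Jacobian
    lbeta_S = math.lgamma(aS) + math.lgamma(bS) - math.lgamma(aS + bS)
    for c in range(C):
        al = q[o_alpha + c]
        if al > 0.0:
            log_S = -math.log1p(math.exp(-al))
            log_1mS = -al + log_S
        else:
            log_1mS = -math.log1p(math.exp(al))
            log_S = al + log_1mS
        S = math.exp(log_S)
        lp += aS * log_S + bS * log_1mS - lbeta_S
        g_alpha[c] += aS * (1.0 - S) - bS * S

    # prior: non-centred participant slopes (multivariate t scale mixture)
    g_L = np.zeros((C, C))
    g_w = np.zeros(P)
    g_lsb = np.zeros(C)
    g_lsd = np.zeros(C)
    for p in range(P):
        for c in range(C):
            zb = q[o_zb + p * C + c]
            lp += -0.5 * zb * zb - 0.5 * LOG2PI
            g_m = g_beta[p, c] * sb[c] / su[p]           # dlp/dM[p,c]
            acc = -zb
            for i in range(c, C):
                acc += (g_beta[p, i] * sb[i] / su[p]) * Lc[i, c]
            grad[o_zb + p * C + c] = acc
            for j in range(c + 1):
                g_L[c, j] += g_m * q[o_zb + p * C + j]
            g_lsb[c] += g_beta[p, c] * beta[p, c]
            g_w[p] += -0.5 * g_beta[p, c] * beta[p, c]
    lp += P * (half_nu * math.log(half_nu) - math.lgamma(half_nu))
    for p in range(P):
        lp += half_nu * q[o_w + p] - half_nu * u[p]
        g_w[p] += half_nu - half_nu * u[p]

    # prior: electrode slopes
    for c in range(C):
        for e in range(E):
            zd = q[o_zd + c * E + e]
            lp += -0.5 * zd * zd - 0.5 * LOG2PI
            grad[o_zd + c * E + e] = -zd + g_delta[c, e] * sd[c]
            g_lsd[c] += g_delta[c, e] * delta[c, e]

    # prior: Bundt radial profile on each (x, y)
    lp += ncell * (k_r * math.log(rate_r) - math.lgamma(k_r))
    for cl in range(ncell):
        xv = q[o_x + cl]
        yv = q[o_y + cl]
        rho = math.hypot(xv, yv)
        lp += (k_r - 1.0) * math.log(rho) - rate_r * rho
        dlp = (k_r - 1.0) / rho - rate_r
        g_x[cl] += dlp * xv / rho
        g_y[cl] += dlp * yv / rho
    for cl in range(ncell):
        grad[o_x + cl] = g_x[cl]
        grad[o_y + cl] = g_y[cl]

    # hyperpriors: half-normal on the scales, log-space
    for c in range(C):
        r1 = sb[c] / sb_scale
        r2 = sd[c] / sd_scale
        lp += (-0.5 * r1 * r1 + math.log(sb[c])
               + 0.5 * math.log(2.0 / math.pi) - math.log(sb_scale))
        lp += (-0.5 * r2 * r2 + math.log(sd[c])
               + 0.5 * math.log(2.0 / math.pi) - math.log(sd_scale))
        grad[o_lsb + c] = g_lsb[c] - r1 * r1 + 1.0
        grad[o_lsd + c] = g_lsd[c] - r2 * r2 + 1.0

    # prior: CPC-Beta factorisation of LKJ on the slope correlation
    if ncorr > 0:
        idx = 0
        for i in range(1, C):
            pref = 1.0
            # tail-sum trick: accumulate sum_{j>m} g_L[i,j] * L[i,j] backwards
            tail = np.zeros(i + 2)
            Lrow = np.empty(i + 1)
            prefs = np.empty(i + 1)
            pr = 1.0
            for j in range(i):
                prefs[j] = pr
                Lrow[j] = zc[idx + j] * pr
                pr *= math.sqrt(1.0 - zc[idx + j] * zc[idx + j])
            prefs[i] = pr
            Lrow[i] = pr
            for j in range(i, -1, -1):
                tail[j] = tail[j + 1] + g_L[i, j] * Lrow[j]
            for m in range(i):
                z = zc[idx + m]
                ash = cpc_shapes[idx + m]
                lp += ((ash - 1.0) * (math.log1p(z) + math.log1p(-z)
                                      - 2.0 * math.log(2.0))
                       - (math.lgamma(ash) * 2.0 - math.lgamma(2.0 * ash))
                       - math.log(2.0) + math.log1p(-z * z))
                g_chain = (g_L[i, m] * prefs[m]
                           - z / (1.0 - z * z) * tail[m + 1])
                grad[o_zc + idx + m] = (-2.0 * z * ash
                                        + g_chain * (1.0 - z * z))
            idx += i

    # prior on nu (when estimated)
    if estimate_nu:
        lp += (nu_shape * t_nu - nu_rate * math.exp(t_nu)
               + nu_shape * math.log(nu_rate) - math.lgamma(nu_shape))
        g_t = nu_shape - nu_rate * math.exp(t_nu)
        dlp_dnu = 0.0
        for p in range(P):
            dlp_dnu += 0.5 * (math.log(half_nu) + 1.0
                              - _nb_digamma(half_nu) + q[o_w + p] - u[p])
        grad[o_t] = g_t + dlp_dnu * math.exp(t_nu)

    for c in range(C):
        grad[o_alpha + c] = g_alpha[c]
    for p in range(P):
        grad[o_w + p] = g_w[p]

    if not np.isfinite(lp):
        return bad
    for i in range(dim):
        if not np.isfinite(grad[i]):
            return bad
    return lp, grad
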