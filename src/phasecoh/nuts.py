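"""A self-contained No-U-Turn Hamiltonian Monte Carlo sampler.

Multinomial NUTS with biased progressive sampling, dual-averaging step-size
adaptation and diagonal mass-matrix estimation during warmup.  The target is
supplied as a callable ``f(q) -> (logp, grad)``; a non-finite log-density is
treated as a rejected (divergent) state, never an exception.

The sampler is generic: it knows nothing about the phase-coherence model and
is exercised directly on Gaussian targets in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChainResult", "nuts_chain"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    """Post-warmup output of one chain."""

    draws: np.ndarray        # (n_draws, dim)
    logp: np.ndarray         # (n_draws,)
    energies: np.ndarray     # (n_draws,) Hamiltonian at each accepted state
    divergent: np.ndarray    # (n_draws,) bool
    accept_stat: np.ndarray  # (n_draws,) mean Metropolis acceptance proxy
    tree_depth: np.ndarray   # (n_draws,) int
    step_size: float
    inv_mass: np.ndarray
    n_divergent_warmup: int


class _Tree:
    __slots__ = ("q_m", "p_m", "g_m", "q_p", "p_p", "g_p", "q_prop", "lp_prop",
                 "p_prop", "g_prop", "log_w", "sum_accept", "n_states",
                 "diverged", "turning", "n_leapfrog")


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * p, inv_mass))


def _uturn(q_p, q_m, p_p, p_m, inv_mass) -> bool:
    dq = q_p - q_m
    return (np.dot(dq, inv_mass * p_m) < 0.0) or (np.dot(dq, inv_mass * p_p) < 0.0)


def nuts_chain(f, q0: np.ndarray, n_warmup: int, n_draws: int, rng,
               *, target_accept: float = 0.9, max_treedepth: int = 10,
               inv_mass: np.ndarray | None = None,
               adapt_mass: bool = True) -> ChainResult:
    """Run one NUTS chain and return the post-warmup draws."""
    q = np.array(q0, dtype=float)
    dim = q.size
    lp, grad = f(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-density")
    inv_mass = np.ones(dim) if inv_mass is None else np.asarray(inv_mass, float)

    def leapfrog(q, p, grad, eps):
        p_half = p + 0.5 * eps * grad
        q_new = q + eps * inv_mass * p_half
        lp_new, g_new = f(q_new)
        p_new = p_half + 0.5 * eps * g_new
        return q_new, p_new, lp_new, g_new

    def find_step(q, lp, grad):
        eps = 1.0
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        H0 = -lp + _kinetic(p, inv_mass)
        _, p1, lp1, _ = leapfrog(q, p, grad, eps)
        dH = H0 - (-lp1 + _kinetic(p1, inv_mass)) if np.isfinite(lp1) else -np.inf
        while not np.isfinite(dH) or dH < np.log(0.5):
            eps *= 0.5
            if eps < 1e-12:
                return 1e-12
            _, p1, lp1, _ = leapfrog(q, p, grad, eps)
            dH = H0 - (-lp1 + _kinetic(p1, inv_mass)) if np.isfinite(lp1) else -np.inf
        direction = 1.0 if dH > np.log(0.5) else -1.0
        while direction * dH > direction * np.log(0.5) and 1e-12 < eps < 1e6:
            eps *= 2.0 ** direction
            _, p1, lp1, _ = leapfrog(q, p, grad, eps)
            dH = H0 - (-lp1 + _kinetic(p1, inv_mass)) if np.isfinite(lp1) else -np.inf
            if not np.isfinite(dH):
                eps *= 0.5
                break
        return eps

    def build_tree(q, p, lp, grad, depth, direction, eps, H0):
        if depth == 0:
            q1, p1, lp1, g1 = leapfrog(q, p, grad, direction * eps)
            t = _Tree()
            t.n_leapfrog = 1
            if np.isfinite(lp1) and np.all(np.isfinite(p1)):
                H = -lp1 + _kinetic(p1, inv_mass)
            else:
                H = np.inf
            dH = H - H0
            t.diverged = (not np.isfinite(H)) or (dH > _DIVERGENCE_THRESHOLD)
            t.log_w = -dH if not t.diverged else -np.inf
            t.sum_accept = float(np.exp(min(0.0, -dH))) if np.isfinite(dH) else 0.0
            t.n_states = 1
            t.q_m = t.q_p = q1
            t.p_m = t.p_p = p1
            t.g_m = t.g_p = g1
            t.q_prop, t.lp_prop, t.p_prop, t.g_prop = q1, lp1, p1, g1
            t.turning = False
            return t

        first = build_tree(q, p, lp, grad, depth - 1, direction, eps, H0)
        if first.diverged or first.turning:
            return first
        if direction > 0:
            second = build_tree(first.q_p, first.p_p, np.nan, first.g_p,
                                depth - 1, direction, eps, H0)
        else:
            second = build_tree(first.q_m, first.p_m, np.nan, first.g_m,
                                depth - 1, direction, eps, H0)
        first.n_leapfrog += second.n_leapfrog
        first.sum_accept += second.sum_accept
        first.n_states += second.n_states
        first.diverged = second.diverged
        if not second.diverged:
            log_tot = np.logaddexp(first.log_w, second.log_w)
            if np.isfinite(second.log_w) and (
                    np.log(rng.uniform()) < second.log_w - log_tot):
                first.q_prop = second.q_prop
                first.lp_prop = second.lp_prop
                first.p_prop = second.p_prop
                first.g_prop = second.g_prop
            first.log_w = log_tot
            if direction > 0:
                first.q_p, first.p_p, first.g_p = second.q_p, second.p_p, second.g_p
            else:
                first.q_m, first.p_m, first.g_m = second.q_m, second.p_m, second.g_m
            first.turning = second.turning or _uturn(
                first.q_p, first.q_m, first.p_p, first.p_m, inv_mass)
        return first

    # -- warmup schedule ---------------------------------------------------
    step = find_step(q, lp, grad)
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75
    mu_da = np.log(10.0 * step)
    h_bar, log_step_bar, da_count = 0.0, np.log(step), 0

    w1 = max(10, int(0.15 * n_warmup))
    w3 = max(w1 + 1, int(0.9 * n_warmup))
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)
    n_div_warmup = 0

    draws = np.empty((n_draws, dim))
    lps = np.empty(n_draws)
    energies = np.empty(n_draws)
    divergent = np.zeros(n_draws, dtype=bool)
    accept_stat = np.empty(n_draws)
    tree_depth = np.empty(n_draws, dtype=int)

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        H0 = -lp + _kinetic(p0, inv_mass)
        sel_q, sel_lp, sel_p, sel_g = q, lp, p0, grad
        log_w_tot = 0.0
        q_m = q_p = q
        p_m = p_p = p0
        g_m = g_p = grad
        sum_acc, n_states, n_leap = 0.0, 0, 0
        diverged_it = False
        depth = 0
        while depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction > 0:
                sub = build_tree(q_p, p_p, np.nan, g_p, depth, 1, step, H0)
            else:
                sub = build_tree(q_m, p_m, np.nan, g_m, depth, -1, step, H0)
            sum_acc += sub.sum_accept
            n_states += sub.n_states
            n_leap += sub.n_leapfrog
            if sub.diverged:
                diverged_it = True
                break
            if sub.turning:
                break
            # biased progressive sampling favours the new subtree
            if np.isfinite(sub.log_w) and (
                    np.log(rng.uniform()) < sub.log_w - log_w_tot):
                sel_q, sel_lp, sel_p, sel_g = (sub.q_prop, sub.lp_prop,
                                               sub.p_prop, sub.g_prop)
            log_w_tot = np.logaddexp(log_w_tot, sub.log_w)
            if direction > 0:
                q_p, p_p, g_p = sub.q_p, sub.p_p, sub.g_p
            else:
                q_m, p_m, g_m = sub.q_m, sub.p_m, sub.g_m
            depth += 1
            if _uturn(q_p, q_m, p_p, p_m, inv_mass):
                break
        q, lp, grad = sel_q, sel_lp, sel_g
        acc = sum_acc / max(n_states, 1)

        if warming:
            if diverged_it:
                n_div_warmup += 1
            da_count += 1
            h_bar = ((1.0 - 1.0 / (da_count + t0_da)) * h_bar
                     + (target_accept - acc) / (da_count + t0_da))
            log_step = mu_da - np.sqrt(da_count) / gamma_da * h_bar
            eta = da_count ** (-kappa_da)
            log_step_bar = eta * log_step + (1.0 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if adapt_mass and w1 <= it < w3:
                welford_n += 1
                d = q - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (q - welford_mean)
            if adapt_mass and it == w3 - 1 and welford_n > 2:
                var = welford_m2 / (welford_n - 1)
                inv_mass = (welford_n / (welford_n + 5.0)) * var \
                    + 1e-3 * (5.0 / (welford_n + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-10)
                step = find_step(q, lp, grad)
                mu_da = np.log(10.0 * step)
                h_bar, log_step_bar, da_count = 0.0, np.log(step), 0
            if it == n_warmup - 1:
                step = float(np.exp(log_step_bar))
        else:
            i = it - n_warmup
            draws[i] = q
            lps[i] = lp
            energies[i] = -sel_lp + _kinetic(sel_p, inv_mass)
            divergent[i] = diverged_it
            accept_stat[i] = acc
            tree_depth[i] = depth

    return ChainResult(draws=draws, logp=lps, energies=energies,
                       divergent=divergent, accept_stat=accept_stat,
                       tree_depth=tree_depth, step_size=step,
                       inv_mass=inv_mass, n_divergent_warmup=n_div_warmup)
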