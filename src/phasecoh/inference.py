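"""Posterior computation and summarisation.

``sample_posterior`` runs the in-package NUTS sampler on the hierarchical
wrapped-Cauchy model; ``map_estimate`` finds the penalised-likelihood mode in
the unconstrained space.  Posterior condition contrasts are reported on the
mean-resultant scale, R_c = 1 - logistic(alpha_c), the quantity of scientific
interest in a frequency-tagged analysis.

Convergence diagnostics (split R-hat, bulk/autocorrelation ESS, E-BFMI) are
delegated to arviz; the highest-density interval follows the
narrowest-contiguous-window definition with a leftmost tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._logp import UnconstrainedModel
from .model import ExperimentLayout, ModelParams, PhaseDataset, PriorConfig
from .nuts import nuts_chain

__all__ = [
    "PosteriorSamples",
    "HdiInterval",
    "DiagnosticsReport",
    "MapResult",
    "ContrastSummary",
    "sample_posterior",
    "map_estimate",
    "split_rhat",
    "effective_sample_size",
    "energy_bfmi",
    "hdi",
    "condition_resultant",
    "condition_difference",
    "electrode_difference",
    "diagnostics_report",
    "summary_table",
]


def _import_arviz():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        import arviz as az
    return az


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Post-warmup posterior draws plus sampler metadata.

    ``posterior`` maps parameter names to arrays of shape
    (chain, draw, *param_shape); all stored parameters are the centred
    quantities (beta_pc, delta_ce themselves, not their non-centred
    sampling-space counterparts).
    """

    layout: ExperimentLayout
    cfg: PriorConfig
    posterior: dict[str, np.ndarray]
    energies: np.ndarray          # (chain, draw)
    divergent: np.ndarray         # (chain, draw) bool
    accept_stat: np.ndarray       # (chain, draw)
    seed: int | None
    warmup_discarded: bool = True
    step_sizes: tuple[float, ...] = ()

    @property
    def n_chains(self) -> int:
        return self.energies.shape[0]

    @property
    def n_draws(self) -> int:
        return self.energies.shape[1]

    @property
    def divergence_count(self) -> int:
        return int(self.divergent.sum())

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains: (chain*draw, ...)."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        az = _import_arviz()
        return az.from_dict(
            posterior=self.posterior,
            sample_stats={"energy": self.energies,
                          "diverging": self.divergent,
                          "acceptance_rate": self.accept_stat},
        )


@dataclass(frozen=True)
class HdiInterval:
    """Narrowest contiguous interval holding ``mass`` posterior probability."""

    lower: float
    upper: float
    mass: float

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class DiagnosticsReport:
    rhat: dict[str, float]        # per parameter block: max split-R-hat
    ess_ratio: dict[str, float]   # per parameter block: min ESS / total draws
    ebfmi: np.ndarray             # per chain
    divergence_count: int

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess_ratio(self) -> float:
        return min(self.ess_ratio.values())


@dataclass
class MapResult:
    params: ModelParams
    logp: float
    success: bool
    message: str
    condition_R: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.condition_R = self.params.condition_R()


@dataclass
class ContrastSummary:
    """Posterior draws of a mean-resultant contrast with Table-style summary."""

    draws: np.ndarray
    mean: float
    median: float
    sd: float
    hdi: HdiInterval
    prob_positive: float

    def round(self, ndigits: int = 3) -> dict:
        return {
            "mean": round(self.mean, ndigits),
            "median": round(self.median, ndigits),
            "sd": round(self.sd, ndigits),
            "hdi_low": round(self.hdi.lower, ndigits),
            "hdi_high": round(self.hdi.upper, ndigits),
            "prob_positive": round(self.prob_positive, ndigits),
        }


# ---------------------------------------------------------------------------
# sampling and optimisation
# ---------------------------------------------------------------------------

def sample_posterior(data: PhaseDataset | None, cfg: PriorConfig,
                     chains: int = 4, iterations: int = 4000,
                     seed: int | None = None, *,
                     layout: ExperimentLayout | None = None,
                     target_accept: float = 0.9, max_treedepth: int = 10,
                     store_cell_params: bool = True,
                     use_likelihood: bool = True,
                     gamma_scale: float = 1.0) -> PosteriorSamples:
    """Sample the joint posterior with NUTS.

    ``iterations`` is the total per-chain count; the first half is warmup
    (step-size and mass adaptation) and discarded.  ``use_likelihood=False``
    samples the prior (for prior-recovery checks); ``gamma_scale`` is the
    deliberate-likelihood-corruption hook used by calibration experiments.
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if iterations < 4:
        raise ValueError("iterations must be at least 4")
    if data is None and layout is None:
        raise ValueError("either data or layout must be given")
    layout = layout if data is None else data.layout
    model = UnconstrainedModel(layout, cfg, data, gamma_scale=gamma_scale,
                               use_likelihood=use_likelihood)
    n_warmup = iterations // 2
    n_draws = iterations - n_warmup

    seq = np.random.SeedSequence(seed)
    child_seeds = seq.spawn(chains)
    results = []
    for ch in range(chains):
        rng = np.random.default_rng(child_seeds[ch])
        q0 = model.initial_point(rng)
        res = nuts_chain(model.logp_grad, q0, n_warmup, n_draws, rng,
                         target_accept=target_accept,
                         max_treedepth=max_treedepth)
        results.append(res)

    first = model.derived(results[0].draws[0], store_cells=store_cell_params)
    posterior = {k: np.empty((chains, n_draws) + v.shape)
                 for k, v in first.items()}
    for ch, res in enumerate(results):
        for i in range(n_draws):
            d = model.derived(res.draws[i], store_cells=store_cell_params)
            for k, v in d.items():
                posterior[k][ch, i] = v
    posterior["lp"] = np.stack([r.logp for r in results])

    n_div = int(sum(r.divergent.sum() for r in results))
    if n_div == n_draws * chains:
        report = diagnostics_report_from_arrays(
            posterior, np.stack([r.energies for r in results]))
        raise RuntimeError(
            f"sampling failed: every post-warmup iteration diverged; {report}")

    return PosteriorSamples(
        layout=layout, cfg=cfg, posterior=posterior,
        energies=np.stack([r.energies for r in results]),
        divergent=np.stack([r.divergent for r in results]),
        accept_stat=np.stack([r.accept_stat for r in results]),
        seed=seed,
        step_sizes=tuple(float(r.step_size) for r in results))


def map_estimate(data: PhaseDataset, cfg: PriorConfig, *, n_starts: int = 1,
                 seed: int | None = None, maxiter: int = 2000) -> MapResult:
    """Penalised-likelihood mode in the unconstrained sampling space.

    Runs L-BFGS-B with the analytic gradient from ``n_starts`` jittered
    data-informed starting points and keeps the best mode found.
    """
    model = UnconstrainedModel(data.layout, cfg, data)
    seq = np.random.SeedSequence(seed)
    best = None
    for child in seq.spawn(max(1, n_starts)):
        rng = np.random.default_rng(child)
        q0 = model.initial_point(rng, jitter=0.05)

        def negf(q):
            lp, g = model.logp_grad(q)
            if not np.isfinite(lp):
                return 1e100, np.zeros_like(q)
            return -lp, -g

        res = optimize.minimize(negf, q0, jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res, model.to_params(res.x))
    logp, res, params = best
    return MapResult(params=params, logp=float(logp),
                     success=bool(res.success), message=str(res.message))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _check_chains(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must have shape (chain, draw)")
    if draws.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    if draws.shape[1] < 4:
        raise ValueError("at least 4 draws per chain are required")
    if np.ptp(draws) == 0.0:
        raise ValueError("draws are constant; diagnostics undefined")
    return draws


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction statistic (rank-normalised)."""
    az = _import_arviz()
    draws = _check_chains(draws)
    return float(az.rhat(draws))


def effective_sample_size(draws: np.ndarray, method: str = "bulk") -> float:
    """Autocorrelation-based effective sample size of pooled chains."""
    az = _import_arviz()
    draws = _check_chains(draws)
    return float(az.ess(draws, method=method))


def energy_bfmi(energies: np.ndarray) -> np.ndarray:
    """E-BFMI per chain: mean squared energy transition over energy variance.

    Low values (< ~0.3) flag that momentum resampling explores the energy
    marginal poorly; values near 1-2 are healthy."""
    az = _import_arviz()
    energies = _check_chains(energies)
    return np.asarray(az.bfmi(energies))


def diagnostics_report_from_arrays(posterior: dict[str, np.ndarray],
                                   energies: np.ndarray) -> DiagnosticsReport:
    az = _import_arviz()
    rhat: dict[str, float] = {}
    ess_ratio: dict[str, float] = {}
    for name, arr in posterior.items():
        if name == "lp":
            continue
        chains, n = arr.shape[:2]
        flat = arr.reshape(chains, n, -1)
        # skip numerically constant slices (e.g. a fixed parameter)
        keep = np.ptp(flat.reshape(chains * n, -1), axis=0) > 1e-12
        if not np.any(keep):
            continue
        flat = flat[:, :, keep]
        r = np.array([float(az.rhat(flat[:, :, j])) for j in range(flat.shape[2])])
        e = np.array([float(az.ess(flat[:, :, j])) for j in range(flat.shape[2])])
        rhat[name] = float(np.nanmax(r))
        ess_ratio[name] = float(np.nanmin(e) / (chains * n))
    try:
        ebfmi = np.asarray(az.bfmi(energies))
    except Exception:
        ebfmi = np.full(energies.shape[0], np.nan)
    return DiagnosticsReport(rhat=rhat, ess_ratio=ess_ratio, ebfmi=ebfmi,
                             divergence_count=0)


def diagnostics_report(samples: PosteriorSamples) -> DiagnosticsReport:
    """Split-R-hat / ESS per parameter block, E-BFMI per chain, divergences."""
    report = diagnostics_report_from_arrays(samples.posterior, samples.energies)
    report.divergence_count = samples.divergence_count
    return report


# ---------------------------------------------------------------------------
# HDIs and contrasts
# ---------------------------------------------------------------------------

def hdi(samples: np.ndarray, mass: float = 0.9) -> HdiInterval:
    """Narrowest contiguous interval containing ``mass`` of the draws.

    Scans every window of ceil(mass * N) consecutive order statistics and
    returns the narrowest; ties resolve to the leftmost window (HDIs are
    non-unique for multimodal draws, so the tie-break is part of the
    contract).
    """
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = samples.size
    if n < 10:
        raise ValueError("need at least 10 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    n_in = int(np.ceil(mass * n))
    if n_in >= n:
        return HdiInterval(float(samples[0]), float(samples[-1]), mass)
    widths = samples[n_in:] - samples[:n - n_in]
    i = int(np.argmin(widths))
    return HdiInterval(float(samples[i]), float(samples[i + n_in]), mass)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def condition_resultant(samples: PosteriorSamples, c) -> np.ndarray:
    """Pooled posterior draws of R_c = 1 - logistic(alpha_c)."""
    c = samples.layout.condition_index(c)
    return 1.0 - _logistic(samples.stacked("alpha")[:, c])


def condition_difference(samples: PosteriorSamples, c1, c2,
                         hdi_mass: float = 0.9) -> ContrastSummary:
    """Posterior draws and summary of Delta R = R_{c1} - R_{c2}."""
    i1 = samples.layout.condition_index(c1)
    i2 = samples.layout.condition_index(c2)
    if i1 == i2:
        raise ValueError("c1 and c2 must differ")
    draws = condition_resultant(samples, i1) - condition_resultant(samples, i2)
    return _summarise(draws, hdi_mass)


def electrode_difference(samples: PosteriorSamples, c1, c2, e,
                         hdi_mass: float = 0.95) -> ContrastSummary:
    """Electrode-resolved contrast using R_ce = 1 - logistic(alpha_c + delta_ce).

    The returned summary's HDI (default 95%) is the basis of the
    filled-circle rule: an electrode is flagged when zero lies outside it.
    """
    lay = samples.layout
    i1, i2 = lay.condition_index(c1), lay.condition_index(c2)
    e = lay.electrode_index(e)
    alpha = samples.stacked("alpha")
    delta = samples.stacked("delta")
    r1 = 1.0 - _logistic(alpha[:, i1] + delta[:, i1, e])
    r2 = 1.0 - _logistic(alpha[:, i2] + delta[:, i2, e])
    return _summarise(r1 - r2, hdi_mass)


def _summarise(draws: np.ndarray, hdi_mass: float) -> ContrastSummary:
    interval = hdi(draws, hdi_mass)
    return ContrastSummary(
        draws=draws,
        mean=float(np.mean(draws)),
        median=float(np.median(draws)),
        sd=float(np.std(draws, ddof=1)),
        hdi=interval,
        prob_positive=float(np.mean(draws > 0.0)),
    )


def summary_table(samples: PosteriorSamples, hdi_mass: float = 0.9):
    """Tidy per-parameter summary (mean, median, sd, HDI, R-hat, ESS)."""
    import pandas as pd
    az = _import_arviz()
    rows = []
    for name, arr in samples.posterior.items():
        chains, n = arr.shape[:2]
        flat = arr.reshape(chains, n, -1)
        for j in range(flat.shape[2]):
            x = flat[:, :, j]
            pooled = x.ravel()
            idx = np.unravel_index(j, arr.shape[2:]) if arr.ndim > 2 else ()
            label = name + ("[" + ",".join(map(str, idx)) + "]" if idx else "")
            if np.ptp(pooled) > 1e-12:
                r = float(az.rhat(x))
                e = float(az.ess(x))
                interval = hdi(pooled, hdi_mass)
                lo, hi = interval.lower, interval.upper
            else:
                r, e = np.nan, np.nan
                lo = hi = float(pooled[0])
            rows.append({
                "parameter": label,
                "mean": float(pooled.mean()),
                "median": float(np.median(pooled)),
                "sd": float(pooled.std(ddof=1)),
                "hdi_low": lo,
                "hdi_high": hi,
                "rhat": r,
                "ess": e,
            })
    return pd.DataFrame(rows)
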