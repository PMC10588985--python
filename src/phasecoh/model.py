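"""Hierarchical generative model for frequency-tagged phase data.

Each trial phase theta_pcek (participant p, condition c, electrode e, trial k)
is wrapped-Cauchy distributed.  The cell location mu_pce is the angle of a
planar pair (x, y)_pce with a rotation-invariant "Bundt" prior (uniform angle,
radius soft-pinned near 1), which gives the circular location a uniform,
topology-respecting prior that gradient-based samplers can traverse.  The cell
scale is driven by a linear model on the logit of the circular variance:

    S_pce = logistic(upsilon_pce),   upsilon_pce = alpha_c + beta_pc + delta_ce
    gamma_pce = -log(1 - S_pce)

alpha_c is the condition effect (the quantity of scientific interest, reported
as the condition mean resultant R_c = 1 - logistic(alpha_c)); beta_pc are
participant-by-condition slopes with a multivariate Student-t prior (partial
pooling within and across conditions, heavy tails to absorb unusually strong
or inattentive participants); delta_ce are electrode slopes pooled within
condition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .circular import (
    S_from_linear,
    gamma_from_linear,
    wrap_angle,
    wrapped_cauchy_logpdf,
)

__all__ = [
    "ExperimentLayout",
    "PhaseDataset",
    "ModelParams",
    "PriorConfig",
    "preset_layout",
    "mu_from_xy",
    "bundt_logprior",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "simulate_dataset",
    "draw_params_from_prior",
]


# ---------------------------------------------------------------------------
# layouts and datasets
# ---------------------------------------------------------------------------

def _default_labels(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class ExperimentLayout:
    """Dimensions of a phase experiment: P participants x C conditions x
    E electrodes with up to K trials per cell."""

    n_participants: int
    n_conditions: int
    n_electrodes: int
    n_trials: int
    condition_labels: tuple[str, ...] = ()
    electrode_labels: tuple[str, ...] = ()
    participant_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_conditions", "n_electrodes", "n_trials"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        for attr, prefix, n in (
            ("condition_labels", "cond", self.n_conditions),
            ("electrode_labels", "E", self.n_electrodes),
            ("participant_labels", "P", self.n_participants),
        ):
            labels = tuple(getattr(self, attr))
            if not labels:
                labels = _default_labels(prefix, n)
            if len(labels) != n:
                raise ValueError(f"{attr} has {len(labels)} entries, expected {n}")
            if len(set(labels)) != len(labels):
                raise ValueError(f"{attr} must be unique")
            object.__setattr__(self, attr, labels)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.n_participants, self.n_conditions, self.n_electrodes,
                self.n_trials)

    @property
    def n_cells(self) -> int:
        return self.n_participants * self.n_conditions * self.n_electrodes

    def condition_index(self, label) -> int:
        if isinstance(label, (int, np.integer)):
            if not 0 <= label < self.n_conditions:
                raise IndexError(f"condition index {label} out of range")
            return int(label)
        return self.condition_labels.index(label)

    def electrode_index(self, label) -> int:
        if isinstance(label, (int, np.integer)):
            if not 0 <= label < self.n_electrodes:
                raise IndexError(f"electrode index {label} out of range")
            return int(label)
        return self.electrode_labels.index(label)


def preset_layout(name: str) -> ExperimentLayout:
    """Layouts emulating the two published study designs.

    ``"phrase"``: 16 participants x 6 conditions x 32 electrodes x 24 trials
    (grammatical-phrase EEG design, analysis frequency 1.5625 Hz).
    ``"sl"``: 39 participants x 2 conditions x 64 electrodes x 132 trials
    (statistical-learning design: three blocks of 44 trials, 4 Hz syllables).
    """
    if name == "phrase":
        return ExperimentLayout(
            16, 6, 32, 24,
            condition_labels=("AN", "AV", "MP", "ML", "RV", "RR"),
        )
    if name == "sl":
        return ExperimentLayout(39, 2, 64, 132, condition_labels=("BL", "EXP"))
    raise ValueError(f"unknown preset {name!r}; expected 'phrase' or 'sl'")


class PhaseDataset:
    """Phase angles on a (P, C, E, K) grid at one analysis frequency.

    Missing trials are carried in an explicit boolean mask (True = observed);
    the phase array holds NaN at unobserved slots so a sentinel angle can
    never leak into an analysis.
    """

    def __init__(self, layout: ExperimentLayout, phases: np.ndarray,
                 mask: np.ndarray | None = None, frequency: float = np.nan):
        phases = np.asarray(phases, dtype=float)
        if phases.shape != layout.shape:
            raise ValueError(
                f"phases shape {phases.shape} does not match layout {layout.shape}")
        if mask is None:
            mask = np.isfinite(phases)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != layout.shape:
            raise ValueError("mask shape does not match layout")
        if not np.all(np.isfinite(phases[mask])):
            raise ValueError("observed phases must be finite")
        obs = phases[mask]
        if obs.size and (obs.min() < -np.pi or obs.max() >= np.pi):
            raise ValueError("phases must be wrapped to [-pi, pi); use wrap_angle")
        self.layout = layout
        self.phases = np.where(mask, phases, np.nan)
        self.mask = mask
        self.frequency = float(frequency)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def cell_phases(self, p: int, c: int, e: int) -> np.ndarray:
        return self.phases[p, c, e][self.mask[p, c, e]]

    def trials_per_cell(self) -> np.ndarray:
        return self.mask.sum(axis=-1)

    def subset_participants(self, n: int) -> "PhaseDataset":
        """First ``n`` participants, in recorded order."""
        if not 1 <= n <= self.layout.n_participants:
            raise ValueError("participant subset out of range")
        lay = ExperimentLayout(
            n, self.layout.n_conditions, self.layout.n_electrodes,
            self.layout.n_trials,
            condition_labels=self.layout.condition_labels,
            electrode_labels=self.layout.electrode_labels,
            participant_labels=self.layout.participant_labels[:n],
        )
        return PhaseDataset(lay, self.phases[:n], self.mask[:n], self.frequency)

    def subset_trials(self, n: int) -> "PhaseDataset":
        """First ``n`` trial slots per cell, in recorded order."""
        if not 1 <= n <= self.layout.n_trials:
            raise ValueError("trial subset out of range")
        lay = ExperimentLayout(
            self.layout.n_participants, self.layout.n_conditions,
            self.layout.n_electrodes, n,
            condition_labels=self.layout.condition_labels,
            electrode_labels=self.layout.electrode_labels,
            participant_labels=self.layout.participant_labels,
        )
        return PhaseDataset(lay, self.phases[..., :n], self.mask[..., :n],
                            self.frequency)


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Hyperparameters of the hierarchical prior.

    S_prior_a, S_prior_b
        Beta shape parameters of the prior on each condition's baseline
        circular variance S_c = logistic(alpha_c).  The default Beta(5, 2)
        has mean ~0.71: for weak frequency-tagged effects the circular
        variance is expected to be large, likely above one half.
    radial_shape, radial_rate
        Gamma parameters of the Bundt radial profile; shape = rate = 100
        pins the radius at mean 1 with sd 0.1.  The profile is not critical,
        it only keeps sampling away from the origin where the angle is
        undefined.
    sigma_beta_scale, sigma_delta_scale
        Scales of the half-normal hyperpriors on the participant- and
        electrode-slope standard deviations.
    lkj_eta
        Shape of the LKJ prior on the across-condition correlation of
        participant slopes; eta = 2 mildly favours identity.
    nu
        Degrees of freedom of the multivariate-t participant-slope prior:
        a fixed number (default 30), or the string "estimate" to give
        nu - 2 a Gamma(nu_prior_shape, nu_prior_rate) prior.
    """

    S_prior_a: float = 5.0
    S_prior_b: float = 2.0
    radial_shape: float = 100.0
    radial_rate: float = 100.0
    sigma_beta_scale: float = 1.0
    sigma_delta_scale: float = 1.0
    lkj_eta: float = 2.0
    nu: float | str = 30.0
    nu_prior_shape: float = 2.0
    nu_prior_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("S_prior_a", "S_prior_b", "radial_shape", "radial_rate",
                     "sigma_beta_scale", "sigma_delta_scale", "lkj_eta",
                     "nu_prior_shape", "nu_prior_rate"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            setattr(self, name, v)
        if self.nu != "estimate":
            nu = float(self.nu)
            if not np.isfinite(nu) or nu <= 2.0:
                raise ValueError("fixed nu must exceed 2")
            self.nu = nu

    @property
    def estimate_nu(self) -> bool:
        return self.nu == "estimate"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(**d)


@dataclass
class ModelParams:
    """Full (centred) parameter vector of the generative model."""

    alpha: np.ndarray            # (C,) condition effects
    beta: np.ndarray             # (P, C) participant x condition slopes
    delta: np.ndarray            # (C, E) condition x electrode slopes
    mu_xy: np.ndarray            # (P, C, E, 2) planar coordinates of mean phase
    sigma_beta: np.ndarray       # (C,) scale of participant slopes
    corr_beta: np.ndarray        # (C, C) correlation of participant slopes
    sigma_delta: np.ndarray      # (C,) scale of electrode slopes
    nu: float = 30.0             # dof of the multivariate-t slope prior

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.mu_xy = np.asarray(self.mu_xy, dtype=float)
        self.sigma_beta = np.atleast_1d(np.asarray(self.sigma_beta, dtype=float))
        self.sigma_delta = np.atleast_1d(np.asarray(self.sigma_delta, dtype=float))
        self.corr_beta = np.atleast_2d(np.asarray(self.corr_beta, dtype=float))
        self.nu = float(self.nu)
        P, C = self.beta.shape
        E = self.delta.shape[1]
        if self.alpha.shape != (C,) or self.delta.shape != (C, E):
            raise ValueError("inconsistent alpha/beta/delta shapes")
        if self.mu_xy.shape != (P, C, E, 2):
            raise ValueError("mu_xy must have shape (P, C, E, 2)")
        if self.sigma_beta.shape != (C,) or self.sigma_delta.shape != (C,):
            raise ValueError("sigma shapes must be (C,)")
        if np.any(self.sigma_beta <= 0) or np.any(self.sigma_delta <= 0):
            raise ValueError("scales must be strictly positive")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2")
        R = self.corr_beta
        if R.shape != (C, C) or not np.allclose(R, R.T):
            raise ValueError("corr_beta must be a symmetric C x C matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("corr_beta must have unit diagonal")
        if np.any(np.linalg.eigvalsh(R) <= 0):
            raise ValueError("corr_beta must be positive definite")

    @property
    def shape(self) -> tuple[int, int, int]:
        P, C = self.beta.shape
        return P, C, self.delta.shape[1]

    def upsilon(self) -> np.ndarray:
        """Linear predictor alpha_c + beta_pc + delta_ce on the (P, C, E) grid."""
        return (self.alpha[None, :, None] + self.beta[:, :, None]
                + self.delta[None, :, :])

    def gamma(self) -> np.ndarray:
        return gamma_from_linear(self.upsilon())

    def mu(self) -> np.ndarray:
        return mu_from_xy(self.mu_xy[..., 0], self.mu_xy[..., 1])

    def condition_R(self) -> np.ndarray:
        """Condition-level mean resultant length R_c = 1 - logistic(alpha_c)."""
        return 1.0 - S_from_linear(self.alpha)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def mu_from_xy(x, y):
    """Mean phase angle(x, y) = atan2(y, x), wrapped to [-pi, pi).

    The planar pair must not sit at the origin, where the angle is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x == 0.0) & (y == 0.0)):
        raise ValueError("(x, y) = (0, 0) has no angle")
    out = np.arctan2(y, x)
    out = np.where(out >= np.pi, -np.pi, out)  # atan2 returns +pi for y=-0
    return float(out) if out.ndim == 0 else out


def bundt_logprior(x, y, cfg: PriorConfig):
    """Log-density increment of the planar Bundt prior at (x, y).

    Rotation-invariant by construction: the increment is the Gamma
    log-density of the radius rho = sqrt(x^2 + y^2) and depends on (x, y)
    only through rho.  With the default shape = rate = 100 the radius
    concentrates at 1 +/- 0.1.  No polar Jacobian is added; only the angle
    enters the model, and angular uniformity holds either way (see
    docs/methods.md for the radial-marginal consequence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x == 0.0) & (y == 0.0)):
        raise ValueError("(x, y) = (0, 0) is outside the support")
    rho = np.hypot(x, y)
    out = sps.gamma.logpdf(rho, a=cfg.radial_shape, scale=1.0 / cfg.radial_rate)
    return float(out) if out.ndim == 0 else out


def linear_predictor(params: ModelParams, p: int, c: int, e: int) -> float:
    """upsilon_pce = alpha_c + beta_pc + delta_ce."""
    P, C, E = params.shape
    if not (0 <= p < P and 0 <= c < C and 0 <= e < E):
        raise IndexError(f"index ({p}, {c}, {e}) outside layout ({P}, {C}, {E})")
    return float(params.alpha[c] + params.beta[p, c] + params.delta[c, e])


def log_likelihood(params: ModelParams, data: PhaseDataset) -> float:
    """Sum of wrapped-Cauchy log-densities over all observed trials.

    Raises FloatingPointError if any cell's circular variance underflows to
    0 or rounds to 1 in float64 (the density is degenerate there).
    """
    if params.shape != data.layout.shape[:3]:
        raise ValueError("params do not match the dataset layout")
    if data.n_observed == 0:
        raise ValueError("dataset has no observed trials")
    ups = params.upsilon()
    S = S_from_linear(ups)
    if np.any(S <= 0.0) or np.any(S >= 1.0):
        raise FloatingPointError("circular variance numerically 0 or 1")
    gamma = gamma_from_linear(ups)
    mu = params.mu()
    ll = wrapped_cauchy_logpdf(data.phases, mu=mu[..., None], gamma=gamma[..., None])
    return float(np.sum(ll[data.mask]))


def _lkj_unnormalised_logpdf(R: np.ndarray, eta: float) -> float:
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    return float((eta - 1.0) * logdet)


def log_prior(params: ModelParams, cfg: PriorConfig) -> float:
    """Joint log-prior of the centred parameters (up to the LKJ normaliser).

    Terms: Beta(a, b) on S_c = logistic(alpha_c) with the logit Jacobian;
    multivariate Student-t(nu, 0, diag(sigma_beta) R diag(sigma_beta)) on each
    participant's slope row; Normal(0, sigma_delta[c]) on each delta_ce; the
    Bundt increment on each planar pair; half-normal hyperpriors on the
    scales; LKJ(eta) on the correlation; and, when nu is estimated, a
    Gamma prior on nu - 2.
    """
    C = params.alpha.shape[0]
    S = S_from_linear(params.alpha)
    lp = float(np.sum(sps.beta.logpdf(S, cfg.S_prior_a, cfg.S_prior_b)
                      + np.log(S) + np.log1p(-S)))

    D = np.diag(params.sigma_beta)
    Sigma = D @ params.corr_beta @ D
    lp += float(np.sum(sps.multivariate_t.logpdf(
        params.beta, loc=np.zeros(C), shape=Sigma, df=params.nu)))

    lp += float(np.sum(sps.norm.logpdf(
        params.delta, scale=params.sigma_delta[:, None])))

    lp += float(np.sum(bundt_logprior(
        params.mu_xy[..., 0], params.mu_xy[..., 1], cfg)))

    lp += float(np.sum(sps.halfnorm.logpdf(params.sigma_beta,
                                           scale=cfg.sigma_beta_scale)))
    lp += float(np.sum(sps.halfnorm.logpdf(params.sigma_delta,
                                           scale=cfg.sigma_delta_scale)))
    if C > 1:
        lp += _lkj_unnormalised_logpdf(params.corr_beta, cfg.lkj_eta)
    if cfg.estimate_nu:
        lp += float(sps.gamma.logpdf(params.nu - 2.0, a=cfg.nu_prior_shape,
                                     scale=1.0 / cfg.nu_prior_rate))
    return lp


def simulate_dataset(params: ModelParams, layout: ExperimentLayout, seed=None,
                     *, frequency: float = np.nan,
                     degenerate: bool = False) -> PhaseDataset:
    """Forward-simulate a complete phase dataset from the generative model.

    Each trial is an independent wrapped-Cauchy draw with its cell's
    (mu_pce, gamma_pce).  ``degenerate=True`` allows gamma == 0 cells (all
    trials equal to mu, coherence exactly 1)."""
    if params.shape != (layout.n_participants, layout.n_conditions,
                        layout.n_electrodes):
        raise ValueError("params do not match layout")
    rng = np.random.default_rng(seed)
    mu = params.mu()
    gamma = params.gamma()
    if not degenerate and np.any(gamma <= 0.0):
        raise FloatingPointError(
            "gamma underflowed to 0; pass degenerate=True for point-mass cells")
    K = layout.n_trials
    # wrap(mu + gamma * standard_cauchy) is an exact wrapped-Cauchy draw
    raw = rng.standard_cauchy(size=mu.shape + (K,))
    phases = wrap_angle(mu[..., None] + gamma[..., None] * raw)
    if degenerate:
        point = np.broadcast_to((gamma == 0.0)[..., None], phases.shape)
        phases = np.where(point, np.broadcast_to(
            np.asarray(wrap_angle(mu))[..., None], phases.shape), phases)
    return PhaseDataset(layout, phases, np.ones(phases.shape, dtype=bool),
                        frequency)


def _cpc_beta_shapes(C: int, eta: float) -> np.ndarray:
    """Beta shape parameter for each canonical partial correlation, row-major
    over the strict lower triangle (i > j): a_ij = eta + (C - 2 - j) / 2."""
    return np.array([eta + 0.5 * (C - 2 - j)
                     for i in range(1, C) for j in range(i)])


def _cholesky_from_cpc(z: np.ndarray, C: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations (strict-lower-triangle, row-major).  Complex-safe."""
    L = np.zeros((C, C), dtype=z.dtype if np.iscomplexobj(z) else float)
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, C):
        rem = 1.0 + 0j if np.iscomplexobj(z) else 1.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(rem)
            rem = rem - L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


def _sample_lkj_cholesky(C: int, eta: float, rng) -> np.ndarray:
    """Draw the Cholesky factor of an LKJ(eta) correlation matrix via its
    canonical-partial-correlation factorisation."""
    if C == 1:
        return np.ones((1, 1))
    shapes = _cpc_beta_shapes(C, eta)
    z = 2.0 * rng.beta(shapes, shapes) - 1.0
    return _cholesky_from_cpc(z, C)


def draw_params_from_prior(cfg: PriorConfig, layout: ExperimentLayout,
                           seed=None) -> ModelParams:
    """One joint draw of all model parameters from the prior.

    The draw is generated in the same parameterisation the sampler uses
    (non-centred slopes, canonical partial correlations, Gamma scale-mixture
    for the multivariate t), so prior draws and the sampled posterior target
    the identical joint distribution -- the property simulation-based
    calibration exercises.
    """
    rng = np.random.default_rng(seed)
    P, C, E = layout.n_participants, layout.n_conditions, layout.n_electrodes

    S_c = rng.beta(cfg.S_prior_a, cfg.S_prior_b, size=C)
    alpha = np.log(S_c) - np.log1p(-S_c)

    sigma_beta = np.abs(rng.normal(0.0, cfg.sigma_beta_scale, size=C))
    sigma_delta = np.abs(rng.normal(0.0, cfg.sigma_delta_scale, size=C))
    L = _sample_lkj_cholesky(C, cfg.lkj_eta, rng)
    corr = L @ L.T

    nu = cfg.nu if not cfg.estimate_nu else 2.0 + rng.gamma(
        cfg.nu_prior_shape, 1.0 / cfg.nu_prior_rate)
    u = rng.gamma(nu / 2.0, 2.0 / nu, size=P)
    z = rng.standard_normal((P, C))
    beta = (z @ L.T) * sigma_beta[None, :] / np.sqrt(u)[:, None]

    delta = rng.standard_normal((C, E)) * sigma_delta[:, None]

    # log-prior adds the Gamma density of rho on the plane without the polar
    # Jacobian, so the implied radial marginal is rho ~ Gamma(shape + 1, rate)
    rho = rng.gamma(cfg.radial_shape + 1.0, 1.0 / cfg.radial_rate,
                    size=(P, C, E))
    phi = rng.uniform(-np.pi, np.pi, size=(P, C, E))
    mu_xy = np.stack([rho * np.cos(phi), rho * np.sin(phi)], axis=-1)

    return ModelParams(alpha=alpha, beta=beta, delta=delta, mu_xy=mu_xy,
                       sigma_beta=sigma_beta, corr_beta=corr,
                       sigma_delta=sigma_delta, nu=float(nu))
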