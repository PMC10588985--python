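import numpy as np
import pytest
from scipy import stats as sps

from phasecoh._logp import UnconstrainedModel
from phasecoh.circular import wrapped_cauchy_logpdf
from phasecoh.model import (
    ExperimentLayout,
    ModelParams,
    PhaseDataset,
    PriorConfig,
    bundt_logprior,
    draw_params_from_prior,
    linear_predictor,
    log_likelihood,
    log_prior,
    mu_from_xy,
    preset_layout,
    simulate_dataset,
)

from conftest import recovery_params


def tiny_layout(C=2):
    return ExperimentLayout(2, C, 2, 3)


class TestLayoutAndDataset:
    def test_preset_layouts_match_study_designs(self):
        phrase = preset_layout("phrase")
        assert phrase.shape == (16, 6, 32, 24)
        assert phrase.condition_labels[0] == "AN"
        sl = preset_layout("sl")
        assert sl.shape == (39, 2, 64, 132)

    def test_labels_validated(self):
        with pytest.raises(ValueError):
            ExperimentLayout(2, 2, 2, 2, condition_labels=("a", "a"))
        with pytest.raises(ValueError):
            ExperimentLayout(0, 2, 2, 2)

    def test_dataset_rejects_unwrapped_phases(self):
        lay = tiny_layout()
        phases = np.zeros(lay.shape)
        phases[0, 0, 0, 0] = 7.0
        with pytest.raises(ValueError, match="wrap"):
            PhaseDataset(lay, phases)

    def test_missingness_is_masked_not_sentinel(self):
        lay = tiny_layout()
        phases = np.zeros(lay.shape)
        mask = np.ones(lay.shape, bool)
        mask[0, 0, 0, :2] = False
        ds = PhaseDataset(lay, phases, mask)
        assert ds.n_observed == mask.sum()
        assert np.isnan(ds.phases[0, 0, 0, 0])
        assert ds.cell_phases(0, 0, 0).size == 1

    def test_subsets_preserve_order(self):
        params = recovery_params(ExperimentLayout(4, 2, 2, 6), [0.4, 0.2], 0)
        data = simulate_dataset(params, ExperimentLayout(4, 2, 2, 6), 1)
        sub = data.subset_participants(2)
        np.testing.assert_array_equal(sub.phases, data.phases[:2])
        subt = data.subset_trials(3)
        np.testing.assert_array_equal(subt.phases, data.phases[..., :3])
        # a full-size subset is the unmodified dataset
        full = data.subset_participants(4)
        np.testing.assert_array_equal(full.phases, data.phases)
        np.testing.assert_array_equal(full.mask, data.mask)


class TestMuFromXy:
    @pytest.mark.parametrize("x, y, expected", [
        (1.0, 0.0, 0.0),
        (0.0, -1.0, -np.pi / 2),
        (0.0, 1.0, np.pi / 2),
        (-1.0, 0.0, -np.pi),  # atan2 gives +pi; wrapped to -pi
    ])
    def test_known_angles(self, x, y, expected):
        assert mu_from_xy(x, y) == pytest.approx(expected)

    def test_branch_cut_continuity(self):
        above = mu_from_xy(-1.0, 1e-12)
        below = mu_from_xy(-1.0, -1e-12)
        assert above == pytest.approx(np.pi, abs=1e-11)
        assert below == pytest.approx(-np.pi, abs=1e-11)
        assert -np.pi <= above < np.pi or above == pytest.approx(np.pi)

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            mu_from_xy(0.0, 0.0)


class TestBundtPrior:
    def test_rotational_symmetry_exact(self):
        cfg = PriorConfig()
        for x, y in [(1.2, 0.3), (0.5, -0.8), (-1.0, 0.1)]:
            assert bundt_logprior(x, y, cfg) == bundt_logprior(-y, x, cfg)

    def test_angle_uniform_under_prior_draws(self):
        cfg = PriorConfig()
        lay = ExperimentLayout(10, 2, 10, 1)
        params = draw_params_from_prior(cfg, lay, seed=4)
        ang = (np.arctan2(params.mu_xy[..., 1], params.mu_xy[..., 0])
               .ravel())
        stat = sps.kstest((ang + np.pi) / (2 * np.pi), "uniform")
        assert stat.pvalue > 0.01

    def test_radius_concentrates_near_one(self):
        cfg = PriorConfig()  # shape = rate = 100: mean 1, sd 0.1
        lay = ExperimentLayout(20, 2, 25, 1)
        params = draw_params_from_prior(cfg, lay, seed=5)
        rho = np.hypot(params.mu_xy[..., 0], params.mu_xy[..., 1]).ravel()
        assert rho.mean() == pytest.approx(1.0, abs=0.02)
        assert rho.std() == pytest.approx(0.1, abs=0.02)

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            bundt_logprior(0.0, 0.0, PriorConfig())


class TestLinearPredictor:
    def test_zero_parameters_give_half_variance(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.5, 0.5], 0, sigma=1e-12)
        params.alpha[:] = 0.0
        params.beta[:] = 0.0
        params.delta[:] = 0.0
        assert linear_predictor(params, 0, 0, 0) == pytest.approx(0.0)
        # S = logistic(0) = 0.5 hence R = 0.5
        assert params.condition_R()[0] == pytest.approx(0.5)

    def test_negative_two_gives_strong_coherence(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.5, 0.5], 0)
        params.alpha[:] = -2.0
        params.beta[:] = 0.0
        params.delta[:] = 0.0
        ups = linear_predictor(params, 1, 0, 1)
        assert ups == pytest.approx(-2.0)
        assert params.condition_R()[0] == pytest.approx(0.8808, abs=1e-4)

    def test_additivity_in_beta(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 1)
        before = linear_predictor(params, 0, 1, 1)
        params.beta[0, 1] += 0.37
        assert linear_predictor(params, 0, 1, 1) == pytest.approx(
            before + 0.37)

    def test_out_of_range_indices(self):
        params = recovery_params(tiny_layout(), [0.4, 0.2], 1)
        with pytest.raises(IndexError):
            linear_predictor(params, 5, 0, 0)


class TestLikelihood:
    def test_decomposes_into_per_trial_densities(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 2)
        data = simulate_dataset(params, lay, 3)
        mu = params.mu()
        gamma = params.gamma()
        total = 0.0
        for p in range(2):
            for c in range(2):
                for e in range(2):
                    for th in data.cell_phases(p, c, e):
                        total += wrapped_cauchy_logpdf(
                            th, mu=mu[p, c, e], gamma=gamma[p, c, e])
        assert log_likelihood(params, data) == pytest.approx(total, abs=1e-10)

    def test_duplicating_trials_doubles_loglik(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 2)
        data = simulate_dataset(params, lay, 3)
        doubled_lay = ExperimentLayout(2, 2, 2, 6)
        doubled = PhaseDataset(
            doubled_lay, np.concatenate([data.phases, data.phases], axis=-1))
        assert log_likelihood(params, doubled) == pytest.approx(
            2 * log_likelihood(params, data), rel=1e-12)

    def test_uniform_limit_single_phase(self):
        lay = ExperimentLayout(1, 1, 1, 1)
        params = recovery_params(lay, [0.5], 0, sigma=1e-12)
        params.alpha[:] = 20.0   # gamma = softplus(20) ~ 20: near uniform
        params.beta[:] = 0.0
        params.delta[:] = 0.0
        data = PhaseDataset(lay, np.full(lay.shape, 0.7))
        assert log_likelihood(params, data) == pytest.approx(
            -np.log(2 * np.pi), abs=1e-6)

    def test_missing_cells_contribute_nothing(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 2)
        data = simulate_dataset(params, lay, 3)
        mask = data.mask.copy()
        mask[0, 0, 0, :] = False
        masked = PhaseDataset(lay, data.phases, mask)
        manual = log_likelihood(params, data) - sum(
            wrapped_cauchy_logpdf(th, mu=params.mu()[0, 0, 0],
                                  gamma=params.gamma()[0, 0, 0])
            for th in data.cell_phases(0, 0, 0))
        assert log_likelihood(params, masked) == pytest.approx(manual,
                                                               abs=1e-10)


class TestLogPrior:
    def test_single_condition_reduces_to_univariate_t(self):
        lay = ExperimentLayout(3, 1, 2, 2)
        params = recovery_params(lay, [0.5], 3)
        lp = log_prior(params, PriorConfig())
        # replace the multivariate-t term with the scipy univariate t
        delta_term = float(np.sum(sps.t.logpdf(
            params.beta[:, 0], df=params.nu, scale=params.sigma_beta[0])))
        params2 = recovery_params(lay, [0.5], 3)
        params2.beta[:] = 0.0
        lp0 = log_prior(params2, PriorConfig())
        zero_term = float(np.sum(sps.t.logpdf(
            0.0, df=params.nu, scale=params.sigma_beta[0])) * 3)
        assert lp - delta_term == pytest.approx(lp0 - zero_term, abs=1e-8)

    def test_rotation_invariance_of_mean_phase_prior(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 4)
        lp = log_prior(params, PriorConfig())
        # rotate every planar pair by 37 degrees
        a = np.deg2rad(37)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        params.mu_xy = params.mu_xy @ rot.T
        assert log_prior(params, PriorConfig()) == pytest.approx(lp,
                                                                 rel=1e-12)

    def test_uniform_beta_prior_leaves_pure_jacobian(self):
        # with Beta(1, 1) the alpha term is exactly log S + log(1 - S)
        lay = tiny_layout()
        cfg = PriorConfig(S_prior_a=1.0, S_prior_b=1.0)
        params = recovery_params(lay, [0.4, 0.2], 4)
        base = log_prior(params, cfg)
        params2 = recovery_params(lay, [0.4, 0.2], 4)
        params2.alpha = params.alpha + np.array([0.5, -0.3])
        shifted = log_prior(params2, cfg)

        def jac(alpha):
            S = 1 / (1 + np.exp(-alpha))
            return np.sum(np.log(S) + np.log(1 - S))
        assert shifted - base == pytest.approx(
            jac(params2.alpha) - jac(params.alpha), abs=1e-10)

    def test_exchangeable_under_participant_permutation(self):
        lay = ExperimentLayout(4, 2, 2, 3)
        params = recovery_params(lay, [0.4, 0.2], 5)
        data = simulate_dataset(params, lay, 6)
        cfg = PriorConfig()
        joint = log_prior(params, cfg) + log_likelihood(params, data)
        perm = np.array([2, 0, 3, 1])
        params.beta = params.beta[perm]
        params.mu_xy = params.mu_xy[perm]
        permuted = PhaseDataset(lay, data.phases[perm], data.mask[perm])
        assert log_prior(params, cfg) + log_likelihood(params, permuted) \
            == pytest.approx(joint, rel=1e-12)

    def test_invalid_correlation_rejected(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 5)
        with pytest.raises(ValueError):
            ModelParams(alpha=params.alpha, beta=params.beta,
                        delta=params.delta, mu_xy=params.mu_xy,
                        sigma_beta=params.sigma_beta,
                        corr_beta=np.array([[1.0, 1.2], [1.2, 1.0]]),
                        sigma_delta=params.sigma_delta)


class TestSimulation:
    def test_degenerate_cells_are_point_masses(self):
        lay = ExperimentLayout(1, 1, 1, 20)
        params = recovery_params(lay, [0.5], 0, sigma=1e-12)
        params.alpha[:] = -800.0   # softplus underflows to 0
        params.beta[:] = 0.0
        params.delta[:] = 0.0
        data = simulate_dataset(params, lay, 1, degenerate=True)
        phases = data.cell_phases(0, 0, 0)
        assert np.all(phases == phases[0])

    def test_cell_coherence_matches_target(self):
        lay = ExperimentLayout(1, 1, 1, 10_000)
        params = recovery_params(lay, [0.3], 0, sigma=1e-12)
        params.beta[:] = 0.0
        params.delta[:] = 0.0
        data = simulate_dataset(params, lay, 2)
        r = abs(np.exp(1j * data.cell_phases(0, 0, 0)).mean())
        assert r == pytest.approx(0.3, abs=0.03)

    def test_zero_electrode_effects_leave_only_trial_noise(self):
        # with delta = 0, across-electrode spread of cell ITPC shrinks as K
        # grows (mirrors the ground-truth electrode-effect simulation)
        spreads = []
        for K in (20, 2000):
            lay = ExperimentLayout(1, 1, 16, K)
            params = recovery_params(lay, [0.4], 1, sigma=1e-12)
            params.beta[:] = 0.0
            params.delta[:] = 0.0
            data = simulate_dataset(params, lay, 3)
            r = np.abs(np.where(data.mask, np.exp(1j * data.phases), 0)
                       .mean(axis=-1))[0, 0]
            spreads.append(r.std())
        assert spreads[1] < spreads[0] / 3

    def test_seed_reproducibility(self):
        lay = tiny_layout()
        params = recovery_params(lay, [0.4, 0.2], 2)
        d1 = simulate_dataset(params, lay, 9)
        d2 = simulate_dataset(params, lay, 9)
        np.testing.assert_array_equal(d1.phases, d2.phases)


class TestPriorDraws:
    def test_baseline_variance_follows_beta_prior(self):
        cfg = PriorConfig(S_prior_a=5.0, S_prior_b=2.0)
        lay = ExperimentLayout(2, 2, 2, 2)
        S = []
        for child in np.random.SeedSequence(0).spawn(2000):
            p = draw_params_from_prior(cfg, lay, child)
            S.extend(1 / (1 + np.exp(-p.alpha)))
        S = np.asarray(S)
        assert S.mean() == pytest.approx(5 / 7, abs=0.01)
        assert S.var() == pytest.approx(5 * 2 / (49 * 8), abs=0.005)

    def test_reproducible(self):
        cfg = PriorConfig()
        lay = tiny_layout()
        p1 = draw_params_from_prior(cfg, lay, 7)
        p2 = draw_params_from_prior(cfg, lay, 7)
        np.testing.assert_array_equal(p1.beta, p2.beta)
        np.testing.assert_array_equal(p1.mu_xy, p2.mu_xy)

    def test_prior_predictive_coherence_is_weak(self):
        # prior belief: circular variance likely above 1/2, so cell-level
        # mean resultant lengths concentrate below 0.5
        cfg = PriorConfig()
        R_cell = []
        lay = ExperimentLayout(4, 2, 4, 2)
        for child in np.random.SeedSequence(1).spawn(300):
            p = draw_params_from_prior(cfg, lay, child)
            R_cell.extend(np.exp(-p.gamma()).ravel())
        assert np.mean(np.asarray(R_cell) < 0.5) > 0.6
        assert np.median(R_cell) < 0.4


class TestUnconstrainedDensity:
    @pytest.mark.parametrize("C, estimate_nu", [(1, False), (2, False),
                                                (3, True)])
    def test_kernel_matches_reference(self, C, estimate_nu):
        lay = ExperimentLayout(3, C, 2, 4)
        cfg = PriorConfig(nu="estimate") if estimate_nu else PriorConfig()
        params = draw_params_from_prior(cfg, lay, 1)
        data = simulate_dataset(params, lay, 2)
        m = UnconstrainedModel(lay, cfg, data)
        rng = np.random.default_rng(0)
        for _ in range(5):
            q = m.initial_point(rng, jitter=0.5)
            lp1, g1 = m.logp_grad(q)
            lp2, g2 = m.logp_grad_reference(q)
            assert lp1 == pytest.approx(lp2, rel=1e-10)
            np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-8)

    @pytest.mark.parametrize("C, estimate_nu", [(2, False), (3, True)])
    def test_gradient_matches_finite_differences(self, C, estimate_nu):
        lay = ExperimentLayout(3, C, 2, 4)
        cfg = PriorConfig(nu="estimate") if estimate_nu else PriorConfig()
        params = draw_params_from_prior(cfg, lay, 1)
        data = simulate_dataset(params, lay, 2)
        m = UnconstrainedModel(lay, cfg, data)
        rng = np.random.default_rng(3)
        q = m.initial_point(rng, jitter=0.3)
        _, g = m.logp_grad(q)
        eps = 1e-6
        for i in range(0, m.dim, 3):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            fd = (m.logp_grad(qp)[0] - m.logp_grad(qm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=5e-4, abs=1e-5)

    def test_prior_sampling_space_consistency(self):
        # transforming an unconstrained point and evaluating the centred
        # log-prior must differ from the sampling-space density only by
        # parameterisation (Jacobian) terms; both must be finite and move
        # together under a likelihood-free shift of alpha
        lay = tiny_layout()
        cfg = PriorConfig()
        m = UnconstrainedModel(lay, cfg, None, use_likelihood=False)
        rng = np.random.default_rng(1)
        q = m.initial_point(rng, jitter=0.2)
        lp, _ = m.logp_grad(q)
        assert np.isfinite(lp)
        assert np.isfinite(log_prior(m.to_params(q), cfg))
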