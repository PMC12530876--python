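"""Error measures, objective, finite-difference gradients and the descent loop."""

import numpy as np
import pytest

import smaopt as sm
from smaopt.errors import ContractError
from smaopt.optimizer import (
    OptimizationTargets,
    OptimizerConfig,
    err_dens,
    err_rce,
    gradient,
    objective,
    optimize,
    verify,
)
from smaopt.oracle import oracle_predictor


class TestErrorMeasures:
    def test_err_dens_reference_values(self):
        # documented benchmark pair: 707.0 -> +1.0 %, 693.2 -> ~-1.0 %
        assert err_dens(707.0, 700.0) == pytest.approx(1.0, rel=1e-12)
        assert round(err_dens(693.2, 700.0), 1) == -1.0

    def test_err_dens_signed(self):
        assert err_dens(650.0, 700.0) < 0 < err_dens(750.0, 700.0)

    def test_err_dens_nonpositive_target_rejected(self):
        with pytest.raises(ContractError):
            err_dens(700.0, 0.0)

    def test_err_rce_hand_example(self):
        # |9-10|/10 = 10 %, |22-20|/20 = 10 % -> mean 10 %
        assert err_rce([9.0, 22.0], [10.0, 20.0]) == pytest.approx(10.0, rel=1e-12)

    def test_err_rce_excludes_zero_targets(self):
        # the reference conformer entry (target 0) must not contribute
        assert err_rce([5.0, 9.0], [0.0, 10.0]) == pytest.approx(10.0, rel=1e-12)

    def test_err_rce_all_zero_targets_rejected(self):
        with pytest.raises(ContractError):
            err_rce([1.0, 2.0], [0.0, 0.0])

    def test_err_rce_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            err_rce([1.0], [1.0, 2.0])


class TestObjective:
    def test_density_only_identity(self):
        targets = OptimizationTargets(target_density=700.0)
        rep = objective(sm.LJParamSet(0.2, 0.15, 0.5, 0.05), targets,
                        lambda p: 714.0, weights=(1.0, 0.0))
        assert rep.err_dens == pytest.approx(2.0)
        assert rep.err_rce == 0.0
        assert rep.loss == pytest.approx(0.02 ** 2)

    def test_combined_weights(self, small_conformers):
        targets = OptimizationTargets(700.0, small_conformers)
        p = sm.LJParamSet(0.30, 0.24, 0.60, 0.10)
        rep = objective(p, targets, lambda q: 707.0, weights=(2.0, 0.5))
        expected = 2.0 * (rep.err_dens / 100) ** 2 + 0.5 * (rep.err_rce / 100) ** 2
        assert rep.loss == pytest.approx(expected, rel=1e-12)

    def test_rce_weight_without_conformers_rejected(self):
        with pytest.raises(ContractError):
            objective(sm.LJParamSet(0.2, 0.15, 0.5, 0.05),
                      OptimizationTargets(700.0), lambda p: 700.0, weights=(1.0, 1.0))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ContractError):
            objective(sm.LJParamSet(0.2, 0.15, 0.5, 0.05),
                      OptimizationTargets(700.0), lambda p: 700.0, weights=(0.0, 0.0))

    def test_zero_loss_at_exact_targets(self, small_conformers):
        targets = OptimizationTargets(700.0, small_conformers)
        from smaopt.conformers import DEFAULT_TRUE_PARAMS
        rep = objective(DEFAULT_TRUE_PARAMS, targets, lambda p: 700.0)
        assert rep.loss == pytest.approx(0.0, abs=1e-20)


class TestGradient:
    def test_exact_for_linear_function(self, space):
        coeffs = np.array([3.0, -1.5, 0.25, 10.0])
        f = lambda p: float(p.as_array() @ coeffs)
        g = gradient(f, sm.LJParamSet(0.2, 0.2, 0.5, 0.08), space)
        np.testing.assert_allclose(g, coeffs, rtol=1e-9)

    def test_zero_for_constant(self, space):
        g = gradient(lambda p: 7.0, sm.LJParamSet(0.2, 0.2, 0.5, 0.08), space)
        np.testing.assert_array_equal(g, np.zeros(4))

    def test_central_difference_second_order(self, space):
        """Halving h shrinks the error on a smooth cubic by about 4x."""
        f = lambda p: float(np.sum(p.as_array() ** 3))
        p = sm.LJParamSet(0.2, 0.2, 0.5, 0.08)
        exact = 3.0 * p.as_array() ** 2
        e1 = np.abs(gradient(f, p, space, h_rel=0.02) - exact).max()
        e2 = np.abs(gradient(f, p, space, h_rel=0.01) - exact).max()
        assert e2 < e1 / 3.0

    def test_one_sided_at_bound(self, space):
        p = sm.LJParamSet.from_array(space.lower_array())
        g = gradient(lambda q: float(q.as_array().sum()), p, space)
        np.testing.assert_allclose(g, np.ones(4), rtol=1e-8)

    def test_invalid_step_rejected(self, space):
        with pytest.raises(ContractError):
            gradient(lambda p: 0.0, sm.LJParamSet(0.2, 0.2, 0.5, 0.08), space, h_rel=0.0)


class TestOptimize:
    def _quadratic_density(self, space, optimum_norm):
        """Density function whose err_dens vanishes exactly at optimum_norm."""
        def fn(p):
            x = space.normalize(p.as_array())
            return 700.0 * (1.0 + float(np.sum((x - optimum_norm) ** 2)))
        return fn

    def test_zero_loss_start_terminates_immediately(self, space):
        opt = np.array([0.5, 0.5, 0.5, 0.5])
        fn = self._quadratic_density(space, opt)
        p0 = sm.LJParamSet.from_array(space.denormalize(opt))
        traj = optimize(p0, OptimizationTargets(700.0), fn, space,
                        OptimizerConfig(weights=(1.0, 0.0)))
        assert traj.termination == "already optimal"
        assert len(traj.points) == 1 and traj.final.iteration == 0

    def test_loss_non_increasing_and_converges(self, space):
        opt = np.array([0.4, 0.6, 0.5, 0.45])
        fn = self._quadratic_density(space, opt)
        p0 = sm.LJParamSet.from_array(space.denormalize([0.8, 0.2, 0.7, 0.6]))
        traj = optimize(p0, OptimizationTargets(700.0), fn, space,
                        OptimizerConfig(weights=(1.0, 0.0), max_iter=50))
        losses = [pt.report.loss for pt in traj.points]
        assert all(b <= a for a, b in zip(losses, losses[1:]))
        assert losses[-1] < losses[0] / 100.0
        # "no decreasing step" is a legitimate floor once loss reaches
        # machine precision
        assert traj.termination in ("converged", "max iterations", "no decreasing step")
        # accounting: every iteration logs its evaluation budget
        assert traj.total_evals >= len(traj.points)

    def test_start_outside_space_rejected(self, space):
        p0 = sm.LJParamSet.from_array(space.upper_array() * 2)
        with pytest.raises(ContractError):
            optimize(p0, OptimizationTargets(700.0), lambda p: 700.0, space)

    def test_iterates_stay_inside_box(self, space):
        opt = np.array([0.02, 0.98, 0.5, 0.5])  # pulls toward the boundary
        fn = self._quadratic_density(space, opt)
        p0 = sm.LJParamSet.from_array(space.denormalize([0.9, 0.1, 0.5, 0.5]))
        traj = optimize(p0, OptimizationTargets(700.0), fn, space,
                        OptimizerConfig(weights=(1.0, 0.0), max_iter=30))
        for pt in traj.points:
            assert sm.contains(space, pt.params)

    def test_reaches_target_on_smooth_landscape(self, space, smooth_cfg):
        """Direct noiseless descent on the smooth oracle lands within 0.5 %
        of the target density inside the default iteration budget."""
        fn = oracle_predictor(smooth_cfg)
        p0 = sm.LJParamSet.from_array(space.denormalize([0.3, 0.3, 0.5, 0.5]))
        traj = optimize(p0, OptimizationTargets(700.0), fn, space,
                        OptimizerConfig(weights=(1.0, 0.0)))
        assert abs(traj.final.report.err_dens) <= 0.5


class TestVerify:
    def test_noiseless_replicates_have_zero_sd(self, space, smooth_cfg):
        p = sm.LJParamSet(0.2, 0.15, 0.5, 0.05)
        rep = verify(p, OptimizationTargets(700.0), smooth_cfg, n_rep=4)
        assert rep.rho_sim_sd == 0.0
        assert rep.err_dens == pytest.approx(
            err_dens(rep.rho_sim_mean, 700.0), rel=1e-12)

    def test_single_replicate(self, smooth_cfg):
        p = sm.LJParamSet(0.2, 0.15, 0.5, 0.05)
        rep = verify(p, OptimizationTargets(700.0), smooth_cfg, n_rep=1)
        assert rep.rho_sim_sd == 0.0

    def test_noise_produces_spread(self):
        cfg = sm.OracleConfig(master_seed=2)
        p = sm.LJParamSet(0.2, 0.15, 0.5, 0.05)
        rep = verify(p, OptimizationTargets(700.0), cfg, n_rep=10)
        assert 0.0 < rep.rho_sim_sd < 20.0

    def test_rce_error_zero_at_true_params(self, small_conformers, smooth_cfg):
        from smaopt.conformers import DEFAULT_TRUE_PARAMS
        rep = verify(DEFAULT_TRUE_PARAMS, OptimizationTargets(700.0, small_conformers),
                     smooth_cfg, n_rep=2)
        assert rep.err_rce == pytest.approx(0.0, abs=1e-10)

    def test_invalid_n_rep_rejected(self, smooth_cfg):
        with pytest.raises(ContractError):
            verify(sm.LJParamSet(0.2, 0.15, 0.5, 0.05),
                   OptimizationTargets(700.0), smooth_cfg, n_rep=0)
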