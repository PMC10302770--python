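"""SE objective, SD-error metric and the two-stage estimators."""

import numpy as np
import pytest

import viafit as vf
from viafit.estimation import OptimizerConfig, ViabilitySeries
from viafit.model import ModelParams


@pytest.fixture(scope="module")
def tiny_domain(blob_img):
    return vf.image_to_alpha0(blob_img, nx=10, ny=10)


@pytest.fixture(scope="module")
def noiseless_data(tiny_domain, treatment_truth, sim_config):
    alpha0, grid = tiny_domain
    sc = vf.SynthConfig(seed=3, noise_sigma=0.0)
    fit, _ = vf.generate_rtca(treatment_truth, alpha0, grid, sim_config, sc)
    snaps = vf.generate_flow(treatment_truth, alpha0, grid, sim_config, sc,
                             jitter=False)
    return fit, vf.flow_to_series(snaps)


class TestViabilitySeries:
    def test_rejects_unsorted_or_out_of_window_times(self):
        with pytest.raises(ValueError):
            ViabilitySeries(times=[24.0, 24.0], values=[1, 1])
        with pytest.raises(ValueError):
            ViabilitySeries(times=[24.0, 80.0], values=[1, 1])
        with pytest.raises(ValueError):
            ViabilitySeries(times=[24.0], values=[-1.0])


class TestSEObjective:
    def test_zero_residual_when_data_equals_simulation(self, tiny_domain):
        alpha0, grid = tiny_domain
        a1 = np.where(alpha0 > 0, 1.0, 0.0)
        data = ViabilitySeries(times=[24.0, 72.0], values=[100.0, 100.0])
        assert vf.se_objective(ModelParams(), data, a1, grid) == 0.0

    def test_hand_summed_residual(self, tiny_domain):
        # simulation sits at 100% everywhere; data reads 100 and 90
        alpha0, grid = tiny_domain
        a1 = np.where(alpha0 > 0, 1.0, 0.0)
        data = ViabilitySeries(times=[24.0, 72.0], values=[100.0, 90.0])
        assert vf.se_objective(ModelParams(), data, a1, grid) == \
            pytest.approx(100.0)  # 0^2 + 10^2

    def test_duplicated_series_doubles_the_contribution(self, tiny_domain):
        alpha0, grid = tiny_domain
        a1 = np.where(alpha0 > 0, 1.0, 0.0)
        s = ViabilitySeries(times=[24.0, 72.0], values=[95.0, 90.0])
        f = ViabilitySeries(times=[24.0, 72.0], values=[95.0, 90.0],
                            modality="flow")
        one = vf.se_objective(ModelParams(), s, a1, grid)
        two = vf.se_objective(ModelParams(), [s, f], a1, grid)
        assert two == pytest.approx(2 * one)

    def test_invariant_under_splitting_a_series(self, tiny_domain,
                                                treatment_truth):
        alpha0, grid = tiny_domain
        whole = ViabilitySeries(times=[24.0, 48.0, 72.0],
                                values=[90.0, 80.0, 70.0])
        parts = [ViabilitySeries(times=[24.0], values=[90.0]),
                 ViabilitySeries(times=[48.0, 72.0], values=[80.0, 70.0])]
        a = vf.se_objective(treatment_truth, whole, alpha0, grid)
        b = vf.se_objective(treatment_truth, parts, alpha0, grid)
        assert a == pytest.approx(b, rel=1e-12)

    def test_off_grid_time_is_an_error_not_interpolation(self, tiny_domain):
        alpha0, grid = tiny_domain
        data = ViabilitySeries(times=[24.5], values=[90.0])
        with pytest.raises(ValueError, match="time grid"):
            vf.se_objective(ModelParams(), data, alpha0, grid)


class TestSDError:
    def mk(self, values, times=(24.0, 48.0)):
        return ViabilitySeries(times=np.array(times), values=np.array(values))

    def test_identical_series_gives_zero(self):
        assert vf.sd_error(self.mk([90.0, 80.0]), self.mk([90.0, 80.0])) == 0.0

    def test_constant_offset_example(self):
        # residuals all +0.1 NCI on a mean of 2.0 NCI -> 5%
        sim = self.mk([190.0, 190.0])
        exp = self.mk([200.0, 200.0])
        assert vf.sd_error(sim, exp) == pytest.approx(5.0)

    def test_scale_invariance(self):
        sim, exp = self.mk([90.0, 70.0]), self.mk([95.0, 75.0])
        a = vf.sd_error(sim, exp)
        b = vf.sd_error(self.mk([180.0, 140.0]), self.mk([190.0, 150.0]))
        assert a == pytest.approx(b)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="time grid"):
            vf.sd_error(self.mk([90.0, 80.0]),
                        self.mk([90.0, 80.0], times=(24.0, 72.0)))


class TestEstimation:
    def test_start_at_truth_converges_immediately(self, tiny_domain,
                                                  treatment_truth,
                                                  noiseless_data, sim_config):
        alpha0, grid = tiny_domain
        fit, flow = noiseless_data
        opt = OptimizerConfig(n_starts=1, seed=0,
                              x0=(treatment_truth.s1, treatment_truth.s2,
                                  treatment_truth.s3, treatment_truth.s4))
        res = vf.estimate_treatment([fit, flow], alpha0, grid, sim_config,
                                    frozen_q=(0.0, 0.0), opt=opt)
        assert res.se <= 1e-10

    def test_noiseless_round_trip_recovers_the_curve(self, tiny_domain,
                                                     treatment_truth,
                                                     noiseless_data,
                                                     sim_config):
        alpha0, grid = tiny_domain
        fit, flow = noiseless_data
        opt = OptimizerConfig(n_starts=6, seed=1)
        res = vf.estimate_treatment([fit, flow], alpha0, grid, sim_config,
                                    frozen_q=(0.0, 0.0),
                                    control=treatment_truth, opt=opt)
        assert res.se <= 1e-6
        truth_traj = vf.simulate(alpha0, grid, treatment_truth, sim_config)
        fit_traj = vf.simulate(alpha0, grid, res.params, sim_config)
        for t in fit.times:
            assert abs(fit_traj.viability_at(t)
                       - truth_traj.viability_at(t)) < 0.1
        # SE over 5 RTCA + 2 flow points
        assert len(fit) + 2 == 7

    def test_frozen_parameters_returned_bit_identical(self, tiny_domain,
                                                      noiseless_data,
                                                      sim_config):
        alpha0, grid = tiny_domain
        fit, _ = noiseless_data
        q = (5.3200000000000003, 4.9700000000000006)
        opt = OptimizerConfig(n_starts=2, seed=0, stage2_maxfev=200)
        res = vf.estimate_treatment(fit, alpha0, grid, sim_config,
                                    frozen_q=q, opt=opt)
        assert res.params.Q == q[0] and res.params.Q1 == q[1]
        assert res.frozen == ("Q", "Q1")

    def test_same_seed_gives_identical_results(self, tiny_domain,
                                               noiseless_data, sim_config):
        alpha0, grid = tiny_domain
        fit, _ = noiseless_data
        opt = OptimizerConfig(n_starts=2, seed=7, stage2_maxfev=300)
        r1 = vf.estimate_treatment(fit, alpha0, grid, sim_config,
                                   frozen_q=(0.0, 0.0), opt=opt)
        r2 = vf.estimate_treatment(fit, alpha0, grid, sim_config,
                                   frozen_q=(0.0, 0.0), opt=opt)
        assert r1.to_dict() == r2.to_dict()

    def test_parameters_respect_bounds(self, tiny_domain, noiseless_data,
                                       sim_config):
        alpha0, grid = tiny_domain
        fit, _ = noiseless_data
        opt = OptimizerConfig(n_starts=3, seed=2, stage2_maxfev=300)
        res = vf.estimate_treatment(fit, alpha0, grid, sim_config,
                                    frozen_q=(0.0, 0.0), opt=opt)
        for n in ("s1", "s2", "s3", "s4"):
            assert 0.0 <= getattr(res.params, n) <= 50.0

    def test_null_treatment_fits_control_data(self, tiny_domain, sim_config):
        alpha0, grid = tiny_domain
        control = ModelParams(s1=1.0, s2=0.1, s3=0.1, s4=1.0)
        sc = vf.SynthConfig(seed=5, noise_sigma=0.0)
        fit, _ = vf.generate_rtca(control, alpha0, grid, sim_config, sc)
        opt = OptimizerConfig(n_starts=4, seed=3)
        res = vf.estimate_treatment(fit, alpha0, grid, sim_config,
                                    frozen_q=(0.0, 0.0), control=control,
                                    opt=opt)
        assert res.se <= 1e-6
        assert set(res.rel_change_pct) == {"s1", "s2", "s3", "s4"}

    def test_objective_landscape_prefers_truth(self, tiny_domain,
                                               treatment_truth,
                                               noiseless_data, sim_config):
        alpha0, grid = tiny_domain
        fit, flow = noiseless_data
        se_truth = vf.se_objective(treatment_truth, [fit, flow], alpha0, grid,
                                   sim_config)
        perturbed = treatment_truth.replace(s2=treatment_truth.s2 * 1.5)
        se_pert = vf.se_objective(perturbed, [fit, flow], alpha0, grid,
                                  sim_config)
        assert se_truth <= se_pert
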