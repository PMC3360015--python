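"""Lesion geometry, the cost function, the learning rule, and the trial loop."""

import numpy as np
import pandas as pd
import pytest

from pdrehab import (
    Condition,
    ConfigurationError,
    LearningConfig,
    LesionSpec,
    NoiseModel,
    Population,
    Protocol,
    angular_error,
    apply_lesion,
    cost_gradient,
    fd_cost_gradient,
    learning_step,
    make_quenched_rotations,
    mean_activity,
    population_vector,
    run_rehabilitation,
    trial_cost,
    unimanual,
    wrap_signed_deg,
)


def brute_force_wedge(base_pd, center, fraction):
    out = []
    for pd_i in base_pd:
        d = (pd_i - center) % 360.0
        if d > 180.0:
            d -= 360.0
        out.append(abs(d) <= fraction * 180.0 or d == -180.0 and fraction == 1.0)
    return np.array(out)


class TestLesion:
    def test_zero_fraction_changes_nothing(self, uniform500):
        out = apply_lesion(uniform500, LesionSpec(90.0, 0.0))
        # only neurons exactly at the center die (|wrap| <= 0)
        assert out.n_alive >= uniform500.n - 1

    def test_full_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            LesionSpec(90.0, 1.0)

    def test_wedge_matches_brute_force_on_grid(self):
        pop = Population.uniform(360)
        out = apply_lesion(pop, LesionSpec(90.0, 0.25))
        expected = ~brute_force_wedge(pop.base_pd, 90.0, 0.25)
        np.testing.assert_array_equal(out.alive, expected)

    def test_wedge_matches_brute_force_on_random_specs(self, rng):
        pop = Population(base_pd=rng.uniform(0, 360, 200))
        for _ in range(100):
            center = rng.uniform(0, 360)
            fraction = rng.uniform(0, 0.99)
            out = apply_lesion(pop, LesionSpec(center, fraction))
            expected = ~brute_force_wedge(pop.base_pd, center, fraction)
            np.testing.assert_array_equal(out.alive, expected)

    def test_other_fields_untouched_and_original_returned_intact(self, uniform500, lesion):
        out = apply_lesion(uniform500, lesion)
        assert uniform500.alive.all()  # input not mutated
        np.testing.assert_array_equal(out.base_pd, uniform500.base_pd)
        np.testing.assert_array_equal(out.depth, uniform500.depth)

    def test_lesion_slows_reaching_toward_its_center(self, lesioned500, uni):
        """The noiseless PV norm collapses at the lesion center, not opposite it."""
        a90 = mean_activity(lesioned500, uni, 90.0)
        a270 = mean_activity(lesioned500, uni, 270.0)
        assert (
            population_vector(lesioned500, a90, uni).norm
            < population_vector(lesioned500, a270, uni).norm
        )


class TestAngularError:
    @pytest.mark.parametrize(
        "pv, target, expected",
        [(45.0, 45.0, 0.0), (359.0, 1.0, -2.0), (270.0, 90.0, 180.0)],
    )
    def test_signed_wrap_convention(self, pv, target, expected):
        assert angular_error(pv, target) == pytest.approx(expected)

    def test_undefined_pv_counts_as_maximal_error(self):
        assert angular_error(float("nan"), 10.0) == 180.0


class TestTrialCost:
    def test_zero_error_zero_activity_is_free(self):
        assert trial_cost(45.0, 45.0, np.zeros(5), 0.1) == 0.0

    def test_lam_zero_is_pure_squared_error(self):
        assert trial_cost(50.0, 45.0, np.ones(10), 0.0) == pytest.approx(25.0)

    def test_hand_computed_value(self):
        # err 10 deg, activities [1, 0.5], lam 0.1: 100 + 0.1 * 1.25 = 100.125
        assert trial_cost(55.0, 45.0, np.array([1.0, 0.5]), 0.1) == pytest.approx(100.125)

    def test_negative_lam_rejected(self):
        with pytest.raises(ConfigurationError):
            trial_cost(0.0, 0.0, np.zeros(1), -0.5)


class TestLearningStep:
    def test_zero_rates_zero_drift_is_identity(self, rng, uni):
        pop = Population.uniform(30)
        a = mean_activity(pop, uni, 45.0)
        cfg = LearningConfig(eta_sup=0.0, eta_unsup=0.0, drift_sigma=0.0)
        out = learning_step(pop, uni, 45.0, a, cfg, rng)
        np.testing.assert_array_equal(out.base_pd, pop.base_pd)

    @pytest.mark.parametrize("mode", ["encoding_only", "encoding_and_decoding"])
    def test_analytic_gradient_matches_finite_differences(self, mode):
        """Both cost-term gradients agree with central differences on smooth configs."""
        r = np.random.default_rng(0)
        worst = 0.0
        for _ in range(20):
            n = 12
            pop = Population(
                base_pd=r.uniform(0, 360, n),
                rotation_offset=r.normal(0, 20, n),
                depth=r.uniform(0.5, 1.5, n),
            )
            cond = Condition(regime="bimanual_quenched", sigma=20.0)
            target = float(r.uniform(0, 360))
            a = mean_activity(pop, cond, target) + r.uniform(0.01, 0.1, n)
            cfg = LearningConfig(update_targets=mode)
            g_sup, g_unsup = cost_gradient(pop, cond, target, a, cfg)
            f_sup, f_unsup = fd_cost_gradient(pop, cond, target, a, mode)
            for g, f in [(g_sup, f_sup), (g_unsup, f_unsup)]:
                worst = max(worst, np.abs(g - f).max() / max(np.abs(f).max(), 1e-8))
        assert worst < 1e-4

    def test_finite_difference_mode_reproduces_analytic_step(self, rng):
        pop = Population.uniform(10).with_(rotation_offset=make_quenched_rotations(10, 20.0, 1))
        cond = Condition(regime="bimanual_quenched", sigma=20.0)
        a = mean_activity(pop, cond, 100.0) + 0.05
        out_a = learning_step(pop, cond, 100.0, a, LearningConfig(), rng)
        out_f = learning_step(
            pop, cond, 100.0, a, LearningConfig(gradient_mode="finite_difference"), rng
        )
        np.testing.assert_allclose(out_f.base_pd, out_a.base_pd, atol=1e-6)

    def test_single_neuron_descends_with_full_path_gradient(self, rng):
        """A lone neuron can only reduce error by rotating its readout, so the
        full-path (encoding+decoding) gradient must drive its PD to the target."""
        uni = unimanual()
        cfg = LearningConfig(
            eta_sup=0.1, eta_unsup=0.0, lam=0.0, update_targets="encoding_and_decoding"
        )
        cur = Population(base_pd=[80.0])
        costs = []
        for _ in range(100):
            a = mean_activity(cur, uni, 90.0)
            pv = population_vector(cur, a, uni)
            costs.append(trial_cost(pv.angle, 90.0, a, 0.0))
            cur = learning_step(cur, uni, 90.0, a, cfg, rng)
        assert np.all(np.diff(costs) <= 1e-12)
        assert abs(wrap_signed_deg(cur.base_pd[0] - 90.0)) < 0.1

    def test_learning_conserves_dead_neurons_depths_and_offsets(self, rng):
        pop = apply_lesion(
            Population.uniform(50).with_(rotation_offset=make_quenched_rotations(50, 40.0, 2)),
            LesionSpec(),
        )
        cond = Condition(regime="bimanual_quenched", sigma=40.0)
        cfg = LearningConfig(drift_sigma=1.0)
        cur = pop
        for t in (0.0, 45.0, 90.0, 200.0):
            a = mean_activity(cur, cond, t)
            cur = learning_step(cur, cond, t, a, cfg, rng)
        np.testing.assert_array_equal(cur.alive, pop.alive)
        np.testing.assert_array_equal(cur.depth, pop.depth)
        np.testing.assert_array_equal(cur.rotation_offset, pop.rotation_offset)
        dead = ~pop.alive
        np.testing.assert_array_equal(cur.base_pd[dead], pop.base_pd[dead])

    def test_ablations_zero_each_term_exactly(self, rng):
        pop = Population.uniform(20)
        cond = unimanual()
        a = mean_activity(pop, cond, 50.0) + 0.02
        g_sup, g_unsup = cost_gradient(pop, cond, 50.0, a, LearningConfig())
        sup_only = learning_step(
            pop, cond, 50.0, a, LearningConfig(eta_sup=0.3, eta_unsup=0.0), rng
        )
        np.testing.assert_allclose(sup_only.base_pd, (pop.base_pd - 0.3 * g_sup) % 360)
        unsup_only = learning_step(
            pop, cond, 50.0, a, LearningConfig(eta_sup=0.0, eta_unsup=0.3, lam=0.5), rng
        )
        np.testing.assert_allclose(
            unsup_only.base_pd, (pop.base_pd - 0.3 * 0.5 * g_unsup) % 360
        )

    def test_nonfinite_gradient_rejects_step(self, rng, monkeypatch):
        import pdrehab.rehab as rb

        pop = Population.uniform(5)
        monkeypatch.setattr(
            rb, "cost_gradient", lambda *a, **k: (np.full(5, np.inf), np.zeros(5))
        )
        out = rb.learning_step(
            pop, unimanual(), 0.0, np.ones(5), LearningConfig(drift_sigma=1.0), rng
        )
        np.testing.assert_array_equal(out.base_pd, pop.base_pd)


class TestNoiselessDescent:
    def test_cost_nonincreasing_for_fixed_target_small_rates(self, rng):
        """Gradient descent on the noiseless cost never climbs (up to kink slack)."""
        pop = apply_lesion(
            Population.uniform(100).with_(rotation_offset=make_quenched_rotations(100, 30.0, 7)),
            LesionSpec(),
        )
        cond = Condition(regime="bimanual_quenched", sigma=30.0)
        cfg = LearningConfig(eta_sup=1e-3, eta_unsup=1e-3)
        cur, costs = pop, []
        for _ in range(500):
            a = mean_activity(cur, cond, 90.0)
            pv = population_vector(cur, a, cond)
            costs.append(trial_cost(pv.angle, 90.0, a, cfg.lam))
            cur = learning_step(cur, cond, 90.0, a, cfg, rng)
        costs = np.array(costs)
        assert np.all(np.diff(costs) <= 1e-7 * costs[0])
        assert costs[-1] < costs[0]


class TestRunRehabilitation:
    def small_setup(self):
        pop = apply_lesion(
            Population.uniform(100).with_(rotation_offset=make_quenched_rotations(100, 60.0, 3)),
            LesionSpec(),
        )
        cond = Condition(regime="bimanual_quenched", sigma=60.0)
        return pop, cond

    def test_zero_trials_returns_initial_population(self):
        pop, cond = self.small_setup()
        traj = run_rehabilitation(
            pop, cond, Protocol(n_trials=0, snapshot_trials=()), LearningConfig(), NoiseModel(), 0
        )
        assert len(traj.trials) == 0
        np.testing.assert_array_equal(traj.final.base_pd, pop.base_pd)

    def test_identical_seeds_give_bit_identical_trajectories(self):
        pop, cond = self.small_setup()
        kw = dict(protocol=Protocol(n_trials=200, snapshot_trials=(100,)),
                  cfg=LearningConfig(drift_sigma=0.5), noise=NoiseModel(k=0.1))
        t1 = run_rehabilitation(pop, cond, kw["protocol"], kw["cfg"], kw["noise"], 42)
        t2 = run_rehabilitation(pop, cond, kw["protocol"], kw["cfg"], kw["noise"], 42)
        pd.testing.assert_frame_equal(t1.trials, t2.trials)
        np.testing.assert_array_equal(t1.final.base_pd, t2.final.base_pd)
        np.testing.assert_array_equal(
            t1.snapshots[100].base_pd, t2.snapshots[100].base_pd
        )

    def test_record_count_and_snapshot_indexing(self):
        pop, cond = self.small_setup()
        traj = run_rehabilitation(
            pop, cond, Protocol(n_trials=50, snapshot_trials=(10, 50)),
            LearningConfig(), NoiseModel(), 0,
        )
        assert len(traj.trials) == 50
        assert set(traj.snapshots) == {10, 50}
        np.testing.assert_array_equal(traj.snapshots[50].base_pd, traj.final.base_pd)

    def test_unimanual_rehab_reduces_trial_error(self):
        """Late-trial angular error is below early-trial error, averaged over seeds."""
        from pdrehab import run_scenario

        firsts, lasts = [], []
        for seed in range(1, 6):
            tr = run_scenario("unimanual", seed=seed, eval_reps=1).trajectory.trials
            firsts.append(tr.err_deg.abs().head(200).mean())
            lasts.append(tr.err_deg.abs().tail(200).mean())
        assert np.mean(lasts) < np.mean(firsts)

    def test_trajectory_write_outputs(self, tmp_path):
        pop, cond = self.small_setup()
        traj = run_rehabilitation(
            pop, cond, Protocol(n_trials=20, snapshot_trials=(20,)),
            LearningConfig(), NoiseModel(), 0,
        )
        traj.write(tmp_path)
        assert (tmp_path / "trials.csv").exists()
        assert (tmp_path / "population_trial00020.csv").exists()
        assert (tmp_path / "run_meta.json").exists()
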