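"""tICA, k-means discretization, MSM estimation and FEL reweighting."""

import numpy as np
import pandas as pd
import pytest
from _oracles import boltzmann_free_energy_difference, sample_markov_chain_pairs

from camdesign import felmsm, stringpath as sp, toyworld as tw


class _FakeRecord:
    def __init__(self, iteration, n_images=2, n_swarms=3, d=1):
        self.iteration = iteration
        rng = np.random.default_rng(iteration)
        self.swarm_starts = rng.normal(size=(n_images, n_swarms, d))
        self.swarm_ends = self.swarm_starts + 0.1


class TestSelectConverged:
    def test_only_final_iterations_kept(self):
        history = [_FakeRecord(i) for i in range(400)]
        data = felmsm.select_converged(history, last_n=100)
        assert data.iteration_tags.min() == 300
        assert data.iteration_tags.max() == 399

    def test_pair_count_is_lastn_images_swarms(self):
        history = [_FakeRecord(i) for i in range(10)]
        data = felmsm.select_converged(history, last_n=4)
        assert data.n_pairs == 4 * 2 * 3

    def test_full_history_and_validation(self):
        history = [_FakeRecord(i) for i in range(5)]
        assert felmsm.select_converged(history, 5).n_pairs == 5 * 2 * 3
        with pytest.raises(ValueError):
            felmsm.select_converged(history, 0)
        with pytest.raises(ValueError):
            felmsm.select_converged(history, 6)


def _ar1(phi, n, rng):
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


class TestTica:
    def test_first_component_finds_slow_coordinate(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([_ar1(0.99, 20000, rng), _ar1(0.1, 20000, rng)])
        model = felmsm.fit_tica(x, lag=1, n_components=2)
        v = model.components[:, 0]
        assert abs(v[0]) / np.linalg.norm(v) > 0.99
        assert np.all(np.diff(model.eigenvalues) <= 0)

    def test_projected_data_has_zero_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 3)) + 5.0
        model = felmsm.fit_tica(x, lag=2, n_components=2)
        proj = model.transform(np.concatenate([x[:-2], x[2:]]))
        assert np.all(np.abs(proj.mean(axis=0)) < 1e-10)

    def test_singular_covariance_advises_regularization(self):
        x = np.zeros((100, 2))
        x[:, 0] = np.arange(100.0)
        x[:, 1] = 2.0 * x[:, 0]          # perfectly collinear
        with pytest.raises(ValueError, match="regulari"):
            felmsm.fit_tica(x, lag=1, n_components=1)
        felmsm.fit_tica(x, lag=1, n_components=1, regularization=1e-6)


class TestDiscretize:
    def test_single_cluster_center_is_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200, 2))
        disc = felmsm.discretize(pts, k=1, seed=0)
        assert np.allclose(disc.centers[0], pts.mean(axis=0), atol=1e-10)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.concatenate([m + rng.normal(scale=0.5, size=(300, 2))
                              for m in means])
        disc = felmsm.discretize(pts, k=3, seed=1)
        se = 0.5 / np.sqrt(300)
        for m in means:
            d = np.linalg.norm(disc.centers - m, axis=1).min()
            assert d < 3 * se * np.sqrt(2) + 0.1

    def test_fixed_seed_identical_assignments(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(100, 2))
        a = felmsm.discretize(pts, k=5, seed=7).assign(pts)
        b = felmsm.discretize(pts, k=5, seed=7).assign(pts)
        assert np.array_equal(a, b)

    def test_validation(self):
        with pytest.raises(ValueError):
            felmsm.discretize(np.zeros((5, 1)), k=0)
        with pytest.raises(ValueError, match="distinct"):
            felmsm.discretize(np.zeros((5, 1)), k=2)


def _pairs_from_states(si, sj):
    return felmsm.SwarmTransitionData(
        starts=si[:, None] * 2.0 - 1.0, ends=sj[:, None] * 2.0 - 1.0,
        iteration_tags=np.zeros(len(si), dtype=int), lag=1)


TWO_STATE_DISC = felmsm.Discretization(
    centers=np.array([[-1.0], [1.0]]), seed=0)


class TestEstimateMsm:
    def test_stationary_distribution_of_two_state_chain(self):
        t_true = np.array([[0.9, 0.1], [0.2, 0.8]])
        si, sj = sample_markov_chain_pairs(t_true, 100000, seed=0)
        model = felmsm.estimate_msm(_pairs_from_states(si, sj),
                                    TWO_STATE_DISC)
        assert abs(model.stationary_distribution[0] - 2 / 3) < 0.01

    def test_symmetric_counts_give_uniform_pi(self):
        si = np.array([0, 1, 0, 1])
        sj = np.array([1, 0, 0, 1])
        model = felmsm.estimate_msm(_pairs_from_states(si, sj),
                                    TWO_STATE_DISC)
        assert np.all(np.abs(model.stationary_distribution - 0.5) < 1e-10)

    def test_model_invariants(self):
        t_true = np.array([[0.7, 0.3], [0.4, 0.6]])
        si, sj = sample_markov_chain_pairs(t_true, 5000, seed=1)
        model = felmsm.estimate_msm(_pairs_from_states(si, sj),
                                    TWO_STATE_DISC, reversible=True)
        t, pi = model.transition_matrix, model.stationary_distribution
        assert np.all(np.abs(t.sum(axis=1) - 1.0) < 1e-12)
        assert np.max(np.abs(pi @ t - pi)) < 1e-10
        flux = pi[:, None] * t
        assert np.max(np.abs(flux - flux.T)) < 1e-8

    def test_disconnected_blocks_keep_larger_and_report_discarded(self):
        # microstates {0,1} interconvert (many counts); {2} is separate
        disc = felmsm.Discretization(
            centers=np.array([[-1.0], [1.0], [5.0]]), seed=0)
        si = np.array([0, 1] * 20 + [2, 2])
        sj = np.array([1, 0] * 20 + [2, 2])
        data = felmsm.SwarmTransitionData(
            starts=disc.centers[si], ends=disc.centers[sj],
            iteration_tags=np.zeros(len(si), dtype=int), lag=1)
        model = felmsm.estimate_msm(data, disc)
        assert model.n_states == 2
        assert model.discarded_states.tolist() == [2]
        assert model.model_state(np.array([0, 1, 2])).tolist() == [0, 1, -1]

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            felmsm.estimate_msm(
                felmsm.SwarmTransitionData(
                    starts=np.zeros((0, 1)), ends=np.zeros((0, 1)),
                    iteration_tags=np.zeros(0, dtype=int), lag=1),
                TWO_STATE_DISC)


def _manual_model(pi):
    pi = np.asarray(pi, dtype=float)
    t = np.tile(pi, (len(pi), 1))     # trivially stationary chain
    return felmsm.TransitionModel(
        counts=np.ones((len(pi), len(pi))), transition_matrix=t,
        stationary_distribution=pi, reversible=True,
        state_labels=np.arange(len(pi)))


class TestWeightedFel:
    def _surface(self, pi=(0.8, 0.2)):
        model = _manual_model(pi)
        disc = felmsm.Discretization(
            centers=np.array([[0.0, 0.0], [1.0, 0.0]]), seed=0,
            feature_labels=["x", "y"])
        samples = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 0.0]})
        return felmsm.weighted_fel(samples, model, disc, ("x", "y"),
                                   bins=2, kT_proj=1.0,
                                   bin_range=((-0.5, 1.5), (-0.5, 0.5)))

    def test_four_to_one_weight_ratio_gives_ln4(self):
        surf = self._surface(pi=(0.8, 0.2))
        occupied = surf.free_energy[~surf.mask]
        assert occupied.min() == 0.0
        assert abs(occupied.max() - np.log(4.0)) < 1e-12

    def test_uniform_weights_give_flat_surface(self):
        surf = self._surface(pi=(0.5, 0.5))
        occupied = surf.free_energy[~surf.mask]
        assert np.all(occupied == 0.0)

    def test_empty_bins_masked_not_interpolated(self):
        surf = self._surface()
        assert surf.mask.sum() == 2
        assert np.all(np.isnan(surf.free_energy[surf.mask]))

    def test_missing_cv_label_rejected(self):
        model = _manual_model((1.0,))
        disc = felmsm.Discretization(centers=np.array([[0.0]]), seed=0)
        with pytest.raises(KeyError, match="z"):
            felmsm.weighted_fel(pd.DataFrame({"x": [0.0]}), model, disc,
                                ("x", "z"))

    def test_unassigned_samples_raise_unless_dropped(self):
        disc = felmsm.Discretization(
            centers=np.array([[0.0], [1.0], [9.0]]), seed=0,
            feature_labels=["x"])
        model = felmsm.TransitionModel(
            counts=np.ones((2, 2)), transition_matrix=np.full((2, 2), 0.5),
            stationary_distribution=np.array([0.5, 0.5]), reversible=True,
            state_labels=np.array([0, 1]),
            discarded_states=np.array([2]))
        samples = pd.DataFrame({"x": [0.0, 1.0, 9.0], "y": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="discarded"):
            felmsm.weighted_fel(samples, model, disc, ("x", "y"), bins=2)
        surf = felmsm.weighted_fel(samples, model, disc, ("x", "y"), bins=2,
                                   on_unassigned="drop")
        assert surf.metadata["n_samples"] == 2


class TestBoltzmannRecovery:
    def test_double_well_basin_free_energy_matches_quadrature(self):
        """MSM-reweighted basin populations reproduce the Boltzmann integral
        ratio of a tilted double well within 0.2 kT."""
        pot = tw.DoubleWell(tilt=0.3)
        kT = 0.6
        engine = sp.OverdampedLangevinEngine(pot, time_step=0.01,
                                             thermal_energy=kT)
        n_walkers, n_steps = 20, 15000
        rngs = [np.random.default_rng((8, w)) for w in range(n_walkers)]
        x = np.tile([[-1.0], [1.0]], (n_walkers // 2, 1))
        frames = []
        for step in range(n_steps):
            noise = engine.noise_sigma * np.stack(
                [r.standard_normal(1) for r in rngs])
            x = tw.langevin_step_batch(pot, x, noise, engine.time_step,
                                       engine.friction)
            if step > 2000 and step % 10 == 0:
                frames.append(x.copy())
        frames = np.asarray(frames)
        lag = 5
        data = felmsm.SwarmTransitionData(
            starts=frames[:-lag].reshape(-1, 1),
            ends=frames[lag:].reshape(-1, 1),
            iteration_tags=np.zeros((len(frames) - lag) * n_walkers,
                                    dtype=int), lag=lag)
        disc = felmsm.discretize(data.all_points(), k=30, seed=1)
        model = felmsm.estimate_msm(data, disc)
        pts = data.all_points()
        states = model.model_state(disc.assign(pts))
        w = felmsm.msm_sample_weights(states, model)
        valid = states >= 0
        p_hi = w[valid & (pts[:, 0] > 0)].sum() / w[valid].sum()
        df_est = -kT * np.log(p_hi / (1.0 - p_hi))
        df_true = boltzmann_free_energy_difference(pot, kT)
        assert abs(df_est - df_true) < 0.2 * kT
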