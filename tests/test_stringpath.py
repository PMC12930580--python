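"""String method: CVs, initialization, reparameterization, iterations."""

import numpy as np
import pytest
from _oracles import arclength_positions, equal_arclength_resample

from camdesign import stringpath as sp, toyworld as tw


class TestCollectiveVariables:
    def test_raw_cv_scaling_and_inversion(self):
        cvs = sp.raw_cv_set(2, scales=[2.0, 1.0])
        x = np.array([4.0, 3.0])
        v = cvs.evaluate(x)
        assert np.array_equal(v, [2.0, 3.0])
        assert np.array_equal(cvs.invert(v), x)

    def test_distance_cv(self):
        cv = sp.DistanceCV(atom_a=0, atom_b=1)
        conf = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert cv.evaluate(conf) == 5.0

    def test_rmsd_cv_zero_for_rotated_copy(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(5, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        conf = ref @ rot.T + 2.0
        cv = sp.RMSDCV(atom_indices=tuple(range(5)),
                       reference=tuple(map(tuple, ref)))
        assert cv.evaluate(conf) == pytest.approx(0.0, abs=1e-9)

    def test_microswitch_presets_expose_four_projections(self):
        rng = np.random.default_rng(1)
        refs = {m: rng.normal(size=(3, 3)) for m in ("CWxP", "PIF", "NPxxY")}
        sets = {m: (0, 1, 2) for m in refs}
        cvs = sp.microswitch_cv_presets(refs, sets, ionic_lock_atoms=(0, 2))
        assert cvs.labels == ["rmsd_CWxP", "rmsd_PIF", "rmsd_NPxxY",
                              "dist_ionic_lock"]
        conf = rng.normal(size=(4, 3))
        assert cvs.evaluate(conf).shape == (4,)

    def test_non_invertible_set_rejected(self):
        cvs = sp.CollectiveVariableSet(cvs=[sp.DistanceCV(0, 1)])
        with pytest.raises(ValueError, match="invertible"):
            cvs.invert(np.array([1.0]))


class TestInitializeString:
    def test_linear_midpoint(self):
        s = sp.initialize_string((0.0, 0.0), (2.0, 2.0), n_images=3)
        assert np.array_equal(s.images[1], [1.0, 1.0])

    def test_endpoints_bitwise_equal_inputs(self):
        start, end = np.array([0.1, -0.7]), np.array([1.3, 2.9])
        s = sp.initialize_string(start, end, n_images=7)
        assert np.array_equal(s.images[0], start)
        assert np.array_equal(s.images[-1], end)

    def test_from_path_images_at_uniform_arclength(self):
        t = np.linspace(0.0, 1.0, 400)
        path = tw.ToyTrajectory(np.column_stack([t, t ** 2]))
        s = sp.initialize_string(path.coords[0], path.coords[-1],
                                 n_images=9, mode="from_path", path=path)
        expected = equal_arclength_resample(path.coords, 9)
        assert np.allclose(s.images, expected, rtol=1e-9, atol=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="differ"):
            sp.initialize_string((1.0,), (1.0,), 5)
        flat = tw.ToyTrajectory(np.ones((10, 2)))
        with pytest.raises(ValueError, match="arclength"):
            sp.initialize_string((0.0, 0.0), (1.0, 1.0), 5,
                                 mode="from_path", path=flat)


class TestReparameterize:
    def test_equally_spaced_collinear_is_fixed_point(self):
        pts = np.column_stack([np.linspace(0, 1, 6), np.linspace(0, 2, 6)])
        out = sp.reparameterize(pts)
        assert np.allclose(out, pts, atol=1e-12)

    def test_off_center_middle_moves_to_midpoint(self):
        pts = np.array([[0.0], [0.9], [2.0]])
        out = sp.reparameterize(pts)
        assert out[1, 0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_strings_spacing_uniform_endpoints_exact(self, seed):
        """Output points sit on the input polyline at uniform arclength."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        out = sp.reparameterize(pts)
        s = arclength_positions(out, pts)
        spacing = np.diff(s)
        assert spacing.std() / spacing.mean() < 1e-9
        assert np.array_equal(out[0], pts[0])
        assert np.array_equal(out[-1], pts[-1])

    def test_zero_arclength_raises(self):
        with pytest.raises(ValueError, match="arclength"):
            sp.reparameterize(np.zeros((4, 2)))


class TestStringIteration:
    def test_flat_potential_zero_temperature_no_drift(self):
        flat = tw.Harmonic(k=0.0, dimension=2)
        engine = sp.OverdampedLangevinEngine(flat, time_step=0.01,
                                             thermal_energy=0.0)
        cvs = sp.raw_cv_set(2)
        string = sp.initialize_string((0.0, 0.0), (1.0, 1.0), 5)
        new, rec = sp.string_iteration(string, engine, cvs,
                                       sp.SwarmConfig(seed=0, n_swarms=4))
        assert np.all(rec.drifts() == 0.0)
        assert np.allclose(new.images,
                           sp.reparameterize(string.images), atol=1e-12)

    def test_quadratic_well_drift_points_downhill(self):
        c = 0.7
        engine = sp.OverdampedLangevinEngine(
            tw.Harmonic(k=1.0, center=[c]), time_step=0.01,
            thermal_energy=0.0)
        cvs = sp.raw_cv_set(1)
        string = sp.StringPath(images=np.array([[0.0], [0.25], [1.5]]))
        _, rec = sp.string_iteration(
            string, engine, cvs,
            sp.SwarmConfig(seed=0, n_swarms=2, restraint_constant=100.0))
        drifts = rec.drifts()[:, 0]
        assert np.sign(drifts[1]) == np.sign(c - 0.25)
        assert np.sign(drifts[2]) == np.sign(c - 1.5)

    def test_mean_drift_matches_short_time_force_oracle(self):
        """Mean swarm drift equals -(dt/gamma) V'(x) * swarm_length within
        3 standard errors at low temperature."""
        pot = tw.DoubleWell()
        dt, L = 1e-3, 5
        engine = sp.OverdampedLangevinEngine(pot, time_step=dt,
                                             thermal_energy=1e-3)
        cvs = sp.raw_cv_set(1)
        string = sp.StringPath(images=np.array([[-1.0], [0.5], [1.0]]))
        drifts, starts = [], []
        for it in range(200):
            _, rec = sp.string_iteration(
                string, engine, cvs,
                sp.SwarmConfig(seed=11, n_swarms=32, swarm_length=L,
                               equil_length=50, restraint_constant=1000.0),
                iteration=it)
            d = rec.swarm_ends[1, :, 0] - rec.swarm_starts[1, :, 0]
            drifts.extend(d)
            starts.append(rec.swarm_starts[1, 0, 0])
        drifts = np.asarray(drifts)
        x = np.mean(starts)
        expected = -dt * pot.gradient(np.array([x]))[0] * L
        se = drifts.std(ddof=1) / np.sqrt(drifts.size)
        assert abs(drifts.mean() - expected) < 3 * se + 5e-6

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_engine_failure_names_iteration(self):
        engine = sp.OverdampedLangevinEngine(tw.DoubleWell(), time_step=10.0,
                                             thermal_energy=0.0)
        string = sp.initialize_string((-1.5,), (1.5,), 3)
        with pytest.raises(FloatingPointError, match="iteration 4"):
            sp.string_iteration(string, engine, sp.raw_cv_set(1),
                                sp.SwarmConfig(seed=0), iteration=4)


class TestRunString:
    def _run_double_well(self, seed=5):
        engine = sp.OverdampedLangevinEngine(tw.DoubleWell(), time_step=0.01,
                                             thermal_energy=0.2)
        cvs = sp.raw_cv_set(1)
        initial = sp.initialize_string((-1.0,), (1.0,), 3)
        cfg = sp.SwarmConfig(seed=seed, restraint_constant=50.0)
        return sp.run_string(initial, engine, cvs, cfg,
                             max_iterations=60, block=10)

    def test_symmetric_double_well_interior_image_at_barrier(self):
        _, final = self._run_double_well()
        assert abs(final.images[1, 0]) < 0.05

    def test_endpoints_bit_identical_across_history(self):
        history, final = self._run_double_well()
        for rec in history:
            assert np.array_equal(rec.string_after[0], [-1.0])
            assert np.array_equal(rec.string_after[-1], [1.0])

    def test_spacing_uniform_after_every_iteration(self):
        history, _ = self._run_double_well()
        for rec in history:
            seg = np.linalg.norm(np.diff(rec.string_after, axis=0), axis=1)
            assert seg.std() / seg.mean() < 1e-9

    def test_same_seed_identical_history(self):
        h1, f1 = self._run_double_well(seed=3)
        h2, f2 = self._run_double_well(seed=3)
        assert np.array_equal(f1.images, f2.images)
        assert all(np.array_equal(a.swarm_ends, b.swarm_ends)
                   for a, b in zip(h1, h2))

    def test_max_iterations_must_cover_two_blocks(self):
        engine = sp.OverdampedLangevinEngine(tw.DoubleWell(), time_step=0.01)
        with pytest.raises(ValueError, match="twice"):
            sp.run_string(sp.initialize_string((-1.0,), (1.0,), 3), engine,
                          sp.raw_cv_set(1), sp.SwarmConfig(seed=0),
                          max_iterations=10, block=10)


class TestConvergenceProfile:
    class _Rec:
        def __init__(self, images, it):
            self.string_after = images
            self.iteration = it

    def test_identical_strings_give_zero_profile(self):
        images = np.random.default_rng(0).normal(size=(5, 2))
        history = [self._Rec(images, i) for i in range(12)]
        prof = sp.convergence_profile(history, block=3)
        assert np.all(prof.values == 0.0)

    def test_profile_length_is_floor_blocks_minus_one(self):
        images = np.zeros((3, 1))
        history = [self._Rec(images, i) for i in range(10)]
        assert len(sp.convergence_profile(history, 5).values) == 1
        assert len(sp.convergence_profile(history, 3).values) == 2

    def test_uniform_translation_gives_block_times_step(self):
        base = np.zeros((4, 2))
        v = np.array([0.3, -0.4])      # |v| = 0.5
        history = [self._Rec(base + i * v, i) for i in range(20)]
        prof = sp.convergence_profile(history, block=5)
        assert np.allclose(prof.values, 5 * 0.5, atol=1e-12)

    def test_oversized_block_rejected(self):
        history = [self._Rec(np.zeros((3, 1)), i) for i in range(6)]
        with pytest.raises(ValueError, match="half"):
            sp.convergence_profile(history, block=4)
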