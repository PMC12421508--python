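"""Unwrapping, drift removal, MSD and the two diffusion estimators."""

import numpy as np
import pytest

from acetwall import (
    BrownianSpec,
    MSDSeries,
    SelectionGroup,
    StructureModel,
    Trajectory,
    block_error,
    diffusion_linear,
    diffusion_sliding,
    gen_brownian,
    msd_fixed_origin,
    remove_reference_drift,
    unwrap,
    wrap_coords,
)


def _tracer_traj(coords, box=(10.0, 10.0, 10.0), dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    s = StructureModel(
        elements=np.array(["O"] * n, dtype=object), masses=np.full(n, 18.02),
        components=np.array(["water"] * n, dtype=object),
        groups=np.array(["none"] * n, dtype=object), resids=np.arange(1, n + 1))
    return Trajectory(structure=s, coords=coords, boxes=np.asarray(box),
                      frame_interval=dt, equilibration=0.0)


def _all(traj):
    return SelectionGroup(name="all", indices=np.arange(traj.n_atoms))


class TestUnwrap:
    def test_boundary_crossing(self):
        traj = _tracer_traj([[[9.9, 5, 5]], [[0.1, 5, 5]]])
        out = unwrap(traj)
        assert np.allclose(out.coords[:, 0, 0], [9.9, 10.1])

    def test_stationary_identity(self):
        traj = _tracer_traj([[[3.0, 4, 5]]] * 5)
        assert np.allclose(unwrap(traj).coords, traj.coords)

    def test_wrap_then_unwrap_recovers_continuous_path(self):
        rng = np.random.default_rng(0)
        path = np.cumsum(rng.normal(0, 0.8, (200, 15, 3)), axis=0) + 5.0
        box = (12.0, 12.0, 12.0)
        traj = _tracer_traj(wrap_coords(path, box), box=box)
        out = unwrap(traj)
        # recovered up to the initial wrap offset, constant per particle
        offset = out.coords[0] - path[0]
        assert np.allclose(out.coords, path + offset, atol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            unwrap(_tracer_traj([[[1.0, 1, 1]]]))


class TestDriftRemoval:
    def test_uniform_translation_removed(self):
        base = np.tile(np.array([[2.0, 2, 2], [5.0, 5, 5]]), (10, 1, 1))
        drift = np.arange(10)[:, None, None] * np.array([0.3, 0.0, 0.1])
        traj = _tracer_traj(base + drift, box=(100, 100, 100))
        ref = SelectionGroup(name="ref", indices=np.array([0]))
        out = remove_reference_drift(traj, ref)
        assert np.allclose(out.coords, base, atol=1e-12)
        msd = msd_fixed_origin(out, _all(traj), t_ref=0)
        assert np.allclose(msd.values, 0.0, atol=1e-18)

    def test_resting_reference_is_identity(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 50, (6, 4, 3))
        coords[:, 0] = [10.0, 10, 10]
        traj = _tracer_traj(coords, box=(50, 50, 50))
        out = remove_reference_drift(traj, SelectionGroup("ref", np.array([0])))
        assert np.allclose(out.coords, coords)

    def test_recovery_with_drifting_reference(self):
        traj, truth = gen_brownian(BrownianSpec(d_true=2.0, seed=1))
        u = unwrap(traj)
        drift = np.linspace(0, 40, traj.n_frames)[:, None, None] \
            * np.array([1.0, 0.5, -0.2])
        drifted = u.with_coords(u.coords + drift)
        # one stationary-in-the-drifting-frame reference particle
        ref_coord = np.zeros((traj.n_frames, 1, 3)) + drift
        s = drifted.structure
        merged = _tracer_traj(np.concatenate([drifted.coords, ref_coord], axis=1),
                              box=(60, 60, 60), dt=traj.frame_interval)
        out = remove_reference_drift(merged, SelectionGroup(
            "ref", np.array([traj.n_atoms])))
        grp = SelectionGroup("tracers", np.arange(traj.n_atoms))
        est = diffusion_linear(msd_fixed_origin(out, grp, t_ref=0))
        assert est.d_A2_ns == pytest.approx(truth.d_true, rel=0.05)

    def test_empty_reference_rejected(self):
        traj = _tracer_traj([[[1.0, 1, 1]], [[1.0, 1, 1]]])
        with pytest.raises(ValueError):
            remove_reference_drift(traj, SelectionGroup("ref", np.array([], int)))


class TestMSD:
    def test_stationary_is_zero(self):
        traj = _tracer_traj([[[1.0, 1, 1], [2.0, 2, 2]]] * 6, box=(50, 50, 50))
        msd = msd_fixed_origin(traj, _all(traj), t_ref=0)
        assert np.allclose(msd.values, 0.0)

    def test_ballistic_closed_form(self):
        times = np.arange(20.0)
        coords = np.zeros((20, 1, 3))
        coords[:, 0, 0] = times * 1.0   # v = 1 Å/ns
        traj = _tracer_traj(coords, box=(1000, 1000, 1000))
        msd = msd_fixed_origin(traj, _all(traj), t_ref=0)
        assert np.allclose(msd.values, msd.times ** 2)

    def test_t_ref_past_end_rejected(self):
        traj = _tracer_traj([[[1.0, 1, 1]], [[1.0, 1, 1]]])
        with pytest.raises(ValueError):
            msd_fixed_origin(traj, _all(traj), t_ref=10.0)


class TestDiffusionLinear:
    def test_exact_linear_msd(self):
        t = np.arange(0.0, 10.0, 0.1)
        msd = MSDSeries(times=t, values=36.0 * t, n_members=10, t_ref=0.0)
        for method in ("gls", "ols"):
            est = diffusion_linear(msd, method=method)
            assert est.d_cm2_s == pytest.approx(6.0e-7, rel=1e-12)
            assert est.d_A2_ns == pytest.approx(6.0, rel=1e-12)

    def test_zero_msd_gives_zero(self):
        t = np.arange(0.0, 5.0, 0.1)
        msd = MSDSeries(times=t, values=np.zeros_like(t), n_members=3, t_ref=0.0)
        assert diffusion_linear(msd).d_cm2_s == 0.0

    def test_degenerate_window_rejected(self):
        msd = MSDSeries(times=np.array([0.0, 1.0]), values=np.array([0.0, 6.0]),
                        n_members=1, t_ref=0.0)
        with pytest.raises(ValueError):
            diffusion_linear(msd, fit_range=(0.9, 0.95))


class TestDiffusionSliding:
    def test_frozen_group_is_zero(self):
        traj = _tracer_traj([[[1.0, 1, 1]]] * 100, box=(50, 50, 50), dt=0.1)
        est = diffusion_sliding(traj, _all(traj), window=2.0,
                                use_equilibration_cutoff=False)
        assert est.d_cm2_s == 0.0

    def test_full_window_equals_single_interval_estimate(self):
        rng = np.random.default_rng(2)
        coords = np.cumsum(rng.normal(0, 0.3, (50, 8, 3)), axis=0)
        traj = _tracer_traj(coords, box=(1000, 1000, 1000), dt=0.5)
        T = traj.duration
        est = diffusion_sliding(traj, _all(traj), window=T,
                                use_equilibration_cutoff=False)
        disp = coords[-1] - coords[0]
        expected = np.mean(np.sum(disp ** 2, axis=1)) / (6.0 * T)
        assert est.d_A2_ns == pytest.approx(expected, rel=1e-12)

    def test_oversized_window_rejected(self):
        traj = _tracer_traj([[[0.0, 0, 0]]] * 10, dt=0.1)
        with pytest.raises(ValueError):
            diffusion_sliding(traj, _all(traj), window=5.0,
                              use_equilibration_cutoff=False)


class TestBlockError:
    def test_identical_blocks_give_zero(self):
        assert block_error(np.ones(20), 4) == 0.0

    def test_two_block_hand_value(self):
        # blocks {1, 3}: sd = sqrt(2), se = sqrt(2)/sqrt(2) = 1
        assert block_error(np.array([1.0, 3.0]), 2) == pytest.approx(1.0)

    def test_gaussian_blocks_match_theory(self):
        rng = np.random.default_rng(10)
        ses = [block_error(rng.normal(0, 1, 19), 19) for _ in range(60)]
        theory = 1.0 / np.sqrt(19)
        assert np.mean(ses) == pytest.approx(theory, rel=0.15)
        assert max(ses) < 3 * theory and min(ses) > theory / 3

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_error(np.arange(5.0), 1)


class TestEstimatorProperties:
    @pytest.mark.parametrize("d_true,seed", [(0.05, 0), (0.62, 1), (6.1, 2)])
    def test_parameter_recovery_both_estimators(self, d_true, seed):
        traj, _ = gen_brownian(BrownianSpec(d_true=d_true, seed=seed))
        u = unwrap(traj)
        grp = u.structure.select("tracers", component="water")
        lin = diffusion_linear(msd_fixed_origin(u, grp, t_ref=0))
        sli = diffusion_sliding(u, grp, window=50.0,
                                use_equilibration_cutoff=False)
        assert lin.d_A2_ns == pytest.approx(d_true, rel=0.05)
        assert sli.d_A2_ns == pytest.approx(d_true, rel=0.10)
        # consistency: the two estimates agree within combined 2 SE
        if lin.stderr_cm2_s and sli.stderr_cm2_s:
            gap = abs(lin.d_cm2_s - sli.d_cm2_s)
            assert gap <= 2 * np.hypot(lin.stderr_cm2_s, sli.stderr_cm2_s) + 1e-12

    def test_drift_invariance_of_estimates(self):
        traj, _ = gen_brownian(BrownianSpec(d_true=1.0, n_particles=50,
                                            n_frames=200, seed=4))
        u = unwrap(traj)
        ref_coord = np.zeros((u.n_frames, 1, 3))
        base = _tracer_traj(np.concatenate([u.coords, ref_coord], axis=1),
                            box=(60, 60, 60), dt=u.frame_interval)
        drift = np.linspace(0, 25, u.n_frames)[:, None, None] \
            * np.array([0.7, -0.4, 0.2])
        shifted = base.with_coords(base.coords + drift)
        ref = SelectionGroup("ref", np.array([u.n_atoms]))
        grp = SelectionGroup("tracers", np.arange(u.n_atoms))
        d0 = diffusion_linear(msd_fixed_origin(
            remove_reference_drift(base, ref), grp, t_ref=0)).d_cm2_s
        d1 = diffusion_linear(msd_fixed_origin(
            remove_reference_drift(shifted, ref), grp, t_ref=0)).d_cm2_s
        assert d0 == pytest.approx(d1, rel=1e-9)
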