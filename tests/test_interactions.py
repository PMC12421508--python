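"""Contacts, free energies, RDFs and dwell-time machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acetwall import (
    RDFProfile,
    SelectionGroup,
    StructureModel,
    Trajectory,
    contact_free_energy,
    contact_score,
    delta_g,
    delta_g_error,
    dwell_times,
    gen_boltzmann_sites,
    group_contact_timeseries,
    integrate_rdf_to_first_minimum,
    interaction_probability,
    rdf,
    rdf_free_energy,
    switching_weight,
    time_weighted_cdf,
)
from acetwall.interactions import eval_time_weighted_cdf
from acetwall import BoltzmannSiteSpec

from conftest import brute_contact_score, brute_runs

KT_300 = 0.59616   # R*T at 300 K, kcal/mol


def _point_traj(coords_per_frame, box, dt=0.2, components=None, groups=None):
    coords = np.asarray(coords_per_frame, dtype=float)
    n = coords.shape[1]
    comps = np.array(components or ["hemicellulose"] * n, dtype=object)
    grps = np.array(groups or ["none"] * n, dtype=object)
    s = StructureModel(
        elements=np.array(["O"] * n, dtype=object), masses=np.full(n, 15.999),
        components=comps, groups=grps, resids=np.arange(1, n + 1))
    return Trajectory(structure=s, coords=coords, boxes=np.asarray(box, float),
                      frame_interval=dt, equilibration=0.0)


class TestSwitchingFunction:
    def test_midpoint_is_half(self):
        assert switching_weight(5.0) == pytest.approx(0.5)

    def test_value_at_4A(self):
        assert switching_weight(4.0) == pytest.approx(1 / (1 + np.exp(-5)),
                                                      abs=1e-9)
        assert switching_weight(4.0) == pytest.approx(0.993307, abs=1e-6)

    def test_strictly_decreasing(self):
        d = np.linspace(0.1, 12.0, 200)
        w = switching_weight(d)
        assert np.all(np.diff(w) < 0)


class TestContactScore:
    def test_single_pair_values(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        a = SelectionGroup("a", np.array([0]))
        b = SelectionGroup("b", np.array([1]))
        assert contact_score(a, b, coords, (40, 40, 40)) == pytest.approx(0.5)
        coords[1, 0] = 4.0
        assert contact_score(a, b, coords, (40, 40, 40)) == \
            pytest.approx(0.993307, abs=1e-6)

    def test_matches_untruncated_brute_force(self):
        rng = np.random.default_rng(13)
        box = np.array([30.0, 30.0, 30.0])
        coords = rng.uniform(0, box, (200, 3))
        ia, ib = np.arange(100), np.arange(100, 200)
        got = contact_score(SelectionGroup("a", ia), SelectionGroup("b", ib),
                            coords, box)
        assert abs(got - brute_contact_score(ia, ib, coords, box)) < 1e-9

    def test_invariant_under_translation_and_rewrap(self):
        rng = np.random.default_rng(14)
        box = np.array([25.0, 25.0, 25.0])
        coords = rng.uniform(0, box, (60, 3))
        ia, ib = np.arange(30), np.arange(30, 60)
        a, b = SelectionGroup("a", ia), SelectionGroup("b", ib)
        ref = contact_score(a, b, coords, box)
        shifted = np.mod(coords + np.array([11.3, -4.2, 7.7]), box)
        assert contact_score(a, b, shifted, box) == pytest.approx(ref, abs=1e-9)


class TestContactSeries:
    def test_ion_near_single_carboxyl(self):
        # ion 3 Å from one carboxyl oxygen, everything else remote
        coords = np.array([[[10.0, 10, 10], [13.0, 10, 10], [40.0, 40, 40]]] * 4)
        traj = _point_traj(coords, (60, 60, 60),
                           components=["hemicellulose", "ion", "hemicellulose"],
                           groups=["carboxyl", "none", "carboxyl"])
        ions = SelectionGroup("ions", np.array([1]))
        carbs = SelectionGroup("carboxyl", np.array([0, 2]), abundance=2)
        series = group_contact_timeseries(traj, [(ions, carbs)],
                                          use_equilibration_cutoff=False)[0]
        expected = 1 / (1 + np.exp(5 * (3 - 5)))    # = 0.9999546
        assert np.allclose(series.scores, expected, atol=1e-6)

    def test_empty_frame_range_rejected(self):
        coords = np.zeros((2, 2, 3))
        traj = _point_traj(coords, (30, 30, 30))
        traj.equilibration = 100.0
        g = SelectionGroup("g", np.array([0]))
        h = SelectionGroup("h", np.array([1]))
        with pytest.raises(ValueError, match="equilibration"):
            group_contact_timeseries(traj, [(g, h)])


class TestFreeEnergyArithmetic:
    def test_per_site_normalisation_ratio(self):
        probs = interaction_probability({"acetyl": 100.0, "carboxyl": 30.0},
                                        {"acetyl": 50, "carboxyl": 10})
        # per-site scores 2 and 3
        assert probs["acetyl"] / probs["carboxyl"] == pytest.approx(2 / 3)

    def test_equal_per_site_scores_give_ratio_one(self):
        probs = interaction_probability({"a": 10.0, "b": 20.0}, {"a": 5, "b": 10})
        assert probs["a"] == pytest.approx(probs["b"])

    def test_delta_g_identity_and_hand_value(self):
        assert delta_g(0.3, 0.3) == pytest.approx(0.0)
        # -R*T*ln(0.5) = 1.987204e-3 * 300 * ln 2 = 0.413226 kcal/mol
        assert delta_g(0.2, 0.4) == pytest.approx(0.413226, abs=1e-5)
        assert delta_g(1.0, 1.0, is_reference=True) == 0.0

    def test_delta_g_zero_probability_signalled(self):
        with pytest.raises(ValueError, match="not estimable"):
            delta_g(0.0, 0.5)

    def test_error_propagation(self):
        assert delta_g_error(0.5, 0.0, 0.5, 0.0) == 0.0
        # 10% relative errors on both probabilities
        assert delta_g_error(0.5, 0.05, 0.2, 0.02) == \
            pytest.approx(KT_300 * np.sqrt(0.02), abs=1e-5)
        assert delta_g_error(0.5, 0.05, 0.2, 0.02) == pytest.approx(0.08431,
                                                                    abs=1e-5)
        one = delta_g_error(0.4, 0.01, 0.4, 0.02)
        two = delta_g_error(0.4, 0.02, 0.4, 0.04)
        assert two == pytest.approx(2 * one)


class TestBoltzmannRecovery:
    def test_contact_ratio_tracks_occupancy(self, boltzmann_118):
        traj, truth = boltzmann_118
        ions = traj.structure.select("ions", component="ion")
        groups = traj.structure.functional_group_map()
        series = group_contact_timeseries(
            traj, [(ions, groups["acetyl"]), (ions, groups["carboxyl"])],
            use_equilibration_cutoff=False)
        per_site_ratio = (series[0].mean / groups["acetyl"].abundance) \
            / (series[1].mean / groups["carboxyl"].abundance)
        assert per_site_ratio == pytest.approx(np.exp(-1.18 / KT_300), rel=0.15)

    def test_both_routes_recover_planted_offset(self, boltzmann_118):
        traj, truth = boltzmann_118
        ions = traj.structure.select("ions", component="ion")
        groups = traj.structure.functional_group_map()
        ct = contact_free_energy(traj, ions, groups,
                                 use_equilibration_cutoff=False)
        rt = rdf_free_energy(traj, ions, groups, use_equilibration_cutoff=False)
        for table in (ct, rt):
            assert table.delta_g["carboxyl"] == 0.0
            assert table.sigma["carboxyl"] == 0.0
            assert abs(table.delta_g["acetyl"] - 1.18) <= 2 * table.sigma["acetyl"]
        gap = abs(ct.delta_g["acetyl"] - rt.delta_g["acetyl"])
        assert gap <= 2 * np.hypot(ct.sigma["acetyl"], rt.sigma["acetyl"])


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(21)
        box = np.array([42.0, 42.0, 42.0])
        coords = rng.uniform(0, box, (30, 800, 3))
        traj = _point_traj(coords, box)
        g = SelectionGroup("gas", np.arange(800))
        prof = rdf(traj, g, g, r_max=10.0, bin_width=0.5,
                   use_equilibration_cutoff=False)
        far = prof.bin_centers > 1.0
        assert np.all(np.abs(prof.g[far] - 1.0) < 0.05)

    def test_two_particle_clamp(self):
        coords = np.array([[[10.0, 10, 10], [13.0, 10, 10]]] * 3)
        traj = _point_traj(coords, (40, 40, 40))
        a = SelectionGroup("a", np.array([0]))
        b = SelectionGroup("b", np.array([1]))
        prof = rdf(traj, a, b, r_max=10.0, bin_width=0.1,
                   use_equilibration_cutoff=False)
        occupied = np.flatnonzero(prof.raw_counts > 0)
        assert occupied.size == 1
        assert prof.bin_centers[occupied[0]] == pytest.approx(3.05, abs=0.051)
        coord, r_min = integrate_rdf_to_first_minimum(prof)
        assert coord == pytest.approx(1.0)

    def test_integral_matches_direct_neighbour_count(self):
        rng = np.random.default_rng(22)
        box = np.array([30.0, 30.0, 30.0])
        coords = rng.uniform(0, box, (5, 150, 3))
        traj = _point_traj(coords, box)
        a = SelectionGroup("a", np.arange(50))
        b = SelectionGroup("b", np.arange(50, 150))
        prof = rdf(traj, a, b, r_max=9.0, bin_width=0.1,
                   use_equilibration_cutoff=False)
        total_from_bins = prof.raw_counts.sum()
        # direct count oracle
        from acetwall import minimum_image_distance
        count = 0
        for f in range(5):
            d = minimum_image_distance(coords[f, :50][:, None, :],
                                       coords[f, 50:150][None, :, :], box)
            count += int((d <= 9.0).sum())
        assert total_from_bins == pytest.approx(count / (5 * 50), rel=1e-9)

    def test_constructed_profile_integrates_to_given_minimum(self):
        r = np.arange(0.05, 10.0, 0.1)
        g = np.exp(-((r - 2.0) ** 2)) * 3.0 + np.exp(-((r - 5.0) ** 2) / 2)
        counts = g * r ** 2 * 0.01
        prof = RDFProfile(bin_centers=r, g=g, raw_counts=counts,
                          center_name="a", target_name="b", r_max=10.0,
                          first_minimum=3.5)
        coord, r_min = integrate_rdf_to_first_minimum(prof)
        assert r_min == 3.5
        assert coord == pytest.approx(counts[r <= 3.5].sum())

    def test_oversized_r_max_rejected(self):
        traj = _point_traj(np.zeros((2, 3, 3)), (15, 15, 15))
        g = SelectionGroup("g", np.arange(3))
        with pytest.raises(ValueError):
            rdf(traj, g, g, r_max=10.0)

    def test_noise_shrinks_with_sampling(self):
        rng = np.random.default_rng(23)
        box = np.array([42.0, 42.0, 42.0])
        errs = []
        for n_frames in (8, 32):
            coords = rng.uniform(0, box, (n_frames, 500, 3))
            traj = _point_traj(coords, box)
            g = SelectionGroup("gas", np.arange(500))
            prof = rdf(traj, g, g, r_max=10.0, bin_width=0.5,
                       use_equilibration_cutoff=False)
            far = prof.bin_centers > 2.0
            errs.append(np.sqrt(np.mean((prof.g[far] - 1.0) ** 2)))
        # quadrupled sampling should roughly halve the rms error
        assert errs[1] < errs[0] / 1.3
        assert errs[1] > errs[0] / 4.0


class TestDwellTimes:
    def _binary_traj(self, pattern, dt=0.2):
        # ion at origin when bound (d=3), teleported far when unbound
        coords = np.array([
            [[10.0, 10, 10], [13.0, 10, 10] if x else [40.0, 40, 40]]
            for x in pattern
        ])
        return _point_traj(coords, (90, 90, 90), dt=dt,
                           components=["hemicellulose", "ion"],
                           groups=["carboxyl", "none"])

    def test_constructed_pattern_with_censoring(self):
        traj = self._binary_traj([0, 1, 1, 1, 0, 1, 1])
        ions = SelectionGroup("ions", np.array([1]))
        sites = SelectionGroup("sites", np.array([0]))
        dist = dwell_times(traj, ions, sites, cutoff=6.0)
        assert np.allclose(dist.durations, [0.4, 0.6])
        # the 0.4 ns run touches the trajectory end: censored
        assert list(dist.censored) == [True, False]

    def test_never_bound_is_empty(self):
        traj = self._binary_traj([0, 0, 0, 0])
        dist = dwell_times(traj, SelectionGroup("i", np.array([1])),
                           SelectionGroup("s", np.array([0])))
        assert dist.durations.size == 0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_run_length_coder_matches_brute_force(self, pattern):
        traj = self._binary_traj(pattern)
        dist = dwell_times(traj, SelectionGroup("i", np.array([1])),
                           SelectionGroup("s", np.array([0])))
        expected = brute_runs(pattern)
        got = sorted(zip(np.round(dist.durations / 0.2).astype(int),
                         dist.censored))
        assert got == sorted((l, c) for l, c in expected)


class TestTimeWeightedCDF:
    def test_hand_arithmetic(self):
        d, cdf = time_weighted_cdf(np.array([1.0, 1.0, 8.0]))
        assert eval_time_weighted_cdf(np.array([1.0, 1.0, 8.0]), 1.0) == \
            pytest.approx(0.2)
        assert cdf[-1] == pytest.approx(1.0)

    def test_equal_durations_match_unweighted(self):
        d, cdf = time_weighted_cdf(np.full(5, 2.0))
        assert np.allclose(cdf, np.arange(1, 6) / 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_weighted_cdf(np.array([]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.1, 50.0), min_size=1, max_size=40))
    def test_matches_weighted_sort_oracle(self, vals):
        arr = np.array(vals)
        d, cdf = time_weighted_cdf(arr)
        order = np.argsort(arr, kind="stable")
        expected = np.cumsum(arr[order]) / arr.sum()
        assert np.allclose(d, arr[order])
        assert np.allclose(cdf, expected)
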