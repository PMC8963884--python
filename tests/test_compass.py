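import numpy as np
import pytest

from cellcompass.compass import (
    CompassParams,
    EventTemplateParams,
    PhaseDiagram,
    alignment_from_simulation,
    estimate_parameters,
    event_duration_frames,
    event_footprint_markers,
    make_transfer_function,
    map_to_trajectory,
    natural_axis_path,
    phase_diagram,
    protrusion_force,
    render_movie,
    simulate,
    simulation_observables,
    single_event_template,
    unicity_index,
)
from cellcompass.morphomap import MorphodynamicMap
from cellcompass.trajectory import direction_autocorrelation


class TestTransferFunction:
    def test_single_term_is_separable_positive_gaussian(self):
        p = EventTemplateParams(
            amp_lateral_inhibition=0, amp_wave=0, amp_central_inhibition=0
        )
        k = make_transfer_function(p)
        assert np.all(k >= 0)
        # rank-1: outer product of a spatial Gaussian and a temporal decay
        u, s, vt = np.linalg.svd(k)
        assert s[1] / s[0] < 1e-10

    def test_wave_term_ridges_travel_at_wave_speed(self):
        p = EventTemplateParams(
            amp_lateral_inhibition=0, amp_protrusion=0, amp_central_inhibition=0,
            amp_wave=1.0, wave_speed=2.0, tau_wave=50.0, sigma_narrow=2.0,
        )
        k = make_transfer_function(p)
        offsets = ((np.arange(100) + 50) % 100) - 50
        for t in (3, 6, 10):
            col = k[:, t]
            peaks = np.sort(np.abs(offsets[np.argsort(col)[-2:]]))
            assert np.all(np.abs(peaks - 2.0 * t) <= 1)

    def test_excessive_width_rejected(self):
        with pytest.raises(ValueError):
            make_transfer_function(EventTemplateParams(sigma_wide=80.0))


class TestEventTemplate:
    def test_sums_to_zero(self):
        t = single_event_template()
        assert abs(t.sum()) < 1e-9

    def test_peak_protrusion_speed_is_one(self):
        assert single_event_template().max() == pytest.approx(1.0)

    def test_duration_calibration_about_ten_frames(self):
        t = single_event_template()
        assert 8 <= event_duration_frames(t) <= 12

    def test_spatial_footprint_under_a_fifth_of_contour(self):
        assert event_footprint_markers(single_event_template()) <= 20

    def test_near_delta_puff_reduces_to_normalized_kernel(self):
        p = EventTemplateParams(sigma_puff=1e-3, tau_puff=1e-3)
        t = single_event_template(p)
        k = make_transfer_function(p)[:, : t.shape[1]].copy()
        # apply the same zero-sum rule: rescale the lighter-signed part
        pos, neg = k[k > 0].sum(), -k[k < 0].sum()
        if neg >= pos:
            k[k < 0] *= pos / neg
        else:
            k[k > 0] *= neg / pos
        k = k / k.max()
        assert np.allclose(t, k, atol=1e-6)

    def test_sign_structure_core_with_retraction_elsewhere(self):
        t = single_event_template()
        peak_t = int(np.argmax(t[0]))
        assert t[0, peak_t] > 0  # protrusive core at the centre row
        assert t[:, peak_t].min() < 0  # flanked laterally by retraction
        assert abs(t.sum()) < 1e-9  # retraction balances protrusion overall


class _ConstRng:
    """Generator stub producing a constant 'random' function."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low, high, size=None):
        return np.full(size, self.value)


class TestNaturalAxis:
    def test_zero_variance_input_gives_zero_basal_force(self):
        c, f = natural_axis_path(100, rng=_ConstRng(300.0))
        assert np.allclose(f, 0)

    def test_same_seed_identical_path(self):
        a, _ = natural_axis_path(200, rng=np.random.default_rng(5))
        b, _ = natural_axis_path(200, rng=np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_median_time_to_span_contour_about_four_hours(self):
        # ~48 frames (4 h at 5 min/frame), generously +-24
        rng = np.random.default_rng(0)
        times = []
        for _ in range(100):
            c, _ = natural_axis_path(500, rng=rng)
            span = np.maximum.accumulate(c) - np.minimum.accumulate(c)
            hit = np.flatnonzero(span >= 100)
            times.append(hit[0] if len(hit) else np.nan)
        assert 24 <= np.nanmedian(times) <= 72


class TestProtrusionForce:
    def test_symmetric_protrusion_on_axis_gives_no_net_pull(self):
        v = np.zeros(100)
        v[45:56] = 1.0
        assert protrusion_force(v, 50.0, 100) == pytest.approx(0.0)

    def test_pull_is_toward_the_protrusion(self):
        v = np.zeros(100)
        v[30] = 1.0
        assert protrusion_force(v, 10.0, 100) > 0
        assert protrusion_force(v, 60.0, 100) < 0

    def test_retraction_does_not_pull(self):
        v = np.zeros(100)
        v[30] = -5.0
        assert protrusion_force(v, 10.0, 100) == 0.0

    def test_axis_converges_to_pinned_protrusion_within_event_duration(self):
        # axis-gain calibration contract, kappa = 1
        params = CompassParams()
        duration = event_duration_frames(single_event_template(params.template))
        offsets = np.minimum(np.abs(np.arange(100) - 25), 100 - np.abs(np.arange(100) - 25))
        v = np.exp(-0.5 * (offsets / params.template.sigma_narrow) ** 2)
        c = 0.0
        reached = None
        for t in range(duration):
            c = (c + params.axis_gain * protrusion_force(v, c, 100)) % 100
            dist = abs((c - 25 + 50) % 100 - 50)
            if reached is None and dist <= params.sigma_c:
                reached = t + 1
        assert reached is not None and reached <= duration


class TestSimulate:
    def test_no_nucleation_means_no_motion_and_natural_axis(self):
        # kappa = 0 so the axis update reduces to the pure basal drift
        params = CompassParams(p_polarized=0.5, kappa=0.0, p_nuc=0.0, t_tot=200, seed=9)
        res = simulate(params)
        assert np.all(res.morphomap.values == 0)
        assert np.allclose(res.trajectory, 0)
        c_nat, _ = natural_axis_path(200, 100, params.axis_window, np.random.default_rng(9))
        assert np.allclose(res.c_axis, c_nat % 100)

    def test_fixed_seed_bit_identical(self):
        a = simulate(CompassParams(p_polarized=0.7, kappa=0.9, t_tot=300, seed=4))
        b = simulate(CompassParams(p_polarized=0.7, kappa=0.9, t_tot=300, seed=4))
        assert np.array_equal(a.morphomap.values, b.morphomap.values)
        assert np.array_equal(a.c_axis, b.c_axis)
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_strong_feedback_low_noise_moves_near_straight(self):
        res = simulate(CompassParams(p_polarized=1.0, kappa=1.0, sigma_c=1.0, seed=2))
        ac = direction_autocorrelation(res.trajectory, dt=5.0, max_lag=20)
        assert ac.ac[10] > 0.8

    def test_no_feedback_is_non_persistent(self):
        taus = []
        for seed in range(5):
            res = simulate(CompassParams(p_polarized=0.0, kappa=0.0, seed=seed))
            taus.append(simulation_observables(res)["tau_hours"])
        assert np.nanmedian(taus) < 1.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            CompassParams(p_polarized=1.3, kappa=0.5)

    def test_trajectory_matches_map_to_trajectory(self):
        res = simulate(CompassParams(p_polarized=0.6, kappa=0.4, t_tot=200, seed=1))
        assert np.allclose(res.trajectory, map_to_trajectory(res.morphomap.values))


class TestUnicityIndex:
    def test_single_events_one_at_a_time_give_unity(self):
        v = np.zeros((100, 60))
        for k, t0 in enumerate(range(0, 60, 15)):
            v[20 * k : 20 * k + 5, t0 : t0 + 5] = 1.0
        assert unicity_index(v) == pytest.approx(1.0)

    def test_two_simultaneous_fronts_give_half(self):
        v = np.zeros((100, 30))
        v[10:16, :] = 1.0
        v[60:66, :] = 1.0
        assert unicity_index(v) == pytest.approx(0.5)

    def test_front_spanning_the_seam_counts_once(self):
        v = np.zeros((100, 30))
        v[95:, :] = 1.0
        v[:5, :] = 1.0  # same front, wrapped across row 0
        assert unicity_index(v) == pytest.approx(1.0)

    def test_no_protrusion_is_undefined(self):
        assert np.isnan(unicity_index(-np.ones((100, 30))))

    def test_map_scope_uses_global_threshold(self):
        v = np.zeros((100, 30))
        v[10:16, :] = 1.0
        v[60:66, :] = 0.5  # below 70% of the global max
        assert unicity_index(v, threshold_scope="map") == pytest.approx(1.0)
        assert unicity_index(v, threshold_scope="window") == pytest.approx(1.0)


class TestAlignment:
    def test_axis_equal_to_motion_gives_one(self):
        traj = np.column_stack([np.arange(50.0), np.zeros(50)])
        res = simulate(CompassParams(t_tot=50, seed=0))
        res.trajectory = traj
        res.c_axis = np.zeros(50)
        assert alignment_from_simulation(res) == pytest.approx(1.0)

    def test_random_axis_dissolves_alignment(self, rng):
        traj = np.column_stack([np.arange(2000.0), np.zeros(2000)])
        res = simulate(CompassParams(t_tot=50, seed=0))
        res.trajectory = traj
        res.c_axis = rng.uniform(0, 100, 2000)
        assert alignment_from_simulation(res) < 0.1


class TestPhaseDiagramAndInversion:
    def test_single_node_grid_runs_replicates(self):
        small = CompassParams(t_tot=150)
        d = phase_diagram([0.5], [0.5], replicates=2, base_params=small, base_seed=3)
        assert d.tau_hours.shape == (1, 1)
        assert np.isfinite(d.unicity[0, 0])

    def test_diagram_deterministic_in_base_seed(self):
        small = CompassParams(t_tot=150)
        a = phase_diagram([0.2, 0.8], [0.5], replicates=2, base_params=small, base_seed=11)
        b = phase_diagram([0.2, 0.8], [0.5], replicates=2, base_params=small, base_seed=11)
        assert np.array_equal(a.tau_hours, b.tau_hours)
        assert np.array_equal(a.alignment, b.alignment)

    def _toy_diagram(self):
        p = np.linspace(0, 1, 6)
        k = np.linspace(0, 1, 6)
        P, K = np.meshgrid(p, k, indexing="ij")
        zeros = np.zeros_like(P)
        return PhaseDiagram(
            p_values=p, kappa_values=k,
            tau_hours=1 + 4 * P * K, unicity=0.4 + 0.4 * P,
            alignment=0.1 + 0.5 * P + 0.3 * K,
            tau_sd=zeros + 0.1, unicity_sd=zeros + 0.02, alignment_sd=zeros + 0.02,
            replicates=1,
        )

    def test_node_values_returned_exactly(self):
        d = self._toy_diagram()
        i, j = 3, 2  # p = 0.6, kappa = 0.4
        est = estimate_parameters(
            d,
            tau_hours=d.tau_hours[i, j],
            unicity=d.unicity[i, j],
            alignment=d.alignment[i, j],
            smooth_sigma=0.0,
        )
        assert est.p_polarized == pytest.approx(0.6, abs=0.01)
        assert est.kappa == pytest.approx(0.4, abs=0.01)
        assert not est.extrapolated

    def test_out_of_range_measurement_flagged_extrapolated(self):
        est = estimate_parameters(self._toy_diagram(), tau_hours=50.0, unicity=0.99)
        assert est.extrapolated

    def test_missing_alignment_uses_two_observables(self):
        d = self._toy_diagram()
        est = estimate_parameters(d, tau_hours=d.tau_hours[2, 2], unicity=d.unicity[2, 2])
        assert est.used_observables == ("tau_hours", "unicity")

    def test_fewer_than_two_observables_rejected(self):
        with pytest.raises(ValueError):
            estimate_parameters(self._toy_diagram(), tau_hours=2.0)


class TestRenderMovie:
    def test_zero_map_gives_static_contour(self):
        res = simulate(CompassParams(p_nuc=0.0, t_tot=30, seed=0))
        frames = render_movie(res)
        assert np.allclose(frames[0], frames[-1])

    def test_movie_centroid_drifts_along_map_trajectory(self):
        res = simulate(CompassParams(p_polarized=0.9, kappa=0.9, t_tot=80, seed=6))
        frames = render_movie(res)
        drift = np.mean(frames[-1], axis=0) - np.mean(frames[0], axis=0)
        traj = map_to_trajectory(res.morphomap.values[:, : len(frames) - 1])
        expected = traj[-1] - traj[0]
        cos = np.dot(drift, expected) / (np.linalg.norm(drift) * np.linalg.norm(expected))
        assert cos > 0.7  # elastic-contour geometry rescales but keeps direction
        assert np.linalg.norm(drift) > 1.0
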