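"""Excitation pulses, digital phantoms, and the one-to-all echo simulator."""

import numpy as np
import pytest
import scipy.signal

from ringbeam.arraygeom import RingArray
from ringbeam.echosim import (
    Pulse,
    ScattererSet,
    bandlimit_pulse,
    make_breast_phantom,
    make_pulse,
    make_resolution_phantom,
    resolution_phantom_line_centers,
    simulate_rf_frame,
    simulate_scan,
)


class TestPulse:
    def test_one_square_period_at_8x_sampling(self):
        p = make_pulse(1.0, 1, 8.0, "bipolar_square")
        np.testing.assert_allclose(p.samples, [1, 1, 1, 1, -1, -1, -1, -1])

    def test_sample_count_rounding_rule(self):
        # 5 cycles at 3 MHz sampled at 40 MHz: 66.7 -> round -> 67 samples
        p = make_pulse(3e6, 5, 40e6)
        assert len(p.samples) == 67

    @pytest.mark.parametrize("shape", ["bipolar_square", "gated_sine"])
    def test_unit_peak_and_near_zero_mean(self, shape):
        p = make_pulse(3e6, 5, 40e6, shape)
        assert np.abs(p.samples).max() == pytest.approx(1.0)
        assert abs(p.samples.mean()) <= 0.01

    def test_duration_within_one_sample(self):
        p = make_pulse(3e6, 5, 40e6)
        assert abs(p.duration - 5 / 3e6) <= 1 / 40e6

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            make_pulse(3e6, 5, 5e6)

    def test_bandlimit_preserves_support_and_peak(self):
        p = make_pulse(3e6, 5, 40e6)
        bl = bandlimit_pulse(p, 0.6)
        assert len(bl.samples) == len(p.samples)
        assert np.abs(bl.samples).max() == pytest.approx(1.0)


class TestResolutionPhantom:
    def test_default_group_gaps_read_back(self):
        phant = make_resolution_phantom()
        for group, expected in (("axial", [4, 3, 2, 1]), ("lateral", [3, 2, 1, 0.5])):
            axis = 1 if group == "axial" else 0
            centers = sorted(
                phant.select(f"{group}_{i}").positions[:, axis].mean() for i in range(1, 6)
            )
            np.testing.assert_allclose(np.diff(centers), expected, atol=1e-12)

    def test_cloud_lines_stay_within_stated_diameter(self):
        phant = make_resolution_phantom(line_diameter=0.3, scatterers_per_line=25, seed=3)
        for label, center in resolution_phantom_line_centers().items():
            pts = phant.select(label).positions
            r = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
            assert r.max() <= 0.15 + 1e-12
            # gap read-back from cloud centroids stays within half a diameter
            assert np.hypot(*(pts[:, :2].mean(axis=0) - center)) <= 0.15

    def test_single_scatterer_lines_are_exact_points(self):
        phant = make_resolution_phantom(scatterers_per_line=1)
        for label, center in resolution_phantom_line_centers().items():
            np.testing.assert_allclose(phant.select(label).positions[0, :2], center)

    def test_seeded_determinism(self):
        a = make_resolution_phantom(scatterers_per_line=9, seed=11)
        b = make_resolution_phantom(scatterers_per_line=9, seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.reflectivities, b.reflectivities)

    def test_optional_lesions(self):
        bare = make_resolution_phantom(seed=0)
        with_lesions = make_resolution_phantom(seed=0, include_lesions=True)
        assert len(with_lesions) > len(bare)
        assert "stone_10mm" in with_lesions.labels


class TestBreastPhantom:
    def test_cylinder_diameters_read_back(self):
        phant = make_breast_phantom(seed=5)
        for label, diameter in (("tumor_10mm", 10.0), ("cyst_6mm", 6.0)):
            pts = phant.select(label).positions
            center = pts[:, :2].mean(axis=0)
            width = 2 * np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]).max()
            assert width == pytest.approx(diameter, abs=0.5)

    def test_cyst_interior_is_anechoic(self):
        phant = make_breast_phantom(seed=5)
        rim = phant.select("cyst_6mm").positions
        center = rim[:, :2].mean(axis=0)
        bg = phant.select("background").positions
        inside = np.hypot(bg[:, 0] - center[0], bg[:, 1] - center[1]) < 2.9
        assert not inside.any()

    def test_no_background_option(self):
        phant = make_breast_phantom(seed=1, n_background=0)
        assert "background" not in set(phant.labels)

    def test_seeded_determinism(self):
        a = make_breast_phantom(seed=2)
        b = make_breast_phantom(seed=2)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestSimulator:
    def test_empty_scatterer_set_gives_silence(self, small_array, small_pulse):
        frame = simulate_rf_frame(
            small_array, ScattererSet(np.empty((0, 3)), np.empty(0)), 1500.0, small_pulse
        )
        assert not frame.data.any()

    def test_echo_envelope_peaks_at_geometric_delay(self):
        # centered target, 110 mm ring: round trip 220 mm at 1513 m/s, 40 MHz
        arr = RingArray(4, 110.0, 3e6, 40e6)
        pulse = make_pulse(3e6, 5, 40e6)
        scat = ScattererSet(np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        frame = simulate_rf_frame(arr, scat, 1513.0, pulse)
        expected = (2 * 110.0 / (1513.0 * 1000.0)) * 40e6  # 5816.26
        for n in range(4):
            env = np.abs(scipy.signal.hilbert(frame.data[n, n].astype(float)))
            assert abs(int(np.argmax(env)) - expected) <= len(pulse.samples) / 2

    def test_superposition_of_disjoint_sets(self, small_array, small_pulse):
        a = ScattererSet(np.array([[2.0, 1.0, 0.0]]), np.array([1.0]))
        b = ScattererSet(np.array([[-3.0, 0.5, 0.0]]), np.array([0.7]))
        fa = simulate_rf_frame(small_array, a, 1500.0, small_pulse)
        fb = simulate_rf_frame(small_array, b, 1500.0, small_pulse)
        fab = simulate_rf_frame(small_array, ScattererSet.merge(a, b), 1500.0, small_pulse)
        np.testing.assert_allclose(fab.data, fa.data + fb.data, atol=1e-5)

    def test_speed_scales_arrival_index(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        idx = {}
        for c in (1400.0, 1600.0):
            fr = simulate_rf_frame(small_array, scat, c, small_pulse)
            env2 = np.abs(scipy.signal.hilbert(fr.data[0, 0].astype(float))) ** 2
            # energy centroid: robust against ripple on the square envelope
            idx[c] = float((np.arange(env2.size) * env2).sum() / env2.sum())
        assert idx[1400.0] / idx[1600.0] == pytest.approx(1600.0 / 1400.0, rel=0.01)

    def test_noise_is_bit_reproducible(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[1.0, 1.0, 0.0]]), np.array([1.0]))
        f1 = simulate_rf_frame(small_array, scat, 1500.0, small_pulse, noise_snr_db=20, seed=42)
        f2 = simulate_rf_frame(small_array, scat, 1500.0, small_pulse, noise_snr_db=20, seed=42)
        np.testing.assert_array_equal(f1.data, f2.data)

    def test_scatterer_outside_ring_rejected(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[30.0, 0.0, 0.0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="outside the ring"):
            simulate_rf_frame(small_array, scat, 1500.0, small_pulse)

    def test_unphysical_speed_rejected(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[1.0, 0.0, 0.0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="sanity window"):
            simulate_rf_frame(small_array, scat, 900.0, small_pulse)

    def test_record_covers_ring_round_trip(self, point_frame, small_array):
        t_min = int(np.ceil(2 * (2 * small_array.radius) / (1500.0 * 1000.0) * 16e6))
        assert point_frame.n_samples >= t_min


class TestScan:
    def test_slice_metadata_and_count(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[1.0, 0.0, 10.0]]), np.array([1.0]))
        frames = simulate_scan(small_array, scat, 0.0, 1.0, 5, 1500.0, small_pulse)
        assert [f.slice_z for f in frames] == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_single_slice_matches_direct_simulation(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[1.0, 0.0, 2.0]]), np.array([1.0]))
        scan = simulate_scan(
            small_array, scat, 2.0, 1.0, 1, 1500.0, small_pulse, noise_snr_db=25, seed=3
        )
        direct = simulate_rf_frame(
            small_array, scat, 1500.0, small_pulse, noise_snr_db=25, seed=3, slice_z=2.0
        )
        np.testing.assert_array_equal(scan[0].data, direct.data)

    def test_narrow_elevation_isolates_slice(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[1.0, 0.0, 3.0]]), np.array([1.0]))
        frames = simulate_scan(
            small_array, scat, 0.0, 1.0, 6, 1500.0, small_pulse, sigma_elev=1e-3
        )
        energy = np.array([float((f.data.astype(float) ** 2).sum()) for f in frames])
        assert np.argmax(energy) == 3
        assert energy[[0, 1, 2, 4, 5]].max() <= 1e-12 * energy[3]

    def test_bad_steps_rejected(self, small_array, small_pulse):
        scat = ScattererSet(np.array([[1.0, 0.0, 0.0]]), np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_scan(small_array, scat, 0.0, -1.0, 3, 1500.0, small_pulse)
        with pytest.raises(ValueError):
            simulate_scan(small_array, scat, 0.0, 1.0, 0, 1500.0, small_pulse)
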