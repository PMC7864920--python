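"""Stimulus protocols, response simulation, RF detection, tuning statistics."""

import numpy as np
import pytest
from scipy import stats

import tankvision as tv
from tankvision.neuro_forward import (ArenaSpec, ModelNeuron, NT_DIRECTION,
                                      TN_DIRECTION, detect_receptive_field,
                                      fit_von_mises_mixture, generate_protocol,
                                      histogram_preferred_directions,
                                      simulate_responses, tuning_indices,
                                      two_proportion_test)


@pytest.fixture(scope="module")
def arena():
    return ArenaSpec()


class TestArena:
    def test_patch_grid_arithmetic(self, arena):
        assert arena.patch_az_deg == pytest.approx(30.0)
        assert arena.patch_el_deg == pytest.approx(13.0)
        assert arena.n_patches == 36
        assert arena.patch_area_deg2 == pytest.approx(390.0)
        # smallest patch is exactly 1/36 of the mapped field
        field = ((arena.map_az_range[1] - arena.map_az_range[0])
                 * (arena.map_el_range[1] - arena.map_el_range[0]))
        assert arena.patch_area_deg2 == pytest.approx(field / 36)

    def test_small_rf_threshold_is_three_patches(self, arena):
        assert arena.small_rf_threshold_deg2 == pytest.approx(1170.0)


class TestProtocol:
    def test_direction_tuning_has_eight_whole_field_phases(self, arena):
        phases = generate_protocol(arena, "direction_tuning")
        assert len(phases) == 8
        assert sorted(p.direction for p in phases) == [45.0 * k for k in range(8)]
        assert all(p.kind == "whole_field" for p in phases)

    def test_rf_mapping_smallest_tier(self, arena):
        phases = generate_protocol(arena, "rf_mapping")
        smallest = [p for p in phases if p.tier == (6, 6)]
        assert len(smallest) == 36 * 2  # TN and NT motion per patch
        for p in smallest:
            assert p.area_deg2 == pytest.approx(390.0)
        dirs = {p.direction for p in smallest}
        assert dirs == {TN_DIRECTION, NT_DIRECTION}

    def test_tiers_bisect_down_from_whole_field(self, arena):
        phases = generate_protocol(arena, "rf_mapping")
        whole = [p for p in phases if p.tier == (1, 1)]
        assert len(whole) == 2
        assert whole[0].area_deg2 == pytest.approx(180.0 * 78.0)

    def test_shuffle_is_seed_deterministic(self, arena):
        a = generate_protocol(arena, "rf_mapping", seed=7, shuffle=True)
        b = generate_protocol(arena, "rf_mapping", seed=7, shuffle=True)
        c = generate_protocol(arena, "rf_mapping", seed=8, shuffle=True)
        assert a == b and a != c

    def test_unknown_mode_rejected(self, arena):
        with pytest.raises(ValueError):
            generate_protocol(arena, "orientation_mapping")


class TestSimulateResponses:
    def test_seed_required_with_noise(self, arena, neuro_pano_bulb_full):
        neurons = [ModelNeuron(rf_center=(90.0, 0.0))]
        protocol = generate_protocol(arena, "direction_tuning")
        with pytest.raises(ValueError):
            simulate_responses(neurons, protocol, neuro_pano_bulb_full,
                               noise_sd=0.01, seed=None)

    def test_identical_seeds_are_bit_identical(self, arena, neuro_pano_bulb_full):
        neurons = tv.generate_fixture_population(20, seed=3)
        protocol = generate_protocol(arena, "rf_mapping")
        a = simulate_responses(neurons, protocol, neuro_pano_bulb_full, seed=11)
        b = simulate_responses(neurons, protocol, neuro_pano_bulb_full, seed=11)
        assert np.array_equal(a.raw, b.raw) and np.array_equal(a.z, b.z)

    def test_neuron_outside_stimulus_stays_at_baseline(self, arena,
                                                       neuro_pano_bulb_full):
        """An RF that no optical path connects to a patch stays at baseline.

        (A contralateral RF at the equator would still be driven by the ~4%
        far-wall reflection, so the probe sits below the stimulated band.)
        """
        neurons = [ModelNeuron(rf_center=(90.0, -55.0), preferred_direction=0.0)]
        protocol = generate_protocol(arena, "rf_mapping")
        rec = simulate_responses(neurons, protocol, neuro_pano_bulb_full,
                                 noise_sd=0.01, seed=5)
        assert np.all(np.abs(rec.raw[0] - neurons[0].baseline) < 0.05)


class TestRFDetection:
    def _record(self, arena, patch_drives, seed=0):
        """Synthetic rf_mapping record with prescribed smallest-patch drives."""
        protocol = generate_protocol(arena, "rf_mapping")
        raw = np.full((1, len(protocol)), 0.05)
        for j, ph in enumerate(protocol):
            if ph.tier == (6, 6) and ph.patch_index in patch_drives:
                raw[0, j] = 0.05 + patch_drives[ph.patch_index]
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0, 0.005, raw.shape)
        z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
        from tankvision.neuro_forward import ResponseRecord
        return ResponseRecord(z, raw, protocol, [None], seed, "rf_mapping")

    def test_two_adjacent_patches_form_one_small_rf(self, arena):
        rec = self._record(arena, {(2, 3): 1.0, (3, 3): 0.9})
        rf = detect_receptive_field(rec, arena=arena)[0]
        assert rf.n_components == 1 and not rf.bipartite
        assert rf.area_deg2 == pytest.approx(780.0)  # 2 x 30 x 13
        assert rf.small_rf

    def test_two_disjoint_patches_are_bipartite_and_oriented(self, arena):
        # same column, separated rows: vertically aligned pair
        rec = self._record(arena, {(2, 1): 1.0, (2, 4): 1.0})
        rf = detect_receptive_field(rec, arena=arena)[0]
        assert rf.bipartite and rf.n_components == 2
        ori = rf.pair_orientation % 180.0
        assert min(ori, 180.0 - ori) < 1.0  # vertical
        rec = self._record(arena, {(0, 2): 1.0, (4, 2): 1.0})
        rf = detect_receptive_field(rec, arena=arena)[0]
        ori = rf.pair_orientation % 180.0
        assert abs(ori - 90.0) < 1.0  # horizontal

    def test_unresponsive_neuron_is_not_mapped(self, arena):
        rec = self._record(arena, {})  # noise only
        rf = detect_receptive_field(rec, arena=arena)[0]
        assert rf.n_components == 0 and not rf.bipartite

    def test_rejects_direction_tuning_records(self, arena,
                                              neuro_pano_bulb_full):
        neurons = [ModelNeuron(rf_center=(90.0, 0.0))]
        protocol = generate_protocol(arena, "direction_tuning")
        rec = simulate_responses(neurons, protocol, neuro_pano_bulb_full, seed=1)
        with pytest.raises(ValueError):
            detect_receptive_field(rec, arena=arena)


class TestTuningIndices:
    def test_single_direction_response_is_fully_selective(self):
        r = np.zeros(8)
        r[2] = 1.0
        ti = tuning_indices(r)
        assert ti.dsi == pytest.approx(1.0)
        assert ti.preferred_direction == pytest.approx(90.0)

    def test_uniform_responses_are_unselective(self):
        ti = tuning_indices(np.ones(8))
        assert ti.dsi == pytest.approx(0.0)
        assert ti.osi == pytest.approx(0.0, abs=1e-12)

    def test_rectified_cosine_has_unit_dsi(self):
        theta = np.arange(8) * 45.0
        r = np.clip(np.cos(np.radians(theta - 90.0)), 0.0, None)
        ti = tuning_indices(r)
        assert ti.dsi == pytest.approx(1.0)  # null response is zero
        assert ti.preferred_direction == pytest.approx(90.0)

    def test_all_zero_curve_is_flagged(self):
        ti = tuning_indices(np.zeros(8))
        assert not ti.defined

    def test_vector_method_is_bounded(self):
        r = np.clip(np.cos(np.radians(np.arange(8) * 45.0)), 0, None)
        ti = tuning_indices(r, method="vector")
        assert 0.0 < ti.dsi <= 1.0
        with pytest.raises(ValueError):
            tuning_indices(r, method="banana")


class TestVonMisesMixture:
    def test_two_component_recovery(self, rng):
        """Means of a two-peak sample (80/292 deg, kappa 8) recover within 5 deg."""
        a = np.degrees(rng.vonmises(np.radians(80.0), 8.0, 250)) % 360
        b = np.degrees(rng.vonmises(np.radians(292.0), 8.0, 250)) % 360
        centers, counts = histogram_preferred_directions(np.concatenate([a, b]))
        fit = fit_von_mises_mixture(centers, counts, k=2)
        assert abs(fit.means[0] - 80.0) < 5.0
        assert abs(fit.means[1] - 292.0) < 5.0

    def test_mean_bias_small_at_large_n(self, rng):
        a = np.degrees(rng.vonmises(np.radians(80.0), 8.0, 1000)) % 360
        b = np.degrees(rng.vonmises(np.radians(292.0), 8.0, 1000)) % 360
        centers, counts = histogram_preferred_directions(np.concatenate([a, b]))
        fit = fit_von_mises_mixture(centers, counts, k=2)
        assert abs(fit.means[0] - 80.0) < 2.0
        assert abs(fit.means[1] - 292.0) < 2.0

    def test_single_peak_lands_in_its_bin(self):
        centers, counts = histogram_preferred_directions([100.0] * 40)
        fit = fit_von_mises_mixture(centers, counts, k=1)
        assert abs(fit.means[0] - 105.0) <= 30.0  # within the bin width

    def test_uniform_histogram_splits_evenly(self):
        centers = np.arange(15.0, 360.0, 30.0)
        fit = fit_von_mises_mixture(centers, np.full(12, 10.0), k=4)
        assert fit.weights.max() / fit.weights.min() < 2.0

    def test_weights_sum_to_histogram_mass(self, rng):
        a = np.degrees(rng.vonmises(0.0, 4.0, 300)) % 360
        centers, counts = histogram_preferred_directions(a)
        fit = fit_von_mises_mixture(centers, counts, k=2)
        assert fit.weights.sum() == pytest.approx(counts.sum())
        assert np.all(fit.weights >= 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_von_mises_mixture([10.0], [1.0], k=3)
        with pytest.raises(ValueError):
            fit_von_mises_mixture([], [], k=1)


class TestTwoProportionTest:
    def test_reported_imbalance_is_highly_significant(self):
        # 109 temporal-nasal vs 44 nasal-temporal direction-selective cells
        z, p = two_proportion_test(109, 44)
        assert p < 1e-5
        assert z > 0

    def test_balanced_counts(self):
        z, p = two_proportion_test(50, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(40, 30), (60, 35), (109, 44), (80, 50)])
    def test_agrees_with_exact_binomial(self, n1, n2):
        _, p = two_proportion_test(n1, n2)
        exact = stats.binomtest(n1, n1 + n2, 0.5).pvalue
        assert 0.5 < p / exact < 2.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0)
        with pytest.raises(ValueError):
            two_proportion_test(-1, 5)
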