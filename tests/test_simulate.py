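"""Physics and bookkeeping of the synthetic drying-experiment generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncrus.errors import ConfigurationError, InvalidAnnotationError
from ncrus.simulate import (
    AIR_IMPEDANCE,
    BAND_DEFS,
    LayerState,
    NoiseConfig,
    compute_rwc,
    first_resonance_frequency,
    plate_transmission,
    read_dataset_csv,
    simulate_dataset,
    simulate_measurement,
    traits_at_rwc,
    write_dataset_csv,
)
from .conftest import ZERO_NOISE, random_layer_state


class TestComputeRwc:
    @pytest.mark.parametrize(
        "fm, tm, dm, expected",
        [
            (3.0, 3.0, 1.0, 1.0),   # fully turgid leaf saturates at 1
            (1.0, 3.0, 1.0, 0.0),   # oven-dry leaf is 0
            (2.0, 3.0, 1.0, 0.5),   # linear in fresh mass
        ],
    )
    def test_reference_points(self, fm, tm, dm, expected):
        assert compute_rwc(fm, tm, dm) == pytest.approx(expected, abs=1e-15)

    def test_inconsistent_masses_rejected(self):
        with pytest.raises(InvalidAnnotationError):
            compute_rwc(1.0, 1.0, 2.0)

    def test_artifact_range_warns_but_returns(self):
        with pytest.warns(UserWarning):
            value = compute_rwc(3.5, 3.0, 1.0)
        assert value == pytest.approx(1.25)  # unclamped


class TestPlateTransmission:
    def test_matched_lossless_plate_is_transparent(self):
        state = LayerState(thickness=300e-6, speed=300.0,
                           density=AIR_IMPEDANCE / 300.0, attenuation=0.0, rwc=1.0)
        f = np.linspace(0.1e6, 1.6e6, 256)
        mag, _ = plate_transmission(f, state)
        assert np.allclose(mag, 0.0, atol=1e-9)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_lossless_resonance_transmits_fully(self, n):
        state = LayerState(thickness=300e-6, speed=300.0, density=800.0,
                           attenuation=0.0, rwc=0.9)
        f_n = n * state.speed / (2 * state.thickness)
        mag, _ = plate_transmission(np.array([f_n / 2, f_n]), state)
        assert mag[1] == pytest.approx(0.0, abs=1e-9)

    def test_peak_sits_at_first_thickness_resonance(self):
        # brute-force scan of the closed form on a 100 Hz grid
        state = LayerState(thickness=300e-6, speed=300.0, density=800.0,
                           attenuation=500.0, rwc=0.9)
        f = np.arange(0.1e6, 1.6e6, 100.0)
        mag, _ = plate_transmission(f, state)
        f_peak = f[np.argmax(mag)]
        assert abs(f_peak - 500e3) <= 1000.0  # within 10 grid steps of c/(2h)

    def test_energy_bound_on_randomized_states(self):
        rng = np.random.default_rng(1234)
        f = np.linspace(0.1e6, 1.6e6, 64)
        for _ in range(500):
            mag, _ = plate_transmission(f, random_layer_state(rng))
            assert mag.max() <= 1e-9

    def test_invalid_impedance_rejected(self):
        state = LayerState(thickness=300e-6, speed=300.0, density=800.0,
                           attenuation=0.0, rwc=1.0)
        with pytest.raises(ConfigurationError):
            plate_transmission(np.array([1e5, 2e5]), state, medium_impedance=0.0)


class TestTraitsAtRwc:
    def test_endpoints_recovered_exactly(self, toy_traits):
        turgid = traits_at_rwc(toy_traits, 1.0)
        assert turgid.thickness == toy_traits.thickness_turgid
        assert turgid.speed == toy_traits.speed_turgid
        assert turgid.attenuation == toy_traits.attenuation_turgid
        nearly_dry = traits_at_rwc(toy_traits, 1e-9)
        assert nearly_dry.thickness == pytest.approx(toy_traits.thickness_dry, rel=1e-6)
        assert nearly_dry.speed == pytest.approx(toy_traits.speed_dry, rel=1e-6)

    def test_first_resonance_strictly_monotone_in_rwc(self, toy_traits):
        grid = np.linspace(0.5, 1.0, 26)
        f1 = [first_resonance_frequency(traits_at_rwc(toy_traits, r)) for r in grid]
        assert np.all(np.diff(f1) < 0)  # drying shifts the resonance up

    @given(rwc=st.floats(min_value=1.021, max_value=10.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_out_of_range_rwc_rejected(self, toy_traits, rwc):
        with pytest.raises(InvalidAnnotationError):
            traits_at_rwc(toy_traits, rwc)


class TestSimulateMeasurement:
    def test_zero_noise_matches_forward_model(self, toy_traits):
        bands = simulate_measurement(toy_traits, 0.8, ZERO_NOISE)
        state = traits_at_rwc(toy_traits, 0.8)
        for band in bands:
            mag, ph = plate_transmission(band.frequencies, state)
            assert np.array_equal(band.magnitude_db, mag)
            assert np.array_equal(band.phase_rad, ph)

    def test_band_grids_span_nominal_ranges(self, toy_traits):
        bands = simulate_measurement(toy_traits, 0.9, ZERO_NOISE)
        for band in bands:
            f_min, f_max, n = BAND_DEFS[band.band_id]
            assert band.frequencies.size == n
            assert band.frequencies[0] == pytest.approx(f_min)
            assert band.frequencies[-1] == pytest.approx(f_max)

    def test_same_seed_reproduces_spectra(self, toy_traits):
        a = simulate_measurement(toy_traits, 0.8, None, np.random.default_rng(5))
        b = simulate_measurement(toy_traits, 0.8, None, np.random.default_rng(5))
        for ba, bb in zip(a, b):
            assert np.array_equal(ba.magnitude_db, bb.magnitude_db)
            assert np.array_equal(ba.phase_rad, bb.phase_rad)

    def test_noise_level_matches_configuration(self, toy_traits):
        # Monte-Carlo estimate of the per-point magnitude noise std
        cfg = NoiseConfig()
        reps = np.stack(
            [
                simulate_measurement(toy_traits, 0.9, cfg, np.random.default_rng(900 + i))[1]
                .magnitude_db
                for i in range(100)
            ]
        )
        interior = slice(20, 100)  # away from the inflated band edges
        stds = reps[:, interior].std(axis=0)
        assert abs(np.median(stds) - cfg.magnitude_db_std) < 0.2 * cfg.magnitude_db_std


class TestSimulateDataset:
    def test_default_study_shape(self):
        records = simulate_dataset(seed=3)
        assert len(records) == 31
        assert sum(len(r.measurements) for r in records) == 280

    def test_rwc_round_trips_through_masses(self, small_records):
        for rec in small_records:
            for m in rec.measurements:
                assert compute_rwc(m.fresh_mass, rec.turgid_mass, rec.dry_mass) == pytest.approx(
                    m.rwc, abs=1e-12
                )

    def test_drying_order_descending(self, small_records):
        for rec in small_records:
            rwcs = [m.rwc for m in rec.measurements]
            assert rwcs == sorted(rwcs, reverse=True)

    def test_mixture_mass_above_tlp(self):
        from ncrus.simulate import _draw_rwc

        rng = np.random.default_rng(77)
        draws = _draw_rwc(rng, 10_000, (0.63, 0.52, 0.88, 1.0))
        frac = np.mean((draws >= 0.88) & (draws <= 1.0))
        assert 0.60 <= frac <= 0.66

    def test_same_seed_identical_datasets(self, tmp_path):
        a = simulate_dataset(n_leaves=3, total_measurements=27, seed=9)
        b = simulate_dataset(n_leaves=3, total_measurements=27, seed=9)
        write_dataset_csv(a, tmp_path / "a")
        write_dataset_csv(b, tmp_path / "b")
        assert (tmp_path / "a" / "spectra.csv").read_text() == (
            tmp_path / "b" / "spectra.csv"
        ).read_text()

    def test_infeasible_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_dataset(n_leaves=2, measurements_per_leaf_range=(2, 3),
                             total_measurements=100, seed=0)

    def test_csv_round_trip(self, tmp_path, small_records):
        write_dataset_csv(small_records, tmp_path / "ds")
        back = read_dataset_csv(tmp_path / "ds")
        assert len(back) == len(small_records)
        orig = small_records[0].measurements[0]
        loaded = back[0].measurements[0]
        assert loaded.rwc == pytest.approx(orig.rwc, abs=1e-12)
        for b_orig, b_load in zip(orig.bands, loaded.bands):
            assert b_orig.band_id == b_load.band_id
            np.testing.assert_allclose(b_load.magnitude_db, b_orig.magnitude_db, rtol=1e-12)
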