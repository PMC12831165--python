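import numpy as np
import pandas as pd
import pytest

from quantalci.dose_response import ec50, fit_hill
from quantalci.single_complex_model import SingleComplexParams
from quantalci.synthetic_data import (
    MeltCurveSpec,
    SyntheticCohortSpec,
    gen_melt_curve,
    gen_single_spot_tracks,
    gen_spot_count_timecourses,
    pulse_shape,
)


class TestPulseShape:
    def test_peaks_at_peak_time_with_unit_height(self):
        t = np.linspace(0, 120, 1201)
        s = pulse_shape(t, 15.0, 90.0)
        assert t[np.argmax(s)] == pytest.approx(15.0, abs=0.1)
        assert s.max() == pytest.approx(1.0, abs=1e-9)

    def test_decayed_by_adaptation_time(self):
        s = pulse_shape(np.array([90.0]), 15.0, 90.0)
        assert s[0] == pytest.approx(0.05, rel=1e-9)

    def test_tight_peak_to_adaptation_ratio_supported(self):
        s = pulse_shape(np.array([60.0]), 30.0, 60.0)
        assert s[0] == pytest.approx(0.05, rel=1e-9)


class TestSpotCountCohort:
    def test_noiseless_saturation_peak(self):
        spec = SyntheticCohortSpec(noise_cv=0.0, n_cells_per_dose=1,
                                   doses=(1e6,))
        df = gen_spot_count_timecourses(spec)
        peak_row = df.loc[df["count"].idxmax()]
        assert peak_row["count"] == pytest.approx(spec.max_amplitude, rel=1e-4)
        assert peak_row["time"] == pytest.approx(spec.peak_time_mean)

    def test_noiseless_hill_midpoint(self):
        spec = SyntheticCohortSpec(noise_cv=0.0, n_cells_per_dose=1,
                                   relative_affinity=2.0,
                                   doses=(0.5,))  # = reference_ec50 / affinity
        df = gen_spot_count_timecourses(spec)
        assert df["count"].max() == pytest.approx(spec.max_amplitude / 2.0)

    def test_same_seed_byte_identical(self):
        spec = SyntheticCohortSpec(seed=7, n_cells_per_dose=5)
        a = gen_spot_count_timecourses(spec).to_csv()
        b = gen_spot_count_timecourses(spec).to_csv()
        assert a == b

    def test_different_seeds_differ(self):
        a = gen_spot_count_timecourses(SyntheticCohortSpec(seed=1, n_cells_per_dose=5))
        b = gen_spot_count_timecourses(SyntheticCohortSpec(seed=2, n_cells_per_dose=5))
        assert not np.allclose(a["count"], b["count"])

    def test_stochastic_counts_nonnegative_integers(self):
        df = gen_spot_count_timecourses(SyntheticCohortSpec(noise_cv=0.4,
                                                            n_cells_per_dose=5))
        counts = df["count"].to_numpy()
        assert np.all(counts >= 0)
        assert np.all(counts == np.round(counts))

    def test_hill_round_trip_recovers_effective_ec50(self):
        """Noiseless peak-vs-dose refit recovers reference_ec50/affinity to <1%."""
        for aff in (1.0, 0.1):
            spec = SyntheticCohortSpec(noise_cv=0.0, n_cells_per_dose=1,
                                       relative_affinity=aff)
            df = gen_spot_count_timecourses(spec)
            peaks = df.groupby("dose")["count"].max()
            fit = fit_hill(peaks.index.to_numpy(), peaks.to_numpy())
            assert ec50(fit) == pytest.approx(spec.effective_ec50, rel=0.01)

    def test_amplitude_jitter_has_requested_cv(self):
        spec = SyntheticCohortSpec(noise_cv=0.3, n_cells_per_dose=400,
                                   doses=(1e4,), seed=3)
        df = gen_spot_count_timecourses(spec)
        aucs = df.groupby("cell_id")["count"].sum()
        # Poisson adds variability on top of the lognormal factor, so the
        # integrated-count CV should bracket the configured amplitude CV
        assert 0.2 < aucs.std() / aucs.mean() < 0.45

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(doses=(0.0, 1.0))
        with pytest.raises(ValueError):
            SyntheticCohortSpec(relative_affinity=-1.0)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(noise_cv=-0.1)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(duration=30.0)


class TestSingleSpotTracks:
    def test_zero_growth_tracks_all_zero(self):
        tracks = gen_single_spot_tracks(SingleComplexParams(kgrowth=0.0, t_end=5.0),
                                        n_tracks=3)
        assert len(tracks) == 3
        for tr in tracks:
            assert np.all(tr.intensity == 0.0)

    def test_empty_request(self):
        assert gen_single_spot_tracks(SingleComplexParams(), 0) == []

    def test_ten_second_framing_and_reproducibility(self):
        p = SingleComplexParams(t_end=5.0)
        a = gen_single_spot_tracks(p, 2, seed=5)
        b = gen_single_spot_tracks(p, 2, seed=5)
        assert np.allclose(np.diff(a[0].times), 1.0 / 6.0)
        np.testing.assert_array_equal(a[1].intensity, b[1].intensity)


class TestMeltCurveGen:
    def test_noiseless_max_derivative_at_midpoint(self):
        curve = gen_melt_curve(MeltCurveSpec(midpoint=60.0, noise_sd=0.0))
        i = np.argmax(np.gradient(curve.fluorescence, curve.temperatures))
        assert abs(curve.temperatures[i] - 60.0) <= 0.25  # nearest grid point

    def test_noiseless_monotone(self):
        curve = gen_melt_curve(MeltCurveSpec(noise_sd=0.0))
        assert np.all(np.diff(curve.fluorescence) >= 0)

    def test_seeds_differ_only_in_noise(self):
        clean = gen_melt_curve(MeltCurveSpec(noise_sd=0.0))
        a = gen_melt_curve(MeltCurveSpec(noise_sd=0.02, seed=1))
        b = gen_melt_curve(MeltCurveSpec(noise_sd=0.02, seed=2))
        assert not np.allclose(a.fluorescence, b.fluorescence)
        assert np.std(a.fluorescence - clean.fluorescence) < 0.05
        assert np.std(b.fluorescence - clean.fluorescence) < 0.05

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            MeltCurveSpec(grid=(3.0, 2.0, 1.0))
        with pytest.raises(ValueError):
            MeltCurveSpec(midpoint=10.0)
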