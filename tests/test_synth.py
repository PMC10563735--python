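"""Generator tests: trajectory statistics, sensor response shapes, spectra."""

import numpy as np
import pytest

from kiwifusion.evaluation import one_way_anova
from kiwifusion.synth import (
    ATTRIBUTES,
    AttributeTrajectory,
    ExperimentDesign,
    SensorPanel,
    SpectralModelParams,
    TrajectoryParams,
    generate_enose_recording,
    generate_experiment,
    generate_quality_trajectories,
    generate_reflectance_spectrum,
    logistic_mean,
)


class TestQualityTrajectories:
    def test_zero_residual_sd_makes_fruits_of_a_day_identical(self, default_design):
        table = generate_quality_trajectories(
            default_design, TrajectoryParams().noise_free(), seed=3)
        per_day_spread = table.groupby("day")[list(ATTRIBUTES)].std()
        assert (per_day_spread.to_numpy() == 0).all()

    def test_day_means_move_in_the_ripening_directions(self, default_design):
        # the model's day-mean curve is strictly monotone; sample means with
        # noise can wiggle inside the late plateau, so check the noise-free curve
        table = generate_quality_trajectories(
            default_design, TrajectoryParams().noise_free(), seed=5)
        means = table.groupby("day")[list(ATTRIBUTES)].mean()
        assert (means["firmness"].diff().dropna() < 0).all()
        assert (means["ssc"].diff().dropna() > 0).all()
        assert (means["ta"].diff().dropna() < 0).all()

    def test_anova_reproduces_reference_magnitudes(self, default_design):
        """Between-day SS ~ 470.9 and error MS ~ 0.042 for firmness (default
        calibration), averaged over seeds."""
        ss, ms = [], []
        for seed in range(5):
            table = generate_quality_trajectories(default_design, TrajectoryParams(), seed=seed)
            t = one_way_anova(table["firmness"], table["day"])
            ss.append(t.ss_time)
            ms.append(t.ms_error)
        assert abs(np.mean(ss) - 470.862) / 470.862 < 0.25
        assert abs(np.mean(ms) - 0.042) / 0.042 < 0.25

    def test_expected_error_mean_square_is_residual_variance(self, default_design):
        # closed form: E(MS_error) = sigma^2 = 0.206^2 ~ 0.0424
        sigma = TrajectoryParams().firmness.residual_sd
        assert sigma**2 == pytest.approx(0.042436)
        ms = [
            one_way_anova(
                generate_quality_trajectories(default_design, TrajectoryParams(), seed=s)
                ["firmness"],
                generate_quality_trajectories(default_design, TrajectoryParams(), seed=s)
                ["day"]).ms_error
            for s in range(6)
        ]
        assert np.mean(ms) == pytest.approx(sigma**2, rel=0.25)

    def test_day_effect_significant_across_many_seeds(self, default_design):
        for seed in range(20):
            table = generate_quality_trajectories(default_design, TrajectoryParams(), seed=seed)
            for attr in ATTRIBUTES:
                assert one_way_anova(table[attr], table["day"]).p < 0.01

    def test_negative_residual_sd_rejected(self):
        with pytest.raises(ValueError):
            AttributeTrajectory(8.0, 2.0, residual_sd=-0.1)

    def test_wrong_trend_directions_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryParams(firmness=AttributeTrajectory(2.0, 8.0))

    def test_values_driven_negative_are_clipped_with_warning(self):
        design = ExperimentDesign(day_offsets=(0, 20), fruits_per_day=10)
        params = TrajectoryParams(
            ta=AttributeTrajectory(0.05, 0.01, residual_sd=0.2))
        with pytest.warns(UserWarning, match="clipped"):
            table = generate_quality_trajectories(design, params, seed=0)
        assert (table["ta"] > 0).all()


class TestEnoseRecording:
    def test_zero_intensity_zero_noise_stays_at_baseline(self):
        panel = SensorPanel(noise_sd=0.0)
        rec = generate_enose_recording(0.0, panel, seed=0)
        assert np.allclose(rec.response, np.asarray(panel.baseline)[:, None])

    def test_sample_count_matches_protocol(self):
        rec = generate_enose_recording(1.0, rate=1.0, seed=0)
        assert rec.response.shape == (13, 311)
        rec2 = generate_enose_recording(1.0, rate=2.0, seed=0)
        assert rec2.response.shape == (13, 621)

    def test_response_monotone_in_intensity(self):
        panel = SensorPanel(noise_sd=0.0)
        lo = generate_enose_recording(1.0, panel, seed=0)
        hi = generate_enose_recording(2.0, panel, seed=0)
        assert (hi.response.max(axis=1) > lo.response.max(axis=1)).all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_enose_recording(1.0, rate=0.0)

    def test_hydrocarbon_sensors_have_largest_gains(self):
        panel = SensorPanel()
        gains = dict(zip(panel.sensor_ids, panel.gain))
        top3 = sorted(gains, key=gains.get)[-3:]
        assert set(top3) == {"TGS822", "TGS2610", "MQ9"}


class TestReflectanceSpectra:
    ATTRS = {"firmness": 5.0, "ssc": 9.5, "ta": 1.0, "day": 8.0}

    def _noise_free_params(self):
        return SpectralModelParams(noise_sd=0.0, mismatch_sd=(0.0, 0.0, 0.0),
                                   day_mismatch_sd=0.0)

    def test_identical_attributes_give_identical_spectra_without_noise(self):
        params = self._noise_free_params()
        a = generate_reflectance_spectrum(self.ATTRS, params, seed=1)
        b = generate_reflectance_spectrum(self.ATTRS, params, seed=99)
        np.testing.assert_array_equal(a.values, b.values)

    def test_planted_band_linear_in_firmness(self):
        """Noise-free: the reflectance at a firmness-coupled center regresses
        on firmness with R^2 = 1."""
        params = self._noise_free_params()
        center = next(b for b in params.planted if b.attribute == "firmness")
        idx = int(np.argmin(np.abs(params.grid.wavelengths - center.center_nm)))
        firmness = np.linspace(2.6, 7.8, 15)
        refl = []
        for f in firmness:
            rec = dict(self.ATTRS, firmness=f)
            refl.append(generate_reflectance_spectrum(rec, params, seed=0).values[idx])
        r = np.corrcoef(firmness, refl)[0, 1]
        assert r**2 > 0.999999

    def test_reflectance_in_unit_interval_and_band_count(self):
        spec = generate_reflectance_spectrum(self.ATTRS, seed=4)
        assert spec.values.shape == (568,)
        assert spec.values.min() >= 0 and spec.values.max() <= 1

    def test_incomplete_record_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            generate_reflectance_spectrum({"firmness": 5.0}, seed=0)

    def test_planted_centers_inside_working_range(self):
        params = SpectralModelParams()
        centers = params.planted_centers()
        assert (centers >= 450).all() and (centers <= 900).all()


class TestExperimentBundle:
    def test_default_design_yields_120_fruits(self, default_design):
        assert default_design.n_samples == 120

    def test_small_design_counts(self):
        assert ExperimentDesign(day_offsets=(0, 5, 20), fruits_per_day=2).n_samples == 6

    def test_one_recording_and_spectrum_per_fruit(self, small_bundle):
        n = len(small_bundle.attributes)
        assert len(small_bundle.recordings) == n
        assert small_bundle.spectra.shape == (n, 568)

    def test_same_seed_gives_byte_identical_serialization(self, small_design, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_experiment(small_design, seed=42).save(d1)
        generate_experiment(small_design, seed=42).save(d2)
        for rel in ["attributes.csv", "spectra.csv"]:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        recs1 = sorted((d1 / "enose").iterdir())
        recs2 = sorted((d2 / "enose").iterdir())
        assert [p.name for p in recs1] == [p.name for p in recs2]
        assert all(a.read_bytes() == b.read_bytes() for a, b in zip(recs1, recs2))

    def test_different_seeds_differ(self, small_design):
        a = generate_experiment(small_design, seed=1)
        b = generate_experiment(small_design, seed=2)
        assert not np.allclose(a.spectra.to_numpy(), b.spectra.to_numpy())


def test_logistic_mean_plateaus_late():
    traj = AttributeTrajectory(7.8, 2.6)
    early = logistic_mean(2, traj) - logistic_mean(5, traj)
    late = logistic_mean(17, traj) - logistic_mean(20, traj)
    assert abs(late) < abs(early) / 10
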