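import dataclasses

import numpy as np
import pytest

from pcnir import (CONSTITUENTS, PretreatmentSpec, SyntheticConfig,
                   ValidationError, apply_pretreatment, component_profiles,
                   evaluate_regression, fit_plsr, inject_outliers,
                   kennard_stone_split, scaled_config, simulate_dataset)

PSC_MEANS = {"YN": 6.81, "XQ": 5.67, "DBM": 4.59}


def quiet(config: SyntheticConfig) -> SyntheticConfig:
    return dataclasses.replace(
        config, noise_sd=0.0, baseline_sd=0.0, scatter_slope_sd=0.0,
        scatter_offset_sd=0.0, region_effect_amplitude=0.0)


class TestProfiles:
    def test_single_band_peaks_at_center(self):
        cfg = scaled_config(band_centers=(6000.0,), band_widths=(150.0,),
                            component_loadings=np.array([[1.0], [0.5],
                                                         [0.2], [0.1]]))
        prof = component_profiles(cfg)
        for row in prof:
            assert cfg.axis[np.argmax(row)] == pytest.approx(6000.0, abs=40)

    def test_zero_loadings_give_zero_profiles(self):
        cfg = scaled_config(component_loadings=np.zeros((4, 5)))
        assert not component_profiles(cfg).any()

    def test_mean_mixture_peaks_near_5180(self):
        cfg = SyntheticConfig(seed=1)
        _, table = simulate_dataset(cfg)
        mean_conc = table.data[list(CONSTITUENTS)].mean().to_numpy()
        mixture = mean_conc @ component_profiles(cfg)
        assert abs(cfg.axis[np.argmax(mixture)] - 5180.0) <= 50.0

    def test_invalid_band_width_rejected(self):
        with pytest.raises(ValidationError, match="width"):
            scaled_config(band_widths=(120.0, 150.0, 100.0, -1.0, 110.0))


class TestSimulate:
    def test_deterministic_limit_is_exact_mixture(self):
        cfg = quiet(scaled_config(seed=5))
        spectra, table = simulate_dataset(cfg)
        conc = table.data[list(CONSTITUENTS)].to_numpy()
        expected = conc @ component_profiles(cfg)
        np.testing.assert_allclose(spectra.absorbance, expected, atol=1e-12)

    def test_beer_lambert_superposition(self):
        # doubling every concentration doubles the noiseless spectrum
        cfg = quiet(scaled_config(seed=6))
        spectra, table = simulate_dataset(cfg)
        conc = table.data[list(CONSTITUENTS)].to_numpy()
        prof = component_profiles(cfg)
        np.testing.assert_allclose((2 * conc) @ prof, 2 * (conc @ prof),
                                   atol=1e-12)

    def test_same_seed_bitwise_identical(self):
        a_sp, a_tab = simulate_dataset(SyntheticConfig(seed=11))
        b_sp, b_tab = simulate_dataset(SyntheticConfig(seed=11))
        np.testing.assert_array_equal(a_sp.absorbance, b_sp.absorbance)
        assert a_tab.data.equals(b_tab.data)

    def test_region_counts_exact(self):
        _, table = simulate_dataset(SyntheticConfig(seed=2))
        counts = table.data["region"].value_counts()
        assert counts["YN"] == 58 and counts["XQ"] == 28 and counts["DBM"] == 52

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_regional_psc_means_match_published_summaries(self, seed):
        """Sample means land within 2 SE of the published regional means."""
        _, table = simulate_dataset(SyntheticConfig(seed=seed))
        for region, target in PSC_MEANS.items():
            v = table.data.loc[table.data.region == region, "psc"]
            se = v.std(ddof=1) / np.sqrt(len(v))
            assert abs(v.mean() - target) <= 2 * se

    def test_lognormal_option_is_right_skewed_within_ranges(self):
        cfg = dataclasses.replace(SyntheticConfig(seed=4),
                                  concentration_distribution="lognormal")
        _, table = simulate_dataset(cfg)
        v = table.data.loc[table.data.region == "YN", "psc"]
        lo, hi = cfg.region_params["psc"]["YN"][2:]
        assert v.min() >= lo and v.max() <= hi
        assert v.skew() > 0  # right skew like the published ranges
        with pytest.raises(ValidationError, match="distribution"):
            dataclasses.replace(cfg, concentration_distribution="gamma")

    def test_concentrations_respect_published_ranges(self):
        cfg = SyntheticConfig(seed=3)
        _, table = simulate_dataset(cfg)
        for name in CONSTITUENTS:
            for region, (_, _, lo, hi) in cfg.region_params[name].items():
                v = table.data.loc[table.data.region == region, name]
                assert v.min() >= lo - 1e-12 and v.max() <= hi + 1e-12


class TestInjectOutliers:
    def test_perturbed_rows_are_most_distant(self, small_dataset):
        spectra, _ = small_dataset
        bad = ["S2", "S9", "S17"]
        out = inject_outliers(spectra, bad, magnitude=10.0, seed=0)
        dist = np.linalg.norm(out.absorbance - out.absorbance.mean(axis=0),
                              axis=1)
        idx = [out.sample_ids.index(s) for s in bad]
        clean = np.delete(dist, idx)
        assert dist[idx].min() > clean.max()

    def test_empty_ids_is_identity(self, small_dataset):
        spectra, _ = small_dataset
        out = inject_outliers(spectra, [], magnitude=5.0, seed=0)
        np.testing.assert_array_equal(out.absorbance, spectra.absorbance)

    def test_unlisted_rows_untouched(self, small_dataset):
        spectra, _ = small_dataset
        out = inject_outliers(spectra, ["S4"], magnitude=5.0, seed=0)
        keep = [i for i, s in enumerate(spectra.sample_ids) if s != "S4"]
        np.testing.assert_array_equal(out.absorbance[keep],
                                      spectra.absorbance[keep])
        i = spectra.sample_ids.index("S4")
        assert not np.array_equal(out.absorbance[i], spectra.absorbance[i])

    def test_unknown_id_rejected(self, small_dataset):
        spectra, _ = small_dataset
        with pytest.raises(ValidationError, match="unknown"):
            inject_outliers(spectra, ["nope"], magnitude=2.0)


class TestNoiseDegradesPrediction:
    def test_r2pre_decreases_with_noise(self):
        """Mean validation R2 falls as white noise grows (3 levels, 5 seeds)."""
        means = []
        for noise in (0.002, 0.02, 0.08):
            scores = []
            for seed in range(5):
                cfg = scaled_config(seed=seed, noise_sd=noise)
                spectra, table = simulate_dataset(cfg)
                split = kennard_stone_split(spectra, ratio=4.0)
                spec = PretreatmentSpec("SNV")
                cal, st = apply_pretreatment(
                    spectra.subset(split.calibration_ids), spec)
                val, _ = apply_pretreatment(
                    spectra.subset(split.validation_ids), spec, st)
                y = dict(zip(table.sample_ids, table.response("psc")))
                y_cal = np.array([y[s] for s in split.calibration_ids])
                y_val = np.array([y[s] for s in split.validation_ids])
                model = fit_plsr(cal.absorbance, y_cal, 6)
                ev = evaluate_regression(model, cal.absorbance, y_cal,
                                         val.absorbance, y_val)
                scores.append(ev.r2_pre)
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]
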