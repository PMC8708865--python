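"""Synthetic generators: determinism, closure with the detectors, and
controllable ground truth."""

import numpy as np
import pandas as pd
import pytest

from lakeso.hydrophysics import stratification_metrics
from lakeso.overlap import SPECTRAL_GROUPS, spatial_overlap
from lakeso.diversity import shannon
from lakeso.synthetic import (
    LakeScenario,
    StructuralTruth,
    default_trait_matrix,
    gen_community,
    gen_spectral_profiles,
    gen_structural_dataset,
    gen_temperature_profile,
    simulate_lake_dataset,
)


class TestTemperatureGenerator:
    def test_detector_closure_over_depth_width_grid(self, quiet_scenario):
        """Noise-free profiles give back the requested thermocline depth
        within one sensor spacing and the requested metalimnion width
        within two sensor spacings."""
        sp = quiet_scenario.sensor_spacing
        for td in (3.0, 4.25, 5.0, 6.4, 8.0):
            for mw in (1.2, 1.8, 2.5, 3.2):
                prof = gen_temperature_profile(td, mw, quiet_scenario)
                m = stratification_metrics(prof)
                assert m.stratified
                assert abs(m.thermo_depth - td) <= sp + 1e-9
                assert abs(m.meta_width - mw) <= 2 * sp + 1e-9

    def test_step_limit_width_at_grid_resolution(self, quiet_scenario):
        # a requested zero-width metalimnion collapses to a step between
        # two sensors; the detector reports at most the grid limit
        prof = gen_temperature_profile(4.25, 0.0, quiet_scenario)
        m = stratification_metrics(prof)
        assert m.meta_width <= 2 * quiet_scenario.sensor_spacing + 1e-9

    def test_deeper_inflection_detected_deeper(self, quiet_scenario):
        m4 = stratification_metrics(gen_temperature_profile(4.0, 1.5, quiet_scenario))
        m8 = stratification_metrics(gen_temperature_profile(8.0, 1.5, quiet_scenario))
        assert m8.thermo_depth > m4.thermo_depth

    def test_invalid_depth_rejected(self, quiet_scenario):
        with pytest.raises(ValueError):
            gen_temperature_profile(12.0, 1.0, quiet_scenario)


class TestSpectralGenerator:
    def test_identical_peaks_give_so_one(self, quiet_scenario):
        peaks = tuple((5.0, 1.0, 4.0) for _ in range(4))
        pset = gen_spectral_profiles(peaks, quiet_scenario)
        assert spatial_overlap(pset).so == pytest.approx(1.0, abs=0.01)

    def test_separated_narrow_peaks_give_low_so(self, quiet_scenario):
        peaks = tuple((m, 0.3, 4.0) for m in (1.0, 4.0, 7.0, 10.0))
        pset = gen_spectral_profiles(peaks, quiet_scenario)
        assert spatial_overlap(pset).so < 0.2

    def test_zero_total_group_flagged_absent(self, quiet_scenario):
        peaks = ((2.0, 1.0, 4.0), (5.0, 1.0, 4.0), (8.0, 1.0, 4.0), (5.0, 1.0, 0.0))
        pset = gen_spectral_profiles(peaks, quiet_scenario)
        res = spatial_overlap(pset)
        assert "mixed" not in res.groups_used

    def test_negative_total_rejected(self, quiet_scenario):
        peaks = ((2.0, 1.0, -1.0),) + tuple((5.0, 1.0, 4.0) for _ in range(3))
        with pytest.raises(ValueError):
            gen_spectral_profiles(peaks, quiet_scenario)

    def test_so_monotone_in_peak_spread(self, quiet_scenario):
        """Spreading the four peaks apart never increases SO."""
        prev = np.inf
        for spread in (0.0, 0.5, 1.0, 1.5, 2.5, 3.5):
            peaks = tuple(
                (5.0 + spread * k, 0.8, 4.0) for k in (-1.5, -0.5, 0.5, 1.5)
            )
            pset = gen_spectral_profiles(peaks, quiet_scenario)
            so = spatial_overlap(pset, bandwidth=0.4).so
            assert so <= prev + 1e-9
            prev = so

    def test_concentrations_non_negative_with_noise(self):
        sc = LakeScenario(noise_sd_chla=0.5, seed=3)
        peaks = tuple((m, 0.5, 2.0) for m in (2.0, 4.0, 6.0, 8.0))
        pset = gen_spectral_profiles(peaks, sc, rng=np.random.default_rng(0))
        for g in SPECTRAL_GROUPS:
            assert np.all(pset.concentrations[g] >= 0)


class TestStructuralGenerator:
    def test_same_seed_identical(self):
        t = StructuralTruth(seed=5)
        pd.testing.assert_frame_equal(gen_structural_dataset(t), gen_structural_dataset(t))

    def test_null_coefficients_give_vanishing_correlations(self):
        t = StructuralTruth(
            path_coefficients={k: 0.0 for k in StructuralTruth().path_coefficients},
            n_events=4000,
            seed=9,
        )
        df = gen_structural_dataset(t)
        corr = df.corr()
        for endo in ("Cladocera_Biom", "SO", "Diversity"):
            assert abs(corr.loc["Thermo_Depth", endo]) < 0.06
            assert abs(corr.loc["Meta_Width", endo]) < 0.06

    def test_implied_r_squared_near_study_values(self):
        r2 = StructuralTruth().implied_r_squared()
        assert r2["Cladocera_Biom"] == pytest.approx(0.22, abs=0.03)
        assert r2["SO"] == pytest.approx(0.18, abs=0.03)
        assert r2["Diversity"] == pytest.approx(0.35, abs=0.03)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            StructuralTruth(n_events=5)


class TestCommunityGenerator:
    def test_equal_expected_biomass_mean_h_near_ln4(self):
        traits = default_trait_matrix().iloc[:4]
        b = gen_community(500, trait_matrix=traits, seed=0, log_sd=0.3)
        h = np.array([shannon(row) for row in b.to_numpy()])
        assert h.mean() == pytest.approx(np.log(4), abs=0.1)

    def test_negative_driver_reduces_mixotroph_share(self):
        traits = default_trait_matrix()
        driver = np.random.default_rng(2).normal(size=1000)
        b = gen_community(
            1000, trait_matrix=traits, composition_driver=driver, driver_coef=-0.6, seed=1
        )
        mixo = (traits["mixotrophy"] == "Y").to_numpy()
        share = b.to_numpy()[:, mixo].sum(axis=1) / b.to_numpy().sum(axis=1)
        slope = np.polyfit(driver, share, 1)[0]
        assert slope < 0

    def test_single_genus_rejected(self):
        with pytest.raises(ValueError):
            gen_community(10, trait_matrix=default_trait_matrix().iloc[:1], seed=0)


class TestFullScenario:
    def test_deterministic_under_seed(self):
        sc = LakeScenario(seed=21)
        a = simulate_lake_dataset(sc)
        b = simulate_lake_dataset(sc)
        pd.testing.assert_frame_equal(a["biomass"], b["biomass"])
        for key in a["temperature"]:
            assert np.array_equal(a["temperature"][key].values, b["temperature"][key].values)

    def test_deeper_thermocline_raises_so(self, quiet_scenario):
        """The mechanistic coupling: a deepened thermocline compresses the
        group peaks and raises SO on average."""
        data = simulate_lake_dataset(quiet_scenario)
        so = {
            basin: np.mean(
                [
                    spatial_overlap(data["spectral"][(basin, d)]).so
                    for d in range(quiet_scenario.n_dates)
                ]
            )
            for basin in quiet_scenario.basins
        }
        assert so["B3"] > so["B1"]  # 8 m vs 4 m thermocline
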