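"""Phantom generator: determinism, monotone age encoding, cohorts, lesions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroage.errors import ConfigError, DomainError
from neuroage.phantom import (
    LesionSpec,
    LongitudinalMSSpec,
    PhantomSpec,
    extract_age_features,
    generate_cohort,
    generate_longitudinal_ms_cohort,
    generate_phantom,
    ms_visit_pairs,
    simulate_lesion_pair,
    structural_masks,
)
from neuroage.ms_analysis import classify_worsening


class TestGeneratePhantom:
    def test_deterministic_given_all_inputs(self, spec32):
        a = generate_phantom(40.0, "F", "siteA", seed=7, spec=spec32)
        b = generate_phantom(40.0, "F", "siteA", seed=7, spec=spec32)
        np.testing.assert_array_equal(a.data, b.data)

    def test_background_exactly_zero_and_finite(self, spec32):
        vol = generate_phantom(60.0, seed=1, spec=spec32)
        assert np.all(np.isfinite(vol.data))
        outside = ~structural_masks(60.0, spec32)["brain"]
        assert np.all(vol.data[outside] == 0.0)
        assert np.all(vol.data >= 0.0)

    def test_ventricle_volume_strictly_increases_with_age(self, spec32):
        counts = [
            extract_age_features(generate_phantom(age, seed=3, spec=spec32))[0]
            for age in (20, 40, 60, 80)
        ]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_cortical_thickness_strictly_decreases_with_age(self, spec32_clean):
        thicknesses = [
            extract_age_features(
                generate_phantom(age, seed=3, spec=spec32_clean)
            )[1]
            for age in (10, 35, 60, 85)
        ]
        assert all(b < a for a, b in zip(thicknesses, thicknesses[1:]))

    def test_site_effect_disabled_gives_identical_volumes(self):
        spec = PhantomSpec(grid_dims=(32, 32, 32), noise_sd=0.0, site_gain=None)
        a = generate_phantom(50.0, site="siteA", seed=0, spec=spec)
        b = generate_phantom(50.0, site="siteB", seed=0, spec=spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_site_gain_scales_foreground(self):
        spec = PhantomSpec(
            grid_dims=(32, 32, 32), noise_sd=0.0, site_gain={"bright": 1.1}
        )
        base = generate_phantom(50.0, site="other", seed=0, spec=spec)
        bright = generate_phantom(50.0, site="bright", seed=0, spec=spec)
        np.testing.assert_allclose(bright.data, base.data * 1.1, rtol=1e-6)

    @pytest.mark.parametrize("age", [4.9, 95.1, -3.0])
    def test_age_out_of_range_raises(self, age, spec32):
        with pytest.raises(DomainError):
            generate_phantom(age, spec=spec32)

    def test_linear_readout_recovers_age(self, spec32_clean):
        """Two hand-computed features predict age with R^2 > 0.9."""
        ages = np.arange(10.0, 95.0, 10.0)
        feats = np.array(
            [
                extract_age_features(
                    generate_phantom(a, seed=5, spec=spec32_clean)
                )
                for a in ages
            ]
        )
        design = np.column_stack([np.ones(len(ages)), feats])
        coef, *_ = np.linalg.lstsq(design, ages, rcond=None)
        pred = design @ coef
        ss_res = np.sum((ages - pred) ** 2)
        ss_tot = np.sum((ages - ages.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            PhantomSpec(grid_dims=(8, 32, 32))
        with pytest.raises(ConfigError):
            PhantomSpec(base_intensities={"background": 0.1, "wm": 1.0,
                                          "gm": 0.7, "csf": 0.35})


class TestGenerateCohort:
    def test_empty_cohort(self, tmp_path, spec32):
        table = generate_cohort(0, (5, 95), ["siteA"], 0, spec32, tmp_path)
        assert len(table) == 0
        assert not list(tmp_path.glob("*.nii.gz"))

    def test_ages_match_uniform_distribution(self, spec32):
        table = generate_cohort(500, (5.0, 95.0), ["siteA"], seed=3,
                                spec=spec32, out_dir=None)
        assert len(table) == 500
        _, p = sps.kstest(table.age.values, sps.uniform(5, 90).cdf)
        assert p > 0.01

    def test_both_sites_present_and_files_written(self, tmp_path, spec32):
        table = generate_cohort(10, (20, 80), ["siteA", "site7T"], seed=1,
                                spec=spec32, out_dir=tmp_path)
        assert set(table.site) == {"siteA", "site7T"}
        assert set(table.field_strength) == {"3T", "7T"}
        assert all((tmp_path / f"{s}_T1w.nii.gz").exists()
                   for s in table.subject_id)
        assert (tmp_path / "metadata.csv").exists()


class TestLongitudinalMSCohort:
    def test_zero_interval_degenerate_mode(self, spec32):
        ms = LongitudinalMSSpec(n_subjects=5, visit_interval_range=(0.0, 0.0))
        cohort, _ = generate_longitudinal_ms_cohort(ms, spec32, seed=0)
        for _, grp in cohort.groupby("subject_id"):
            ages = grp.sort_values("visit").structural_age.values
            assert ages[0] == pytest.approx(ages[1])

    def test_followup_structural_age_is_exact(self, spec32):
        ms = LongitudinalMSSpec(n_subjects=20)
        cohort, _ = generate_longitudinal_ms_cohort(ms, spec32, seed=1)
        for _, grp in cohort.groupby("subject_id"):
            grp = grp.sort_values("visit")
            s0, s1 = grp.structural_age.values
            rate = grp.true_annual_rate.iloc[0]
            interval = grp.interval_years.iloc[0]
            assert s1 == pytest.approx(s0 + rate * interval, abs=1e-9)

    def test_mean_rate_recovered_from_stored_deltas(self, spec32):
        ms = LongitudinalMSSpec(n_subjects=100, annual_ba_rate=1.15)
        cohort, _ = generate_longitudinal_ms_cohort(ms, spec32, seed=2)
        rates = []
        for _, grp in cohort.groupby("subject_id"):
            grp = grp.sort_values("visit")
            s0, s1 = grp.structural_age.values
            rates.append((s1 - s0) / grp.interval_years.iloc[0])
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 1.15) < 3 * se

    def test_zero_prevalence_yields_no_worsening(self, spec32):
        ms = LongitudinalMSSpec(n_subjects=40, worsening_prevalence=0.0)
        cohort, clinical = generate_longitudinal_ms_cohort(ms, spec32, seed=3)
        pairs = ms_visit_pairs(cohort, clinical)
        assert len(pairs) == 40
        assert not any(
            classify_worsening(p.baseline_visit, p.followup_visit)
            for p in pairs
        )

    def test_full_prevalence_yields_all_worsening(self, spec32):
        ms = LongitudinalMSSpec(n_subjects=30, worsening_prevalence=1.0)
        cohort, clinical = generate_longitudinal_ms_cohort(ms, spec32, seed=4)
        pairs = ms_visit_pairs(cohort, clinical)
        assert all(
            classify_worsening(p.baseline_visit, p.followup_visit)
            for p in pairs
        )

    def test_tables_written(self, tmp_path, spec32):
        ms = LongitudinalMSSpec(n_subjects=3)
        generate_longitudinal_ms_cohort(ms, spec32, seed=0, out_dir=tmp_path)
        assert (tmp_path / "cohort.csv").exists()
        assert (tmp_path / "clinical.csv").exists()

    def test_rendered_volumes(self, tmp_path, spec32):
        ms = LongitudinalMSSpec(n_subjects=2)
        cohort, _ = generate_longitudinal_ms_cohort(
            ms, spec32, seed=0, out_dir=tmp_path, write_volumes=True
        )
        assert all(cohort.path.map(lambda p: p.endswith(".nii.gz")))


class TestLesionPair:
    def test_zero_lesions_identity(self, spec32_clean):
        vol = generate_phantom(50.0, seed=0, spec=spec32_clean)
        spec = LesionSpec(count_range=(0, 0))
        lesioned, filled, mask = simulate_lesion_pair(vol, spec, seed=1)
        assert not mask.any()
        np.testing.assert_array_equal(lesioned.data, vol.data)
        np.testing.assert_array_equal(filled.data, vol.data)

    def test_lesions_local_inside_wm_and_filling_helps(self, spec32):
        vol = generate_phantom(45.0, seed=2, spec=spec32)
        spec = LesionSpec(count_range=(2, 4), radius_range_mm=(1.5, 2.5))
        lesioned, filled, mask = simulate_lesion_pair(vol, spec, seed=5)
        assert mask.any()
        # locality: untouched outside the mask
        np.testing.assert_array_equal(lesioned.data[~mask], vol.data[~mask])
        np.testing.assert_array_equal(filled.data[~mask], lesioned.data[~mask])
        # lesions live entirely in white matter
        wm = structural_masks(45.0, spec32)["wm"]
        assert np.all(wm[mask])
        # filling approximates the pre-lesion intensities better
        err_filled = np.abs(filled.data[mask] - vol.data[mask]).mean()
        err_lesion = np.abs(lesioned.data[mask] - vol.data[mask]).mean()
        assert err_filled < err_lesion

    def test_oversized_lesion_demand_raises(self, spec32):
        vol = generate_phantom(45.0, seed=2, spec=spec32)
        spec = LesionSpec(count_range=(5, 5), radius_range_mm=(14.0, 15.0))
        with pytest.raises(DomainError):
            simulate_lesion_pair(vol, spec, seed=0)
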