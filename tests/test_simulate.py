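import numpy as np
import pytest

from ramanfp import (
    BandSpec,
    BaselineSpec,
    CohortDesign,
    NoiseSpec,
    PhenotypeCoupling,
    average_to_fingerprint,
    compute_ratios,
    pearson_with_p,
    simulate_cohort,
    simulate_coupling_trials,
    simulate_spectrum,
)

AXIS = np.arange(600.0, 1801.0)
SILENT = NoiseSpec(0, 0, 0, 0)
FLAT = BaselineSpec()


class TestSimulateSpectrum:
    def test_null_model_is_identically_zero(self):
        s = simulate_spectrum([], FLAT, SILENT, AXIS, seed=0)
        assert np.all(s.intensities == 0.0)

    def test_single_lorentzian_matches_closed_form(self):
        band = BandSpec(1450.0, 1.0, 8.0, "lorentzian")
        s = simulate_spectrum([band], FLAT, SILENT, AXIS, seed=0)
        expected = 1.0 * 8.0**2 / (8.0**2 + (AXIS - 1450.0) ** 2)
        np.testing.assert_allclose(s.intensities, expected, rtol=1e-12)
        assert AXIS[np.argmax(s.intensities)] == 1450.0

    def test_seed_determinism(self):
        noise = NoiseSpec(0.05, 0.02, 0.002, 3.0)
        a = simulate_spectrum([BandSpec(1340, 1, 7)], FLAT, noise, AXIS, seed=42)
        b = simulate_spectrum([BandSpec(1340, 1, 7)], FLAT, noise, AXIS, seed=42)
        c = simulate_spectrum([BandSpec(1340, 1, 7)], FLAT, noise, AXIS, seed=43)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_spectrum([], FLAT, SILENT, np.array([]), seed=0)


class TestSimulateCohort:
    def test_study_design_counts(self):
        design = CohortDesign(seed=1)  # 3 groups x 3 timepoints x 3 samples x 30 reps
        sets, cohort, truth = simulate_cohort(design)
        assert len(sets) == 27
        assert sum(len(s) for s in sets) == 810
        assert len(cohort) == 27
        assert all(len(s) == 30 for s in sets)
        assert set(truth.samples) == set(cohort.sample_ids)

    def test_ground_truth_closure(self, noiseless_design):
        """Re-evaluating stored amplitudes reproduces the noiseless spectra."""
        sets, _, truth = simulate_cohort(noiseless_design)
        for sset in sets:
            for r_idx, rep in enumerate(sset.replicates):
                again = truth.noiseless_spectrum(sset.sample_id, replicate=r_idx)
                np.testing.assert_allclose(rep.intensities, again.intensities, rtol=1e-12)

    def test_seed_hierarchy_stable_under_design_growth(self):
        small = CohortDesign(seed=5, samples_per_cell=1, replicates_per_sample=2)
        big = CohortDesign(seed=5, samples_per_cell=2, replicates_per_sample=2)
        sets_s, _, _ = simulate_cohort(small)
        sets_b, _, _ = simulate_cohort(big)
        by_id = {s.sample_id: s for s in sets_b}
        for s in sets_s:
            np.testing.assert_array_equal(
                s.replicates[0].intensities, by_id[s.sample_id].replicates[0].intensities
            )

    def test_undefined_ratio_coupling_rejected(self):
        with pytest.raises(ValueError, match="no_such_ratio"):
            CohortDesign(
                couplings=(PhenotypeCoupling("grip", "no_such_ratio", 1.0, 0.1),)
            )

    def test_group_multiplier_recovered_in_noiseless_limit(self):
        """A 1.5x multiplier on the 1340 band shifts the 1340/1450 ratio of
        that group by 1.5x relative to reference, within 1%."""
        effects = {("old_hypoxia", tp): {1340.0: 1.5} for tp in ("BL", "4d", "7d")}
        design = CohortDesign(
            seed=3, effects=effects, samples_per_cell=1, replicates_per_sample=1,
            noise=SILENT, between_sample_cv=0.0, within_sample_cv=0.0,
        )
        sets, cohort, _ = simulate_cohort(design)
        fps = [average_to_fingerprint(s) for s in sets]
        table = compute_ratios(fps).values
        treated = table.loc["old_hypoxia_BL_s1", "nucleic_acid_lipid"]
        reference = table.loc["young_control_BL_s1", "nucleic_acid_lipid"]
        assert treated / reference == pytest.approx(1.5, rel=0.01)


class TestPhenotypeCoupling:
    def test_null_coupling_gives_no_correlation(self):
        """Slope 0: over 200 cohorts the mean Pearson r is ~0."""
        design = CohortDesign(seed=0)
        x, y = simulate_coupling_trials(
            design, "nucleic_acid_lipid", slope=0.0, noise_sd=1.0,
            n_cohorts=200, seed=99,
        )
        rs = [pearson_with_p(x[i], y[i])[0] for i in range(200)]
        assert x.shape == (200, 18)
        assert abs(float(np.mean(rs))) < 0.05

    def test_trials_are_seed_deterministic(self):
        design = CohortDesign(seed=0)
        a = simulate_coupling_trials(design, "lipid_protein", -1.0, 0.1, 5, seed=12)
        b = simulate_coupling_trials(design, "lipid_protein", -1.0, 0.1, 5, seed=12)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestSpecValidation:
    def test_spike_rate_cap(self):
        with pytest.raises(ValueError):
            NoiseSpec(spike_rate=0.2)

    def test_band_width_positive(self):
        with pytest.raises(ValueError):
            BandSpec(1450, 1.0, 0.0)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="multiplier"):
            CohortDesign(effects={("old_control", "4d"): {1340.0: 0.0}})
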