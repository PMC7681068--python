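import dataclasses

import numpy as np
import pandas as pd
import pytest

import plasmaclock as pc


class TestGenerateCohort:
    def test_noise_free_values_lie_on_the_generative_line(self, noisefree_cohort, noisefree_spec):
        cohort, truth = noisefree_cohort
        a0 = noisefree_spec.age_center()
        ages = cohort.ages.to_numpy()
        logx = cohort.log10().to_numpy()
        expected = (
            truth.table["baseline"].to_numpy()[None, :]
            + np.outer(ages - a0, truth.true_beta.to_numpy())
        )
        np.testing.assert_allclose(logx, expected, atol=1e-12)

    def test_same_seed_gives_bit_identical_cohorts(self, small_spec):
        c1, t1 = pc.generate_cohort(small_spec)
        c2, t2 = pc.generate_cohort(small_spec)
        assert (c1.intensities.to_numpy() == c2.intensities.to_numpy()).all()
        assert (c1.subject_meta["age"] == c2.subject_meta["age"]).all()
        assert (t1.table["true_beta"] == t2.table["true_beta"]).all()

    def test_informative_count_follows_rounding_rule(self):
        spec = pc.CohortSpec(n_subjects=10, n_analytes=3000, frac_informative=0.15, seed=0)
        _, truth = pc.generate_cohort(spec)
        assert truth.informative_flag.sum() == 450

    def test_increasing_share_follows_rounding_rule(self, small_cohort):
        _, truth = small_cohort
        beta = truth.true_beta[truth.informative_flag]
        n_inf = len(beta)
        assert (beta > 0).sum() == round(0.7584 * n_inf)

    def test_direction_matches_beta_sign(self, small_cohort):
        _, truth = small_cohort
        assert (truth.true_direction == np.sign(truth.true_beta)).all()
        assert (truth.true_beta[~truth.informative_flag] == 0).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_subjects", -1),
            ("age_range", (50.0, 50.0)),
            ("frac_informative", 1.5),
            ("frac_increasing", -0.1),
            ("beta_range", (0.0, 0.01)),
            ("beta_range", (0.02, 0.01)),
            ("noise_sd", -0.5),
            ("age_distribution", "gamma"),
        ],
    )
    def test_invalid_spec_raises_naming_the_field(self, field, value):
        spec = dataclasses.replace(pc.CohortSpec(), **{field: value})
        with pytest.raises(pc.SpecValidationError, match=field.split("_")[0]):
            pc.generate_cohort(spec)

    def test_triangular_age_option_hits_requested_median(self):
        spec = pc.CohortSpec(
            n_subjects=20000, n_analytes=2, frac_informative=0.0,
            age_distribution="triangular", seed=3,
        )
        cohort, _ = pc.generate_cohort(spec)
        assert abs(np.median(cohort.ages) - 45.0) < 0.5
        lo, hi = spec.age_range
        assert cohort.ages.between(lo, hi).all()


class TestResampleCohort:
    def test_shares_the_generative_line_of_its_truth(self, noisefree_spec, noisefree_cohort):
        _, truth = noisefree_cohort
        new = pc.resample_cohort(noisefree_spec, truth, seed=99, n_subjects=25)
        assert new.n_subjects == 25
        logx = new.log10().to_numpy()
        expected = (
            truth.table["baseline"].to_numpy()[None, :]
            + np.outer(new.ages.to_numpy() - truth.age_center, truth.true_beta.to_numpy())
        )
        np.testing.assert_allclose(logx, expected, atol=1e-12)


class TestInjectAgingShift:
    def test_zero_shift_is_identity(self, small_cohort):
        cohort, truth = small_cohort
        ids = list(cohort.intensities.index[:10])
        shifted = pc.inject_aging_shift(cohort, truth, ids, 0.0)
        np.testing.assert_allclose(
            shifted.intensities.to_numpy(), cohort.intensities.to_numpy()
        )

    def test_noise_free_shift_matches_an_older_subject(self, noisefree_cohort):
        cohort, truth = noisefree_cohort
        ages = cohort.ages
        i, j = cohort.intensities.index[0], cohort.intensities.index[1]
        delta = float(ages[j] - ages[i])
        shifted = pc.inject_aging_shift(cohort, truth, [i], delta)
        np.testing.assert_allclose(
            shifted.intensities.loc[i].to_numpy(),
            cohort.intensities.loc[j].to_numpy(),
            rtol=1e-9,
        )

    def test_unselected_subjects_and_ages_untouched(self, small_cohort):
        cohort, truth = small_cohort
        ids = list(cohort.intensities.index[:5])
        shifted = pc.inject_aging_shift(cohort, truth, ids, 8.0)
        others = cohort.intensities.index[5:]
        np.testing.assert_array_equal(
            shifted.intensities.loc[others].to_numpy(),
            cohort.intensities.loc[others].to_numpy(),
        )
        assert (shifted.subject_meta["age"] == cohort.subject_meta["age"]).all()

    def test_unknown_subject_raises(self, small_cohort):
        cohort, truth = small_cohort
        with pytest.raises(KeyError):
            pc.inject_aging_shift(cohort, truth, ["nope"], 1.0)


class TestPlatformMask:
    def test_keep_all_is_identity(self, small_cohort):
        cohort, _ = small_cohort
        masked = pc.apply_platform_mask(cohort, list(cohort.intensities.columns))
        pd.testing.assert_frame_equal(masked.intensities, cohort.intensities)

    def test_panel_restriction_count_and_order(self, small_cohort):
        cohort, _ = small_cohort
        keep = list(cohort.intensities.columns[::3])
        masked = pc.apply_platform_mask(cohort, keep)
        assert list(masked.intensities.columns) == keep
        assert masked.n_subjects == cohort.n_subjects

    def test_remasking_with_superset_is_idempotent(self, small_cohort):
        cohort, _ = small_cohort
        keep = list(cohort.intensities.columns[:40])
        once = pc.apply_platform_mask(cohort, keep)
        twice = pc.apply_platform_mask(once, keep)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)

    def test_empty_keep_list_raises(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            pc.apply_platform_mask(cohort, [])

    def test_shift_and_mask_commute(self, small_cohort):
        cohort, truth = small_cohort
        ids = list(cohort.intensities.index[:8])
        keep = list(cohort.intensities.columns[:30])
        a = pc.apply_platform_mask(pc.inject_aging_shift(cohort, truth, ids, 5.0), keep)
        b = pc.inject_aging_shift(pc.apply_platform_mask(cohort, keep), truth, ids, 5.0)
        np.testing.assert_allclose(a.intensities.to_numpy(), b.intensities.to_numpy())


class TestPathwayCollection:
    def test_sizes_within_range_and_deterministic(self, small_cohort):
        cohort, truth = small_cohort
        coll = pc.generate_pathway_collection(
            cohort.analyte_meta, truth, n_pathways=12, size_range=(5, 15),
            n_enriched=3, seed=5,
        )
        coll2 = pc.generate_pathway_collection(
            cohort.analyte_meta, truth, n_pathways=12, size_range=(5, 15),
            n_enriched=3, seed=5,
        )
        assert len(coll) == 12
        assert all(5 <= s <= 15 for s in coll.sizes().values())
        assert coll.entries == coll2.entries

    def test_size_range_beyond_panel_raises(self, small_cohort):
        cohort, truth = small_cohort
        with pytest.raises(ValueError):
            pc.generate_pathway_collection(
                cohort.analyte_meta, truth, 3, (10, 10_000), 0, seed=0
            )

    def test_enriched_sets_are_informative_heavy(self, small_cohort):
        """Over seeds, enriched sets carry more informative analytes than average."""
        cohort, truth = small_cohort
        informative = set(truth.informative_ids)

        def frac(members):
            return len(set(members) & informative) / len(members)

        enriched_fracs, background_fracs = [], []
        for seed in range(100):
            coll = pc.generate_pathway_collection(
                cohort.analyte_meta, truth, n_pathways=6, size_range=(8, 12),
                n_enriched=2, seed=seed,
            )
            pids = list(coll)
            enriched_fracs += [frac(coll.members(p)) for p in pids[:2]]
            background_fracs += [frac(coll.members(p)) for p in pids[2:]]
        assert np.mean(enriched_fracs) > np.mean(background_fracs)
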