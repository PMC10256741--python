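import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from latgrad.cohort import (
    CohortConfig,
    CohortConfigError,
    GroupEffect,
    PedigreeSpec,
    build_region_covariance,
    make_atlas,
    make_pedigree,
    read_cohort,
    simulate_cohort,
    simulate_heritable_trait,
    simulate_task_betas,
    simulate_timeseries,
    write_cohort,
)
from latgrad.metrics import task_asymmetry


def pair_correlation(trait, pedigree, relation):
    t = pedigree.table
    mask = t["relation"] == relation
    pairs = t[mask].groupby("twin_pair_id")["subject_id"].apply(list)
    a = trait[[p[0] for p in pairs]].to_numpy()
    b = trait[[p[1] for p in pairs]].to_numpy()
    return float(np.corrcoef(a, b)[0, 1])


class TestHeritableTrait:
    def test_mz_dz_correlations_track_h2(self):
        ped = make_pedigree(PedigreeSpec(2000, 2000, 0, 0))
        trait = simulate_heritable_trait(ped, 0.6, seed=1)
        assert abs(pair_correlation(trait, ped, "MZ_twin") - 0.6) < 0.05
        assert abs(pair_correlation(trait, ped, "DZ_twin") - 0.3) < 0.05

    def test_zero_heritability_gives_independent_cotwins(self):
        ped = make_pedigree(PedigreeSpec(500, 0, 0, 0))
        trait = simulate_heritable_trait(ped, 0.0, seed=2)
        assert abs(pair_correlation(trait, ped, "MZ_twin")) < 0.1

    def test_deterministic_under_seed(self):
        ped = make_pedigree(PedigreeSpec(5, 5, 5, 5))
        a = simulate_heritable_trait(ped, 0.4, seed=3)
        b = simulate_heritable_trait(ped, 0.4, seed=3)
        pd.testing.assert_series_equal(a, b)

    @pytest.mark.parametrize("h2", [-0.1, 1.0, 1.5])
    def test_h2_outside_unit_interval_rejected(self, h2):
        ped = make_pedigree(PedigreeSpec(1, 0, 0, 0))
        with pytest.raises(CohortConfigError):
            simulate_heritable_trait(ped, h2, seed=0)


class TestTimeseries:
    def test_homotopic_pairs_dominate_interhemispheric_correlation(self):
        cfg = CohortConfig(
            n_regions_per_hemisphere=12,
            n_language_rois=4,
            ts_length=4000,
            n_scans=1,
            homotopic_coupling=0.9,
        )
        atlas, g = make_atlas(12, 4, 2)
        scans = simulate_timeseries(atlas, "mild_typical", 1.0, cfg, seed=4, g=g)
        r = np.corrcoef(scans[0])
        partner = atlas.partner_positions
        left = np.flatnonzero(atlas.left_mask)
        wins = 0
        total = 0
        for i in left:
            homo = r[i, partner[i]]
            others = [r[i, j] for j in np.flatnonzero(atlas.right_mask) if j != partner[i]]
            wins += sum(homo > o for o in others)
            total += len(others)
        assert wins / total > 0.95

    def test_all_couplings_zero_gives_uncorrelated_noise(self):
        cfg = CohortConfig(
            n_regions_per_hemisphere=10,
            n_language_rois=3,
            ts_length=3000,
            n_scans=1,
            homotopic_coupling=0.0,
            within_network_coupling=0.0,
            within_hemisphere_base=0.0,
            cross_hemisphere_base=0.0,
            beta_effects={g: GroupEffect(0, 0) for g in ("strong_typical", "mild_typical", "atypical")},
        )
        atlas, g = make_atlas(10, 3, 2)
        scans = simulate_timeseries(atlas, "strong_typical", 1.0, cfg, seed=5, g=g)
        r = np.corrcoef(scans[0])
        off = r[~np.eye(20, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert np.abs(off).max() < 0.12  # pure sampling noise at T=3000

    def test_language_blocks_symmetric_without_asymmetry_boost(self):
        cfg = CohortConfig(n_regions_per_hemisphere=12, n_language_rois=4)
        atlas, g = make_atlas(12, 4, 2)
        eff = {g_: GroupEffect(0, 0, strength_sym=0.1, strength_asym=0.0) for g_ in
               ("strong_typical", "mild_typical", "atypical")}
        cfg.beta_effects = eff
        sigma = build_region_covariance(atlas, g, "strong_typical", 1.0, cfg)
        perm = atlas.partner_positions
        np.testing.assert_allclose(sigma, sigma[np.ix_(perm, perm)], atol=1e-12)

    def test_asymmetry_boost_mirrors_under_hemisphere_exchange(self):
        # the boosted left language block in the typical configuration equals
        # the hemisphere-permuted covariance of a right-boosted counterpart
        cfg = CohortConfig(n_regions_per_hemisphere=12, n_language_rois=4)
        atlas, g = make_atlas(12, 4, 2)
        sigma = build_region_covariance(atlas, g, "strong_typical", 1.0, cfg)
        lang = atlas.is_language
        L = sigma[np.ix_(lang & atlas.left_mask, lang & atlas.left_mask)]
        R = sigma[np.ix_(lang & atlas.right_mask, lang & atlas.right_mask)]
        off = ~np.eye(L.shape[0], dtype=bool)
        assert L[off].mean() > R[off].mean()
        mirrored = sigma[np.ix_(atlas.partner_positions, atlas.partner_positions)]
        Lm = mirrored[np.ix_(lang & atlas.left_mask, lang & atlas.left_mask)]
        np.testing.assert_allclose(Lm, R, atol=1e-12)

    def test_sample_covariance_matches_analytic_sigma(self):
        cfg = CohortConfig(
            n_regions_per_hemisphere=12, n_language_rois=4, ts_length=50_000, n_scans=1
        )
        atlas, g = make_atlas(12, 4, 2)
        sigma = build_region_covariance(atlas, g, "mild_typical", 1.0, cfg)
        scans = simulate_timeseries(atlas, "mild_typical", 1.0, cfg, seed=6, g=g, sigma=sigma)
        sample = np.cov(scans[0])
        assert np.abs(sample - sigma).max() < 0.02


class TestTaskBetas:
    def test_noise_free_network_asymmetry_equals_group_effect(self):
        atlas, _ = make_atlas(12, 4, 2)
        cfg = CohortConfig(n_regions_per_hemisphere=12, n_language_rois=4, beta_noise_sd=0.0)
        betas = simulate_task_betas(atlas, "strong_typical", 1.0, cfg, seed=0)
        assert task_asymmetry(betas, atlas, "network") == pytest.approx(1.74, abs=1e-12)
        assert task_asymmetry(betas, atlas, "hubs") == pytest.approx(2.64, abs=1e-12)
        betas = simulate_task_betas(atlas, "atypical", 1.0, cfg, seed=0)
        assert task_asymmetry(betas, atlas, "network") == pytest.approx(-0.96, abs=1e-12)
        assert task_asymmetry(betas, atlas, "hubs") == pytest.approx(-1.16, abs=1e-12)

    def test_null_effect_gives_zero_mean_asymmetry(self):
        atlas, _ = make_atlas(12, 4, 2)
        cfg = CohortConfig(
            n_regions_per_hemisphere=12,
            n_language_rois=4,
            beta_noise_sd=0.5,
            beta_effects={"strong_typical": GroupEffect(0.0, 0.0)},
        )
        rng = np.random.default_rng(7)
        asyms = [
            task_asymmetry(
                simulate_task_betas(atlas, "strong_typical", 1.0, cfg, rng), atlas, "network"
            )
            for _ in range(1000)
        ]
        se = np.std(asyms, ddof=1) / np.sqrt(len(asyms))
        assert abs(np.mean(asyms)) < 3 * se + 1e-12

    def test_unknown_group_rejected(self):
        atlas, _ = make_atlas(12, 4, 2)
        with pytest.raises(CohortConfigError, match="unknown group"):
            simulate_task_betas(atlas, "ambidextrous", 1.0, CohortConfig(), seed=0)

    def test_nonlanguage_regions_have_zero_mean(self):
        atlas, _ = make_atlas(12, 4, 2)
        cfg = CohortConfig(n_regions_per_hemisphere=12, n_language_rois=4, beta_noise_sd=0.0)
        betas = simulate_task_betas(atlas, "strong_typical", 1.0, cfg, seed=0)
        assert np.all(betas[~atlas.is_language] == 0.0)


class TestCohortAssembly:
    def test_group_counts_follow_proportions(self):
        # binomial 99% interval for the atypical count at n=1000, p=0.08
        cfg = CohortConfig(
            n_subjects=1000,
            n_regions_per_hemisphere=8,
            n_language_rois=3,
            n_hubs=1,
            ts_length=10,
            n_scans=1,
            seed=8,
        )
        bundle = simulate_cohort(cfg)
        n_atyp = (bundle.truth["group"] == "atypical").sum()
        lo, hi = sps.binom.ppf([0.005, 0.995], 1000, 0.08)
        assert lo <= n_atyp <= hi

    def test_empty_cohort_warns(self):
        cfg = CohortConfig(n_subjects=0, pedigree=PedigreeSpec(0, 0, 0, 0))
        with pytest.warns(UserWarning, match="empty"):
            bundle = simulate_cohort(cfg)
        assert bundle.subjects == []

    def test_fixed_seed_reproduces_bundle(self, small_config, small_bundle):
        again = simulate_cohort(small_config)
        for a, b in zip(small_bundle.subjects, again.subjects):
            np.testing.assert_array_equal(a.task_betas, b.task_betas)
            np.testing.assert_array_equal(a.scans[0], b.scans[0])
        pd.testing.assert_frame_equal(small_bundle.truth, again.truth)

    def test_mz_cotwins_share_group_more_often_than_unrelated(self):
        cfg = CohortConfig(
            n_subjects=800,
            pedigree=PedigreeSpec(400, 0, 0, 0),
            n_regions_per_hemisphere=8,
            n_language_rois=3,
            n_hubs=1,
            ts_length=10,
            n_scans=1,
            h2_asym=0.6,
            seed=9,
        )
        bundle = simulate_cohort(cfg)
        truth = bundle.truth.set_index("subject_id")
        ped = bundle.pedigree.table
        pairs = ped.groupby("twin_pair_id")["subject_id"].apply(list)
        same = np.mean([truth.loc[p[0], "group"] == truth.loc[p[1], "group"] for p in pairs])
        groups = truth["group"].to_numpy()
        chance = float(np.mean([np.mean(groups == g) ** 2 for g in np.unique(groups)]) * 3)
        assert same > chance + 0.1

    def test_cohort_roundtrip_through_disk(self, tmp_path, small_bundle):
        write_cohort(small_bundle, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert back.atlas.n_regions == small_bundle.atlas.n_regions
        assert [s.subject_id for s in back.subjects] == [
            s.subject_id for s in small_bundle.subjects
        ]
        np.testing.assert_allclose(
            back.subjects[0].task_betas, small_bundle.subjects[0].task_betas, rtol=1e-10
        )
        np.testing.assert_allclose(
            back.subjects[0].scans[0], small_bundle.subjects[0].scans[0], rtol=1e-6, atol=1e-8
        )
        np.testing.assert_allclose(
            back.latent_coordinate, small_bundle.latent_coordinate, rtol=1e-10
        )

    def test_pedigree_spec_mismatch_rejected(self):
        cfg = CohortConfig(n_subjects=10, pedigree=PedigreeSpec(1, 1, 1, 1))
        with pytest.raises(CohortConfigError, match="pedigree spec"):
            simulate_cohort(cfg)
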