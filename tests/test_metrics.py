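import numpy as np
import pytest

from latgrad.cohort import CohortConfig, make_atlas
from latgrad.datamodel import RegionAtlas, SubjectFunctionalData, hemisphere_swap
from latgrad.metrics import (
    ConnectivityMatrix,
    MetricsError,
    build_connectivity,
    compute_language_features,
    homotopic_connectivity,
    strength_metrics,
    task_asymmetry,
)

from conftest import toy_atlas_frame


def pearson_atanh_reference(scans, clip=1e-7):
    """Independent scan-averaged connectivity: explicit Pearson formula per
    pair, clipped, Fisher-averaged, tanh back-transformed."""
    n = scans[0].shape[0]
    z = np.zeros((n, n))
    for scan in scans:
        for i in range(n):
            for j in range(n):
                xi = scan[i] - scan[i].mean()
                xj = scan[j] - scan[j].mean()
                r = float(xi @ xj / np.sqrt((xi @ xi) * (xj @ xj)))
                r = min(max(r, -(1 - clip)), 1 - clip)
                z[i, j] += np.arctanh(r)
    z /= len(scans)
    np.fill_diagonal(z, 0.0)
    return np.tanh(z)


class TestBuildConnectivity:
    def test_perfect_linear_dependence_is_clipped(self):
        scan = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        conn = build_connectivity([scan])
        assert conn.values[0, 1] == pytest.approx(1 - 1e-7, rel=1e-12)
        assert np.isfinite(conn.z_values).all()

    def test_identical_scans_average_to_single_scan(self):
        rng = np.random.default_rng(0)
        scan = rng.normal(size=(5, 60))
        one = build_connectivity([scan])
        four = build_connectivity([scan] * 4)
        np.testing.assert_allclose(four.values, one.values, atol=1e-14)
        assert four.n_scans_averaged == 4

    def test_matches_independent_pearson_atanh_oracle(self):
        rng = np.random.default_rng(1)
        scans = [rng.normal(size=(5, 200)) for _ in range(3)]
        conn = build_connectivity(scans)
        np.testing.assert_allclose(conn.values, pearson_atanh_reference(scans), atol=1e-12)

    def test_tanh_z_consistency_invariant(self):
        rng = np.random.default_rng(2)
        conn = build_connectivity([rng.normal(size=(6, 80))])
        np.testing.assert_allclose(np.tanh(conn.z_values), conn.values, atol=1e-12)
        np.testing.assert_allclose(conn.values, conn.values.T, atol=1e-12)
        assert np.all(np.diag(conn.values) == 0)

    def test_constant_region_named_in_error(self):
        scan = np.vstack([np.ones(10), np.random.default_rng(3).normal(size=10)])
        with pytest.raises(MetricsError, match=r"\[0\]"):
            build_connectivity([scan])

    def test_mismatched_region_counts_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(MetricsError, match="regions"):
            build_connectivity([rng.normal(size=(4, 30)), rng.normal(size=(5, 30))])

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(MetricsError, match="3 time points"):
            build_connectivity([np.random.default_rng(5).normal(size=(4, 2))])


class TestTaskAsymmetry:
    def test_simple_mean_difference(self, toy_atlas):
        betas = np.array([0.0, 2.0, 0.0, 1.0])  # lang L = 2, lang R = 1
        assert task_asymmetry(betas, toy_atlas, "network") == pytest.approx(1.0)

    def test_symmetric_betas_give_zero(self, toy_atlas):
        betas = np.array([0.5, 2.0, 0.5, 2.0])
        assert task_asymmetry(betas, toy_atlas, "network") == 0.0

    def test_hemisphere_swap_negates(self, toy_atlas):
        rng = np.random.default_rng(6)
        betas = rng.normal(size=4)
        perm = toy_atlas.partner_positions
        a = task_asymmetry(betas, toy_atlas, "network")
        b = task_asymmetry(betas[perm], toy_atlas, "network")
        assert a == pytest.approx(-b, abs=1e-15)

    def test_empty_roi_set_rejected(self):
        df = toy_atlas_frame()
        df["is_hub"] = False
        atlas = RegionAtlas(df)
        with pytest.raises(MetricsError, match="empty"):
            task_asymmetry(np.zeros(4), atlas, "hubs")


def block_atlas(n_lang=3):
    """Atlas with n_lang language ROIs per hemisphere (all regions language)."""
    n = 2 * n_lang
    import pandas as pd

    return RegionAtlas(
        pd.DataFrame(
            {
                "region_id": list(range(1, n_lang + 1)) + list(range(101, 101 + n_lang)),
                "hemisphere": ["L"] * n_lang + ["R"] * n_lang,
                "homotopic_partner": list(range(101, 101 + n_lang)) + list(range(1, n_lang + 1)),
                "network": ["default"] * n,
                "is_language_roi": [True] * n,
                "is_hub": [True] + [False] * (n_lang - 1) + [True] + [False] * (n_lang - 1),
            }
        )
    )


class TestStrengthAndHomotopic:
    def test_uniform_half_correlation_strength(self):
        atlas = block_atlas(3)
        r = np.full((6, 6), 0.0)
        lang_l = np.ix_(range(3), range(3))
        r[lang_l] = 0.5
        r[np.ix_(range(3, 6), range(3, 6))] = 0.25
        np.fill_diagonal(r, 0.0)
        conn = ConnectivityMatrix(r, np.arctanh(np.clip(r, -0.999, 0.999)), 1)
        s_sum, s_asym = strength_metrics(conn, atlas)
        # each left ROI sums two 0.5 entries -> 1.0; right sums two 0.25 -> 0.5
        assert s_sum == pytest.approx(1.5)
        assert s_asym == pytest.approx(0.5)

    def test_identical_blocks_have_zero_asymmetry(self):
        atlas = block_atlas(3)
        rng = np.random.default_rng(7)
        block = rng.uniform(0.1, 0.6, size=(3, 3))
        block = 0.5 * (block + block.T)
        r = np.zeros((6, 6))
        r[np.ix_(range(3), range(3))] = block
        r[np.ix_(range(3, 6), range(3, 6))] = block
        np.fill_diagonal(r, 0.0)
        conn = ConnectivityMatrix(r, np.arctanh(r), 1)
        _, s_asym = strength_metrics(conn, atlas)
        assert s_asym == pytest.approx(0.0, abs=1e-15)

    def test_hemisphere_swap_negates_asymmetry_keeps_sum(self):
        atlas = block_atlas(3)
        rng = np.random.default_rng(8)
        r = rng.uniform(-0.3, 0.7, size=(6, 6))
        r = 0.5 * (r + r.T)
        np.fill_diagonal(r, 0.0)
        perm = atlas.partner_positions
        conn = ConnectivityMatrix(r, np.arctanh(r), 1)
        swapped = ConnectivityMatrix(r[np.ix_(perm, perm)], np.arctanh(r[np.ix_(perm, perm)]), 1)
        s1, a1 = strength_metrics(conn, atlas)
        s2, a2 = strength_metrics(swapped, atlas)
        assert s1 == pytest.approx(s2, abs=1e-14)
        assert a1 == pytest.approx(-a2, abs=1e-14)
        assert homotopic_connectivity(conn, atlas) == pytest.approx(
            homotopic_connectivity(swapped, atlas), abs=1e-14
        )

    def test_homotopic_mean_of_pair_z_values(self):
        atlas = block_atlas(3)
        z = np.zeros((6, 6))
        for i, zz in zip(range(3), (0.3, 0.5, 0.7)):
            z[i, i + 3] = z[i + 3, i] = zz
        conn = ConnectivityMatrix(np.tanh(z), z, 1)
        assert homotopic_connectivity(conn, atlas) == pytest.approx(0.5)
        conn0 = ConnectivityMatrix(np.zeros((6, 6)), np.zeros((6, 6)), 1)
        assert homotopic_connectivity(conn0, atlas) == 0.0

    def test_too_few_language_rois_rejected(self, toy_atlas):
        conn = ConnectivityMatrix(np.zeros((4, 4)), np.zeros((4, 4)), 1)
        with pytest.raises(MetricsError, match="at least 2"):
            strength_metrics(conn, toy_atlas)


class TestFeatureComposition:
    def test_mirrored_subject_negates_asymmetries_only(self):
        atlas, g = make_atlas(12, 4, 2)
        cfg = CohortConfig(n_regions_per_hemisphere=12, n_language_rois=4, ts_length=100, n_scans=2)
        from latgrad.cohort import simulate_task_betas, simulate_timeseries

        rng = np.random.default_rng(9)
        sub = SubjectFunctionalData(
            "s",
            simulate_timeseries(atlas, "strong_typical", 1.0, cfg, rng, g=g),
            simulate_task_betas(atlas, "strong_typical", 1.0, cfg, rng),
        )
        mirror = hemisphere_swap(sub, atlas)
        f1 = compute_language_features(sub, atlas)
        f2 = compute_language_features(mirror, atlas)
        assert f1.beta_network_asym == pytest.approx(-f2.beta_network_asym, abs=1e-12)
        assert f1.beta_hubs_asym == pytest.approx(-f2.beta_hubs_asym, abs=1e-12)
        assert f1.strength_asym == pytest.approx(-f2.strength_asym, abs=1e-12)
        assert f1.strength_sum == pytest.approx(f2.strength_sum, abs=1e-12)
        assert f1.interhemi_rz == pytest.approx(f2.interhemi_rz, abs=1e-12)

    def test_region_relabeling_leaves_features_unchanged(self):
        atlas, g = make_atlas(10, 3, 1)
        cfg = CohortConfig(
            n_regions_per_hemisphere=10, n_language_rois=3, n_hubs=1, ts_length=80, n_scans=1
        )
        from latgrad.cohort import simulate_task_betas, simulate_timeseries

        rng = np.random.default_rng(10)
        scans = simulate_timeseries(atlas, "mild_typical", 1.0, cfg, rng, g=g)
        betas = simulate_task_betas(atlas, "mild_typical", 1.0, cfg, rng)
        sub = SubjectFunctionalData("s", scans, betas)
        f1 = compute_language_features(sub, atlas)

        perm = np.random.default_rng(11).permutation(atlas.n_regions)
        shuffled = RegionAtlas(atlas.table.iloc[perm].reset_index(drop=True))
        sub2 = SubjectFunctionalData("s", [s[perm, :] for s in scans], betas[perm])
        f2 = compute_language_features(sub2, shuffled)
        for name in ("beta_network_asym", "beta_hubs_asym", "interhemi_rz",
                     "strength_sum", "strength_asym"):
            assert getattr(f1, name) == pytest.approx(getattr(f2, name), abs=1e-12)

    def test_composition_equals_component_oracles(self):
        atlas = block_atlas(3)
        rng = np.random.default_rng(12)
        scans = [rng.normal(size=(6, 120)) for _ in range(2)]
        betas = rng.normal(size=6)
        sub = SubjectFunctionalData("s", scans, betas)
        fv = compute_language_features(sub, atlas)
        ref_vals = pearson_atanh_reference(scans)
        ref_z = np.arctanh(ref_vals)
        np.fill_diagonal(ref_z, 0.0)
        conn = ConnectivityMatrix(ref_vals, ref_z, 2)
        s_sum, s_asym = strength_metrics(conn, atlas)
        assert fv.beta_network_asym == pytest.approx(task_asymmetry(betas, atlas, "network"), abs=1e-12)
        assert fv.beta_hubs_asym == pytest.approx(task_asymmetry(betas, atlas, "hubs"), abs=1e-12)
        assert fv.interhemi_rz == pytest.approx(homotopic_connectivity(conn, atlas), abs=1e-12)
        assert fv.strength_sum == pytest.approx(s_sum, abs=1e-12)
        assert fv.strength_asym == pytest.approx(s_asym, abs=1e-12)
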