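"""Z-scoring, control normalization, asymmetry, and matrix assembly."""

import numpy as np
import pandas as pd
import pytest

import fcdsurf as f
from fcdsurf.normalization import (CANONICAL_COLUMNS, FULL_CHAIN_FEATURES,
                                   HEMIS, assemble_feature_matrix,
                                   compute_control_stats, normalize_subject,
                                   training_view)


class TestIntraSubjectZscore:
    def test_mean_zero_sd_one(self):
        x = np.random.default_rng(0).normal(3, 7, 500)
        z = f.intra_subject_zscore(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        x = np.random.default_rng(1).normal(size=300)
        np.testing.assert_allclose(f.intra_subject_zscore(2.5 * x + 11),
                                   f.intra_subject_zscore(x), atol=1e-9)

    def test_constant_map_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="zero spread"):
            z = f.intra_subject_zscore(np.full(50, 3.0))
        np.testing.assert_array_equal(z, 0.0)

    def test_mask_respected(self):
        x = np.arange(100, dtype=float)
        mask = x < 50
        z = f.intra_subject_zscore(x, mask)
        assert z[mask].mean() == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(z[~mask]).all()


class TestControlNormalize:
    def _stats(self, n=8, nv=200, seed=0):
        rng = np.random.default_rng(seed)
        maps = [{("thickness.z", "left"): rng.normal(1.0, 0.5, nv)}
                for _ in range(n)]
        return compute_control_stats(maps), maps

    def test_control_mean_map_gives_zero(self):
        stats, maps = self._stats()
        z = f.control_normalize(stats.mean[("thickness.z", "left")], stats,
                                "thickness.z", "left")
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_cohort_mean_of_normalized_controls_near_zero(self):
        stats, maps = self._stats()
        zs = [f.control_normalize(m[("thickness.z", "left")], stats,
                                  "thickness.z", "left") for m in maps]
        np.testing.assert_allclose(np.mean(zs, axis=0), 0.0, atol=1e-9)

    def test_lesion_offset_recovers_in_sd_units(self):
        stats, _ = self._stats()
        key = ("thickness.z", "left")
        probe = stats.mean[key] + 2.5 * stats.sd[key]
        z = f.control_normalize(probe, stats, "thickness.z", "left")
        np.testing.assert_allclose(z, 2.5, atol=1e-9)

    def test_missing_feature_raises(self):
        stats, _ = self._stats()
        with pytest.raises(KeyError, match="missing feature"):
            f.control_normalize(np.zeros(200), stats, "lcd.z", "left")


class TestControlNormalizerTransformer:
    def test_transform_matches_functional_path(self):
        rng = np.random.default_rng(5)
        X_ctrl = rng.normal(2, 3, size=(12, 6))
        cn = f.ControlNormalizer().fit(X_ctrl)
        probe = X_ctrl.mean(axis=0) + 1.5 * X_ctrl.std(axis=0, ddof=1)
        np.testing.assert_allclose(cn.transform(probe[None, :]), 1.5,
                                   atol=1e-9)

    def test_zero_variance_column_floors_to_zero(self):
        X = np.random.default_rng(6).normal(size=(10, 3))
        X[:, 1] = 4.0
        cn = f.ControlNormalizer().fit(X)
        out = cn.transform(np.ones((2, 3)) * 9)
        np.testing.assert_array_equal(out[:, 1], 0.0)


class TestAsymmetry:
    def test_identical_hemispheres_zero(self):
        x = np.random.default_rng(2).normal(size=100)
        corr = f.CorrespondenceMap.identity(100)
        la, ra = f.interhemispheric_asymmetry(x, x.copy(), corr)
        np.testing.assert_array_equal(la, 0.0)
        np.testing.assert_array_equal(ra, 0.0)

    def test_antisymmetry_exact_under_permuted_correspondence(self):
        rng = np.random.default_rng(3)
        left = rng.normal(size=64)
        right = rng.normal(size=64)
        corr = f.CorrespondenceMap(rng.permutation(64))
        la, ra = f.interhemispheric_asymmetry(left, right, corr)
        np.testing.assert_allclose(la, -ra[corr.left_to_right], atol=0)

    def test_lesion_patch_plus_two(self):
        left = np.zeros(50)
        right = np.zeros(50)
        left[10:20] += 2.0
        corr = f.CorrespondenceMap.identity(50)
        la, ra = f.interhemispheric_asymmetry(left, right, corr)
        np.testing.assert_array_equal(la[10:20], 2.0)
        np.testing.assert_array_equal(ra[10:20], -2.0)

    def test_non_bijective_correspondence_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            f.CorrespondenceMap(np.array([0, 0, 1]))

    def test_inverse_is_self_inverse(self):
        corr = f.CorrespondenceMap(np.random.default_rng(4).permutation(32))
        np.testing.assert_array_equal(
            corr.left_to_right[corr.right_to_left], np.arange(32))


def _fake_subject_rows(n_vertices=120, lesion_size=30, n_controls=4,
                       seed=0):
    """Directly-constructed normalized maps for matrix-assembly tests."""
    rng = np.random.default_rng(seed)
    corr = f.CorrespondenceMap.identity(n_vertices)
    masks = {h: np.ones(n_vertices, dtype=bool) for h in HEMIS}

    def raw_maps():
        raw = {}
        for name in ["thickness", "gw_contrast", "sulc", "curv", "lcd",
                     *f.FLAIR_NAMES]:
            for h in HEMIS:
                raw[(name, h)] = rng.normal(size=n_vertices)
        for name in ["thickness", "gw_contrast", *f.FLAIR_NAMES]:
            for h in HEMIS:
                raw[(f"doughnut.{name}", h)] = rng.normal(size=n_vertices)
        return raw

    rows = []
    control_normed = []
    for i in range(n_controls):
        normed = normalize_subject(raw_maps(), corr, masks)
        control_normed.append(normed)
        rows.append((f"c{i}", "control", normed, masks, None))
    lesion = ("left", np.arange(lesion_size))
    rows.append(("p0", "patient", normalize_subject(raw_maps(), corr, masks),
                 masks, lesion))
    stats = compute_control_stats([
        {k: v for k, v in m.items()} for m in control_normed])
    return rows, stats, n_vertices, lesion_size


class TestFeatureMatrix:
    def test_canonical_column_count_and_order(self):
        rows, stats, _, _ = _fake_subject_rows()
        m = assemble_feature_matrix(rows, stats)
        assert list(m.columns[4:4 + 28]) == list(CANONICAL_COLUMNS)
        assert len(CANONICAL_COLUMNS) == 28

    def test_training_view_row_count(self):
        nv, les = 120, 30
        rows, stats, _, _ = _fake_subject_rows(n_vertices=nv, lesion_size=les)
        m = assemble_feature_matrix(rows, stats)
        tv = training_view(m[m.subject == "p0"])
        # lesional rows + full contralateral hemisphere
        assert len(tv) == les + nv
        assert (tv.label == 1).sum() == les
        assert (tv.label == 0).sum() == nv

    def test_ipsilateral_nonlesional_excluded(self):
        rows, stats, nv, les = _fake_subject_rows()
        m = assemble_feature_matrix(rows, stats)
        ipsi = m[(m.subject == "p0") & (m.hemisphere == "left")]
        assert ((ipsi.label == -1).sum()) == nv - les

    def test_controls_contribute_no_labeled_rows(self):
        rows, stats, _, _ = _fake_subject_rows()
        m = assemble_feature_matrix(rows, stats)
        assert (training_view(m).subject == "p0").all()

    def test_column_order_deterministic_across_runs(self):
        m1 = assemble_feature_matrix(*_fake_subject_rows(seed=5)[:2])
        m2 = assemble_feature_matrix(*_fake_subject_rows(seed=5)[:2])
        pd.testing.assert_frame_equal(m1, m2)

    def test_missing_feature_names_subject(self):
        rows, stats, _, _ = _fake_subject_rows()
        subject_id, group, normed, masks, lesion = rows[-1]
        broken = {k: v for k, v in normed.items()
                  if k != ("lcd.z", "left")}
        with pytest.raises(KeyError, match="p0.*lcd.z"):
            assemble_feature_matrix(
                rows[:-1] + [(subject_id, group, broken, masks, lesion)],
                stats)

    def test_doughnut_maps_skip_control_normalization(self):
        # doughnut columns must be identical with and without control stats
        # rescaling: they undergo steps 1-2 only
        rows, stats, _, _ = _fake_subject_rows()
        m = assemble_feature_matrix(rows, stats)
        _, _, normed, masks, _ = rows[-1]
        direct = normed[("doughnut.thickness", "left")]
        got = m[(m.subject == "p0") & (m.hemisphere == "left")
                ]["doughnut.thickness"].to_numpy()
        np.testing.assert_allclose(got, direct, atol=1e-12)

    def test_full_chain_features_are_control_normalized(self):
        rows, stats, _, _ = _fake_subject_rows()
        m = assemble_feature_matrix(rows, stats)
        _, _, normed, masks, _ = rows[-1]
        key = ("thickness.z", "left")
        expect = f.control_normalize(normed[key], stats, *key)
        got = m[(m.subject == "p0") & (m.hemisphere == "left")
                ]["thickness.z"].to_numpy()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_asymmetry_antisymmetry_in_matrix(self):
        rows, stats, _, _ = _fake_subject_rows()
        _, _, normed, _, _ = rows[-1]
        for name in FULL_CHAIN_FEATURES:
            la = normed[(f"asym.{name}", "left")]
            ra = normed[(f"asym.{name}", "right")]
            np.testing.assert_allclose(la, -ra, atol=1e-12)
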