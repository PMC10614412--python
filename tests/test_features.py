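"""Feature extraction, nuisance regression, and the case-control exploration."""

import numpy as np
import pytest

from wmdev import CohortSpec, generate_cohort
from wmdev.features import (FeatureTable, age_correlation_by_group,
                            case_control_compare, covariate_matrix,
                            extract_features, regress_nuisance)
from wmdev.synthetic_cohort import METRICS, null_spec
from conftest import small_spec


def constant_volumes(value=0.4):
    records, volumes = generate_cohort(small_spec(n_td=3, n_asd=1))
    for v in volumes:
        for m in METRICS:
            v.metric_maps[m] = np.full_like(v.metric_maps[m], value)
    return records, volumes


class TestExtractFeatures:
    def test_constant_map_means(self):
        _, volumes = constant_volumes(0.4)
        for kind in ("global_mean", "bundle_means"):
            tables = extract_features(volumes, kind)
            for m in METRICS:
                assert np.allclose(tables[m].values, 0.4)

    def test_label_index_map_recovers_labels(self):
        _, volumes = generate_cohort(small_spec(n_td=2, n_asd=1))
        labels = volumes[0].bundle_labels
        for v in volumes:
            v.metric_maps["FA"] = labels.astype(float) / 10  # keep FA in [0,1]
        table = extract_features(volumes, "bundle_means")["FA"]
        label_ids = [int(k) for k in np.unique(labels) if k != 0]
        for j, k in enumerate(label_ids):
            assert np.allclose(table.values[:, j], k / 10)

    def test_bundle_means_match_masked_average_oracle(self, default_cohort):
        _, volumes = default_cohort
        table = extract_features(volumes[:5], "bundle_means")["MD"]
        labels = volumes[0].bundle_labels
        for i, v in enumerate(volumes[:5]):
            for j, k in enumerate(int(x) for x in np.unique(labels) if x != 0):
                expected = v.metric_maps["MD"][labels == k].mean()
                assert table.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_global_mean_is_weighted_bundle_mean(self, default_cohort):
        # default skeleton bundles all have equal size, so the unweighted
        # average of bundle means equals the skeleton-wide mean
        _, volumes = default_cohort
        gm = extract_features(volumes[:4], "global_mean")["FA"].values[:, 0]
        bm = extract_features(volumes[:4], "bundle_means")["FA"].values
        assert np.allclose(gm, bm.mean(axis=1), atol=1e-12)

    def test_voxel_vector_c_order(self, default_cohort):
        _, volumes = default_cohort
        table = extract_features(volumes[:2], "voxel_vector")["FA"]
        mask = volumes[0].skeleton_mask.astype(bool)
        assert np.array_equal(table.values[0], volumes[0].metric_maps["FA"][mask])

    def test_mismatched_masks_rejected(self, default_cohort):
        _, volumes = default_cohort
        import copy
        bad = copy.deepcopy(volumes[1])
        bad.bundle_labels = bad.bundle_labels.copy()
        bad.bundle_labels[bad.bundle_labels == 2] = 1
        with pytest.raises(ValueError, match="share"):
            extract_features([volumes[0], bad], "bundle_means")


class TestRegressNuisance:
    def make_table(self, values):
        values = np.atleast_2d(values)
        return FeatureTable([f"s{i}" for i in range(values.shape[0])],
                            "FA", "bundle_means", values)

    def test_perfect_confound_residual_zero(self, rng):
        motion = rng.uniform(0.1, 0.5, 30)
        table = self.make_table((3 * motion)[:, None])
        out = regress_nuisance(table, motion[:, None])
        assert np.allclose(out.values, 0, atol=1e-10)

    def test_orthogonal_covariate_only_centers(self, rng):
        n = 40
        cov = rng.normal(size=(n, 1))
        feat = rng.normal(size=n)
        feat -= feat.mean()
        c = cov[:, 0] - cov[:, 0].mean()
        feat -= c * (feat @ c) / (c @ c)  # orthogonalize to the covariate
        out = regress_nuisance(self.make_table(feat[:, None]), cov)
        assert np.allclose(out.values[:, 0], feat, atol=1e-10)

    def test_residuals_match_hat_matrix_oracle(self, rng):
        n, p, q = 25, 3, 2
        x = rng.normal(size=(n, q))
        y = rng.normal(size=(n, p))
        out = regress_nuisance(self.make_table(y), x)
        design = np.column_stack([np.ones(n), x])
        hat = design @ np.linalg.inv(design.T @ design) @ design.T
        expected = y - hat @ y
        assert np.allclose(out.values, expected, atol=1e-10)
        for j in range(q):  # orthogonality to each covariate
            assert np.allclose(out.values.T @ (x[:, j] - x[:, j].mean()), 0,
                               atol=1e-8)

    def test_idempotent(self, rng):
        x = rng.normal(size=(20, 2))
        y = rng.normal(size=(20, 4))
        once = regress_nuisance(self.make_table(y), x)
        twice = regress_nuisance(once, x)
        assert np.allclose(once.values, twice.values, atol=1e-12)


class TestCaseControl:
    def split_tables(self, records, volumes):
        gm = extract_features(volumes, "global_mean")
        asd = [r.subject_id for r in records if r.group == "ASD"]
        td = [r.subject_id for r in records if r.group == "TD"]
        return ({m: t.subset(asd) for m, t in gm.items()},
                {m: t.subset(td) for m, t in gm.items()})

    def test_identical_groups_p_one(self, default_cohort):
        _, volumes = default_cohort
        gm = extract_features(volumes[:6], "global_mean")
        res = case_control_compare(gm, gm)
        assert all(r.p_value == pytest.approx(1.0) for r in res.values())

    def test_type_one_error_rate_under_null(self):
        rejections = {m: 0 for m in METRICS}
        n_seeds = 50
        for seed in range(n_seeds):
            spec = null_spec(seed=seed, n_td=30, n_asd=30,
                             grid_shape=(8, 8, 4), n_bundles=4,
                             affected_bundles=(1,))
            records, volumes = generate_cohort(spec)
            asd_t, td_t = self.split_tables(records, volumes)
            for m, r in case_control_compare(asd_t, td_t).items():
                rejections[m] += r.p_value < 0.05
        for m in METRICS:
            assert 0.0 <= rejections[m] / n_seeds <= 0.12

    def test_subgroup_masking_hides_group_difference(self):
        # opposite-signed subgroup offsets cancel in the group mean, so the
        # case-control test stays null despite real regional effects
        non_significant = 0
        n_seeds = 20
        for seed in range(n_seeds):
            records, volumes = generate_cohort(CohortSpec(seed=seed))
            asd_t, td_t = self.split_tables(records, volumes)
            res = case_control_compare(asd_t, td_t)
            non_significant += all(r.p_value > 0.05 for r in res.values())
        assert non_significant / n_seeds >= 0.5


class TestAgeCorrelation:
    def test_td_signs_and_flat_asd(self):
        spec = CohortSpec(seed=3, asd_slope_attenuation=0.0,
                          subgroup_effect={m: 0.0 for m in METRICS})
        records, volumes = generate_cohort(spec)
        gm = extract_features(volumes, "global_mean")
        out = age_correlation_by_group(gm, records)
        assert out["TD"]["FA"][0] > 0
        for m in ("MD", "RD", "AD"):
            assert out["TD"][m][0] < 0
        # flat ASD trajectory: correlations should be weak
        assert all(abs(out["ASD"][m][0]) < 0.5 for m in METRICS)

    def test_duplicated_group_identical_r(self, default_cohort):
        records, volumes = default_cohort
        td = [r for r in records if r.group == "TD"]
        relabeled = [type(r)(subject_id=r.subject_id, group="ASD", age=r.age,
                             sex=r.sex, handedness=r.handedness,
                             head_motion=r.head_motion, true_subgroup=1)
                     for r in td]
        gm = extract_features(volumes, "global_mean")
        out = age_correlation_by_group(gm, td + relabeled)
        for m in METRICS:
            assert out["TD"][m][0] == pytest.approx(out["ASD"][m][0])


def test_covariate_matrix_codes(default_cohort):
    records, _ = default_cohort
    cov = covariate_matrix(records[:5], include=("sex", "head_motion"))
    assert cov.shape == (5, 2)
    assert set(np.unique(cov[:, 0])) <= {0.0, 1.0}
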