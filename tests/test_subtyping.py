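"""Cluster discovery and subgroup comparisons."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from wmdev.subtyping import (deviation_age_correlation, kmeans_cluster,
                             mean_silhouette, order_clusters_by_age,
                             silhouette_select_k, subgroup_compare)
from wmdev.synthetic_cohort import METRICS, SubjectRecord
import pandas as pd


def asd_records(ages, subgroups, **kw):
    defaults = dict(sex="M", handedness="R", head_motion=0.25,
                    ados_total=18.0, ados_social=8.0)
    defaults.update(kw)
    return [SubjectRecord(subject_id=f"a{i:03d}", group="ASD", age=a,
                          true_subgroup=g, **defaults)
            for i, (a, g) in enumerate(zip(ages, subgroups))]


class TestKMeans:
    def test_separated_points_perfect_split(self):
        x = np.array([[0.0] * 4] * 3 + [[10.0] * 4] * 3)
        labels, _, inertia = kmeans_cluster(x, 2, seed=0)
        assert inertia == pytest.approx(0.0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_inertia_decreases_with_k(self, rng):
        x = rng.normal(size=(12, 4))
        _, _, i2 = kmeans_cluster(x, 2, seed=0)
        _, _, i11 = kmeans_cluster(x, 11, seed=0)
        assert i11 < i2

    def test_matches_exhaustive_partition_oracle(self, rng):
        x = rng.normal(size=(8, 2))
        _, _, inertia = kmeans_cluster(x, 2, seed=0, n_init=100)
        best = np.inf
        for assign in itertools.product([0, 1], repeat=8):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            ssq = sum(((x[assign == c] - x[assign == c].mean(axis=0)) ** 2).sum()
                      for c in (0, 1))
            best = min(best, ssq)
        assert inertia == pytest.approx(best, rel=1e-9)

    def test_label_agreement_across_seeds_on_separated_data(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (10, 4)),
                       rng.normal(5, 0.1, (12, 4))])
        l1, _, _ = kmeans_cluster(x, 2, seed=1)
        l2, _, _ = kmeans_cluster(x, 2, seed=99)
        assert adjusted_rand_score(l1, l2) == pytest.approx(1.0)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        x = np.array([[0, 0, 0, 0], [0.1, 0, 0, 0],
                      [10, 0, 0, 0], [10.1, 0, 0, 0]])
        labels = np.array([1, 1, 2, 2])
        # within-pair a = 0.1; nearest-other b = (9.9+10)/2 or (10+10.1)/2
        expected = np.mean([(9.95 - 0.1) / 9.95, (10.05 - 0.1) / 10.05,
                            (9.95 - 0.1) / 9.95, (10.05 - 0.1) / 10.05])
        assert mean_silhouette(x, labels) == pytest.approx(expected, abs=1e-9)

    def test_two_blobs_select_k2(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.vstack([rng.normal(0, 0.5, (30, 4)),
                           rng.normal(4, 0.5, (30, 4))])
            sel = silhouette_select_k(x, seed=seed, n_init=10)
            hits += sel.chosen_k == 2
        assert hits >= 18

    def test_singleton_cluster_scores_zero(self):
        x = np.array([[0.0, 0], [0.1, 0], [0.2, 0], [50.0, 0]])
        labels = np.array([1, 1, 1, 2])
        from sklearn.metrics import silhouette_samples
        assert silhouette_samples(x, labels)[3] == 0.0

    def test_tie_breaks_toward_smaller_k(self, rng):
        sel = silhouette_select_k(rng.normal(size=(30, 4)), seed=0, n_init=5)
        best = max(sel.silhouette_by_k.values())
        tied = [k for k, s in sel.silhouette_by_k.items()
                if s == pytest.approx(best)]
        assert sel.chosen_k == min(tied)


class TestSubgroupCompare:
    def make_cohort(self, rng, n=40):
        ages = np.concatenate([rng.uniform(4, 5.4, n // 2),
                               rng.uniform(5.6, 7, n // 2)])
        subgroups = np.array([1] * (n // 2) + [2] * (n // 2))
        records = []
        for i, (a, g) in enumerate(zip(ages, subgroups)):
            records.append(SubjectRecord(
                subject_id=f"a{i:03d}", group="ASD", age=a, sex="M",
                handedness="R", head_motion=0.25,
                ados_total=float(rng.normal(18 + g, 2)),
                ados_social=float(rng.normal(6 + 2 * g, 1)),
                true_subgroup=int(g)))
        dev = pd.DataFrame(
            {m: np.where(subgroups == 1, 1.0, -1.0) + rng.normal(0, 0.3, n)
             for m in METRICS})
        return records, subgroups, dev

    def test_true_split_detects_age_difference(self, rng):
        records, subgroups, dev = self.make_cohort(rng)
        report = subgroup_compare(subgroups, records, dev)
        age_row = report.loc[report.variable == "age_years"].iloc[0]
        assert age_row.p < 0.05 and age_row.mean_2 > age_row.mean_1

    def test_deviation_tests_fdr_flagged(self, rng):
        records, subgroups, dev = self.make_cohort(rng)
        report = subgroup_compare(subgroups, records, dev)
        dev_rows = report[report.variable.str.startswith("deviation_")]
        assert dev_rows.significant_fdr.all()

    def test_identical_deviations_t_zero(self, rng):
        records, subgroups, dev = self.make_cohort(rng)
        for m in METRICS:
            dev[m] = np.tile(dev[m][: len(dev) // 2].to_numpy(), 2)[: len(dev)]
        dev.iloc[:, :] = 1.0
        report = subgroup_compare(subgroups, records, dev)
        dev_rows = report[report.variable.str.startswith("deviation_")]
        assert np.allclose(dev_rows.statistic, 0.0)

    def test_random_labels_type_one_rate(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 40
            records = asd_records(rng.uniform(4, 7, n), [1] * n)
            dev = pd.DataFrame({m: rng.normal(size=n) for m in METRICS})
            labels = rng.integers(1, 3, n)
            if len(set(labels)) < 2 or min((labels == 1).sum(),
                                           (labels == 2).sum()) < 2:
                continue
            report = subgroup_compare(labels, records, dev)
            dev_rows = report[report.variable.str.startswith("deviation_")]
            hits += dev_rows.significant_fdr.any()
        assert hits / n_seeds <= 0.12

    def test_three_clusters_rejected(self, rng):
        records, subgroups, dev = self.make_cohort(rng)
        labels = subgroups.copy()
        labels[0] = 3
        with pytest.raises(ValueError, match="2 subgroups"):
            subgroup_compare(labels, records, dev)


class TestDeviationAgeCorrelation:
    def test_negative_trend_recovered(self, rng):
        n = 50
        ages = rng.uniform(4, 7, n)
        records = asd_records(ages, [1] * n)
        dev = pd.DataFrame({m: -0.7 * (ages - 5.5) + rng.normal(0, 0.3, n)
                            for m in METRICS})
        out = deviation_age_correlation(dev, records)
        assert (out.r < 0).all()
        assert out.significant_fdr.all()

    def test_constant_deviation_errors_with_metric_name(self, rng):
        n = 20
        records = asd_records(rng.uniform(4, 7, n), [1] * n)
        dev = pd.DataFrame({m: rng.normal(size=n) for m in METRICS})
        dev["MD"] = 1.0
        with pytest.raises(ValueError, match="MD"):
            deviation_age_correlation(dev, records)


def test_order_clusters_by_age(rng):
    records = asd_records([4.2, 4.3, 6.5, 6.6], [1, 1, 2, 2])
    labels = np.array([2, 2, 1, 1])
    assert list(order_clusters_by_age(labels, records)) == [1, 1, 2, 2]
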