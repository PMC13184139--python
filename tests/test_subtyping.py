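import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rehonorm import subtyping
from rehonorm import synthetic as syn


def two_blob_map(n=60, sep=10.0, n_features=5, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = rng.standard_normal((n, n_features))
    x[:half, 0] += sep / 2
    x[half:, 0] -= sep / 2
    z = pd.DataFrame(
        x,
        index=[f"S{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(n_features)],
    )
    truth = np.array([1] * half + [2] * (n - half))
    return z, truth


class TestMajorityVote:
    def test_modal_vote_wins(self):
        k, tally = subtyping.majority_vote({"a": 2, "b": 2, "c": 3})
        assert k == 2 and tally == {2: 2, 3: 1}

    def test_tie_goes_to_smallest_k(self):
        k, _ = subtyping.majority_vote({"a": 2, "b": 3})
        assert k == 2

    def test_empty_battery_rejected(self):
        with pytest.raises(ValueError, match="votes"):
            subtyping.majority_vote({})


class TestSelectK:
    def test_two_planted_clusters_found_by_majority(self):
        z, _ = two_blob_map(n=80, sep=8.0, seed=1)
        report = subtyping.select_k(z, k_range=(2, 6), seed=0)
        assert report.winning_k == 2
        assert report.tally[2] >= len(subtyping.DEFAULT_INDEX_BATTERY) / 2
        assert sum(report.tally.values()) == len(subtyping.DEFAULT_INDEX_BATTERY)

    def test_k_stays_inside_range(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(rng.standard_normal((40, 4)))
        report = subtyping.select_k(z, k_range=(2, 5), seed=0)
        assert 2 <= report.winning_k <= 5
        assert all(2 <= v <= 5 for v in report.votes.values())

    def test_reproducible_under_seed(self):
        z, _ = two_blob_map(n=50, sep=3.0, seed=3)
        a = subtyping.select_k(z, seed=9)
        b = subtyping.select_k(z, seed=9)
        assert a.votes == b.votes and a.winning_k == b.winning_k

    def test_empty_battery_rejected(self):
        z, _ = two_blob_map()
        with pytest.raises(ValueError, match="battery"):
            subtyping.select_k(z, index_battery=())


class TestClusterSubjects:
    def test_separable_clouds(self):
        z, truth = two_blob_map(sep=20.0, seed=4)
        res = subtyping.cluster_subjects(z, 2, n_restarts=10, seed=0)
        assert subtyping.adjusted_rand(res.labels.to_numpy(), truth) == 1.0
        dist = np.linalg.norm(res.centroids[0] - res.centroids[1])
        assert dist == pytest.approx(20.0, rel=0.1)
        assert res.within_distance_mean < res.between_distance_mean

    def test_duplicates_get_same_label(self):
        z, _ = two_blob_map(n=20, sep=6.0, seed=5)
        dup = pd.concat([z, z.set_index(z.index + "_dup")])
        res = subtyping.cluster_subjects(dup, 2, n_restarts=10, seed=0)
        for s in z.index:
            assert res.labels[s] == res.labels[s + "_dup"]

    def test_k_bounds(self):
        z, _ = two_blob_map(n=10)
        with pytest.raises(ValueError, match="k must be >= 2"):
            subtyping.cluster_subjects(z, 1)
        with pytest.raises(ValueError, match="exceeds"):
            subtyping.cluster_subjects(z, 11)

    def test_objective_matches_exhaustive_two_partitions(self):
        """k-means on 8 points reaches the global 2-partition optimum
        (checked by enumerating all 2^7 - 1 bipartitions)."""
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((8, 3))
        z = pd.DataFrame(pts, index=[f"S{i}" for i in range(8)])
        res = subtyping.cluster_subjects(z, 2, n_restarts=50, seed=0)
        best = np.inf
        for assign in itertools.product([0, 1], repeat=8):
            if len(set(assign)) < 2:
                continue
            a = np.asarray(assign, bool)
            wcss = sum(
                ((pts[idx] - pts[idx].mean(axis=0)) ** 2).sum()
                for idx in (a, ~a)
            )
            best = min(best, wcss)
        assert res.inertia == pytest.approx(best, abs=1e-6)


class TestNetworkAggregate:
    def test_simple_mean(self):
        z = pd.DataFrame(
            {"region_001": [1.0], "region_002": [3.0]}, index=["S0"]
        )
        mapping = pd.Series({"region_001": "DMN", "region_002": "DMN"})
        out = subtyping.network_aggregate(z, mapping)
        assert out.loc["S0", "DMN"] == pytest.approx(2.0)

    def test_missing_region_rejected(self):
        z = pd.DataFrame({"region_001": [1.0], "region_002": [3.0]})
        mapping = pd.Series({"region_001": "DMN"})
        with pytest.raises(ValueError, match="missing"):
            subtyping.network_aggregate(z, mapping)

    def test_matches_groupby_oracle(self, regions246):
        rng = np.random.default_rng(7)
        cols = [f"region_{r.region_id:03d}" for r in regions246]
        z = pd.DataFrame(rng.standard_normal((6, 246)), columns=cols)
        mapping = syn.region_network_map(regions246)
        out = subtyping.network_aggregate(z, mapping)
        for net in syn.NETWORKS:
            members = [c for c in cols if mapping[c] == net]
            np.testing.assert_allclose(out[net], z[members].mean(axis=1))


class TestAlignLabels:
    def test_identical_and_swapped(self):
        ref = pd.Series([1, 1, 2, 2], index=list("abcd"))
        _, ov = subtyping.align_labels(ref, ref)
        assert ov == 100.0
        swapped = pd.Series([2, 2, 1, 1], index=list("abcd"))
        aligned, ov = subtyping.align_labels(ref, swapped)
        assert ov == 100.0
        assert (aligned == ref).all()

    def test_partial_agreement(self):
        ref = pd.Series([1, 1, 1, 2], index=list("abcd"))
        cand = pd.Series([1, 1, 2, 2], index=list("abcd"))
        _, ov = subtyping.align_labels(ref, cand)
        assert ov == pytest.approx(75.0)

    def test_disjoint_subjects_rejected(self):
        ref = pd.Series([1, 2], index=["a", "b"])
        cand = pd.Series([1, 2], index=["c", "d"])
        with pytest.raises(ValueError, match="share no subjects"):
            subtyping.align_labels(ref, cand)

    @given(st.integers(0, 2_000))
    def test_overlap_symmetric_and_rename_invariant(self, seed):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(12)]
        a = pd.Series(rng.integers(1, 4, 12), index=idx)
        b = pd.Series(rng.integers(1, 4, 12), index=idx)
        _, ov_ab = subtyping.align_labels(a, b)
        _, ov_ba = subtyping.align_labels(b, a)
        assert ov_ab == pytest.approx(ov_ba)
        b_renamed = b.map({1: 7, 2: 9, 3: 5})
        _, ov_ren = subtyping.align_labels(a, b_renamed)
        assert ov_ren == pytest.approx(ov_ab)


class TestAdjustedRand:
    def test_identical_and_permuted(self):
        assert subtyping.adjusted_rand([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert subtyping.adjusted_rand([1, 1, 2, 2], [5, 5, 3, 3]) == 1.0

    def test_matches_pair_counting_enumeration(self):
        """ARI recomputed from scratch by enumerating all C(n,2) pairs."""
        from math import comb

        a = np.array([1, 1, 1, 2])
        b = np.array([1, 1, 2, 2])

        def pair_ari(x, y):
            n = len(x)
            both = same_x = same_y = 0
            for i, j in itertools.combinations(range(n), 2):
                sx, sy = x[i] == x[j], y[i] == y[j]
                both += sx and sy
                same_x += sx
                same_y += sy
            total = comb(n, 2)
            expected = same_x * same_y / total
            max_index = (same_x + same_y) / 2
            return (both - expected) / (max_index - expected)

        assert subtyping.adjusted_rand(a, b) == pytest.approx(pair_ari(a, b))
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.integers(0, 3, 10)
            y = rng.integers(0, 3, 10)
            assert subtyping.adjusted_rand(x, y) == pytest.approx(
                pair_ari(x, y), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            subtyping.adjusted_rand([1, 2], [1, 2, 3])


class TestSiteFilters:
    def test_small_site_dropped_and_identity_at_zero(self):
        cohort = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(19)],
             "site_id": [1] * 10 + [2] * 9}
        )
        out = subtyping.site_filters(cohort, 10)
        assert set(out["site_id"]) == {1}
        assert len(out) == 10
        same = subtyping.site_filters(cohort, 0)
        assert len(same) == len(cohort)

    def test_everything_filtered_rejected(self):
        cohort = pd.DataFrame({"subject_id": ["a", "b"], "site_id": [1, 2]})
        with pytest.raises(ValueError, match="every subject"):
            subtyping.site_filters(cohort, 5)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(9)
        cohort = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(200)],
             "site_id": rng.integers(1, 9, 200)}
        )
        thr = 25
        out = subtyping.site_filters(cohort, thr)
        expected = sum(
            c for c in cohort["site_id"].value_counts() if c >= thr
        )
        assert len(out) == expected


class TestLeaveOneSiteOut:
    def test_separable_limit_all_folds_perfect(self):
        z, truth = two_blob_map(n=90, sep=20.0, seed=10)
        sites = pd.Series(
            np.tile([1, 2, 3], 30), index=z.index, name="site_id"
        )
        report = subtyping.leave_one_site_out(z, sites, 2, seed=0, n_restarts=10)
        assert report.min_overlap == 100.0
        assert not report.failed_folds

    def test_too_few_sites_rejected(self):
        z, _ = two_blob_map(n=20)
        sites = pd.Series([1] * 10 + [2] * 10, index=z.index)
        with pytest.raises(ValueError, match="3 sites"):
            subtyping.leave_one_site_out(z, sites, 2)

    def test_folds_beat_random_relabeling_control(self):
        cfg = syn.CohortConfig(n_hc=5, n_mdd=240, n_sites=4, seed=12)
        regions = syn.generate_region_specs(seed=2)
        cohort, z = syn.generate_mdd_deviations(cfg, regions)
        sites = cohort.set_index("subject_id")["site_id"]
        primary = subtyping.cluster_subjects(z, 2, n_restarts=10, seed=0)
        report = subtyping.leave_one_site_out(
            z, sites, 2, seed=0, primary=primary, n_restarts=10
        )
        rng = np.random.default_rng(0)
        control = pd.Series(
            rng.permutation(primary.labels.to_numpy()), index=z.index
        )
        _, control_overlap = subtyping.align_labels(primary.labels, control)
        assert min(report.fold_overlap.values()) > control_overlap


class TestSubgroupValidation:
    def test_full_cohort_subgroup_is_perfect(self):
        z, truth = two_blob_map(n=40, sep=15.0, seed=13)
        cohort = pd.DataFrame(
            {
                "subject_id": z.index,
                "sex": ["M"] * 40,
                "age": np.linspace(20, 60, 40),
            }
        )
        primary = subtyping.cluster_subjects(z, 2, n_restarts=10, seed=0)
        with pytest.warns(UserWarning, match="female"):
            report = subtyping.subgroup_validation(z, cohort, primary, seed=0)
        assert report.fold_overlap["male"] == 100.0
        assert report.fold_ari["male"] == pytest.approx(1.0)

    def test_sex_independent_subtypes_stable_in_male_subgroup(self):
        cfg = syn.CohortConfig(n_hc=5, n_mdd=300, n_sites=3, seed=14)
        regions = syn.generate_region_specs(seed=2)
        cohort, z = syn.generate_mdd_deviations(cfg, regions)
        primary = subtyping.cluster_subjects(z, 2, n_restarts=10, seed=0)
        report = subtyping.subgroup_validation(z, cohort, primary, seed=0,
                                               n_restarts=10)
        assert report.fold_overlap["male"] >= 90.0
        assert report.fold_overlap["female"] >= 90.0

    def test_structureless_small_subgroup_ari_near_zero(self):
        # reclustering a random subgroup of 10 subjects from a map with no
        # cluster structure agrees with the primary labels only at chance
        rng = np.random.default_rng(15)
        z = pd.DataFrame(
            rng.standard_normal((120, 20)),
            index=[f"S{i}" for i in range(120)],
        )
        primary = subtyping.cluster_subjects(z, 2, n_restarts=10, seed=0)
        aris = []
        for rep in range(20):
            pick = rng.choice(z.index, 10, replace=False)
            sub = subtyping.cluster_subjects(z.loc[pick], 2, n_restarts=10,
                                             seed=rep)
            aris.append(
                subtyping.adjusted_rand(
                    primary.labels.loc[pick].to_numpy(), sub.labels.to_numpy()
                )
            )
        assert abs(np.mean(aris)) < 0.15


def test_end_to_end_recovery_on_generator_defaults(mdd_default_deviations):
    """Planted-subtype recovery: ARI > 0.8 and proportions within 3 points."""
    cohort, z = mdd_default_deviations
    res = subtyping.cluster_subjects(z, 2, n_restarts=10, seed=0)
    truth = cohort.set_index("subject_id")["true_subtype"]
    ari = subtyping.adjusted_rand(truth.to_numpy(), res.labels.to_numpy())
    assert ari > 0.8
    minority = res.labels.value_counts(normalize=True).min()
    planted = (truth == "1").mean()
    assert abs(minority - planted) < 0.03
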