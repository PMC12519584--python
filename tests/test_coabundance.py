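import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from plaquedyn import (
    CommunityTable,
    adjacency,
    assign_stages,
    correlation_matrix,
    detect_modules,
    distance_matrix,
    module_profile,
    module_time_association,
    simulate_tree,
    to_relative,
    tom_similarity,
)
from plaquedyn.synthetic_data import correlated_blocks

from conftest import small_scenario


class TestCorrelationMatrix:
    def test_duplicate_taxon_perfect_correlation(self):
        df = pd.DataFrame({"s1": [1, 1, 5], "s2": [2, 2, 1], "s3": [3, 3, 4]},
                          index=["a", "b", "c"]).T.T
        C = correlation_matrix(CommunityTable(df))
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame([x, 5 - x], index=["up", "down"],
                          columns=[f"s{i}" for i in range(4)])
        C = correlation_matrix(CommunityTable(df))
        assert C.loc["up", "down"] == pytest.approx(-1.0)

    def test_spearman_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.random((4, 12)), index=list("abcd"))
        C = correlation_matrix(CommunityTable(df), method="spearman")
        for i in "abcd":
            for j in "abcd":
                ref = spearmanr(df.loc[i], df.loc[j]).statistic
                assert C.loc[i, j] == pytest.approx(ref, abs=1e-10)

    def test_constant_taxon_zeroed_and_min_samples(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [1, 3], "s3": [1, 4]}, index=["flat", "x"])
        C = correlation_matrix(CommunityTable(df))
        assert C.loc["flat", "x"] == 0.0 and C.loc["flat", "flat"] == 1.0
        with pytest.raises(ValueError):
            correlation_matrix(CommunityTable(df[["s1", "s2"]]))


class TestAdjacencyAndTom:
    def test_adjacency_closed_forms(self):
        C = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        assert adjacency(C, power=12).loc["a", "b"] == 1.0
        C.loc["a", "b"] = C.loc["b", "a"] = -1.0
        assert adjacency(C, power=12, signed=True).loc["a", "b"] == 0.0
        C.loc["a", "b"] = C.loc["b", "a"] = 0.5
        assert adjacency(C, power=2).loc["a", "b"] == pytest.approx(0.25)
        with pytest.raises(ValueError):
            adjacency(C, power=0.5)

    def test_tom_two_nodes(self):
        A = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        assert tom_similarity(A).loc["a", "b"] == pytest.approx(1.0)

    def test_tom_triangle(self):
        A = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("abc"), columns=list("abc"))
        T = tom_similarity(A)
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        assert T.loc["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_tom_isolated_pair(self):
        A = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        assert tom_similarity(A).loc["a", "b"] == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_tom_bounds_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 10)
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        T = tom_similarity(pd.DataFrame(A)).to_numpy()
        assert T.min() >= -1e-12 and T.max() <= 1 + 1e-12
        # elementwise lower bound: overlap at least the direct-adjacency term
        bound = A / (A.sum(axis=1).max() + 1 - A)
        assert (T >= bound - 1e-12).all()

    def test_tom_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.random((5, 5)) * 0.8
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        T = tom_similarity(pd.DataFrame(A)).to_numpy()
        k = A.sum(axis=1)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(5))
                expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expected, abs=1e-10)


def _detect(table, **kw):
    tom = tom_similarity(adjacency(correlation_matrix(table), power=kw.pop("power", 12)))
    return detect_modules(1 - tom, **kw)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        table, blocks = correlated_blocks(seed=1)
        ms = _detect(table, min_size=7, split_depth=4)
        assert adjusted_rand_score(blocks, ms.labels) >= 0.9
        assert all(len(ms.members(m)) >= 7 for m in ms.module_ids)

    def test_fully_correlated_single_module(self):
        base = np.arange(1.0, 11.0)
        df = pd.DataFrame([base * s for s in (1, 2, 3, 4, 5)],
                          index=[f"t{i}" for i in range(5)])
        ms = _detect(CommunityTable(df), min_size=2, split_depth=4)
        assert len(ms.module_ids) == 1
        assert (ms.labels == 1).all()

    def test_small_block_unassigned(self):
        table, blocks = correlated_blocks(
            n_blocks=1, block_size=6, n_background=20, n_samples=40, seed=2
        )
        ms = _detect(table, min_size=7, split_depth=4)
        members = blocks.index[blocks == 1]
        assert (ms.labels.loc[members] == 0).all()

    def test_order_invariance_up_to_labels(self):
        table, _ = correlated_blocks(seed=3)
        ms1 = _detect(table, min_size=7, split_depth=4)
        shuffled = CommunityTable(table.data.sample(frac=1, random_state=7))
        ms2 = _detect(shuffled, min_size=7, split_depth=4)
        joined = pd.concat([ms1.labels, ms2.labels.reindex(ms1.labels.index)], axis=1)
        assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0

    def test_color_names_follow_size_ranking(self):
        table, _ = correlated_blocks(seed=4)
        ms = _detect(table, min_size=7, split_depth=4)
        assert ms.colors[0] == "grey"
        assert [ms.colors[i] for i in ms.module_ids[:3]] == ["turquoise", "blue", "brown"]

    def test_bad_arguments(self):
        table, _ = correlated_blocks(seed=5)
        tom = tom_similarity(adjacency(correlation_matrix(table)))
        with pytest.raises(ValueError):
            detect_modules(1 - tom, min_size=1)
        with pytest.raises(ValueError):
            detect_modules(1 - tom, min_size=31)
        with pytest.raises(ValueError):
            detect_modules(1 - tom, split_depth=5)


class TestModuleProfile:
    def test_identical_members_give_common_profile(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        df = pd.DataFrame([base, base, base], index=["a", "b", "c"])
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        profiles, degen = module_profile(CommunityTable(df), labels)
        assert degen == set()
        expected = (base - base.mean()) / base.std()
        np.testing.assert_allclose(profiles.loc[1], expected, atol=1e-10)

    def test_orientation_tracks_mean(self):
        rng = np.random.default_rng(0)
        base = rng.random(10)
        df = pd.DataFrame([base + rng.normal(0, 0.01, 10) for _ in range(4)],
                          index=list("abcd"))
        labels = pd.Series(1, index=list("abcd"))
        profiles, _ = module_profile(CommunityTable(df), labels)
        mean_std = (df.mean(0) - df.mean(0).mean()) / df.mean(0).std()
        assert np.corrcoef(profiles.loc[1], mean_std)[0, 1] > 0.99
        assert np.std(profiles.loc[1].to_numpy()) == pytest.approx(1.0)

    def test_planted_factor_recovered(self):
        table, blocks = correlated_blocks(n_blocks=1, block_size=10, n_samples=40, seed=6)
        labels = pd.Series(np.where(blocks == 1, 1, 0), index=blocks.index)
        profiles, _ = module_profile(table, labels)
        member_mean = table.data.loc[blocks == 1].mean(axis=0)
        assert abs(np.corrcoef(profiles.loc[1], member_mean)[0, 1]) >= 0.9

    def test_degenerate_module_flagged(self):
        df = pd.DataFrame([[1.0] * 4, [2.0] * 4], index=["a", "b"])
        labels = pd.Series(1, index=["a", "b"])
        _, degen = module_profile(CommunityTable(df), labels)
        assert degen == {1}


class TestModuleTimeAssociation:
    def test_indicator_profile_perfect_association(self):
        md = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(6)],
             "subject_id": ["A", "B"] * 3,
             "timepoint": ["0h", "0h", "1d", "1d", "1y", "1y"],
             "hours": [0.0, 0.0, 24.0, 24.0, 8760.0, 8760.0]}
        )
        ind = np.array([0, 0, 1, 1, 0, 0], dtype=float)
        profiles = pd.DataFrame([ind], index=[1], columns=md["sample_id"])
        assoc, stages = module_time_association(profiles, md)
        r_1d = assoc[(assoc["module"] == 1) & (assoc["timepoint"] == "1d")]["r"].iloc[0]
        assert r_1d == pytest.approx(1.0)
        assert stages.loc[1] == "middle"

    def test_constant_profile_undefined(self):
        md = pd.DataFrame(
            {"sample_id": ["s0", "s1", "s2", "s3"], "subject_id": list("ABAB"),
             "timepoint": ["0h", "0h", "1d", "1d"], "hours": [0.0, 0.0, 24.0, 24.0]}
        )
        profiles = pd.DataFrame([[1.0] * 4], index=[1], columns=md["sample_id"])
        assoc, stages = module_time_association(profiles, md)
        assert assoc["r"].isna().all()
        assert stages.loc[1] == "none"

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_simulated_early_module_peaks_early(self, seed):
        cfg, _, table, md, _ = small_scenario(seed=seed)
        labels = pd.Series(0, index=table.taxa)
        labels.loc[cfg.module_members()["black"]] = 1
        profiles, _ = module_profile(to_relative(table), labels)
        assoc, stages = module_time_association(profiles, md)
        assert stages.loc[1] == "early"


class TestAssignStages:
    def test_fixed_reproduces_printed_schedule(self, recovery_small):
        _, _, _, md, _ = recovery_small
        stages = assign_stages(md, mode="fixed")
        assert list(stages.index) == ["0h", "1h", "4h", "7h", "1d", "3d", "7d", "14d", "1m", "3m", "1y"]
        assert list(stages) == ["early"] * 4 + ["middle"] * 3 + ["late"] * 4

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_cluster_mode_matches_fixed_on_strong_structure(self, seed):
        _, tree, table, md, _ = small_scenario(seed=seed, noise_sd=0.1)
        D = distance_matrix(to_relative(table), tree)
        fixed = assign_stages(md, mode="fixed")
        clustered = assign_stages(md, mode="cluster", distance_matrix=D)
        # same partition structure (names may be assigned by time order anyway)
        assert adjusted_rand_score(fixed.loc[clustered.index], clustered) == 1.0

    def test_three_timepoints_forced(self):
        md = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "subject_id": ["S"] * 3,
             "timepoint": ["t1", "t2", "t3"], "hours": [0.0, 24.0, 8760.0]}
        )
        from skbio import DistanceMatrix

        D = DistanceMatrix(np.array([[0, 0.5, 0.9], [0.5, 0, 0.4], [0.9, 0.4, 0]]),
                           ids=["a", "b", "c"])
        stages = assign_stages(md, mode="cluster", distance_matrix=D)
        assert list(stages) == ["early", "middle", "late"]

    def test_cluster_needs_three_timepoints(self):
        md = pd.DataFrame(
            {"sample_id": ["a", "b"], "subject_id": ["S", "S"],
             "timepoint": ["t1", "t2"], "hours": [0.0, 24.0]}
        )
        with pytest.raises(ValueError):
            assign_stages(md, mode="cluster")
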