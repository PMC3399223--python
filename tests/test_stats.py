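"""ANOSIM, BEST/BIOENV environmental correlation, OTU profile statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import chemocline as cc
from chemocline.profiles import Peak, TRFLPProfile
from chemocline.stats import _anosim_r
from conftest import random_resemblance


def profile(peaks, sample="s1", enzyme="MspI", sigma=16.0):
    return TRFLPProfile(
        sample_id=sample, enzyme=enzyme, peaks=tuple(Peak(*p) for p in peaks), sigma_theta=sigma
    )


def block_matrix(n_per_group, groups=2, within=90.0, between=10.0):
    n = n_per_group * groups
    sim = np.full((n, n), between)
    for g in range(groups):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        sim[sl, sl] = within
    np.fill_diagonal(sim, 100.0)
    ids = tuple(f"g{i // n_per_group}s{i}" for i in range(n))
    labels = {s: s.split("s")[0] for s in ids}
    return cc.ResemblanceMatrix(ids, sim), labels


class TestAnosim:
    def test_fully_separated_groups_give_r_1(self):
        mat, labels = block_matrix(4, groups=3)
        res = cc.anosim(mat, labels, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_null_mean_near_zero(self):
        """Random labels: E[R] = 0; mean over 200 simulations within 3 SE."""
        rng = np.random.default_rng(12)
        mat = random_resemblance(rng, 12)
        rs = []
        from scipy.stats import rankdata

        d = 100.0 - mat.similarity
        ranks = rankdata(d[np.triu_indices(12, k=1)])
        base = np.array(["a"] * 6 + ["b"] * 6)
        for _ in range(200):
            rs.append(_anosim_r(ranks, rng.permutation(base)))
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 1e-12

    def test_hand_computed_four_samples(self):
        # 2+2 groups; dissimilarities chosen with distinct ranks
        sim = np.array(
            [
                [100.0, 90.0, 40.0, 30.0],
                [90.0, 100.0, 20.0, 10.0],
                [40.0, 20.0, 100.0, 35.0],
                [30.0, 10.0, 35.0, 100.0],
            ]
        )
        mat = cc.ResemblanceMatrix(("a1", "a2", "b1", "b2"), sim)
        labels = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        # dissimilarities: within {10 (a1,a2), 65 (b1,b2)} -> ranks {1, 3};
        # between {60, 70, 80, 90} -> ranks {2, 4, 5, 6}; M = 6
        expected = ((2 + 4 + 5 + 6) / 4 - (1 + 3) / 2) / (6 / 2)
        res = cc.anosim(mat, labels, n_perm=9, seed=0)
        assert res.r == pytest.approx(expected)

    def test_r_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(5)
        mat = random_resemblance(rng, 10)
        labels = {s: ("a" if i < 5 else "b") for i, s in enumerate(mat.sample_ids)}
        mine = cc.anosim(mat, labels, n_perm=99, seed=0)
        dm = DistanceMatrix(100.0 - mat.similarity, ids=mat.sample_ids)
        theirs = skbio_anosim(dm, [labels[s] for s in mat.sample_ids], permutations=99)
        assert mine.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_small_group_errors(self):
        mat, labels = block_matrix(2)
        labels[mat.sample_ids[0]] = "lonely"
        with pytest.raises(ValueError, match="< 2 samples"):
            cc.anosim(mat, labels)

    def test_permutation_p_floor(self):
        mat, labels = block_matrix(5, groups=2)
        res = cc.anosim(mat, labels, n_perm=999, seed=1)
        assert res.p_value >= 1 / 1000


class TestAnosimPairwise:
    def test_three_groups_give_three_pairs(self):
        mat, labels = block_matrix(3, groups=3)
        res = cc.anosim_pairwise(mat, labels, n_perm=49, seed=0)
        assert len(res) == 3

    def test_separated_pair_r_1(self):
        mat, labels = block_matrix(4, groups=2)
        res = cc.anosim_pairwise(mat, labels, n_perm=49, seed=0)
        assert res[("g0", "g1")].r == pytest.approx(1.0)

    def test_identical_composition_r_near_zero(self):
        rng = np.random.default_rng(2)
        mat = random_resemblance(rng, 12)  # no group structure
        labels = {s: ("a" if i % 2 == 0 else "b") for i, s in enumerate(mat.sample_ids)}
        res = cc.anosim_pairwise(mat, labels, n_perm=99, seed=0)
        assert abs(res[("a", "b")].r) < 0.35


class TestBestEnvSubset:
    def test_self_derived_environment_gives_rho_1(self):
        rng = np.random.default_rng(4)
        # environment distance built from the community dissimilarity
        # itself: its subset must reach rho = 1 (distinct pairwise
        # differences avoid ties broken by float noise)
        from scipy.spatial.distance import pdist

        x = np.array([0.0, 1.0, 3.0, 7.0, 15.0, 31.0, 63.0, 127.0])
        d = pdist(x[:, None])
        sim = 100.0 - (d / d.max() * 90.0)
        mat = cc.ResemblanceMatrix(tuple(f"s{i}" for i in range(8)), _sym(sim, 8))
        env = pd.DataFrame({"x": x, "junk": rng.normal(size=8)}, index=mat.sample_ids)
        out = cc.best_env_subset(env, mat)
        top = out.iloc[0]
        assert top["variables"] == ("x",)
        assert top["rho"] == pytest.approx(1.0)

    def test_subset_count_is_2k_minus_1(self):
        rng = np.random.default_rng(6)
        mat = random_resemblance(rng, 7)
        env = pd.DataFrame(
            rng.normal(size=(7, 6)), index=mat.sample_ids,
            columns=["O2", "H2S", "NO3", "NH4", "NO2", "PMn"],
        )
        out = cc.best_env_subset(env, mat)
        assert len(out) == 2**6 - 1

    def test_zero_variance_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        mat = random_resemblance(rng, 6)
        env = pd.DataFrame(
            {"flat": np.ones(6), "x": rng.normal(size=6)}, index=mat.sample_ids
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cc.best_env_subset(env, mat)
        assert len(out) == 1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        mat = random_resemblance(rng, 8)
        env = pd.DataFrame(rng.normal(size=(8, 3)), index=mat.sample_ids, columns=list("abc"))
        out1 = cc.best_env_subset(env, mat)
        env2 = env.copy()
        env2["b"] = env2["b"] * 1000.0 - 77.0
        out2 = cc.best_env_subset(env2, mat)
        np.testing.assert_allclose(out1["rho"].to_numpy(), out2["rho"].to_numpy(), atol=1e-12)

    def test_random_environment_rarely_correlates(self):
        """Independent environment: max rho over subsets stays small
        (median over 100 simulations < 0.5 at n = 20)."""
        rng = np.random.default_rng(14)
        maxima = []
        ids = tuple(f"s{i}" for i in range(20))
        for _ in range(100):
            mat = random_resemblance(rng, 20)
            env = pd.DataFrame(rng.normal(size=(20, 3)), index=ids, columns=list("abc"))
            maxima.append(cc.best_env_subset(env, mat)["rho"].max())
        assert np.median(maxima) < 0.5


def _sym(condensed, n):
    from scipy.spatial.distance import squareform

    sim = squareform(condensed)
    np.fill_diagonal(sim, 100.0)
    return sim


class TestOtuDepthProfile:
    def test_absent_fragment_is_zero(self):
        profs = [profile([(100.0, 5.0)], sample="a"), profile([(465.0, 5.0)], sample="b"),
                 profile([(200.0, 5.0)], sample="c")]
        out = cc.otu_depth_profile(profs, 465.0, 0.5)
        assert out["a"] == 0.0 and out["c"] == 0.0
        assert out["b"] == pytest.approx(1.0)

    def test_tolerance_is_inclusive_window(self):
        profs = [profile([(465.4, 1.0), (480.0, 1.0)], sample="a")]
        out = cc.otu_depth_profile(profs, 465.0, 0.5)
        assert out["a"] == pytest.approx(0.5)

    def test_overlapping_targets_warn(self):
        profs = [profile([(100.0, 1.0)], sample="a")]
        with pytest.warns(UserWarning, match="overlap"):
            cc.otu_depth_profiles(profs, [100.0, 100.6], tolerance_bp=0.5)


class TestCrossEnzymeConcordance:
    def test_same_otu_across_enzymes_rho_1(self, three_group_clean):
        sim = three_group_clean
        targets = {"MspI": 100.0, "HaeIII": 107.0, "MnlI": 113.0}  # g0_otu0 signature
        res = cc.cross_enzyme_concordance(sim.profiles, targets)
        assert len(res) == 3
        for r in res:
            assert r.rho == pytest.approx(1.0)
            assert r.supported

    def test_all_zero_profile_unsupported(self):
        a = [profile([(100.0, 1.0)], sample=f"s{i}") for i in range(4)]
        b = [profile([(900.0, 1.0)], sample=f"s{i}", enzyme="HaeIII") for i in range(4)]
        res = cc.cross_enzyme_concordance(
            {"MspI": a, "HaeIII": b}, {"MspI": 100.0, "HaeIII": 100.0}
        )
        assert res[0].rho is None and not res[0].supported

    def test_too_few_shared_samples(self):
        a = [profile([(100.0, 1.0)], sample=f"s{i}") for i in range(2)]
        b = [profile([(100.0, 1.0)], sample=f"s{i}", enzyme="HaeIII") for i in range(2)]
        with pytest.raises(ValueError, match="share only"):
            cc.cross_enzyme_concordance({"MspI": a, "HaeIII": b}, {"MspI": 100.0, "HaeIII": 100.0})


class TestAbundanceEnvCorrelation:
    def test_monotone_decreasing_rho_minus_1(self):
        res = cc.abundance_env_correlation([5, 4, 3, 2, 1], [10, 20, 30, 40, 50])
        assert res.coefficient == pytest.approx(-1.0)
        assert res.sign == -1

    def test_identity_rho_plus_1(self):
        res = cc.abundance_env_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.coefficient == pytest.approx(1.0)

    def test_exact_permutation_p_for_perfect_rank_correlation(self):
        """|rho| = 1 at n = 5: only identity and reversal achieve it,
        p = 2/120 over all permutations."""
        res = cc.abundance_env_correlation(
            [1, 2, 3, 4, 5], [2, 4, 6, 8, 10], p_method="exact"
        )
        assert res.p_value == pytest.approx(2 / 120)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cc.abundance_env_correlation([1, 1, 1], [1, 2, 3])

    def test_pearson_option(self):
        res = cc.abundance_env_correlation([1, 2, 3, 5], [2, 4, 6, 10], method="pearson")
        assert res.coefficient == pytest.approx(1.0)


class TestPlantedDriverRecovery:
    def test_planted_environmental_driver_tops_best_subsets(self):
        """A community whose composition tracks one environmental variable:
        that variable is in the top-ranked subset in >= 95% of simulations."""
        rng = np.random.default_rng(99)
        n = 15
        hits = 0
        n_sim = 100
        ids = tuple(f"s{i}" for i in range(n))
        for _ in range(n_sim):
            driver = np.sort(rng.uniform(0, 1, n))
            p = 1.0 / (1.0 + np.exp(-8.0 * (driver - 0.5)))  # OTU fraction
            comp = np.c_[p, 1.0 - p]
            sim = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    sim[i, j] = 100.0 * (1.0 - 0.5 * np.abs(comp[i] - comp[j]).sum())
            np.fill_diagonal(sim, 100.0)
            mat = cc.ResemblanceMatrix(ids, sim)
            env = pd.DataFrame(
                {
                    "driver": driver + rng.normal(0, 0.02, n),
                    "noise1": rng.normal(size=n),
                    "noise2": rng.normal(size=n),
                    "noise3": rng.normal(size=n),
                },
                index=ids,
            )
            top = cc.best_env_subset(env, mat).iloc[0]
            if "driver" in top["variables"]:
                hits += 1
        assert hits >= 95
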