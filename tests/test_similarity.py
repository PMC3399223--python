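"""Whittaker resemblance, UPGMA clustering, Monte Carlo significance."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import braycurtis, squareform

import chemocline as cc
from chemocline.profiles import Peak, TRFLPProfile
from conftest import random_resemblance


def profile(peaks, sample="s1", enzyme="MspI"):
    return TRFLPProfile(sample_id=sample, enzyme=enzyme, peaks=tuple(Peak(*p) for p in peaks))


class TestWhittaker:
    def test_identical_vectors(self):
        p = np.array([0.2, 0.3, 0.5])
        assert cc.whittaker_similarity(p, p) == 100.0

    def test_disjoint_supports(self):
        assert cc.whittaker_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_worked_example(self):
        assert cc.whittaker_similarity([0.6, 0.4, 0.0], [0.0, 0.4, 0.6]) == pytest.approx(40.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            cc.whittaker_similarity([0.5, 0.2], [0.5, 0.5])

    def test_equals_bray_curtis_complement(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(2, 30)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            assert cc.whittaker_similarity(p, q) == pytest.approx(
                100.0 * (1.0 - braycurtis(p, q)), abs=1e-9
            )


class TestResemblance:
    def test_identical_samples_all_frames(self):
        profs = [profile([(100.2, 1.0), (150.0, 3.0)], sample=s) for s in ("a", "b")]
        mat = cc.resemblance(cc.bin_frames(profs))
        assert mat.pair("a", "b") == pytest.approx(100.0)

    def test_max_dominates_every_frame(self):
        rng = np.random.default_rng(1)
        profs = []
        for s in range(5):
            peaks = [(float(rng.uniform(80, 500)), float(rng.uniform(10, 1000))) for _ in range(12)]
            profs.append(profile(peaks, sample=f"s{s}"))
        frames = cc.bin_frames(profs)
        mat = cc.resemblance(frames)
        for fr in frames:
            arr = fr.abundance.to_numpy()
            for i in range(5):
                for j in range(i + 1, 5):
                    s = 100.0 * (1.0 - 0.5 * np.abs(arr[i] - arr[j]).sum())
                    assert mat.similarity[i, j] >= s - 1e-9

    def test_neighbouring_peaks_rescued_by_some_frame(self):
        profs = [profile([(100.9, 1.0)], sample="a"), profile([(101.1, 1.0)], sample="b")]
        frames = cc.bin_frames(profs)
        per_frame = {
            f.frame_offset: 100.0 * (1.0 - 0.5 * np.abs(
                f.abundance.loc["a"].to_numpy() - f.abundance.loc["b"].to_numpy()).sum())
            for f in frames
        }
        assert per_frame[0.0] == pytest.approx(100.0)
        assert per_frame[1.0] == pytest.approx(0.0)
        assert cc.resemblance(frames).pair("a", "b") == pytest.approx(100.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        profs = [
            profile([(float(rng.uniform(80, 300)), float(rng.uniform(1, 100))) for _ in range(6)],
                    sample=f"s{k}")
            for k in range(4)
        ]
        mat = cc.resemblance(cc.bin_frames(profs)).to_frame()
        rev = cc.resemblance(cc.bin_frames(profs[::-1])).to_frame()
        rev = rev.loc[mat.index, mat.columns]
        np.testing.assert_allclose(mat.to_numpy(), rev.to_numpy(), atol=1e-9)

    def test_mismatched_frames_error(self):
        fa = cc.bin_frames([profile([(100, 1)], sample="a")])
        fb = cc.bin_frames([profile([(100, 1)], sample="b")])
        with pytest.raises(ValueError):
            cc.resemblance([fa[0], fb[1]])


def brute_force_upgma(d: np.ndarray):
    """Independent UPGMA oracle: explore every tie-compatible merge order,
    return the set of achievable sorted merge-height tuples."""
    import itertools

    results = set()

    def step(clusters, dists, heights):
        if len(clusters) == 1:
            results.add(tuple(sorted(round(h, 9) for h in heights)))
            return
        pairs = list(itertools.combinations(range(len(clusters)), 2))
        dmin = min(dists[p] for p in pairs)
        for a, b in pairs:
            if dists[(a, b)] > dmin + 1e-12:
                continue
            merged = clusters[a] + clusters[b]
            new_clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
            new_dists = {}
            remaining = [k for k in range(len(clusters)) if k not in (a, b)]
            for x_idx, x in enumerate(remaining):
                for y in remaining[x_idx + 1:]:
                    xi, yi = remaining.index(x), remaining.index(y)
                    new_dists[(xi, yi)] = dists[tuple(sorted((x, y)))]
                last = len(new_clusters) - 1
                na, nb = len(clusters[a]), len(clusters[b])
                val = (na * dists[tuple(sorted((x, a)))] + nb * dists[tuple(sorted((x, b)))]) / (na + nb)
                new_dists[(remaining.index(x), last)] = val
            step(new_clusters, new_dists, heights + [dmin])

    n = d.shape[0]
    clusters = [(i,) for i in range(n)]
    dists = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    step(clusters, dists, [])
    return results


class TestUpgma:
    def test_hand_computed_three_leaf_example(self):
        sim = 100.0 - np.array([[0, 20, 60], [20, 0, 40], [60, 40, 0]], dtype=float)
        np.fill_diagonal(sim, 100.0)
        mat = cc.ResemblanceMatrix(("A", "B", "C"), sim)
        dend = cc.upgma_cluster(mat)
        assert dend.nodes[0].similarity == pytest.approx(80.0)  # (A,B) at S=80
        assert dend.nodes[1].similarity == pytest.approx(50.0)  # C joins at 100-(60+40)/2

    def test_duplicates_merge_first_at_100(self):
        profs = [profile([(100, 1.0)], sample="a"), profile([(100, 1.0)], sample="b"),
                 profile([(300, 1.0)], sample="c")]
        dend = cc.upgma_cluster(cc.resemblance(cc.bin_frames(profs)))
        assert dend.nodes[0].similarity == pytest.approx(100.0)
        assert set(dend.nodes[0].members) == {0, 1}

    def test_matches_brute_force_oracle_small(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            mat = random_resemblance(rng, n)
            dend = cc.upgma_cluster(mat)
            mine = tuple(sorted(round(100.0 - s, 9) for s in dend.merge_similarities))
            oracle = brute_force_upgma(100.0 - mat.similarity)
            assert mine in oracle

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            mat = random_resemblance(rng, n)
            dend = cc.upgma_cluster(mat)
            z = linkage(squareform(100.0 - mat.similarity, checks=False), method="average")
            np.testing.assert_allclose(
                sorted(100.0 - np.array(dend.merge_similarities)), np.sort(z[:, 2]), atol=1e-8
            )

    def test_ultrametric_reconstruction(self):
        # a matrix that is exactly ultrametric: UPGMA recovers its levels
        sim = np.array(
            [
                [100.0, 90.0, 60.0, 60.0],
                [90.0, 100.0, 60.0, 60.0],
                [60.0, 60.0, 100.0, 80.0],
                [60.0, 60.0, 80.0, 100.0],
            ]
        )
        dend = cc.upgma_cluster(cc.ResemblanceMatrix(("a", "b", "c", "d"), sim))
        assert sorted(dend.merge_similarities) == [60.0, 80.0, 90.0]

    def test_merge_similarities_non_increasing(self):
        rng = np.random.default_rng(23)
        mat = random_resemblance(rng, 8)
        dend = cc.upgma_cluster(mat)
        sims = dend.merge_similarities
        assert all(a >= b - 1e-9 for a, b in zip(sims, sims[1:]))

    def test_newick_well_formed(self):
        rng = np.random.default_rng(5)
        mat = random_resemblance(rng, 5)
        dend = cc.upgma_cluster(mat)
        dend.flag_significance(77.0)
        nwk = dend.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 4
        assert "significant=" in nwk
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk.replace("[&", "[").replace("]", "]")), "newick")
        assert tree.count_terminals() == 5


class TestPerturb:
    def test_zero_noise_is_identity(self, three_group_clean):
        profs = three_group_clean.profiles["MspI"][:3]
        out = cc.perturb_profiles(profs, cc.NoiseModel(0.0, 18000.0, 0.0), seed=1)
        for a, b in zip(profs, out):
            np.testing.assert_allclose(a.heights, b.heights)
            np.testing.assert_allclose(a.fragment_lengths, b.fragment_lengths)

    def test_seed_reproducibility(self, three_group_clean):
        profs = three_group_clean.profiles["MspI"][:3]
        a = cc.perturb_profiles(profs, cc.NoiseModel(), seed=42)
        b = cc.perturb_profiles(profs, cc.NoiseModel(), seed=42)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.heights, y.heights)

    def test_height_noise_sd_matches_nominal(self):
        prof = profile([(100.0, 9000.0), (200.0, 9000.0)])  # total = reference
        noise = cc.NoiseModel(sigma_height=46.0, reference_total=18000.0, sigma_bp=0.0)
        rng = np.random.default_rng(7)
        draws = []
        for _ in range(5000):
            out = cc.perturb_profiles([prof], noise, rng)[0]
            draws.extend(out.heights - prof.heights)
        assert np.std(draws) == pytest.approx(46.0, rel=0.05)


class TestMonteCarloSignificance:
    def test_zero_noise_threshold_100(self, three_group_clean):
        profs = three_group_clean.profiles["MspI"][:4]
        res = cc.monte_carlo_significance(
            profs, cc.NoiseModel(0.0, 18000.0, 0.0), n_replicates=2, seed=0
        )
        assert res.threshold == pytest.approx(100.0)

    def test_default_replicates_is_50(self):
        import inspect

        sig = inspect.signature(cc.monte_carlo_significance)
        assert sig.parameters["n_replicates"].default == 50

    def test_replicate_count_validation(self, three_group_clean):
        with pytest.raises(ValueError):
            cc.monte_carlo_significance(
                three_group_clean.profiles["MspI"][:3], cc.NoiseModel(), n_replicates=1
            )

    def test_threshold_non_increasing_in_height_noise(self, three_group_clean):
        """More replicate noise can only lower the worst replicate
        similarity (paired seeds)."""
        profs = three_group_clean.profiles["MspI"][:4]
        worse = 0
        for seed in range(20):
            lo = cc.monte_carlo_significance(
                profs, cc.NoiseModel(sigma_height=20.0, sigma_bp=0.02), n_replicates=8, seed=seed
            ).threshold
            hi = cc.monte_carlo_significance(
                profs, cc.NoiseModel(sigma_height=400.0, sigma_bp=0.02), n_replicates=8, seed=seed
            ).threshold
            if hi > lo + 1e-9:
                worse += 1
        assert worse == 0

    def test_nodes_flagged_against_threshold(self, three_group_clean):
        profs = three_group_clean.profiles["MspI"][:6]
        res = cc.monte_carlo_significance(profs, cc.NoiseModel(), n_replicates=5, seed=3)
        for node in res.dendrogram.nodes:
            assert node.significant == (node.similarity < res.threshold)
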