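import itertools

import numpy as np
import pytest

import irisphylo as ip
from irisphylo.shades import (
    ImageShadeSet,
    TierReference,
    assign_tiers,
    cluster_image,
    consensus_k,
    embed_pixels,
    extract_group_profile,
    match_shades,
    merge_group,
    select_k_elbow,
    stability_curve,
    tier_reference_from_profiles,
)

THREE_SHADES = [((30, 20, 10), 0.5, "d"), ((150, 120, 80), 0.3, "m"), ((220, 200, 180), 0.2, "l")]


class TestEmbedding:
    def test_pca_deterministic_and_distance_preserving(self):
        iris = ip.gen_iris(500, THREE_SHADES, noise_sd=3, seed=1)
        e1 = embed_pixels(iris.pixels, "pca")
        e2 = embed_pixels(iris.pixels, "pca")
        assert np.array_equal(e1, e2)
        # rank-2 data: 2-D pca embedding preserves pairwise distances
        t = np.random.default_rng(0).uniform(0, 1, (200, 2))
        X = t @ np.array([[50.0, 20.0, 10.0], [5.0, 40.0, 30.0]])
        emb = embed_pixels(X, "pca")
        i, j = np.triu_indices(50, k=1)
        d_orig = np.linalg.norm(X[i] - X[j], axis=1)
        d_emb = np.linalg.norm(emb[i] - emb[j], axis=1)
        assert np.abs(d_orig - d_emb).max() < 1e-6

    def test_separated_blobs_silhouette(self):
        from sklearn.metrics import silhouette_score

        iris = ip.gen_iris(600, [((20, 20, 20), 0.5), ((220, 220, 220), 0.5)], noise_sd=4, seed=2)
        emb = embed_pixels(iris.pixels, "pca")
        labels = iris.shade_labels
        assert silhouette_score(emb, labels) > 0.8

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            embed_pixels(np.array([[1.0, 2.0, 3.0]]), "pca")


class TestElbow:
    def test_degenerate_identical_pixels(self):
        emb = np.zeros((50, 2))
        assert select_k_elbow(emb) == 1

    @pytest.mark.parametrize("true_k", [2, 3, 4])
    def test_planted_k_recovered(self, true_k):
        spec = {
            2: [((30, 20, 10), 0.6), ((150, 120, 80), 0.4)],
            3: THREE_SHADES,
            4: [
                ((20, 20, 20), 0.25),
                ((90, 90, 90), 0.25),
                ((160, 160, 160), 0.25),
                ((230, 230, 230), 0.25),
            ],
        }[true_k]
        iris = ip.gen_iris(2000, spec, noise_sd=5, seed=true_k)
        emb = embed_pixels(iris.pixels, "pca")
        assert select_k_elbow(emb, seed=0) == true_k


class TestClusterImage:
    def test_k1_mean(self):
        iris = ip.gen_iris(300, [((90, 60, 30), 1.0, "x")], noise_sd=3, seed=0)
        emb = embed_pixels(iris.pixels, "pca")
        cs = cluster_image(iris.pixels, emb, 1)
        assert np.allclose(cs.clusters[0][0], iris.pixels.mean(axis=0))

    def test_zero_noise_exact_centroids(self):
        iris = ip.gen_iris(400, [((30, 20, 10), 0.5), ((150, 120, 80), 0.5)], noise_sd=0, seed=0)
        emb = embed_pixels(iris.pixels, "pca")
        cs = cluster_image(iris.pixels, emb, 2, seed=0)
        got = sorted(tuple(c[0]) for c in cs.clusters)
        assert got == [(30.0, 20.0, 10.0), (150.0, 120.0, 80.0)]

    def test_noisy_three_shades_close(self):
        iris = ip.gen_iris(3000, THREE_SHADES, noise_sd=5, seed=3)
        emb = embed_pixels(iris.pixels, "pca")
        cs = cluster_image(iris.pixels, emb, 3, seed=0)
        got = sorted(tuple(c[0]) for c in cs.clusters)
        planted = sorted(s.centroid for s in iris.shades)
        for g, p in zip(got, planted):
            assert np.abs(np.array(g) - np.array(p)).max() < 2.0

    def test_k_exceeding_distinct_points(self):
        iris = ip.gen_iris(100, [((10, 10, 10), 1.0, "x")], noise_sd=0, seed=0)
        emb = embed_pixels(iris.pixels, "pca")
        with pytest.raises(ValueError):
            cluster_image(iris.pixels, emb, 2)


class TestConsensusK:
    @pytest.mark.parametrize("ks,expected", [([2, 3, 3], 3), ([2, 2, 3], 2), ([2, 3], 3)])
    def test_half_up_rounding(self, ks, expected):
        assert consensus_k(ks) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_k([])


class TestMatchShades:
    def _set(self, means, counts=None):
        counts = counts or [10] * len(means)
        return ImageShadeSet("x", len(means), [(np.array(m, float), c) for m, c in zip(means, counts)])

    def test_identity_and_reversal(self):
        ref = self._set([(0, 0, 0), (100, 100, 100), (200, 200, 200)])
        assert match_shades(ref, ref) == (0, 1, 2)
        rev = self._set([(200, 200, 200), (100, 100, 100), (0, 0, 0)])
        assert match_shades(ref, rev) == (2, 1, 0)

    def test_matches_exhaustive_oracle_k4(self, rng):
        for _ in range(20):
            ref = self._set(rng.uniform(0, 255, (4, 3)))
            oth = self._set(rng.uniform(0, 255, (4, 3)))
            perm = match_shades(ref, oth)
            r = np.array([c[0] for c in ref.clusters])
            o = np.array([c[0] for c in oth.clusters])
            cost = lambda p: sum(((r[i] - o[p[i]]) ** 2).sum() for i in range(4))
            best = min(itertools.permutations(range(4)), key=cost)
            assert abs(cost(perm) - cost(best)) < 1e-9

    def test_unequal_k_rejected(self):
        with pytest.raises(ValueError):
            match_shades(self._set([(0, 0, 0)]), self._set([(0, 0, 0), (1, 1, 1)]))


class TestMergeGroup:
    def _set(self, name, means, counts):
        return ImageShadeSet(name, len(means), [(np.array(m, float), c) for m, c in zip(means, counts)])

    def test_single_image_identity(self):
        s = self._set("a", [(10, 10, 10), (200, 200, 200)], [30, 70])
        prof = merge_group([s])
        assert prof.k == 2
        assert prof.primary.count == 70

    def test_pixel_count_weighting(self):
        a = self._set("a", [(100, 0, 0)], [100])
        b = self._set("b", [(200, 0, 0)], [300])
        prof = merge_group([a, b])
        assert abs(prof.shades[0].rgb[0] - 175.0) < 1e-12

    def test_order_invariance(self, rng):
        sets = [
            self._set(f"i{k}", rng.uniform(0, 255, (2, 3)), rng.integers(10, 100, 2).tolist())
            for k in range(4)
        ]
        p1 = merge_group(sets)
        p2 = merge_group(list(reversed(sets)))
        for s1, s2 in zip(p1.shades, p2.shades):
            assert np.allclose(s1.rgb, s2.rgb)
            assert s1.count == s2.count

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_group([])


class TestAssignTiers:
    def _profile(self, means, counts):
        sets = ImageShadeSet("a", len(means), [(np.array(m, float), c) for m, c in zip(means, counts)])
        return merge_group([sets], taxon="t", color="brown")

    def test_three_shades_by_distance_from_black(self):
        prof = self._profile([(30, 30, 20), (80, 60, 50), (200, 160, 140)], [50, 30, 20])
        out = assign_tiers(prof)
        tiers = out.tiered()
        d = lambda t: np.linalg.norm(tiers[t].rgb)
        assert d("dark") < d("medium") < d("light")

    def test_two_shades_fill_medium_by_average(self):
        ref = TierReference(dark=(20, 20, 20), medium=(110, 110, 110), light=(220, 220, 220))
        prof = self._profile([(25, 20, 20), (210, 220, 215)], [60, 40])
        out = assign_tiers(prof, ref)
        tiers = out.tiered()
        assert set(tiers) == {"dark", "medium", "light"}
        expected_med = (np.asarray(tiers["dark"].rgb) + np.asarray(tiers["light"].rgb)) / 2
        assert np.allclose(tiers["medium"].rgb, expected_med)

    def test_two_shades_fill_light_by_duplication(self):
        ref = TierReference(dark=(20, 20, 20), medium=(110, 110, 110), light=(220, 220, 220))
        prof = self._profile([(25, 20, 20), (100, 110, 105)], [60, 40])
        out = assign_tiers(prof, ref)
        tiers = out.tiered()
        assert np.allclose(tiers["light"].rgb, tiers["medium"].rgb)

    def test_single_shade_duplicated_everywhere(self):
        prof = self._profile([(90, 80, 70)], [100])
        out = assign_tiers(prof)
        assert all(np.allclose(s.rgb, (90, 80, 70)) for s in out.shades)

    def test_four_shades_merge_two_closest(self):
        prof = self._profile(
            [(30, 30, 30), (100, 100, 100), (104, 100, 100), (220, 220, 220)], [40, 30, 10, 20]
        )
        out = assign_tiers(prof)
        tiers = out.tiered()
        assert set(tiers) == {"dark", "medium", "light"}
        # merged middle shade: count-weighted mean of the two closest, counts summed
        assert tiers["medium"].count == 40
        assert abs(tiers["medium"].rgb[0] - (100 * 30 + 104 * 10) / 40) < 1e-9

    def test_always_three_populated_tiers(self, rng):
        ref = TierReference(dark=(20, 20, 20), medium=(110, 110, 110), light=(220, 220, 220))
        for n in (1, 2, 3, 4):
            means = rng.uniform(0, 255, (n, 3))
            prof = self._profile(means, rng.integers(5, 50, n).tolist())
            out = assign_tiers(prof, ref)
            assert len(out.tiered()) == 3


class TestGroupPipeline:
    def test_zero_noise_exact_recovery(self):
        imgs = {
            f"i{j}": ip.gen_iris(1500, THREE_SHADES, noise_sd=0, seed=j).pixels for j in range(3)
        }
        prof = extract_group_profile(imgs, taxon="t", color="brown")
        assert prof.k == 3
        got = sorted(tuple(np.round(s.rgb, 9)) for s in prof.shades)
        assert got == sorted(s[0] for s in [( (30.0,20.0,10.0),), ((150.0,120.0,80.0),), ((220.0,200.0,180.0),)])

    def test_tier_reference_from_run(self):
        imgs = {
            f"i{j}": ip.gen_iris(1500, THREE_SHADES, noise_sd=3, seed=j).pixels for j in range(2)
        }
        prof = assign_tiers(extract_group_profile(imgs, taxon="t", color="brown"))
        ref = tier_reference_from_profiles([prof])
        assert np.allclose(ref.dark, prof.tiered()["dark"].rgb)

    def test_stability_identical_images_converges(self):
        px = ip.gen_iris(1000, THREE_SHADES, noise_sd=0, seed=0).pixels
        rows, conv = stability_curve({"a": px, "b": px, "c": px})
        assert conv
        assert np.allclose(rows[-1]["shade_rgbs"], rows[1]["shade_rgbs"])

    def test_stability_heterogeneous_does_not_converge(self):
        a = ip.gen_iris(1000, [((30, 20, 10), 0.5), ((150, 120, 80), 0.5)], noise_sd=0, seed=0).pixels
        b = ip.gen_iris(1000, [((90, 90, 90), 0.5), ((250, 240, 230), 0.5)], noise_sd=0, seed=1).pixels
        rows, conv = stability_curve({"a": a, "b": b})
        assert not conv
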