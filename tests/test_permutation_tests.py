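import numpy as np
import pytest

from odorkin import pipeline, synthetic_data as sd
from odorkin.dissimilarity import DissimilarityMatrix, bray_curtis
from odorkin.pedigree import classify_dyads
from odorkin.permutation_tests import (
    BlockedLabels,
    anosim_statistic,
    anosim_test,
    blocked_permutation,
    kin_anosim,
    mantel_test,
)

from _oracles import oracle_anosim_R


def labels_of(sample_ids, groups):
    """One block per sample (no repeated measures)."""
    return BlockedLabels(
        list(sample_ids),
        {s: s for s in sample_ids},
        dict(zip(sample_ids, groups)),
    )


def square(condensed4):
    w1, w2, b1, b2, b3, b4 = condensed4
    D = np.array([
        [0, w1, b1, b2],
        [w1, 0, b3, b4],
        [b1, b3, 0, w2],
        [b2, b4, w2, 0],
    ], dtype=float)
    return DissimilarityMatrix(["s1", "s2", "s3", "s4"], D)


class TestAnosimStatistic:
    def test_hand_rank_example_perfect_separation(self):
        D = square([1, 2, 3, 4, 5, 6])
        lab = labels_of(D.ids, ["A", "A", "B", "B"])
        assert anosim_statistic(D, lab) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 12))
            X = rng.uniform(0.1, 5, (n, 4))
            D = bray_curtis(X)
            groups = rng.choice(["A", "B"], n)
            # ensure every label has >= 2 samples
            groups[:4] = ["A", "A", "B", "B"]
            lab = labels_of(D.ids, groups)
            assert anosim_statistic(D, lab) == pytest.approx(
                oracle_anosim_R(D.values, np.asarray(lab.sample_labels()))
            )

    def test_monotone_transform_invariance(self, rng):
        X = rng.uniform(0.1, 5, (10, 4))
        D = bray_curtis(X)
        D2 = DissimilarityMatrix(D.ids, D.values**2)
        lab = labels_of(D.ids, ["A"] * 5 + ["B"] * 5)
        assert anosim_statistic(D, lab) == pytest.approx(anosim_statistic(D2, lab))

    def test_singleton_label_errors(self):
        D = square([1, 2, 3, 4, 5, 6])
        lab = labels_of(D.ids, ["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than two"):
            anosim_statistic(D, lab)


class TestBlockedPermutation:
    def _labels(self):
        samples = [f"s{i}" for i in range(6)]
        block_of = {"s0": "i1", "s1": "i1", "s2": "i2", "s3": "i2", "s4": "i3", "s5": "i3"}
        return BlockedLabels(samples, block_of, {"i1": "A", "i2": "B", "i3": "A"})

    def test_label_multiset_preserved(self, rng):
        lab = self._labels()
        for _ in range(20):
            perm = blocked_permutation(lab, rng)
            assert sorted(perm.label_of.values()) == sorted(lab.label_of.values())
            # samples still inherit their block's label
            sl = perm.sample_labels()
            assert sl[0] == sl[1] and sl[2] == sl[3] and sl[4] == sl[5]

    def test_fixed_seed_reproducible(self):
        lab = self._labels()
        a = blocked_permutation(lab, np.random.default_rng(9)).sample_labels()
        b = blocked_permutation(lab, np.random.default_rng(9)).sample_labels()
        assert (a == b).all()


class TestAnosimTest:
    def test_perfect_separation_min_p(self):
        # 10 samples in 5+5 groups, distances perfectly separated
        X = np.vstack([np.tile([5.0, 0.1], (5, 1)) + np.arange(5)[:, None] * 0.01,
                       np.tile([0.1, 5.0], (5, 1)) + np.arange(5)[:, None] * 0.01])
        D = bray_curtis(X)
        lab = labels_of(D.ids, ["A"] * 5 + ["B"] * 5)
        res = anosim_test(D, lab, n_perm=999, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.p >= 1 / 1000
        assert res.p < 0.05

    def test_determinism(self, rng):
        X = rng.uniform(0.1, 5, (10, 4))
        D = bray_curtis(X)
        lab = labels_of(D.ids, ["A"] * 5 + ["B"] * 5)
        r1 = anosim_test(D, lab, n_perm=99, seed=7)
        r2 = anosim_test(D, lab, n_perm=99, seed=7)
        assert r1.R == r2.R and r1.p == r2.p

    def test_p_on_permutation_grid(self, rng):
        X = rng.uniform(0.1, 5, (8, 3))
        D = bray_curtis(X)
        lab = labels_of(D.ids, ["A"] * 4 + ["B"] * 4)
        res = anosim_test(D, lab, n_perm=9, seed=1)
        assert round(res.p * 10) == pytest.approx(res.p * 10)

    def test_matches_skbio_R(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        X = rng.uniform(0.1, 5, (12, 5))
        D = bray_curtis(X)
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        lab = labels_of(D.ids, groups)
        dm = skbio_stats.DistanceMatrix(D.values, D.ids)
        expected = skbio_stats.anosim(dm, grouping=groups, permutations=0)
        assert anosim_statistic(D, lab) == pytest.approx(expected["test statistic"])


class TestKinAnosim:
    def _setup(self, seed=4):
        cfg = sd.SimulationConfig(seed=seed, maternal_family_sd=2.0, residual_sd=0.5)
        meta, ped, peaks, blanks = sd.simulate_study(cfg)
        rel, _ = pipeline.preprocess_peaks(peaks, blanks)
        from odorkin.preprocess import transform_similarity
        D = bray_curtis(transform_similarity(rel), ids=list(rel.sample_ids))
        dyads = classify_dyads(ped, list(meta.individuals.index))
        return D, dyads, meta

    def test_planted_maternal_effect_positive_R(self):
        D, dyads, meta = self._setup()
        res = kin_anosim(D, dyads, meta.sample_map, "maternal", n_perm=99, seed=0)
        assert res.R > 0
        assert res.scheme == "blocked_sibship_maternal"
        assert res.n_within > 0 and res.n_between > 0

    def test_identical_profiles_degenerate_flag(self):
        cfg = sd.SimulationConfig(seed=1)
        meta, ped = sd.simulate_colony(cfg)
        n = len(meta.sample_map)
        D = DissimilarityMatrix(list(meta.sample_map.index), np.zeros((n, n)))
        dyads = classify_dyads(ped, list(meta.individuals.index))
        res = kin_anosim(D, dyads, meta.sample_map, "maternal", n_perm=49, seed=0)
        assert res.R == 0.0
        assert res.degenerate_ties

    def test_planted_effect_detected_across_replicates(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = sd.SimulationConfig(seed=100 + rep, maternal_family_sd=2.0,
                                      residual_sd=0.5)
            meta, ped, peaks, blanks = sd.simulate_study(cfg)
            rel, _ = pipeline.preprocess_peaks(peaks, blanks)
            from odorkin.preprocess import transform_similarity
            D = bray_curtis(transform_similarity(rel), ids=list(rel.sample_ids))
            dyads = classify_dyads(ped, list(meta.individuals.index))
            res = kin_anosim(D, dyads, meta.sample_map, "maternal", n_perm=49, seed=rep)
            hits += res.R > 0
        assert hits >= int(0.95 * n_rep)


class TestMantel:
    def _rand_dm(self, rng, n=12):
        X = rng.uniform(0.1, 5, (n, 4))
        return bray_curtis(X, ids=[f"i{k}" for k in range(n)], level="individual")

    def test_self_correlation_one(self, rng):
        D = self._rand_dm(rng)
        res = mantel_test(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        D = self._rand_dm(rng)
        D2 = DissimilarityMatrix(D.ids, 3.0 * D.values + 0.0, D.level)
        assert mantel_test(D, D2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_matches_skbio_r(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        D1, D2 = self._rand_dm(rng), self._rand_dm(rng)
        r_skbio, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(D1.values, D1.ids),
            skbio_stats.DistanceMatrix(D2.values, D2.ids),
            method="pearson", permutations=0,
        )
        assert mantel_test(D1, D2, n_perm=9, seed=0).r == pytest.approx(float(r_skbio))

    def test_independent_matrices_small_r(self, rng):
        ok = 0
        n_draw = 200
        for _ in range(n_draw):
            D1, D2 = self._rand_dm(rng, n=30), self._rand_dm(rng, n=30)
            D2 = DissimilarityMatrix(D1.ids, D2.values, "individual")
            if abs(mantel_test(D1, D2, n_perm=1, seed=0).r) < 0.3:
                ok += 1
        assert ok >= int(0.95 * n_draw)

    def test_constant_matrix_errors(self):
        ids = ["a", "b", "c"]
        D1 = DissimilarityMatrix(ids, np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        ones = np.ones((3, 3)) - np.eye(3)
        D2 = DissimilarityMatrix(ids, ones)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(D1, D2, n_perm=9, seed=0)

    def test_mismatched_ids_error(self, rng):
        D1 = self._rand_dm(rng)
        D2 = DissimilarityMatrix([f"x{k}" for k in range(len(D1.ids))], D1.values)
        with pytest.raises(ValueError, match="ids"):
            mantel_test(D1, D2)
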