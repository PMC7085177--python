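"""Sketch distances, Bray-Curtis, BioEnv, permutation tests, matrix
correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from dwmeta import distance, simulate
from dwmeta.distance import (
    bioenv,
    bray_curtis,
    bray_curtis_matrix,
    group_distance_test,
    matrix_correlation,
    minhash_sketch,
    sketch_distance,
)

COMP = str.maketrans("ACGT", "TGCA")


def exact_jaccard(seq_a, seq_b, k):
    """Brute-force canonical k-mer sets and exact Jaccard index."""

    def canon_set(seq):
        out = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= set("ACGT"):
                rc = kmer.translate(COMP)[::-1]
                out.add(min(kmer, rc))
        return out

    a, b = canon_set(seq_a), canon_set(seq_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def mash_formula(j, k):
    if j == 0:
        return 1.0
    return min(1.0, -(1.0 / k) * math.log(2 * j / (1 + j)))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSketch:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        seqs = [random_seq(rng, 500)]
        a = minhash_sketch(seqs, k=15, size=100, seed=1)
        b = minhash_sketch(seqs, k=15, size=100, seed=1)
        assert np.array_equal(a.hashes, b.hashes)
        assert sketch_distance(a, b) == 0.0

    def test_sequence_shorter_than_k_gives_empty_sketch(self):
        sk = minhash_sketch(["ACGT"], k=21, size=10, seed=1)
        assert len(sk.hashes) == 0

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 300)
        rc = seq.translate(COMP)[::-1]
        a = minhash_sketch([seq], k=15, size=1000, seed=1)
        b = minhash_sketch([rc], k=15, size=1000, seed=1)
        assert np.array_equal(a.hashes, b.hashes)

    def test_non_acgt_kmers_skipped(self):
        a = minhash_sketch(["ACGTNNNNACGT"], k=5, size=100, seed=1)
        assert len(a.hashes) == 0  # every 5-mer overlaps an N

    def test_mismatched_parameters_rejected(self):
        a = minhash_sketch(["ACGTACGTACGT"], k=5, size=10, seed=1)
        b = minhash_sketch(["ACGTACGTACGT"], k=7, size=10, seed=1)
        with pytest.raises(ValueError):
            sketch_distance(a, b)

    def test_min_copies_filter(self):
        # the duplicated k-mer survives, the singleton does not
        seqs = ["AAAAA", "AAAAA", "CCCCC"]
        sk = minhash_sketch(seqs, k=5, size=10, seed=1, min_copies=2)
        assert len(sk.hashes) == 1

    def test_exact_jaccard_oracle(self):
        """With sketch cardinality above the distinct k-mer count the merged
        estimator reproduces the closed form at the exact Jaccard index."""
        rng = np.random.default_rng(42)
        k = 15
        for _ in range(20):
            base = random_seq(rng, int(rng.integers(200, 1000)))
            # related pair: mutate a copy so the Jaccard spans (0, 1)
            other = list(base)
            n_mut = int(rng.integers(0, len(base) // 4))
            for pos in rng.integers(0, len(base), n_mut):
                other[pos] = "ACGT"[rng.integers(4)]
            other = "".join(other)
            a = minhash_sketch([base], k=k, size=50_000, seed=9)
            b = minhash_sketch([other], k=k, size=50_000, seed=9)
            j = exact_jaccard(base, other, k)
            assert sketch_distance(a, b) == pytest.approx(mash_formula(j, k), abs=1e-12)

    def test_disjoint_sets_distance_one(self):
        a = minhash_sketch(["AAAAAAAAAA"], k=7, size=10, seed=1)
        b = minhash_sketch(["CCCCCCCCCC"], k=7, size=10, seed=1)
        assert sketch_distance(a, b) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = minhash_sketch([random_seq(rng, 400)], k=15, size=200, seed=1)
        b = minhash_sketch([random_seq(rng, 400)], k=15, size=200, seed=1)
        assert sketch_distance(a, b) == sketch_distance(b, a)

    def test_distance_tracks_planted_divergence(self):
        """Across seeds, sample sketch distance grows with the divergence of
        the planted abundance vectors (rank correlation against a
        Monte-Carlo-style divergence oracle)."""
        study = simulate.generate_study(simulate.StudyConfig(seed=3))
        s_ref = study.samples.index[0]
        frags_ref = simulate.generate_sample_sequences(study, s_ref, seed=0)
        sk_ref = minhash_sketch(frags_ref, k=15, size=20_000, seed=1)
        divergences, distances = [], []
        for other in study.samples.index[1:11]:
            frags = simulate.generate_sample_sequences(study, other, seed=0)
            sk = minhash_sketch(frags, k=15, size=20_000, seed=1)
            a = study.taxon_abundance[s_ref]
            b = study.taxon_abundance[other]
            divergences.append(bray_curtis(a / a.sum(), b / b.sum()))
            distances.append(sketch_distance(sk_ref, sk))
        rho = spearmanr(divergences, distances)[0]
        assert rho > 0.5


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1.0, 0.0], [0.0, 3.0]) == 1.0

    def test_direct_value(self):
        assert bray_curtis([2.0, 1.0], [1.0, 1.0]) == pytest.approx(0.2)

    def test_both_zero(self):
        assert bray_curtis([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([-1.0], [1.0])

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=8),
        st.lists(st.floats(0, 100), min_size=2, max_size=8),
        st.randoms(use_true_random=False),
    )
    @settings(derandomize=True, max_examples=100)
    def test_range_and_permutation_invariance(self, x, y, rnd):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        perm = list(range(n))
        rnd.shuffle(perm)
        assert bray_curtis([x[i] for i in perm], [y[i] for i in perm]) == pytest.approx(d)


def env_fixture(seed=0, n=12):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    env = pd.DataFrame(
        {v: rng.normal(size=n) for v in [f"v{j}" for j in range(9)]}, index=idx
    )
    return env


class TestBioEnv:
    def test_evaluates_all_511_subsets(self):
        env = env_fixture()
        dm = DistanceMatrix(
            np.abs(env["v0"].to_numpy()[:, None] - env["v0"].to_numpy()[None, :]),
            list(env.index),
        )
        res = bioenv(dm, env)
        assert res.n_subsets == 2**9 - 1 == 511
        assert len(set(res.results["subset"])) == 511

    def test_perfect_singleton_attains_rho_one(self):
        env = env_fixture(seed=1)
        z = (env["v3"] - env["v3"].mean()) / env["v3"].std(ddof=1)
        dm = DistanceMatrix(
            np.abs(z.to_numpy()[:, None] - z.to_numpy()[None, :]), list(env.index)
        )
        res = bioenv(dm, env)
        assert "v3" in res.best_subset
        singleton = res.results[res.results["subset"] == ("v3",)]
        assert singleton["rho"].iloc[0] == pytest.approx(1.0)

    def test_best_rho_bounds_singletons(self):
        env = env_fixture(seed=2)
        rng = np.random.default_rng(0)
        mat = np.abs(rng.normal(size=(12, 12)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        res = bioenv(DistanceMatrix(mat, list(env.index)), env)
        singles = res.results[res.results["size"] == 1]["rho"]
        assert res.best_rho >= singles.max() - 1e-12

    def test_matches_skbio_bioenv_per_size(self):
        """Cross-check the exhaustive search against scikit-bio's independent
        implementation: for each subset size the best subset and rho agree."""
        from skbio.stats.distance import bioenv as skbio_bioenv

        env = env_fixture(seed=3, n=10)[["v0", "v1", "v2", "v3"]]
        rng = np.random.default_rng(4)
        mat = np.abs(rng.normal(size=(10, 10)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        dm = DistanceMatrix(mat, list(env.index))
        mine = bioenv(dm, env)
        theirs = skbio_bioenv(dm, env)
        for size, row in theirs.iterrows():
            best_at_size = mine.results[mine.results["size"] == row["size"]].iloc[0]
            assert best_at_size["rho"] == pytest.approx(
                row["correlation"], abs=1e-12
            )

    def test_constant_variable_excluded_with_warning(self):
        env = env_fixture(seed=5)
        env["flat"] = 1.0
        rng = np.random.default_rng(6)
        mat = np.abs(rng.normal(size=(12, 12)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        with pytest.warns(UserWarning, match="constant"):
            res = bioenv(DistanceMatrix(mat, list(env.index)), env)
        assert res.n_subsets == 2**9 - 1
        assert all("flat" not in s for s in res.results["subset"])


def clustered_dm(n_per=4, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate([rng.normal(0, 0.1, n_per), rng.normal(gap, 0.1, n_per)])
    ids = [f"s{i}" for i in range(2 * n_per)]
    mat = np.abs(pts[:, None] - pts[None, :])
    np.fill_diagonal(mat, 0)
    groups = {ids[i]: ("D" if i < n_per else "ND") for i in range(2 * n_per)}
    return DistanceMatrix(mat, ids), groups


class TestGroupDistanceTest:
    def test_separated_clusters_attain_minimum_p(self):
        # groups large enough that no permutation reproduces the true split
        dm, groups = clustered_dm(n_per=8)
        res = group_distance_test(dm, groups, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_deterministic_under_seed_and_label_permutation(self):
        dm, groups = clustered_dm(seed=3)
        res1 = group_distance_test(dm, groups, n_perm=99, seed=5)
        # feed the samples in a different order: null stream must be identical
        order = list(reversed(dm.ids))
        dm2 = dm.filter(order)
        res2 = group_distance_test(dm2, groups, n_perm=99, seed=5)
        assert res1.p_value == res2.p_value
        assert res1.observed == pytest.approx(res2.observed)

    def test_degenerate_grouping_rejected(self):
        dm, groups = clustered_dm()
        bad = dict(groups)
        for k in list(bad)[1:4]:
            bad[k] = "ND"  # leaves a single D sample
        with pytest.raises(ValueError):
            group_distance_test(dm, bad)

    def test_null_calibration_quick(self):
        """Under exchangeable distances the test should reject ~5% at alpha
        0.05 (quick version; the full 500-replicate calibration runs in the
        acceptance suite)."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            n = 12
            mat = np.abs(rng.normal(size=(n, n)))
            mat = (mat + mat.T) / 2
            np.fill_diagonal(mat, 0)
            ids = [f"s{i}" for i in range(n)]
            labels = ["D"] * 6 + ["ND"] * 6
            rng.shuffle(labels)
            groups = dict(zip(ids, labels))
            res = group_distance_test(
                DistanceMatrix(mat, ids), groups, n_perm=199, seed=rep
            )
            rejections += res.p_value <= 0.05
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 4 * se

    def test_permanova_mode_agrees_with_skbio(self):
        dm, groups = clustered_dm(seed=9)
        res = group_distance_test(dm, groups, n_perm=99, seed=1, method="permanova")
        assert res.p_value <= 0.05
        assert res.method == "permanova"


class TestMatrixCorrelation:
    def square(self, mat, ids):
        return DistanceMatrix(mat, ids)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        mat = np.abs(rng.normal(size=(4, 4)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        dm = self.square(mat, list("abcd"))
        assert matrix_correlation(dm, dm) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        mat = np.abs(rng.normal(size=(4, 4)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        a = self.square(mat, list("abcd"))
        b = self.square(2 * mat + 0.1 * (1 - np.eye(4)), list("abcd"))
        assert matrix_correlation(a, b) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        m1 = np.abs(rng.normal(size=(4, 4)))
        m1 = (m1 + m1.T) / 2
        np.fill_diagonal(m1, 0)
        m2 = np.abs(rng.normal(size=(4, 4)))
        m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m2, 0)
        a, b = self.square(m1, list("abcd")), self.square(m2, list("abcd"))
        x = m1[np.triu_indices(4, 1)]
        y = m2[np.triu_indices(4, 1)]
        expected = np.corrcoef(x, y)[0, 1]
        assert matrix_correlation(a, b) == pytest.approx(expected)

    def test_sample_to_system_aggregation(self):
        # 4 samples in 2 systems; aggregated matrix is the mean of cross pairs
        ids = ["a1", "a2", "b1", "b2"]
        mat = np.array(
            [
                [0.0, 0.1, 0.5, 0.7],
                [0.1, 0.0, 0.3, 0.5],
                [0.5, 0.3, 0.0, 0.2],
                [0.7, 0.5, 0.2, 0.0],
            ]
        )
        a = self.square(mat, ids)
        mapping = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        agg = distance.aggregate_distance_matrix(a, mapping)
        assert agg["A", "B"] == pytest.approx(np.mean([0.5, 0.7, 0.3, 0.5]))

    def test_too_few_pairs_rejected(self):
        mat = np.array([[0.0, 1.0], [1.0, 0.0]])
        dm = self.square(mat, list("ab"))
        with pytest.raises(ValueError):
            matrix_correlation(dm, dm)
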