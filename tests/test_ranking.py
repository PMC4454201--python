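"""Impact vectors, PCC scoring, ranking, permutation significance."""

import numpy as np
import pytest

from proteinrank.network import build_network, column_normalize
from proteinrank.propagation import WalkConfig
from proteinrank.ranking import (
    ImpactVectorSet,
    SeedSet,
    compute_impact_vectors,
    impact_vector,
    pcc,
    permutation_pvalue,
    prioritize,
    rank_score,
    read_seed_list,
    write_rank_result,
)
from proteinrank.synthetic import SyntheticSpec, generate
from proteinrank.weighting import FoldChangeTable

from conftest import random_network


class TestPcc:
    def test_self_correlation_is_one(self):
        x = np.array([0.1, 0.4, 0.2, 0.3])
        assert pcc(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.array([0.1, 0.4, 0.2, 0.3])
        assert pcc(x, 2.5 * x + 7.0) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pcc(np.array([1, 2, 3, 4.0]), np.array([4, 3, 2, 1.0])) == \
            pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pcc(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(50), rng.random(50)
        assert pcc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


class TestSeedSet:
    def test_empty_and_duplicate_rejected(self):
        with pytest.raises(ValueError):
            SeedSet(ids=())
        with pytest.raises(ValueError):
            SeedSet(ids=("A", "A"))

    def test_unmatched_seeds_dropped(self, triangle):
        ss = SeedSet(ids=("A", "GHOST")).restrict_to(triangle)
        assert ss.ids == ("A",)

    def test_no_seed_in_network_raises(self, triangle):
        with pytest.raises(ValueError):
            SeedSet(ids=("GHOST",)).restrict_to(triangle)

    def test_reader(self, tmp_path):
        p = tmp_path / "seeds.txt"
        p.write_text("# known\nA\nB\n\nC\n")
        assert read_seed_list(p).ids == ("A", "B", "C")


class TestImpactVector:
    def test_full_restart_is_unit_vector(self, triangle):
        wt = column_normalize(triangle)
        v = impact_vector("A", wt, triangle.node_ids,
                          WalkConfig(restart_prob=1.0))
        expect = np.zeros(3)
        expect[triangle.node_ids.index("A")] = 1.0
        assert np.array_equal(v, expect)

    def test_two_node_vectors_are_mirror_images(self, two_node):
        wt = column_normalize(two_node)
        cfg = WalkConfig(tol=1e-13)
        va = impact_vector("A", wt, two_node.node_ids, cfg)
        vb = impact_vector("B", wt, two_node.node_ids, cfg)
        assert np.allclose(va, vb[::-1], atol=1e-10)

    def test_unknown_node_raises(self, triangle):
        with pytest.raises(KeyError):
            impact_vector("GHOST", column_normalize(triangle),
                          triangle.node_ids, WalkConfig())

    def test_set_matches_resolvent_columns(self):
        net = random_network(40, seed=21)
        ivs = compute_impact_vectors(net, None, WalkConfig(restart_prob=0.4))
        w = column_normalize(net).matrix.toarray()
        n = net.n_nodes
        oracle = 0.4 * np.linalg.inv(np.eye(n) - 0.6 * w)
        assert np.abs(ivs.matrix - oracle).max() < 1e-10

    def test_restart_floor_on_own_entry(self):
        net = random_network(30, seed=22)
        ivs = compute_impact_vectors(net, None, WalkConfig(restart_prob=0.4))
        assert np.all(np.diag(ivs.matrix) >= 0.4 - 1e-12)
        assert np.abs(ivs.matrix.sum(axis=0) - 1.0).max() < 1e-9


class TestRankScore:
    def test_sole_seed_self_term_is_one(self):
        net = random_network(20, seed=23)
        ivs = compute_impact_vectors(net, None, WalkConfig())
        s = net.node_ids[0]
        assert rank_score(s, ivs, SeedSet(ids=(s,))) == pytest.approx(1.0)

    def test_bounded_by_seed_count(self):
        net = random_network(30, seed=24)
        ivs = compute_impact_vectors(net, None, WalkConfig())
        seeds = SeedSet(ids=tuple(net.node_ids[:4]))
        for v in net.node_ids:
            assert 0.0 <= rank_score(v, ivs, seeds) <= 4.0 + 1e-12

    def test_matches_bruteforce_abs_pcc_loop(self):
        net = random_network(30, seed=25)
        fc = FoldChangeTable(entries={net.node_ids[i]: f
                                      for i, f in enumerate((3.0, 0.5, 2.0))})
        ivs = compute_impact_vectors(net, fc, WalkConfig())
        seeds = SeedSet(ids=tuple(net.node_ids[5:8]))
        for cand in net.node_ids[:10]:
            expect = sum(
                abs(np.corrcoef(ivs.vector(cand), ivs.vector(s))[0, 1])
                for s in seeds.ids
            )
            assert rank_score(cand, ivs, seeds) == pytest.approx(expect, abs=1e-10)


class TestPrioritize:
    def test_automorphic_nodes_tie(self, path_abc):
        fc = FoldChangeTable(entries={v: 2.0 for v in path_abc.node_ids})
        res = prioritize(path_abc, fc, SeedSet(ids=("B",)))
        t = res.table.set_index("protein_id")
        assert t.loc["A", "rank_score"] == pytest.approx(
            t.loc["C", "rank_score"], abs=1e-12)

    def test_fold_change_scale_invariance(self, study):
        net, fc, seeds, _ = study
        doubled = FoldChangeTable(
            entries={k: 2 * v for k, v in fc.entries.items()})
        a = prioritize(net, fc, seeds).table
        b = prioritize(net, doubled, seeds).table
        assert list(a.protein_id) == list(b.protein_id)
        assert np.abs(a.rank_score.values - b.rank_score.values).max() < 1e-10

    def test_deterministic_and_complete(self, study):
        net, fc, seeds, _ = study
        a = prioritize(net, fc, seeds, n_permutations=20, rng_seed=3).table
        b = prioritize(net, fc, seeds, n_permutations=20, rng_seed=3).table
        assert a.equals(b)
        assert len(a) == net.n_nodes
        assert list(a["rank"]) == list(range(1, net.n_nodes + 1))
        # descending scores with id tie-break
        assert (np.diff(a.rank_score.values) <= 1e-15).all()

    def test_seeds_are_scored_with_self_term(self, study):
        net, fc, seeds, _ = study
        t = prioritize(net, fc, seeds).table.set_index("protein_id")
        for s in seeds.ids:
            assert t.loc[s, "is_seed"]
            assert t.loc[s, "rank_score"] >= 1.0 - 1e-12

    def test_no_permutations_means_no_pvalue_column(self, study):
        net, fc, seeds, _ = study
        assert "p_value" not in prioritize(net, fc, seeds).table.columns

    def test_writer_precision(self, study, tmp_path):
        import pandas as pd
        net, fc, seeds, _ = study
        res = prioritize(net, fc, seeds)
        out = tmp_path / "rank.tsv"
        write_rank_result(res, out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["rank", "protein_id", "rank_score", "is_seed"]
        # scores rendered at 4 decimals
        txt = out.read_text().splitlines()[1]
        assert len(txt.split("\t")[2].split(".")[1]) == 4


class TestPermutationPvalue:
    def test_maximal_score_gets_smallest_p(self):
        net = random_network(30, seed=26)
        ivs = compute_impact_vectors(net, None, WalkConfig())
        p = permutation_pvalue(3.0, net.node_ids[0], ivs, k=3,
                               n_permutations=49, rng_seed=0)
        assert p == pytest.approx(1 / 50)

    def test_impossible_low_score_gets_p_one(self):
        net = random_network(30, seed=27)
        ivs = compute_impact_vectors(net, None, WalkConfig())
        p = permutation_pvalue(-1.0, net.node_ids[0], ivs, k=3,
                               n_permutations=49, rng_seed=0)
        assert p == 1.0

    def test_deterministic_given_rng_seed(self):
        net = random_network(30, seed=28)
        ivs = compute_impact_vectors(net, None, WalkConfig())
        args = (1.2, net.node_ids[4], ivs, 4, 99)
        assert permutation_pvalue(*args, rng_seed=5) == \
            permutation_pvalue(*args, rng_seed=5)

    def test_k_too_large_raises(self, triangle):
        ivs = compute_impact_vectors(triangle, None, WalkConfig())
        with pytest.raises(ValueError):
            permutation_pvalue(1.0, "A", ivs, k=3, n_permutations=10, rng_seed=0)


def brute_force_pipeline(net, fc_entries, seed_ids, r=0.4, n_iter=5000):
    """Straight-line dense re-implementation of the whole method.

    Power iteration, explicit neighborhood sums, np.corrcoef — sharing no
    code path with the package implementation.
    """
    n = net.n_nodes
    A = net.adjacency.toarray()
    deg = A.sum(axis=0)
    W = A / deg  # column j divided by deg(j)
    p0 = np.zeros(n)
    for pid, f in fc_entries.items():
        if pid in net.node_ids:
            p0[net.node_ids.index(pid)] = f
    p0 /= p0.sum()
    p = p0.copy()
    for _ in range(n_iter):
        p = (1 - r) * W @ p + r * p0
    impact = p
    weights = np.zeros((n, n))
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        total = impact[nbrs].sum()
        for j in nbrs:
            weights[i, j] = impact[j] / total
    Wt = weights.T  # column u holds u's out-distribution
    vectors = np.zeros((n, n))
    for u in range(n):
        e = np.zeros(n)
        e[u] = 1.0
        q = e.copy()
        for _ in range(n_iter):
            q = (1 - r) * Wt @ q + r * e
        vectors[:, u] = q
    seed_idx = [net.node_ids.index(s) for s in seed_ids]
    scores = np.zeros(n)
    for c in range(n):
        scores[c] = sum(
            abs(np.corrcoef(vectors[:, c], vectors[:, s])[0, 1])
            for s in seed_idx
        )
    return scores


def test_prioritize_matches_straight_line_oracle():
    """End-to-end agreement with an independent dense re-implementation."""
    net = random_network(50, seed=29, p=0.12)
    rng = np.random.default_rng(1)
    dep_ids = list(rng.choice(net.node_ids, size=10, replace=False))
    fc = {pid: float(np.exp(rng.normal(0.7, 0.3))) for pid in dep_ids}
    seeds = tuple(rng.choice(net.node_ids, size=4, replace=False))
    oracle = brute_force_pipeline(net, fc, seeds)
    res = prioritize(net, FoldChangeTable(entries=fc), SeedSet(ids=seeds),
                     WalkConfig(tol=1e-14, max_iter=10_000))
    got = res.table.set_index("protein_id").rank_score
    for i, pid in enumerate(net.node_ids):
        assert abs(got.loc[pid] - oracle[i]) < 1e-8
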