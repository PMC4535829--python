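"""Complete-linkage clustering, DB-guided cuts, MDS and agreement scoring."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from asdist.cluster import (
    ClusterAssignment,
    classical_mds,
    cluster_agreement,
    complete_linkage,
    cut_by_db,
    davies_bouldin,
    dendrogram_to_newick,
    pairwise_matrix,
)
from asdist.synthetic import make_family, make_random_walk


def _planted(n_families, seed, n_perturbed=5):
    frags = []
    for fam in range(n_families):
        fam_frags, _ = make_family(
            1000 * seed + fam, n_perturbed=n_perturbed, n_indel=0, n_decoys=0
        )
        frags += [f.with_coords(f.coords, id=f"f{fam}.{f.id}") for f in fam_frags]
    return frags


def _naive_complete_linkage(values):
    """O(n^3) agglomeration oracle: merge the closest pair, max-update."""
    n = values.shape[0]
    active = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): values[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(active) > 1:
        pair = min(d, key=lambda k: (d[k], sorted(k)))
        a, b = sorted(pair)
        heights.append(d[pair])
        merged = active.pop(a) + active.pop(b)
        for k in list(d):
            if a in k or b in k:
                del d[k]
        for c, members in active.items():
            d[frozenset((next_id, c))] = max(
                values[i, j] for i in merged for j in members
            )
        active[next_id] = merged
        next_id += 1
    return heights


class TestPairwiseMatrix:
    def test_identical_fragments_zero_matrix(self):
        f = make_random_walk(10, 1)
        bank = [f.with_coords(f.coords, id=f"c{i}") for i in range(3)]
        m = pairwise_matrix(bank)
        assert np.abs(m.to_numpy()).max() < 1e-8

    def test_mixed_lengths_computable(self):
        bank = [make_random_walk(n, n) for n in range(6, 11)]
        m = pairwise_matrix(bank)
        assert m.shape == (5, 5)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.all(np.diag(m.to_numpy()) == 0)

    def test_symmetric_by_construction(self):
        bank = [make_random_walk(8, 50 + i) for i in range(4)]
        m = pairwise_matrix(bank).to_numpy()
        assert np.array_equal(m, m.T)  # each pair scored exactly once

    def test_cache_roundtrip(self, tmp_path):
        bank = [make_random_walk(8, 60 + i) for i in range(4)]
        cache = tmp_path / "m.tsv"
        m1 = pairwise_matrix(bank, cache=str(cache))
        m2 = pairwise_matrix(bank, cache=str(cache))
        pd.testing.assert_frame_equal(m1, m2)

    def test_unscorable_pair_named(self):
        bank = [make_random_walk(8, 1), make_random_walk(9, 2)]
        with pytest.raises(ValueError, match=bank[0].id):
            pairwise_matrix(bank, scorer="rmsd")


class TestCompleteLinkage:
    def test_three_points_first_merge(self):
        m = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        dendro = complete_linkage(m)
        assert dendro.heights[0] == pytest.approx(1.0)
        assert dendro.heights[-1] == pytest.approx(10.0)

    def test_two_families_top_split(self):
        frags = _planted(2, seed=1)
        m = pairwise_matrix(frags)
        dendro = complete_linkage(m)
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(dendro.linkage, t=2, criterion="maxclust")
        groups = {fid.split(".")[0] for fid, c in zip(dendro.leaf_ids, flat) if c == 1}
        assert len(groups) == 1  # top split separates the planted families

    def test_heights_match_naive_oracle(self):
        rng = np.random.default_rng(42)
        frags = [make_random_walk(10, int(rng.integers(2**31))) for _ in range(12)]
        values = pairwise_matrix(frags).to_numpy()
        dendro = complete_linkage(values)
        assert dendro.heights == pytest.approx(_naive_complete_linkage(values))

    def test_heights_nondecreasing(self):
        frags = _planted(3, seed=2)
        dendro = complete_linkage(pairwise_matrix(frags))
        assert np.all(np.diff(dendro.heights) >= -1e-12)

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(3)
        frags = [make_random_walk(9, int(rng.integers(2**31))) for _ in range(9)]
        m = pairwise_matrix(frags)
        perm = rng.permutation(len(frags))
        m2 = m.iloc[perm, perm]
        h1 = complete_linkage(m).heights
        h2 = complete_linkage(m2).heights
        assert h1 == pytest.approx(h2)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(np.array([[0, 1.0], [2.0, 0]]))


class TestDaviesBouldin:
    def test_zero_for_separated_zero_diameter_clusters(self):
        # two duplicated points far apart
        m = np.array(
            [[0, 0, 9, 9], [0, 0, 9, 9], [9, 9, 0, 0], [9, 9, 0, 0]], dtype=float
        )
        a = ClusterAssignment({"0": 0, "1": 0, "2": 1, "3": 1}, k=2)
        assert davies_bouldin(m, a) == 0.0

    def test_true_split_beats_random_split(self):
        frags = _planted(2, seed=5)
        m = pairwise_matrix(frags)
        ids = list(m.columns)
        truth = ClusterAssignment({i: 0 if i.startswith("f0") else 1 for i in ids}, k=2)
        half = len(ids) // 2
        interleaved = ClusterAssignment(
            {i: n % 2 for n, i in enumerate(ids)}, k=2
        )
        assert davies_bouldin(m, truth) < davies_bouldin(m, interleaved)
        assert half > 0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        frags = [make_random_walk(10, int(rng.integers(2**31))) for _ in range(9)]
        m = pairwise_matrix(frags)
        values = m.to_numpy()
        ids = list(m.columns)
        labels = {i: n % 3 for n, i in enumerate(ids)}
        a = ClusterAssignment(labels, k=3)
        # direct evaluation with the same medoid convention
        scatter, medoid = {}, {}
        for c in range(3):
            members = [n for n, i in enumerate(ids) if labels[i] == c]
            med = min(members, key=lambda i: sum(values[i, j] for j in members))
            medoid[c] = med
            scatter[c] = np.mean([values[j, med] for j in members])
        expected = np.mean(
            [
                max(
                    (scatter[a_] + scatter[b_]) / values[medoid[a_], medoid[b_]]
                    for b_ in range(3)
                    if b_ != a_
                )
                for a_ in range(3)
            ]
        )
        assert davies_bouldin(m, a) == pytest.approx(expected, abs=1e-12)

    def test_separation_lowers_index(self):
        # scaling up between-cluster distances, all else fixed, lowers DB
        rng = np.random.default_rng(9)
        base = np.abs(rng.normal(size=(6, 6)))
        within = (base + base.T) / 2
        np.fill_diagonal(within, 0)
        labels = ClusterAssignment({str(i): i // 3 for i in range(6)}, k=2)
        scores = []
        for sep in (5.0, 50.0):
            m = within.copy()
            m[:3, 3:] = sep
            m[3:, :3] = sep
            scores.append(davies_bouldin(m, labels))
        assert scores[1] < scores[0]


class TestCutByDb:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_planted_k(self, k_true):
        frags = _planted(k_true, seed=7)
        m = pairwise_matrix(frags)
        assignment = cut_by_db(complete_linkage(m), m, range(2, 7))
        assert assignment.k == k_true

    def test_matches_exhaustive_profile(self):
        frags = _planted(3, seed=13, n_perturbed=3)
        m = pairwise_matrix(frags)
        dendro = complete_linkage(m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignment = cut_by_db(dendro, m, range(2, 8))
        from scipy.cluster.hierarchy import fcluster

        for k, db in assignment.db_profile.items():
            flat = fcluster(dendro.linkage, t=k, criterion="maxclust")
            manual = ClusterAssignment(
                {fid: int(c) for fid, c in zip(dendro.leaf_ids, flat)},
                k=len(set(flat)),
            )
            assert db == pytest.approx(davies_bouldin(m, manual))

    def test_invalid_k_range(self):
        frags = _planted(2, seed=3, n_perturbed=2)
        m = pairwise_matrix(frags)
        dendro = complete_linkage(m)
        with pytest.raises(ValueError):
            cut_by_db(dendro, m, [1])


class TestClusterAgreement:
    def test_identical_assignments(self):
        a = ClusterAssignment({"a": 0, "b": 0, "c": 1}, k=2)
        assert cluster_agreement(a, a) == 1.0

    def test_one_of_four_moved(self):
        a = ClusterAssignment({"a": 0, "b": 0, "c": 1, "d": 1}, k=2)
        b = ClusterAssignment({"a": 0, "b": 0, "c": 1, "d": 0}, k=2)
        assert cluster_agreement(a, b) == pytest.approx(0.75)

    def test_label_permutation_irrelevant(self):
        a = ClusterAssignment({"a": 0, "b": 0, "c": 1, "d": 2}, k=3)
        b = ClusterAssignment({"a": 2, "b": 2, "c": 0, "d": 1}, k=3)
        assert cluster_agreement(a, b) == 1.0

    def test_matches_permutation_search(self):
        rng = np.random.default_rng(15)
        ids = [f"x{i}" for i in range(12)]
        la = {i: int(rng.integers(0, 4)) for i in ids}
        lb = {i: int(rng.integers(0, 4)) for i in ids}
        a, b = ClusterAssignment(la, k=4), ClusterAssignment(lb, k=4)
        best = 0
        for perm in itertools.permutations(range(4)):
            best = max(best, sum(perm[la[i]] == lb[i] for i in ids))
        assert cluster_agreement(a, b) == pytest.approx(best / len(ids))

    def test_disjoint_ids_rejected(self):
        a = ClusterAssignment({"a": 0, "b": 1}, k=2)
        b = ClusterAssignment({"x": 0}, k=1)
        with pytest.raises(ValueError):
            cluster_agreement(a, b)


class TestClassicalMds:
    def test_euclidean_triangle_reproduced(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        coords = classical_mds(m).to_numpy()
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert (d01, d02, d12) == pytest.approx((3, 4, 5), abs=1e-6)

    def test_duplicates_coincide(self):
        m = np.array([[0, 0, 7], [0, 0, 7], [7, 7, 0]], dtype=float)
        coords = classical_mds(m).to_numpy()
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-9

    def test_embedding_correlates_with_scores(self):
        from scipy.stats import spearmanr

        frags = [make_random_walk(10, 70 + i) for i in range(10)]
        m = pairwise_matrix(frags)
        coords = classical_mds(m).to_numpy()
        emb, orig = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                emb.append(np.linalg.norm(coords[i] - coords[j]))
                orig.append(m.iloc[i, j])
        rho, _ = spearmanr(emb, orig)
        assert rho > 0


class TestNewick:
    def test_roundtrip_heights_through_dendropy(self):
        import dendropy

        frags = _planted(2, seed=21, n_perturbed=3)
        m = pairwise_matrix(frags)
        dendro = complete_linkage(m)
        newick = dendrogram_to_newick(dendro)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        # ultrametric: every root-to-leaf path spans the top merge height
        top = dendro.heights[-1]
        for leaf in tree.leaf_node_iter():
            depth = leaf.distance_from_root()
            assert depth == pytest.approx(top, rel=1e-6)
        names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert names == {fid.replace("_", " ") for fid in dendro.leaf_ids}
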