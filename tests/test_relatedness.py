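import numpy as np
import pytest

from eigensel.errors import InputError
from eigensel.io import MISSING
from eigensel.relatedness import (
    RelationshipMatrix,
    neighbor_joining,
    pca,
    rogers_distance,
    standardized_grm,
    tree_path_lengths,
    vanraden_kinship,
)

from conftest import hwe_matrix, make_matrix


class TestVanRadenKinship:
    def test_matches_hand_computation_before_clamping(self):
        # 3 samples x 2 SNPs: X = [[0,2],[2,0],[1,1]]
        m = make_matrix([[0, 2], [2, 0], [1, 1]])
        # p = (0.5, 0.5); Z = X - 1; denom = 2 * (0.25 + 0.25) = 1
        Z = np.array([[-1.0, 1.0], [1.0, -1.0], [0.0, 0.0]])
        expected = Z @ Z.T  # / 1
        got = vanraden_kinship(m, clamp_negative=False)
        assert np.allclose(got.values, expected)

    def test_negative_entries_clamped_to_zero(self):
        m = make_matrix([[0, 2], [2, 0], [1, 1]])
        got = vanraden_kinship(m)
        assert got.values.min() == 0.0

    def test_duplicated_samples_share_diagonal_value(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, size=30).astype(np.int8)
        other = rng.integers(0, 3, size=(3, 30)).astype(np.int8)
        m = make_matrix(np.vstack([row, row, other]))
        got = vanraden_kinship(m, clamp_negative=False).values
        assert got[0, 1] == pytest.approx(got[0, 0])
        assert got[0, 1] == pytest.approx(got[1, 1])

    def test_monomorphic_only_input_rejected(self):
        with pytest.raises(InputError):
            vanraden_kinship(make_matrix([[2, 0], [2, 0]]))

    def test_missing_dosage_contributes_zero(self):
        m1 = make_matrix([[0, 2], [2, 0], [1, MISSING]])
        got = vanraden_kinship(m1, clamp_negative=False).values
        # sample 2's second SNP imputed to 2p -> centered 0: row unaffected
        # by that locus
        assert got[2, 0] == pytest.approx(0.0, abs=1e-12)


class TestStandardizedGrm:
    def test_two_samples_one_snp_off_diagonal(self):
        # z = (-1, +1), 2pq = 1/2: A01 = z0*z1 / (2pq) = -2
        got = standardized_grm(make_matrix([[0], [2]]))
        assert got.values[0, 1] == pytest.approx(-2.0)

    def test_row_sums_vanish_and_mean_offdiag_identity(self):
        # with sample-estimated frequencies the centered rows sum to zero,
        # hence mean offdiag == -mean diag / (n-1)
        m = hwe_matrix(25, 400, seed=1)
        A = standardized_grm(m).values
        assert np.allclose(A.sum(axis=1), 0.0, atol=1e-9)
        n = A.shape[0]
        off = A[~np.eye(n, dtype=bool)].mean()
        assert off == pytest.approx(-np.diag(A).mean() / (n - 1), rel=1e-10)
        assert off == pytest.approx(-1.0 / (n - 1), rel=0.05)

    def test_hwe_panmictic_diagonal_near_one(self):
        m = hwe_matrix(200, 2000, seed=2)
        A = standardized_grm(m).values
        assert np.diag(A).mean() == pytest.approx(1.0, abs=0.02)

    def test_monomorphic_snp_rejected(self):
        with pytest.raises(InputError):
            standardized_grm(make_matrix([[0, 1], [0, 1]]))

    def test_sample_permutation_equivariance(self):
        m = hwe_matrix(10, 50, seed=3)
        A = standardized_grm(m).values
        perm = np.random.default_rng(0).permutation(10)
        Ap = standardized_grm(m.take_samples(perm)).values
        assert np.allclose(Ap, A[np.ix_(perm, perm)])


class TestPCA:
    def test_rank_one_matrix_explains_everything(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        A = np.outer(u, u)
        res = pca(RelationshipMatrix(np.array(list("abcd"), dtype=object), A, "standardized_grm"), k=2)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert res.eigenvalues[0] == pytest.approx(u @ u)

    def test_identity_matrix_spreads_variance_equally(self):
        A = np.eye(5)
        res = pca(RelationshipMatrix(np.arange(5).astype(object), A, "standardized_grm"), k=5)
        assert np.allclose(res.variance_explained, 0.2)
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_sign_convention_largest_loading_positive(self):
        u = np.array([0.1, -0.9, 0.2])
        res = pca(RelationshipMatrix(np.arange(3).astype(object), np.outer(u, u), "g"), k=1)
        j = np.argmax(np.abs(res.eigenvectors[:, 0]))
        assert res.eigenvectors[j, 0] > 0

    def test_first_component_separates_two_subpopulations(self):
        from eigensel.simulate import SimulationConfig, simulate_balding_nichols
        from eigensel.io import qc_filter

        cfg = SimulationConfig(
            n_per_subpop=(60, 60), n_snps=1500, fst_drift=0.05, n_selected=0, seed=4
        )
        matrix, _ = simulate_balding_nichols(cfg)
        matrix, _ = qc_filter(matrix)
        res = pca(standardized_grm(matrix), k=2)
        labels = (matrix.groups == "POP1").to_numpy().astype(float)
        r = np.corrcoef(res.eigenvectors[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_k_larger_than_n_truncated(self):
        res = pca(RelationshipMatrix(np.arange(3).astype(object), np.eye(3), "g"), k=10)
        assert res.eigenvalues.shape == (3,)


class TestRogersDistance:
    def test_identical_genotypes_zero(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert rogers_distance(m).values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix([[0, 0], [2, 2]])
        assert rogers_distance(m).values[0, 1] == pytest.approx(1.0)

    def test_hom_vs_het_half(self):
        m = make_matrix([[2], [1]])
        assert rogers_distance(m).values[0, 1] == pytest.approx(0.5)

    def test_missing_loci_skipped_per_pair(self):
        m = make_matrix([[2, 0, MISSING], [2, 2, 2]])
        # shared loci: first (d=0) and second (d=1) -> mean 0.5
        assert rogers_distance(m).values[0, 1] == pytest.approx(0.5)

    def test_no_shared_loci_flagged_nan(self):
        m = make_matrix([[2, MISSING], [MISSING, 2]])
        assert np.isnan(rogers_distance(m).values[0, 1])


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(D, labels=list("ABCD"))
        paths = tree_path_lengths(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert paths.loc[a, b] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(D, labels=list("XYZ"))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"X": pytest.approx(1.0), "Y": pytest.approx(3.0), "Z": pytest.approx(5.0)}

    def test_tie_break_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(D).to_newick()
        t2 = neighbor_joining(D).to_newick()
        assert t1 == t2

    def test_matches_skbio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        import networkx as nx

        # additive matrix from an explicit 7-leaf tree (path metric)
        edges = [
            ("R", "u", 0.5), ("u", "t0", 1.0), ("u", "t1", 2.0),
            ("R", "v", 0.6), ("v", "w", 0.4), ("w", "t2", 0.7), ("w", "t3", 1.3),
            ("v", "t4", 2.0),
            ("R", "x", 0.3), ("x", "t5", 0.9), ("x", "t6", 1.1),
        ]
        G = nx.Graph()
        G.add_weighted_edges_from(edges)
        n = 7
        labels = [f"t{i}" for i in range(n)]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = nx.shortest_path_length(
                    G, labels[i], labels[j], weight="weight"
                )
        ours = tree_path_lengths(neighbor_joining(D, labels=labels))
        dm = skbio.DistanceMatrix(D, ids=labels)
        theirs = skbio.tree.nj(dm)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = labels[i], labels[j]
                assert ours.loc[a, b] == pytest.approx(
                    theirs.find(a).distance(theirs.find(b)), abs=1e-6
                )

    def test_newick_parses_and_covers_all_leaves(self, two_pop_sim):
        matrix, _ = two_pop_sim
        sub = matrix.take_samples(np.arange(12))
        tree = neighbor_joining(rogers_distance(sub))
        import io as _io

        skbio = pytest.importorskip("skbio")
        parsed = skbio.TreeNode.read(_io.StringIO(tree.to_newick()), convert_underscores=False)
        tips = {t.name for t in parsed.tips()}
        assert tips == set(map(str, sub.samples))

    def test_requires_symmetric_zero_diagonal(self):
        with pytest.raises(InputError):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]))
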