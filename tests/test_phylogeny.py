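"""Neighbor joining, AND distances and the four-gamete recombination
screen: exactness on additive matrices and the printed threshold rules."""

import numpy as np
import pytest

from genelossclock.phylogeny import (
    DistanceMatrix,
    compute_and_matrix,
    filter_nonrecombining,
    four_gamete_pass,
    nj_tree,
    trimmed_tree,
)
from genelossclock.simulate import sample_species_tree, ingroup_subtree
from genelossclock.trees import Tree


def random_rooted_tree(n_leaves: int, seed: int) -> Tree:
    return ingroup_subtree(sample_species_tree(n_leaves, 1.0, seed))


def additive_matrix(tree: Tree) -> DistanceMatrix:
    labels, mat = tree.leaf_distance_matrix()
    return DistanceMatrix(labels, np.array(mat))


def with_outgroup(tree_seed: int, n_leaves: int) -> tuple[Tree, DistanceMatrix]:
    """Additive matrix of a random rooted tree plus a distant outgroup."""
    full = sample_species_tree(n_leaves, 1.0, tree_seed)
    return ingroup_subtree(full), additive_matrix(full)


class TestFourGamete:
    def test_few_segregating_sites_pass(self):
        aln = {"A": "AAAA", "B": "AAAA", "C": "AATA"}
        assert four_gamete_pass(aln)

    def test_all_four_haplotypes_fail(self):
        aln = {"A": "AA", "B": "ab".upper(), "C": "Ab".upper(), "D": "aB".upper()}
        aln = {"A": "CC", "B": "TT", "C": "CT", "D": "TC"}
        assert not four_gamete_pass(aln)

    def test_compatible_biallelic_sites_pass(self):
        # nested mutations: only three haplotypes at any site pair
        aln = {"A": "CC", "B": "TC", "C": "TT", "D": "CC"}
        assert four_gamete_pass(aln)

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            four_gamete_pass({"A": "ACGT", "B": "ACG"})

    def test_recombination_free_fixture_mostly_passes(self, small_pangenome):
        core = [p for p in small_pangenome.pangenes if p.class_label == "core"]
        alignments = {}
        for p in core:
            seqs = small_pangenome.member_seqs(p)
            if len({len(s) for s in seqs.values()}) == 1:
                alignments[p.pangene_id] = seqs
        passed = filter_nonrecombining(alignments)
        # recurrent mutation occasionally fakes a four-gamete violation
        # even without recombination, so the screen is conservative: the
        # overwhelming majority (not strictly all) of core genes pass
        assert len(passed) / len(alignments) >= 0.95


class TestNeighborJoining:
    def test_forced_quartet_split(self):
        labels = ["A", "B", "C", "D", "OUT"]
        d = np.array(
            [
                [0, 2, 3, 3, 8],
                [2, 0, 3, 3, 8],
                [3, 3, 0, 2, 8],
                [3, 3, 2, 0, 8],
                [8, 8, 8, 8, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(labels, d), "OUT")
        clades = {frozenset(tree.leafset_below(n)) for n in tree.branches()}
        assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_recovered_exactly(self, seed):
        n = int(np.random.default_rng(seed).integers(5, 9))
        true_tree, matrix = with_outgroup(seed, n)
        est = nj_tree(matrix, "OUT")
        est_labels, est_mat = est.leaf_distance_matrix()
        sub = matrix.submatrix(est_labels)
        assert np.allclose(np.array(est_mat), sub.values, atol=1e-9)
        true_clades = {frozenset(true_tree.leafset_below(b)) for b in true_tree.branches()}
        est_clades = {frozenset(est.leafset_below(b)) for b in est.branches()}
        assert {c for c in est_clades if len(c) > 1} <= true_clades | {
            frozenset(est.leaf_names())
        }

    def test_star_matrix_has_equal_path_lengths(self):
        labels = ["A", "B", "C", "D", "OUT"]
        d = np.full((5, 5), 4.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(labels, d), "OUT")
        _, mat = tree.leaf_distance_matrix()
        arr = np.array(mat)
        off = arr[~np.eye(len(arr), dtype=bool)]
        assert np.allclose(off, off[0], atol=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        true_tree, matrix = with_outgroup(3, 7)
        est = nj_tree(matrix, "OUT")
        sk_tree = sk_nj(SkDM(matrix.values, matrix.labels))
        names = [l for l in matrix.labels if l != "OUT"]
        mine = est.leaf_distance_matrix()
        sk = {
            (a, b): sk_tree.find(a).distance(sk_tree.find(b))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        }
        idx = {l: i for i, l in enumerate(mine[0])}
        for (a, b), d in sk.items():
            assert mine[1][idx[a]][idx[b]] == pytest.approx(d, abs=1e-6)

    def test_nonsymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestTrimmedTree:
    def test_full_strain_set_matches_nj_tree(self):
        _, matrix = with_outgroup(5, 6)
        ingroup = [l for l in matrix.labels if l != "OUT"]
        a = nj_tree(matrix, "OUT").to_newick()
        b = trimmed_tree(matrix, ingroup, "OUT").to_newick()
        assert a == b

    def test_dropping_a_leaf_matches_pruned_true_tree(self):
        true_tree, matrix = with_outgroup(7, 8)
        keep = sorted(true_tree.leaf_names())[:-1]
        est = trimmed_tree(matrix, keep, "OUT")
        pruned = true_tree.prune_leaf(sorted(true_tree.leaf_names())[-1])
        est_clades = {frozenset(est.leafset_below(b)) for b in est.branches() if not b.is_leaf}
        true_clades = {
            frozenset(pruned.leafset_below(b)) for b in pruned.branches() if not b.is_leaf
        }
        assert est_clades == true_clades

    def test_too_few_strains_is_an_error(self):
        _, matrix = with_outgroup(1, 5)
        with pytest.raises(ValueError, match="too few"):
            trimmed_tree(matrix, matrix.labels[:2], "OUT")


class TestAndMatrix:
    def test_identical_genomes_have_zero_and(self, rng):
        from genelossclock.pangenome import build_pangenome, classify_pangenes
        from tests.conftest import random_cds, toy_genome

        seqs = {f"g{i}": random_cds(rng, 80) for i in range(10)}
        genomes = [toy_genome(s, seqs) for s in "ABC"]
        pg = classify_pangenes(build_pangenome(genomes))
        core = [p for p in pg.pangenes if p.class_label == "core"]
        m = compute_and_matrix(genomes, pg, core)
        assert np.allclose(m.values, 0.0)

    def test_and_is_100_minus_mean_identity(self, rng):
        # two strains whose orthologs average 99.2% identity -> AND 0.8
        from genelossclock.pangenome import build_pangenome, classify_pangenes
        from tests.conftest import random_cds, toy_genome

        n_genes, L = 10, 125  # 375 nt; 3 mismatches = 99.2% identity
        seqs = {f"g{i}": random_cds(rng, L) for i in range(n_genes)}
        other = {}
        for gid, seq in seqs.items():
            arr = list(seq)
            for p in rng.choice(len(arr), size=3, replace=False):
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            other[gid] = "".join(arr)
        genomes = [toy_genome("A", seqs), toy_genome("B", other), toy_genome("C", seqs)]
        pg = classify_pangenes(build_pangenome(genomes))
        core = [p for p in pg.pangenes if p.class_label == "core"]
        m = compute_and_matrix(genomes, pg, core)
        assert m.get("A", "B") == pytest.approx(100 - (100 * (375 - 3) / 375), abs=1e-9)
        assert m.get("A", "C") == 0.0

    def test_low_identity_orthologs_excluded_from_ani(self, rng):
        # a pangene member pair at ~25% identity must not enter the average
        from genelossclock.pangenome import Pangene, Pangenome
        from tests.conftest import random_cds

        good = random_cds(rng, 100)
        junk_a, junk_b = random_cds(rng, 100), random_cds(rng, 100)
        strains = ["A", "B", "C"]
        seqs = {
            ("A", "g0"): good, ("B", "g0"): good, ("C", "g0"): good,
            ("A", "g1"): junk_a, ("B", "g1"): junk_b, ("C", "g1"): junk_a,
        }
        pangenes = [
            Pangene("PG0", {s: "g0" for s in strains}, ("A", "g0"), 1.0, "core"),
            Pangene("PG1", {s: "g1" for s in strains}, ("A", "g1"), 1.0, "core"),
        ]
        pg = Pangenome("toy", strains, pangenes, 80.0, seqs)
        from tests.conftest import toy_genome

        genomes = [
            toy_genome("A", {"g0": good, "g1": junk_a}),
            toy_genome("B", {"g0": good, "g1": junk_b}),
            toy_genome("C", {"g0": good, "g1": junk_a}),
        ]
        m = compute_and_matrix(genomes, pg, pangenes, min_identity=30.0)
        assert m.get("A", "B") == 0.0  # only the identical ortholog qualified
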