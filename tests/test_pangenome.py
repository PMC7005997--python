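import numpy as np
import pandas as pd
import pytest

from cladecompare.pangenome import (
    OrthologClusterSet,
    branch_unique_counts,
    cluster_orthologs,
    concatenate_core,
    core_and_single_copy,
    distance_tree,
    unique_per_genome,
)
from cladecompare.synthetic import parse_tree, poisson_mutate, _random_protein, _aa_str

from oracles import branch_counts_by_enumeration, core_sets_by_scan, unique_by_scan

SIX_LEAF = (
    "(((CL1:0.1,SCTE542:0.1):0.1,((BP1:0.05,NIES2134:0.05):0.1,NK55:0.1):0.1):0.1,"
    "SLIV:0.3)root;"
)


def _random_proteins(rng, n, length=60):
    return [_aa_str(_random_protein(length, rng)) for _ in range(n)]


def _matrix_to_cluster_set(matrix: pd.DataFrame) -> OrthologClusterSet:
    clusters = {}
    for cid, row in matrix.iterrows():
        members = {}
        for g in matrix.columns:
            if row[g] >= 1:
                members[g] = [f"{cid}_{g}_{i}" for i in range(int(row[g]))]
        clusters[cid] = members
    return OrthologClusterSet(clusters=clusters, phyletic_matrix=matrix)


def _random_matrix(rng, n_clusters, genomes):
    data = rng.integers(0, 3, size=(n_clusters, len(genomes)))
    return pd.DataFrame(
        data, index=[f"C{i:04d}" for i in range(n_clusters)], columns=genomes
    )


class TestClustering:
    def test_perfect_one_to_one_hits_give_pairs(self, rng):
        seqs = _random_proteins(rng, 3)
        proteins = {
            "g1": {f"g1_{i}": s for i, s in enumerate(seqs)},
            "g2": {f"g2_{i}": s for i, s in enumerate(seqs)},
        }
        cs = cluster_orthologs(proteins)
        sizes = sorted(int(cs.phyletic_matrix.loc[c].sum()) for c in cs.clusters)
        assert sizes == [2, 2, 2]

    def test_single_genome_gives_singletons(self, rng):
        proteins = {"g1": {f"p{i}": s for i, s in enumerate(_random_proteins(rng, 5))}}
        cs = cluster_orthologs(proteins)
        assert len(cs.clusters) == 5

    def test_cluster_sizes_sum_to_gene_total(self, small_clade):
        genomes, _, families = small_clade
        proteins = {g.genome_id: {} for g in genomes}
        for fam in families:
            for gn, (gid, seq) in fam.members.items():
                proteins[gn][gid] = seq
        cs = cluster_orthologs(proteins)
        total = sum(len(d) for d in proteins.values())
        assert int(cs.phyletic_matrix.to_numpy().sum()) == total

    def test_simulated_families_recovered_exactly(self, small_clade):
        genomes, _, families = small_clade
        proteins = {g.genome_id: {} for g in genomes}
        true_sets = set()
        for fam in families:
            members = set()
            for gn, (gid, seq) in fam.members.items():
                proteins[gn][gid] = seq
                members.add(gid)
            true_sets.add(frozenset(members))
        cs = cluster_orthologs(proteins)
        recovered = {
            frozenset(g for gs in members.values() for g in gs)
            for members in cs.clusters.values()
        }
        assert recovered == true_sets


class TestPhyleticAccounting:
    def test_missing_in_one_genome_is_not_core(self):
        m = pd.DataFrame([[1, 1, 1, 1, 1, 0]], index=["C0"],
                         columns=list("ABCDEF"))
        core, single = core_and_single_copy(_matrix_to_cluster_set(m), list("ABCDEF"))
        assert core == set() and single == set()

    def test_two_copies_is_core_but_not_single(self):
        m = pd.DataFrame([[1, 1, 2]], index=["C0"], columns=list("ABC"))
        core, single = core_and_single_copy(_matrix_to_cluster_set(m), list("ABC"))
        assert core == {"C0"} and single == set()

    def test_empty_genome_list_rejected(self):
        m = pd.DataFrame([[1]], index=["C0"], columns=["A"])
        with pytest.raises(ValueError, match="empty"):
            core_and_single_copy(_matrix_to_cluster_set(m), [])

    def test_core_sets_match_brute_force_scan(self, rng):
        m = _random_matrix(rng, 50, list("ABCDEF"))
        cs = _matrix_to_cluster_set(m)
        assert core_and_single_copy(cs, list("ABCDEF")) == core_sets_by_scan(m)

    def test_unique_counts_match_brute_force_scan(self, rng):
        m = _random_matrix(rng, 50, list("ABCDEF"))
        assert unique_per_genome(_matrix_to_cluster_set(m)) == unique_by_scan(m)


class TestBranchCounts:
    def test_single_leaf_presence_gets_plus_one(self):
        tree = parse_tree(SIX_LEAF)
        genomes = sorted(t.name for t in tree.tips())
        m = pd.DataFrame(np.zeros((1, 6), dtype=int), index=["C0"], columns=genomes)
        m.loc["C0", "CL1"] = 1
        out = {b.branch: b for b in branch_unique_counts(tree, m)}
        assert out["CL1"].n_uniquely_present == 1
        assert all(b.n_uniquely_present == 0 for k, b in out.items() if k != "CL1")

    def test_single_leaf_absence_gets_minus_one(self):
        tree = parse_tree(SIX_LEAF)
        genomes = sorted(t.name for t in tree.tips())
        m = pd.DataFrame(np.ones((1, 6), dtype=int), index=["C0"], columns=genomes)
        m.loc["C0", "CL1"] = 0
        out = {b.branch: b for b in branch_unique_counts(tree, m)}
        assert out["CL1"].n_uniquely_absent == 1

    def test_root_branch_excluded_and_leafsets_proper(self):
        tree = parse_tree(SIX_LEAF)
        genomes = sorted(t.name for t in tree.tips())
        m = _random_matrix(np.random.default_rng(1), 20, genomes)
        annotations = branch_unique_counts(tree, m)
        all_leaves = frozenset(genomes)
        for b in annotations:
            assert b.leaf_set and b.leaf_set != all_leaves

    def test_leaf_mismatch_lists_difference(self):
        tree = parse_tree(SIX_LEAF)
        m = _random_matrix(np.random.default_rng(1), 5, ["CL1", "GHOST"])
        with pytest.raises(ValueError, match="GHOST"):
            branch_unique_counts(tree, m)

    def test_counts_match_exhaustive_enumeration(self):
        tree = parse_tree(SIX_LEAF)
        genomes = sorted(t.name for t in tree.tips())
        for seed in range(20):
            m = _random_matrix(np.random.default_rng(seed), 100, genomes)
            annotations = branch_unique_counts(tree, m)
            oracle = branch_counts_by_enumeration([b.leaf_set for b in annotations], m)
            for b in annotations:
                assert (b.n_uniquely_present, b.n_uniquely_absent) == oracle[b.leaf_set]

    def test_uniquely_present_sums_bounded_by_cluster_count(self, rng):
        tree = parse_tree(SIX_LEAF)
        genomes = sorted(t.name for t in tree.tips())
        m = _random_matrix(rng, 100, genomes)
        annotations = branch_unique_counts(tree, m)
        assert sum(b.n_uniquely_present for b in annotations) <= len(m)


class TestSupermatrix:
    def test_column_count_is_sum_of_family_lengths(self):
        fams = {
            "f1": {"A": "M" * 10, "B": "L" * 10},
            "f2": {"A": "K" * 15, "B": "R" * 15},
        }
        sm = concatenate_core(fams, ["A", "B"])
        assert len(sm["A"]) == 25

    def test_no_families_is_an_error(self):
        with pytest.raises(ValueError, match="no families"):
            concatenate_core({}, ["A"])

    def test_ragged_family_is_named(self):
        fams = {"bad": {"A": "MMM", "B": "MM"}}
        with pytest.raises(ValueError, match="bad"):
            concatenate_core(fams, ["A", "B"])


class TestDistanceTree:
    def _evolved_supermatrix(self, seed=0, n_sites=4000):
        # four taxa evolved on ((A,B),(C,D)) with long internal branch
        rng = np.random.default_rng(seed)
        root = _random_protein(n_sites, rng)
        left = poisson_mutate(root, 0.15, rng)
        right = poisson_mutate(root, 0.15, rng)
        return {
            "A": _aa_str(poisson_mutate(left, 0.05, rng)),
            "B": _aa_str(poisson_mutate(left, 0.05, rng)),
            "C": _aa_str(poisson_mutate(right, 0.05, rng)),
            "D": _aa_str(poisson_mutate(right, 0.05, rng)),
        }

    def test_recovers_four_taxon_topology(self):
        tree = distance_tree(self._evolved_supermatrix(), outgroup="D",
                             n_bootstrap=50, seed=0)
        clades = {frozenset(t.name for t in n.tips())
                  for n in tree.non_tips(include_self=False)}
        assert frozenset({"A", "B"}) in clades

    def test_identical_sequences_warn_star_tree(self):
        sm = {g: "M" * 100 for g in "ABCD"}
        with pytest.warns(UserWarning, match="star"):
            distance_tree(sm, outgroup="D", n_bootstrap=10, seed=0)

    def test_zero_mismatch_gives_zero_distance(self):
        sm = self._evolved_supermatrix()
        sm["B"] = sm["A"]
        tree = distance_tree(sm, outgroup="D", n_bootstrap=10, seed=0)
        a = tree.find("A")
        b = tree.find("B")
        assert a.parent is b.parent
        assert a.length + b.length == pytest.approx(0.0, abs=1e-12)

    def test_supports_in_range_and_deterministic(self):
        sm = self._evolved_supermatrix(seed=3)
        t1 = distance_tree(sm, outgroup="D", n_bootstrap=50, seed=5)
        t2 = distance_tree(sm, outgroup="D", n_bootstrap=50, seed=5)
        s1 = [n.support for n in t1.non_tips(include_self=False)]
        s2 = [n.support for n in t2.non_tips(include_self=False)]
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)

    def test_taxon_input_order_does_not_change_topology(self):
        sm = self._evolved_supermatrix(seed=4)
        shuffled = {k: sm[k] for k in ["C", "A", "D", "B"]}
        t1 = distance_tree(sm, outgroup="D", n_bootstrap=0, seed=0)
        t2 = distance_tree(shuffled, outgroup="D", n_bootstrap=0, seed=0)
        c1 = {frozenset(t.name for t in n.tips()) for n in t1.non_tips(include_self=False)}
        c2 = {frozenset(t.name for t in n.tips()) for n in t2.non_tips(include_self=False)}
        assert c1 == c2

    def test_outgroup_must_be_present(self):
        with pytest.raises(ValueError, match="outgroup"):
            distance_tree(self._evolved_supermatrix(), outgroup="Z")
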