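import math

import numpy as np
import pytest

from retrokit.phylo import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    partial_deletion_filter,
    robinson_foulds,
    tree_bipartitions,
)
from retrokit.seqio import Msa, SequenceRecord
from retrokit.simulate import evolve_sequences, random_dna, random_tree


def msa(*rows, alphabet="protein", ids=None):
    ids = ids or [f"t{i}" for i in range(len(rows))]
    return Msa(
        records=[SequenceRecord(id=i, residues=s) for i, s in zip(ids, rows)],
        alphabet=alphabet,
    )


class TestPartialDeletionFilter:
    def test_three_row_column_with_one_gap_removed(self):
        m = msa("MK", "M-", "MK")
        out = partial_deletion_filter(m, 0.95)
        assert out.n_cols == 1
        assert out.records[0].residues == "M"

    def test_twenty_row_column_with_one_gap_retained(self):
        # 19/20 = 0.95 coverage sits exactly on the threshold and is kept
        rows = ["MK"] * 19 + ["M-"]
        out = partial_deletion_filter(msa(*rows), 0.95)
        assert out.n_cols == 2

    def test_gap_free_alignment_unchanged(self):
        m = msa("MKW", "MKW", "MRW")
        out = partial_deletion_filter(m)
        assert [r.residues for r in out.records] == [r.residues for r in m.records]

    def test_idempotence(self, rng):
        rows = ["".join(rng.choice(list("MKWDE-"), size=50)) for _ in range(8)]
        m = msa(*rows)
        once = partial_deletion_filter(m, 0.8)
        twice = partial_deletion_filter(once, 0.8)
        assert [r.residues for r in once.records] == [r.residues for r in twice.records]

    def test_ambiguity_counts_as_missing(self):
        m = msa("MX", "MK", "MK")
        out = partial_deletion_filter(m, 0.95)
        assert out.n_cols == 1

    def test_everything_removed_is_an_error(self):
        m = msa("M-", "-K")
        with pytest.raises(ValueError):
            partial_deletion_filter(m, 0.95)

    def test_matches_brute_force_column_scan(self, rng):
        rows = ["".join(rng.choice(list("ACGT-N"), size=80)) for _ in range(10)]
        m = msa(*rows, alphabet="dna")
        out = partial_deletion_filter(m, 0.9)
        keep = [
            i
            for i in range(80)
            if sum(r[i] not in "-N" for r in rows) / 10 >= 0.9
        ]
        assert out.records[0].residues == "".join(rows[0][i] for i in keep)


class TestDistanceMatrix:
    def test_closed_form_p_and_poisson(self):
        m = msa("AAAA", "AAAT", "AATT", alphabet="protein")
        dm_p = distance_matrix(m, "p")
        assert dm_p.d[0, 1] == pytest.approx(0.25)
        dm_poisson = distance_matrix(m, "poisson")
        assert dm_poisson.d[0, 1] == pytest.approx(-math.log(0.75))

    def test_jc69_closed_form(self):
        m = msa("AAAA", "AAAT", "AATT", alphabet="dna")
        dm = distance_matrix(m, "jc69")
        assert dm.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 4 * 0.25 / 3))

    def test_identical_pair_distance_zero(self):
        m = msa("ACGT", "ACGT", "ACGG", alphabet="dna")
        for model in ("p", "poisson", "jc69"):
            assert distance_matrix(m, model).d[0, 1] == 0.0

    def test_saturation_capped_and_flagged(self):
        m = msa("AAAA", "TTTT", "ACGT", alphabet="dna")
        dm = distance_matrix(m, "jc69", max_distance=5.0)
        assert dm.d[0, 1] == 5.0
        assert ("t0", "t1") in dm.saturated

    def test_gap_columns_deleted_pairwise(self):
        m = msa("AC-T", "ACGT", "AC-A", alphabet="dna")
        dm = distance_matrix(m, "p")
        assert dm.d[0, 1] == 0.0  # only 3 comparable sites, all equal
        assert dm.d[0, 2] == pytest.approx(1 / 3)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNjTree:
    def test_additive_four_taxon_recovery_with_lengths(self):
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        assert tree_bipartitions(tree) == {frozenset({"c", "d"})}
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert all(abs(v - 1.0) < 1e-9 for v in lengths.values())
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node
        ]
        assert internal == [pytest.approx(2.0)]

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(taxa=["a", "b", "c"], d=d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["b"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["c"] == pytest.approx((5 + 4 - 3) / 2)

    def test_random_additive_matrices_recovered_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 10))
            tree = random_tree(rng, [f"t{i}" for i in range(n)])
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(t.label for t in tree.taxon_namespace)
            lookup = {t.label: t for t in tree.taxon_namespace}
            d = np.zeros((n, n))
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i < j:
                        d[i, j] = d[j, i] = pdm.patristic_distance(
                            lookup[a], lookup[b]
                        )
            est = nj_tree(DistanceMatrix(taxa=taxa, d=d))
            assert robinson_foulds(est, tree) == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2))))


@pytest.fixture(scope="module")
def evolved():
    rng = np.random.default_rng(31)
    tree = random_tree(rng, [f"t{i}" for i in range(8)], (0.05, 0.1))
    root = SequenceRecord(id="r", residues=random_dna(rng, 4000))
    msa_, _ = evolve_sequences(tree, root, subst_rate=1.0, seed=5)
    return tree, msa_


class TestBootstrap:

    def test_same_seed_reproduces_supports_exactly(self, evolved):
        _, m = evolved
        t1 = bootstrap_support(m, replicates=50, seed=9, model="jc69")
        t2 = bootstrap_support(m, replicates=50, seed=9, model="jc69")
        s1 = sorted(n.label for n in t1.preorder_node_iter() if n.label and not n.is_leaf())
        s2 = sorted(n.label for n in t2.preorder_node_iter() if n.label and not n.is_leaf())
        assert s1 == s2 and len(s1) == 5

    def test_single_replicate_supports_are_all_or_nothing(self, evolved):
        _, m = evolved
        t = bootstrap_support(m, replicates=1, seed=3, model="jc69")
        supports = {
            int(n.label)
            for n in t.preorder_node_iter()
            if n.label and not n.is_leaf()
        }
        assert supports <= {0, 100}

    def test_strong_signal_yields_high_supports(self, evolved):
        tree, m = evolved
        t = bootstrap_support(m, replicates=100, seed=1, model="jc69")
        supports = [
            int(n.label)
            for n in t.preorder_node_iter()
            if n.label and not n.is_leaf()
        ]
        assert min(supports) >= 95

    def test_invalid_replicate_count_rejected(self, evolved):
        _, m = evolved
        with pytest.raises(ValueError):
            bootstrap_support(m, replicates=0, seed=1)

    def test_taxon_order_invariance(self, evolved):
        _, m = evolved
        shuffled = Msa(records=list(reversed(m.records)), alphabet=m.alphabet)
        t1 = nj_tree(distance_matrix(m, "jc69"))
        t2 = nj_tree(distance_matrix(shuffled, "jc69"))
        assert robinson_foulds(t1, t2) == 0
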