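import io
import math

import numpy as np
import pytest

from paleohybrid.formats import (
    Alignment,
    DistanceMatrix,
    FastaError,
    NewickError,
    SaturatedDistanceError,
    Sequence,
    concatenate_alignments,
    jc_distance,
    jc_distance_matrix,
    neighbor_joining,
    parse_newick,
    read_fasta,
    write_fasta,
    write_newick,
)
from .conftest import random_sequences


class TestFasta:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (">a\nACGT\n", [("a", "ACGT")]),
            (">a\nAC\nGT\n", [("a", "ACGT")]),
            (">a extra words\nacgt\n", [("a", "ACGT")]),
            (">a\nAC\n>b\nGT\n", [("a", "AC"), ("b", "GT")]),
        ],
    )
    def test_parse(self, text, expected):
        records = read_fasta(io.StringIO(text))
        assert [(r.id, r.residues) for r in records] == expected

    @pytest.mark.parametrize("bad", [">a\n>a\nAC\n", ">a\n>b\nAC\n", "ACGT\n", ""])
    def test_malformed_records_raise(self, bad):
        with pytest.raises(FastaError):
            read_fasta(io.StringIO(bad))

    def test_write_wraps_lines(self):
        assert write_fasta([Sequence("a", "ACGT")], width=2) == ">a\nAC\nGT\n"

    def test_write_rejects_empty_and_zero_width(self):
        with pytest.raises(FastaError):
            write_fasta([])
        with pytest.raises(ValueError):
            write_fasta([Sequence("a", "AC")], width=0)

    def test_round_trip_arbitrary_records(self):
        from hypothesis import given, settings, strategies as st

        record = st.tuples(
            st.text(alphabet="abcXYZ019_", min_size=1, max_size=12),
            st.text(alphabet="ACGTN-", min_size=1, max_size=200),
        )

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(st.lists(record, min_size=1, max_size=8, unique_by=lambda r: r[0]))
        def check(records):
            seqs = [Sequence(i, r) for i, r in records]
            back = read_fasta(io.StringIO(write_fasta(seqs, width=13)))
            assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]

        check()

    def test_round_trip_random_records(self, rng):
        for _ in range(10):
            seqs = random_sequences(rng, n=10)
            for width in (1, 7, 70):
                back = read_fasta(io.StringIO(write_fasta(seqs, width=width)))
                assert [(s.id, s.residues) for s in back] == [
                    (s.id, s.residues) for s in seqs
                ]


def _random_tree_newick(rng, n_leaves):
    """Random binary topology with positive branch lengths, as newick."""
    nodes = [f"L{i}:{rng.uniform(0.05, 2.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 2.0):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"


class TestNewick:
    def test_parse_lengths_and_support(self):
        t = parse_newick("((a:1,b:2)95:0.5,c:3);")
        leaves = {l.taxon.label for l in t.leaf_node_iter()}
        assert leaves == {"a", "b", "c"}
        internal = t.mrca(taxon_labels=["a", "b"])
        assert internal.edge.length == pytest.approx(0.5)
        assert internal.label == "95"

    @pytest.mark.parametrize("bad", ["((a,b;", "((a,b),)c;", "((a:x,b),c);"])
    def test_parse_errors(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_single_leaf(self):
        t = parse_newick("a;")
        assert [l.taxon.label for l in t.leaf_node_iter()] == ["a"]

    def test_round_trip_random_trees(self, rng):
        import dendropy

        for _ in range(300):
            nwk = _random_tree_newick(rng, int(rng.integers(3, 12)))
            t1 = parse_newick(nwk)
            t2 = parse_newick(write_newick(t1))
            tns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
            b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
            a.encode_bipartitions()
            b.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


class TestJukesCantor:
    def test_identical_pair_is_zero(self):
        aln = Alignment([Sequence("a", "ACGTACGT"), Sequence("b", "ACGTACGT")])
        assert jc_distance_matrix(aln)[("a", "b")] == 0.0

    def test_known_value(self):
        # p = 0.2: d = -(3/4) ln(1 - 4*0.2/3)
        assert jc_distance(0.2) == pytest.approx(0.232616, abs=1e-6)

    def test_saturation_flagged(self):
        with pytest.raises(SaturatedDistanceError):
            jc_distance(0.8)
        aln = Alignment([Sequence("a", "AAAAA"), Sequence("b", "CCCCC")])
        dm = jc_distance_matrix(aln, on_saturation="inf")
        assert math.isinf(dm[("a", "b")])
        with pytest.raises(SaturatedDistanceError):
            jc_distance_matrix(aln, on_saturation="error")

    def test_monotone_in_p(self):
        grid = np.linspace(0.0, 0.74, 100)
        vals = [jc_distance(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_gap_and_ambiguity_excluded_pairwise(self):
        aln = Alignment([Sequence("a", "ACGT-N"), Sequence("b", "ACGAAN")])
        # comparable columns: 1-4 (gap and N excluded); one mismatch of 4
        assert jc_distance_matrix(aln)[("a", "b")] == pytest.approx(jc_distance(0.25))


class TestNeighborJoining:
    def test_three_taxon_exact(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = neighbor_joining(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.05)
        assert lengths["b"] == pytest.approx(0.15)
        assert lengths["c"] == pytest.approx(0.25)

    def test_two_taxa_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_additive_matrix_recovered_exactly(self, rng):
        import dendropy

        for _ in range(15):
            nwk = _random_tree_newick(rng, 8)
            source = parse_newick(nwk, rooted=False)
            pdm = source.phylogenetic_distance_matrix()
            taxa = sorted(source.taxon_namespace, key=lambda t: t.label)
            labels = [t.label for t in taxa]
            n = len(taxa)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
            nj = neighbor_joining(DistanceMatrix(labels, d))
            pdm2 = nj.phylogenetic_distance_matrix()
            taxa2 = {t.label: t for t in nj.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm2.patristic_distance(taxa2[labels[i]], taxa2[labels[j]])
                    assert got == pytest.approx(d[i, j], abs=1e-9)


class TestConcatenate:
    def test_lengths_and_partitions(self):
        a = Alignment([Sequence("x", "A" * 100), Sequence("y", "C" * 100)])
        b = Alignment([Sequence("x", "G" * 200), Sequence("y", "T" * 200)])
        sup = concatenate_alignments([("g1", a), ("g2", b)])
        assert sup.length == 300
        assert sup.partition_map == [("g1", 0, 100), ("g2", 100, 300)]

    def test_missing_taxon_gap_filled(self):
        a = Alignment([Sequence("x", "ACGT"), Sequence("y", "ACGT")])
        b = Alignment([Sequence("x", "GG")])
        sup = concatenate_alignments([("g1", a), ("g2", b)])
        y = next(s for s in sup.sequences if s.id == "y")
        assert y.residues == "ACGT--"

    def test_duplicate_gene_name_rejected(self):
        a = Alignment([Sequence("x", "AC")])
        with pytest.raises(ValueError, match="duplicate gene"):
            concatenate_alignments([("g", a), ("g", a)])
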