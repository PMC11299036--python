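import json
import math
from collections import Counter
from pathlib import Path

import numpy as np
import pytest

from paleohybrid.formats import jc_distance_matrix, parse_newick
from paleohybrid.ks import codon_align_pair, ng86_ks
from paleohybrid.simulate import (
    HKY85,
    JC69,
    LocusClassMix,
    SimulationConfig,
    SpeciesNetwork,
    build_case_study,
    selaginella_network,
    simulate_alignment,
    simulate_case_loci,
    simulate_msc_gene_trees,
    simulate_paralog_pairs,
)


class TestSpeciesNetwork:
    def test_gamma_bounds_enforced(self):
        with pytest.raises(ValueError, match="gamma"):
            selaginella_network(gamma=1.5)

    def test_attachment_height_validated(self):
        with pytest.raises(ValueError):
            SpeciesNetwork(
                backbone_newick="((a:1,b:1):1,c:2);",
                hybrid_newick="h;",
                parent1_clade=frozenset(["a"]),
                parent2_clade=frozenset(["b"]),
                hybridization_time=1.5,  # above the parental split
            )

    def test_non_ultrametric_backbone_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            SpeciesNetwork(backbone_newick="((a:1,b:2):1,c:2);")


class TestMscGeneTrees:
    def test_gamma_one_routes_everything_to_p1(self):
        net = selaginella_network(gamma=1.0)
        loci = simulate_msc_gene_trees(net, 50, seed=1)
        assert all(r == "P1" for l in loci for r in l.routing)

    def test_routing_fraction_matches_gamma(self):
        gamma = 0.4511
        net = selaginella_network(gamma=gamma)
        loci = simulate_msc_gene_trees(net, 10_000, seed=2)
        routes = [r for l in loci for r in l.routing]
        frac = sum(r == "P1" for r in routes) / len(routes)
        se = math.sqrt(gamma * (1 - gamma) / len(routes))
        assert abs(frac - gamma) < 3 * se

    @pytest.mark.parametrize("t", [0.1, 0.5, 2.0])
    def test_triplet_concordance_closed_form(self, t):
        net = SpeciesNetwork(backbone_newick=f"((a:1,b:1):{t},c:{1 + t});")
        loci = simulate_msc_gene_trees(net, 10_000, seed=3)
        conc = sum(
            len(l.tree.mrca(taxon_labels=["a", "b"]).leaf_nodes()) == 2 for l in loci
        ) / len(loci)
        expected = 1 - (2 / 3) * math.exp(-t)
        se = math.sqrt(expected * (1 - expected) / 10_000)
        assert abs(conc - expected) < 3 * se

    def test_reproducible_given_seed(self):
        from paleohybrid.formats import write_newick

        net = selaginella_network()
        a = simulate_msc_gene_trees(net, 5, seed=7)
        b = simulate_msc_gene_trees(net, 5, seed=7)
        assert [write_newick(x.tree) for x in a] == [write_newick(x.tree) for x in b]


class TestSequenceEvolution:
    def test_zero_branch_lengths_give_identical_sequences(self):
        tree = parse_newick("((a:0,b:0):0,c:0);")
        aln = simulate_alignment(tree, JC69(), 200, seed=1)
        assert len({s.residues for s in aln.sequences}) == 1

    def test_two_leaf_jc_distance_recovered(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = simulate_alignment(tree, JC69(), 100_000, seed=2)
        d = jc_distance_matrix(aln)[("a", "b")]
        # SE of the JC estimate at p* = 0.75(1-exp(-4*0.2/3))
        p = 0.75 * (1 - math.exp(-4 * 0.2 / 3))
        se = math.sqrt(p * (1 - p) / 100_000) / (1 - 4 * p / 3)
        assert abs(d - 0.2) < 3 * se

    def test_hky_kappa_one_matches_jc_pattern_frequencies(self):
        tree = parse_newick("(a:0.3,b:0.3);")
        jc = simulate_alignment(tree, JC69(), 50_000, seed=3)
        hky = simulate_alignment(tree, HKY85(kappa=1.0), 50_000, seed=3)

        def mismatch(aln):
            a, b = (s.residues for s in aln.sequences)
            return sum(x != y for x, y in zip(a, b)) / len(a)

        assert mismatch(jc) == pytest.approx(mismatch(hky), abs=0.01)

    def test_nonpositive_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate_alignment(parse_newick("(a:1,b:1);"), JC69(), 0, seed=1)

    def test_dendropy_simulator_agrees_on_pairwise_distance(self):
        """Independent oracle: dendropy's discrete-character simulator."""
        import dendropy
        from dendropy.model.discrete import Hky85, simulate_discrete_chars

        tree = dendropy.Tree.get(data="(a:0.15,b:0.15);", schema="newick")
        mat = simulate_discrete_chars(
            100_000, tree, Hky85(kappa=1.0), rng=np.random.RandomState(5)
        )
        seqs = {t.label: str(mat[t]) for t in mat.taxon_namespace}
        p_oracle = sum(x != y for x, y in zip(seqs["a"], seqs["b"])) / 100_000
        ours = simulate_alignment(parse_newick("(a:0.15,b:0.15);"), JC69(), 100_000, seed=5)
        a, b = (s.residues for s in ours.sequences)
        p_ours = sum(x != y for x, y in zip(a, b)) / 100_000
        assert p_ours == pytest.approx(p_oracle, abs=0.01)


class TestParalogPairs:
    def test_contaminated_pairs_are_near_identical(self):
        pairs = simulate_paralog_pairs(30, contamination_fraction=1.0, seed=1)
        for a, b in pairs:
            est = ng86_ks(codon_align_pair(a, b))
            assert est.identity >= 0.90

    def test_zero_pairs_gives_empty_list(self):
        assert simulate_paralog_pairs(0, seed=1) == []

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            simulate_paralog_pairs(5, ks_mixture=[(1.0, -2.0, 0.1)], seed=1)

    def test_realized_ks_tracks_drawn_mixture(self):
        pairs = simulate_paralog_pairs(
            120, ks_mixture=[(1.0, 1.5, 0.15)], contamination_fraction=0.0, seed=2
        )
        ks = [ng86_ks(codon_align_pair(a, b)).ks for a, b in pairs]
        assert np.mean(ks) == pytest.approx(1.5, abs=0.1)


class TestLocusClassMix:
    def test_paper_partition_quota_is_exact(self):
        quota = LocusClassMix().quota(347)
        assert quota == {"sister_to_A": 81, "sister_to_C": 136, "sister_to_both": 130}

    def test_simplex_enforced(self):
        with pytest.raises(ValueError):
            LocusClassMix(0.5, 0.2, 0.1)

    def test_class_mode_realizes_quota(self, case_loci):
        counts = Counter(l.locus_class for l in case_loci)
        expected = LocusClassMix().quota(len(case_loci))
        assert counts == expected

    def test_both_retained_loci_realize_their_topology(self, case_loci):
        both = [l for l in case_loci if l.locus_class == "sister_to_both"]
        assert all(l.realized_class == "sister_to_both" for l in both)


class TestCaseStudy:
    def test_byte_identical_given_seed(self, tmp_path):
        import hashlib

        cfg = SimulationConfig(n_loci=8, sites_per_locus=150, seed=5)

        def digest(d):
            h = hashlib.sha256()
            for p in sorted(Path(d).rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        build_case_study(cfg, tmp_path / "one")
        build_case_study(cfg, tmp_path / "two")
        assert digest(tmp_path / "one") == digest(tmp_path / "two")

    def test_truth_log_carries_config_gamma(self, tmp_path):
        cfg = SimulationConfig(n_loci=4, sites_per_locus=60, seed=6, mode="network", gamma=0.33)
        out = build_case_study(cfg, tmp_path / "cs")
        truth = json.loads((out / "truth.json").read_text())
        assert truth["gamma"] == 0.33
        assert len(truth["loci"]) == 4
        assert (out / "groups.yaml").exists()

    def test_existing_directory_requires_overwrite(self, tmp_path):
        cfg = SimulationConfig(n_loci=2, sites_per_locus=50, seed=1)
        build_case_study(cfg, tmp_path / "cs")
        with pytest.raises(FileExistsError):
            build_case_study(cfg, tmp_path / "cs")
        build_case_study(cfg, tmp_path / "cs", overwrite=True)
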