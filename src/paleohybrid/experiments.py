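"""Reproduction experiments: canned end-to-end analyses at fixed sizes.

These functions regenerate the package's headline numbers from scratch —
gene-set shares, coalescent concordance, γ recovery by both estimators,
false-positive rate of the gene-flow test, Ks peak recovery with the
identity cutoff, classifier accuracy, and split-time concordance.  They are
used by the test suite and by ``scripts/acceptance.py``; every function
takes an explicit seed.
"""

from __future__ import annotations

import math

import numpy as np

from .chronology import Calibration, hybrid_time_consistency, strict_clock_dates
from .formats import concatenate_alignments, jc_distance_matrix, neighbor_joining, parse_newick
from .genetreesort import (
    GroupScheme,
    classify_focal_position,
    partition_gene_sets,
    reroot_outgroup,
    triplet_frequencies,
)
from .hybrid import count_site_patterns, fit_triplet_network, hyde_gamma_test
from .ks import codon_align_pair, fit_ks_peaks, identity_cutoff_filter, ng86_ks
from .simulate import (
    SCENARIO_GROUPS,
    SimulationConfig,
    SpeciesNetwork,
    simulate_alignment,
    simulate_case_loci,
    simulate_msc_gene_trees,
    simulate_paralog_pairs,
    scale_tree,
    selaginella_network,
)

GAMMA_STUDY = 0.4511
PAPER_GENE_SET_COUNTS = (130, 81, 136)  # sister-to-both, sister-to-A, sister-to-C

_SCHEME = GroupScheme.from_dict(SCENARIO_GROUPS)
_ROLES = {
    "outgroup": SCENARIO_GROUPS["outgroup"],
    "p1": SCENARIO_GROUPS["parent1"],
    "hybrid": SCENARIO_GROUPS["focal"],
    "p2": SCENARIO_GROUPS["parent2"],
}
_TRIPLET_GROUPS = [
    ("A", set(SCENARIO_GROUPS["parent1"])),
    ("B", set(SCENARIO_GROUPS["focal"])),
    ("C", set(SCENARIO_GROUPS["parent2"])),
]


def gene_set_percentages(counts=PAPER_GENE_SET_COUNTS) -> dict:
    """Percentage shares of the three gene sets, via the partition machinery.

    Builds one literal gene tree per locus with the class topology and runs
    the classifier-backed partition, so the reported shares exercise the
    whole path rather than a division.
    """
    n_both, n_a, n_c = counts
    topo = {
        "sister_to_both": "((B1,((A1,A2),(C1,C2))),O);",
        "sister_to_A": "(((B1,(A1,A2)),(C1,C2)),O);",
        "sister_to_C": "(((B1,(C1,C2)),(A1,A2)),O);",
    }
    scheme = GroupScheme.from_dict(
        dict(outgroup=["O"], focal=["B1"], parent1=["A1", "A2"], parent2=["C1", "C2"])
    )
    trees = (
        [parse_newick(topo["sister_to_both"]) for _ in range(n_both)]
        + [parse_newick(topo["sister_to_A"]) for _ in range(n_a)]
        + [parse_newick(topo["sister_to_C"]) for _ in range(n_c)]
    )
    part = partition_gene_sets(trees, scheme)
    return part.percentages


def msc_concordance(internal_branch: float, n_loci: int, seed: int) -> tuple[float, float]:
    """(observed, expected) concordant-triplet fraction for a 3-species tree."""
    t = internal_branch
    net = SpeciesNetwork(backbone_newick=f"((a:1,b:1):{t},c:{1 + t});")
    loci = simulate_msc_gene_trees(net, n_loci, seed=seed)
    conc = 0
    for locus in loci:
        node = locus.tree.mrca(taxon_labels=["a", "b"])
        conc += len(node.leaf_nodes()) == 2
    return conc / n_loci, 1.0 - (2.0 / 3.0) * math.exp(-t)


def routed_fraction(gamma: float, n_loci: int, seed: int) -> float:
    """Fraction of hybrid lineages routed to the parent-1 side."""
    net = selaginella_network(gamma=gamma)
    loci = simulate_msc_gene_trees(net, n_loci, seed=seed)
    routes = [r for l in loci for r in l.routing]
    return sum(r == "P1" for r in routes) / len(routes)


def simulate_network_dataset(n_loci: int, sites: int, seed: int, gamma: float = GAMMA_STUDY):
    """Gene trees and sequence alignments under the γ-routing network."""
    cfg = SimulationConfig(
        n_loci=n_loci, sites_per_locus=sites, seed=seed, mode="network", gamma=gamma
    )
    loci = simulate_case_loci(cfg)
    rng = np.random.default_rng(seed + 1)
    model = cfg.substitution_model()
    alignments = [
        simulate_alignment(scale_tree(l.tree, cfg.clock_rate_per_cu), model, sites, rng=rng)
        for l in loci
    ]
    return loci, alignments


def gamma_recovery_network_fit(n_loci: int = 10_000, seed: int = 0, gamma: float = GAMMA_STUDY):
    """Fit γ by triplet pseudo-likelihood from true simulated gene trees."""
    net = selaginella_network(gamma=gamma)
    loci = simulate_msc_gene_trees(net, n_loci, seed=seed)
    counts = triplet_frequencies([l.tree for l in loci], _TRIPLET_GROUPS)
    return fit_triplet_network(counts)


def gamma_recovery_hyde(n_loci: int = 500, sites: int = 1000, seed: int = 0,
                        gamma: float = GAMMA_STUDY):
    """Site-pattern γ test on concatenated sequence data from the network."""
    _, alignments = simulate_network_dataset(n_loci, sites, seed, gamma)
    sup = concatenate_alignments([(f"l{i:04d}", a) for i, a in enumerate(alignments)])
    return hyde_gamma_test(count_site_patterns(sup, _ROLES))


def hyde_type_one_error(n_replicates: int = 200, n_loci: int = 100, sites: int = 300,
                        seed: int = 0, alpha: float = 0.05) -> float:
    """False-positive rate of the γ test on tree-like (γ = 0) data."""
    hits = 0
    for rep in range(n_replicates):
        _, alignments = simulate_network_dataset(n_loci, sites, seed + 1000 * (rep + 1), gamma=0.0)
        sup = concatenate_alignments([(f"l{i:04d}", a) for i, a in enumerate(alignments)])
        res = hyde_gamma_test(count_site_patterns(sup, _ROLES), alpha=alpha)
        hits += res.significant
    return hits / n_replicates


def ks_peak_recovery(n_pairs: int = 2000, contamination: float = 0.3, seed: int = 0,
                     identity_cutoff: float = 0.90):
    """Ks mixture fits before and after the high-identity cutoff.

    Returns (before_fit, after_fit, n_removed).
    """
    pairs = simulate_paralog_pairs(
        n_pairs, contamination_fraction=contamination, seed=seed
    )
    estimates = [ng86_ks(codon_align_pair(a, b)) for a, b in pairs]
    before = fit_ks_peaks([e.ks for e in estimates], ks_window=(0.01, 5.0), seed=seed)
    kept, n_removed = identity_cutoff_filter(estimates, identity_cutoff)
    after = fit_ks_peaks([e.ks for e in kept], seed=seed)
    return before, after, n_removed


def classifier_accuracy(n_loci: int = 150, sites: int = 10_000, seed: int = 0,
                        estimated: bool = False, n_bootstrap: int = 50,
                        support_threshold: float = 0.70) -> float:
    """Fraction of classified loci whose position matches the recorded truth.

    With ``estimated=True`` the classifier runs on outgroup-rooted
    neighbor-joining trees built from simulated alignments, keeping only
    positions with bootstrap support at or above ``support_threshold``
    (loci with unsupported positions are left out of both numerator and
    denominator, as when sorting real loci by well-supported positions
    only).  Otherwise the true gene trees are classified directly and every
    locus counts.
    """
    from .genetreesort import bootstrap_classify

    cfg = SimulationConfig(n_loci=n_loci, sites_per_locus=sites, seed=seed, mode="classes")
    loci = simulate_case_loci(cfg)
    correct = classified = 0
    if estimated:
        rng = np.random.default_rng(seed + 1)
        model = cfg.substitution_model()
        for locus in loci:
            aln = simulate_alignment(
                scale_tree(locus.tree, cfg.clock_rate_per_cu), model, sites, rng=rng
            )
            cls, _support = bootstrap_classify(
                aln, _SCHEME, n_reps=n_bootstrap,
                seed=int(rng.integers(2**31)), support_threshold=support_threshold,
            )
            if cls != "unresolved":
                classified += 1
                correct += cls == locus.realized_class
    else:
        for locus in loci:
            classified += 1
            correct += classify_focal_position(locus.tree, _SCHEME) == locus.realized_class
    if classified == 0:
        raise RuntimeError("no locus was confidently classified")
    return correct / classified


def ils_only_network(internal_branch: float = 0.3) -> SpeciesNetwork:
    """A reticulation-free species tree with the focal clade sister to C.

    The short branch between the (B,C) split and A's join drives ILS; the
    resulting triplet counts show one dominant topology with the two
    alternatives nearly equal — the classic ILS signature.
    """
    s = 268.0 * 0.125  # parental split, CU
    bc = s - internal_branch
    w = 50.0 * 0.125  # crown ages
    wp = 150.0 * 0.125
    backbone = (
        f"(Iso:{370 * 0.125:.6g},(Sel:{304 * 0.125:.6g},"
        f"((A1:{wp:.6g},A2:{wp:.6g}):{s - wp:.6g},"
        f"((B1:{w:.6g},B2:{w:.6g}):{bc - w:.6g},"
        f"(C1:{wp:.6g},C2:{wp:.6g}):{bc - wp:.6g}):{internal_branch:.6g})"
        f":{(304 - 268) * 0.125:.6g}):{(370 - 304) * 0.125:.6g});"
    )
    return SpeciesNetwork(backbone_newick=backbone)


def pattern_verdict_rates(scenario: str, n_replicates: int = 200, n_loci: int = 300,
                          seed: int = 0) -> dict:
    """Verdict frequencies of the topology-frequency diagnostic.

    ``scenario`` is ``"hybrid"`` (the paper-mix three-class case study) or
    ``"ils"`` (reticulation-free tree with a short internal branch).  Only
    gene-tree topologies are needed, so no sequences are simulated.
    """
    from .genetreesort import ils_vs_hybrid_pattern

    verdicts: dict = {"ILS_like": 0, "hybrid_like": 0, "ambiguous": 0}
    for rep in range(n_replicates):
        rep_seed = seed + 7919 * (rep + 1)
        if scenario == "hybrid":
            cfg = SimulationConfig(
                n_loci=n_loci, sites_per_locus=10, seed=rep_seed, mode="classes"
            )
            loci = simulate_case_loci(cfg)
            trees = [l.tree for l in loci]
        elif scenario == "ils":
            loci = simulate_msc_gene_trees(ils_only_network(), n_loci, seed=rep_seed)
            trees = [l.tree for l in loci]
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        counts = triplet_frequencies(trees, _TRIPLET_GROUPS)
        verdict = ils_vs_hybrid_pattern(counts.as_tuple()).verdict
        verdicts[verdict] += 1
    return {k: v / n_replicates for k, v in verdicts.items()}


def date_case_study(n_loci: int = 90, sites: int = 2000, seed: int = 0,
                    tolerance: float = 0.05):
    """One dating replicate: sort true trees, NJ-date both gene sets, compare.

    Returns the :class:`~paleohybrid.chronology.ConsistencyReport`.
    """
    cfg = SimulationConfig(n_loci=n_loci, sites_per_locus=sites, seed=seed, mode="classes")
    loci = simulate_case_loci(cfg)
    rng = np.random.default_rng(seed + 1)
    model = cfg.substitution_model()
    ingroup = [t for k, v in SCENARIO_GROUPS.items() if k != "outgroup" for t in v]
    cals = [Calibration(frozenset(ingroup), 304.0)]
    chrons = {}
    for gene_set, cls in (("B", "sister_to_A"), ("C", "sister_to_C")):
        idx = [i for i, l in enumerate(loci) if l.realized_class == cls]
        named = []
        for i in idx:
            aln = simulate_alignment(
                scale_tree(loci[i].tree, cfg.clock_rate_per_cu), model, sites, rng=rng
            )
            named.append((f"l{i:04d}", aln))
        sup = concatenate_alignments(named)
        tree = reroot_outgroup(
            neighbor_joining(jc_distance_matrix(sup)), set(SCENARIO_GROUPS["outgroup"])
        )
        chrons[gene_set] = strict_clock_dates(tree, cals)
    return hybrid_time_consistency(chrons["B"], chrons["C"], _SCHEME, tolerance=tolerance)
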