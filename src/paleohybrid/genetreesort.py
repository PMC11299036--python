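"""Rooting, classification and topology-frequency diagnostics for gene trees.

The central operation places a focal clade (B) relative to two parental
superclades (A and C) in each rooted gene tree, partitioning loci into the
three gene sets that discriminate an ancient hybrid origin: B sister to
both parents, B sister to A only, or B sister to C only.  Frequencies of
rooted-triplet topologies feed the incomplete-lineage-sorting (ILS) versus
hybridization pattern test: under ILS the species-tree topology dominates
and the two alternatives are equally frequent; under hybrid origin two
topologies are similarly common and one is clearly rarest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
from scipy.stats import binomtest

from .formats import node_support, parse_newick

__all__ = [
    "GroupScheme",
    "GeneSetPartition",
    "TripletCounts",
    "PatternTest",
    "AmbiguousRootingError",
    "reroot_outgroup",
    "classify_focal_position",
    "bootstrap_classify",
    "partition_gene_sets",
    "triplet_frequencies",
    "ils_vs_hybrid_pattern",
]

CLASSES = ("sister_to_both", "sister_to_A", "sister_to_C", "unresolved")


class AmbiguousRootingError(ValueError):
    """Outgroup taxa cannot be separated from the ingroup by one edge."""


@dataclass(frozen=True)
class GroupScheme:
    """Named taxon groups: outgroup O, focal B, parents A and C, plus the rest."""

    outgroup: frozenset
    focal: frozenset
    parent1: frozenset
    parent2: frozenset
    other: frozenset = frozenset()

    def __post_init__(self):
        named = {
            "outgroup": self.outgroup,
            "focal": self.focal,
            "parent1": self.parent1,
            "parent2": self.parent2,
        }
        for name, group in named.items():
            if not group:
                raise ValueError(f"group {name!r} must be nonempty")
        groups = list(named.values()) + [self.other]
        seen: set = set()
        for g in groups:
            if seen & set(g):
                raise ValueError(f"taxon groups overlap: {sorted(seen & set(g))}")
            seen |= set(g)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GroupScheme":
        return cls(
            outgroup=frozenset(mapping["outgroup"]),
            focal=frozenset(mapping["focal"]),
            parent1=frozenset(mapping["parent1"]),
            parent2=frozenset(mapping["parent2"]),
            other=frozenset(mapping.get("other", ())),
        )


def _leaf_labels(node: dendropy.Node) -> set:
    return {l.taxon.label for l in node.leaf_iter()}


def _tree_labels(tree: dendropy.Tree) -> set:
    return {l.taxon.label for l in tree.leaf_node_iter()}


def reroot_outgroup(tree: dendropy.Tree, outgroup_taxa: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the edge separating the outgroup from everything else.

    The branch carrying the new root is split equally.  Raises
    :class:`AmbiguousRootingError` when the outgroup taxa do not form one
    side of any edge (i.e. cannot be monophyletic under any rooting), and
    ``ValueError`` when no outgroup taxon is present.
    """
    og = set(outgroup_taxa) & _tree_labels(tree)
    if not og:
        raise ValueError("no outgroup taxon present in tree")
    t = tree.clone(depth=1)
    ingroup = _tree_labels(t) - og
    if not ingroup:
        raise ValueError("outgroup covers the whole tree")
    # the separating edge has exactly the outgroup (or exactly the ingroup)
    # below it; its existence is rooting-invariant
    target = None
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = _leaf_labels(nd)
        if below == og or below == ingroup:
            target = nd.edge
            break
    if target is None:
        raise AmbiguousRootingError(
            "outgroup taxa are not separable from the ingroup (non-monophyletic)"
        )
    half = (target.length or 0.0) / 2.0
    t.reroot_at_edge(target, length1=half, length2=half, update_bipartitions=False)
    t.is_rooted = True
    t.suppress_unifurcations()
    return t


def _pruned_to(tree: dendropy.Tree, keep: set) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(keep & _tree_labels(tree)))
    return t


def classify_focal_position(
    tree: dendropy.Tree,
    scheme: GroupScheme,
    support_threshold: float = 0.0,
) -> str:
    """Class of a rooted gene tree by the focal clade's sister group.

    The tree is pruned to A∪B∪C; B must be monophyletic; the taxon content S
    of B's sister clade decides: S meeting both A and C -> ``sister_to_both``,
    S within A -> ``sister_to_A``, S within C -> ``sister_to_C``.  Anything
    else — B non-monophyletic, or the defining bipartition supported below
    ``support_threshold`` — is ``unresolved``.  Support values absent from
    the tree are not held against it.
    """
    labels = _tree_labels(tree)
    a = set(scheme.parent1) & labels
    b = set(scheme.focal) & labels
    c = set(scheme.parent2) & labels
    if not a or not b or not c:
        missing = [n for n, g in (("parent1", a), ("focal", b), ("parent2", c)) if not g]
        raise ValueError(f"tree shares no taxa with group(s): {missing}")
    t = _pruned_to(tree, a | b | c)
    if len(b) == 1:
        node = next(l for l in t.leaf_node_iter() if l.taxon.label in b)
    else:
        node = t.mrca(taxon_labels=sorted(b))
        if _leaf_labels(node) != b:
            return "unresolved"
    parent = node.parent_node
    if parent is None:
        return "unresolved"
    if support_threshold > 0:
        sup = node_support(parent)
        if sup is not None and sup < support_threshold:
            return "unresolved"
    sister = _leaf_labels(parent) - b
    if not sister:
        return "unresolved"
    in_a, in_c = sister & a, sister & c
    if in_a and in_c:
        return "sister_to_both"
    if in_a and not in_c:
        return "sister_to_A"
    if in_c and not in_a:
        return "sister_to_C"
    return "unresolved"


def bootstrap_classify(
    alignment,
    scheme: GroupScheme,
    n_reps: int = 50,
    seed: int | None = None,
    support_threshold: float = 0.70,
) -> tuple[str, float]:
    """Classify the focal position from sequence data, with bootstrap support.

    An outgroup-rooted neighbor-joining tree is built from the alignment and
    classified; the class's support is the fraction of column-resampling
    bootstrap replicates whose tree yields the same class.  Positions
    supported below ``support_threshold`` are reported ``unresolved`` —
    mirroring the practice of sorting loci only by well-supported positions.
    Returns ``(class, support)``.
    """
    import numpy as np

    from .formats import DistanceMatrix, jc_distance_matrix, neighbor_joining

    def classify_tree(tree):
        rooted = reroot_outgroup(tree, set(scheme.outgroup))
        return classify_focal_position(rooted, scheme)

    primary = classify_tree(neighbor_joining(jc_distance_matrix(alignment)))
    if primary == "unresolved" or n_reps < 1:
        return "unresolved", 0.0

    # precompute per-pair validity/mismatch masks so each bootstrap replicate
    # needs only column resummation, not a rebuilt alignment
    arr = alignment.to_array()
    taxa = alignment.ids
    n_taxa, n_cols = arr.shape
    valid = np.isin(arr, list("ACGT"))
    pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    pair_valid = np.array([valid[i] & valid[j] for i, j in pairs])
    pair_mismatch = np.array([(arr[i] != arr[j]) & pair_valid[k] for k, (i, j) in enumerate(pairs)])

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        v = pair_valid[:, cols].sum(axis=1)
        m = pair_mismatch[:, cols].sum(axis=1)
        if (v == 0).any():
            continue
        p = m / v
        if (p >= 0.75).any():
            continue  # saturated pair in this replicate
        dist = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        d = np.zeros((n_taxa, n_taxa))
        for k, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = dist[k]
        try:
            agree += classify_tree(neighbor_joining(DistanceMatrix(list(taxa), d))) == primary
        except (ValueError, AmbiguousRootingError):
            continue
    support = agree / n_reps
    if support < support_threshold:
        return "unresolved", support
    return primary, support


@dataclass
class GeneSetPartition:
    """Per-locus classes, class counts, and percentage shares of resolved loci."""

    counts: dict
    assignments: dict
    percentages: dict
    all_unresolved: bool = False

    @property
    def n_loci(self) -> int:
        return sum(self.counts.values())

    def summary(self) -> str:
        lines = ["gene-set partition", "-" * 38]
        for k in CLASSES:
            pct = f"{self.percentages[k]:6.2f}%" if k in self.percentages else "      -"
            lines.append(f"{k:>16}: {self.counts[k]:5d}  {pct}")
        return "\n".join(lines)


def partition_gene_sets(
    trees,
    scheme: GroupScheme,
    support_threshold: float = 0.0,
) -> GeneSetPartition:
    """Classify every tree and tabulate the three gene sets.

    ``trees`` is a sequence of rooted trees or of ``(name, tree)`` pairs.
    Percentages are shares of the three resolved classes only, rounded to
    two decimals.
    """
    items = []
    for i, entry in enumerate(trees):
        if isinstance(entry, tuple):
            items.append(entry)
        else:
            items.append((f"locus{i:04d}", entry))
    if not items:
        raise ValueError("no trees to partition")
    counts = {k: 0 for k in CLASSES}
    assignments = {}
    for name, tree in items:
        cls = classify_focal_position(tree, scheme, support_threshold)
        counts[cls] += 1
        assignments[name] = cls
    resolved = sum(counts[k] for k in CLASSES[:3])
    percentages = {}
    if resolved:
        for k in CLASSES[:3]:
            percentages[k] = round(100.0 * counts[k] / resolved, 2)
    return GeneSetPartition(
        counts=counts,
        assignments=assignments,
        percentages=percentages,
        all_unresolved=(resolved == 0),
    )


@dataclass
class TripletCounts:
    """Tallies of the three rooted-triplet topologies over designated groups."""

    names: tuple
    n_ab: int = 0
    n_ac: int = 0
    n_bc: int = 0
    n_unclassified: int = 0

    @property
    def total_resolved(self) -> int:
        return self.n_ab + self.n_ac + self.n_bc

    def as_tuple(self) -> tuple:
        return (self.n_ab, self.n_ac, self.n_bc)


def triplet_frequencies(trees, groups) -> TripletCounts:
    """Count which pair of three taxon groups is sister, per rooted tree.

    ``groups`` is an ordered sequence of three ``(name, taxa)`` pairs.  Trees
    in which any group is non-monophyletic (after pruning to the union) are
    tallied as unclassified.
    """
    named = [(n, set(g)) for n, g in groups]
    if len(named) != 3:
        raise ValueError("exactly three groups are required")
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    union = set().union(*(g for _, g in named))
    for name, g in named:
        if not any(g & _tree_labels(t) for t in trees):
            raise ValueError(f"group {name!r} absent from every tree")
    counts = TripletCounts(names=tuple(n for n, _ in named))
    (na, ga), (nb, gb), (nc, gc) = named
    for tree in trees:
        labels = _tree_labels(tree)
        if not (ga & labels and gb & labels and gc & labels):
            counts.n_unclassified += 1
            continue
        t = _pruned_to(tree, union)
        present = {n: g & labels for n, g in named}
        mono = {}
        ok = True
        for n, g in present.items():
            if len(g) == 1:
                mono[n] = g
            else:
                node = t.mrca(taxon_labels=sorted(g))
                if _leaf_labels(node) != g:
                    ok = False
                    break
                mono[n] = g
        if not ok:
            counts.n_unclassified += 1
            continue
        sister_pair = None
        for x, y, attr in (
            (na, nb, "n_ab"),
            (na, nc, "n_ac"),
            (nb, nc, "n_bc"),
        ):
            pair = mono[x] | mono[y]
            node = t.mrca(taxon_labels=sorted(pair))
            if _leaf_labels(node) == pair:
                sister_pair = attr
                break
        if sister_pair is None:
            counts.n_unclassified += 1
        else:
            setattr(counts, sister_pair, getattr(counts, sister_pair) + 1)
    return counts


@dataclass
class PatternTest:
    """Verdict of the topology-frequency diagnostic, with the two binomial tests."""

    verdict: str  # ILS_like | hybrid_like | ambiguous
    p_top_vs_second: float
    p_second_vs_third: float
    sorted_counts: tuple
    alpha: float


def ils_vs_hybrid_pattern(counts, alpha: float = 0.05) -> PatternTest:
    """Discriminate ILS-type from hybridization-type topology frequencies.

    With counts sorted n1 >= n2 >= n3, exact two-sided binomial tests of a
    50:50 split are applied to (n1, n2) and to (n2, n3).  ILS predicts one
    dominant topology with the two alternatives nearly equal (n1 > n2,
    n2 ~ n3); hybrid origin predicts two similarly frequent topologies and
    one clearly rarest (n1 ~ n2, n2 > n3).
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValueError("three nonnegative counts are required")
    if sum(counts) == 0:
        raise ValueError("all counts are zero")
    n1, n2, n3 = sorted(counts, reverse=True)
    p12 = binomtest(n1, n1 + n2).pvalue if n1 + n2 else 1.0
    p23 = binomtest(n2, n2 + n3).pvalue if n2 + n3 else 1.0
    top_differs = p12 < alpha
    alts_differ = p23 < alpha
    if top_differs and not alts_differ:
        verdict = "ILS_like"
    elif not top_differs and alts_differ:
        verdict = "hybrid_like"
    else:
        verdict = "ambiguous"
    return PatternTest(
        verdict=verdict,
        p_top_vs_second=p12,
        p_second_vs_third=p23,
        sorted_counts=(n1, n2, n3),
        alpha=alpha,
    )
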