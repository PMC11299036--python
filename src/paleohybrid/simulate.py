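"""Synthetic data: the multispecies coalescent on a one-reticulation network.

Everything downstream of ortholog filtering can be exercised on data from
this module: gene trees drawn from the multispecies coalescent (MSC) on a
species network with a single reticulation, nucleotide alignments evolved
along those trees, coding-sequence paralog pairs with a target Ks mixture,
and a packaged case study emulating the hybrid-origin scenario of the
*Selaginella sanguinolenta* clade (a focal clade B that inherited its genome
from the ancestors of two parental superclades A and C, with inheritance
probability ``gamma`` from the A side).

Units: species-network node heights and gene-tree branch lengths are in
coalescent units (CU, time / 2N generations); a single clock rate converts
CU to expected substitutions per site when sequences are simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml
from scipy.linalg import expm

from .formats import Alignment, Sequence, parse_newick, write_fasta, write_newick

__all__ = [
    "SpeciesNetwork",
    "LocusClassMix",
    "SimulationConfig",
    "SimulatedLocus",
    "JC69",
    "HKY85",
    "simulate_msc_gene_trees",
    "simulate_alignment",
    "simulate_paralog_pairs",
    "selaginella_network",
    "simulate_case_loci",
    "build_case_study",
    "scale_tree",
]

CLASS_NAMES = ("sister_to_A", "sister_to_C", "sister_to_both")


# ---------------------------------------------------------------------------
# Species network


@dataclass(frozen=True)
class SpeciesNetwork:
    """A rooted, ultrametric species tree with at most one reticulation.

    ``backbone_newick`` carries the non-hybrid taxa with CU branch lengths.
    The hybrid clade (``hybrid_newick``; ``None`` for a network-free species
    tree) attaches at ``hybridization_time`` to the stem edges above the
    clades ``parent1_clade`` and ``parent2_clade``; each gene lineage entering
    the reticulation follows the parent-1 side with probability ``gamma``.
    """

    backbone_newick: str
    hybrid_newick: str | None = None
    parent1_clade: frozenset = frozenset()
    parent2_clade: frozenset = frozenset()
    hybridization_time: float = 0.0
    gamma: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.hybrid_newick is not None and not (self.parent1_clade and self.parent2_clade):
            raise ValueError("a reticulated network needs both parental attachment clades")
        _SpeciesTable(self)  # validates backbone shape and attachment heights

    @property
    def has_reticulation(self) -> bool:
        return self.hybrid_newick is not None


class _SpNode:
    __slots__ = ("name", "age", "children", "parent")

    def __init__(self, name=None, age=0.0):
        self.name = name
        self.age = age
        self.children: list[_SpNode] = []
        self.parent: _SpNode | None = None

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _species_tree_from_newick(newick: str) -> _SpNode:
    """Parse an ultrametric newick (CU branch lengths) into aged nodes."""
    tree = parse_newick(newick, rooted=True)
    depth: dict = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            bl = nd.edge.length
            if bl is None:
                raise ValueError("species tree branch lengths are required")
            depth[nd] = depth[nd.parent_node] + bl
    max_depth = max(depth[nd] for nd in tree.leaf_node_iter())
    for nd in tree.leaf_node_iter():
        if abs(depth[nd] - max_depth) > 1e-9 * max(1.0, max_depth):
            raise ValueError("species tree must be ultrametric in coalescent units")

    def build(nd) -> _SpNode:
        node = _SpNode(
            name=nd.taxon.label if nd.taxon else None,
            age=max_depth - depth[nd],
        )
        for c in nd.child_nodes():
            child = build(c)
            child.parent = node
            node.children.append(child)
        return node

    return build(tree.seed_node)


class _SpeciesTable:
    """Resolved attachment points and ages for one network."""

    def __init__(self, net: SpeciesNetwork):
        self.root = _species_tree_from_newick(net.backbone_newick)
        self.net = net
        by_leafset = {}
        for node in self._walk(self.root):
            by_leafset[frozenset(l.name for l in node.leaves())] = node
        self.p1_node = by_leafset.get(frozenset(net.parent1_clade))
        self.p2_node = by_leafset.get(frozenset(net.parent2_clade))
        if net.has_reticulation:
            if self.p1_node is None or self.p2_node is None:
                raise ValueError("parental attachment clades are not clades of the backbone")
            for node, label in ((self.p1_node, "parent1"), (self.p2_node, "parent2")):
                top = node.parent.age if node.parent else math.inf
                if not (node.age <= net.hybridization_time < top):
                    raise ValueError(
                        f"hybridization time {net.hybridization_time} outside the {label} stem edge"
                    )
            self.hybrid_root = _species_tree_from_newick(_as_subtree(net.hybrid_newick))
            if self.hybrid_root.age > net.hybridization_time:
                raise ValueError("hybrid clade root is older than the hybridization time")
            # parental split = species MRCA of the two attachment clades
            union = frozenset(net.parent1_clade) | frozenset(net.parent2_clade)
            self.parental_split_age = min(
                node.age
                for node in self._walk(self.root)
                if union <= frozenset(l.name for l in node.leaves())
            )

    @staticmethod
    def _walk(node):
        yield node
        for c in node.children:
            yield from _SpeciesTable._walk(c)


def _as_subtree(newick_or_name: str) -> str:
    text = newick_or_name.strip()
    if not text.endswith(";"):
        text += ";"
    return text


# ---------------------------------------------------------------------------
# Gene-tree nodes


class _GNode:
    __slots__ = ("name", "height", "children")

    def __init__(self, name=None, height=0.0, children=()):
        self.name = name
        self.height = height
        self.children = list(children)

    def leaf_names(self):
        if not self.children:
            return {self.name}
        out = set()
        for c in self.children:
            out |= c.leaf_names()
        return out


def _coalesce(lineages, t0, t1, rng):
    """Kingman coalescent among ``lineages`` on [t0, t1]; rate C(k,2)."""
    lin = list(lineages)
    t = t0
    while len(lin) > 1:
        rate = len(lin) * (len(lin) - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        if t > t1:
            break
        i, j = rng.choice(len(lin), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = lin.pop(j)
        a = lin.pop(i)
        lin.append(_GNode(height=t, children=(a, b)))
    return lin


def _gnode_to_dendropy(root: _GNode) -> dendropy.Tree:
    def render(n: _GNode, parent_height: float) -> str:
        bl = parent_height - n.height
        if not n.children:
            return f"{n.name}:{bl:.10g}"
        inner = ",".join(render(c, n.height) for c in n.children)
        return f"({inner}):{bl:.10g}"

    inner = ",".join(render(c, root.height) for c in root.children)
    return parse_newick(f"({inner});", rooted=True)


def _pop_sim(node: _SpNode, top: float, rng) -> list[_GNode]:
    """Lineages of ``node``'s subtree surviving to height ``top``.

    Within-branch coalescences below ``node`` are drawn recursively.
    """
    if not node.children:
        lin = [_GNode(name=node.name, height=node.age)]
    else:
        lin = [l for c in node.children for l in _pop_sim(c, node.age, rng)]
    return _coalesce(lin, node.age, top, rng)


# ---------------------------------------------------------------------------
# MSC simulation on the network


@dataclass
class SimulatedLocus:
    """One simulated locus: rooted gene tree (CU branch lengths) plus truth."""

    tree: dendropy.Tree
    routing: tuple[str, ...] = ()
    locus_class: str | None = None  # intended class, when class-constrained
    realized_class: str | None = None


def _simulate_network_locus(tab: _SpeciesTable, rng, force_side: str | None = None):
    """One MSC draw on the network; hybrid lineages route at the reticulation."""
    net = tab.net
    routing: list[str] = []
    inject: dict[_SpNode, list[_GNode]] = {}
    if net.has_reticulation:
        hyb = _pop_sim(tab.hybrid_root, net.hybridization_time, rng)
        for lineage in hyb:
            if force_side is not None:
                side = force_side
            else:
                side = "P1" if rng.random() < net.gamma else "P2"
            routing.append(side)
            target = tab.p1_node if side == "P1" else tab.p2_node
            inject.setdefault(target, []).append(lineage)

    def sim(node: _SpNode) -> list[_GNode]:
        if not node.children:
            lin = [_GNode(name=node.name, height=node.age)]
        else:
            lin = []
            for c in node.children:
                lin.extend(sim(c))
        top = node.parent.age if node.parent else math.inf
        if node in inject:
            lin = _coalesce(lin, node.age, net.hybridization_time, rng)
            lin = lin + inject[node]
            lin = _coalesce(lin, net.hybridization_time, top, rng)
        else:
            lin = _coalesce(lin, node.age, top, rng)
        return lin

    roots = sim(tab.root)
    assert len(roots) == 1
    return roots[0], tuple(routing)


def _simulate_both_retained_locus(tab: _SpeciesTable, rng):
    """A locus whose gene tree puts the hybrid clade sister to both parents.

    The backbone coalesces without the hybrid; the hybrid clade coalesces to a
    single stem lineage which is grafted onto the gene-tree edge above the
    MRCA of the two parental clades, at the parental split age plus an
    exponential coalescent waiting time (truncated below the next node up).
    """
    net = tab.net
    hyb = _pop_sim(tab.hybrid_root, math.inf, rng)
    assert len(hyb) == 1
    hyb_anc = hyb[0]
    root = _pop_sim(tab.root, math.inf, rng)[0]
    union = frozenset(net.parent1_clade) | frozenset(net.parent2_clade)
    # locate the minimal gene node containing all parental taxa, and its parent
    target, parent = None, None

    def find(n: _GNode, par):
        nonlocal target, parent
        for c in n.children:
            find(c, n)
        if target is None and union <= n.leaf_names():
            target, parent = n, par

    find(root, None)
    lo = max(tab.parental_split_age, target.height, hyb_anc.height)
    hi = parent.height if parent is not None else math.inf
    hg = lo + rng.exponential(1.0)
    if hg >= hi:
        hg = lo + 0.5 * (hi - lo)
    graft = _GNode(height=hg, children=(target, hyb_anc))
    if parent is None:
        root = graft
    else:
        parent.children[parent.children.index(target)] = graft
    return root


def _topology_class(root: _GNode, group_a: set, group_b: set, group_c: set) -> str:
    """Position of clade B relative to A and C, read off a gene-tree root.

    Kept local to the simulator so that recorded truth is independent of the
    downstream classifier implementation.
    """
    abc = group_a | group_b | group_c

    def pruned(n: _GNode):
        return n.leaf_names() & abc

    # minimal node whose pruned leaf set contains B
    best = None

    def find(n: _GNode):
        nonlocal best
        for c in n.children:
            find(c)
        if best is None and group_b <= pruned(n):
            best = n

    find(root)
    if pruned(best) != group_b:
        return "unresolved"
    # ascend to the first strictly larger pruned leaf set
    path = []

    def trail(n: _GNode):
        if n is best:
            return True
        for c in n.children:
            if trail(c):
                path.append(n)
                return True
        return False

    trail(root)
    for anc in path:
        sister = pruned(anc) - group_b
        if sister:
            in_a, in_c = sister & group_a, sister & group_c
            if in_a and in_c:
                return "sister_to_both"
            if in_a:
                return "sister_to_A"
            return "sister_to_C"
    return "unresolved"


def simulate_msc_gene_trees(
    network: SpeciesNetwork,
    n_loci: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    class_groups: tuple[set, set, set] | None = None,
) -> list[SimulatedLocus]:
    """Draw ``n_loci`` gene trees under the MSC on ``network``.

    Each lineage entering the reticulation independently follows the
    parent-1 side with probability ``network.gamma``; the chosen sides are
    recorded per locus.  When ``class_groups`` (A, B, C taxon sets) is given,
    the realized topology class of the focal clade is recorded as well.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    tab = _SpeciesTable(network)
    out = []
    for _ in range(n_loci):
        root, routing = _simulate_network_locus(tab, rng)
        locus = SimulatedLocus(tree=_gnode_to_dendropy(root), routing=routing)
        if class_groups is not None:
            locus.realized_class = _topology_class(root, *map(set, class_groups))
        out.append(locus)
    return out


# ---------------------------------------------------------------------------
# Sequence evolution


class JC69:
    """Jukes-Cantor 1969: equal base frequencies, one exchange rate."""

    base_freqs = np.full(4, 0.25)

    def transition_matrix(self, t: float) -> np.ndarray:
        same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
        diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
        p = np.full((4, 4), diff)
        np.fill_diagonal(p, same)
        return p


class HKY85:
    """Hasegawa-Kishino-Yano 1985: transition/transversion ratio ``kappa``."""

    def __init__(self, kappa: float = 2.0, base_freqs=(0.25, 0.25, 0.25, 0.25)):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        freqs = np.asarray(base_freqs, dtype=float)
        if freqs.shape != (4,) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("base frequencies must be 4 values summing to 1")
        self.kappa = kappa
        self.base_freqs = freqs
        # bases ordered A, C, G, T; transitions are A<->G and C<->T
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(freqs * np.diag(q)).sum()  # mean rate, for unit branch-length scaling
        self._q = q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        return expm(self._q * t)


BASES = np.array(list("ACGT"))


def simulate_alignment(
    gene_tree: dendropy.Tree,
    model,
    n_sites: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Evolve independent sites along ``gene_tree``.

    Branch lengths must already be in expected substitutions per site.
    The root sequence is drawn from the model's stationary frequencies.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    states: dict = {}
    root = gene_tree.seed_node
    states[root] = rng.choice(4, size=n_sites, p=model.base_freqs)
    for nd in gene_tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length or 0.0
        if t <= 0.0:
            states[nd] = states[nd.parent_node].copy()
            continue
        p = model.transition_matrix(t)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n_sites)
        parent = states[nd.parent_node]
        states[nd] = (u[:, None] > cum[parent]).sum(axis=1)
    seqs = []
    for leaf in gene_tree.leaf_node_iter():
        seqs.append(Sequence(leaf.taxon.label, "".join(BASES[states[leaf]])))
    return Alignment(sorted(seqs, key=lambda s: s.id))


def scale_tree(tree: dendropy.Tree, rate: float) -> dendropy.Tree:
    """Clone a tree with branch lengths multiplied by ``rate``."""
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * rate
    return out


# ---------------------------------------------------------------------------
# Paralog pairs for the Ks pipeline

#: second codon position fixed to C keeps every xCn codon coding and stop-free
_P2 = "C"


def _random_cds(n_codons: int, rng) -> np.ndarray:
    codons = np.empty((n_codons, 3), dtype="<U1")
    codons[:, 0] = BASES[rng.integers(0, 4, n_codons)]
    codons[:, 1] = _P2
    codons[:, 2] = BASES[rng.integers(0, 4, n_codons)]
    return codons


def _mutate_positions(codons: np.ndarray, column: int, n_changes: int, rng) -> np.ndarray:
    out = codons.copy()
    idx = rng.choice(codons.shape[0], size=n_changes, replace=False)
    for i in idx:
        current = out[i, column]
        choices = [b for b in "ACGT" if b != current]
        out[i, column] = choices[int(rng.integers(0, 3))]
    return out


def _quantized(n: int, frac: float, rng) -> int:
    whole = math.floor(n * frac)
    if rng.random() < n * frac - whole:
        whole += 1
    return min(whole, n)


def simulate_paralog_pairs(
    n_pairs: int,
    ks_mixture: list[tuple[float, float, float]] | None = None,
    contamination_fraction: float = 0.0,
    seed: int | None = None,
    n_codons: int = 400,
    ka_over_ks: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[tuple[Sequence, Sequence]]:
    """Coding-sequence pairs whose synonymous divergence follows a Gaussian mixture.

    ``ks_mixture`` is a list of ``(weight, mean, sd)`` components (default:
    equal-weight peaks at 1.5 and 3.0, as in the hybrid-clade scenario).
    Codons use a fixed second position so every third-position change is
    synonymous and every first-position change nonsynonymous; the number of
    changed sites is matched to the drawn Ks (quantile rounding), so the
    realized NG86 estimate sits on the drawn value up to 1/n_codons.
    Contaminated pairs (redundant transcripts / assembly artifacts) have
    nucleotide identity >= 0.90 by construction.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if not 0.0 <= contamination_fraction <= 1.0:
        raise ValueError("contamination_fraction must be in [0, 1]")
    if ks_mixture is None:
        ks_mixture = [(0.5, 1.5, 0.15), (0.5, 3.0, 0.3)]
    weights = np.array([w for w, _, _ in ks_mixture], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mixture weights must be nonnegative and sum > 0")
    if any(sd <= 0 or mu <= 0 for _, mu, sd in ks_mixture):
        raise ValueError("mixture means and SDs must be positive")
    weights = weights / weights.sum()
    if rng is None:
        rng = np.random.default_rng(seed)

    n_contam = _quantized(n_pairs, contamination_fraction, rng) if n_pairs else 0
    pairs = []
    for i in range(n_pairs):
        anc = _random_cds(n_codons, rng)
        if i < n_contam:
            # near-identical transcript: small synonymous-only divergence
            ks = rng.uniform(0.02, 0.30)
        else:
            comp = rng.choice(len(ks_mixture), p=weights)
            ks = max(0.02, rng.normal(ks_mixture[comp][1], ks_mixture[comp][2]))
        ps = 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))
        d_syn = _quantized(n_codons, ps, rng)
        other = _mutate_positions(anc, 2, d_syn, rng)
        if ka_over_ks > 0 and i >= n_contam:
            ka = ka_over_ks * ks
            pn = 0.75 * (1.0 - math.exp(-4.0 * ka / 3.0))
            other = _mutate_positions(other, 0, _quantized(n_codons, pn, rng), rng)
        pairs.append(
            (
                Sequence(f"pair{i:05d}_a", "".join(anc.ravel())),
                Sequence(f"pair{i:05d}_b", "".join(other.ravel())),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Packaged case study


@dataclass(frozen=True)
class LocusClassMix:
    """Proportions of the three locus classes (must sum to 1)."""

    parent1_retained: float = 0.2334
    parent2_retained: float = 0.3919
    both_retained: float = 0.3746

    def __post_init__(self):
        vals = (self.parent1_retained, self.parent2_retained, self.both_retained)
        # printed-precision proportions (e.g. 37.46/23.34/39.19%) sum to 0.9999
        if any(v < 0 for v in vals) or not math.isclose(sum(vals), 1.0, abs_tol=1e-3):
            raise ValueError("class proportions must be nonnegative and sum to 1")

    def normalized(self) -> dict[str, float]:
        total = self.parent1_retained + self.parent2_retained + self.both_retained
        return {
            "sister_to_A": self.parent1_retained / total,
            "sister_to_C": self.parent2_retained / total,
            "sister_to_both": self.both_retained / total,
        }

    def quota(self, n_loci: int) -> dict[str, int]:
        """Largest-remainder apportionment of ``n_loci`` over the classes."""
        props = self.normalized()
        floors = {k: math.floor(n_loci * p) for k, p in props.items()}
        rem = {k: n_loci * p - floors[k] for k, p in props.items()}
        short = n_loci - sum(floors.values())
        for k in sorted(rem, key=lambda k: (-rem[k], k))[:short]:
            floors[k] += 1
        return floors


@dataclass
class SimulationConfig:
    """Knobs of the packaged case study."""

    n_loci: int = 347
    sites_per_locus: int = 1000
    seed: int = 0
    mode: str = "classes"  # "classes" (quota), "classes_multinomial", or "network"
    model: str = "jc69"
    kappa: float = 2.0
    gamma: float = 0.4511
    locus_class_mix: LocusClassMix = field(default_factory=LocusClassMix)
    time_scale: float = 0.125  # coalescent units per My
    clock_rate_per_my: float = 0.002  # substitutions / site / My

    def __post_init__(self):
        if self.n_loci < 1 or self.sites_per_locus < 1:
            raise ValueError("counts must be positive")
        if self.mode not in ("classes", "classes_multinomial", "network"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def clock_rate_per_cu(self) -> float:
        return self.clock_rate_per_my / self.time_scale

    def substitution_model(self):
        if self.model == "jc69":
            return JC69()
        if self.model == "hky85":
            return HKY85(self.kappa)
        raise ValueError(f"unknown substitution model {self.model!r}")


#: Node ages (Ma) of the emulated scenario: Isoetes split, the earliest-
#: diverging non-rhizophoric lineage, the parental-superclade split, the
#: hybridization, and the within-clade crown splits.
SCENARIO_AGES_MA = {
    "root": 370.0,
    "other_split": 304.0,
    "parental_split": 268.0,
    "hybridization": 248.0,
    "within_parent1": 150.0,
    "within_parent2": 150.0,
    "within_hybrid": 50.0,
}

SCENARIO_GROUPS = {
    "outgroup": ["Iso"],
    "other": ["Sel"],
    "parent1": ["A1", "A2"],
    "focal": ["B1", "B2"],
    "parent2": ["C1", "C2"],
}


def selaginella_network(
    gamma: float = 0.4511,
    time_scale: float = 0.125,
    ages_ma: dict | None = None,
) -> SpeciesNetwork:
    """The case-study network: focal clade B of hybrid origin between A and C."""
    ages = dict(SCENARIO_AGES_MA)
    if ages_ma:
        ages.update(ages_ma)
    s = {k: v * time_scale for k, v in ages.items()}
    ap = s["within_parent1"]
    cp = s["within_parent2"]
    backbone = (
        f"(Iso:{s['root']:.10g},"
        f"(Sel:{s['other_split']:.10g},"
        f"((A1:{ap:.10g},A2:{ap:.10g}):{s['parental_split'] - ap:.10g},"
        f"(C1:{cp:.10g},C2:{cp:.10g}):{s['parental_split'] - cp:.10g})"
        f":{s['other_split'] - s['parental_split']:.10g})"
        f":{s['root'] - s['other_split']:.10g});"
    )
    hybrid = f"(B1:{s['within_hybrid']:.10g},B2:{s['within_hybrid']:.10g});"
    return SpeciesNetwork(
        backbone_newick=backbone,
        hybrid_newick=hybrid,
        parent1_clade=frozenset(SCENARIO_GROUPS["parent1"]),
        parent2_clade=frozenset(SCENARIO_GROUPS["parent2"]),
        hybridization_time=s["hybridization"],
        gamma=gamma,
    )


def simulate_case_loci(config: SimulationConfig) -> list[SimulatedLocus]:
    """Simulate the case-study gene trees (CU branch lengths) with truth labels."""
    rng = np.random.default_rng(config.seed)
    net = selaginella_network(gamma=config.gamma, time_scale=config.time_scale)
    tab = _SpeciesTable(net)
    groups = (
        set(SCENARIO_GROUPS["parent1"]),
        set(SCENARIO_GROUPS["focal"]),
        set(SCENARIO_GROUPS["parent2"]),
    )
    loci: list[SimulatedLocus] = []
    if config.mode == "network":
        for _ in range(config.n_loci):
            root, routing = _simulate_network_locus(tab, rng)
            loci.append(
                SimulatedLocus(
                    tree=_gnode_to_dendropy(root),
                    routing=routing,
                    realized_class=_topology_class(root, *groups),
                )
            )
        return loci
    if config.mode == "classes":
        quota = config.locus_class_mix.quota(config.n_loci)
        labels = [k for k in CLASS_NAMES for _ in range(quota[k])]
    else:
        norm = config.locus_class_mix.normalized()
        probs = [norm[k] for k in CLASS_NAMES]
        draws = rng.choice(3, size=config.n_loci, p=probs)
        labels = [CLASS_NAMES[d] for d in draws]
    for label in labels:
        if label == "sister_to_both":
            root = _simulate_both_retained_locus(tab, rng)
            routing: tuple[str, ...] = ()
        else:
            side = "P1" if label == "sister_to_A" else "P2"
            root, routing = _simulate_network_locus(tab, rng, force_side=side)
        loci.append(
            SimulatedLocus(
                tree=_gnode_to_dendropy(root),
                routing=routing,
                locus_class=label,
                realized_class=_topology_class(root, *groups),
            )
        )
    return loci


def build_case_study(config: SimulationConfig, out_dir, overwrite: bool = False) -> Path:
    """Write a complete on-disk input set for the pipeline, plus a truth log.

    Layout: ``loci/<locus>.fasta`` (simulated nucleotide alignments),
    ``trees/<locus>.nwk`` (true gene trees, CU branch lengths),
    ``groups.yaml`` (taxon-group scheme), ``truth.json`` (true gamma, class
    labels, node ages, seeds).  Deterministic given the config.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} exists; pass overwrite=True")
    (out / "loci").mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(parents=True, exist_ok=True)

    loci = simulate_case_loci(config)
    model = config.substitution_model()
    seq_rng = np.random.default_rng(config.seed + 1)
    records = []
    for i, locus in enumerate(loci):
        name = f"locus{i:04d}"
        subst_tree = scale_tree(locus.tree, config.clock_rate_per_cu)
        aln = simulate_alignment(subst_tree, model, config.sites_per_locus, rng=seq_rng)
        (out / "loci" / f"{name}.fasta").write_text(write_fasta(aln.sequences))
        (out / "trees" / f"{name}.nwk").write_text(write_newick(locus.tree) + "\n")
        records.append(
            {
                "locus": name,
                "class": locus.locus_class,
                "realized_class": locus.realized_class,
                "routing": list(locus.routing),
            }
        )

    groups = {k: list(v) for k, v in SCENARIO_GROUPS.items()}
    (out / "groups.yaml").write_text(yaml.safe_dump(groups, sort_keys=True))
    truth = {
        "gamma": config.gamma,
        "mode": config.mode,
        "seed": config.seed,
        "n_loci": config.n_loci,
        "sites_per_locus": config.sites_per_locus,
        "time_scale_cu_per_my": config.time_scale,
        "clock_rate_per_my": config.clock_rate_per_my,
        "clock_rate_per_cu": config.clock_rate_per_cu,
        "node_ages_ma": SCENARIO_AGES_MA,
        "class_proportions": {
            "sister_to_A": config.locus_class_mix.parent1_retained,
            "sister_to_C": config.locus_class_mix.parent2_retained,
            "sister_to_both": config.locus_class_mix.both_retained,
        },
        "loci": records,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out
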