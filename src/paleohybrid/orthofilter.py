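"""Ortholog selection: redundancy clustering, two-pass paralog filtering,
and a substitution-saturation screen.

The two-pass filter mirrors transcriptome ortholog curation: a first pass
over a small set of representative species (every species present, known
reference clades monophyletic in the gene tree), then a second pass over
all accessions that additionally requires a minimum aligned length
(default 1,000 bp).  Redundant near-identical transcripts are collapsed
beforehand by greedy longest-first clustering at high identity (default
0.98), emulating CD-HIT-style deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TSequence

import numpy as np
from Bio.Align import PairwiseAligner

from .formats import Alignment, Sequence

__all__ = [
    "HomologGroup",
    "FilterReport",
    "SaturationReport",
    "cluster_redundant",
    "filter_orthologs",
    "saturation_index",
]

CRITERIA = ("missing_species", "non_monophyletic_reference_clade", "short_alignment", "saturated")


@dataclass
class HomologGroup:
    """One homolog group: per-species sequences, optional alignment and tree."""

    group_id: str
    members: dict  # species -> list[Sequence]
    alignment: Alignment | None = None
    tree: object = None  # dendropy.Tree, optional

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.group_id}: no species")
        ids = [s.id for seqs in self.members.values() for s in seqs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"group {self.group_id}: duplicate member ids")

    @property
    def species(self) -> set:
        return set(self.members)


@dataclass
class FilterReport:
    group_id: str
    passed: bool
    failed_criteria: frozenset

    def __post_init__(self):
        unknown = set(self.failed_criteria) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        if self.passed != (not self.failed_criteria):
            raise ValueError("passed flag inconsistent with failed criteria")


# ---------------------------------------------------------------------------
# Redundancy clustering


def _global_identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    """Matches over alignment columns, terminal gaps excluded."""
    aln = aligner.align(a, b)[0]
    g1, g2 = str(aln[0]), str(aln[1])
    # trim terminal gap runs on either sequence
    start = 0
    end = len(g1)
    while start < end and (g1[start] == "-" or g2[start] == "-"):
        start += 1
    while end > start and (g1[end - 1] == "-" or g2[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    cols = end - start
    matches = sum(g1[i] == g2[i] for i in range(start, end))
    return matches / cols


def cluster_redundant(
    seqs: TSequence[Sequence], identity_threshold: float = 0.98
) -> tuple[list[Sequence], dict]:
    """Greedy longest-first clustering of near-identical sequences.

    A sequence joins the first existing cluster whose representative it
    matches at or above the identity threshold (global alignment identity,
    terminal gaps excluded); otherwise it founds a new cluster.
    Representatives are the longest members (ties by id).  Returns the
    representatives and a map representative id -> member ids.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    reps: list[Sequence] = []
    clusters: dict = {}
    for seq in ordered:
        home = None
        for rep in reps:
            if seq.residues == rep.residues or _global_identity(
                seq.residues, rep.residues, aligner
            ) >= identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(seq)
            clusters[seq.id] = [seq.id]
        else:
            clusters[home.id].append(seq.id)
    return reps, clusters


# ---------------------------------------------------------------------------
# Two-pass ortholog filtering


def _clade_is_monophyletic(tree, clade: set) -> bool:
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    present = clade & labels
    if len(present) <= 1:
        return True
    node = tree.mrca(taxon_labels=sorted(present))
    return {l.taxon.label for l in node.leaf_iter()} == present


def filter_orthologs(
    groups: Iterable[HomologGroup],
    stage: str,
    species_required: Iterable[str],
    reference_clades: Mapping[str, Iterable[str]] | None = None,
    min_aligned_length: int = 1000,
    missing_clade_policy: str = "fail",
) -> tuple[list[HomologGroup], list[FilterReport]]:
    """Apply one pass of the paralog-removal filter.

    A group passes iff every required species has at least one member, every
    reference clade is monophyletic in the group's tree, and — in the second
    pass only — the aligned length is at least ``min_aligned_length``
    (a gene shorter than the cutoff is excluded).  Reference-clade taxa
    absent from the tree count as a failure under the default policy
    (``"fail"``); ``"skip"`` ignores such clades.
    """
    if stage not in ("first_pass", "second_pass"):
        raise ValueError("stage must be 'first_pass' or 'second_pass'")
    if missing_clade_policy not in ("fail", "skip"):
        raise ValueError("missing_clade_policy must be 'fail' or 'skip'")
    species_required = set(species_required)
    reference_clades = {k: set(v) for k, v in (reference_clades or {}).items()}
    kept: list[HomologGroup] = []
    reports: list[FilterReport] = []
    for group in groups:
        failed: set = set()
        present = {sp for sp, seqs in group.members.items() if seqs}
        if species_required - present:
            failed.add("missing_species")
        if reference_clades:
            if group.tree is None:
                failed.add("non_monophyletic_reference_clade")
            else:
                labels = {l.taxon.label for l in group.tree.leaf_node_iter()}
                for clade in reference_clades.values():
                    if clade - labels:
                        if missing_clade_policy == "fail":
                            failed.add("non_monophyletic_reference_clade")
                        continue
                    if not _clade_is_monophyletic(group.tree, clade):
                        failed.add("non_monophyletic_reference_clade")
        if stage == "second_pass":
            length = group.alignment.length if group.alignment is not None else 0
            if length < min_aligned_length:
                failed.add("short_alignment")
        report = FilterReport(group.group_id, passed=not failed, failed_criteria=frozenset(failed))
        reports.append(report)
        if report.passed:
            kept.append(group)
    return kept, reports


# ---------------------------------------------------------------------------
# Saturation screen


@dataclass
class SaturationReport:
    """Entropy-based saturation index with a randomization-null critical value."""

    iss: float
    iss_critical: float
    saturated: bool
    n_columns_used: int


def _entropy_from_codes(codes: np.ndarray) -> tuple[float, int]:
    """Mean plug-in Shannon entropy over columns with >= 2 coded bases.

    ``codes`` holds 0..3 for A/C/G/T and -1 for gap/ambiguity.
    """
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])  # (4, n_col)
    totals = counts.sum(axis=0)
    usable = totals >= 2
    if not usable.any():
        raise ValueError("alignment has no usable (unambiguous) columns")
    p = counts[:, usable] / totals[usable]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    site_entropy = terms.sum(axis=0)
    return float(site_entropy.mean()), int(usable.sum())


def saturation_index(
    alignment: Alignment, n_randomizations: int = 1000, seed: int | None = None
) -> SaturationReport:
    """Screen an alignment for substitution saturation.

    The index is the mean per-site Shannon entropy divided by its
    expectation under full saturation (every cell an independent draw from
    the alignment's base composition); a fully saturated alignment scores
    about 1, an invariant one 0.  The critical value is the 5th percentile
    of the index over fully randomized alignments of the same shape, so
    ``saturated`` flags data indistinguishable from noise at alpha = 0.05.
    """
    if len(alignment.sequences) < 4:
        raise ValueError("saturation screen needs at least 4 sequences")
    rng = np.random.default_rng(seed)
    arr = alignment.to_array()
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for code, base in enumerate("ACGT"):
        codes[arr == base] = code
    if not (codes >= 0).any():
        raise ValueError("alignment has no unambiguous nucleotide columns")
    base_counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
    composition = base_counts / base_counts.sum()
    obs_entropy, n_used = _entropy_from_codes(codes)

    shape = arr.shape
    null_entropies = np.empty(n_randomizations)
    for r in range(n_randomizations):
        rand = rng.choice(4, size=shape, p=composition).astype(np.int8)
        null_entropies[r], _ = _entropy_from_codes(rand)
    expected = float(null_entropies.mean())
    if expected <= 0:
        return SaturationReport(0.0, 0.0, False, n_used)
    iss = obs_entropy / expected
    iss_critical = float(np.percentile(null_entropies / expected, 5))
    return SaturationReport(
        iss=iss,
        iss_critical=iss_critical,
        saturated=iss >= iss_critical,
        n_columns_used=n_used,
    )
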