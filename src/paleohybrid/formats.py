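"""Sequence, alignment and tree plumbing shared by every pipeline stage.

FASTA and newick handling is deliberately strict: duplicate ids, empty
records and malformed trees are errors, because silently dropped records
are the classic way ortholog pipelines go wrong.  Trees are carried as
:class:`dendropy.Tree` objects throughout; internal node labels hold
support values when numeric.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import dendropy
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

__all__ = [
    "Sequence",
    "Alignment",
    "DistanceMatrix",
    "FastaError",
    "NewickError",
    "SaturatedDistanceError",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "node_support",
    "jc_distance",
    "jc_distance_matrix",
    "neighbor_joining",
    "concatenate_alignments",
]

NUCLEOTIDES = frozenset("ACGT")
#: Characters treated as missing/ambiguous in pairwise distance computations.
AMBIGUOUS = frozenset("-NRYSWKMBDHVU?X")


class FastaError(ValueError):
    pass


class NewickError(ValueError):
    pass


class SaturatedDistanceError(ValueError):
    """Raised when a pairwise mismatch fraction is beyond the JC domain."""


@dataclass(frozen=True)
class Sequence:
    """A named residue string (nucleotide or amino acid)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length sequences plus an optional gene partition map.

    ``partition_map`` entries are ``(name, start, end)`` half-open 0-based
    column ranges; when present they must tile ``[0, length)``.
    """

    sequences: list[Sequence]
    partition_map: list[tuple[str, int, int]] | None = None

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dup}")
        if self.partition_map is not None:
            spans = sorted((s, e, n) for n, s, e in self.partition_map)
            pos = 0
            for s, e, n in spans:
                if s != pos:
                    raise ValueError(f"partition {n!r} does not tile alignment (gap/overlap at {pos})")
                pos = e
            if pos != self.length:
                raise ValueError("partitions do not cover the full alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def to_array(self) -> np.ndarray:
        """Alignment as a (n_sequences, n_columns) array of single characters.

        Cached; treat the returned array as read-only.
        """
        cached = getattr(self, "_array", None)
        if cached is None:
            rows = [np.frombuffer(s.residues.encode(), dtype="S1") for s in self.sequences]
            cached = np.vstack(rows).astype("U1")
            self._array = cached
        return cached

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        by_id = {s.id: s for s in self.sequences}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"taxa absent from alignment: {missing}")
        return Alignment([by_id[i] for i in wanted])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.d)
        if np.any(self.d[finite] < 0):
            raise ValueError("distances must be nonnegative")
        if not np.array_equal(self.d, self.d.T):
            if np.allclose(self.d, self.d.T, equal_nan=True):
                self.d = (self.d + self.d.T) / 2.0
            else:
                raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> list[Sequence]:
    """Parse FASTA from a path or text stream.

    The id is the header token up to the first whitespace; residues are
    upper-cased; folding across lines is joined.  Duplicate ids and empty
    records are errors.
    """
    if isinstance(source, (str, bytes)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        records: list[Sequence] = []
        seen: set[str] = set()
        cur_id: str | None = None
        cur: list[str] = []

        def flush():
            if cur_id is None:
                return
            residues = "".join(cur)
            if not residues:
                raise FastaError(f"empty FASTA record {cur_id!r}")
            if cur_id in seen:
                raise FastaError(f"duplicate FASTA id {cur_id!r}")
            seen.add(cur_id)
            records.append(Sequence(cur_id, residues))

        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FastaError("FASTA header with empty id")
                cur = []
            else:
                if cur_id is None:
                    raise FastaError("sequence data before first FASTA header")
                cur.append(line.strip().upper())
        flush()
        if not records:
            raise FastaError("no FASTA records found")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(seqs: TSequence[Sequence], width: int = 70) -> str:
    """Render sequences as multi-line FASTA text (inverse of read_fasta)."""
    if not seqs:
        raise FastaError("refusing to write an empty FASTA")
    if width < 1:
        raise ValueError("line width must be >= 1")
    out = io.StringIO()
    for s in seqs:
        out.write(f">{s.id}\n")
        for i in range(0, len(s.residues), width):
            out.write(s.residues[i : i + width] + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a newick string into a dendropy Tree.

    Internal node labels are preserved (read as support values by
    :func:`node_support` when numeric).  ``rooted`` overrides the rooting
    flag; by default a basal bifurcation is treated as rooted.
    """
    for bad in (",)", "(,", ",,", "()"):
        pos = text.find(bad)
        if pos != -1:
            raise NewickError(f"empty subtree ({bad!r}) at position {pos}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"newick parse error: {exc}") from exc
    if rooted is None:
        rooted = len(tree.seed_node.child_nodes()) == 2
    tree.is_rooted = rooted
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line newick string with branch lengths."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return text


def node_support(node: dendropy.Node) -> float | None:
    """The numeric support stored in an internal node label, if any."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected distance for mismatch fraction ``p``."""
    if p < 0:
        raise ValueError("mismatch fraction must be >= 0")
    if p >= 0.75:
        raise SaturatedDistanceError(f"mismatch fraction {p:.4f} >= 0.75 (saturated)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc_distance_matrix(alignment: Alignment, on_saturation: str = "inf") -> DistanceMatrix:
    """Pairwise JC distances over shared ungapped, unambiguous columns.

    Gap and ambiguity columns are excluded pairwise.  A pair with mismatch
    fraction >= 0.75 is handled per ``on_saturation``: ``"inf"`` stores
    ``+inf`` as a saturation sentinel, ``"error"`` raises.
    """
    if len(alignment.sequences) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    if on_saturation not in ("inf", "error"):
        raise ValueError("on_saturation must be 'inf' or 'error'")
    arr = alignment.to_array()
    valid = np.isin(arr, sorted(NUCLEOTIDES))
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / n_shared
            try:
                d[i, j] = d[j, i] = jc_distance(p)
            except SaturatedDistanceError:
                if on_saturation == "error":
                    raise
                d[i, j] = d[j, i] = math.inf
    return DistanceMatrix(list(alignment.ids), d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree; negative estimated branch lengths are clamped to 0.

    Exact (topology and lengths) on additive matrices.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries (saturated pairs?)")
    sk = _SkbioDM(dm.d, ids=dm.taxa)
    tree = _skbio_nj(sk, neg_as_zero=True)
    newick = str(tree)
    out = parse_newick(newick, rooted=False)
    # NJ lengths may carry a tiny negative epsilon through skbio's clamp
    for edge in out.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return out


def concatenate_alignments(
    named_alignments: TSequence[tuple[str, Alignment]],
) -> Alignment:
    """Build a gap-filled supermatrix with a per-gene partition map.

    Taxa missing from a gene are padded with ``-``; taxon order is first
    appearance across genes.  Duplicate gene names are errors.
    """
    if not named_alignments:
        raise ValueError("no alignments to concatenate")
    names = [n for n, _ in named_alignments]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names: {dup}")
    taxa: list[str] = []
    for _, aln in named_alignments:
        for t in aln.ids:
            if t not in taxa:
                taxa.append(t)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for name, aln in named_alignments:
        by_id = {s.id: s.residues for s in aln.sequences}
        for t in taxa:
            chunks[t].append(by_id.get(t, "-" * aln.length))
        partitions.append((name, pos, pos + aln.length))
        pos += aln.length
    seqs = [Sequence(t, "".join(chunks[t])) for t in taxa]
    return Alignment(seqs, partition_map=partitions)
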