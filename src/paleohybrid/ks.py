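"""Synonymous-substitution (Ks) pipeline: pairing, codon alignment, NG86,
identity filtering, mixture peaks and rate calibration.

Peaks in the distribution of Ks (synonymous substitutions per synonymous
site) between duplicated or cross-species gene pairs mark polyploidization
and divergence events.  Transcriptome data contaminate the low-Ks region
with redundant near-identical transcripts (splice variants, assembly
artifacts); removing pairs above a nucleotide-identity cutoff before
fitting recovers the genuine peaks.

Ks/Ka are estimated with the Nei–Gojobori (1986) counting method:
fractional synonymous site counts per codon, minimal-pathway averaging for
multi-hit codons, and the Jukes–Cantor multiple-hit correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .formats import Sequence

__all__ = [
    "CodonPairAlignment",
    "KsEstimate",
    "BestHit",
    "KsMixtureModel",
    "KsPeakResult",
    "best_hit_pairs",
    "codon_align_pair",
    "ng86_ks",
    "identity_cutoff_filter",
    "fit_ks_peaks",
    "calibrate_ks",
]

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
GAP_CODON = "---"
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Pairing and codon alignment


@dataclass(frozen=True)
class BestHit:
    query: str
    target: str
    score: float
    reciprocal: bool


def _is_nucleotide(seqs: Iterable[Sequence]) -> bool:
    alphabet = set("".join(s.residues for s in seqs))
    return alphabet <= set("ACGTUN-")


def _local_aligner(nucleotide: bool) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    if nucleotide:
        al.match_score = 2.0
        al.mismatch_score = -3.0
        al.open_gap_score = -5.0
        al.extend_gap_score = -2.0
    else:
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    return al


def best_hit_pairs(
    query_seqs: TSequence[Sequence],
    target_seqs: TSequence[Sequence],
    min_score: float = 30.0,
) -> tuple[list[BestHit], list[str]]:
    """Best-scoring local-alignment hit per query (a blast-style pairing).

    Self-hits (identical ids) are skipped, ties go to the lexicographically
    smaller target id, queries with no hit at or above ``min_score`` are
    returned unpaired.  Hits whose target's own best hit is the query are
    flagged reciprocal.
    """
    if not target_seqs:
        raise ValueError("empty target set")
    aligner = _local_aligner(_is_nucleotide(list(query_seqs) + list(target_seqs)))

    def best_for(seq: Sequence, pool: TSequence[Sequence]):
        best: tuple[float, str] | None = None
        for cand in pool:
            if cand.id == seq.id:
                continue
            score = aligner.score(seq.residues, cand.residues)
            if best is None or score > best[0] or (score == best[0] and cand.id < best[1]):
                best = (score, cand.id)
        return best

    hits: list[BestHit] = []
    unpaired: list[str] = []
    forward: dict[str, tuple[float, str]] = {}
    for q in query_seqs:
        b = best_for(q, target_seqs)
        if b is None or b[0] < min_score:
            unpaired.append(q.id)
        else:
            forward[q.id] = b
    target_by_id = {t.id: t for t in target_seqs}
    query_pool = list(query_seqs)
    for qid, (score, tid) in forward.items():
        back = best_for(target_by_id[tid], query_pool)
        hits.append(BestHit(qid, tid, score, reciprocal=bool(back and back[1] == qid)))
    return hits, unpaired


@dataclass
class CodonPairAlignment:
    """Two codon-aligned coding sequences (gaps in whole codons)."""

    id1: str
    id2: str
    codons1: str
    codons2: str

    def __post_init__(self):
        if len(self.codons1) != len(self.codons2):
            raise ValueError("aligned codon strings differ in length")
        if len(self.codons1) % 3:
            raise ValueError("aligned length is not a multiple of 3")
        for i, (c1, c2) in enumerate(self.codon_pairs()):
            for c in (c1, c2):
                if c != GAP_CODON and ("-" in c):
                    raise ValueError(f"partial-codon gap at codon {i}")
                if c in STOP_CODONS:
                    raise ValueError(f"in-frame stop codon {c} at codon {i}")

    def codon_pairs(self):
        for i in range(0, len(self.codons1), 3):
            yield self.codons1[i : i + 3], self.codons2[i : i + 3]

    @property
    def identity(self) -> float:
        """Fraction of identical nucleotide columns, gaps excluded."""
        same = total = 0
        for a, b in zip(self.codons1, self.codons2):
            if a == "-" or b == "-":
                continue
            total += 1
            same += a == b
        return same / total if total else 0.0


def _prepare_cds(seq: Sequence) -> str:
    residues = seq.residues.upper().replace("U", "T")
    residues = residues[: len(residues) - len(residues) % 3]
    if residues[-3:] in STOP_CODONS:
        residues = residues[:-3]
    if not residues:
        raise ValueError(f"{seq.id}: no complete codons")
    for i in range(0, len(residues), 3):
        codon = residues[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"{seq.id}: internal stop codon {codon} at codon {i // 3}")
        if codon not in CODON_TO_AA:
            raise ValueError(f"{seq.id}: untranslatable codon {codon!r} at codon {i // 3}")
    return residues


def _translate(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def codon_align_pair(cds1: Sequence, cds2: Sequence) -> CodonPairAlignment:
    """Protein-guided pairwise codon alignment of two coding sequences.

    Sequences are trimmed to complete codons (a terminal stop is dropped),
    translated, globally aligned at the protein level (BLOSUM62), and the
    alignment is back-threaded onto codons so gaps occupy whole codons.
    """
    c1, c2 = _prepare_cds(cds1), _prepare_cds(cds2)
    p1, p2 = _translate(c1), _translate(c2)
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    aln = al.align(p1, p2)[0]
    g1, g2 = str(aln[0]), str(aln[1])
    out1, out2 = [], []
    i = j = 0
    for a, b in zip(g1, g2):
        if a == "-":
            out1.append(GAP_CODON)
        else:
            out1.append(c1[3 * i : 3 * i + 3])
            i += 1
        if b == "-":
            out2.append(GAP_CODON)
        else:
            out2.append(c2[3 * j : 3 * j + 3])
            j += 1
    return CodonPairAlignment(cds1.id, cds2.id, "".join(out1), "".join(out2))


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites: sum over positions of the synonymous
    fraction among single-nucleotide changes, changes to stops excluded."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_TO_AA[alt] == aa
        if valid:
            s += syn / valid
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal mutational pathways that avoid stop codons."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        # every pathway crosses a stop; fall back to counting through them
        for order in itertools.permutations(diffs):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                same = nxt not in STOP_CODONS and cur not in STOP_CODONS and CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt)
                sd += same
                nd += not same
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class KsEstimate:
    """Nei-Gojobori Ks/Ka for one gene pair."""

    pair: tuple[str, str]
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    ps: float
    pn: float
    identity: float
    saturated: bool

    @property
    def omega(self) -> float:
        return self.ka / self.ks if self.ks > 0 else math.nan


def _jc_correct(p: float) -> float:
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def ng86_ks(pair: CodonPairAlignment) -> KsEstimate:
    """Estimate Ks and Ka from a codon pair alignment (NG86 + JC correction).

    ``ps >= 0.75`` (or ``pn``) flags saturation: the JC correction is
    undefined and the corresponding rate is reported as ``inf``.
    """
    s_total = n_total = sd = nd = 0.0
    n_codons = 0
    for c1, c2 in pair.codon_pairs():
        if c1 == GAP_CODON or c2 == GAP_CODON:
            continue
        n_codons += 1
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        s_total += (s1 + s2) / 2.0
        n_total += 3.0 - (s1 + s2) / 2.0
        d_s, d_n = _pair_differences(c1, c2)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no ungapped codons in pair")
    if s_total <= 0:
        raise ValueError("zero synonymous sites")
    ps = sd / s_total
    pn = nd / n_total if n_total > 0 else 0.0
    sat_s, sat_n = ps >= 0.75, pn >= 0.75
    ks = math.inf if sat_s else _jc_correct(ps)
    ka = math.inf if sat_n else _jc_correct(pn)
    return KsEstimate(
        pair=(pair.id1, pair.id2),
        ks=ks,
        ka=ka,
        s_sites=s_total,
        n_sites=n_total,
        ps=ps,
        pn=pn,
        identity=pair.identity,
        saturated=sat_s or sat_n,
    )


def identity_cutoff_filter(
    estimates: TSequence[KsEstimate], identity_threshold: float = 0.90
) -> tuple[list[KsEstimate], int]:
    """Drop pairs with nucleotide identity above the threshold.

    Redundant transcripts (splice variants, false paralogs from assembly)
    masquerade as very recent duplicates; removing identity > threshold
    pairs cleans the low-Ks region without touching surviving estimates.
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity threshold must be in (0, 1)")
    kept = [e for e in estimates if e.identity <= identity_threshold]
    return kept, len(estimates) - len(kept)


# ---------------------------------------------------------------------------
# Peak fitting and calibration


@dataclass
class KsPeakResult:
    """Fitted Gaussian mixture over a Ks window.

    Components are (mean, sd, weight) sorted by descending mean; the two
    focal peaks are labelled Ks1 (older) and Ks2 (younger).
    """

    components: list[tuple[float, float, float]]
    bic: float
    n_values: int
    window: tuple[float, float]
    bic_by_k: dict
    responsibilities: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def ks1(self) -> float:
        return self.components[0][0]

    @property
    def ks2(self) -> float | None:
        return self.components[1][0] if self.k > 1 else None

    def summary(self) -> str:
        lines = [
            f"Ks mixture fit: k={self.k} (BIC {self.bic:.1f}), "
            f"n={self.n_values} in window [{self.window[0]}, {self.window[1]}]"
        ]
        for i, (m, s, w) in enumerate(self.components):
            label = {0: " (Ks1)", 1: " (Ks2)"}.get(i, "")
            lines.append(f"  peak {i + 1}{label}: mean {m:.3f}, sd {s:.3f}, weight {w:.3f}")
        return "\n".join(lines)


class KsMixtureModel:
    """Gaussian-mixture model of a Ks distribution, selected by BIC."""

    def __init__(
        self,
        values,
        k_range=(1, 2, 3),
        window: tuple[float, float] = (0.05, 5.0),
        n_restarts: int = 50,
        min_sd: float = 0.03,
    ):
        values = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
        self.window = tuple(window)
        self.values = values[(values >= window[0]) & (values <= window[1])]
        self.k_range = tuple(k_range)
        self.n_restarts = n_restarts
        # variance floor: keeps EM from collapsing a component onto repeated
        # identical estimates (Ks values are effectively gridded at 1/L)
        self.min_sd = min_sd
        if len(self.values) < 50:
            raise ValueError(
                f"only {len(self.values)} Ks values inside {self.window}; need >= 50"
            )
        if np.std(self.values) == 0:
            raise ValueError("degenerate (constant) Ks values; cannot fit a mixture")

    def fit(self, seed: int | None = None) -> KsPeakResult:
        x = self.values[:, None]
        best = None
        bic_by_k = {}
        for k in self.k_range:
            gm = GaussianMixture(
                n_components=k,
                n_init=self.n_restarts,
                init_params="k-means++",
                random_state=seed,
                reg_covar=self.min_sd**2,
            ).fit(x)
            bic = gm.bic(x)
            bic_by_k[k] = float(bic)
            if best is None or bic < best[0]:
                best = (bic, gm)
        bic, gm = best
        order = np.argsort(gm.means_.ravel())[::-1]
        comps = [
            (
                float(gm.means_.ravel()[i]),
                float(np.sqrt(gm.covariances_.ravel()[i])),
                float(gm.weights_[i]),
            )
            for i in order
        ]
        return KsPeakResult(
            components=comps,
            bic=float(bic),
            n_values=len(self.values),
            window=self.window,
            bic_by_k=bic_by_k,
            responsibilities=gm.predict_proba(x)[:, order],
        )


def fit_ks_peaks(
    ks_values,
    k_range=(1, 2, 3),
    ks_window: tuple[float, float] = (0.05, 5.0),
    seed: int | None = None,
) -> KsPeakResult:
    """Fit Gaussian-mixture peaks to Ks values inside a window (BIC-selected)."""
    return KsMixtureModel(ks_values, k_range=k_range, window=ks_window).fit(seed=seed)


def _kde_mode(values: np.ndarray, grid_points: int = 512) -> float:
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def calibrate_ks(
    distributions: dict,
    reference_pair: str,
    reference_value: float,
) -> tuple[dict, float]:
    """Rescale Ks distributions so the reference pair's mode hits a known value.

    Rate variation across lineages shifts whole Ks distributions; anchoring
    the mode of a reference species pair to its known divergence rescales
    every distribution by the same factor.  Modes are kernel-density argmax
    (Silverman bandwidth, 512-point grid).
    """
    if reference_pair not in distributions:
        raise KeyError(f"reference pair {reference_pair!r} not among distributions")
    ref = np.asarray(distributions[reference_pair], dtype=float)
    ref = ref[np.isfinite(ref)]
    mode = _kde_mode(ref)
    if mode <= 0:
        raise ValueError("reference distribution mode is not positive")
    factor = reference_value / mode
    scaled = {
        name: np.asarray(vals, dtype=float) * factor for name, vals in distributions.items()
    }
    return scaled, factor
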