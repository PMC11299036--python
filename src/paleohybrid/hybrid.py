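"""Gene-flow detection and inheritance-probability (γ) estimation.

Two estimators of the same quantity, from different data summaries:

* a site-pattern invariant test in the style of HyDe (Blischak et al.):
  given quartet roles (outgroup, P1, hybrid, P2), the frequencies of the
  three biallelic bipartition classes determine γ, the fraction of the
  hybrid's genome inherited from the P1 side, with a Z-score against the
  tree null (γ = 0, hybrid sister to P2);
* a triplet pseudo-likelihood fit on a fixed one-reticulation network:
  the rooted-triplet topology counts over loci are multinomial with
  closed-form MSC probabilities in (γ, t_A, t_C).

The classic ABBA-BABA D-statistic with a block jackknife is included as a
companion diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence as TSequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .formats import Alignment

__all__ = [
    "SitePatternCounts",
    "HybridTestResult",
    "BootstrapResult",
    "DStatResult",
    "NetworkFit",
    "TripletNetworkModel",
    "count_site_patterns",
    "d_statistic",
    "hyde_gamma_test",
    "bootstrap_hybrid_test",
    "fit_triplet_network",
]

ROLES = ("outgroup", "p1", "hybrid", "p2")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SitePatternCounts:
    """Quartet site-pattern tallies for roles (outgroup, P1, hybrid, P2).

    Pattern classes are named by which pair shares a state against the other
    pair: ``hp2`` (hybrid with P2; AABB in outgroup-first notation), ``p1h``
    (P1 with hybrid; ABBA) and ``p1p2`` (P1 with P2; ABAB), plus
    ``monomorphic`` and ``other``.  With several individuals per role the
    tallies are averaged over all role-respecting quartets, so counts sum to
    ``n_sites_used``.  Per-column weights are retained for block jackknives.
    """

    roles: dict
    n_sites_used: int
    n_sites_skipped: int
    counts: dict
    w_hp2: np.ndarray
    w_p1h: np.ndarray
    w_p1p2: np.ndarray
    n_quartets: int

    def __post_init__(self):
        total = sum(self.counts.values())
        if self.n_sites_used and not math.isclose(total, self.n_sites_used, rel_tol=1e-9):
            raise ValueError("pattern counts do not sum to the number of used sites")


def count_site_patterns(
    alignment: Alignment,
    role_map: Mapping[str, TSequence[str]],
    multi_individual_policy: str = "all_quartets",
) -> SitePatternCounts:
    """Tally quartet site patterns from an alignment.

    ``role_map`` maps each of ``outgroup``, ``p1``, ``hybrid``, ``p2`` to one
    or more sequence ids.  Columns with a gap or ambiguity in any involved
    sequence, or with a polymorphic outgroup, are skipped.  Policy
    ``all_quartets`` averages tallies over every role-respecting quartet of
    individuals; ``representative`` uses the first id of each role.
    """
    if multi_individual_policy not in ("all_quartets", "representative"):
        raise ValueError(f"unknown policy {multi_individual_policy!r}")
    ids_by_role = {}
    for role in ROLES:
        ids = list(role_map.get(role, ()))
        if not ids:
            raise ValueError(f"role {role!r} has no sequence")
        if multi_individual_policy == "representative":
            ids = ids[:1]
        ids_by_role[role] = ids

    arr = alignment.to_array()
    index = {s.id: k for k, s in enumerate(alignment.sequences)}
    for role, ids in ids_by_role.items():
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"sequences {missing} (role {role!r}) absent from alignment")

    involved = [index[i] for ids in ids_by_role.values() for i in ids]
    coded = np.full(arr.shape, -1, dtype=np.int8)
    for b, code in _BASE_CODE.items():
        coded[arr == b] = code
    usable = np.all(coded[involved] >= 0, axis=0)
    og_rows = [index[i] for i in ids_by_role["outgroup"]]
    og_mono = np.all(coded[og_rows] == coded[og_rows[0]], axis=0)
    usable &= og_mono

    n_cols = arr.shape[1]
    w_hp2 = np.zeros(n_cols)
    w_p1h = np.zeros(n_cols)
    w_p1p2 = np.zeros(n_cols)
    w_mono = np.zeros(n_cols)
    o = coded[og_rows[0]]
    n_quartets = 0
    for i1 in ids_by_role["p1"]:
        for ih in ids_by_role["hybrid"]:
            for i2 in ids_by_role["p2"]:
                n_quartets += 1
                x1, xh, x2 = coded[index[i1]], coded[index[ih]], coded[index[i2]]
                mono = (o == x1) & (o == xh) & (o == x2)
                hp2 = (o == x1) & (xh == x2) & (o != xh)
                p1h = (o == x2) & (x1 == xh) & (o != x1)
                p1p2 = (o == xh) & (x1 == x2) & (o != x1)
                w_mono += mono & usable
                w_hp2 += hp2 & usable
                w_p1h += p1h & usable
                w_p1p2 += p1p2 & usable
    n_used = int(usable.sum())
    counts = {
        "monomorphic": float(w_mono.sum()) / n_quartets,
        "hp2": float(w_hp2.sum()) / n_quartets,
        "p1h": float(w_p1h.sum()) / n_quartets,
        "p1p2": float(w_p1p2.sum()) / n_quartets,
    }
    counts["other"] = n_used - sum(counts.values())
    return SitePatternCounts(
        roles={r: list(i) for r, i in ids_by_role.items()},
        n_sites_used=n_used,
        n_sites_skipped=n_cols - n_used,
        counts=counts,
        w_hp2=w_hp2 / n_quartets,
        w_p1h=w_p1h / n_quartets,
        w_p1p2=w_p1p2 / n_quartets,
        n_quartets=n_quartets,
    )


# ---------------------------------------------------------------------------
# D-statistic


@dataclass
class DStatResult:
    d: float
    z: float
    p_value: float
    n_abba: float
    n_baba: float
    n_blocks: int

    def summary(self) -> str:
        return (
            f"D = {self.d:.4f} (ABBA {self.n_abba:.1f}, BABA {self.n_baba:.1f}), "
            f"Z = {self.z:.2f}, p = {self.p_value:.3g} "
            f"[{self.n_blocks}-block jackknife]"
        )


def d_statistic(counts: SitePatternCounts, block_size: int = 500) -> DStatResult:
    """ABBA-BABA test on quartet ((P1, H), P2, outgroup).

    ABBA sites share the derived allele between the hybrid and P2, BABA
    between P1 and P2; D = (ABBA - BABA) / (ABBA + BABA), with the Z-score
    from a block jackknife over contiguous site blocks.
    """
    abba, baba = counts.w_hp2, counts.w_p1p2
    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    if tot_a + tot_b <= 0:
        raise ValueError("no informative (ABBA/BABA) sites")
    d = (tot_a - tot_b) / (tot_a + tot_b)
    n_cols = len(abba)
    n_blocks = max(1, math.ceil(n_cols / block_size))
    if n_blocks < 2:
        return DStatResult(d, math.nan, math.nan, tot_a, tot_b, n_blocks)
    pseudo = []
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        a_out = tot_a - abba[sl].sum()
        b_out = tot_b - baba[sl].sum()
        if a_out + b_out > 0:
            pseudo.append((a_out - b_out) / (a_out + b_out))
    pseudo = np.array(pseudo)
    m = len(pseudo)
    jk_var = (m - 1) / m * ((pseudo - pseudo.mean()) ** 2).sum()
    se = math.sqrt(jk_var)
    z = d / se if se > 0 else math.inf * np.sign(d) if d else 0.0
    p = 2 * norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return DStatResult(d, z, p, tot_a, tot_b, m)


# ---------------------------------------------------------------------------
# HyDe-style invariant test


@dataclass
class HybridTestResult:
    """γ estimate with its tree-null Z-score (γ measured from the P1 side)."""

    gamma_hat: float
    z_score: float
    p_value: float
    significant: bool
    alpha: float
    n_sites_used: int
    counts: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"hybridization test: gamma = {self.gamma_hat:.4f} (from P1), "
            f"Z = {self.z_score:.4f}, p = {self.p_value:.3g}, "
            f"{'significant' if self.significant else 'not significant'} "
            f"at alpha = {self.alpha}"
        )


def hyde_gamma_test(counts: SitePatternCounts, alpha: float = 0.05) -> HybridTestResult:
    """Invariant-based hybridization test from quartet site patterns.

    Writing f(AABB), f(ABBA), f(ABAB) for the three bipartition classes on
    (outgroup, P1, H, P2), the hybrid-speciation model gives
    q = (ABBA - ABAB) / (AABB - ABAB) = γ / (1 - γ), hence
    γ̂ = q / (1 + q), clamped to [0, 1].  The Z-score contrasts ABBA with
    ABAB (equal under the γ = 0 tree null, H sister to P2) with a
    multinomial variance; p is one-sided.  Significance additionally
    requires γ̂ strictly inside (0, 1), as a genuine mixture demands.
    """
    n = counts.n_sites_used
    aabb = counts.counts["hp2"]
    abba = counts.counts["p1h"]
    abab = counts.counts["p1p2"]
    if n == 0 or (aabb + abba + abab) == 0:
        raise ValueError("degenerate site patterns: no bipartition-informative sites")
    denom = aabb - abab
    numer = abba - abab
    # gamma = q/(1+q) with q = numer/denom, written in the symmetric form
    # numer/(numer + denom) so a P1/P2 role swap maps gamma -> 1 - gamma
    # exactly, clamping included
    total = numer + denom
    gamma = 0.5 if total == 0 else numer / total
    gamma = min(1.0, max(0.0, gamma))
    pa, pb = abba / n, abab / n
    var = (pa + pb - (pa - pb) ** 2) / n
    z = (pa - pb) / math.sqrt(var) if var > 0 else 0.0
    p = float(norm.sf(z))
    significant = (p < alpha) and (0.0 < gamma < 1.0)
    return HybridTestResult(
        gamma_hat=gamma,
        z_score=z,
        p_value=p,
        significant=significant,
        alpha=alpha,
        n_sites_used=n,
        counts=dict(counts.counts),
    )


@dataclass
class BootstrapResult:
    """γ across individual-resampling bootstrap replicates."""

    gammas: np.ndarray
    fraction_significant: float
    gamma_range: tuple

    def summary(self) -> str:
        lo, hi = self.gamma_range
        return (
            f"bootstrap: {len(self.gammas)} replicates, "
            f"{100 * self.fraction_significant:.1f}% significant, "
            f"gamma in [{lo:.4f}, {hi:.4f}], median {np.median(self.gammas):.4f}"
        )


def bootstrap_hybrid_test(
    alignment: Alignment,
    role_map: Mapping[str, TSequence[str]],
    n_reps: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Resample individuals within each ingroup role and rerun the γ test.

    With a single individual per ingroup role every replicate is identical
    (degenerate but legal).  The outgroup is held fixed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    gammas = np.empty(n_reps)
    signif = np.empty(n_reps, dtype=bool)
    ingroups = ("p1", "hybrid", "p2")
    for r in range(n_reps):
        resampled = {"outgroup": list(role_map["outgroup"])}
        for role in ingroups:
            ids = list(role_map[role])
            take = rng.integers(0, len(ids), size=len(ids))
            resampled[role] = [ids[t] for t in take]
        counts = count_site_patterns(alignment, resampled)
        res = hyde_gamma_test(counts, alpha=alpha)
        gammas[r] = res.gamma_hat
        signif[r] = res.significant
    return BootstrapResult(
        gammas=gammas,
        fraction_significant=float(signif.mean()),
        gamma_range=(float(gammas.min()), float(gammas.max())),
    )


# ---------------------------------------------------------------------------
# Triplet pseudo-likelihood network fit


def _triplet_probs(gamma: float, t_a: float, t_c: float) -> tuple[float, float, float]:
    """MSC probabilities of the three rooted triplets on the one-reticulation
    network: (AB|C, BC|A, AC|B), with γ the hybrid's inheritance from A."""
    ea, ec = math.exp(-t_a), math.exp(-t_c)
    p_ab = gamma * (1.0 - 2.0 / 3.0 * ea) + (1.0 - gamma) * ec / 3.0
    p_bc = (1.0 - gamma) * (1.0 - 2.0 / 3.0 * ec) + gamma * ea / 3.0
    p_ac = gamma * ea / 3.0 + (1.0 - gamma) * ec / 3.0
    return p_ab, p_bc, p_ac


@dataclass
class NetworkFit:
    """Results of the fixed-topology one-reticulation fit."""

    gamma_hat: float
    t_a: float
    t_c: float
    log_pseudolikelihood: float
    identifiable: bool
    n_loci: int
    counts: tuple
    fitted_probs: tuple

    def summary(self) -> str:
        na, nb, nc = self.counts
        pa, pb, pc = self.fitted_probs
        lines = [
            "one-reticulation triplet pseudo-likelihood fit",
            f"  loci (AB|C, BC|A, AC|B): {na}, {nb}, {nc}",
            f"  gamma (from A-side parent): {self.gamma_hat:.4f}",
            f"  internal branches t_A = {self.t_a:.3f}, t_C = {self.t_c:.3f} CU",
            f"  fitted probs: {pa:.4f}, {pb:.4f}, {pc:.4f}",
            f"  log pseudo-likelihood: {self.log_pseudolikelihood:.3f}",
        ]
        if not self.identifiable:
            lines.append("  WARNING: likelihood surface flat in gamma (not identifiable)")
        return "\n".join(lines)


class TripletNetworkModel:
    """Multinomial model of rooted-triplet counts on a fixed network.

    The focal clade B is a hybrid of parents A and C; (n_ab, n_bc, n_ac)
    are the loci whose triplet puts B with A, B with C, and A with C
    (B sister to both).  ``fit`` maximizes the multinomial likelihood over
    γ ∈ [0, 1] and the internal branch lengths (coalescent units).

    Three triplet counts carry two degrees of freedom, so γ together with
    two free branch lengths sits on a likelihood ridge.  By default the two
    internal branches are constrained equal (``equal_branches=True``) —
    they span the same parental-split-to-hybridization interval, so under
    equal ancestral population sizes they are the same quantity — which
    makes the model just-identified.  The unconstrained variant is kept for
    exploration and is flagged non-identifiable.
    """

    _T_MAX = 10.0

    def __init__(self, n_ab: int, n_bc: int, n_ac: int, equal_branches: bool = True):
        if min(n_ab, n_bc, n_ac) < 0:
            raise ValueError("negative triplet counts")
        if n_ab + n_bc + n_ac < 1:
            raise ValueError("at least one resolved triplet is required")
        self.counts = (int(n_ab), int(n_bc), int(n_ac))
        self.equal_branches = equal_branches

    def _nll(self, params, counts):
        if self.equal_branches:
            gamma, t = params
            ta = tc = t
        else:
            gamma, ta, tc = params
        probs = _triplet_probs(gamma, ta, tc)
        out = 0.0
        for n, p in zip(counts, probs):
            if n:
                out -= n * math.log(max(p, 1e-300))
        return out

    def _optimize(self, counts):
        best = None
        t_bounds = (1e-8, self._T_MAX)
        if self.equal_branches:
            starts = [(g, t) for g in (0.1, 0.3, 0.5, 0.7, 0.9) for t in (0.3, 1.0, 3.0)]
            bounds = [(0.0, 1.0), t_bounds]
        else:
            starts = [
                (g, t, t) for g in (0.1, 0.3, 0.5, 0.7, 0.9) for t in (0.3, 1.0, 3.0)
            ]
            bounds = [(0.0, 1.0), t_bounds, t_bounds]
        for x0 in starts:
            res = minimize(
                self._nll, x0, args=(counts,), method="L-BFGS-B", bounds=bounds
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    def fit(self) -> NetworkFit:
        counts = self.counts
        # canonical orientation: keep the more common parent-side first so a
        # role swap maps gamma -> 1 - gamma exactly
        swapped = counts[1] > counts[0]
        work = (counts[1], counts[0], counts[2]) if swapped else counts
        res = self._optimize(work)
        if self.equal_branches:
            gamma, ta = res.x
            tc = ta
        else:
            gamma, ta, tc = res.x
        if swapped:
            gamma, ta, tc = 1.0 - gamma, tc, ta
        # identifiability: profile the likelihood over gamma
        spread = self._gamma_profile_spread(counts)
        n = sum(counts)
        return NetworkFit(
            gamma_hat=float(gamma),
            t_a=float(ta),
            t_c=float(tc),
            log_pseudolikelihood=float(-res.fun),
            identifiable=spread > 1e-6 * max(1, n),
            n_loci=n,
            counts=counts,
            fitted_probs=_triplet_probs(float(gamma), float(ta), float(tc)),
        )

    def _gamma_profile_spread(self, counts) -> float:
        """Range of the profile (over branch lengths) negative log-likelihood
        across a γ grid; a flat profile means γ is not identifiable."""
        n_t = 1 if self.equal_branches else 2
        vals = []
        for g in np.linspace(0.0, 1.0, 11):
            best = None
            for t in (0.1, 0.5, 1.0, 2.0, 5.0):
                res = minimize(
                    lambda x, g=g: self._nll((g, *x), counts),
                    (t,) * n_t,
                    method="L-BFGS-B",
                    bounds=[(1e-8, self._T_MAX)] * n_t,
                )
                if best is None or res.fun < best:
                    best = res.fun
            vals.append(best)
        return float(max(vals) - min(vals))


def fit_triplet_network(triplet_counts, roles=("A", "B", "C")) -> NetworkFit:
    """Fit γ and internal branch lengths from rooted-triplet counts.

    ``triplet_counts`` may be a :class:`~paleohybrid.genetreesort.TripletCounts`
    (with groups ordered A, B-hybrid, C) or a plain ``(n_ab, n_bc, n_ac)``
    tuple.
    """
    if hasattr(triplet_counts, "n_ab"):
        n_ab, n_bc, n_ac = triplet_counts.n_ab, triplet_counts.n_bc, triplet_counts.n_ac
    else:
        n_ab, n_bc, n_ac = triplet_counts
    return TripletNetworkModel(n_ab, n_bc, n_ac).fit()
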