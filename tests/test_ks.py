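"""Ks pipeline tests, including an independent brute-force NG86 oracle.

The oracle below re-derives synonymous site fractions and pathway-averaged
difference counts directly from the genetic code with its own enumeration
logic; it shares nothing with the implementation but the standard codon
table.
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from paleohybrid.formats import Sequence
from paleohybrid.ks import (
    CodonPairAlignment,
    best_hit_pairs,
    calibrate_ks,
    codon_align_pair,
    fit_ks_peaks,
    identity_cutoff_filter,
    ng86_ks,
)

AA = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


def oracle_ng86(codons1, codons2):
    """Brute-force NG86: exhaustive per-position enumeration, all pathways."""
    s_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for c1, c2 in zip(codons1, codons2):
        if "-" in c1 or "-" in c2:
            continue
        n_codons += 1
        for codon in (c1, c2):
            for pos in range(3):
                changes = []
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if alt in STOPS:
                        continue
                    changes.append(AA[alt] == AA[codon])
                if changes:
                    s_sites += 0.5 * sum(changes) / len(changes)
        diffs = [k for k in range(3) if c1[k] != c2[k]]
        if not diffs:
            continue
        outcomes = []
        for order in itertools.permutations(diffs):
            cur, s_steps, n_steps, blocked = c1, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOPS:
                    blocked = True
                    break
                if AA[cur] == AA[nxt]:
                    s_steps += 1
                else:
                    n_steps += 1
                cur = nxt
            if not blocked:
                outcomes.append((s_steps, n_steps))
        assert outcomes, "oracle fixture should not need stop-crossing pathways"
        sd += sum(o[0] for o in outcomes) / len(outcomes)
        nd += sum(o[1] for o in outcomes) / len(outcomes)
    n_sites = 3.0 * n_codons - s_sites
    ps, pn = sd / s_sites, nd / n_sites
    corr = lambda p: math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return corr(ps), corr(pn)


def random_codon_pair(rng, n_codons=30, max_ks=1.2):
    """A random stop-free codon pair with moderate divergence."""
    safe = [c for c, a in AA.items() if all(
        (c[:p] + b + c[p + 1:]) not in STOPS for p in range(3) for b in BASES
    )]
    c1 = [safe[i] for i in rng.integers(0, len(safe), n_codons)]
    c2 = []
    for codon in c1:
        out = codon
        for pos in range(3):
            if rng.random() < 0.25:
                b = BASES[rng.integers(0, 4)]
                cand = out[:pos] + b + out[pos + 1 :]
                if cand not in STOPS:
                    out = cand
        c2.append(out)
    return "".join(c1), "".join(c2)


class TestNg86:
    def test_identical_sequences(self):
        est = ng86_ks(CodonPairAlignment("a", "b", "ATGGCT", "ATGGCT"))
        assert est.ks == 0.0 and est.ka == 0.0

    def test_synonymous_worked_example(self):
        # AAA x4 + AAG vs AAA x5: S = 5/3, Sd = 1, ps = 0.6
        est = ng86_ks(CodonPairAlignment("a", "b", "AAA" * 4 + "AAG", "AAA" * 5))
        assert est.s_sites == pytest.approx(5 / 3)
        assert est.ps == pytest.approx(0.6)
        assert est.ks == pytest.approx(-0.75 * math.log(0.2), abs=1e-9)
        assert est.ka == 0.0

    def test_nonsynonymous_worked_example(self):
        # AAA x4 + AAC vs AAA x5: N = 40/3, pn = 0.075
        est = ng86_ks(CodonPairAlignment("a", "b", "AAA" * 4 + "AAC", "AAA" * 5))
        assert est.n_sites == pytest.approx(40 / 3)
        assert est.pn == pytest.approx(0.075)
        assert est.ka == pytest.approx(-0.75 * math.log(0.9), abs=1e-9)
        assert est.ks == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(500):
            c1, c2 = random_codon_pair(rng)
            est = ng86_ks(CodonPairAlignment("x", "y", c1, c2))
            ks_o, ka_o = oracle_ng86(
                [c1[i : i + 3] for i in range(0, len(c1), 3)],
                [c2[i : i + 3] for i in range(0, len(c2), 3)],
            )
            assert est.ks == pytest.approx(ks_o, abs=1e-12)
            assert est.ka == pytest.approx(ka_o, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(50):
            c1, c2 = random_codon_pair(rng)
            a = ng86_ks(CodonPairAlignment("x", "y", c1, c2))
            b = ng86_ks(CodonPairAlignment("y", "x", c2, c1))
            assert a.ks == pytest.approx(b.ks, abs=1e-9)
            assert a.ka == pytest.approx(b.ka, abs=1e-9)

    def test_biopython_cross_check(self, rng):
        """Loose agreement with Bio.codonalign's NG86 (site counting differs
        slightly around stop-adjacent codons)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for _ in range(10):
            c1, c2 = random_codon_pair(rng)
            est = ng86_ks(CodonPairAlignment("x", "y", c1, c2))
            dn, ds = cal_dn_ds(CodonSeq(c1), CodonSeq(c2), method="NG86")
            assert est.ks == pytest.approx(ds, rel=0.05, abs=0.01)
            assert est.ka == pytest.approx(dn, rel=0.05, abs=0.01)

    def test_zero_synonymous_sites_rejected(self):
        # ATG (Met) and TGG (Trp) have no synonymous changes
        with pytest.raises(ValueError, match="synonymous"):
            ng86_ks(CodonPairAlignment("a", "b", "ATGTGG", "ATGTGG"))


class TestCodonAlign:
    def test_identical_cds(self):
        pair = codon_align_pair(Sequence("a", "ATGGCTAAA"), Sequence("b", "ATGGCTAAA"))
        assert pair.identity == 1.0
        assert "-" not in pair.codons1 + pair.codons2

    def test_single_codon_insertion_makes_whole_codon_gap(self):
        pair = codon_align_pair(Sequence("a", "ATGGCTGCTAAA"), Sequence("b", "ATGGCTAAA"))
        assert pair.codons2.count("-") == 3
        assert pair.codons2.index("-") % 3 == 0

    def test_internal_stop_rejected_with_position(self):
        with pytest.raises(ValueError, match="codon 1"):
            codon_align_pair(Sequence("a", "ATGTAAGCT"), Sequence("b", "ATGGCTAAA"))

    def test_terminal_stop_trimmed(self):
        pair = codon_align_pair(Sequence("a", "ATGGCTTGA"), Sequence("b", "ATGGCT"))
        assert len(pair.codons1) == 6


class TestBestHits:
    def test_identical_target_wins_and_is_reciprocal(self):
        q = [Sequence("q1", "ATGGCTGCTAAACCCGGG")]
        t = [
            Sequence("t1", "ATGGCTGCTAAACCCGGG"),
            Sequence("t2", "TTTTTTTTTTTTTTTTTT"),
        ]
        hits, unpaired = best_hit_pairs(q, t)
        assert hits[0].target == "t1" and hits[0].reciprocal
        assert not unpaired

    def test_tie_broken_lexicographically(self):
        cds = "ATGGCTGCTAAACCCGGGTTTACA"
        q = [Sequence("q1", cds)]
        t = [Sequence("t2", cds), Sequence("t1", cds)]
        hits, _ = best_hit_pairs(q, t)
        assert hits[0].target == "t1"

    def test_no_hit_above_floor_logged_unpaired(self):
        q = [Sequence("q1", "ATGGCT")]
        t = [Sequence("t1", "CCCAAA")]
        hits, unpaired = best_hit_pairs(q, t, min_score=100.0)
        assert not hits and unpaired == ["q1"]

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            best_hit_pairs([Sequence("q", "ATG")], [])


class TestIdentityCutoff:
    def test_threshold_rule(self):
        import dataclasses

        base = ng86_ks(CodonPairAlignment("a", "b", "AAA" * 4 + "AAG", "AAA" * 5))
        ests = [dataclasses.replace(base, identity=i) for i in (0.95, 0.91, 0.85)]
        kept, removed = identity_cutoff_filter(ests, 0.90)
        assert len(kept) == 1 and removed == 2
        assert kept[0].identity == 0.85
        assert kept[0].ks == base.ks  # pure filter: survivors unchanged


class TestPeakFit:
    def test_single_component_recovered(self, rng):
        vals = rng.normal(3.0, 0.3, 5000)
        res = fit_ks_peaks(vals, seed=0)
        assert res.k == 1
        assert res.ks1 == pytest.approx(3.0, abs=0.05)

    def test_two_components_recovered(self, rng):
        vals = np.concatenate([rng.normal(1.5, 0.15, 2500), rng.normal(3.0, 0.3, 2500)])
        res = fit_ks_peaks(vals, seed=0)
        assert res.k == 2
        assert res.ks1 == pytest.approx(3.0, abs=0.1)
        assert res.ks2 == pytest.approx(1.5, abs=0.1)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_ks_peaks([1.0] * 100)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="need >= 50"):
            fit_ks_peaks([1.0, 2.0, 3.0])


class TestCalibration:
    def test_reference_mode_maps_to_reference_value(self, rng):
        ref = rng.normal(2.0, 0.1, 3000)
        other = rng.normal(1.0, 0.1, 3000)
        scaled, factor = calibrate_ks({"ref": ref, "other": other}, "ref", 3.0)
        assert factor == pytest.approx(1.5, abs=0.05)
        assert np.median(scaled["other"]) == pytest.approx(1.5, abs=0.1)

    def test_self_calibration_is_identity(self, rng):
        ref = rng.normal(2.0, 0.1, 3000)
        from paleohybrid.ks import _kde_mode

        mode = _kde_mode(ref)
        scaled, factor = calibrate_ks({"ref": ref}, "ref", mode)
        assert factor == pytest.approx(1.0, abs=1e-9)

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            calibrate_ks({"a": np.ones(10)}, "b", 1.0)
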