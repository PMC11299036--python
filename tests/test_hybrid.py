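import math

import numpy as np
import pytest

from paleohybrid.formats import Alignment, Sequence
from paleohybrid.hybrid import (
    TripletNetworkModel,
    _triplet_probs,
    bootstrap_hybrid_test,
    count_site_patterns,
    d_statistic,
    fit_triplet_network,
    hyde_gamma_test,
)

ROLES1 = {"outgroup": ["O"], "p1": ["P1"], "hybrid": ["H"], "p2": ["P2"]}


def quartet_alignment(o, p1, h, p2):
    return Alignment(
        [Sequence("O", o), Sequence("P1", p1), Sequence("H", h), Sequence("P2", p2)]
    )


class TestSitePatterns:
    def test_monomorphic_only(self):
        counts = count_site_patterns(quartet_alignment("AAAA", "AAAA", "AAAA", "AAAA"), ROLES1)
        assert counts.counts["monomorphic"] == 4
        assert counts.n_sites_used == 4

    def test_hand_tallied_eight_columns(self):
        # col: 1 mono, 2 hp2(AABB), 3 p1h(ABBA), 4 p1p2(ABAB), 5 other
        # (singleton), 6 skipped (N), 7 skipped (gap), 8 other (3 states)
        aln = quartet_alignment(
            o="A A A A A N A A".replace(" ", ""),
            p1="A A G G A A - G".replace(" ", ""),
            h="A G G A A A A C".replace(" ", ""),
            p2="A G A G A A A A".replace(" ", ""),
        )
        counts = count_site_patterns(aln, ROLES1)
        assert counts.n_sites_skipped == 2
        assert counts.counts["monomorphic"] == 2
        assert counts.counts["hp2"] == 1
        assert counts.counts["p1h"] == 1
        assert counts.counts["p1p2"] == 1
        assert counts.counts["other"] == 1

    def test_polymorphic_outgroup_column_skipped(self):
        aln = Alignment(
            [
                Sequence("O1", "AC"),
                Sequence("O2", "AA"),
                Sequence("P1", "AA"),
                Sequence("H", "AA"),
                Sequence("P2", "AA"),
            ]
        )
        roles = {"outgroup": ["O1", "O2"], "p1": ["P1"], "hybrid": ["H"], "p2": ["P2"]}
        counts = count_site_patterns(aln, roles)
        assert counts.n_sites_used == 1 and counts.n_sites_skipped == 1

    def test_missing_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            count_site_patterns(quartet_alignment("A", "A", "A", "A"), {"outgroup": ["O"]})


class TestDStatistic:
    def _counts(self, n_abba, n_baba, n_cols=4000, block=1000):
        w = np.zeros(n_cols)
        hp2 = w.copy()
        p1p2 = w.copy()
        hp2[:n_abba] = 1
        p1p2[n_cols - n_baba :] = 1
        from paleohybrid.hybrid import SitePatternCounts

        return SitePatternCounts(
            roles={}, n_sites_used=n_cols, n_sites_skipped=0,
            counts={"monomorphic": n_cols - n_abba - n_baba, "hp2": float(n_abba),
                    "p1h": 0.0, "p1p2": float(n_baba), "other": 0.0},
            w_hp2=hp2, w_p1h=w, w_p1p2=p1p2, n_quartets=1,
        )

    def test_symmetric_counts_give_zero(self):
        res = d_statistic(self._counts(100, 100))
        assert res.d == 0.0

    def test_arithmetic(self):
        res = d_statistic(self._counts(150, 50))
        assert res.d == pytest.approx(0.5)

    def test_no_informative_sites_rejected(self):
        with pytest.raises(ValueError):
            d_statistic(self._counts(0, 0))


class TestHydeGamma:
    def test_hybrid_identical_to_p1(self):
        rng = np.random.default_rng(0)
        n = 2000
        bases = np.array(list("ACGT"))
        o = bases[rng.integers(0, 4, n)]
        p1 = o.copy()
        flip = rng.random(n) < 0.3
        p1[flip] = bases[(rng.integers(1, 4, flip.sum()) + 0) % 4]
        h = p1.copy()
        p2 = o.copy()
        aln = quartet_alignment("".join(o), "".join(p1), "".join(h), "".join(p2))
        res = hyde_gamma_test(count_site_patterns(aln, ROLES1))
        assert res.gamma_hat >= 0.95

    def test_orientation_symmetry(self):
        rng = np.random.default_rng(1)
        n = 3000
        bases = np.array(list("ACGT"))
        seqs = {k: bases[rng.integers(0, 4, n)] for k in ("O", "P1", "H", "P2")}
        aln = Alignment([Sequence(k, "".join(v)) for k, v in seqs.items()])
        swapped = {"outgroup": ["O"], "p1": ["P2"], "hybrid": ["H"], "p2": ["P1"]}
        g1 = hyde_gamma_test(count_site_patterns(aln, ROLES1)).gamma_hat
        g2 = hyde_gamma_test(count_site_patterns(aln, swapped)).gamma_hat
        assert g1 == pytest.approx(1.0 - g2, abs=1e-9)

    def test_degenerate_counts_rejected(self):
        aln = quartet_alignment("AAAA", "AAAA", "AAAA", "AAAA")
        with pytest.raises(ValueError, match="degenerate"):
            hyde_gamma_test(count_site_patterns(aln, ROLES1))


class TestBootstrap:
    def _aln(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        ids = ["O", "P1a", "P1b", "Ha", "Hb", "P2a", "P2b"]
        return Alignment(
            [Sequence(i, "".join(bases[rng.integers(0, 4, n)])) for i in ids]
        )

    ROLES = {
        "outgroup": ["O"],
        "p1": ["P1a", "P1b"],
        "hybrid": ["Ha", "Hb"],
        "p2": ["P2a", "P2b"],
    }

    def test_fixed_seed_reproducible(self):
        aln = self._aln()
        a = bootstrap_hybrid_test(aln, self.ROLES, n_reps=10, seed=3)
        b = bootstrap_hybrid_test(aln, self.ROLES, n_reps=10, seed=3)
        assert np.array_equal(a.gammas, b.gammas)
        assert a.fraction_significant == b.fraction_significant

    def test_single_individual_roles_are_degenerate(self):
        aln = self._aln()
        roles = {"outgroup": ["O"], "p1": ["P1a"], "hybrid": ["Ha"], "p2": ["P2a"]}
        res = bootstrap_hybrid_test(aln, roles, n_reps=5, seed=1)
        assert len(set(res.gammas.tolist())) == 1
        assert res.fraction_significant in (0.0, 1.0)

    def test_invalid_rep_count(self):
        with pytest.raises(ValueError):
            bootstrap_hybrid_test(self._aln(), self.ROLES, n_reps=0, seed=1)


class TestTripletNetwork:
    def test_probabilities_sum_to_one_on_grid(self):
        for g in np.linspace(0, 1, 6):
            for ta in (0.1, 1.0, 5.0):
                for tc in (0.1, 1.0, 5.0):
                    assert sum(_triplet_probs(g, ta, tc)) == pytest.approx(1.0, abs=1e-12)

    def test_parameter_recovery(self, rng):
        n = rng.multinomial(10_000, _triplet_probs(0.4, 1.0, 1.0))
        fit = fit_triplet_network(tuple(n))
        assert fit.gamma_hat == pytest.approx(0.4, abs=0.03)

    def test_recovery_across_gamma_range(self, rng):
        errs = []
        for _ in range(20):
            g = rng.uniform(0.1, 0.9)
            n = rng.multinomial(5000, _triplet_probs(g, 1.0, 1.0))
            errs.append(abs(fit_triplet_network(tuple(n)).gamma_hat - g))
        assert np.median(errs) <= 0.03

    def test_all_ab_hits_boundary(self):
        assert fit_triplet_network((100, 0, 0)).gamma_hat == pytest.approx(1.0)

    def test_symmetric_counts_not_identifiable(self):
        assert not fit_triplet_network((100, 100, 100)).identifiable

    def test_orientation_symmetry_exact(self):
        a = fit_triplet_network((321, 510, 70))
        b = fit_triplet_network((510, 321, 70))
        assert a.gamma_hat == pytest.approx(1.0 - b.gamma_hat, abs=1e-9)
        assert a.t_a == pytest.approx(b.t_c, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TripletNetworkModel(-1, 2, 3)
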