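"""Strand unification, phasing score, PHAS scanning, registers, TAS counts."""

import math

import numpy as np
import pytest

import srnafrac as sf
from srnafrac.phasing import PhasingParams, TasLocus
from srnafrac.records import AlignmentRecord
from srnafrac.simulate import simulate_tas_reads, _collapse


def brute_force_window(unified: dict[int, int], anchor: int, params: PhasingParams):
    """Independent oracle: explicit loop over every position of the window."""
    P = U = n = 0
    for k in range(params.window_cycles):
        base = anchor + k * params.cycle
        hit = unified.get(base, 0)
        P += hit
        if hit > 0:
            n += 1
        for off in range(1, params.cycle):
            U += unified.get(base + off, 0)
    if n <= 3:
        return P, U, n, None
    return P, U, n, (n - 2) * math.log(1 + 10 * P / (1 + U))


class TestUnifyStrands:
    def test_plus_read_contributes_its_five_prime(self):
        u = sf.unify_strands([AlignmentRecord("c", 100, 21, "+", copies=3)])
        assert u == {100: 3}

    def test_duplex_partner_collapses_to_same_position(self):
        # plus 21-mer at 100 spans [100,121); its 2-nt-3'-overhang partner
        # spans [98,119) on the minus strand (5' end 118)
        plus = AlignmentRecord("c", 100, 21, "+")
        minus = AlignmentRecord("c", 98, 21, "-")
        u = sf.unify_strands([plus, minus])
        assert u == {100: 2}

    def test_non_cycle_lengths_excluded_by_default(self):
        u = sf.unify_strands([AlignmentRecord("c", 100, 24, "+")])
        assert u == {}
        u2 = sf.unify_strands([AlignmentRecord("c", 100, 24, "+")], lengths=(21, 24))
        assert u2 == {100: 1}

    def test_empty_input(self):
        assert sf.unify_strands([]) == {}


class TestPhasingScore:
    def test_direct_formula_evaluation(self):
        # 8 occupied phase positions holding 50 reads total, 4 out of phase
        params = PhasingParams()
        unified = {}
        for k in range(8):
            unified[1000 + 21 * k] = 7 if k else 1  # 7*7+1 = 50
        unified[1000 + 5] = 4
        w = sf.phasing_score(unified, 1000, params)
        assert (w.P, w.U, w.n) == (50, 4, 8)
        assert w.score == pytest.approx(6 * math.log(101), abs=1e-12)

    def test_undefined_when_n_at_most_3(self):
        unified = {1000: 100, 1021: 100, 1042: 100}
        assert sf.phasing_score(unified, 1000).score is None

    def test_out_of_phase_reads_only(self):
        unified = {1003: 50, 1010: 20}
        w = sf.phasing_score(unified, 1000)
        assert w.n == 0 and w.P == 0 and w.score is None

    def test_alternative_parse_available(self):
        params = PhasingParams(alt_parse=True)
        unified = {1000 + 21 * k: 5 for k in range(10)}
        w = sf.phasing_score(unified, 1000, params)
        assert w.score == pytest.approx(8 * math.log(501))

    def test_monotonic_in_P_and_U(self):
        base = {1000 + 21 * k: 5 for k in range(5)}
        s0 = sf.phasing_score(base, 1000).score
        more_p = dict(base)
        more_p[1000] += 10
        assert sf.phasing_score(more_p, 1000).score >= s0
        more_u = dict(base)
        more_u[1001] = 10
        assert sf.phasing_score(more_u, 1000).score <= s0


class TestScanPhasing:
    def test_matches_brute_force_on_random_windows(self, rng):
        params = PhasingParams()
        for _ in range(200):
            n_reads = int(rng.integers(1, 60))
            positions = rng.integers(0, 400, n_reads)
            reads = [AlignmentRecord("c", int(p), 21, "+", copies=int(rng.integers(1, 4))) for p in positions]
            scan = sf.scan_phasing(reads, ("c", 0, 400), params)
            unified = sf.unify_strands(reads, params)
            anchor = int(rng.integers(0, 400 - params.window_span + 1))
            row = scan[scan.anchor == anchor].iloc[0]
            P, U, n, score = brute_force_window(unified, anchor, params)
            assert (row.P, row.U, row.n) == (P, U, n)
            if score is None:
                assert np.isnan(row.score)
            else:
                assert row.score == pytest.approx(score, abs=1e-9)

    def test_translation_equivariance(self, rng):
        params = PhasingParams()
        positions = rng.integers(0, 300, 40)
        reads = [AlignmentRecord("c", int(p) + 1000, 21, "+") for p in positions]
        shift = 137
        shifted = [AlignmentRecord("c", r.start + shift, 21, "+") for r in reads]
        s1 = sf.scan_phasing(reads, ("c", 1000, 1400), params)
        s2 = sf.scan_phasing(shifted, ("c", 1000 + shift, 1400 + shift), params)
        assert np.array_equal(s1["P"], s2["P"])
        assert np.array_equal(s1["U"], s2["U"])
        assert np.allclose(s1["score"], s2["score"], equal_nan=True)

    def test_region_too_short_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            scan = sf.scan_phasing([], ("c", 0, 100))
        assert scan.empty

    def test_zero_reads_gives_no_calls(self):
        scan = sf.scan_phasing([], ("c", 0, 400))
        assert not scan["called"].any()
        assert scan["score"].isna().all()

    def test_phased_locus_peak_near_cleavage_site(self, rng):
        from srnafrac.simulate import TasTruth

        t = TasTruth("TASx", "c", "+", 1000, 1600, 1150, 0.8, 10, 1.0)
        reads = _collapse(simulate_tas_reads(t, 3000, rng))
        scan = sf.scan_phasing(reads, ("c", t.start, t.end))
        best = scan.loc[scan["score"].idxmax()]
        assert abs(best.anchor - t.cleavage_site) <= 21
        # calls are confined to anchors whose downstream window reaches the
        # phased run (cleavage site .. cleavage + cycles*21)
        called = scan[scan["called"]]
        span = PhasingParams().window_span
        assert (called["anchor"] >= t.cleavage_site - span).all()
        assert (called["anchor"] <= t.cleavage_site + t.cycles * 21).all()


class TestRegisterDistribution:
    def _locus(self):
        return TasLocus("TAS1", "c", 1000, 1600, "+", 1150)

    def test_all_reads_on_cleavage_register(self):
        reads = [AlignmentRecord("c", 1150 + 21 * k, 21, "+", copies=2) for k in range(5)]
        reg = sf.register_distribution(reads, self._locus())
        assert reg.fractions[0] == pytest.approx(1.0)
        assert reg.in_register and not reg.low_confidence

    def test_uniform_reads_flagged_low_confidence(self, rng):
        starts = rng.integers(1000, 1579, 600)
        reads = [AlignmentRecord("c", int(s), 21, "+") for s in starts]
        reg = sf.register_distribution(reads, self._locus())
        assert reg.low_confidence

    def test_minus_strand_locus_register_direction(self):
        locus = TasLocus("TASm", "c", 1000, 1600, "-", 1400)
        # phasing proceeds toward lower coordinates on a minus-strand locus
        reads = [AlignmentRecord("c", 1400 - 21 * k, 21, "+") for k in range(1, 4)]
        reg = sf.register_distribution(reads, locus)
        assert reg.prominent_register == 0

    def test_zero_reads_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            sf.register_distribution([], self._locus())

    def test_truth_register_recovered(self, rng):
        locus = self._locus()
        hits = 0
        for _ in range(50):
            reads = []
            for _ in range(300):
                if rng.random() < 0.9:
                    k = int(rng.integers(0, 10))
                    reads.append(AlignmentRecord("c", 1150 + 21 * k, 21, "+"))
                else:
                    reads.append(AlignmentRecord("c", int(rng.integers(1000, 1579)), 21, "+"))
            reg = sf.register_distribution(reads, locus)
            hits += reg.prominent_register == 0
        assert hits >= 48


class TestQuantifyTas:
    def _loci(self):
        return [TasLocus("TAS1", "c", 1000, 1600, "+", 1150)]

    def test_contained_reads_counted_per_size_class(self):
        reads = [
            AlignmentRecord("c", 1100, 21, "+", copies=3),
            AlignmentRecord("c", 1200, 24, "-", copies=2),
        ]
        q = sf.quantify_tas(reads, self._loci()).set_index("size_class")["raw"]
        assert q[21] == 3 and q[24] == 2

    def test_straddling_read_excluded(self):
        q = sf.quantify_tas([AlignmentRecord("c", 990, 21, "+")], self._loci())
        assert q["raw"].sum() == 0

    def test_overlapping_loci_counted_toward_each_with_warning(self):
        loci = self._loci() + [TasLocus("TAS2", "c", 1100, 1700, "+", 1200)]
        with pytest.warns(UserWarning, match="overlap"):
            q = sf.quantify_tas([AlignmentRecord("c", 1200, 21, "+")], loci)
        by_locus = q.groupby("locus_id")["raw"].sum()
        assert by_locus["TAS1"] == 1 and by_locus["TAS2"] == 1
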