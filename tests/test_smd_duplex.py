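"""Duplex thermodynamics, SINE scanning/parsing, and the log-normal ΔG null."""

import numpy as np
import pytest
from scipy import stats

from lncnet import smd_duplex as smd
from lncnet.seqs import random_seq, revcomp
from lncnet.synthetic_data import load_sine_consensi
from lncnet.types import RepeatHit


class TestEnergyModel:
    def test_perfect_complement_equals_hand_summed_stacks(self):
        """ΔG of an exact antiparallel complement is the initiation term plus
        the chain of nearest-neighbor stack energies from the parameter
        table, summed by hand."""
        P = smd.default_params()
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            a = random_seq(rng, n)
            b = revcomp(a)
            res = smd.duplex_energy(a, b, P)
            ca = smd._encode(a)
            cb = smd._encode(b)[::-1]  # cb[i] pairs ca[i]
            pids = [smd._PAIR_ID[ca[i], cb[i]] for i in range(n)]
            hand = P.initiation + sum(
                P.stacks[pids[i], pids[i + 1]] for i in range(n - 1)
            )
            assert res is not None
            assert res.delta_g == pytest.approx(hand, abs=1e-9)
            assert res.a_interval == (0, n) and res.b_interval == (0, n)

    def test_hybridization_is_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = random_seq(rng, int(rng.integers(15, 60)))
            b = random_seq(rng, int(rng.integers(15, 60)))
            ra = smd.duplex_energy(a, b)
            rb = smd.duplex_energy(b, a)
            if ra is None:
                assert rb is None
            else:
                assert ra.delta_g == pytest.approx(rb.delta_g, abs=1e-9)

    def test_extending_a_complement_strictly_stabilises(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 20)
        ext = random_seq(rng, 5)
        short = smd.duplex_energy(a, revcomp(a)).delta_g
        long_ = smd.duplex_energy(a + ext, revcomp(a + ext)).delta_g
        assert long_ < short

    def test_no_complementarity_reports_no_duplex(self):
        assert smd.duplex_energy("A" * 20, "A" * 20) is None

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            smd.duplex_energy("ACGT", "ACGT")

    def test_stack_table_is_strand_symmetric(self):
        """Reading any stack from the opposite strand gives the same energy."""
        P = smd.default_params()
        for q in range(6):
            for p in range(6):
                x1, y1 = smd._PAIRS[q]
                x2, y2 = smd._PAIRS[p]
                q2 = smd._PAIR_ID[y2, x2]
                p2 = smd._PAIR_ID[y1, x1]
                assert P.stacks[q, p] == pytest.approx(P.stacks[q2, p2])


class TestRepeatMaskerIO:
    OUT = """   SW  perc perc perc  query      position in query           matching  repeat        position in  repeat
score  div. del. ins.  sequence    begin     end    (left)    repeat    class/family    begin  end (left)   ID

  225  10.0  2.1  0.0  TCONS00001      101      250  (50)  +  B1  SINE/Alu  1  150  (0)  1
  180   8.2  0.0  1.1  MRNA00007        11       90  (10)  C  L1  LINE/L1   1   80  (0)  2
"""

    def test_fixture_parses_families_and_coordinates(self, tmp_path):
        from lncnet.io.rmout import read_rmout

        p = tmp_path / "r.out"
        p.write_text(self.OUT)
        hits = read_rmout(p)
        assert len(hits) == 2
        assert hits[0].family == "B1/Alu" and hits[0].host_id == "TCONS00001"
        # 1-based inclusive 101..250 -> 0-based half-open [100, 250), length 150
        assert (hits[0].start, hits[0].end) == (100, 250)
        assert hits[0].end - hits[0].start == 150
        assert hits[1].family == "other" and hits[1].strand == "-"

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text("225 10.0 2.1\n")
        from lncnet.io.rmout import read_rmout

        with pytest.raises(ValueError, match=":1"):
            read_rmout(p)

    def test_write_read_roundtrip(self, tmp_path):
        from lncnet.io.rmout import read_rmout, write_rmout

        hits = [RepeatHit("T1", "B2", 5, 130, "+", 200.0),
                RepeatHit("U9", "B1/Alu", 0, 88, "-", 150.0)]
        p = tmp_path / "x.out"
        write_rmout(hits, p)
        back = read_rmout(p)
        assert [(h.host_id, h.family, h.start, h.end, h.strand) for h in back] == [
            (h.host_id, h.family, h.start, h.end, h.strand) for h in hits
        ]


class TestSineScanner:
    def test_planted_consensus_recovered_at_coordinates(self):
        rng = np.random.default_rng(3)
        lib = load_sine_consensi()
        cons = lib["B2"]
        host = random_seq(rng, 200) + cons + random_seq(rng, 150)
        hits = smd.scan_sines(host, {"B2": cons}, host_id="h")
        assert len(hits) == 1
        assert hits[0].start == 200 and hits[0].end == 200 + len(cons)
        assert hits[0].strand == "+"

    def test_antisense_copy_found_on_minus_strand(self):
        rng = np.random.default_rng(4)
        lib = load_sine_consensi()
        cons = lib["B4"]
        host = random_seq(rng, 100) + revcomp(cons) + random_seq(rng, 100)
        hits = smd.scan_sines(host, {"B4": cons}, host_id="h")
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_random_hosts_rarely_hit_at_stringent_threshold(self):
        rng = np.random.default_rng(5)
        lib = load_sine_consensi()
        n_hit = 0
        for _ in range(20):
            host = random_seq(rng, 1000)
            n_hit += bool(smd.scan_sines(host, lib, min_score=100))
        assert n_hit <= 1  # >= 95% of random hosts clean

    def test_empty_library_gives_no_hits(self):
        assert smd.scan_sines("ACGT" * 100, {}) == []


class TestLognormalNull:
    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(6)
        dgs = -rng.lognormal(mean=5.0, sigma=0.3, size=10_000)
        null = smd.fit_lognormal_null(dgs)
        assert null.meanlog == pytest.approx(5.0, abs=0.01)
        assert null.sdlog == pytest.approx(0.3, abs=0.01)

    def test_scaling_by_e_shifts_meanlog_by_one(self):
        rng = np.random.default_rng(7)
        dgs = -rng.lognormal(3.0, 0.4, size=500)
        a = smd.fit_lognormal_null(dgs)
        b = smd.fit_lognormal_null(dgs * np.e)
        assert b.meanlog - a.meanlog == pytest.approx(1.0, abs=1e-12)
        assert b.sdlog == pytest.approx(a.sdlog, abs=1e-12)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="identical"):
            smd.fit_lognormal_null([-5.0] * 40)
        with pytest.raises(ValueError, match="negative"):
            smd.fit_lognormal_null([-5.0] * 39 + [1.0])
        with pytest.raises(ValueError, match=">= 30"):
            smd.fit_lognormal_null([-5.0, -6.0])

    def test_pvalue_at_median_and_quantiles(self):
        null = smd.LognormalNull(meanlog=5.0, sdlog=0.3, n=1000, ks_distance=0.01)
        assert smd.duplex_pvalue(-np.exp(5.0), null) == pytest.approx(0.5)
        q95 = -np.exp(5.0 + 1.6448536269514722 * 0.3)
        assert smd.duplex_pvalue(q95, null) == pytest.approx(0.05, abs=1e-6)
        assert smd.duplex_pvalue(-1e9, null) < 1e-10

    def test_held_out_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(8)
        train = -rng.lognormal(5.0, 0.3, size=10_000)
        null = smd.fit_lognormal_null(train)
        held = -rng.lognormal(5.0, 0.3, size=10_000)
        ps = np.array([smd.duplex_pvalue(d, null) for d in held])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestNetwork:
    def _cand(self, lnc, mrna, dg, p):
        from lncnet.types import DuplexCandidate

        c = DuplexCandidate(lnc, (0, 50), mrna, (0, 50), dg, ("B1/Alu", "B1/Alu"))
        c.p_value = p
        return c

    def test_restriction_to_de_genes(self):
        cands = [self._cand("L1", "M1", -90.0, 0.001), self._cand("L2", "M2", -85.0, 0.001)]
        g = smd.build_smd_network(cands, de_ids={"L1", "M1"}, restrict_to_de=True)
        assert set(g.edges) == {("L1", "M1")}
        g2 = smd.build_smd_network(cands, de_ids=set(), restrict_to_de=True)
        assert g2.number_of_edges() == 0

    def test_p_threshold_applied(self):
        cands = [self._cand("L1", "M1", -90.0, 0.06)]
        g = smd.build_smd_network(cands, de_ids={"L1", "M1"}, p_max=0.05)
        assert g.number_of_edges() == 0

    def test_planted_pair_round_trip_through_scanner(self, small_study):
        """The consensus scanner must find the planted SINE copies and the
        duplex engine must pair them at the planted coordinates."""
        lnc_id, mrna_id, fam = small_study.ground_truth.planted_smd_pairs[0]
        lib = load_sine_consensi()
        lnc_seq = small_study.transcript(lnc_id).sequence
        utr_seq = small_study.utr3_seq(mrna_id)
        lnc_hits = smd.scan_sines(lnc_seq, lib, host_id=lnc_id)
        utr_hits = smd.scan_sines(utr_seq, lib, host_id=mrna_id)
        assert any(h.family == fam for h in lnc_hits)
        assert any(h.family == fam and h.strand == "-" for h in utr_hits)
        cands = smd.find_duplex_candidates(
            {lnc_id: lnc_seq}, {mrna_id: utr_seq}, lnc_hits, utr_hits
        )
        best = min(cands, key=lambda c: c.delta_g)
        truth = [s for s in small_study.ground_truth.sine_sites
                 if s["planted_pair"] and s["host"] == lnc_id][0]
        # recovered duplex overlaps the planted lncRNA interval
        a, b = best.lnc_interval
        assert a < truth["end"] and b > truth["start"]
        assert best.delta_g < -100
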