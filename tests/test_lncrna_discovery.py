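"""Discovery cascade: structural filters, novelty selection, coding-potential
scoring and cutoff calibration."""

import numpy as np
import pytest

from lncnet import lncrna_discovery as disc
from lncnet.seqs import random_cds, random_seq
from lncnet.types import TranscriptModel


def _t(tid, exons, detected=10, cc="u", chrom="chr1", strand="+", seq=None):
    return TranscriptModel(
        id=tid, chrom=chrom, strand=strand, exons=exons,
        class_code=cc, detected_in=detected, sequence=seq,
    )


class TestStructuralFilter:
    def test_multiexon_long_halfdetected_retained(self):
        t = _t("a", [(0, 150), (300, 450)], detected=5)  # 2 exons, 300 nt, 5/10
        assert disc.filter_transcripts([t]) == [t]

    def test_single_exon_removed_regardless_of_length(self):
        t = _t("a", [(0, 5000)], detected=10)
        assert disc.filter_transcripts([t]) == []

    def test_short_transcript_removed(self):
        t = _t("a", [(0, 100), (200, 250)], detected=10)  # 150 nt
        assert disc.filter_transcripts([t]) == []

    def test_low_detection_removed_and_order_stable(self):
        keep1 = _t("k1", [(0, 150), (300, 450)], detected=7)
        drop = _t("d", [(0, 150), (300, 450)], detected=4)
        keep2 = _t("k2", [(0, 200), (400, 600)], detected=5)
        assert disc.filter_transcripts([keep1, drop, keep2]) == [keep1, keep2]

    def test_empty_exon_list_is_malformed(self):
        with pytest.raises(ValueError):
            TranscriptModel(id="x", chrom="chr1", strand="+", exons=[])


class TestNoveltySelection:
    def test_class_code_rules(self):
        known = [_t("kn", [(1000, 1200)], cc="=")]
        novel = _t("n", [(0, 300), (400, 600)], cc="u")
        known_code = _t("k", [(0, 300), (400, 600)], cc="=")
        out = disc.select_novel_candidates([novel, known_code], known)
        assert out == [novel]

    def test_unknown_class_code_warns_and_excludes(self):
        known = []
        odd = _t("odd", [(0, 300)], cc="?")
        with pytest.warns(UserWarning):
            assert disc.select_novel_candidates([odd], known) == []

    def test_one_bp_same_strand_overlap_excludes(self):
        known = [_t("kn", [(599, 800)], cc="=")]
        touching = _t("n", [(0, 300), (400, 600)], cc="u")  # overlaps base 599
        adjacent = _t("m", [(0, 300), (400, 599)], cc="u")  # half-open: no overlap
        out = disc.select_novel_candidates([touching, adjacent], known)
        assert out == [adjacent]

    def test_opposite_strand_overlap_allowed_unstranded_not(self):
        known = [_t("kn", [(100, 300)], cc="=", strand="+")]
        anti = _t("a", [(150, 250), (400, 500)], cc="x", strand="-")
        unstranded = _t("u", [(150, 250), (400, 500)], cc="u", strand=".")
        out = disc.select_novel_candidates([anti, unstranded], known)
        assert out == [anti]

    def test_overlap_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        known_ivs = [(int(a), int(a) + int(w)) for a, w in
                     zip(rng.integers(0, 5000, 40), rng.integers(20, 200, 40))]
        known = [_t(f"k{i}", [iv], cc="=") for i, iv in enumerate(known_ivs)]
        for trial in range(50):
            exons = sorted(
                (int(a), int(a) + int(w))
                for a, w in zip(rng.integers(0, 5000, 2), rng.integers(20, 150, 2))
            )
            if exons[0][1] > exons[1][0]:
                continue
            cand = _t(f"c{trial}", exons, cc="u")
            brute = any(
                max(a1, a2) < min(b1, b2)
                for a1, b1 in exons
                for a2, b2 in known_ivs
            )
            got = disc.select_novel_candidates([cand], known) == []
            assert got == brute


class TestCodingFeatures:
    def test_no_atg_means_zero_orf(self):
        seq = "CCCGGGCCCGGG" * 30  # no ATG anywhere
        a, b = disc.longest_orf(seq)
        assert (a, b) == (0, 0)
        table = np.zeros(4096)
        feats = disc.features(seq, table)
        assert feats[0] == 0.0 and feats[1] == 0.0  # log ORF length, coverage

    def test_longest_orf_finds_planted_frame(self):
        rng = np.random.default_rng(1)
        cds = random_cds(rng, 100)  # 300 nt, ATG..stop
        seq = "CCC" + cds + "CCCCC"
        a, b = disc.longest_orf(seq)
        assert seq[a : a + 3] == "ATG" and seq[b - 3 : b] in ("TAA", "TAG", "TGA")
        assert b - a >= 0.9 * len(cds)

    def test_score_deterministic_and_in_unit_interval(self, coding_model):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 600)
        s1 = disc.coding_score(seq, coding_model)
        s2 = disc.coding_score(seq, coding_model)
        assert s1 == s2 and 0.0 <= s1 <= 1.0

    def test_generated_coding_sequence_scores_above_cutoff(self, coding_model):
        rng = np.random.default_rng(3)
        held_out = random_cds(rng, 220)
        assert disc.coding_score(held_out, coding_model) > coding_model.cutoff

    def test_generated_noncoding_scores_below_cutoff(self, coding_model):
        rng = np.random.default_rng(4)
        assert disc.coding_score(random_seq(rng, 700), coding_model) < coding_model.cutoff

    def test_too_many_ambiguous_bases_rejected(self, coding_model):
        with pytest.raises(ValueError):
            disc.features("ATGNNNNNNNNNNNNGGG", coding_model.hexamer_table)


class TestCutoffCalibration:
    def test_perfect_separation_gives_midpoint(self):
        cutoff, sens, spec = disc.youden_cutoff(
            np.full(30, 0.9), np.full(30, 0.1)
        )
        assert cutoff == pytest.approx(0.5)
        assert sens == 1.0 and spec == 1.0

    def test_youden_equals_bruteforce_sweep_on_overlapping_sets(self):
        rng = np.random.default_rng(7)
        cod = rng.beta(5, 2, size=200)
        non = rng.beta(2, 5, size=200)
        cutoff, sens, spec = disc.youden_cutoff(cod, non)
        # oracle: exhaustive sweep over all midpoints, lowest threshold wins ties
        scores = np.unique(np.r_[cod, non])
        mids = (scores[:-1] + scores[1:]) / 2
        js = [(cod >= t).mean() + (non < t).mean() for t in mids]
        best_j = max(js)
        best_t = mids[next(i for i, j in enumerate(js) if j >= best_j - 1e-12)]
        assert cutoff == pytest.approx(best_t)
        assert sens + spec == pytest.approx(best_j)

    def test_swapped_labels_raise(self):
        from lncnet.synthetic_data import generate_training_sequences

        cod, non = generate_training_sequences(2, n_each=30)
        with pytest.raises(ValueError, match="swapped"):
            disc.train_and_calibrate(non, cod)

    def test_small_training_class_rejected(self):
        from lncnet.synthetic_data import generate_training_sequences

        cod, non = generate_training_sequences(2, n_each=30)
        with pytest.raises(ValueError):
            disc.train_and_calibrate(cod[:10], non)


class TestHomologyFilter:
    def _cands(self):
        return [
            _t("a", [(0, 150), (200, 400)], seq="A" * 350),
            _t("b", [(0, 150), (200, 400)], seq="C" * 350),
        ]

    def test_empty_hits_retains_all(self):
        out = disc.apply_homology_filter(self._cands(), {})
        assert [t.id for t in out] == ["a", "b"]
        assert all(t.biotype == "novel_lncRNA" for t in out)

    def test_strong_hit_removes(self):
        out = disc.apply_homology_filter(self._cands(), {"a": 1e-10})
        assert [t.id for t in out] == ["b"]

    def test_weak_hit_above_threshold_retained(self):
        out = disc.apply_homology_filter(self._cands(), {"a": 0.5}, evalue_max=1e-3)
        assert [t.id for t in out] == ["a", "b"]

    def test_unknown_query_warns(self):
        with pytest.warns(UserWarning):
            disc.apply_homology_filter(self._cands(), {"zzz": 1e-10})


class TestPipelineProperties:
    def test_each_stage_returns_subset(self, small_study, coding_model):
        txs = small_study.transcripts
        bona = disc.filter_transcripts(txs)
        cands = disc.select_novel_candidates(bona, small_study.known_annotation)
        novel, _ = disc.discover_lncrnas(txs, small_study.known_annotation, coding_model)
        ids = lambda lst: {t.id for t in lst}
        assert ids(bona) <= ids(txs)
        assert ids(cands) <= ids(bona)
        assert ids(novel) <= ids(cands)

    def test_coding_score_ignores_exon_structure(self, coding_model):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 600)
        one_exon = _t("a", [(0, 600)], seq=seq)
        three_exon = _t("b", [(0, 200), (300, 500), (900, 1100)], seq=seq)
        assert disc.coding_score(one_exon.sequence, coding_model) == disc.coding_score(
            three_exon.sequence, coding_model
        )
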