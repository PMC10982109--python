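"""Seed-and-extend engine: HSP detection, statistics, BLAST-tab interchange."""

import numpy as np
import pytest

from syntelign import (
    AlignParams,
    SeqRecord,
    all_pairs,
    find_hsps_nt,
    find_hsps_tx,
    read_blast_tab,
    validate_input_set,
    write_blast_tab,
)
from syntelign.fixtures import (
    make_orf_sequence,
    make_related_set,
    missense_variant,
    orf_interval,
    random_sequence,
    synonymous_variant,
)
from syntelign.seqio import InputError

from conftest import brute_force_best_diag_score, make_record


class TestNucleotideMode:
    def test_self_alignment_full_length(self, nt_params):
        a = make_record("a", 1000, seed=1)
        b = SeqRecord(id="b", sequence=a.sequence)
        hsps = find_hsps_nt(a, b, nt_params)
        top = hsps[0]
        assert (top.qstart, top.qend, top.sstart, top.send) == (0, 1000, 0, 1000)
        assert top.identity_pct == 100.0
        assert not top.subject_reversed

    def test_reverse_complement_flagged(self, nt_params):
        a = make_record("a", 500, seed=2)
        b = SeqRecord(id="b", sequence=a.reverse_complement())
        top = find_hsps_nt(a, b, nt_params)[0]
        assert top.subject_reversed
        assert top.identity_pct == 100.0
        assert (top.sstart, top.send) == (0, 500)

    def test_scores_match_diagonal_brute_force(self, nt_params):
        """Reported scores equal the per-diagonal ungapped optimum (oracle)."""
        rng = np.random.default_rng(101)
        checked = 0
        for _ in range(10):
            a = SeqRecord(id="a", sequence=random_sequence(250, rng))
            # derived with mutations so real HSPs exist
            arr = list(a.sequence)
            for i in rng.integers(0, 250, size=25):
                arr[i] = "ACGT"[rng.integers(0, 4)]
            b = SeqRecord(id="b", sequence="".join(arr))
            for h in find_hsps_nt(a, b, nt_params):
                subj = b.reverse_complement() if h.subject_reversed else b.sequence
                ss = len(subj) - h.send if h.subject_reversed else h.sstart
                diag = h.qstart - ss
                assert h.raw_score == brute_force_best_diag_score(
                    a.sequence, subj, diag
                )
                checked += 1
        assert checked > 0

    def test_symmetry_under_role_swap(self, nt_params):
        recs, _ = make_related_set(2, 2000, 0.9, seed=5)
        a, b = recs
        fwd = find_hsps_nt(a, b, nt_params)
        rev = [h.swapped() for h in find_hsps_nt(b, a, nt_params)]
        key = lambda h: (h.qstart, h.qend, h.sstart, h.send, h.subject_reversed)
        assert sorted(key(h) for h in fwd) == sorted(key(h) for h in rev)

    def test_strand_involution(self, nt_params):
        """Reverse-complementing the subject flips flags and mirrors coords."""
        recs, _ = make_related_set(2, 2000, 0.85, seed=6)
        a, b = recs
        brc = SeqRecord(id="b", sequence=b.reverse_complement())
        orig = find_hsps_nt(a, b, nt_params)
        flipped = find_hsps_nt(a, brc, nt_params)
        key = lambda h: (h.qstart, h.qend, h.sstart, h.send, h.subject_reversed)
        expect = sorted(
            (h.qstart, h.qend, b.length - h.send, b.length - h.sstart,
             not h.subject_reversed)
            for h in orig
        )
        assert sorted(key(h) for h in flipped) == expect

    def test_evalue_filter_monotone(self, nt_params):
        recs, _ = make_related_set(2, 3000, 0.8, seed=7)
        a, b = recs
        loose = find_hsps_nt(a, b, nt_params)
        strict_params = AlignParams(mode="nucleotide", evalue_max=1e-20)
        strict = find_hsps_nt(a, b, strict_params)
        loose_keys = {(h.qstart, h.qend, h.sstart, h.send) for h in loose}
        strict_keys = {(h.qstart, h.qend, h.sstart, h.send) for h in strict}
        assert strict_keys <= loose_keys

    def test_n_never_seeds_or_matches(self, nt_params):
        a = SeqRecord(id="a", sequence="N" * 400)
        b = SeqRecord(id="b", sequence="N" * 400)
        assert find_hsps_nt(a, b, nt_params) == []

    def test_span_at_least_word_size(self, nt_params):
        recs, _ = make_related_set(2, 2000, 0.75, seed=8)
        for h in find_hsps_nt(recs[0], recs[1], nt_params):
            assert h.qend - h.qstart >= nt_params.word_size
            assert h.send - h.sstart >= nt_params.word_size


class TestTranslatedMode:
    def test_self_orf_full_identity_in_frame(self, tx_params):
        a = make_orf_sequence(100, seed=1)
        b = SeqRecord(id="b", sequence=a.sequence)
        hsps = find_hsps_tx(a, b, tx_params)
        s0, s1 = orf_interval(a)
        top = hsps[0]
        assert top.identity_pct == 100.0
        assert not top.subject_reversed
        # covers the ORF codons (stop codon terminates extension)
        assert top.qstart <= s0 + 3 and top.qend >= s1 - 3

    def test_synonymous_variant_translated_identity_100(self, tx_params, nt_params):
        """Third-position changes: translated identity stays 100%, nt drops."""
        a = make_orf_sequence(120, seed=2)
        b = synonymous_variant(a, seed=3)
        tx_top = find_hsps_tx(a, b, tx_params)[0]
        assert tx_top.identity_pct == 100.0
        nt_hits = find_hsps_nt(a, b, nt_params)
        assert all(h.identity_pct < 100.0 for h in nt_hits
                   if h.qend - h.qstart > 50)

    def test_missense_variant_one_mismatch(self, tx_params):
        a = make_orf_sequence(100, seed=4)
        b = missense_variant(a, seed=5)
        top = find_hsps_tx(a, b, tx_params)[0]
        n_aa = (top.qend - top.qstart) // 3
        mismatches = round(n_aa * (1 - top.identity_pct / 100.0))
        assert mismatches == 1

    def test_orf_vs_reverse_complement(self, tx_params):
        a = make_orf_sequence(100, seed=6)
        b = SeqRecord(id="b", sequence=a.reverse_complement())
        top = find_hsps_tx(a, b, tx_params)[0]
        assert top.subject_reversed
        assert top.identity_pct == 100.0

    def test_short_sequence_frames_skipped(self, tx_params):
        a = SeqRecord(id="a", sequence="ATGAA")
        b = SeqRecord(id="b", sequence="ATGAA")
        assert find_hsps_tx(a, b, tx_params) == []


class TestAllPairs:
    def test_pair_count_includes_self_pairs(self, nt_params):
        recs, _ = make_related_set(3, 1500, 0.9, seed=9)
        hits = all_pairs(validate_input_set(recs), nt_params)
        assert len(hits.pairs) == 6  # 3 self + 3 cross

    def test_identical_pair_full_length_hsp(self, nt_params):
        a = make_record("a", 1200, seed=10)
        b = SeqRecord(id="b", sequence=a.sequence)
        hits = all_pairs(validate_input_set([a, b]), nt_params)
        top = hits.get("a", "b")[0]
        assert (top.qstart, top.qend) == (0, 1200)

    def test_role_swap_accessor(self, nt_params):
        recs, _ = make_related_set(2, 1500, 0.9, seed=11)
        hits = all_pairs(validate_input_set(recs), nt_params)
        ab = hits.get("s1", "s2")
        ba = hits.get("s2", "s1")
        assert [(h.qstart, h.sstart) for h in ba] == [
            (h.sstart, h.qstart) for h in ab
        ]


class TestBlastTab:
    def test_coordinate_conversion_reversed_subject(self, tmp_path, nt_params):
        recs = [make_record("a", 600, seed=1), make_record("b", 1200, seed=2)]
        p = tmp_path / "hits.tsv"
        p.write_text("a\tb\t98.5\t500\t7\t0\t1\t500\t1000\t501\t1e-50\t900\n")
        hits = read_blast_tab(p, recs, nt_params)
        h = hits.get("a", "b")[0]
        assert (h.qstart, h.qend, h.sstart, h.send) == (0, 500, 500, 1000)
        assert h.subject_reversed
        assert h.identity_pct == 98.5
        assert h.bit_score == 900.0

    def test_rows_above_evalue_threshold_dropped(self, tmp_path, nt_params):
        recs = [make_record("a", 600, seed=1), make_record("b", 600, seed=2)]
        p = tmp_path / "hits.tsv"
        p.write_text(
            "a\tb\t90.0\t100\t10\t0\t1\t100\t1\t100\t5e-1\t50\n"
            "a\tb\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-9\t50\n"
        )
        hits = read_blast_tab(p, recs, nt_params)
        assert len(hits.get("a", "b")) == 1

    def test_self_hit_retained(self, tmp_path, nt_params):
        recs = [make_record("a", 600, seed=1), make_record("b", 600, seed=2)]
        p = tmp_path / "hits.tsv"
        p.write_text("a\ta\t100.0\t600\t0\t0\t1\t600\t1\t600\t0.0\t1100\n")
        hits = read_blast_tab(p, recs, nt_params)
        assert len(hits.get("a", "a")) == 1

    def test_unknown_id_hard_error(self, tmp_path, nt_params):
        recs = [make_record("a", 600, seed=1)]
        p = tmp_path / "hits.tsv"
        p.write_text("a\tzz\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-9\t50\n")
        with pytest.raises(InputError, match="zz"):
            read_blast_tab(p, recs, nt_params)

    def test_wrong_column_count_row_error(self, tmp_path, nt_params):
        recs = [make_record("a", 600, seed=1)]
        p = tmp_path / "hits.tsv"
        p.write_text("a\ta\t90.0\t100\n")
        with pytest.raises(InputError):
            read_blast_tab(p, recs, nt_params)

    def test_write_read_roundtrip(self, tmp_path, nt_params):
        recs, _ = make_related_set(2, 2000, 0.9, seed=12)
        hits = all_pairs(validate_input_set(recs), nt_params)
        p = tmp_path / "out.tsv"
        write_blast_tab(hits, p)
        back = read_blast_tab(p, recs, nt_params)
        for pair in hits.pairs:
            orig = {(h.qstart, h.qend, h.sstart, h.send, h.subject_reversed)
                    for h in hits.pairs[pair]}
            rt = {(h.qstart, h.qend, h.sstart, h.send, h.subject_reversed)
                  for h in back.get(*pair)}
            assert rt == orig
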