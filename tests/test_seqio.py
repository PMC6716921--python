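import pytest
from hypothesis import given, settings, strategies as st

from ampminer import seqio
from ampminer.errors import (AlphabetError, CoordinateError,
                             DegenerateInputError, FastaFormatError)
from oracles import codon_interval_oracle

nt_seq = st.text(alphabet="ACGTN", min_size=1, max_size=200)
ids = st.text(alphabet="abcdefgh_0123456789", min_size=1, max_size=12)


class TestRecords:
    def test_scaffold_rejects_ambiguity_codes(self):
        with pytest.raises(AlphabetError):
            seqio.ScaffoldRecord("s", "ACGU")

    def test_protein_rejects_selenocysteine(self):
        with pytest.raises(AlphabetError):
            seqio.ProteinRecord("p", "MUK")

    def test_length_matches_sequence(self):
        assert seqio.ScaffoldRecord("s", "ACGT").length == 4


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">s\nACGT\n")
        (rec,) = seqio.read_fasta(path, "nucleotide")
        assert rec.id == "s" and rec.sequence == "ACGT" and rec.length == 4

    def test_lowercase_uppercased_on_ingest(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">s\nacgt\n")
        assert seqio.read_fasta(path, "nucleotide")[0].sequence == "ACGT"

    @pytest.mark.parametrize("text,fragment", [
        ("ACGT\n", "before first '>'"),
        (">\nACGT\n", "empty header"),
        (">a\n>b\nACGT\n", "no sequence"),
        ("", "no FASTA records"),
    ])
    def test_malformed_input_names_the_line(self, tmp_path, text, fragment):
        path = tmp_path / "bad.fasta"
        path.write_text(text)
        with pytest.raises(FastaFormatError, match=fragment):
            seqio.read_fasta(path, "nucleotide")

    def test_duplicate_protein_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nMK\n>a\nMR\n")
        with pytest.raises(FastaFormatError, match="duplicate"):
            seqio.read_fasta(path, "protein")

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            seqio.write_fasta([], tmp_path / "x.fasta")

    def test_sixty_column_wrap(self, tmp_path):
        rec = seqio.ScaffoldRecord("s", "A" * 130)
        path = tmp_path / "wrap.fasta"
        seqio.write_fasta([rec], path)
        lines = path.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 60, 10]

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(ids, nt_seq), min_size=1, max_size=50,
                    unique_by=lambda t: t[0]))
    def test_round_trip_identity(self, records):
        import tempfile, pathlib
        recs = [seqio.ScaffoldRecord(i, s) for i, s in records]
        with tempfile.TemporaryDirectory() as d:
            path = pathlib.Path(d) / "rt.fasta"
            seqio.write_fasta(recs, path)
            assert seqio.read_fasta(path, "nucleotide") == recs


class TestTranslation:
    def test_standard_code_with_stop(self):
        frames = seqio.six_frame_translate(seqio.ScaffoldRecord("s", "ATGAAATAA"))
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame_offset == 0)
        assert fwd0.peptide == "MK*"

    def test_codons_containing_n_become_x(self):
        frames = seqio.six_frame_translate(seqio.ScaffoldRecord("s", "GGNATG"))
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame_offset == 0)
        assert fwd0.peptide == "XM"   # even resolvable GGN stays X

    def test_too_short_scaffold_rejected(self):
        with pytest.raises(DegenerateInputError):
            seqio.six_frame_translate(seqio.ScaffoldRecord("s", "AC"))

    def test_reverse_complement_involution(self, rng):
        for _ in range(20):
            s = "".join("ACGTN"[i] for i in rng.integers(5, size=60))
            assert seqio.reverse_complement(seqio.reverse_complement(s)) == s

    def test_rc_scaffold_swaps_strands(self, rng):
        s = "".join("ACGT"[i] for i in rng.integers(4, size=90))
        fwd = seqio.six_frame_translate(seqio.ScaffoldRecord("s", s))
        rev = seqio.six_frame_translate(
            seqio.ScaffoldRecord("s", seqio.reverse_complement(s)))
        assert (sorted(f.peptide for f in fwd)
                == sorted(f.peptide for f in rev))
        by_key = {(f.strand, f.frame_offset): f.peptide for f in rev}
        for f in fwd:
            other = "-" if f.strand == "+" else "+"
            assert by_key[(other, f.frame_offset)] == f.peptide

    def test_frame_lengths_tile_codons(self, rng):
        for length in (90, 91, 92):
            s = "".join("ACGT"[i] for i in rng.integers(4, size=length))
            for f in seqio.six_frame_translate(seqio.ScaffoldRecord("s", s)):
                assert len(f.peptide) == (length - f.frame_offset) // 3

    def test_coordinate_map_matches_arithmetic_oracle(self, rng):
        for _ in range(100):
            length = int(rng.integers(300, 310))
            s = "".join("ACGT"[i] for i in rng.integers(4, size=length))
            for frame in seqio.six_frame_translate(seqio.ScaffoldRecord("s", s)):
                for idx in range(len(frame.peptide)):
                    assert frame.codon_interval(idx) == codon_interval_oracle(
                        length, frame.strand, frame.frame_offset, idx)

    def test_codon_interval_retranslates_to_residue(self, rng):
        s = "".join("ACGT"[i] for i in rng.integers(4, size=120))
        scaffold = seqio.ScaffoldRecord("s", s)
        for frame in seqio.six_frame_translate(scaffold):
            for idx in (0, len(frame.peptide) // 2, len(frame.peptide) - 1):
                lo, hi = frame.codon_interval(idx)
                codon = s[lo - 1:hi]
                if frame.strand == "-":
                    codon = seqio.reverse_complement(codon)
                assert seqio.translate_codon(codon) == frame.peptide[idx]


class TestGff3:
    def test_single_feature_line(self, tmp_path):
        rec = seqio.AnnotationRecord("scaffold210", 100, 160, "+",
                                     "polypeptide_domain", "hit1")
        path = tmp_path / "one.gff3"
        seqio.write_gff3([rec], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert len(lines) == 2
        cols = lines[1].split("\t")
        assert cols[0] == "scaffold210" and cols[3:5] == ["100", "160"]

    def test_round_trip_preserves_coordinates_and_strand(self, tmp_path):
        recs = [seqio.AnnotationRecord("s1", 5, 10, "-", "gene", "a"),
                seqio.AnnotationRecord("s1", 20, 45, "+", "gene", "b"),
                seqio.AnnotationRecord("s2", 1, 3, ".", "region", "c")]
        path = tmp_path / "rt.gff3"
        seqio.write_gff3(recs, path)
        back = seqio.read_gff3(path)
        assert ({(r.scaffold_id, r.start, r.end, r.strand, r.name)
                 for r in back}
                == {(r.scaffold_id, r.start, r.end, r.strand, r.name)
                    for r in recs})

    def test_semicolon_in_name_is_escaped(self, tmp_path):
        rec = seqio.AnnotationRecord("s", 1, 2, "+", "gene", "a;b")
        path = tmp_path / "esc.gff3"
        seqio.write_gff3([rec], path)
        assert "a%3Bb" in path.read_text()
        assert seqio.read_gff3(path)[0].name == "a;b"

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(CoordinateError):
            seqio.AnnotationRecord("s", 10, 5, "+", "gene", "x")
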