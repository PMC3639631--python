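import pytest

from fractalseq.seq_io import (
    AmbiguousPlacementError,
    MrnaCdsPair,
    NucleotideSequence,
    PairingError,
    SequenceAlphabetError,
    build_pair,
    extract_noncoding,
    load_pairs,
    locate_cds,
    read_fasta,
    write_fasta,
)


def fasta(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_lowercase_is_normalized(self, tmp_path):
        (seq,) = read_fasta(fasta(tmp_path, ">x\nacgt\n"))
        assert seq.id == "x" and seq.residues == "ACGT"

    def test_uracil_folds_to_thymine(self, tmp_path):
        (seq,) = read_fasta(fasta(tmp_path, ">x\nACGU\n"))
        assert seq.residues == "ACGT"

    def test_ambiguity_code_rejected_with_position(self, tmp_path):
        with pytest.raises(SequenceAlphabetError, match=r"'x'.*'N'.*position 3"):
            read_fasta(fasta(tmp_path, ">x\nACNT\n"))

    def test_drop_invalid_skips_offending_record(self, tmp_path):
        seqs = read_fasta(fasta(tmp_path, ">x\nACNT\n>y\nACGT\n"), drop_invalid=True)
        assert [s.id for s in seqs] == ["y"]

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(fasta(tmp_path, ""))

    def test_wrapped_multirecord_roundtrip(self, tmp_path, rng, random_sequence_factory):
        originals = [random_sequence_factory(rng, n, id=f"s{i}") for i, n in enumerate([5, 73, 200])]
        out = tmp_path / "out.fasta"
        write_fasta(originals, out)
        back = read_fasta(out)
        assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in originals]


class TestNoncodingExtraction:
    def test_flanks_are_concatenated_in_order(self):
        m = NucleotideSequence("m", "AAACCCGGGTTT", role="mrna")
        c = NucleotideSequence("c", "CCCGGG", role="cds")
        nc = extract_noncoding(m, c)
        assert nc.residues == "AAATTT"
        assert nc.role == "noncoding"

    def test_cds_spanning_whole_mrna_gives_empty_remainder(self):
        m = NucleotideSequence("m", "ACGTACGT", role="mrna")
        c = NucleotideSequence("c", "ACGTACGT", role="cds")
        assert extract_noncoding(m, c).residues == ""

    def test_ambiguous_placement_is_an_error(self):
        m = NucleotideSequence("m", "ACACAC", role="mrna")
        c = NucleotideSequence("c", "CA", role="cds")
        with pytest.raises(AmbiguousPlacementError):
            extract_noncoding(m, c)

    def test_lengths_partition_the_mrna(self, rng, random_sequence_factory):
        for _ in range(20):
            m = random_sequence_factory(rng, int(rng.integers(20, 200)), id="m")
            start = int(rng.integers(1, len(m) - 5))
            end = int(rng.integers(start + 1, len(m)))
            c = NucleotideSequence("c", m.residues[start - 1 : end], role="cds")
            nc = extract_noncoding(m, c, start, end)
            assert len(nc) == len(m) - len(c)
            # position-faithful: noncoding characters appear in mRNA order
            assert nc.residues == m.residues[: start - 1] + m.residues[end:]

    def test_locate_cds_finds_unique_hit(self):
        m = NucleotideSequence("m", "TTTACGTTT", role="mrna")
        c = NucleotideSequence("c", "ACG", role="cds")
        assert locate_cds(m, c) == (4, 6)


class TestPairValidation:
    def test_coordinates_must_match_cds(self):
        m = NucleotideSequence("m", "AAACCCGGGTTT", role="mrna")
        c = NucleotideSequence("c", "CCCGGG", role="cds")
        with pytest.raises(PairingError, match="does not match"):
            MrnaCdsPair("g", m, c, cds_start=1, cds_end=6)

    def test_cds_longer_than_mrna_rejected(self):
        m = NucleotideSequence("m", "ACGT", role="mrna")
        c = NucleotideSequence("c", "ACGTACGT", role="cds")
        with pytest.raises(PairingError, match="out of range"):
            MrnaCdsPair("g", m, c)

    def test_build_pair_without_substring_match_keeps_pair_without_noncoding(self):
        m = NucleotideSequence("m", "AAAACCCC", role="mrna")
        c = NucleotideSequence("c", "GGG", role="cds")
        pair = build_pair("g", m, c)
        assert pair.noncoding is None and pair.cds_start is None


class TestManifest:
    def write_inputs(self, tmp_path, manifest_rows):
        write_fasta(
            [
                NucleotideSequence("m1", "AAACCCGGGT", role="mrna"),
                NucleotideSequence("m2", "TTTACGTTT", role="mrna"),
                NucleotideSequence("c2", "ACG", role="cds"),
            ],
            tmp_path / "seqs.fasta",
        )
        header = "gene\tmrna_id\tcds_id\tcds_start\tcds_end\n"
        (tmp_path / "manifest.tsv").write_text(header + "".join(manifest_rows))
        return tmp_path / "manifest.tsv", tmp_path

    def test_coordinate_row_resolves_lengths(self, tmp_path):
        manifest, d = self.write_inputs(tmp_path, ["geneX\tm1\t\t3\t8\n"])
        (pair,) = load_pairs(manifest, d)
        assert len(pair.cds) == 6 and len(pair.noncoding) == 4
        assert pair.cds.residues == "ACCCGG"

    def test_out_of_range_coordinates_rejected(self, tmp_path):
        manifest, d = self.write_inputs(tmp_path, ["geneX\tm1\t\t3\t99\n"])
        with pytest.raises(PairingError, match="out of range"):
            load_pairs(manifest, d)

    def test_cds_as_separate_record(self, tmp_path):
        manifest, d = self.write_inputs(tmp_path, ["geneY\tm2\tc2\t\t\n"])
        (pair,) = load_pairs(manifest, d)
        assert pair.cds.id == "c2"
        assert pair.noncoding.residues == "TTTTTT"

    def test_unknown_id_rejected(self, tmp_path):
        manifest, d = self.write_inputs(tmp_path, ["geneZ\tnope\t\t1\t2\n"])
        with pytest.raises(PairingError, match="unknown mrna_id"):
            load_pairs(manifest, d)

    def test_both_cds_id_and_coordinates_rejected(self, tmp_path):
        manifest, d = self.write_inputs(tmp_path, ["geneY\tm2\tc2\t1\t3\n"])
        with pytest.raises(PairingError, match="not both"):
            load_pairs(manifest, d)
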