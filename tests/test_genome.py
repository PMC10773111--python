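"""Modification calling, genome rewriting, BED tracks and region extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modmotif.alphabet import reverse_complement
from modmotif.genome import (
    GenomeError,
    ModificationRecord,
    Peak,
    apply_bed_tracks,
    build_modified_genome,
    call_symbol,
    call_symbol_single_channel,
    combine_channels,
    extract_regions,
    read_bed_track,
    read_peaks,
    read_track,
    write_bed_tracks,
    write_track,
)


def rec(pos=0, strand="+", m=0.0, h=0.0, conflicts=0, chrom="chr1"):
    return ModificationRecord(chrom=chrom, pos=pos, strand=strand,
                              level_m=m, level_h=h, conflicts=conflicts)


class TestCallSymbol:
    @pytest.mark.parametrize("m,h,conflicts,t,expected", [
        (0.9, 0.05, 0, 0.3, "m"),   # 5mC level alone clears the threshold
        (0.05, 0.9, 0, 0.3, "h"),
        (0.5, 0.4, 1, 0.3, "z"),    # any conflict wins regardless of levels
        (0.0, 0.0, 2, 0.3, "z"),
        (0.2, 0.15, 0, 0.3, "x"),   # neither level alone, but m + h >= t
        (0.1, 0.1, 0, 0.3, "C"),
        (0.4, 0.4, 0, 0.3, "x"),    # both clear t: cannot disambiguate
        (0.3, 0.0, 0, 0.3, "m"),    # threshold is inclusive
    ])
    def test_fixed_cases(self, m, h, conflicts, t, expected):
        assert call_symbol(rec(m=m, h=h, conflicts=conflicts), t) == expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(GenomeError):
            call_symbol(rec(m=0.5), 0.0)
        with pytest.raises(GenomeError):
            call_symbol(rec(m=0.5), 1.5)

    @given(m=st.floats(0, 1), h=st.floats(0, 1),
           t1=st.floats(0.01, 1.0), t2=st.floats(0.01, 1.0))
    @settings(deadline=None, max_examples=300)
    def test_threshold_monotonicity_of_modified_calls(self, m, h, t1, t2):
        # raising the threshold can only turn modified calls unmodified,
        # never the reverse; conflict calls are threshold-independent
        if m + h > 1:
            m, h = m / 2, h / 2
        t1, t2 = min(t1, t2), max(t1, t2)
        r = rec(m=m, h=h)
        call_lo, call_hi = call_symbol(r, t1), call_symbol(r, t2)
        if call_hi != "C":
            assert call_lo != "C"
        assert call_symbol(rec(m=m, h=h, conflicts=1), t1) == "z"
        assert call_symbol(rec(m=m, h=h, conflicts=1), t2) == "z"

    def test_single_channel_yields_x_or_relabelled_m(self):
        assert call_symbol_single_channel(rec(m=0.5), 0.3) == "x"
        assert call_symbol_single_channel(rec(m=0.5), 0.3, relabel_x_as_m=True) == "m"
        assert call_symbol_single_channel(rec(m=0.1), 0.3) == "C"
        assert call_symbol_single_channel(rec(m=0.9, conflicts=1), 0.3) == "z"


class TestCombineChannels:
    @pytest.mark.parametrize("wgbs,ox,expected", [
        (0.8, 0.5, (0.5, 0.3, 0)),
        (0.5, 0.5, (0.5, 0.0, 0)),
        (0.3, 0.5, (0.5, 0.0, 1)),  # oxidative above conventional: conflict
    ])
    def test_examples(self, wgbs, ox, expected):
        lm, lh, c = combine_channels(wgbs, ox)
        assert (round(lm, 12), round(lh, 12), c) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(GenomeError):
            combine_channels(1.2, 0.5)


class TestBuildModifiedGenome:
    GENOME = {"chr1": "ACGTCG"}

    def test_plus_and_minus_records_full_methylation(self):
        records = [rec(pos=4, strand="+", m=0.9), rec(pos=5, strand="-", m=0.9)]
        out = build_modified_genome(self.GENOME, records, 0.3)
        assert out.sequences["chr1"] == "ACGTm1"
        assert out.call_counts == {"m": 1, "1": 1}

    def test_no_records_is_identity(self):
        out = build_modified_genome(self.GENOME, [], 0.3)
        assert out.sequences == self.GENOME

    def test_hemi_hydroxymethylation_minus_strand_only(self):
        # only the minus strand is modified: C stays, its G becomes 2
        out = build_modified_genome(self.GENOME, [rec(pos=5, strand="-", h=0.8)], 0.3)
        assert out.sequences["chr1"] == "ACGTC2"

    def test_length_preserved_on_every_chromosome(self):
        genome = {"a": "CGCGCG", "b": "ATCGAT"}
        records = [rec(chrom="a", pos=0, m=1.0), rec(chrom="b", pos=2, m=1.0)]
        out = build_modified_genome(genome, records, 0.3)
        assert {k: len(v) for k, v in out.sequences.items()} == \
               {k: len(v) for k, v in genome.items()}

    def test_record_on_wrong_base_skipped_by_default(self):
        out = build_modified_genome(self.GENOME, [rec(pos=0, strand="+", m=1.0)], 0.3)
        assert out.sequences == self.GENOME
        assert out.n_skipped == 1

    def test_record_on_wrong_base_aborts_when_asked(self):
        with pytest.raises(GenomeError, match="expected C"):
            build_modified_genome(self.GENOME, [rec(pos=0, strand="+", m=1.0)],
                                  0.3, on_reference_mismatch="abort")

    def test_record_outside_chromosome_aborts(self):
        with pytest.raises(GenomeError, match="outside"):
            build_modified_genome(self.GENOME, [rec(pos=99, m=1.0)], 0.3)

    def test_softmask_preserved_but_masked_c_uppercased(self):
        out = build_modified_genome({"chr1": "acgtcg"},
                                    [rec(pos=4, strand="+", m=0.9)], 0.3)
        assert out.sequences["chr1"] == "aCgtmg"

    def test_single_channel_mode_writes_x_and_7(self):
        records = [rec(pos=4, strand="+", m=0.9), rec(pos=5, strand="-", m=0.9)]
        out = build_modified_genome(self.GENOME, records, 0.3, single_channel=True)
        assert out.sequences["chr1"] == "ACGTx7"

    def test_conflict_writes_z_and_9(self):
        records = [rec(pos=4, strand="+", m=0.9, conflicts=1),
                   rec(pos=5, strand="-", h=0.9, conflicts=2)]
        out = build_modified_genome(self.GENOME, records, 0.3)
        assert out.sequences["chr1"] == "ACGTz9"

    def test_bed_round_trip_reconstructs_modified_fasta(self, tmp_path):
        genome = {"chr1": "ACGTCGCGATCGGCTA"}
        records = [rec(pos=4, m=0.9), rec(pos=5, strand="-", h=0.8),
                   rec(pos=6, m=0.2, h=0.2), rec(pos=10, m=0.5, conflicts=1),
                   rec(pos=12, strand="-", m=0.9)]
        out = build_modified_genome(genome, records, 0.3)
        paths = write_bed_tracks(out, tmp_path / "mod")
        tracks = {p.name.split(".")[-2]: read_bed_track(p) for p in paths}
        assert apply_bed_tracks(genome, tracks) == out.sequences

    def test_complement_strand_symmetry(self):
        genome = {"chr1": "ACGTCGCGAT"}
        n = len(genome["chr1"])
        records = [rec(pos=4, m=0.9), rec(pos=7, strand="-", h=0.8)]
        fwd = build_modified_genome(genome, records, 0.3)
        flipped = [ModificationRecord(chrom="chr1", pos=n - 1 - r.pos,
                                      strand="-" if r.strand == "+" else "+",
                                      level_m=r.level_m, level_h=r.level_h,
                                      conflicts=r.conflicts) for r in records]
        rev = build_modified_genome({"chr1": reverse_complement(genome["chr1"])},
                                    flipped, 0.3)
        assert rev.sequences["chr1"] == reverse_complement(fwd.sequences["chr1"])

    def test_merge_max_keeps_strongest_record(self):
        records = [rec(pos=4, m=0.1), rec(pos=4, m=0.9)]
        first = build_modified_genome(self.GENOME, records, 0.3, merge="first")
        strongest = build_modified_genome(self.GENOME, records, 0.3, merge="max")
        assert first.sequences["chr1"] == "ACGTCG"
        assert strongest.sequences["chr1"] == "ACGTmG"

    def test_track_file_round_trip(self, tmp_path):
        records = [rec(pos=4, m=0.9, h=0.05), rec(pos=5, strand="-", h=0.8)]
        path = tmp_path / "track.tsv"
        write_track(records, path)
        assert list(read_track(path)) == records


class TestExtractRegions:
    def test_summit_centred_window(self):
        genome = {"c": "A" * 600}
        regions, dropped = extract_regions(
            genome, [Peak("c", 0, 600, 250)], width=500)
        assert dropped == 0
        assert len(regions) == 1 and len(regions[0]) == 500

    def test_edge_regions_dropped_and_counted(self):
        genome = {"c": "A" * 600}
        peaks = [Peak("c", 0, 600, 10), Peak("c", 0, 600, 300)]
        regions, dropped = extract_regions(genome, peaks, width=500)
        assert dropped == 1
        assert [len(r) for r in regions] == [500]

    def test_region_content_and_coordinates(self):
        genome = {"c": "".join("ACGT"[i % 4] for i in range(40))}
        regions, _ = extract_regions(genome, [Peak("c", 0, 40, 20)], width=10)
        assert regions[0] == genome["c"][15:25]

    def test_narrowpeak_summit_column(self, tmp_path):
        path = tmp_path / "peaks.narrowPeak"
        path.write_text("c\t100\t300\tpeak0\t0\t.\t0\t-1\t-1\t50\n")
        peaks = read_peaks(path)
        assert peaks[0].summit == 150

    def test_malformed_bed_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("c\t100\t300\nc\tnotanumber\t400\n")
        with pytest.raises(GenomeError, match=":2"):
            read_peaks(path)
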