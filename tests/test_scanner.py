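"""Scanner correctness: window semantics, FASTA I/O, oracle equivalence."""

import random

import pytest
from hypothesis import given, strategies as st

from filamentid import (
    SequenceRecord,
    parse_pattern,
    read_fasta,
    scan_fasta,
    scan_sequence,
    write_fasta,
)
from filamentid.scanner import report_to_tsv

from conftest import brute_force_scan, random_pattern, random_sequence


def seq(residues, id="s1"):
    return SequenceRecord(id=id, residues=residues)


class TestScanSequence:
    def test_single_window_hit_and_miss(self):
        p = parse_pattern("N-x-[ST]")
        hits = scan_sequence(p, seq("NAS"))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 3)
        assert scan_sequence(p, seq("NAP")) == []

    def test_combined_pattern_on_tmem106b(self, combined_pattern, tmem106b):
        hits = scan_sequence(combined_pattern, tmem106b)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.end) == (145, 185)
        assert hit.anchor_positions == (145, 151, 164, 183)
        assert hit.matched_text == tmem106b.residues[144:185]

    def test_pattern_longer_than_sequence_is_empty_not_error(self):
        assert scan_sequence(parse_pattern("x(10)"), seq("NAS")) == []

    def test_overlapping_matches_all_reported(self):
        hits = scan_sequence(parse_pattern("A-x-A"), seq("AAAAA"))
        assert [h.start for h in hits] == [1, 2, 3]

    def test_x_satisfies_wildcard_but_never_a_class(self):
        p = parse_pattern("N-x-[ST]")
        assert len(scan_sequence(p, seq("NXS"))) == 1
        assert scan_sequence(p, seq("XAS")) == []
        assert scan_sequence(p, seq("NAX")) == []

    def test_region_restriction_keeps_full_sequence_coordinates(self, tmem106b):
        p = parse_pattern("C-x(38)-C")
        hits = scan_sequence(p, tmem106b, region=(120, 254))
        assert len(hits) == 1
        assert hits[0].anchor_positions == (214, 253)

    def test_scanner_equals_brute_force_oracle_on_random_instances(self):
        rng = random.Random(20260918)
        for _ in range(300):
            alphabet = random.Random(rng.random()).sample(
                "ACDEFGHIKLMNPQRSTVWY", rng.randint(2, 20)
            )
            p = parse_pattern(random_pattern(rng, alphabet))
            s = random_sequence(rng, rng.randint(1, 200), alphabet)
            got = [h.start for h in scan_sequence(p, seq(s))]
            assert got == brute_force_scan(p, s)


@given(st.data())
def test_scanner_oracle_property(data):
    """Scanner and position-by-position oracle agree on arbitrary inputs."""
    alphabet = data.draw(
        st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=2, max_size=20, unique=True)
    )
    rng = random.Random(data.draw(st.integers(0, 2**31)))
    p = parse_pattern(random_pattern(rng, alphabet))
    s = data.draw(st.text(alphabet=alphabet, min_size=1, max_size=500))
    assert [h.start for h in scan_sequence(p, seq(s))] == brute_force_scan(p, s)


class TestScanFasta:
    def test_unique_hit_on_tmem106b_among_decoys(self, combined_pattern, tmem106b):
        from filamentid import DecoySpec, LengthDistribution, generate_proteome

        decoys = generate_proteome(
            DecoySpec(seed=11, n_sequences=100, lengths=LengthDistribution(length=300))
        ).records
        report = scan_fasta(combined_pattern, decoys + [tmem106b])
        assert report.unique_hit
        assert report.hit_sequence_ids == [tmem106b.id]
        assert report.n_sequences == 101
        span = combined_pattern.span
        assert report.n_windows == sum(max(0, len(r) - span + 1) for r in decoys + [tmem106b])

    def test_duplicate_ids_rejected(self, combined_pattern):
        with pytest.raises(ValueError, match="duplicate"):
            scan_fasta(combined_pattern, [seq("NAS", "a"), seq("NAT", "a")])

    def test_no_hits_means_not_unique(self):
        report = scan_fasta(parse_pattern("W-W-W"), [seq("NAS")])
        assert report.hits == [] and not report.unique_hit

    def test_hit_count_invariant_under_renaming_and_permutation(self, combined_pattern, tmem106b):
        records = [seq("NASAAAA", "a"), seq(tmem106b.residues, "b"), seq("WWWWW", "c")]
        base = scan_fasta(combined_pattern, records)
        shuffled = [
            SequenceRecord(id=f"r{i}", residues=r.residues)
            for i, r in enumerate(reversed(records))
        ]
        assert len(scan_fasta(combined_pattern, shuffled).hits) == len(base.hits)

    def test_added_constraint_never_increases_hits(self, tmem106b):
        loose = parse_pattern("N-x-[ST]")
        tight = parse_pattern("N-I-[ST]")
        records = [tmem106b]
        assert len(scan_fasta(tight, records).hits) <= len(scan_fasta(loose, records).hits)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        rng = random.Random(3)
        records = [
            seq(random_sequence(rng, rng.randint(10, 150)), id=f"rec{i}") for i in range(3)
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in records]

    def test_wrap_at_60_columns(self, tmp_path):
        path = tmp_path / "x.fasta"
        write_fasta([seq("A" * 150)], path)
        lines = path.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 60, 30]

    def test_id_is_first_header_token(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">sp|Q9NUM4|T106B_HUMAN some description\nMGKSL\n")
        (record,) = read_fasta(path)
        assert record.id == "sp|Q9NUM4|T106B_HUMAN"
        assert "some description" in record.description

    def test_crlf_equals_lf(self, tmp_path):
        lf, crlf = tmp_path / "lf.fasta", tmp_path / "crlf.fasta"
        lf.write_text(">a x\nMKV\n>b y\nNAS\n")
        crlf.write_bytes(b">a x\r\nMKV\r\n>b y\r\nNAS\r\n")
        assert [(r.id, r.residues) for r in read_fasta(lf)] == [
            (r.id, r.residues) for r in read_fasta(crlf)
        ]

    def test_empty_file_and_empty_record_are_errors(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_fasta(empty)
        norec = tmp_path / "norec.fasta"
        norec.write_text(">a desc\n\n>b desc\nMKV\n")
        with pytest.raises(ValueError):
            read_fasta(norec)


def test_report_tsv_export(tmp_path, combined_pattern, tmem106b):
    report = scan_fasta(combined_pattern, [tmem106b])
    out = tmp_path / "hits.tsv"
    report_to_tsv(report, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "sequence_id\tstart\tend\tanchors\tmatched_text"
    fields = lines[1].split("\t")
    assert fields[1:4] == ["145", "185", "145;151;164;183"]
    assert any(line.startswith("# unique_hit: True") for line in lines)
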