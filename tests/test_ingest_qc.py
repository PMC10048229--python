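"""Reading, QC rules, terminal-stop stripping and codon counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cds
from cubkit import (CodonCounts, concatenate_counts, count_codons,
                    extract_cds_from_genbank, qc_filter, read_cds_fasta,
                    strip_terminal_stop)
from cubkit.ingest_qc import (AMBIGUOUS_EXCESS, INTERNAL_STOP, NO_START,
                              NO_TERMINAL_STOP, NOT_MULTIPLE_OF_3, TOO_SHORT,
                              normalize_sequence)

# --------------------------------------------------------------------------
# FASTA reading
# --------------------------------------------------------------------------

def test_read_fasta_header_convention(tmp_path):
    fa = tmp_path / "in.fasta"
    fa.write_text(">rbcL|Paeonia suffruticosa|Paeoniaceae\natggcaugg\n")
    (seq,) = read_cds_fasta(fa)
    assert seq.gene == "rbcL"
    assert seq.taxon == "Paeonia suffruticosa"
    assert seq.family == "Paeoniaceae"
    assert seq.seq == "ATGGCATGG"  # uppercased, U -> T


def test_read_fasta_with_metadata_sidecar(tmp_path):
    fa = tmp_path / "in.fasta"
    fa.write_text(">rec1\nATGAAATAA\n>rec2\nATGCCCTAA\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text("id\tgene\ttaxon\tfamily\n"
                    "rec1\trbcL\tTaxon a\tFamA\n"
                    "rec2\tmatK\tTaxon b\tFamB\n")
    seqs = read_cds_fasta(fa, metadata=meta)
    assert [s.gene for s in seqs] == ["rbcL", "matK"]
    assert seqs[1].family == "FamB"


def test_read_fasta_missing_metadata_lists_ids(tmp_path):
    fa = tmp_path / "in.fasta"
    fa.write_text(">rec1\nATG\n>orphan\nATG\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text("id\tgene\ttaxon\tfamily\nrec1\tg\tt\tf\n")
    with pytest.raises(KeyError, match="orphan"):
        read_cds_fasta(fa, metadata=meta)


def test_read_fasta_empty_file_warns(tmp_path, caplog):
    fa = tmp_path / "empty.fasta"
    fa.write_text("")
    with caplog.at_level("WARNING"):
        assert read_cds_fasta(fa) == []
    assert "empty" in caplog.text.lower()


def test_read_fasta_malformed_names_line(tmp_path):
    fa = tmp_path / "bad.fasta"
    fa.write_text("ATGATG\n>ok\nATG\n")
    with pytest.raises(ValueError, match="line 1"):
        read_cds_fasta(fa)


def test_normalize_rejects_foreign_characters():
    with pytest.raises(ValueError):
        normalize_sequence("ATGXP")


# --------------------------------------------------------------------------
# GenBank extraction
# --------------------------------------------------------------------------

GENBANK_SEQ = ("atggcaaaat aagcctttgg gcccaaattt gggcccaaat ttgggcccaa "
               "atttgggccc")


def _genbank_text():
    return f"""LOCUS       TESTREC                   60 bp    DNA     linear   PLN 01-JAN-2020
DEFINITION  synthetic test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
SOURCE      Fakeplant testus
  ORGANISM  Fakeplant testus
            Eukaryota.
FEATURES             Location/Qualifiers
     source          1..60
     CDS             4..15
                     /gene="aaa"
     CDS             join(10..15,22..27)
                     /gene="bbb"
     CDS             complement(10..21)
                     /gene="ccc"
     CDS             31..36
ORIGIN
        1 {GENBANK_SEQ}
//
"""


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def test_genbank_extraction(tmp_path, caplog):
    gb = tmp_path / "rec.gb"
    gb.write_text(_genbank_text())
    plain = GENBANK_SEQ.replace(" ", "").upper()
    with caplog.at_level("WARNING"):
        seqs = extract_cds_from_genbank(
            gb, family_map={"Fakeplant testus": "FamX"})
    by_gene = {s.gene: s for s in seqs}
    assert set(by_gene) == {"aaa", "bbb", "ccc"}  # no-gene CDS skipped
    assert "lacks a gene qualifier" in caplog.text
    assert by_gene["aaa"].seq == plain[3:15]
    assert by_gene["bbb"].seq == plain[9:15] + plain[21:27]
    assert by_gene["ccc"].seq == _revcomp(plain[9:21])
    assert by_gene["aaa"].taxon == "Fakeplant testus"
    assert by_gene["aaa"].family == "FamX"


# --------------------------------------------------------------------------
# QC filtering
# --------------------------------------------------------------------------

def test_qc_passes_well_formed_cds(code11):
    seq = make_cds("ATG" + "AAA" * 120 + "TAA")  # 366 nt
    passed, (report,) = qc_filter([seq], code11)
    assert report.passed and passed == [seq]
    assert report.reasons == ()


def test_qc_too_short(code11):
    _, (report,) = qc_filter([make_cds("ATGAAATAA")], code11)
    assert report.reasons == (TOO_SHORT,)


def test_qc_internal_stop_and_short(code11):
    _, (report,) = qc_filter([make_cds("ATGAAATAAAAATAA")], code11)
    assert INTERNAL_STOP in report.reasons
    assert TOO_SHORT in report.reasons


@pytest.mark.parametrize("seq, expected", [
    ("CTG" + "AAA" * 120 + "TAA", NO_START),
    ("ATG" + "AAA" * 120 + "AAA", NO_TERMINAL_STOP),
    ("ATG" + "AAA" * 120 + "TAAA", NOT_MULTIPLE_OF_3),
])
def test_qc_single_rule_failures(code11, seq, expected):
    _, (report,) = qc_filter([make_cds(seq)], code11)
    assert expected in report.reasons


def test_qc_ambiguous_excess(code11):
    body = ["AAA"] * 120
    for i in range(10):  # 10 N codons of 122 total > 5%
        body[i] = "ANA"
    _, (report,) = qc_filter([make_cds("ATG" + "".join(body) + "TAA")], code11)
    assert AMBIGUOUS_EXCESS in report.reasons
    # a single N codon stays under the ceiling
    body = ["AAA"] * 120
    body[0] = "ANA"
    _, (report,) = qc_filter([make_cds("ATG" + "".join(body) + "TAA")], code11)
    assert report.passed


def test_qc_idempotent_on_passed(code11):
    seqs = [make_cds("ATG" + "AAA" * 120 + "TAA", gene=f"g{i}")
            for i in range(5)] + [make_cds("ATGAAATAA", gene="short")]
    passed, _ = qc_filter(seqs, code11)
    again, reports = qc_filter(passed, code11)
    assert again == passed and all(r.passed for r in reports)


def test_qc_alternate_starts_config(code11):
    from cubkit import GeneticCode
    seq = make_cds("GTG" + "AAA" * 120 + "TAA")
    _, (strict,) = qc_filter([seq], code11)
    assert NO_START in strict.reasons
    relaxed_code = GeneticCode.from_ncbi(11, accepted_starts=("ATG", "GTG"))
    _, (relaxed,) = qc_filter([seq], relaxed_code)
    assert relaxed.passed


# --------------------------------------------------------------------------
# stop stripping and codon counting
# --------------------------------------------------------------------------

def test_strip_terminal_stop(code11):
    assert strip_terminal_stop(make_cds("ATGGCCTAA"), code11).seq == "ATGGCC"
    assert strip_terminal_stop(make_cds("ATGTGA"), code11).seq == "ATG"
    with pytest.raises(ValueError):
        strip_terminal_stop(make_cds("ATGGCC"), code11)


@pytest.mark.parametrize("seq, expected, n", [
    ("ATGGCC", {"ATG": 1, "GCC": 1}, 2),
    ("AAAAAAAAA", {"AAA": 3}, 3),
    ("ATGNNNGCC", {"ATG": 1, "GCC": 1}, 2),  # N codon skipped entirely
])
def test_count_codons(seq, expected, n):
    counts = count_codons(make_cds(seq))
    assert counts.counts == expected
    assert counts.n_codons == n


def test_count_codons_rejects_partial_frame():
    with pytest.raises(ValueError):
        count_codons(make_cds("ATGA"))


def test_round_trip_codon_total(code11, rng):
    codons = [c for c in code11.sense_codons()]
    for _ in range(25):
        m = int(rng.integers(1, 200))
        body = "".join(rng.choice(codons, size=m))
        seq = make_cds("ATG" + body + "TAA")
        counts = count_codons(strip_terminal_stop(seq, code11))
        assert counts.n_codons == seq.length_nt // 3 - 1


def test_counts_equal_naive_slicing_tally(code11, rng):
    """1,000 random synthetic CDSs against a naive string-slicing oracle."""
    codons = np.array(code11.sense_codons())
    for _ in range(1000):
        m = int(rng.integers(2, 60))
        s = "".join(rng.choice(codons, size=m))
        naive = {}
        for i in range(0, len(s), 3):
            naive[s[i:i + 3]] = naive.get(s[i:i + 3], 0) + 1
        assert count_codons(make_cds(s)).counts == naive


# --------------------------------------------------------------------------
# concatenation
# --------------------------------------------------------------------------

def test_concatenate_examples():
    a = CodonCounts(counts={"AAA": 2})
    b = CodonCounts(counts={"AAA": 1, "GCC": 4})
    out = concatenate_counts([a, b], label="grp")
    assert out.counts == {"AAA": 3, "GCC": 4}
    assert out.n_codons == 7
    single = concatenate_counts([b], label="solo")
    assert single.counts == b.counts and single.labels == "solo"
    with pytest.raises(ValueError):
        concatenate_counts([], label="none")


def test_concatenate_matches_retally_of_concatenated_sequence(code11, rng):
    codons = np.array(code11.sense_codons())
    seqs = [make_cds("".join(rng.choice(codons, size=40)), gene=f"g{i}")
            for i in range(50)]
    summed = concatenate_counts([count_codons(s) for s in seqs], label="fam")
    retally = count_codons(make_cds("".join(s.seq for s in seqs)))
    assert summed.counts == retally.counts
    assert summed.n_codons == sum(count_codons(s).n_codons for s in seqs)


@given(st.permutations(list(range(4))))
@settings(deadline=None, max_examples=24, derandomize=True)
def test_concatenate_order_invariant_and_associative(perm):
    tables = [CodonCounts(counts={"AAA": i + 1, "GGG": 2 * i}) for i in range(4)]
    reference = concatenate_counts(tables, label="x").counts
    shuffled = [tables[i] for i in perm]
    assert concatenate_counts(shuffled, label="x").counts == reference
    left = concatenate_counts(
        [concatenate_counts(shuffled[:2], "a"), *shuffled[2:]], "x")
    assert left.counts == reference
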