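"""GenBank flat-file reader: field extraction, error recovery, RefSeq policy.

The generated corpus is written through Biopython's GenBank writer while
the package's reader is an independent scanner, so round-trip agreement
(including a direct cross-check against Bio.SeqIO) is a genuine
dual-route test.
"""

import io

from Bio import SeqIO
from Bio.Seq import Seq

from cladehouse import GenBankReport, parse_genbank
from cladehouse.genbank import reverse_complement

MINIMAL_ENTRY = """\
LOCUS       NC_000001                 60 bp    DNA     linear   SYN 01-JAN-2020
DEFINITION  minimal fixture record.
VERSION     NC_000001.1
FEATURES             Location/Qualifiers
     source          1..60
                     /organism="Testus minimus"
                     /db_xref="taxon:1234"
                     /chromosome="1"
     CDS             join(10..20,30..40)
                     /gene="tst"
                     /locus_tag="TST_001"
                     /protein_id="NP_000001.1"
                     /product="test protein"
                     /translation="MKVLAAG"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""

NO_CDS_ENTRY = """\
LOCUS       NC_000002                 30 bp    DNA     linear   SYN 01-JAN-2020
DEFINITION  record without coding features.
VERSION     NC_000002.1
FEATURES             Location/Qualifiers
     source          1..30
                     /db_xref="taxon:1234"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac
//
"""


def test_minimal_entry_field_extraction():
    report = GenBankReport()
    (rec,) = parse_genbank(io.StringIO(MINIMAL_ENTRY), report)
    assert rec.accession == "NC_000001.1"
    assert rec.taxid == 1234
    assert rec.sequence_length == 60
    assert rec.molecule_label == "chromosome 1"
    assert rec.definition == "minimal fixture record."
    (cds,) = rec.cds_features
    assert cds.location.segments == ((10, 20), (30, 40))
    assert cds.refseq_protein_ac == "NP_000001.1"
    assert cds.gene_name == "tst"
    assert cds.locus_tag == "TST_001"
    assert cds.translation == "MKVLAAG"
    assert report.records_parsed == 1 and report.records_rejected == 0


def test_cds_sequence_is_spliced_from_origin():
    (rec,) = parse_genbank(io.StringIO(MINIMAL_ENTRY))
    (cds,) = rec.cds_features
    origin = "ACGT" * 15
    expected = origin[9:20] + origin[29:40]
    assert cds.nt_sequence == expected


def test_entry_without_cds_yields_empty_feature_list():
    (rec,) = parse_genbank(io.StringIO(NO_CDS_ENTRY))
    assert rec.cds_features == []


def test_missing_version_is_record_error_parser_continues():
    broken = MINIMAL_ENTRY.replace("VERSION     NC_000001.1\n", "")
    report = GenBankReport()
    records = list(parse_genbank(io.StringIO(broken + NO_CDS_ENTRY), report))
    assert [r.accession for r in records] == ["NC_000002.1"]
    assert report.records_rejected == 1
    assert report.records_seen == 2


def test_non_refseq_accession_rejected_with_warning():
    entry = MINIMAL_ENTRY.replace("NC_000001", "AB123456")
    report = GenBankReport()
    assert list(parse_genbank(io.StringIO(entry), report)) == []
    assert report.non_refseq_rejected == 1


def test_bad_cds_location_drops_feature_keeps_record():
    entry = MINIMAL_ENTRY.replace("join(10..20,30..40)", "join(20..10,30..40)")
    report = GenBankReport()
    (rec,) = parse_genbank(io.StringIO(entry), report)
    assert rec.cds_features == []
    assert report.location_errors == 1


def test_external_reference_location_counted_separately():
    entry = MINIMAL_ENTRY.replace(
        "join(10..20,30..40)", "join(NC_000009.1:10..20,30..40)"
    )
    report = GenBankReport()
    (rec,) = parse_genbank(io.StringIO(entry), report)
    assert rec.cds_features == []
    assert report.external_location_warnings == 1
    assert report.location_errors == 0


def test_parser_is_streaming():
    """The first record must be available before later lines are consumed."""
    lines = (MINIMAL_ENTRY + NO_CDS_ENTRY).splitlines(keepends=True)
    consumed = 0

    def counting_stream():
        nonlocal consumed
        for line in lines:
            consumed += 1
            yield line

    gen = parse_genbank(counting_stream())
    first = next(gen)
    assert first.accession == "NC_000001.1"
    assert consumed < len(lines)
    assert next(gen).accession == "NC_000002.1"


def test_corpus_totals_match_manifest(corpus):
    corpus_dir, manifest = corpus
    report = GenBankReport()
    with open(corpus_dir / "genomes.gbff") as handle:
        records = list(parse_genbank(handle, report))
    assert report.records_parsed == len(manifest.genomes)
    assert sum(len(r.cds_features) for r in records) == len(manifest.cds)
    by_ac = {g["accession"]: g for g in manifest.genomes}
    for rec in records:
        expected = by_ac[rec.accession]
        assert rec.taxid == expected["taxid"]
        assert rec.sequence_length == expected["length"]
        assert len(rec.cds_features) == expected["n_cds"]


def test_reader_agrees_with_biopython_oracle(corpus):
    """Independent cross-check: our scanner vs Bio.SeqIO on the same file."""
    corpus_dir, _ = corpus
    with open(corpus_dir / "genomes.gbff") as handle:
        ours = {r.accession: r for r in parse_genbank(handle)}
    for ref in SeqIO.parse(str(corpus_dir / "genomes.gbff"), "genbank"):
        accession = ref.id
        mine = ours[accession]
        assert mine.sequence_length == len(ref.seq)
        ref_cds = [f for f in ref.features if f.type == "CDS"]
        assert len(mine.cds_features) == len(ref_cds)
        for mine_cds, ref_feat in zip(mine.cds_features, ref_cds):
            assert mine_cds.translation == ref_feat.qualifiers["translation"][0]
            extracted = str(ref_feat.extract(ref.seq))
            assert mine_cds.nt_sequence == extracted


def test_translations_are_genuine_codon_translations(corpus):
    corpus_dir, _ = corpus
    with open(corpus_dir / "genomes.gbff") as handle:
        for rec in parse_genbank(handle):
            for cds in rec.cds_features:
                aa = str(Seq(cds.nt_sequence).translate())
                assert aa == cds.translation + "*"
                assert len(cds.translation) * 3 <= cds.location.total_length + 3


def test_reverse_complement_helper():
    assert reverse_complement("ACGTT") == "AACGT"
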